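import numpy as np
import pytest

from acmap import widefield as wf


class TestPreprocessMovie:
    def test_constant_movie_zero_dff(self):
        movie = np.full((300, 4, 4), 500.0)
        dff, valid = wf.preprocess_movie(movie)
        assert valid.all()
        np.testing.assert_allclose(dff, 0.0, atol=1e-9)

    def test_cubic_drift_absorbed(self):
        t = np.linspace(0, 1, 600)
        drift = 1000 + 50 * t + 30 * t**2 - 20 * t**3
        movie = np.tile(drift[:, None, None], (1, 3, 3))
        dff, _ = wf.preprocess_movie(movie)
        assert np.abs(dff).max() < 0.5  # percent

    def test_step_recovered(self):
        movie = np.full((600, 2, 2), 1000.0)
        movie[300:310] *= 1.10  # +10% for 1 s
        dff, _ = wf.preprocess_movie(movie)
        # part of the step is absorbed by the 15 s baseline fit; the peak
        # stays close to the planted 10%
        assert dff[300:310, 0, 0].max() == pytest.approx(10.0, rel=0.25)
        # oracle: direct per-frame cubic fit over the centered window
        trace = movie[:, 0, 0]
        for t in (295, 300, 305, 315):
            lo, hi = t - 75, t + 76
            coef = np.polyfit(np.arange(lo, hi), trace[lo:hi], 3)
            f0 = np.polyval(coef, t)
            expected = (trace[t] - f0) / f0 * 100.0
            assert dff[t, 0, 0] == pytest.approx(expected, abs=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        movie = 1000 + 20 * rng.normal(size=(400, 3, 3)).cumsum(axis=0) * 0.01
        dff1, _ = wf.preprocess_movie(movie)
        dff2, _ = wf.preprocess_movie(movie * 7.3)
        np.testing.assert_allclose(dff1, dff2, atol=1e-9)

    def test_nonpositive_baseline_flagged(self):
        movie = np.full((300, 2, 2), 100.0)
        movie[:, 0, 0] = 0.0
        dff, valid = wf.preprocess_movie(movie)
        assert not valid[0, 0]
        assert valid[1, 1]
        assert np.isnan(dff[:, 0, 0]).all()

    def test_too_short_movie(self):
        with pytest.raises(ValueError, match="short"):
            wf.preprocess_movie(np.ones((100, 2, 2)))


class TestEvokedAmplitude:
    def _trace(self, n=200, base=0.0, sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        return base + sd * rng.normal(size=(n, 1))

    def test_flat_post_not_evoked(self):
        trace = self._trace()
        amps, evoked = wf.evoked_amplitude(trace, [100])
        assert not evoked[0, 0]

    def test_spike_amplitude_hand_computed(self):
        # constant baseline of alternating +-1 (sd 1), spike of 10 at
        # onset+2 flanked by baseline-level frames
        trace = np.tile([1.0, -1.0], 100).astype(float)[:, None]
        onset = 100
        trace[onset + 2, 0] += 10.0
        amps, evoked = wf.evoked_amplitude(trace, [onset], frame_rate=10.0)
        base = trace[onset - 20 : onset, 0]
        mu, sd = base.mean(), base.std()
        window = trace[onset - 1 : onset + 9, 0]
        three = [
            (trace[k - 1, 0] + trace[k, 0] + trace[k + 1, 0]) / 3
            for k in range(onset, onset + 7)
        ]
        expected = max(three) - mu
        assert amps[0, 0] == pytest.approx(expected)
        assert evoked[0, 0] == ((max(three) - mu) / sd > 2)
        assert evoked[0, 0]

    def test_z_exactly_two_not_evoked(self):
        trace = np.tile([1.0, -1.0], 150).astype(float)[:, None]
        onset = 100
        base = trace[onset - 20 : onset, 0]
        mu, sd = base.mean(), base.std()
        # build three consecutive frames whose mean sits exactly at mu + 2 sd
        target = mu + 2.0 * sd
        trace[onset + 1 : onset + 4, 0] = target
        # flatten the rest of the window below the target
        trace[onset + 4 : onset + 9, 0] = mu
        amps, evoked = wf.evoked_amplitude(trace, [onset], frame_rate=10.0)
        assert amps[0, 0] <= 2.0 * sd + 1e-12
        assert not evoked[0, 0]  # strict >

    def test_zero_sd_skipped(self):
        trace = np.zeros((200, 1))
        trace[105] = 5.0
        with pytest.warns(RuntimeWarning, match="zero baseline sd"):
            amps, evoked = wf.evoked_amplitude(trace, [100])
        assert np.isnan(amps[0, 0])
        assert not evoked[0, 0]

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            wf.evoked_amplitude(np.zeros((50, 1)), [5])


class TestPixelBf:
    def test_three_of_sixteen_not_responsive(self, rng):
        amps = np.abs(rng.normal(size=(5, 16, 2, 2)))
        evoked = np.zeros((5, 16, 2, 2), dtype=bool)
        evoked[:, :3] = True  # every tone: only 3 evoked reps
        bfm = wf.pixel_bf(amps, evoked, np.array([4.0, 8.0, 16.0, 32.0, 64.0]))
        assert not bfm.responsive.any()
        assert np.isnan(bfm.bf_khz).all()

    def test_single_strong_tone_wins(self, rng):
        freqs = np.array([4.0, 8.0, 16.0, 32.0, 64.0])
        amps = np.zeros((5, 16, 1, 1))
        evoked = np.zeros((5, 16, 1, 1), dtype=bool)
        amps[2] = 3.0
        evoked[2] = True
        bfm = wf.pixel_bf(amps, evoked, freqs)
        assert bfm.bf_khz[0, 0] == 16.0

    def test_tie_breaks_to_lower_frequency(self):
        freqs = np.array([4.0, 8.0, 16.0, 32.0, 64.0])
        amps = np.zeros((5, 16, 1, 1))
        evoked = np.zeros((5, 16, 1, 1), dtype=bool)
        for t in (1, 3):
            amps[t] = 2.0
            evoked[t, :8] = True
        bfm = wf.pixel_bf(amps, evoked, freqs)
        assert bfm.bf_khz[0, 0] == 8.0

    def test_matches_bruteforce_on_random_stacks(self, rng):
        freqs = np.array([4.0, 8.0, 16.0, 32.0, 64.0])
        for _ in range(5):
            amps = rng.normal(1.0, 0.5, size=(5, 16, 16, 16))
            evoked = rng.uniform(size=(5, 16, 16, 16)) < 0.4
            bfm = wf.pixel_bf(amps, evoked, freqs)
            for y in range(16):
                for x in range(16):
                    best_amp, best_f = -np.inf, np.nan
                    for t in range(5):
                        sel = evoked[t, :, y, x]
                        if sel.sum() < 4:
                            continue
                        m = amps[t, sel, y, x].mean()
                        if m > best_amp:
                            best_amp, best_f = m, freqs[t]
                    if np.isnan(best_f):
                        assert not bfm.responsive[y, x]
                    else:
                        assert bfm.bf_khz[y, x] == best_f
                        assert bfm.amplitude[y, x] == pytest.approx(best_amp)


def _make_map(bf, responsive, fov="a"):
    amp = np.where(responsive, 1.0, np.nan)
    return wf.PixelBFMap(
        bf_khz=np.where(responsive, bf, np.nan),
        amplitude=amp,
        responsive=responsive,
        fov_id=fov,
    )


class TestMergeFovMaps:
    def test_single_map_normalized(self):
        resp = np.zeros((8, 8), dtype=bool)
        resp[2:6, 2:6] = True
        amp = np.where(resp, 4.0, np.nan)
        amp[3, 3] = 8.0
        m = wf.PixelBFMap(
            bf_khz=np.where(resp, 8.0, np.nan), amplitude=amp, responsive=resp
        )
        merged = wf.merge_fov_maps([m])
        assert np.nanmax(merged.amplitude) == pytest.approx(1.0)
        assert merged.amplitude[3, 3] == pytest.approx(1.0)
        assert merged.amplitude[2, 2] == pytest.approx(0.5)

    def test_overlap_higher_normalized_wins(self):
        resp = np.ones((4, 4), dtype=bool)
        a = _make_map(np.full((4, 4), 8.0), resp)
        a.amplitude[:] = 0.9
        b = _make_map(np.full((4, 4), 32.0), resp, fov="b")
        b.amplitude[:] = 0.4
        a.amplitude[0, 0] = 1.0  # normalization anchors
        b.amplitude[0, 0] = 1.0
        merged = wf.merge_fov_maps([a, b])
        assert merged.bf_khz[2, 2] == 8.0

    def test_disjoint_union(self):
        r1 = np.zeros((6, 6), dtype=bool)
        r1[:3] = True
        r2 = np.zeros((6, 6), dtype=bool)
        r2[3:] = True
        m1 = _make_map(np.full((6, 6), 8.0), r1)
        m2 = _make_map(np.full((6, 6), 32.0), r2, fov="b")
        merged = wf.merge_fov_maps([m1, m2])
        assert (merged.bf_khz[:3] == 8.0).all()
        assert (merged.bf_khz[3:] == 32.0).all()
        assert merged.responsive.all()

    def test_unregistered_rejected(self):
        m1 = _make_map(np.full((6, 6), 8.0), np.ones((6, 6), dtype=bool))
        m2 = _make_map(np.full((8, 8), 8.0), np.ones((8, 8), dtype=bool), "b")
        with pytest.raises(ValueError, match="registered"):
            wf.merge_fov_maps([m1, m2])


def _radial_map(size=128, crest=40.0, extent=52.0, hub=None):
    """Radial BF field rising to a crest then falling; silent margin."""
    hub = hub or (size / 2.0, size / 2.0)
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(xx - hub[0], yy - hub[1])
    oct_field = np.where(
        r <= crest, 4.0 * r / crest, np.maximum(4.0 - (r - crest) / 4.0, 1.0)
    )
    responsive = r <= extent
    bf = np.where(responsive, 4.0 * 2.0**oct_field, np.nan)
    amp = np.where(responsive, 1.0, np.nan)
    return (
        wf.PixelBFMap(bf_khz=bf, amplitude=amp, responsive=responsive),
        hub,
        crest,
        extent,
    )


class TestReversalsAndBoundary:
    def test_reversal_near_planted_crest(self):
        bfm, hub, crest, _ = _radial_map()
        res = wf.find_reversals_and_boundary(bfm, [hub], n_angles=72)
        err = np.abs(res.reversal_radii[0] - crest)
        assert np.isfinite(err).mean() > 0.9
        assert (err[np.isfinite(err)] <= 5.0).mean() >= 0.9

    def test_monotone_profile_no_reversal(self):
        size = 128
        yy, xx = np.mgrid[0:size, 0:size]
        hub = (64.0, 64.0)
        r = np.hypot(xx - hub[0], yy - hub[1])
        responsive = r <= 52
        bf = np.where(responsive, 4.0 * 2.0 ** np.clip(r / 13.0, 0, 4), np.nan)
        bfm = wf.PixelBFMap(
            bf_khz=bf, amplitude=np.where(responsive, 1.0, np.nan),
            responsive=responsive,
        )
        res = wf.find_reversals_and_boundary(bfm, [hub], n_angles=36)
        assert np.isnan(res.reversal_radii).all()

    def test_boundary_inside_planted_margin(self):
        bfm, hub, _, extent = _radial_map()
        res = wf.find_reversals_and_boundary(bfm, [hub], n_angles=72)
        br = res.boundary_radii[0]
        assert np.isfinite(br).all()
        margin = 64.0 - extent  # 12 px silent ring before frame edge
        assert margin >= 12 - 1e-9 or margin >= 10
        assert np.all(br >= extent - 1.0)
        assert np.all(br <= extent + margin + 1.0)

    def test_hub_outside_frame(self):
        bfm, _, _, _ = _radial_map()
        with pytest.raises(ValueError, match="outside"):
            wf.find_reversals_and_boundary(bfm, [(500.0, 500.0)])

    def test_no_hub(self):
        bfm, _, _, _ = _radial_map()
        with pytest.raises(ValueError, match="hub"):
            wf.find_reversals_and_boundary(bfm, [])

    def test_smooth_mode_agrees_roughly(self):
        bfm, hub, crest, _ = _radial_map()
        res = wf.find_reversals_and_boundary(
            bfm, [hub], n_angles=36, fit_mode="smooth"
        )
        err = np.abs(res.reversal_radii[0] - crest)
        assert np.nanmedian(err) <= 6.0


class TestDetectHubs:
    def test_finds_planted_hub(self):
        bfm, hub, _, _ = _radial_map()
        hubs = wf.detect_hubs(bfm)
        assert len(hubs) >= 1
        d = min(np.hypot(h[0] - hub[0], h[1] - hub[1]) for h in hubs)
        assert d <= 10.0


class TestParcellate:
    def test_import_rectangles_exact(self):
        bfm, hub, _, _ = _radial_map(size=64, crest=20, extent=26)
        sq1 = [(5.0, 5.0), (25.0, 5.0), (25.0, 25.0), (5.0, 25.0), (5.0, 5.0)]
        sq2 = [(35.0, 35.0), (55.0, 35.0), (55.0, 55.0), (35.0, 55.0),
               (35.0, 35.0)]
        res = wf.ParcellationResult(
            hubs=[hub], angles_deg=np.array([]),
            reversal_radii=np.empty((1, 0)), reversal_points=np.empty((1, 0, 2)),
            boundary_radii=np.empty((1, 0)), boundary_points=np.empty((1, 0, 2)),
        )
        out = wf.parcellate(bfm, res, mode="import",
                            borders={"A1": sq1, "A2": sq2})
        assert out.label_map[10, 10] == "A1"
        assert out.label_map[40, 40] == "A2"
        assert out.label_map[30, 30] == "none"

    def test_open_border_rejected(self):
        bfm, hub, _, _ = _radial_map(size=64, crest=20, extent=26)
        res = wf.ParcellationResult(
            hubs=[hub], angles_deg=np.array([]),
            reversal_radii=np.empty((1, 0)), reversal_points=np.empty((1, 0, 2)),
            boundary_radii=np.empty((1, 0)), boundary_points=np.empty((1, 0, 2)),
        )
        with pytest.raises(ValueError, match="open"):
            wf.parcellate(
                bfm, res, mode="import",
                borders={"A1": [(0.0, 0.0), (5.0, 0.0), (5.0, 5.0)]},
            )

    def test_auto_labels_relative_to_hub(self):
        bfm, hub, crest, _ = _radial_map()
        res = wf.find_reversals_and_boundary(bfm, [hub], n_angles=72)
        out = wf.parcellate(bfm, res, mode="auto")
        inside = out.label_map[int(hub[1]), int(hub[0])]
        assert inside == "A1"
        labels = set(np.unique(out.label_map.astype(str)))
        assert {"A1", "AAF", "A2"} <= labels

    def test_auto_no_reversals_unassigned(self):
        bfm, hub, _, _ = _radial_map()
        res = wf.ParcellationResult(
            hubs=[hub], angles_deg=np.zeros(4),
            reversal_radii=np.full((1, 4), np.nan),
            reversal_points=np.full((1, 4, 2), np.nan),
            boundary_radii=np.full((1, 4), np.nan),
            boundary_points=np.full((1, 4, 2), np.nan),
        )
        out = wf.parcellate(bfm, res, mode="auto")
        assert (out.label_map[bfm.responsive] == "unassigned").all()

    def test_unknown_mode(self):
        bfm, hub, _, _ = _radial_map()
        res = wf.ParcellationResult(
            hubs=[hub], angles_deg=np.array([]),
            reversal_radii=np.empty((1, 0)), reversal_points=np.empty((1, 0, 2)),
            boundary_radii=np.empty((1, 0)), boundary_points=np.empty((1, 0, 2)),
        )
        with pytest.raises(ValueError, match="mode"):
            wf.parcellate(bfm, res, mode="magic")
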
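"""Group-comparison decision rule and reporting.

Each comparison first tests both groups for normality; normal pairs get
a two-tailed t test (paired or unpaired), anything else a Wilcoxon
signed rank or Mann-Whitney U test.  No multiple-testing correction is
applied anywhere in this package.  The pooling unit (neuron, FOV,
animal) is always the caller's explicit choice; nothing is pooled
implicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.diagnostic import lilliefors

NORMALITY_ALPHA = 0.05


@dataclass
class ComparisonResult:
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    normal_p_a: float
    normal_p_b: float
    test_name: str
    statistic: float
    p_value: float
    stars: str

    def summary(self) -> str:
        return (
            f"{self.mean_a:.3g} ± {self.sem_a:.3g} (n={self.n_a}) vs "
            f"{self.mean_b:.3g} ± {self.sem_b:.3g} (n={self.n_b}), "
            f"{self.test_name}, p = {self.p_value:.3g} {self.stars}"
        )

    def to_json(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def star_code(p: float) -> str:
    """Significance stars at 0.05 / 0.01 / 0.001."""
    if not np.isfinite(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def normality_p(x: np.ndarray, method: str = "lilliefors") -> float:
    """Normality p-value (KS-type test).

    Default is the Lilliefors correction for estimated mean/sd; the
    naive KS test against the fitted normal is selectable.
    """
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0:
        return 0.0  # constant data: not normal
    if method == "lilliefors":
        _, p = lilliefors(x, dist="norm")
        return float(p)
    if method == "ks":
        _, p = sstats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        return float(p)
    raise ValueError(f"unknown normality method {method!r}")


def compare_groups(
    a,
    b,
    paired: bool = False,
    normality_alpha: float = NORMALITY_ALPHA,
    normality_method: str = "lilliefors",
) -> ComparisonResult:
    """Compare two samples with the parametric-or-not decision rule.

    Both groups pass normality -> two-tailed t test (paired or
    unpaired); otherwise Wilcoxon signed rank (paired) or Mann-Whitney U
    (unpaired).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")
    if paired and a.size != b.size:
        raise ValueError("paired comparison needs equal-length groups")
    p_a = normality_p(a, normality_method)
    p_b = normality_p(b, normality_method)
    normal = p_a >= normality_alpha and p_b >= normality_alpha
    if paired and np.all(a == b):
        warnings.warn(
            "paired groups are identical; p reported as 1",
            RuntimeWarning,
            stacklevel=2,
        )
        test_name, stat, p = ("paired t" if normal else "Wilcoxon signed rank"), 0.0, 1.0
    elif normal:
        if paired:
            stat, p = sstats.ttest_rel(a, b)
            test_name = "paired t"
        else:
            stat, p = sstats.ttest_ind(a, b)
            test_name = "unpaired t"
    else:
        if paired:
            stat, p = sstats.wilcoxon(a, b)
            test_name = "Wilcoxon signed rank"
        else:
            stat, p = sstats.mannwhitneyu(a, b, alternative="two-sided")
            test_name = "Mann-Whitney U"
    return ComparisonResult(
        mean_a=float(a.mean()),
        sem_a=float(sstats.sem(a)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sem_b=float(sstats.sem(b)),
        n_b=int(b.size),
        normal_p_a=p_a,
        normal_p_b=p_b,
        test_name=test_name,
        statistic=float(stat),
        p_value=float(p),
        stars=star_code(float(p)),
    )
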
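"""Agreement statistics for test-retest designs.

Implements the statistical core of the drawing-reproducibility analysis:

* ICC(3,1) — the two-way mixed-model, single-measure, *consistency*
  intraclass correlation of the Shrout–Fleiss classification, with its
  standard F-based confidence interval.  With subjects as rows and the
  two drawing sessions as columns, ICC(3,1) quantifies how much of the
  measurement variance is between patients rather than between sessions.
* Bland–Altman limits of agreement (absolute and percent-of-mean).
* Two-sample t tests computed from printed summary statistics
  (mean, SD, n), pooled-variance Student or Welch.
* Pearson chi-square on contingency tables (no continuity correction).
* ICC sample-size planning from the expected confidence-interval width
  of Giraudeau & Mary: for a planning ICC ``rho`` measured over ``k``
  sessions, the expected full width of the 100(1-alpha)% CI at ``n``
  subjects is

      w(n) = 2 z * (1 - rho) * (1 + (k-1) rho) * sqrt(2 / (k (k-1) n))

  and the planner returns the smallest ``n`` with ``w(n) <= width``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementResult",
    "BlandAltmanResult",
    "SummaryTTest",
    "ChiSquareResult",
    "SampleSizeQuery",
    "anova_two_way",
    "icc31",
    "bland_altman",
    "plot_bland_altman",
    "t_test_from_summary",
    "chi_square_counts",
    "expected_ci_width",
    "icc_sample_size",
    "format_p",
]


# ---------------------------------------------------------------------------
# ICC(3,1)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementResult:
    """ICC(3,1) point estimate with 95% (or 1-alpha) CI and the mean
    squares of the underlying subjects-by-sessions ANOVA."""

    icc: float
    ci_low: float
    ci_high: float
    msr: float  # between-subject mean square
    mse: float  # residual mean square
    n: int
    k: int


def _as_ratings(m) -> np.ndarray:
    x = np.asarray(m, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects-by-sessions matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 sessions, got {n}x{k}")
    if not np.isfinite(x).all():
        raise ValueError("ratings matrix contains missing or non-finite cells")
    return x


def anova_two_way(m) -> tuple[float, float, float]:
    """Mean squares (MSR, MSC, MSE) of the two-way subjects x sessions ANOVA."""
    x = _as_ratings(m)
    n, k = x.shape
    grand = x.mean()
    ssr = k * float(((x.mean(axis=1) - grand) ** 2).sum())
    ssc = n * float(((x.mean(axis=0) - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc31(m, alpha: float = 0.05) -> AgreementResult:
    """ICC(3,1) with the Shrout–Fleiss F-based confidence interval.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE).  The CI maps the F-quantile
    bounds of F = MSR/MSE through g(F) = (F-1)/(F+k-1).

    Raises ``ValueError`` on a constant matrix (no variance at all — the
    correlation is undefined) or on missing cells.
    """
    x = _as_ratings(m)
    n, k = x.shape
    if np.ptp(x) == 0:
        raise ValueError("constant ratings matrix: ICC undefined (zero total variance)")
    msr, _, mse = anova_two_way(x)
    dfr, dfe = n - 1, (n - 1) * (k - 1)
    if mse == 0.0:
        # perfect within-subject consistency
        return AgreementResult(1.0, 1.0, 1.0, msr, 0.0, n, k)
    icc = (msr - mse) / (msr + (k - 1) * mse)
    f_obs = msr / mse
    fq_u = stats.f.ppf(1 - alpha / 2, dfr, dfe)
    fq_l = stats.f.ppf(1 - alpha / 2, dfe, dfr)
    fl = f_obs / fq_u
    fu = f_obs * fq_l
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return AgreementResult(float(icc), float(ci_low), float(ci_high), float(msr), float(mse), n, k)


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    mode: str  # "absolute" | "percent_of_mean"


def _ba_arrays(pairs, mode: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (x1, x2) pairs")
    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]
    if mode == "percent_of_mean":
        if (means == 0).any():
            raise ValueError("percent mode undefined for a pair with zero mean")
        diffs = 100.0 * diffs / means
    elif mode != "absolute":
        raise ValueError(f"unknown mode {mode!r}")
    return means, diffs


def bland_altman(pairs, mode: str = "absolute") -> BlandAltmanResult:
    """Mean difference, SD of differences and 95% limits of agreement.

    Differences are ``x1 - x2`` (or 100*(x1-x2)/mean in percent mode);
    the limits use the conventional 1.96 multiplier on the sample SD.
    """
    _, diffs = _ba_arrays(pairs, mode)
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        mode=mode,
    )


def plot_bland_altman(pairs, path, mode: str = "absolute", title: str | None = None) -> BlandAltmanResult:
    """Write a Bland–Altman scatter (mean-difference line, dotted LoA) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means, diffs = _ba_arrays(pairs, mode)
    res = bland_altman(pairs, mode)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(means, diffs, s=24, color="tab:blue", zorder=3)
    ax.axhline(res.mean_diff, color="black", lw=2)
    ax.axhline(res.loa_low, color="black", lw=1, ls=":")
    ax.axhline(res.loa_high, color="black", lw=1, ls=":")
    ax.set_xlabel("mean of test and retest")
    ax.set_ylabel("difference (%. of mean)" if mode == "percent_of_mean" else "difference (test - retest)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return res


# ---------------------------------------------------------------------------
# Summary-statistics t tests and chi-square
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SummaryTTest:
    t: float
    df: float
    p: float
    variant: str  # "pooled" | "welch"
    inputs: tuple[float, float, int, float, float, int]


def t_test_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int, variant: str = "pooled"
) -> SummaryTTest:
    """Two-tailed two-sample t test from group means, SDs and sizes."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise ValueError("SDs must be non-negative and not both zero")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return SummaryTTest(float(t), float(df), float(p), variant, (m1, s1, n1, m2, s2, n2))


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def chi_square_counts(table) -> ChiSquareResult:
    """Pearson chi-square on an r x c count table, without continuity
    correction; all-zero rows/columns are dropped first."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2-D non-negative integer counts")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least 2 non-empty rows and columns")
    res = stats.chi2_contingency(t, correction=False)
    return ChiSquareResult(float(res.statistic), int(res.dof), float(res.pvalue))


# ---------------------------------------------------------------------------
# ICC sample-size planning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSizeQuery:
    """Planning inputs: anticipated ICC ``rho``, sessions ``k``, target
    full CI ``width`` and two-sided ``alpha``."""

    rho: float
    k: int = 2
    width: float = 0.1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must be in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @property
    def z(self) -> float:
        return float(stats.norm.ppf(1 - self.alpha / 2))


def expected_ci_width(rho: float, k: int, n: int, alpha: float = 0.05) -> float:
    """Expected full width of the ICC confidence interval at n subjects."""
    q = SampleSizeQuery(rho=rho, k=k, alpha=alpha)
    return 2.0 * q.z * (1 - rho) * (1 + (k - 1) * rho) * math.sqrt(2.0 / (k * (k - 1) * n))


def icc_sample_size(q: SampleSizeQuery) -> int:
    """Smallest n >= 2 whose expected CI width does not exceed the target."""
    c = 2.0 * q.z * (1 - q.rho) * (1 + (q.k - 1) * q.rho) * math.sqrt(2.0 / (q.k * (q.k - 1)))
    n = max(2, math.ceil((c / q.width) ** 2))
    # guard the ceil against float rounding at the boundary
    while n > 2 and expected_ci_width(q.rho, q.k, n - 1, q.alpha) <= q.width:
        n -= 1
    while expected_ci_width(q.rho, q.k, n, q.alpha) > q.width:
        n += 1
    return n


def format_p(p: float) -> str:
    """P value in journal style: two decimals, three when p < .01, no
    leading zero (0.0032 -> ".003", 0.837 -> ".84")."""
    if not (0.0 < p <= 1.0):
        raise ValueError("p must be in (0, 1]")
    s = f"{p:.3f}" if p < 0.01 else f"{p:.2f}"
    return s.lstrip("0")
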
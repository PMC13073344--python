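"""Method-comparison statistics: correlation, bias, concordance, BCa bootstrap.

The full agreement ledger for comparing two measurement methods over the
same samples (here: laser diffraction vs image-based morphometry):

* Pearson correlation r (linear association);
* Lin's concordance correlation coefficient r_c, penalizing deviation
  from the identity line: r_c = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with
  population (1/n) moments — Lin's original convention; the 1/(n−1)
  variant differs by O(1/n);
* paired t-test for systematic bias of the mean difference;
* Bland–Altman mean difference d̄ with 95% limits of agreement
  d̄ ± 1.96·SD (sample SD, 1/(n−1)); differences are method A − method B;
* proportional bias: OLS slope of the difference on the pairwise mean,
  declared significant when its BCa bootstrap CI excludes zero (the
  bootstrap CI, not the OLS t-test, is the criterion);
* bias-corrected and accelerated (BCa) bootstrap confidence intervals
  (default 3000 resamples): bias constant z₀ = Φ⁻¹(#{θ*<θ̂}/B),
  acceleration a from jackknife skewness, endpoints taken as order
  statistics of the bootstrap distribution (never extrapolated). Paired
  rows are resampled jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "BootstrapConfig",
    "AgreementResult",
    "BlandAltmanResult",
    "pearson",
    "lin_ccc",
    "bland_altman",
    "proportional_bias",
    "bca_ci",
    "paired_t",
    "two_sample_t",
    "compare_methods",
    "plot_bland_altman",
]


@dataclass
class PairedMeasurements:
    """Two methods' values over the same samples (x = method A, y = method B)."""

    sample_ids: list[str]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.sample_ids) != self.x.size:
            raise ValueError("sample_ids length must match the measurements")
        if self.x.size < 3:
            raise ValueError("paired comparison requires n >= 3")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError("missing values are not allowed")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class BootstrapConfig:
    n_resamples: int = 3000
    method: str = "BCa"
    seed: int | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.n_resamples < 1000:
            warnings.warn(
                "fewer than 1000 resamples: reported CIs may be unstable",
                stacklevel=2,
            )


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa: tuple[float, float]
    means: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)


@dataclass
class AgreementResult:
    """Everything the agreement ledger reports for one metric pair."""

    r: float
    r_ci: tuple[float, float]
    r_p: float
    t_p: float
    mean_diff: float
    sd_diff: float
    loa: tuple[float, float]
    ccc: float
    slope: float
    slope_ci: tuple[float, float]
    proportional_bias: bool


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x, y = _as_xy(x, y)
    if x.size < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def pearson_test(x, y) -> tuple[float, float]:
    """(r, two-sided p) via the classical t transform."""
    x, y = _as_xy(x, y)
    if x.size < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient, 1/n moment convention."""
    x, y = _as_xy(x, y)
    if x.size < 3:
        raise ValueError("CCC requires n >= 3")
    sx2, sy2 = x.var(), y.var()
    dx = x.mean() - y.mean()
    denom = sx2 + sy2 + dx * dx
    if denom == 0:
        raise ValueError("CCC undefined: zero variances and equal means")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * sxy / denom)


def bland_altman(x, y) -> BlandAltmanResult:
    """Mean difference (x − y), sample SD, and 95% limits of agreement."""
    x, y = _as_xy(x, y)
    if x.size < 2:
        raise ValueError("Bland-Altman requires n >= 2")
    d = x - y
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd,
        loa=(mean_diff - 1.96 * sd, mean_diff + 1.96 * sd),
        means=(x + y) / 2.0,
        diffs=d,
    )


def _ols_slope(x, y, axis=None):
    """Slope of y on x; vectorized over leading axes when axis=-1."""
    xm = x.mean(axis=axis, keepdims=axis is not None)
    ym = y.mean(axis=axis, keepdims=axis is not None)
    num = ((x - xm) * (y - ym)).sum(axis=axis)
    den = ((x - xm) ** 2).sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bca_ci(
    statistic,
    data,
    config: BootstrapConfig | None = None,
    vectorized: bool = False,
) -> tuple[float, float]:
    """BCa bootstrap confidence interval of ``statistic`` over ``data``.

    ``data`` is one 1-D array or a tuple of equal-length arrays resampled
    jointly (paired rows). ``statistic(*arrays)`` must return a scalar;
    with ``vectorized=True`` it must accept ``axis=-1`` on stacked
    resamples. Deterministic given ``config.seed``. If every bootstrap
    statistic is identical the interval degenerates to a point and a
    warning is emitted.
    """
    config = config or BootstrapConfig()
    arrays = data if isinstance(data, tuple) else (data,)
    arrays = tuple(np.asarray(a, dtype=float).ravel() for a in arrays)
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("all data arrays must have equal length")
    if n < 3:
        raise ValueError("BCa bootstrap requires n >= 3")
    rng = np.random.default_rng(config.seed)
    theta_hat = float(statistic(*arrays))

    B = config.n_resamples
    idx = rng.integers(0, n, size=(B, n))
    if vectorized:
        thetas = np.asarray(statistic(*(a[idx] for a in arrays), axis=-1), dtype=float)
    else:
        thetas = np.array(
            [float(statistic(*(a[row] for a in arrays))) for row in idx]
        )
    finite = np.isfinite(thetas)
    if not finite.all():
        # resamples where the statistic is undefined (e.g. a degenerate
        # regressor drawn by chance) are dropped from the distribution
        thetas = thetas[finite]
        B = thetas.size
    if B == 0 or np.all(thetas == thetas[0]):
        warnings.warn("degenerate bootstrap: all resampled statistics identical",
                      stacklevel=2)
        return theta_hat, theta_hat

    # bias constant
    prop = np.count_nonzero(thetas < theta_hat) / B
    prop = min(max(prop, 1.0 / (B + 1)), B / (B + 1.0))
    z0 = stats.norm.ppf(prop)

    # acceleration from jackknife skewness
    jack_idx = np.arange(n)
    if vectorized:
        loo = np.stack([np.delete(jack_idx, i) for i in range(n)])
        jack = np.asarray(statistic(*(a[loo] for a in arrays), axis=-1), dtype=float)
    else:
        jack = np.array(
            [
                float(statistic(*(np.delete(a, i) for a in arrays)))
                for i in range(n)
            ]
        )
    dev = jack.mean() - jack
    s2 = np.sum(dev**2)
    a = 0.0 if s2 == 0 else np.sum(dev**3) / (6.0 * s2**1.5)

    z = stats.norm.ppf([config.alpha / 2.0, 1.0 - config.alpha / 2.0])
    adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
    q = np.clip(stats.norm.cdf(adj), 0.0, 1.0)
    lo, hi = np.quantile(thetas, q, method="inverted_cdf")
    return float(lo), float(hi)


def proportional_bias(
    x, y, config: BootstrapConfig | None = None
) -> tuple[float, tuple[float, float]]:
    """OLS slope of (x − y) on (x + y)/2 with a BCa CI of the slope."""
    config = config or BootstrapConfig()
    x, y = _as_xy(x, y)
    if x.size < 3:
        raise ValueError("proportional-bias regression requires n >= 3")
    m = (x + y) / 2.0
    if m.std() == 0:
        raise ValueError("degenerate regressor: paired means have zero spread")

    def slope_stat(xs, ys, axis=None):
        return _ols_slope((xs + ys) / 2.0, xs - ys, axis=axis)

    slope = float(slope_stat(x, y))
    ci = bca_ci(slope_stat, (x, y), config, vectorized=True)
    return slope, ci


def paired_t(x, y) -> tuple[float, float]:
    """Paired t-test of mean(x − y) = 0; (t, two-sided p)."""
    x, y = _as_xy(x, y)
    if x.size < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = x - y
    if d.std(ddof=1) == 0:
        raise ValueError("zero variance of paired differences: t undefined")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class TwoSampleResult:
    mean_a: float
    mean_b: float
    mean_diff: float
    ci: tuple[float, float]
    t: float
    p: float


def two_sample_t(a, b, config: BootstrapConfig | None = None) -> TwoSampleResult:
    """Dichotomous-covariate contrast: group means, t-test, and a BCa CI
    of the mean difference (groups resampled independently)."""
    config = config or BootstrapConfig()
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b)

    # BCa interval of the difference of group means; rows carry a group
    # indicator so resampling stays joint over (value, group).
    g = np.concatenate([np.zeros(a.size), np.ones(b.size)])
    v = np.concatenate([a, b])

    def diff_stat(vals, groups, axis=None):
        if axis is None:
            return vals[groups == 0].mean() - vals[groups == 1].mean()
        ga = np.where(groups == 0, vals, np.nan)
        gb = np.where(groups == 1, vals, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(ga, axis=axis) - np.nanmean(gb, axis=axis)

    ci = bca_ci(diff_stat, (v, g), config, vectorized=True)
    return TwoSampleResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_diff=float(a.mean() - b.mean()),
        ci=ci,
        t=float(res.statistic),
        p=float(res.pvalue),
    )


def compare_methods(
    paired: PairedMeasurements, config: BootstrapConfig | None = None
) -> AgreementResult:
    """Full agreement ledger for one metric pair."""
    config = config or BootstrapConfig()
    x, y = paired.x, paired.y

    def r_stat(xs, ys, axis=None):
        if axis is None:
            return pearson(xs, ys)
        xm = xs.mean(axis=axis, keepdims=True)
        ym = ys.mean(axis=axis, keepdims=True)
        num = ((xs - xm) * (ys - ym)).sum(axis=axis)
        den = np.sqrt(((xs - xm) ** 2).sum(axis=axis) * ((ys - ym) ** 2).sum(axis=axis))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)

    r, r_p = pearson_test(x, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r_ci = bca_ci(r_stat, (x, y), config, vectorized=True)
    try:
        t_stat, t_p = paired_t(x, y)
    except ValueError:
        t_p = float("nan")  # zero-variance differences (e.g. identical methods)
    ba = bland_altman(x, y)
    slope, slope_ci = proportional_bias(x, y, config)
    return AgreementResult(
        r=r,
        r_ci=r_ci,
        r_p=r_p,
        t_p=t_p,
        mean_diff=ba.mean_diff,
        sd_diff=ba.sd_diff,
        loa=ba.loa,
        ccc=lin_ccc(x, y),
        slope=slope,
        slope_ci=slope_ci,
        proportional_bias=not (slope_ci[0] <= 0.0 <= slope_ci[1]),
    )


def plot_bland_altman(result: BlandAltmanResult, path) -> None:
    """Optional PNG of the Bland–Altman plot (matplotlib, Agg backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=18)
    ax.axhline(result.mean_diff, color="k")
    for lim in result.loa:
        ax.axhline(lim, color="k", linestyle="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (A − B)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
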
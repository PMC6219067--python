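"""Method-comparison and discrimination statistics.

The validation battery used to compare a new measurement method against an
established one on paired data: Pearson correlation, Passing-Bablok
non-parametric regression with rank-based confidence intervals, Bland-Altman
bias and limits of agreement, the duplicate-measurement coefficient of
variation, and empirical ROC analysis with a Youden-index operating point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, ValidationError


@dataclass
class PairedMeasurements:
    """n paired values from two methods measuring the same quantity."""

    x: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValidationError("x and y must be equal-length 1D arrays")
        if len(self.x) < 3:
            raise ValidationError("need at least 3 pairs")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass
class AgreementResult:
    r: float
    pb_slope: float
    pb_intercept: float
    pb_slope_ci: tuple[float, float]
    pb_intercept_ci: tuple[float, float]
    bias: float
    loa_low: float
    loa_high: float
    cv_percent: float
    label: str = ""

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "pb_slope": self.pb_slope,
            "pb_intercept": self.pb_intercept,
            "pb_slope_ci": list(self.pb_slope_ci),
            "pb_intercept_ci": list(self.pb_intercept_ci),
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "cv_percent": self.cv_percent,
            "label": self.label,
        }


@dataclass
class ROCResult:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    direction: str  # "greater": higher scores indicate disease

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
            "direction": self.direction,
        }


def pearson_r(pairs: PairedMeasurements) -> float:
    """Product-moment correlation coefficient."""
    if np.std(pairs.x) == 0 or np.std(pairs.y) == 0:
        raise DomainError("correlation undefined: zero variance")
    return float(stats.pearsonr(pairs.x, pairs.y).statistic)


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(len(x), k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = dy / dx
    s = s[dx != 0]  # ties in x contribute no slope
    return s[s != -1.0]  # slopes of exactly -1 are excluded by the procedure


def passing_bablok(pairs: PairedMeasurements, alpha: float = 0.05):
    """Passing-Bablok regression (1983 procedure).

    The slope is the shifted median of all pairwise slopes S_ij, with ties
    x_i = x_j and slopes of exactly -1 excluded and the offset K = number of
    slopes < -1 compensating for the method's symmetry around -1; the
    intercept is median(y - slope*x).  Confidence bounds come from the
    rank-based normal approximation; intercept bounds use the opposite slope
    bounds.

    Returns ``(slope, intercept, (slope_lo, slope_hi), (intercept_lo, intercept_hi))``.
    """
    x, y = pairs.x, pairs.y
    if np.all(x == x[0]):
        raise DomainError("Passing-Bablok undefined: all x identical")
    s = np.sort(_pairwise_slopes(x, y))
    n_s = len(s)
    if n_s == 0:
        raise DomainError("Passing-Bablok undefined: no valid pairwise slopes")
    k = int(np.sum(s < -1.0))

    def shifted_median(offset: int) -> float:
        # median over s with index shift `offset`, 0-based
        if n_s % 2 == 1:
            idx = (n_s - 1) // 2 + offset
            idx = min(max(idx, 0), n_s - 1)
            return float(s[idx])
        i1 = n_s // 2 - 1 + offset
        i2 = n_s // 2 + offset
        i1 = min(max(i1, 0), n_s - 1)
        i2 = min(max(i2, 0), n_s - 1)
        return float(0.5 * (s[i1] + s[i2]))

    slope = shifted_median(k)
    intercept = float(np.median(y - slope * x))

    n = pairs.n
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    c = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(np.round((n_s - c) / 2.0))
    m2 = n_s - m1 + 1
    lo_idx = min(max(m1 + k - 1, 0), n_s - 1)  # 1-based ranks -> 0-based
    hi_idx = min(max(m2 + k - 1, 0), n_s - 1)
    slope_lo, slope_hi = float(s[lo_idx]), float(s[hi_idx])
    intercept_lo = float(np.median(y - slope_hi * x))
    intercept_hi = float(np.median(y - slope_lo * x))
    return slope, intercept, (slope_lo, slope_hi), (intercept_lo, intercept_hi)


def bland_altman(pairs: PairedMeasurements) -> tuple[float, float, float]:
    """Mean difference (bias) and 95% limits of agreement bias ± 1.96·SD(d).

    Differences are d = x - y; the SD uses the n-1 denominator.
    """
    d = pairs.x - pairs.y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def coefficient_of_variation(pairs: PairedMeasurements, method: str = "rms") -> float:
    """Within-subject CV of duplicate measurements, in percent.

    ``rms`` (default): sqrt(mean(d²)/2) / grand mean * 100 — the
    root-mean-square formulation for test-retest designs.  ``sd``:
    SD(d) / grand mean * 100.
    """
    grand_mean = float(np.mean(np.concatenate([pairs.x, pairs.y])))
    if grand_mean == 0:
        raise DomainError("CV undefined: zero grand mean")
    d = pairs.x - pairs.y
    if method == "rms":
        ws = np.sqrt(np.mean(d**2) / 2.0)
    elif method == "sd":
        ws = np.std(d, ddof=1)
    else:
        raise ValidationError(f"unknown CV method {method!r}")
    return float(ws / abs(grand_mean) * 100.0)


def agreement_report(pairs: PairedMeasurements, cv_method: str = "rms") -> AgreementResult:
    """All method-comparison statistics for one paired variable."""
    slope, intercept, slope_ci, intercept_ci = passing_bablok(pairs)
    bias, lo, hi = bland_altman(pairs)
    return AgreementResult(
        r=pearson_r(pairs),
        pb_slope=slope, pb_intercept=intercept,
        pb_slope_ci=slope_ci, pb_intercept_ci=intercept_ci,
        bias=bias, loa_low=lo, loa_high=hi,
        cv_percent=coefficient_of_variation(pairs, cv_method),
        label=pairs.label,
    )


def roc_analysis(scores, labels, direction: str = "greater") -> ROCResult:
    """Empirical ROC with trapezoidal AUC and a Youden-index operating point.

    ``labels`` are truthy for cases; ``direction="greater"`` means cases are
    expected to score higher (use ``"less"`` for markers that decrease with
    disease).  The trapezoidal AUC over the tie-grouped empirical curve
    equals the Mann-Whitney estimator with ties counted 1/2.  The reported
    threshold maximizes J = sensitivity + specificity - 1; ties in J are
    broken toward higher sensitivity.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1D arrays")
    if labels.all() or not labels.any():
        raise DomainError("ROC undefined: both classes must be present")
    if direction not in ("greater", "less"):
        raise ValidationError("direction must be 'greater' or 'less'")

    signed = scores if direction == "greater" else -scores
    fpr, tpr, thresholds = roc_curve(labels, signed)
    auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)
    k = best[np.argmax(tpr[best])]
    thr = float(thresholds[k])
    if direction == "less":
        thr = -thr
    return ROCResult(
        auc=auc,
        sensitivity=float(tpr[k]),
        specificity=float(1.0 - fpr[k]),
        threshold=thr,
        direction=direction,
    )


def bland_altman_plot(pairs: PairedMeasurements, path) -> None:
    """Save a Bland-Altman plot (bias solid, limits of agreement dashed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bias, lo, hi = bland_altman(pairs)
    mean = (pairs.x + pairs.y) / 2.0
    diff = pairs.x - pairs.y
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=18, alpha=0.8)
    ax.axhline(bias, color="k")
    ax.axhline(lo, color="k", linestyle="--")
    ax.axhline(hi, color="k", linestyle="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (A - B)")
    ax.set_title(pairs.label or "Bland-Altman")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def regression_plot(pairs: PairedMeasurements, path) -> None:
    """Save a scatter with the Passing-Bablok line, its CI band and identity."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    slope, intercept, slope_ci, intercept_ci = passing_bablok(pairs)
    xs = np.linspace(pairs.x.min(), pairs.x.max(), 50)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pairs.x, pairs.y, s=18, alpha=0.8)
    ax.plot(xs, slope * xs + intercept, "b-", label=f"PB: y={slope:.2f}x+{intercept:.2f}")
    ax.plot(xs, slope_ci[0] * xs + intercept_ci[1], "k--", lw=0.8)
    ax.plot(xs, slope_ci[1] * xs + intercept_ci[0], "k--", lw=0.8)
    ax.plot(xs, xs, "r:", label="identity")
    ax.set_xlabel("method A")
    ax.set_ylabel("method B")
    ax.legend(fontsize=8)
    ax.set_title(pairs.label or "Passing-Bablok")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def roc_plot(scores, labels, path, direction: str = "greater") -> None:
    """Save the empirical ROC curve with the Youden operating point marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    res = roc_analysis(scores, labels, direction)
    signed = np.asarray(scores, float) if direction == "greater" else -np.asarray(scores, float)
    fpr, tpr, _ = roc_curve(np.asarray(labels).astype(bool), signed)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, tpr, "-", drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.plot(1 - res.specificity, res.sensitivity, "ro")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {res.auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
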
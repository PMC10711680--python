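"""ROI statistics and method-agreement measures.

Validation against a reference perfusion measurement uses hemispheric or
cortical ROI means, ordinary least-squares regression, Bland-Altman limits
of agreement and Lin's concordance correlation coefficient (agreement with
the 45-degree identity line, combining precision and accuracy).  A
leave-one-out cross-validated T2 cutoff separates CSF-dominated voxels from
tissue before ROI averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AgreementReport", "roi_mean", "asymmetry_ratio", "lin_ccc",
           "bland_altman", "linear_fit", "agreement_report", "t2_threshold_loocv"]


@dataclass
class AgreementReport:
    """Regression + agreement summary for paired measurements."""

    slope: float
    intercept: float
    r_squared: float
    ba_mean: float
    ba_limits: tuple
    ccc: float
    ccc_ci: tuple
    n: int

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared, "ba_mean": self.ba_mean,
                "ba_limits": list(self.ba_limits), "ccc": self.ccc,
                "ccc_ci": list(self.ccc_ci), "n": self.n}


def roi_mean(values, mask, exclusion_mask=None):
    """Arithmetic mean of a map over mask voxels not excluded upstream.

    Returns (mean, n_survivors); zero survivors give (nan, 0) rather than an
    error so a missing ROI propagates as a flagged missing value.
    """
    values = np.asarray(values, dtype=float)
    sel = np.asarray(mask, dtype=bool)
    if exclusion_mask is not None:
        sel = sel & ~np.asarray(exclusion_mask, dtype=bool)
    sel = sel & np.isfinite(values)
    n = int(sel.sum())
    if n == 0:
        return float("nan"), 0
    return float(values[sel].mean()), n


def asymmetry_ratio(left_value: float, right_value: float) -> float:
    """Left/right ROI ratio; nan when the denominator is not positive."""
    if not np.isfinite(right_value) or right_value <= 0 or not np.isfinite(left_value):
        return float("nan")
    return float(left_value / right_value)


def lin_ccc(x, y, alpha: float = 0.05):
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    CCC = 2*cov(x,y) / (var(x) + var(y) + (mean(x)-mean(y))^2) using
    population (1/n) moments — the original definition.  The confidence
    interval transforms to z = atanh(CCC) with Lin's asymptotic standard
    error and back.  Returns (ccc, (lo, hi)); degenerate input (zero total
    variance with equal means) returns nan.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()            # population moments
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return float("nan"), (float("nan"), float("nan"))
    ccc = 2.0 * cov / denom

    if vx == 0 or vy == 0 or abs(ccc) >= 1 or n < 4:
        return float(ccc), (float("nan"), float("nan"))
    r = cov / np.sqrt(vx * vy)
    u = (mx - my) / (vx * vy) ** 0.25
    # Lin (1989) variance of the z-transformed CCC
    se_z2 = ((1 - r**2) * ccc**2 / ((1 - ccc**2) * r**2)
             + 2 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - ccc**2) ** 2)
             - ccc**4 * u**4 / (2 * r**2 * (1 - ccc**2) ** 2)) / (n - 2)
    z = np.arctanh(ccc)
    half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(max(se_z2, 0.0))
    return float(ccc), (float(np.tanh(z - half)), float(np.tanh(z + half)))


def bland_altman(x, y):
    """Bland-Altman mean difference and 95% limits of agreement.

    d = x - y; limits are mean(d) +/- 1.96 * sd(d) with the sample (n-1)
    standard deviation.  Returns (mean, (lower, upper), stable) where
    ``stable`` is False for n < 3 (limits from so few pairs are not
    meaningful).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D vectors")
    d = x - y
    mean = float(d.mean())
    if d.size < 2:
        return mean, (mean, mean), False
    sd = float(d.std(ddof=1))
    return mean, (mean - 1.96 * sd, mean + 1.96 * sd), d.size >= 3


def linear_fit(x, y):
    """Ordinary least squares y = slope*x + intercept with R^2.

    R^2 is the squared Pearson correlation.  Raises on zero x-variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a regression")
    if np.var(x) == 0:
        raise ValueError("zero variance in x: regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def agreement_report(x, y) -> AgreementReport:
    """Bundle regression, Bland-Altman and CCC for paired measurements."""
    slope, intercept, r2 = linear_fit(x, y)
    ba_mean, ba_limits, _ = bland_altman(x, y)
    ccc, ci = lin_ccc(x, y)
    return AgreementReport(slope, intercept, r2, ba_mean, ba_limits, ccc, ci,
                           n=int(np.asarray(x).size))


def t2_threshold_loocv(t2_values, csf_labels):
    """CSF/tissue T2 cutoff maximizing leave-one-out 0/1 accuracy.

    Candidate cut-points are the midpoints between adjacent sorted samples;
    a voxel is called CSF when its T2 is at/above the cut.  Ties between
    equally accurate candidates break toward the higher threshold (more
    conservative CSF removal).  Returns (threshold, accuracy, reliable);
    ``reliable`` is False when the best accuracy is no better than chance
    (inseparable labels).  Single-class input raises.
    """
    t2 = np.asarray(t2_values, dtype=float)
    lab = np.asarray(csf_labels, dtype=bool)
    if t2.ndim != 1 or t2.shape != lab.shape:
        raise ValueError("t2_values and csf_labels must be matching 1D vectors")
    if t2.size < 4:
        raise ValueError("need at least 4 labeled samples")
    if lab.all() or not lab.any():
        raise ValueError("both CSF and tissue samples are required")

    order = np.argsort(t2)
    t2s = t2[order]
    cuts = np.unique((t2s[:-1] + t2s[1:]) / 2.0)
    # leave-one-out: each held-out sample is classified by the cut fitted on
    # the rest; for a fixed candidate cut this equals the plain accuracy
    acc = np.array([np.mean((t2 >= c) == lab) for c in cuts])
    best = acc.max()
    threshold = float(cuts[np.flatnonzero(acc == best)[-1]])
    return threshold, float(best), bool(best > 0.5)
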
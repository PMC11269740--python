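"""Trait derivation and Rensch's rule.

Sexual size dimorphism (SSD) is the log2 ratio of average adult male to average
adult female body mass; positive values mean males are larger. Relative brain
size is the residual of an ordinary least-squares regression of log10 brain mass
on log10 body mass. Rensch's rule (SSD increasing with overall size) is
diagnosed by a major-axis regression of log10 male on log10 female mass with a
slope exceeding 1.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError


def compute_ssd(male_mass, female_mass):
    """log2(male/female) body-mass ratio; positive = males larger.

    Accepts scalars or arrays; both masses must be strictly positive.
    """
    m = np.asarray(male_mass, dtype=float)
    f = np.asarray(female_mass, dtype=float)
    if np.any(m <= 0) or np.any(f <= 0):
        raise ValidationError("body masses must be strictly positive")
    out = np.log2(m) - np.log2(f)
    return float(out) if out.ndim == 0 else out


def relative_brain_size(brain_mass, body_mass) -> np.ndarray:
    """Residuals of OLS log10(brain) ~ log10(body), one per species.

    Residuals sum to zero and are invariant to rescaling body mass by a
    constant (the shift is absorbed by the intercept).
    """
    brain = np.asarray(brain_mass, dtype=float)
    body = np.asarray(body_mass, dtype=float)
    if brain.shape != body.shape:
        raise ValidationError("brain_mass and body_mass must have the same length")
    if brain.size < 3:
        raise DegenerateInputError("relative brain size needs >= 3 complete cases")
    if np.any(brain <= 0) or np.any(body <= 0):
        raise ValidationError("brain and body masses must be strictly positive")
    x = np.log10(body)
    y = np.log10(brain)
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance in body mass; allometric slope undefined")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclasses.dataclass
class MAResult:
    """Major-axis regression summary.

    slope/intercept define the first principal axis of the (x, y) scatter;
    r is the Pearson correlation; p_slope_vs_1 tests H0: slope = 1;
    p_assoc tests H0: r = 0. For :func:`test_rensch`, x is log10 female mass
    and y is log10 male mass, and r_assoc/p_assoc_ssd carry the separate
    SSD-vs-log10-body-mass association.
    """

    slope: float
    intercept: float
    r: float
    n: int
    p_slope_vs_1: float
    p_assoc: float
    degenerate: bool = False
    r_assoc: float | None = None
    p_assoc_ssd: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


def _ma_slope(sxx: float, syy: float, sxy: float) -> float:
    # first principal-axis slope from the 2x2 covariance entries
    return (syy - sxx + math.hypot(syy - sxx, 2.0 * sxy)) / (2.0 * sxy)


def _ma_slope_test(x: np.ndarray, y: np.ndarray, b0: float) -> float:
    # MA slope hypothesis test (Warton et al. 2006, as in the smatr package):
    # under H0 slope = b0, the residual axis y - b0*x is uncorrelated with the
    # fitted axis x + b0*y; test that correlation with F = r^2 (n-2)/(1-r^2)
    # against F(1, n-2).
    res = y - b0 * x
    fit = x + b0 * y
    n = x.size
    if np.ptp(res) == 0 or np.ptp(fit) == 0:
        return 1.0
    r = np.corrcoef(res, fit)[0, 1]
    r2 = min(r * r, 1.0 - 1e-15)
    F = r2 * (n - 2) / (1.0 - r2)
    return float(stats.f.sf(F, 1, n - 2))


def major_axis_regression(x, y) -> MAResult:
    """Major-axis (first principal axis) regression of y on x.

    Treats both variables symmetrically: swapping x and y inverts the slope.
    ``p_slope_vs_1`` is the MA slope test against unity; ``p_assoc`` the
    two-sided test of zero Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise DegenerateInputError("major-axis regression needs >= 3 points")
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxx == 0 or syy == 0:
        raise DegenerateInputError("zero variance in x or y; major axis undefined")
    degenerate = False
    if sxy == 0:
        if math.isclose(sxx, syy):
            # circular scatter: every axis is a principal axis
            return MAResult(math.nan, math.nan, 0.0, n, 1.0, 1.0, degenerate=True)
        slope = 0.0 if sxx > syy else math.inf
        degenerate = True
    else:
        slope = _ma_slope(sxx, syy, sxy)
    intercept = float(np.mean(y) - slope * np.mean(x)) if math.isfinite(slope) else math.nan
    r, p_assoc = stats.pearsonr(x, y)
    if math.isclose(abs(r), 1.0):
        # exact line: no sampling noise, no evidence against any slope through it
        p_slope = 1.0 if math.isclose(slope, 1.0) else 0.0
    else:
        p_slope = _ma_slope_test(x, y, 1.0)
    return MAResult(float(slope), intercept, float(r), n, p_slope, float(p_assoc),
                    degenerate=degenerate)


def augment_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Add derived columns to a traits table.

    Adds ``mean_mass`` (arithmetic mean of the sexes, grams), ``ssd``
    (log2 male/female), ``log10_mass`` (log10 mean mass) and, where
    ``brain_mass`` is present for >= 3 species, ``rel_brain``.
    """
    out = traits.copy()
    out["mean_mass"] = (out["male_mass"] + out["female_mass"]) / 2.0
    out["ssd"] = compute_ssd(out["male_mass"].to_numpy(), out["female_mass"].to_numpy())
    out["log10_mass"] = np.log10(out["mean_mass"])
    if "brain_mass" in out.columns:
        have = out["brain_mass"].notna() & (out["brain_mass"] > 0)
        if have.sum() >= 3:
            res = relative_brain_size(
                out.loc[have, "brain_mass"].to_numpy(),
                out.loc[have, "mean_mass"].to_numpy(),
            )
            out["rel_brain"] = np.nan
            out.loc[have, "rel_brain"] = res
    return out


def test_rensch(traits: pd.DataFrame, assoc_method: str = "pearson") -> MAResult:
    """Test Rensch's rule on a traits table.

    Runs a major-axis regression of log10 male mass on log10 female mass and
    tests the slope against 1 (hyperallometry: slope > 1 means SSD grows with
    size). Additionally reports ``r_assoc``, the correlation between SSD and
    log10 mean body mass, with its own p-value.
    """
    t = traits
    if not {"ssd", "log10_mass"}.issubset(t.columns):
        t = augment_traits(t)
    x = np.log10(t["female_mass"].to_numpy(dtype=float))
    y = np.log10(t["male_mass"].to_numpy(dtype=float))
    res = major_axis_regression(x, y)
    ssd = t["ssd"].to_numpy(dtype=float)
    lmass = t["log10_mass"].to_numpy(dtype=float)
    if (np.ptp(ssd) <= 1e-10 * max(1.0, float(np.abs(ssd).max()))
            or np.ptp(lmass) <= 1e-10 * max(1.0, float(np.abs(lmass).max()))):
        # constant trait: association undefined
        res.r_assoc, res.p_assoc_ssd = math.nan, 1.0
        return res
    if assoc_method == "spearman":
        r_assoc, p_assoc = stats.spearmanr(ssd, lmass)
    else:
        r_assoc, p_assoc = stats.pearsonr(ssd, lmass)
    res.r_assoc = float(r_assoc)
    res.p_assoc_ssd = float(p_assoc)
    return res
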
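"""Phylogenetic generalized least squares screen of gene-family sizes.

Under Brownian motion, trait covariance between two species equals the depth
(root-to-node path length) of their most recent common ancestor. The screen
fits, for every gene family, a two-predictor GLS

    family size ~ intercept + SSD + covariate        (error covariance ∝ C)

where the covariate is log10 mean body mass or relative brain size. Per
predictor it reports t, a correlation-scale effect size r = t/sqrt(t^2 + df),
Benjamini–Hochberg adjusted p-values across families, and an
expanding/contracting call.

Numerically the GLS is solved by Cholesky whitening: with C = L Lᵀ, regress
L⁻¹y on L⁻¹X by ordinary least squares. This is algebraically identical to
beta = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y but never forms C⁻¹.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .errors import DegenerateInputError, ValidationError
from .phenotypes import augment_traits
from .trees import normalize_species_name, prune_to_species, tip_labels

logger = logging.getLogger(__name__)

PREDICTORS = ("ssd", "log10_mass", "rel_brain")


def phylo_covariance(
    tree: dendropy.Tree, species: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix for an ordered species list.

    C[i, j] is the shared root-to-MRCA path length of tips i and j; the
    diagonal holds root-to-tip depths. Species absent from the request are
    pruned before computing depths, so the root of the pruned tree defines
    time zero.

    Returns the matrix and the species order it is indexed by (the request
    order, normalized).
    """
    order = [normalize_species_name(s) for s in species]
    if len(set(order)) != len(order):
        raise ValidationError("duplicate species in covariance request")
    pruned = prune_to_species(tree, order)
    depth = {}
    for leaf in pruned.leaf_node_iter():
        depth[leaf.taxon.label] = leaf.distance_from_root()
    pdm = pruned.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in pdm.taxon_iter()}
    n = len(order)
    C = np.zeros((n, n))
    for i, a in enumerate(order):
        C[i, i] = depth[a]
        for j in range(i + 1, n):
            b = order[j]
            d = pdm.patristic_distance(taxa[a], taxa[b])
            # shared path = (depth_a + depth_b - patristic distance) / 2
            C[i, j] = C[j, i] = 0.5 * (depth[a] + depth[b] - d)
    return C, order


@dataclasses.dataclass
class PGLSFit:
    """One generalized least-squares fit.

    ``beta``, ``se``, ``t``, ``p_raw`` are per-column of the design matrix;
    ``df`` = n - k residual degrees of freedom; ``sigma2`` the residual
    variance scale. ``degenerate`` flags a perfect fit (zero residual
    variance), for which se/t/p are undefined (NaN) rather than infinite.
    """

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: int
    sigma2: float
    p_raw: np.ndarray
    degenerate: bool = False


def pgls_fit(y: np.ndarray, X: np.ndarray, C: np.ndarray) -> PGLSFit:
    """Fit y = X beta + e, cov(e) = sigma2 * C, by Cholesky whitening.

    The design matrix must include its intercept column. Raises on
    rank-deficient designs and on non-positive-definite C.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if y.size != n or C.shape != (n, n):
        raise ValidationError("dimension mismatch between y, X and C")
    if n <= k:
        raise DegenerateInputError(f"need n > k predictors (n={n}, k={k})")
    try:
        L = linalg.cholesky(C, lower=True)
    except linalg.LinAlgError as exc:
        raise DegenerateInputError(f"covariance matrix not positive definite: {exc}") from exc
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    if np.linalg.matrix_rank(Xw) < k:
        raise DegenerateInputError("design matrix is rank deficient after whitening")
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    beta = xtx_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    ssr = float(resid @ resid)
    df = n - k
    sigma2 = ssr / df
    scale = max(1.0, float(yw @ yw))
    if ssr <= 1e-12 * scale:
        nan = np.full(k, np.nan)
        return PGLSFit(beta, nan, nan.copy(), df, 0.0, nan.copy(), degenerate=True)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return PGLSFit(beta, se, t, df, sigma2, p)


def effect_size_r(t, df):
    """Correlation-scale effect size r = t / sqrt(t^2 + df).

    Strictly increasing in t at fixed df and bounded in (-1, 1); this is the
    conventional conversion of a regression t-statistic to an r effect size.
    """
    t = np.asarray(t, dtype=float)
    if np.any(np.asarray(df) < 1):
        raise ValidationError("degrees of freedom must be >= 1")
    out = t / np.sqrt(t * t + df)
    return float(out) if out.ndim == 0 else out


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _classify(r: float, p: float, alpha: float, degenerate: bool) -> tuple[str, bool]:
    if degenerate or not np.isfinite(p) or p >= alpha:
        return "ns", False
    return ("expanding", True) if r > 0 else ("contracting", True)


def screen_families(
    counts: pd.DataFrame,
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    predictors: Sequence[str] = ("ssd", "log10_mass"),
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """PGLS screen of every gene family against a pair of trait predictors.

    Parameters
    ----------
    counts : DataFrame
        Filtered families x species counts.
    traits : DataFrame
        Traits table; derived columns (ssd, log10_mass, rel_brain) are added if
        absent. Species with a missing value in either predictor are dropped
        for the whole screen, not per family.
    tree : dendropy.Tree
        Rooted phylogeny with branch lengths covering the analyzed species.
    predictors : ordered pair from {"ssd", "log10_mass", "rel_brain"}
    config : AnalysisConfig

    Returns
    -------
    DataFrame in long format: one row per (family, predictor) with beta, se, t,
    df, p_raw, p_adj (BH across families, separately per predictor), effect
    size r, call in {expanding, contracting, ns}, strong flag
    (|r| > effect_r_threshold among significant calls) and degenerate flag.
    """
    if config is None:
        config = AnalysisConfig()
    for pname in predictors:
        if pname not in PREDICTORS:
            raise ValidationError(f"unknown predictor {pname!r}; expected from {PREDICTORS}")
    t = augment_traits(traits) if not set(predictors).issubset(traits.columns) else traits
    t = t.set_index("species") if "species" in t.columns else t

    usable = t.index[t[list(predictors)].notna().all(axis=1)]
    species = [s for s in counts.columns if s in set(usable) and s in set(tip_labels(tree))]
    dropped = counts.shape[1] - len(species)
    if dropped:
        logger.warning("screen: dropped %d species missing from traits/tree", dropped)
    if len(species) <= len(predictors) + 1:
        raise DegenerateInputError("too few species with complete data for the screen")
    if counts.shape[0] == 0:
        warnings.warn("screen received zero families", stacklevel=2)
        return pd.DataFrame(
            columns=["family", "predictor", "beta", "se", "t", "df",
                     "p_raw", "p_adj", "r", "call", "strong", "degenerate"]
        )

    C, order = phylo_covariance(tree, species)
    X = np.column_stack(
        [np.ones(len(order))] + [t.loc[order, p].to_numpy(dtype=float) for p in predictors]
    )
    Y = counts[order].to_numpy(dtype=float).T  # n_species x n_families
    n, k = X.shape
    df_resid = n - k
    logger.info("screen: %d families, %d species, predictors=%s, df=%d",
                Y.shape[1], n, list(predictors), df_resid)

    L = linalg.cholesky(C, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    Yw = linalg.solve_triangular(L, Y, lower=True)
    if np.linalg.matrix_rank(Xw) < k:
        raise DegenerateInputError("design matrix is rank deficient (collinear predictors?)")
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    beta = xtx_inv @ (Xw.T @ Yw)           # k x F
    resid = Yw - Xw @ beta
    ssr = np.einsum("ij,ij->j", resid, resid)
    sigma2 = ssr / df_resid
    scale = np.maximum(1.0, np.einsum("ij,ij->j", Yw, Yw))
    degen = ssr <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
        tstat = np.where(degen, np.nan, beta / se)
    p_raw = 2.0 * stats.t.sf(np.abs(tstat), df_resid)

    rows = []
    for pi, pname in enumerate(predictors, start=1):
        pr = p_raw[pi]
        ok = ~degen & np.isfinite(pr)
        p_adj = np.full(pr.shape, np.nan)
        if ok.any():
            p_adj[ok] = bh_adjust(pr[ok])
        r = effect_size_r(np.where(ok, tstat[pi], 0.0), df_resid)
        r = np.where(ok, r, np.nan)
        gate = pr if config.use_raw_p else p_adj
        for j, fam in enumerate(counts.index):
            call, signif = _classify(
                r[j] if ok[j] else np.nan,
                gate[j] if ok[j] else np.nan,
                config.alpha,
                bool(degen[j]),
            )
            rows.append({
                "family": fam,
                "predictor": pname,
                "beta": beta[pi, j],
                "se": se[pi, j] if ok[j] else np.nan,
                "t": tstat[pi, j],
                "df": df_resid,
                "p_raw": pr[j] if ok[j] else np.nan,
                "p_adj": p_adj[j] if ok[j] else np.nan,
                "r": r[j],
                "call": call,
                "strong": bool(signif and abs(r[j]) > config.effect_r_threshold),
                "degenerate": bool(degen[j]),
            })
    out = pd.DataFrame(rows)
    for pname in predictors:
        sub = out[out["predictor"] == pname]
        logger.info("screen[%s]: %d expanding, %d contracting, %d degenerate",
                    pname, (sub["call"] == "expanding").sum(),
                    (sub["call"] == "contracting").sum(), sub["degenerate"].sum())
    return out


def select_families(result: pd.DataFrame, predictor: str, direction: str) -> list[str]:
    """Families called in a given direction for a predictor, from a screen table."""
    if direction not in ("expanding", "contracting"):
        raise ValidationError("direction must be 'expanding' or 'contracting'")
    sub = result[(result["predictor"] == predictor) & (result["call"] == direction)]
    return sub["family"].tolist()
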
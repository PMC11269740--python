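"""GO-term enrichment of gene-family sets by randomization.

A GO term is linked to a gene family whenever any member gene of that family
carries the term in any species. Terms annotated to fewer than ``small_go_min``
families are pooled into a single pseudo-term ``small_GO`` that is kept in the
map for bookkeeping but excluded from testing.

Enrichment of a focal family set (e.g. the expanding families from the PGLS
screen) is tested against ``n_resamples`` equally sized random draws without
replacement from the background set: per term, the observed count of focal
families carrying the term is converted to a Z score against the null draws'
mean and SD, with an upper-tail normal p-value and BH correction across terms.
Marginally each null count is hypergeometric, which the tests use as an exact
cross-check.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import DegenerateInputError, ValidationError
from .pgls import bh_adjust

logger = logging.getLogger(__name__)

SMALL_GO_LABEL = "small_GO"


@dataclasses.dataclass
class FamilyTermMap:
    """term -> set of member families, plus the set of terms excluded from testing."""

    terms: dict[str, frozenset[str]]
    excluded: frozenset[str] = frozenset()

    @property
    def testable_terms(self) -> list[str]:
        return sorted(t for t in self.terms if t not in self.excluded)

    def n_families(self, term: str) -> int:
        return len(self.terms[term])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "n_families": len(fams), "excluded": t in self.excluded}
            for t, fams in sorted(self.terms.items())
        ]
        return pd.DataFrame(rows)


def map_go_to_families(
    gene_go: pd.DataFrame | Mapping[str, Iterable[str]],
    membership: pd.DataFrame | Mapping[str, str],
) -> FamilyTermMap:
    """Lift gene-level GO annotations to the family level.

    A term-family edge exists iff at least one member gene of the family
    carries the term (set semantics: several member genes sharing a term still
    make one edge). Genes annotated with GO terms but absent from the family
    membership map are skipped with a logged count.

    Parameters
    ----------
    gene_go : DataFrame with columns gene, term — or mapping gene -> terms
    membership : DataFrame with columns gene, family — or mapping gene -> family
    """
    if isinstance(gene_go, pd.DataFrame):
        pairs = gene_go[["gene", "term"]].itertuples(index=False)
    else:
        pairs = ((g, t) for g, ts in gene_go.items() for t in ts)
    if isinstance(membership, pd.DataFrame):
        gene2fam = dict(zip(membership["gene"], membership["family"]))
    else:
        gene2fam = dict(membership)

    terms: dict[str, set[str]] = {}
    skipped = set()
    matched = 0
    for gene, term in pairs:
        fam = gene2fam.get(gene)
        if fam is None:
            skipped.add(gene)
            continue
        matched += 1
        terms.setdefault(term, set()).add(fam)
    if skipped:
        logger.warning("map_go_to_families: %d annotated genes absent from membership map, skipped",
                       len(skipped))
    if matched == 0:
        raise ValidationError("no annotated gene appears in the family membership map")
    return FamilyTermMap({t: frozenset(f) for t, f in terms.items()})


def pool_small_terms(fmap: FamilyTermMap, config: AnalysisConfig | None = None) -> FamilyTermMap:
    """Merge terms annotated to fewer than ``small_go_min`` families into ``small_GO``.

    The pooled pseudo-term keeps the union of its members' families (every
    term-family edge is preserved, only relabelled) but is flagged excluded
    from testing. Terms at or above the threshold pass through unchanged.
    """
    if config is None:
        config = AnalysisConfig()
    if not fmap.terms:
        raise ValidationError("family-term map is empty")
    big: dict[str, frozenset[str]] = {}
    small_members: set[str] = set()
    n_small = 0
    for term, fams in fmap.terms.items():
        if len(fams) < config.small_go_min:
            small_members.update(fams)
            n_small += 1
        else:
            big[term] = fams
    excluded = set(fmap.excluded) & set(big)
    if n_small:
        big[SMALL_GO_LABEL] = frozenset(small_members)
        excluded.add(SMALL_GO_LABEL)
    logger.info("pool_small_terms: pooled %d terms (< %d families) into %s; %d testable",
                n_small, config.small_go_min, SMALL_GO_LABEL,
                len(big) - (1 if n_small else 0))
    if not set(big) - excluded:
        warnings.warn("all GO terms were pooled as small; nothing is testable", stacklevel=2)
    return FamilyTermMap(big, frozenset(excluded))


def randomization_enrichment(
    focal: Iterable[str],
    background: Iterable[str],
    fmap: FamilyTermMap,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Test each GO term for overrepresentation in a focal family set.

    Draws ``n_resamples`` samples of size ``|focal|`` uniformly without
    replacement from ``background``; per testable term, reports the observed
    count ``x_obs`` of focal families carrying the term, the null mean and SD
    over draws, Z = (x_obs - mean)/sd, an upper-tail normal p (two-sided if
    configured), and BH-adjusted p across terms. Terms whose null SD is zero
    fall back to the add-one empirical tail probability and are flagged.

    Output is invariant to the ordering of families and terms in the input
    (families are sorted before sampling).
    """
    if config is None:
        config = AnalysisConfig()
    focal_set = {str(f) for f in focal}
    bg = sorted({str(f) for f in background})
    if not focal_set:
        raise ValidationError("focal set is empty")
    if not focal_set.issubset(bg):
        raise ValidationError(
            f"focal families not contained in background: {sorted(focal_set - set(bg))[:5]}"
        )
    if len(focal_set) == len(bg):
        raise DegenerateInputError(
            "focal set equals the background: every draw reproduces the observation; "
            "enrichment needs a strict subset"
        )
    terms = fmap.testable_terms
    if not terms:
        raise ValidationError("no testable terms in the family-term map")
    if config.n_resamples < 100:
        raise ValidationError("n_resamples must be >= 100 for a usable null")

    rng = np.random.default_rng(config.random_seed if seed is None else seed)
    n_bg, m = len(bg), len(focal_set)
    bg_index = {f: i for i, f in enumerate(bg)}
    # terms x background incidence
    M = np.zeros((len(terms), n_bg), dtype=bool)
    for ti, term in enumerate(terms):
        for fam in fmap.terms[term]:
            j = bg_index.get(fam)
            if j is not None:
                M[ti, j] = True
    focal_idx = np.fromiter((bg_index[f] for f in sorted(focal_set)), dtype=int)
    x_obs = M[:, focal_idx].sum(axis=1)

    R = config.n_resamples
    null_counts = np.empty((len(terms), R), dtype=np.int32)
    for r in range(R):
        draw = rng.choice(n_bg, size=m, replace=False)
        null_counts[:, r] = M[:, draw].sum(axis=1)
    null_mean = null_counts.mean(axis=1)
    null_sd = null_counts.std(axis=1, ddof=0)

    z = np.full(len(terms), np.nan)
    p_raw = np.empty(len(terms))
    degenerate = null_sd == 0
    ok = ~degenerate
    z[ok] = (x_obs[ok] - null_mean[ok]) / null_sd[ok]
    if config.enrichment_two_sided:
        p_raw[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    else:
        p_raw[ok] = stats.norm.sf(z[ok])
    if degenerate.any():
        # constant null count: add-one empirical upper tail
        ge = (null_counts[degenerate] >= x_obs[degenerate, None]).sum(axis=1)
        p_raw[degenerate] = (1.0 + ge) / (1.0 + R)
        logger.info("randomization_enrichment: %d terms with zero null SD, empirical fallback",
                    int(degenerate.sum()))

    out = pd.DataFrame({
        "term": terms,
        "n_families": [fmap.n_families(t) for t in terms],
        "x_obs": x_obs,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "z": z,
        "p_raw": p_raw,
        "degenerate": degenerate,
    })
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    logger.info("randomization_enrichment: |focal|=%d |background|=%d terms=%d resamples=%d",
                m, n_bg, len(terms), R)
    return out
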
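"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the pipeline assumes on real
data: a time-calibrated phylogeny (pure-birth tree rescaled to unit root
depth), correlated Brownian evolution of sexual size dimorphism and log body
mass, family counts with a linear trait effect plus phylogenetically
correlated Gaussian noise (matching the Gaussian PGLS the screen fits), flat
GO annotations with one planted enriched term, and an expression compendium
with planted brain bias and sex bias.

Every generator is deterministic given its seed, and the planted truth is
returned alongside the data so parameter recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg

from .errors import ValidationError
from .pgls import phylo_covariance
from .phenotypes import augment_traits
from .trees import tip_labels

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SimulationTruth:
    """Planted ground truth of one simulated dataset.

    family_effects : per-family true coefficient of SSD (0 for null families)
    planted_terms : GO terms planted as enriched in the focal set
    brain_bias_genes : genes planted with elevated brain expression
    sex_log2fc : per-gene true female-vs-male log2 fold change
    """

    family_effects: pd.Series | None = None
    planted_terms: frozenset[str] = frozenset()
    brain_bias_genes: frozenset[str] = frozenset()
    sex_log2fc: pd.Series | None = None


def simulate_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree with unit birth rate, rescaled to root depth 1.

    Tips are labeled sp1..spN in order of appearance. All branch lengths are
    strictly positive: the process runs one extra exponential waiting time
    after the last speciation so no tip sits exactly at a birth event.
    """
    if n_tips < 2:
        raise ValidationError(f"need n_tips >= 2, got {n_tips}")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    # active lineages as (node, birth_time)
    root = tree.seed_node
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = [(root, 0.0)]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.edge.length = (t - born) if node is not root else None
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active.append((left, t))
        active.append((right, t))
    t += rng.exponential(1.0 / len(active))  # extend tips past the last split
    for k, (node, born) in enumerate(active):
        node.edge.length = t - born
    # label tips in leaf-iteration order for a stable sp1..spN assignment
    for k, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"sp{k}")
    # rescale to unit root depth (tree is ultrametric by construction)
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    logger.info("simulate_tree: %d tips, seed=%d", n_tips, seed)
    return tree


def simulate_traits(
    tree: dendropy.Tree,
    sigma_ssd: float = 0.5,
    sigma_bm: float = 1.0,
    rho: float = 0.4,
    seed: int = 0,
    root_ssd: float = 0.5,
    root_log10_mass: float = 3.5,
    include_brain: bool = False,
    brain_exponent: float = 0.75,
    brain_intercept: float = -1.2,
    sigma_brain: float = 0.15,
) -> pd.DataFrame:
    """Correlated Brownian evolution of SSD and log10 body mass along the tree.

    On a branch of length l the bivariate increment is normal with covariance
    l * [[sigma_ssd^2, rho*sigma_ssd*sigma_bm], [., sigma_bm^2]]. Male and
    female masses are back-derived from (ssd, mean mass) by inverting their
    defining formulas, so the phenotype stage reproduces the simulated SSD
    exactly. Defaults put SSD roughly in the observed mammalian range (about
    -0.5 to 3) around a male-biased mean, body masses in the gram-to-tonne
    range, and a positive SSD/size correlation of the magnitude reported for
    mammals.

    With ``include_brain``, brain mass follows a log-log allometry
    (slope ``brain_exponent``) plus an independent Brownian residual with rate
    ``sigma_brain``, giving a nontrivial relative brain size.
    """
    if abs(rho) > 1:
        raise ValidationError(f"|rho| must be <= 1, got {rho}")
    if sigma_ssd < 0 or sigma_bm < 0:
        raise ValidationError("sigmas must be >= 0")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValidationError("tree lacks branch lengths; Brownian simulation needs them")
    rng = np.random.default_rng(seed)
    cov = np.array([
        [sigma_ssd**2, rho * sigma_ssd * sigma_bm],
        [rho * sigma_ssd * sigma_bm, sigma_bm**2],
    ])
    # Cholesky-like factor that tolerates zero sigmas
    w, V = np.linalg.eigh(cov)
    A = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    state: dict[int, np.ndarray] = {}
    rows = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            x = np.array([root_ssd, root_log10_mass])
        else:
            x = state[id(node.parent_node)] + A @ rng.standard_normal(2) * np.sqrt(
                node.edge.length
            )
        state[id(node)] = x
        if node.is_leaf():
            ssd, l10m = x
            mean_mass = 10.0**l10m
            female = 2.0 * mean_mass / (1.0 + 2.0**ssd)
            male = female * 2.0**ssd
            rows.append({"species": node.taxon.label, "male_mass": male,
                         "female_mass": female})
    traits = pd.DataFrame(rows)
    if include_brain:
        brown = _brownian_scalar(tree, sigma_brain, rng)
        order = traits["species"].to_numpy()
        l10body = np.log10((traits["male_mass"] + traits["female_mass"]) / 2.0)
        traits["brain_mass"] = 10.0 ** (
            brain_intercept + brain_exponent * l10body + brown.loc[order].to_numpy()
        )
    logger.info("simulate_traits: %d species, rho=%.2f, seed=%d", len(traits), rho, seed)
    return augment_traits(traits)


def _brownian_scalar(tree: dendropy.Tree, sigma: float, rng: np.random.Generator) -> pd.Series:
    state: dict[int, float] = {}
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            x = 0.0
        else:
            x = state[id(node.parent_node)] + sigma * np.sqrt(node.edge.length) * rng.standard_normal()
        state[id(node)] = x
        if node.is_leaf():
            out[node.taxon.label] = x
    return pd.Series(out)


def simulate_family_counts(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    n_families: int = 1000,
    frac_assoc: float = 0.1,
    effect_scale: float = 1.0,
    noise_sigma: float = 2.0,
    seed: int = 0,
    base_count: float = 10.0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Gene-family counts with a planted linear SSD effect and phylogenetic noise.

    For family j the latent value of species i is a_j + b_j * SSD_i + u_i with
    u ~ N(0, noise_sigma^2 * C), C the Brownian covariance of the tree. Counts
    are the latent values rounded and clipped at zero. The first
    round(frac_assoc * n_families) families get b_j = +/-effect_scale (random
    sign); the rest are null (b_j = 0). The intercept a_j = base_count -
    b_j * mean(SSD) keeps the mean latent count at ``base_count`` (>= 3 so the
    inclusion filters do not mass-reject, and large enough that clipping at
    zero is rare at the default noise scale).
    """
    if not (0.0 <= frac_assoc <= 1.0):
        raise ValidationError(f"frac_assoc must be in [0, 1], got {frac_assoc}")
    if base_count < 3:
        raise ValidationError("base_count must be >= 3 so mean counts stay testable")
    t = traits.set_index("species") if "species" in traits.columns else traits
    species = tip_labels(tree)
    missing = sorted(set(species) - set(t.index))
    if missing:
        raise ValidationError(f"traits missing for tree species: {missing[:5]}")
    ssd = t.loc[species, "ssd"].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    C, _ = phylo_covariance(tree, species)
    L = linalg.cholesky(noise_sigma**2 * C, lower=True) if noise_sigma > 0 else None

    n_assoc = int(round(frac_assoc * n_families))
    b = np.zeros(n_families)
    b[:n_assoc] = effect_scale * rng.choice([-1.0, 1.0], size=n_assoc)
    fam_ids = [f"OG{j:05d}" for j in range(n_families)]

    counts = np.empty((n_families, len(species)), dtype=np.int64)
    for j in range(n_families):
        a = base_count - b[j] * ssd.mean()
        latent = a + b[j] * ssd
        if L is not None:
            latent = latent + L @ rng.standard_normal(len(species))
        counts[j] = np.clip(np.rint(latent), 0, None).astype(np.int64)
    df = pd.DataFrame(counts, index=pd.Index(fam_ids, name="family"), columns=species)
    truth = SimulationTruth(family_effects=pd.Series(b, index=fam_ids, name="b"))
    logger.info("simulate_family_counts: %d families (%d associated), %d species, seed=%d",
                n_families, n_assoc, len(species), seed)
    return df, truth


def effect_for_target_r(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    noise_sigma: float,
    target_r: float,
    predictors: Sequence[str] = ("ssd", "log10_mass"),
) -> float:
    """Planted SSD coefficient whose expected effect size is ``target_r``.

    In the screen's GLS, the SSD t-statistic has expectation ~ b / se(b_hat)
    with se from the whitened design and the generator's noise scale. Solving
    r = t/sqrt(t^2+df) for t and t = b/se for b gives the coefficient to plant
    so the true effect lands at the requested correlation-scale size.
    """
    if not (0.0 < abs(target_r) < 1.0):
        raise ValidationError("target_r must be in (0, 1) in absolute value")
    t_ = traits.set_index("species") if "species" in traits.columns else traits
    species = tip_labels(tree)
    C, order = phylo_covariance(tree, species)
    X = np.column_stack(
        [np.ones(len(order))] + [t_.loc[order, p].to_numpy(dtype=float) for p in predictors]
    )
    L = linalg.cholesky(C, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    se = noise_sigma * np.sqrt(xtx_inv[1, 1])
    df = len(order) - X.shape[1]
    t_star = abs(target_r) * np.sqrt(df / (1.0 - target_r**2))
    return float(t_star * se)


def simulate_go_annotations(
    families: Sequence[str],
    focal: Iterable[str],
    n_terms: int = 20,
    planted_term_size: int = 30,
    focal_overlap: float = 1.0,
    term_size: int = 80,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Flat GO annotations with one planted enriched term.

    Background terms (GO:B0001...) draw their member families uniformly at
    random. The planted term (GO:PLANT0) takes round(focal_overlap *
    planted_term_size) members from the designated focal set and the rest from
    outside it. One synthetic gene per family (g_<family>) carries the
    family's terms, producing the gene-level map and membership tables the
    enrichment stage consumes.
    """
    families = [str(f) for f in families]
    focal_set = sorted({str(f) for f in focal})
    if not set(focal_set).issubset(families):
        raise ValidationError("focal families must be a subset of the family list")
    if planted_term_size > len(families):
        raise ValidationError("planted_term_size exceeds the number of families")
    if not (0.0 <= focal_overlap <= 1.0):
        raise ValidationError("focal_overlap must be in [0, 1]")
    n_in = int(round(focal_overlap * planted_term_size))
    if n_in > len(focal_set):
        raise ValidationError(
            f"overlap needs {n_in} focal families but only {len(focal_set)} exist"
        )
    n_out = planted_term_size - n_in
    non_focal = sorted(set(families) - set(focal_set))
    if n_out > len(non_focal):
        raise ValidationError("planted term needs more non-focal families than exist")

    rng = np.random.default_rng(seed)
    term_members: dict[str, np.ndarray] = {}
    for k in range(n_terms):
        size = min(term_size, len(families))
        term_members[f"GO:B{k:04d}"] = rng.choice(families, size=size, replace=False)
    planted = "GO:PLANT0"
    inside = rng.choice(focal_set, size=n_in, replace=False) if n_in else np.array([], dtype=object)
    outside = rng.choice(non_focal, size=n_out, replace=False) if n_out else np.array([], dtype=object)
    term_members[planted] = np.concatenate([inside, outside])

    gene_rows = [{"gene": f"g_{fam}", "family": fam} for fam in families]
    go_rows = [
        {"gene": f"g_{fam}", "term": term}
        for term, members in term_members.items()
        for fam in members
    ]
    truth = SimulationTruth(planted_terms=frozenset({planted}))
    logger.info("simulate_go_annotations: %d terms + planted (%d members, overlap %.2f), seed=%d",
                n_terms, planted_term_size, focal_overlap, seed)
    return pd.DataFrame(go_rows), pd.DataFrame(gene_rows), truth


def simulate_expression(
    n_genes: int = 500,
    tissues: Sequence[str] | None = None,
    stages: Sequence[tuple[str, str]] | None = None,
    brain_bias_set: Iterable[str] = (),
    sexbias_spec: Mapping[str, float] | None = None,
    seed: int = 0,
    baseline: float = 5.0,
    noise_sd: float = 1.0,
    brain_shift: float = 3.0,
    brain_label: str = "brain",
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Expression compendium with planted brain bias and sex bias.

    One row per gene x tissue x stage x sex. The latent log2 signal is
    ``baseline`` plus i.i.d. N(0, noise_sd^2) noise; genes in
    ``brain_bias_set`` get ``brain_shift`` added in brain tissues, and female
    samples get the gene's planted log2 fold change added. Values are reported
    on the raw scale as 2^latent - 1, so the pipeline's log2(x+1) transform
    recovers the latent signal.

    Genes are g0001..gN; default tissues are the brain plus 19 other adult
    tissues; default stages are 4 prenatal and 4 adult, carried in ``stage``,
    ``stage_index`` and ``phase`` columns.
    """
    if tissues is None:
        tissues = [brain_label] + [f"tissue{i:02d}" for i in range(1, 20)]
    if brain_label not in tissues:
        raise ValidationError(f"brain label {brain_label!r} must be among tissues")
    if stages is None:
        stages = [(f"pcw{w}", "prenatal") for w in (8, 12, 21, 37)] + \
                 [(f"yrs{y}", "adult") for y in (2, 13, 21, 40)]
    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    gene_set = set(genes)
    bias = {str(g) for g in brain_bias_set}
    unknown = bias - gene_set
    if unknown:
        raise ValidationError(f"brain_bias_set contains unknown genes: {sorted(unknown)[:5]}")
    sexfc = pd.Series(0.0, index=genes, name="log2fc")
    if sexbias_spec:
        unknown = set(sexbias_spec) - gene_set
        if unknown:
            raise ValidationError(f"sexbias_spec contains unknown genes: {sorted(unknown)[:5]}")
        for g, v in sexbias_spec.items():
            sexfc[g] = float(v)

    rng = np.random.default_rng(seed)
    gene_arr = np.array(genes)
    is_bias = np.isin(gene_arr, sorted(bias))
    fc = sexfc.to_numpy()
    rows = []
    for tissue in tissues:
        t_shift = np.where(is_bias & (tissue == brain_label), brain_shift, 0.0)
        for si, (stage, phase) in enumerate(stages):
            for sex in ("female", "male"):
                latent = (baseline + t_shift
                          + (fc if sex == "female" else 0.0)
                          + noise_sd * rng.standard_normal(n_genes))
                value = np.maximum(2.0**latent - 1.0, 0.0)
                rows.append(pd.DataFrame({
                    "gene": gene_arr, "tissue": tissue, "stage": stage,
                    "stage_index": si, "phase": phase, "sex": sex, "value": value,
                }))
    expr = pd.concat(rows, ignore_index=True)
    truth = SimulationTruth(brain_bias_genes=frozenset(bias), sex_log2fc=sexfc)
    logger.info("simulate_expression: %d genes x %d tissues x %d stages x 2 sexes, seed=%d",
                n_genes, len(tissues), len(stages), seed)
    return expr, truth
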
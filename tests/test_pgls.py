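import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ssdscreen import simulate
from ssdscreen.config import AnalysisConfig
from ssdscreen.errors import DegenerateInputError, ValidationError
from ssdscreen.family_filter import filter_families
from ssdscreen.pgls import (
    bh_adjust,
    effect_size_r,
    pgls_fit,
    phylo_covariance,
    screen_families,
    select_families,
)
from ssdscreen.trees import parse_newick, tip_labels


def brute_force_covariance(tree, species):
    """Oracle: enumerate root-to-tip paths; C_ij = depth of deepest shared node."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        node, path = leaf, []
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = list(reversed(path))

    def depth_of(node):
        d, n = 0.0, node
        while n.parent_node is not None:
            d += n.edge.length
            n = n.parent_node
        return d

    n = len(species)
    C = np.zeros((n, n))
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            shared = [x for x, y in zip(paths[a], paths[b]) if x is y]
            C[i, j] = depth_of(shared[-1])
    return C


class TestPhyloCovariance:
    def test_three_taxon_textbook_matrix(self, three_taxon_tree):
        C, order = phylo_covariance(three_taxon_tree, ["A", "B", "C"])
        expected = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        assert np.allclose(C, expected)
        assert order == ["A", "B", "C"]

    def test_star_tree_gives_identity(self, star_tree_8):
        C, _ = phylo_covariance(star_tree_8, tip_labels(star_tree_8))
        assert np.allclose(C, np.eye(8))

    def test_matches_root_path_oracle_on_random_tree(self):
        tree = simulate.simulate_tree(8, seed=3)
        species = sorted(tip_labels(tree))
        C, _ = phylo_covariance(tree, species)
        assert np.allclose(C, brute_force_covariance(tree, species), atol=1e-10)

    def test_pruning_respects_subset_depths(self, yule_tree_20):
        species = sorted(tip_labels(yule_tree_20))[:6]
        C, _ = phylo_covariance(yule_tree_20, species)
        assert np.allclose(C, C.T)
        # diagonal dominates each row (shared path <= either depth)
        assert np.all(np.diag(C)[:, None] >= C - 1e-12)

    def test_unknown_species_error(self, three_taxon_tree):
        with pytest.raises(ValidationError, match="ghost"):
            phylo_covariance(three_taxon_tree, ["A", "ghost"])


class TestPGLSFit:
    def test_identity_covariance_reduces_to_ols(self, rng):
        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ [1.0, 2.0, -0.5] + rng.normal(size=n)
        fit = pgls_fit(y, X, np.eye(n))
        ols = sm.OLS(y, X).fit()
        assert np.allclose(fit.beta, ols.params, atol=1e-8)
        assert np.allclose(fit.se, ols.bse, atol=1e-8)
        assert np.allclose(fit.t, ols.tvalues, atol=1e-8)
        assert np.allclose(fit.p_raw, ols.pvalues, atol=1e-8)
        assert fit.df == n - 3

    def test_matches_dense_inverse_oracle_on_toy_tree(self, rng):
        # 6-species tree extending the 3-taxon pattern
        tree = parse_newick("(((A:1,B:1):1,(C:1.5,D:0.5):0.7):0.5,(E:1,F:1):1.2);")
        species = ["A", "B", "C", "D", "E", "F"]
        C, _ = phylo_covariance(tree, species)
        X = np.column_stack([np.ones(6), rng.normal(size=6), rng.normal(size=6)])
        y = rng.normal(size=6)
        fit = pgls_fit(y, X, C)
        # brute-force generalized normal equations via explicit inverses
        Ci = np.linalg.inv(C)
        beta = np.linalg.inv(X.T @ Ci @ X) @ X.T @ Ci @ y
        resid = y - X @ beta
        sigma2 = resid @ Ci @ resid / (6 - 3)
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ Ci @ X)))
        assert np.allclose(fit.beta, beta, atol=1e-8)
        assert np.allclose(fit.se, se, atol=1e-8)
        assert np.allclose(fit.t, beta / se, atol=1e-8)

    def test_agrees_with_statsmodels_gls(self, yule_tree_20, rng):
        species = tip_labels(yule_tree_20)
        C, _ = phylo_covariance(yule_tree_20, species)
        n = len(species)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        fit = pgls_fit(y, X, C)
        gls = sm.GLS(y, X, sigma=C).fit()
        assert np.allclose(fit.beta, gls.params, atol=1e-8)
        assert np.allclose(fit.se, gls.bse, atol=1e-8)
        assert np.allclose(fit.p_raw, gls.pvalues, atol=1e-8)

    def test_perfect_fit_flagged_degenerate(self):
        n = 8
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        y = X @ [2.0, 3.0]
        fit = pgls_fit(y, X, np.eye(n))
        assert fit.degenerate
        assert fit.sigma2 == 0.0
        assert np.all(np.isnan(fit.t))

    def test_scale_invariance_of_inference(self, yule_tree_20, rng):
        species = tip_labels(yule_tree_20)
        C, _ = phylo_covariance(yule_tree_20, species)
        n = len(species)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        a = pgls_fit(y, X, C)
        b = pgls_fit(y, X, 7.3 * C)
        assert np.allclose(a.beta, b.beta, atol=1e-10)
        assert np.allclose(a.t, b.t, atol=1e-10)
        assert b.sigma2 == pytest.approx(a.sigma2 / 7.3)

    def test_rank_deficiency_rejected(self):
        n = 10
        x = np.arange(n, dtype=float)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(DegenerateInputError, match="rank"):
            pgls_fit(np.random.default_rng(0).normal(size=n), X, np.eye(n))


class TestEffectSize:
    @pytest.mark.parametrize("t,df,expected", [
        (0.0, 50, 0.0),
        (11.0, 121, 1 / np.sqrt(2)),   # t^2 = df
        (-11.0, 121, -1 / np.sqrt(2)),
    ])
    def test_algebraic_identities(self, t, df, expected):
        assert effect_size_r(t, df) == pytest.approx(expected, abs=1e-12)

    def test_round_trips_reported_minimum_effect(self):
        # |r| = 0.243 at df = 121 (n=124 species, 3 coefficients)
        r = effect_size_r(-2.76, 121)
        assert r == pytest.approx(-0.243, abs=5e-3)
        t_back = r * np.sqrt(121 / (1 - r**2))
        assert t_back == pytest.approx(-2.76, abs=1e-9)

    def test_monotone_in_t_and_bounded(self):
        t = np.linspace(-50, 50, 201)
        r = effect_size_r(t, 30)
        assert np.all(np.diff(r) > 0)
        assert np.all(np.abs(r) < 1)

    def test_df_below_one_rejected(self):
        with pytest.raises(ValidationError):
            effect_size_r(1.0, 0)


def brute_force_bh(p):
    """Literal step-up definition: q_i = min_{j >= i}(p_(j) * m / j), capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        q[i] = min(1.0, min(sorted_p[j] * m / (j + 1) for j in range(i, m)))
    out = np.empty(m)
    out[order] = q
    return out


class TestBHAdjust:
    def test_constant_ratio_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_matches_literal_step_up_definition(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestScreen:
    def test_star_tree_screen_equals_ols_screen(self, star_tree_8, rng):
        species = tip_labels(star_tree_8)
        traits = pd.DataFrame({
            "species": species,
            "male_mass": rng.uniform(1e3, 1e5, 8),
            "female_mass": rng.uniform(1e3, 1e5, 8),
        })
        counts = pd.DataFrame(rng.poisson(8, size=(30, 8)),
                              index=[f"OG{i}" for i in range(30)],
                              columns=species).rename_axis("family")
        res = screen_families(counts, traits, star_tree_8)
        from ssdscreen.phenotypes import augment_traits
        t = augment_traits(traits).set_index("species")
        X = np.column_stack([np.ones(8), t.loc[species, "ssd"], t.loc[species, "log10_mass"]])
        for fam in ["OG0", "OG7", "OG29"]:
            ols = sm.OLS(counts.loc[fam, species].to_numpy(float), X).fit()
            row = res[(res["family"] == fam) & (res["predictor"] == "ssd")].iloc[0]
            assert row["beta"] == pytest.approx(ols.params[1], abs=1e-8)
            assert row["t"] == pytest.approx(ols.tvalues[1], abs=1e-8)

    def test_planted_families_called_with_correct_sign_at_high_signal(self):
        tree = simulate.simulate_tree(40, seed=21)
        traits = simulate.simulate_traits(tree, seed=22)
        counts, truth = simulate.simulate_family_counts(
            tree, traits, n_families=60, frac_assoc=0.25,
            effect_scale=12.0, noise_sigma=1.0, seed=23)
        kept, _ = filter_families(counts)
        res = screen_families(kept, traits, tree)
        ssd_rows = res[res["predictor"] == "ssd"].set_index("family")
        for fam, b in truth.family_effects.items():
            if b == 0 or fam not in ssd_rows.index:
                continue
            call = ssd_rows.loc[fam, "call"]
            assert call == ("expanding" if b > 0 else "contracting")

    def test_permuting_species_labels_kills_discoveries(self, rng):
        tree = simulate.simulate_tree(40, seed=31)
        traits = simulate.simulate_traits(tree, seed=32)
        counts, _ = simulate.simulate_family_counts(
            tree, traits, n_families=150, frac_assoc=0.3,
            effect_scale=8.0, noise_sigma=1.0, seed=33)
        kept, _ = filter_families(counts)
        res = screen_families(kept, traits, tree)
        n_hits = (res.loc[res["predictor"] == "ssd", "call"] != "ns").sum()
        assert n_hits > 10
        shuffled = kept.copy()
        shuffled.columns = rng.permutation(kept.columns)
        res_perm = screen_families(shuffled, traits, tree)
        n_perm = (res_perm.loc[res_perm["predictor"] == "ssd", "call"] != "ns").sum()
        assert n_perm <= max(2, n_hits // 10)

    def test_select_families_reads_calls(self):
        df = pd.DataFrame({
            "family": ["a", "b", "c"],
            "predictor": ["ssd"] * 3,
            "call": ["expanding", "ns", "contracting"],
        })
        assert select_families(df, "ssd", "expanding") == ["a"]
        assert select_families(df, "ssd", "contracting") == ["c"]
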
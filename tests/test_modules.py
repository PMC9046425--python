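"""Module detection, eigengenes, and module-trait statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr, t as t_dist

from coexnet import modules as mod
from coexnet import network as net
from coexnet.evaluation import module_recovery


def block_expression(sizes, n_samples, noise, seed=0, factors=None):
    """Block-correlated expression: one latent factor per block plus noise."""
    rng = np.random.default_rng(seed)
    if factors is None:
        factors = rng.standard_normal((len(sizes), n_samples))
    rows, labels = [], []
    for b, size in enumerate(sizes):
        for i in range(size):
            rows.append(factors[b] + noise * rng.standard_normal(n_samples))
            labels.append(f"B{b}")
    expr = pd.DataFrame(rows, index=[f"g{i:03d}" for i in range(sum(sizes))],
                        columns=[f"s{j:02d}" for j in range(n_samples)])
    return expr, pd.Series(labels, index=expr.index), factors


def tom_of(expr, beta=6):
    s = net.similarity(expr)
    return net.topological_overlap(net.adjacency(s, beta))


class TestDetectModules:
    def test_two_clean_blocks_recovered_exactly(self):
        # no background here, so the natural cut sits just below the root merge
        expr, truth, _ = block_expression([40, 35], 60, noise=1e-6)
        tom = tom_of(expr)
        asg = mod.detect_modules(net.diss_tom(tom), min_module_size=30,
                                 cut_height_quantile=0.99)
        assert set(asg.module_ids) == {"M1", "M2"}
        # perfect agreement up to label names
        tab = pd.crosstab(truth, asg.labels)
        assert (tab.to_numpy() > 0).sum() == 2

    def test_pure_noise_yields_no_stable_modules(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.standard_normal((120, 40)))
        expr.index = [f"g{i}" for i in range(120)]
        tom = tom_of(expr)
        asg = mod.detect_modules(net.diss_tom(tom), min_module_size=30)
        from sklearn.metrics import adjusted_rand_score
        planted = ["A"] * 60 + ["B"] * 60
        detected = asg.labels.to_numpy()
        keep = detected != mod.UNASSIGNED
        if keep.sum() > 1:
            ari = adjusted_rand_score(np.array(planted)[keep], detected[keep])
            assert abs(ari) < 0.1

    def test_planted_module_recovery_on_generator_output(self):
        result = module_recovery(seed=12)
        assert result.ari >= 0.8
        assert result.trait_module_is_top

    def test_fewer_genes_than_min_size_rejected(self):
        d = pd.DataFrame(1 - np.eye(10))
        with pytest.raises(ValueError):
            mod.detect_modules(d, min_module_size=30)

    def test_gene_permutation_permutes_labels(self):
        expr, _, _ = block_expression([35, 30], 50, noise=0.3, seed=3)
        tom = tom_of(expr)
        asg = mod.detect_modules(net.diss_tom(tom))
        perm = np.random.default_rng(0).permutation(len(expr))
        tom_p = tom.iloc[perm, perm]
        asg_p = mod.detect_modules(net.diss_tom(tom_p))
        # same partition of gene ids regardless of input order
        part = lambda a: {m: frozenset(a.genes_in(m)) for m in a.module_ids}
        assert set(part(asg).values()) == set(part(asg_p).values())

    def test_me_merge_collapses_duplicated_factor(self):
        """Two blocks driven by the same factor merge at high ME correlation."""
        rng = np.random.default_rng(5)
        f = rng.standard_normal(60)
        expr, _, _ = block_expression([35, 35], 60, noise=0.3, seed=5,
                                      factors=np.vstack([f, f * 1.0 + 0.05 * rng.standard_normal(60)]))
        tom = tom_of(expr)
        merged = mod.detect_modules(net.diss_tom(tom), merge_me_cor=0.8, expr=expr)
        assert len(merged.module_ids) == 1


class TestModuleEigengenes:
    def test_identical_genes_reproduce_shared_profile(self):
        rng = np.random.default_rng(0)
        profile = rng.standard_normal(30)
        expr = pd.DataFrame([profile] * 10 + [rng.standard_normal(30) for _ in range(30)],
                            index=[f"g{i}" for i in range(40)],
                            columns=[f"s{i}" for i in range(30)])
        labels = pd.Series(["M1"] * 10 + ["M2"] * 30, index=expr.index)
        asg = mod.ModuleAssignment(labels, 5, 0.5, np.empty((0, 4)))
        me = mod.module_eigengenes(expr, asg)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(me.me.loc["M1"], z, atol=1e-8)
        assert me.explained_variance["M1"] == pytest.approx(1.0)

    def test_recovers_planted_eigengene(self):
        expr, truth, factors = block_expression([40], 50, noise=0.5, seed=7)
        labels = pd.Series("M1", index=expr.index)
        asg = mod.ModuleAssignment(labels, 5, 0.5, np.empty((0, 4)))
        me = mod.module_eigengenes(expr, asg)
        assert abs(np.corrcoef(me.me.loc["M1"], factors[0])[0, 1]) > 0.9

    def test_sign_anchor_restores_orientation_after_flip(self):
        expr, _, _ = block_expression([20], 40, noise=0.3, seed=8)
        labels = pd.Series("M1", index=expr.index)
        asg = mod.ModuleAssignment(labels, 5, 0.5, np.empty((0, 4)))
        me1 = mod.module_eigengenes(expr, asg).me.loc["M1"]
        me2 = mod.module_eigengenes(-expr, asg).me.loc["M1"]
        # anchored to the mean profile, which flips with the data
        np.testing.assert_allclose(me1.to_numpy(), -me2.to_numpy(), atol=1e-8)
        assert np.corrcoef(me1, expr.mean(axis=0))[0, 1] >= 0

    def test_unit_variance(self):
        expr, _, _ = block_expression([25], 35, noise=0.4, seed=9)
        labels = pd.Series("M1", index=expr.index)
        asg = mod.ModuleAssignment(labels, 5, 0.5, np.empty((0, 4)))
        me = mod.module_eigengenes(expr, asg).me.loc["M1"]
        assert me.std(ddof=1) == pytest.approx(1.0)

    def test_eigengene_explains_at_least_mean_gene_share(self):
        expr, _, _ = block_expression([30], 45, noise=0.6, seed=10)
        labels = pd.Series("M1", index=expr.index)
        asg = mod.ModuleAssignment(labels, 5, 0.5, np.empty((0, 4)))
        me = mod.module_eigengenes(expr, asg)
        assert me.explained_variance["M1"] >= 1.0 / 30


class TestModuleTraitStats:
    def _stats_for(self, me_vector, trait, n_genes=6, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(len(trait))]
        expr = pd.DataFrame(rng.standard_normal((n_genes, len(trait))),
                            index=[f"g{i}" for i in range(n_genes)], columns=samples)
        labels = pd.Series("M1", index=expr.index)
        asg = mod.ModuleAssignment(labels, 2, 0.5, np.empty((0, 4)))
        me = mod.ModuleEigengenes(
            me=pd.DataFrame([me_vector], index=pd.Index(["M1"], name="module"),
                            columns=samples),
            explained_variance=pd.Series({"M1": 0.5}),
        )
        meta = pd.DataFrame({"trait": trait}, index=pd.Index(samples, name="sample_id"))
        return mod.module_trait_stats(expr, me, meta, asg)

    def test_me_equal_to_trait_gives_r_one(self):
        trait = [0, 1] * 10
        stats = self._stats_for(np.array(trait, dtype=float), trait)
        row = stats.module_trait.iloc[0]
        assert row["cor"] == pytest.approx(1.0)
        assert row["p"] < 1e-12

    def test_zero_correlation_gives_p_one(self):
        # ME orthogonal to the trait by construction
        trait = [0] * 50 + [1] * 50
        me = np.concatenate([np.tile([1.0, -1.0], 25), np.tile([1.0, -1.0], 25)])
        stats = self._stats_for(me, trait)
        assert stats.module_trait.iloc[0]["p"] == pytest.approx(1.0)

    def test_p_value_matches_t_distribution_closed_form(self):
        """r = 0.5, n = 22 against the exact two-sided t probability."""
        r, n = 0.5, 22
        t = r * np.sqrt((n - 2) / (1 - r**2))
        expected = 2 * t_dist.sf(t, df=n - 2)
        # build data achieving exactly r = 0.5 between ME and trait
        trait = np.array([1] * 11 + [0] * 11)
        tc = (trait - trait.mean()) / np.linalg.norm(trait - trait.mean())
        ortho = np.tile([1.0, -1.0], 11)
        ortho = ortho - ortho @ tc * tc
        ortho /= np.linalg.norm(ortho)
        me = r * tc + np.sqrt(1 - r**2) * ortho
        stats = self._stats_for(me, list(trait))
        assert stats.module_trait.iloc[0]["cor"] == pytest.approx(r, abs=1e-12)
        assert stats.module_trait.iloc[0]["p"] == pytest.approx(expected, rel=1e-10)

    def test_gs_mm_ranges_and_columns(self):
        trait = [0, 1] * 15
        stats = self._stats_for(np.random.default_rng(2).standard_normal(30), trait)
        gs = stats.gene_stats
        assert ((gs["GS"] >= 0) & (gs["GS"] <= 1)).all()
        assert ((gs["MM"] >= -1) & (gs["MM"] <= 1)).all()
        assert ((gs["p.GS"] > 0) & (gs["p.GS"] <= 1)).all()
        assert (stats.module_trait["p.adj"] >= stats.module_trait["p"] - 1e-15).all()

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError):
            self._stats_for(np.arange(10.0), [1] * 10)

    def test_trait_module_has_top_cor_and_gs_mm_couple(self):
        """The planted trait module wins |cor(ME, trait)| and GS tracks |MM|."""
        from coexnet import preprocess as pp
        from coexnet.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(seed=21, n_outliers=0)
        _, tpm, meta, truth = simulate_dataset(cfg)
        adj = pp.estimate_and_remove_surrogates(pp.log_transform(tpm), meta, n_sv=3)
        sim = net.similarity(adj.adjusted)
        fit = net.pick_soft_threshold(sim)
        tom = net.topological_overlap(net.adjacency(sim, fit.chosen_beta))
        asg = mod.detect_modules(net.diss_tom(tom))
        me = mod.module_eigengenes(adj.adjusted, asg)
        stats = mod.module_trait_stats(adj.adjusted, me, meta, asg)

        labels = pd.Series(truth.gene_module_labels)
        planted_in = asg.labels[labels == "M1"].value_counts()
        detected = next(m for m in planted_in.index if m != mod.UNASSIGNED)
        mt = stats.module_trait.set_index("module")
        assert mt["cor"].abs().idxmax() == detected

    def test_gs_couples_with_mm_under_heterogeneous_loadings(self):
        """When gene-eigengene loadings vary, GS ranks track |MM| ranks."""
        rng = np.random.default_rng(4)
        n = 80
        trait = np.array([1] * 40 + [0] * 40)
        tc = (trait - trait.mean()) / trait.std()
        factor = 0.5 * tc + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        loadings = rng.uniform(0.3, 0.95, size=40)
        expr = pd.DataFrame(
            [l * factor + np.sqrt(1 - l**2) * rng.standard_normal(n) for l in loadings],
            index=[f"g{i}" for i in range(40)], columns=[f"s{i}" for i in range(n)])
        labels = pd.Series("M1", index=expr.index)
        asg = mod.ModuleAssignment(labels, 5, 0.5, np.empty((0, 4)))
        me = mod.module_eigengenes(expr, asg)
        meta = pd.DataFrame({"trait": trait}, index=pd.Index(expr.columns,
                                                             name="sample_id"))
        stats = mod.module_trait_stats(expr, me, meta, asg)
        rho, _ = spearmanr(stats.gene_stats["GS"], stats.gene_stats["MM"].abs())
        assert rho > 0.5

    def test_no_detected_modules_yields_empty_stats(self):
        """All genes in the sink: stats frames are empty but well-formed."""
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.standard_normal((10, 20)),
                            index=[f"g{i}" for i in range(10)],
                            columns=[f"s{i}" for i in range(20)])
        labels = pd.Series(mod.UNASSIGNED, index=expr.index)
        asg = mod.ModuleAssignment(labels, 30, 0.5, np.empty((0, 4)))
        me = mod.module_eigengenes(expr, asg)
        meta = pd.DataFrame({"trait": [0, 1] * 10},
                            index=pd.Index(expr.columns, name="sample_id"))
        stats = mod.module_trait_stats(expr, me, meta, asg)
        assert stats.module_trait.empty
        assert list(stats.module_trait.columns) == ["module", "cor", "p", "p.adj"]
        assert stats.significant_modules() == []

    def test_hub_genes_ranked_by_abs_mm(self):
        trait = [0, 1] * 15
        stats = self._stats_for(np.random.default_rng(3).standard_normal(30), trait,
                                n_genes=8)
        hubs = mod.hub_genes(stats, "M1", top=5)
        mm = hubs["MM"].abs().to_numpy()
        assert (np.diff(mm) <= 1e-12).all()
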
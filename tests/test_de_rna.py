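"""Differential-expression engine: normalization, filtering, NB LRT, FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from evoparallel import nb_glm
from evoparallel.de_rna import (
    cpm_normalize,
    de_call,
    filter_expressed,
    fit_nb_lrt,
    significant_sets,
)
from evoparallel.simulate import SimParams, simulate_counts, simulate_effects
from evoparallel.stats import bh_adjust
from evoparallel.types import RunConfig, ValidationError


class TestCPM:
    def test_definition_and_column_sums(self, tiny_counts):
        cpm = cpm_normalize(tiny_counts)
        lib = tiny_counts.values.sum(axis=0)
        np.testing.assert_allclose(cpm.values.iloc[0, 0], 10 * 1e6 / lib.iloc[0])
        np.testing.assert_allclose(cpm.values.sum(axis=0), 1e6)

    def test_scale_invariance(self, tiny_counts):
        doubled = tiny_counts.with_values(tiny_counts.values * 2)
        np.testing.assert_allclose(
            cpm_normalize(doubled).values, cpm_normalize(tiny_counts).values
        )

    def test_zero_library_rejected(self, tiny_counts):
        zeroed = tiny_counts.values.copy()
        zeroed.iloc[:, 0] = 0
        with pytest.raises(ValidationError):
            cpm_normalize(tiny_counts.with_values(zeroed))


class TestFilter:
    def test_zero_gene_removed_threshold_zero_keeps_all(self, tiny_counts):
        cpm = cpm_normalize(tiny_counts)
        kept, _ = filter_expressed(cpm, 0.1)
        assert "gC" not in kept and {"gA", "gB"} <= set(kept)
        kept_all, _ = filter_expressed(cpm, 0.0)
        assert set(kept_all) == {"gA", "gB", "gC"}

    def test_boundary_gene_kept(self, tiny_counts):
        """'at least' reading: mean CPM exactly at the threshold passes."""
        cpm = cpm_normalize(tiny_counts)
        thr = float(cpm.values.loc["gA"].mean())
        kept, _ = filter_expressed(cpm, thr)
        assert "gA" in kept

    def test_min_mode_stricter_than_mean(self, small_study):
        _, counts, _ = small_study
        cpm = cpm_normalize(counts)
        kept_mean, _ = filter_expressed(cpm, 0.5, mode="mean")
        kept_min, _ = filter_expressed(cpm, 0.5, mode="min")
        assert set(kept_min) <= set(kept_mean)


class TestNBLRT:
    def test_no_difference_gives_null_stat(self):
        """Identical counts in both groups with equal libraries: beta1 ~ 0, p ~ 1."""
        y = np.tile([[50.0]], (1, 8))
        lib = np.full(8, 1e4)
        fit = nb_glm.nb_lrt_contrast(y, lib, np.arange(5), np.arange(5, 8), ["g"], phi=0.1)
        assert abs(fit.beta1[0]) < 1e-6
        assert fit.lrt[0] < 1e-8
        assert fit.p[0] > 0.999

    def test_matches_statsmodels_at_fixed_dispersion(self, small_study):
        _, counts, _ = small_study
        anc = counts.ancestral_samples()
        evo = counts.evolved_samples("pop1")
        y = counts.values[anc + evo].to_numpy(float)
        lib = y.sum(axis=0)
        ok = (y.min(axis=1) >= 5)  # keep statsmodels away from boundary genes
        idx = np.flatnonzero(ok)[:10]
        fit = nb_glm.nb_lrt_contrast(y, lib, np.arange(5), np.arange(5, 8),
                                     counts.feature_ids, phi=0.05)
        X = np.column_stack([np.ones(8), np.r_[np.zeros(5), np.ones(3)]])
        off = np.log(lib)
        fam = sm.families.NegativeBinomial(alpha=0.05)
        for i in idx:
            m1 = sm.GLM(y[i], X, family=fam, offset=off).fit()
            m0 = sm.GLM(y[i], X[:, :1], family=fam, offset=off).fit()
            np.testing.assert_allclose(fit.lrt[i], 2 * (m1.llf - m0.llf), rtol=1e-5, atol=1e-7)
            np.testing.assert_allclose(fit.beta1[i], m1.params[1], rtol=1e-5, atol=1e-8)

    def test_lrt_invariant_to_library_rescaling(self, small_study):
        _, counts, _ = small_study
        anc = counts.ancestral_samples()
        evo = counts.evolved_samples("pop2")
        y = counts.values[anc + evo].to_numpy(float)[:100]
        lib = y.sum(axis=0)
        genes = counts.feature_ids[:100]
        f1 = nb_glm.nb_lrt_contrast(y, lib, np.arange(5), np.arange(5, 8), genes, phi=0.1)
        f2 = nb_glm.nb_lrt_contrast(y, lib * 7.5, np.arange(5), np.arange(5, 8), genes, phi=0.1)
        np.testing.assert_allclose(f1.lrt, f2.lrt, rtol=1e-6, atol=1e-8)

    def test_power_on_large_effect(self):
        """A 4x shift at healthy expression is detected essentially always."""
        hits = 0
        n_sims = 30
        for rep in range(n_sims):
            rng = np.random.default_rng(500 + rep)
            lib = np.full(8, 1e5)
            mu = np.r_[np.full(5, 200.0), np.full(3, 800.0)]
            r = 1 / 0.05
            y = rng.negative_binomial(r, r / (r + mu), size=(1, 8)).astype(float)
            fit = nb_glm.nb_lrt_contrast(y, lib, np.arange(5), np.arange(5, 8), ["g"], phi=0.05)
            hits += fit.p[0] < 0.05
        assert hits >= int(0.95 * n_sims)


class TestDECall:
    def test_common_universe_and_schema(self, small_study, config):
        _, counts, _ = small_study
        de = de_call(counts, config)
        per_pop = {p: set(g["feature_id"]) for p, g in de.groupby("population")}
        universes = list(per_pop.values())
        assert all(u == universes[0] for u in universes)
        assert set(de.columns) == {"population", "feature_id", "log2fc", "pvalue", "padj", "significant"}
        assert len(per_pop) == 10

    def test_threshold_monotonicity(self, small_study, config):
        _, counts, _ = small_study
        de5 = de_call(counts, config)
        de1 = de_call(counts, config.replace(fdr_threshold=0.01))
        s5 = significant_sets(de5)
        s1 = significant_sets(de1)
        for pop in s5:
            assert s1[pop] <= s5[pop]

    def test_sample_order_invariance(self, small_study, config):
        _, counts, _ = small_study
        rng = np.random.default_rng(0)
        order = rng.permutation(counts.sample_ids).tolist()
        shuffled = type(counts)(counts.values[order], counts.meta.loc[order], "counts")
        de_a = de_call(counts, config).set_index(["population", "feature_id"])
        de_b = de_call(shuffled, config).set_index(["population", "feature_id"])
        np.testing.assert_allclose(
            de_a["pvalue"], de_b.loc[de_a.index, "pvalue"], rtol=1e-8, equal_nan=True
        )

    def test_effect_monotonicity(self):
        """More true effect, same noise stream: never fewer significant genes."""
        params = SimParams(n_genes=500, n_metabolites=50, seed=77)
        base_truth = simulate_effects(params)
        cfg = RunConfig(rng_seed=77)
        n_sig = []
        for factor in (0.25, 1.0, 4.0):
            truth = simulate_effects(params)
            truth.gene_effects *= factor
            counts = simulate_counts(truth, params)
            de = de_call(counts, cfg)
            n_sig.append(len(significant_sets(de)["pop1"]))
        assert n_sig[0] <= n_sig[1] <= n_sig[2]

    def test_too_few_replicates_rejected(self, tiny_counts):
        one_rep = type(tiny_counts)(
            tiny_counts.values.iloc[:, :6], tiny_counts.meta.iloc[:6], "counts"
        )
        with pytest.raises(ValidationError):
            fit_nb_lrt(one_rep, "pop1")


class TestBH:
    def test_matches_brute_force_definition(self):
        """BH == sort, p*n/rank, cumulative min from the largest rank."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(1, 1000))
            p = rng.random(n) ** rng.uniform(0.5, 3)
            adj = bh_adjust(p)
            order = np.argsort(p, kind="mergesort")
            brute = p[order] * n / np.arange(1, n + 1)
            brute = np.minimum.accumulate(brute[::-1])[::-1]
            brute = np.minimum(brute, 1.0)
            expect = np.empty(n)
            expect[order] = brute
            np.testing.assert_allclose(adj, expect, rtol=1e-12)

    def test_nan_passthrough(self):
        p = np.array([0.01, np.nan, 0.5])
        adj = bh_adjust(p)
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], bh_adjust(np.array([0.01, 0.5])))
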
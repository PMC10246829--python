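"""Global-test quadratic score, Fisher integration, joint analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from evoparallel.io import PathwayAnnotation
from evoparallel.pathways import fisher_combine, global_test, joint_pathway_analysis
from evoparallel.simulate import SimParams, module_annotations, simulate_effects, simulate_metabolites, simulate_study
from evoparallel.types import OmicsMatrix, RunConfig, SampleMeta, ValidationError, meta_frame
from evoparallel import de_rna
from evoparallel.de_met import log_transform_filter


class TestFisherCombine:
    def test_identity_at_unit_p(self):
        s, p = fisher_combine([1.0, 1.0])
        assert s == 0.0
        assert p == pytest.approx(1.0)

    def test_known_value(self):
        """S = -4 ln 0.05 ~ 11.983; combined p is the chi2(4) upper tail."""
        s, p = fisher_combine([0.05, 0.05])
        assert s == pytest.approx(-4 * np.log(0.05), rel=1e-12)
        assert s == pytest.approx(11.9829, abs=1e-4)
        assert p == pytest.approx(chi2.sf(s, 4), rel=1e-12)

    def test_single_p_is_identity(self):
        for p_in in (0.001, 0.05, 0.31, 0.9, 1.0):
            _, p_out = fisher_combine([p_in])
            assert p_out == pytest.approx(p_in, rel=1e-10)

    def test_chi_square_null_distribution(self):
        """-2 sum(ln U) for uniform U is chi-square distributed: combined p
        of two independent uniforms is itself uniform (Monte Carlo)."""
        rng = np.random.default_rng(0)
        ps = np.array([fisher_combine(list(u))[1] for u in rng.random((2000, 2))])
        assert abs(ps.mean() - 0.5) < 0.03
        assert abs((ps < 0.1).mean() - 0.1) < 0.025

    def test_monotone_in_each_input(self):
        _, base = fisher_combine([0.2, 0.4])
        _, lower = fisher_combine([0.1, 0.4])
        _, higher = fisher_combine([0.2, 0.8])
        assert lower < base < higher

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            fisher_combine([0.0, 0.5])
        with pytest.raises(ValidationError):
            fisher_combine([1.5])
        s, p = fisher_combine([0.0, 0.5], floor=1e-3)
        assert np.isfinite(s)


def _contrast_matrix(values, n_anc=5, n_evo=3):
    samples = [SampleMeta(f"a{i}", "anc", "ancestral", i + 1) for i in range(n_anc)]
    samples += [SampleMeta(f"e{i}", "pop1", "evolved", i + 1) for i in range(n_evo)]
    df = pd.DataFrame(values, index=[f"f{i}" for i in range(len(values))],
                      columns=[s.sample_id for s in samples])
    return OmicsMatrix(df, meta_frame(samples), "log_area")


class TestGlobalTest:
    def test_null_uniformity(self):
        """Pure-noise members: the permutation p is close to uniform."""
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(300):
            mat = _contrast_matrix(rng.normal(size=(4, 8)))
            p = global_test(mat, {"f0", "f1", "f2", "f3"}, "pop1", 200,
                            np.random.default_rng(rng.integers(2**31)))
            ps.append(p)
        ps = np.asarray(ps)
        frac = (ps < 0.05).mean()
        assert 0.01 < frac < 0.10
        assert abs(ps.mean() - 0.5) < 0.06

    def test_shifted_members_hit_permutation_floor(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(3, 8))
        vals[:, 5:] += 5.0
        mat = _contrast_matrix(vals)
        p = global_test(mat, {"f0", "f1", "f2"}, "pop1", 500, np.random.default_rng(3))
        assert p == pytest.approx(1 / 501, abs=5e-3)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(3, 8))
        mat_a = _contrast_matrix(vals)
        scaled = vals.copy()
        scaled[1] = scaled[1] * 13.0 + 100.0
        mat_b = _contrast_matrix(scaled)
        members = {"f0", "f1", "f2"}
        p_a = global_test(mat_a, members, "pop1", 300, np.random.default_rng(5))
        p_b = global_test(mat_b, members, "pop1", 300, np.random.default_rng(5))
        assert p_a == p_b

    def test_min_members_skip(self):
        rng = np.random.default_rng(6)
        mat = _contrast_matrix(rng.normal(size=(3, 8)))
        assert global_test(mat, {"f0"}, "pop1", 100, np.random.default_rng(0)) is None
        assert global_test(mat, {"f0"}, "pop1", 100, np.random.default_rng(0),
                           min_members=1) is not None


@pytest.fixture(scope="module")
def joint_setup():
    params = SimParams(n_genes=300, n_metabolites=30, shared_effect_sd=1.5, seed=33)
    truth, counts, mets = simulate_study(params)
    cfg = RunConfig(rng_seed=33, n_perm_pathway=300)
    cpm = de_rna.cpm_normalize(counts)
    _, cpm_f = de_rna.filter_expressed(cpm, cfg.cpm_filter)
    rna_log = cpm_f.with_values(np.log2(cpm_f.values + cfg.pseudocount), value_kind="cpm")
    met_f = log_transform_filter(mets, cfg.met_detection_floor)
    gene_ann, met_ann = module_annotations(truth)
    # add pure-noise pathways from genes outside every module
    noise_genes = [f"g{i + 1:05d}" for i in range(150, 300)]
    gene_sets = dict(gene_ann.members)
    for i in range(10):
        gene_sets[f"NOISE{i}"] = frozenset(noise_genes[i * 5 : i * 5 + 5])
    gene_ann = PathwayAnnotation(gene_sets)
    return truth, cfg, rna_log, met_f, gene_ann, met_ann


class TestJointAnalysis:
    def test_schema_and_bh_monotonicity(self, joint_setup):
        truth, cfg, rna_log, met_f, gene_ann, met_ann = joint_setup
        table, shared = joint_pathway_analysis(rna_log, met_f, gene_ann, met_ann, cfg, seed=1)
        assert {"population", "pathway", "p_gene", "p_met", "fisher_s",
                "p_combined", "padj", "significant"} <= set(table.columns)
        sig_01 = set(table.loc[table["padj"] < 0.01, ["population", "pathway"]].itertuples(index=False))
        sig_05 = set(table.loc[table["padj"] < 0.05, ["population", "pathway"]].itertuples(index=False))
        assert sig_01 <= sig_05
        # shared table only lists pathways significant in every population
        n_pops = table["population"].nunique()
        for _, row in shared.iterrows():
            sub = table[table["pathway"] == row["pathway"]]
            assert sub["significant"].all() and len(sub) == n_pops

    def test_modules_with_strong_effects_outrank_noise(self, joint_setup):
        """Pathways carrying true shared effects get smaller combined p than
        pure-noise pathways in nearly every module/noise pair."""
        truth, cfg, rna_log, met_f, gene_ann, met_ann = joint_setup
        table, _ = joint_pathway_analysis(rna_log, met_f, gene_ann, met_ann, cfg, seed=1)
        one = table[table["population"] == "pop1"]
        # restrict to modules whose shared effect is substantial
        strong = [
            f"MOD{i + 1:04d}"
            for i, met in enumerate(truth.met_effects.index)
            if abs(truth.met_effects.loc[met]).mean() > 1.0
        ]
        mod_p = one[one["pathway"].isin(strong)]["p_combined"].to_numpy()
        noise_p = one[one["pathway"].str.startswith("NOISE")]["p_combined"].to_numpy()
        assert len(mod_p) >= 3 and len(noise_p) == 10
        wins = (mod_p[:, None] < noise_p[None, :]).mean()
        assert wins >= 0.95

    def test_null_population_fdr_controlled(self):
        """With no true effects anywhere, few pathways pass the FDR cut."""
        params = SimParams(n_genes=200, n_metabolites=40, shared_effect_sd=0.0,
                           specific_effect_sd=0.0, seed=44)
        truth, counts, mets = simulate_study(params)
        cfg = RunConfig(rng_seed=44, n_perm_pathway=400)
        cpm = de_rna.cpm_normalize(counts)
        _, cpm_f = de_rna.filter_expressed(cpm, cfg.cpm_filter)
        rna_log = cpm_f.with_values(np.log2(cpm_f.values + cfg.pseudocount), "cpm")
        met_f = log_transform_filter(mets, cfg.met_detection_floor)
        gene_ann, met_ann = module_annotations(truth)
        table, _ = joint_pathway_analysis(rna_log, met_f, gene_ann, met_ann, cfg, seed=2)
        frac_sig = table.groupby("population")["significant"].mean()
        assert (frac_sig <= 0.10).all()
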
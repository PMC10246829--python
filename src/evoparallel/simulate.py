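"""Synthetic multi-omics data with a hierarchical redundancy structure.

The generator emulates an experimental-evolution common-garden design:
five ancestral replicate samples, ten evolved populations with three
replicate samples each for the transcriptome, and the first six evolved
populations (three replicates each) for the metabolome.

The core modeling idea is functional redundancy within gene modules.
Each metabolite owns a disjoint module of ``genes_per_module`` genes.  A
module carries one shared effect, drawn once and common to every
population; in any given population each module gene is independently
"active" with probability ``redundancy_fraction``.  An active gene's
log2 effect is the module's shared effect plus a population-specific
deviation; an inactive gene does not respond at all.  The metabolite's
effect is the aggregate (mean by default) of its module genes' effects.
Averaging over partially overlapping active subsets makes the metabolite
layer more parallel across populations than the gene layer whenever
redundancy_fraction < 1 — different gene sets, similar metabolic output.

Counts are drawn negative-binomially around library-size-scaled means;
metabolite values are Gaussian on the log scale above a detection floor.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .io import PathwayAnnotation, write_gmt, write_omics_matrix, write_table
from .types import ANCESTRAL, EVOLVED, OmicsMatrix, ValidationError

LN2 = float(np.log(2.0))

Aggregation = Literal["mean", "sum", "max"]


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults mirror the study design.

    Effect sizes are on the log2 scale.  ``nb_dispersion`` is the negative
    binomial dispersion phi in Var = mu + phi * mu^2.  Gene baselines are
    drawn log-uniform in log2-CPM so a 0.1-CPM expression filter removes a
    nontrivial fraction of genes by construction.
    """

    n_genes: int = 2000
    n_metabolites: int = 200
    genes_per_module: int = 5
    n_pops_rna: int = 10
    n_pops_met: int = 6
    n_anc: int = 5
    n_rep: int = 3
    shared_effect_sd: float = 1.0
    specific_effect_sd: float = 0.5
    redundancy_fraction: float = 0.5
    nb_dispersion: float = 0.05
    met_noise_sd: float = 0.1
    lib_size_mean: int = 1_000_000
    lib_size_cv: float = 0.1
    log2cpm_range: tuple[float, float] = (-5.0, 9.0)
    met_baseline_range: tuple[float, float] = (10.5, 14.0)
    aggregation: Aggregation = "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes_per_module < 1:
            raise ValidationError("genes_per_module must be >= 1")
        if self.n_metabolites * self.genes_per_module > self.n_genes:
            raise ValidationError(
                "n_metabolites * genes_per_module must not exceed n_genes "
                "(modules are disjoint)"
            )
        if min(self.shared_effect_sd, self.specific_effect_sd, self.met_noise_sd) < 0:
            raise ValidationError("effect and noise SDs must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        if not 0.0 <= self.redundancy_fraction <= 1.0:
            raise ValidationError("redundancy_fraction must be in [0, 1]")
        if self.n_pops_met > self.n_pops_rna:
            raise ValidationError("n_pops_met cannot exceed n_pops_rna")
        if self.aggregation not in ("mean", "sum", "max"):
            raise ValidationError("aggregation must be one of mean/sum/max")

    def replace(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


@dataclass
class SimTruth:
    """Ground truth of a simulation run.

    ``gene_effects`` and ``met_effects`` hold the true per-population log2
    effects (features x populations); ``module_map`` maps each metabolite to
    its disjoint gene module.
    """

    gene_effects: pd.DataFrame
    met_effects: pd.DataFrame
    module_map: dict[str, tuple[str, ...]]
    params: SimParams


def _pop_labels(n_pops: int) -> list[str]:
    return [f"pop{i + 1}" for i in range(n_pops)]


def gene_ids(params: SimParams) -> list[str]:
    return [f"g{i + 1:05d}" for i in range(params.n_genes)]


def metabolite_ids(params: SimParams) -> list[str]:
    return [f"m{i + 1:04d}" for i in range(params.n_metabolites)]


def _rng(params: SimParams, stage: str) -> np.random.Generator:
    key = list(stage.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([params.seed, *key]))


def simulate_effects(params: SimParams) -> SimTruth:
    """Draw the true per-population effects under the redundancy model."""
    rng = _rng(params, "effects")
    genes = gene_ids(params)
    mets = metabolite_ids(params)
    pops = _pop_labels(params.n_pops_rna)
    k = params.genes_per_module
    n_mod = params.n_metabolites

    # one shared effect per module, common to all populations
    shared = rng.normal(0.0, params.shared_effect_sd, size=n_mod)
    # per-population activation of each module gene, then specific deviation
    active = rng.random(size=(n_mod, k, len(pops))) < params.redundancy_fraction
    specific = rng.normal(0.0, params.specific_effect_sd, size=(n_mod, k, len(pops)))
    delta = active * (shared[:, None, None] + specific)  # (module, gene-in-module, pop)

    gene_eff = np.zeros((params.n_genes, len(pops)))
    gene_eff[: n_mod * k] = delta.reshape(n_mod * k, len(pops))

    if params.aggregation == "mean":
        met_eff = delta.mean(axis=1)
    elif params.aggregation == "sum":
        met_eff = delta.sum(axis=1)
    else:  # max by absolute value, sign preserved
        idx = np.abs(delta).argmax(axis=1)
        met_eff = np.take_along_axis(delta, idx[:, None, :], axis=1)[:, 0, :]

    module_map = {
        mets[m]: tuple(genes[m * k : (m + 1) * k]) for m in range(n_mod)
    }
    return SimTruth(
        gene_effects=pd.DataFrame(gene_eff, index=genes, columns=pops),
        met_effects=pd.DataFrame(met_eff, index=mets, columns=pops),
        module_map=module_map,
        params=params,
    )


def _design(params: SimParams, n_pops: int) -> pd.DataFrame:
    rows = []
    for r in range(params.n_anc):
        rows.append((f"anc_{r + 1}", "anc", ANCESTRAL, r + 1))
    for pop in _pop_labels(n_pops):
        for r in range(params.n_rep):
            rows.append((f"{pop}_{r + 1}", pop, EVOLVED, r + 1))
    df = pd.DataFrame(rows, columns=["sample_id", "population", "role", "replicate"])
    return df.set_index("sample_id", drop=False)


def simulate_counts(truth: SimTruth, params: SimParams | None = None) -> OmicsMatrix:
    """Draw the RNA count matrix: NB noise around offset-scaled means."""
    params = params or truth.params
    rng = _rng(params, "counts")
    meta = _design(params, params.n_pops_rna)
    genes = list(truth.gene_effects.index)

    lo, hi = params.log2cpm_range
    base_log2cpm = rng.uniform(lo, hi, size=len(genes))
    sigma = np.sqrt(np.log1p(params.lib_size_cv**2))
    lib = rng.lognormal(np.log(params.lib_size_mean) - sigma**2 / 2, sigma, size=len(meta))

    log2cpm = np.tile(base_log2cpm[:, None], (1, len(meta)))
    for j, (_, s) in enumerate(meta.iterrows()):
        if s["role"] == EVOLVED:
            log2cpm[:, j] += truth.gene_effects[s["population"]].to_numpy()
    mu = np.exp2(log2cpm) * lib[None, :] / 1e6

    r = 1.0 / params.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    values = pd.DataFrame(counts, index=genes, columns=list(meta["sample_id"]))
    return OmicsMatrix(values=values, meta=meta, value_kind="counts")


def simulate_metabolites(truth: SimTruth, params: SimParams | None = None) -> OmicsMatrix:
    """Draw the metabolite matrix (natural-log peak areas, Gaussian noise).

    Only the first ``n_pops_met`` evolved populations are assayed, matching
    the study design.  True log2 effects enter scaled by ln 2 so the
    downstream log2 fold change recovers them.
    """
    params = params or truth.params
    rng = _rng(params, "metabolites")
    meta = _design(params, params.n_pops_met)
    mets = list(truth.met_effects.index)

    lo, hi = params.met_baseline_range
    baseline = rng.uniform(lo, hi, size=len(mets))
    vals = np.tile(baseline[:, None], (1, len(meta)))
    for j, (_, s) in enumerate(meta.iterrows()):
        if s["role"] == EVOLVED:
            vals[:, j] += LN2 * truth.met_effects[s["population"]].to_numpy()
    if params.met_noise_sd > 0:
        vals = vals + rng.normal(0.0, params.met_noise_sd, size=vals.shape)
    values = pd.DataFrame(vals, index=mets, columns=list(meta["sample_id"]))
    return OmicsMatrix(values=values, meta=meta, value_kind="log_area")


def module_annotations(truth: SimTruth) -> tuple[PathwayAnnotation, PathwayAnnotation]:
    """Paired pathway annotations: module -> gene members / metabolite member."""
    gene_sets = {}
    met_sets = {}
    desc = {}
    for i, (met, genes) in enumerate(truth.module_map.items()):
        pid = f"MOD{i + 1:04d}"
        gene_sets[pid] = frozenset(genes)
        met_sets[pid] = frozenset([met])
        desc[pid] = f"synthetic module of {met}"
    return (
        PathwayAnnotation(gene_sets, desc),
        PathwayAnnotation(met_sets, desc),
    )


def write_truth_and_gmt(truth: SimTruth, outdir: str | Path) -> dict[str, Path]:
    """Write ground-truth effect tables and the paired GMT files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_mets": outdir / "truth_mets.tsv",
        "pathways_genes": outdir / "pathways_genes.gmt",
        "pathways_mets": outdir / "pathways_mets.gmt",
    }
    write_table(truth.gene_effects.rename_axis("feature_id"), paths["truth_genes"], index=True)
    write_table(truth.met_effects.rename_axis("feature_id"), paths["truth_mets"], index=True)
    gene_ann, met_ann = module_annotations(truth)
    write_gmt(gene_ann, paths["pathways_genes"])
    write_gmt(met_ann, paths["pathways_mets"])
    return paths


def simulate_study(params: SimParams) -> tuple[SimTruth, OmicsMatrix, OmicsMatrix]:
    """One full draw of the study: truth, RNA counts, metabolite matrix."""
    truth = simulate_effects(params)
    return truth, simulate_counts(truth, params), simulate_metabolites(truth, params)


def write_study(params: SimParams, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write the complete input bundle for the pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, counts, mets = simulate_study(params)
    paths = write_truth_and_gmt(truth, outdir)
    paths.update(
        counts=outdir / "counts.tsv",
        meta_rna=outdir / "meta_rna.tsv",
        metabolites=outdir / "metabolites.tsv",
        meta_met=outdir / "meta_met.tsv",
    )
    write_omics_matrix(counts, paths["counts"], paths["meta_rna"])
    write_omics_matrix(mets, paths["metabolites"], paths["meta_met"])
    return paths
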
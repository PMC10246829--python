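"""Per-population differential expression from RNA-seq counts.

Each evolved population's replicates are contrasted against the ancestral
replicates with a negative-binomial GLM (log link, log-library-size
offset) and a likelihood-ratio test of the evolution effect; p-values are
Benjamini-Hochberg adjusted per population.  Genes enter the analysis
only if they pass a counts-per-million expression filter computed across
all samples, so every population is tested on the same gene universe.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import nb_glm
from .parallelism import log2fc
from .stats import bh_adjust
from .types import OmicsMatrix, RunConfig, ValidationError

log = logging.getLogger(__name__)


def library_sizes(counts: OmicsMatrix) -> pd.Series:
    return counts.values.sum(axis=0)


def cpm_normalize(counts: OmicsMatrix) -> OmicsMatrix:
    """Counts per million: each sample column scaled by 1e6 / library size."""
    if counts.value_kind != "counts":
        raise ValidationError("cpm_normalize expects a counts matrix")
    lib = library_sizes(counts)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValidationError(f"zero library size for samples {bad}")
    cpm = counts.values * (1e6 / lib)
    return counts.with_values(cpm, value_kind="cpm")


def filter_expressed(
    cpm: OmicsMatrix, threshold: float, mode: str = "mean"
) -> tuple[list[str], OmicsMatrix]:
    """Keep genes expressed at >= ``threshold`` CPM across all samples.

    ``mode='mean'`` keeps genes whose mean CPM over all samples reaches the
    threshold (the common low-threshold idiom); ``mode='min'`` requires
    every sample to reach it.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    if mode == "mean":
        stat = cpm.values.mean(axis=1)
    elif mode == "min":
        stat = cpm.values.min(axis=1)
    else:
        raise ValidationError(f"unknown filter mode {mode!r}")
    kept = list(cpm.values.index[stat >= threshold])
    log.info("expression filter (%s >= %g CPM): kept %d / %d genes", mode, threshold, len(kept), cpm.n_features)
    return kept, cpm.subset_features(kept)


def fit_nb_lrt(
    counts: OmicsMatrix, population: str, phi: float | None = None
) -> nb_glm.NBFit:
    """NB likelihood-ratio test of the evolution effect for one population.

    The contrast comprises all ancestral replicates plus the named
    population's evolved replicates.  Dispersion is a common value
    estimated from the contrast samples unless ``phi`` is given.
    """
    anc = counts.ancestral_samples()
    evo = counts.evolved_samples(population)
    if len(evo) < 2 or len(anc) < 2:
        raise ValidationError(
            f"population {population!r}: need >= 2 replicates per group "
            f"(got {len(evo)} evolved, {len(anc)} ancestral)"
        )
    samples = anc + evo
    y = counts.values[samples].to_numpy(dtype=float)
    lib = counts.values[samples].sum(axis=0).to_numpy(dtype=float)
    anc_idx = np.arange(len(anc))
    evo_idx = np.arange(len(anc), len(samples))
    fit = nb_glm.nb_lrt_contrast(y, lib, anc_idx, evo_idx, counts.feature_ids, phi=phi)
    n_bad = int((~fit.converged).sum())
    if n_bad:
        log.warning("population %s: %d genes did not converge; p set missing", population, n_bad)
    return fit


def de_call(counts: OmicsMatrix, config: RunConfig) -> pd.DataFrame:
    """Run the full DE stage for every evolved population.

    Returns a long-format table with columns ``population, feature_id,
    log2fc, pvalue, padj, significant`` over the shared filtered gene
    universe.  log2FC is computed from the filtered CPM matrix with the
    configured pseudocount; the test p comes from the NB LRT.
    """
    pops = counts.evolved_populations()
    if not pops:
        raise ValidationError("no evolved populations in metadata")
    cpm = cpm_normalize(counts)
    kept, cpm_f = filter_expressed(cpm, config.cpm_filter, config.filter_mode)
    counts_f = counts.subset_features(kept)
    anc = counts.ancestral_samples()

    frames = []
    for pop in pops:
        fit = fit_nb_lrt(counts_f, pop)
        fc = log2fc(cpm_f, cpm_f.evolved_samples(pop), anc, config.pseudocount)
        padj = bh_adjust(fit.p)
        sig = (padj < config.fdr_threshold) & ~np.isnan(padj)
        frames.append(
            pd.DataFrame(
                {
                    "population": pop,
                    "feature_id": kept,
                    "log2fc": fc.to_numpy(),
                    "pvalue": fit.p,
                    "padj": padj,
                    "significant": sig,
                }
            )
        )
        log.info("DE %s: %d significant genes (FDR < %g, phi=%.4g)", pop, int(sig.sum()), config.fdr_threshold, fit.phi)
    return pd.concat(frames, ignore_index=True)


def significant_sets(de_table: pd.DataFrame) -> dict[str, set[str]]:
    """Per-population significant feature sets from a long DE table."""
    return {
        pop: set(grp.loc[grp["significant"], "feature_id"])
        for pop, grp in de_table.groupby("population", sort=False)
    }


def fc_matrix(de_table: pd.DataFrame) -> pd.DataFrame:
    """Features x populations log2FC matrix from a long DE table."""
    return de_table.pivot(index="feature_id", columns="population", values="log2fc")
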
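"""Permutation null for population-specific heterogeneity.

Observed parallelism (mean pairwise Jaccard or mean pairwise Pearson)
is compared against a null in which evolved-sample values carry no
population structure: for each feature independently, the values of the
evolved samples are reshuffled among the evolved sample slots while the
ancestral samples stay fixed.  Differential calls and the parallelism
statistics are then recomputed from scratch on each permuted matrix.
The test is one-sided: an observed mean *below* the null distribution
indicates a heterogeneous (population-specific) evolutionary response,
and p is the proportion of permutations whose mean statistic is smaller
than the observed mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import de_met, de_rna
from .parallelism import log2fc_table, pairwise_parallelism
from .types import EVOLVED, OmicsMatrix, RunConfig, ValidationError

log = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Observed mean parallelism against its permutation null."""

    statistic: str  # mean_jaccard | mean_pearson
    level: str  # transcriptome | metabolome
    observed_mean: float
    permuted_means: list[float]
    n_permutations: int

    @property
    def p_plain(self) -> float:
        """Proportion of permuted means strictly below the observed mean."""
        return float(np.mean(np.asarray(self.permuted_means) < self.observed_mean))

    @property
    def p_add_one(self) -> float:
        """Add-one variant (k+1)/(B+1); never exactly zero."""
        k = int(np.sum(np.asarray(self.permuted_means) < self.observed_mean))
        return (k + 1) / (self.n_permutations + 1)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "level": self.level,
            "observed_mean": self.observed_mean,
            "permuted_means": list(map(float, self.permuted_means)),
            "n_permutations": self.n_permutations,
            "p_plain": self.p_plain,
            "p_add_one": self.p_add_one,
        }


def permute_evolved(
    matrix: OmicsMatrix, rng: np.random.Generator, mode: str = "per_feature"
) -> OmicsMatrix:
    """Shuffle evolved-sample values; ancestral columns are untouched.

    ``per_feature`` (default) independently reshuffles each feature's
    evolved values across the evolved sample slots.  ``columns`` instead
    permutes whole evolved columns — a stricter null that preserves
    within-sample correlation between features.
    """
    evo = matrix.evolved_samples()
    if len(evo) < 2:
        return matrix.with_values(matrix.values.copy())
    values = matrix.values.copy()
    block = values[evo].to_numpy()
    if mode == "per_feature":
        block = rng.permuted(block, axis=1)
    elif mode == "columns":
        block = block[:, rng.permutation(block.shape[1])]
    else:
        raise ValidationError(f"unknown permutation mode {mode!r}")
    values[evo] = block
    return matrix.with_values(values)


def _mean_offdiag(corr: np.ndarray) -> float:
    iu = np.triu_indices(corr.shape[0], k=1)
    return float(corr[iu].mean())


class _FastPearson:
    """Array-level mean-pairwise-Pearson statistic for the permutation loop.

    Mirrors the general path (CPM -> expression filter -> per-population
    log2FC -> mean pairwise correlation) on raw numpy arrays; the
    permutation loop calls it hundreds of times, so the pandas container
    overhead is hoisted out once.  Equivalence with the general path on
    the observed data is pinned by a test.

    Permutations act on the *normalized* values (CPM for counts, log
    areas for metabolites): library size is an attribute of the sample,
    not of a gene's value, so shuffling raw counts across samples with
    different depths would inject spurious noise into the null.  The
    per-gene value multiset is conserved by the shuffle, so the
    expression filter is fixed once up front.
    """

    def __init__(self, matrix: OmicsMatrix, config: RunConfig, level: str) -> None:
        self.level = level
        self.config = config
        values = matrix.values.to_numpy(dtype=float)
        if level == "transcriptome":
            lib = values.sum(axis=0)
            values = values * (1e6 / lib)
            if config.filter_mode == "mean":
                keep = values.mean(axis=1) >= config.cpm_filter
            else:
                keep = values.min(axis=1) >= config.cpm_filter
            values = values[keep]
        self.values = values
        col = {s: i for i, s in enumerate(matrix.sample_ids)}
        self.anc = np.array([col[s] for s in matrix.ancestral_samples()])
        self.pops = matrix.evolved_populations()
        self.evo_by_pop = [
            np.array([col[s] for s in matrix.evolved_samples(p)]) for p in self.pops
        ]
        self.evo_all = np.array([col[s] for s in matrix.evolved_samples()])

    def stat(self, values: np.ndarray) -> float:
        cfg = self.config
        if self.level == "transcriptome":
            anc_mean = values[:, self.anc].mean(axis=1) + cfg.pseudocount
            fcs = [
                np.log2((values[:, idx].mean(axis=1) + cfg.pseudocount) / anc_mean)
                for idx in self.evo_by_pop
            ]
        else:
            anc_mean = values[:, self.anc].mean(axis=1)
            fcs = [values[:, idx].mean(axis=1) - anc_mean for idx in self.evo_by_pop]
        return _mean_offdiag(np.corrcoef(np.array(fcs)))

    def permuted_stat(self, rng: np.random.Generator) -> float:
        values = self.values.copy()
        values[:, self.evo_all] = rng.permuted(values[:, self.evo_all], axis=1)
        return self.stat(values)


def _mean_pair_stat(
    matrix: OmicsMatrix,
    config: RunConfig,
    level: str,
    statistic: str,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean pairwise parallelism of one (possibly permuted) matrix."""
    if level == "transcriptome":
        if statistic == "mean_pearson":
            cpm = de_rna.cpm_normalize(matrix)
            _, cpm_f = de_rna.filter_expressed(cpm, config.cpm_filter, config.filter_mode)
            fc = log2fc_table(cpm_f, config.pseudocount)
            pairs = pairwise_parallelism(fc_table=fc, level=level, mode="pearson")
            return float(pairs["pearson_r"].mean())
        de = de_rna.de_call(matrix, config)
        sets = de_rna.significant_sets(de)
        pairs = pairwise_parallelism(sig_sets=sets, level=level, mode="jaccard")
        return float(pairs["jaccard"].mean())
    if level == "metabolome":
        if statistic == "mean_pearson":
            fc = log2fc_table(matrix)
            pairs = pairwise_parallelism(fc_table=fc, level=level, mode="pearson")
            return float(pairs["pearson_r"].mean())
        de = de_met.met_de_call(matrix, config, rng=rng, prefiltered=True)
        sets = de_rna.significant_sets(de)
        pairs = pairwise_parallelism(sig_sets=sets, level=level, mode="jaccard")
        return float(pairs["jaccard"].mean())
    raise ValidationError(f"unknown level {level!r}")


def heterogeneity_test(
    matrix: OmicsMatrix,
    config: RunConfig,
    level: str,
    statistic: str,
    rng: np.random.Generator,
    permute_mode: str = "per_feature",
) -> NullDistribution:
    """One-sided permutation test for population-specific heterogeneity.

    ``matrix`` is the counts matrix for the transcriptome or the
    *detection-filtered* log-area matrix for the metabolome.  For each of
    ``config.n_permutations_null`` rounds the evolved values are permuted,
    the per-population differential calls (or log2FC vectors) are rebuilt,
    and the mean pairwise statistic is recorded.
    """
    if statistic not in ("mean_jaccard", "mean_pearson"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    if config.n_permutations_null < 1:
        raise ValidationError("n_permutations_null must be >= 1")

    if statistic == "mean_pearson" and permute_mode == "per_feature":
        fast = _FastPearson(matrix, config, level)
        observed = fast.stat(fast.values)
        permuted = [fast.permuted_stat(rng) for _ in range(config.n_permutations_null)]
    else:
        observed = _mean_pair_stat(matrix, config, level, statistic, rng=rng)
        permuted = []
        for _ in range(config.n_permutations_null):
            perm = permute_evolved(matrix, rng, mode=permute_mode)
            permuted.append(_mean_pair_stat(perm, config, level, statistic, rng=rng))
    null = NullDistribution(
        statistic=statistic,
        level=level,
        observed_mean=observed,
        permuted_means=permuted,
        n_permutations=config.n_permutations_null,
    )
    log.info(
        "heterogeneity %s/%s: observed %.4f vs null mean %.4f, p=%.3g",
        level, statistic, observed, float(np.mean(permuted)), null.p_plain,
    )
    return null
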
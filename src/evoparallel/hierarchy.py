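"""Cross-level comparison of parallelism: transcriptome vs metabolome.

Gene-level parallelism statistics are biased upward/downward relative to
metabolite-level ones simply by counting many more features, so feature
numbers are equalized by downsampling before the comparison: the
expressed-gene universe is subsampled to the number of detected
metabolites for the correlation statistic, and each population's
significant DE gene set is subsampled to its significant-metabolite
count for the Jaccard statistic.  Downsampling is repeated and averaged
per population pair; the resulting per-pair distributions for the two
molecular levels are then compared with a t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .parallelism import jaccard
from .types import ValidationError

log = logging.getLogger(__name__)


def downsample_pearson(
    fc_table: pd.DataFrame,
    n_target: int,
    reps: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-pair mean correlation of log2FC over random feature subsets.

    Each rep draws ``n_target`` features without replacement, computes all
    pairwise Pearson correlations between population columns, and the
    per-pair values are averaged over reps.
    """
    clean = fc_table.dropna()
    n = len(clean)
    if n_target > n:
        raise ValidationError(f"n_target {n_target} exceeds the {n} available features")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    pops = list(fc_table.columns)
    arr = clean.to_numpy()
    acc = np.zeros((len(pops), len(pops)))
    for _ in range(reps):
        idx = rng.choice(n, size=n_target, replace=False)
        acc += np.corrcoef(arr[idx].T)
    acc /= reps
    rows = [
        {"pop_a": pops[i], "pop_b": pops[j], "pearson_r": acc[i, j]}
        for i, j in combinations(range(len(pops)), 2)
    ]
    return pd.DataFrame(rows)


def _exact_expected_jaccard(set_a: frozenset, set_b: frozenset, ta: int, tb: int) -> float:
    """Expected Jaccard of independent uniform subsamples, by enumeration."""
    total, count = 0.0, 0
    for sub_a in combinations(sorted(set_a), ta):
        for sub_b in combinations(sorted(set_b), tb):
            total += jaccard(sub_a, sub_b)
            count += 1
    return total / count


def downsample_jaccard(
    sig_sets: dict[str, set[str]],
    targets: dict[str, int],
    reps: int,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Per-pair mean Jaccard of subsampled significant-feature sets.

    Each population's set is subsampled uniformly without replacement to
    its target size; pairwise Jaccard indices are averaged over reps.
    ``exhaustive=True`` instead enumerates every subsample pair and
    returns the exact expectation (feasible only for small sets).
    """
    for pop, target in targets.items():
        if target > len(sig_sets[pop]):
            raise ValidationError(
                f"population {pop!r}: target {target} exceeds its "
                f"significant set size {len(sig_sets[pop])}"
            )
        if target < 0:
            raise ValidationError(f"population {pop!r}: negative target")
    pops = list(sig_sets)
    ordered = {pop: sorted(sig_sets[pop]) for pop in pops}

    rows = []
    if exhaustive:
        for pa, pb in combinations(pops, 2):
            rows.append(
                {
                    "pop_a": pa,
                    "pop_b": pb,
                    "jaccard": _exact_expected_jaccard(
                        frozenset(ordered[pa]), frozenset(ordered[pb]), targets[pa], targets[pb]
                    ),
                }
            )
        return pd.DataFrame(rows)

    if rng is None:
        raise ValidationError("Monte-Carlo downsampling requires an rng")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    acc = {pair: 0.0 for pair in combinations(pops, 2)}
    for _ in range(reps):
        subs = {
            pop: set(rng.choice(ordered[pop], size=targets[pop], replace=False))
            if targets[pop] < len(ordered[pop])
            else set(ordered[pop])
            for pop in pops
        }
        for pair in acc:
            acc[pair] += jaccard(subs[pair[0]], subs[pair[1]])
    for (pa, pb), tot in acc.items():
        rows.append({"pop_a": pa, "pop_b": pb, "jaccard": tot / reps})
    return pd.DataFrame(rows)


@dataclass
class LevelComparison:
    """t-test comparing per-pair parallelism between molecular levels."""

    statistic: str  # jaccard | pearson
    gene_values: np.ndarray
    metabolite_values: np.ndarray
    t_statistic: float
    p_value: float
    mean_gene: float
    mean_metabolite: float
    variant: str
    n_downsample_reps: int

    @property
    def metabolome_higher(self) -> bool:
        return self.mean_metabolite > self.mean_gene

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "gene_values": list(map(float, self.gene_values)),
            "metabolite_values": list(map(float, self.metabolite_values)),
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "mean_gene": self.mean_gene,
            "mean_metabolite": self.mean_metabolite,
            "metabolome_higher": self.metabolome_higher,
            "variant": self.variant,
            "n_downsample_reps": self.n_downsample_reps,
        }


def compare_levels(
    gene_values: np.ndarray,
    metabolite_values: np.ndarray,
    statistic: str = "pearson",
    variant: str = "welch",
    n_downsample_reps: int = 0,
) -> LevelComparison:
    """Two-sample t-test of the per-pair parallelism distributions.

    ``variant='welch'`` (default) uses unequal variances; ``'student'``
    the pooled-variance test.  The sign of t follows metabolite - gene.
    """
    g = np.asarray(gene_values, dtype=float)
    m = np.asarray(metabolite_values, dtype=float)
    if len(g) != len(m):
        raise ValidationError("paired per-pair value lists must have equal length")
    if len(g) < 3:
        raise ValidationError("need at least 3 population pairs per level")
    if variant not in ("welch", "student"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    t, p = sps.ttest_ind(m, g, equal_var=(variant == "student"))
    return LevelComparison(
        statistic=statistic,
        gene_values=g,
        metabolite_values=m,
        t_statistic=float(t),
        p_value=float(p),
        mean_gene=float(g.mean()),
        mean_metabolite=float(m.mean()),
        variant=variant,
        n_downsample_reps=n_downsample_reps,
    )


def hierarchy_comparison(
    gene_fc: pd.DataFrame,
    gene_sig_sets: dict[str, set[str]],
    met_fc: pd.DataFrame,
    met_sig_sets: dict[str, set[str]],
    n_downsample_reps: int,
    rng: np.random.Generator,
    variant: str = "welch",
) -> dict[str, LevelComparison]:
    """Full cross-level stage: restrict, equalize by downsampling, test.

    Only populations present at both molecular levels enter.  The gene
    log2FC universe is downsampled to the metabolite-universe size; each
    population's significant gene set is downsampled to its significant-
    metabolite count (clamped, with a warning, if a population has fewer
    significant genes than metabolites).
    """
    common = [p for p in met_fc.columns if p in gene_fc.columns]
    if len(common) < 3:
        raise ValidationError("need at least 3 populations shared between levels")
    gene_fc = gene_fc[common]
    met_fc = met_fc[common]

    # correlation statistic, equalized feature counts
    n_target = len(met_fc.dropna())
    gene_pairs_r = downsample_pearson(gene_fc, n_target, n_downsample_reps, rng)
    met_arr = met_fc.dropna().to_numpy()
    met_corr = np.corrcoef(met_arr.T)
    met_pairs_r = [
        met_corr[i, j] for i, j in combinations(range(len(common)), 2)
    ]
    res_pearson = compare_levels(
        gene_pairs_r["pearson_r"].to_numpy(),
        np.asarray(met_pairs_r),
        statistic="pearson",
        variant=variant,
        n_downsample_reps=n_downsample_reps,
    )

    # Jaccard statistic, equalized significant-set sizes
    targets = {}
    for pop in common:
        n_genes = len(gene_sig_sets.get(pop, set()))
        n_mets = len(met_sig_sets.get(pop, set()))
        if n_mets > n_genes:
            log.warning(
                "population %s: %d significant metabolites but only %d significant "
                "genes; downsampling target clamped", pop, n_mets, n_genes,
            )
        targets[pop] = min(n_mets, n_genes)
    gene_sets_common = {p: gene_sig_sets.get(p, set()) for p in common}
    gene_pairs_j = downsample_jaccard(gene_sets_common, targets, n_downsample_reps, rng)
    met_pairs_j = [
        jaccard(met_sig_sets.get(pa, set()), met_sig_sets.get(pb, set()))
        for pa, pb in combinations(common, 2)
    ]
    res_jaccard = compare_levels(
        gene_pairs_j["jaccard"].to_numpy(),
        np.asarray(met_pairs_j),
        statistic="jaccard",
        variant=variant,
        n_downsample_reps=n_downsample_reps,
    )
    return {"pearson": res_pearson, "jaccard": res_jaccard}
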
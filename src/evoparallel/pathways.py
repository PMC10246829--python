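"""Joint pathway analysis across transcriptome and metabolome.

Per evolved population and pathway, each omic is tested for association
between the pathway's member features and the ancestral/evolved grouping
with a global-test-style quadratic score,

    Q = y_c' X X' y_c / (m * y_c' y_c),

where ``y_c`` is the centered group indicator over the contrast samples
and ``X`` the samples x m matrix of standardized member-feature values.
Significance comes from permuting the group labels (exact in spirit at
eight samples; add-one convention, never exactly zero).  The two omic
p-values are then integrated with Fisher's method, S = -2 * sum(ln p)
against chi-square with 2k degrees of freedom, and Benjamini-Hochberg
adjusted across pathways within each population.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import PathwayAnnotation
from .stats import bh_adjust
from .types import OmicsMatrix, RunConfig, ValidationError

log = logging.getLogger(__name__)


def global_test_stat(values: np.ndarray, y_centered: np.ndarray) -> float:
    """Quadratic score Q for standardized member columns ``values``."""
    m = values.shape[1]
    z = values.T @ y_centered
    return float(z @ z / (m * (y_centered @ y_centered)))


def _standardize_columns(x: np.ndarray) -> np.ndarray | None:
    """Column-standardize; constant columns are dropped with a logged count."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        log.info("global test: dropped %d constant feature columns", int((~keep).sum()))
    if keep.sum() == 0:
        return None
    return (x[:, keep] - mu[keep]) / sd[keep]


def global_test(
    matrix: OmicsMatrix,
    members: frozenset[str] | set[str],
    population: str,
    n_perm: int,
    rng: np.random.Generator,
    min_members: int = 2,
    perm_block: np.ndarray | None = None,
) -> float | None:
    """Permutation p for one pathway in one population's contrast.

    Returns None (pathway skipped) when fewer than ``min_members`` member
    features are present and non-constant in the matrix.  ``perm_block``
    optionally supplies a pre-drawn (n_samples x n_perm) matrix of
    permuted centered indicators so many pathways can share one set of
    relabelings.
    """
    anc = matrix.ancestral_samples()
    evo = matrix.evolved_samples(population)
    samples = anc + evo
    present = [f for f in matrix.feature_ids if f in members]
    if len(present) < min_members:
        log.info("pathway skipped for %s: %d member(s) present < %d", population, len(present), min_members)
        return None
    x = matrix.values.loc[present, samples].to_numpy(dtype=float).T  # samples x m
    x = _standardize_columns(x)
    if x is None or x.shape[1] < min_members:
        log.info("pathway skipped for %s: too few non-constant members", population)
        return None
    y = np.zeros(len(samples))
    y[len(anc):] = 1.0
    y_c = y - y.mean()

    q_obs = global_test_stat(x, y_c)
    if perm_block is None:
        perm_block = permutation_block(y_c, n_perm, rng)
    z = x.T @ perm_block  # m x B
    denom = x.shape[1] * (y_c @ y_c)
    q_perm = (z * z).sum(axis=0) / denom
    k = int((q_perm > q_obs).sum())
    return (k + 1) / (perm_block.shape[1] + 1)


def permutation_block(y_centered: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_perm`` random relabelings of the centered group indicator."""
    n = len(y_centered)
    order = rng.random((n_perm, n)).argsort(axis=1)
    return y_centered[order].T  # n x B


def fisher_combine(p_values: list[float], floor: float | None = None) -> tuple[float, float]:
    """Fisher's method: S = -2 sum(ln p), combined p from chi2 with 2k df.

    With a single p-value the transform is the chi-square(2) identity and
    the input p is returned unchanged (up to floating point).  Zero or
    negative inputs are floored to ``floor`` when given, else rejected.
    """
    ps = []
    for p in p_values:
        if p <= 0.0:
            if floor is None:
                raise ValidationError("fisher_combine requires p in (0, 1]")
            log.warning("fisher_combine: flooring p=%g to %g", p, floor)
            p = floor
        if p > 1.0:
            raise ValidationError("fisher_combine requires p in (0, 1]")
        ps.append(p)
    if not ps:
        raise ValidationError("fisher_combine needs at least one p-value")
    s = -2.0 * float(np.sum(np.log(ps)))
    combined = float(chi2.sf(s, df=2 * len(ps)))
    return s, combined


def joint_pathway_analysis(
    rna_log: OmicsMatrix,
    met_log: OmicsMatrix,
    gene_annotation: PathwayAnnotation,
    met_annotation: PathwayAnnotation,
    config: RunConfig,
    seed: int,
    min_members_gene: int = 2,
    min_members_met: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population joint enrichment over all annotated pathways.

    ``rna_log`` is the expression matrix on a continuous (log-CPM) scale,
    ``met_log`` the detection-filtered log-area matrix.  Only populations
    present at both levels are analyzed.  Single-metabolite pathways are
    tested in the univariate limit of the quadratic score
    (``min_members_met=1``), since the synthetic annotation maps each
    pathway to one metabolite.

    Returns the long result table (population, pathway, p_gene, p_met,
    fisher_s, p_combined, padj, significant) and a shared-pathways summary
    (pathways significant in every population, with the mean adjusted p).
    """
    pops = [p for p in met_log.evolved_populations() if p in rna_log.evolved_populations()]
    if not pops:
        raise ValidationError("no evolved population is present at both omics levels")
    pathway_ids = sorted(set(gene_annotation) | set(met_annotation))
    if not pathway_ids:
        raise ValidationError("no pathways in the annotations")

    rows = []
    for pi, pop in enumerate(pops):
        # one permutation block per (population, omic): shared relabelings
        # across pathways keep the scan fast and comparisons consistent
        rng_g = np.random.default_rng(np.random.SeedSequence([seed, pi, 0]))
        rng_m = np.random.default_rng(np.random.SeedSequence([seed, pi, 1]))
        y_len_g = len(rna_log.ancestral_samples()) + len(rna_log.evolved_samples(pop))
        y_g = np.zeros(y_len_g)
        y_g[len(rna_log.ancestral_samples()):] = 1.0
        block_g = permutation_block(y_g - y_g.mean(), config.n_perm_pathway, rng_g)
        y_len_m = len(met_log.ancestral_samples()) + len(met_log.evolved_samples(pop))
        y_m = np.zeros(y_len_m)
        y_m[len(met_log.ancestral_samples()):] = 1.0
        block_m = permutation_block(y_m - y_m.mean(), config.n_perm_pathway, rng_m)

        for pathway in pathway_ids:
            p_gene = p_met = None
            if pathway in gene_annotation.members:
                p_gene = global_test(
                    rna_log, gene_annotation[pathway], pop,
                    config.n_perm_pathway, rng_g,
                    min_members=min_members_gene, perm_block=block_g,
                )
            if pathway in met_annotation.members:
                p_met = global_test(
                    met_log, met_annotation[pathway], pop,
                    config.n_perm_pathway, rng_m,
                    min_members=min_members_met, perm_block=block_m,
                )
            present = [p for p in (p_gene, p_met) if p is not None]
            if not present:
                continue
            s, combined = fisher_combine(present, floor=1.0 / (config.n_perm_pathway + 1))
            rows.append(
                {
                    "population": pop,
                    "pathway": pathway,
                    "p_gene": np.nan if p_gene is None else p_gene,
                    "p_met": np.nan if p_met is None else p_met,
                    "n_omics": len(present),
                    "fisher_s": s,
                    "p_combined": combined,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValidationError("all pathways were skipped in all populations")

    adj = []
    for pop, grp in table.groupby("population", sort=False):
        padj = bh_adjust(grp["p_combined"].to_numpy())
        adj.append(pd.Series(padj, index=grp.index))
    table["padj"] = pd.concat(adj).sort_index()
    table["significant"] = table["padj"] < config.fdr_threshold

    sig_per_pop = {
        pop: set(grp.loc[grp["significant"], "pathway"])
        for pop, grp in table.groupby("population", sort=False)
    }
    shared = set.intersection(*sig_per_pop.values()) if sig_per_pop else set()
    shared_rows = []
    for pathway in sorted(shared):
        sub = table[table["pathway"] == pathway]
        shared_rows.append(
            {
                "pathway": pathway,
                "mean_padj": float(sub["padj"].mean()),
                "n_populations": int(sub["significant"].sum()),
            }
        )
    shared_table = pd.DataFrame(shared_rows, columns=["pathway", "mean_padj", "n_populations"])
    log.info(
        "joint pathway analysis: %d pathways significant in every one of %d populations",
        len(shared), len(pops),
    )
    return table, shared_table
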
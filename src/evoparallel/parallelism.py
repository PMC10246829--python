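"""Parallelism statistics across replicate evolved populations.

Two complementary measures quantify how similar the evolutionary response
of two populations is:

* the Jaccard index JI = |A ∩ B| / |A ∪ B| over their significant-feature
  sets (cutoff-dependent, set-based), and
* Pearson's correlation of their log2 fold-change vectors over the full
  tested feature universe (cutoff-free, quantitative).

Both are computed for every pair of populations, C(P, 2) pairs in total.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import OmicsMatrix

log = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


def jaccard(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Jaccard index of two feature sets; both-empty is 0 by convention."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        log.warning("jaccard of two empty sets; returning 0")
        return 0.0
    return len(a & b) / len(union)


def log2fc(
    matrix: OmicsMatrix | pd.DataFrame,
    evolved: Sequence[str],
    ancestral: Sequence[str],
    pseudocount: float = 0.0,
    value_kind: str | None = None,
) -> pd.Series:
    """Per-feature log2 fold change of evolved over ancestral group means.

    For abundance-scale values (counts/CPM/areas) this is
    log2((mean_evo + c) / (mean_anc + c)) with pseudocount ``c``; c = 0
    recovers the plain ratio of means and yields NaN when both means are
    zero.  For log-scale values (natural-log areas) the equivalent is the
    difference of group means divided by ln 2 — the log2 ratio of
    geometric means — and the pseudocount does not apply.
    """
    if not len(evolved) or not len(ancestral):
        raise ValueError("both groups must be nonempty")
    if isinstance(matrix, OmicsMatrix):
        values = matrix.values
        value_kind = value_kind or matrix.value_kind
    else:
        values = matrix
        value_kind = value_kind or "cpm"

    mean_evo = values[list(evolved)].mean(axis=1)
    mean_anc = values[list(ancestral)].mean(axis=1)
    if value_kind == "log_area":
        return (mean_evo - mean_anc) / LN2
    num = mean_evo + pseudocount
    den = mean_anc + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(num / den)
    out[(num == 0) & (den == 0)] = np.nan
    n_missing = int(out.isna().sum())
    if n_missing:
        log.info("log2fc: %d features undefined (both group means zero)", n_missing)
    return out


def log2fc_table(matrix: OmicsMatrix, pseudocount: float = 0.0) -> pd.DataFrame:
    """log2 fold change of every evolved population vs the ancestral group."""
    anc = matrix.ancestral_samples()
    cols = {
        pop: log2fc(matrix, matrix.evolved_samples(pop), anc, pseudocount)
        for pop in matrix.evolved_populations()
    }
    return pd.DataFrame(cols, index=matrix.values.index)


def pairwise_parallelism(
    sig_sets: Mapping[str, Iterable[str]] | None = None,
    fc_table: pd.DataFrame | None = None,
    level: str = "transcriptome",
    mode: str = "both",
) -> pd.DataFrame:
    """Jaccard and/or Pearson parallelism for all population pairs.

    Parameters
    ----------
    sig_sets
        Per-population significant feature sets (required for jaccard).
    fc_table
        Features x populations log2FC table (required for pearson);
        rows with missing values are dropped pairwise with a logged count.
    mode
        ``jaccard``, ``pearson`` or ``both``.

    Returns a DataFrame with one row per unordered pair, columns
    ``level, pop_a, pop_b, jaccard, pearson_r, n_intersection, n_union,
    n_features``.
    """
    if mode not in ("jaccard", "pearson", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    want_j = mode in ("jaccard", "both")
    want_r = mode in ("pearson", "both")
    if want_j and sig_sets is None:
        raise ValueError("jaccard mode requires sig_sets")
    if want_r and fc_table is None:
        raise ValueError("pearson mode requires fc_table")

    pops: list[str]
    if fc_table is not None:
        pops = list(fc_table.columns)
    else:
        pops = list(sig_sets)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")

    rows = []
    for pop_a, pop_b in itertools.combinations(pops, 2):
        row = {
            "level": level,
            "pop_a": pop_a,
            "pop_b": pop_b,
            "jaccard": np.nan,
            "pearson_r": np.nan,
            "n_intersection": np.nan,
            "n_union": np.nan,
            "n_features": np.nan,
        }
        if want_j:
            a, b = set(sig_sets[pop_a]), set(sig_sets[pop_b])
            row["jaccard"] = jaccard(a, b)
            row["n_intersection"] = len(a & b)
            row["n_union"] = len(a | b)
        if want_r:
            sub = fc_table[[pop_a, pop_b]].dropna()
            dropped = len(fc_table) - len(sub)
            if dropped:
                log.info("pearson %s-%s: dropped %d rows with missing log2FC", pop_a, pop_b, dropped)
            row["n_features"] = len(sub)
            x = sub[pop_a].to_numpy()
            y = sub[pop_b].to_numpy()
            if len(sub) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
                log.warning("pearson %s-%s undefined (constant vector)", pop_a, pop_b)
            else:
                row["pearson_r"] = float(np.corrcoef(x, y)[0, 1])
        rows.append(row)
    return pd.DataFrame(rows)
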
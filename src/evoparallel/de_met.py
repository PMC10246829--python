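"""Per-population differential abundance of metabolites.

The contrast per metabolite is tiny — five ancestral and three evolved
replicate values — so significance comes from a group-reassignment
permutation test on the log-transformed areas: the eight observations are
reassigned into groups of five and three, and the p-value is the
proportion of reassignments whose absolute mean difference exceeds the
observed one.  Only C(8,3) = 56 distinct reassignments exist, so the
exact (exhaustive) test is the default; a random-sampling mode with a
configurable number of reassignments reproduces the sampled variant.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .parallelism import log2fc
from .stats import bh_adjust
from .types import OmicsMatrix, RunConfig, ValidationError

log = logging.getLogger(__name__)


def log_transform_filter(
    areas: OmicsMatrix, floor: float, base: str = "natural"
) -> OmicsMatrix:
    """Log-transform raw areas if needed and apply the detection floor.

    A metabolite is kept only when its log value strictly exceeds
    ``floor`` in every sample ("detected in all samples").  Matrices that
    are already log-scale (``value_kind='log_area'``) are filtered as-is;
    raw-area matrices are log-transformed first, with non-positive areas
    excluded (they cannot be log-transformed, and the affected metabolite
    fails the all-samples detection rule).
    """
    if floor < 0:
        raise ValidationError("detection floor must be >= 0")
    if areas.value_kind == "log_area":
        vals = areas.values
    elif areas.value_kind == "area":
        raw = areas.values.to_numpy(dtype=float)
        n_bad = int((raw <= 0).sum())
        if n_bad:
            log.warning("log transform: %d non-positive areas excluded", n_bad)
        with np.errstate(divide="ignore", invalid="ignore"):
            logged = np.log(np.where(raw > 0, raw, np.nan))
        if base == "log2":
            logged = logged / np.log(2.0)
        vals = pd.DataFrame(logged, index=areas.values.index, columns=areas.values.columns)
    else:
        raise ValidationError("log_transform_filter expects area or log_area values")
    detected = (vals > floor).all(axis=1)
    kept = list(vals.index[detected])
    log.info("detection filter (> %g in all samples): kept %d / %d metabolites", floor, len(kept), len(vals))
    out = OmicsMatrix(vals.loc[kept].copy(), areas.meta, "log_area")
    return out


def _reassignment_masks(n_total: int, n_evo: int) -> np.ndarray:
    """Boolean masks (n_assignments x n_total), True marks the evolved slot."""
    masks = np.zeros((comb(n_total, n_evo), n_total), dtype=bool)
    for i, idx in enumerate(combinations(range(n_total), n_evo)):
        masks[i, list(idx)] = True
    return masks


def perm_test_metabolites(
    values: np.ndarray,
    n_anc: int,
    mode: str = "exhaustive",
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Group-reassignment test for each row of ``values``.

    ``values`` is metabolites x observations with the ancestral replicates
    in the first ``n_anc`` columns and the evolved replicates after them.
    Returns columns ``obs_diff`` (mean evolved - mean ancestral),
    ``p_raw`` (the plain exceedance proportion) and ``pvalue`` (floored so
    downstream FDR adjustment never sees an exact zero: 1/(n_assignments+1)
    exhaustively, 1/(n_perm+1) in random mode).  Rows with zero variance
    across all observations get p = 1 by convention.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_total = values.shape[1]
    n_evo = n_total - n_anc
    if n_evo < 1 or n_anc < 1:
        raise ValidationError("need at least one observation per group")

    obs = values[:, n_anc:].mean(axis=1) - values[:, :n_anc].mean(axis=1)

    masks = _reassignment_masks(n_total, n_evo)
    if mode == "exhaustive":
        chosen = masks
        floor = 1.0 / (masks.shape[0] + 1)
    elif mode == "random":
        if n_perm < 1:
            raise ValidationError("n_perm must be >= 1 in random mode")
        if rng is None:
            raise ValidationError("random mode requires an rng")
        chosen = masks[rng.integers(0, masks.shape[0], size=n_perm)]
        floor = 1.0 / (n_perm + 1)
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    # null mean differences for every reassignment at once
    evo_means = values @ chosen.T.astype(float) / n_evo
    anc_means = values @ (~chosen).T.astype(float) / n_anc
    null = evo_means - anc_means
    # strict exceedance with a scaled tolerance so the observed split never
    # counts against itself through floating-point rounding
    tol = 1e-9 * (1.0 + np.abs(obs))[:, None]
    p_raw = (np.abs(null) > np.abs(obs)[:, None] + tol).mean(axis=1)

    constant = np.ptp(values, axis=1) == 0
    p_raw = np.where(constant, 1.0, p_raw)
    pvalue = np.maximum(p_raw, floor)
    pvalue = np.where(constant, 1.0, pvalue)
    return pd.DataFrame({"obs_diff": obs, "p_raw": p_raw, "pvalue": pvalue})


def perm_test_metabolite(
    ancestral: np.ndarray,
    evolved: np.ndarray,
    mode: str = "exhaustive",
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Single-metabolite convenience wrapper: (observed difference, p)."""
    vals = np.concatenate([np.asarray(ancestral, float), np.asarray(evolved, float)])
    res = perm_test_metabolites(vals[None, :], len(ancestral), mode, n_perm, rng)
    return float(res["obs_diff"].iloc[0]), float(res["pvalue"].iloc[0])


def met_de_call(
    areas: OmicsMatrix,
    config: RunConfig,
    rng: np.random.Generator | None = None,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Permutation differential-abundance test for every evolved population.

    Returns a long table ``population, feature_id, log2fc, obs_diff,
    pvalue, padj, significant`` over the shared detected-metabolite
    universe.  ``prefiltered`` skips the detection filter when the caller
    already applied it.
    """
    mat = areas if prefiltered else log_transform_filter(areas, config.met_detection_floor)
    pops = mat.evolved_populations()
    if not pops:
        raise ValidationError("no evolved populations in metabolite metadata")
    anc = mat.ancestral_samples()

    if config.n_permutations_met_test == "exhaustive":
        mode, n_perm = "exhaustive", 0
    else:
        mode, n_perm = "random", int(config.n_permutations_met_test)

    frames = []
    for pop in pops:
        evo = mat.evolved_samples(pop)
        if len(evo) < 2:
            raise ValidationError(f"population {pop!r} has fewer than 2 replicates")
        vals = mat.values[anc + evo].to_numpy(dtype=float)
        res = perm_test_metabolites(vals, len(anc), mode, n_perm, rng)
        fc = log2fc(mat, evo, anc)
        padj = bh_adjust(res["pvalue"].to_numpy())
        sig = (padj < config.fdr_threshold) & ~np.isnan(padj)
        frames.append(
            pd.DataFrame(
                {
                    "population": pop,
                    "feature_id": mat.feature_ids,
                    "log2fc": fc.to_numpy(),
                    "obs_diff": res["obs_diff"].to_numpy(),
                    "pvalue": res["pvalue"].to_numpy(),
                    "padj": padj,
                    "significant": sig,
                }
            )
        )
        log.info("metabolite DE %s: %d significant (FDR < %g)", pop, int(sig.sum()), config.fdr_threshold)
    return pd.concat(frames, ignore_index=True)
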
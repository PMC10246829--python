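"""End-to-end pipeline: chains every analysis stage and writes one
output table per stage plus a JSON run manifest.

Stage order: expression filter + per-population DE (RNA), metabolite
detection filter + permutation DE, pairwise parallelism at both levels,
heterogeneity permutation nulls, downsampling-equalized cross-level
comparison, joint pathway analysis.  A single master seed derives
independent per-stage generators, so identical config + seed gives
byte-identical outputs and stages can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, de_met, de_rna, hierarchy, pathways
from .heterogeneity import heterogeneity_test
from .io import PathwayAnnotation, write_table
from .parallelism import log2fc_table, pairwise_parallelism
from .types import OmicsMatrix, RunConfig, ValidationError, stage_rng

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineInputs:
    counts: OmicsMatrix | None = None
    metabolites: OmicsMatrix | None = None
    gene_annotation: PathwayAnnotation | None = None
    met_annotation: PathwayAnnotation | None = None


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - reraised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
        return out

    return wrap


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(
    config: RunConfig,
    inputs: PipelineInputs,
    outdir: str | Path,
    stages: tuple[str, ...] = (
        "de_rna", "de_met", "parallelism", "null_test", "hierarchy", "pathways",
    ),
    null_statistics: tuple[str, ...] = ("mean_jaccard", "mean_pearson"),
) -> dict[str, Path]:
    """Execute the selected stages in order; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    want = set(stages)
    if "pathways" in want and (
        inputs.metabolites is None
        or inputs.gene_annotation is None
        or inputs.met_annotation is None
    ):
        raise ValidationError(
            "pathway stage enabled but metabolite matrix or annotations missing"
        )
    if {"de_rna", "parallelism", "null_test", "hierarchy"} & want and inputs.counts is None:
        raise ValidationError("count matrix required for the requested stages")
    if {"de_met", "hierarchy"} & want and inputs.metabolites is None:
        raise ValidationError("metabolite matrix required for the requested stages")

    de_table = met_table = None
    met_filtered = None
    if inputs.metabolites is not None:
        met_filtered = _stage("met_filter")(
            de_met.log_transform_filter, inputs.metabolites, config.met_detection_floor
        )

    if "de_rna" in want:
        de_table = _stage("de_rna")(de_rna.de_call, inputs.counts, config)
        paths["de_rna"] = outdir / "de_rna.tsv"
        write_table(de_table, paths["de_rna"])

    if "de_met" in want:
        met_table = _stage("de_met")(
            de_met.met_de_call, met_filtered, config,
            rng=stage_rng(config.rng_seed, "de_met"), prefiltered=True,
        )
        paths["de_met"] = outdir / "de_met.tsv"
        write_table(met_table, paths["de_met"])

    if "parallelism" in want:
        if de_table is None:
            raise ValidationError("parallelism stage requires the de_rna stage")
        frames = []
        sets_rna = de_rna.significant_sets(de_table)
        fc_rna = de_rna.fc_matrix(de_table)[inputs.counts.evolved_populations()]
        frames.append(
            _stage("parallelism")(
                pairwise_parallelism, sig_sets=sets_rna, fc_table=fc_rna,
                level="transcriptome", mode="both",
            )
        )
        if met_table is not None:
            sets_met = de_rna.significant_sets(met_table)
            fc_met = de_rna.fc_matrix(met_table)[met_filtered.evolved_populations()]
            frames.append(
                pairwise_parallelism(
                    sig_sets=sets_met, fc_table=fc_met, level="metabolome", mode="both"
                )
            )
        paths["parallelism"] = outdir / "parallelism.tsv"
        write_table(pd.concat(frames, ignore_index=True), paths["parallelism"])

    if "null_test" in want:
        rng = stage_rng(config.rng_seed, "null_test")
        results = []
        for statistic in null_statistics:
            results.append(
                _stage("null_test")(
                    heterogeneity_test, inputs.counts, config,
                    "transcriptome", statistic, rng,
                ).to_dict()
            )
            if met_filtered is not None:
                results.append(
                    heterogeneity_test(
                        met_filtered, config, "metabolome", statistic, rng
                    ).to_dict()
                )
        paths["null_test"] = outdir / "null_test.json"
        _json_dump({"seed": config.rng_seed, "tests": results}, paths["null_test"])

    if "hierarchy" in want:
        if de_table is None or met_table is None:
            raise ValidationError("hierarchy stage requires both DE stages")
        rng = stage_rng(config.rng_seed, "hierarchy")
        res = _stage("hierarchy")(
            hierarchy.hierarchy_comparison,
            de_rna.fc_matrix(de_table)[inputs.counts.evolved_populations()],
            de_rna.significant_sets(de_table),
            de_rna.fc_matrix(met_table)[met_filtered.evolved_populations()],
            de_rna.significant_sets(met_table),
            config.n_downsample_reps,
            rng,
        )
        paths["hierarchy"] = outdir / "hierarchy.json"
        _json_dump({k: v.to_dict() for k, v in res.items()}, paths["hierarchy"])

    if "pathways" in want:
        cpm = de_rna.cpm_normalize(inputs.counts)
        _, cpm_f = de_rna.filter_expressed(cpm, config.cpm_filter, config.filter_mode)
        rna_log = cpm_f.with_values(
            np.log2(cpm_f.values + config.pseudocount), value_kind="cpm"
        )
        table, shared = _stage("pathways")(
            pathways.joint_pathway_analysis,
            rna_log, met_filtered,
            inputs.gene_annotation, inputs.met_annotation,
            config, seed=config.rng_seed,
        )
        paths["pathways"] = outdir / "pathways.tsv"
        paths["pathways_shared"] = outdir / "pathways_shared.tsv"
        write_table(table, paths["pathways"])
        write_table(shared, paths["pathways_shared"])

    manifest = {
        "package": "evoparallel",
        "version": __version__,
        "seed": config.rng_seed,
        "config": config.to_dict(),
        "stages": sorted(want),
        "outputs": {k: str(v.name) for k, v in paths.items()},
    }
    paths["manifest"] = outdir / "manifest.json"
    _json_dump(manifest, paths["manifest"])
    return paths
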
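"""Readers and writers for the tabular formats used by the pipeline.

TSV for matrices and metadata, GMT for pathway membership, YAML for run
configuration.  Matrix TSVs carry the feature id in the first column and
one column per sample; metadata TSVs carry ``sample_id, population, role,
replicate``.  All writers emit numbers at 6 significant digits so repeated
runs are byte-comparable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .types import (
    META_COLUMNS,
    OmicsMatrix,
    RunConfig,
    SchemaError,
    ValidationError,
    ValueKind,
)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


class PathwayAnnotation:
    """Mapping pathway id -> member feature set, with descriptions."""

    def __init__(
        self,
        members: Mapping[str, frozenset[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        for pid, mem in members.items():
            if not mem:
                raise ValidationError(f"pathway {pid!r} has no members")
        self.members: dict[str, frozenset[str]] = {
            pid: frozenset(mem) for pid, mem in members.items()
        }
        self.descriptions = dict(descriptions or {})

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, pathway_id: str) -> frozenset[str]:
        return self.members[pathway_id]

    def items(self):
        return self.members.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, PathwayAnnotation) and self.members == other.members


def read_omics_matrix(
    path_values: str | Path, path_meta: str | Path, value_kind: ValueKind
) -> OmicsMatrix:
    """Load a value matrix and its sample metadata, cross-validating the two.

    The matrix columns are reordered to the metadata row order, so sample
    bookkeeping downstream follows the metadata file.
    """
    values = pd.read_csv(path_values, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    meta = pd.read_csv(path_meta, sep="\t", dtype={"sample_id": str, "population": str})
    missing_cols = set(META_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise SchemaError(f"metadata is missing columns {sorted(missing_cols)}")
    meta = meta.set_index("sample_id", drop=False)

    matrix_samples = set(values.columns)
    meta_samples = set(meta["sample_id"])
    if matrix_samples != meta_samples:
        only_meta = sorted(meta_samples - matrix_samples)
        only_matrix = sorted(matrix_samples - meta_samples)
        raise SchemaError(
            "sample ids disagree between matrix and metadata "
            f"(metadata only: {only_meta[:5]}, matrix only: {only_matrix[:5]})"
        )
    values = values[list(meta["sample_id"])]
    return OmicsMatrix(values=values, meta=meta, value_kind=value_kind)


def write_omics_matrix(matrix: OmicsMatrix, path_values: str | Path, path_meta: str | Path) -> None:
    if matrix.value_kind == "counts":
        matrix.values.astype("int64").to_csv(path_values, sep="\t", index_label="feature_id")
    else:
        matrix.values.to_csv(
            path_values, sep="\t", index_label="feature_id", float_format=FLOAT_FMT
        )
    matrix.meta[list(META_COLUMNS)].to_csv(path_meta, sep="\t", index=False)


def read_gmt(path: str | Path) -> PathwayAnnotation:
    """Parse a GMT file: one pathway per line: id, description, members..."""
    members: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: pathway line has no members"
                )
            pid, desc, *mem = parts
            mem = [m for m in mem if m]
            if not mem:
                raise ValidationError(f"{path}:{lineno}: pathway {pid!r} has no members")
            if pid in members:
                raise ValidationError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            members[pid] = frozenset(mem)
            descriptions[pid] = desc
    return PathwayAnnotation(members, descriptions)


def write_gmt(annotation: PathwayAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in annotation:
            desc = annotation.descriptions.get(pid, "")
            mem = "\t".join(sorted(annotation[pid]))
            fh.write(f"{pid}\t{desc}\t{mem}\n")


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(raw)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with 6-significant-digit floats."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
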
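"""Core containers: sample metadata, omics matrices, and run configuration.

An :class:`OmicsMatrix` couples a features x samples value table with
per-sample metadata (population label, ancestral/evolved role, replicate
number).  It is the single in-memory currency passed between pipeline
stages; every stage validates the pieces it relies on rather than trusting
the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

ANCESTRAL = "ancestral"
EVOLVED = "evolved"

ValueKind = Literal["counts", "cpm", "area", "log_area"]

META_COLUMNS = ("sample_id", "population", "role", "replicate")


class SchemaError(ValueError):
    """Input files disagree with each other or with the declared schema."""


class ValidationError(ValueError):
    """A container violates one of its invariants."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one biological sample."""

    sample_id: str
    population: str
    role: str
    replicate: int

    def __post_init__(self) -> None:
        if self.role not in (ANCESTRAL, EVOLVED):
            raise ValidationError(
                f"sample {self.sample_id!r}: role must be "
                f"'{ANCESTRAL}' or '{EVOLVED}', got {self.role!r}"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )


def meta_frame(samples: Iterable[SampleMeta]) -> pd.DataFrame:
    """Tabulate SampleMeta records into the canonical metadata frame."""
    rows = [(s.sample_id, s.population, s.role, s.replicate) for s in samples]
    df = pd.DataFrame(rows, columns=list(META_COLUMNS))
    return df.set_index("sample_id", drop=False)


@dataclass
class OmicsMatrix:
    """Features x samples abundance table with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, one column per sample id, in the
        same order as ``meta``.
    meta
        DataFrame with columns ``sample_id, population, role, replicate``,
        indexed by sample_id.
    value_kind
        ``counts`` (non-negative integers), ``cpm`` (library-normalized),
        ``area`` (raw normalized peak areas) or ``log_area``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    value_kind: ValueKind

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if list(self.values.columns) != list(self.meta["sample_id"]):
            raise SchemaError(
                "sample columns of the value matrix do not match the "
                "metadata sample_id order"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature ids: {list(dups[:5])!r}")
        if self.meta["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        if self.values.index.isna().any():
            raise ValidationError("missing feature ids")
        bad_role = set(self.meta["role"]) - {ANCESTRAL, EVOLVED}
        if bad_role:
            raise ValidationError(f"unknown sample roles: {sorted(bad_role)}")
        if self.value_kind == "counts":
            arr = self.values.to_numpy()
            if np.any(arr < 0):
                raise ValidationError("negative values in a counts matrix")
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("non-integer values in a counts matrix")
        for pop, grp in self.meta.groupby(["population", "role"], sort=False):
            if len(grp) < 1:
                raise ValidationError(f"empty sample group {pop}")

    # -- convenience accessors -----------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta["sample_id"])

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def ancestral_samples(self) -> list[str]:
        return list(self.meta.loc[self.meta["role"] == ANCESTRAL, "sample_id"])

    def evolved_samples(self, population: str | None = None) -> list[str]:
        mask = self.meta["role"] == EVOLVED
        if population is not None:
            mask &= self.meta["population"] == population
        return list(self.meta.loc[mask, "sample_id"])

    def evolved_populations(self) -> list[str]:
        evo = self.meta.loc[self.meta["role"] == EVOLVED, "population"]
        return list(dict.fromkeys(evo))  # first-seen order, no duplicates

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[list(feature_ids)].copy(), self.meta, self.value_kind)

    def with_values(self, values: pd.DataFrame, value_kind: ValueKind | None = None) -> "OmicsMatrix":
        return OmicsMatrix(values, self.meta, value_kind or self.value_kind)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide thresholds, permutation sizes, and the master seed.

    ``n_permutations_met_test`` may be the string ``"exhaustive"`` (default):
    the 5-vs-3 metabolite contrast has only C(8,3) = 56 distinct group
    reassignments, so the exact test costs nothing extra.
    """

    fdr_threshold: float = 0.05
    n_permutations_null: int = 100
    n_permutations_met_test: int | str = "exhaustive"
    n_downsample_reps: int = 100
    cpm_filter: float = 0.1
    met_detection_floor: float = 10.0
    pseudocount: float = 0.5
    n_perm_pathway: int = 1000
    filter_mode: str = "mean"  # "mean" or "min" CPM across samples
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValidationError("fdr_threshold must be in (0, 1)")
        if self.n_permutations_null < 1:
            raise ValidationError("n_permutations_null must be >= 1")
        if self.n_downsample_reps < 1:
            raise ValidationError("n_downsample_reps must be >= 1")
        if self.cpm_filter < 0 or self.met_detection_floor < 0:
            raise ValidationError("thresholds must be non-negative")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be non-negative")
        if isinstance(self.n_permutations_met_test, str):
            if self.n_permutations_met_test != "exhaustive":
                raise ValidationError(
                    "n_permutations_met_test must be an integer or 'exhaustive'"
                )
        elif self.n_permutations_met_test < 1:
            raise ValidationError("n_permutations_met_test must be >= 1")
        if self.filter_mode not in ("mean", "min"):
            raise ValidationError("filter_mode must be 'mean' or 'min'")

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed.

    Stage names are hashed into SeedSequence spawn keys so each stage can be
    re-run in isolation with the draws it would have seen in a full run.
    """
    key = np.frombuffer(stage.encode("utf8"), dtype=np.uint8)
    return np.random.default_rng(np.random.SeedSequence([seed, *key.tolist()]))
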
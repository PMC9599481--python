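"""Core data containers shared by every pipeline stage.

A :class:`QuantTable` is a wide concentration matrix (samples x features)
plus per-feature metadata describing which omics layer each feature belongs
to.  A :class:`GroupDesign` maps samples to study groups and fixes the
reference (control) group used by all downstream comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical study group labels, in reporting order.
GROUPS: tuple[str, ...] = ("HC", "HT", "HL", "HG", "NL")

#: Lipid class codes accepted in feature metadata.
LIPID_CLASSES: tuple[str, ...] = (
    "CE", "CER", "DAG", "FFA", "HCER", "LCER",
    "LPC", "LPE", "PC", "PE", "SM", "TAG",
)

LAYERS = ("lipid", "protein")


class TableError(ValueError):
    """Raised when a table or design violates its structural contract."""


@dataclass
class QuantTable:
    """Samples x features concentration matrix with feature metadata.

    Parameters
    ----------
    values :
        DataFrame indexed by sample id with one column per feature.
        ``NaN`` encodes a missing measurement; observed values must be
        nonnegative (zeroes count as observed).
    feature_meta :
        DataFrame indexed by feature id with columns ``layer``
        (``lipid``/``protein``), ``lipid_class`` (class code for lipids,
        empty for proteins) and ``units``.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.values
        meta = self.feature_meta
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise TableError(f"duplicate sample ids: {dups}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].tolist()
            raise TableError(f"duplicate feature ids: {dups}")
        missing_meta = [f for f in values.columns if f not in meta.index]
        if missing_meta:
            raise TableError(f"features absent from metadata: {missing_meta}")
        for col in ("layer", "lipid_class", "units"):
            if col not in meta.columns:
                raise TableError(f"feature metadata lacks column {col!r}")
        bad_layer = meta.loc[~meta["layer"].isin(LAYERS)]
        if len(bad_layer):
            raise TableError(
                f"unknown layer for features {bad_layer.index.tolist()}"
            )
        lipids = meta.loc[meta["layer"] == "lipid"]
        no_class = lipids.loc[
            ~lipids["lipid_class"].isin(LIPID_CLASSES)
        ]
        if len(no_class):
            raise TableError(
                f"lipid features without a valid class: {no_class.index.tolist()}"
            )
        arr = values.to_numpy(dtype=float, copy=False)
        if np.nanmin(arr, initial=0.0) < 0:
            bad = values.columns[(values < 0).any(axis=0)].tolist()
            raise TableError(f"negative concentrations in features: {bad}")
        # keep metadata aligned and restricted to the table's features;
        # normalize axis names so IO round-trips are exact
        self.values.index.name = "sample_id"
        self.values.columns.name = None
        self.feature_meta = meta.loc[values.columns]
        self.feature_meta.index.name = "feature_id"

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def layer_features(self, layer: str) -> list[str]:
        """Feature ids belonging to one omics layer."""
        if layer not in LAYERS:
            raise TableError(f"unknown layer {layer!r}")
        mask = self.feature_meta["layer"] == layer
        return list(self.feature_meta.index[mask])

    @property
    def lipid_features(self) -> list[str]:
        return self.layer_features("lipid")

    @property
    def protein_features(self) -> list[str]:
        return self.layer_features("protein")

    def lipid_class_of(self, feature: str) -> str:
        return str(self.feature_meta.loc[feature, "lipid_class"])

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of missing cells."""
        return self.values.isna().mean(axis=0)

    def subset_features(self, features: Sequence[str]) -> "QuantTable":
        return QuantTable(
            self.values.loc[:, list(features)].copy(),
            self.feature_meta.loc[list(features)].copy(),
        )

    def subset_samples(self, samples: Sequence[str]) -> "QuantTable":
        return QuantTable(
            self.values.loc[list(samples)].copy(),
            self.feature_meta.copy(),
        )

    def copy(self) -> "QuantTable":
        return QuantTable(self.values.copy(), self.feature_meta.copy())

    def equals(self, other: "QuantTable") -> bool:
        return self.values.equals(other.values) and self.feature_meta.equals(
            other.feature_meta
        )


@dataclass
class GroupDesign:
    """Sample-to-group assignment with a designated reference group."""

    assignment: pd.Series  # index sample id -> group label
    reference: str = "NL"

    def __post_init__(self) -> None:
        if isinstance(self.assignment, Mapping):
            self.assignment = pd.Series(self.assignment)
        self.assignment = self.assignment.astype(str)
        if self.assignment.index.duplicated().any():
            raise TableError("duplicate sample ids in design")
        if self.reference not in set(self.assignment):
            raise TableError(
                f"reference group {self.reference!r} has no samples"
            )
        if (self.assignment == self.reference).sum() < 2:
            raise TableError("reference group needs at least 2 samples")

    @property
    def groups(self) -> list[str]:
        """Group labels, canonical order first, then any extras sorted."""
        present = set(self.assignment)
        ordered = [g for g in GROUPS if g in present]
        ordered += sorted(present - set(GROUPS))
        return ordered

    @property
    def non_reference_groups(self) -> list[str]:
        return [g for g in self.groups if g != self.reference]

    def samples_in(self, group: str) -> list[str]:
        return list(self.assignment.index[self.assignment == group])

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.samples_in(g)) for g in self.groups}

    @property
    def n_samples(self) -> int:
        return len(self.assignment)

    def check_table(self, table: QuantTable) -> None:
        """Every table sample must be assigned to a group."""
        unassigned = [s for s in table.sample_ids if s not in self.assignment.index]
        if unassigned:
            raise TableError(f"samples not in design: {unassigned}")


def design_total(design: GroupDesign | Mapping[str, int]) -> int:
    """Total cohort size from a design or a group->count mapping."""
    if isinstance(design, GroupDesign):
        return design.n_samples
    return int(sum(design.values()))
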
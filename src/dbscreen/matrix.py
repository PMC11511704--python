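"""Core in-memory containers for DBS proteome data.

All tabular data ride on pandas: a quantification matrix is a float
DataFrame with protein symbols on the index and sample identifiers on the
columns.  Two kinds of "no number here" are distinguished throughout the
package:

* ``MISSING`` — the protein was simply not quantified in that sample
  (a NaN cell whose ``below_lod`` mask entry is False);
* ``BELOW_LOD`` — the instrument reported the protein under its limit of
  detection (a NaN cell whose ``below_lod`` mask entry is True).  A
  below-LOD observation is still an observation: the screening rules flag
  it, and the clinical reference table prints it as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

GROUPS = ("healthy_newborn", "healthy_adult", "patient")
ONSET_STATES = ("pre_symptomatic", "post_onset", "not_applicable")

#: transform states a NormalizedMatrix can be in
TRANSFORM_STATES = ("percent_actb", "log2", "zscore")


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


def _check_unique(labels: Iterable[str], what: str) -> None:
    labels = pd.Index(labels)
    if labels.has_duplicates:
        dupes = sorted(labels[labels.duplicated()].unique())
        raise ValidationError(f"duplicate {what} identifier(s): {dupes}")


def _empty_mask(values: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(False, index=values.index, columns=values.columns)


@dataclass
class AbundanceMatrix:
    """Raw protein x sample quantification with peptide-evidence counts.

    Parameters
    ----------
    intensities
        Float DataFrame, proteins on the index, samples on the columns.
        NaN encodes an absent value; which kind is told by ``below_lod``.
    peptide_counts
        Integer Series indexed like ``intensities`` (identified peptides
        supporting each protein).
    below_lod
        Optional boolean mask of the same shape; True marks cells censored
        at the detection limit.  Defaults to all-False.
    """

    intensities: pd.DataFrame
    peptide_counts: pd.Series
    below_lod: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.below_lod is None:
            self.below_lod = _empty_mask(self.intensities)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        _check_unique(self.intensities.index, "protein")
        _check_unique(self.intensities.columns, "sample")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            bad = self.intensities.stack()
            bad = bad[bad < 0]
            raise ValidationError(
                f"negative intensity for {list(bad.index[:5])}"
            )
        if not self.peptide_counts.index.equals(self.intensities.index):
            raise ValidationError(
                "peptide_counts must be indexed by the same proteins as the matrix"
            )
        if (self.peptide_counts < 0).any():
            raise ValidationError("peptide counts must be non-negative")
        if self.below_lod.shape != self.intensities.shape:
            raise ValidationError("below_lod mask shape mismatch")
        # censored cells carry no numeric value
        if np.isfinite(vals[self.below_lod.to_numpy(bool)]).any():
            raise ValidationError("BELOW_LOD cells must not carry a numeric value")

    # -- conveniences ----------------------------------------------------
    @property
    def proteins(self) -> pd.Index:
        return self.intensities.index

    @property
    def samples(self) -> pd.Index:
        return self.intensities.columns

    def missing_mask(self) -> pd.DataFrame:
        """Cells absent for reasons other than censoring."""
        return self.intensities.isna() & ~self.below_lod

    def subset_proteins(self, proteins: Iterable[str]) -> "AbundanceMatrix":
        idx = pd.Index(proteins)
        return AbundanceMatrix(
            self.intensities.loc[idx],
            self.peptide_counts.loc[idx],
            self.below_lod.loc[idx],
        )

    def equals(self, other: "AbundanceMatrix") -> bool:
        return (
            self.intensities.equals(other.intensities)
            and self.peptide_counts.equals(other.peptide_counts)
            and self.below_lod.equals(other.below_lod)
        )


@dataclass
class NormalizedMatrix:
    """Protein levels in %beta-actin units (or a log2/z-scored view).

    ``values`` rows are proteins, columns samples.  ``transform_state``
    tracks which scale the numbers are on so downstream stages can refuse
    input on the wrong scale.
    """

    values: pd.DataFrame
    transform_state: str = "percent_actb"
    below_lod: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.transform_state not in TRANSFORM_STATES:
            raise ValidationError(
                f"transform_state must be one of {TRANSFORM_STATES}, "
                f"got {self.transform_state!r}"
            )
        if self.below_lod is None:
            self.below_lod = _empty_mask(self.values)
        _check_unique(self.values.index, "protein")
        _check_unique(self.values.columns, "sample")

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def with_values(self, values: pd.DataFrame, state: str) -> "NormalizedMatrix":
        return NormalizedMatrix(values, state, self.below_lod.copy())

    def equals(self, other: "NormalizedMatrix") -> bool:
        return (
            self.values.equals(other.values)
            and self.transform_state == other.transform_state
            and self.below_lod.equals(other.below_lod)
        )


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

META_COLUMNS = (
    "group",
    "disease",
    "causative_gene",
    "onset_status",
    "age_months",
)


def make_sample_meta(records: Iterable[dict]) -> pd.DataFrame:
    """Build and validate a sample-metadata table.

    Each record needs ``sample_id`` and ``group``; patient records also need
    ``disease`` (and usually ``causative_gene``).
    """
    df = pd.DataFrame(list(records)).set_index("sample_id")
    for col in META_COLUMNS:
        if col not in df.columns:
            df[col] = None
    df = df[list(META_COLUMNS)]
    df["onset_status"] = df["onset_status"].where(
        df["onset_status"].notna(),
        np.where(df["group"] == "patient", "post_onset", "not_applicable"),
    )
    validate_sample_meta(df)
    return df


def validate_sample_meta(meta: pd.DataFrame) -> None:
    _check_unique(meta.index, "sample")
    bad_group = set(meta["group"]) - set(GROUPS)
    if bad_group:
        raise ValidationError(f"unknown group(s) {sorted(bad_group)}; allowed: {GROUPS}")
    is_patient = meta["group"] == "patient"
    if (is_patient & meta["disease"].isna()).any():
        raise ValidationError("patient samples must carry a disease label")
    if (~is_patient & meta["disease"].notna()).any():
        raise ValidationError("disease label only allowed on patient samples")
    bad_onset = set(meta["onset_status"]) - set(ONSET_STATES)
    if bad_onset:
        raise ValidationError(f"unknown onset status {sorted(bad_onset)}")
    if (~is_patient & (meta["onset_status"] != "not_applicable")).any():
        raise ValidationError("onset_status must be not_applicable for non-patients")
    if (is_patient & (meta["onset_status"] == "not_applicable")).any():
        raise ValidationError("patients must carry a pre/post onset status")


# ---------------------------------------------------------------------------
# reference statistics
# ---------------------------------------------------------------------------


@dataclass
class ReferenceStats:
    """Per-protein mean / sample-SD / minimum of a healthy reference group.

    ``table`` is indexed by protein and has columns ``mean``, ``sd``,
    ``min`` and ``n`` in %beta-actin units.
    """

    group: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"mean", "sd", "min", "n"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"reference table needs columns {sorted(required)}")
        present = self.table.dropna(subset=["mean", "min"])
        if (present["min"] > present["mean"] + 1e-12).any():
            bad = present.index[present["min"] > present["mean"] + 1e-12]
            raise ValidationError(f"reference minimum exceeds mean for {list(bad)}")
        if (self.table["sd"].dropna() < 0).any():
            raise ValidationError("reference SD must be non-negative")

    def for_protein(self, protein: str) -> pd.Series | None:
        """Row for one protein, or None when no reference exists (e.g. the
        reference cohort never detected the protein)."""
        if protein not in self.table.index or pd.isna(self.table.loc[protein, "mean"]):
            return None
        return self.table.loc[protein]
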
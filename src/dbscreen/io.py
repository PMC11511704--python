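"""Readers and writers for the package's tabular formats.

Formats handled here:

* protein x sample quantification matrices (TSV/CSV, one protein per row,
  a peptide-evidence column, one intensity column per sample);
* normalized matrices (same layout plus a ``#transform_state=`` header);
* sample metadata tables;
* gene-set collections in GMT;
* mutation tables (one allele per row with consequence class, NMD
  annotation, FoldX total-energy change and the observed-loss label);
* the embedded clinical fixtures (reference cohort and mutation table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix import (
    AbundanceMatrix,
    NormalizedMatrix,
    ReferenceStats,
    ValidationError,
    validate_sample_meta,
)

# tokens accepted for "no value" cells; configurable because upstream tools
# disagree (empty cell, NA, NaN ...)
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan")
#: token used on disk for values censored at the detection limit
LOD_TOKEN = "<LOD"


@dataclass
class Dialect:
    """How a matrix file is laid out on disk."""

    delimiter: str = "\t"
    protein_column: str = "protein"
    peptides_column: str = "peptides"
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS
    lod_token: str = LOD_TOKEN


# ---------------------------------------------------------------------------
# abundance / normalized matrices
# ---------------------------------------------------------------------------


def _parse_cell(raw: str, dialect: Dialect, where: str) -> tuple[float, bool]:
    """Return (value, below_lod) for one matrix cell."""
    token = raw.strip()
    if token in dialect.missing_tokens:
        return np.nan, False
    if token == dialect.lod_token:
        return np.nan, True
    try:
        value = float(token)
    except ValueError:
        raise ValidationError(f"unrecognized cell token {raw!r} at {where}") from None
    return value, False


def _read_matrix_body(
    lines: list[str], dialect: Dialect, expect_peptides: bool
) -> tuple[pd.DataFrame, pd.Series | None, pd.DataFrame]:
    header = lines[0].rstrip("\n").split(dialect.delimiter)
    if header[0] != dialect.protein_column:
        raise ValidationError(
            f"first column must be {dialect.protein_column!r}, got {header[0]!r}"
        )
    col = 1
    if expect_peptides:
        if len(header) < 2 or header[1] != dialect.peptides_column:
            raise ValidationError(
                f"second column must be {dialect.peptides_column!r}"
            )
        col = 2
    samples = header[col:]
    proteins, counts, values, lod = [], [], [], []
    for line in lines[1:]:
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split(dialect.delimiter)
        if len(parts) != len(header):
            raise ValidationError(
                f"row {parts[0]!r} has {len(parts)} fields, expected {len(header)}"
            )
        proteins.append(parts[0])
        if expect_peptides:
            counts.append(int(parts[1]))
        row_vals, row_lod = [], []
        for sample, raw in zip(samples, parts[col:]):
            v, c = _parse_cell(raw, dialect, f"({parts[0]}, {sample})")
            row_vals.append(v)
            row_lod.append(c)
        values.append(row_vals)
        lod.append(row_lod)
    vdf = pd.DataFrame(values, index=pd.Index(proteins, name="protein"), columns=samples)
    ldf = pd.DataFrame(lod, index=vdf.index, columns=samples)
    pep = pd.Series(counts, index=vdf.index, name="peptides") if expect_peptides else None
    return vdf, pep, ldf


def read_abundance_matrix(path: str | Path, dialect: Dialect | None = None) -> AbundanceMatrix:
    """Read a raw quantification matrix; row and column order are preserved.

    Duplicate identifiers and negative intensities are hard errors.
    """
    dialect = dialect or Dialect()
    lines = [
        ln for ln in Path(path).read_text().splitlines(keepends=True)
        if not ln.startswith("#")
    ]
    values, peptides, lod = _read_matrix_body(lines, dialect, expect_peptides=True)
    return AbundanceMatrix(values, peptides, lod)


def write_abundance_matrix(
    matrix: AbundanceMatrix, path: str | Path, dialect: Dialect | None = None
) -> None:
    dialect = dialect or Dialect()
    _write_matrix(
        matrix.intensities, matrix.below_lod, path, dialect,
        peptides=matrix.peptide_counts, header_lines=(),
    )


def read_normalized_matrix(path: str | Path, dialect: Dialect | None = None) -> NormalizedMatrix:
    dialect = dialect or Dialect()
    raw_lines = Path(path).read_text().splitlines(keepends=True)
    state = "percent_actb"
    body = []
    for ln in raw_lines:
        if ln.startswith("#transform_state="):
            state = ln.split("=", 1)[1].strip()
        elif not ln.startswith("#"):
            body.append(ln)
    values, _, lod = _read_matrix_body(body, dialect, expect_peptides=False)
    return NormalizedMatrix(values, state, lod)


def write_normalized_matrix(
    matrix: NormalizedMatrix, path: str | Path, dialect: Dialect | None = None
) -> None:
    dialect = dialect or Dialect()
    _write_matrix(
        matrix.values, matrix.below_lod, path, dialect, peptides=None,
        header_lines=(f"#transform_state={matrix.transform_state}",),
    )


def _format_value(v: float) -> str:
    # repr round-trips float64 exactly
    return repr(float(v))


def _write_matrix(values, lod, path, dialect, peptides, header_lines) -> None:
    d = dialect.delimiter
    out = [*header_lines]
    header = [dialect.protein_column]
    if peptides is not None:
        header.append(dialect.peptides_column)
    header.extend(map(str, values.columns))
    out.append(d.join(header))
    varr = values.to_numpy(dtype=float)
    larr = lod.to_numpy(dtype=bool)
    for i, protein in enumerate(values.index):
        row = [str(protein)]
        if peptides is not None:
            row.append(str(int(peptides.iloc[i])))
        for j in range(varr.shape[1]):
            if larr[i, j]:
                row.append(dialect.lod_token)
            elif np.isnan(varr[i, j]):
                row.append("")
            else:
                row.append(_format_value(varr[i, j]))
        out.append(d.join(row))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    meta = meta.set_index("sample_id")
    validate_sample_meta(meta)
    return meta


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit background list."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with a universe, dropping sets that vanish."""
        uni = set(universe)
        kept = {}
        for name, members in self.sets.items():
            inter = [m for m in members if m in uni]
            if inter:
                kept[name] = inter
        return GeneSetCollection(kept, dict(self.descriptions), sorted(uni))


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member...

    Duplicate set names are a hard error; repeated members within a set are
    de-duplicated with a warning; an empty set is a hard error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"GMT line {lineno} needs name, description and >=1 member"
            )
        name, description, *members = parts
        members = [m for m in members if m]
        if name in sets:
            raise ValidationError(f"duplicate gene-set name {name!r}")
        if not members:
            raise ValidationError(f"gene set {name!r} (line {lineno}) is empty")
        deduped = list(dict.fromkeys(members))
        if len(deduped) != len(members):
            warnings.warn(
                f"gene set {name!r}: {len(members) - len(deduped)} repeated "
                "member(s) removed",
                stacklevel=2,
            )
        sets[name] = deduped
        descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, ""), *members])
        for name, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "splicing",
    "inframe_deletion",
    "transcriptional_dysregulation",
    "synonymous_splice",
)

NMD_STATES = (
    "NMD",
    "NMD_escaping",
    "exon_skip",
    "splicing_anomaly",
    "unknown",
    "not_applicable",
)

OBSERVED_LOSS = ("yes", "no", "reduced_but_detectable", "not_determined")

_CONSEQUENCE_ALIASES = {
    "missense": "missense",
    "missense mutation": "missense",
    "nonsense": "nonsense",
    "nonsense mutation": "nonsense",
    "frameshift": "frameshift",
    "splicing": "splicing",
    "splicing anomaly": "splicing",
    "deletion": "inframe_deletion",
    "inframe deletion": "inframe_deletion",
    "inframe_deletion": "inframe_deletion",
    "transcriptional dysregulation": "transcriptional_dysregulation",
    "transcriptional_dysregulation": "transcriptional_dysregulation",
    "synonymous splice": "synonymous_splice",
    "synonymous_splice": "synonymous_splice",
}

_LOSS_ALIASES = {
    "yes": "yes",
    "no": "no",
    "reduced but detectable": "reduced_but_detectable",
    "reduced_but_detectable": "reduced_but_detectable",
    "nd": "not_determined",
    "not determined": "not_determined",
    "not_determined": "not_determined",
}


@dataclass
class MutationRecord:
    """One allele of a disease-causing gene with its loss annotations."""

    gene: str
    allele: str
    consequence: str
    nmd_annotation: str = "not_applicable"
    ddg: float | None = None
    observed_loss: str = "not_determined"
    disease: str | None = None
    pathogenicity: str | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(
                f"unknown consequence {self.consequence!r}; allowed: {CONSEQUENCES}"
            )
        if self.nmd_annotation not in NMD_STATES:
            raise ValidationError(
                f"unknown NMD annotation {self.nmd_annotation!r}; allowed: {NMD_STATES}"
            )
        if self.observed_loss not in OBSERVED_LOSS:
            raise ValidationError(
                f"unknown observed-loss label {self.observed_loss!r}; "
                f"allowed: {OBSERVED_LOSS}"
            )


def _normalize_consequence(token: str) -> str:
    key = token.strip().lower()
    if key not in _CONSEQUENCE_ALIASES:
        raise ValidationError(
            f"unrecognized consequence {token!r}; allowed: {CONSEQUENCES}"
        )
    return _CONSEQUENCE_ALIASES[key]


def _normalize_nmd(token: str, consequence: str) -> str:
    key = token.strip()
    if not key:
        # truncating/splicing alleles without an annotation are unknown;
        # classes where NMD is not a mechanism are not_applicable
        if consequence in ("missense", "inframe_deletion", "transcriptional_dysregulation"):
            return "not_applicable"
        return "unknown"
    low = key.lower()
    if low == "nmd":
        return "NMD"
    if low in ("nmd escaping", "nmd_escaping"):
        return "NMD_escaping"
    if low.startswith("exon skip") or low == "exon_skip":
        return "exon_skip"
    if low in ("splicing anomaly", "splicing_anomaly"):
        return "splicing_anomaly"
    if low in ("unknown", "not_applicable"):
        return low if low == "unknown" else "not_applicable"
    raise ValidationError(f"unrecognized NMD annotation {token!r}")


def _normalize_loss(token: str) -> str:
    key = token.strip().lower()
    if key not in _LOSS_ALIASES:
        raise ValidationError(
            f"unrecognized observed-loss label {token!r}; allowed: {OBSERVED_LOSS}"
        )
    return _LOSS_ALIASES[key]


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read a mutation TSV (columns: gene, allele, consequence, and
    optionally disease, pathogenicity, nmd_annotation, ddg, observed_loss)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"gene", "allele", "consequence"}
    if not required.issubset(df.columns):
        raise ValidationError(f"mutation table needs columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        consequence = _normalize_consequence(row["consequence"])
        ddg_raw = row.get("ddg", "").strip()
        records.append(
            MutationRecord(
                gene=row["gene"],
                allele=row["allele"],
                consequence=consequence,
                nmd_annotation=_normalize_nmd(row.get("nmd_annotation", ""), consequence),
                ddg=float(ddg_raw) if ddg_raw else None,
                observed_loss=_normalize_loss(row.get("observed_loss", "") or "not_determined"),
                disease=row.get("disease") or None,
                pathogenicity=row.get("pathogenicity") or None,
            )
        )
    return records


def write_mutation_table(records: Sequence[MutationRecord], path: str | Path) -> None:
    rows = [
        {
            "disease": r.disease or "",
            "gene": r.gene,
            "allele": r.allele,
            "consequence": r.consequence,
            "pathogenicity": r.pathogenicity or "",
            "nmd_annotation": r.nmd_annotation,
            "ddg": "" if r.ddg is None else repr(r.ddg),
            "observed_loss": r.observed_loss,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# embedded clinical fixtures
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(resources.files("dbscreen") / "data" / name)


def load_table1_fixture() -> tuple[pd.DataFrame, dict[str, ReferenceStats]]:
    """Embedded clinical reference cohort.

    Returns
    -------
    observations
        One row per patient sample: patient, sample, age_months, disease,
        gene, protein_name, ``value`` (%beta-actin, NaN when below the
        detection limit), ``below_lod`` flag and ``presymptomatic`` flag.
    references
        ``{"healthy_newborn": ReferenceStats, "healthy_adult": ReferenceStats}``
        keyed by causative gene symbol.  Genes whose reference row prints NA
        (below detection in every healthy sample) carry NaN statistics.
    """
    obs = pd.read_csv(
        _data_path("table1_patients.tsv"), sep="\t", comment="#",
        dtype={"value": str},
    )
    obs["below_lod"] = obs["value"].str.strip() == "BLD"
    obs["value"] = pd.to_numeric(obs["value"], errors="coerce")
    obs["presymptomatic"] = obs["presymptomatic"] == "yes"

    ref = pd.read_csv(_data_path("table1_reference.tsv"), sep="\t", comment="#")
    references = {}
    for group, sub in ref.groupby("group"):
        table = sub.set_index("gene")[["mean", "sd", "min", "n"]]
        references[group] = ReferenceStats(group, table)
    return obs, references


def load_table2_fixture() -> list[MutationRecord]:
    """Embedded clinical mutation table: one record per allele row."""
    return read_mutation_table(_data_path("table2_mutations.tsv"))
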
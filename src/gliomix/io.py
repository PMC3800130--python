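"""Readers, writers and validated containers for cohort-level expression data.

The pipeline works on three tabular inputs per study: an expression matrix
(probes x samples, log2-scale RMA-style values, TSV), a per-sample clinical
table (grade, histology, survival), and gene-set collections in GMT format.
Everything downstream consumes the containers defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: gene symbol attached to probes with no mapping entry
UNMAPPED_GENE = "UNMAPPED"

GRADE_LEVELS = ("I", "II", "III", "IV", "unknown")
HISTOLOGY_LEVELS = (
    "astrocytoma",
    "oligoastrocytoma",
    "oligodendroglioma",
    "GBM",
    "normal",
    "other",
)
RECURRENCE_LEVELS = ("primary", "recurrent", "unknown")
SEX_LEVELS = ("male", "female", "unknown")

_GRADE_ALIASES = {
    "1": "I", "i": "I",
    "2": "II", "ii": "II",
    "3": "III", "iii": "III",
    "4": "IV", "iv": "IV",
    "": "unknown", "na": "unknown", "nan": "unknown", "unknown": "unknown",
}

CLINICAL_COLUMNS = (
    "sample_id",
    "cohort_id",
    "grade",
    "histology",
    "recurrence_status",
    "age_years",
    "sex",
    "os_months",
    "event",
)


class FormatError(ValueError):
    """Malformed input file (duplicates, non-numeric cells, bad GMT lines)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates a container invariant."""


@dataclass
class ExpressionCohort:
    """One study's probe x sample log2 expression matrix plus probe→gene map.

    Values are log2-scale by contract (RMA-normalized upstream); operations
    that need a linear scale (fold changes, subtype ratios) exponentiate
    internally.
    """

    cohort_id: str
    matrix: pd.DataFrame  # index = probe_ids, columns = sample_ids
    probe_to_gene: dict[str, str] = field(default_factory=dict)
    platform_tag: str = ""

    def __post_init__(self) -> None:
        idx = self.matrix.index
        cols = self.matrix.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate probe ID {dup!r} in cohort {self.cohort_id}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r} in cohort {self.cohort_id}")
        if self.matrix.size == 0:
            raise FormatError(f"empty expression matrix for cohort {self.cohort_id}")
        values = self.matrix.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError(f"non-numeric expression values in cohort {self.cohort_id}")
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at probe {idx[i]!r}, sample {cols[j]!r} "
                f"in cohort {self.cohort_id}"
            )
        # every probe carries a gene symbol; unmapped probes get a sentinel
        for probe in idx:
            self.probe_to_gene.setdefault(probe, UNMAPPED_GENE)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def expression(self, probe_id: str) -> np.ndarray:
        """log2 expression vector of one probe, sample order preserved."""
        if probe_id not in self.matrix.index:
            raise KeyError(f"probe {probe_id!r} not in cohort {self.cohort_id}")
        return self.matrix.loc[probe_id].to_numpy(dtype=float)

    def gene_of(self, probe_id: str) -> str:
        return self.probe_to_gene.get(probe_id, UNMAPPED_GENE)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations with controlled vocabularies."""

    table: pd.DataFrame  # columns = CLINICAL_COLUMNS, one row per sample

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        for cohort, sub in df.groupby("cohort_id"):
            if sub["sample_id"].duplicated().any():
                dup = sub.loc[sub["sample_id"].duplicated(), "sample_id"].iloc[0]
                raise FormatError(f"duplicate sample ID {dup!r} in cohort {cohort}")
        has_os = df["os_months"].notna()
        if (has_os & df["event"].isna()).any():
            bad = df.loc[has_os & df["event"].isna(), "sample_id"].iloc[0]
            raise ValidationError(f"sample {bad!r} has os_months but no event flag")
        if (df.loc[has_os, "os_months"] < 0).any():
            bad = df.loc[has_os & (df["os_months"] < 0), "sample_id"].iloc[0]
            raise ValidationError(f"sample {bad!r} has negative os_months")
        iv = df["grade"] == "IV"
        bad_iv = iv & ~df["histology"].isin(["astrocytoma", "GBM"])
        if bad_iv.any():
            bad = df.loc[bad_iv, "sample_id"].iloc[0]
            raise ValidationError(
                f"sample {bad!r} is grade IV but histology is not astrocytoma/GBM"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def for_samples(self, sample_ids: list[str]) -> pd.DataFrame:
        """Rows for the given samples, in the given order."""
        sub = self.table.set_index("sample_id").loc[list(sample_ids)]
        return sub.reset_index()


@dataclass
class SignatureCollection:
    """Named gene sets (molecular-subtype signatures or pathway collections)."""

    name: str
    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for set_name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {set_name!r} is empty")
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    logger.warning("duplicate gene %s in set %s dropped", g, set_name)
                seen[g] = None
            self.sets[set_name] = list(seen)

    def set_names(self) -> list[str]:
        return list(self.sets)

    def intersection(self, a: str, b: str) -> list[str]:
        """Genes shared by two sets, order of set *a* preserved."""
        other = set(self.sets[b])
        return [g for g in self.sets[a] if g in other]


# ---------------------------------------------------------------------------
# readers / writers


def read_probe_map(path) -> dict[str, str]:
    """2-column TSV (probe_id, gene symbol) → mapping dict."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"probe map {path} needs 2 columns, got {df.shape[1]}")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_expression_matrix(path, cohort_id: str, probe_map_path=None,
                           platform_tag: str = "") -> ExpressionCohort:
    """Read a probes x samples TSV into a validated :class:`ExpressionCohort`.

    First column holds probe IDs, first row sample IDs, body is numeric
    log2-scale expression. Row/column order is preserved as read.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.size == 0:
        raise FormatError(f"empty expression matrix in {path}")
    try:
        matrix = raw.astype(float)
    except ValueError:
        for j, col in enumerate(raw.columns):
            converted = pd.to_numeric(raw[col], errors="coerce")
            if converted.isna().any() and raw[col].notna().all():
                i = int(np.argmax(converted.isna().to_numpy()))
                raise FormatError(
                    f"non-numeric cell at row {raw.index[i]!r} (row {i + 2}), "
                    f"column {col!r} (column {j + 2}) in {path}"
                ) from None
        raise
    probe_to_gene = read_probe_map(probe_map_path) if probe_map_path else {}
    return ExpressionCohort(cohort_id=cohort_id, matrix=matrix,
                            probe_to_gene=probe_to_gene, platform_tag=platform_tag)


def write_expression_matrix(cohort: ExpressionCohort, path) -> None:
    """Write the matrix back as TSV; round-trips with the reader."""
    out = cohort.matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def normalize_grade(value) -> str:
    s = "" if pd.isna(value) else str(value).strip()
    key = s.lower()
    if key in _GRADE_ALIASES:
        return _GRADE_ALIASES[key]
    if s.upper() in GRADE_LEVELS:
        return s.upper()
    raise ValidationError(f"unrecognized WHO grade {value!r}")


def _normalize_level(value, levels: tuple, label: str) -> str:
    s = "" if pd.isna(value) else str(value).strip()
    if s == "" or s.lower() in ("na", "nan", "unknown"):
        return "unknown" if "unknown" in levels else "other"
    for lv in levels:
        if s.lower() == lv.lower():
            return lv
    if label == "histology":
        if s.lower() in ("gbm", "glioblastoma", "glioblastoma multiforme"):
            return "GBM"
        return "other"
    raise ValidationError(f"unrecognized {label} {value!r}")


def read_clinical_table(path) -> ClinicalTable:
    """Read a clinical TSV/CSV and normalize to the controlled vocabularies.

    Unknown columns are ignored; missing values in categorical fields become
    'unknown', numeric missing stays NaN. Delimiter sniffed between tab/comma.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical file {path} missing columns: {missing}")
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "cohort_id": df["cohort_id"].astype(str),
            "grade": df["grade"].map(normalize_grade),
            "histology": df["histology"].map(
                lambda v: _normalize_level(v, HISTOLOGY_LEVELS, "histology")),
            "recurrence_status": df["recurrence_status"].map(
                lambda v: _normalize_level(v, RECURRENCE_LEVELS, "recurrence_status")),
            "age_years": pd.to_numeric(df["age_years"], errors="coerce"),
            "sex": df["sex"].map(lambda v: _normalize_level(v, SEX_LEVELS, "sex")),
            "os_months": pd.to_numeric(df["os_months"], errors="coerce"),
            "event": pd.to_numeric(df["event"], errors="coerce"),
        }
    )
    if (out["age_years"].dropna() < 0).any():
        raise ValidationError(f"negative age_years in {path}")
    return ClinicalTable(out)


def write_clinical_table(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", index=False)


def read_gene_sets_gmt(path, name: str | None = None) -> SignatureCollection:
    """Standard GMT: one set per line — name, description, tab-separated genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} in {path} has "
                                  f"{len(fields)} fields (need >= 3)")
            set_name = fields[0]
            if set_name in sets:
                raise FormatError(f"duplicate set name {set_name!r} at "
                                  f"GMT line {lineno} in {path}")
            genes = [g for g in fields[2:] if g.strip()]
            if not genes:
                raise FormatError(f"GMT line {lineno} in {path} has no genes")
            sets[set_name] = genes
    return SignatureCollection(name=name or str(path), sets=sets, source=str(path))


def write_gene_sets_gmt(collection: SignatureCollection, path) -> None:
    with open(path, "w") as fh:
        for set_name, genes in collection.sets.items():
            fh.write("\t".join([set_name, collection.source or "na", *genes]) + "\n")


def intersect_probes(cohorts: list[ExpressionCohort]) -> list[str]:
    """Probes present on every cohort's platform, first cohort's order.

    Cross-cohort analyses require a probe on each array; this utility leaves
    the inclusion policy to callers.
    """
    if not cohorts:
        return []
    common = set(cohorts[0].matrix.index)
    for c in cohorts[1:]:
        common &= set(c.matrix.index)
    return [p for p in cohorts[0].matrix.index if p in common]
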
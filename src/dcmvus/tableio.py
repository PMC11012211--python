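"""Reading and writing the tab-separated variant-table dialect.

The interchange format is a TSV with a mandatory header; missing values are
the literal token ``NA``; the MAF column is in percent. One row per variant
per patient. Unknown columns are preserved as passthrough, so
``write(read(f))`` is byte-identical (modulo line endings) for files in the
dialect.

The packaged cohort fixture (125 rare variants in 65 DCM patients, 16
genes) ships in this dialect with curated evidence columns and the
published 2023 labels for cross-checking; the classifier never reads the
``expected_2023`` column.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import numpy as np
import pandas as pd

from .engine import derive_default_data_status
from .model import (
    Classification,
    ClinVarStatus,
    ConsequenceClass,
    DataStatus,
    EvidenceProfile,
    VariantRecord,
)

log = logging.getLogger(__name__)

__all__ = [
    "VariantTableDialect",
    "VariantTableError",
    "read_variant_table",
    "write_variant_table",
    "records_to_frame",
    "format_maf",
    "load_fixture",
    "fixture_path",
]

NA = "NA"

MANDATORY_COLUMNS = [
    "patient_id",
    "gene",
    "cdna_hgvs",
    "clinvar_status",
    "maf_percent",
    "prior_class",
    "prior_year",
]
KNOWN_OPTIONAL_COLUMNS = [
    "protein_hgvs",
    "dbsnp_id",
    "data_status",
    "corroborated",
    "current_class",
    "consequence",
    "rule_trace",
]

# canonical positional decimal, e.g. 0.00006 / 0.827 / 12 — no exponents,
# no thousands separators, no comma decimal marks
_CANONICAL_FLOAT = re.compile(r"^\d+(\.\d+)?$")


class VariantTableError(ValueError):
    """Raised on a malformed variant table (missing column, bad value)."""


@dataclass(frozen=True)
class VariantTableDialect:
    """TSV dialect: delimiter, NA token."""

    delimiter: str = "\t"
    na_token: str = NA


DEFAULT_DIALECT = VariantTableDialect()


def _parse_maf(token: str, row: int) -> Optional[float]:
    if token in (NA, ""):
        return None
    if not _CANONICAL_FLOAT.match(token):
        raise VariantTableError(
            f"row {row}: unparseable maf_percent {token!r} (expected a plain decimal or NA)"
        )
    return float(token)


def read_variant_table(
    path: Union[str, Path, IO[str]],
    dialect: VariantTableDialect = DEFAULT_DIALECT,
) -> list[VariantRecord]:
    """Parse a variant TSV into records.

    Missing or ``NA`` evidence cells are filled from the ClinVar-derived
    defaults (:func:`~dcmvus.engine.derive_default_data_status`); an
    explicit ``data_status`` value on a row takes precedence and is marked
    curated. Raises :class:`VariantTableError` on a missing mandatory
    column or an unparseable value, naming the row.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"missing mandatory column(s): {', '.join(missing)}")
    extra_cols = [c for c in df.columns if c not in MANDATORY_COLUMNS + KNOWN_OPTIONAL_COLUMNS]
    if extra_cols:
        log.info("passthrough columns: %s", ", ".join(extra_cols))

    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = dict(zip(df.columns, row))

        def cell(col: str) -> str:
            return str(d.get(col, NA)).strip()

        def opt(col: str) -> Optional[str]:
            v = cell(col)
            return None if v in (NA, "") else v

        maf = _parse_maf(cell("maf_percent"), i)
        try:
            clinvar = ClinVarStatus(cell("clinvar_status"))
        except ValueError:
            raise VariantTableError(f"row {i}: unknown clinvar_status {cell('clinvar_status')!r}") from None
        try:
            prior = Classification.from_label(cell("prior_class"))
        except ValueError as exc:
            raise VariantTableError(f"row {i}: {exc}") from None
        try:
            year = int(cell("prior_year"))
        except ValueError:
            raise VariantTableError(f"row {i}: unparseable prior_year {cell('prior_year')!r}") from None

        status_token = opt("data_status")
        if status_token is None:
            data_status, curated = derive_default_data_status(clinvar), False
        else:
            try:
                data_status, curated = DataStatus(status_token), True
            except ValueError:
                raise VariantTableError(f"row {i}: unknown data_status {status_token!r}") from None

        corr_token = opt("corroborated")
        if corr_token is None:
            corroborated = False
        elif corr_token.lower() in ("true", "yes", "1"):
            corroborated = True
        elif corr_token.lower() in ("false", "no", "0"):
            corroborated = False
        else:
            raise VariantTableError(f"row {i}: unparseable corroborated {corr_token!r}")

        current = opt("current_class")
        consequence = opt("consequence")
        records.append(
            VariantRecord(
                patient_id=cell("patient_id"),
                gene=cell("gene"),
                cdna_hgvs=cell("cdna_hgvs"),
                protein_hgvs=opt("protein_hgvs"),
                dbsnp_id=opt("dbsnp_id"),
                clinvar_status=clinvar,
                maf_percent=maf,
                prior_class=prior,
                prior_year=year,
                evidence=EvidenceProfile(
                    data_status=data_status,
                    corroborated_pathogenic=corroborated,
                    curated=curated,
                ),
                current_class=Classification.from_label(current) if current else None,
                consequence=ConsequenceClass(consequence) if consequence else None,
                extra={c: cell(c) for c in extra_cols},
            )
        )
    return records


def format_maf(maf: Optional[float]) -> str:
    """Render a percent MAF as a plain positional decimal (``NA`` if absent)."""
    if maf is None:
        return NA
    return np.format_float_positional(maf, trim="-")


def records_to_frame(
    records: Iterable[VariantRecord],
    *,
    traces: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Render records into the TSV dialect's column layout (string dtype).

    Evidence cells are written only where informative (curated status,
    positive corroboration); derived defaults stay ``NA`` so a written
    table reads back identically. The ``current_class``, ``consequence``
    and ``rule_trace`` columns appear only when at least one record (or the
    ``traces`` argument) carries them; passthrough columns come last.
    """
    recs = list(records)
    rows = []
    for rec in recs:
        rows.append(
            {
                "patient_id": rec.patient_id,
                "gene": rec.gene,
                "cdna_hgvs": rec.cdna_hgvs,
                "protein_hgvs": rec.protein_hgvs or NA,
                "dbsnp_id": rec.dbsnp_id or NA,
                "clinvar_status": rec.clinvar_status.value,
                "maf_percent": format_maf(rec.maf_percent),
                "prior_class": rec.prior_class.label,
                "prior_year": str(rec.prior_year),
                "data_status": rec.evidence.data_status.value if rec.evidence.curated else NA,
                "corroborated": "true" if rec.evidence.corroborated_pathogenic else NA,
                "current_class": rec.current_class.label if rec.current_class else NA,
                "consequence": rec.consequence.value if rec.consequence else NA,
                **rec.extra,
            }
        )
    columns = [
        "patient_id", "gene", "cdna_hgvs", "protein_hgvs", "dbsnp_id",
        "clinvar_status", "maf_percent", "prior_class", "prior_year",
        "data_status", "corroborated",
    ]
    if any(r.current_class is not None for r in recs):
        columns.append("current_class")
    if any(r.consequence is not None for r in recs):
        columns.append("consequence")
    extra_cols: list[str] = []
    for rec in recs:
        for c in rec.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    df = pd.DataFrame(rows, columns=columns + extra_cols)
    if traces is not None:
        df["rule_trace"] = traces
    return df


def write_variant_table(
    records: Iterable[VariantRecord],
    path: Union[str, Path, IO[str]],
    dialect: VariantTableDialect = DEFAULT_DIALECT,
    *,
    traces: Optional[list[str]] = None,
) -> None:
    """Write records as TSV in the standard dialect (LF line endings)."""
    df = records_to_frame(records, traces=traces)
    df.to_csv(path, sep=dialect.delimiter, index=False, lineterminator="\n")


def fixture_path() -> Path:
    """Filesystem path of the packaged DCM cohort table."""
    return Path(str(importlib.resources.files("dcmvus") / "data" / "dcm_cohort.tsv"))


def load_fixture(with_expected: bool = False):
    """Load the packaged 125-variant DCM cohort.

    Returns the record list; with ``with_expected=True`` returns
    ``(records, expected)`` where ``expected`` is the list of published
    2023 classifications (for cross-checking only — the engine never sees
    them).
    """
    path = fixture_path()
    records = read_variant_table(path)
    if not with_expected:
        return records
    expected = [Classification.from_label(r.extra["expected_2023"]) for r in records]
    return records, expected
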
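"""Cohort-level summaries of the reinterpretation results.

Aggregates classified records into the counts a reanalysis report prints:
class totals, a consequence-type × classification cross-tab, per-gene
counts, outcomes stratified by the year of first classification, and
per-patient carrier categories. Raw integer counts are authoritative;
percentages are derived for display (two decimals, half-up).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import pandas as pd

from .consequence import classify_consequence
from .model import Classification, ConsequenceClass, VariantRecord

__all__ = [
    "CohortSummary",
    "PatientCounts",
    "summarize",
    "year_breakdown",
    "patient_breakdown",
    "gene_subreport",
    "ttn_subreport",
    "percent",
]

#: display order: benign end to pathogenic end (matches the report layout)
CLASS_ORDER = [
    Classification.B,
    Classification.LB,
    Classification.VUS_LB,
    Classification.VUS,
    Classification.VUS_LP,
    Classification.LP,
    Classification.P,
]
TYPE_ORDER = [
    ConsequenceClass.INTRONIC,
    ConsequenceClass.INDEL,
    ConsequenceClass.NONSENSE,
    ConsequenceClass.MISSENSE,
]


def percent(count: int, denominator: int, places: int = 2) -> float:
    """count/denominator as a percentage rounded half-up to ``places``."""
    if denominator == 0:
        return 0.0
    q = Decimal(count) * 100 / Decimal(denominator)
    return float(q.quantize(Decimal(10) ** -places, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PatientCounts:
    """Carrier categories; LP-carrying patients are partitioned into
    LP-only and LP-plus-VUS-LP, so the first two below sum to the third is
    not double-counted. ``patients_vuslp_no_lp`` counts patients whose most
    suspicious finding is a VUS-LP (no LP/P variant)."""

    patients_with_lp: int
    patients_lp_only: int
    patients_lp_plus_vuslp: int
    patients_vuslp_no_lp: int


@dataclass
class CohortSummary:
    """All aggregate tallies for one (sub)cohort."""

    class_counts: dict[Classification, int]
    type_by_class: dict[tuple[ConsequenceClass, Classification], int]
    gene_counts: dict[str, int]
    year_transitions: dict[int, dict]
    patient_counts: PatientCounts
    n_variants: int
    n_remaining_vus: int
    warnings: list[str] = field(default_factory=list)

    # -- renderers --------------------------------------------------------

    def class_table(self) -> pd.DataFrame:
        """Classification × consequence-type cross-tab with margins, in the
        standard report layout (counts; percentages of the grand total)."""
        rows = []
        n = self.n_variants
        for cls in CLASS_ORDER:
            row = {"classification": cls.label}
            for t in TYPE_ORDER:
                row[t.value] = self.type_by_class.get((t, cls), 0)
            row["total"] = self.class_counts.get(cls, 0)
            rows.append(row)
        totals = {"classification": "total"}
        for t in TYPE_ORDER:
            totals[t.value] = sum(self.type_by_class.get((t, c), 0) for c in CLASS_ORDER)
        totals["total"] = n
        rows.append(totals)
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        """Markdown rendering of :meth:`class_table` with percentages."""
        df = self.class_table()
        n = self.n_variants
        header = ["2023"] + [c for c in df.columns if c != "classification"]
        lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
        for _, row in df.iterrows():
            cells = [str(row["classification"])]
            for col in header[1:]:
                count = int(row[col])
                cells.append(f"{count} ({percent(count, n)}%)" if count else "0")
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines)

    def to_tsv(self) -> str:
        return self.class_table().to_csv(sep="\t", index=False, lineterminator="\n")


def _ensure_classified(records: list[VariantRecord]) -> list[VariantRecord]:
    for r in records:
        if r.current_class is None:
            raise ValueError(
                f"unclassified record: {r.gene} {r.cdna_hgvs} (run the engine before summarizing)"
            )
    return records


def _with_consequence(rec: VariantRecord) -> ConsequenceClass:
    if rec.consequence is not None:
        return rec.consequence
    return classify_consequence(rec.cdna_hgvs, rec.protein_hgvs)


def summarize(records: Iterable[VariantRecord]) -> CohortSummary:
    """Aggregate classified records into a :class:`CohortSummary`.

    Every record must carry ``current_class``; the consequence type is
    computed from the HGVS strings where not already present. Order of the
    input is irrelevant.
    """
    recs = _ensure_classified(list(records))
    class_counts: Counter = Counter(r.current_class for r in recs)
    type_by_class: Counter = Counter((_with_consequence(r), r.current_class) for r in recs)
    gene_counts: Counter = Counter(r.gene.strip().upper() for r in recs)
    n_remaining = sum(1 for r in recs if r.current_class.is_vus_family())
    return CohortSummary(
        class_counts=dict(class_counts),
        type_by_class=dict(type_by_class),
        gene_counts=dict(gene_counts),
        year_transitions=year_breakdown(recs),
        patient_counts=patient_breakdown(recs),
        n_variants=len(recs),
        n_remaining_vus=n_remaining,
    )


def year_breakdown(records: Iterable[VariantRecord]) -> dict[int, dict]:
    """2023 outcomes among variants first classified in each year.

    Returns ``{year: {"n": count, Classification: count, ...}}``.
    """
    recs = _ensure_classified(list(records))
    out: dict[int, dict] = {}
    for r in recs:
        ybin = out.setdefault(r.prior_year, {"n": 0})
        ybin["n"] += 1
        ybin[r.current_class] = ybin.get(r.current_class, 0) + 1
    return dict(sorted(out.items()))


def patient_breakdown(records: Iterable[VariantRecord]) -> PatientCounts:
    """Partition patients by their most actionable 2023 finding.

    A patient carrying any LP/P variant counts once in ``patients_with_lp``
    and in exactly one of ``patients_lp_only`` / ``patients_lp_plus_vuslp``.
    ``patients_vuslp_no_lp`` counts patients with at least one VUS-LP and
    no LP/P variant, so the categories are mutually exclusive.
    """
    recs = _ensure_classified(list(records))
    by_patient: dict[str, set[Classification]] = defaultdict(set)
    for r in recs:
        by_patient[r.patient_id].add(r.current_class)
    with_lp = lp_only = lp_plus = vuslp_no_lp = 0
    for classes in by_patient.values():
        has_lp = bool(classes & {Classification.LP, Classification.P})
        has_vuslp = Classification.VUS_LP in classes
        if has_lp:
            with_lp += 1
            if has_vuslp:
                lp_plus += 1
            else:
                lp_only += 1
        elif has_vuslp:
            vuslp_no_lp += 1
    return PatientCounts(
        patients_with_lp=with_lp,
        patients_lp_only=lp_only,
        patients_lp_plus_vuslp=lp_plus,
        patients_vuslp_no_lp=vuslp_no_lp,
    )


def gene_subreport(records: Iterable[VariantRecord], gene: str) -> CohortSummary:
    """Summary restricted to one gene symbol (case-insensitive).

    An unknown gene yields an all-zero summary carrying a warning rather
    than an error.
    """
    recs = list(records)
    sym = gene.strip().upper()
    sub = [r for r in recs if r.gene.strip().upper() == sym]
    if not sub:
        empty = CohortSummary(
            class_counts={},
            type_by_class={},
            gene_counts={},
            year_transitions={},
            patient_counts=PatientCounts(0, 0, 0, 0),
            n_variants=0,
            n_remaining_vus=0,
        )
        empty.warnings.append(f"no records for gene {gene!r}")
        return empty
    return summarize(sub)


def ttn_subreport(records: Iterable[VariantRecord]) -> CohortSummary:
    """Summary restricted to titin (TTN), the dominant DCM gene."""
    return gene_subreport(records, "TTN")
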
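"""Domain types for rare-variant reinterpretation in genetic dilated cardiomyopathy.

A cohort is a list of :class:`VariantRecord` objects, one per observed rare
variant per patient. Records carry the fields a diagnostic lab would have on
file: HGVS strings, the gnomAD minor allele frequency (in percent), the
ClinVar assertion code, the classification given at first report, and a
curated evidence profile summarising the literature review.

Allele frequencies are stored and compared in **percent** throughout (the
gnomAD browser convention for reporting MAF in clinical tables). An absent
MAF is a first-class state, distinct from 0: a variant never seen in the
population database is treated as maximally rare.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "Classification",
    "ClinVarStatus",
    "DataStatus",
    "MafBin",
    "ConsequenceClass",
    "EvidenceProfile",
    "GenePanel",
    "VariantRecord",
    "ValidationFinding",
    "validate_record",
    "DEFAULT_PANEL",
]


class Classification(enum.IntEnum):
    """Five-point ACMG scale extended with the two VUS sub-categories.

    The integer values encode the benign-to-pathogenic total order used by
    the monotonicity guarantees of the rule engine: increasing population
    frequency may only move a call toward the benign end.
    """

    B = 0
    LB = 1
    VUS_LB = 2
    VUS = 3
    VUS_LP = 4
    LP = 5
    P = 6

    @property
    def label(self) -> str:
        return _CLASS_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "Classification":
        try:
            return _CLASS_BY_LABEL[label.strip()]
        except KeyError:
            raise ValueError(f"unknown classification label: {label!r}") from None

    def is_vus_family(self) -> bool:
        """True for VUS and both sub-categories (still ambiguous calls)."""
        return self in (Classification.VUS_LB, Classification.VUS, Classification.VUS_LP)


_CLASS_LABELS = {
    Classification.B: "B",
    Classification.LB: "LB",
    Classification.VUS_LB: "VUS-LB",
    Classification.VUS: "VUS",
    Classification.VUS_LP: "VUS-LP",
    Classification.LP: "LP",
    Classification.P: "P",
}
_CLASS_BY_LABEL = {v: k for k, v in _CLASS_LABELS.items()}


class ClinVarStatus(str, enum.Enum):
    """ClinVar aggregate assertion as reported in the input table.

    ``VUSC`` (table token ``VUSc``) marks a VUS with conflicting submissions
    and is kept distinct from plain ``VUS``. ``NA``: no ClinVar record.
    """

    NA = "NA"
    B = "B"
    LB = "LB"
    VUS = "VUS"
    VUSC = "VUSc"
    LP = "LP"
    P = "P"


class DataStatus(str, enum.Enum):
    """Outcome of the per-variant literature/database review.

    ``NONE``: no published data. ``SUPPORTIVE``: data consistent with a
    deleterious role. ``EQUIVOCAL``: data exist but are uninformative either
    way. ``CONFLICTING``: contradictory reports.
    """

    NONE = "none"
    SUPPORTIVE = "supportive"
    EQUIVOCAL = "equivocal"
    CONFLICTING = "conflicting"


class MafBin(str, enum.Enum):
    """Population-frequency strata used by the VUS subclassification tree.

    VERY_LOW: absent from gnomAD or MAF < 0.005%. MEDIUM: MAF above the
    familial-DCM prevalence threshold of 0.04%. LOW: in between.
    """

    VERY_LOW = "very_low"
    LOW = "low"
    MEDIUM = "medium"


class ConsequenceClass(str, enum.Enum):
    """Variant-type taxonomy: missense / nonsense / indel / intronic.

    Frameshifts count as indels; stop-loss extensions count as nonsense;
    UTR changes are bucketed with intronic (non-coding).
    """

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    INDEL = "indel"
    INTRONIC = "intronic"


@dataclass(frozen=True)
class EvidenceProfile:
    """Curated evidence attached to one variant.

    ``data_status`` operationalises the "existence or not of data; if
    available, contradictory data" node of the subclassification tree.
    ``corroborated_pathogenic`` is True only when functional or other
    ancillary evidence is sufficient to support a definitive upgrade of a
    ClinVar-LP/P variant to likely pathogenic. ``curated`` records whether
    ``data_status`` came from an explicit per-variant review (True) or was
    derived from the ClinVar code by the default mapping (False); the
    engine ignores it, but the table writer round-trips it.
    """

    data_status: DataStatus = DataStatus.NONE
    corroborated_pathogenic: bool = False
    curated: bool = False


@dataclass(frozen=True)
class GenePanel:
    """Gene panel with definite disease association.

    ``definite_genes``: genes with definite/strong DCM association; panel
    membership is the first node of the subclassification tree.
    ``lof_mechanism_genes``: subset where loss of function is the
    established disease mechanism (TTN truncating variants).
    Symbols are matched case-insensitively after trimming.
    """

    definite_genes: frozenset[str]
    lof_mechanism_genes: frozenset[str] = frozenset({"TTN"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "definite_genes", frozenset(g.strip().upper() for g in self.definite_genes))
        object.__setattr__(
            self, "lof_mechanism_genes", frozenset(g.strip().upper() for g in self.lof_mechanism_genes)
        )
        if not self.definite_genes:
            raise ValueError("definite_genes must be non-empty")
        if not self.lof_mechanism_genes <= self.definite_genes:
            raise ValueError("lof_mechanism_genes must be a subset of definite_genes")

    def __contains__(self, gene: str) -> bool:
        return gene.strip().upper() in self.definite_genes


#: The 19 genes with a definite/strong DCM association.
DEFAULT_PANEL = GenePanel(
    definite_genes=frozenset(
        {
            "ACTC1", "ACTN2", "BAG3", "DES", "DSP", "FLNC", "JPH2", "LMNA",
            "MYH7", "NEXN", "PLN", "RBM20", "SCN5A", "TNNC1", "TNNI3",
            "TNNT2", "TPM1", "TTN", "VCL",
        }
    ),
    lof_mechanism_genes=frozenset({"TTN"}),
)


@dataclass
class VariantRecord:
    """One rare variant observed in one patient.

    ``maf_percent`` is the gnomAD minor allele frequency in percent; ``None``
    means the variant is absent from the database. ``prior_class`` is the
    classification assigned at first report (``prior_year``);
    ``current_class`` is filled by the rule engine.
    """

    patient_id: str
    gene: str
    cdna_hgvs: str
    protein_hgvs: Optional[str] = None
    dbsnp_id: Optional[str] = None
    clinvar_status: ClinVarStatus = ClinVarStatus.NA
    maf_percent: Optional[float] = None
    prior_class: Classification = Classification.VUS
    prior_year: int = 2016
    evidence: EvidenceProfile = field(default_factory=EvidenceProfile)
    current_class: Optional[Classification] = None
    consequence: Optional[ConsequenceClass] = None
    #: passthrough of columns the table dialect does not define
    extra: dict = field(default_factory=dict)

    def with_class(self, cls: Classification) -> "VariantRecord":
        return replace(self, current_class=cls)


@dataclass(frozen=True)
class ValidationFinding:
    """One coded validation finding; ``severity`` is 'error' or 'warning'."""

    severity: str
    code: str
    message: str

    @property
    def is_error(self) -> bool:
        return self.severity == "error"


def validate_record(
    record: VariantRecord,
    panel: GenePanel = DEFAULT_PANEL,
    rare_cutoff: float = 1.0,
) -> list[ValidationFinding]:
    """Check one record against the domain contract.

    Returns a list of findings (empty for a well-formed record); callers
    decide whether warnings are fatal. Errors: empty cDNA HGVS, negative
    MAF, MAF at or above the rare-variant inclusion cutoff (1% by default).
    Warnings: gene outside the definite panel; a corroborated-pathogenic
    flag on a record whose ClinVar status is not LP/P; non-positive year.
    """
    findings: list[ValidationFinding] = []
    if not record.cdna_hgvs or not record.cdna_hgvs.strip():
        findings.append(ValidationFinding("error", "empty_cdna", "cdna_hgvs must be non-empty"))
    if record.maf_percent is not None:
        if record.maf_percent < 0:
            findings.append(
                ValidationFinding("error", "negative_maf", f"maf_percent is negative: {record.maf_percent}")
            )
        elif record.maf_percent >= rare_cutoff:
            findings.append(
                ValidationFinding(
                    "error",
                    "not_rare",
                    f"maf_percent {record.maf_percent} >= {rare_cutoff}%: not a rare variant",
                )
            )
    if record.gene not in panel:
        findings.append(
            ValidationFinding("warning", "off_panel", f"gene {record.gene!r} not in definite-association panel")
        )
    if record.evidence.corroborated_pathogenic and record.clinvar_status not in (
        ClinVarStatus.LP,
        ClinVarStatus.P,
    ):
        findings.append(
            ValidationFinding(
                "warning",
                "corroboration_without_lp",
                "corroborated_pathogenic set but ClinVar status is not LP/P",
            )
        )
    if record.prior_year <= 0:
        findings.append(ValidationFinding("warning", "odd_year", f"prior_year {record.prior_year} is not positive"))
    return findings


def validate_records(
    records: Iterable[VariantRecord],
    panel: GenePanel = DEFAULT_PANEL,
) -> dict[int, list[ValidationFinding]]:
    """Validate many records; returns {index: findings} for non-clean rows only."""
    out: dict[int, list[ValidationFinding]] = {}
    for i, rec in enumerate(records):
        findings = validate_record(rec, panel)
        if findings:
            out[i] = findings
    return out
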
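"""The 2023 reinterpretation engine for ambiguous DCM variants.

The engine takes a rare variant previously classified as a VUS and emits an
updated classification using only population frequency, the ClinVar status,
panel membership and the curated evidence profile. Three rules fire in
order:

1. **Demotion to likely benign** — the updated gnomAD MAF is at or above
   ``lb_promotion_cutoff`` (default 0.1%): the variant is too common in the
   population to drive a dominant cardiomyopathy.
2. **Promotion to likely pathogenic** — ClinVar asserts LP/P, the updated
   MAF satisfies the PM2 rarity criterion (absent or ≤ 0.01%), and
   corroborating functional/ancillary evidence is on file.
3. **VUS subclassification** — the remaining variants are placed in
   VUS-LB / VUS / VUS-LP by a decision tree on (panel membership, evidence
   data status, MAF bin). Genes outside the definite-association panel stay
   plain VUS.

The engine never emits B or P: the definitive extremes require evidence
types (segregation, functional assays at strong weight) outside its scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import yaml

from .model import (
    DEFAULT_PANEL,
    Classification,
    ClinVarStatus,
    DataStatus,
    GenePanel,
    MafBin,
    VariantRecord,
)

__all__ = [
    "EngineConfig",
    "classify_maf_bin",
    "meets_pm2",
    "reclassify",
    "reclassify_with_trace",
    "reclassify_all",
    "derive_default_data_status",
]


@dataclass(frozen=True)
class EngineConfig:
    """Thresholds (all in percent MAF) and the gene panel.

    very_low_cutoff : below this (or no MAF) a variant is maximally rare
        (0.005%, the ceiling observed for definitively pathogenic variants
        in inherited arrhythmia syndromes).
    medium_cutoff : familial-DCM prevalence ~1/2500 → 0.04%; above it a
        VUS leans benign.
    pm2_cutoff : PM2 (rarity) is met at MAF ≤ 0.01%.
    lb_promotion_cutoff : at or above 0.1% a prior VUS is demoted to LB
        outright (BS1-style strong benign frequency).
    rare_cutoff : cohort inclusion filter; variants at ≥ 1% are not rare.
    """

    very_low_cutoff: float = 0.005
    medium_cutoff: float = 0.04
    pm2_cutoff: float = 0.01
    lb_promotion_cutoff: float = 0.1
    rare_cutoff: float = 1.0
    panel: GenePanel = field(default_factory=lambda: DEFAULT_PANEL)

    def __post_init__(self) -> None:
        if not (0 < self.very_low_cutoff < self.medium_cutoff < self.lb_promotion_cutoff <= self.rare_cutoff):
            raise ValueError(
                "thresholds must satisfy 0 < very_low_cutoff < medium_cutoff "
                "< lb_promotion_cutoff <= rare_cutoff; got "
                f"{self.very_low_cutoff}/{self.medium_cutoff}/{self.lb_promotion_cutoff}/{self.rare_cutoff}"
            )
        if self.pm2_cutoff < self.very_low_cutoff:
            raise ValueError("pm2_cutoff must be >= very_low_cutoff")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "very_low_cutoff": self.very_low_cutoff,
            "medium_cutoff": self.medium_cutoff,
            "pm2_cutoff": self.pm2_cutoff,
            "lb_promotion_cutoff": self.lb_promotion_cutoff,
            "rare_cutoff": self.rare_cutoff,
            "definite_genes": sorted(self.panel.definite_genes),
            "lof_mechanism_genes": sorted(self.panel.lof_mechanism_genes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EngineConfig":
        d = dict(d)
        genes = d.pop("definite_genes", None)
        lof = d.pop("lof_mechanism_genes", None)
        panel = DEFAULT_PANEL
        if genes is not None:
            panel = GenePanel(
                definite_genes=frozenset(genes),
                lof_mechanism_genes=frozenset(lof) if lof is not None else frozenset(genes) & {"TTN"},
            )
        unknown = set(d) - {"very_low_cutoff", "medium_cutoff", "pm2_cutoff", "lb_promotion_cutoff", "rare_cutoff"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(panel=panel, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EngineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def classify_maf_bin(maf_percent: Optional[float], config: EngineConfig = EngineConfig()) -> MafBin:
    """Place a MAF (percent) into the very-low / low / medium strata.

    Absent MAF or MAF < 0.005% → VERY_LOW; MAF > 0.04% → MEDIUM; otherwise
    LOW. The bin edges themselves (exactly 0.005 or 0.04) fall to LOW: the
    defining inequalities are strict on both sides, so boundary values are
    assigned to the middle stratum.
    """
    if maf_percent is None:
        return MafBin.VERY_LOW
    if maf_percent < 0:
        raise ValueError(f"maf_percent must be non-negative, got {maf_percent}")
    if maf_percent < config.very_low_cutoff:
        return MafBin.VERY_LOW
    if maf_percent > config.medium_cutoff:
        return MafBin.MEDIUM
    return MafBin.LOW


def meets_pm2(maf_percent: Optional[float], config: EngineConfig = EngineConfig()) -> bool:
    """PM2 rarity criterion: absent from gnomAD or MAF ≤ 0.01%."""
    if maf_percent is None:
        return True
    if maf_percent < 0:
        raise ValueError(f"maf_percent must be non-negative, got {maf_percent}")
    return maf_percent <= config.pm2_cutoff


def derive_default_data_status(clinvar_status: ClinVarStatus) -> DataStatus:
    """Default literature-review outcome implied by the ClinVar code.

    Used when no curated per-variant review is supplied: no ClinVar record →
    no data; conflicting submissions → conflicting; a benign assertion
    contradicts a pathogenic hypothesis → conflicting; VUS or LP/P
    submissions → supportive. Explicit per-row curation takes precedence.
    """
    try:
        return _DEFAULT_STATUS[clinvar_status]
    except KeyError:
        raise ValueError(f"unknown ClinVar status: {clinvar_status!r}") from None


_DEFAULT_STATUS = {
    ClinVarStatus.NA: DataStatus.NONE,
    ClinVarStatus.VUSC: DataStatus.CONFLICTING,
    ClinVarStatus.VUS: DataStatus.SUPPORTIVE,
    ClinVarStatus.LB: DataStatus.CONFLICTING,
    ClinVarStatus.B: DataStatus.CONFLICTING,
    ClinVarStatus.LP: DataStatus.SUPPORTIVE,
    ClinVarStatus.P: DataStatus.SUPPORTIVE,
}

# VUS subclassification tree, step 3: (MafBin, DataStatus) → Classification
# for in-panel genes. MEDIUM ignores data status entirely.
_TREE: dict[tuple[MafBin, DataStatus], Classification] = {}
for _ds in DataStatus:
    _TREE[(MafBin.MEDIUM, _ds)] = Classification.VUS_LB
_TREE.update(
    {
        (MafBin.LOW, DataStatus.CONFLICTING): Classification.VUS_LB,
        (MafBin.LOW, DataStatus.EQUIVOCAL): Classification.VUS,
        (MafBin.LOW, DataStatus.NONE): Classification.VUS_LP,
        (MafBin.LOW, DataStatus.SUPPORTIVE): Classification.VUS_LP,
        (MafBin.VERY_LOW, DataStatus.CONFLICTING): Classification.VUS,
        (MafBin.VERY_LOW, DataStatus.EQUIVOCAL): Classification.VUS,
        (MafBin.VERY_LOW, DataStatus.NONE): Classification.VUS_LP,
        (MafBin.VERY_LOW, DataStatus.SUPPORTIVE): Classification.VUS_LP,
    }
)


def reclassify_with_trace(
    record: VariantRecord, config: EngineConfig = EngineConfig()
) -> tuple[Classification, str]:
    """Reinterpret one prior-VUS record; returns (classification, rule trace).

    The trace names the branch that fired, e.g. ``maf_demotion``,
    ``lp_promotion``, ``off_panel``, ``tree:medium``,
    ``tree:low/conflicting`` — enough to replay the decision from the
    record's own fields.
    """
    if not record.prior_class.is_vus_family():
        raise ValueError(
            f"engine reinterprets VUS only; prior_class is {record.prior_class.label} "
            f"for {record.gene} {record.cdna_hgvs}"
        )
    maf = record.maf_percent
    if maf is not None and maf < 0:
        raise ValueError(f"maf_percent must be non-negative, got {maf}")

    if maf is not None and maf >= config.lb_promotion_cutoff:
        return Classification.LB, "maf_demotion"

    if (
        record.clinvar_status in (ClinVarStatus.LP, ClinVarStatus.P)
        and meets_pm2(maf, config)
        and record.evidence.corroborated_pathogenic
    ):
        return Classification.LP, "lp_promotion"

    if record.gene not in config.panel:
        return Classification.VUS, "off_panel"

    bin_ = classify_maf_bin(maf, config)
    status = record.evidence.data_status
    cls = _TREE[(bin_, status)]
    if bin_ is MafBin.MEDIUM:
        return cls, "tree:medium"
    return cls, f"tree:{bin_.value}/{status.value}"


def reclassify(record: VariantRecord, config: EngineConfig = EngineConfig()) -> Classification:
    """Reinterpret one prior-VUS record (see :func:`reclassify_with_trace`)."""
    return reclassify_with_trace(record, config)[0]


def reclassify_all(
    records: Iterable[VariantRecord], config: EngineConfig = EngineConfig()
) -> list[VariantRecord]:
    """Reclassify a cohort; returns new records with ``current_class`` set."""
    return [replace(r, current_class=reclassify(r, config)) for r in records]
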
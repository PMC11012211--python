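"""Seeded synthetic cohorts and the exhaustive decision-table oracle.

``generate_cohort`` emulates the structure of a real DCM reanalysis table:
roughly two rare variants per patient, gnomAD MAFs spanning four orders of
magnitude below the 1% rare-variant filter (drawn log-uniform, with a
substantial absent-from-gnomAD fraction), a ClinVar mix dominated by
VUS/VUSc/no-record, HGVS strings synthesised per consequence class so the
consequence classifier round-trips, and genes drawn from the definite
panel plus an off-panel decoy.

``enumerate_decision_space`` tabulates the engine's entire input space —
panel membership × evidence status × frequency stratum × ClinVar code ×
corroboration — as a literal lookup table, written independently of the
engine's control flow. It is the brute-force oracle used to cross-check
the engine cell by cell and row by row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .engine import EngineConfig, derive_default_data_status
from .model import (
    Classification,
    ClinVarStatus,
    ConsequenceClass,
    DataStatus,
    EvidenceProfile,
    VariantRecord,
)

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "FreqStratum",
    "stratum_of",
    "enumerate_decision_space",
    "oracle_classify",
]

# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

#: consequence mix of a DCM panel reanalysis (missense-dominated)
DEFAULT_TYPE_WEIGHTS = {
    ConsequenceClass.MISSENSE: 0.76,
    ConsequenceClass.NONSENSE: 0.096,
    ConsequenceClass.INDEL: 0.088,
    ConsequenceClass.INTRONIC: 0.056,
}

#: ClinVar mix: mostly VUS/VUSc/absent, few LB/LP assertions
DEFAULT_CLINVAR_MIX = {
    ClinVarStatus.NA: 0.30,
    ClinVarStatus.VUS: 0.26,
    ClinVarStatus.VUSC: 0.28,
    ClinVarStatus.LB: 0.08,
    ClinVarStatus.LP: 0.08,
}

_AA3 = [
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]
_BASES = "ACGT"


@dataclass(frozen=True)
class CohortSpec:
    """Tunable composition of a synthetic cohort.

    ``mean_variants_per_patient``: Poisson mean (zero-truncated) for
    variants per patient. ``maf_absent_prob``: fraction of variants absent
    from gnomAD. ``maf_log10_range``: log10 bounds (percent) for the
    log-uniform MAF draw; defaults span 0.0001%–0.9%.
    ``p_off_panel``: probability of drawing the off-panel decoy gene.
    ``p_status_override``: probability of attaching an explicit curated
    data status (uniform over the four levels) instead of the
    ClinVar-derived default. ``p_corroborated``: probability that a
    ClinVar-LP/P variant carries corroborating functional evidence.
    """

    mean_variants_per_patient: float = 2.0
    maf_absent_prob: float = 0.25
    maf_log10_range: tuple[float, float] = (-4.0, np.log10(0.9))
    clinvar_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLINVAR_MIX))
    type_weights: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_WEIGHTS))
    p_off_panel: float = 0.03
    p_status_override: float = 0.1
    p_corroborated: float = 0.5

    def __post_init__(self) -> None:
        for name, probs in (("clinvar_mix", self.clinvar_mix), ("type_weights", self.type_weights)):
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} probabilities must sum to 1, got {total}")
        if not 0 <= self.maf_absent_prob <= 1:
            raise ValueError("maf_absent_prob must be a probability")
        if self.mean_variants_per_patient <= 0:
            raise ValueError("mean_variants_per_patient must be positive")
        lo, hi = self.maf_log10_range
        if lo >= hi:
            raise ValueError("maf_log10_range must be increasing")


def _synth_hgvs(kind: ConsequenceClass, rng: np.random.Generator) -> tuple[str, Optional[str]]:
    """Synthesise a (cdna, protein) HGVS pair of the requested class.

    Positions are arbitrary; no reference sequence is implied.
    """
    cpos = int(rng.integers(1, 100000))
    ppos = max(1, cpos // 3)
    ref, alt = rng.choice(list(_BASES), size=2, replace=False)
    if kind is ConsequenceClass.MISSENSE:
        a, b = rng.choice(_AA3, size=2, replace=False)
        return f"c.{cpos}{ref}>{alt}", f"p.{a}{ppos}{b}"
    if kind is ConsequenceClass.NONSENSE:
        a = rng.choice(_AA3)
        return f"c.{cpos}{ref}>{alt}", f"p.{a}{ppos}Ter"
    if kind is ConsequenceClass.INTRONIC:
        offset = int(rng.integers(1, 20))
        sign = rng.choice(["+", "-"])
        return f"c.{cpos}{sign}{offset}{ref}>{alt}", None
    # indel: single-base deletion or duplication with frameshift
    a, b = rng.choice(_AA3, size=2, replace=False)
    token = rng.choice(["del", "dup"])
    shift = int(rng.integers(2, 60))
    return f"c.{cpos}{token}", f"p.{a}{ppos}{b}fsTer{shift}"


def generate_cohort(
    n_patients: int,
    spec: CohortSpec = CohortSpec(),
    seed: int = 0,
    config: EngineConfig = EngineConfig(),
) -> list[VariantRecord]:
    """Generate a deterministic synthetic cohort of prior-VUS records.

    Every record passes validation with zero errors (MAF < the rare-variant
    cutoff, non-empty HGVS); genes are drawn from the configured panel plus
    an off-panel decoy (``MYBPC3``) with probability ``spec.p_off_panel``.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(config.panel.definite_genes)
    clinvar_codes = list(spec.clinvar_mix)
    clinvar_p = np.array([spec.clinvar_mix[c] for c in clinvar_codes])
    kinds = list(spec.type_weights)
    kinds_p = np.array([spec.type_weights[k] for k in kinds])
    lo, hi = spec.maf_log10_range
    hi = min(hi, np.log10(config.rare_cutoff) - 1e-9)

    records: list[VariantRecord] = []
    for p in range(1, n_patients + 1):
        n_var = 0
        while n_var == 0:
            n_var = int(rng.poisson(spec.mean_variants_per_patient))
        for _ in range(n_var):
            if rng.random() < spec.p_off_panel:
                gene = "MYBPC3"
            else:
                gene = str(rng.choice(genes))
            kind = kinds[int(rng.choice(len(kinds), p=kinds_p))]
            cdna, prot = _synth_hgvs(kind, rng)
            clinvar = clinvar_codes[int(rng.choice(len(clinvar_codes), p=clinvar_p))]
            maf = None if rng.random() < spec.maf_absent_prob else float(10 ** rng.uniform(lo, hi))
            if rng.random() < spec.p_status_override:
                status = DataStatus(str(rng.choice([s.value for s in DataStatus])))
                curated = True
            else:
                status = derive_default_data_status(clinvar)
                curated = False
            corroborated = (
                clinvar in (ClinVarStatus.LP, ClinVarStatus.P) and rng.random() < spec.p_corroborated
            )
            records.append(
                VariantRecord(
                    patient_id=f"S{p:04d}",
                    gene=gene,
                    cdna_hgvs=cdna,
                    protein_hgvs=prot,
                    dbsnp_id=None,
                    clinvar_status=clinvar,
                    maf_percent=maf,
                    prior_class=Classification.VUS,
                    prior_year=int(rng.integers(2016, 2020)),
                    evidence=EvidenceProfile(
                        data_status=status, corroborated_pathogenic=corroborated, curated=curated
                    ),
                    consequence=kind,
                )
            )
    return records


# ---------------------------------------------------------------------------
# decision-space oracle
# ---------------------------------------------------------------------------


class FreqStratum:
    """Five frequency strata refining the three MAF bins.

    The three published bins are ambiguous with respect to the two
    threshold rules that cut across them — PM2 (≤0.01%) splits the low bin
    and the likely-benign demotion cutoff (≥0.1%) splits the medium bin —
    so the oracle enumerates five strata that make every rule a pure
    function of the stratum.
    """

    ABSENT_OR_VERY_LOW = "absent_or_very_low"  # absent or < 0.005 (PM2 met)
    LOW_PM2 = "low_pm2"                        # [0.005, 0.01]  (PM2 met)
    LOW = "low"                                # (0.01, 0.04]
    MEDIUM = "medium"                          # (0.04, 0.1)
    HIGH = "high"                              # >= 0.1 (demotion)

    ALL = [ABSENT_OR_VERY_LOW, LOW_PM2, LOW, MEDIUM, HIGH]


def stratum_of(maf_percent: Optional[float], config: EngineConfig = EngineConfig()) -> str:
    if maf_percent is None or maf_percent < config.very_low_cutoff:
        return FreqStratum.ABSENT_OR_VERY_LOW
    if maf_percent <= config.pm2_cutoff:
        return FreqStratum.LOW_PM2
    if maf_percent <= config.medium_cutoff:
        return FreqStratum.LOW
    if maf_percent < config.lb_promotion_cutoff:
        return FreqStratum.MEDIUM
    return FreqStratum.HIGH


# literal subclassification table: (in_panel, stratum→bin, data_status) → label.
# Written out cell by cell, not computed, so it can disagree with the engine.
_SUBCLASS_TABLE: dict[tuple[str, str], Classification] = {
    # very-low frequency (absent or < 0.005%)
    ("very_low", "none"): Classification.VUS_LP,
    ("very_low", "supportive"): Classification.VUS_LP,
    ("very_low", "equivocal"): Classification.VUS,
    ("very_low", "conflicting"): Classification.VUS,
    # low frequency (0.005–0.04%)
    ("low", "none"): Classification.VUS_LP,
    ("low", "supportive"): Classification.VUS_LP,
    ("low", "equivocal"): Classification.VUS,
    ("low", "conflicting"): Classification.VUS_LB,
    # medium frequency (> 0.04%)
    ("medium", "none"): Classification.VUS_LB,
    ("medium", "supportive"): Classification.VUS_LB,
    ("medium", "equivocal"): Classification.VUS_LB,
    ("medium", "conflicting"): Classification.VUS_LB,
}

_STRATUM_TO_BIN = {
    FreqStratum.ABSENT_OR_VERY_LOW: "very_low",
    FreqStratum.LOW_PM2: "low",
    FreqStratum.LOW: "low",
    FreqStratum.MEDIUM: "medium",
    FreqStratum.HIGH: "medium",
}

_PM2_STRATA = {FreqStratum.ABSENT_OR_VERY_LOW, FreqStratum.LOW_PM2}


def enumerate_decision_space() -> dict[tuple, Classification]:
    """Exhaustive truth table of the reinterpretation decision.

    Keys are ``(in_panel, data_status, stratum, clinvar, corroborated)``
    over all 2 × 4 × 5 × 7 × 2 = 560 combinations; values are the expected
    classification. The table applies, in order: demotion in the HIGH
    stratum, LP promotion for corroborated ClinVar-LP/P variants in a
    PM2-satisfying stratum, the off-panel hold, then the literal
    subclassification table.
    """
    table: dict[tuple, Classification] = {}
    for in_panel in (True, False):
        for status in DataStatus:
            for stratum in FreqStratum.ALL:
                for clinvar in ClinVarStatus:
                    for corroborated in (True, False):
                        if stratum == FreqStratum.HIGH:
                            cls = Classification.LB
                        elif (
                            clinvar in (ClinVarStatus.LP, ClinVarStatus.P)
                            and corroborated
                            and stratum in _PM2_STRATA
                        ):
                            cls = Classification.LP
                        elif not in_panel:
                            cls = Classification.VUS
                        else:
                            cls = _SUBCLASS_TABLE[(_STRATUM_TO_BIN[stratum], status.value)]
                        table[(in_panel, status, stratum, clinvar, corroborated)] = cls
    return table


_TABLE_CACHE: Optional[dict[tuple, Classification]] = None


def oracle_classify(record: VariantRecord, config: EngineConfig = EngineConfig()) -> Classification:
    """Classify one record by pure table lookup (no engine code path)."""
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        _TABLE_CACHE = enumerate_decision_space()
    key = (
        record.gene.strip().upper() in config.panel.definite_genes,
        record.evidence.data_status,
        stratum_of(record.maf_percent, config),
        record.clinvar_status,
        record.evidence.corroborated_pathogenic,
    )
    return _TABLE_CACHE[key]
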
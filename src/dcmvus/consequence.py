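"""Consequence typing from HGVS strings.

Assigns each variant to one of four buckets — missense, nonsense, indel,
intronic — from its cDNA (c.) and protein (p.) HGVS descriptions alone, with
no transcript model. The taxonomy groups variants by their molecular
footprint rather than strict Sequence Ontology terms:

* frameshifts (``p.…fsTer``) are *indels* — the driving lesion is the
  inserted/deleted bases, not the downstream stop;
* stop-loss extensions (``p.Ter…ext…``) are bucketed with *nonsense*
  (both alter the stop codon);
* UTR changes (``c.-n`` / ``c.*n``) are bucketed with *intronic*
  (non-coding);
* a gross exon-level deletion written as ``del ex. N_M`` is an *indel*.

Precedence is intronic > indel > nonsense > missense; classification is a
pure function of the two strings.
"""

from __future__ import annotations

import re
from typing import Optional

from .model import ConsequenceClass

__all__ = ["classify_consequence", "HgvsParseError"]


class HgvsParseError(ValueError):
    """Raised when neither classification rule matches the HGVS strings."""


# exon-level gross deletion, a non-HGVS token used in clinical tables
_GROSS_DELETION = re.compile(r"^del\s+ex\.?\s*\d+(_\d+)?$", re.IGNORECASE)

# intron offset (c.123+4, c.123-4) or UTR position (c.-8, c.*12)
_INTRON_OFFSET = re.compile(r"\d+[+-]\d+")
_UTR_PREFIX = re.compile(r"^c\.[-*]\d+")

_INDEL_TOKEN = re.compile(r"(delins|del|dup|ins)")
_FRAMESHIFT = re.compile(r"fs(Ter\d*|\*\d*)?$")

# p.Trp287Ter / p.W287* (not a frameshift)
_STOP_GAIN = re.compile(r"^p\.(\(?)[A-Za-z]{1,3}\d+(Ter|\*)\)?$")
# p.Ter1228TrpextTer33 — stop-loss extension
_STOP_LOSS = re.compile(r"^p\.\(?(Ter|\*)\d+[A-Za-z]{1,3}ext", re.IGNORECASE)

# p.Arg369Gln single-residue substitution (three-letter codes; tolerant of
# transcription slips in the letters themselves, e.g. 'IIe' for 'Ile')
_MISSENSE = re.compile(r"^p\.\(?[A-Za-z]{3}\d+[A-Za-z]{3}\)?$")


def classify_consequence(
    cdna_hgvs: str, protein_hgvs: Optional[str] = None
) -> ConsequenceClass:
    """Classify one variant as MISSENSE / NONSENSE / INDEL / INTRONIC.

    Parameters
    ----------
    cdna_hgvs
        The c.-notation string, or the gross-deletion token ``del ex. N_M``.
    protein_hgvs
        The p.-notation string if a protein change is annotated; ``None``
        or ``"NA"`` otherwise.

    Raises
    ------
    HgvsParseError
        If no rule matches, naming the offending token.
    """
    if not cdna_hgvs or not cdna_hgvs.strip():
        raise HgvsParseError("empty cDNA HGVS string")
    cdna = cdna_hgvs.strip()
    prot = None if protein_hgvs is None or protein_hgvs.strip() in ("", "NA") else protein_hgvs.strip()

    if _GROSS_DELETION.match(cdna):
        return ConsequenceClass.INDEL

    if prot is None and (_INTRON_OFFSET.search(cdna) or _UTR_PREFIX.match(cdna)):
        return ConsequenceClass.INTRONIC

    if _INDEL_TOKEN.search(cdna) or (prot is not None and (_INDEL_TOKEN.search(prot) or _FRAMESHIFT.search(prot))):
        return ConsequenceClass.INDEL

    if prot is not None and (_STOP_GAIN.match(prot) or _STOP_LOSS.match(prot)):
        return ConsequenceClass.NONSENSE

    if prot is not None and _MISSENSE.match(prot):
        return ConsequenceClass.MISSENSE

    offender = prot if prot is not None else cdna
    raise HgvsParseError(f"cannot classify consequence from {offender!r}")
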
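"""Restriction-site gain/loss (RFLP) genotyping assay design.

A candidate SNV can be genotyped on a gel when it creates or destroys a
restriction enzyme recognition site. For each enzyme, both the ref-allele
and alt-allele flanking sequences are scanned on both strands for IUPAC
motif matches that overlap the variant position: GAIN when only the alt
allele has a site, LOSS when only the ref allele does.

The default enzyme table covers the enzymes used for the worked candidate
set: HaeIII (GGCC), MluCI (AATT), SfcI (CTRYAG) and MboI (GATC). (The
MboI entry is presumed where a source lists the nonexistent "MobI".)
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

_IUPAC = {code: frozenset(bases) for code, bases in ambiguous_dna_values.items()}
_VALID_CODES = frozenset("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class EnzymeMotif:
    """A restriction enzyme's recognition sequence in IUPAC code."""

    name: str
    recognition: str

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        if len(rec) < 4:
            raise ValueError(f"{self.name}: recognition shorter than 4 bp")
        bad = set(rec) - _VALID_CODES
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC codes {sorted(bad)}")


DEFAULT_ENZYMES: Tuple[EnzymeMotif, ...] = (
    EnzymeMotif("HaeIII", "GGCC"),
    EnzymeMotif("MluCI", "AATT"),
    EnzymeMotif("SfcI", "CTRYAG"),
    EnzymeMotif("MboI", "GATC"),
)


class AssayChange(str, enum.Enum):
    GAIN = "GAIN"
    LOSS = "LOSS"


def load_enzymes(path) -> list[EnzymeMotif]:
    """Read a user enzyme table (TSV: name, IUPAC recognition)."""
    enzymes = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, recognition = line.split("\t")[:2]
            enzymes.append(EnzymeMotif(name, recognition))
    return enzymes


def _matches_at(seq: str, i: int, motif: str) -> bool:
    if i < 0 or i + len(motif) > len(seq):
        return False
    return all(seq[i + k] in _IUPAC[motif[k]] for k in range(len(motif)))


def _site_overlapping(seq: str, offset: int, motif: str) -> bool:
    """Any match of motif (either strand) in a window overlapping offset?"""
    rc = reverse_complement(motif)
    for m in (motif, rc):
        for i in range(offset - len(m) + 1, offset + 1):
            if _matches_at(seq, i, m):
                return True
    return False


def rflp_assay(
    flank: str,
    offset: int,
    ref: str,
    alt: str,
    enzymes: Sequence[EnzymeMotif] = DEFAULT_ENZYMES,
) -> list[Tuple[EnzymeMotif, AssayChange]]:
    """Find enzymes whose recognition site the variant creates or destroys.

    ``flank`` is reference sequence around the variant; ``offset`` is the
    variant's 0-based index within it. Give the flank at least one motif
    length minus one on each side of the variant, or windows running past
    its ends are silently not scanned.
    """
    flank = flank.upper()
    if not (0 <= offset < len(flank)):
        raise ValueError("offset outside flank")
    if flank[offset] != ref.upper():
        raise ValueError(
            f"flank base {flank[offset]} at offset {offset} != ref allele {ref}"
        )
    alt_seq = flank[:offset] + alt.upper() + flank[offset + 1 :]
    assays = []
    for enzyme in enzymes:
        in_ref = _site_overlapping(flank, offset, enzyme.recognition)
        in_alt = _site_overlapping(alt_seq, offset, enzyme.recognition)
        if in_alt and not in_ref:
            assays.append((enzyme, AssayChange.GAIN))
        elif in_ref and not in_alt:
            assays.append((enzyme, AssayChange.LOSS))
    return assays
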
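"""Restriction-enzyme models and in-silico digestion.

This module owns the three primitives the CAPS/RFLP workflow is built on:

* scanning a DNA sequence for all (possibly overlapping) matches of an
  IUPAC recognition sequence (:func:`find_sites`);
* deciding, for a SNP embedded in flanking context, whether each allele
  creates a recognition site overlapping the variant base
  (:func:`allele_site_status`) — the "[G/A] completes GAATTC" logic that
  makes a SNP allele-diagnostic on a gel;
* simulating a complete digestion of a PCR amplicon into fragment sizes
  (:func:`digest`).

Only the given strand is scanned by default. EcoRI (the default enzyme,
G^AATTC) is palindromic, so a single-strand scan is lossless; pass
``both_strands=True`` for non-palindromic enzymes. Partial digestion,
methylation sensitivity and star activity are not modeled: digestion is
assumed complete.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Optional

logger = logging.getLogger(__name__)

# IUPAC degeneracy is honoured in recognition sequences only.  Genomic N is
# deliberately absent from every expansion, so an N in the genome never
# matches any recognition letter (including recognition-side N).
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


class SequenceError(ValueError):
    """A sequence contains a character outside A/C/G/T/N."""


class ReferenceMismatchError(ValueError):
    """The base observed in a sequence does not equal the expected REF allele."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type II restriction enzyme.

    Parameters
    ----------
    name:
        Catalogue name, e.g. ``"EcoRI"``.
    recognition:
        IUPAC recognition sequence, length >= 4 (e.g. ``"GAATTC"``).
    cut_offset:
        Top-strand cleavage point within the recognition sequence, in
        ``[0, len(recognition)]``.  EcoRI cuts G^AATTC, i.e. offset 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        if len(rec) < 4:
            raise ValueError(f"recognition sequence too short: {rec!r}")
        bad = [c for c in rec if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"non-IUPAC code(s) {bad} in recognition {rec!r}")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside [0, {len(rec)}]"
            )

    @property
    def is_palindromic(self) -> bool:
        """True if the recognition sequence equals its reverse complement
        (comparing IUPAC sets, e.g. GAATTC, GGATCC)."""
        rec = self.recognition
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
                "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
                "D": "H", "H": "D", "N": "N"}
        return rec == "".join(comp[c] for c in reversed(rec))


#: Default enzyme throughout the package: EcoRI, G^AATTC.
ECORI = RestrictionEnzyme("EcoRI", "GAATTC", 1)


@lru_cache(maxsize=64)
def _site_regex(recognition: str) -> re.Pattern[str]:
    # lookahead so overlapping matches are all reported
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else "[" + IUPAC_CODES[c] + "]"
        for c in recognition
    )
    return re.compile(f"(?={body})")


def _validate_seq(seq: str) -> str:
    seq = seq.upper()
    for i, c in enumerate(seq):
        if c not in "ACGTN":
            raise SequenceError(f"non-nucleotide character {c!r} at offset {i}")
    return seq


def find_sites(seq: str, enzyme: RestrictionEnzyme = ECORI,
               both_strands: bool = False) -> list[int]:
    """All 0-based start offsets of recognition matches in ``seq``, ascending.

    Overlapping matches are all reported; genomic ``N`` never matches.  With
    ``both_strands=True`` the reverse complement is also scanned and its
    matches are mapped back to top-strand coordinates (the reported offset is
    the start of the matched window on the top strand).
    """
    seq = _validate_seq(seq)
    hits = {m.start() for m in _site_regex(enzyme.recognition).finditer(seq)}
    if both_strands:
        L = len(enzyme.recognition)
        rc = revcomp(seq)
        for m in _site_regex(enzyme.recognition).finditer(rc):
            hits.add(len(seq) - m.start() - L)
    return sorted(hits)


@dataclass(frozen=True)
class AlleleSiteStatus:
    """Per-allele recognition-site status at one SNP.

    ``ref_cut`` / ``alt_cut`` report whether any recognition match overlaps
    the variant base when that allele is substituted into the context.  The
    SNP is *discriminating* (usable as a binary marker) iff exactly one
    allele is cut.  Site starts are 0-based offsets within the context.
    """

    ref: str
    alt: str
    ref_cut: bool
    alt_cut: bool
    ref_site_start: Optional[int] = None
    alt_site_start: Optional[int] = None

    @property
    def discriminating(self) -> bool:
        return self.ref_cut != self.alt_cut

    @property
    def cut_allele(self) -> Optional[str]:
        """The allele that is cut, if exactly one is."""
        if not self.discriminating:
            return None
        return self.ref if self.ref_cut else self.alt


def allele_site_status(context: str, variant_offset: int, ref: str, alt: str,
                       enzyme: RestrictionEnzyme = ECORI,
                       both_strands: bool = False) -> AlleleSiteStatus:
    """Decide per-allele cut status of a SNP inside its flanking context.

    Each allele is substituted at ``variant_offset`` and the context is
    scanned; only matches *overlapping* the variant base count.  Matches
    elsewhere in the context are allele-independent (constitutive) and are
    ignored here — they shift both alleles' fragment patterns identically
    and are flagged separately during assay design.
    """
    context = _validate_seq(context)
    ref, alt = ref.upper(), alt.upper()
    if not 0 <= variant_offset < len(context):
        raise IndexError(f"variant_offset {variant_offset} outside context")
    if context[variant_offset] != ref:
        raise ReferenceMismatchError(
            f"context base {context[variant_offset]!r} at offset "
            f"{variant_offset} != REF allele {ref!r}"
        )
    L = len(enzyme.recognition)

    def first_overlap(base: str) -> Optional[int]:
        sub = context[:variant_offset] + base + context[variant_offset + 1:]
        for p in find_sites(sub, enzyme, both_strands=both_strands):
            if p <= variant_offset < p + L:
                return p
        return None

    r, a = first_overlap(ref), first_overlap(alt)
    return AlleleSiteStatus(ref=ref, alt=alt,
                            ref_cut=r is not None, alt_cut=a is not None,
                            ref_site_start=r, alt_site_start=a)


@dataclass(frozen=True)
class DigestProfile:
    """Fragment sizes from a complete digestion of one amplicon.

    ``fragments`` are in 5'->3' positional order and always sum to
    ``amplicon_length``; an amplicon with *k* internal cut points yields
    *k* + 1 fragments, each >= 1 bp.
    """

    amplicon_length: int
    fragments: tuple[int, ...]

    def __post_init__(self) -> None:
        if sum(self.fragments) != self.amplicon_length:
            raise ValueError("fragments do not sum to amplicon length")
        if any(f < 1 for f in self.fragments):
            raise ValueError("empty fragment")

    @property
    def n_sites(self) -> int:
        return len(self.fragments) - 1

    @property
    def sorted_fragments(self) -> tuple[int, ...]:
        """Fragment multiset, descending — the gel-band order."""
        return tuple(sorted(self.fragments, reverse=True))


def digest(amplicon: str, enzyme: RestrictionEnzyme = ECORI,
           both_strands: bool = False) -> DigestProfile:
    """Complete digestion of ``amplicon``: fragments between top-strand cut
    points (match offset + ``cut_offset``).

    A cut point falling exactly at position 0 or at the amplicon end would
    create an empty fragment (the site is truncated at the amplicon edge);
    such cuts are dropped with a log message.
    """
    amplicon = _validate_seq(amplicon)
    if len(amplicon) < 1:
        raise ValueError("empty amplicon")
    n = len(amplicon)
    cuts = sorted({p + enzyme.cut_offset for p in
                   find_sites(amplicon, enzyme, both_strands=both_strands)})
    kept = [c for c in cuts if 0 < c < n]
    for c in cuts:
        if c <= 0 or c >= n:
            logger.info("dropping edge-truncated cut point %d (amplicon %d bp)",
                        c, n)
    bounds = [0] + kept + [n]
    frags = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestProfile(amplicon_length=n, fragments=frags)


# ---------------------------------------------------------------------------
# Enzyme catalogue (editable TSV bundled with the package)
# ---------------------------------------------------------------------------

def load_catalogue() -> dict[str, RestrictionEnzyme]:
    """Load the bundled enzyme catalogue (``data/enzymes.tsv``).

    Keys are lower-cased enzyme names.  The catalogue is a plain TSV with
    columns ``name``, ``recognition``, ``cut_offset`` so users can extend it.
    """
    text = (resources.files("rflpkit") / "data" / "enzymes.tsv").read_text()
    catalogue: dict[str, RestrictionEnzyme] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        name, rec, off = line.split("\t")
        catalogue[name.lower()] = RestrictionEnzyme(name, rec, int(off))
    return catalogue


def get_enzyme(name: str) -> RestrictionEnzyme:
    """Look an enzyme up by (case-insensitive) name in the bundled catalogue."""
    catalogue = load_catalogue()
    try:
        return catalogue[name.lower()]
    except KeyError:
        known = ", ".join(sorted(e.name for e in catalogue.values()))
        raise KeyError(f"unknown enzyme {name!r}; catalogue has: {known}") from None
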
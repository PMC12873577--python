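"""Turn selected markers into lab-ready PCR/RFLP (CAPS) assays.

For each discriminating SNP: extract the reference flank (default 300 bp
each side), rank candidate regions by GC content to ease primer design,
pick a primer pair by window scan under Tm/GC/product-size constraints,
predict per-allele digestion fragment sizes, and render an expected
agarose-gel lane diagram.

Melting temperatures come from nearest-neighbor thermodynamics
(Bio.SeqUtils.MeltingTemp.Tm_NN) with a fixed parameter set: the unified
SantaLucia NN table, 50 mM Na+, 50 nM primer.  Published primer3 Tm values
for the same sequences can differ by a degree or so depending on the
parameter set, so Tm is treated as a design constraint here, not a value to
reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pyfaidx
from Bio.SeqUtils import MeltingTemp as _mt

from .restriction import (
    ECORI,
    AlleleSiteStatus,
    DigestProfile,
    ReferenceMismatchError,
    RestrictionEnzyme,
    allele_site_status,
    digest,
    find_sites,
    revcomp,
)
from .variant_store import Variant

# Fixed nearest-neighbor Tm parameters (documented in the methods note).
TM_PARAMS = dict(nn_table=_mt.DNA_NN3, Na=50, K=0, Tris=0, Mg=0,
                 dnac1=50, dnac2=0, saltcorr=5)


def primer_tm(seq: str) -> float:
    """Nearest-neighbor melting temperature (deg C) under :data:`TM_PARAMS`."""
    return float(_mt.Tm_NN(seq, **TM_PARAMS))


def gc_percent(seq: str) -> float:
    """GC content as a percentage, case-insensitive.

    N (or any non-GC character) counts in the denominator only.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class FlankRegion:
    """A variant plus its extracted reference flank.

    ``start``/``end`` are 0-based half-open reference coordinates;
    ``variant_offset`` indexes the SNP within ``sequence`` (which carries the
    REF allele there).  Full-length regions are 2*flank + 1 bp; regions near
    a chromosome edge are clipped with ``variant_offset`` adjusted.
    """

    chrom: str
    start: int
    end: int
    sequence: str
    variant_offset: int
    gc: float
    variant: Optional[Variant] = None

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("interval length != sequence length")
        if not 0 <= self.variant_offset < len(self.sequence):
            raise ValueError("variant_offset outside sequence")

    @property
    def gc_percent(self) -> float:
        return self.gc


def extract_flank(reference, v: Variant, flank: int = 300) -> FlankRegion:
    """Extract ``[pos-1-flank, pos+flank)`` around a SNP from the reference.

    ``reference`` may be a FASTA path, an open ``pyfaidx.Fasta``, or any
    mapping of chromosome name to sequence string.  The interval is clipped
    at chromosome ends.  If the reference base at ``pos`` is not the REF
    allele, the VCF and FASTA are out of sync and a
    :class:`ReferenceMismatchError` is raised.
    """
    ref = (pyfaidx.Fasta(str(reference))
           if isinstance(reference, (str, Path)) else reference)
    try:
        rec = ref[v.chrom]
    except KeyError:
        raise KeyError(f"chromosome {v.chrom!r} not in reference") from None
    chrom_len = len(rec)
    if not 1 <= v.pos <= chrom_len:
        raise IndexError(f"pos {v.pos} outside {v.chrom} (len {chrom_len})")
    start = max(0, v.pos - 1 - flank)
    end = min(chrom_len, v.pos - 1 + flank + 1)
    seq = str(rec[start:end]).upper()
    offset = v.pos - 1 - start
    if seq[offset] != v.ref_allele:
        raise ReferenceMismatchError(
            f"{v.key}: reference base {seq[offset]!r} at {v.chrom}:{v.pos} "
            f"!= VCF REF {v.ref_allele!r} (stale VCF/reference pairing?)"
        )
    return FlankRegion(chrom=v.chrom, start=start, end=end, sequence=seq,
                       variant_offset=offset, gc=gc_percent(seq), variant=v)


def rank_candidates(regions: Iterable[FlankRegion]) -> list[FlankRegion]:
    """Order candidate regions for primer design: GC closest to 50% first.

    Stable; ties broken by genomic position (chrom, start).
    """
    return sorted(regions, key=lambda r: (abs(r.gc - 50.0), r.chrom, r.start))


@dataclass(frozen=True)
class PrimerConstraints:
    """Primer-design constraint ranges.

    Defaults: primers 18-27 nt, Tm within [59, 61] deg C targeting 60, primer
    GC within [35, 60]%, product length within [300, 450] bp targeting 380.
    """

    min_len: int = 18
    max_len: int = 27
    tm_min: float = 59.0
    tm_max: float = 61.0
    tm_opt: float = 60.0
    gc_min: float = 35.0
    gc_max: float = 60.0
    product_min: int = 300
    product_max: int = 450
    product_opt: int = 380

    def __post_init__(self) -> None:
        if (self.min_len > self.max_len or self.tm_min > self.tm_max
                or self.gc_min > self.gc_max
                or self.product_min > self.product_max):
            raise ValueError("empty constraint range")


@dataclass(frozen=True)
class PrimerPair:
    """A designed primer pair within one flank region.

    ``rev_seq`` is given 5'->3' on the reverse strand.  ``fwd_start`` /
    ``rev_end`` delimit the amplicon as a 0-based half-open interval in
    region coordinates, so ``product_length == rev_end - fwd_start``.
    """

    fwd_seq: str
    rev_seq: str
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float
    fwd_start: int
    rev_end: int

    @property
    def product_length(self) -> int:
        return self.rev_end - self.fwd_start


class NoPrimerError(RuntimeError):
    """No primer pair satisfies the constraints; message names the binding one."""


def _scan_windows(seq: str, lo: int, hi: int, c: PrimerConstraints,
                  reverse: bool, fails: dict[str, int]):
    """Yield (start, end, primer_seq, tm, gc) for compliant windows in
    [lo, hi).  ``reverse`` reports the primer on the reverse strand."""
    for start in range(lo, hi):
        for length in range(c.min_len, c.max_len + 1):
            end = start + length
            if end > hi:
                break
            window = seq[start:end]
            if "N" in window:
                fails["window contains N"] += 1
                continue
            primer = revcomp(window) if reverse else window
            gc = gc_percent(primer)
            if not c.gc_min <= gc <= c.gc_max:
                fails["primer GC outside range"] += 1
                continue
            tm = primer_tm(primer)
            if not c.tm_min <= tm <= c.tm_max:
                fails["primer Tm outside range"] += 1
                continue
            yield start, end, primer, tm, gc


def pick_primers(region: FlankRegion, enzyme: RestrictionEnzyme = ECORI,
                 constraints: Optional[PrimerConstraints] = None) -> PrimerPair:
    """Pick the best-scoring primer pair for one marker region.

    All (forward window, reverse window) pairs keeping the variant and its
    full recognition window strictly inside the amplicon are enumerated;
    windows containing N are skipped.  Pairs are scored lexicographically by
    summed |Tm - tm_opt|, then summed GC deviation from 50%, then product
    length closeness to ``product_opt``; ties resolve to the leftmost
    windows, making the choice deterministic.  Raises :class:`NoPrimerError`
    naming the binding constraint when nothing qualifies.
    """
    c = constraints or PrimerConstraints()
    seq = region.sequence.upper()
    L = len(enzyme.recognition)
    vo = region.variant_offset
    # primers must clear every recognition placement overlapping the SNP
    win_lo = max(0, vo - L + 1)
    win_hi = min(len(seq), vo + L)
    fails: dict[str, int] = {
        "primer GC outside range": 0, "primer Tm outside range": 0,
        "window contains N": 0, "product length outside range": 0,
    }
    fwds = list(_scan_windows(seq, 0, win_lo, c, reverse=False, fails=fails))
    revs = list(_scan_windows(seq, win_hi, len(seq), c, reverse=True,
                              fails=fails))

    best = None
    for fs, fe, fseq, ftm, fgc in fwds:
        for rs, re_, rseq, rtm, rgc in revs:
            product = re_ - fs
            if not c.product_min <= product <= c.product_max:
                fails["product length outside range"] += 1
                continue
            score = (abs(ftm - c.tm_opt) + abs(rtm - c.tm_opt),
                     abs(fgc - 50.0) + abs(rgc - 50.0),
                     abs(product - c.product_opt),
                     fs, fe, rs, re_)
            if best is None or score < best[0]:
                best = (score, PrimerPair(
                    fwd_seq=fseq, rev_seq=rseq, fwd_tm=ftm, rev_tm=rtm,
                    fwd_gc=fgc, rev_gc=rgc, fwd_start=fs, rev_end=re_))
    if best is None:
        binding = max(fails, key=fails.get)
        if not fwds and fails["primer GC outside range"] >= max(
                fails["primer Tm outside range"], 1):
            binding = "no GC-compliant window"
        raise NoPrimerError(
            f"no primer pair satisfies constraints for region "
            f"{region.chrom}:{region.start}-{region.end}; binding constraint: "
            f"{binding} (rejections: {fails})"
        )
    return best[1]


def check_primer_pair(region: FlankRegion, pair: PrimerPair,
                      enzyme: RestrictionEnzyme = ECORI,
                      constraints: Optional[PrimerConstraints] = None
                      ) -> list[str]:
    """Re-verify every design constraint for a primer pair; returns the list
    of violations (empty = compliant).  Usable on externally designed
    primers as well as on :func:`pick_primers` output."""
    c = constraints or PrimerConstraints()
    seq = region.sequence.upper()
    out = []
    if seq[pair.fwd_start:pair.fwd_start + len(pair.fwd_seq)] != pair.fwd_seq:
        out.append("forward primer does not match region at fwd_start")
    if seq[pair.rev_end - len(pair.rev_seq):pair.rev_end] != revcomp(pair.rev_seq):
        out.append("reverse primer does not match region at rev_end")
    for label, p, tm, gc in (("forward", pair.fwd_seq, pair.fwd_tm, pair.fwd_gc),
                             ("reverse", pair.rev_seq, pair.rev_tm, pair.rev_gc)):
        if not c.min_len <= len(p) <= c.max_len:
            out.append(f"{label} primer length {len(p)} outside range")
        if not c.gc_min <= gc <= c.gc_max:
            out.append(f"{label} primer GC {gc:.1f}% outside range")
        if not c.tm_min <= tm <= c.tm_max:
            out.append(f"{label} primer Tm {tm:.2f} outside range")
    if not c.product_min <= pair.product_length <= c.product_max:
        out.append(f"product length {pair.product_length} outside range")
    L = len(enzyme.recognition)
    vo = region.variant_offset
    fwd_end = pair.fwd_start + len(pair.fwd_seq)
    rev_start = pair.rev_end - len(pair.rev_seq)
    if not (pair.fwd_start < vo < pair.rev_end - 1):
        out.append("variant not strictly inside product")
    if fwd_end > max(0, vo - L + 1) or rev_start < min(len(seq), vo + L):
        out.append("primer overlaps the variant recognition window")
    return out


@dataclass
class RflpAssay:
    """One marker's complete PCR/RFLP assay prediction.

    ``profiles`` maps each allele base to its :class:`DigestProfile`;
    ``cut_allele`` is the allele producing >1 fragment.  Warnings flag
    constitutive sites (cut on both alleles — extra bands that carry no
    information) and fragments under 100 bp (hard to see on 2% agarose).
    """

    marker: str
    primers: PrimerPair
    profiles: dict[str, DigestProfile]
    cut_allele: str
    uncut_allele: str
    warnings: list[str] = field(default_factory=list)
    variant: Optional[Variant] = None

    @property
    def product_length(self) -> int:
        return self.primers.product_length

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "fwd_seq": self.primers.fwd_seq, "rev_seq": self.primers.rev_seq,
            "fwd_tm": round(self.primers.fwd_tm, 2),
            "rev_tm": round(self.primers.rev_tm, 2),
            "fwd_gc": round(self.primers.fwd_gc, 2),
            "rev_gc": round(self.primers.rev_gc, 2),
            "fwd_start": self.primers.fwd_start,
            "rev_end": self.primers.rev_end,
            "product_length": self.product_length,
            "cut_allele": self.cut_allele,
            "uncut_allele": self.uncut_allele,
            "fragments": {a: list(p.fragments)
                          for a, p in self.profiles.items()},
            "warnings": self.warnings,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RflpAssay":
        primers = PrimerPair(
            fwd_seq=d["fwd_seq"], rev_seq=d["rev_seq"],
            fwd_tm=d["fwd_tm"], rev_tm=d["rev_tm"],
            fwd_gc=d["fwd_gc"], rev_gc=d["rev_gc"],
            fwd_start=d["fwd_start"], rev_end=d["rev_end"])
        profiles = {a: DigestProfile(amplicon_length=sum(f),
                                     fragments=tuple(f))
                    for a, f in d["fragments"].items()}
        return cls(marker=d["marker"], primers=primers, profiles=profiles,
                   cut_allele=d["cut_allele"], uncut_allele=d["uncut_allele"],
                   warnings=list(d.get("warnings", [])))


MIN_VISIBLE_FRAGMENT = 100  # bp, 2% agarose heuristic
CO_MIGRATION_BP = 20        # bands closer than this render as one


def predict_assay(region: FlankRegion, primers: PrimerPair,
                  enzyme: RestrictionEnzyme = ECORI,
                  status: Optional[AlleleSiteStatus] = None) -> RflpAssay:
    """Predict per-allele digestion fragments for a designed assay.

    Primers are located in the region by sequence (so externally supplied
    primers work); both allele amplicons are built by substituting the SNP
    base and digested.  Raises if a primer cannot be found in the region or
    if the SNP is not discriminating.
    """
    seq = region.sequence.upper()
    v = region.variant
    if v is None:
        raise ValueError("region carries no variant")
    fs = seq.find(primers.fwd_seq.upper())
    if fs < 0:
        raise ValueError(f"forward primer {primers.fwd_seq} not found in region")
    rc = revcomp(primers.rev_seq.upper())
    rs = seq.find(rc)
    if rs < 0:
        raise ValueError(f"reverse primer {primers.rev_seq} not found in region")
    re_ = rs + len(rc)
    vo = region.variant_offset
    if not fs <= vo < re_:
        raise ValueError("variant falls outside the amplicon")
    if status is None:
        status = allele_site_status(seq, vo, v.ref_allele, v.alt_allele, enzyme)
    if not status.discriminating:
        raise ValueError(f"{v.key}: SNP is not allele-diagnostic for "
                         f"{enzyme.name}")
    cut_allele = status.cut_allele
    uncut_allele = status.alt if cut_allele == status.ref else status.ref

    profiles, warnings = {}, []
    L = len(enzyme.recognition)
    for allele in (status.ref, status.alt):
        amplicon = (seq[fs:vo] + allele + seq[vo + 1:re_])
        profiles[allele] = digest(amplicon, enzyme)
        v_in_amp = vo - fs
        constitutive = [p for p in find_sites(amplicon, enzyme)
                        if not p <= v_in_amp < p + L]
        if constitutive and allele == cut_allele:
            warnings.append(
                f"constitutive {enzyme.name} site(s) at amplicon offset(s) "
                f"{constitutive}: extra band(s) on both alleles")
    small = sorted({f for p in profiles.values() for f in p.fragments
                    if f < MIN_VISIBLE_FRAGMENT})
    if small:
        warnings.append(f"fragment(s) {small} bp under {MIN_VISIBLE_FRAGMENT} "
                        f"bp may be hard to see on 2% agarose")
    return RflpAssay(marker=v.key, primers=primers, profiles=profiles,
                     cut_allele=cut_allele, uncut_allele=uncut_allele,
                     warnings=warnings, variant=v)


# ---------------------------------------------------------------------------
# Gel rendering
# ---------------------------------------------------------------------------

def _merge_bands(fragments: Sequence[int]) -> list[tuple[list[int], bool]]:
    """Cluster fragment sizes that co-migrate (within CO_MIGRATION_BP)."""
    out: list[list[int]] = []
    for f in sorted(fragments, reverse=True):
        if out and out[-1][-1] - f <= CO_MIGRATION_BP:
            out[-1].append(f)
        else:
            out.append([f])
    return [(grp, len(grp) > 1) for grp in out]


def render_gel(assays: Sequence[RflpAssay], strain_code: str,
               rows: int = 18) -> str:
    """ASCII lane diagram of the expected gel for one strain code.

    One lane per assay; bit '1' selects the cut allele's fragments, '0' the
    uncut allele's.  Band vertical position is proportional to -log(bp),
    mimicking electrophoretic migration; bands within
    :data:`CO_MIGRATION_BP` render as one with a co-migration note.
    """
    if len(assays) != len(strain_code):
        raise ValueError("one assay per code bit required")
    lanes, notes = [], []
    for i, (assay, bit) in enumerate(zip(assays, strain_code)):
        allele = assay.cut_allele if bit == "1" else assay.uncut_allele
        bands = _merge_bands(assay.profiles[allele].fragments)
        lanes.append(bands)
        for grp, merged in bands:
            if merged:
                notes.append(f"lane {i + 1}: {'/'.join(map(str, grp))} bp "
                             f"co-migrate as one band")
    all_bp = [g[0] for lane in lanes for g, _ in lane]
    hi, lo = max(all_bp), min(all_bp)
    span = (math.log(hi) - math.log(lo)) or 1.0

    def row_of(bp: int) -> int:
        return round((math.log(hi) - math.log(bp)) / span * (rows - 1))

    width = 7
    grid = [[" " * width for _ in lanes] for _ in range(rows)]
    for j, lane in enumerate(lanes):
        for grp, merged in lane:
            label = f"{grp[0]}{'*' if merged else ''}"
            grid[row_of(grp[0])][j] = f"{label:>5}==".rjust(width)
    header = "".join(f"{'lane ' + str(j + 1):>{width}}"
                     for j in range(len(lanes)))
    body = "\n".join("".join(r) for r in grid)
    text = header + "\n" + body
    if notes:
        text += "\n" + "\n".join("note: " + n for n in notes)
    return text + "\n"


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def regions_to_bed(regions: Iterable[FlankRegion]) -> str:
    """BED (0-based half-open) of the marker flank regions."""
    lines = []
    for r in regions:
        name = r.variant.key if r.variant else f"{r.chrom}:{r.start}-{r.end}"
        lines.append(f"{r.chrom}\t{r.start}\t{r.end}\t{name}")
    return "\n".join(lines) + "\n"


def regions_to_fasta(regions: Iterable[FlankRegion], width: int = 60) -> str:
    """FASTA of the flank regions, one record per marker."""
    chunks = []
    for r in regions:
        name = r.variant.key if r.variant else f"{r.chrom}:{r.start}-{r.end}"
        chunks.append(f">{name} {r.chrom}:{r.start}-{r.end}")
        chunks.extend(r.sequence[i:i + width]
                      for i in range(0, len(r.sequence), width))
    return "\n".join(chunks) + "\n"


def assay_sheet(assays: Sequence[RflpAssay],
                cut_strains: Mapping[str, Sequence[str]],
                regions: Optional[Mapping[str, FlankRegion]] = None) -> str:
    """TSV assay sheet: marker, primers, coordinates, SNP, cut strains,
    expected fragment sizes — the layout of a wet-lab primer table."""
    lines = ["marker\tforward_primer\treverse_primer\tchrom\tstart\tend\t"
             "snp\tproduct_bp\tcut_fragments\tcut_strains"]
    for a in assays:
        v = a.variant
        region = regions.get(a.marker) if regions else None
        chrom = v.chrom if v else "."
        start = str(region.start) if region else "."
        end = str(region.end) if region else "."
        snp = f"{v.ref_allele}/{v.alt_allele}" if v else "."
        frags = "+".join(str(f) for f in a.profiles[a.cut_allele].fragments)
        lines.append("\t".join([
            a.marker, a.primers.fwd_seq, a.primers.rev_seq, chrom, start, end,
            snp, str(a.product_length), frags,
            ",".join(cut_strains.get(a.marker, [])),
        ]))
    return "\n".join(lines) + "\n"


def to_primer3_input(region: FlankRegion,
                     constraints: Optional[PrimerConstraints] = None) -> str:
    """Boulder-IO record for users who prefer designing with primer3."""
    c = constraints or PrimerConstraints()
    name = region.variant.key if region.variant else \
        f"{region.chrom}:{region.start}-{region.end}"
    return "\n".join([
        f"SEQUENCE_ID={name}",
        f"SEQUENCE_TEMPLATE={region.sequence}",
        f"SEQUENCE_TARGET={region.variant_offset},1",
        f"PRIMER_PRODUCT_SIZE_RANGE={c.product_min}-{c.product_max}",
        f"PRIMER_MIN_SIZE={c.min_len}",
        f"PRIMER_MAX_SIZE={c.max_len}",
        f"PRIMER_MIN_TM={c.tm_min}",
        f"PRIMER_OPT_TM={c.tm_opt}",
        f"PRIMER_MAX_TM={c.tm_max}",
        f"PRIMER_MIN_GC={c.gc_min}",
        f"PRIMER_MAX_GC={c.gc_max}",
        "=",
    ]) + "\n"
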
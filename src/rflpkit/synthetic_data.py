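"""Seeded generator of DGRP-like toy fixtures.

Produces a small reference FASTA plus a multi-strain VCF v4.2 of fully
homozygous biallelic SNP calls, with *planted* discriminating markers —
SNPs where exactly one allele completes the enzyme recognition site (the
[G/A]-completes-GAATTC pattern) — whose homozygous genotypes realize a
chosen strains x markers code matrix, and *decoy* SNPs that are clean
homozygous calls but not allele-diagnostic.  Amplicon-scale windows around
planted sites are scrubbed of constitutive recognition sites so each
planted marker yields a clean single-site assay.

Everything derives from ``SynthSpec.seed`` via one PCG64 stream, so the
same spec reproduces byte-identical FASTA/VCF text.  No population-genetic
realism is attempted (no linkage, no site-frequency spectrum): the fixtures
exercise the marker-design logic, not an evolutionary model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .panel_design import required_marker_count
from .restriction import ECORI, IUPAC_CODES, RestrictionEnzyme, \
    allele_site_status, find_sites

BASES = np.array(list("ACGT"))
CHROM = "syn1"


@dataclass
class SynthSpec:
    """Parameters of one synthetic fixture.

    Defaults mirror the motivating use case: 10 inbred strains resolved by
    4 binary markers (2^4 = 16 >= 10) on a toy chromosome long enough for
    four non-overlapping 601-bp marker windows.  ``code_matrix`` (strains x
    markers, bool) overrides the default balanced binary codes 0..n-1.
    ``decoy_density`` is non-discriminating SNPs per bp outside marker
    windows (default one per kb).
    """

    n_strains: int = 10
    n_markers: int = 4
    genome_length: int = 8000
    seed: int = 0
    code_matrix: Optional[np.ndarray] = None
    decoy_density: float = 1e-3
    enzyme: RestrictionEnzyme = ECORI
    flank: int = 300

    def codes(self) -> np.ndarray:
        if self.code_matrix is not None:
            cm = np.asarray(self.code_matrix, dtype=bool)
            if cm.shape != (self.n_strains, self.n_markers):
                raise ValueError(
                    f"code_matrix shape {cm.shape} != "
                    f"({self.n_strains}, {self.n_markers})")
            return cm
        need = required_marker_count(self.n_strains)
        if self.n_markers < need:
            raise ValueError(
                f"{self.n_markers} markers cannot uniquely encode "
                f"{self.n_strains} strains (need >= {need})")
        return np.array(
            [[bool((i >> (self.n_markers - 1 - j)) & 1)
              for j in range(self.n_markers)]
             for i in range(self.n_strains)], dtype=bool)

    @property
    def strains(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_strains)]


def _resolve_site(recognition: str, rng: np.random.Generator) -> str:
    """One concrete A/C/G/T realization of an IUPAC recognition sequence."""
    return "".join(c if len(IUPAC_CODES[c]) == 1
                   else rng.choice(list(IUPAC_CODES[c]))
                   for c in recognition)


def _scrub_window(genome: np.ndarray, lo: int, hi: int,
                  enzyme: RestrictionEnzyme, rng: np.random.Generator,
                  protect: range = range(0)) -> None:
    """Re-randomize bases until [lo, hi) holds no recognition site outside
    ``protect`` (genome coordinates).  Sites overlapping ``protect`` only
    partially get their unprotected bases re-randomized."""
    L = len(enzyme.recognition)
    for _ in range(200):
        window = "".join(genome[lo:hi])
        offending = []
        for p in find_sites(window, enzyme):
            g = lo + p
            span = range(g, g + L)
            if protect and span.start >= protect.start and \
                    span.stop <= protect.stop:
                continue  # the planted site itself
            offending.append(span)
        if not offending:
            return
        for span in offending:
            for pos in span:
                if pos not in protect and lo <= pos < hi:
                    genome[pos] = rng.choice(BASES)
    raise RuntimeError("could not scrub recognition sites from window")


@dataclass
class TruthRecord:
    """Ground truth for one generated fixture (for round-trip checks)."""

    seed: int
    chrom: str
    strains: list[str]
    codes: dict[str, str]            # strain -> bit string, '1' = cut
    markers: list[dict]              # pos, ref, alt, cut_allele per marker
    decoys: list[int]                # decoy positions (1-based)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "chrom": self.chrom,
                "strains": self.strains, "codes": self.codes,
                "markers": self.markers, "decoys": self.decoys}


def generate(spec: SynthSpec) -> tuple[str, str, TruthRecord]:
    """Generate (reference FASTA text, VCF text, truth record).

    Raises ``ValueError`` if the genome cannot hold ``n_markers``
    non-overlapping flank windows.
    """
    rng = np.random.default_rng(spec.seed)
    enzyme = spec.enzyme
    L = len(enzyme.recognition)
    window = 2 * spec.flank + 1
    spacing = spec.genome_length // max(spec.n_markers, 1)
    if spacing < window + L or spec.genome_length < spec.n_markers * (window + L):
        raise ValueError(
            f"genome_length {spec.genome_length} too short for "
            f"{spec.n_markers} non-overlapping {window}-bp marker windows")
    codes = spec.codes()
    if spec.code_matrix is None:
        # default balanced codes are distinct by construction
        pass
    genome = rng.choice(BASES, size=spec.genome_length)

    # non-degenerate position inside the recognition sequence for the SNP
    site_off = next(i for i, c in enumerate(enzyme.recognition)
                    if len(IUPAC_CODES[c]) == 1)

    markers: list[dict] = []
    windows: list[tuple[int, int]] = []
    for j in range(spec.n_markers):
        center = j * spacing + spacing // 2
        lo, hi = center - spec.flank, center + spec.flank + 1
        site_start = center - site_off
        site = _resolve_site(enzyme.recognition, rng)
        genome[site_start:site_start + L] = list(site)
        cut_base = site[site_off]
        noncut = rng.choice([b for b in "ACGT" if b != cut_base])
        ref_is_cut = bool(rng.integers(2))
        ref, alt = (cut_base, noncut) if ref_is_cut else (noncut, cut_base)
        genome[center] = ref
        protect = range(site_start, site_start + L)
        _scrub_window(genome, max(0, lo), min(spec.genome_length, hi),
                      enzyme, rng, protect=protect)
        # verify the planted SNP is allele-diagnostic on both alleles
        ctx_lo = max(0, center - spec.flank)
        ctx = "".join(genome[ctx_lo:min(spec.genome_length, hi)])
        st = allele_site_status(ctx, center - ctx_lo, ref, alt, enzyme)
        if not (st.discriminating and st.cut_allele == cut_base):
            raise RuntimeError("planted marker failed allele-status check")
        markers.append({"id": f"mk{j + 1}", "pos": center + 1, "ref": ref,
                        "alt": alt, "cut_allele": cut_base,
                        "site_start": site_start})
        windows.append((max(0, lo - L), min(spec.genome_length, hi + L)))

    # decoys: clean homozygous SNPs that toggle no overlapping site
    n_decoys = int(round(spec.decoy_density
                         * (spec.genome_length - spec.n_markers * window)))
    in_window = np.zeros(spec.genome_length, dtype=bool)
    for lo, hi in windows:
        in_window[lo:hi] = True
    allowed = np.flatnonzero(~in_window)
    allowed = allowed[(allowed >= L) & (allowed < spec.genome_length - L)]
    decoys: list[dict] = []
    taken: set[int] = set()
    attempts = 0
    while len(decoys) < n_decoys and attempts < 50 * max(n_decoys, 1):
        attempts += 1
        pos = int(rng.choice(allowed))
        if pos in taken:
            continue
        ref = str(genome[pos])
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        ctx_lo, ctx_hi = pos - (L - 1), pos + L
        ctx = "".join(genome[ctx_lo:ctx_hi])
        st = allele_site_status(ctx, pos - ctx_lo, ref, alt, enzyme)
        if st.discriminating:
            continue  # would be a real marker, not a decoy
        gts = rng.integers(0, 2, size=spec.n_strains)
        decoys.append({"pos": pos + 1, "ref": ref, "alt": alt, "gts": gts})
        taken.add(pos)

    # ---- serialize -------------------------------------------------------
    fasta = f">{CHROM}\n" + "\n".join(
        "".join(genome[i:i + 60]) for i in range(0, spec.genome_length, 60)
    ) + "\n"

    strains = spec.strains
    records = []
    for j, mk in enumerate(markers):
        alt_is_cut = mk["alt"] == mk["cut_allele"]
        gt_bits = [(codes[i, j] == alt_is_cut) for i in range(spec.n_strains)]
        records.append((mk["pos"], mk["id"], mk["ref"], mk["alt"],
                        ["1/1" if b else "0/0" for b in gt_bits]))
    for k, d in enumerate(decoys):
        records.append((d["pos"], f"dcy{k + 1}", d["ref"], d["alt"],
                        ["1/1" if g else "0/0" for g in d["gts"]]))
    records.sort(key=lambda r: r[0])

    header = [
        "##fileformat=VCFv4.2",
        "##source=rflpkit-synth",
        f"##synth_seed={spec.seed}",
        f"##contig=<ID={CHROM},length={spec.genome_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(strains),
    ]
    body = [
        "\t".join([CHROM, str(pos), vid, ref, alt, ".", "PASS", ".", "GT"]
                  + gts)
        for pos, vid, ref, alt, gts in records
    ]
    vcf = "\n".join(header + body) + "\n"

    truth = TruthRecord(
        seed=spec.seed, chrom=CHROM, strains=strains,
        codes={s: "".join("1" if codes[i, j] else "0"
                          for j in range(spec.n_markers))
               for i, s in enumerate(strains)},
        markers=markers, decoys=[d["pos"] for d in decoys],
    )
    return fasta, vcf, truth


def write_fixture(spec: SynthSpec, outdir: Union[str, Path]
                  ) -> dict[str, Path]:
    """Generate and write ``ref.fa``, ``calls.vcf`` and ``truth.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta, vcf, truth = generate(spec)
    paths = {"fasta": outdir / "ref.fa", "vcf": outdir / "calls.vcf",
             "truth": outdir / "truth.json"}
    paths["fasta"].write_text(fasta)
    paths["vcf"].write_text(vcf)
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=2) + "\n")
    return paths
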
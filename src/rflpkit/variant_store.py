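"""VCF ingestion for inbred-line genotype panels.

Reads a multi-sample VCF (plain or bgzipped, v4.x) into a strains x variants
homozygous-call matrix and filters it down to the clean biallelic SNPs a
cut/no-cut marker can be built on.  Inbred lines (e.g. DGRP) are expected to
be fully homozygous, so a heterozygous call flags an unreliable site and
disqualifies the *variant*, not the strain.
"""

from __future__ import annotations

import enum
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF


class Call(enum.IntEnum):
    """Diploid genotype collapsed to the categories the marker logic needs."""

    REF_HOM = 0   # 0/0
    ALT_HOM = 1   # 1/1 (or any other homozygous non-reference)
    HET = 2       # 0/1, 1/0, ...
    MISSING = 3   # ./.


class VcfParseError(ValueError):
    """A VCF record could not be parsed; the message carries the record number."""


@dataclass(frozen=True)
class Variant:
    """One VCF record's site information.

    ``pos`` is the 1-based reference coordinate (VCF convention; BED export
    converts to 0-based half-open).  ``alt_allele`` holds the raw ALT field
    (comma-joined when multi-allelic); only records for which
    :attr:`is_biallelic_snp` holds survive :func:`filter_biallelic_snps`.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    vid: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in "ACGT"
            and self.alt_allele in "ACGT"
            and self.ref_allele != self.alt_allele
        )

    @property
    def key(self) -> str:
        """Stable marker identifier, ``chrom:pos:REF>ALT``."""
        return f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


@dataclass
class GenotypeMatrix:
    """Variants x strains table of collapsed diploid calls.

    ``calls[i, j]`` is the :class:`Call` of strain ``strains[j]`` at
    ``variants[i]``.  Strain order is whatever the caller requested, not the
    VCF sample order.
    """

    strains: list[str]
    variants: list[Variant]
    calls: np.ndarray  # shape (n_variants, n_strains), dtype int8

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.strains)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.variants)}, {len(self.strains)})"
            )
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain identifiers")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def call(self, variant_idx: int, strain: str) -> Call:
        return Call(self.calls[variant_idx, self.strains.index(strain)])

    def to_frame(self) -> pd.DataFrame:
        """Human-readable DataFrame (variant keys x strains, Call names)."""
        names = np.array([c.name for c in Call])
        return pd.DataFrame(
            names[self.calls],
            index=[v.key for v in self.variants],
            columns=self.strains,
        )


def _genotype_to_call(alleles: Sequence[int]) -> Call:
    if any(a < 0 for a in alleles):
        return Call.MISSING
    first = alleles[0]
    if all(a == first for a in alleles):
        return Call.REF_HOM if first == 0 else Call.ALT_HOM
    return Call.HET


def read_strain_list(path: Union[str, Path]) -> list[str]:
    """One strain ID per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def load_genotypes(vcf_source, strain_subset: Optional[Iterable[str]] = None,
                   pass_only: bool = False) -> GenotypeMatrix:
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    vcf_source:
        Path to a VCF (plain or bgzipped), a string of VCF text, or a
        file-like object yielding VCF text.
    strain_subset:
        Strain IDs to keep, in the desired output column order.  Empty or
        ``None`` keeps all samples in VCF order.  An unknown ID raises
        ``KeyError`` naming the missing sample(s).
    pass_only:
        If true, drop records whose FILTER is set (anything other than
        PASS / '.').  Off by default: FILTER conventions vary between
        VCF releases.
    """
    with _as_path(vcf_source) as path:
        vcf = VCF(path)
        samples = list(vcf.samples)
        requested = list(strain_subset) if strain_subset else samples
        missing = [s for s in requested if s not in samples]
        if missing:
            raise KeyError(f"strain ID(s) not in VCF samples: {missing}")
        cols = [samples.index(s) for s in requested]

        variants: list[Variant] = []
        rows: list[list[int]] = []
        record_no = 0
        try:
            for rec in vcf:
                record_no += 1
                if pass_only and rec.FILTER is not None:
                    continue
                alt = ",".join(rec.ALT) if rec.ALT else "."
                variants.append(Variant(rec.CHROM, rec.POS, rec.REF, alt,
                                        vid=rec.ID))
                gts = rec.genotypes  # [allele_a, allele_b, phased] per sample
                rows.append([_genotype_to_call(gts[j][:-1]) for j in cols])
        except Exception as exc:
            if isinstance(exc, (KeyError, ValueError)):
                raise
            raise VcfParseError(
                f"malformed VCF record #{record_no + 1}: {exc}"
            ) from exc

        calls = (np.array(rows, dtype=np.int8) if rows
                 else np.empty((0, len(requested)), dtype=np.int8))
        return GenotypeMatrix(strains=requested, variants=variants, calls=calls)


def filter_biallelic_snps(m: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only clean, informative biallelic SNPs.

    Drops records that are not single-base REF / single single-base ALT;
    drops variants with any HET or MISSING call among the selected strains;
    drops monomorphic variants (all strains share one call).  Every retained
    variant therefore partitions the strains into two non-empty groups.
    Idempotent; may return an empty matrix.
    """
    keep: list[int] = []
    for i, v in enumerate(m.variants):
        if not v.is_biallelic_snp:
            continue
        row = m.calls[i]
        if np.any(row == Call.HET) or np.any(row == Call.MISSING):
            continue
        if np.all(row == row[0]):  # monomorphic
            continue
        keep.append(i)
    return GenotypeMatrix(
        strains=list(m.strains),
        variants=[m.variants[i] for i in keep],
        calls=m.calls[keep] if keep else np.empty((0, m.n_strains), dtype=np.int8),
    )


class _as_path:
    """Context manager normalizing a VCF source to a filesystem path.

    Paths pass through; VCF text (str with newlines) and file-like objects
    are materialized to a temporary file for the htslib-based reader.
    """

    def __init__(self, source) -> None:
        self.source = source
        self._tmp: Optional[str] = None

    def __enter__(self) -> str:
        src = self.source
        if isinstance(src, Path):
            return str(src)
        if isinstance(src, str):
            if "\n" not in src:
                return src
            text = src
        elif hasattr(src, "read"):
            text = src.read()
        else:
            raise TypeError(f"cannot read VCF from {type(src).__name__}")
        fd, self._tmp = tempfile.mkstemp(suffix=".vcf")
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        return self._tmp

    def __exit__(self, *exc) -> None:
        if self._tmp is not None:
            os.unlink(self._tmp)
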
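"""Shared fixtures: the published 10-strain / 4-marker cut table, a toy VCF
builder, and a session-scoped synthetic fixture on disk."""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

from rflpkit import CutPatternMatrix, SynthSpec, write_fixture
from rflpkit.synthetic_data import generate

settings.register_profile("det", derandomize=True, max_examples=150)
settings.load_profile("det")

# The published DGRP panel: which strains carry the cut allele at each of
# the four EcoRI markers.
STRAINS = [
    "DGRP-42", "DGRP-57", "DGRP-217", "DGRP-357", "DGRP-391",
    "DGRP-399", "DGRP-437", "DGRP-491", "DGRP-508", "DGRP-810",
]
CUT_SETS = {
    "marker1": {"DGRP-57", "DGRP-42", "DGRP-217", "DGRP-391", "DGRP-357"},
    "marker2": {"DGRP-57", "DGRP-42", "DGRP-399", "DGRP-491", "DGRP-437"},
    "marker3": {"DGRP-57", "DGRP-217", "DGRP-391", "DGRP-399", "DGRP-491",
                "DGRP-810"},
    "marker4": {"DGRP-217", "DGRP-399"},
}
MARKERS = list(CUT_SETS)

# Published forward primers (marker -> sequence); the GC endpoints of the
# panel's forward-primer range.
FWD_PRIMERS = {
    "marker1": "CAGTAACGACGGCAGGATGT",
    "marker2": "ATGTATCGAGAGCACGGCAA",
    "marker3": "TGCATACATTTATCCAAATCGCAAC",
    "marker4": "TCCCTTGGCTGCATTTGTCT",
}
REV_PRIMERS = {
    "marker1": "CTGGCATTGTGTGCGTTCTG",
    "marker2": "TTTTCACGGCGTTCTTTGGA",
    "marker3": "GCGTCAACAAGACCCACAAC",
    "marker4": "CATTTCGATCGCTCCCCCAG",
}


@pytest.fixture
def table_matrix() -> CutPatternMatrix:
    """The 10 x 4 cut-pattern matrix transcribed from the published panel."""
    return CutPatternMatrix.from_cut_sets(STRAINS, CUT_SETS)


def make_vcf(samples: list[str], records: list[tuple]) -> str:
    """Minimal VCF v4.2 text.  Records: (chrom, pos, vid, ref, alt, gts)
    with optional 7th element FILTER (default '.')."""
    contigs = sorted({r[0] for r in records})
    header = ["##fileformat=VCFv4.2"]
    header += [f"##contig=<ID={c},length=100000000>" for c in contigs]
    header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">')
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(samples))
    body = []
    for rec in records:
        chrom, pos, vid, ref, alt, gts = rec[:6]
        filt = rec[6] if len(rec) > 6 else "."
        body.append("\t".join([chrom, str(pos), vid, ref, alt, ".", filt,
                               ".", "GT"] + list(gts)))
    return "\n".join(header + body) + "\n"


@pytest.fixture(scope="session")
def synth_fixture(tmp_path_factory):
    """Default synthetic fixture (10 strains, 4 planted markers) on disk."""
    spec = SynthSpec(seed=11)
    outdir = tmp_path_factory.mktemp("synth")
    paths = write_fixture(spec, outdir)
    _, _, truth = generate(spec)
    return {"spec": spec, "truth": truth, "fasta": paths["fasta"],
            "vcf": paths["vcf"], "truth_path": paths["truth"]}
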
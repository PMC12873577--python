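"""Flank extraction, GC ranking, primer picking, fragment prediction and
gel rendering."""

import numpy as np
import pytest

from rflpkit import (
    ECORI,
    DigestProfile,
    FlankRegion,
    NoPrimerError,
    PrimerConstraints,
    PrimerPair,
    ReferenceMismatchError,
    RflpAssay,
    Variant,
    check_primer_pair,
    digest,
    extract_flank,
    gc_percent,
    pick_primers,
    predict_assay,
    primer_tm,
    rank_candidates,
    regions_to_bed,
    render_gel,
    revcomp,
    to_primer3_input,
)

from conftest import FWD_PRIMERS, REV_PRIMERS


def _region_from(seq: str, vo: int, ref: str, alt: str,
                 chrom: str = "c", start: int = 0) -> FlankRegion:
    v = Variant(chrom, start + vo + 1, ref, alt)
    return FlankRegion(chrom=chrom, start=start, end=start + len(seq),
                       sequence=seq, variant_offset=vo,
                       gc=gc_percent(seq), variant=v)


def _clean_random_seq(rng, n: int) -> str:
    """Random sequence guaranteed free of EcoRI sites."""
    from rflpkit import find_sites
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=n))
        if not find_sites(seq, ECORI):
            return seq


class TestGcPercent:
    @pytest.mark.parametrize("seq,expected", [
        (FWD_PRIMERS["marker3"], 36.0),   # published forward-GC lower end
        (FWD_PRIMERS["marker1"], 55.0),   # published forward-GC upper end
        ("GGCC", 100.0),
        ("atgc", 50.0),                   # case-insensitive
        ("GCNN", 50.0),                   # N counts in denominator only
    ])
    def test_values(self, seq, expected):
        assert gc_percent(seq) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_percent("")


class TestExtractFlank:
    def test_toy_arithmetic(self):
        ref = {"c": "AAAAGAATTCAAAA"}
        v = Variant("c", 5, "G", "A")
        r = extract_flank(ref, v, flank=3)
        assert (r.start, r.end) == (1, 8)
        assert r.sequence == "AAAGAAT" and r.variant_offset == 3
        assert r.sequence[r.variant_offset] == "G"

    def test_full_flank_and_offset(self):
        rng = np.random.default_rng(0)
        chrom = "".join(rng.choice(list("ACGT"), size=2000))
        pos = 1000
        v = Variant("c", pos, chrom[pos - 1], "A" if chrom[pos - 1] != "A"
                    else "C")
        r = extract_flank({"c": chrom}, v, flank=300)
        assert r.end - r.start == 601 and r.variant_offset == 300
        assert (r.start, r.end) == (pos - 1 - 300, pos + 300)

    def test_clipped_at_chromosome_start(self):
        ref = {"c": "TTGAATTC" + "A" * 700}
        v = Variant("c", 3, "G", "A")
        r = extract_flank(ref, v, flank=300)
        assert r.start == 0 and r.variant_offset == 2

    def test_stale_reference_detected(self):
        ref = {"c": "AAAA"}
        with pytest.raises(ReferenceMismatchError, match="stale"):
            extract_flank(ref, Variant("c", 2, "G", "T"), flank=1)

    def test_unknown_chromosome(self):
        with pytest.raises(KeyError):
            extract_flank({"c": "ACGT"}, Variant("chrX", 2, "C", "T"))

    def test_reads_fasta_from_disk(self, tmp_path):
        fa = tmp_path / "r.fa"
        fa.write_text(">c\nAAAAGAATTCAAAA\n")
        r = extract_flank(fa, Variant("c", 5, "G", "A"), flank=3)
        assert r.sequence == "AAAGAAT"


class TestRankCandidates:
    def test_closest_to_fifty_first(self):
        seqs = {36: "G" * 36 + "A" * 64, 50: "G" * 50 + "A" * 50,
                65: "G" * 65 + "A" * 35}
        regions = [_region_from(seqs[gc], 10, seqs[gc][10],
                                "C" if seqs[gc][10] != "C" else "T",
                                start=i * 1000)
                   for i, gc in enumerate([36, 50, 65])]
        ranked = rank_candidates(regions)
        assert [round(r.gc) for r in ranked] == [50, 36, 65]

    def test_ties_keep_genomic_order(self):
        seq = "G" * 45 + "A" * 55
        r1 = _region_from(seq, 10, "G", "A", start=100)
        r2 = _region_from(seq, 10, "G", "A", start=900)
        assert rank_candidates([r2, r1]) == [r1, r2]

    def test_agrees_with_brute_force_sort(self):
        rng = np.random.default_rng(2)
        regions = []
        for i in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            regions.append(_region_from(seq, 40, seq[40],
                                        "A" if seq[40] != "A" else "C",
                                        start=int(rng.integers(0, 10000))))
        ranked = rank_candidates(regions)
        oracle = sorted(regions,
                        key=lambda r: (abs(r.gc - 50), r.chrom, r.start))
        assert ranked == oracle


class TestPickPrimers:
    def test_satisfies_all_constraints(self):
        rng = np.random.default_rng(7)
        seq = _clean_random_seq(rng, 601)
        seq = seq[:300] + "G" + "AATTC" + seq[306:]  # discriminating site
        region = _region_from(seq, 300, "G", "A")
        c = PrimerConstraints()
        pair = pick_primers(region, ECORI, c)
        assert check_primer_pair(region, pair, ECORI, c) == []
        # independent re-verification of every constraint range
        for p, tm, gc in [(pair.fwd_seq, pair.fwd_tm, pair.fwd_gc),
                          (pair.rev_seq, pair.rev_tm, pair.rev_gc)]:
            assert c.min_len <= len(p) <= c.max_len
            assert c.gc_min <= gc_percent(p) <= c.gc_max
            assert c.tm_min <= primer_tm(p) <= c.tm_max
            assert gc == pytest.approx(gc_percent(p))
            assert tm == pytest.approx(primer_tm(p))
        assert c.product_min <= pair.product_length <= c.product_max
        # primers anchor the amplicon and clear the recognition window
        assert seq[pair.fwd_start:].startswith(pair.fwd_seq)
        assert seq[:pair.rev_end].endswith(revcomp(pair.rev_seq))
        assert pair.fwd_start + len(pair.fwd_seq) <= 300 - 5
        assert pair.rev_end - len(pair.rev_seq) >= 300 + 6

    def test_homopolymer_region_fails_with_gc_reason(self):
        region = _region_from("A" * 601, 300, "A", "G")
        with pytest.raises(NoPrimerError, match="GC"):
            pick_primers(region, ECORI)

    def test_published_primers_pass_gc_bounds(self):
        c = PrimerConstraints()
        for mk in FWD_PRIMERS:
            assert c.gc_min <= gc_percent(FWD_PRIMERS[mk]) <= c.gc_max
            assert c.gc_min <= gc_percent(REV_PRIMERS[mk]) <= c.gc_max

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        seq = _clean_random_seq(rng, 601)
        seq = seq[:300] + "GAATTC" + seq[306:]
        region = _region_from(seq, 300, "G", "T")
        assert pick_primers(region) == pick_primers(region)


class TestPredictAssay:
    def _marker3_like(self):
        """326-bp amplicon whose cut point is 213 bp from the 5' end."""
        rng = np.random.default_rng(12)
        seq = _clean_random_seq(rng, 400)
        fs = 30
        # site start 212 bp into the amplicon -> cut point 212 + 1 = 213
        amp_site = fs + 212
        seq = seq[:amp_site] + "GAATTC" + seq[amp_site + 6:]
        region = _region_from(seq, amp_site, "G", "A")
        fwd = seq[fs:fs + 20]
        rev = revcomp(seq[fs + 306:fs + 326])
        pair = PrimerPair(fwd_seq=fwd, rev_seq=rev,
                          fwd_tm=60.0, rev_tm=60.0,
                          fwd_gc=gc_percent(fwd), rev_gc=gc_percent(rev),
                          fwd_start=fs, rev_end=fs + 326)
        return region, pair

    def test_cut_allele_fragments_213_113(self):
        region, pair = self._marker3_like()
        assay = predict_assay(region, pair, ECORI)
        assert assay.product_length == 326
        assert assay.profiles[assay.cut_allele].fragments == (213, 113)

    def test_uncut_allele_single_fragment(self):
        region, pair = self._marker3_like()
        assay = predict_assay(region, pair, ECORI)
        assert assay.profiles[assay.uncut_allele].fragments == (326,)

    def test_constitutive_site_warned(self):
        rng = np.random.default_rng(13)
        seq = _clean_random_seq(rng, 400)
        fs, amp_site = 30, 30 + 212
        seq = seq[:amp_site] + "GAATTC" + seq[amp_site + 6:]
        seq = seq[:fs + 50] + "GAATTC" + seq[fs + 56:]   # allele-independent
        region = _region_from(seq, amp_site, "G", "A")
        fwd, rev = seq[fs:fs + 20], revcomp(seq[fs + 306:fs + 326])
        pair = PrimerPair(fwd_seq=fwd, rev_seq=rev, fwd_tm=60, rev_tm=60,
                          fwd_gc=gc_percent(fwd), rev_gc=gc_percent(rev),
                          fwd_start=fs, rev_end=fs + 326)
        assay = predict_assay(region, pair, ECORI)
        assert len(assay.profiles[assay.cut_allele].fragments) == 3
        assert len(assay.profiles[assay.uncut_allele].fragments) == 2
        assert any("constitutive" in w for w in assay.warnings)

    def test_fragment_conservation_on_random_assays(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            seq = _clean_random_seq(rng, 500)
            fs = int(rng.integers(0, 40))
            site = fs + int(rng.integers(60, 250))
            seq = seq[:site] + "GAATTC" + seq[site + 6:]
            plen = int(rng.integers(site - fs + 20, 420))
            region = _region_from(seq, site, "G", "C")
            fwd = seq[fs:fs + 20]
            rev = revcomp(seq[fs + plen - 20:fs + plen])
            pair = PrimerPair(fwd_seq=fwd, rev_seq=rev, fwd_tm=60, rev_tm=60,
                              fwd_gc=gc_percent(fwd), rev_gc=gc_percent(rev),
                              fwd_start=fs, rev_end=fs + plen)
            assay = predict_assay(region, pair, ECORI)
            cut = assay.profiles[assay.cut_allele]
            assert sum(cut.fragments) == plen and len(cut.fragments) >= 2
            assert assay.profiles[assay.uncut_allele].fragments == (plen,)

    def test_missing_primer_rejected(self):
        region, pair = self._marker3_like()
        bad = PrimerPair(fwd_seq="GGGGGGGGGGGGGGGGGGGG", rev_seq=pair.rev_seq,
                         fwd_tm=60, rev_tm=60, fwd_gc=100, rev_gc=50,
                         fwd_start=0, rev_end=pair.rev_end)
        with pytest.raises(ValueError, match="not found"):
            predict_assay(region, bad, ECORI)

    def test_strand_consistency_mirrored_fragments(self):
        # digesting the reverse complement yields mirrored fragment sizes
        rng = np.random.default_rng(15)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            fwd = digest(seq, ECORI).fragments
            rev = digest(revcomp(seq), ECORI).fragments
            assert rev == tuple(reversed(fwd))


class TestRenderGel:
    def _assay(self, cut_frags, plen):
        pair = PrimerPair(fwd_seq="A" * 20, rev_seq="T" * 20, fwd_tm=60,
                          rev_tm=60, fwd_gc=50, rev_gc=50, fwd_start=0,
                          rev_end=plen)
        return RflpAssay(
            marker="m", primers=pair,
            profiles={"G": DigestProfile(plen, tuple(cut_frags)),
                      "A": DigestProfile(plen, (plen,))},
            cut_allele="G", uncut_allele="A")

    def test_cut_lane_two_bands(self):
        text = render_gel([self._assay((213, 113), 326)], "1")
        assert "213==" in text and "113==" in text

    def test_uncut_lane_single_band(self):
        text = render_gel([self._assay((213, 113), 326)], "0")
        assert "326==" in text and "213" not in text

    def test_close_fragments_merge_with_note(self):
        text = render_gel([self._assay((210, 200), 410)], "1")
        assert "co-migrate" in text and "210/200" in text

    def test_one_lane_per_bit_required(self):
        with pytest.raises(ValueError):
            render_gel([self._assay((213, 113), 326)], "10")


class TestExports:
    def test_bed_is_zero_based_half_open(self):
        r = _region_from("AAAAGAATTCAAAA", 4, "G", "A", chrom="3L",
                         start=12248747)
        line = regions_to_bed([r]).strip().split("\t")
        assert line[:3] == ["3L", "12248747", str(12248747 + 14)]

    def test_primer3_export_boulder_format(self):
        r = _region_from("ACGTACGTACGT", 5, "C", "T")
        text = to_primer3_input(r)
        assert "SEQUENCE_TEMPLATE=ACGTACGTACGT" in text
        assert "SEQUENCE_TARGET=5,1" in text
        assert text.rstrip().endswith("=")
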
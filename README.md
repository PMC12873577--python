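# rflpkit

Design and decode minimal RFLP/CAPS marker panels for routine authentication
of inbred laboratory strains.

## The problem

Laboratories that maintain panels of sequenced inbred lines — Drosophila
DGRP stocks are the motivating case — need a fast, cheap way to confirm that
a vial labelled *strain X* really is strain X. Whole-genome or Sanger
sequencing is overkill for routine checks; a classic solution is the
cleaved amplified polymorphic sequence (CAPS) assay: PCR a short region
containing a SNP where **one allele completes a restriction-enzyme
recognition site** (e.g. a [G/A] SNP whose G creates EcoRI's `GAATTC`),
digest, and read cut vs. no-cut off a 2% agarose gel.

Each such marker yields one bit of information per strain, so a panel of
*k* markers distinguishes at most 2^k strains and *n* strains need at least
⌈log₂ n⌉ markers — a dichotomous key in gel form. rflpkit automates the
whole computational side:

1. **variant_store** — load a multi-sample VCF of homozygous inbred-line
   calls, keep clean biallelic SNPs that split the strains.
2. **restriction** — IUPAC site scanning, per-allele cut status at each
   SNP, complete in-silico digestion (EcoRI `G^AATTC` by default; the
   bundled catalogue TSV is editable).
3. **panel_design** — greedy selection of an ordered marker panel whose
   cut/no-cut codes are unique per strain, with tiering (which markers are
   optional for which strains), residual-ambiguity reporting, and decoding
   of observed patterns back to strain identity (MATCH / AMBIGUOUS /
   NO_MATCH).
4. **assay_design** — 300-bp flank extraction, GC ranking, window-scan
   primer picking (Tm 59–61 °C by nearest-neighbor thermodynamics, GC
   35–60%, product 300–450 bp), per-allele fragment-size prediction, and an
   ASCII expected-gel rendering.
5. **synthetic_data** — seeded DGRP-like fixtures (reference FASTA +
   VCF + truth JSON) with planted discriminating SNPs, for end-to-end
   testing without downloads.

## Worked example

Generate a 10-strain toy fixture and design its panel:

```sh
$ rflpkit synth --seed 42 --out-dir fixture
$ rflpkit design fixture/calls.vcf fixture/ref.fa --out-dir panel
panel: 4 markers over 10 strains
  S01	0000
  S02	1000
  ...
  S10	1001
```

Ten strains resolve with exactly ⌈log₂ 10⌉ = 4 markers; each strain's code
is its cut (1) / no-cut (0) pattern across the panel in order. The output
directory holds `panel.json` (codes, tiers, residual ambiguities),
`panel.tsv`, `markers.bed`, `flanks.fa`, and the assay sheet:

```
marker         forward_primer               reverse_primer               product_bp  cut_fragments
syn1:7001:A>G  TTTAGAAGCGTAGTCGCTATTTCGCCT  AATGTACGTAAAGAGTAATCCCCCGCC  353         211+142
syn1:5001:C>G  ACTATCACGAATGCTTCGACGATTCCA  GAGTGATTAAACGCTCGAGACCCTGAT  396         232+164
...
```

A strain whose cut allele is present yields the two `cut_fragments` bands;
the other allele runs as a single `product_bp` band. Decode a gel result:

```sh
$ rflpkit authenticate panel/panel.json "cut,not,cut,not"
MATCH
candidates: S06
```

Exit codes are scriptable: 0 MATCH, 3 AMBIGUOUS (e.g. a partial pattern
consistent with several strains), 4 NO_MATCH (mislabeled or contaminated
stock). `rflpkit gel panel/assays.json panel/panel.json S03` prints the
expected lane diagram for strain S03, and `rflpkit verify-panel` re-checks
a saved panel's internal consistency.

The same operations are available as a library
(`from rflpkit import load_genotypes, select_panel, authenticate, ...`);
see `docs/methods.md` for the model and parameter choices.

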
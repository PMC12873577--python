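# Methods

## Model

A CAPS/RFLP marker is a biallelic SNP at which exactly one allele completes
a restriction-enzyme recognition site overlapping the variant base. For
fully inbred lines every informative site is homozygous, so each marker
assigns each strain one bit — cut or not cut — and a panel of *k* markers
encodes at most 2^k strains. The package's job is to find, from a
multi-sample VCF and a reference FASTA, a small ordered set of such SNPs
whose bit codes are pairwise distinct, and to design the PCR/digest assay
for each.

Assumptions baked into the model:

* **Homozygosity.** A heterozygous or missing call at a candidate site
  disqualifies the *variant*, not the strain: in an inbred panel a het call
  signals an unreliable site, and a cut/no-cut marker must be binary per
  strain. Multi-allelic records are dropped rather than decomposed, since
  the assay reads only two states off the gel.
* **Complete digestion.** Fragment prediction assumes every site is cut;
  partial digestion, methylation sensitivity and star activity are not
  modeled.
* **Single-strand scanning.** Site search runs on the given strand only.
  The default enzyme (EcoRI, `G^AATTC`, cut offset 1) is palindromic, so
  this loses nothing; non-palindromic enzymes from the editable catalogue
  TSV can be scanned with `both_strands=True`.
* **Allele dependence is local.** A SNP's cut status considers only
  recognition matches *overlapping* the variant base. Matches elsewhere in
  the amplicon are allele-independent ("constitutive"): they shift both
  alleles' fragment patterns identically, carry no information, and are
  flagged as assay-design warnings instead.

The VCF FILTER column is ignored by default (`--pass-only` honours PASS),
because FILTER conventions differ between genotype releases. Coordinates
are 1-based internally (VCF convention); BED export is 0-based half-open.

## Panel selection

`required_marker_count(n) = ⌈log₂ n⌉` is the information-theoretic floor.
Selection is greedy: starting from one all-strains ambiguity class, each
step adds the candidate that minimizes the size of the largest remaining
class, breaking ties by fewest unresolved strain pairs, then by a
caller-supplied ranking (the CLI ranks flank regions by GC closeness to
50%, the same ordering used to prioritize primer design), then by
lexicographic marker ID. The loop stops when all codes are unique or no
candidate improves the (largest class, unresolved pairs) pair; leftover
classes are reported as explicit residual ambiguities rather than raising —
a three-marker panel for ten strains is a legitimate intermediate state
that simply leaves two tied pairs.

Exact minimality of greedy set-splitting is not guaranteed in general (the
underlying problem is set-cover-like), so `exhaustive_min_panel` provides a
brute-force oracle for ≤ 20 candidates; the test suite uses it to confirm
greedy optimality on balanced planted matrices and on matrices with
redundant candidates.

Tiering reproduces the dichotomous-key reading of a panel: marker *m* is
*optional* for strain *s* if removing *m* still leaves *s*'s code unique;
`tiers[m]` lists the strain groups that would collapse without *m* — the
groups *m* exists to separate.

Authentication is subset-consistent matching: an observed pattern may be
shorter than the panel or contain explicit `untested` positions, and a
strain is consistent iff its code agrees at every tested position. Exactly
one consistent strain ⇒ MATCH; several ⇒ AMBIGUOUS with the candidate set;
none ⇒ NO_MATCH, the mislabeling/contamination signal.

## Assay design

Flanks default to 300 bp each side of the SNP (601-bp regions), clipped at
chromosome ends. Candidate regions are ranked by |GC − 50%| ascending —
the ranking's purpose is primer-design feasibility, and near-50% GC is
where primer constraints are easiest to satisfy.

Primer picking is a deterministic window scan rather than a call into an
external design binary: all 18–27-nt windows clear of the variant's
recognition window are enumerated on both sides, filtered to GC ∈ [35, 60]%
and Tm ∈ [59, 61] °C, paired under a product length of 300–450 bp, and
scored lexicographically by summed |Tm − 60|, then summed |GC − 50|, then
product closeness to 380 bp, with positional tie-breaks making the result
reproducible. A Boulder-IO export (`to_primer3_input`) is provided for
users who prefer designing with primer3 itself. Tm uses nearest-neighbor
thermodynamics (biopython's unified SantaLucia table) with fixed
conditions: 50 mM Na⁺, 50 nM primer, no divalents. Published Tm values for
the same primer under a different parameter set can differ by ~1 °C, so Tm
is a constraint here, never a reproduction target.

Fragment prediction substitutes each allele at the SNP, digests the
amplicon completely, and checks the conservation invariants (fragments sum
to product length; cut allele ≥ 2 fragments; uncut allele exactly 1).
Warnings cover constitutive sites and fragments under 100 bp (hard to see
on 2% agarose). The gel renderer places bands at height proportional to
−log(bp) and merges bands within 20 bp into one annotated band; both
thresholds are heuristics for 2% agarose and are module constants.

Degenerate inputs: an empty amplicon, a cut point falling exactly on an
amplicon edge (dropped with a log message — the site is truncated), a
homopolymer region (primer search fails naming the binding constraint), and
a reference base disagreeing with the VCF REF (raised as a stale
VCF/reference pairing) are all handled explicitly.

## Synthetic data

The generator emulates an inbred-panel genotype release at toy scale:
uniform-random background sequence, `n_markers` planted discriminating
SNPs realizing a strains × markers code matrix (default: the balanced
binary codes 0…n−1, so ten strains get exactly four markers), and decoy
SNPs (default density 1 SNP/kb) that are clean homozygous calls toggling no
recognition site. Marker windows (601 bp) are scrubbed of constitutive
recognition sites by re-randomizing offending hexamers, so every planted
assay is single-site; whether the reference carries the cut or the non-cut
allele is random per marker. Everything derives from one seeded PCG64
stream and the seed is recorded in the VCF header, making fixtures
byte-reproducible. Defaults (10 strains, 4 markers, 8-kb genome) keep a
full generate→design→authenticate round trip under ~50 ms, so the suite
runs it across 100 seeds.

What the fixtures deliberately lack: linkage disequilibrium, realistic
site-frequency spectra, sequencing error, and low-complexity/repetitive
sequence. Passing round trips therefore demonstrate the correctness of the
marker logic and plumbing, not robustness to real-genome artifacts such as
paralogous amplification or reference gaps.

## Design choices where the design was open

* **Cut-offset convention.** Fragment sizes are computed from the
  top-strand cleavage point within the recognition sequence (`G^AATTC` ⇒
  offset 1); with this convention a single-site 433-bp amplicon whose site
  starts 182 bp in yields 183 + 250.
* **Greedy criterion.** "Split the largest ambiguity class" was chosen over
  alternatives (e.g. maximize entropy) because it directly targets the
  worst-case residual group and reproduces minimal panels on balanced
  inputs, verified against the exhaustive oracle.
* **GC ranking direction.** Closest-to-50% first (not ascending or
  descending GC), since the ranking exists to feed primer design.
* **Residual ambiguity is a state, not an error** — it is the natural
  intermediate while markers are being added, and the CLI maps it to a
  distinct exit code (3) so maintenance scripts can react.

## Known limitations

No genome-wide specificity screening of primers (a primer pair is checked
only within its flank region), no multiplex-PCR compatibility scoring, no
dCAPS mismatch-primer design, no mixture/contamination deconvolution, and
no probabilistic treatment of genotype uncertainty. The exhaustive
minimality oracle is capped at 20 candidate markers by design.
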
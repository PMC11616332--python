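# Methods

## Coordinate and cut-site model

All coordinates are 0-based, half-open, on the amplicon's plus strand;
cut sites are between-base indices. For a guide whose protospacer+PAM is
placed on either strand, the blunt Cas9 cut lies 3 nt 5′ of the PAM on
the protospacer-bearing strand. The staggered-cut donor is the base
adjacent to the blunt cut on the side away from the PAM — the 4th
nucleotide upstream of the PAM on the non-target strand, which RuvC
sometimes cuts past, leaving a 1-nt 5′ overhang whose fill-in duplicates
that base. Guides whose extra placements fall fully inside the repeat
tract are legitimate (a repeat-targeting guide cuts at many registers);
the leftmost placement is canonical and the multiplicity is reported.
More than one placement outside the tract is an error.

## The bundled locus

The bundled amplicon is synthetic: 40 nt left flank + (CAG)41 + 79 nt
right flank = 242 bp. Real repeat-flanking sequence is
construct-specific, so every operation takes the locus as a parameter
(FASTA + JSON sidecar); the synthetic default keeps the package
self-contained while reproducing the geometry that matters:

- a minus-strand guide (`g_upstream`) cutting 2 nt upstream of the
  tract, whose staggered-donor base is **A** — its +1 product is the
  single-A insertion characteristic of a staggered cut at this flank;
- a plus-strand in-tract guide (`g_tract`) with a noncanonical NAG PAM
  and 34 cut registers;
- a plus-strand downstream guide (`g_downstream`) cutting 58 nt past the
  tract;
- ≥ 14 microhomology pairs (CC, CA, CCTT, TGG, ≥ 2 nt) bracketing the
  tract within 10 nt of its ends, so microhomology-anchored whole-tract
  deletions exist in both frames;
- flanks free of any CAG triplet, and verified free of deletion-placement
  ambiguity that could slide a flank deletion into the tract.

## Alignment

Reads are merged per template and aligned fully globally to the amplicon
with affine gaps (match +1, mismatch −2, a gap of length L costs
6 + 0.5·L), via Bio.Align.PairwiseAligner. Full global — rather than
free reference end gaps — is deliberate: amplicon reads are
primer-defined and span the molecule end to end, and free end gaps were
observed to absorb genuine deletions adjacent to the amplicon ends as
zero-cost clips. Identity is read-centric (matches over read-consuming
columns): a read carrying a real 131-nt deletion is ~100 % identical,
while random 250-mers measure 0.26–0.47 and are rejected at the 0.6
threshold. Indels are then left-normalized (each event shifted to its
leftmost equivalent placement, insertions with cyclic rotation), making
junction coordinates reproducible across aligners; the pass is
idempotent and is validated against brute-force enumeration of
equivalent placements.

Pair merging maximizes ungapped overlap matches, resolves disagreements
to the higher-quality base (merged quality = max), and returns UNMERGED
below 20 nt overlap or above 10 % overlap mismatch. "Quality below 5" is
read as mean Phred < 5, boundary inclusive on the keep side.

## Classification

Per read: net indel Δ = Σins − Σdel; frameshift ⇔ Δ mod 3 ≠ 0. The
repeat count is the longest exact tandem run of the motif — computed on
the read's *inferred template* (the reference with the alignment's
indels applied, i.e. sequencing substitutions reverted). This mirrors
the tolerant tandem-repeat detection of instrument pipelines: at 1 %
substitution error ~70 % of reads carry an error inside a 123-nt tract,
and a raw exact-run count would fragment and miscall them as
contractions. `count_repeats` itself (exact-run, leftmost tie-break) is
exposed and oracle-tested separately.

Categories: no indels → UNEDITED; frameshift → INS / DEL / INDEL by
event kinds; in-frame with more/fewer units than the reference →
INS_CAG / DEL_CAG. In-frame indels that leave the unit count unchanged
(pure-flank in-frame events) get the explicit internal label
OTHER_INFRAME rather than being silently folded into a headline
category; summaries report it as its own key so the six-category table
stays interpretable.

Flank-change and whole-tract-excision flags are computed over the
*placement-ambiguity range* of each indel: a deletion counts as
tract-only if **some** equivalent placement lies entirely inside the
tract, and as whole-tract if some placement covers it — left-alignment
alone would overcall flank changes at the tract's left edge and miss
coverage at its right edge. Insertions are tract-internal if some
placement falls strictly between the tract boundaries (a non-repeat base
inserted exactly at the boundary is a flank change; a repeat-phase
insertion shifts inside and is not).

Signatures: junction microhomology of the longest deletion is the
longest word (≤ 10 nt) repeated at both junctions, maximum over the
left-side and right-side registers; templated insertions are inserted
sequences ≥ 4 nt with an exact local donor within ±25 nt (longest
prefix/suffix fallback, nearest donor); the staggered-cut flag requires
a 1-nt insertion within 1 nt of a guide's blunt cut matching its donor
base.

## Stutter

PCR slippage over a long repeat produces whole-unit length changes even
in unedited samples. `estimate_stutter` takes the empirical distribution
of unit deviations among in-frame, tract-only reads of an unedited
control; `summarize` can then subtract the kernel, scaled by the
observed unedited fraction, from the in-frame tract-only deviation mass
(non-negativity clamp, renormalized). Both raw and corrected tables are
always reported — the correction is a first-order deconvolution, not a
model fit. The generator's stutter law (slip probability 0.1, geometric
magnitude p = 0.5, 9:1 contraction bias, clamped at zero; zero-unit
templates cannot slip for lack of repeats to misprime on) is a
placeholder: real stutter rates are locus- and polymerase-specific and
should be estimated from a control sample.

## Synthetic reads

The generator emulates deep sequencing of the edited amplicon: 250-bp
reads (merged or paired with guaranteed overlap), constant Phred-30
qualities, optional uniform substitution errors, one truth row per read
(class, intended category, unit count, net Δ, signature flags). Outcome
classes and their defaults:

- WHOLE_TRACT_MH_DEL samples uniformly among all deletions spanning the
  tract plus 0–10 nt of each flank whose junctions carry ≥ 2 nt of
  microhomology.
- INFRAME_DEL_CAG / INS_CAG remove/add geometric numbers of units
  (p = 0.15 / 0.5; removal capped at expected − 1 so the tract never
  vanishes, addition capped at 10 units to stay within read length).
- STAGGERED_INS duplicates the guide's donor base at the blunt cut;
  TEMPLATED_INS copies 4–12 nt from within 25 nt upstream of the cut.
- FLANK_DEL deletes 1–12 nt in the flank at the cut, on the side away
  from the tract.
- COMPLEX is built from two *separated* lesions: a 4–10 nt deletion at
  the cut plus a ≥ 7 nt random insertion in the opposite flank, net
  frameshift enforced. A deletion-plus-insert at a single junction next
  to the elastic repeat is **not** uniquely recoverable by any optimal
  affine aligner (the insert is score-equivalently absorbed as
  mismatches whenever it is short or partially matches), so the
  composite class is constructed from events that survive alignment —
  a generator condition, not a classifier workaround.
- DUAL_CUT_EXCISION deletes between the outermost blunt cuts of two
  guides.

Truth categories/flags are derived from the constructed event list by
the same frame/geometry arithmetic the classifier uses, so
generator→classifier closure tests exercise the entire read path
(FASTQ → alignment → normalization → classification), which is where
all the nontrivial failure modes live.

What the simulations do **not** model: position-dependent Illumina error
profiles, indel sequencing errors, chimeras, adapter read-through, real
stutter spectra, and allele mixtures. Passing tests therefore
demonstrate correctness of the analytical pipeline under controlled
conditions, not robustness to every artifact of real libraries.

## Assay calculators

**Resection.** ssDNA% = 100 / (2^(ΔCq−1) + 0.5), ΔCq = Cq(digested) −
Cq(mock); 100 % at ΔCq = 0, strictly decreasing, → 0. Negative ΔCq is
clamped to 100 % with a warning. Technical replicates are averaged on
the Cq scale before exponentiation; biological replicates are summarized
(mean ± SD) after transformation. The unedited-sample level per site is
the detection cutoff (10 % default when no unedited table is supplied);
the flag-based report avoids asserting whether a baseline should be
subtracted. The generator inverts the formula analytically
(ΔCq = log2(100/ssDNA% − 0.5) + 1), so the round trip is exact at zero
noise.

**ChIP/DRIP.** recovery% = 100 · 2^((Cq_input − log2 dilution) − Cq_IP);
fold enrichment = target recovery / reference recovery, significant at
≥ 2 (inclusive). ANOVA-style testing across replicates is out of scope;
tables carry means/SDs for downstream statistics packages.

**Capillary electrophoresis.** Peaks below 5 % of the sample's tallest
peak height are background (boundary inclusive: exactly 5 % is kept).
Full-length matching uses a ±2 bp sizing window (configurable; CE sizing
error). percent_shortened is the area share of peaks *below* the window;
peaks above it are reported separately as possible expansions rather
than being counted as shortened.

**LFQ.** Proteins are dropped only when *both* groups have fewer than 3
valid values (the "either" reading; the stricter both-groups variant is
a flag). Intensities are log10 (matching volcano-plot convention);
missing values are imputed per sample from
Normal(mean − 1.8·sd, (0.3·sd)²) of that sample's observed moments
(global-moment option available). The t-test is equal-variance
two-sample (the classical default for this pipeline; Welch by flag),
q-values Benjamini–Hochberg, with a seeded permutation-FDR option.
Significance: q < 0.05 and linear |fold change| ≥ 1.5, where
fold change = ±10^|difference|, signed by direction (test − reference
group, groups ordered alphabetically). The simulator's replicate noise
default (log10 SD 0.10, ~25 % CV — mid-range for LFQ replicates) is
chosen so its reference design (log2 effect 1.5, 5 + 5 replicates,
2000 proteins, 100 shifted) is well-powered: recall ≥ 0.9 at q < 0.05
with empirical FDR at the nominal level. MNAR missingness uses a
logistic dropout in intensity (steepness 0.25 log10 units, midpoint
1.2 SD below the mean), giving monotone-decreasing missingness across
intensity deciles.

## Numerical and scale choices

Problem sizes in the test suite and acceptance script are desk-scale by
design: 50 000-read mixtures for closure runs (binomial 3σ at the
dominant class ≈ 0.007, comfortably inside the ±0.01 check band),
1000/500 cases for the brute-force oracles, 2000 × 10 matrices for LFQ
calibration. Determinism: every stochastic component takes an explicit
seed; simulation outputs are byte-identical across runs of the same
configuration. Alignment results are cached per unique read sequence,
which makes error-free runs nearly free and deduplicates real data.

## Known limitations

- Expansions beyond read length are invisible by construction, as in any
  amplicon-sequencing design with ~250 bp reads.
- The per-read categories follow frame arithmetic strictly; a dual-cut
  excision whose net length is a multiple of 3 is therefore DEL_CAG
  (in-frame), even though mechanistically it is a simple excision.
- The stutter correction is subtractive, clamps at zero, and excludes
  flank-changed in-frame reads from the deviation mass; with very high
  editing rates the unedited-fraction estimate it relies on is noisy.
- `merge_pair` considers ungapped overlaps only; indel sequencing errors
  in the overlap would reduce merge rates rather than corrupt sequences.
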
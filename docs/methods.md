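# Methods

## Motif scanning and positional classification

The CUIC element is scanned as the IUPAC consensus `YYYYTTYC` (32 concrete
8-mers) over 5′ UTR sequences, case- and U/T-insensitively, reporting all
(possibly overlapping) windows in 5′→3′ order. Coordinates are 0-based and
half-open on the UTR; position `L` (the UTR length) is the first nucleotide
of the initiation codon. The distance of a hit to the start codon is
`L − end`, so a motif abutting the AUG has distance 0. The literature does
not pin the measurement point, so the anchor is a deliberate choice: the
motif's 3′ end reflects the "immediately upstream" reading, and the
alternative (motif start) is available by construction (`start = end − 8`).

A transcript is CUIC-positive when at least one hit lies strictly less than
`max_dist` (default 100) nt upstream; the *best* hit is the one closest to
the AUG, ties resolved toward the 3′-most start. The positional summary is
the fraction of best hits with distance in the inclusive band [20, 80].

5′-end observations are reduced to signed offsets `end_pos − hit.start`
(negative = transcript starts upstream of the motif). A 5′ end within
±10 nt of the motif start is called a truncated isoform; 10 nt is a default
chosen because the reference data show ends "at" the motif without a stated
window, and it is a parameter. The 5′ TOP-like rule — first base C and the
first ≥ 5 bases all pyrimidines — follows the classical TOP definition
(cap-adjacent C followed by a 4–15 nt pyrimidine tract); run length is a
parameter.

## Secondary-structure profile

Structures are consumed as plain three-character dot-bracket strings
(pseudoknot alphabets are rejected, not silently stripped) and validated by
a stack. The pairing profile aligns each structure at its motif anchor
(default: motif start) and averages the per-nucleotide paired indicator at
each offset in −H..+H; the denominator at each offset counts only the
transcripts whose UTR covers that offset, and these counts are reported
alongside the means. A centred moving average (default 7 nt, odd widths
only) smooths the offsets; edge offsets average over the neighbours that
exist. With window 1 the smoothed profile equals the raw one.

`fold_maxpair` is a Nussinov maximum-pairing folder (AU/UA, GC/CG, GU/UG;
hairpin loops ≥ 3 nt; deterministic traceback preferring, for the leftmost
base, the largest admissible partner). It is a self-contained stand-in so
the pipeline runs with no external folder; it maximises pair count, not free
energy, and should not be mistaken for a thermodynamic prediction. External
dot-bracket files (e.g. from RNAfold) are the primary input path, and the
profile assumes one (MFE-style) structure per transcript rather than an
ensemble.

## CLIP specificity

For one RNA-binding protein, the specificity score is
`n_overlap / n_total`: the number of its clusters on RP transcripts that
overlap the transcript's CUIC region, over all of its clusters on RP
transcripts. Intervals are half-open and overlap is strict interval
intersection. The "CUIC region" is the motif footprint extended by a
configurable flank (default 10 nt each side, clipped to the UTR) — the
extent is not defined in the source analysis, so the flank is always
reported with the scores. Records are de-duplicated on
(rbp, transcript, interval, dataset); RBPs with fewer than 5 clusters on RP
transcripts are excluded as unstable (a guard, not a literature value).
Ranking is by descending score, ties by larger cluster count then name.
The plain ratio is used — no pseudocount or log transform.

## Interface-index

Per protein chain, `interface-index = n_interface / n_residues`, where the
denominator counts residues with at least one resolved heavy atom
(unresolved residues are excluded, not imputed). Two interface criteria:

- **ΔSASA** (default): a residue is interfacial when its solvent-accessible
  surface area drops by more than 1.0 Å² between the isolated chain and the
  chain in complex with the rRNA partners. SASA is Shrake–Rupley with probe
  1.4 Å, 960 deterministic golden-spiral points per atom, and element radii
  C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å. Hydrogens are ignored; altlocs
  resolve to the highest-occupancy conformer. The single-atom quadrature
  error is below 1% of the closed-form sphere area.
- **contact**: any heavy atom within 5.0 Å of a partner heavy atom. Provided
  because published interface-residue callers do not document their SASA
  parameters; results are therefore cutoff-dependent and the mode and
  cutoffs are recorded with every output table.

Chains above index 0.6 (strict) are classed "penetrated", the rest
"surface". Small-subunit proteins are scored against 18S rRNA and
large-subunit proteins against 5S + 5.8S + 28S, driven entirely by the
user-supplied chain-role table, so any complex (including the human 80S
ribosome entry 6ek0) can be analysed without hard-coded chain ids. Both
modes are exactly invariant under rigid-body transforms of the complex.

## Bias statistics

The abundance split is FPKM > 100 (strict), the index split 0.6 (strict).
`bias_report` compares the index distributions of the abundant and
non-abundant groups with the two-sample KS test, tests the 2×2
(high-index × abundant) table with Fisher's exact test, and reports
fold-depletion = fraction of high-index RPs among the non-abundant group
divided by that among the abundant group (baseline configurable to all
RPs). A zero abundant-group fraction yields +inf with a warning rather than
an error.

KS and rank-sum default to their large-sample forms (Kolmogorov limiting
distribution; tie-corrected normal approximation with continuity
correction) and provide exact label-permutation enumeration for n+m ≤ 16.
The permutation distributions at very small n are discrete with jumps
larger than 0.05, so the asymptotic p should only be expected to track the
permutation p at moderate sizes (tests verify agreement within 0.05 at
n = m = 100). Fisher's two-sided p sums all hypergeometric tables whose
conditional probability does not exceed the observed one (relative
tolerance 1e−9 for float round-off); it matches exact-rational enumeration
on every table with total ≤ 40.

Stage ratios are `(fpkm_late + 1) / (fpkm_early + 1)` (pseudocount 1.0 to
absorb zero FPKM, configurable), reported as log2 and compared RP vs non-RP
by KS. FRAP recovery applies `Rx = (Ix − Ipost) / (Ipre − Ipost)` after
per-timepoint background subtraction and requires `Ipre > Ipost`.

## Synthetic data

The generators define the conditions under which the pipeline is validated:

- **Transcripts**: UTR lengths uniform on 100–300 nt; backgrounds
  purine-only (A/G) by default so the pyrimidine consensus has zero
  background hit rate (a "uniform" hard mode exercises false positives).
  A motif word drawn uniformly from the 32 consensus words is planted in
  70% of RP transcripts at a distance uniform on 20–80 nt from the AUG
  (both figures match the reference prevalence and positional band); each
  planted motif is wrapped in a G/C stem (arm length 10) so a hairpin can
  close over it. Per-transcript FPKM is log-normal (median 80, σ = 1 on the
  natural-log scale) with a 2-fold RP-specific decline between the two
  developmental stages and 0.25 log-noise.
- **Structures**: the planted stem pairs, everything else is unpaired, so
  the motif footprint is single-stranded by construction — the loop
  signature, idealised. Real RNAfold structures have paired stretches
  elsewhere; the generator only preserves the motif/flank contrast, so
  profile tests demonstrate signal recovery, not realistic base-pairing
  densities.
- **CLIP**: each cluster (width 20) overlaps its transcript's CUIC region
  with probability ρ (default 0.3, 200 RBPs × 100 clusters), otherwise it is
  placed entirely outside the region, making the expected score exactly ρ.
- **Toy complexes**: a straight P-backbone RNA and a CA-only peptide whose
  residues sit at 3.5 Å (interface) or 20 Å (non-interface) from the RNA,
  planting an exact contact-mode interface fraction.
- **Abundance bias**: P(abundant) = expit(baseline − β·index); baseline and
  β are solved numerically so the expected abundant-group size and the
  expected fold-depletion hit their targets (30 of 80 and 5-fold in the
  validation runs; β = 0 is the null). FPKM is then log10-normal truncated
  to the correct side of the 100 cut so membership and threshold agree by
  construction. Interface indices are drawn as a two-part mixture: 25%
  uniform above 0.6, 75% uniform below — matching the roughly one-quarter
  core-penetrating fraction among the ~80 eukaryotic RPs.

One global seed fans out to fixed, named substreams (numpy `default_rng`
seeded with `[stream_id, seed]`), so outputs are byte-reproducible and new
generators never shift existing ones.

What passing tests show — and what they do not: the planted-signal designs
prove that each statistic recovers its own generating parameter (prevalence,
ρ, interface fraction, fold-depletion) and that the null calibration of the
Fisher/KS pipeline is honest (type-I rate within [0.03, 0.07] at α = 0.05
over 2,000 simulations; ≥ 80% power against a planted 5-fold depletion with
80 RPs and a 30-member abundant group). They do not certify behaviour on
real transcriptomes, where backgrounds are pyrimidine-rich, structures are
thermodynamic, CLIP clusters cluster biologically, and abundance is
confounded — the desk-scale numbers are validation measurements, not
re-estimates of the published dataset values.

## Numerical and degenerate-input choices

- Scanning rejects non-ACGTU characters with the offending position; empty
  consensus or invalid IUPAC codes are configuration errors.
- Empty inputs where a ratio or profile is undefined raise
  `UndefinedResultError` rather than returning NaN; per-offset profile
  positions covered by no transcript are NaN with count 0.
- Odds ratios for tables with a zero cross-product are ±extremes (inf when
  only `b·c = 0`, NaN when both products vanish).
- Exact permutation modes are capped at n+m ≤ 16 (enumeration size
  C(16, 8) = 12,870) and raise beyond it.
- Problem sizes used by the validation suite (80 RPs, 480 transcripts,
  200 RBPs × 100 clusters, 2,000 null / 500 power simulations, toy complexes
  of 10–20 residues) were chosen to estimate each recovered quantity to
  within a few percent while keeping the whole suite fast on a laptop-class
  single core.

## Known limitations

- The ΔSASA cutoff (1.0 Å²) and SASA parameters of published
  interface-residue callers are not documented; interface-index values are
  cutoff-dependent and should be compared only within one parameter set.
- The maximum-pairing folder ignores thermodynamics; it exists for
  self-contained testing, and real analyses should supply external
  dot-bracket structures.
- Genome-to-transcript coordinate lifting, CLIP peak calling, FPKM
  estimation and de novo motif discovery are out of scope: inputs arrive in
  transcript space with abundances precomputed, and the consensus is given,
  not discovered.
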
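# Methods

This note documents the models and procedures implemented in
`sigattrib`, the parameter defaults and why they were chosen, the
numerical choices that affect results, and the limits of what the
synthetic-data tests demonstrate.

## Channel schemes

**SBS-96.** A single-base substitution is labelled
`5'[REF>ALT]3'` with the mutated base expressed on the pyrimidine
strand: when the reference base is A or G, the substitution and both
flanking bases are reverse-complemented before labelling. Channel
order is the conventional one: six substitution classes (C>A, C>G,
C>T, T>A, T>C, T>G), each over the 16 flank combinations in 5'-then-3'
lexicographic order. The trinucleotide context is read directly from
the reference at the 1-based call position; a call whose context
window leaves the contig or contains an N is skipped with a logged
warning rather than failing the whole cohort.

**DBS-78.** Doublet substitutions are collapsed onto the canonical
78-channel set by reverse complement: for every raw doublet change in
which *both* positions differ, exactly one of the two strand
presentations appears in the canonical list, which is hard-coded and
verified exhaustively in the tests (144 raw cases → 78 channels).
Doublet calls in which one position is unchanged are rejected as
validation errors: such an event is a single-base substitution in
disguise and has no doublet channel.

**ID-83.** Indels are classified by:

1. length — 1, 2, 3, 4, or 5+ bases;
2. for 1-bp events, the event base collapsed to C/T and the number of
   identical bases adjacent in the reference (the homopolymer run
   excluding the event base), capped at 5+;
3. for longer events, the number of exact adjacent tandem copies of
   the indel sequence in the reference (excluding the deleted copy for
   deletions), capped at 5+;
4. deletions of length ≥ 2 with zero tandem copies are checked for
   flanking microhomology — the longest proper prefix of the deleted
   sequence matching the right flank, or proper suffix matching the
   left flank — and classified into the microhomology channels (bins
   1 … L−1, capped at 5+) when the overlap is at least one base.

Labels are written `OP.SUBTYPE.LENGTH.CONTEXT`, e.g. `DEL.T.1.5+`
(1-bp T deletion in a run of ≥ 6 T's), `INS.R.3.2` (3-bp insertion
next to two existing tandem copies), `DEL.M.4.2` (4-bp deletion with
2-bp microhomology). The test suite constructs a designed reference/
record pair for every one of the 83 channels and checks the classifier
emits each exactly as intended.

**Subsets.** SBS spectra can be restricted to the "AA" subset —
substitutions that alter the protein sequence (Missense, Nonsense,
Nonstop, Translation_Start_Site) — or built from all SNPs ("ALL").
Silent and Splice_Site changes are excluded from AA because a splice
change does not substitute an amino acid; this reading of
"amino-acid-altering" is a deliberate package choice where the
boundary is genuinely ambiguous. Unknown classification strings in a
MAF are preserved but never enter AA.

## Per-case GLM mapping

For each case, the spectrum is converted to proportions
`x = counts / total`, and each catalog signature `s_i` is fit with
ordinary least squares `s_i ~ 1 + x`. The two-sided p-value of the
slope is compared against `alpha` (default 1e-6, i.e. −log10 P > 6).
The set of signatures with `p < alpha` is the case's significant set;
the smallest p-value (largest −log10 P) picks the single best
signature, with ties broken by catalog order (first wins) for
determinism. A case with an empty significant set is `NoMapping`.

Orientation: the default regresses the signature on the spectrum. The
transposed orientation is available via
`MapperConfig(orientation="spectrum_on_signature")`; because the slope
t-statistic of a simple regression with intercept is symmetric in the
two variables, both orientations produce identical p-values, and the
switch exists only to make the modelling choice explicit.

Degenerate inputs: an empty spectrum, a spectrum below
`min_mutations` (default 1), or a perfectly uniform spectrum gives a
zero-variance predictor for which the slope test is undefined; every
p-value is recorded as 1 and the case is `NoMapping`.

Frequency tables: in `all_significant` mode each signature is counted
once per case in which it is significant and the denominator is the
number of mapped cases; in `best_only` mode each case contributes its
single best signature (or `NoMapping`) and the denominator is all
cases. Report frequencies are rounded to 2 decimals.

Unmapped cases are clustered by average-linkage agglomerative
clustering on cosine distance between proportion-normalized spectra,
cutting the dendrogram at `k` groups (default 3). Cosine distance
matches standard spectrum-similarity practice; average linkage is
robust to unequal cluster sizes at cohort scale.

## Exposure refitting

Refitting solves nonnegative least squares (NNLS) of the spectrum
proportion vector against the catalog (channels × signatures), then
prunes:

1. **Weight cutoff** (default 0.02): signatures whose solved weight
   falls below the cutoff are removed one at a time, smallest first,
   re-solving the NNLS after each removal. Zero-weight signatures are
   dropped outright since their exclusion cannot change the solution.
2. **Similarity gain** (default 0.02): remaining signatures are
   tested greedily, smallest weight first; a signature is removed if
   re-solving without it lowers the cosine similarity between the
   observed and reconstructed spectrum by at most the threshold.
   Removal order is fixed (smallest first) for determinism.

The two steps repeat until no rule fires (bounded by
`max_iterations`, default 100; in practice the loop terminates after
at most one pass per signature since each removal shrinks the active
set). At least one signature is always retained. Retained weights are
renormalized to sum 1; attributed counts are `weight × spectrum
total`.

Cohort attribution rules, applied after refitting in the order floor
→ presence:

* **floor** (default 0.006): any per-sample weight strictly below
  0.6 % is set to zero and the survivors renormalized. A profile
  zeroed entirely is flagged (`empty_after_floor`) and left
  unnormalized rather than dividing by zero.
* **presence** (default 100): a signature is present in a sample
  only when its attributed mutation count is ≥ 100; fewer than 100
  attributed mutations means absent. The boundary is inclusive at
  exactly 100.

Solver choice: least squares on proportion vectors, in the lineage of
standard refitting tools; a KL-divergence refit objective is not
provided. The "similarity gain" reading of the pruning rule —
a signature is kept only when removing it costs more than 0.02 in
cosine similarity — resolves an ambiguity in how such pruning is
usually described; each pruning decision is logged so runs can be
audited.

## De novo extraction and catalog matching

`extract_denovo` implements KL-NMF with multiplicative updates on the
channels × samples count matrix: random uniform initialization from a
seeded generator, the standard W/H update pair per iteration, and the
generalized KL divergence recorded after every iteration. The
objective is non-increasing (a property of the updates, checked in
tests with a 1e-8 relative slack for floating-point noise); a small
epsilon (1e-12) guards divisions. Factors are normalized so each
signature sums to 1, with the scale moved into the exposures. The
implementation is hand-written so the per-iteration objective trace is
available as part of the contract; scikit-learn's multiplicative-update
KL solver serves as an independent cross-check in the test suite, not
as the implementation.

Candidate signatures (e.g. NMF factors) are matched to a catalog by
cosine similarity; a match is declared at similarity ≥ 0.85 (default),
otherwise the candidate is reported "unmatched". The threshold is a
conventional catalog-matching level; reported similarities are exact
regardless of the threshold.

## Cohort statistics

The two-group frequency comparison uses the pooled two-proportion
z-test without continuity correction, `p = 2(1 − Φ(|z|))`, which is
identical to the uncorrected chi-square test on the 2×2 table
(checked to 1e-10 in tests). This test reproduces the published
White-vs-Asian comparison p-values (0.012, 0.025) exactly at three
decimals from the presence counts, which is why it is the default;
Fisher's exact test is available as an option. Signatures absent from
both groups are reported with z = 0, p = 1.

Per-gene tables count alterations by variant classification, total
alterations, distinct altered samples, and frequency
(= altered samples / cohort size, reported at 3 decimals), sorted by
frequency ascending. Burden is alterations per megabase of target
territory (default 50 Mb, a typical exome capture size; configurable).

## Simulator

`simulate_cohort` emulates a medium-sized exome cohort:

* per-case mutation totals are log-normal with median 66 and
  log-scale sigma 1.3, which over ~175 cases spans roughly 1–2000
  mutations with a heavy upper tail (a handful of hypermutated cases,
  ~10 % of cases below 10 mutations);
* each case mixes 1–4 catalog signatures with Dirichlet-distributed
  weights (concentration 1.0 by default; `min_exposure` optionally
  enforces a floor on true weights by rejection);
* each substitution draws a channel from its signature and is placed
  at a uniformly chosen reference position whose trinucleotide context
  matches the channel on either strand, so the emitted MAF
  re-classifies exactly to the drawn channels;
* indels (default 10 % of the substitution count) are single-base
  insertions/duplications or deletions placed preferentially at
  homopolymer sites;
* variant classifications are assigned synthetically (60 % Missense,
  25 % Silent, 10 % Splice_Site, 5 % Nonsense) so the ALL/AA split is
  exercised without transcript annotation.

Context-consistent placement is the key design decision: spectra
follow the signature mixture exactly, which gives the attribution
stages a known truth. The cost is realism — simulated spectra do not
reflect the toy genome's trinucleotide composition, there are no
driver hotspots or selection, and doublet events are not simulated
beyond what adjacent placement produces. Passing recovery tests
therefore demonstrate correctness of the attribution machinery under
the stated generative model, not performance on real tumors, where
flat or correlated signatures make refitting harder than any
well-separated synthetic catalog.

Synthetic catalogs are Dirichlet draws over the 96 channels
(concentration 0.1, i.e. sparse, spiky signatures); the
`well_separated` flag re-draws until all pairwise cosine similarities
are below 0.5. Real catalog signatures can be substantially more
similar to each other, which is exactly why the pruning rules above
exist.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run on deliberately small
instances chosen to exercise every code path at desk scale: references
of 20–50 kb, catalogs of 5–10 signatures, cohorts of 10–50 samples,
and 2 000–20 000 mutations per constructed spectrum. Recovery metrics
(exposure-weight error < 0.05, NMF recovery cosine ≥ 0.99) are stable
across seeds at these sizes. Cohort-scale published quantities that
depend on controlled-access sequencing data (e.g. the exact 132/43
mapped/unmapped split of a real 175-case cohort) are out of reach by
construction; the corresponding machinery is instead verified against
printed worked numbers (frequency rounding fixtures, the two-group
p-values) and simulation ground truth.

## Known limitations

* The GLM mapper treats the 96 channel values as independent
  observations in an ordinary regression; this is the procedure as
  specified, not a calibrated generative model of spectra, and its
  p-values should be read as a ranking device with a fixed
  conservative cutoff.
* NNLS refitting is least-squares on proportions; for very low-count
  spectra a Poisson/KL objective would weight channels differently.
* ID-83 microhomology uses the longest flank overlap definition;
  annotation-dependent subtleties (e.g. ambiguous indel left-alignment
  in repetitive regions) are the caller's responsibility upstream.
* The MAF reader requires the eight standard columns by their
  canonical names and does not guess synonyms.
* DBS spectra are built from records typed `DNP` only; adjacent SNP
  pairs are not merged into doublets.
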
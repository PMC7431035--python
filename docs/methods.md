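# Methods

This note records the models, parameter choices, numerical conventions
and known limitations behind `crescan`.  Everything quantitative stated
here is computed by the test suite or `scripts/acceptance.py`; nothing
is quoted from elsewhere.

## Coordinates and sequence conventions

All coordinates are 0-based half-open on the + strand of the stored
sequence (BED convention); GFF3 input is converted on read.  Sequences
are uppercase over {A,C,G,T,N}.  `N` scores as a mismatch against
everything (including another `N`) and never counts as identical — a
deliberately conservative treatment of ambiguity.  FASTA ids are the
first whitespace-delimited header token.

## Alignment

`smith_waterman`, `waterman_eggert` and `needleman_wunsch` are exact
affine-gap dynamic programs (numba kernels, no seeding, no banding); a
gap of length L costs `gap_open + L·gap_extend`.  Default scoring is
match +5 / mismatch −4 (EDNAFULL-like) with gap open 16 and extend 4,
close to the DNA defaults of the classical pairwise tools this package
stands in for; every value is overridable per call and in the run
config.  Sequences above 100 kb per window are refused — the package
targets desk-scale exactness, not genome-scale heuristics.

Tie-breaking is fixed (diagonal > gap-in-b > gap-in-a, first-best end
cell by row then column), so alignments are bit-reproducible.  Identity
is identical columns over total alignment columns — gap columns count
in the denominator only, the "identities / alignment length" convention
of standard search tools.  The criterion-2 length is likewise the
gapped column count; both choices are internally consistent and
documented here because the alternative (ungapped match span) is also
defensible.

**X-drop splitting.**  An optimal local alignment will bridge two
strong blocks across hundreds of bases of unrelated sequence whenever
the total stays positive (measured bridge cost under the default
scoring: ≈ 0.7 points per random spacer column, i.e. a 150 bp element
at 85% identity is profitably chained across ≈ 800 bp).  Seeded tools
terminate extension when the running score drops X below its maximum
and report the blocks as separate HSPs.  `split_alignment` reproduces
this as a post-pass with `x_drop = 100` (20 match-equivalents): deep
enough that a genuine 62%-identity element is essentially never cut
(that would need ~25 consecutive net-mismatch columns), shallow enough
to sever any spacer beyond ~140 bp.  The synthetic generator spaces
planted features ≥ 200 bp apart (`min_feature_spacing`) so that
conserved neighbors are separable under exactly this setting.

## E-value statistics

Ungapped: λ solves Σᵢⱼ pᵢpⱼ e^(λ sᵢⱼ) = 1 by bisection to residual
< 1e−9; K is computed from the classical renewal series over partial
sums of the score walk (convolution, truncated when terms < 1e−6).
The implementation reproduces the published ungapped nucleotide
(reward, penalty) parameter tables to printed precision — e.g.
(1, −2) → λ = 1.33, K = 0.621; (1, −3) → λ = 1.37, K = 0.711 — which
the test suite pins.

Gapped (the screen's default): best local scores of `n_sims = 500`
random pairs of length 500 are fitted to a Gumbel law by maximum
likelihood; λ = 1/scale and K = e^(location/scale)/len².  The
calibration is deterministic given its seed, cached per
(scheme, background, length) in a TSV, and reused across the run.
Because both strands of the subject window are searched, E-values use
a search space of m·(2n).  No finite-length ("edge") correction is
applied: at the window sizes used here alignments are short relative
to the windows and the correction is below the Gumbel-fit noise.

## The conservation screen

Thresholds (all configurable): identity ≥ 0.62 (inclusive — the
cutoff wording is ambiguous between "minimum 62%" and ">62%", and the
inclusive reading is adopted), alignment length ≥ 55 columns, E ≤ 0.1,
flank 20 kb around homolog genes (the anchor regions are not sized by
any external constraint; 20 kb covers near-gene and intragenic
regulatory elements).  The search reports up to `k_max = 5` declumped
candidates per window pair with a permissive pre-filter at E ≤ 10.

Criterion 3 (non-coding) vetoes on any annotated exon overlap
(`max_exon_overlap = 0`); when no exon annotation exists (or when
`orf_veto` is enabled) an open reading frame of ≥ 300 bp on either
strand inside the candidate also vetoes.

Criterion 4 (non-repetitive) flags low-complexity windows (16 bp
sliding Shannon entropy < 1.0 bits) and tandem repeats (≥ 4 copies of
a unit of period ≤ 6 spanning ≥ 12 bp), merges the intervals, and
fails a candidate when > 50% of its span is flagged — the screen
excludes elements that *are* repeats, not elements touching one.  On
i.i.d. uniform sequence the flagged fraction is ≈ 0.3% of positions
(the suite asserts ≤ 5%).

Reciprocal uniqueness tiles the full partner sequence set into 2 kb
windows (overlapping by the query length), aligns the query both
strands with the same declumped aligner, and requires every
criterion-2-passing hit to fall inside the homologous gene's window.
A candidate with no passing hit anywhere is vacuously unique and
logged as a warning.  Refinement is a global alignment of the matched
intervals; it records `refined_identity` and the block structure used
for TFBS mapping and never changes the verdict.

## TFBS scanning

PWMs are log-odds in natural log units (bits only for display):
column probabilities `(count + pseudocount·p_bg)/(total + pseudocount)`
with pseudocount 0.01 by default.  The null score distribution is
computed exactly by column-wise convolution on a 1e−3 score grid
(round-half-even); scanning scores each window on the same integer
grid, so reported p-values equal exhaustive enumeration over all 4^w
words exactly (asserted for w ≤ 8).  The default call threshold is
p ≤ 1e−4; a relative-score mode (≥ 80% of max) is provided for parity
with common practice, p-values still reported.  Any N in a window
disqualifies it.  Width is capped at 25 (grid support growth).
Mapping onto the refined alignment marks a hit `inside_conserved` iff
its whole window lies in columns whose 21-column moving-average
identity is ≥ the screen's identity cutoff.

## Synthetic data

The generator emulates exactly the axes the screen measures — identity,
length, E-value, coding and repeat confounders — and none of the
genomic texture it does not (no rate heterogeneity, no CpG effects, no
rearrangements; background is i.i.d. uniform, the null under which the
E-statistics are calibrated).  Passing benchmarks therefore demonstrate
correct threshold behavior of the pipeline, not performance on real
genomes.

Divergence: substitution count ~ Binomial(L, 1 − target_identity),
positions uniform, substitutions to one of the three other bases;
indel events ~ Binomial(n_subs, indel_rate), lengths 1–3 (truncated
geometric), insertion/deletion equiprobable.  The expected global
identity equals the target (verified to ±0.02 over 100 seeds); the
*realized* identity of every planted element is measured post hoc by
global alignment and recorded in the truth set, because the classifier
consumes realized, not nominal, similarity.

Defaults (one locus pair): 3 kb loci; a central gene with two 120 bp
exons (real ORFs: ATG + sense codons + stop) 100 bp apart, conserved
at the element target identity; one 150 bp conserved element at target
identity 0.85; one 60 bp repeat (tandem by default) copied verbatim
into both species; features ≥ 200 bp apart (see X-drop above); element
copies in non-coding, non-repeat positions in both loci.  Homology
table links the two genes.  Everything is a pure function of
(spec, seed).

## Benchmarks (problem sizes)

`crescan.benchmarks` fixes the measurement protocols: recovery uses 50
seeds of the default 3 kb pair, counting elements with realized
identity ≥ 0.75 and requiring a passing candidate with ≥ 50%
reciprocal overlap; specificity uses 50 seeds of 10 kb
background-only pairs (no planted elements or repeats) and reports
passing candidates per pair; threshold sharpness generates pairs at
target identity 0.55 and scores only those whose realized identity
lands in [0.52, 0.58], a band centered on 0.55 and safely below the
cutoff; reciprocal flipping uses 20 constructed single/double-copy
loci; motif recovery uses 50 planted instances of a near-unanimous
width-8 PWM in 1 kb backgrounds at p ≤ 1e−4; the decision-tree gate
frequencies use 1000 simulated triplets (n = 30 per group).  These
sizes keep the full battery around six minutes on one core.

## Behavioral statistics

The SING performance score is the arithmetic mean of the 15 per-trial
counts of flies above the 2 cm mark; the experimental unit is the tube
average (10 tubes per sex per genotype), not the fly.  A trial count
other than 15 warns rather than errors.

Decision tree: every group must pass Anderson–Darling normality at
α = 0.05 (scipy's tabulated critical values; n ≥ 5 required) AND the
variance ratio max/min must not exceed Hartley's f-max critical value
— computed here as the 95% quantile of max/min of k independent
χ²(df)/df variates from a 200 000-draw fixed-seed simulation, which
matches the classical tables to within ~0.5% (k = 2, df = 9 → 4.05 vs
4.03) and is supported for k ≤ 10, df ≤ 60; outside that range the
gate fails with a warning and the nonparametric branch is used.  The
parametric branch is one-way ANOVA then Tukey–Kramer (studentized-range
p-values, valid for unequal n); the nonparametric branch is
Kruskal–Wallis then pairwise two-sided Mann–Whitney U at the
Dunn–Šidák-adjusted level α′ = 1 − (1 − α)^(1/3) = 0.016952.  The
correction applies to the post hoc pairwise level, not the omnibus.
A non-significant omnibus marks all pairs non-significant.

Under three i.i.d. normal groups the parametric branch fires at
≈ 0.95³ · 0.95 ≈ 81% (three normality gates and one variance gate,
each calibrated at 5%) — a direct consequence of the gate structure,
asserted at 1000 seeds.  The dual-control rule (experimental
significantly different from both controls, controls not from each
other) is a conjunction and keeps its null rate well below α.
Sexes are analysed separately and pooled, both reported, since the
pooling convention is a free choice.

## Known limitations

* Exact DP only: quadratic time/memory caps windows around 100 kb;
  genome-scale runs need the loci pre-cut to homolog neighborhoods.
* Gapped (λ, K) from a 500 bp calibration are extrapolated to larger
  windows via K·m·n scaling; finite-size effects are visible as a few
  tens of percent on E near the decision boundary (the E ≤ 0.1 gate is
  coarse enough that this does not move verdicts in the benchmarks).
* The repeat detector is an entropy/tandem screen, not a repeat
  library; diverged transposon copies would not be flagged.
* A sub-threshold element (realized identity ≈ 0.55) can still contain
  a chance sub-segment that legitimately clears 62%/55 bp — local
  alignment reports maximal-scoring cores, so "sharpness" at the
  cutoff is window-size dependent: the larger the search windows, the
  higher the E-threshold score and the rarer such cores.
* The behavioral module implements the decision tree for the three-arm
  (experimental + two controls) design only.
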
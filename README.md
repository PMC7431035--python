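# crescan

Cross-species screening for deeply conserved cis-regulatory elements
(CREs), with planted-truth benchmarking and the companion behavioral
statistics.

## The problem

Enhancers that have survived since before the protostome/deuterostome
split — for example fly regulatory sequences with recognizable
counterparts near the homologous mouse and human genes — are found by
*phylogenetic footprinting*: align a candidate regulatory sequence
against the genomic neighborhood of the homologous gene in the other
species, and keep matches that are too similar, too long, and too
improbable to be chance.  `crescan` implements that screen as an
explicit, exact, testable pipeline:

1. **Homolog-anchored search windows.**  Candidates are only sought in
   windows around genes listed as homologs (gene span ± `flank`,
   default 20 kb), because a raw genome-wide identity threshold has no
   power at these evolutionary distances.
2. **Declumped local alignment** (Waterman–Eggert): exact affine-gap
   Smith–Waterman, recomputed after barring previously used residue
   pairs, so successive sub-optimal matches share no aligned pair.
   Alignments are post-split at internal score drops (X-drop), matching
   the HSP semantics of seeded search tools.  Both strands are searched.
3. **Karlin–Altschul statistics.**  Each match gets an E-value
   E = K·m·n·e^(−λS).  For ungapped scoring λ solves
   Σ pᵢpⱼe^(λ·sᵢⱼ) = 1 and K comes from the classical renewal series;
   for the gapped default the (λ, K) pair is calibrated once by fitting
   a Gumbel law to simulated null scores.
4. **Four-criterion classifier.**  A candidate passes iff it is
   (1) linked to the same homologous gene pair, (2) ≥ 62% identity over
   ≥ 55 alignment columns with E ≤ 0.1, (3) non-coding (no exon
   overlap; optional ORF veto), and (4) not a repetitive element
   (< 50% of its span flagged by entropy/tandem repeat detection).
5. **Reciprocal uniqueness.**  The candidate searched back against the
   entire partner sequence set must hit only the homologous gene's
   window.
6. **Refinement and TFBS mapping.**  Passing candidates are globally
   re-aligned; transcription-factor binding sites are scanned with
   log-odds PWMs whose p-values come from the *exact* null score
   distribution (column-wise convolution), and mapped onto conserved
   alignment stretches.

Because real cross-phylum inputs require genome downloads, the package
ships a first-class synthetic generator: ortholog locus pairs with a
central gene (ORF-bearing exons), planted conserved elements at
controlled identity, repeats, and planted PWM motifs — plus the exact
coordinates of everything planted, so recovery and false-positive rates
are measurable quantities, not hopes.

A second, smaller component scores the startle-induced negative
geotaxis (SING) climbing assay used to test the behavioral consequences
of silencing the neurons such elements control: per-tube trial
averages, an Anderson–Darling normality gate and Hartley's f-max
variance gate feeding either ANOVA + Tukey–Kramer or Kruskal–Wallis +
Mann–Whitney with Dunn–Šidák correction, and the dual-control rule
(experimental ≠ both controls, controls ≈ each other).

## Worked example

```bash
python examples/03_run_screen.py
```

prints, for a 3 kb synthetic pair with one planted element
(seed 7; your numbers will match, the pipeline is deterministic):

```
planted element: 2588-2738 (realized identity 0.887)

geneA~geneB~0: A 2573-2738 (+), identity 86.1% over 165 bp, E=6.6e-41
    homolog-linked=True  id/len/E=True  noncoding=True  nonrepetitive=True  reciprocal=True  verdict=PASS
geneA~geneB~1: A 1316-1450 (+), identity 80.7% over 135 bp, E=2.8e-27
    homolog-linked=True  id/len/E=True  noncoding=False  nonrepetitive=True  reciprocal=None  verdict=fail
...
```

The passing candidate is the planted element (86% identity over
165 columns, E ≈ 10⁻⁴¹, unique in the partner locus); the conserved
exons of the homologous gene are found too but rejected as coding, and
the planted tandem repeat is rejected as repetitive.  The other
examples cover the generator (`01`), declumped alignment + E-values
(`02`), exact-p-value motif scanning (`04`) and the SING decision tree
(`05`).

A thin CLI wraps the same library calls:

```bash
crescan synth --seed 3 --out fixtures/
crescan screen --config run.cfg
crescan benchmark --identities 0.55,0.65,0.75,0.85 --n-seeds 10
crescan behavior --trials trials.tsv --experimental exp \
    --control-uas c1 --control-gal4 c2
```

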
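# Methods

## Design and data model

The pipeline assumes a two-strain, multi-timepoint, sham/irradiated
microarray design: 8 experimental treatment groups (BALB/c sham and IR at
2, 4 and 8 weeks after exposure; SPRET/EiJ sham and IR at 4 weeks), 3
biological replicates per group, 24 arrays in all. Probes are partitioned
into lncRNA and mRNA classes by an annotation table; gene symbols may be
empty. All analysis is probe-level; collapsing probes to genes is left to
the user (the annotation carries the symbols needed to do so). Expression
values enter on the linear intensity scale and must be positive; a scale
flag on the matrix object prevents accidental double log-transforms.

The canonical group order used everywhere (group-mean columns, reports) is
strain, then week ascending, then sham before IR.

## Normalization

Per-sample 75th-percentile shift in log2 space: values are floored at 1.0
linear intensity (log2 = 0), log2-transformed, and each sample column's
75th percentile is subtracted, which equals division by that percentile in
linear space. No per-probe (baseline) transformation is applied. The
percentile uses linear interpolation between order statistics — percentile
q of sorted x1..xn sits at rank 1+(n−1)q/100, numpy's default ("type 7") —
a choice the normalization names explicitly so results are bit-exactly
reproducible. Normalization is computed over all probes on the array, not
a detected subset. The operation is idempotent and rank-preserving;
postcondition: each column's 75th percentile is 0 to within 1e-12.

## Differential expression

Unpaired pooled-variance Student's t-test (df = n_a + n_b − 2), two-sided
p from the t distribution; fold change is 2^|Δ| of the log2 group means,
with direction the sign of Δ. A probe is called DE when p < p_cutoff AND
FC > fc_cutoff, both strict, so boundary values (FC exactly 1.5) fail. The
two standard cutoff regimes are p < 0.05 / FC > 1.5 for IR-vs-sham
contrasts and p < 0.001 / FC > 1.5 for the strain-baseline contrast.
No multiple-testing correction gates the calls — the raw-p criterion is
the method being reproduced — but a Benjamini–Hochberg FDR column is
emitted for reference. Degenerate probes (zero pooled variance) report
t = 0, p = 1 when the means agree, and are flagged with p = 0 when they
differ. Welch's correction is deliberately not used (the method specifies
Student's test); with n = 3 per group and shared array noise the pooled
estimator is also the more stable choice.

The radiation-responsive ("LDIR") set of a strain is the union of DE
probes over that strain's timepoint contrasts; the cross-strain set is the
union over strains. Which contrasts enter the union is configurable
(`union_contrasts`), since the baseline comparison should not contribute.

## Signature exclusion

DE genes matching a variable-gene signature (e.g. genes fluctuating across
the mouse estrous cycle) are removed before interpretation. The signature
is gene-level while DE calls are probe-level, so every probe of a matching
symbol is dropped. Matching is case-insensitive exact symbol matching
(mouse symbol casing varies by source); probes with empty symbols never
match and are retained. Because the fraction overlapping depends on the
denominator, the report gives it both over lncRNA+mRNA and over mRNA only.

## Permutation correlation

Replicates are first averaged within each of the 8 groups (arithmetic mean
of log2 values — correlating on the log scale keeps the statistic
insensitive to multiplicative outliers). For each (lncRNA, mRNA) pair the
Pearson correlation r of the two length-8 group-mean vectors is tested by
rearranging the lncRNA vector while the mRNA vector stays fixed:

* Monte-Carlo mode: 10,000 uniform random permutations from a seeded
  generator; p = fraction whose statistic strictly exceeds the observed
  one. Strict counting makes ties non-exceeding and the estimate
  conservative; p can be exactly 0, and a (b+1)/(m+1)-corrected value is
  exposed for users who need positive p.
* Exhaustive mode: all 8! = 40,320 permutations, exact; limited to n ≤ 10
  groups. This is the testing oracle for the Monte-Carlo mode and is
  cheap enough (< 1 ms/pair) to use directly.

The default statistic is |r|, so strongly anticorrelated pairs are
significant; the literal one-sided reading ("a higher correlation", r
itself) is selectable. Spearman ranks are available by flag.

Determinism and order-independence: each pair's Monte-Carlo stream is
seeded by (global seed, CRC32(lnc id), CRC32(mrna id)), so an all-pairs
scan returns identical results regardless of iteration order or
parallelization. Constant-vector pairs are recorded with a skip reason
rather than a p-value.

A practical caveat the simulation makes visible: the exhaustive p is a
function of the whole configuration of the 8 values, not of |r| alone.
Across many random pairs the p < 5e-4 set overwhelmingly has |r| > 0.9
(its 1st percentile sits near 0.90), but individual configurations can
reach p < 5e-4 with |r| ≈ 0.83. A fixed p threshold therefore corresponds
to a correlation cutoff only approximately.

## Network summaries

Edges are pairs with p below a threshold (strict), giving nested edge sets
across thresholds. The robustness summary counts lncRNAs with at least one
significant mRNA partner at p < 5e-2, 5e-3 and 5e-4. The denominator is
every lncRNA with ≥ 1 testable pair; never-testable lncRNAs (constant
vectors) are reported separately. Under independence, a lncRNA tested
against M candidate mRNAs connects by chance with probability
1 − (1−α)^M, which is why near-total connectivity at α = 0.05 carries
little information and the tight thresholds do the discriminating. Export
is GraphML (round-trippable, Cytoscape-compatible) or edge-list TSV.

## Synthetic data

The generator produces the 8×3 design with log2 expression

    probe i, group g, replicate k:
    baseline_i + strain_i·[g is SPRET] + ldir_i·[g is probe's IR group]
    + c·s·z_{j,g}·[probe in coupling j] + ε,   ε ~ N(0, σ²)

with baseline_i ~ N(8, 1.5²) log2 units, strain and LDIR effects of fixed
magnitude (defaults 2.0 log2) and random sign, and replicate noise
σ = 0.25 log2. Each planted radiation response belongs to one specific
(strain, week) IR group. Coupling: regulator lncRNA j carries a latent
group-level factor z_{j,g} ~ N(0,1); the regulator and each of its targets
add c·s·z_{j,g} to their group-g mean (c = coupling strength in [0,1],
s = coupling scale in log2 units, default 1.0). Because coupling acts on
group means while noise averages over n_reps replicates, the population
correlation of a coupled pair's group-mean vectors has the closed form

    ρ = c²s² / (c²s² + σ²/n_reps)

— with defaults, ρ ≈ 0.98 — making planted-pair recovery analytically
checkable. Coupled probes are drawn disjoint from DE-planted probes so
this closed form is not contaminated by shared deterministic IR-response
patterns. The synthetic estrous-signature stand-in is a random subset
(default 20%) of the DE-planted mRNA symbols, giving the exclusion stage
non-trivial work without claiming biological fidelity. A small fraction of
probes (2%) get empty gene symbols to exercise the no-match rule. All
outputs, including the truth tables, are a pure function of the config and
seed.

What the simulator does not emulate: probe-level array artifacts (spatial
effects, dye bias, saturation), correlated noise between replicates,
heavy-tailed intensity distributions, or mechanistic estrous dynamics.
Passing tests on synthetic data therefore validate the statistical
machinery and its calibration, not the biology of any particular dataset.

## Pipeline and reproducibility

`run_all` executes normalize → DE per contrast → union of LDIR sets →
signature exclusion (skipped with a notice when no signature is
configured) → group means → correlation scan → network summaries, writing
each stage's table with a header comment naming the stage and the config
hash. The manifest records package version, seed, config hash and
per-stage status; no timestamps are embedded, and the config hash excludes
the output directory, so a rerun with the same config and seed is
byte-identical wherever it lands. Every stage output is a plain TSV
re-loadable on its own.

Problem sizes used in the validation suite are desk-scale by design: the
default simulated universe is 2,000 mRNA + 800 lncRNA probes with 50
regulators × 5 targets; calibration experiments use 2,000–5,000 simulated
pairs and the full 40,320-permutation enumeration, which the vectorized
implementation evaluates in well under a millisecond per pair.

## Known limitations

* Probe-level only; no probe-to-gene summarization or collapsing.
* No moderated-variance (limma-style) estimators, paired designs, or
  multiple-testing-gated DE calls — the reproduced method uses raw p.
* Permutation p-values are granular (multiples of 1/40320 exactly, or
  1/n_perms); downstream consumers should not treat p = 0 as literal zero
  (use the corrected column).
* Correlation is association only: no partial correlation, lagging, or
  causal direction.
* The GEO series this design mirrors can be analyzed by supplying its
  matrix/annotation as the TSV inputs, but no download client is included.
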
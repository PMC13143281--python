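# Methods

This note records the models, defaults and numerical choices behind
`streamtx`, and what the simulation-based validation does and does not
establish.

## 1. The streaming model

A sequencing run is a monotone stream: batches of reads arrive under
`fastq_pass/<barcode>/` and are never retracted. The analyzer's state is
therefore a set of monotone counters — transcript×sample and gene×sample
count matrices plus per-sample ambiguous/unassigned/total tallies — and
every analysis artifact is a pure function of a frozen copy of that state
(a *snapshot*, labelled by minutes post-sequencing-initiation). Two exact
invariants are enforced after every update and re-checked before every
snapshot:

- conservation: `Σ_t transcript_counts[t, s] + ambiguous[s] +
  unassigned[s] = total[s]` per sample `s`;
- aggregation: gene counts equal the sum of their isoforms' counts.

Batch files are eligible as soon as they exist under their final name; the
simulator writes to a temporary name and renames atomically, so no
size-stability polling is needed. Batch filenames carry zero-padded minute
stamps, making lexicographic order temporal order; replaying batches in any
interleaving yields the identical final state because accumulation is
additive.

## 2. Read-to-transcript assignment

The assigner is a minimizer sketch matcher, not an aligner. Canonical
k-mers (minimum of a k-mer and its reverse complement, `k` = 15 so no k-mer
is its own reverse complement) are reduced to minimizers over windows of
`w` = 10 k-mers. Assignment counts *distinct* shared minimizers per
transcript: ASSIGNED to the argmax if the best count ≥ `min_hits` = 5 and
the margin over the runner-up is ≥ `margin` = 2; AMBIGUOUS when the count
suffices but the margin does not (ties included); UNASSIGNED otherwise.
Ambiguous reads are excluded from all downstream testing — a conservative
unique-assignment policy with no expectation-maximization reallocation.

Defaults were chosen so that, at the simulator's default error rates
(2% substitution, 1% insertion, 1% deletion), a ≥ 300 nt read retains
roughly half of its ~2L/(w+1) minimizers intact, far above `min_hits`,
while 15-mer collisions between unrelated random transcripts stay
negligible. On error-free fragments the assigner is validated for exact
agreement with a brute-force substring-search oracle wherever that oracle
is unique.

Gene-level counts are derived from transcript assignment rather than from
genomic overlap: the simulated reads are transcriptomic, so exon-projection
counting would add machinery without changing any tested quantity.

## 3. Synthetic runs: what is emulated

`ScenarioConfig` defines a two-condition design (2–10 replicates per
condition; default 3). The generator emulates:

- **Reference.** Lognormal transcript lengths (median 1,500 nt, σ_log
  0.35, floor 200 nt). Isoforms of a gene share a 5' prefix (40% of
  length) and have isoform-specific 3' tails — an alternative-last-exon
  caricature that keeps isoforms distinguishable under 3'-anchored reads.
  Coordinates are written twice, deliberately in both dialects: GTF
  1-based closed, BED 0-based half-open.
- **Expression.** Gene abundances are lognormal (σ_log 1.0) on a simplex;
  rRNA-class genes are boosted 50× to mimic total-RNA dominance, and
  per-(condition, class) factors model rRNA depletion/enrichment library
  designs. Condition B edits — fold changes, knockouts (abundance zero),
  overexpression, heat-shock-style induction — apply multiplicatively
  before renormalization, so a configured fold change `f` is exact
  pre-normalization. Marker (foreign cassette) genes are present in the
  annotation for *all* samples but expressed only where configured:
  detecting them is a positive control for strain identity.
- **Replicates.** Each replicate perturbs its condition's gene abundances
  by i.i.d. lognormal noise (σ_log 0.2, a biological CV of ~20%) and is
  renormalized, giving realistic between-replicate overdispersion
  (α ≈ e^{σ²} − 1 ≈ 0.04) on top of counting noise.
- **Reads.** 3'-anchored fragments (oligo(dT)-primed double-stranded cDNA
  behavior), either strand with probability ½, truncated-lognormal lengths
  (median 1,000 nt, σ_log 0.6, clipped to [100, transcript length]),
  substitution/insertion/deletion channel as above, constant-Q placeholder
  qualities.
- **Timing.** A `RunSchedule` fixes batch interval, per-batch read counts
  (constant or per-batch, so throughput decay and geometric depth doubling
  are both expressible) and snapshot minutes; the default snapshot grid is
  60/120/300/600/1440 — the 1/2/5/10/24 h views of a day-long run.
- **Usage switches.** Genes in `isoform_switch_set` get a *defined* usage
  simplex (major isoform fraction 0.8 by default) that is reversed in the
  perturbed condition; reversing a random Dirichlet draw would often be a
  near-no-op.

Ground truth (read origins, per-replicate realized profiles, expected DE
directions) is written alongside the run.

For deep scenarios the generator also provides counts-level shortcuts:
multinomial draws from the same per-replicate profiles, equivalent in
distribution to error-free unique assignment, and a gamma-Poisson sampler
for pure negative-binomial counts. The statistical validations use these
at 100k–200k reads/sample; the read-level FASTQ pipeline is exercised
end-to-end at smaller scale where the question is plumbing correctness
(conservation, determinism, file formats), not asymptotics. That split is
a deliberate problem-size choice: the quantity being measured never
depends on re-serializing 10⁶ reads.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: basecalling and raw signal, barcode
misassignment, PCR/UMI artifacts, genomic contamination and splice-aware
mapping ambiguity, 3' bias interacting with degradation, batch effects
between replicates, and non-lognormal abundance tails. Calibration
statements below are statements about this generative model.

## 4. Differential expression

Counts are modelled as NB(μ, α) with `Var = μ + αμ²`,
`log μ_gj = log s_j + β0_g + β1_g x_j`.

- **Size factors**: median-of-ratios over genes with positive counts in
  every sample; an informative error asks for more depth when no such gene
  exists yet (early snapshots). Library-level factors computed on gene
  counts are reused for transcript-level testing.
- **Dispersion**: per-gene method of moments, `α = max(floor, (s² − μ)/μ²)`
  with μ the grand mean of normalized counts and s² the *within-group
  pooled* variance (condition effects must not inflate dispersion); a
  hyperbolic trend `α(μ) = a0 + a1/μ` is least-squares fitted over genes
  with μ > 1; the final value is the unweighted mean of gene-wise and
  trend values, floored at 1e-8. This simple 50/50 shrinkage stabilizes
  the n = 2–3 regime without empirical-Bayes machinery.
- **Wald test**: IRLS with fixed α, vectorized across genes (the
  two-parameter normal equations solve in closed form), max 50 iterations,
  step tolerance 1e-8, linear predictor clipped to ±30. `log2FC = β1/ln 2`;
  SE from observed Fisher information at the final estimate; two-sided
  normal p; BH step-up adjustment with NaN propagation for untested
  features. Features with total raw count < 10 are reported but not tested
  (fixed pre-filter in place of adaptive independent filtering).
- **Complete separation.** When one group is all zero the NB likelihood is
  maximized at |β1| → ∞ and the unbounded Wald statistic degenerates to 0
  (the Hauck–Donner effect) — precisely the genes a knockout/marker screen
  must flag. The estimate is therefore bounded at |log2FC| ≤ 8 and the
  Wald statistic evaluated at the boundary, where the information is still
  finite; the slope is solved first and the intercept conditionally on the
  (possibly bounded) slope, so the pinned fit converges to the constrained
  optimum. This mirrors the operational behavior of bounded GLM fitting in
  the established NB-DE implementations, which report such genes as
  strongly significant with large bounded fold changes. The *reported*
  log2FC for separated features uses +0.5-pseudo-count group means. The
  bound only binds near separation; a true 8× induction (log2FC = 3) is
  far from it.
- **Not implemented**, by design: posterior LFC shrinkage, outlier
  (Cook's-distance) refitting, multi-factor designs, likelihood-ratio
  tests. PCA and sample distances run on `log2(normalized + 1)` (top 500
  variable features, gene-centered, no scaling) rather than a variance-
  stabilizing transform — chosen for exactness and testability.

**Calibration, honestly stated.** At n = 3 per group the Wald normal
approximation is mildly anti-conservative: on all-null NB simulations
(α = 0.2) the raw p < 0.05 rate measures ≈ 0.06, and on the standard power
scenario the realized FDR at padj < 0.05 fluctuates around 6–12% across
seeds rather than the nominal 5%. Sensitivity for 4× shifts at ≥ 50 mean
counts is ≈ 1.0 and median |log2FC| error ≈ 0.2. Users wanting strict FDR
at tiny n should treat padj near the threshold with caution — as with any
Wald-based NB test.

## 5. Differential transcript usage

For each transcript of a gene with ≥ 2 annotated isoforms and gene-level
count ≥ 10 in ≥ 2 replicates per condition: Haldane-corrected proportion
`(x + 0.5)/(n + 1)`, logit transform, Welch two-sample t across conditions
(Satterthwaite df), BH across all tested transcripts. Zero-variance
degeneracies use explicit conventions: equal means → (t = 0, p = 1);
unequal means with zero variance → variance floored at 1e-16, effectively
certain. For two-isoform genes the construction is antisymmetric (deltas
sum to zero, |t| equal), and the test is invariant to per-sample depth
scaling up to the vanishing Haldane term.

This deliberately replaces Dirichlet-multinomial and per-bin NB GLM
machinery with a fully specified proportion test. Its known weakness is
the t distribution's instability at n = 3 (Satterthwaite df can collapse
to ≈ 2, flooring attainable p near 1e-3); the package's standard DTU
scenarios therefore use 5 replicates per condition, where a 0.8↔0.2 switch
at ~200 gene counts/sample is detected at padj < 0.05 essentially always
and the null p < 0.05 rate measures ≈ 0.03–0.06. Gene-level two-stage
aggregation is out of scope.

## 6. QC and stopping

"Expression variability over iterations" is operationalized as the pair
(genes-detected saturation curve, per-iteration newly-detected gene sets),
both per sample and per condition (pooled counts). The plateau rule fires
at the first iteration where the last `window` = 3 consecutive detection
gains are all ≤ `epsilon` = 0; both knobs are configuration because any
specific rule is a policy, not a fact. The rule is translation-invariant
in the iteration index, and on runs whose expressed gene set is exhausted
at iteration T it fires at T + window (validated within ±1 across seeds).
Stopping remains the user's call; the tool only reports.

Read-length summaries use 100 nt bins centered on multiples of 100; the
mean is exact (running totals), median and N50 are bin representatives, so
values on the grid are bin-exact. Histogram mass equals reads consumed.

## 7. Timecourse persistence

DEG membership (padj < 0.05; optional |log2FC| cutoff, off by default,
since the appropriate effect-size threshold is analysis-specific) is
tracked per snapshot. Venn region counts are computed over all non-empty
membership signatures and provably partition the union of DEG sets. The
persistent set requires significance at *every* snapshot with a consistent
sign; the direction-agnostic intersection is reported alongside, since a
Venn diagram alone ignores direction. On the standard power scenario
streamed over five geometrically deepening snapshots (12.5k → 200k
reads/sample), ~98% of first-snapshot calls persist with stable sign and
the DEG set grows monotonically in ≥ 95% of seeded runs.

## 8. Determinism and seeds

All randomness flows through `numpy.random.Generator` seeded from explicit
integers; simulation outputs are byte-reproducible per seed (enforced by
test). The analyzer is deterministic given a run directory. The
reproduction script derives every scenario's seed from its single `--seed`
via `SeedSequence` spawning.

## 9. Known limitations

- The minimizer assigner has no notion of position or colinearity; highly
  repetitive transcripts could in principle accumulate spurious shared
  minimizers. Irrelevant at the simulator's sequence complexity; real
  transcriptomes with paralog families would need the margin rule
  re-examined.
- Reusing gene-level size factors for transcript-level tests assumes
  within-gene usage shifts do not move library-level normalization;
  true at realistic DTU prevalence.
- The dispersion trend is hyperbolic least squares, not an empirical-Bayes
  fit; with very few expressed genes (< ~50) the trend can be noisy, which
  matters exactly when everything else is underpowered too.
- Wall-clock mode for live directories exists but all validation runs in
  simulated time; filesystem-event latency and partially written files
  from non-atomic writers are untested territory.
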
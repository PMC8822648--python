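# Methods

## The model

`satdyn` treats a satDNA family as a population of paralogous monomer
copies evolving under two mutation classes:

1. **Point mutation.** Each site of each copy mutates independently as
   a Poisson process with rate μ (substitutions/site/Ma). Events are
   transitions with probability κ/(κ+2) and otherwise one of the two
   transversions — a Kimura two-parameter (K2P) process, chosen so
   that the distances estimated downstream (also K2P) are
   self-consistent with the generator. Multiple hits per site are
   applied sequentially, so back-mutation and saturation emerge
   naturally rather than by correction.
2. **Amplification.** A burst appends `burst_size` identical copies of
   one template (a random existing copy by default, optionally the
   running consensus). Bursts are the only homogenizing force; there
   is no gene conversion or unequal-crossover shuffling between
   copies. Tandem placement is handled separately by the genome
   layout, so unequal crossing-over, rolling-circle reinsertion and
   transposition-mediated spread are represented only implicitly, as
   burst + layout.

A two-lineage run evolves an ancestral copy pool for `ancestral_time`
Ma (creating standing ancestral polymorphism), duplicates it into two
lineages at the split, and evolves each independently for `split_time`
Ma under its own amplification schedule. The copy genealogy, the
ancestral consensus and the true array coordinates are recorded as
ground truth.

### What the measured indices recover

- After a burst of age Δt, copy-vs-consensus divergence concentrates
  near 100·μ·Δt percent, so the landscape mode (DIVPEAK) estimates
  time since amplification. Landscape classes are half-open 1% bins
  assigned by `floor(divergence)`; the class *midpoint* (class + 0.5)
  is the right point estimate of peak divergence — comparing the raw
  class index to 100·μ·Δt carries a built-in −0.5 binning bias.
- With no post-split amplification and a short post-split time, both
  lineage consensuses stay near the ancestral consensus while copies
  carry the full ancestral polymorphism: interspecific divergence is
  *smaller* than intraspecific divergence and CEI < 0. Independent
  post-split bursts in both lineages homogenize each around a
  different variant and flip CEI positive — concerted evolution as an
  emergent property of amplification, reproduced in
  `tests/test_acceptance.py` at desk scale.

## Key parameter choices

| parameter | default | rationale |
|---|---|---|
| monomer length | 185 nt | typical grasshopper satellite repeat unit |
| μ | 0.01 /site/Ma | order implied by consensus turnover rates ~1%/Ma |
| κ (ts/tv) | 2.0 | standard nuclear-DNA transition bias |
| split time T | 22.81 Ma | divergence of the two reference lineages |
| read length / insert | 101 / 180 nt | short-read geometry of the reference libraries |
| landscape bins | 1% classes, 0–40% | convention for repeat landscapes; >40% dropped and logged |
| PEAK window | DIVPEAK ± 2 classes | "within 5% of the peak" ≡ the subfamily identity criterion |
| clustering thresholds | >95 / >80 / >40 % | subfamily / family / superfamily homology levels |
| read positivity | ≥50% read coverage at ≥80% identity | family homology threshold applied to mates |
| array merging | gap ≤ 3 nt, length ≥ 1.5 RUL | absorbs slippage indels; requires at least a dimer |
| motif scan | direct ≥8 nt exact; arms ≥6 nt, loop ≤50, ≤1 mismatch | typical EMBOSS-style scan settings |
| bootstrap | 5000 resamples, BCa 95% CI | estimation-statistics standard; percentile fallback logged |
| stepwise p-to-enter | 0.05 | conventional default, configurable |

## Numerical and procedural decisions

- **DIVPEAK ties** break toward the lower divergence class (the
  conservative degeneration estimate) and are logged. The PEAK window
  truncates at class 0 and at the 40% cap.
- **Kurtosis** is the abundance-weighted *excess* kurtosis of
  bin-center divergences, so leptokurtic landscapes read as > 0; it is
  NaN for a single-class landscape (zero variance).
- **Identity** is matching columns / alignment columns excluding
  terminal gaps; internal gaps count as mismatches. Alignment scoring
  is global, match +1 / mismatch −1 / gap −2. For *homology calling*
  (clustering), a pair additionally needs ≥50% mutual length coverage
  and a positive alignment score: gapped alignment of unrelated DNA
  still matches about half of its columns, so raw column identity
  cannot separate distant homology from noise, while the alignment
  score of unrelated pairs is reliably negative under this scoring.
- **Cyclic phase.** Tandem monomers have arbitrary phase, so monomer
  and cross-family comparisons try all cyclic rotations of the second
  sequence and keep the best (rotation search ON); subfamily
  consensuses already phased within a family are compared directly.
- **K2P saturation** (non-positive log argument) yields a
  flagged-undefined value, never an exception and never a silent
  drop; interspecific divergences above 100% are valid K2P values.
- **CEI is emitted in two variants.** The difference form
  (inter − intra, percent scale) is the one numerically consistent
  with published satellitome tables; the log₂ ratio
  (log₂(inter/intra)) matches the verbal definition of the index.
  They agree in sign whenever both are defined, and both are always
  reported. Intraspecific divergence defaults to the
  abundance-weighted mean copy-to-consensus divergence of the family
  landscape (`landscape_mean`); mean pairwise K2P among subfamily
  consensuses is available as `subconsensus`.
- **maxCTR** defaults to the largest CTR in the analyzed pair set and
  can be pinned externally (e.g. to a published reference value).
- **Consensus building** uses a center-star alignment anchored on the
  most abundant monomer, per-column majority with the fixed tie order
  A<C<G<T (no IUPAC ambiguity codes, which would poison K2P), and
  deletion of majority-gap columns. Family names track the consensus
  length after gap deletion.
- **Clustering** is single linkage at strict ">" thresholds — the
  closest formal analog of chained all-vs-all homology searches —
  and is order-invariant (canonical ids from sorted labels). Raising
  a threshold never merges clusters (nesting by construction).
- **MST** construction is Kruskal with edge ties broken
  lexicographically by (u, v) labels, so results are deterministic;
  it is verified against exhaustive spanning-tree enumeration for
  n ≤ 6.
- **MAL units.** Array lengths are reported in nucleotides *and* in
  monomer equivalents (length/RUL). Published MAL figures are on the
  base-pair scale for long-read data even where described as repeat
  units; emitting both sidesteps the ambiguity.
- **Coordinates** are 0-based half-open internally; RepeatMasker
  `.out` rows (1-based inclusive) are converted on input; BED output
  is 0-based half-open. Reverse-strand hits are normalized to the
  read's forward frame before merging.
- **Holm step-down** is the implementation of "sequential Bonferroni";
  it is cross-checked against statsmodels in the test suite.
- **BCa intervals** are computed directly (bias correction from the
  resample distribution, acceleration from a leave-one-out jackknife
  over both groups) so that two-sample intervals are seeded and
  reproducible; degenerate corrections fall back to the percentile
  interval with a log note.
- **VIF** of an entered predictor is 1/(1−R²) from regressing it on
  *all other candidates*, entered or not, matching how redundancy is
  assessed in stepwise satellitome regressions.
- **Conserved-motif flag.** There is no quantitative field standard;
  runs of ≥8 alignment columns with π below 0.05 are flagged as
  *candidate* conserved motifs and labelled as an operational
  criterion in output.

## What the simulator does and does not emulate

The generator reproduces the statistical structure the pipeline
consumes: mutationally decayed copies of a common ancestor produced by
discrete amplification bursts, two lineages with independent burst
histories, tandem arrays with random flanking DNA, innie paired reads
of configurable geometry, and long reads with independent
substitution/indel errors. It does **not** model selection,
population-level transmission (drift across individuals, bottlenecks,
meiotic drive), length mutation of monomers, higher-order repeat
formation, or mechanistic variants of spread (unequal crossover
tracts, rolling circles, TE hitchhiking). Consequently, green
simulator tests show that the *estimators* recover the generating
amplification–degeneration parameters under the model's assumptions —
not that real satellitomes obey those assumptions. Real-data
correlation magnitudes (e.g. RPS vs divergence) are not reproducible
without the original genomic reads; the suite instead checks that the
qualitative association (strongly negative rank correlation) holds on
simulated satellitomes spanning a range of amplification ages.

## Problem sizes

The test suite and acceptance checks run at desk scale, chosen so the
statistical assertions have adequate power while the whole suite stays
quick: copy pools of 10–200 monomers of 100–300 nt, 50 seeds for the
DIVPEAK recovery check, 20 seeded runs × 8 families for the RPS–
divergence association, 250–300 read pairs for TSI saturation, 1000
random landscapes/seeds for the index-oracle and bootstrap-coverage
checks, and exhaustive MST enumeration up to n = 6.

## Known limitations

- Cyclic alignment tries all rotations (O(L³) per pair); fine for
  monomers up to a few hundred nt, slow beyond.
- TSI is an underestimate that depends on insert size and array count;
  no correction is applied, matching field practice.
- `scan_read_arrays` is a single-consensus, best-hit-with-masking
  scanner intended for simulated or low-coverage long reads; real
  annotation pipelines should feed RepeatMasker `.out` tables in via
  `parse_rm_out`.
- The identity-score homology gate is conservative near the 40%
  superfamily threshold: true homologs right at the edge of
  detectability may be left unlinked.
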
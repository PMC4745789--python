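# Methods

This note records the exact definitions, defaults, and conventions used
throughout `sescreen`. Everything below is implemented in
`src/sescreen/` and exercised by the test suite.

## Coordinate conventions

All genomic coordinates are **0-based, half-open** (`[start, end)`),
matching BED. Lengths are `end - start`. The gap between two intervals
on the same chromosome is `max(0, later.start - earlier.end)`; touching
intervals have gap 0. TSS positions are single base coordinates taken
from the strand-aware 5' end of the gene model. Distances between an
enhancer and a TSS are measured from the nearer enhancer boundary
(0 if the TSS falls inside the enhancer).

## Super-enhancer calling (`sescreen.enhancers`)

1. **Candidate definition** (`define_candidates`). An H3K27Ac peak is
   dropped if its **midpoint** lies within `tss_exclusion_bp = 2500` bp
   of any TSS, or if a **single** H3K4me3 peak covers at least
   `k4me3_overlap_fraction = 0.5` of the H3K27Ac peak's length
   (promoter-mark exclusion; overlaps from different H3K4me3 peaks are
   not summed).
2. **Stitching** (`stitch`). Surviving peaks whose gap is at most
   `stitch_distance_bp = 12500` bp are merged transitively; the enhancer
   is the hull of its constituents. Stitching is idempotent and the
   resulting enhancers are pairwise separated by more than the stitch
   distance.
3. **Quantification and ranking** (`quantify_and_rank`). Enhancer
   signal is the integral of the H3K27Ac track over the hull, in reads
   per million. An optional control track is subtracted and the result
   floored at zero. Enhancers are sorted **ascending** by signal, ties
   broken by genomic position, so rank index `i` (0-based) is
   deterministic.
4. **Cutoff** (`call_super`). Three methods:
   - `tangent` (default): scale rank index to `x ∈ [0, 1]` and signal
     to `y ∈ [0, 1]`; the cutoff point is `argmin(y − x)`, i.e. the
     point where the tangent to the curve has slope 1. Every enhancer
     with signal **strictly greater** than the cutoff signal is SUPER.
   - `top_n`: the `n` highest-signal enhancers are SUPER.
   - `half_signal`: the smallest suffix of the ascending curve holding
     at least half the total signal is SUPER.

   Under all methods the SUPER class is a suffix of the ascending
   ranking: no typical enhancer outranks a super-enhancer.

## Gene assignment (`sescreen.genes`)

A gene is **active** if its expression value is at least
`expression_threshold = 1.0`. Active genes are linked to every enhancer
whose boundary lies within `window_bp = 50000` bp of the TSS
(inclusive: a gap of exactly 50,000 bp still links). A gene linked to
both classes is counted as SE-associated (SUPER takes precedence when
genes are partitioned by class).

## GGAA microsatellites (`sescreen.microsat`)

`scan_microsatellites` reports every **maximal** tandem run of at least
`min_repeats = 2` copies of the unit (default `GGAA`) on the forward
strand, and likewise for the reverse complement (`TTCC`), recorded with
the unit actually matched. Runs are maximal in both directions; an `N`
(or any mismatch) terminates a run; adjacent runs of opposite
orientation are reported separately. `repeat_count` is the number of
whole unit copies.

- `region_overlap_enrichment` builds the 2×2 table (SE vs TE) ×
  (contains ≥1 feature vs none) and applies the two-sided exact Fisher
  test. Containment means the feature midpoint lies inside the
  enhancer.
- `repeat_count_comparison` compares microsatellite repeat counts
  inside vs outside FLI1 peaks with Welch's unequal-variance t test.

## Statistics (`sescreen.stats`)

- **Fisher exact** (own implementation, two-sided): the p-value is the
  sum of hypergeometric point probabilities not exceeding that of the
  observed table, computed with exact integer binomial coefficients, so
  it is accurate to float rounding only at the final division. The
  sample odds ratio is `ad/bc` (`inf` when `ad > 0, bc = 0`; `nan` when
  both products are 0).
- **Welch's t test** and the **asymptotic Mann-Whitney** use scipy.
  Mann-Whitney switches to the exact null distribution when the pooled
  sample is ≤ 16 and tie-free.

## Metagene profiles (`sescreen.metagene`)

Each region body is scaled to `body_bins = 50` equal bins; fixed flanks
of `flank_bp = 5000` bp are split into `flank_bins = 25` bins each.
Values are **densities** (signal per bp), so regions of different
lengths average on a common axis without length bias. Flank windows
falling off a chromosome end are clipped and their bins averaged over
the covered width; fully off-end regions are skipped and tallied.

## GSEA (`sescreen.gsea`)

Genes are ranked descending by associated enhancer signal. Walking the
list top-down, set members add `|metric|^w / Σ|metric|^w` (over the
set) and non-members subtract `1/(N − N_set)`; the enrichment score is
the running-sum extremum of largest magnitude, with
`weight_exponent w = 1` by default. When the positive and negative
excursions tie in magnitude (within a relative tolerance of 1e-12) the
positive one is reported, so algebraically symmetric cases are
deterministic. The null is **gene-set permutation**: random same-size
sets drawn from the ranked universe, `p = (1 + #{|ES_perm| ≥ |ES|}) /
(1 + B)` with `B = 1000` permutations by default; NES divides ES by the
mean |ES| of matching-sign permutations.

## Screens (`sescreen.screens`)

- **Selectivity**: for each gene,
  `snr = (μ_target − μ_other) / (σ_target + σ_other)`, with each
  standard deviation floored at `max(0.2·max(|μ_target|, |μ_other|),
  1e-8)`. The floor keeps near-constant groups from producing unbounded
  scores (two constant groups at −2 and 0 give snr = −2.5) and makes
  the statistic antisymmetric under group swap. Rank 1 is the most
  negative (most selectively depleted) gene. P-values come from
  label permutation of the line-to-lineage assignment (1000 by
  default), `p = (1 + #{snr_perm ≤ snr}) / (1 + B)`.
- **Drug response**: one-sided Mann-Whitney (`less`) on IC50s, target
  lineage vs the rest; summaries report geometric means since IC50s are
  log-normal.
- **Integration**: `integrate_hits` partitions the union of the SE-gene,
  dependency-hit, and drug-validated sets into the seven disjoint Venn
  regions, each sorted for determinism.

## Synthetic data generator (`sescreen.simulate`)

`SyntheticConfig` defaults define the reference landscape; all values
are overridable. Randomness flows from one master seed through fixed
`SeedSequence` spawn keys, one substream per component, so any
component's draws are independent of whether the others are generated.

- **Genome**: 8 chromosomes × 4 Mb, uniform random A/C/G/T sequence.
- **Enhancers**: 1,000 typical (log-normal length, median 2 kb) and 20
  super (median 30 kb, built from 3–6 constituent peaks with 0.5–2 kb
  gaps so stitching at 12.5 kb reassembles each hull exactly), placed
  with ≥ 25 kb spacing — twice the stitch distance — so planted regions
  never merge with each other. Typical strength is log-normal; super
  strength multiplies it by 10 × a Pareto(α=2) draw, producing the
  hockey-stick curve.
- **Signal track**: per-50-bp-bin Poisson counts around the expected
  density (background 0.02, enhancer bodies 0.5 × strength), so signal
  recovery is statistical, not exact.
- **FLI1 peaks and microsatellites**: a 400 bp FLI1 peak is planted in
  85 % of supers and 26 % of typicals; each peak carries a GGAA/TTCC
  microsatellite with `2 + Poisson(5.3)` repeats (mean 7.3). Extra
  peak-free microsatellites appear in 53 % of supers, plus genome-wide
  background microsatellites at 3 per Mb with mean 2.3 repeats. All
  microsatellites are spliced verbatim into the genome sequence so the
  scanner rediscovers them.
- **Genes**: 1,100 gene models; every super-enhancer gets a target gene
  with TSS 5–20 kb away; 30 % of remaining genes get a promoter-like
  decoy H3K27Ac peak plus an H3K4me3 peak at the TSS (exercising the
  candidate filters). Expression is log-normal (median 5); SE targets
  are boosted 4-fold. SE target genes form the `fli1_target_genes` set
  used by the GSEA stage.
- **Screens**: 500 screened genes × 40 cell lines (10 in the target
  lineage `EWING`). Dependency scores are standard normal with −2.5
  added for 5 planted selective genes in target lines. IC50s are
  log-normal (log-mean 0, log-sd 1) with target lines multiplied by
  0.2. Two of the selective genes are designated drivers: they are
  SE-associated, selectively depleted, and drug-validated, so the
  triple Venn intersection recovers exactly them.

`SyntheticTruth` records everything planted (enhancers with class,
microsatellites, FLI1 peaks, target/selective/driver genes, line
labels) and is written as `truth.json` alongside the dataset.

## Pipeline (`sescreen.pipeline`)

`run_pipeline(config, outdir)` executes
`simulate → call-se → assign → msat-enrich → metagene → gsea →
integrate`, writing one artifact set per stage plus `summary.json` and
a `manifest.json` with sha256 digests of every output. Config errors,
missing/invalid inputs, and stage failures raise `ConfigError`,
`InputError`, and `StageError`, which the CLI maps to exit codes 2, 3,
and 4. Reruns with the same config are digest-identical.
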
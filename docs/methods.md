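# Methods

## Scope and model

`lncnet` implements the downstream half of a two-condition bulk RNA-seq
lncRNA study: normalisation, differential expression (DE), candidate
filtering, co-expression network construction with resampling-based edge
significance, cis-window annotation and set-level reports. Upstream steps
(alignment, read counting, transcript assembly, coding-potential
computation) are consumed as inputs: a count matrix plus a transcript
annotation carrying exonic length, exon count and three externally supplied
coding-potential verdicts.

## Differential expression

The DE contract downstream stages rely on is minimal: a group-mean fold
ratio and an adjusted p-value, filtered at ratio ≥ 2 and adjusted p < 0.05.
The test behind the p-value is a Welch two-sample t-test on log₂(RPKM + 1),
adjusted by Benjamini–Hochberg jointly across all transcripts (lncRNA and
mRNA together; separate-family adjustment is a defensible alternative but
the joint family is the conservative default when the downstream network
mixes both). The statistic is deliberately pluggable: any procedure
producing the two filter inputs can replace it without touching the rest of
the pipeline.

Edge cases are pinned down explicitly: a transcript constant across all
samples gets p = 1 and ratio 1; zero within-group variance with unequal
means is treated as the Welch limit p = 0; a zero group mean makes the
ratio infinite, which is capped at 10⁶ and flagged in a `ratio_capped`
column. The fold bound is inclusive (ratio ≥ 2) and the significance bound
strict (p < 0.05).

## Permutation-tested correlation edges

With three replicates per group, n = 6 samples, a t-approximation for the
null distribution of Pearson's r has four degrees of freedom and is
fragile; the edge test therefore uses a shuffling null. In exact mode all
n! rearrangements of one profile are enumerated — 720 at n = 6, at most
40,320 at the n ≤ 8 threshold where `auto` switches to Monte-Carlo — and
the two-sided p is the fraction of arrangements whose |r| ties or exceeds
the observed |r| (the identity arrangement is always counted, so p > 0).
Monte-Carlo mode uses the add-one estimator (1 + hits)/(B + 1) with a
seeded generator, which keeps p strictly positive and reproducible.

Consequences worth knowing:

* the smallest achievable exact p at n = 6 is 2/720 ≈ 0.0028, so the
  retention rule |r| ≥ 0.95 ∧ p < 0.05 is attainable;
* for a profile with pure two-level group structure and no consistent
  within-group co-variation, the ~2·(3!·3!) = 72 group-respecting
  arrangements all reach essentially the observed |r|, so exact p ≈ 0.1:
  the permutation test deliberately does not reward group separation
  alone — that is the DE test's job;
* tied |r| values are counted as hits with a 10⁻¹² tolerance;
* constant profiles have undefined r; such edges carry NaN and are never
  retained.

Edge p-values are not multiplicity-adjusted by default (the retention rule
is a raw p < 0.05); BH across edges is available as an option. Degrees are
counted over retained edges only, and the bipartite handshake
(Σ lncRNA degrees = Σ mRNA degrees = edge count) is structural.

## Cis windows, enrichment, overlap

Cis-target calls take the lncRNA locus ends (not the TSS) and search both
flanks symmetrically, strand-agnostically, with an inclusive 10-kb
boundary; overlap is distance 0. Printed 1-based closed coordinates are
converted to the in-memory 0-based half-open convention on ingest.
Enrichment is the upper-tail hypergeometric test with the quantified
transcript set as the default universe (standard over-representation
practice; configurable), raw p < 0.05 as the enrichment call and a BH
column for reference. Set-overlap reports normalise identifiers
(case-fold, trim) and emit every exclusive Venn region of 2–3 sets.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
any particular organism: a 3-vs-3 design, integer counts, a right-skewed
baseline expression distribution, planted two-group effects and planted
co-expressed pairs, with full ground truth. Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| n_per_group | 3 | the small-replicate design the pipeline targets |
| n_lncrna / n_mrna | 20 / 100 | desk-scale slice with a realistic lncRNA:mRNA ratio |
| frac_de | 0.2 | enough planted signal to measure recovery rates |
| planted_fc | 4 | comfortably above the ratio ≥ 2 filter |
| n_planted_pairs / planted_r | 5 / 0.99 | above the 0.95 edge cutoff with margin |
| nb_dispersion | 0.02 | BCV ≈ 14%: sorted, pure cell populations from inbred animals |
| mean_log_expression / sd | 5 / 1 | log-normal counts spanning ~2–3 orders of magnitude |

Design choices that were forced by the small-sample regime rather than
free:

* **Clipped baselines.** Baseline means are log-normal draws clipped at
  ±2σ. In a ~10²-transcript slice an unclipped tail draw dominates the
  per-sample column sums, so planted shifts on it would move every other
  transcript's RPKM — a composition artifact a real 20k-gene library does
  not show at these DE fractions. Planted-effect transcripts are floored
  at the median baseline (a 4-fold shift at the Poisson noise floor is
  undetectable at n = 3 and would measure nothing), and planted-pair
  members one σ above it (near-perfect empirical correlation requires
  integer counting noise to be far below the coupling jitter).
* **Balanced DE directions.** Planted up/down calls are assigned exactly
  half-and-half, again to keep the column sums comparable between groups
  in a small slice.
* **Latent-profile pair coupling.** Both members of a planted pair derive
  from one latent per-sample profile — the lncRNA's planted group means
  with bounded ±2% multiplicative jitter, shared by both members, plus a
  4× smaller independent residual per member. The coupling acts on the
  library-proportion scale so it survives RPKM's per-sample division;
  negative pairs reflect the latent profile about its range midpoint.
  Three alternatives fail: independent per-member noise lets the
  group-respecting permutations tie the observed |r| (exact p ≈ 0.1, see
  above); reflecting a full-dispersion count profile explodes the
  relative noise at the reflected low end and destroys the mRNA's DE
  call; multiplicative inversion (y ∝ 1/x) preserves CV but its curvature
  caps |r| below 0.99. The construction is verified empirically on both
  the raw-count and depth-normalised scales and regenerated (with
  shrinking jitter) when below target; planting runs twice so the second
  pass couples against the column sums of the emitted matrix.
* **Pair members are planted DE.** The network stage only sees
  DE-filtered transcripts, so a planted edge that should be recoverable
  end-to-end must connect transcripts that are themselves differentially
  expressed; the coupled mRNA inherits its partner's (possibly flipped)
  direction and is recorded as planted DE in the truth object.

What the generator does **not** emulate: read-level artifacts (adapter
content, rRNA carry-over, GC bias), gene-length-dependent power,
correlated null structure between transcripts, batch effects, and
heavy-tailed outlier samples. A pipeline that recovers planted structure
here has been shown to implement its stated statistics correctly at the
study's sample size — not that those statistics are powerful or robust on
arbitrary real data; in particular the Welch t-test at n = 3 is honest but
weak, and real biological dispersion above ~0.05 will cost it substantial
sensitivity at 4-fold effects.

## Numerical choices

* Library sizes are raw column sums; RPKM of a zero count is exactly 0.
* BH via the standard step-up procedure (statsmodels), verified in-test
  against an independent implementation.
* Ranking keys: DE top tables by ratio descending, ties by smaller
  adjusted p then lexical id; hubs by degree descending, ties by id.
* All RNG flows through `numpy.random.default_rng` seeded from one config
  value; identical config + seed reproduces every artifact byte-for-byte.
* Pipeline artifacts are staged in a temporary directory and moved into
  the output directory only after every stage succeeds.

## Problem sizes used in the checks

The bundled tests and the acceptance script run at desk scale: fixtures of
120 transcripts × 6 samples, 2000-pair networks with full 720-arrangement
enumeration per pair, 200-replicate null batteries for calibration, and
100-seed Monte-Carlo checks of the planted fold change. These sizes keep
the whole suite in the seconds-to-minutes range while leaving every
statistic in the regime the pipeline is designed for (n! enumeration,
small-sample t-tests).
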
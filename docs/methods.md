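# Methods

This note documents the models, rules, defaults and numerical choices the
package implements, what the synthetic data does and does not emulate, and
the known limitations.

## Restriction maps

Digestion scans the forward strand for exact occurrences of the recognition
site and cuts at `occurrence_start + cut_offset`. Only palindromic sites are
accepted (DpnII `^GATC`, offset 0; HindIII `A^AGCTT`, offset 1), for which a
single-strand scan finds every cleavage position; non-palindromic enzymes
are rejected rather than silently half-digested. Ambiguity codes never
match, so assembly N-runs sit inside long fragments instead of being masked
out — configurable N-run exclusion is deliberately out of scope. Coordinates
are 0-based half-open everywhere inside the package; 1-based variant
positions are converted exactly once, in `sleepv2g.io`.

Four-fragment concatenation merges consecutive runs of k = 4 fragments,
with a shorter final run kept as its own fragment, so the tiling of the
chromosome is preserved at every resolution. Fragment statistics are the
arithmetic mean and median of all fragment lengths pooled across whatever
records the input FASTA contains; `genome_fragment_stats` offers a
`primary_only` switch (chr1–22, X, Y) because published genome-wide numbers
do not always state whether alternate/unplaced contigs were included.
Position lookup is a binary search over the boundary array.

## Variant-to-gene rules

All four thresholds are strict inequalities and exposed as configuration:
r² > 0.7 for LD proxies, CHiCAGO score > 5 for interactions, TPM > 1.5 and
percentile > 50 for expression. Where a choice was genuinely open:

- *Proxy openness* is evaluated at the single SNP base (pos − 1 in 0-based
  coordinates), not at fragment granularity: open-chromatin intersection is
  a point-in-interval test against peak intervals.
- *Non–bait-to-bait* means the proxy position lies in **no** baited region,
  not merely outside the linked bait.
- *Other-end overlap* is any-overlap (≥ 1 bp) between the proxy's fragment
  at the interaction's stated resolution and the other-end interval. When
  the fragment maps agree with the interaction coordinates, containment and
  overlap coincide; any-overlap is robust to off-by-one coordinate dialects.
- Each gene of a multi-gene bait yields its own link; links are
  deduplicated on (proxy, bait, gene), keeping the best score. Distinct
  interactions are counted as (bait, other-end interval, resolution)
  triples.
- Expression percentiles, when absent from the input table, are computed as
  average-rank percent ranks of TPM over all genes in the table.

When several peaks contain one proxy the lexicographically smallest
(start, end, id) peak is recorded, purely to keep outputs deterministic.

## Fly sleep

A minute is immobile iff its beam count is zero; sleep bouts are maximal
immobile runs of ≥ 5 min (the threshold is a parameter), and a run
truncated by the trace end still counts if its observed length reaches the
threshold. Sleep minutes are attributed to day (ZT0–ZT12) or night
minute-by-minute, so a bout spanning lights-off contributes to both phases;
bout *counts* are attributed to the phase of the bout's first minute.
Multi-day traces are reduced to per-day values by dividing totals by the
number of recorded days. Waking activity is total counts over wake minutes
divided by wake minutes, undefined (None, never 0) for an animal that never
wakes. Animals with zero activity through the final day of recording are
flagged dead and dropped by default (configurable) — standard DAM hygiene.

The screen band is pooled animal-level mean ± k·SD (sample SD, k = 2
default). Both reference pools are implemented: every animal tested, or the
animals of designated control lines. The synthetic validation uses the
control-lines pool because in a small synthetic screen the planted hit line
is a non-negligible fraction of "every animal tested" and would inflate the
band against itself; in a real screen of ~70 lines the two pools nearly
coincide.

Arousal trials require strictly increasing stimulus intensities, exclude
flies awake (per the 5-min rule) at first-stimulus onset, score a response
as displacement > 3 mm within a 60 s window (both parameters configurable;
the window matches 1-frame/s tracking granularity), and right-censor trials
with no response at the maximum intensity. Reactivity assigns each sleeping
(fly, stimulus) trial to a 5-min-wide immobility bin starting at 5 min;
bins with no trials are omitted. The group comparison fits
proportion ~ bin midpoint + group by weighted least squares with trial
counts as weights and reports the group (elevation) coefficient — a linear
ANCOVA on binned proportions, adequate for sign-and-magnitude comparisons
but not a substitute for a trial-level logistic model.

Rebound is the per-animal percent change in daytime sleep between baseline
and recovery; animals with zero baseline are flagged and excluded from the
percentage. The deprivation window itself is configuration, not code.

## Zebrafish sleep

Movement-seconds per minute strictly below 0.5 s score as sleep; every
maximal run of sleep minutes is a bout (minimum length 1). Day is
09:00–23:00 and night 23:00–09:00 to match 14:10 rearing; both boundaries
are parameters. Trimming removes everything before the first lights-on at
or after recording start and keeps exactly two 1440-min cycles, so analysis
windows always align with phase boundaries. Cumulative day/night sleep sums
both analyzed cycles per larva. Waking activity is computed per clock hour
(sum of movement over wake minutes / wake minutes, undefined for fully
asleep hours) and reduced per larva either as the mean of defined hourly
values (default) or over all wake minutes pooled — both reductions are
provided because published "average activity" values do not fully pin down
the reduction.

Group comparison defaults to the Welch t-test with Welch–Satterthwaite
degrees of freedom, implemented in closed form and cross-checked against an
independent reference implementation in the tests. An optional mode runs an
F-ratio variance pre-test and falls back to the pooled test; the default
avoids an unspecified pre-test while remaining valid under unequal
variances. Inclusion of F0 crispants requires headloop/standard PCR ratio
strictly above 0.9.

## Synthetic data: what it emulates and what it does not

The landscape generator digests a random uniform-composition genome
(DpnII fragments average ~256 bp there, vs. ~430 bp on a real genome whose
base composition is not uniform), then places each planted locus on
dedicated fragments: proxies inside a peak on one fragment, an open bait
with 1–2 genes on another, and an interaction between them with score > 5
at one- or four-fragment resolution. All selected fragments occupy distinct
four-fragment bins, which guarantees the ledger equals the pipeline output
exactly rather than merely being a subset. Decoy suites add four loci each
violating exactly one link condition (closed proxy, proxy inside a baited
region, score < 5, closed bait), one locus carries deliberately
unexpressed genes, and every locus includes one sub-cutoff LD record.
What is *not* emulated: realistic LD decay, peak width/score distributions,
trans interactions, and genomic base composition — so recovery results
demonstrate the correctness of the rule chain, not its behavior on real
noise.

Behavior traces come from a two-state (sleep/wake) per-minute Markov chain
with separate day/night transition matrices — the minimal structure that
makes run-length sleep scoring and day/night contrasts meaningful. Fly wake
minutes carry Poisson(λ = 2) counts clipped to ≥ 1, so wake is never
miscalled immobile and waking activity is controllable independently of
sleep. Defaults (wake→sleep 0.02/0.06 day/night, sleep→wake 0.06/0.015)
give ≈ 180 day + 575 night sleep min — an unremarkable wild-type-like fly.
Zebrafish sleep minutes draw movement from Uniform[0, 0.5) and wake minutes
from Gamma(3, 2) clipped to [0.5, 60], so the strict 0.5-s boundary is
respected on both sides and scoring recovers the latent state exactly.
Defaults (0.015/0.12 day, 0.06/0.045 night) give ≈ 11% day and 57% night
sleep. Not emulated: circadian waveform shape within phases, startle
transients at light transitions, inter-animal parameter heterogeneity, and
measurement noise on movement values — so planted-effect recovery measures
estimator calibration under the model, not robustness to real-world
artifacts.

Planted fly effects are specified in SD units of the null animal-level
total-sleep distribution: the null SD is estimated once by Monte-Carlo
(200 animals), and both sleep→wake probabilities are scaled by a factor
solved (Brent's method) from the closed-form expected scored sleep
Σ_phase minutes · a/(a+b) · q⁴(5−4q) with q = 1−b — the q⁴(5−4q) factor is
the fraction of sleep-state minutes inside geometric sojourns of length
≥ 5. The closed form ignores phase-boundary truncation; that bias is a few
minutes, shared by all lines, and immaterial to a ± 2 SD call rule. The
zebrafish planted delta is calibrated exactly: the expected scored night
sleep in the analysis window is propagated through the alternating
transition matrices in closed form per segment (p_t = s + (p₀ − s)rᵗ,
r = 1 − a − b), and the knockout's night sleep→wake probability is solved
against that expectation, making the group-difference estimator unbiased
for the planted value.

Stimulus-response generation draws Bernoulli responses from a caller-
supplied curve over (intensity, immobility duration), stops stimulating
within an escalating trial once the animal has responded, and renders
responses as 5-mm displacement pulses in per-second movement traces, so the
arousal and reactivity analyses consume exactly the format they would see
from tracking exports.

## Determinism and problem sizes

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning; rerunning any generator or the full
pipeline with the same seed is byte-identical (log lines carry no
timestamps, manifests store sha256 digests). The validation suite uses
20 seeded landscapes for link recovery; a 5000-line × 16-fly null screen
against a 2000-line independently coded oracle; 10⁴ null replicates for
Welch type-I error; and 100 seeded replicates each for zebrafish delta
recovery (42 + 48 larvae, 72-h traces) and fly hit calling (6 lines × 16
flies) — sizes chosen to keep Monte-Carlo error well below the effects
being checked. Note the ± 2 SE recovery check is itself a statistical test
with ~5% intrinsic false-alarm probability for an unbiased estimator.

## Known limitations

- The V2G chain consumes interaction scores; it does not recompute them
  from reads, and r² values are inputs, not computed from genotype panels.
- The reactivity group comparison is a weighted linear fit on binned
  proportions, not a mixed-effects or logistic trial-level model.
- The fly effect calibration's closed form ignores phase-boundary bout
  truncation (small shared bias; see above).
- Real-genome digest statistics require the user to supply the reference
  FASTA; no download is attempted.
- Dead-animal detection is a trailing-zero heuristic and will not catch
  animals that die with residual tube vibration artifacts.
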
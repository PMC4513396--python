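# Methods

This note documents the model, the parameter defaults and why they are
what they are, the numerical choices, what the synthetic generator does
and does not emulate, and the known limitations.

## Model and assumptions

The detector assumes only that repeats are repeated: words of length *k*
drawn from repetitive sequence occur more often than a composition-aware
background predicts, and those excess occurrences cluster along the
genome. Detection is unsupervised and per-genome; nothing learned on one
genome transfers to another unless a saved model is applied deliberately
(`scan`).

**Scoring.** All 4^k words are counted in a dense table indexed by the
quaternary encoding (A,C,G,T → 0,1,2,3, leftmost base most significant).
Window indices are computed incrementally by Horner's rule and windows
containing any non-ACGT base are skipped; counting is single-pass over all
records and forward-strand only (a repeat inserted in reverse orientation
is simply a second word family — no reverse-complement collapsing).
Observed counts are adjusted against a Markov chain of order *o* fitted to
the same genome by maximum likelihood over valid stretches:

    adjusted(w) = 0                        if observed(w) ≤ 2
                = 0                        if observed(w) ≤ expected(w)
                = observed(w) − expected(w)  otherwise

with expected(w) = N · P̂(w₁..w_o) · Π_{j>o} P̂(w_j | w_{j−o}..w_{j−1}),
where N is the number of valid k-windows and the leading factor is the
empirical frequency of the word's order-length prefix among context
positions. The genome-total convention (scale by N) is fixed here so that
observed and expected are on the same scale. Contexts never observed fall
back to the uniform distribution. Adjusted values are stored as reals
because the subtraction is fractional.

The "≤ 2 occurrences" clause removes single-copy sequence and exact
duplications (two exact copies of any text score identically zero); the
expectation clause removes what composition alone explains, including
low-copy polyploid duplication — a word from a gene with c ohnologous
copies has observed ≈ c and, once the chain's order reaches the word's
uniqueness context, expected ≈ c as well.

## Parameter defaults

| parameter | default | units | why |
|---|---|---|---|
| k | round(log₄ valid bases), clamped to [8, 16] | nt | puts the chance expectation of a random word in [0.5, 2], so noise words rarely clear the "> expected, ≥ 3" bar while genuine repetition does. Rounding (not truncation) is what actually delivers expectation ≈ 1: truncating the logarithm lets the expectation drift up to 4, which measurably inflates the false-positive floor (≈ 2.6 % vs ≈ 0.16 % of a 1 Mb background-only genome) and the masked fraction |
| table cap | 4¹⁴ entries | — | ≈ 2 GB of int64 counts; the cap wins over the clamp and `count_kmers` refuses larger k explicitly |
| o (background order) | 6, clamped to < k | — | long enough to absorb composition and low-copy duplication, short enough to leave 200-copy repetition visible; also the order used for the random genomes in `evaluation.random_genome` |
| mask width | 40 (σ = 40/7) | bp | the mask covers ±3.5σ, essentially the whole Gaussian; 40 bp averages over the typical run of zero-scoring mutated windows inside a diverged repeat copy without bridging distinct repeats |
| w (derivative window) | 10 | bp | window of the discrete first/second derivative approximations |
| t (low-score threshold) | 2 | score units | doubles as the HMM log base; base 2 gives the finest level granularity over integer-scale adjusted counts, and a smoothed score of 2 is well above the background mean when k is chosen as above |
| mode | genome | — | `reads` is the same machinery: k derives from the total base count across reads and each read is scored and decoded independently; it exists as a profile so read-set-specific defaults have a home |

All of these are exposed as `PipelineConfig` fields, CLI flags and YAML
config keys.

## Labeling details

Smoothing truncates the mask at sequence ends and renormalizes by the
truncated weight sum, so constant tracks are exact fixed points
everywhere (zero-padding would drag boundaries toward zero). Positions
within w of an end have undefined derivatives and are excluded from the
maxima test.

The discrete first derivative is defined left-minus-right, so at a peak
its sign flips from − to +. A maximum is reported where the sign of f′
flips strictly between consecutive defined positions and the smaller of
the two second derivatives is negative; that smaller-f″ position is the
one reported (the left one on exact ties). Requiring f″ < 0 rejects
minima, so the flip direction never needs to be privileged. A perfectly
flat plateau has no discrete maximum under this rule; real score tracks
carry per-position jitter, so this arises only in synthetic edge cases,
which stay unlabeled — by design, since delineation requires a maximum.

Delineation reconstructs "expand the core until a non-repetitive region
is encountered" as: runs of smoothed scores ≥ t are bridged across
below-threshold gaps shorter than one mask width; a bridged run becomes a
candidate iff it contains a maximum; runs below t at least one mask width
long become non-repeat regions; everything else is unlabeled. The three
constants (t, mask width as gap/length scale) are configurable; this
expansion rule is this package's own reconstruction of the idea, chosen
as the minimal reading.

## HMM details

Levels run 0..⌈log_t(max genome score)⌉; level 0 exists because the
output map sends every non-positive score there, and when the maximum
score is positive but maps to level 0 (max ≤ 1) a second level is still
allocated so that high/low remain distinguishable (the minimal such model
has four states). States are indexed non-repeat track first, by level.

Training adds one pseudocount to every prior and transition cell before
normalization so Viterbi never hits −∞. Transitions are counted inside
each labeled region, plus one transition between the adjoining states of
consecutive labeled regions per sequence — even when an unlabeled gap
separates them. Without cross-boundary counts the repeat↔non-repeat
switching probabilities would be pure pseudocount and segmentation would
be arbitrary; counting across short unlabeled gaps is the price of
having unlabeled leftovers at all (which are otherwise excluded from
training). Unit output probabilities make decoding a two-hypothesis
recursion (repeat/non-repeat track per position); ties prefer the lower
state index, i.e. the non-repeat track — deterministic and conservative.
Final repeat runs are extended by k−1 bp (the tail of the last repeated
word), clipped to the sequence, and merged when extension makes them
touch.

Model persistence stores the adjusted table, the background chain, t,
the level count and the trained counts in one `.npz` container with a
format version; `scan` on the same input reproduces `detect` exactly.

## Evaluation measures

SN_class = 100·O/R on unions of intervals (pooling classes by union
prevents double counting where annotations overlap); SP_exon =
100 − 100·O/E; PP = 100·predicted/valid bases; PR = predicted − O. FPL
runs the detector on a length-matched random genome sampled from
per-sequence order-6 chains; subtracting chance repeats found by a
reference annotator is supported by passing that annotation in, but is
not bundled — without it the value is reported as *unfiltered* FPL.
Ratios with empty denominators are reported as undefined (NaN / "NA"),
never as zero.

## The synthetic generator

`simulate` emulates exactly the features the detector keys on: an
order-o Markov background (per-context conditionals drawn once per seed
from a Dirichlet centred on the requested GC), interspersed families
(uniform-random consensus; each copy independently mutated with
per-base substitutions, uniform over the three alternatives, and
geometric-length indels), tandem arrays (motif repeated with per-copy
substitutions), and unique "exons" rejection-sampled against 13-mer
reuse so exon avoidance has a meaningful ceiling. Elements are placed
uniformly at random without overlap by cutting the background into
gaps; truth intervals are recorded exactly as placed; everything is a
pure function of the seed.

Defaults are the standard study conditions used throughout the tests:
1 Mb, order-3 background, one family of 200 copies × 500 bp at 5 %
divergence (indel rate 0.01), 50 tandem arrays (25 bp motif × 20
copies, 5 % divergence), 20 exons of 300–800 bp. The tandem geometry
and indel rate are this package's choices of a realistic minisatellite
burden where only array count and family geometry were prescribed.

What it does **not** emulate: TE structural features (LTRs, TIRs, target
site duplications), nested or truncated insertions, reverse-complement
copies (available as an explicit option only in the sense that the
machinery counts strands separately), CpG/isochore heterogeneity,
sequencing error profiles. Passing the recovery tests therefore shows
the pipeline recovers *clustered k-mer excess over a Markov background*;
it does not certify sensitivity to structurally complex real TE
landscapes, where reported sensitivities on real genomes are
substantially below the synthetic ones.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at 1 Mb
(and 0.5 Mb for the scaling check) — large enough for k = 10 tables,
16-state models and thousands of labeled regions, while a full run stays
in seconds. The scaling check runs both sizes with default parameters:
the auto-selected word length tracking the genome size is itself part of
the linear-time behaviour — it holds the chance expectation of a word
(and with it the density of noise words, candidate counts and per-base
work) roughly constant as n grows, whereas at a fixed k doubling the
genome doubles every word's expectation and superlinearly inflates the
labeling workload. Wall-clock comparisons use the best of several
repeats because single sub-second runs are noisy.

Ceiling-of-logarithm computations subtract 1e-9 before `ceil` so that
exact powers of t land on their own level despite floating-point log.
Probability rows are validated to sum to 1 within 1e-9. Smoothing equals
a brute-force weighted mean within 1e-9. Viterbi is compared to
exhaustive path enumeration exactly (tolerance 1e-9 on log
probabilities) for all models with ≤ 6 states on tracks ≤ 12.

## Known limitations

* No repeat classification into families; the output is a segmentation.
* Forward-strand counting means a repeat family present in both
  orientations is detected as two independent families — fine for
  masking, halves the per-family copy count.
* The reads mode shares all defaults with the genome mode; read-specific
  parameter tuning is left to the user via the config.
* FPL without a reference annotator overstates false positives on
  backgrounds that genuinely contain chance repeats.
* The dense table makes k > 14 impractical on 8 GB machines; the cap
  produces an explicit error rather than swapping.
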
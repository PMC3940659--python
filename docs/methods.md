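# Methods

This note documents the models, algorithms, parameters and numerical choices
behind `idrscape`, and what its synthetic benchmarks do and do not show.

## Problem setting

Intrinsically disordered proteins (IDPs) lack a stable fold yet aggregate
into amyloid fibrils in several human diseases.  Two kinds of sequence
features matter for that process and are the objects of this package:

- **Amyloidogenic regions (AR)** — short stretches (six residues and up)
  able to nucleate fibril formation, detected here by scanning every
  hexapeptide window with an additive position-specific scoring matrix
  (PSSM).
- **Low-complexity regions (LCR)** — stretches of biased amino-acid
  composition, abundant in IDPs, detected by windowed-entropy segmentation.

The pipeline quantifies, per protein and per disorder class, how much
sequence lies in each kind of region, how often the two overlap, what the
regions are made of, and what distributions their lengths and contents
follow across a cohort.

## Coordinates and interval algebra

All coordinates are 1-based and inclusive at both ends: the interval
(97, 112) has length 16.  Same-kind intervals that *overlap* are merged
before residue counting, so content percentages count every residue once
and can never exceed 100; intervals that merely *abut* are kept distinct so
region counts are preserved.  Content is

    content % = 100 x (residues covered after merging) / protein length,

returned at full precision; presentation rounding is half-up (2.5 -> 3) to
0 decimals for the disordered-protein panel and 2 decimals for the
amyloidogenic panel, matching the curated tables the worked-example tests
reproduce.  Terminal counts use window intersection: a region counts toward
a terminus when any of its residues lies within the first or last 15
positions (the most inclusive reading of "within 15 residues of the
terminal").  One curated entry prints a 4-residue overlap in its text while
its own coordinates give the 5-residue GQNYY (310-314); the package follows
the interval arithmetic.

## LCR detection (entropy segmentation)

A window of W residues is scored by its Shannon entropy in bits,
H = -sum_i (n_i/W) log2(n_i/W).  Windows at or below the **trigger** cutoff
seed candidate stretches; stretches extend through contiguous runs of
windows at or below the looser **extension** cutoff.  Defaults are the
canonical triple W = 12, trigger 2.2 bits, extension 2.5 bits, exposed in
`SegParams`.  Windows containing ambiguity letters (X, B, Z, U, O) are
skipped and can neither seed nor extend a stretch.

Each merged stretch is then refined to its lowest-probability core.  The
composition probability of a window under a uniform 20-letter background is
P = W!/(prod n_i!) x 20^-W.  Raw P decreases with W for almost any
composition, which would make the longest sub-window win by default, so the
criterion is normalised per residue: the contiguous sub-window of length >=
W minimising log(P)/W is selected, ties resolved longest-then-leftmost (a
pure homopolymer run scores exactly -log 20 per residue for every sub-run,
so the tie rule keeps the whole core; score comparisons use a 1e-9
tolerance so float drift cannot defeat the tie rule).  After removing the
selected core the flanking remainders are re-segmented recursively, so one
stretch harbouring two distinct biased cores yields both.  This single-pass
reduction with recursion is a simplification of the original recursive
optimal-segment search; it can be switched off (`refine=False`), in which
case the raw extension spans are reported.  Detection is deterministic and
independent of protein order.  On planted homopolymeric cores (>= 2W
residues) in uniform-random flanks it attains per-residue recall 1.0 and
precision ~0.99 (seeded 200-protein cohort).

## AR detection (hexapeptide PSSM scan)

A 6x20 matrix assigns a weight to every standard residue at each window
position; a window's score is the sum of its six weights and windows with
score >= threshold qualify (closed bound).  Residues covered by qualifying
windows are unioned and maximal runs become AR intervals (length >= 6 by
construction), each carrying its peak window score.  Windows containing
ambiguity letters are skipped, not scored.  Raising the threshold can only
shrink the reported residue set.

No trained matrix is bundled: published amyloid predictors do not disclose
their weights in reusable form, and the scanner accepts any 6x20 TSV.  For
testing and simulation, `motif_pssm` builds a fixture matrix from a list of
experimentally characterised amyloidogenic hexapeptides (defaults KLVFFA,
STVIIE, VQIVYK, NFGAIL): +1 where a motif carries a residue, -1 elsewhere,
threshold preset `best_overall` = 6.  Only windows drawn per-position from
the motif alphabet can reach 6, so listed motifs always qualify while a
uniform-random window qualifies with probability ~(4/20)^6 ~ 6e-5.

## Disorder classes and cohort aggregation

The disorder fraction of a protein is 100 x (residues in merged disordered
intervals)/length; disorder is an *input annotation*, not predicted here.
Classes partition [0, 100]: **PDP** (partially disordered) <= 30, **MDP**
(moderately) in (30, 70], **LDP** (largely) > 70.  The half-open convention
resolves the boundary ambiguity so every real-valued fraction maps to
exactly one class.  A protein is *amyloidogenic* when it has at least one
AR.  Class summaries report protein counts, amyloidogenic counts and
percentages, AR/LCR counts and mean contents, and overlap-record counts,
plus a Total row that equals the sum of the class rows.

Composition profiles are residue frequencies over the concatenation of all
in-context residues (whole protein, AR, or LCR context); ambiguity letters
are excluded from numerator and denominator.  Secondary-structure
preference tallies H/E/C labels per residue over a context; a secondary
mode assigns each region its majority label and reports percentages over
regions.  Per-residue H/E/C strings are expected from an external predictor;
a deterministic Chou-Fasman propensity argmax (helix vs sheet, coil when
neither propensity exceeds 1.0) is bundled strictly as a baseline stand-in.

## Distributional layer

**Stable fits.**  Region lengths and contents are right-skewed and
heavy-tailed, summarised by the four-parameter alpha-stable family
(stability index alpha in (0, 2], skewness beta in [-1, 1], location mu,
scale sigma), pinned to the S0 parameterization, which is continuous in
alpha — relevant because fitted skewness sits near the beta = 1 boundary,
and beta is clipped to [-0.999, 0.999] for numerical stability.  Densities
come from numerical inversion of the characteristic function
(`scipy.stats.levy_stable`).  `fit_stable` initialises at McCulloch-style
quantile estimates and refines by *binned* maximum likelihood: the sample
is compressed into up to 300 equal-count bins represented by their means,
and the weighted log-density is maximised with Nelder-Mead (alpha floored
at 0.35, sigma optimised on the log scale, at most 150 iterations).  Full
per-point stable MLE is orders of magnitude slower for no practical gain at
these sample sizes.  On 5000 simulated variates at the heavy-tailed content
set-point (1.34, 0.99, 9.73, 2.24) the fit recovers alpha within ~0.03 and
mu within ~0.06; Gaussian data drives alpha to 2.  Pooled region lengths
across proteins (not per-protein means) are the fit inputs.

**Kernel density.**  The joint density of content versus protein length
uses a *product* Gaussian kernel with per-dimension Silverman bandwidths
h_i = sd_i (4/((d+2) n))^(1/(d+4)), evaluated on a regular grid padded by
three bandwidths so the surface integrates to ~1.  This is deliberately not
the full-covariance bandwidth matrix some libraries default to; the
brute-force kernel-sum oracle in the tests pins the definition.

**Hyperbolic regression.**  The content-length relation is fitted as
y = a + b/x, ordinary least squares in u = 1/x, with R^2 = 1 - SS_res/SS_tot.
A noiseless curve is recovered to six significant digits.

**Welch tests.**  Class-pair content comparisons use the unequal-variance
t-test with Welch-Satterthwaite degrees of freedom (a pooled-variance
variant is available by flag); the choice of variant is the package's
defensible default where the original analysis tool is unspecified.

**Discrete summaries.**  Min, max, mean, median, plus a mode defined as the
midpoint of the most populated unit-width histogram bin (ties -> lowest
bin), making "mode" well-defined for continuous percentages.

## Synthetic cohorts

`synthetic_data` generates ground-truthed cohorts with the statistical
structure the analysis assumes, so every stage is testable without database
downloads.  Defaults are fixed once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| protein length | log-normal, median 400 aa, log-sd 0.45, clamped [60, 4000] | disordered-protein cohorts peak near 400 aa |
| class mix (PDP, MDP, LDP) | 0.48, 0.26, 0.26 | class proportions of a curated human IDP cohort |
| AR plants per protein | Poisson(4.0) (or fixed) | ~894 ARs over 221 proteins in the same cohort |
| LCR plants per protein | Poisson(2.9) (or fixed) | ~638 LCRs over 221 proteins |
| LCR length law | stable (0.92, 0.99, 14.99, 4.67), truncated [6, L/2], integer-rounded | fitted length law of curated LCRs; truncation prevents absurd draws |
| LCR composition | Ser .131, Pro .121, Gly .098, Ala .092, remainder uniform | enrichment observed in real LCRs; `homopolymer` mode plants single-letter runs |
| background | uniform over 20 residues | maximally distinguishable from plants; a `realistic` mode uses average proteome frequencies |
| min gap between plants | 7 residues | keeps planted ARs from merging under the scanner |

Disorder intervals are sized so the realized fraction lands inside the
requested class band (sampled away from the boundaries), so the generator
and classifier close the loop exactly.  Each protein draws from its own
seeded substream (`default_rng([seed, index])`), making cohorts stable
under growth of `n_proteins` up to the shared prefix and byte-identical
across runs.  When a drawn LCR length cannot fit alongside the other
plants, the longest stretch is trimmed to the remaining room before being
dropped, which preserves the count law and most of the heavy tail; the
stable fit on realized lengths still recovers alpha within ~0.15 of the
set-point despite truncation.

What the generator does *not* emulate: real domain architecture, sequence
evolution, prion-like Q/N tract grammar beyond composition bias, and real
disorder-LCR correlation.  Passing planted-recovery tests therefore shows
the detectors implement their definitions correctly, not that they match
any particular external predictor's output on real proteins; curated
annotations of real proteins are used for the worked-example tests instead.

## Pipeline and determinism

`run_pipeline` takes FASTA plus either annotation tables (AR/LCR/disorder
TSV, 1-based inclusive; secondary structure as H/E/C FASTA-like records) or
the bundled engines, and writes per-protein summaries, class summaries,
overlap catalogs, composition and secondary-structure tables, fits JSON and
a run report listing every parameter used.  Per-protein failures are logged
and skipped with a nonzero count in the report.  Outputs contain no
timestamps; identical configuration and seed give byte-identical files.
The pipeline's default stable-fit method is the fast quantile estimate
(`stable_method="mle"` enables the refined fit); stable fits are attempted
only at >= 50 samples.

## Problem sizes used in the shipped checks

Worked-example reproduction runs in milliseconds.  Oracle-equivalence
suites use >= 200 random small instances per operation.  Stable-parameter
recovery uses 5000 simulated variates; planted-region recovery uses
200-protein cohorts; determinism uses a 20-200-protein cohort run twice.
These sizes give stable pass/fail behaviour at a few minutes of single-CPU
compute.

## Known limitations

- The entropy segmentation is not bit-compatible with any particular build
  of the original SEG program, and no masking output is produced.
- The scanner models only the additive PSSM term of hexapeptide
  amyloidogenicity predictors, not their physical-property corrections;
  published per-protein predictions are therefore not reproducible and the
  numeric "best overall performance" cutoff of such tools must be supplied
  with the user's matrix.
- Database-wide absolute counts require full cohort snapshots and are out
  of scope; the curated worked examples cover per-protein arithmetic only.
- Stable MLE is binned; for very small samples (< 50) the quantile estimate
  dominates and a warning is issued.
- The Chou-Fasman baseline is a 1970s-era propensity argmax and should not
  be used where a real secondary-structure prediction is available.
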
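# Methods

## The search procedure

NRFS is a wrapper method: candidate subsets are scored by the accuracy of
a k-nearest-neighbor classifier built on one half of the training
patterns and evaluated on the other half. The neighborhood structure
enters only through the candidate *ordering* and the pair *filtering*;
acceptance is always decided by the criterion.

The weight kernel is `{distance 1 → 2, distance 2 → 1, otherwise 0}`.
On the chain this is the unique kernel consistent with every value of the
published 10-feature worked example (we verified this against the
brute-force kernel-sum oracle); on the grid, where the source diagram's
cell values are not recoverable, we apply the same kernel to Chebyshev
distance as the most conservative 2-D generalization. Both the kernel and
the topology are user-configurable.

Decision rules, stated precisely:

* **Single addition** (descending weight, ties by lower index): accept iff
  `accuracy_after >= accuracy_before`. Equality is deliberately accepted —
  it is what lets the subset spread into a plateau of equally informative
  neighboring bands.
* **Pair addition**: only pairs with weight sum `>= t_add` (default 7) are
  candidates, in descending-sum order, same acceptance rule. The published
  worked example retains a pair whose sum *equals* 7, so the comparison is
  `>=` even though the accompanying prose says "exceed"; the printed table
  governs. Note the example table is itself incomplete under any fixed
  rule: a fourth pair also sums to exactly 7 but is not printed. Our
  enumeration is exhaustive; its leading entries match the printed table.
* **Single elimination** (ascending weight): accept iff strictly better.
* **Pair elimination**: pairs with weight sum `< t_del` (default 3),
  ascending order, strict improvement. The source's own example here is
  arithmetically inconsistent (it eliminates a pair whose weight sum is 4
  against a stated threshold of 3); we implement the literal rule and
  leave `t_del` configurable.
* After any accepted elimination — single or pair — control returns to the
  weight recomputation, mirroring the explicit instruction given for pair
  elimination.
* The algorithm is one pass (add stage, then eliminate stage); a
  `loop_stages` flag repeats the cycle until a full pass accepts nothing.

Termination: each accepted addition grows the subset (bounded by the
number of features); each accepted elimination strictly raises accuracy by
at least `1/n_validation` (bounded). Every attempted decision is logged;
replaying the accepted records from the initial subset reproduces the
final subset exactly, which the tests assert bit-exactly.

### kNN criterion

`k = 3` by default (the source never states k; an odd value avoids most
vote ties in 2–3-class problems), Euclidean distance on raw subset
columns (band powers are already normalized). Determinism requires
explicit tie rules: a distance tie at the k-th position is resolved toward
the lower pattern index (stable argsort); a vote tie falls back to the
label of the single nearest neighbor. The search driver memoizes
evaluations by subset and, for the Euclidean metric, precomputes
per-feature squared-distance matrices so a subset evaluation is a sum of
slices; squared distances preserve the ordering and tie structure of
Euclidean distances.

The empty subset is defined to score 0, so the first forward step of any
search always succeeds.

### SFFS initialization and stopping

The floating search used for initialization (and as a baseline) keeps a
best-subset record per size. Each round performs the greedy forward
addition, then accepts backward removals only while the reduced subset
strictly beats the record at the smaller size; the search ends when a
round improves neither the best-overall accuracy nor any previously
visited per-size record, and returns the best subset observed. The
source's stopping condition is unspecified ("until the desired target is
reached"); this rule terminates on every input, follows the plain SFS
path while SFS is still improving, and therefore never returns a worse
subset than SFS — a property the tests check. SFS itself is forward-only
hill climbing with strict improvement.

Information gain uses equal-width binning with 10 bins by default
(equal-frequency is available; degenerate bins are merged, a constant
feature scores 0).

## Feature extractors

* **Band powers**: 4-s rectangular windows with 1 s of shared signal
  between consecutive windows (hop 3 s — "overlap" is read as shared
  signal, not hop). Windows start at multiples of the hop; the final
  window is truncated at the signal end so every sample is covered.
  Per window, the periodogram is summed over 32 equal-width bands
  covering (0, 50] Hz — band b is `(b·Δf, (b+1)·Δf]` with
  `Δf = 50/32 = 1.5625 Hz`, DC excluded — and normalized to sum to one,
  which cancels signal gain. (A printed band width of "1.6 Hz" in the
  source is the rounded value of 50/32.)
* **Subregion counts**: a 64×64 binary image yields 256 features, the
  foreground counts of the 4×4 blocks of a 16×16 grid, row-major from
  the top-left — the ordering the 2-D topology assumes. Values lie in
  [0, 16] and sum to the image's foreground count.

## Synthetic data

The original recordings (single-rat EEG; a scanned character database)
are not redistributable, so the package generates structurally analogous
data; the generators are first-class, tested code.

**EEG-like tables.** Three classes (AW / SWS / REM analogues) with
236 / 248 / 56 patterns by default — the training-set composition of the
motivating application — over 32 bands. A decaying positive baseline
(`0.5 + exp(-b/8)`) receives class-specific elevations on contiguous
band runs: SWS a delta-like run (bands 0–2, +2.0); AW and REM share an
alpha-like run (bands 5–7, +1.2) and differ on a gamma-like run (bands
14–21, +0.8 vs +1.6), mirroring the qualitative spectra of the three
vigilance states. Gaussian noise (sd 0.5) is added per band, values are
clipped at zero and normalized to sum to one. The noise level was fixed
so that all-feature kNN accuracy sits near 95%, inside the accuracy band
the motivating study reports; it was chosen once, before the acceptance
checks were run. What this generator does **not** emulate: real spectra's
correlated band noise, heterogeneous per-band signal-to-noise, artifacts,
or epoch autocorrelation — so passing recovery tests show the search
behaves as designed on cleanly planted contiguous structure, not that it
matches the published real-data band selections.

**Character-like tables.** Two classes of 200 images each by default.
Every image draws the same distribution of random thin strokes on a
64×64 canvas; the second class additionally stamps a dense dot whose
pixels are clipped to a "crucial region" (default blocks rows 1–3,
columns 10–13 — a top-right area), so outside that region the
class-conditional feature distributions are identical by construction.
Features are the 256 subregion counts.

**Noise injection** (robustness protocol): exactly
`round(0.2 · n)` patterns are corrupted in exactly 6 randomly chosen
feature cells each — by a uniform draw inside that feature's observed
min–max range (default; redrawn if the draw coincides with the original
value) or by copying the value of a random other pattern. Feature choices
are independent per corrupted pattern. Labels and untouched cells are
preserved bit-exactly; everything is a pure function of the seed.

## Validation problem sizes

The invariant checks (monotonicity, trace replay, termination) run 20
seeded searches on a reduced 100-pattern EEG-like table; the chain
structure-recovery checks use the full default table (540 patterns); the
grid checks use 100 images per class. These sizes are the package's own
test-design choice; the generators default to the full sizes above.

## Known limitations and open points

* The grid kernel is a design choice, not a reproduced artifact; users
  with a different 2-D diagram can supply any distance→weight mapping.
* Equality-accepting additions can grow large subsets on flat accuracy
  plateaus; this is the documented behavior of the procedure (it selects
  more features than the baselines) rather than a defect.
* One property stated for the chain benchmark — that NRFS selections form
  longer contiguous runs than an equal-size information-gain ranking —
  does not hold on this generator: with smooth uniform elevations the IG
  landscape is smooth along the chain, so IG's top-m falls into contiguous
  intervals, and at small subset sizes a wrapper deliberately picks
  complementary features from *different* runs while IG's equal-size list
  sits inside the single strongest run. The corresponding acceptance test
  asserts the property as stated and documents its failure; the effect
  says more about filter behavior on idealized planted data than about
  the search itself.
* Vote-tie and distance-tie rules, k, and the metric are package
  decisions (the source is silent); all are configurable.
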
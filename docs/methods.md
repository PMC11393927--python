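# Methods

## Scope and model overview

`lexidiag` turns the machinery of a tachistoscopic reading clinic into
testable software. Its components are:

1. a **virtual reader** — a small psychophysical model of single-fixation
   word recognition;
2. a **pseudoword generator** that produces pronounceable non-words whose
   letter sequences are attested in a reference lexicon;
3. an **adaptive staircase** that recovers a reader's simultaneous-letter
   capacity per fixation time and the verbal reaction time (VRT) they need;
4. a **causal-condition engine** that classifies conditions for correct
   reading as irreplaceable-necessary (Γ), interchangeable-sufficient
   (Λ1…Λp), or superfluous, from a monotone pass/fail oracle;
5. a **segmentation planner** that splits text into capacity-bounded
   segments, places fixation marks, and detects coverage gaps from
   hypermetric saccades;
6. a **therapy simulator** comparing unguided with computer-guided reading
   and computing error reductions and Hedges' g.

## The virtual reader

A single recognition attempt on a word of `n` letters at presentation time
`t` with allowed VRT `v` is correct if and only if all of:

* the whole word lies inside the seen window (a homonymous field defect with
  foveal involvement masks everything on the blind side of the fixated
  letter; a compensatory gaze strategy — gaze to the segment end for
  right-sided defects, to the beginning for left-sided ones — restores the
  full window);
* `n ≤ capacity(t)`, the reader's simultaneous-recognition capacity at that
  fixation time (a monotone step function on the 250–500 ms grid in 50 ms
  steps; queries between grid points clamp down to the nearest defined
  level);
* `v ≥ required VRT` — pronunciation started only after the sound sequence
  could be retrieved;
* no lapse (Bernoulli with the profile's lapse rate, at most 0.05) and no
  grapheme-sound confusion (each occurrence of a confusable letter such as
  p/q, b/d, m/n is exchanged with probability 0.5 when the pair is listed in
  the profile).

Letter-level errors carry **no positional structure**: conditional on a
capacity or lapse error the error position is uniform over letter positions
(window errors are uniform over the unseen positions). This encodes the
empirical finding that errors show neither a crowding signature at
flanked letters nor an attention-field gradient at word edges, and the test
suite verifies the uniformity by chi-square.

A pure VRT failure is premature pronunciation, not a letter error; it has no
error position.

### Cohort generator

`sample_cohort` emulates the study populations:

| parameter | value | rationale |
|---|---|---|
| capacity ceiling | {3,4,5,6} w.p. (.3,.3,.3,.1) | three to five letters common, six rare; counts unpublished, so "few" is encoded as 0.1 |
| threshold time | uniform on {350,…,500} ms | each reader reaches the ceiling at this time, losing one letter per 50 ms below it (floored at 2) |
| required VRT | N(1316, 712²) (low preset) or N(1670, 641²) ms, truncated below at 200 ms | the two reported cohort means/SDs; 200 ms is a physiological floor for sound retrieval |
| lapse rate | 0.02 | small residual error rate under fully met conditions |
| compliance | 0.9 | children "did not always follow the computer's instructions" |

The truncation shifts the low-preset mean from 1316 ms to ≈1404 ms
(scipy.stats.truncnorm provides the exact truncated moments the tests check
against). The generator emulates *between-child* variability in capacity,
timing, and compliance; it does **not** emulate within-session learning,
fatigue, motivation, attention fluctuations, or language-specific
grapheme–phoneme difficulty. Passing tests therefore show that the
diagnostic and therapy mechanics behave correctly under the stated
generative model, not that real children would show the same numbers.

## Pseudoword generation

"Pronounceable" is operationalized as **bigram attestation**: every adjacent
letter pair of an item occurs in the reference lexicon, and the item itself
is not a (case-folded) lexicon member. Items are sampled as bigram chains
with rejection (budget 10⁵ rejections, then a generation-exhausted error).
This is a deliberate stand-in: no construction procedure beyond the
attestation property is documented for the clinical materials, and a full
phonotactic or syllabification model is out of scope. A ~170-word German
lexicon ships with the package for self-contained use; any plain-text
lexicon (one word per line) can be substituted.

Grapheme clusters that correspond to a single phoneme ("sch", "ch", "ie",
"ah" in German; "ea", "au", "oa" in English; "eau", "eaux", "au", "en" in
French; shipped inventories add a few editable defaults) must never be split
across segments. Matching is longest-first, left to right, resolving
overlaps leftmost — deterministic and consistent with "sch" containing "ch".

## The adaptive staircase

Defaults are the clinical constants: 3-letter items at 250 ms, 20-item
lists, pass criterion ⌈0.95·20⌉ = 19 correct, time steps of 50 ms up to
500 ms, length cap 8.

State machine: administer a list at the current (length, time) with a
*generous* allowed VRT (max time + 3000 ms) so pronunciation timing never
confounds capacity estimation; on a pass increase the length; on a fail
probe whether the first failed item was spelled correctly:

* **not spelled** → a visual-capacity failure → increase the time (up to the
  cap);
* **spelled** → the item was seen but mispronounced: locate the minimal
  sufficient VRT by bisection on the 50 ms grid, then retry the same
  condition once with a fresh list. A second spelled failure at the same
  condition ends the session as VRT-limited.

The retry rule matters under lapses: with a 2% lapse rate a list whose
conditions are truly met still fails the 19/20 criterion about 6% of the
time, and such spurious failures always spell-check positive. Without the
retry the capacity estimate would be truncated early in a large share of
sessions; with it, recovered ceilings stay within one letter of the truth in
well over 95% of sessions (verified over 500 simulated sessions). A failed
*list* is never re-scored; the retry administers fresh items.

The VRT bisection searches from one grid step (50 ms) up to the generous
allowance, doubling the upper bound to a configurable ceiling (default
20 000 ms) when even the generous allowance fails — this makes extreme
readers (clinically observed up to 9–11 s) measurable instead of
unclassifiable, and the capacity phases resume with a raised allowance. If a
session never enters the sweep, a final sweep at the best passing
(length, time) fills the estimate. For lapse-free profiles the protocol
recovers the capacity map exactly and the required VRT within one grid step;
capacities below the 3-letter starting length are left-censored (the
corresponding early times simply have no estimate).

Cause attribution uses the three clinical labels: *trying to recognize too
many letters* (recovered ceiling below the maximal tested length), *too
short a fixation time* (some length needed time escalation beyond the
starting 250 ms), *too short a verbal reaction time* (session VRT-limited,
or the VRT estimate exceeds a configurable clinic norm, default 1000 ms —
deliberately below the reported dyslexic cohort means of 1316/1670 ms; the
norm is a package choice since no threshold is published).

## The causal engine

The pass-function is required to be monotone and is checked exhaustively
(universe capped at 20 conditions; tests use ≤ 6). Minimal clauses (prime
implicates) are enumerated directly: a clause is a minimal condition set C
such that reading fails whenever no element of C is met. Singleton clauses
form Γ, multi-element clauses are the candidate Λ sets, unreferenced
conditions are superfluous. The classification is canonical iff the
multi-element clauses are pairwise disjoint *and* the conjunctive form
(⋀Γ) ∧ (⋀i ⋁Λi) reproduces the oracle on every subset (also checked
exhaustively). Overlapping clauses are merged into disjoint candidate sets
and reported non-canonical with a witness subset where the merged form and
the oracle disagree; cause attribution refuses non-canonical
classifications rather than force-fitting them. Conditions outside the
declared universe (the "brown background" problem) are simply not modelled:
the engine never extrapolates to undeclared conditions.

## Segmentation and saccade planning

Coordinates are 0-based and half-open over the letters-only stream;
whitespace and punctuation are display-only. Segmentation is greedy left to
right within each whitespace-delimited word: take up to `capacity` letters,
shorten to the nearest allowed boundary when the cut would fall inside a
longest-match cluster; word boundaries are always allowed; a cluster longer
than the capacity raises an unsegmentable-input error naming the cluster.
Greedy segmentation is total and lossless, and increasing the capacity never
increases the segment count.

Fixation targets sit on the middle letter of each segment; even lengths
fixate left of center (an arbitrary but fixed tie-break). Amplitudes are
differences of consecutive global fixation indices; for contiguous plans
they never exceed the capacity plus one. `find_gaps` inverts the planning:
given fixated windows it reports every letter run never covered — non-empty
exactly when amplitudes overshoot the recognized windows, as with
uncorrected hypermetric saccades.

## Therapy simulation

Unguided reading applies the reader's strategy with **self-chosen
parameters** that embody the failure mechanisms. These constants are pinned
model choices (the mechanisms are documented clinically, their rates are
not):

| constant | value | mechanism |
|---|---|---|
| self-chosen fixation | 250 ms | fixations too short for the needed temporal summation |
| self-chosen VRT | 0.8 × required | premature pronunciation |
| guess success | 0.5 if ≥ half the letters recognized, else 0.1 | familiar natural words can be guessed from partial information |
| regression rate | 0.1 per transition | isolated single regressions; time cost only, never an outcome change (they are drawn from a separate random stream) |
| hypermetric excess | +2 letters | overshooting saccades leave unread gaps |
| saccade cost | 30 ms | reading-time model: sum of fixation durations plus a per-saccade constant; only relative/monotone time claims are asserted |

Strategies: `whole_word` fixates word middles; `searching` behaves like
whole-word reading with extra back-and-forth fixations (time cost);
`staircase_segments` self-splits at the reader's ceiling with adequate
self-chosen times — correct (lapse-only errors) but slow;
`hypermetric_no_correction` strides ceiling+2 letters and must guess the gap
letters; `letter_by_letter` reads one letter per fixation (slow, still
premature in pronunciation).

Guided reading segments the text at the reader's *diagnosed* capacity and
enforces the diagnosed fixation time and VRT cue per segment. On each
attempt the reader complies with probability `compliance`; otherwise the
self-chosen parameters apply for that attempt. The next segment is withheld
until the current one is read correctly; a segment counts as one error iff
its first attempt failed. With full compliance and no lapses, guided reading
is exactly error-free — all necessary conditions are met by construction.

The default cohort experiment (50 readers, low-VRT preset) diagnoses every
reader with the staircase, then reads the same synthetic text unguided and
guided. The text is built from pseudoword stand-ins for natural words with a
fixed word-length mix (2–8 letters with probabilities
.15/.25/.20/.15/.10/.07/.08, resembling running text for young readers — the
mix was chosen once from an a-priori analysis of the error mechanisms, and
the text size is set so the stream splits into about 200 segments at a
4-letter reference capacity). Under these conditions guidance removes
roughly three quarters of the pooled errors (the acceptance script
recomputes the exact percentage per seed), the guided count is below the
unguided count for every reader, and Hedges' g — computed between-subject on
per-reader error counts as
g = ((m̄_a − m̄_b)/s_pooled)·(1 − 3/(4(n_a+n_b) − 9)) — is large and
positive. The human-study effect sizes (g ≈ 2) and the "errors reduced to a
third" transfer finding are outcomes of human experiments with un-modelled
variance sources; the simulator reproduces the *mechanism*, and no constant
was tuned to match those magnitudes.

## Problem sizes and numerical choices

* Tests and the acceptance script use 50-reader cohorts, ~200-segment texts,
  200-profile recovery sweeps, 500-session robustness sweeps, and 10⁴-draw
  Monte-Carlo checks — sizes at which binomial noise is far below the
  asserted margins while the whole suite runs in well under a minute.
* All randomness flows through `numpy.random.Generator` seeded from explicit
  integers; child streams are split with `SeedSequence.spawn`, so unguided
  correctness draws, regression draws, and per-trial draws are independent
  and individually reproducible.
* Monte-Carlo assertions use 3-standard-error bands; uniformity checks use
  chi-square at α = 0.001.
* Degenerate inputs fail loudly: empty words, zero-capacity queries below
  the grid, zero pooled variance in Hedges' g, a zero error baseline in the
  reduction percentage, non-monotone oracles, over-long clusters.

## Known limitations

* No mechanistic retina/cortex model, no saccade dynamics, no neglect model
  beyond field-defect masking, no learning across sessions.
* Bigram attestation is a weak pronounceability proxy; it admits items a
  phonotactician would reject.
* The causal engine is purely Boolean and exhaustive: no noisy oracles, no
  probabilistic or graph-based causal inference, universes capped at 20
  conditions.
* Whether a second time escalation should resume after a VRT sweep concludes
  "not VRT-limited" is clinically unspecified; the protocol does not resume
  (it retries the same condition once, then stops).
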
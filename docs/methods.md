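# Methods

## The audit representation

Each response is reduced to six binary signals in fixed order
C, E, N, H, O, V. The first five are judged; the sixth is derived:
V = 1 exactly when E = 1 and C = 0. V therefore never carries
independent information — it exists so that the *supported-error*
joint state is directly visible and countable, instead of requiring a
cross-tabulation of two dashboard panels. The other two risky (C, E)
states — unsupported truth (1, 0) and unsupported error (0, 0) — are
visible through the tag but deliberately not counted as veneer, to keep
the marker narrow.

Tags are positional case-coded strings (`cEnhoV`), never reordered and
never aliased. Internally bits are explicit 0/1 values; case coding
exists only at the text boundary. Parsing is strict by default: a V
letter contradicting C and E is an error, because trusting a hand-typed
derived bit silently is worse than rejecting it. A lenient mode
recomputes V and returns a warning, for ingesting legacy human labels
whose V column may predate the derivation rule. This strict/lenient
duality is a package convention, not part of the audit definition.

## Rule scorers and their deliberate limits

The scorers are purely lexical and deterministic. That is a feature for
an audit surface (every bit has a human-readable provenance trail) and
a known limit for real data (no paraphrase tolerance, no entailment).

- **C** — all required qualifier phrases must appear in the normalized
  answer (case-fold, punctuation strip, whitespace collapse; no
  stemming), and no number the answer asserts *for a required slot*
  (same unit and range-shape as a required fact) may contradict the
  gold value. Omitting a number is not a C failure; omitting a
  qualifier is. C flags presence of error, never severity: a shifted
  screening interval and a dangerous dose error both score C=0.
- **E** — operationalized as: cited document equals the gold document
  *and* the item's topic anchor phrase (first required qualifier)
  appears in both answer and evidence sentence. E is deliberately not
  conditioned on the answer's numbers: if it were, the veneer state
  E=1 ∧ C=0 could never arise from a numeric error, and the central
  audit target would be unreachable. Records whose E=1 rests on this
  topic-anchor check alone are flagged in provenance so a human
  reviewer can override; "materially supports" is ultimately a human
  judgement and any lexical proxy is a convention.
- **N** — every required number must appear with equal value and
  compatible unit (unit normalization is case/plural only — mg≡mg,
  years≡year — with no unit conversion; equality is exact for integers
  and 1e-9 relative for decimals, since the synthetic corpus controls
  numbers exactly), and every number the answer states must occur in
  the evidence sentence — invented extras break concordance even when
  they are harmless.
- **H** — word-boundary, case-insensitive match of a configurable
  lexicon, default {may, might, possibly, uncertain, likely}. The
  lexicon is open by design; extensions come from configuration, never
  code. Allowlisted caveat spans (caveats the source itself requires)
  are masked before matching and are the *only* hedge exemption;
  whether a caveat "alters clinical meaning" is not machine-decidable
  and the package does not guess.
- **O** — any of: a run of ≥2 consecutive fully-capitalized words of
  length ≥4, an exclamation mark, ≥3 decorative glyphs
  (★ ✦ ● ▶ ■ ◆ ✧ ☆, configurable), or a configured promotional phrase.
  O never feeds into C, E or N: formatting alone is not clinical error,
  it is tracked to separate style from trust.

## Grids, adjacency, clusters

Records are laid out row-major at a configurable width (default 12 for
n=120, giving 10×12; 4 for the 12-case fixture). Width is a knob
because no canonical grid dimension exists; near-square grids maximize
informative vertical adjacency. Ordering (`STRIPES_BY_DOC`: doc then
item; `TIME_SERIES`: source date, doc, item; both stable sorts with
stated tie-breaks) permutes cells only — every rate is invariant under
reordering, which is asserted by tests.

Adjacency match is the percentage of horizontally or vertically
adjacent occupied cell pairs sharing an identical full six-slot tag; no
diagonals, no wraparound, and partial last rows contribute only pairs
where both cells exist. It is a descriptive continuity measure computed
per condition grid. Block reports count an arbitrary tag predicate
(typically V=1) per source passage and report each block's rate and its
share of all hits; shares are undefined (NaN) when there are no hits.

## Statistics

All proportions carry 95% Wilson score intervals, with no continuity
correction and no multiplicity adjustment — they are descriptive. The
package's display convention is the conventional two-decimal normal
quantile z = 1.96 at the 95% level (the exact quantile is used for any
other level) with half-up rounding to one decimal; this pairing
matches how Wilson bounds are conventionally quoted, including the
boundary cases 0/12 → 0.0–24.3 and 12/12 → 75.7–100.0, where the exact
quantile 1.959964 lands on the other side of the rounding boundary
(24.2/75.8). Full precision is retained internally; rounding is
display-only (the benchmark tables are quoted at one decimal). An
empirical-coverage test (n=120, p ∈ {0.1, 0.5, 0.9},
2000 replicates) checks the interval covers within [93%, 97%].

Masked Delta pairs two regimes strictly by item id (no positional
fallback — the comparison is meaningful only on identical questions),
XORs each tag pair and retains a slot mask: content/trust = {C,E,N,V},
style = {H,O}. The two presets partition the six slots, so an item
differs under the full tag iff it differs under at least one preset —
a property test. Cohen's kappa is included for future multi-rater
C/E/N reliability data; with a constant rater the chance-agreement
denominator vanishes and the function returns NaN as an explicit
undefined marker rather than a number.

## The synthetic benchmark

The generator emulates a guideline-style monitoring corpus: 30
fictional passages over five recurring topics (dosing, screening
interval, treatment threshold, guidance revision date, schedule count),
each with one self-contained evidence sentence containing one or two
numeric facts, and 120 grounded QA items whose gold answers restate
their evidence. One passage (D4) carries a 9-item block, 24 passages
carry 4 items and 5 carry 3 (9 + 96 + 15 = 120) — the plan that
reconciles a 9-item worked-example cluster with the 30/120 shape; it is
configuration, not hard-coded. Source dates are evenly spaced fictional
dates (2019 onward, 31-day steps) to give `TIME_SERIES` something
meaningful to sort. All names are invented by syllable combination; no
real guideline text, drug or condition appears by construction.

Four scripted regimes stress the audit surface; no live model is
queried, so model identity, temperature and decoding settings do not
apply. Responses are built by **inverting the scorers**: C=0 is
realized by substituting a wrong value for a required number (which
also forces N=0 — this is why the allocator never assigns N=1 to a
C=0 item); N=0 with C=1 by appending an unsupported extra percentage;
E=0 by omitting or mis-pointing the citation; H=1 and O=1 by injecting
a hedge sentence or ornament markers. The omitted-number N=0 path
exists in the scorer and is unit-tested directly, but the generator
uses the extra-number realization for simplicity. Every generated
record is re-scored at generation time and the run aborts on any
round-trip mismatch, so scored marginals equal the intended profile
counts *exactly*, for every seed — the benchmark models one fixed
dataset, not a sampling distribution, hence count-exact allocation
rather than Bernoulli draws.

Per-regime (C,E) joint cells are uniquely determined by the target C,
E and V marginals (V identifies the (0,1) cell). H and O marginals
have no canonical values; the defaults are: O on every POSTER response
and (nearly) nowhere else, H concentrated in POETIC (60/120), a small
H count in RUSH (13/120), none in VERIFY — a hedged-styled regime and
a presentation-saturated regime, with the RUSH/POSTER values also
consistent with the packaged delta layout below. All are configurable.

Which *items* err in which regime — the cross-regime overlap that
drives paired Masked Delta percentages — is not derivable from
marginals. It ships as a fixture-pinned layout
(`ceag/data/regime_flag_plan.json`, and labelled as such in the file)
satisfying simultaneously: every regime's joint and marginal counts;
six of RUSH's 31 veneer items inside the 9-item D4 block (block share
6/31 ≈ 19.4%); VERIFY-vs-POSTER differing on 100% of items under the
full tag but 26/120 = 21.7% under the content/trust mask; and
RUSH-vs-VERIFY differing 37/120 = 30.8% on content/trust versus
13/120 = 10.8% on style. `allocate_flags` provides seeded count-exact
allocation (with optional block pinning) for custom profiles when the
pinned layout is not wanted.

The 12-case public-check-style fixture uses the same machinery with 12
single-item fictional passages phrased as claim-verification questions;
its profiles put RUSH at 4/12 correct with 8/12 veneer and VERIFY and
POSTER at 12/12 correct with zero veneer. At n=12 one case moves any
rate by 8.3 points; the fixture exists to exercise the tag logic on
claim-style inputs, not as a benchmark.

### What passing tests do and do not show

The generator controls correctness, citation and numerics exactly, so
round-trip tests validate the *audit machinery* — scorer logic, count
bookkeeping, interval arithmetic, grid and delta computation — under
known ground truth. They do not show that the lexical scorers capture
real LLM output, where paraphrase, partial grounding, ambiguous
citations and fluent hedging dominate; single-rater rule-based labels
are themselves unvalidated until independent raters report agreement
(hence the kappa utility). Problem sizes throughout (120 items × 4
regimes, 2000-replicate coverage simulation) keep the full suite to a
few seconds while matching the scale the statistics are quoted at.

## Degenerate inputs and tie-breaks

Single-cell grids have no adjacent pair: adjacency is an error, not 0
or 100. Zero-hit block reports mark shares NaN. Equal `TIME_SERIES`
dates fall back to doc id then item id; doc ids sort numerically
(D4 before D10). Duplicate or unpaired item ids are errors in Masked
Delta — there is no silent positional pairing. Empty masks, empty
record sets, k > n and n = 0 are rejected with named errors, and every
file-format error reports its file and line.
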
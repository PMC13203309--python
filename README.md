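# ceag — Clinical Evidence Audit Grid

`ceag` is an analyst-facing toolkit for auditing guideline-grounded LLM
responses in clinical and public-health review workflows. Its core
construct is the **CENHOV tag**: six binary trust signals per response,
kept jointly rather than averaged away —

| slot | signal | rule (sketch) |
|------|--------|----------------|
| C | clinical correctness | matches the gold answer; omitted required qualifiers or contradicted required numbers score 0 |
| E | evidential support | cited document is the gold source and the topic anchor appears in answer and evidence |
| N | numeric concordance | every required dose/threshold/age-range/date/interval/count present and matching; no unsupported extras |
| H | hedging | uncertainty markers (*may, might, possibly, uncertain, likely*) outside allowlisted caveats |
| O | ornamentation | poster-like styling: caps runs, `!`, glyph clusters, promo phrases |
| V | citation veneer | **derived**: V = 1 ⟺ E = 1 ∧ C = 0 |

The text form is case-coded (uppercase = present): `CENhov` is a
correct, supported, numerically grounded answer; `cEnhoV` is the
**supported-error citation veneer** state — an answer that *looks*
well-sourced but is substantively wrong. That joint state is the
audit target: marginal accuracy and citation dashboards cannot see it.

On top of the tag the package provides:

- **rule scoring** of responses against gold items (deterministic,
  with per-slot provenance for every 0 on C/E/N);
- **audit grids** (`STRIPES_BY_DOC`, `TIME_SERIES` orderings), an
  adjacency-match continuity statistic, and per-source block reports
  that localize veneer clusters;
- **statistics**: 95% Wilson score intervals for every rate, paired
  **Masked Delta** regime comparison (content/trust mask = C,E,N,V;
  style mask = H,O), and Cohen's kappa for future multi-rater data;
- a **synthetic stress-test benchmark**: a fictional 30-passage /
  120-item guideline-style corpus and four scripted response regimes
  (RUSH, VERIFY, POETIC, POSTER) whose scored marginals are count-exact
  by construction, plus a 12-case public-check-style fixture;
- JSONL/CSV/plain-text/HTML exports (the HTML grid carries a
  text-equivalent description of every cell's slot states).

## Worked example

```bash
ceag synth --out demo --seed 1
ceag score --gold demo/gold_items.jsonl \
           --responses demo/responses_RUSH.jsonl \
           --out demo/scored_RUSH.jsonl
ceag summary --scored demo/scored_RUSH.jsonl
```

prints

```
condition,n,correct_pct,correct_ci,support_pct,support_ci,numeric_pct,numeric_ci,veneer_pct,veneer_ci
RUSH,120,73.3,64.8-80.4,93.3,87.4-96.6,20.8,14.5-28.9,25.8,18.8-34.3
```

i.e. under the fast-answer RUSH regime evidential support stays high
(93.3%, Wilson 95% CI 87.4–96.6) while correctness drops to 73.3%
(64.8–80.4), so 25.8% (18.8–34.3) of responses are supported-error
veneer — the dissociation the tag is designed to expose. The grid view
localizes it:

```bash
ceag grid --scored demo/scored_RUSH.jsonl --gold demo/gold_items.jsonl \
          --out demo/grid_rush
# adjacency_match_pct=71.6
head -2 demo/grid_rush.txt
# cEnhoV cEnhoV cEnhoV cEnhoV CEnhov CEnhov CEnhov CEnhov CEnhov CEnhov CEnhov CEnhov
# cEnhoV cEnhoV cEnhoV cEnhoV cEnhoV cEnhoV CEnhov CEnhov CEnhov cEnHoV cEnHoV cEnHoV
```

`demo/grid_rush_blocks.csv` shows the D4 source block holding 6 veneer
cases among its 9 items (19.4% of all 31 RUSH veneer cases). Masked
Delta separates substance from styling:

```bash
ceag delta --a demo/scored_RUSH.jsonl --b demo/scored_VERIFY.jsonl --mask content_trust
# mask=content_trust n=120 differing=37 percent_nonzero=30.8
```

RUSH vs VERIFY differ on content/trust slots for 30.8% of items but on
style slots for only 10.8%; VERIFY vs POSTER differ everywhere under
the raw tag (POSTER ornaments every response) yet on only 21.7% of
items once style is masked out.

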
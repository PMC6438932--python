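# pufval

Health-state valuation through **personal utility functions (PUFs)**: a
toolkit for building each survey respondent's own utility function over a
simplified 3-level EQ-5D descriptive system, generating the adaptive
interview tasks the protocol requires, anchoring utilities at dead = 0, and
aggregating individual functions into a **social utility function** (a value
set usable for QALY calculation). It is written for health economists and
outcomes researchers who run or study stated-preference valuation surveys,
and ships a simulator of synthetic respondents so the entire pipeline can
be exercised and tested without fieldwork.

## The model

States are 5-digit codes over the dimensions mobility (MO), self-care (SC),
usual activities (UA), pain/discomfort (PD) and anxiety/depression (AD),
each at level 1 (no problems), 2 (moderate) or 3 (extreme) — 3⁵ = 243
states, from full health `11111` to `33333`.

A respondent's PUF is additive in per-dimension decrements. Swing ratings
r_d ∈ [0, 100] (section C of the interview) normalise to weights
w_d = r_d / Σ_e r_e, and a 100-point allocation p_d between the
extreme→moderate and moderate→none improvements (section D) scales the
intermediate level:

    u(s) = 1 − Σ_d δ_{d, level_d(s)},   δ_{d,1} = 0,
    δ_{d,3} = w_d,   δ_{d,2} = w_d · p_d / 100   (default convention)

so u(11111) = 1 and u(33333) = 0 by construction. Ranking all 243 states by
u drives three adaptive task families: non-dominating validation pairs
(section E), a five-task bisection search that brackets the respondent's
location of dead within 15–16 adjacent ranks (section F), and interaction
probes (section G). The bracket midpoint u_dead rescales the PUF to the
dead = 0 / full-health = 1 scale:

    v(s) = (u(s) − u_dead) / (1 − u_dead)

Anchored decrements are summarised across respondents (min, quartiles,
median, mean, max, SD, SE) per dimension-level cell, and the value set
follows as 1 minus the sum of the chosen central (mean or median)
decrements — states worse than dead take negative values.

## Worked example

Simulate a 60-respondent cohort (round-number bias on a grid of 5,
logistic choice noise 0.05, about a quarter of respondents holding no state
worse than dead) and aggregate it into a value set:

```sh
$ puf-valuation simulate --out cohort.json --n 60 --seed 7
wrote 60 simulated respondents to cohort.json
$ puf-valuation valueset --in cohort.json --out valueset.csv --summary-out summary.csv
value set over 60 respondents (mean): value(33333) = -0.279
$ head -4 valueset.csv
code,value
11111,1.000000
11112,0.879181
11113,0.754887
```

`value(33333) = -0.279` is the mean-aggregated value of the worst state:
negative because most simulated respondents locate dead above it, i.e.
consider it worse than being dead. `11112` (moderate anxiety/depression
only) is the mildest impaired state and values highest.

The same arithmetic applied to a published pilot study's mean decrements
(embedded as the `table8`/`table9` fixtures) reproduces that study's
derived values:

```python
>>> from pufval import load_paper_fixture, build_value_set
>>> vs = build_value_set(load_paper_fixture("table9"), "mean")
>>> round(vs.value("33333"), 3)
-0.667
>>> round(vs.value("11112"), 2)
0.85
```

Other subcommands: `validate` (protocol findings per respondent), `puf`
(per-respondent weights/decrements), `tasks` (the generated adaptive tasks
as JSON), `anchor` (243 anchored values per respondent). See
`puf-valuation <cmd> --help`; analysis conventions (`--level2-mapping`,
`--central`, `--outlier-threshold`, `--include-unrescaled`) are recorded in
every study file so results are reproducible from their inputs.

## Layout

- `pufval.state_space` — states, codes, dominance, severity score
- `pufval.responses` — section A–G records, validation, tie-aware ranks
- `pufval.puf` — weights, decrements, state utilities, 243-state ranking
- `pufval.tasks` — validation pairs, bisection dead search, interaction tasks
- `pufval.anchoring` — dead-utility midpoint, rescaling, outlier rule
- `pufval.aggregation` — decrement summaries and value-set construction
- `pufval.simulator` — latent respondents, response synthesis, recovery report
- `pufval.io` / `pufval.fixtures` / `pufval.cli` — study files, embedded
  published tables, command line

See `docs/methods.md` for modelling assumptions, conventions and
limitations.
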
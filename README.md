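# barrierprio

Structured decision support for prioritising barriers to implementing
evidence-based clinical practice.

Implementation teams routinely face a long list of barriers — staffing,
protocols, equipment, beliefs — and limited resources to address them.
`barrierprio` turns per-expert rank ballots into a defensible short list:

1. **Elicitation.** Each member of a multidisciplinary expert panel
   produces, for every targeted clinical behaviour they are eligible to
   judge, two complete rankings of that behaviour's barriers: by
   *influence* (how strongly the barrier prevents the behaviour) and by
   *difficulty* (how hard it would be to overcome). Ballots are total
   orders — no ties, no gaps — on a scale equal to the number of barriers.
2. **Aggregation.** For each behaviour × attribute, ballots are combined
   through the pairwise-majority graph: `prefer(a, b)` counts ballots
   ranking barrier *a* above barrier *b*. The default rule is the Schulze
   (beatpath) method — Condorcet-consistent, monotone, tie-permitting —
   with Copeland and exact Kemeny–Young consensus available as
   alternatives. The result is a group rank per barrier, oriented so
   higher = more influential / less difficult.
3. **Classification.** Each barrier becomes a point
   (influence rank, difficulty rank). Using weak Pareto dominance
   (*a* dominates *b* iff *a* is at least as good on both axes and
   strictly better on one), barriers are labelled:
   - **most desirable** to target — weakly dominates every other barrier
     (top-right corner of the scatter plot);
   - **desirable** — not dominated by any barrier (the Pareto frontier);
   - **least desirable** — dominated by at least one barrier.
4. **Visualisation.** One influence-vs-difficulty quadrant scatter per
   behaviour, with deterministic jitter for exactly tied points.

Because real expert ballots are rarely published, the package also ships a
seeded panel simulator (`panelsim`): ballots are drawn from a Mallows
model, `P(π) ∝ exp(−θ·d_τ(π, reference))`, via exact repeated-insertion
sampling, with per-group eligibility masks mirroring a real
multidisciplinary panel.

## Bundled reference survey

The package bundles the artefacts of a 17-member Australian acute
stroke-care panel (emergency/stroke doctors and nurses, speech
pathologists, bed managers) that ranked 53 barriers to nine evidence-based
care elements in emergency departments — triage, thrombolysis assessment
and delivery, temperature/glucose/swallowing management, and transfer to a
stroke unit: the behaviour/barrier catalogue, the panel demographics, the
per-barrier median (IQR) individual ranks, and the published group
rankings with their desirability labels.

## Worked example

```python
from barrierprio import datasets, classify_dataset

catalogue = datasets.study_catalogue()
rankings = datasets.study_group_ranks()     # published group ranks
for res in classify_dataset(rankings):
    for m in res.barriers_with("most_desirable"):
        beh = catalogue.behaviour(res.behaviour_id)
        desc = {b.barrier_id: b.description for b in beh.barriers}
        print(f"{beh.name}: {m} ({desc[m]})")
```

prints

```
Temperature taken on arrival: 4.1 (Lack of fever protocols)
Finger prick BGL on admission: 6.2 (Not enough BGL machines)
```

i.e. exactly two of the nine behaviours have a barrier that is
simultaneously the most influential and the least difficult to overcome —
both resource/protocol barriers, which is where an implementation
intervention gets the most leverage per unit effort. Across all 53
barriers the classification is 2 most desirable, 26 desirable and 25
least desirable.

The same run from the shell, with plots:

```sh
barrierprio run \
    --catalogue src/barrierprio/data/catalogue.csv \
    --from-group-ranks src/barrierprio/data/group_ranks.csv \
    --outdir out/
```

writes `desirability.csv` (53 rows), one quadrant scatter per behaviour
under `out/plots/`, and a `run_log.json`. A full pipeline from raw
ballots (`--ballots`, `--respondents`) additionally writes median/IQR
summaries and freshly aggregated group ranks; `barrierprio simulate`
generates seeded synthetic ballots to feed it.

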
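# opinionet

Attitude-network analysis for longitudinal Likert surveys: detect the
emergence of **opinion-based groups** — factions defined by what their members
jointly believe rather than by demographics — and quantify their consequences.

The package is aimed at computational social scientists and biostatisticians
who track public-health attitudes over repeated survey waves (the motivating
setting is trust in science, government and health advice during an epidemic
response) and want to know whether the opinion space is polarizing into
identifiable camps, and whether those camps diverge in behaviour.

## The method

For each survey wave, Likert responses are trichotomized into stances
relative to each item's scale midpoint (+1 agree / 0 neutral / −1 disagree)
and assembled into a **bipartite person–attitude graph**: an edge links a
person to an item they hold a non-neutral stance on, signed by the stance.
Two projections follow:

* **Participant projection.** Persons *i, j* are linked with weight
  *w<sub>ij</sub>* = (number of items on which they hold the same stance
  sign) / (number of items both answered non-neutrally) — the proportion of
  attitudes shared. Edges are kept when the pair compared at least
  `min_overlap` items and *w<sub>ij</sub>* ≥ `threshold`.
* **Attitude projection.** Items *a, b* are linked by the net count
  *C − D* of people holding them concordantly (*C*) versus discordantly
  (*D*); positive edges mean alignment, negative edges mean systematic
  disagreement.

Factions are read off the thresholded participant projection as connected
components, cross-validated with k-means on the raw responses
(contingency χ², adjusted Rand index), and given truster/sceptic labels from
their mean stance on anchor trust items. Polarization across waves is
summarized by the count of **bridging edges** between factions. Group
comparisons use one-way ANOVA with partial η² = F·df₁/(F·df₁ + df₂) and
noncentral-F confidence intervals, Wilks Λ MANOVA (η² = 1 − Λ^(1/s)),
binary logistic regression with Wald odds-ratio intervals, χ² association
tests, Pearson correlations, and Cronbach α scale reliability.

Because real panels of this kind are rarely shareable, a **synthetic cohort
generator** plants a two-faction structure — shared consensus items plus
contested items whose between-faction divergence grows over waves, with
attrition and attention-check failures — so that every stage of the pipeline
can be exercised and validated against known ground truth.

## Worked example

Simulate a high-consensus three-wave cohort of 300 participants (60/40
faction split, contested-item divergence ramping 0.2 → 0.6 → 1.0), project
waves 1 and 3, detect factions at wave 3, and compare the factions'
compliance and clarity scores:

```bash
cat > cohort.yaml <<EOF
n_participants: 300
consensus_strength: 0.99
divergence_schedule: [0.2, 0.6, 1.0]
seed: 7
EOF
opinionet simulate --config cohort.yaml --out-dir waves
opinionet network --wave waves/T1.csv --items waves/items.yaml \
    --min-overlap 5 --threshold 0.95 --out T1.graphml
opinionet network --wave waves/T3.csv --items waves/items.yaml \
    --min-overlap 5 --threshold 0.95 --out T3.graphml
opinionet detect --graph T3.graphml --wave waves/T3.csv \
    --items waves/items.yaml --k 2 --seed 7 --out factions.csv
opinionet stats --factions factions.csv --waves waves \
    --items waves/items.yaml --out report.json
```

which prints

```
wrote 3 waves to waves (n=300, factions (180, 120))
participant projection: 300 nodes, 34255 edges -> T1.graphml
participant projection: 275 nodes, 17381 edges -> T3.graphml
components vs k-means: ARI=1.000, X2(1)=257.00
wrote factions.csv
wrote report.json
```

At wave 1 the projection is one dominant component (262 of 300 nodes): the
cohort still agrees broadly. By wave 3 it has split into two components of
160 and 97 participants — the emergent truster and sceptic factions — and
k-means on the raw responses recovers exactly the same partition
(ARI = 1.0, χ²(1) = 257). `report.json` then carries the per-wave Cronbach α
of each scale (e.g. compliance α = .61, clarity α = .74 at T3) and the
faction comparison of wave-3 scale scores, e.g. for compliance: truster mean
5.32 vs sceptic mean 5.12, F(1, 255) = 1.92, p = .17, η² = .007, 90% CI
[0, .035]. With the generator's small planted behavioural effect
(Cohen's d = 0.3) a single cohort of this size is only weakly powered, so a
non-significant wave-level comparison like this one is an expected outcome,
not a failure of the pipeline.

`opinionet panel --waves waves --items waves/items.yaml --threshold 0.95
--out panel.png` renders the wave-by-wave projections side by side with
faction-coloured nodes.

All of this is equally available as a library API (`opinionet.generate_cohort`,
`binarize`, `project_participants`, `connected_components`, `oneway_anova`,
...); see `docs/methods.md` for the underlying models and conventions.

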
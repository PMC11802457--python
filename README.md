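# nichetrack

Trajectory, aging-signature and spatial-neighborhood analyses for
single-cell and spatial transcriptomics of the hippocampal neurogenic
niche.

Adult neurogenesis in the dentate gyrus (DG) declines with age: quiescent
neural stem cells (qNSCs) sink into deeper quiescence, their fate-committed
progeny (aNSPCs, neuroblasts/immature neurons) mature more slowly, and
inflammatory cells invade the tissue regionally. Quantifying these changes
from multimodal data takes a chain of bespoke procedures that are usually
re-written ad hoc per study. `nichetrack` packages that chain as tested,
seeded, reusable components for computational biologists working on aging
or neurogenesis:

- **Module scoring** — per-cell/per-spot mean expression of a gene set
  minus expression-bin-matched random controls
  (`score(cell) = mean(lognorm[set]) − mean(lognorm[controls])`, 24
  equal-frequency bins, 100 controls per gene).
- **Real-time trends** — fuzzy c-means (c = 8) over per-age standardized
  mean profiles; clusters with strictly monotone centers over
  young < middle < old define up-/down-regulation trend sets.
- **Pseudotime** — a Hastie–Stuetzle principal curve over the first 7 PCs,
  with peak-ordered gene modules along the axis.
- **Signatures** — NAS (real-time trends ∩ qNSC pseudotime modules) and
  CAS (whole-DG spatial trend genes shared by ≥ 2 niche populations).
- **Predictors** — a random-forest differentiation score (markers → curve
  pseudotime, top-100 feature retrain) and an elastic-net multinomial age
  classifier with a balanced 70/30 split and 10-fold CV.
- **Spatial inflammation** — inflammatory spots (IFN-γ module score > 0),
  hexagonal neighbor rings IS → NNS → ENS1 → ENS2, and an inside-out
  pseudo-spatial axis with gene modules.
- **Microniches** — 55 µm circles tiled along the SGZ line (50% overlap),
  with a cell-label permutation test of co-occurrence
  (`|nBoth − nA·nB/n|` null) and a proximity fraction.
- **Synthetic data** — negative-binomial generators for a 3-stage lineage
  across three ages, hotspot-bearing Visium-style lattices and labeled
  tissue point patterns, all with planted ground truth.

## Worked example

Simulate a lineage atlas (3 types × 3 ages × 100 cells, planted aging
programs), score the planted up-regulated set, and train the
differentiation-score model:

```python
from nichetrack import synthetic, scoring, predictors
from nichetrack.datatypes import GeneSet
from nichetrack.config import PipelineConfig

m, truth = synthetic.simulate_lineage_atlas(seed=1)
scoring.log_normalize(m)

up = truth["genes"].query("block == 'aging_up'")["gene_id"]
res = scoring.module_score(m, GeneSet("AGING_UP", tuple(up)), seed=1)
print(res.scores.groupby(m.cell_meta["age"]).mean().round(3))

model = predictors.train_differentiation_model(m, cfg=PipelineConfig(seed=1))
pred = predictors.predict_differentiation(model, m)
print(pred.groupby(m.cell_meta["cell_type"]).mean().round(3))
qnsc = pred[(m.cell_meta["cell_type"] == "qNSC").to_numpy()]
print(qnsc.groupby(m.cell_meta["age"]).mean().round(3))
```

Output:

```
age
middle    0.049
old       0.226
young    -0.278
dtype: float64
cell_type
NB/IMN    0.825
aNSPC     0.484
qNSC      0.102
Name: diff_score, dtype: float64
age
middle    0.104
old       0.055
young     0.146
Name: diff_score, dtype: float64
```

The module score of the planted aging program rises monotonically with age
(−0.278 → 0.049 → 0.226): aged cells express the program above their
expression-matched controls. The differentiation score orders the lineage
qNSC < aNSPC < NB/IMN (0.102 < 0.484 < 0.825), and querying only qNSCs
shows the score declining with age (0.146 → 0.104 → 0.055) — older qNSCs
sit deeper in quiescence, the planted drift the model is supposed to
detect.

A `nichetrack` CLI wraps the same stages
(`simulate | score | signatures | diffscore | agepredict | spatial |
microniche`, each with `--config/--seed/--out`).

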
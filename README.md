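# catring

Analysis toolkit for delayed match-to-category fMRI experiments in which
eight stimuli on a ring (7 dva eccentricity, 45° apart) are grouped into two
learned categories by an invisible diameter boundary.  It is aimed at
cognitive-neuroimaging researchers who want a fully testable, synthetic-data
re-implementation of this analysis chain:

* **Position decoding** — leave-one-run-out multiclass linear-SVM decoding of
  stimulus position with recursive feature elimination (drop the 20% of
  voxels with the lowest mean |weight| per iteration, 10-iteration patience,
  nested inner validation), a training-label permutation null, and exact
  binomial group-level inference.
* **Pattern similarity** — Spearman correlations between per-position
  multivoxel patterns; the category index CI = WCS − BCS (within- minus
  between-category similarity) per stimulus separation (5.4 / 9.9 / 12.9 dva)
  and timepoint; a boundary-optimality scan over the four candidate
  boundaries with a chance-¼ binomial control; near/far 14-dva, attention,
  and retinotopy-interaction controls.
* **Effective connectivity** — condition-wise bivariate Granger causality in
  Geweke's log-variance-ratio form, GC(x→y) = ln(σ²ᵣ/σ²_f), on trial
  segments with transients removed, and the bounded condition contrast
  (GCc − GCf)/(GCc + GCf).
* **Brain–behavior link** — runs ranked by reaction time into 11 sliding
  groups of 5 (from 15 runs); Spearman correlation between group-mean
  standardized GC and group-mean z-scored RT.
* **Synthetic experiments** — a seeded generator producing the full design
  (15 runs × 32 × 14-s trials at TR = 2 s, 240 task trials balanced over
  positions), von Mises position-tuned voxels (fine V1-like and coarse
  IPS-like codes), an injectable time-varying category component, an RT model
  that slows near the boundary, and coupled ROI series from a
  regime-switching VAR(1) with condition-dependent top-down coupling.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
from catring.synthetic import SyntheticConfig, generate_experiment
from catring.similarity import (position_patterns, similarity_table,
                                category_index, boundary_scan)
from catring.connectivity import condition_gc_table

cfg = SyntheticConfig(n_subjects=1, seed=1)          # full 15-run design
sub = generate_experiment(cfg).subjects[0]

# category index in the V1-like ROI at 10 s, adjacent (5.4 dva) pairs
st = similarity_table(position_patterns(sub.datasets["V1"], 10.0))
res = category_index(st, cfg.ring, cfg.boundary, steps=1)
print(f"WCS = {res.wcs:.3f}, BCS = {res.bcs:.3f}, CI = {res.ci:.3f}")

cis, best = boundary_scan(st, cfg.ring, steps=1)
print({k: round(v, 3) for k, v in cis.items()}, best.axis_angle)

# condition Granger causality, top-down direction
df = condition_gc_table(sub.series)
td = df[df.direction == "IPS12->V1"]
print(f"GCc = {td[td.condition == 'categorization'].gc.mean():.4f}, "
      f"GCf = {td[td.condition == 'fixation'].gc.mean():.4f}")
```

prints

```
WCS = 0.338, BCS = 0.098, CI = 0.240
{0.0: -0.087, 45.0: 0.24, 90.0: 0.087, 135.0: -0.24} 45.0
GCc = 0.1651, GCf = 0.0175
```

Within-category pairs are more similar than between-category pairs
(CI > 0), the scan over the four candidate boundaries picks the trained 45°
boundary (its CI is the maximum; the perpendicular 135° axis is its mirror
image with the sign flipped), and the top-down Granger influence is an order
of magnitude stronger during categorization than during fixation, as
injected by the generator.

The same chain runs end to end from the shell:

```bash
catring all --seed 1 --out out/          # simulate -> decode -> rsa -> gc -> behavior
catring all --seed 1 --out out2/ --retrain   # add the orthogonal-boundary experiment
catring geometry                          # ring/boundary geometry as JSON
```

`out/report.txt` summarizes decoding accuracies, boundary-scan counts with
their binomial p-values, and the GC–RT correlation; all per-stage tables are
written as CSV next to it.

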
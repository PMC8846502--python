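# detfuse

Image-augmented clinical deterioration indices for hospitalized patients.

Hospitals run EHR-based deterioration indices (DIs) — score streams such as a
proprietary 15-minute-cadence index or a locally developed 4-hourly one — that
estimate a patient's risk of death or escalation to ICU-level therapy
(mechanical ventilation, heated high-flow nasal cannula, IV vasopressors).
Chest radiographs carry complementary information, but they arrive at
irregular times and as images, not scores. `detfuse` implements the late-fusion
approach to combining the two: every radiograph is converted (upstream, by any
image model) into a risk score, and a small feed-forward network fuses, on a
4-hour prediction grid,

```
x_t = [ image_score(t), index_score(t), hours_since_xray(t), hours_since_admit(t) ]
p_t = sigmoid( W2 · relu(W1 · z(x_t) + b1) + b2 ),   z = training z-score
```

with one hidden layer of five ReLU units, trained with binary cross-entropy at
learning rate 0.001 and checkpointed at the lowest validation loss. The image
score is carried forward from the most recent radiograph; the index stream is
reduced to the grid by taking the maximum score in each completed 4-hour
window. Two models are trained: a **low-risk** model (label: ever deteriorates;
windows from the first radiograph through 48 h) and a **high-risk** model
(label: deteriorates within 5 days; windows censored at the event window and
the one before it).

Evaluation follows the deployment questions:

* **Low-risk triage** — per patient, the mean predicted risk over the first
  48 h; patients sorted by ascending risk; the flagging threshold swept.
  `NPV(k)` is the fraction of the `k` lowest-risk patients who never
  deteriorate; the headline count is the largest `k` maintaining NPV ≥ 0.95
  (or 0.90).
* **High-risk discrimination** — per patient, the maximum predicted risk
  before the event / within 5 days, scored by AUROC (Mann–Whitney, ties ½)
  and by specificity at sensitivity 0.8, with 95% CIs from 1000 bootstrap
  resamples of hospitalizations.

Because real DI streams are proprietary and single-center, the package ships a
cohort simulator in which a shared latent severity drives both modalities and
an image-specific latent carries outcome signal only the radiograph can see —
the regime in which augmentation can help — plus the standard cohort filters
(supplemental oxygen required; a radiograph within 48 h; no event or discharge
within 4 h of presentation; no event before the first radiograph).

## Worked example

```python
from detfuse import PipelineConfig, SimConfig, TrainConfig, run_pipeline

cfg = PipelineConfig(sim=SimConfig(), train=TrainConfig(seed=11),
                     n_train=1800, n_valid=600, n_test=600,
                     n_boot=200, seed=11)
report = run_pipeline(cfg)
print(report["headline"])
print(report["high_risk"]["image_augmented"]["auroc"],
      report["high_risk"]["di_baseline"]["auroc"])
```

prints (simulation; exact values are seed-deterministic)

```
{'extra_low_risk_at_0.95': 101, 'extra_low_risk_at_0.9': 43, 'auroc_gain': 0.13025536242247282}
0.8077756268436579 0.6775202644211851
```

i.e. on a held-out simulated test cohort the image-augmented index flagged 101
more patients as low-risk at NPV 0.95 than the DI-only baseline (43 more at
NPV 0.90, both on the patients each model could score), and improved high-risk
AUROC from 0.678 to 0.808. The full report
also carries the NPV curve, counts at 24/32/40/48 h of observation,
per-model evaluable-patient counts, and bootstrap CIs.

The same workflow is available from a shell:

```bash
detfuse simulate --out data/ --seed 1
detfuse align --data data/ --task low_risk --out instances.csv
detfuse fuse train --task low_risk --train tr.csv --valid va.csv --out model.json
detfuse fuse predict --model model.json --in te.csv --out preds.csv
detfuse evaluate lowrisk --preds preds.csv --events data/hospitalizations.csv --out report.json
detfuse run --config cfg.yaml --out report.json --seed 1
```

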
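# shortcutscope

Audit binary-labeled medical image datasets for **intrinsic acquisition
shortcuts** — global image contrast and sharpness differences that
correlate with the class label.

## The problem

Chest radiographs (and medical images generally) carry
*acquisition-dependent attributes* (ADAs): overall contrast and edge
sharpness set by the detector, vendor post-processing and imaging
protocol, not by the patient. When a curated dataset's positive and
negative cohorts come from different scanners, sites or time periods,
these attributes can silently correlate with the label. A deep model
trained on such data learns the attribute instead of the pathology —
a *shortcut* — and collapses on external data. Unlike extrinsic
shortcuts (lead markers, burned-in text), contrast and sharpness are
entangled with genuine image features and cannot be segmented away,
so they must be *detected* in the dataset before any model is trained
on it.

## The method

`shortcutscope` implements a train-certify-deploy framework for
**shortcut detectives**: classifiers taught to recognise exactly one
attribute and provably nothing else.

1. **Forge a training set.** Take a pool of finding-free images, split
   it 50/50 at random, perturb one half with the attribute (label 1),
   leave the other half untouched (label 0). Since the pool contains no
   disease signal, any classifier separating the halves can only have
   learned the attribute. The perturbations are
   - ADA-C (contrast): gamma intensity map `v ↦ 255·(v/255)^γ`,
   - ADA-S (sharpness): unsharp mask `I + a·(I − G_σ(I))`,

   with the strength drawn per image from a configurable range.
2. **Train an ensemble.** K members with different train/validation
   splits; the ensemble score is the mean member probability of class 1.
3. **Certify** on a dataset known to be shortcut-free:
   - *Exam 1*: scored as-is, the detective must sit at chance,
     AUC ≈ 0.5 (its features are not entangled with the real task);
   - *Exam 2a/2b*: with its own perturbation injected into the positive
     / negative class, it must reach AUC ≈ 1 / ≈ 0 (an AUC of 0 is
     perfect separation with inverted labels).
4. **Deploy.** A certified detective scores a curated dataset against
   its labels. The readout is the Mann–Whitney AUC with a 95% stratified
   percentile bootstrap CI (2000 replicates). A shortcut is flagged when
   `|AUC − 0.5| ≥ 0.10` *and* the CI excludes 0.5.

A seeded phantom generator (lung-field ellipses, mediastinum, rib
bands, blur, noise, per-image jitter) supplies finding-free pools and
labeled cohorts, so the entire framework runs self-contained with no
image downloads.

## Worked example

```python
from shortcutscope import run_desk_certification

run = run_desk_certification("S", seed=1, pool_size=400, cohort_size=150)
print(run.report.summary())
```

prints (exact numbers for this seed):

```
ADA(S) detective — CERTIFIED
  Exam 1 (shortcut-free):      0.54 [0.47, 0.60]
  Exam 2a (injected positive): 1.00 [0.99, 1.00]
  Exam 2b (injected negative): 0.00 [0.00, 0.01]
```

Exam 1 sits at chance — the detective cannot see the cohort's own
labels; exams 2a/2b show it detects its sharpness attribute almost
perfectly whichever class carries it, so it is certified. Deploying it
(`examples/05_audit_dataset.py`) on a clean cohort and on one whose
positive class was sharpened:

```
clean-cohort:  ADA(S) 0.44 [0.38, 0.51] -> no shortcut flagged
biased-cohort: ADA(S) 1.00 [1.00, 1.00] -> SHORTCUT FLAGGED
```

More narrative scripts live in `examples/` (phantom generation, the
perturbation operators, AUC/bootstrap, the full CLI chain). The same
workflow is scriptable from the shell:

```sh
shortcutscope synth --out pool --n 1200 --seed 1
shortcutscope build --pool pool --out trainset --kind S --seed 2
shortcutscope train --data trainset --out run --seed 3
shortcutscope certify --run run --exam cohort --out cert.json
shortcutscope detect --run run --data target --certification cert.json --out report.json
```

`detect` exits 0 when nothing is flagged, 2 when a shortcut is flagged,
1 on error.

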
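# tetcad

Image-based diagnosis of obstructive coronary artery disease (CAD) from
treadmill-exercise-test (TET) reports.

A TET records 12-lead ECGs in three physiological states — **pretest**,
**exercise**, **recovery** — and cardiologists read the *changes* between
states (exercise-induced ST depression, T-wave inversion) as ischemia
signs.  `tetcad` implements a complete pipeline that mimics that reading:

1. **Preprocessing** — render report pages (PDF or PNG) at 1080 x 640,
   identify each page's state by OCR keyword matching, crop the ECG
   region, convert to grayscale, binarize.
2. **Lead assembly** — split each state image into the 12 lead tiles and
   stack all states into an H x W x 36 tensor (channel `3*lead + state`).
3. **Network** — a 13-block CNN in which every block pairs an
   *intra-state* operator (depthwise Dk x Dk convolution: temporal
   structure within one lead/state) with an *inter-state* operator
   (grouped 1x1 convolution, one group per lead: correlations of a lead
   across states), followed by a dense 1x1 channel mix.  A pooled
   576 -> 128 -> 2 softmax head thresholds p(CAD) at 0.5.
4. **Evaluation** — accuracy, sensitivity, specificity, precision, NPV,
   ROC/AUC, and gender/age subgroup tables.
5. **Synthetic cohort generator** — the clinical dataset this design
   targets is private, so the package ships a generator that emulates
   its structure (three state pages per patient, grid background,
   printed state keyword, demographic mix) with the class signal carried
   by cross-state waveform changes.

The network is implemented directly in numpy (forward, backward, Adam),
with numba-compiled inner loops for the depthwise convolutions, and an
analytic multiply-accumulate (MAC) counter for complexity comparisons
against the standard 18-layer residual topology.

For one lead's channel `m`, the intra-state operator is

    IR[k,l,m] = sum_{i,j} K[i,j,m] * F[k+i-1, l+j-1, m]

(one Dk x Dk filter per channel, no cross-channel mixing), and the
inter-state operator for lead group `g` is

    IT[k,l,g,m_out] = sum_{m_in} K_IT[g][m_in, m_out] * IR[k,l,g,m_in]

(a per-pixel matrix product within the lead's state channels, g = 12
groups by default).  Training minimizes mean cross-entropy
`L = -(1/N) sum_i sum_c y_ic log(p_ic)`.

## Worked example

Generate a small synthetic cohort, preprocess one report, and inspect
the architecture:

```bash
tetcad generate --n 6 --prevalence 0.5 --seed 0 --out cohort/
tetcad preprocess --in cohort/p0000 --out clean/ --ocr stub
tetcad flops
```

`tetcad flops` prints the per-layer MAC table and ends with:

```
ResNet18 canonical (3ch/1000cls): 1,814,073,344 MACs
ResNet18 adapted (36ch/2cls):     3,111,715,840 MACs
reduction vs canonical: 86.32%
reduction vs adapted:   92.02%
```

i.e. the multi-state network (248,233,504 MACs at 224 x 224 x 36 input)
costs 86.3% less than the canonical residual reference at the same
resolution — the depthwise + grouped decomposition is where the savings
come from.

From Python, the end-to-end synthetic experiment:

```python
from tetcad.harness import run_recovery_experiment

res = run_recovery_experiment(n_patients=300, seed=0)
print(res["full"]["accuracy"], res["ablated"]["accuracy"])
# 0.9 0.7166666666666667
```

This generates 300 patients whose class signal lives purely in the
change between states, runs the full image pipeline (240 train / 60
test), trains the network for 15 epochs, and repeats the identical run
with the inter-state stage ablated to the identity.  At seed 0 the full
model reaches 0.90 test accuracy while the ablated one reaches 0.72:
the lead-aligned cross-state mixing, not generic capacity, is what
makes the signal learnable at this schedule (run-to-run variation at
these problem sizes is a few percentage points; see
`docs/methods.md`).

## Layout

- `src/tetcad/synth.py` — synthetic TET report generator
- `src/tetcad/preprocess.py` — page rendering, OCR-state identification,
  crop/grayscale/binarize (`pdfio.py` for the PDF dialect)
- `src/tetcad/leads.py` — lead splitting and tensor assembly
- `src/tetcad/nn/` — layers, network, MAC counter
- `src/tetcad/train.py`, `evaluate.py`, `augment.py` — training loop,
  metrics/ROC/subgroups, image augmentation
- `src/tetcad/harness.py` — end-to-end synthetic experiments
- `docs/methods.md` — model and design documentation
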
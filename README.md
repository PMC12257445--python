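# modemdwi

Model-free tissue classification from diffusion-weighted MRI (DWI)
signals, with the full simulation harness needed to study it: a
Monte-Carlo random-walk simulator of multi-b-value pulsed-gradient
spin-echo (PGSE) signals in packed-cylinder cellular substrates, Rician
noise doping, five analytical diffusion-model fitters, an MLP signal
classifier ("MODEM"), and a repeated-resampling ROC/accuracy comparison of
the model-free and model-based routes.

It is aimed at quantitative-MRI researchers who want to benchmark
signal-level machine-learning classification against diffusion-model
parameter fitting under controlled microstructure and noise.

## The problem and the models

A DWI experiment measures the decay S(b)/S0 of the MR signal with
diffusion weighting b = (γ Gd δ)² (Δ − δ/3). Classically one fits an
analytical model and classifies tissue from its parameters:

- mono-exponential: S/S0 = exp(−b·ADC)
- IVIM: S/S0 = f·exp(−b·Dperf) + (1−f)·exp(−b·Ddiff)
- DKI: S/S0 = exp(−b·D + b²D²K/6)
- FROC: S/S0 = exp(−D·μ^(2β−2)·(γGdδ)^(2β)·[Δ − (2β−1)/(2β+1)·δ])
- CTRW: S/S0 = E_α(−(b·Dm)^β), with E_α the Mittag-Leffler function

The model-free alternative feeds the normalized signals at the nonzero
b-values directly into a small multilayer perceptron (six hidden ReLU
layers of n units, n = number of nonzero b-values) and classifies from the
predicted class probability, skipping model assumptions and the
degeneracies of nonlinear fitting.

Ground truth comes from Monte-Carlo simulation: periodic substrates of
parallel permeable cylinders spanning four cellular-property axes (cell
size, density, size dispersion, membrane permeability; ten levels each,
forty substrates), walkers with fixed step length sqrt(4·D0·dt), specular
reflection or probabilistic membrane transit, and phase accumulation under
a rectangular PGSE waveform. See `docs/methods.md` for the full model
description and numerical choices.

## Worked example

```python
import numpy as np
import modemdwi as m

protocol = m.AcquisitionProtocol()          # 13 b-values, 0..3000 s/mm^2
specs = [s for s in m.enumerate_substrates() if s.group_id == "cell_size"]
walkers = m.WalkerConfig(n_walkers=2000, n_steps=2000, seed=7)
sets = m.generate_dataset(specs, protocol, walkers, n_sim_repeats=3)
table = m.add_rician_noise(sets, m.NoiseSpec(level=0.05, n_reps=30, seed=1))
report = m.run_study(
    table, methods=("modem", "mono", "dki"), protocol=protocol,
    n_iterations=5, master_seed=2,
    # the full-study MLP settings presume ~10k rows; on this small demo
    # table give the optimizer smaller batches and a longer stopping window
    mlp_overrides={"batch_size": 32, "learning_rate": 1e-2,
                   "early_stop_patience": 20})
print(report.summary.round(4))
print(report.p_values.round(4))
```

Output from this exact script:

```
           auc         accuracy
          mean     std     mean     std
method
dki     0.9923  0.0023   0.9544  0.0114
modem   0.9843  0.0087   0.9267  0.0186
mono    0.8604  0.0067   0.7967  0.0160
  method   p_auc  p_accuracy
0   mono  0.0079      0.0079
1    dki  0.0556      0.0397
```

Each row is one classification method; `auc`/`accuracy` are the mean and
standard deviation over the 5 random 80/20 splits of the test-set area
under the ROC curve and the fraction correct at a 0.5 probability
threshold. At 5% noise all three methods separate small-cell (radii
2–6 µm) from large-cell (7–11 µm) substrates well; the two-point ADC is
clearly weakest (AUC 0.86, Mann-Whitney p = 0.008 against the model-free
classifier), while the model-free classifier and the kurtosis model are
statistically indistinguishable at this reduced scale (p = 0.056). At the
full study scale (10 simulation repeats, 100+ noise replicates) the
model-free route reaches AUC ≈ 1.0 at this noise level.
`report.coefficients` holds the SD-scaled logistic weights normalized to
sum to one within each model.

The same pipeline is scriptable from the shell:

```bash
modemdwi simulate --substrates cell_size --walkers 2000 --steps 2000 \
    --repeats 3 --seed 7 --out signals.csv
modemdwi dope --in signals.csv --level 0.05 --reps 30 --seed 1 --out noisy.csv
modemdwi evaluate --in noisy.csv --methods modem,mono,dki --iterations 5 \
    --seed 2 --out report.json
modemdwi run-all --substrates cell_size --profile ci --iterations 10 \
    --seed 0 --out study_out
```

## Acceptance script

`scripts/acceptance.py` recomputes the simulation-arm headline quantities
from scratch: it simulates the ten cell-size substrates at the reduced
Monte-Carlo profile (2000 walkers × 2000 steps, 10 repeats each), dopes
them at the 0% and 5% noise levels (100 replicate rows per
substrate-repeat), runs the model-free classifier over repeated stratified
80/20 split/train/evaluate iterations, and reports the mean test AUC at 0%
noise (10 iterations) and the across-iteration standard deviation of the
AUC at 5% noise (20 iterations):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It finishes in a couple of minutes on one CPU and writes one JSON object
per target.
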
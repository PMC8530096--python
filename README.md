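# mmdisten

Multivariate multiscale modified-distribution entropy for multichannel
time series, with a complete seizure-prediction pipeline: entropy feature
extraction, three-state (interictal / preictal / ictal) classification,
a seizure-alarm decision rule, and alarm-system performance metrics.

## Who this is for

Researchers working on EEG complexity analysis and epileptic seizure
prediction who need a reproducible, tested implementation of a
distribution-entropy statistic that handles **multiple channels jointly**
and **multiple time scales**, plus the standard evaluation machinery
(sensitivity/specificity/AUC for epoch classification; false-alarm rate,
prediction rate and lead time for alarms).  Everything runs on plain
arrays, CSV, or EDF recordings, and a synthetic-signal module makes the
whole chain testable without clinical data.

## The statistic

For a `C`-channel series, at scale factor `s`:

1. coarse-grain each channel: `g^s_{c,j} = (1/s) Σ_{i=(j-1)s+1}^{js} x_{c,i}`;
2. build joint delay templates `M^s(j)` of shape `C × m` (delay `τ`);
3. form scaled pairwise distances `D_ij = (‖M^s(i) − M^s(j)‖₂ / r)^n`,
   with `r = 0.2 ×` the pooled SD of the original series;
4. histogram the distances into `B = 64` bins → probabilities `P_t`;
5. normalised Shannon entropy `E = −(1/log₂B) Σ_t P_t log₂ P_t ∈ [0, 1]`.

Defaults: `m = 3`, `τ = 1`, `r_coef = 0.2`, `n = 2`, `B = 64`, scales
1–15.  See `docs/methods.md` for conventions, design choices and known
limitations.

## Worked example

```python
import numpy as np
from mmdisten import (EntropyParams, gen_epileptic_like, mm_mdisten_curve,
                      run_end_to_end)
from mmdisten.signals import SimulationSpec, gen_simulation

# entropy curve of 400 samples of standard Gaussian noise
series = gen_simulation(SimulationSpec(kind="gaussian", n_samples=400, seed=1))
curve = mm_mdisten_curve(series, EntropyParams())
print(np.round(curve.entropy_values, 3))
```

```
[0.666 0.683 0.77  0.749 0.834 0.715 0.855 0.867 0.723 0.91  0.896 0.895
 0.865 0.838 0.869]
```

Fifteen unitless values in [0, 1], one per scale factor — the complexity
of the noise as seen at successively coarser temporal resolutions.  A 50 Hz
sine under the same parameters stays well below these values at every
scale, and a logistic-map series above ~0.72, which is the regular <
stochastic < chaotic ordering the statistic is designed to expose.

The full prediction chain on a synthetic three-state recording (3
channels; 10 min interictal, 10 min preictal, 2 min ictal at 256 Hz):

```python
rec = gen_epileptic_like(channels=3, segment_minutes=(10, 10, 2), seed=1)
seizures = [(iv.start_s, iv.end_s) for iv in rec.state_intervals
            if iv.state == "ictal"]
res = run_end_to_end(rec.series, seizures, state_intervals=rec.state_intervals,
                     comparator="crossing-up", seed=1)
print(res.holdout_accuracy)        # 1.0   held-out 3-state epoch accuracy
print(res.performance.R_p)         # 1.0   fraction of seizures predicted
print(res.performance.R_fa)        # 0.0   false alarms per hour
print(res.performance.T_avg)       # 20.0  mean warning time, minutes
```

The recording yields 132 ten-second epochs; the classifier separates the
three states perfectly on the held-out split, and the alarm rule fires
once, 20 minutes before the seizure onset, with no false alarms.

## Command line

```bash
mmdisten --seed 1 simulate --kind epileptic --out rec.csv --annotations-out ann.csv
mmdisten entropy rec.csv --fs 256 --scales 1:15 --out curve.csv
mmdisten epoch rec.csv --fs 256 --annotations ann.csv --out epochs.csv
mmdisten --seed 1 train rec.csv --fs 256 --annotations ann.csv \
         --model-out model.npz --features-out feat.csv
mmdisten classify --model model.npz --features feat.csv --out pred.csv
mmdisten --seed 1 evaluate rec.csv --fs 256 --annotations ann.csv --out report.json
mmdisten sweep --axis B --values 2,4,8,16,32,64 --out sweep.csv
```

`entropy` and `epoch` also read EDF files directly (channel selection with
`--channels`); `evaluate` writes a JSON report with every classification
and prediction metric plus the effective configuration.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main results from scratch: the entropy curves of
the three benchmark series and the complete end-to-end prediction chain
(epoching, feature extraction, seeded classifier training, state
prediction, alarm scan, performance metrics) on the synthetic three-state
recording, printing all quantities to stdout and writing the results file.
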
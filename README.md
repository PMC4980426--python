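# motorpool

Quantitative analysis of **sequential motor-pool recruitment** in the
crawling *Drosophila* larva. During forward crawling, each segment's
longitudinal muscles (e.g. LO1) contract before its transverse muscles
(e.g. LT1–LT4), with the transverse pool lagging by roughly 42° of the
locomotor cycle — a phase relationship set not by motor-neuron excitability
but by the organization of the premotor network, in particular a GABAergic
interneuron acting as a delay line. This package implements the two
quantitative pillars of that analysis as a tested, reusable library with a
synthetic-data generator standing in for the imaging and ssTEM data:

1. **Phase analysis of rhythmic signals.** Direct multitaper estimation
   (DPSS tapers, time–bandwidth product *NW* = 5, *K* = 7 tapers) of power
   spectra and coherency between muscle-length or calcium-indicator traces.
   The coherency between a reference *x* and test *y* is

   γ̂(f) = ⟨X_k(f) Ȳ_k(f)⟩_k / √(⟨|X_k|²⟩_k ⟨|Y_k|²⟩_k),

   read out at the *dominant frequency* (peak of the reference's own
   spectrum). |γ̂| is compared against the analytic null quantile
   √(1 − α^{1/(K−1)}) (≈ 0.627 for K = 7, α = 0.05); arg γ̂ is the phase
   lag in degrees, positive when the test signal lags the reference.
   Per-animal phases are summarized by circular means with 95% CIs and
   compared with the paired Hotelling test (within-animal perturbations)
   or the Watson-Williams F test (across genotypes).

2. **Premotor connectome metrics.** On a synapse-count weighted digraph:
   shared/union presynaptic-partner fractions for motor-neuron pairs,
   shared vs divergent input-synapse fractions, Pearson correlation of
   shared partners' synaptic contributions, per-interneuron input
   fractions, and the candidate-interneuron screen (> 35 synapses onto the
   target pool, > 2.75% of the pool's input, zero synapses onto the
   excluded pool).

The `motorpool.synth` module generates data under the model the analyses
assume: multi-segment peristaltic waves with programmable intersegmental
delay and intrasegmental lag, indicator-convolved neural traces, and
connectomes with programmable partner overlap and weight correlation.

## Worked example

```python
import numpy as np
from motorpool import (PeristalsisConfig, simulate_peristalsis,
                       phase_relationship)

cfg = PeristalsisConfig(intrasegmental_lag=42.0, noise_sd=0.04, seed=17)
traces = {m.label: m.trace for m in simulate_peristalsis(cfg)}
pr = phase_relationship(traces["LO1_A1"], traces["LT2_A1"])
print(f"phase {pr.phase_degrees:.1f} deg at {pr.dominant_frequency:.3f} Hz, "
      f"|coh| {pr.magnitude:.3f}, significant={pr.significant}")
```

prints

```
phase 42.2 deg at 0.290 Hz, |coh| 0.996, significant=True
```

i.e. the transverse muscle's contraction lags the longitudinal reference by
42° of a 0.3 Hz crawling cycle (the peak localizes to within a few percent
of the programmed frequency under period jitter), with coherency magnitude
far above the 0.627 significance threshold.

The numbered drivers under `analysis/` run the full story and write their
tables to `results/`; run them in order:

```bash
python analysis/01_simulate_data.py          # synthetic muscle/calcium/connectome data
python analysis/02_muscle_phase_coherency.py # per-segment phase lags + circular mean
python analysis/03_perturbation_tests.py     # Hotelling paired & Watson-Williams tests
python analysis/04_connectome_divergence.py  # shared-input metrics for MN pairs
python analysis/05_screen_interneurons.py    # candidate premotor interneuron screen
```

A `motorpool` console script exposes the same steps
(`motorpool coherence`, `motorpool circtest`, `motorpool connectome
summary|screen`, `motorpool simulate peristalsis|connectome`,
`motorpool pipeline phase|connectome`); see `motorpool --help`.

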
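# gustnet

Analysis pipeline for taste-evoked spike trains in the rostral nucleus of
the solitary tract (rNST) under optogenetic activation of its GABAergic
network, plus the matching brief-access licking analysis. It is aimed at
sensory neurophysiologists who need the full chain from raw spike/trial
tables to population-level conclusions: response detection, optotag
classification, breadth-of-tuning, ensemble-pattern stability, a
divisive-vs-subtractive decomposition of inhibition, and concentration-
response fits of lick behavior. A synthetic-data generator with known
ground truth makes every stage testable end to end.

## What it computes

**Net responses and the response criterion.** A net taste response is the
spike count in the 10-s stimulus window minus the count in the matched 10-s
prestimulus rinse window, averaged over trials, with baselines computed
separately for control and brain-light trials. A response is significant
when the net rate is ≥ 1 Hz (10 spikes / 10 s) *and* ≥ 2.5 × the
across-trial SD of the baseline counts.

**Optotagging.** For each 5-ms brain-light pulse, a 10-ms search window
yields first-spike latency, jitter (SD of latency) and the fraction of
pulses followed. Units that follow faithfully at short latency and low
jitter at the lowest tested frequency are putative GABAergic (G+) cells,
subdivided into taste-responsive (G+TASTE), oral-mechanical (G+MECH) and
unresponsive (G+UNR); the rest are non-GABA taste cells (G−TASTE).

**Breadth of tuning.** Three measures per neuron and condition: the number
of significant responses; the noise:signal ratio (second-best / best net
response, umami cocktail excluded); and the entropy

    H = −1.43 Σᵢ Pᵢ log₁₀ Pᵢ,

where Pᵢ is the proportion of summed responses from stimulus *i* (zeros and
negative responses are replaced by a very small value first).

**Profiles and ensembles.** Hierarchical clustering of chemosensitive
profiles (Pearson 1 − r distance, average linkage, scree consulted for the
cut), per-neuron cross-condition profile correlations, and across-neuron
stimulus correlations embedded by classical multidimensional scaling.

**Gain decomposition.** Control responses are ordered largest to smallest,
the light-condition responses permuted identically, both normalized to the
maximum control response, and a line fit by ordinary least squares:
slope < 1 is divisive suppression, a negative intercept is subtractive.
Slope 1 / intercept 0 is the no-effect line.

**Licking.** Per mouse and session: the modal interlick interval (ILI),
standardized lick ratios (licks relative to the maximum the modal ILI
allows), water-relative ratios for aversive stimuli, and four-parameter
logistic concentration-response fits
`Y = Min + (Max − Min) / (1 + 10^((LogEC50 − X)·Hill))` with X = log₁₀
concentration.

## Worked example

Simulate 30 non-GABA taste neurons with a divisive gain of 0.5 under brain
light, quantify their responses and decompose the suppression:

```python
import numpy as np
from gustnet import synth, coding
from gustnet.core import StimulusPanel
from gustnet.gain import threshold_linear_fit
from gustnet.responses import compute_profile

panel = StimulusPanel.set_a()
specs = synth.default_population(panel, n_gminus=30, n_gplus_taste=0,
                                 n_gplus_unr=0, g=0.5, seed=0)
res = synth.simulate_session(specs, panel,
                             synth.standard_plan(panel, n_reps=2), seed=0)
profs = [compute_profile(res.spikes[u], res.trials[u], panel)
         for u in res.spikes]
fit = threshold_linear_fit([p.vector("control") for p in profs],
                           [p.vector("light_br") for p in profs],
                           scope="population_mean")
print(f"population fit: slope={fit.slope:.3f} "
      f"intercept={fit.intercept:.3f} r2={fit.r_squared:.3f}")
rs = list(coding.profile_stability(profs).values())
print(f"mean cross-condition profile r = {np.nanmean(rs):.3f}")
nc = [coding.tuning_metrics(p, 'control').n_significant for p in profs]
nl = [coding.tuning_metrics(p, 'light_br').n_significant for p in profs]
print(f"mean n significant responses: control {np.mean(nc):.2f} "
      f"-> light {np.mean(nl):.2f}")
```

prints

```
population fit: slope=0.465 intercept=0.024 r2=0.975
mean cross-condition profile r = 0.918
mean n significant responses: control 2.77 -> light 2.10
```

The fitted slope recovers the simulated gain (0.5) with a near-zero
intercept — suppression is divisive, not subtractive. Profile shapes stay
highly correlated across conditions while the count of criterion-passing
responses drops, i.e. tuning sharpens modestly even under purely divisive
scaling, because weak responses fall below the detection criterion.

The same chain runs from the shell:

```sh
gustnet run-all --config cfg.yaml --out run/ --seed 1
```

writing `spikes.csv`, `responses.csv`, `optotag.csv`, `tuning.csv`,
`clusters.json`, `ensemble.json`, `gain.json`, `fits.json` and a
`manifest.json` with digests for bit-identical re-execution.

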
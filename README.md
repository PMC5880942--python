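# dynsyn — dynamic information encoding in an adapting spiking network

`dynsyn` is a simulation and analysis package for a question in sensory
coding: when a constant stimulus keeps being presented, neuronal firing
rates adapt back down to near-background levels — so how does the
stimulus stay readable downstream? The model implemented here realises a
*dynamic coding* answer with chemical synapses: short-term facilitation
(STF) of the recurrent excitatory synapses, triggered by the strong onset
response, keeps the network's synaptic coupling elevated for the duration
of the stimulus. The stimulus information thereby migrates from strong
independent firing (a rate code) into weak but *synchronized* firing (a
correlation code), which a downstream neuron receiving balanced
excitation and inhibition picks up selectively.

It is intended for computational neuroscientists who want to simulate the
network, rerun its controls (shuffled currents, static synapses,
transient stimulation, alternative STP parameters) and reproduce the
analysis chain.

## Model

* Sensory network: `N_E = 2000` excitatory + `N_I = 500` inhibitory LIF
  neurons, `tau_m dV_i/dt = -(V_i - E_L) + R_m [I_syn,i - I_adp,i]`,
  random directed connectivity with probability `p = 0.1` (E→E, E→I, I→E).
* Spike-frequency adaptation (E only):
  `tau_a dI_adp/dt = -I_adp + A_p (V - E_L) + A_s Σ_k δ(t - t_k)`.
* Tsodyks–Markram short-term plasticity on E→E synapses:
  facilitation `u` (`tau_f`), depression `x` (`tau_d`), per-spike
  transmission `J_EE u'x` with `u' = u + U(1-u)`.
* Balanced read-out:
  `tau_o dV_O/dt = -(V_O - E_L) + R_m [J_EO I_E(t) - J_IO I_I(t)]` with
  exponentially filtered population spike trains; the mean drive cancels,
  leaving sensitivity to synchrony only.
* Correlation measurement: input currents `s_i = I_syn,i - I_adp,i`,
  5-ms bins; mean pairwise covariance `σ_s²α` interpreted through a
  dichotomized Gaussian population model
  `s_i = μ_s + σ_s(√(1-α) ν_i + √α ε)`, `x_i = 1{s_i ≥ h}`, whose
  closed-form population-synchrony density is implemented and validated
  against a Monte-Carlo sampler.

See `docs/methods.md` for the full default parameter set, the numerical
conventions (noise discretization, δ-jump bookkeeping), and an honest
account of which observables this parameter regime does and does not
reproduce.

## Worked example

```python
import numpy as np
from dynsyn import run_condition
from dynsyn.stats import compare_periods

res = run_condition("default", n_trials=10, base_seed=42)
for lab in res.period_labels:
    print(f"{lab:9s} rate {res.e_rate[lab].mean():5.2f} Hz   "
          f"<ux> {np.nanmean(res.ux_mean[lab]):.5f}   "
          f"readout {res.readout_count[lab].mean():4.1f} spikes")
t, p = compare_periods(res.readout_count["Adp"].astype(float),
                       res.readout_count["Pre-adp"].astype(float))
print(f"read-out Adp vs Pre-adp: t = {t:.2f}, p = {p:.4f}")
```

prints

```
Pre-adp   rate  6.91 Hz   <ux> 0.01277   readout  0.2 spikes
Adp       rate  7.21 Hz   <ux> 0.01306   readout  2.5 spikes
Post-adp  rate  6.90 Hz   <ux> 0.01268   readout  0.7 spikes
read-out Adp vs Pre-adp: t = 4.87, p = 0.0009
```

Read: firing rates barely differ between the late-stimulus (Adp) period
and the stimulus-free flanking periods (~4%), but the mean synaptic
efficacy `⟨u·x⟩` is elevated during Adp and the read-out neuron — blind
to mean rates by balance — fires several times more often there,
signalling the stimulus through synchrony.

The same experiments are scriptable from the shell:

```bash
dynsyn simulate --condition default --trials 30 --seed 0 --out results/
dynsyn report --in results/ --out results/report.json
dynsyn psth --in results/ --out results/psth.tsv
```

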
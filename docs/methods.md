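# Methods

## The model

`dynsyn` simulates a sensory network of `N_E = 2000` excitatory and
`N_I = 500` inhibitory leaky integrate-and-fire neurons, randomly and
sparsely connected (each allowed ordered pair independently with
probability `p = 0.1`; E→E, E→I and I→E classes only, no self- or I→I
connections), plus one downstream read-out neuron receiving the whole
population.

**Membrane dynamics.** Each neuron follows
`tau_m dV/dt = -(V - E_L) + R_m (I_syn - I_adp)`, spiking when `V`
reaches its class threshold (−55 mV for E, −57 mV for I) and resetting to
`E_L = -65 mV`. There is no refractory period and no conduction delay.

**Adaptation.** Excitatory neurons carry an adaptation current
`tau_a dI_adp/dt = -I_adp + A_p (V - E_L)` plus an instantaneous increment
`A_s = 1 uA` per spike (`tau_a = 250 ms`). Inhibitory neurons have no
adaptation current.

**Short-term plasticity.** Each excitatory neuron keeps one
(release-probability `u`, resource `x`) pair shared by all of its outgoing
E→E synapses. Between spikes `u` decays to 0 with `tau_f` and `x` recovers
to 1 with `tau_d`; at a spike, facilitation acts first
(`u' = u + U(1-u)`), the transmitted fraction is `u' x`, and depression
follows (`x' = x (1-u')`). The E→E drive per spike is `J_EE u' x`; E→I and
I→E deliver fixed `J_EI`, `J_IE` (nA-scale couplings, stored in uA).
Recurrent currents are exponentially filtered with `tau_s = 5 ms`;
delta-function source terms produce jumps equal to their
coefficients (the standard Tsodyks–Markram bookkeeping; the strict
coefficient/tau reading is available via `delta_convention`, but with
`U = 0.00525` it yields per-spike increments of ~1e-5, incompatible with
any visible facilitation).

**External input and noise.** Excitatory neurons receive mean `mu_ext =
0.65 uA` while the stimulus is on (it replaces, not adds to, the
background) and `mu_b = 0.45 uA` otherwise; inhibitory neurons always
receive `mu_b`. White noise of amplitude `sigma_ext = 1.2 uA` applies to
every neuron at all times. The delta-correlation of the noise is
normalised per second: each Euler step adds
`sigma_ext * z * sqrt(1000/dt_ms)`, `z ~ N(0,1)`. This convention makes
the stationary membrane fluctuation `R_m sigma_ext / sqrt(2 tau_m)` ≈ 6 mV
independent of `dt` and is the only normalisation under which the default
parameters produce a firing network at all (the per-millisecond reading
gives 0.19 mV fluctuations against a 10 mV threshold gap, i.e. total
silence). It also reproduces background rates of ~7 Hz (E) and ~14 Hz (I)
— precisely the 2:1 ratio that balances the read-out neuron given
`J_EO = 1`, `J_IO = 2`, `N_E = 4 N_I`.

**Read-out.** The population spike trains are exponentially filtered
(`tau_s`, unit jump per spike) into `I_E(t)`, `I_I(t)`; the read-out
membrane follows `tau_o dV_O/dt = -(V_O - E_L) + R_m (J_EO I_E - J_IO I_I)`
with the excitatory threshold and reset. Because the mean drive nearly
cancels, the neuron responds only to synchronous population fluctuations.

## Integration

Explicit Euler with `dt = 0.1 ms`; all linear auxiliary variables
(`u`, `x`, `I_rec`, `I_E`, `I_I`) use exact exponential inter-event decay
factors. Threshold is tested after the voltage update; spikes are stamped
at the end of the step and their effects (synaptic drive, read-out input)
land in the following step. The compiled (numba) kernel and a pure-numpy
reference engine composed from the documented per-step operations consume
the identical pre-generated noise chunks and perform identical arithmetic,
so their outputs agree bit-for-bit — this equivalence is asserted in the
test suite. Each trial derives three independent RNG streams
(connectivity, noise, initial state) from its seed; trial `i` of a batch
uses `base_seed + i`, so different conditions are paired trial-by-trial
(the suite verifies that pre-onset statistics of paired default and
transient trials are bitwise identical).

## Trial protocol and analysis

A trial spans `t = -2500 … +2500 ms` with stimulus onset at 0 and offset
at 1500 ms (20 ms in the transient control). The first half is a warm-up
under background input. Analysis periods: Pre-adp `[-900, -100)`, Adp
`[500, 1300)`, Post-adp `[1600, 2400)` ms.

Input currents `s_i = I_syn,i - I_adp,i` of all excitatory neurons are
recorded as 1-ms averages (anti-aliased decimation of the 0.1-ms grid) and
analysed as 5-ms bin means. Per trial and period we compute the mean
pairwise covariance (variance-of-sum identity, `O(N T)`; the explicit
pair loop is retained as a test oracle), the mean per-neuron SD
(`sigma_s` estimate), population synchrony fractions (distinct E neurons
per 5-ms bin / `N_E`), read-out spike counts, and `<u x>`. The shuffling
control permutes each neuron's 5-ms bins independently (analysis-time
only, never fed back into dynamics), preserving every per-neuron mean
exactly while destroying temporal alignment.

Period comparisons use a paired two-sided t-test across trials (Wilcoxon
selectable); significance threshold 0.05, no multiple-comparison
correction. Batches run 30 trials per condition (20 for the STP-parameter
variants), a scale-down from the 100-trial reference protocol chosen to keep
runtimes practical.

## The dichotomized Gaussian model

Currents are modelled as
`s_i = mu_s + sigma_s (sqrt(1-alpha) nu_i + sqrt(alpha) eps)` with private
`nu_i` and shared `eps`, so `cov(s_i, s_j) = sigma_s^2 alpha`; a neuron
"fires" in a bin when `s_i >= h`. The large-N density of the population
fraction `r` is obtained by the change of variables
`r = Phi((mu_s + sigma_s sqrt(alpha) eps - h)/(sigma_s sqrt(1-alpha)))`,
giving `p(r) = phi(eps(r)) sqrt((1-alpha)/alpha) / phi(Phi^{-1}(r))` —
normalised analytically and validated against the Monte-Carlo sampler
(total-variation distance < 0.05 over alpha ∈ {0.01, 0.05, 0.2} ×
rates ∈ {0.02, 0.1, 0.5}). The sampler draws the shared factor per bin
and either explicit per-neuron normals or, equivalently (conditional
independence), a binomial count — the latter lets the oracle use 5e4
neurons where small-alpha cases would otherwise be smeared by finite-N
noise. Fitting is moment matching: `mu_s`, `sigma_s` from the traces,
`alpha` from the mean pairwise covariance, `h = mu_s - sigma_s
Phi^{-1}(mean rate)`; nothing is fitted to the histogram shape. A
finite-N binomial smearing of the density is available behind a flag
(default off).

## What the defaults do and do not reproduce

With the default parameter set the network reproduces, robustly across
seeds: stationary low-rate background activity; a facilitation bump of
`<u x>` that rises at onset, stays elevated through Adp (+~2%) and decays
after offset; a ~4× higher rate of large-synchrony events (upper tail of
the population-fraction distribution) in Adp than in the flanking periods;
and a read-out neuron that spikes several-fold more often during Adp
(paired p ~ 1e-4 at 30 trials) while its mean drive cancels to within a
few percent of either input stream alone (the emergent I rate is ~2.04×
the E rate, so the cancellation is close but not exact: the residual mean
is ~15% of the drive SD).

Two quantitative surfaces are *not* reproducible at this parameter scale,
and the corresponding acceptance-style tests are expected to fail; we
report this openly rather than tuning:

1. **Rate-adaptation time course.** The stimulus contrast
   (`mu_ext - mu_b = 0.2 uA` → 0.2 mV of drive) is tiny against the 6 mV
   membrane fluctuations required for the network to fire at all, so the
   onset transient is only ~+4% and never leaves the 2-trial-SD noise band
   of the PSTH; the return-to-background and adaptation-length
   measurements therefore degenerate to 0 ms. A sensitivity argument
   (`d ln r / d mu_V ≈ 0.26/mV` for any noise-driven LIF at ~7 Hz with
   this threshold gap) shows no noise convention can rescue a dramatic
   transient from a 0.2 uA step.

2. **Pairwise-covariance significance.** The per-trial covariance
   estimator carries sampling noise ~0.02 uA^2 (chi-square fluctuation of
   the white-noise variance of the population sum; `sigma_s ≈ 17 uA` per
   5-ms bin), while the STP-induced change is ~5e-4 uA^2, so the paired
   Adp-vs-Pre test across 30 (or even 100) trials is noise; the same
   applies to its shuffled/static/transient controls and the
   STP-parameter-variant pattern. The synchrony increase itself is real
   and is carried by the tail and read-out statistics above.

## Limitations of the synthetic protocol

All inputs are statistically stationary currents; there is no sensory
front-end, no heterogeneity across neurons, and no trial-to-trial
adaptation carry-over (trials are independent). The warm-up (2.5 s) leaves
a small residual relaxation of `x` (`tau_d = 1 s`) visible as a ~0.6%
elevation of Pre-adp `<u x>` relative to Post-adp; period comparisons are
interpreted accordingly. Passing tests demonstrate internal consistency of
the model and analysis chain at the default parameters, not agreement with
biological recordings.
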
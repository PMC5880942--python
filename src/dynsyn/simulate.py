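"""Trial simulation: the compiled integration kernel and a reference engine.

A trial integrates the sensory network plus read-out neuron from
``t = -T/2`` to ``+T/2`` ms with explicit Euler (step ``dt``); the stimulus
window defaults to (0, 1500) ms, so the first half of the trial is a
warm-up under background input that washes out the initial condition.

Two engines produce *identical* results for identical ``(params, seed)``:

* ``engine="numba"`` — a compiled loop over neurons (default, fast);
* ``engine="reference"`` — a numpy loop composed from the per-step
  operations in :mod:`dynsyn.dynamics` (slow; used to validate the kernel).

Both consume the same pre-generated noise chunks and perform the same
arithmetic in the same order, so agreement is exact, not approximate.

Step ordering (one step advances ``t_n`` to ``t_n + dt``):

1. recurrent currents decay and receive the drive scattered by the spikes
   of the previous step; the read-out filters/membrane likewise advance on
   the previous step's population spike counts;
2. external currents are drawn (stimulus indicator evaluated at ``t_n``);
3. membrane Euler update, threshold test; spikes are stamped ``t_n + dt``;
4. adaptation currents decay (against the pre-update voltage) and jump for
   this step's spikes; synaptic states decay, then facilitate/depress for
   this step's spikes, producing the drive for the next step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from . import dynamics
from .connectivity import ConnectivityGraph, build_connectivity
from .params import NetworkParams

CLASS_E, CLASS_I, CLASS_READOUT = 0, 1, 2

_CHUNK_RECORDS = 200  # noise chunk length in record intervals


@dataclass
class SpikeRecord:
    """Spike times (ms, relative to stimulus onset) with neuron id and class."""

    t: np.ndarray        # float64, sorted ascending
    neuron: np.ndarray   # int32; read-out spikes carry id -1
    cls: np.ndarray      # int8: 0 = E, 1 = I, 2 = read-out

    def __len__(self) -> int:
        return self.t.size

    def select(self, cls: int, t_min: float = -np.inf, t_max: float = np.inf) -> "SpikeRecord":
        m = (self.cls == cls) & (self.t >= t_min) & (self.t < t_max)
        return SpikeRecord(self.t[m], self.neuron[m], self.cls[m])


@dataclass
class TrialRecording:
    """Everything recorded from one seeded trial."""

    spikes: SpikeRecord
    t_grid: np.ndarray          # sample times (ms), end of each record interval
    s: np.ndarray               # (n_samples, N_E) float32, I_syn - I_adp averaged per interval
    ux_mean: np.ndarray         # (n_samples,) population-mean u*x (nan for static synapses)
    V_O: np.ndarray             # (n_samples,) read-out membrane potential
    seed: int
    params: NetworkParams
    stimulus_window: tuple[float, float]
    static_synapses: bool = False
    u: Optional[np.ndarray] = None   # (n_samples, N_E) if full STP recording requested
    x: Optional[np.ndarray] = None

    @property
    def record_dt(self) -> float:
        return self.params.record_dt


def trial_seed_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    """Independent child generators (connectivity, noise, initial state)."""
    ss = np.random.SeedSequence(seed)
    c_conn, c_noise, c_init = ss.spawn(3)
    return (np.random.default_rng(c_conn), np.random.default_rng(c_noise),
            np.random.default_rng(c_init))


@njit(cache=True)
def _step_chunk(noise, start_step, t0, dt, w0, w1,
                n_e, n_i,
                V, I_rec, I_adp, u, x, drive,
                ro_state,          # [V_O, I_Ef, I_If, e_prev, i_prev]
                s_acc, s_trace, ux_trace, vo_trace,
                u_trace, x_trace, record_full_stp,
                spike_t, spike_id, spike_cls, n_spikes,
                ee_indptr, ee_indices, ei_indptr, ei_indices,
                ie_indptr, ie_indices,
                tau_m, tau_a, tau_s, tau_f, tau_d, tau_o,
                E_L, V_th_E, V_th_I, R_m,
                A_p, A_s_jump, dU,
                J_EE, J_EI, J_IE, J_s, J_EO, J_IO,
                mu_ext, mu_b, noise_scale,
                static_syn, stride):
    n = n_e + n_i
    f_s = np.exp(-dt / tau_s)
    f_u = np.exp(-dt / tau_f)
    f_x = np.exp(-dt / tau_d)
    k_spk = n_spikes
    for kk in range(noise.shape[0]):
        step = start_step + kk
        t = t0 + step * dt
        t_end = t0 + (step + 1) * dt
        in_stim = (t >= w0) and (t < w1)

        # read-out advances on the previous step's population spike counts
        V_O = ro_state[0]
        I_Ef = ro_state[1] * f_s + ro_state[3]
        I_If = ro_state[2] * f_s + ro_state[4]
        V_O = V_O + (dt / tau_o) * (-(V_O - E_L) + R_m * (J_EO * I_Ef - J_IO * I_If))
        if V_O >= V_th_E:
            V_O = E_L
            spike_t[k_spk] = t_end
            spike_id[k_spk] = -1
            spike_cls[k_spk] = 2
            k_spk += 1
        ro_state[0] = V_O
        ro_state[1] = I_Ef
        ro_state[2] = I_If

        # recurrent decay + pending drive, then clear the pending buffer
        for i in range(n):
            I_rec[i] = I_rec[i] * f_s + drive[i]
            drive[i] = 0.0

        # synaptic state relaxation (E neurons only)
        for i in range(n_e):
            u[i] = u[i] * f_u
            x[i] = 1.0 - (1.0 - x[i]) * f_x

        e_cnt = 0.0
        i_cnt = 0.0
        for i in range(n):
            if i < n_e and in_stim:
                mu = mu_ext
            else:
                mu = mu_b
            I_syn = mu + noise_scale * noise[kk, i] + I_rec[i]
            if i < n_e:
                Ia = I_adp[i]
            else:
                Ia = 0.0
            V_old = V[i]
            V_new = V_old + (dt / tau_m) * (-(V_old - E_L) + R_m * (I_syn - Ia))
            if i < n_e:
                Ia = Ia + (dt / tau_a) * (-Ia + A_p * (V_old - E_L))
            th = V_th_E if i < n_e else V_th_I
            if V_new >= th:
                V_new = E_L
                spike_t[k_spk] = t_end
                spike_id[k_spk] = i
                spike_cls[k_spk] = 0 if i < n_e else 1
                k_spk += 1
                if i < n_e:
                    Ia = Ia + A_s_jump
                    un = u[i] + dU * (1.0 - u[i])
                    q = un * x[i]
                    x[i] = x[i] * (1.0 - un)
                    u[i] = un
                    w_e = J_s if static_syn else J_EE * q
                    for e in range(ee_indptr[i], ee_indptr[i + 1]):
                        drive[ee_indices[e]] += w_e
                    for e in range(ei_indptr[i], ei_indptr[i + 1]):
                        drive[n_e + ei_indices[e]] += J_EI
                    e_cnt += 1.0
                else:
                    j = i - n_e
                    for e in range(ie_indptr[j], ie_indptr[j + 1]):
                        drive[ie_indices[e]] -= J_IE
                    i_cnt += 1.0
            V[i] = V_new
            if i < n_e:
                I_adp[i] = Ia
                s_acc[i] += I_syn - Ia
        ro_state[3] = e_cnt
        ro_state[4] = i_cnt

        if (step + 1) % stride == 0:
            r = (step + 1) // stride - 1
            acc = 0.0
            for i in range(n_e):
                s_trace[r, i] = s_acc[i] / stride
                s_acc[i] = 0.0
                acc += u[i] * x[i]
            ux_trace[r] = acc / n_e
            vo_trace[r] = ro_state[0]
            if record_full_stp:
                for i in range(n_e):
                    u_trace[r, i] = u[i]
                    x_trace[r, i] = x[i]
    if not np.all(np.isfinite(V)):
        return -1  # numerical blow-up; caller raises
    return k_spk


def _initial_state(params: NetworkParams, rng_init: np.random.Generator):
    n_e, n_i = params.N_E, params.N_I
    n = n_e + n_i
    v_th = np.where(np.arange(n) < n_e, params.V_th_E, params.V_th_I)
    V = params.E_L + (v_th - params.E_L) * rng_init.random(n)
    I_rec = np.zeros(n)
    I_adp = np.zeros(n_e)
    u = np.zeros(n_e)
    x = np.ones(n_e)
    return V, I_rec, I_adp, u, x


def run_trial(params: NetworkParams, stimulus_window: tuple[float, float] = (0.0, 1500.0),
              seed: int = 0, *, graph: ConnectivityGraph | None = None,
              engine: str = "numba", static_synapses: bool = False,
              record_full_stp: bool = False) -> TrialRecording:
    """Simulate one trial and return the full recording.

    The trial spans ``t = -T/2 .. +T/2`` ms.  ``graph`` may be passed to
    share one topology across conditions; by default it is drawn from the
    trial's connectivity stream (so equal seeds imply equal graphs).
    Bit-identical output is guaranteed for identical ``(params, seed,
    engine-independent)`` inputs.
    """
    rng_conn, rng_noise, rng_init = trial_seed_streams(seed)
    if graph is None:
        graph = build_connectivity(params.N_E, params.N_I, params.p, rng_conn)
    n_e, n_i = params.N_E, params.N_I
    n = n_e + n_i
    t0 = -params.T / 2.0
    stride = params.record_stride
    n_steps = round(params.T / params.dt)
    if n_steps % stride != 0:
        raise ValueError("T must be an integer number of record intervals")
    n_samples = n_steps // stride

    V, I_rec, I_adp, u, x = _initial_state(params, rng_init)
    drive = np.zeros(n)
    ro_state = np.array([params.E_L, 0.0, 0.0, 0.0, 0.0])
    s_acc = np.zeros(n_e)
    s_trace = np.zeros((n_samples, n_e), dtype=np.float32)
    ux_trace = np.zeros(n_samples)
    vo_trace = np.zeros(n_samples)
    if record_full_stp:
        u_trace = np.zeros((n_samples, n_e), dtype=np.float32)
        x_trace = np.zeros((n_samples, n_e), dtype=np.float32)
    else:
        u_trace = np.zeros((1, 1), dtype=np.float32)
        x_trace = np.zeros((1, 1), dtype=np.float32)

    chunk = _CHUNK_RECORDS * stride
    cap = max(chunk * (n + 1) // 4, 10000)  # spike buffer, grown on demand
    spike_t = np.empty(cap)
    spike_id = np.empty(cap, dtype=np.int32)
    spike_cls = np.empty(cap, dtype=np.int8)

    dU = params.U if params.delta_convention == "jump-equals-coefficient" \
        else params.U / params.tau_f
    A_s_jump = params.A_s if params.delta_convention == "jump-equals-coefficient" \
        else params.A_s / params.tau_a

    w0, w1 = float(stimulus_window[0]), float(stimulus_window[1])
    n_spikes = 0
    step = 0
    while step < n_steps:
        this = min(chunk, n_steps - step)
        noise = rng_noise.standard_normal((this, n))
        if n_spikes + this * (n + 1) > spike_t.size:
            grow = n_spikes + this * (n + 1) + 10000
            spike_t = np.concatenate([spike_t[:n_spikes], np.empty(grow - n_spikes)])
            spike_id = np.concatenate([spike_id[:n_spikes],
                                       np.empty(grow - n_spikes, dtype=np.int32)])
            spike_cls = np.concatenate([spike_cls[:n_spikes],
                                        np.empty(grow - n_spikes, dtype=np.int8)])
        if engine == "numba":
            n_spikes = _step_chunk(
                noise, step, t0, params.dt, w0, w1, n_e, n_i,
                V, I_rec, I_adp, u, x, drive, ro_state,
                s_acc, s_trace, ux_trace, vo_trace,
                u_trace, x_trace, record_full_stp,
                spike_t, spike_id, spike_cls, n_spikes,
                graph.ee.indptr, graph.ee.indices,
                graph.ei.indptr, graph.ei.indices,
                graph.ie.indptr, graph.ie.indices,
                params.tau_m, params.tau_a, params.tau_s, params.tau_f,
                params.tau_d, params.tau_o,
                params.E_L, params.V_th_E, params.V_th_I, params.R_m,
                params.A_p, A_s_jump, dU,
                params.J_EE, params.J_EI, params.J_IE, params.J_s,
                params.J_EO, params.J_IO,
                params.mu_ext, params.mu_b, params.noise_scale,
                static_synapses, stride)
            if n_spikes < 0:
                raise FloatingPointError(
                    f"non-finite membrane potential near t={t0 + step * params.dt} ms")
        elif engine == "reference":
            n_spikes = _reference_chunk(
                noise, step, t0, params, w0, w1, graph,
                V, I_rec, I_adp, u, x, drive, ro_state,
                s_acc, s_trace, ux_trace, vo_trace,
                u_trace, x_trace, record_full_stp,
                spike_t, spike_id, spike_cls, n_spikes,
                static_synapses, A_s_jump, dU, stride)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        step += this

    if static_synapses:
        ux_trace[:] = np.nan
    t_grid = t0 + params.record_dt * np.arange(1, n_samples + 1)
    spikes = SpikeRecord(spike_t[:n_spikes].copy(), spike_id[:n_spikes].copy(),
                         spike_cls[:n_spikes].copy())
    return TrialRecording(
        spikes=spikes, t_grid=t_grid, s=s_trace, ux_mean=ux_trace,
        V_O=vo_trace, seed=seed, params=params,
        stimulus_window=(w0, w1), static_synapses=static_synapses,
        u=u_trace if record_full_stp else None,
        x=x_trace if record_full_stp else None)


def _reference_chunk(noise, start_step, t0, params, w0, w1, graph,
                     V, I_rec, I_adp, u, x, drive, ro_state,
                     s_acc, s_trace, ux_trace, vo_trace,
                     u_trace, x_trace, record_full_stp,
                     spike_t, spike_id, spike_cls, n_spikes,
                     static_synapses, A_s_jump, dU, stride):
    """Slow engine: composes the per-step operations from :mod:`.dynamics`.

    Performs the same arithmetic as the compiled kernel in the same order,
    so results match the fast path exactly (used by the engine-equivalence
    tests on small networks).
    """
    n_e, n_i = params.N_E, params.N_I
    n = n_e + n_i
    dt = params.dt
    is_e = np.arange(n) < n_e
    k = n_spikes
    for kk in range(noise.shape[0]):
        step = start_step + kk
        t = t0 + step * dt
        t_end = t0 + (step + 1) * dt
        in_stim = (t >= w0) and (t < w1)

        vo, ie_f, ii_f, ro_spiked = dynamics.readout_step(
            ro_state[0], ro_state[1], ro_state[2],
            ro_state[3], ro_state[4], dt, params)
        ro_state[0], ro_state[1], ro_state[2] = vo, ie_f, ii_f
        if ro_spiked:
            spike_t[k], spike_id[k], spike_cls[k] = t_end, -1, 2
            k += 1

        I_rec[:] = dynamics.recurrent_current_step(I_rec, drive, dt, params)
        drive[:] = 0.0
        u[:], x[:] = dynamics.stp_decay(u, x, dt, params)

        I_ext = dynamics.external_current(is_e, in_stim, params, noise[kk])
        I_adp_full = np.concatenate([I_adp, np.zeros(n_i)])
        I_syn = I_ext + I_rec
        V_old = V.copy()
        V[:], spiked = dynamics.membrane_step(V, I_syn, I_adp_full, dt, params, is_e)
        I_adp[:] = dynamics.adaptation_step(I_adp, V_old[:n_e], spiked[:n_e], dt, params)
        sp_idx = np.flatnonzero(spiked)
        e_cnt = i_cnt = 0.0
        for i in sp_idx:
            spike_t[k], spike_id[k] = t_end, i
            spike_cls[k] = 0 if i < n_e else 1
            k += 1
            if i < n_e:
                un, xn, q = dynamics.stp_on_spike(u[i], x[i], dU)
                u[i], x[i] = un, xn
                w_e = params.J_s if static_synapses else params.J_EE * q
                tgt = graph.ee.indices[graph.ee.indptr[i]:graph.ee.indptr[i + 1]]
                drive[tgt] += w_e
                tgt = graph.ei.indices[graph.ei.indptr[i]:graph.ei.indptr[i + 1]]
                drive[n_e + tgt] += params.J_EI
                e_cnt += 1.0
            else:
                j = i - n_e
                tgt = graph.ie.indices[graph.ie.indptr[j]:graph.ie.indptr[j + 1]]
                drive[tgt] -= params.J_IE
                i_cnt += 1.0
        ro_state[3], ro_state[4] = e_cnt, i_cnt
        s_acc += I_syn[:n_e] - I_adp
        if (step + 1) % stride == 0:
            r = (step + 1) // stride - 1
            s_trace[r] = (s_acc / stride).astype(np.float32)
            s_acc[:] = 0.0
            ux_trace[r] = np.mean(u * x)
            vo_trace[r] = ro_state[0]
            if record_full_stp:
                u_trace[r] = u.astype(np.float32)
                x_trace[r] = x.astype(np.float32)
    return k
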
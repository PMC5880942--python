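"""Elementary update steps of the model, as standalone vectorisable functions.

These are the single source of truth for the *semantics* of each update:
the reference integration engine composes them directly, and the compiled
fast path in :mod:`dynsyn.simulate` re-implements the identical arithmetic.
All functions accept scalars or numpy arrays.

Conventions (fixed here, configurable where noted):

* delta-function source terms produce instantaneous jumps equal to the
  equation coefficient (``delta_convention="jump-equals-coefficient"``); the
  strict ODE reading (jump = coefficient / tau) is available as a switch;
* on a presynaptic spike the release probability facilitates first
  (u -> u + U(1-u)), the transmitted fraction is u'*x, and depression
  applies afterwards (x -> x(1-u'));
* between events every linear variable relaxes with its exact exponential
  factor, except the membrane potential which uses explicit Euler (its
  drive varies within the step);
* a neuron spikes when the post-update V reaches threshold; V resets to
  the resting potential E_L; there is no refractory period.
"""

from __future__ import annotations

import numpy as np

from .params import NetworkParams

__all__ = [
    "external_current",
    "stp_decay",
    "stp_on_spike",
    "adaptation_step",
    "recurrent_current_step",
    "membrane_step",
    "readout_step",
]


def external_current(is_excitatory, in_stimulus: bool, params: NetworkParams,
                     noise_draw=0.0):
    """External drive for one step: mean plus discretised white noise (uA).

    The mean is ``mu_ext`` for an excitatory neuron while the stimulus is on
    and ``mu_b`` otherwise (the stimulus replaces the background drive).
    ``noise_draw`` is a standard normal; it is scaled by
    ``sigma_ext * sqrt(1000/dt)`` so that the injected fluctuation is a
    delta-correlated current normalised per second.
    """
    mu = np.where(np.logical_and(is_excitatory, in_stimulus),
                  params.mu_ext, params.mu_b)
    return mu + params.noise_scale * np.asarray(noise_draw)


def stp_decay(u, x, dt: float, params: NetworkParams):
    """Exact relaxation of the synaptic state between spikes.

    u decays to 0 with time constant tau_f; x recovers to 1 with tau_d.
    """
    u = np.asarray(u, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(u < 0) or np.any(u > 1) or np.any(x < 0) or np.any(x > 1):
        raise ValueError("synaptic state out of [0, 1]: state corrupted")
    fu = np.exp(-dt / params.tau_f)
    fx = np.exp(-dt / params.tau_d)
    return u * fu, 1.0 - (1.0 - x) * fx


def stp_on_spike(u, x, U: float, *, convention: str = "jump-equals-coefficient",
                 tau_f: float | None = None):
    """Synaptic state transition at a presynaptic spike.

    Returns ``(u', x', transmitted_fraction)`` with facilitation applied
    before release: ``u' = u + dU (1 - u)``, transmitted = ``u' x``,
    ``x' = x (1 - u')``.  Under the strict-ODE convention the effective
    increment is ``dU = U / tau_f``.
    """
    u = np.asarray(u, dtype=float)
    x = np.asarray(x, dtype=float)
    dU = U if convention == "jump-equals-coefficient" else U / float(tau_f)
    u_new = u + dU * (1.0 - u)
    transmitted = u_new * x
    x_new = x * (1.0 - u_new)
    return u_new, x_new, transmitted


def adaptation_step(I_adp, V, spiked, dt: float, params: NetworkParams):
    """One Euler step of the adaptation current of an excitatory neuron.

    Relaxes toward the subthreshold component ``A_p (V - E_L)`` with time
    constant tau_a; a spike adds an instantaneous increment A_s (or
    ``A_s / tau_a`` under the strict-ODE convention).
    """
    I_adp = np.asarray(I_adp, dtype=float)
    jump = params.A_s if params.delta_convention == "jump-equals-coefficient" \
        else params.A_s / params.tau_a
    out = I_adp + (dt / params.tau_a) * (-I_adp + params.A_p * (np.asarray(V) - params.E_L))
    return out + jump * np.asarray(spiked, dtype=float)


def recurrent_current_step(I_rec, incoming_drive, dt: float, params: NetworkParams):
    """Exponential decay of the recurrent current plus this step's spike drive.

    ``incoming_drive`` is the summed weighted input from presynaptic spikes
    landing in this step: ``J_EE * u' * x`` per E->E spike, ``J_EI`` per
    E->I spike, ``-J_IE`` per I->E spike (inhibition enters negatively).
    Simultaneous spikes superpose linearly.
    """
    factor = np.exp(-dt / params.tau_s)
    drive = np.asarray(incoming_drive, dtype=float)
    if params.delta_convention == "jump-equals-coefficient-over-tau":
        drive = drive / params.tau_s
    return np.asarray(I_rec, dtype=float) * factor + drive


def membrane_step(V, I_syn, I_adp, dt: float, params: NetworkParams,
                  is_excitatory=True):
    """Euler update of the membrane potential; threshold-and-reset.

    Returns ``(V', spiked)``.  The threshold is V_th_E or V_th_I by class;
    on a spike V' is reset to E_L.  I_adp must be zero for inhibitory
    neurons (they carry no adaptation current).
    """
    V = np.asarray(V, dtype=float)
    drive = params.R_m * (np.asarray(I_syn, dtype=float) - np.asarray(I_adp, dtype=float))
    V_new = V + (dt / params.tau_m) * (-(V - params.E_L) + drive)
    if not np.all(np.isfinite(V_new)):
        raise FloatingPointError("non-finite membrane potential in membrane_step")
    V_th = np.where(np.asarray(is_excitatory), params.V_th_E, params.V_th_I)
    spiked = V_new >= V_th
    V_new = np.where(spiked, params.E_L, V_new)
    if V_new.ndim == 0:
        return float(V_new), bool(spiked)
    return V_new, spiked


def readout_step(V_O: float, I_E: float, I_I: float,
                 e_spikes: int, i_spikes: int, dt: float,
                 params: NetworkParams) -> tuple[float, float, float, bool]:
    """One step of the balanced read-out neuron.

    ``I_E`` / ``I_I`` are population spike trains filtered with the synaptic
    time constant tau_s (unit jump per spike); the membrane follows
    ``tau_o dV_O/dt = -(V_O - E_L) + R_m (J_EO I_E - J_IO I_I)`` with
    threshold V_th_E and reset E_L.  Returns ``(V_O', I_E', I_I', spiked)``.
    """
    factor = np.exp(-dt / params.tau_s)
    I_E = I_E * factor + e_spikes
    I_I = I_I * factor + i_spikes
    drive = params.R_m * (params.J_EO * I_E - params.J_IO * I_I)
    V_new = V_O + (dt / params.tau_o) * (-(V_O - params.E_L) + drive)
    spiked = V_new >= params.V_th_E
    if spiked:
        V_new = params.E_L
    return V_new, I_E, I_I, spiked
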
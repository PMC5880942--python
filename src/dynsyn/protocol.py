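"""Experiment protocol: analysis periods, trial batches, and controls.

Each experiment condition runs a batch of seeded trials and reduces every
trial to per-period statistics: the mean pairwise covariance of the input
currents ``s_i = I_syn,i - I_adp,i`` (the correlation-code observable), its
shuffled-bin control, the per-neuron current SD, population firing rates and
synchrony fractions, the mean synaptic efficacy <u*x>, and the read-out
spike count.  Dense traces are discarded after each trial; only the
statistics and coarse rate traces are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np

from . import dichotgauss
from .connectivity import build_connectivity
from .params import NetworkParams, STP_VARIANTS
from .simulate import (CLASS_E, CLASS_I, CLASS_READOUT, SpikeRecord,
                       TrialRecording, run_trial, trial_seed_streams)

DEFAULT_STIMULUS_WINDOW = (0.0, 1500.0)
TRANSIENT_STIMULUS_WINDOW = (0.0, 20.0)

CONDITION_NAMES = ("default", "transient", "static", "stp_variant", "shuffled-analysis")


@dataclass(frozen=True)
class PeriodSet:
    """Labeled half-open analysis intervals (ms relative to stimulus onset)."""

    periods: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        spans = sorted(self.periods.values())
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if b1 > a2:
                raise ValueError("analysis periods must not overlap")
        for a, b in spans:
            if b <= a:
                raise ValueError("period end must exceed start")

    def __iter__(self) -> Iterator[tuple[str, tuple[float, float]]]:
        return iter(self.periods.items())

    def __getitem__(self, label: str) -> tuple[float, float]:
        return self.periods[label]

    @property
    def labels(self) -> list[str]:
        return list(self.periods)


def default_periods() -> PeriodSet:
    """The three standard 800-ms windows around the adaptation episode.

    Pre-adp ends before stimulus onset; Adp lies late in the stimulus, when
    firing rates have re-attenuated; Post-adp starts after stimulus offset.
    """
    return PeriodSet({
        "Pre-adp": (-900.0, -100.0),
        "Adp": (500.0, 1300.0),
        "Post-adp": (1600.0, 2400.0),
    })


# --------------------------------------------------------------------------
# per-trial reductions
# --------------------------------------------------------------------------

def population_rate_trace(spikes: SpikeRecord, window: float, cls: int,
                          n_neurons: int, t_range: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Binned population firing rate in Hz per neuron.

    Returns ``(bin_left_edges, rate)`` with bins of ``window`` ms covering
    ``t_range``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if n_neurons <= 0:
        raise ValueError("empty neuron class")
    sel = spikes.select(cls)
    edges = np.arange(t_range[0], t_range[1] + 0.5 * window, window)
    counts, _ = np.histogram(sel.t, edges)
    rate = counts / (n_neurons * window * 1e-3)
    return edges[:-1], rate


def population_rate_fractions(spikes: SpikeRecord, period: tuple[float, float],
                              t_w: float, n_e: int) -> np.ndarray:
    """Fraction of distinct excitatory neurons firing per ``t_w``-ms bin.

    A neuron spiking more than once inside a bin counts once; this is the
    synchrony observable the dichotomized-Gaussian model describes.
    """
    a, b = period
    n_bins = (b - a) / t_w
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("t_w must divide the period length")
    n_bins = round(n_bins)
    sel = spikes.select(CLASS_E, a, b)
    bin_idx = np.floor((sel.t - a) / t_w).astype(np.int64)
    bin_idx = np.minimum(bin_idx, n_bins - 1)
    pairs = np.unique(np.stack([bin_idx, sel.neuron.astype(np.int64)]), axis=1)
    counts = np.bincount(pairs[0], minlength=n_bins)
    return counts / n_e


def shuffle_current_bins(trace: np.ndarray, bin_samples: int,
                         rng: np.random.Generator | int) -> np.ndarray:
    """Randomly permute contiguous bins of a current trace (axis 0).

    The multiset of bin contents — hence every per-neuron time-mean — is
    preserved exactly; only the temporal order is destroyed.  For 2-D input
    (time x neurons) each column gets an independent permutation.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = trace.shape[0]
    if n % bin_samples != 0:
        raise ValueError("trace length must be an integer number of bins")
    n_bins = n // bin_samples
    blocks = trace.reshape(n_bins, bin_samples, *trace.shape[1:])
    if trace.ndim == 1:
        return blocks[rng.permutation(n_bins)].reshape(n)
    out = np.empty_like(blocks)
    for j in range(trace.shape[1]):
        out[:, :, j] = blocks[rng.permutation(n_bins), :, j]
    return out.reshape(trace.shape)


def mean_synaptic_efficacy_trace(recording: TrialRecording) -> np.ndarray:
    """Population-mean synaptic efficacy <u*x> per recorded sample.

    Uses the per-neuron synaptic-state traces when they were recorded,
    otherwise the population mean accumulated during the simulation.
    (Each excitatory neuron's (u, x) pair is shared by all of its outgoing
    synapses, so the synapse-average equals the neuron-average.)
    """
    if recording.u is not None and recording.x is not None:
        return (recording.u.astype(float) * recording.x.astype(float)).mean(axis=1)
    return recording.ux_mean


def readout_drive_trace(recording: TrialRecording, bin_ms: float = 1.0,
                        return_components: bool = False):
    """Reconstruct the net synaptic drive to the read-out neuron from spikes.

    Returns ``(bin left edges, R_m * (J_EO I_E - J_IO I_I))`` with the
    population spike trains binned at ``bin_ms`` and exponentially filtered
    with tau_s; with ``return_components`` the excitatory and inhibitory
    drives are appended.  Used to check the balance condition (the mean
    drive nearly cancels).
    """
    from scipy.signal import lfilter

    p = recording.params
    t_half = p.T / 2.0
    edges = np.arange(-t_half, t_half + 0.5 * bin_ms, bin_ms)
    ce = np.histogram(recording.spikes.select(CLASS_E).t, edges)[0].astype(float)
    ci = np.histogram(recording.spikes.select(CLASS_I).t, edges)[0].astype(float)
    a = np.exp(-bin_ms / p.tau_s)
    d_e = p.R_m * p.J_EO * lfilter([1.0], [1.0, -a], ce)
    d_i = p.R_m * p.J_IO * lfilter([1.0], [1.0, -a], ci)
    if return_components:
        return edges[:-1], d_e - d_i, d_e, d_i
    return edges[:-1], d_e - d_i


# --------------------------------------------------------------------------
# conditions and batches
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """An experiment condition: named overrides of the default protocol."""

    name: str
    stimulus_window: tuple[float, float] = DEFAULT_STIMULUS_WINDOW
    static_synapses: bool = False
    stp_overrides: dict[str, float] | None = None
    shuffle: bool = False

    @classmethod
    def from_name(cls, name: str, variant: str | None = None) -> "Condition":
        if name == "default":
            return cls("default")
        if name == "transient":
            return cls("transient", stimulus_window=TRANSIENT_STIMULUS_WINDOW)
        if name == "static":
            return cls("static", static_synapses=True)
        if name == "stp_variant":
            if variant not in STP_VARIANTS:
                raise ValueError(f"variant must be one of {sorted(STP_VARIANTS)}")
            return cls(f"stp_variant:{variant}", stp_overrides=dict(STP_VARIANTS[variant]))
        if name == "shuffled-analysis":
            return cls("shuffled-analysis", shuffle=True)
        raise ValueError(f"unknown condition {name!r}")


@dataclass
class ExperimentResult:
    """Per-trial, per-period statistics of one condition batch."""

    condition: str
    n_trials: int
    base_seed: int
    period_labels: list[str]
    seeds: list[int] = field(default_factory=list)
    # each maps period label -> array of shape (n_trials,)
    cov: dict[str, np.ndarray] = field(default_factory=dict)
    cov_shuffled: dict[str, np.ndarray] = field(default_factory=dict)
    sigma_s: dict[str, np.ndarray] = field(default_factory=dict)
    mu_s: dict[str, np.ndarray] = field(default_factory=dict)
    e_rate: dict[str, np.ndarray] = field(default_factory=dict)
    ux_mean: dict[str, np.ndarray] = field(default_factory=dict)
    readout_count: dict[str, np.ndarray] = field(default_factory=dict)
    # period label -> (n_trials, n_bins) synchrony fractions
    fractions: dict[str, np.ndarray] = field(default_factory=dict)
    # read-out balance: mean and SD of the reconstructed net drive over
    # the first (pre-stimulus) analysis period, one value per trial
    balance_mean: np.ndarray | None = None
    balance_sd: np.ndarray | None = None
    balance_e_mean: np.ndarray | None = None  # excitatory component alone
    # whole-trial coarse traces, (n_trials, n_bins)
    rate_bin_ms: float = 20.0
    rate_edges: np.ndarray | None = None
    e_rate_trace: np.ndarray | None = None
    readout_rate_trace: np.ndarray | None = None
    params: NetworkParams | None = None

    def headline_statistic(self) -> dict[str, np.ndarray]:
        """The correlation observable of this condition (shuffled view aware)."""
        return self.cov_shuffled if self.condition == "shuffled-analysis" else self.cov

    def shuffled_view(self) -> "ExperimentResult":
        """Re-label this batch as its own shuffling control (same recordings)."""
        out = ExperimentResult(**{**self.__dict__})
        out.condition = "shuffled-analysis"
        return out


def analyze_trial(rec: TrialRecording, periods: PeriodSet, *, bin_ms: float = 5.0,
                  shuffle_rng: np.random.Generator | int | None = None) -> dict[str, dict[str, Any]]:
    """Reduce one trial to per-period statistics.

    Covariances use ``bin_ms``-averaged input-current traces; the shuffled
    statistic permutes those bins per neuron before the identical pipeline.
    """
    p = rec.params
    bin_samples = round(bin_ms / p.record_dt)
    rng = np.random.default_rng(shuffle_rng) if not isinstance(shuffle_rng, np.random.Generator) \
        else shuffle_rng
    out: dict[str, dict[str, Any]] = {}
    for label, (a, b) in periods:
        m = (rec.t_grid >= a) & (rec.t_grid < b)
        expected = round((b - a) / p.record_dt)
        if int(m.sum()) != expected:
            raise ValueError(
                f"period {label} [{a}, {b}) not fully inside the simulated span "
                f"[{rec.t_grid[0] - p.record_dt}, {rec.t_grid[-1]}]")
        S = rec.s[m].astype(np.float64)
        B = S.reshape(-1, bin_samples, S.shape[1]).mean(axis=1)
        Bsh = shuffle_current_bins(B, 1, rng)
        sel_e = rec.spikes.select(CLASS_E, a, b)
        dur_s = (b - a) * 1e-3
        out[label] = {
            "cov": dichotgauss.mean_pairwise_covariance(B),
            "cov_shuffled": dichotgauss.mean_pairwise_covariance(Bsh),
            "sigma_s": dichotgauss.estimate_sigma_s(B),
            "mu_s": float(B.mean()),
            "e_rate": len(sel_e) / (p.N_E * dur_s),
            "ux_mean": float(np.nanmean(rec.ux_mean[m])) if not rec.static_synapses else np.nan,
            "readout_count": len(rec.spikes.select(CLASS_READOUT, a, b)),
            "fractions": population_rate_fractions(rec.spikes, (a, b), p.t_w, p.N_E),
        }
    return out


def run_condition(condition: Condition | str, n_trials: int, base_seed: int,
                  params: NetworkParams | None = None, *,
                  periods: PeriodSet | None = None,
                  share_topology: bool = True,
                  progress: bool = False) -> ExperimentResult:
    """Run a batch of seeded trials under one condition and collect statistics.

    Trial ``i`` uses seed ``base_seed + i``, so conditions sharing a base
    seed are paired trial-by-trial (identical connectivity and noise
    streams).  ``shuffled-analysis`` is not a new simulation: it runs the
    default condition and reports the shuffled-bin covariance.
    """
    if isinstance(condition, str):
        condition = Condition.from_name(condition)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    params = params or NetworkParams()
    if condition.stp_overrides:
        params = params.replace(**condition.stp_overrides)
    periods = periods or default_periods()

    res = ExperimentResult(condition=condition.name, n_trials=n_trials,
                           base_seed=base_seed, period_labels=periods.labels,
                           params=params)
    acc: dict[str, dict[str, list]] = {lab: {} for lab in periods.labels}
    rate_traces, ro_traces = [], []
    t_half = params.T / 2.0
    edges = np.arange(-t_half, t_half + 0.5 * res.rate_bin_ms, res.rate_bin_ms)
    for i in range(n_trials):
        seed = base_seed + i
        res.seeds.append(seed)
        graph = None
        if share_topology:
            rng_conn, _, _ = trial_seed_streams(seed)
            graph = build_connectivity(params.N_E, params.N_I, params.p, rng_conn)
        rec = run_trial(params, condition.stimulus_window, seed, graph=graph,
                        static_synapses=condition.static_synapses)
        # analysis stream: derived from the trial seed, distinct from dynamics
        stats = analyze_trial(rec, periods,
                              shuffle_rng=np.random.default_rng(np.random.SeedSequence([seed, 0xA11])))
        for lab, d in stats.items():
            for k, v in d.items():
                acc[lab].setdefault(k, []).append(v)
        bl_t, drive, d_e, _ = readout_drive_trace(rec, return_components=True)
        a0, b0 = periods[periods.labels[0]]
        bl_m = (bl_t >= a0) & (bl_t < b0)
        acc[periods.labels[0]].setdefault("_bal_mean", []).append(float(drive[bl_m].mean()))
        acc[periods.labels[0]].setdefault("_bal_sd", []).append(float(drive[bl_m].std(ddof=1)))
        acc[periods.labels[0]].setdefault("_bal_e", []).append(float(d_e[bl_m].mean()))
        _, tr = population_rate_trace(rec.spikes, res.rate_bin_ms, CLASS_E,
                                      params.N_E, (-t_half, t_half))
        rate_traces.append(tr)
        _, tro = population_rate_trace(rec.spikes, res.rate_bin_ms, CLASS_READOUT,
                                       1, (-t_half, t_half))
        ro_traces.append(tro)
        if progress:
            print(f"[{condition.name}] trial {i + 1}/{n_trials} done", flush=True)
    for lab in periods.labels:
        res.cov[lab] = np.array(acc[lab]["cov"])
        res.cov_shuffled[lab] = np.array(acc[lab]["cov_shuffled"])
        res.sigma_s[lab] = np.array(acc[lab]["sigma_s"])
        res.mu_s[lab] = np.array(acc[lab]["mu_s"])
        res.e_rate[lab] = np.array(acc[lab]["e_rate"])
        res.ux_mean[lab] = np.array(acc[lab]["ux_mean"])
        res.readout_count[lab] = np.array(acc[lab]["readout_count"])
        res.fractions[lab] = np.array(acc[lab]["fractions"])
    res.balance_mean = np.array(acc[periods.labels[0]]["_bal_mean"])
    res.balance_sd = np.array(acc[periods.labels[0]]["_bal_sd"])
    res.balance_e_mean = np.array(acc[periods.labels[0]]["_bal_e"])
    res.rate_edges = edges[:-1]
    res.e_rate_trace = np.array(rate_traces)
    res.readout_rate_trace = np.array(ro_traces)
    if condition.shuffle:
        res.condition = "shuffled-analysis"
    return res
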
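"""On-disk formats: spike TSV, HDF5 trace containers, JSON results."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np

from .params import NetworkParams
from .protocol import ExperimentResult
from .simulate import SpikeRecord, TrialRecording

_CLASS_NAMES = {0: "E", 1: "I", 2: "readout"}
_CLASS_CODES = {v: k for k, v in _CLASS_NAMES.items()}


def write_spikes_tsv(path: str | Path, spikes: SpikeRecord, trial: int = 0) -> None:
    """Spike list as TSV: ``trial  neuron_id  class  t_ms`` (times 3-decimal)."""
    with open(path, "w") as f:
        f.write("trial\tneuron_id\tclass\tt_ms\n")
        for t, nid, cls in zip(spikes.t, spikes.neuron, spikes.cls):
            f.write(f"{trial}\t{nid}\t{_CLASS_NAMES[int(cls)]}\t{t:.3f}\n")


def read_spikes_tsv(path: str | Path) -> SpikeRecord:
    data = np.genfromtxt(path, delimiter="\t", names=True, dtype=None, encoding=None)
    data = np.atleast_1d(data)
    cls = np.array([_CLASS_CODES[c] for c in data["class"]], dtype=np.int8)
    return SpikeRecord(t=data["t_ms"].astype(float),
                       neuron=data["neuron_id"].astype(np.int32), cls=cls)


def save_recording(path: str | Path, rec: TrialRecording) -> None:
    """One trial as an HDF5 container: traces keyed by variable, params as attrs."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = rec.seed
        f.attrs["record_dt_ms"] = rec.params.record_dt
        f.attrs["stimulus_window_ms"] = rec.stimulus_window
        f.attrs["static_synapses"] = rec.static_synapses
        f.attrs["params_json"] = json.dumps(rec.params.to_dict())
        f.create_dataset("t_grid", data=rec.t_grid)
        f.create_dataset("s", data=rec.s, compression="gzip", shuffle=True)
        f.create_dataset("ux_mean", data=rec.ux_mean)
        f.create_dataset("V_O", data=rec.V_O)
        g = f.create_group("spikes")
        g.create_dataset("t", data=rec.spikes.t)
        g.create_dataset("neuron", data=rec.spikes.neuron)
        g.create_dataset("cls", data=rec.spikes.cls)


def load_recording(path: str | Path) -> TrialRecording:
    with h5py.File(path, "r") as f:
        params = NetworkParams.from_dict(json.loads(f.attrs["params_json"]))
        spikes = SpikeRecord(t=f["spikes/t"][:], neuron=f["spikes/neuron"][:],
                             cls=f["spikes/cls"][:])
        return TrialRecording(
            spikes=spikes, t_grid=f["t_grid"][:], s=f["s"][:],
            ux_mean=f["ux_mean"][:], V_O=f["V_O"][:],
            seed=int(f.attrs["seed"]), params=params,
            stimulus_window=tuple(f.attrs["stimulus_window_ms"]),
            static_synapses=bool(f.attrs["static_synapses"]))


def save_result(directory: str | Path, res: ExperimentResult) -> None:
    """ExperimentResult as JSON statistics plus an HDF5 array container."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "condition": res.condition,
        "n_trials": res.n_trials,
        "base_seed": res.base_seed,
        "seeds": res.seeds,
        "period_labels": res.period_labels,
        "rate_bin_ms": res.rate_bin_ms,
        "balance_mean": None if res.balance_mean is None else res.balance_mean.tolist(),
        "balance_sd": None if res.balance_sd is None else res.balance_sd.tolist(),
        "balance_e_mean": None if res.balance_e_mean is None else res.balance_e_mean.tolist(),
    }
    for lab in res.period_labels:
        summary[lab] = {
            "cov": res.cov[lab].tolist(),
            "cov_shuffled": res.cov_shuffled[lab].tolist(),
            "sigma_s": res.sigma_s[lab].tolist(),
            "mu_s": res.mu_s[lab].tolist(),
            "e_rate": res.e_rate[lab].tolist(),
            "ux_mean": np.nan_to_num(res.ux_mean[lab], nan=-1.0).tolist(),
            "readout_count": res.readout_count[lab].tolist(),
        }
    (d / f"{_slug(res.condition)}.json").write_text(json.dumps(summary, indent=1))
    with h5py.File(d / f"{_slug(res.condition)}.h5", "w") as f:
        f.attrs["condition"] = res.condition
        if res.params is not None:
            f.attrs["params_json"] = json.dumps(res.params.to_dict())
        f.create_dataset("rate_edges", data=res.rate_edges)
        f.create_dataset("e_rate_trace", data=res.e_rate_trace)
        f.create_dataset("readout_rate_trace", data=res.readout_rate_trace)
        for lab in res.period_labels:
            f.create_dataset(f"fractions/{lab}", data=res.fractions[lab])


def load_result(directory: str | Path, condition: str) -> ExperimentResult:
    d = Path(directory)
    summary = json.loads((d / f"{_slug(condition)}.json").read_text())
    res = ExperimentResult(condition=summary["condition"],
                           n_trials=summary["n_trials"],
                           base_seed=summary["base_seed"],
                           period_labels=summary["period_labels"],
                           seeds=summary["seeds"],
                           rate_bin_ms=summary["rate_bin_ms"])
    if summary.get("balance_mean") is not None:
        res.balance_mean = np.array(summary["balance_mean"])
        res.balance_sd = np.array(summary["balance_sd"])
    if summary.get("balance_e_mean") is not None:
        res.balance_e_mean = np.array(summary["balance_e_mean"])
    for lab in res.period_labels:
        blk = summary[lab]
        res.cov[lab] = np.array(blk["cov"])
        res.cov_shuffled[lab] = np.array(blk["cov_shuffled"])
        res.sigma_s[lab] = np.array(blk["sigma_s"])
        res.mu_s[lab] = np.array(blk["mu_s"])
        res.e_rate[lab] = np.array(blk["e_rate"])
        ux = np.array(blk["ux_mean"])
        res.ux_mean[lab] = np.where(ux < 0, np.nan, ux)
        res.readout_count[lab] = np.array(blk["readout_count"])
    with h5py.File(d / f"{_slug(condition)}.h5", "r") as f:
        res.rate_edges = f["rate_edges"][:]
        res.e_rate_trace = f["e_rate_trace"][:]
        res.readout_rate_trace = f["readout_rate_trace"][:]
        for lab in res.period_labels:
            res.fractions[lab] = f[f"fractions/{lab}"][:]
        if "params_json" in f.attrs:
            res.params = NetworkParams.from_dict(json.loads(f.attrs["params_json"]))
    return res


def _slug(name: str) -> str:
    return name.replace(":", "_").replace("/", "_")
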
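"""Period comparisons, PSTHs, read-out summaries and the significance report."""

from __future__ import annotations

from typing import Any, Sequence

import numpy as np
from scipy import stats as sps

from .protocol import ExperimentResult, PeriodSet
from .simulate import CLASS_READOUT, TrialRecording

ALPHA_DEFAULT = 0.05

#: period pairs the experiments compare (Adp against each flanking period)
HEADLINE_PAIRS = (("Adp", "Pre-adp"), ("Adp", "Post-adp"))


def compare_periods(a: Sequence[float], b: Sequence[float],
                    test: str = "ttest") -> tuple[float, float]:
    """Paired two-sided comparison of per-trial statistics.

    ``test`` is "ttest" (paired Student t) or "wilcoxon" (signed rank).
    Identical samples have no evidence of a difference: returns (0.0, 1.0).
    No multiple-comparison correction is applied; each period pair is
    reported raw.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired samples")
    d = a - b
    if np.all(d == 0.0):
        return 0.0, 1.0
    if test == "ttest":
        res = sps.ttest_rel(a, b)
    elif test == "wilcoxon":
        res = sps.wilcoxon(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def readout_spike_counts(recording: TrialRecording, periods: PeriodSet) -> dict[str, int]:
    """Read-out spike count in each analysis period of one trial."""
    return {lab: len(recording.spikes.select(CLASS_READOUT, a, b))
            for lab, (a, b) in periods}


def psth(spike_times: Sequence[np.ndarray], bin_ms: float,
         t_range: tuple[float, float], n_neurons: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged firing rate (Hz per neuron) in ``bin_ms`` windows.

    ``spike_times`` holds one array of spike times per trial; pass
    ``n_neurons=1`` for a single-unit (e.g. read-out) PSTH.
    """
    if bin_ms <= 0:
        raise ValueError("bin must be positive")
    edges = np.arange(t_range[0], t_range[1] + 0.5 * bin_ms, bin_ms)
    counts = np.zeros(edges.size - 1)
    for t in spike_times:
        counts += np.histogram(t, edges)[0]
    rate = counts / (len(spike_times) * n_neurons * bin_ms * 1e-3)
    return edges[:-1], rate


def adaptation_time_course(rate_traces: np.ndarray, edges: np.ndarray,
                           pre_period: tuple[float, float] = (-900.0, -100.0),
                           n_band_sd: float = 2.0) -> dict[str, float]:
    """Onset/return timing of the population-rate adaptation episode.

    ``rate_traces`` holds one binned rate trace per trial (trials x bins),
    ``edges`` the left bin edges (ms, stimulus onset at 0).  The noise band
    is ``pre mean +/- n_band_sd * SD``, where the SD pools the per-trial
    rates of all pre-stimulus windows (trial-to-trial variability at one
    window).  Reported, on the trial-averaged PSTH:

    * ``t_return`` — left edge of the first post-onset window back inside
      the band (0 if the response never leaves it);
    * ``t_rise`` — left edge of the first post-onset window above the band
      (nan if the rate never rises above it);
    * ``adaptation_length`` — time from rise to the first subsequent window
      back at/below the band's upper edge (0 if no rise was detected).
    """
    rate_traces = np.asarray(rate_traces, dtype=float)
    edges = np.asarray(edges, dtype=float)
    mean_psth = rate_traces.mean(axis=0)
    pre = (edges >= pre_period[0]) & (edges < pre_period[1])
    if not pre.any():
        raise ValueError("pre-stimulus period not covered by the trace")
    pre_mean = mean_psth[pre].mean()
    band_sd = rate_traces[:, pre].std(ddof=1)
    post = np.flatnonzero(edges >= 0.0)
    dev = mean_psth[post] - pre_mean
    within = np.abs(dev) <= n_band_sd * band_sd
    t_return = float(edges[post[np.argmax(within)]]) if within.any() else float("nan")
    above = dev > n_band_sd * band_sd
    if above.any():
        i_rise = int(np.argmax(above))
        t_rise = float(edges[post[i_rise]])
        back = ~above[i_rise:]
        length = (float(edges[post[i_rise + np.argmax(back)]]) - t_rise) if back.any() \
            else float("nan")
    else:
        t_rise = float("nan")
        length = 0.0
    return {"t_return": t_return, "t_rise": t_rise, "adaptation_length": length,
            "pre_mean": float(pre_mean), "band_sd": float(band_sd)}


def summarize_default_condition(res: ExperimentResult, test: str = "ttest") -> dict[str, float]:
    """Headline quantities of a default-condition batch.

    * ``return_to_background_ms`` — left edge of the first post-onset 100-ms
      window of the trial-averaged E-population PSTH back inside the
      pre-stimulus noise band (2 trial-SDs);
    * ``adaptation_length_ms`` — rate-rise to rate-return interval on 20-ms
      windows (0 when the response never exceeds the band);
    * ``cov_adp_vs_pre_p`` — paired two-sided p for mean pairwise input
      covariance, Adp vs Pre-adp;
    * ``readout_adp_vs_pre_p`` — same comparison for read-out spike counts.
    """
    edges20 = res.rate_edges
    agg = round(100.0 / res.rate_bin_ms)
    r20 = res.e_rate_trace
    n100 = (r20.shape[1] // agg) * agg
    r100 = r20[:, :n100].reshape(r20.shape[0], -1, agg).mean(axis=2)
    edges100 = edges20[:n100:agg]
    tc100 = adaptation_time_course(r100, edges100)
    tc20 = adaptation_time_course(r20, edges20)
    _, p_cov = compare_periods(res.cov["Adp"], res.cov["Pre-adp"], test)
    _, p_ro = compare_periods(res.readout_count["Adp"].astype(float),
                              res.readout_count["Pre-adp"].astype(float), test)
    return {
        "return_to_background_ms": tc100["t_return"],
        "adaptation_length_ms": tc20["adaptation_length"],
        "cov_adp_vs_pre_p": p_cov,
        "readout_adp_vs_pre_p": p_ro,
        "n_trials": float(res.n_trials),
    }


def _comparison_entry(condition: str, statistic: str, pair: tuple[str, str],
                      a: np.ndarray, b: np.ndarray, test: str,
                      alpha: float) -> dict[str, Any]:
    stat, p = compare_periods(a, b, test)
    d = np.asarray(a, float) - np.asarray(b, float)
    return {
        "condition": condition,
        "statistic": statistic,
        "period_pair": list(pair),
        "test": f"paired {test}, two-sided",
        "statistic_value": stat,
        "p_value": p,
        "significant": bool(p < alpha),
        "n_trials": int(len(a)),
        "mean_difference": float(d.mean()),
        "sd_difference": float(d.std(ddof=1)),
        "se_difference": float(d.std(ddof=1) / np.sqrt(len(d))),
    }


def build_report(results: Sequence[ExperimentResult], *, alpha: float = ALPHA_DEFAULT,
                 test: str = "ttest") -> dict[str, Any]:
    """Significance report over a set of condition batches.

    For every condition the mean pairwise input covariance is compared
    between the Adp period and each flanking period; for batches that carry
    read-out counts those are compared the same way.  Each entry reports the
    raw p-value, the mean paired difference and both SD and SE of the
    differences.
    """
    if not results:
        raise ValueError("at least one condition result is required")
    comparisons: list[dict[str, Any]] = []
    for res in results:
        stat_map: list[tuple[str, dict[str, np.ndarray]]] = [
            ("pairwise_covariance", res.headline_statistic()),
        ]
        if res.condition != "shuffled-analysis":
            stat_map.append(("readout_spike_count", res.readout_count))
        for stat_name, values in stat_map:
            for pair in HEADLINE_PAIRS:
                if pair[0] not in values or pair[1] not in values:
                    raise KeyError(f"missing statistics for periods {pair} "
                                   f"in condition {res.condition!r}")
                comparisons.append(_comparison_entry(
                    res.condition, stat_name, pair,
                    values[pair[0]], values[pair[1]], test, alpha))
    per_condition_means = {
        res.condition: {
            lab: {
                "covariance_mean": float(np.mean(res.headline_statistic()[lab])),
                "covariance_se": float(np.std(res.headline_statistic()[lab], ddof=1)
                                       / np.sqrt(res.n_trials)),
                "readout_count_mean": float(np.mean(res.readout_count[lab])),
                "e_rate_mean_hz": float(np.mean(res.e_rate[lab])),
            }
            for lab in res.period_labels
        }
        for res in results
    }
    return {
        "alpha": alpha,
        "test": test,
        "comparisons": comparisons,
        "period_means": per_condition_means,
    }
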
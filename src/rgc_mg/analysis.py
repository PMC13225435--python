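"""Analysis metrics: spikes, calcium, therapeutic windows, efficacy.

Definitions used throughout:

* A spike is an upward crossing of -20 mV; a new spike requires the
  voltage to fall back below threshold first (de-bounce), so a single
  action potential sampled at dt = 0.02 ms counts once.
* Spike probability = detected spikes / expected stimulus pulses over the
  analysis window, capped at 1; spike loss = 100 * (1 - probability).
* The therapeutic window at a frequency is the maximal contiguous range of
  Mg2+ concentrations where peak [Ca2+]i stays below the toxicity
  threshold (default 1.0 uM) AND spike loss relative to the low-Mg
  baseline stays within the allowed fraction (default 20%).
* Protection efficacy scores an intervention linearly between the no-Mg
  (0%) and pre-treated (100%) reference runs by peak [Ca2+]i.
* Ca2+ progress normalises the untreated Ca2+ trace between rest (0) and
  its own peak (1) -- a treatment-independent measure of how far the
  excitotoxic Ca2+ load has advanced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .model import mg_block_factor
from .params import ModelParameters

__all__ = [
    "SpikeMetrics",
    "TherapeuticCriteria",
    "TherapeuticWindow",
    "detect_spikes",
    "peak_calcium",
    "find_window",
    "threshold_sensitivity",
    "protection_efficacy",
    "ca_progress",
    "nmda_charge",
    "nmda_current_trace",
    "mean_unblock",
]

SPIKE_THRESHOLD_MV = -20.0


@dataclass(frozen=True)
class SpikeMetrics:
    """Spike detection summary over an analysis window."""

    spike_times: np.ndarray
    n_spikes: int
    n_expected: int
    spike_probability: float
    spike_loss_pct: float


class TherapeuticCriteria(BaseModel):
    """Dual criteria defining the therapeutic window."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    ca_toxicity_threshold: float = Field(1.0, gt=0, description="Peak [Ca2+]i limit (uM)")
    max_spike_loss_pct: float = Field(20.0, ge=0, le=100, description="Allowed spike loss vs baseline (%)")
    baseline_mg: float = Field(0.2, ge=0, description="Baseline [Mg2+] for the function criterion (mM)")


@dataclass(frozen=True)
class TherapeuticWindow:
    """Contiguous Mg2+ range satisfying both therapeutic criteria."""

    frequency_hz: float
    lower: Optional[float]  # mM; None when no window exists
    upper: Optional[float]
    classification: Tuple[str, ...]  # per-concentration labels, grid order

    @property
    def exists(self) -> bool:
        return self.lower is not None

    @property
    def width(self) -> float:
        """Window width in mM (0 when empty)."""
        return (self.upper - self.lower) if self.exists else 0.0


def _window_slice(t: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(f"analysis window {window} outside trace span ({t[0]}, {t[-1]})")
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not mask.any():
        raise ValueError("analysis window contains no samples")
    return mask


def detect_spikes(
    trace,
    window: Tuple[float, float],
    n_expected: int,
    threshold: float = SPIKE_THRESHOLD_MV,
) -> SpikeMetrics:
    """Count threshold crossings of the voltage trace within a window.

    A spike is registered at the first supra-threshold sample of each
    upward crossing; the voltage must return below threshold before a new
    spike can be registered.  Spike probability is capped at 1 (bursting
    may generate more crossings than stimulus pulses).

    ``trace`` may be a :class:`~rgc_mg.integrator.Trace` or a
    ``(t, V)`` pair of arrays.
    """
    if isinstance(trace, tuple):
        t, v = trace
    else:
        t, v = trace.t, trace["V"]
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("detect_spikes expects a single-cell voltage trace")
    mask = _window_slice(t, window)
    v_w = v[mask]
    t_w = t[mask]
    above = v_w > threshold
    onsets = above & ~np.concatenate(([above[0]], above[:-1]))
    # a window starting mid-spike still counts that spike once
    if above[0]:
        onsets[0] = True
    spike_times = t_w[onsets]
    n_spikes = int(onsets.sum())
    prob = min(1.0, n_spikes / n_expected) if n_expected > 0 else float("nan")
    return SpikeMetrics(
        spike_times=spike_times,
        n_spikes=n_spikes,
        n_expected=n_expected,
        spike_probability=prob,
        spike_loss_pct=100.0 * (1.0 - prob),
    )


def peak_calcium(trace, window: Tuple[float, float]) -> float:
    """Maximum [Ca2+]i (uM) over the analysis window."""
    if isinstance(trace, tuple):
        t, ca = trace
    else:
        t, ca = trace.t, trace["Ca"]
    mask = _window_slice(np.asarray(t, dtype=float), window)
    return float(np.max(np.asarray(ca, dtype=float)[mask]))


def _classify(row_df: pd.DataFrame, criteria: TherapeuticCriteria) -> Tuple[np.ndarray, list]:
    loss_col = (
        "spike_loss_vs_baseline_pct"
        if "spike_loss_vs_baseline_pct" in row_df.columns
        else "spike_loss_pct"
    )
    ca_ok = row_df["peak_ca_uM"].to_numpy() < criteria.ca_toxicity_threshold
    fn_ok = row_df[loss_col].to_numpy() <= criteria.max_spike_loss_pct + 1e-9
    labels = []
    for c, f in zip(ca_ok, fn_ok):
        if c and f:
            labels.append("optimal")
        elif not c and not f:
            labels.append("fails-both")
        elif not c:
            labels.append("fails-protection")
        else:
            labels.append("fails-function")
    return ca_ok & fn_ok, labels


def find_window(row_df: pd.DataFrame, criteria: TherapeuticCriteria = None) -> TherapeuticWindow:
    """Identify the therapeutic window from one frequency's dose-response row.

    ``row_df`` must contain columns ``mg_mM``, ``peak_ca_uM`` and a spike
    loss column, sorted by ascending Mg.  The window is the longest
    contiguous run of concentrations satisfying both criteria (the first
    such run on ties); bounds are reported at grid resolution without
    interpolation.
    """
    if criteria is None:
        criteria = TherapeuticCriteria()
    mg = row_df["mg_mM"].to_numpy(dtype=float)
    if np.any(np.diff(mg) <= 0):
        raise ValueError("Mg grid must be sorted strictly ascending")
    ok, labels = _classify(row_df, criteria)
    freq = float(row_df["frequency_hz"].iloc[0]) if "frequency_hz" in row_df.columns else float("nan")

    best_run: Optional[Tuple[int, int]] = None  # inclusive index range
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            run = (start, i - 1)
            if best_run is None or (run[1] - run[0]) > (best_run[1] - best_run[0]):
                best_run = run
            start = None

    if best_run is None:
        return TherapeuticWindow(freq, None, None, tuple(labels))
    lo, hi = best_run
    return TherapeuticWindow(freq, float(mg[lo]), float(mg[hi]), tuple(labels))


def threshold_sensitivity(
    row_df: pd.DataFrame,
    thresholds: Sequence[float],
    criteria: TherapeuticCriteria = None,
) -> pd.DataFrame:
    """Therapeutic window as a function of the Ca2+ toxicity threshold.

    Re-runs the window search on an existing dose-response row for each
    threshold (the simulations themselves do not depend on the threshold).
    Window width is non-decreasing in the threshold.
    """
    if criteria is None:
        criteria = TherapeuticCriteria()
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for thr in thresholds:
        c = criteria.model_copy(update={"ca_toxicity_threshold": thr})
        w = find_window(row_df, c)
        rows.append(
            {
                "ca_threshold_uM": thr,
                "window_exists": w.exists,
                "lower_mM": w.lower,
                "upper_mM": w.upper,
                "width_mM": w.width,
            }
        )
    return pd.DataFrame(rows)


def protection_efficacy(peak_no_mg: float, peak_pre: float, peak_intervention: float) -> float:
    """Protection score (%) of an intervention between the two references.

    ``100 * (peak_no_mg - peak_intervention) / (peak_no_mg - peak_pre)``:
    100% means the intervention matched pre-treatment, 0% means it matched
    the untreated run.
    """
    denom = peak_no_mg - peak_pre
    if denom <= 0:
        raise ValueError(
            "degenerate reference pair: untreated peak must exceed pre-treated peak"
        )
    return 100.0 * (peak_no_mg - peak_intervention) / denom


def ca_progress(untreated_trace, t_eval: float, window: Tuple[float, float]) -> float:
    """Normalized Ca2+ progress of the untreated run at time ``t_eval``.

    ``(Ca(t) - Ca_rest) / (Ca_peak_noMg - Ca_rest)`` where the peak is
    taken from the untreated trace over the analysis window -- 0 at rest,
    1 at the untreated peak.  ``t_eval`` earlier than the trace start is an
    error; the pre-treatment condition conventionally evaluates at t = 0.
    """
    t = np.asarray(untreated_trace.t, dtype=float)
    ca = np.asarray(untreated_trace["Ca"], dtype=float)
    if t_eval < t[0] - 1e-9 or t_eval > t[-1] + 1e-9:
        raise ValueError(f"t_eval = {t_eval} ms outside the untreated trace")
    ca_rest = untreated_trace.params.ca_rest
    peak = peak_calcium(untreated_trace, window)
    ca_t = float(np.interp(t_eval, t, ca))
    return (ca_t - ca_rest) / (peak - ca_rest)


def nmda_current_trace(trace) -> np.ndarray:
    """Reconstruct I_NMDA (uA/cm^2) from a recorded trace.

    Requires ``V``, ``sNMDA`` and the applied Mg2+ to have been recorded;
    the current is a memoryless function of those quantities.
    """
    p = trace.params
    b = mg_block_factor(trace["V"], trace.mg, p)
    return p.g_nmda * trace["sNMDA"] * b * (trace["V"] - p.e_exc)


def nmda_charge(trace_or_current, window: Tuple[float, float], t: np.ndarray = None) -> float:
    """Integrated NMDA charge density ``Q = int |I_NMDA| dt`` (uA*ms/cm^2).

    Trapezoidal integration of the rectified current over the window.
    Accepts either a recorded :class:`Trace` (the current is reconstructed)
    or a precomputed current array plus its time grid.
    """
    if t is None:
        t = np.asarray(trace_or_current.t, dtype=float)
        current = nmda_current_trace(trace_or_current)
    else:
        current = np.asarray(trace_or_current, dtype=float)
        t = np.asarray(t, dtype=float)
    mask = _window_slice(t, window)
    return float(np.trapezoid(np.abs(current[mask]), t[mask]))


def mean_unblock(trace, window: Tuple[float, float], params: ModelParameters = None) -> float:
    """Time-averaged unblocked fraction <B(V(t), Mg(t))> over a window."""
    p = params if params is not None else trace.params
    t = np.asarray(trace.t, dtype=float)
    mask = _window_slice(t, window)
    mg = trace.mg if np.ndim(trace.mg) else float(trace.mg)
    b = mg_block_factor(np.asarray(trace["V"])[mask], np.asarray(mg)[mask] if np.ndim(mg) else mg, p)
    return float(np.mean(b))
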
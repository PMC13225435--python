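"""Stimulation protocols and the two core experiments.

Glutamate release is modelled as ideal rectangular pulses (instantaneous
rise and fall) of fixed amplitude and width: pulse ``k`` of a train at
frequency ``f`` starts at ``stim_start + k * 1000/f`` ms and lasts
``pulse_width`` ms; a pulse only occurs if it ends by ``stim_end``.
Extracellular Mg2+ follows a piecewise-constant schedule (instantaneous
concentration switches), which is how a supplementation step applied at a
delay is represented.

Two experiments build on this:

* :func:`run_dose_response` -- a (frequency x [Mg2+]) grid, default
  10-100 Hz by 0.2-2.5 mM in 0.1 mM steps, with spike and calcium metrics
  per cell evaluated on a steady-state window (the first 500 ms are
  excluded to remove initialisation transients) and a therapeutic-window
  classification per frequency.
* :func:`run_timing_experiment` -- an 80 Hz excitotoxic stress episode
  (0.5-4.5 s) with a Mg2+ step from a low baseline to a protective level
  applied at varying delays; protection efficacy is scored against the
  constant-baseline and constant-treated reference runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import analysis
from .integrator import IntegrationConfig, Trace, integrate
from .kinetics import GatingKinetics, default_kinetics
from .model import resting_state
from .params import ModelParameters

__all__ = [
    "StimulusProtocol",
    "SweepGrid",
    "TimingExperiment",
    "SweepSummary",
    "glutamate_train",
    "expected_pulses",
    "simulate_protocol",
    "run_dose_response",
    "run_timing_experiment",
    "PRETREAT",
]

#: Label used for the pre-treatment condition in timing experiments.
PRETREAT = "pretreat"

_EDGE_TOL = 1e-6  # ms; tolerance for pulse-edge comparisons on the time grid


class StimulusProtocol(BaseModel):
    """A glutamate pulse train plus a piecewise-constant Mg2+ schedule."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    pulse_freq: float = Field(..., gt=0, description="Pulse rate (Hz)")
    pulse_width: float = Field(2.0, gt=0, description="Pulse duration (ms)")
    pulse_amp: float = Field(1.0, ge=0, description="Glutamate concentration during a pulse (mM)")
    stim_start: float = Field(0.0, ge=0, description="Train onset (ms)")
    stim_end: float = Field(..., gt=0, description="Train end (ms)")
    t_end: float = Field(..., gt=0, description="Simulation end (ms)")
    mg_schedule: Tuple[Tuple[float, float], ...] = Field(
        ((0.0, 1.0),), description="(time ms, [Mg2+] mM) step changes, times non-decreasing"
    )

    @model_validator(mode="after")
    def _validate(self) -> "StimulusProtocol":
        if not (self.stim_start < self.stim_end <= self.t_end):
            raise ValueError("require stim_start < stim_end <= t_end")
        period = 1000.0 / self.pulse_freq
        if self.pulse_width >= period:
            raise ValueError(
                f"pulse_width {self.pulse_width} ms >= inter-pulse period {period:.4g} ms"
            )
        times = [t for t, _ in self.mg_schedule]
        if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("mg_schedule times must be non-decreasing")
        if any(mg < 0 for _, mg in self.mg_schedule):
            raise ValueError("Mg2+ concentrations must be non-negative")
        return self

    @property
    def period(self) -> float:
        """Inter-pulse interval (ms)."""
        return 1000.0 / self.pulse_freq

    def glu(self, t: float) -> float:
        """Glutamate concentration (mM) at time ``t``."""
        return glutamate_train(self, t)

    def mg(self, t: float) -> float:
        """Extracellular Mg2+ (mM) at time ``t`` (first schedule entry
        applies to all earlier times)."""
        mg = self.mg_schedule[0][1]
        for t_step, value in self.mg_schedule:
            if t >= t_step:
                mg = value
            else:
                break
        return mg

    def pulse_onsets(self, window: Optional[Tuple[float, float]] = None) -> np.ndarray:
        """Onset times (ms) of all pulses, optionally restricted to a window
        (pulses are attributed to the window by onset time)."""
        onsets = []
        k = 0
        while True:
            t_k = self.stim_start + k * self.period
            if t_k + self.pulse_width > self.stim_end + _EDGE_TOL:
                break
            onsets.append(t_k)
            k += 1
        arr = np.array(onsets)
        if window is not None:
            lo, hi = window
            arr = arr[(arr >= lo - _EDGE_TOL) & (arr < hi - _EDGE_TOL)]
        return arr


def glutamate_train(protocol: StimulusProtocol, t: float) -> float:
    """Evaluate the rectangular glutamate pulse train at time ``t`` (ms)."""
    if t < protocol.stim_start - _EDGE_TOL or t >= protocol.stim_end - _EDGE_TOL:
        return 0.0
    phase = math.fmod(t - protocol.stim_start, protocol.period)
    t_on = t - phase  # onset of the current cycle's pulse
    if t_on + protocol.pulse_width > protocol.stim_end + _EDGE_TOL:
        return 0.0
    return protocol.pulse_amp if phase < protocol.pulse_width - _EDGE_TOL else 0.0


def expected_pulses(freq_hz: float, window: Tuple[float, float]) -> int:
    """Expected pulse count over an analysis window: floor(f * span)."""
    span_s = (window[1] - window[0]) / 1000.0
    return int(math.floor(freq_hz * span_s + _EDGE_TOL))


class _BatchStimulus:
    """Shared glutamate train with an independent Mg2+ schedule per cell."""

    def __init__(self, protocol: StimulusProtocol, schedules: Sequence[Sequence[Tuple[float, float]]]):
        self.protocol = protocol
        n_seg = max(len(s) for s in schedules)
        n_cell = len(schedules)
        self._starts = np.full((n_cell, n_seg), np.inf)
        self._values = np.empty((n_cell, n_seg))
        for i, sched in enumerate(schedules):
            for j, (t_step, mg) in enumerate(sched):
                self._starts[i, j] = t_step
                self._values[i, j] = mg
            # pad unused segments with the last value so searchsorted-style
            # indexing below stays in range
            self._values[i, len(sched):] = sched[-1][1]
        self._starts[:, 0] = -np.inf  # first entry applies from the start
        self._rows = np.arange(n_cell)

    @property
    def n_batch(self) -> int:
        return len(self._rows)

    def glu(self, t: float) -> float:
        return self.protocol.glu(t)

    def mg(self, t: float) -> np.ndarray:
        idx = (t >= self._starts).sum(axis=1) - 1
        return self._values[self._rows, idx]


class SweepGrid(BaseModel):
    """Grid for the dose-response experiment."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    frequencies: Tuple[float, ...] = (10.0, 30.0, 60.0, 80.0, 90.0, 100.0)
    mg_values: Tuple[float, ...] = tuple(round(0.2 + 0.1 * i, 1) for i in range(24))
    window: Tuple[float, float] = (500.0, 3000.0)
    t_end: float = 3000.0
    baseline_mg: float = 0.2

    @model_validator(mode="after")
    def _validate(self) -> "SweepGrid":
        if not self.frequencies or not self.mg_values:
            raise ValueError("frequency and Mg grids must be non-empty")
        if list(self.frequencies) != sorted(self.frequencies) or list(self.mg_values) != sorted(self.mg_values):
            raise ValueError("grids must be sorted ascending")
        if not (0 <= self.window[0] < self.window[1] <= self.t_end):
            raise ValueError("analysis window must lie inside the simulation span")
        if self.baseline_mg not in self.mg_values:
            raise ValueError("baseline_mg must be one of mg_values")
        return self


class TimingExperiment(BaseModel):
    """Intervention-timing protocol: Mg2+ step at varying delays."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    delays: Tuple[Union[str, float], ...] = (
        PRETREAT, 0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.75, 1.0, 2.0, 3.0,
    )
    baseline_mg: float = Field(0.2, ge=0)
    treated_mg: float = Field(1.8, ge=0)
    stress_start: float = Field(500.0, ge=0, description="Stress onset (ms)")
    stress_end: float = Field(4500.0, gt=0, description="Stress end (ms)")
    t_end: float = Field(6000.0, gt=0)
    pulse_freq: float = Field(80.0, gt=0)
    pulse_width: float = Field(2.0, gt=0)
    pulse_amp: float = Field(1.0, ge=0)

    @model_validator(mode="after")
    def _validate(self) -> "TimingExperiment":
        if not (self.stress_start < self.stress_end <= self.t_end):
            raise ValueError("require stress_start < stress_end <= t_end")
        stress_s = (self.stress_end - self.stress_start) / 1000.0
        for d in self.delays:
            if d == PRETREAT:
                continue
            if not isinstance(d, (int, float)):
                raise ValueError(f"delay must be a number of seconds or {PRETREAT!r}: {d!r}")
            if not (0 <= d <= stress_s):
                raise ValueError(f"delay {d} s outside the stress duration")
        return self

    @property
    def window(self) -> Tuple[float, float]:
        """Analysis window: stress onset to stress end (ms)."""
        return (self.stress_start, self.stress_end)

    def stimulus_protocol(self, mg_schedule: Sequence[Tuple[float, float]]) -> StimulusProtocol:
        return StimulusProtocol(
            pulse_freq=self.pulse_freq,
            pulse_width=self.pulse_width,
            pulse_amp=self.pulse_amp,
            stim_start=self.stress_start,
            stim_end=self.stress_end,
            t_end=self.t_end,
            mg_schedule=tuple((float(t), float(mg)) for t, mg in mg_schedule),
        )

    def intervention_time(self, delay: Union[str, float]) -> float:
        """Absolute time (ms) at which the Mg2+ step occurs for a delay."""
        if delay == PRETREAT:
            return 0.0
        return self.stress_start + 1000.0 * float(delay)


@dataclass
class SweepSummary:
    """Dose-response results: per-cell metrics plus per-frequency windows."""

    table: pd.DataFrame
    windows: Dict[float, "analysis.TherapeuticWindow"]
    criteria: "analysis.TherapeuticCriteria"
    grid: SweepGrid


def simulate_protocol(
    protocol: StimulusProtocol,
    params: ModelParameters = None,
    kin: GatingKinetics = None,
    dt: float = 0.02,
    method: str = "euler",
    record: Tuple[str, ...] = ("V", "Ca", "sAMPA", "sNMDA"),
) -> Trace:
    """Run a single cell under a protocol from the resting state."""
    if params is None:
        params = ModelParameters()
    if kin is None:
        kin = default_kinetics()
    cfg = IntegrationConfig(t_end=protocol.t_end, dt=dt, method=method, record=record)
    return integrate(resting_state(params, kin), protocol, params, cfg, kin)


def run_frequency_row(
    freq: float,
    mg_values: Sequence[float],
    params: ModelParameters = None,
    kin: GatingKinetics = None,
    t_end: float = 3000.0,
    dt: float = 0.02,
    record: Tuple[str, ...] = ("V", "Ca", "sNMDA"),
) -> Trace:
    """Batched run of one stimulation frequency across a Mg2+ grid."""
    if params is None:
        params = ModelParameters()
    if kin is None:
        kin = default_kinetics()
    protocol = StimulusProtocol(pulse_freq=freq, stim_start=0.0, stim_end=t_end, t_end=t_end)
    stim = _BatchStimulus(protocol, [[(0.0, mg)] for mg in mg_values])
    cfg = IntegrationConfig(t_end=t_end, dt=dt, record=record)
    y0 = resting_state(params, kin, n_batch=len(mg_values))
    return integrate(y0, stim, params, cfg, kin)


def run_dose_response(
    grid: SweepGrid = None,
    params: ModelParameters = None,
    criteria: "analysis.TherapeuticCriteria" = None,
    kin: GatingKinetics = None,
    dt: float = 0.02,
    progress=None,
) -> SweepSummary:
    """Run the full (frequency x Mg2+) dose-response experiment.

    For every cell the summary reports spike metrics (against the expected
    pulse count), peak [Ca2+]i, and the reductions relative to the
    ``baseline_mg`` run at the same frequency; each frequency row is then
    classified into its therapeutic window under ``criteria``.

    ``progress``, if given, is called as ``progress(freq)`` after each
    frequency row completes.
    """
    if grid is None:
        grid = SweepGrid()
    if params is None:
        params = ModelParameters()
    if criteria is None:
        criteria = analysis.TherapeuticCriteria(baseline_mg=grid.baseline_mg)
    if kin is None:
        kin = default_kinetics()

    rows = []
    windows: Dict[float, analysis.TherapeuticWindow] = {}
    mg_values = list(grid.mg_values)
    base_idx = mg_values.index(grid.baseline_mg)

    for freq in grid.frequencies:
        trace = run_frequency_row(freq, mg_values, params, kin, t_end=grid.t_end, dt=dt)
        n_expected = expected_pulses(freq, grid.window)
        freq_rows = []
        for j, mg in enumerate(mg_values):
            cell = trace.cell(j)
            spikes = analysis.detect_spikes(cell, window=grid.window, n_expected=n_expected)
            peak_ca = analysis.peak_calcium(cell, grid.window)
            freq_rows.append(
                {
                    "frequency_hz": freq,
                    "mg_mM": mg,
                    "n_spikes": spikes.n_spikes,
                    "n_expected": n_expected,
                    "spike_prob": spikes.spike_probability,
                    "spike_loss_pct": spikes.spike_loss_pct,
                    "peak_ca_uM": peak_ca,
                }
            )
        base = freq_rows[base_idx]
        for r in freq_rows:
            if base["spike_prob"] > 0:
                r["spike_loss_vs_baseline_pct"] = 100.0 * (1.0 - r["spike_prob"] / base["spike_prob"])
            else:
                r["spike_loss_vs_baseline_pct"] = float("nan")
            r["ca_reduction_pct"] = 100.0 * (1.0 - r["peak_ca_uM"] / base["peak_ca_uM"])
        row_df = pd.DataFrame(freq_rows)
        window = analysis.find_window(row_df, criteria)
        windows[freq] = window
        row_df["in_window"] = [
            window.lower is not None and window.lower - 1e-9 <= mg <= window.upper + 1e-9
            for mg in row_df["mg_mM"]
        ]
        rows.append(row_df)
        if progress is not None:
            progress(freq)

    table = pd.concat(rows, ignore_index=True)
    return SweepSummary(table=table, windows=windows, criteria=criteria, grid=grid)


def run_timing_experiment(
    experiment: TimingExperiment = None,
    params: ModelParameters = None,
    kin: GatingKinetics = None,
    dt: float = 0.02,
) -> pd.DataFrame:
    """Run the intervention-timing protocol.

    Returns one row per delay with the peak [Ca2+]i over the stress window,
    the protection efficacy scored against the constant-baseline ("no Mg")
    and constant-treated ("pre-treated") reference runs, and the normalized
    Ca2+ progress of the untreated trace at the moment of intervention.
    """
    if experiment is None:
        experiment = TimingExperiment()
    if params is None:
        params = ModelParameters()
    if kin is None:
        kin = default_kinetics()

    schedules: List[List[Tuple[float, float]]] = [
        [(0.0, experiment.baseline_mg)],  # reference: no supplementation
        [(0.0, experiment.treated_mg)],  # reference: pre-treated
    ]
    for d in experiment.delays:
        if d == PRETREAT:
            schedules.append([(0.0, experiment.treated_mg)])
        else:
            schedules.append(
                [(0.0, experiment.baseline_mg), (experiment.intervention_time(d), experiment.treated_mg)]
            )

    protocol = experiment.stimulus_protocol([(0.0, experiment.baseline_mg)])
    stim = _BatchStimulus(protocol, schedules)
    cfg = IntegrationConfig(t_end=experiment.t_end, dt=dt, record=("V", "Ca"))
    y0 = resting_state(params, kin, n_batch=len(schedules))
    trace = integrate(y0, stim, params, cfg, kin)

    window = experiment.window
    untreated = trace.cell(0)
    peak_no_mg = analysis.peak_calcium(untreated, window)
    peak_pre = analysis.peak_calcium(trace.cell(1), window)

    rows = []
    for i, d in enumerate(experiment.delays):
        cell = trace.cell(i + 2)
        peak = analysis.peak_calcium(cell, window)
        efficacy = analysis.protection_efficacy(peak_no_mg, peak_pre, peak)
        t_int = experiment.intervention_time(d)
        progress_at_int = analysis.ca_progress(untreated, t_int, window=window)
        rows.append(
            {
                "delay": PRETREAT if d == PRETREAT else float(d),
                "delay_s": float("nan") if d == PRETREAT else float(d),
                "t_intervention_ms": t_int,
                "peak_ca_uM": peak,
                "efficacy_pct": efficacy,
                "ca_progress_at_intervention": progress_at_int,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["peak_ca_no_mg_uM"] = peak_no_mg
    df.attrs["peak_ca_pretreated_uM"] = peak_pre
    return df
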
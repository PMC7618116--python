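"""Intrinsic membrane properties and paired-pulse ratios from patch-clamp sweeps.

Current-clamp protocols yield the standard intrinsic-property panel:

* **RMP** — resting membrane potential, mean of a pre-stimulus baseline;
* **TC** — membrane time constant, single-exponential fit to the response
  to a small hyperpolarizing step;
* **IR** — input resistance, mean ΔV_ss/ΔI over five increasing 10 pA
  steps;
* **sag** — Ih sag on a 1 s pulse hyperpolarizing the cell toward
  −100 mV: mean voltage over the final 100 ms minus the pulse minimum;
* **APmax / MFF / fAHP** — action-potential peak, maximum firing frequency
  over increasing 100 pA steps, and threshold-to-AHP-minimum difference of
  the first spike at the rheobase-adjacent step;
* **capacitance** — TC/IR (ms/MΩ → nF, reported in pF), an exact identity.

Voltage-clamp paired-pulse sweeps (two stimuli 50 ms apart, ten sweeps)
give PPR = amplitude2/amplitude1, with recordings flagged for exclusion
when the averaged first amplitude is below 50 pA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class StepStimulus:
    """Rectangular current/voltage step."""

    onset: float  # s
    duration: float  # s
    amplitude: float  # pA (current clamp) or mV (voltage clamp)


@dataclass
class Sweep:
    """One uniformly sampled sweep.

    ``signal`` is mV (current clamp) or pA (voltage clamp).  ``stimulus``
    is a :class:`StepStimulus` for step protocols, or ``stim_times`` holds
    extracellular-stimulation times for evoked-response protocols.
    """

    time: np.ndarray  # s
    signal: np.ndarray
    sampling_rate: float  # Hz
    stimulus: StepStimulus | None = None
    stim_times: list[float] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal lengths differ")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be > 0")
        dt = np.diff(self.time)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("non-uniform sampling")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Signal samples with t0 <= t < t1."""
        sel = (self.time >= t0) & (self.time < t1)
        return self.signal[sel]


@dataclass
class APEvent:
    """One detected action potential."""

    threshold_voltage: float  # mV, at the dV/dt crossing
    threshold_time: float  # s
    peak_voltage: float  # mV
    peak_time: float  # s
    ahp_min_voltage: float  # mV, minimum within the AHP window after the peak


@dataclass
class IntrinsicProperties:
    """The intrinsic-property panel; fields are None when the protocol
    component needed to compute them was absent."""

    rmp: float | None = None  # mV
    tc: float | None = None  # ms
    ir: float | None = None  # MΩ
    sag: float | None = None  # mV
    ap_max: float | None = None  # mV
    mff: float | None = None  # Hz
    fahp: float | None = None  # mV
    capacitance: float | None = None  # pF


@dataclass
class PPRResult:
    """Paired-pulse ratio of averaged evoked amplitudes."""

    amp1: float  # pA
    amp2: float  # pA
    ppr: float
    excluded: bool
    n_sweeps_used: int


def detect_action_potentials(
    sweep: Sweep,
    dvdt_threshold: float = 20.0,  # mV/ms
    refractory: float = 2.0,  # ms
    ahp_window: float = 5.0,  # ms
    smooth_window: float = 0.1,  # ms, boxcar applied before differentiation
    min_spike_height: float = 20.0,  # mV above threshold voltage
) -> list[APEvent]:
    """Detect APs at upward dV/dt threshold crossings.

    An event starts where dV/dt first reaches ``dvdt_threshold`` (mV/ms);
    subsequent crossings within ``refractory`` ms are ignored.  The voltage
    is boxcar-smoothed over ``smooth_window`` ms before differentiation —
    at 50 kHz the raw sample-to-sample derivative of even sub-mV noise
    exceeds any physiological dV/dt criterion.  Candidate events whose
    peak rises less than ``min_spike_height`` mV above the threshold
    voltage are rejected as noise.  The threshold voltage is the voltage
    at the crossing sample, the peak is the maximum within 5 ms, and the
    AHP minimum is taken within ``ahp_window`` ms after the peak.
    """
    from scipy.ndimage import uniform_filter1d

    v = sweep.signal
    dt_ms = sweep.dt * 1e3
    n_smooth = max(1, int(round(smooth_window / dt_ms)))
    vs = uniform_filter1d(v, n_smooth) if n_smooth > 1 else v
    dvdt = np.diff(vs) / dt_ms
    above = dvdt >= dvdt_threshold
    crossings = np.flatnonzero(above & ~np.roll(above, 1))
    if above.size and above[0]:
        crossings = np.concatenate([[0], crossings[crossings != 0]])

    refr_n = max(1, int(round(refractory / dt_ms)))
    ahp_n = max(1, int(round(ahp_window / dt_ms)))
    events: list[APEvent] = []
    last = -np.inf
    for i in crossings:
        if i - last < refr_n:
            continue
        last = i
        stop = min(len(v), i + 1 + int(round(5.0 / dt_ms)))  # peak within 5 ms
        seg = v[i : stop]
        pk = int(np.argmax(seg))
        peak_idx = i + pk
        if v[peak_idx] < v[i] + min_spike_height:
            continue  # subthreshold fluctuation, not a spike
        ahp_seg = v[peak_idx + 1 : peak_idx + 1 + ahp_n]
        ahp_min = float(ahp_seg.min()) if ahp_seg.size else float(v[peak_idx])
        events.append(
            APEvent(
                threshold_voltage=float(v[i]),
                threshold_time=float(sweep.time[i]),
                peak_voltage=float(v[peak_idx]),
                peak_time=float(sweep.time[peak_idx]),
                ahp_min_voltage=ahp_min,
            )
        )
    return events


def _baseline(sweep: Sweep) -> float:
    if sweep.stimulus is None:
        return float(sweep.signal.mean())
    base = sweep.window(sweep.time[0], sweep.stimulus.onset)
    if base.size == 0:
        raise ValueError("no pre-stimulus baseline samples")
    return float(base.mean())


def fit_membrane_time_constant(sweep: Sweep) -> float:
    """Membrane time constant (ms) from a single-exponential fit.

    Fits ``V(t) = V_ss + A·exp(−(t−onset)/τ)`` over the window from step
    onset to 90% of the step duration, initialized by log-linear
    regression on the early decay.
    """
    if sweep.stimulus is None:
        raise ValueError("TC sweep needs a step stimulus descriptor")
    on, dur = sweep.stimulus.onset, sweep.stimulus.duration
    sel = (sweep.time >= on) & (sweep.time < on + 0.9 * dur)
    t = sweep.time[sel] - on
    v = sweep.signal[sel]
    if t.size < 10:
        raise ValueError("too few samples in the fit window")
    v_ss0 = float(v[int(0.8 * len(v)) :].mean())
    resid = v[: len(v) // 2] - v_ss0
    sign = np.sign(resid[np.argmax(np.abs(resid))]) or 1.0
    good = sign * resid > 1e-9
    if good.sum() >= 3:
        slope, intercept = np.polyfit(t[: len(resid)][good], np.log(sign * resid[good]), 1)
        tau0 = -1.0 / slope if slope < 0 else 0.1 * dur
        a0 = sign * np.exp(intercept)
    else:
        tau0, a0 = 0.1 * dur, float(v[0] - v_ss0)

    def model(t, v_ss, a, tau):
        return v_ss + a * np.exp(-t / tau)

    popt, _ = curve_fit(
        model, t, v, p0=[v_ss0, a0, max(tau0, 1e-4)], maxfev=10000
    )
    tau = float(popt[2])
    if not (tau > 0):
        raise RuntimeError("time-constant fit did not converge to τ > 0")
    return tau * 1e3  # s → ms


def input_resistance(sweeps: list[Sweep]) -> float:
    """Mean ΔV_ss/ΔI over a family of small current steps, in MΩ.

    The steady state is the mean over the last 20% of the step; ΔV is
    taken from each sweep's own pre-stimulus baseline, which makes the
    estimate invariant to any constant voltage offset.
    """
    rs = []
    for sw in sweeps:
        if sw.stimulus is None or sw.stimulus.amplitude == 0:
            raise ValueError("IR sweeps need non-zero step stimuli")
        on, dur = sw.stimulus.onset, sw.stimulus.duration
        v_ss = sw.window(on + 0.8 * dur, on + dur)
        if v_ss.size == 0:
            raise ValueError("empty steady-state window")
        dv = float(v_ss.mean()) - _baseline(sw)  # mV
        rs.append(1e3 * dv / sw.stimulus.amplitude)  # mV/pA = GΩ → MΩ
    return float(np.mean(rs))


def sag_amplitude(sweep: Sweep, tail: float = 0.1, smooth_window: float = 1.0) -> float:
    """Ih sag (mV): mean voltage over the final ``tail`` s of the pulse
    minus the minimum voltage during the pulse.

    The pulse minimum is taken on a boxcar-smoothed copy
    (``smooth_window`` ms) — the raw minimum over tens of thousands of
    samples is an extreme-value statistic that would report a spurious
    positive sag on any noisy recording.
    """
    from scipy.ndimage import uniform_filter1d

    if sweep.stimulus is None:
        raise ValueError("sag sweep needs a step stimulus descriptor")
    on, dur = sweep.stimulus.onset, sweep.stimulus.duration
    n_smooth = max(1, int(round(smooth_window * 1e-3 * sweep.sampling_rate)))
    smoothed = uniform_filter1d(sweep.signal, n_smooth)
    sel = (sweep.time >= on) & (sweep.time < on + dur)
    end_sel = (sweep.time >= on + dur - tail) & (sweep.time < on + dur)
    if not sel.any() or not end_sel.any():
        raise ValueError("empty sag windows")
    return float(smoothed[end_sel].mean() - smoothed[sel].min())


def compute_intrinsic_properties(
    sweeps: dict[str, Sweep | list[Sweep]],
    dvdt_threshold: float = 20.0,
    refractory: float = 2.0,
    ahp_window: float = 5.0,
) -> IntrinsicProperties:
    """Extract the intrinsic-property panel from a labeled protocol set.

    Expected keys (each optional; missing components leave their fields
    ``None``):

    - ``"rmp"`` — a baseline sweep (falls back to the TC sweep baseline);
    - ``"tc"`` — one small hyperpolarizing step sweep;
    - ``"ir"`` — five increasing 10 pA step sweeps;
    - ``"sag"`` — the 1 s pulse toward −100 mV;
    - ``"ff"`` — increasing 100 pA suprathreshold steps (firing).
    """
    props = IntrinsicProperties()

    rmp_sweep = sweeps.get("rmp") or sweeps.get("tc")
    if rmp_sweep is not None:
        sw = rmp_sweep if isinstance(rmp_sweep, Sweep) else rmp_sweep[0]
        props.rmp = float(sw.signal.mean()) if sw.stimulus is None else _baseline(sw)

    if "tc" in sweeps:
        props.tc = fit_membrane_time_constant(sweeps["tc"])
    if "ir" in sweeps:
        props.ir = input_resistance(list(sweeps["ir"]))
    if "sag" in sweeps:
        props.sag = sag_amplitude(sweeps["sag"])

    if "ff" in sweeps:
        ff = list(sweeps["ff"])
        peaks: list[float] = []
        mff = 0.0
        first_spiking: list[APEvent] | None = None
        for sw in ff:
            events = detect_action_potentials(sw, dvdt_threshold, refractory, ahp_window)
            if sw.stimulus is not None and sw.stimulus.duration > 0:
                mff = max(mff, len(events) / sw.stimulus.duration)
            peaks.extend(e.peak_voltage for e in events)
            if events and first_spiking is None:
                first_spiking = events
        if peaks:
            props.ap_max = float(max(peaks))
            props.mff = float(mff)
        if first_spiking:
            first = first_spiking[0]
            props.fahp = float(first.threshold_voltage - first.ahp_min_voltage)

    if props.tc is not None and props.ir is not None:
        props.capacitance = 1e3 * props.tc / props.ir  # ms/MΩ = nF → pF
    return props


def compute_ppr(
    sweeps: list[Sweep],
    stim_times: tuple[float, float] | None = None,
    baseline_window: float = 0.005,  # s before each stimulus
    peak_window: float = 0.02,  # s after each stimulus
    min_amp1: float = 50.0,  # pA exclusion threshold
    per_sweep_ratios: bool = False,
) -> PPRResult:
    """Paired-pulse ratio from evoked voltage-clamp sweeps.

    Per stimulus and sweep, the amplitude is the absolute extremal
    deviation within ``peak_window`` after the stimulus from the local
    pre-stimulus baseline.  Amplitudes are averaged across sweeps and
    PPR = amp2/amp1 (default); ``per_sweep_ratios`` averages per-sweep
    ratios instead.  The result is flagged ``excluded`` when the averaged
    first amplitude is below ``min_amp1`` pA (the ratio is still
    reported).
    """
    if not sweeps:
        raise ValueError("no sweeps")
    if stim_times is None:
        if not sweeps[0].stim_times:
            raise ValueError("no stimulus times given or embedded in sweeps")
        stim_times = tuple(sweeps[0].stim_times)  # type: ignore[assignment]
    if len(stim_times) != 2:
        raise ValueError("paired-pulse analysis needs exactly two stimulus times")

    amps = np.empty((len(sweeps), 2))
    for k, sw in enumerate(sweeps):
        t_end = float(sw.time[-1])
        for s, ts in enumerate(stim_times):
            if ts + peak_window > t_end + sw.dt:
                raise ValueError("peak window exceeds the trace")
            base = sw.window(ts - baseline_window, ts)
            if base.size == 0:
                raise ValueError("empty baseline window")
            seg = sw.window(ts, ts + peak_window)
            dev = seg - base.mean()
            amps[k, s] = np.abs(dev).max()

    amp1, amp2 = amps.mean(axis=0)
    ppr = float(np.mean(amps[:, 1] / amps[:, 0])) if per_sweep_ratios else float(amp2 / amp1)
    return PPRResult(
        amp1=float(amp1),
        amp2=float(amp2),
        ppr=ppr,
        excluded=bool(amp1 < min_amp1),
        n_sweeps_used=len(sweeps),
    )
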
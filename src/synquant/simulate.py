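"""Seeded synthetic-data generators with exact ground truth.

Every generator is a pure function of its parameters and a seed, and emits
data with the statistical structure the corresponding analysis stage
assumes:

* :func:`simulate_cell_image` — a soma (marker channel) decorated with
  presynaptic boutons placed as a Poisson process along its perimeter,
  a fraction of which carry a paired postsynaptic cluster just inside the
  boundary; spots are rendered as pixel-integrated Gaussians, blurred by a
  PSF and corrupted by Poisson + Gaussian noise.
* :func:`simulate_synaptosome_field` — plated pre/post puncta with a known
  paired fraction and a measurement channel whose per-pair intensity is
  drawn from a condition-dependent distribution.
* :func:`simulate_membrane_protocol` — closed-form RC responses, an
  optional slow sag conductance, and leaky-integrate-and-fire spiking with
  analytically known spike counts.
* :func:`simulate_ppr_sweeps` — double-exponential evoked EPSCs with a
  planted paired-pulse ratio.
* :func:`simulate_gene_table` — a gene table with a planted fraction of
  DEGs, a planted down-regulated proportion, and a reference list with a
  planted overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import erf

from synquant.ephys import StepStimulus, Sweep
from synquant.genes import GeneRecord
from synquant.image_io import CalibratedImage


# --------------------------------------------------------------------------
# rendering primitives
# --------------------------------------------------------------------------

def _integrated_gaussian_spot(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    sigma_px: float,
    peak: float,
    out: np.ndarray,
) -> None:
    """Add a pixel-integrated Gaussian spot (peak-normalized) to ``out``.

    Integrating the Gaussian over each pixel (via erf differences) keeps
    total flux — and hence detected area — independent of sub-pixel
    placement.
    """
    cy, cx = center_px
    r = int(math.ceil(4 * sigma_px)) + 1
    y0, y1 = max(0, int(cy) - r), min(shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(shape[1], int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    s = sigma_px * math.sqrt(2)
    ys = np.arange(y0, y1)
    xs = np.arange(x0, x1)
    fy = 0.5 * (erf((ys + 0.5 - cy) / s) - erf((ys - 0.5 - cy) / s))
    fx = 0.5 * (erf((xs + 0.5 - cx) / s) - erf((xs - 0.5 - cx) / s))
    f0 = 0.5 * (erf(0.5 / s) - erf(-0.5 / s))  # centered-pixel fraction
    out[y0:y1, x0:x1] += peak * np.outer(fy, fx) / f0**2


def _ellipse_mask(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    semi_axes_px: tuple[float, float],
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    a, b = semi_axes_px  # a along x, b along y
    return ((xx - center_px[1]) / a) ** 2 + ((yy - center_px[0]) / b) ** 2 <= 1.0


def ellipse_perimeter_um(a: float, b: float) -> float:
    """Ramanujan's approximation to the perimeter of an ellipse (μm)."""
    return math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))


def _apply_noise(
    plane: np.ndarray, gaussian_sd: float, rng: np.random.Generator
) -> np.ndarray:
    noisy = rng.poisson(np.clip(plane, 0, None)).astype(np.float64)
    noisy += rng.normal(0.0, gaussian_sd, size=plane.shape)
    return np.clip(noisy, 0, None)


# --------------------------------------------------------------------------
# decorated-cell images
# --------------------------------------------------------------------------

@dataclass
class ImageSimParams:
    """Conditions for :func:`simulate_cell_image`.

    Geometry is in μm.  Boutons sit just outside the soma boundary,
    paired clusters just inside, at sub-resolution tangential jitter, so
    planted structures satisfy the bouton/cluster/synapse rules by
    construction at the stated thresholds.
    """

    field_size: float = 40.0  # μm
    pixel_size: float = 0.1  # μm/px
    soma_semi_axes: tuple[float, float] = (8.0, 5.0)  # μm (x, y)
    bouton_density: float = 0.15  # per μm of perimeter
    pairing_fraction: float = 0.8
    #: hard-core exclusion between bouton centers along the perimeter (μm);
    #: boutons are extended objects, so centers closer than this would merge
    #: into a single punctum under any threshold-based detection
    min_bouton_separation: float = 0.9
    bouton_sigma_mean: float = 0.30  # μm, spot Gaussian sd
    bouton_sigma_sd: float = 0.04
    cluster_sigma_mean: float = 0.35
    cluster_sigma_sd: float = 0.04
    bouton_offset: float = 0.15  # μm outside the boundary
    cluster_offset: float = 0.15  # μm inside the boundary
    tangential_jitter: float = 0.10  # μm, uniform ±
    spot_peak: float = 160.0
    soma_level: float = 120.0
    background: float = 8.0
    psf_sigma: float = 0.10  # μm
    gaussian_noise_sd: float = 2.0
    #: thresholds a pipeline run should use on these images
    detection_threshold: float = 60.0
    roi_threshold: float = 60.0

    def __post_init__(self) -> None:
        if not (0 <= self.pairing_fraction <= 1):
            raise ValueError("pairing_fraction must be in [0, 1]")
        if self.bouton_density < 0:
            raise ValueError("bouton_density must be >= 0")
        a, b = self.soma_semi_axes
        if 2 * max(a, b) + 2 >= self.field_size:
            raise ValueError("soma does not fit in the field")


@dataclass
class CellGroundTruth:
    """What :func:`simulate_cell_image` actually planted."""

    soma_mask: np.ndarray
    perimeter_um: float  # analytic (Ramanujan) perimeter
    bouton_xy_um: np.ndarray  # (n, 2)
    cluster_xy_um: np.ndarray  # (m, 2)
    paired: np.ndarray  # bool per bouton
    n_boutons: int = 0
    n_synapses: int = 0
    bouton_density: float = 0.0  # realized, per μm
    synapse_density: float = 0.0  # realized, per μm


def simulate_cell_image(
    params: ImageSimParams, seed: int
) -> tuple[CalibratedImage, CellGroundTruth]:
    """Render one decorated cell: channels ``marker``, ``pre``, ``post``."""
    rng = np.random.default_rng(seed)
    px = params.pixel_size
    n = int(round(params.field_size / px))
    shape = (n, n)
    a, b = params.soma_semi_axes
    center = (params.field_size / 2, params.field_size / 2)  # (y, x) μm
    center_px = (center[0] / px, center[1] / px)

    soma_mask = _ellipse_mask(shape, center_px, (a / px, b / px))
    perim = ellipse_perimeter_um(a, b)

    # Poisson number of boutons; positions uniform by arc length with a
    # hard-core exclusion so planted puncta stay individually resolvable.
    n_boutons = rng.poisson(params.bouton_density * perim)
    theta_grid = np.linspace(0, 2 * math.pi, 4096)
    dx = -a * np.sin(theta_grid)
    dy = b * np.cos(theta_grid)
    arc = np.concatenate([[0], np.cumsum(np.hypot(dx, dy)[:-1] * np.diff(theta_grid))])
    total_arc = arc[-1]
    positions: list[float] = []
    min_sep = params.min_bouton_separation * total_arc / perim  # grid-arc units
    for _ in range(n_boutons):
        for _attempt in range(200):
            s = rng.uniform(0, total_arc)
            circ_d = [
                min(abs(s - q), total_arc - abs(s - q)) for q in positions
            ]
            if not circ_d or min(circ_d) >= min_sep:
                break
        positions.append(s)
    thetas = np.interp(np.array(positions), arc, theta_grid)

    # outward unit normal of the ellipse at parameter θ
    nx = np.cos(thetas) / a
    ny = np.sin(thetas) / b
    norm = np.hypot(nx, ny)
    nx, ny = nx / norm, ny / norm
    tx, ty = -ny, nx  # tangent
    bx = center[1] + a * np.cos(thetas)
    by = center[0] + b * np.sin(thetas)

    jit = rng.uniform(-params.tangential_jitter, params.tangential_jitter, n_boutons)
    bout_x = bx + params.bouton_offset * nx + jit * tx
    bout_y = by + params.bouton_offset * ny + jit * ty
    paired = rng.uniform(size=n_boutons) < params.pairing_fraction
    jit2 = rng.uniform(-params.tangential_jitter, params.tangential_jitter, n_boutons)
    clus_x = (bx - params.cluster_offset * nx + jit2 * tx)[paired]
    clus_y = (by - params.cluster_offset * ny + jit2 * ty)[paired]

    marker = np.full(shape, params.background, dtype=np.float64)
    marker[soma_mask] += params.soma_level
    pre = np.full(shape, params.background, dtype=np.float64)
    post = np.full(shape, params.background, dtype=np.float64)

    sig_b = np.clip(
        rng.normal(params.bouton_sigma_mean, params.bouton_sigma_sd, n_boutons), 0.1, None
    )
    sig_c = np.clip(
        rng.normal(params.cluster_sigma_mean, params.cluster_sigma_sd, int(paired.sum())),
        0.1,
        None,
    )
    for x, y, s in zip(bout_x, bout_y, sig_b):
        _integrated_gaussian_spot(shape, (y / px, x / px), s / px, params.spot_peak, pre)
    for x, y, s in zip(clus_x, clus_y, sig_c):
        _integrated_gaussian_spot(shape, (y / px, x / px), s / px, params.spot_peak, post)

    psf_px = params.psf_sigma / px
    planes = []
    for plane in (marker, pre, post):
        blurred = ndimage.gaussian_filter(plane, psf_px)
        planes.append(_apply_noise(blurred, params.gaussian_noise_sd, rng))

    img = CalibratedImage(
        pixels=np.stack(planes),
        pixel_size_xy=px,
        channel_names=["marker", "pre", "post"],
    )
    n_syn = int(paired.sum())
    truth = CellGroundTruth(
        soma_mask=soma_mask,
        perimeter_um=perim,
        bouton_xy_um=np.column_stack([bout_x, bout_y]),
        cluster_xy_um=np.column_stack([clus_x, clus_y]),
        paired=paired,
        n_boutons=n_boutons,
        n_synapses=n_syn,
        bouton_density=n_boutons / perim,
        synapse_density=n_syn / perim,
    )
    return img, truth


# --------------------------------------------------------------------------
# plated synaptosome fields
# --------------------------------------------------------------------------

@dataclass
class SynaptosomeSimParams:
    """Conditions for :func:`simulate_synaptosome_field`."""

    field_size: float = 40.0
    pixel_size: float = 0.1
    n_pre: int = 120
    paired_fraction: float = 0.7
    min_separation: float = 1.8  # μm between pre puncta
    pair_offset: float = 0.20  # μm pre→post center displacement
    pre_sigma: float = 0.28
    post_sigma: float = 0.28
    spot_peak: float = 160.0
    background: float = 8.0
    psf_sigma: float = 0.10
    gaussian_noise_sd: float = 2.0
    detection_threshold: float = 60.0
    #: per-pair measurement intensity ~ LogNormal(mean, sigma) of total flux
    measurement_log_mean: float = 7.0
    measurement_log_sd: float = 0.4


@dataclass
class SynaptosomeGroundTruth:
    pre_xy_um: np.ndarray
    post_xy_um: np.ndarray
    paired: np.ndarray  # bool per pre punctum
    pair_flux: np.ndarray  # measurement-channel total flux per pair
    paired_fraction: float = 0.0


def _poisson_disc(
    rng: np.random.Generator, n: int, low: float, high: float, min_sep: float
) -> np.ndarray:
    """Rejection-sample n points in [low, high]² at pairwise distance ≥ min_sep."""
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n and attempts < 200 * n:
        cand = rng.uniform(low, high, size=2)
        if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
            pts.append(cand)
        attempts += 1
    if len(pts) < n:
        raise RuntimeError("field too crowded for the requested punctum count")
    return np.array(pts)


def simulate_synaptosome_field(
    params: SynaptosomeSimParams, seed: int, condition: str = "control"
) -> tuple[CalibratedImage, SynaptosomeGroundTruth]:
    """Render a plated-synaptosome field: channels ``pre``, ``post``, ``meas``.

    ``condition="mutant"`` shifts the per-pair measurement intensity down
    by 40% (log-scale shift), emulating reduced ribosomal-protein
    phosphorylation in paired synaptosomes.
    """
    rng = np.random.default_rng(seed)
    px = params.pixel_size
    n = int(round(params.field_size / px))
    shape = (n, n)
    margin = 2.0
    pre_xy = _poisson_disc(
        rng, params.n_pre, margin, params.field_size - margin, params.min_separation
    )
    paired = rng.uniform(size=params.n_pre) < params.paired_fraction
    ang = rng.uniform(0, 2 * math.pi, size=params.n_pre)
    offset = np.column_stack([np.cos(ang), np.sin(ang)]) * params.pair_offset
    post_xy = (pre_xy + offset)[paired]

    log_mean = params.measurement_log_mean
    if condition == "mutant":
        log_mean += math.log(0.6)
    elif condition != "control":
        raise ValueError(f"unknown condition {condition!r}")
    flux = rng.lognormal(log_mean, params.measurement_log_sd, size=int(paired.sum()))

    pre = np.full(shape, params.background, dtype=np.float64)
    post = np.full(shape, params.background, dtype=np.float64)
    meas = np.full(shape, params.background, dtype=np.float64)
    for x, y in pre_xy:
        _integrated_gaussian_spot(shape, (y / px, x / px), params.pre_sigma / px, params.spot_peak, pre)
    for x, y in post_xy:
        _integrated_gaussian_spot(shape, (y / px, x / px), params.post_sigma / px, params.spot_peak, post)
    s = params.post_sigma / px
    f0 = (0.5 * (erf(0.5 / (s * math.sqrt(2))) - erf(-0.5 / (s * math.sqrt(2))))) ** 2
    for (x, y), fl in zip((pre_xy[paired] + post_xy) / 2, flux):
        # flux-parameterized: peak chosen so the spot integrates to ``fl``
        _integrated_gaussian_spot(shape, (y / px, x / px), s, fl * f0, meas)

    psf_px = params.psf_sigma / px
    planes = [
        _apply_noise(ndimage.gaussian_filter(p, psf_px), params.gaussian_noise_sd, rng)
        for p in (pre, post, meas)
    ]
    img = CalibratedImage(
        pixels=np.stack(planes), pixel_size_xy=px, channel_names=["pre", "post", "meas"]
    )
    truth = SynaptosomeGroundTruth(
        pre_xy_um=pre_xy,
        post_xy_um=post_xy,
        paired=paired,
        pair_flux=flux,
        paired_fraction=float(paired.mean()) if params.n_pre else 0.0,
    )
    return img, truth


# --------------------------------------------------------------------------
# membrane / spiking protocols
# --------------------------------------------------------------------------

@dataclass
class MembraneGroundTruth:
    r_mohm: float
    c_pf: float
    tau_ms: float
    rmp_mv: float
    spike_counts: list[int] = field(default_factory=list)
    ap_peak_mv: float = 30.0
    fahp_mv: float = 15.0
    v_threshold_mv: float = -40.0


def _rc_step(
    t: np.ndarray, onset: float, duration: float, dv_ss: float, tau: float, rmp: float
) -> np.ndarray:
    """Closed-form RC membrane response to a rectangular current step (mV)."""
    v = np.full_like(t, rmp)
    on = (t >= onset) & (t < onset + duration)
    v[on] = rmp + dv_ss * (1 - np.exp(-(t[on] - onset) / tau))
    off = t >= onset + duration
    v_end = rmp + dv_ss * (1 - math.exp(-duration / tau))
    v[off] = rmp + (v_end - rmp) * np.exp(-(t[off] - onset - duration) / tau)
    return v


def lif_spike_times(
    v_inf: float,
    v_start: float,
    v_reset: float,
    v_th: float,
    tau: float,
    duration: float,
    t_ref: float,
) -> list[float]:
    """Closed-form leaky-integrate-and-fire spike times within a step.

    The membrane charges from ``v_start`` (first interval) or ``v_reset``
    (after each spike + refractory period) toward ``v_inf``; a spike fires
    when it reaches ``v_th``, so the steady inter-spike interval is
    ``t_ref + τ·ln((V∞−V_reset)/(V∞−V_th))``.
    """
    if v_inf <= v_th:
        return []
    t = tau * math.log((v_inf - v_start) / (v_inf - v_th))
    isi = t_ref + tau * math.log((v_inf - v_reset) / (v_inf - v_th))
    times = []
    while t <= duration:
        times.append(t)
        t += isi
    return times


def simulate_membrane_protocol(
    r_mohm: float = 150.0,
    c_pf: float = 80.0,
    rmp_mv: float = -65.0,
    sag_amplitude_mv: float = 0.0,
    sag_tau_s: float = 0.15,
    noise_sd_mv: float = 0.2,
    seed: int = 0,
    sampling_rate: float = 50_000.0,
) -> tuple[dict[str, Sweep | list[Sweep]], MembraneGroundTruth]:
    """Generate the labeled current-clamp protocol set for one model cell.

    The passive membrane is an RC circuit (τ = R·C); ``sag_amplitude_mv``
    adds a slow depolarizing relaxation on the −100 mV pulse emulating Ih.
    Depolarizing 100 pA steps drive a leaky-integrate-and-fire mechanism
    with stereotyped action-potential waveforms, so per-step spike counts,
    AP peak and fAHP are known exactly.
    """
    rng = np.random.default_rng(seed)
    tau_s = r_mohm * 1e6 * c_pf * 1e-12  # s
    tau_ms = tau_s * 1e3

    def noisy(v: np.ndarray) -> np.ndarray:
        return v + rng.normal(0, noise_sd_mv, v.shape) if noise_sd_mv > 0 else v

    def times(total: float) -> np.ndarray:
        return np.arange(0, total, 1.0 / sampling_rate)

    sweeps: dict[str, Sweep | list[Sweep]] = {}

    t = times(0.3)
    sweeps["rmp"] = Sweep(t, noisy(np.full_like(t, rmp_mv)), sampling_rate, label="rmp")

    # TC: current step sized for a 10 mV hyperpolarization
    i_tc = -10.0 / (r_mohm * 1e-3)  # pA
    t = times(0.7)
    stim = StepStimulus(onset=0.1, duration=0.5, amplitude=i_tc)
    v = _rc_step(t, stim.onset, stim.duration, -10.0, tau_s, rmp_mv)
    sweeps["tc"] = Sweep(t, noisy(v), sampling_rate, stimulus=stim, label="tc")

    # IR: five increasing 10 pA (hyperpolarizing) steps
    ir_sweeps = []
    for k in range(1, 6):
        amp = -10.0 * k
        dv = amp * r_mohm * 1e-3
        stim = StepStimulus(onset=0.1, duration=0.5, amplitude=amp)
        t = times(0.7)
        v = _rc_step(t, stim.onset, stim.duration, dv, tau_s, rmp_mv)
        ir_sweeps.append(Sweep(t, noisy(v), sampling_rate, stimulus=stim, label=f"ir{k}"))
    sweeps["ir"] = ir_sweeps

    # sag: 1 s pulse targeting −100 mV
    dv_sag = -100.0 - rmp_mv
    stim = StepStimulus(onset=0.1, duration=1.0, amplitude=dv_sag / (r_mohm * 1e-3))
    t = times(1.3)
    v = _rc_step(t, stim.onset, stim.duration, dv_sag, tau_s, rmp_mv)
    if sag_amplitude_mv:
        on = (t >= stim.onset) & (t < stim.onset + stim.duration)
        v[on] += sag_amplitude_mv * (1 - np.exp(-(t[on] - stim.onset) / sag_tau_s))
    sweeps["sag"] = Sweep(t, noisy(v), sampling_rate, stimulus=stim, label="sag")

    # firing: increasing 100 pA steps with LIF spiking
    truth = MembraneGroundTruth(r_mohm=r_mohm, c_pf=c_pf, tau_ms=tau_ms, rmp_mv=rmp_mv)
    v_th, ap_peak, fahp = truth.v_threshold_mv, truth.ap_peak_mv, truth.fahp_mv
    v_reset = v_th - fahp  # post-spike reset doubles as the AHP minimum
    t_ref = 0.002
    ff_sweeps = []
    for k in range(1, 6):
        amp = 100.0 * k
        stim = StepStimulus(onset=0.1, duration=0.5, amplitude=amp)
        t = times(0.7)
        v_inf = rmp_mv + amp * r_mohm * 1e-3
        st = lif_spike_times(v_inf, rmp_mv, v_reset, v_th, tau_s, stim.duration, t_ref)
        v = _rc_step(t, stim.onset, stim.duration, v_inf - rmp_mv, tau_s, rmp_mv)
        # overwrite the subthreshold trajectory piecewise between resets
        on = stim.onset
        for ts in st:
            t_spk = on + ts
            seg = (t >= t_spk) & (t < on + stim.duration)
            v[seg] = v_inf + (v_reset - v_inf) * np.exp(-(t[seg] - t_spk - t_ref) / tau_s)
            # stereotyped AP: 0.5 ms linear rise to peak, 0.5 ms fall to AHP min
            rise = (t >= t_spk) & (t < t_spk + 0.0005)
            fall = (t >= t_spk + 0.0005) & (t < t_spk + 0.001)
            refr = (t >= t_spk + 0.001) & (t < t_spk + t_ref)
            v[rise] = v_th + (ap_peak - v_th) * (t[rise] - t_spk) / 0.0005
            v[fall] = ap_peak + (v_reset - ap_peak) * (t[fall] - t_spk - 0.0005) / 0.0005
            v[refr] = v_reset
        # keep the trace continuous at stimulus offset: decay from the
        # voltage actually reached, not from the spike-free RC endpoint
        off = t >= on + stim.duration
        if off.any() and st:
            i_end = int(np.searchsorted(t, on + stim.duration))
            v_last = v[i_end - 1]
            v[off] = rmp_mv + (v_last - rmp_mv) * np.exp(
                -(t[off] - on - stim.duration) / tau_s
            )
        ff_sweeps.append(Sweep(t, noisy(v), sampling_rate, stimulus=stim, label=f"ff{k}"))
        truth.spike_counts.append(len(st))
    sweeps["ff"] = ff_sweeps
    return sweeps, truth


def simulate_ppr_sweeps(
    amp1: float = 150.0,  # pA
    true_ppr: float = 0.8,
    tau_rise_ms: float = 0.5,
    tau_decay_ms: float = 4.0,
    n_sweeps: int = 10,
    isi_s: float = 0.05,
    noise_sd_pa: float = 2.0,
    seed: int = 0,
    sampling_rate: float = 50_000.0,
) -> list[Sweep]:
    """Simulate paired evoked EPSC sweeps with a planted PPR.

    Each sweep holds two inward (negative) double-exponential EPSCs with
    peak amplitudes ``amp1`` and ``amp1·true_ppr``, stimuli ``isi_s``
    apart, plus Gaussian current noise.  Stimulus times are embedded in
    each sweep.
    """
    tr, td = tau_rise_ms * 1e-3, tau_decay_ms * 1e-3
    if not td > tr:
        raise ValueError("tau_decay must exceed tau_rise")
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    norm = math.exp(-t_peak / td) - math.exp(-t_peak / tr)

    def epsc(t: np.ndarray, t0: float, amp: float) -> np.ndarray:
        dt = np.clip(t - t0, 0, None)
        return -amp / norm * (np.exp(-dt / td) - np.exp(-dt / tr)) * (t >= t0)

    rng = np.random.default_rng(seed)
    t = np.arange(0, 0.1 + isi_s + 0.15, 1.0 / sampling_rate)
    t1, t2 = 0.1, 0.1 + isi_s
    clean = epsc(t, t1, amp1) + epsc(t, t2, amp1 * true_ppr)
    sweeps = []
    for k in range(n_sweeps):
        noise = rng.normal(0, noise_sd_pa, t.shape) if noise_sd_pa > 0 else 0.0
        sweeps.append(
            Sweep(t, clean + noise, sampling_rate, stim_times=[t1, t2], label=f"ppr{k}")
        )
    return sweeps


# --------------------------------------------------------------------------
# gene tables
# --------------------------------------------------------------------------

@dataclass
class GeneTableTruth:
    de_ids: set[str]
    down_ids: set[str]
    up_ids: set[str]
    reference_ids: set[str]
    planted_overlap: int
    frac_down_among_de: float


def simulate_gene_table(
    n_genes: int = 12_000,
    frac_de: float = 0.04,
    frac_down_among_de: float = 0.7,
    fc_scale: float = 0.8,
    reference_size: int = 200,
    planted_reference_overlap: int = 15,
    seed: int = 0,
) -> tuple[list[GeneRecord], GeneTableTruth]:
    """Simulate a differential-expression gene table with planted truth.

    DEGs receive fold changes of 1.5 + Exp(``fc_scale``) and strong
    p-values; null genes get fold changes near 1 and uniform p-values, so
    at the nominal thresholds (p ≤ 0.05, FC ≥ 1.5) essentially only the
    planted DEGs qualify.  A reference gene list of ``reference_size``
    genes is planted to overlap the down-regulated set by exactly
    ``planted_reference_overlap`` genes (capped by the realized set
    sizes).
    """
    rng = np.random.default_rng(seed)
    n_de = int(round(n_genes * frac_de))
    ids = [f"g{i:05d}" for i in range(n_genes)]
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_idx] = True

    down = rng.uniform(size=n_genes) < frac_down_among_de
    fc = np.exp(np.abs(rng.normal(0, 0.1, n_genes)))  # null genes: FC near 1
    fc[is_de] = 1.5 + rng.exponential(fc_scale, n_de)
    p = rng.uniform(0, 1, n_genes)
    p[is_de] = 10.0 ** rng.uniform(-8, -2, n_de)
    rpkm = rng.lognormal(math.log(20), 1.2, n_genes)

    genes = [
        GeneRecord(
            gene_id=ids[i],
            fold_change=float(fc[i]),
            p_value=float(p[i]),
            direction="down" if down[i] else "up",
            rpkm=float(rpkm[i]),
        )
        for i in range(n_genes)
    ]

    down_ids = {ids[i] for i in range(n_genes) if is_de[i] and down[i]}
    up_ids = {ids[i] for i in range(n_genes) if is_de[i] and not down[i]}
    non_de_ids = [ids[i] for i in range(n_genes) if not is_de[i]]
    k = min(planted_reference_overlap, len(down_ids), reference_size)
    ref = set(rng.choice(sorted(down_ids), size=k, replace=False)) if k else set()
    ref |= set(rng.choice(non_de_ids, size=reference_size - k, replace=False))

    truth = GeneTableTruth(
        de_ids=down_ids | up_ids,
        down_ids=down_ids,
        up_ids=up_ids,
        reference_ids=ref,
        planted_overlap=k,
        frac_down_among_de=frac_down_among_de,
    )
    return genes, truth
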
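"""Two-channel neuro-kinematic swimming simulator.

The fish backbone is divided into 10 segments, each with a left and a right
motor channel.  Swimming is driven by a train of sharp pulses: during half
cycle h the active side (sides alternate every half cycle) fires segment j
at time τ_f[h] + j·d with amplitude a[h], where d is the segment-to-segment
delay that propagates the wave from head to tail.  Each channel's pulse
train is convolved with a bi-exponential neuromuscular-junction response,
yielding the muscle force F_m(s_j, t_i) per side.  The net force bends the
body against a stiffness profile W(s_j): the local curvature is
κ = (F_m^R − F_m^L) / W, and integrating κ along arc length gives the
head-referenced spine angles Δθ(s_j, t_i) in the same format the video
pipeline produces.

A scoot is produced by equal amplitudes on the two channels; a turn by
boosting the first half-cycle amplitude on one side and increasing d.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .spine import InvalidInputError, SpineAngleMatrix

N_SEGMENTS = 10  # neurons per side; segment 0 is the head reference
DS = 1.0 / (N_SEGMENTS - 1)  # normalized arc length per segment


class ResolutionWarningError(ValueError):
    """dt too coarse to resolve the segment-to-segment delay."""


@dataclass
class StiffnessProfile:
    """Body stiffness W(s_j) for the 9 non-head segments, head value 1.

    The default profile decreases monotonically from head to tail and
    recovers over the last tail segment, making the tail the most
    compliant part of the body (compliance = 1/W).
    """

    W: np.ndarray = field(
        default_factory=lambda: np.concatenate(
            [np.linspace(1.0, 0.53, 8), [0.61]]
        )
    )

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (N_SEGMENTS - 1,):
            raise InvalidInputError(f"W must have {N_SEGMENTS - 1} values")
        if np.any(self.W <= 0):
            raise InvalidInputError("W must be positive")


@dataclass
class NeuroParams:
    """Spike-train parameters of one bout.

    ``tau_f_ms[h]`` is the head-segment firing time of half cycle h and
    ``a[h]`` its spike amplitude; half cycles alternate sides starting
    with ``start_side``.  ``d_ms`` is the segment-to-segment delay.  Each
    segment fires a short burst of ``burst_ms`` worth of dt-wide spikes of
    height a (motoneurons burst rather than emit a lone spike); a burst
    covering most of the half period suppresses the odd harmonics of the
    alternating drive, which keeps the muscle-force wave near-sinusoidal.
    ``burst_ms = 0`` reduces to a single spike per half cycle.
    """

    tau_f_ms: np.ndarray
    a: np.ndarray
    d_ms: float | np.ndarray
    n_c: int
    tau_rise_ms: float = 3.0
    tau_decay_ms: float = 8.5
    burst_ms: float = 12.0
    start_side: str = "left"

    def __post_init__(self) -> None:
        self.tau_f_ms = np.asarray(self.tau_f_ms, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if not (2 <= self.n_c <= 16):
            raise InvalidInputError("n_c must be in 2..16")
        if self.tau_f_ms.shape != (self.n_c,) or self.a.shape != (self.n_c,):
            raise InvalidInputError("tau_f_ms and a must have n_c entries")
        if np.any(self.a < 0):
            raise InvalidInputError("amplitudes must be non-negative")
        # d may be a single value or one value per half cycle (a turn uses a
        # larger delay during its first cycle only)
        self.d_ms = np.broadcast_to(
            np.asarray(self.d_ms, dtype=float), (self.n_c,)
        ).copy()
        if np.any(self.d_ms < 0):
            raise InvalidInputError("delay must be non-negative")
        if not self.tau_rise_ms < self.tau_decay_ms:
            raise InvalidInputError("need tau_rise < tau_decay")
        if self.start_side not in ("left", "right"):
            raise InvalidInputError("start_side must be 'left' or 'right'")
        # firing times must be strictly increasing on each side separately
        for phase in (0, 1):
            tf = self.tau_f_ms[phase::2]
            if tf.size > 1 and np.any(np.diff(tf) <= 0):
                raise InvalidInputError("tau_f must increase per side")

    @property
    def sides(self) -> list[str]:
        """Active side of each half cycle."""
        other = "right" if self.start_side == "left" else "left"
        return [self.start_side if h % 2 == 0 else other for h in range(self.n_c)]

    @property
    def d_first_ms(self) -> float:
        """Segment-to-segment delay of the first half cycle."""
        return float(self.d_ms[0])

    def mirrored(self) -> "NeuroParams":
        """Swap the left and right channels."""
        return replace(
            self,
            tau_f_ms=self.tau_f_ms.copy(),
            a=self.a.copy(),
            d_ms=self.d_ms.copy(),
            start_side="right" if self.start_side == "left" else "left",
        )


@dataclass
class SimulatedDrive:
    """Intermediate fields of one simulated bout."""

    time_ms: np.ndarray
    F_osc: dict[str, np.ndarray]  # side -> (N_SEGMENTS, T) pulse trains
    F_m: dict[str, np.ndarray]  # side -> (N_SEGMENTS, T) muscle force
    curvature: np.ndarray | None = None  # (N_SEGMENTS-1, T)


@dataclass
class NoiseConfig:
    """White-Gaussian parameter noise, scaled as σ = mean(|x|) / snr."""

    snr_a: float = np.inf
    snr_tau_f: float = np.inf
    snr_d: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.snr_a, self.snr_tau_f, self.snr_d) <= 0:
            raise InvalidInputError("snr must be positive")


def generate_spike_train(
    p: NeuroParams, dt_ms: float = 2.0, duration_ms: float | None = None
) -> SimulatedDrive:
    """Build per-side, per-segment spike trains F_osc(s_j, t_i).

    Segment j of the active side fires once per half cycle, starting at
    τ_f[h] + j·d[h], as a burst of dt-wide spikes of height a[h] covering
    ``burst_ms`` (a single spike when burst_ms <= dt).
    """
    d_pos = p.d_ms[p.d_ms > 0]
    if d_pos.size and dt_ms > d_pos.min():
        raise ResolutionWarningError(
            f"dt={dt_ms} ms cannot resolve segment delay d={d_pos.min()} ms"
        )
    last = float(np.max(p.tau_f_ms + (N_SEGMENTS - 1) * p.d_ms))
    if duration_ms is None:
        duration_ms = last + 5 * p.tau_decay_ms
    if duration_ms < last:
        raise InvalidInputError("duration does not cover the last spike")
    t = np.arange(0.0, duration_ms + 0.5 * dt_ms, dt_ms)
    F = {s: np.zeros((N_SEGMENTS, t.size)) for s in ("left", "right")}
    n_spikes = max(1, int(round(p.burst_ms / dt_ms)))
    for h, side in enumerate(p.sides):
        for j in range(N_SEGMENTS):
            idx = int(round((p.tau_f_ms[h] + j * p.d_ms[h]) / dt_ms))
            for k in range(n_spikes):
                if 0 <= idx + k < t.size:
                    F[side][j, idx + k] += p.a[h]
    return SimulatedDrive(time_ms=t, F_osc=F, F_m={})


def biexp_kernel(
    tau_rise_ms: float, tau_decay_ms: float, dt_ms: float
) -> np.ndarray:
    """Peak-normalized bi-exponential kernel e^{-t/τd} − e^{-t/τr}."""
    if tau_rise_ms <= 0 or tau_decay_ms <= 0:
        raise InvalidInputError("time constants must be positive")
    if not tau_rise_ms < tau_decay_ms:
        raise InvalidInputError("need tau_rise < tau_decay")
    t_peak = (
        tau_rise_ms
        * tau_decay_ms
        / (tau_decay_ms - tau_rise_ms)
        * np.log(tau_decay_ms / tau_rise_ms)
    )
    peak = np.exp(-t_peak / tau_decay_ms) - np.exp(-t_peak / tau_rise_ms)
    t = np.arange(0.0, 8.0 * tau_decay_ms, dt_ms)
    k = (np.exp(-t / tau_decay_ms) - np.exp(-t / tau_rise_ms)) / peak
    return k


def neuromuscular_filter(
    drive: SimulatedDrive, tau_rise_ms: float, tau_decay_ms: float, dt_ms: float
) -> SimulatedDrive:
    """Convolve each channel with the neuromuscular-junction response."""
    k = biexp_kernel(tau_rise_ms, tau_decay_ms, dt_ms)
    T = drive.time_ms.size
    for side, F in drive.F_osc.items():
        Fm = fftconvolve(F, k[None, :], axes=1)[:, :T]
        drive.F_m[side] = np.maximum(Fm, 0.0)  # clip fft round-off
    return drive


def force_to_angles(
    drive: SimulatedDrive, stiffness: StiffnessProfile, ds: float = DS
) -> SpineAngleMatrix:
    """Net muscle force -> curvature -> head-referenced spine angles.

    Curvature per non-head segment is κ(s_j) = (F_m^R − F_m^L) / W(s_j);
    Δθ(s_j) is the running arc-length integral of κ, with Δθ(s_0) = 0.
    Right-side force bends toward positive Δθ; that choice is a convention,
    and what is pinned down is exact antisymmetry under left/right exchange.
    """
    F_net = drive.F_m["right"] - drive.F_m["left"]  # (N_SEGMENTS, T)
    kappa = F_net[1:, :] / stiffness.W[:, None]  # non-head segments
    drive.curvature = kappa
    dtheta_body = np.cumsum(kappa * ds, axis=0)  # (N_SEGMENTS-1, T)
    dtheta = np.vstack([np.zeros(dtheta_body.shape[1]), dtheta_body]).T
    return SpineAngleMatrix(dtheta=dtheta, time_ms=drive.time_ms.copy())


def simulate_bout(
    p: NeuroParams,
    stiffness: StiffnessProfile | None = None,
    dt_ms: float = 2.0,
    duration_ms: float | None = None,
    bout_id: str = "sim",
) -> SpineAngleMatrix:
    """Full simulator chain: spike train -> muscle force -> spine angles."""
    stiffness = stiffness or StiffnessProfile()
    drive = generate_spike_train(p, dt_ms=dt_ms, duration_ms=duration_ms)
    drive = neuromuscular_filter(drive, p.tau_rise_ms, p.tau_decay_ms, dt_ms)
    spine = force_to_angles(drive, stiffness)
    spine.bout_id = bout_id
    return spine


def perturb_params(p: NeuroParams, noise: NoiseConfig) -> NeuroParams:
    """Add white Gaussian noise to a, τ_f and d at the configured SNRs.

    Each targeted value x becomes x + σ·z with σ = mean(|x|)/snr.  Firing
    times are re-sorted per side if the noise violates their ordering, and
    amplitudes are clipped at zero to respect their sign constraint.
    """
    rng = np.random.default_rng(noise.seed)
    a = p.a.copy()
    tau_f = p.tau_f_ms.copy()
    d = p.d_ms.copy()
    if np.isfinite(noise.snr_a):
        sigma = np.mean(np.abs(a)) / noise.snr_a
        a = np.maximum(a + sigma * rng.standard_normal(a.shape), 0.0)
    if np.isfinite(noise.snr_tau_f):
        sigma = np.mean(np.abs(tau_f)) / noise.snr_tau_f
        tau_f = tau_f + sigma * rng.standard_normal(tau_f.shape)
        for phase in (0, 1):
            tau_f[phase::2] = np.sort(tau_f[phase::2])
    if np.isfinite(noise.snr_d):
        sigma = np.mean(np.abs(d)) / noise.snr_d
        d = np.maximum(d + sigma * rng.standard_normal(d.shape), 0.0)
    return replace(p, tau_f_ms=tau_f, a=a, d_ms=d)


class DestabilizedBoutError(RuntimeError):
    """Noise destroyed the cyclic structure of the bout."""


def noise_response(
    reference: SpineAngleMatrix,
    noisy: SpineAngleMatrix,
    basis,
    fit_residual_sq: float = 0.0,
    grid_points: int = 50,
) -> float:
    """Behavioral-space response of the model to parameter noise.

    Both bouts are projected onto the given eigenshape basis, their first
    oscillation cycles time-normalized onto a common grid, and the
    singular-value-weighted squared trajectory distance between them is
    returned, minus the (model-vs-data) fit residual squared distance when
    one is supplied.
    """
    from .behavior import pairwise_distance
    from .eigenshape import project
    from .trajectory import detect_cycles, extract_cycle_segments

    segs = []
    for spine, tag in ((reference, "ref"), (noisy, "noisy")):
        traj = project(spine, basis, k_max=3)
        ann = detect_cycles(traj)
        if not ann.cycle_bounds_ms:
            raise DestabilizedBoutError(f"{tag} bout has no detectable cycles")
        seg = extract_cycle_segments(traj, ann, grid_points=grid_points)[0]
        segs.append(seg)
    dm = pairwise_distance(segs, basis.S[:3])
    return float(dm.d[0, 1] ** 2 - fit_residual_sq)
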
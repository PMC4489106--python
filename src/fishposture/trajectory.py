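"""Cycle segmentation and time/handedness normalization of postural trajectories.

A swim bout appears in postural space as a few oscillation cycles of the
leading amplitude U_1 before decaying to rest.  Cycles are delimited by
alternate zero crossings of (smoothed) U_1: cycle 1 runs from the first to
the third crossing, cycle 2 from the third to the fifth, and so on.  To
compare cycles across bouts and fish, each cycle is resampled onto a fixed
normalized-time grid, and the left/right handedness of the bout is removed
by a sign convention so that a turn and its mirror image become identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .eigenshape import EigenshapeBasis, PosturalTrajectory, project, render_real_space
from .spine import InvalidInputError, SpineAngleMatrix


@dataclass
class BoutAnnotation:
    """Cycle boundaries and rest onset of one bout."""

    cycle_bounds_ms: list[tuple[float, float]]
    rest_onset_ms: float
    handedness: int = +1  # +1 kept, -1 mirrored during normalization

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_bounds_ms)


@dataclass
class CycleSegment:
    """One oscillation cycle resampled onto the normalized-time grid.

    ``U`` has shape (K, T): K mode amplitudes at T grid points spanning the
    cycle.  ``duration_ms`` is the raw cycle duration; ``scaled_duration``
    is duration divided by the bout's cycle-1 duration.
    """

    U: np.ndarray
    cycle_index: int
    duration_ms: float
    scaled_duration: float = 1.0
    bout_id: str = "bout"
    fish_id: str = "fish"
    age_group: str = "A"
    handedness: int = +1

    @property
    def grid_points(self) -> int:
        return self.U.shape[1]


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    if window % 2 == 0:
        window += 1  # symmetric window: no phase shift of the crossings
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad : pad + x.size]


def _zero_crossings(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Linearly interpolated times where x changes sign."""
    s = np.sign(x)
    # treat exact zeros as belonging to the previous sign run
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    tc = t[idx] - x[idx] * (t[idx + 1] - t[idx]) / (x[idx + 1] - x[idx])
    return tc


def detect_cycles(
    traj: PosturalTrajectory,
    smooth_ms: float = 4.0,
    rest_fraction: float = 0.1,
    rest_hold_ms: float = 20.0,
    lobe_fraction: float = 0.1,
) -> BoutAnnotation:
    """Delimit oscillation cycles by alternate zero crossings of U_1.

    U_1 is smoothed with a ``smooth_ms`` moving average before crossing
    detection (suppresses pixel-noise crossings at 500 fps), and a
    crossing counts only if an adjacent lobe of U_1 reaches at least
    ``lobe_fraction`` of the bout's peak |U_1| (suppresses crossings of
    the numerically tiny pre-bout and post-bout tails).  The rest onset is
    the first time after the last cycle at which every amplitude stays
    below ``rest_fraction`` of its bout maximum for ``rest_hold_ms``.
    """
    t = traj.time_ms
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    window = max(1, int(round(smooth_ms / dt)))
    u1 = _smooth(traj.U[:, 0], window)
    peak = np.max(np.abs(traj.U)) if traj.U.size else 0.0
    if peak == 0.0:
        return BoutAnnotation(cycle_bounds_ms=[], rest_onset_ms=float(t[0]))
    crossings = _zero_crossings(t, u1)
    # no cycle can begin before the trajectory actually moves: discard
    # crossings of the numerically tiny pre-activity baseline
    active = np.abs(u1) >= 0.02 * np.max(np.abs(u1))
    t_active = float(t[np.argmax(active)]) if active.any() else float(t[-1])
    crossings = crossings[crossings >= t_active]
    # keep crossings with a significant lobe on at least one side
    thr = lobe_fraction * np.max(np.abs(u1))
    lobe_edges = np.concatenate([[t[0]], crossings, [t[-1]]])
    lobe_peak = np.array(
        [
            np.max(np.abs(u1[(t >= a) & (t <= b)]), initial=0.0)
            for a, b in zip(lobe_edges[:-1], lobe_edges[1:])
        ]
    )
    crossings = np.array(
        [
            c
            for i, c in enumerate(crossings)
            if lobe_peak[i] >= thr or lobe_peak[i + 1] >= thr
        ]
    )
    bounds = [
        (float(crossings[i]), float(crossings[i + 2]))
        for i in range(0, crossings.size - 2, 2)
    ]
    # rest onset: all |U_k| below threshold sustained for rest_hold_ms
    start = bounds[-1][1] if bounds else float(t[0])
    envelope = np.max(np.abs(traj.U), axis=1)
    below = envelope < rest_fraction * peak
    hold = max(1, int(round(rest_hold_ms / dt)))
    rest_onset = float(t[-1])
    i0 = int(np.searchsorted(t, start))
    for i in range(i0, t.size):
        j = min(i + hold, t.size)
        if np.all(below[i:j]) and (j - i >= hold or j == t.size):
            rest_onset = float(t[i])
            break
    return BoutAnnotation(cycle_bounds_ms=bounds, rest_onset_ms=rest_onset)


def _resample_segment(
    t: np.ndarray, U: np.ndarray, t0: float, t1: float, grid_points: int
) -> np.ndarray:
    """Linear resampling of (m, K) amplitudes onto grid_points in [t0, t1]."""
    if t1 <= t0:
        raise InvalidInputError("zero-duration cycle")
    tg = np.linspace(t0, t1, grid_points)
    return np.vstack([np.interp(tg, t, U[:, k]) for k in range(U.shape[1])])


def extract_cycle_segments(
    traj: PosturalTrajectory,
    annotation: BoutAnnotation,
    grid_points: int = 50,
    bout_id: str | None = None,
    fish_id: str = "fish",
    age_group: str = "A",
) -> list[CycleSegment]:
    """Cut a bout into cycle segments on the normalized-time grid.

    Each cycle's time axis is shifted to start at zero, scaled by the
    bout's cycle-1 duration, and linearly resampled to ``grid_points``
    points spanning the cycle.  A bout with no detected cycles yields a
    single all-zero "rest" segment (cycle_index 0) so that resting
    behavior remains represented downstream.
    """
    bout_id = bout_id or traj.bout_id
    K = traj.n_modes
    if not annotation.cycle_bounds_ms:
        return [
            CycleSegment(
                U=np.zeros((K, grid_points)),
                cycle_index=0,
                duration_ms=0.0,
                scaled_duration=0.0,
                bout_id=bout_id,
                fish_id=fish_id,
                age_group=age_group,
            )
        ]
    t1_duration = annotation.cycle_bounds_ms[0][1] - annotation.cycle_bounds_ms[0][0]
    segs = []
    for idx, (t0, t1) in enumerate(annotation.cycle_bounds_ms, start=1):
        U = _resample_segment(traj.time_ms, traj.U, t0, t1, grid_points)
        segs.append(
            CycleSegment(
                U=U,
                cycle_index=idx,
                duration_ms=t1 - t0,
                scaled_duration=(t1 - t0) / t1_duration,
                bout_id=bout_id,
                fish_id=fish_id,
                age_group=age_group,
            )
        )
    return segs


def normalize_and_align(
    trajs: list[PosturalTrajectory],
    grid_points: int = 50,
    smooth_ms: float = 4.0,
    meta: list[dict] | None = None,
) -> list[CycleSegment]:
    """Detect, cut, and time-normalize cycles for a whole ensemble."""
    out = []
    for i, traj in enumerate(trajs):
        info = meta[i] if meta else {}
        ann = detect_cycles(traj, smooth_ms=smooth_ms)
        out.extend(
            extract_cycle_segments(
                traj,
                ann,
                grid_points=grid_points,
                bout_id=info.get("bout_id", traj.bout_id),
                fish_id=info.get("fish_id", "fish"),
                age_group=info.get("age_group", "A"),
            )
        )
    return out


def mirror_flip_modes(basis: EigenshapeBasis) -> np.ndarray:
    """Which modes change sign when the fish is mirrored left/right.

    Determined from the basis itself: each eigenshape is rendered in real
    space, reflected about the head tangent axis, converted back to
    head-referenced angles and re-projected.  Modes whose self-projection
    negates are in the flip set.  (For tangent-angle eigenshapes the
    reflection negates every angle, so this generically returns all
    modes — the procedure stays basis-agnostic regardless.)
    """
    def headref_angles(pts: np.ndarray) -> np.ndarray:
        seg = np.diff(pts, axis=0)
        theta = np.unwrap(np.arctan2(seg[:, 1], seg[:, 0]))
        return theta - theta[0]  # head-referenced segment angles

    flips = []
    for k in range(1, basis.n_modes + 1):
        pts = render_real_space(basis, k, amplitude=1.0)
        orig = headref_angles(pts)
        mirr = headref_angles(pts * np.array([1.0, -1.0]))
        dot = float(orig @ mirr)
        flips.append(dot < 0 or not np.any(orig))
    return np.array(flips, dtype=bool)


def normalize_handedness(
    segment: CycleSegment,
    flip_modes: np.ndarray,
    reference: CycleSegment | None = None,
) -> tuple[CycleSegment, int]:
    """Remove left/right handedness from a cycle segment.

    If the signed area (mean) of U_1 over the segment is negative, the
    flip-set modes are negated so that a bout and its mirror image map to
    the same normalized segment.  ``reference`` supplies the sign decision
    for later cycles of the same bout (cycle 1 decides for the whole bout).
    """
    decider = reference if reference is not None else segment
    area = float(np.trapezoid(decider.U[0]))
    if area >= 0 or abs(area) < 1e-12 * max(np.max(np.abs(decider.U)), 1e-300):
        return segment, +1
    U = segment.U.copy()
    U[flip_modes[: U.shape[0]]] *= -1
    return replace(segment, U=U, handedness=-1), -1


def normalize_ensemble_handedness(
    segments: list[CycleSegment], flip_modes: np.ndarray
) -> list[CycleSegment]:
    """Handedness-normalize per bout, cycle 1 deciding the bout's sign."""
    by_bout: dict[str, list[CycleSegment]] = {}
    for seg in segments:
        by_bout.setdefault(seg.bout_id, []).append(seg)
    out = []
    for segs in by_bout.values():
        segs = sorted(segs, key=lambda s: s.cycle_index)
        ref = segs[0]
        for seg in segs:
            norm, _ = normalize_handedness(seg, flip_modes, reference=ref)
            out.append(norm)
    return out


def write_cycles(segments: list[CycleSegment], path) -> None:
    """Cycle table: labels, duration, then the T x K flattened amplitudes."""
    import pandas as pd

    rows = []
    for s in segments:
        row = {
            "bout_id": s.bout_id,
            "fish_id": s.fish_id,
            "age_group": s.age_group,
            "cycle_index": s.cycle_index,
            "duration_ms": s.duration_ms,
            "scaled_duration": s.scaled_duration,
            "handedness": s.handedness,
        }
        K, T = s.U.shape
        for k in range(K):
            for i in range(T):
                row[f"U{k + 1}_{i}"] = s.U[k, i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_cycles(path) -> list[CycleSegment]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    ucols = [c for c in df.columns if c.startswith("U") and "_" in c]
    K = max(int(c[1 : c.index("_")]) for c in ucols)
    T = max(int(c.split("_")[1]) for c in ucols) + 1
    segs = []
    for _, row in df.iterrows():
        U = np.array(
            [[row[f"U{k + 1}_{i}"] for i in range(T)] for k in range(K)]
        )
        segs.append(
            CycleSegment(
                U=U,
                cycle_index=int(row["cycle_index"]),
                duration_ms=float(row["duration_ms"]),
                scaled_duration=float(row["scaled_duration"]),
                bout_id=str(row["bout_id"]),
                fish_id=str(row["fish_id"]),
                age_group=str(row["age_group"]),
                handedness=int(row["handedness"]),
            )
        )
    return segs
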
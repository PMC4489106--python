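"""Synthetic study data: bout ensembles and rendered image sequences.

Everything downstream of raw video can be exercised without recordings:
the two-channel simulator provides spine-angle bouts drawn from three
archetypes (scoot, turn, rest) with population variability, and a simple
renderer paints those bouts as grayscale frame stacks with ground-truth
midlines for testing the extraction chain.

The ensemble defaults emulate the study conditions: ~115 bouts from ~20
fish, bouts of 180–250 ms with 6–8 half tail cycles, first-cycle durations
in the 15–33 ms range, random left/right handedness, ~15% parameter
coefficient of variation across the population, and two age-like parameter
regimes (the "older" regime B has a more compliant tail, which enlarges
the spread of the third postural amplitude in cycle 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .neuro import NeuroParams, StiffnessProfile, simulate_bout
from .spine import InvalidInputError, SpineAngleMatrix, angles_to_midline


class RenderError(RuntimeError):
    """Fish does not fit inside the frame."""


# ---------------------------------------------------------------------------
# archetype library


def scoot_params(
    a0: float = 0.095,
    half_period_ms: float = 15.0,
    d_ms: float = 2.05,
    n_c: int = 6,
    t0_ms: float = 20.0,
    start_side: str = "left",
) -> NeuroParams:
    """Symmetric drive: equal burst amplitudes on both channels.

    The drive is trapezoidal: half-amplitude first and last bursts ease
    the bout in and out of the oscillation and give the two sides the
    same total impulse for any half-cycle count, so the bout carries no
    net bend.  Burst length is set to ~0.84 of the half period, which
    (together with the fast neuromuscular kernel) keeps the muscle-force
    wave near-sinusoidal.
    """
    tau_f = t0_ms + half_period_ms * np.arange(n_c)
    a = np.full(n_c, a0)
    a[0] *= 0.5
    a[-1] *= 0.5
    return NeuroParams(
        tau_f_ms=tau_f,
        a=a,
        d_ms=d_ms,
        n_c=n_c,
        burst_ms=0.84 * half_period_ms,
        start_side=start_side,
    )


def turn_params(
    a0: float = 0.095,
    turn_ratio: float = 5.0,
    half_period_ms: float = 15.0,
    d_ms: float = 2.05,
    turn_d_ms: float = 2.15,
    catch_fraction: float = 0.5,
    echo_fraction: float = 0.2,
    n_c: int = 6,
    t0_ms: float = 20.0,
    start_side: str = "left",
) -> NeuroParams:
    """Asymmetric drive producing a turn.

    The bout opens with a normal soft half cycle, then the opposite side
    fires a "whip": its burst amplitude is ``turn_ratio`` times the bout
    amplitude, with a slightly larger segment delay ``turn_d_ms``.  The
    next half cycle carries a partial counter-stroke ("catch",
    ``catch_fraction`` of the extra whip impulse) that swings the body
    back, so the bend is a transient excursion rather than a held
    posture, and a weaker same-side echo on the following half cycle
    rings the excursion down into the ordinary swimming wave.  From the second full cycle on the drive is identical to a
    scoot, reflecting that turning bouts settle into ordinary scoot
    cycles after the turn.  The turn direction is the side of the whip,
    i.e. opposite ``start_side``.
    """
    p = scoot_params(
        a0=a0,
        half_period_ms=half_period_ms,
        d_ms=d_ms,
        n_c=n_c,
        t0_ms=t0_ms,
        start_side=start_side,
    )
    a = p.a.copy()
    boost = (turn_ratio - 1.0) * a0
    a[1] += boost
    if n_c > 2:
        a[2] += catch_fraction * boost
    if n_c > 3:
        a[3] += echo_fraction * boost  # ring-down echo ends the excursion
    d = p.d_ms.copy()
    d[1:3] = turn_d_ms
    return replace(p, a=a, d_ms=d)


def rest_params(n_c: int = 2, start_side: str = "left") -> NeuroParams:
    """Zero drive: the resting fixed point."""
    return NeuroParams(
        tau_f_ms=np.array([20.0, 40.0])[:n_c],
        a=np.zeros(n_c),
        d_ms=2.05,
        n_c=n_c,
        start_side=start_side,
    )


ARCHETYPES = {"scoot": scoot_params, "turn": turn_params, "rest": rest_params}


def regime_stiffness(regime: str) -> StiffnessProfile:
    """Age-like stiffness regimes: B softens the tail by 30%."""
    W = StiffnessProfile().W.copy()
    if regime == "B":
        W[-3:] *= 0.85
    return StiffnessProfile(W=W)


# ---------------------------------------------------------------------------
# ensemble generation


@dataclass
class EnsembleSpec:
    """Composition and conditions of a synthetic bout ensemble."""

    n_scoot: int = 60
    n_turn: int = 40
    n_rest: int = 15
    n_fish: int = 20
    cv: float = 0.15  # population coefficient of variation
    handedness_prob: float = 0.5
    seed: int = 0
    dt_ms: float = 2.0
    duration_ms: float = 280.0

    @property
    def n_bouts(self) -> int:
        return self.n_scoot + self.n_turn + self.n_rest


@dataclass
class BoutRecord:
    """One simulated bout with its full ground truth."""

    spine: SpineAngleMatrix
    archetype: str
    handedness: int  # +1 left-starting, -1 right-starting
    fish_id: str
    age_group: str  # regime "A" (younger-like) or "B" (older-like)
    params: NeuroParams
    stiffness: StiffnessProfile


def _vary(rng: np.random.Generator, value: float, cv: float, lo: float = 0.05) -> float:
    """Multiplicative Gaussian variation, truncated away from zero."""
    return float(value * max(1.0 + cv * rng.standard_normal(), lo))


def generate_ensemble(spec: EnsembleSpec) -> list[BoutRecord]:
    """Sample a labeled, fully reproducible ensemble of simulated bouts.

    Parameter variability is split between a per-fish factor and a
    per-bout factor (each cv/√2), emulating fish-to-fish differences plus
    bout-to-bout variation within a fish.
    """
    rng = np.random.default_rng(spec.seed)
    cv_fish = cv_bout = spec.cv / np.sqrt(2.0)
    fish = []
    for i in range(spec.n_fish):
        fish.append(
            {
                "fish_id": f"fish{i:02d}",
                "age_group": "A" if i < (spec.n_fish + 1) // 2 else "B",
                "f_amp": max(1.0 + cv_fish * rng.standard_normal(), 0.05),
                "f_period": max(1.0 + cv_fish * rng.standard_normal(), 0.05),
                "f_delay": max(1.0 + cv_fish * rng.standard_normal(), 0.05),
            }
        )
    kinds = (
        ["scoot"] * spec.n_scoot + ["turn"] * spec.n_turn + ["rest"] * spec.n_rest
    )
    records = []
    for b, kind in enumerate(kinds):
        f = fish[int(rng.integers(spec.n_fish))]
        side = "left" if rng.random() < spec.handedness_prob else "right"
        n_c = int(rng.integers(6, 9))  # 6-8 half cycles
        if kind == "rest":
            p = rest_params(start_side=side)
        else:
            a0 = _vary(rng, 0.095 * f["f_amp"], cv_bout)
            hp = _vary(rng, 15.0 * f["f_period"], cv_bout)
            hp = float(np.clip(hp, 11.0, 19.0))  # cycle-1 durations ~22-38 ms
            d = _vary(rng, 2.05 * f["f_delay"], cv_bout)
            d = float(np.clip(d, spec.dt_ms * 1.01, 2.6))
            if kind == "scoot":
                p = scoot_params(
                    a0=a0, half_period_ms=hp, d_ms=d, n_c=n_c, start_side=side
                )
            else:
                ratio = _vary(rng, 5.0, cv_bout)
                p = turn_params(
                    a0=a0,
                    turn_ratio=ratio,
                    half_period_ms=hp,
                    d_ms=d,
                    turn_d_ms=d * 1.05,
                    n_c=n_c,
                    start_side=side,
                )
        stiff = regime_stiffness(f["age_group"])
        spine = simulate_bout(
            p,
            stiffness=stiff,
            dt_ms=spec.dt_ms,
            duration_ms=spec.duration_ms,
            bout_id=f"bout{b:03d}_{kind}",
        )
        records.append(
            BoutRecord(
                spine=spine,
                archetype=kind,
                handedness=+1 if side == "left" else -1,
                fish_id=f["fish_id"],
                age_group=f["age_group"],
                params=p,
                stiffness=stiff,
            )
        )
    return records


# ---------------------------------------------------------------------------
# frame rendering


@dataclass
class RenderConfig:
    """How to paint a bout as a grayscale frame stack."""

    image_size: tuple[int, int] = (220, 220)  # (rows, cols)
    fish_length_px: float = 120.0
    head_half_width_px: float = 6.5
    tail_half_width_px: float = 1.5
    body_value: float = 200.0
    background: str = "constant"  # or "gradient"
    background_level: float = 30.0
    noise_sd: float = 0.0
    margin_px: float = 5.0
    oversample: int = 12
    seed: int = 0

    def half_width(self, s: np.ndarray) -> np.ndarray:
        """Body half-width profile along normalized arc length."""
        w = self.tail_half_width_px + (
            self.head_half_width_px - self.tail_half_width_px
        ) * (1.0 - s) ** 1.2
        return w


@dataclass
class RenderedBout:
    frames: np.ndarray  # (m, rows, cols) float
    midlines: list[np.ndarray]  # ground-truth (P, 2) (x, y) per frame
    frame_rate: float
    config: RenderConfig


def _background(rc: RenderConfig) -> np.ndarray:
    rows, cols = rc.image_size
    if rc.background == "gradient":
        col = np.linspace(0.7, 1.3, cols) * rc.background_level
        return np.tile(col, (rows, 1))
    return np.full((rows, cols), rc.background_level)


def render_fish_frames(
    spine: SpineAngleMatrix, rc: RenderConfig | None = None
) -> RenderedBout:
    """Paint a bout's midlines as a filled fish body on a background.

    Each frame integrates the spine angles (plus the head angle) into a
    planar midline centered in the image and sweeps the half-width profile
    along it; an anti-aliased edge keeps the outline smooth.  Returns the
    true midline coordinates per frame for oracle tests.
    """
    rc = rc or RenderConfig()
    rows, cols = rc.image_size
    rng = np.random.default_rng(rc.seed)
    bg = _background(rc)
    frames = np.empty((spine.n_frames, rows, cols))
    midlines = []
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    for i in range(spine.n_frames):
        pts = angles_to_midline(
            spine.dtheta[i],
            theta_head=float(spine.theta_head[i]),
            length=rc.fish_length_px,
            oversample=rc.oversample,
        )
        pts = pts - pts.mean(axis=0) + np.array([cols / 2.0, rows / 2.0])
        s = np.linspace(0.0, 1.0, pts.shape[0])
        radii = rc.half_width(s)
        if (
            (pts[:, 0] - radii < rc.margin_px).any()
            or (pts[:, 0] + radii > cols - rc.margin_px).any()
            or (pts[:, 1] - radii < rc.margin_px).any()
            or (pts[:, 1] + radii > rows - rc.margin_px).any()
        ):
            raise RenderError(f"fish exits frame {i}")
        # signed distance to the swept body: min over samples of dist - w(s)
        dist = np.sqrt(
            (xx[:, :, None] - pts[None, None, :, 0]) ** 2
            + (yy[:, :, None] - pts[None, None, :, 1]) ** 2
        )
        D = np.min(dist - radii[None, None, :], axis=2)
        cover = np.clip(0.5 - D, 0.0, 1.0)  # anti-aliased coverage
        frame = bg * (1.0 - cover) + rc.body_value * cover
        if rc.noise_sd > 0:
            frame = frame + rng.normal(0.0, rc.noise_sd, frame.shape)
        frames[i] = np.clip(frame, 0.0, 255.0)
        midlines.append(pts)
    return RenderedBout(
        frames=frames,
        midlines=midlines,
        frame_rate=spine.frame_rate,
        config=rc,
    )


def roi_polygon(rendered: RenderedBout, pad_px: float = 12.0) -> np.ndarray:
    """Rectangular region of interest around the fish in frame 0."""
    pts = rendered.midlines[0]
    rc = rendered.config
    w = rc.head_half_width_px
    x0 = max(pts[:, 0].min() - w - pad_px, 1.0)
    x1 = min(pts[:, 0].max() + w + pad_px, rc.image_size[1] - 2.0)
    y0 = max(pts[:, 1].min() - w - pad_px, 1.0)
    y1 = min(pts[:, 1].max() + w + pad_px, rc.image_size[0] - 2.0)
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])


def write_labels(records: list[BoutRecord], path) -> None:
    """Ground-truth label table for an ensemble."""
    import pandas as pd

    rows = [
        {
            "bout_id": r.spine.bout_id,
            "archetype": r.archetype,
            "handedness": r.handedness,
            "fish_id": r.fish_id,
            "age_group": r.age_group,
            "n_c": r.params.n_c,
            "d_ms": r.params.d_ms,
            "a_max": float(r.params.a.max(initial=0.0)),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.9g")
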
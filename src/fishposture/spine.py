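"""Spine-angle matrices: the pipeline's central exchange format.

A swim bout is represented by the m x n matrix ``dtheta[i, j]`` of
head-referenced tangent angles Δθ(s_j, t_i): the tangent direction of the
body midline at normalized arc position s_j (s_0 = 0 at the head,
s_{n-1} = 1 at the tail), relative to the head tangent, at frame time t_i.
Column 0 is identically zero by construction.  The same container is
produced by video midline extraction and by the neuro-kinematic simulator,
so real and simulated bouts are interchangeable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class InvalidInputError(ValueError):
    """Raised when an operation's input violates its contract."""


@dataclass
class SpineAngleMatrix:
    """Head-referenced spine angles Δθ(s_j, t_i) for one or more bouts.

    Parameters
    ----------
    dtheta
        (m, n) array of angles in radians; column 0 must be all zeros.
    time_ms
        (m,) strictly increasing frame times in milliseconds.
    theta_head
        (m,) absolute head tangent angle θ(s_0, t_i) in radians
        (counterclockwise from +x).  Zero if unknown.
    """

    dtheta: np.ndarray
    time_ms: np.ndarray
    theta_head: np.ndarray | None = None
    bout_id: str = "bout"

    def __post_init__(self) -> None:
        self.dtheta = np.asarray(self.dtheta, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.dtheta.ndim != 2:
            raise InvalidInputError("dtheta must be 2-D (frames x arc points)")
        m, n = self.dtheta.shape
        if self.time_ms.shape != (m,):
            raise InvalidInputError("time_ms length must match frame count")
        if n < 3:
            raise InvalidInputError("need at least 3 arc points")
        if not np.allclose(self.dtheta[:, 0], 0.0, atol=1e-9):
            raise InvalidInputError("head column of dtheta must be zero")
        if self.theta_head is None:
            self.theta_head = np.zeros(m)
        else:
            self.theta_head = np.asarray(self.theta_head, dtype=float)
            if self.theta_head.shape != (m,):
                raise InvalidInputError("theta_head length must match frames")

    @property
    def n_frames(self) -> int:
        return self.dtheta.shape[0]

    @property
    def n_points(self) -> int:
        return self.dtheta.shape[1]

    @property
    def arc_positions(self) -> np.ndarray:
        """Normalized arc positions s_j, equally spaced on [0, 1]."""
        return np.linspace(0.0, 1.0, self.n_points)

    @property
    def frame_rate(self) -> float:
        """Frames per second inferred from the timebase."""
        dt = np.diff(self.time_ms)
        return 1000.0 / float(np.median(dt))

    def tail_angle(self) -> np.ndarray:
        """Δθ at the tail tip (s = 1), one value per frame."""
        return self.dtheta[:, -1]

    def mirrored(self) -> "SpineAngleMatrix":
        """Left/right mirror image of the bout (all bend angles negated)."""
        return SpineAngleMatrix(
            dtheta=-self.dtheta,
            time_ms=self.time_ms.copy(),
            theta_head=-self.theta_head,
            bout_id=self.bout_id,
        )


def write_spine(spine: SpineAngleMatrix, path: str | Path) -> None:
    """Write the standard delimited exchange format.

    One row per frame: ``time_ms  theta_head_rad  dtheta_0 ... dtheta_{n-1}``
    (tab separated, ``dtheta_0`` always 0).
    """
    n = spine.n_points
    cols = ["time_ms", "theta_head_rad"] + [f"dtheta_{j}" for j in range(n)]
    data = np.column_stack([spine.time_ms, spine.theta_head, spine.dtheta])
    df = pd.DataFrame(data, columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_spine(path: str | Path, bout_id: str | None = None) -> SpineAngleMatrix:
    """Read a spine-angle matrix written by :func:`write_spine`."""
    df = pd.read_csv(path, sep="\t")
    dth_cols = [c for c in df.columns if c.startswith("dtheta_")]
    dth_cols.sort(key=lambda c: int(c.split("_")[1]))
    return SpineAngleMatrix(
        dtheta=df[dth_cols].to_numpy(),
        time_ms=df["time_ms"].to_numpy(),
        theta_head=df["theta_head_rad"].to_numpy(),
        bout_id=bout_id or Path(path).stem,
    )


def angles_to_midline(
    dtheta_row: np.ndarray,
    theta_head: float = 0.0,
    length: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
    oversample: int = 1,
) -> np.ndarray:
    """Integrate tangent angles into planar midline coordinates.

    The tangent angle along arc length is θ(s) = ``theta_head`` + Δθ(s),
    with Δθ interpolated (cubic when possible) between the sample points.
    Returns an ((n-1) * oversample + 1, 2) array of (x, y) points starting
    at ``origin`` and spanning total arc length ``length``.
    """
    from scipy.interpolate import CubicSpline

    dtheta_row = np.asarray(dtheta_row, dtype=float)
    n = dtheta_row.size
    s = np.linspace(0.0, 1.0, n)
    s_fine = np.linspace(0.0, 1.0, (n - 1) * oversample + 1)
    if n >= 4:
        dth_fine = CubicSpline(s, dtheta_row)(s_fine)
    else:
        dth_fine = np.interp(s_fine, s, dtheta_row)
    theta = theta_head + dth_fine
    ds = length / (s_fine.size - 1)
    # midpoint rule on the tangent keeps the chord of each sub-segment honest
    mid = 0.5 * (theta[:-1] + theta[1:])
    dx = np.cos(mid) * ds
    dy = np.sin(mid) * ds
    x = np.concatenate([[0.0], np.cumsum(dx)]) + origin[0]
    y = np.concatenate([[0.0], np.cumsum(dy)]) + origin[1]
    return np.column_stack([x, y])
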
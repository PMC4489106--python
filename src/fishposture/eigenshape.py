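"""Eigenshape decomposition of spine-angle matrices.

The head-referenced spine angles of a swimming larva are decomposed by
singular value decomposition into orthonormal basis functions over arc
length ("eigenshapes", by analogy with the eigenworms of C. elegans):

    Δθ(s_j, t_i) = Σ_k U_k(t_i) S_kk V_k(s_j)

with the singular values normalized so that Σ_k S_kk = 1; each S_kk is then
the fractional weight of mode k.  The head column of Δθ is identically zero
and is excluded from the decomposition, so the basis lives on the n-1
non-head arc positions.  Three modes suffice to capture >96% of free
swimming, which is what makes the low-dimensional "postural space"
spanned by U_1..U_3 useful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spine import InvalidInputError, SpineAngleMatrix, angles_to_midline


class DegenerateInputError(ValueError):
    """Raised when a decomposition input has no signal (rank 0)."""


@dataclass
class EigenshapeBasis:
    """Orthonormal eigenshapes over the non-head arc positions.

    Attributes
    ----------
    V
        (n-1, K) matrix; column k is eigenshape V_k(s_j), j = 1..n-1.
    S
        (K,) normalized singular values (non-increasing, sum to 1 when all
        modes are kept); ``S[k]`` is the fractional weight of mode k.
    total_scale
        Sum of the raw singular values; ``S * total_scale`` recovers them.
    provenance
        "collective" (all bouts pooled) or "per-movie".
    """

    V: np.ndarray
    S: np.ndarray
    total_scale: float
    provenance: str = "collective"

    @property
    def n_modes(self) -> int:
        return self.V.shape[1]

    @property
    def weights(self) -> np.ndarray:
        """Fractional weight of each mode (S_kk / Σ S over all modes)."""
        return self.S

    def cumulative_weight(self, k: int) -> float:
        """Cumulative fractional weight of the first ``k`` modes."""
        return float(self.S[:k].sum())


@dataclass
class PosturalTrajectory:
    """Mode amplitudes U_k(t_i) of one bout in a fixed eigenshape basis."""

    U: np.ndarray  # (m, K)
    time_ms: np.ndarray
    basis: EigenshapeBasis
    bout_id: str = "bout"

    @property
    def n_frames(self) -> int:
        return self.U.shape[0]

    @property
    def n_modes(self) -> int:
        return self.U.shape[1]


def _fix_signs(V: np.ndarray, U: np.ndarray) -> None:
    """Flip each mode so its largest-magnitude element of V is positive.

    Deterministic across linear-algebra backends; flips U in step so the
    product U S Vᵀ is unchanged.
    """
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] *= -1
            U[:, k] *= -1


def decompose(
    matrices: SpineAngleMatrix | list[SpineAngleMatrix],
    provenance: str = "collective",
) -> tuple[EigenshapeBasis, list[PosturalTrajectory]]:
    """SVD of one or more spine-angle matrices into a shared basis.

    All inputs are concatenated along the time axis (the "collective"
    analysis); per-input amplitude trajectories are recovered by slicing
    the rows back apart.
    """
    if isinstance(matrices, SpineAngleMatrix):
        matrices = [matrices]
    if not matrices:
        raise InvalidInputError("no input matrices")
    n = matrices[0].n_points
    if any(sp.n_points != n for sp in matrices):
        raise InvalidInputError("all inputs must share n_points")
    X = np.vstack([sp.dtheta[:, 1:] for sp in matrices])  # drop head column
    if X.shape[0] < n - 1:
        raise InvalidInputError("need at least n-1 total frames")
    if not np.any(X):
        raise DegenerateInputError("all-zero input has no eigenshapes")

    u, s, vh = np.linalg.svd(X, full_matrices=False)
    V = vh.T.copy()
    total = float(s.sum())
    S = s / total
    U = u * total  # so that U @ diag(S) @ V.T == X exactly
    _fix_signs(V, U)

    basis = EigenshapeBasis(V=V, S=S, total_scale=total, provenance=provenance)
    trajs = []
    row = 0
    for sp in matrices:
        m = sp.n_frames
        trajs.append(
            PosturalTrajectory(
                U=U[row : row + m].copy(),
                time_ms=sp.time_ms.copy(),
                basis=basis,
                bout_id=sp.bout_id,
            )
        )
        row += m
    return basis, trajs


def reconstruct(
    basis: EigenshapeBasis,
    traj: PosturalTrajectory,
    k_max: int,
) -> SpineAngleMatrix:
    """Reconstruct spine angles from the first ``k_max`` modes."""
    if k_max < 1:
        raise InvalidInputError("k_max must be >= 1")
    if k_max > basis.n_modes:
        raise InvalidInputError("k_max exceeds basis mode count")
    body = (traj.U[:, :k_max] * basis.S[:k_max]) @ basis.V[:, :k_max].T
    dtheta = np.hstack([np.zeros((body.shape[0], 1)), body])
    return SpineAngleMatrix(
        dtheta=dtheta, time_ms=traj.time_ms.copy(), bout_id=traj.bout_id
    )


def relative_residual(
    spines: SpineAngleMatrix | list[SpineAngleMatrix],
    basis: EigenshapeBasis,
    trajs: PosturalTrajectory | list[PosturalTrajectory],
    k_max: int = 3,
) -> float:
    """Frobenius-norm ratio ‖Δθ − Δθ^r‖ / ‖Δθ‖ over all frames pooled."""
    if isinstance(spines, SpineAngleMatrix):
        spines = [spines]
    if isinstance(trajs, PosturalTrajectory):
        trajs = [trajs]
    num = 0.0
    den = 0.0
    for sp, tr in zip(spines, trajs, strict=True):
        rec = reconstruct(basis, tr, k_max)
        num += float(np.sum((sp.dtheta - rec.dtheta) ** 2))
        den += float(np.sum(sp.dtheta**2))
    return np.sqrt(num / den)


def project(
    spine: SpineAngleMatrix, basis: EigenshapeBasis, k_max: int | None = None
) -> PosturalTrajectory:
    """Express a (possibly held-out) bout in a fixed eigenshape basis.

    U_k(t_i) = Σ_j Δθ(s_j, t_i) V_k(s_j) / S_kk.
    """
    if spine.n_points - 1 != basis.V.shape[0]:
        raise InvalidInputError("n_points does not match basis")
    K = basis.n_modes if k_max is None else k_max
    S = basis.S[:K]
    if np.any(S <= 0):
        raise DegenerateInputError("cannot project onto zero-weight mode")
    U = spine.dtheta[:, 1:] @ basis.V[:, :K] / S
    return PosturalTrajectory(
        U=U, time_ms=spine.time_ms.copy(), basis=basis, bout_id=spine.bout_id
    )


def render_real_space(
    basis: EigenshapeBasis,
    k: int,
    amplitude: float,
    body_length: float = 1.0,
    theta_head: float = 0.0,
) -> np.ndarray:
    """Planar shape of a single eigenshape at a given amplitude.

    Integrates the tangent angles ``amplitude * S_kk * V_k(s_j)`` along arc
    length, starting at the origin heading +x.  Returns (n, 2) coordinates.
    """
    if not 1 <= k <= basis.n_modes:
        raise InvalidInputError(f"mode {k} outside 1..{basis.n_modes}")
    dth = np.concatenate([[0.0], amplitude * basis.S[k - 1] * basis.V[:, k - 1]])
    n = dth.size
    pts = angles_to_midline(dth, theta_head=theta_head, length=body_length)
    # return at the native resolution of the basis
    assert pts.shape[0] == n
    return pts


def write_basis(basis: EigenshapeBasis, path) -> None:
    """Delimited text: header of normalized S_kk, then rows = s_j, cols = V_k."""
    with open(path, "w") as fh:
        fh.write("# S_kk\t" + "\t".join(f"{v:.9g}" for v in basis.S) + "\n")
        fh.write(f"# total_scale\t{basis.total_scale:.9g}\n")
        fh.write(f"# provenance\t{basis.provenance}\n")
        np.savetxt(fh, basis.V, delimiter="\t", fmt="%.9g")


def read_basis(path) -> EigenshapeBasis:
    S = total = provenance = None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for ln in lines:
        if ln.startswith("# S_kk"):
            S = np.array([float(v) for v in ln.split("\t")[1:]])
        elif ln.startswith("# total_scale"):
            total = float(ln.split("\t")[1])
        elif ln.startswith("# provenance"):
            provenance = ln.split("\t")[1].strip()
        elif ln.strip():
            body.append([float(v) for v in ln.split("\t")])
    return EigenshapeBasis(
        V=np.array(body), S=S, total_scale=total, provenance=provenance or "collective"
    )


def write_trajectory(traj: PosturalTrajectory, path) -> None:
    """Delimited text: time_ms, U_1 ... U_K."""
    import pandas as pd

    cols = ["time_ms"] + [f"U_{k + 1}" for k in range(traj.n_modes)]
    pd.DataFrame(
        np.column_stack([traj.time_ms, traj.U]), columns=cols
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_trajectory(path, basis: EigenshapeBasis) -> PosturalTrajectory:
    import pandas as pd
    from pathlib import Path

    df = pd.read_csv(path, sep="\t")
    ucols = sorted(
        [c for c in df.columns if c.startswith("U_")], key=lambda c: int(c[2:])
    )
    return PosturalTrajectory(
        U=df[ucols].to_numpy(),
        time_ms=df["time_ms"].to_numpy(),
        basis=basis,
        bout_id=Path(path).stem,
    )
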
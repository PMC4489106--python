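"""Midline extraction: grayscale frames -> head-referenced spine angles.

The chain mirrors a standard larval-tracking pipeline: a background image
is built from the first frame by inpainting the region of interest that
contains the fish; each background-subtracted frame is thresholded and
skeletonized; the longest simple path of the skeleton (side branches
pruned, then extended to the body outline so skeleton shrinkage does not
shorten the midline) is smoothed with a cubic spline and resampled at n
points equally spaced in arc length; tangent angles of the spline at
those points, referenced to the head tangent, form the spine-angle matrix
Δθ(s_j, t_i) that the rest of the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize
from skimage.restoration import inpaint_biharmonic

from .spine import InvalidInputError, SpineAngleMatrix


class SegmentationError(RuntimeError):
    """No unambiguous fish component in the frame."""


@dataclass
class FrameStack:
    """A sequence of grayscale frames at a fixed frame rate."""

    frames: np.ndarray  # (m, rows, cols)
    frame_rate: float = 500.0
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise InvalidInputError("frames must be (m, rows, cols)")
        if self.frame_rate <= 0:
            raise InvalidInputError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class BackboneFrame:
    """Ordered backbone points of one frame, head first."""

    points: np.ndarray  # (n, 2) as (x, y) pixels
    timestamp_ms: float

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def arc_positions(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n)


def subtract_background(stack: FrameStack, roi: np.ndarray) -> FrameStack:
    """Remove the static background, estimated by inpainting the ROI.

    The background image B is frame 0 with the interior of the
    user-supplied region of interest (which must enclose the fish)
    replaced by a smooth fill interpolated from the ROI boundary; the
    output frames are |G − B|.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or roi.shape[0] < 3:
        raise InvalidInputError("roi must be a polygon of >= 3 vertices")
    rows, cols = stack.frames.shape[1:]
    # polygon2mask expects (row, col) vertex order
    mask = polygon2mask((rows, cols), roi[:, ::-1])
    if mask.sum() < 4:
        raise InvalidInputError("roi degenerate (area < 4 px)")
    first = stack.frames[0]
    scale = max(float(first.max()), 1.0)
    background = inpaint_biharmonic(first / scale, mask) * scale
    out = np.abs(stack.frames - background[None, :, :])
    return FrameStack(
        frames=out, frame_rate=stack.frame_rate, pixel_size=stack.pixel_size
    )


def _skeleton_longest_path(skel: np.ndarray) -> np.ndarray:
    """Longest simple path through a skeleton, as ordered (row, col) pixels.

    The skeleton is treated as an 8-connected graph; a double
    breadth-first sweep from an arbitrary pixel finds the two most
    distant endpoints (exact on trees, which pruned skeletons are up to
    small loops) and the path between them; side branches fall away.
    """
    pix = np.argwhere(skel)
    if pix.shape[0] == 0:
        raise SegmentationError("empty skeleton")
    index = {tuple(p): i for i, p in enumerate(pix)}
    nbrs: list[list[int]] = [[] for _ in range(len(pix))]
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for i, (r, c) in enumerate(pix):
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                nbrs[i].append(j)

    def bfs(start: int) -> tuple[int, list[int]]:
        prev = {start: -1}
        queue = [start]
        last = start
        while queue:
            nxt = []
            for u in queue:
                for v in nbrs[u]:
                    if v not in prev:
                        prev[v] = u
                        nxt.append(v)
            if nxt:
                last = nxt[-1]
            queue = nxt
        path = [last]
        while prev[path[-1]] != -1:
            path.append(prev[path[-1]])
        return last, path[::-1]

    far, _ = bfs(0)
    _, path = bfs(far)
    return pix[path]


def _extend_to_mask_edge(
    path_xy: np.ndarray, mask: np.ndarray, max_steps: int = 30
) -> np.ndarray:
    """Extend both path ends along their local tangent to the mask edge.

    Skeletons recede from the body outline by roughly the local
    half-width; walking outward along the end tangent until leaving the
    binary mask recovers the snout and tail tip.
    """
    rows, cols = mask.shape
    edt = ndimage.distance_transform_edt(mask)

    def extension(tail: np.ndarray) -> list[np.ndarray]:
        # extend along the least-squares end tangent (raw 8-connected
        # pixels zigzag, so the tangent is fit over the last few pixels)
        arc = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(tail, axis=0).T))])
        if arc[-1] == 0:
            return []
        gx = np.polyfit(arc, tail[:, 0], 1)[0]
        gy = np.polyfit(arc, tail[:, 1], 1)[0]
        norm = np.hypot(gx, gy)
        if norm == 0:
            return []
        tang = np.array([gx, gy]) / norm
        ext = []
        pos = tail[-1].astype(float)
        r0, c0 = int(round(pos[1])), int(round(pos[0]))
        prev_width = edt[r0, c0] if (0 <= r0 < rows and 0 <= c0 < cols) else 0.0
        for _ in range(max_steps):
            pos = pos + tang
            r, c = int(round(pos[1])), int(round(pos[0]))
            if not (0 <= r < rows and 0 <= c < cols) or not mask[r, c]:
                break
            # past the true tip the body is a rounded cap and the width
            # transform falls at unit slope; along the body it only tapers
            if edt[r, c] < prev_width - 0.7:
                break
            prev_width = edt[r, c]
            ext.append(pos.copy())
        return ext

    k = min(7, path_xy.shape[0])
    head_ext = extension(path_xy[:k][::-1])
    tail_ext = extension(path_xy[-k:])
    parts = [np.array(head_ext[::-1]).reshape(-1, 2), path_xy,
             np.array(tail_ext).reshape(-1, 2)]
    return np.vstack([p for p in parts if p.size])


def segment_and_skeletonize(
    frame: np.ndarray,
    threshold: float | None = None,
    min_area: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold a background-subtracted frame and trace the backbone.

    ``threshold`` is an absolute intensity; by default half the Otsu
    value of the frame is used.  Returns the ordered (x, y) pixel path of
    the skeleton's longest simple path (extended to the outline) and the
    binary mask.
    """
    frame = np.asarray(frame, dtype=float)
    if threshold is None:
        if not np.any(frame > 0) or frame.max() == frame.min():
            raise SegmentationError("blank frame")
        threshold = 0.5 * threshold_otsu(frame)
    binary = frame > threshold
    labels, n_comp = ndimage.label(binary)
    if n_comp == 0:
        raise SegmentationError("no foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n_comp + 1))
    big = np.nonzero(sizes >= min_area)[0]
    if big.size == 0:
        raise SegmentationError("no component of sufficient size")
    if big.size > 1:
        raise SegmentationError(f"{big.size} large components; ambiguous frame")
    mask = labels == big[0] + 1
    skel = skeletonize(mask)
    path_rc = _skeleton_longest_path(skel)
    path_xy = path_rc[:, ::-1].astype(float)  # (x, y)
    path_xy = _extend_to_mask_edge(path_xy, mask)
    return path_xy, mask


def fit_spline_sample(
    path_xy: np.ndarray,
    n: int = 10,
    smooth: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline smoothing of a pixel path, resampled by arc length.

    Returns (points, tangent_angles): ``points`` are n backbone samples
    equally spaced in arc length; ``tangent_angles`` the analytic spline
    tangent direction at those samples (radians, CCW from +x), which is
    more stable at n = 10 than finite differences of the samples.
    """
    path_xy = np.asarray(path_xy, dtype=float)
    if path_xy.shape[0] < 4:
        raise InvalidInputError("path must have at least 4 points")
    if n < 3:
        raise InvalidInputError("n must be >= 3")
    if n > path_xy.shape[0]:
        raise InvalidInputError("n exceeds path length")
    # collapse consecutive duplicates, which break splprep
    keep = np.ones(path_xy.shape[0], dtype=bool)
    keep[1:] = np.any(np.diff(path_xy, axis=0) != 0, axis=1)
    path_xy = path_xy[keep]
    if smooth is None:
        smooth = path_xy.shape[0] * 0.5  # ~0.7 px rms pixelation noise
    tck, _ = splprep(path_xy.T, s=smooth, k=3)
    # dense arc-length table
    u_fine = np.linspace(0.0, 1.0, 40 * path_xy.shape[0])
    x, y = splev(u_fine, tck)
    seg = np.hypot(np.diff(x), np.diff(y))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n)
    u_samples = np.interp(targets, arc, u_fine)
    xs, ys = splev(u_samples, tck)
    dx, dy = splev(u_samples, tck, der=1)
    angles = np.arctan2(dy, dx)
    return np.column_stack([xs, ys]), np.asarray(angles)


def orient_head(
    points: np.ndarray,
    mask: np.ndarray,
    prev_head: np.ndarray | None = None,
) -> bool:
    """Decide whether the path is head-first; True means keep as is.

    The head end is the end with the larger local body width (Euclidean
    distance transform of the mask averaged over the first 15% of arc).
    When both ends are within 20% width of each other the decision is
    ambiguous and falls back to temporal continuity: the end closer to
    the previous frame's head position wins.
    """
    dist = ndimage.distance_transform_edt(mask)
    n = points.shape[0]
    k = max(1, int(round(0.15 * n)))

    def width(pts: np.ndarray) -> float:
        r = np.clip(pts[:, 1].round().astype(int), 0, mask.shape[0] - 1)
        c = np.clip(pts[:, 0].round().astype(int), 0, mask.shape[1] - 1)
        return float(dist[r, c].mean())

    w_head = width(points[:k])
    w_tail = width(points[-k:])
    if prev_head is not None and abs(w_head - w_tail) < 0.2 * max(w_head, w_tail):
        d_keep = np.hypot(*(points[0] - prev_head))
        d_flip = np.hypot(*(points[-1] - prev_head))
        return d_keep <= d_flip
    return w_head >= w_tail


def compute_spine_angles(frames: list[BackboneFrame]) -> SpineAngleMatrix:
    """Tangent angles along each backbone, referenced to the head.

    θ(s_j) is the unwrapped tangent direction at arc sample j (no ±π
    jumps along the body); Δθ(s_j) = θ(s_j) − θ(s_0).
    """
    if not frames:
        raise InvalidInputError("no frames")
    n = frames[0].n
    if any(f.n != n for f in frames):
        raise InvalidInputError("mixed n across frames")
    m = len(frames)
    dtheta = np.zeros((m, n))
    theta_head = np.zeros(m)
    times = np.zeros(m)
    for i, f in enumerate(frames):
        seg = np.diff(f.points, axis=0)
        theta = np.arctan2(seg[:, 1], seg[:, 0])
        # segment angles approximate tangents at midpoints; average
        # adjacent segments for interior samples
        full = np.empty(n)
        full[0] = theta[0]
        full[-1] = theta[-1]
        full[1:-1] = theta[:-1] + 0.5 * _angdiff(theta[1:], theta[:-1])
        full = np.unwrap(full)
        dtheta[i] = full - full[0]
        theta_head[i] = full[0]
        times[i] = f.timestamp_ms
    return SpineAngleMatrix(dtheta=dtheta, time_ms=times, theta_head=theta_head)


def _angdiff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed angular difference a - b wrapped to (-pi, pi]."""
    return (a - b + np.pi) % (2 * np.pi) - np.pi


def spine_angles_from_tangents(
    points: list[np.ndarray],
    tangents: list[np.ndarray],
    time_ms: np.ndarray,
) -> SpineAngleMatrix:
    """Spine-angle matrix from analytic spline tangents per frame."""
    n = tangents[0].size
    m = len(tangents)
    dtheta = np.zeros((m, n))
    theta_head = np.zeros(m)
    for i, th in enumerate(tangents):
        full = np.unwrap(np.asarray(th))
        dtheta[i] = full - full[0]
        theta_head[i] = full[0]
    return SpineAngleMatrix(
        dtheta=dtheta, time_ms=np.asarray(time_ms, float), theta_head=theta_head
    )


def extract_spine(
    stack: FrameStack,
    roi: np.ndarray,
    n_points: int = 10,
    threshold: float | None = None,
) -> SpineAngleMatrix:
    """Full chain: background -> segmentation -> spline -> spine angles."""
    sub = subtract_background(stack, roi)
    dt = 1000.0 / stack.frame_rate
    tangents = []
    pts_all = []
    prev_head = None
    for i in range(sub.n_frames):
        path, mask = segment_and_skeletonize(sub.frames[i], threshold=threshold)
        pts, ang = fit_spline_sample(path, n=n_points)
        if not orient_head(pts, mask, prev_head):
            pts = pts[::-1]
            # tangent of the reversed curve points the other way
            ang = np.flip(ang) + np.pi
        prev_head = pts[0]
        pts_all.append(pts)
        tangents.append(ang)
    time_ms = dt * np.arange(sub.n_frames)
    return spine_angles_from_tangents(pts_all, tangents, time_ms)
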
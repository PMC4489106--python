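"""Stage orchestration: synth -> eigen -> cycles -> embed -> cluster/density.

Each stage reads and writes the documented delimited-text formats, so any
stage can also be run on its own (or from the command line) with results
identical to the orchestrated run.  A manifest records every output file
with its SHA-256 checksum and the seed used, making reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, eigenshape, trajectory
from .spine import read_spine, write_spine
from .synthetic import EnsembleSpec, generate_ensemble, write_labels

log = logging.getLogger("fishposture.pipeline")

STAGE_ORDER = ["synth", "eigen", "cycles", "embed", "cluster", "density"]


class MissingDependencyError(RuntimeError):
    """An upstream stage output required by this stage does not exist."""


@dataclass
class RunConfig:
    stages: list[str]
    out_dir: Path
    seed: int = 0
    ensemble: EnsembleSpec | None = None
    n_modes: int = 3
    grid_points: int = 50
    k_max: int = 8
    b_refs: int = 50

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        order = {s: i for i, s in enumerate(STAGE_ORDER)}
        unknown = [s for s in self.stages if s not in order]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        self.stages = sorted(self.stages, key=order.__getitem__)

    def stage_seed(self, stage: str) -> int:
        """Independent per-stage seed derived from the global seed."""
        return (self.seed * 1000 + STAGE_ORDER.index(stage)) % (2**31 - 1)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> list[dict]:
    """Execute the configured stages in order; return the output manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def record(stage: str, *paths: Path) -> None:
        for p in paths:
            manifest.append(
                {
                    "file": str(p),
                    "stage": stage,
                    "sha256": _checksum(p),
                    "seed": config.stage_seed(stage),
                }
            )

    def require(path: Path, stage: str) -> Path:
        if not path.exists():
            raise MissingDependencyError(f"stage '{stage}' needs missing {path}")
        return path

    for stage in config.stages:
        t0 = time.perf_counter()
        if stage == "synth":
            spec = config.ensemble or EnsembleSpec()
            spec.seed = config.stage_seed("synth")
            recs = generate_ensemble(spec)
            spine_dir = out / "spines"
            spine_dir.mkdir(exist_ok=True)
            for r in recs:
                write_spine(r.spine, spine_dir / f"{r.spine.bout_id}.tsv")
            write_labels(recs, out / "labels.tsv")
            record(stage, out / "labels.tsv", *sorted(spine_dir.glob("*.tsv")))
        elif stage == "eigen":
            spine_dir = require(out / "spines", stage)
            spines = [read_spine(p) for p in sorted(spine_dir.glob("*.tsv"))]
            basis, trajs = eigenshape.decompose(spines)
            eigenshape.write_basis(basis, out / "basis.tsv")
            traj_dir = out / "trajectories"
            traj_dir.mkdir(exist_ok=True)
            for tr in trajs:
                eigenshape.write_trajectory(tr, traj_dir / f"{tr.bout_id}.tsv")
            record(stage, out / "basis.tsv", *sorted(traj_dir.glob("*.tsv")))
        elif stage == "cycles":
            basis = eigenshape.read_basis(require(out / "basis.tsv", stage))
            traj_dir = require(out / "trajectories", stage)
            labels = pd.read_csv(require(out / "labels.tsv", stage), sep="\t")
            meta = {
                row.bout_id: dict(
                    bout_id=row.bout_id, fish_id=row.fish_id, age_group=row.age_group
                )
                for row in labels.itertuples()
            }
            trajs = [
                eigenshape.read_trajectory(p, basis)
                for p in sorted(traj_dir.glob("*.tsv"))
            ]
            trajs = [
                eigenshape.PosturalTrajectory(
                    U=t.U[:, : config.n_modes],
                    time_ms=t.time_ms,
                    basis=basis,
                    bout_id=t.bout_id,
                )
                for t in trajs
            ]
            segs = trajectory.normalize_and_align(
                trajs,
                grid_points=config.grid_points,
                meta=[meta.get(t.bout_id, {}) for t in trajs],
            )
            flips = trajectory.mirror_flip_modes(basis)[: config.n_modes]
            segs = trajectory.normalize_ensemble_handedness(segs, flips)
            trajectory.write_cycles(segs, out / "cycles.tsv")
            record(stage, out / "cycles.tsv")
        elif stage == "embed":
            basis = eigenshape.read_basis(require(out / "basis.tsv", stage))
            segs = trajectory.read_cycles(require(out / "cycles.tsv", stage))
            dm = behavior.pairwise_distance(segs, basis.S[: config.n_modes])
            emb = behavior.embed_mds(dm, D=3, D_max=6)
            df = pd.DataFrame(
                emb.coords, columns=[f"mds_{i + 1}" for i in range(emb.coords.shape[1])]
            )
            df.insert(0, "id", dm.ids)
            df.to_csv(out / "embedding.tsv", sep="\t", index=False)
            pd.DataFrame(
                {
                    "D": np.arange(1, emb.max_rel_error.size + 1),
                    "max_rel_error": emb.max_rel_error,
                }
            ).to_csv(out / "embedding_error.tsv", sep="\t", index=False)
            record(stage, out / "embedding.tsv", out / "embedding_error.tsv")
        elif stage == "cluster":
            df = pd.read_csv(require(out / "embedding.tsv", stage), sep="\t")
            coords = df[["mds_1", "mds_2"]].to_numpy()
            res = behavior.cluster_gap(
                coords,
                k_max=config.k_max,
                B_refs=config.b_refs,
                seed=config.stage_seed("cluster"),
            )
            df["cluster"] = res.labels
            df.to_csv(out / "clusters.tsv", sep="\t", index=False)
            pd.DataFrame(
                {"k": np.arange(1, res.gap.size + 1), "gap": res.gap, "log_W": res.log_W}
            ).to_csv(out / "gap.tsv", sep="\t", index=False)
            record(stage, out / "clusters.tsv", out / "gap.tsv")
        elif stage == "density":
            df = pd.read_csv(require(out / "embedding.tsv", stage), sep="\t")
            dmap = behavior.density_map(df[["mds_1", "mds_2"]].to_numpy())
            np.savetxt(out / "density.tsv", dmap.density, delimiter="\t", fmt="%.9g")
            record(stage, out / "density.tsv")
        log.info(
            "stage=%s wall_s=%.2f out_dir=%s", stage, time.perf_counter() - t0, out
        )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
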
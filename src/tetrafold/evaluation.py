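"""Docking-log aggregation and predicted-vs-reference structure comparison.

Docking itself is external: this module consumes the plain-text pose tables
that docking tools emit (one row per pose: run id, pose rank, affinity in
kcal/mol, RMSD lower bound, RMSD upper bound), aggregates them into the
three-metric score (mean affinity / RLB / RUB over all records, e.g. 20 runs
x 9 poses = 180 records), and compares C-alpha backbones by Kabsch RMSD.
A seeded fixture generator makes all of the aggregation math testable without
running any docking binary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .structure import BackboneStructure, kabsch_rmsd, kabsch_rotation

__all__ = [
    "DockingPose",
    "DockingSummary",
    "parse_docking_table",
    "aggregate_docking",
    "compare_structures",
    "make_docking_fixture",
]

_REQUIRED_COLUMNS = ("run", "rank", "affinity", "rmsd_lb", "rmsd_ub")


@dataclass(frozen=True)
class DockingPose:
    """One docking pose record."""

    run_id: int
    pose_rank: int
    affinity: float
    rmsd_lb: float
    rmsd_ub: float

    def __post_init__(self) -> None:
        if self.pose_rank < 1:
            raise ValueError("pose_rank must be >= 1")
        if self.rmsd_lb > self.rmsd_ub:
            raise ValueError(
                f"rmsd_lb ({self.rmsd_lb}) exceeds rmsd_ub ({self.rmsd_ub})"
            )


@dataclass(frozen=True)
class DockingSummary:
    """Mean affinity / RLB / RUB over all records, with a completeness flag."""

    n_records: int
    mean_affinity: float
    mean_rlb: float
    mean_rub: float
    complete: bool = True


def parse_docking_table(path) -> list[DockingPose]:
    """Read a whitespace- or comma-delimited pose table.

    Required columns: run, rank, affinity, rmsd_lb, rmsd_ub.  Rows violating
    rmsd_lb <= rmsd_ub are reported with their line numbers.
    """
    with open(path) as fh:
        if not fh.read().strip():
            import warnings

            warnings.warn("docking table is empty", stacklevel=2)
            return []
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"docking table is missing columns: {', '.join(missing)}")
    if df.empty:
        import warnings

        warnings.warn("docking table contains no pose records", stacklevel=2)
        return []
    bad = df.index[df["rmsd_lb"] > df["rmsd_ub"]]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad)  # +2: header + 1-based
        raise ValueError(f"rmsd_lb > rmsd_ub on line(s) {lines}")
    return [
        DockingPose(
            run_id=int(r.run),
            pose_rank=int(r.rank),
            affinity=float(r.affinity),
            rmsd_lb=float(r.rmsd_lb),
            rmsd_ub=float(r.rmsd_ub),
        )
        for r in df.itertuples()
    ]


def aggregate_docking(
    poses: Sequence[DockingPose],
    expected_runs: int | None = None,
    expected_poses: int | None = None,
) -> DockingSummary:
    """Arithmetic means of the three metrics over all pose records.

    If expected run/pose counts are given, ``complete`` reports whether the
    record count equals runs x poses (missing data is flagged, never imputed).
    """
    if not poses:
        raise ValueError("no pose records to aggregate")
    n = len(poses)
    complete = True
    if expected_runs is not None and expected_poses is not None:
        complete = n == expected_runs * expected_poses
    return DockingSummary(
        n_records=n,
        mean_affinity=float(np.mean([p.affinity for p in poses])),
        mean_rlb=float(np.mean([p.rmsd_lb for p in poses])),
        mean_rub=float(np.mean([p.rmsd_ub for p in poses])),
        complete=complete,
    )


def compare_structures(
    predicted: BackboneStructure, reference: BackboneStructure
) -> dict:
    """Kabsch RMSD between two C-alpha traces plus a per-residue profile."""
    if predicted.residue_count != reference.residue_count:
        raise ValueError(
            f"residue count mismatch: predicted has {predicted.residue_count}, "
            f"reference has {reference.residue_count}; trim both to the shared "
            "residue range before comparing"
        )
    a = predicted.ca_coords - predicted.ca_coords.mean(axis=0)
    b = reference.ca_coords - reference.ca_coords.mean(axis=0)
    rot = kabsch_rotation(a, b)
    per_residue = np.linalg.norm(a @ rot.T - b, axis=1)
    return {
        "rmsd": kabsch_rmsd(predicted.ca_coords, reference.ca_coords),
        "per_residue_deviation": per_residue,
        "n_residues": predicted.residue_count,
    }


def make_docking_fixture(runs: int, poses: int, seed: int, path) -> None:
    """Write a seeded-deterministic synthetic pose table.

    Plausible ranges: affinity in [-10, 0] kcal/mol, 0 <= rmsd_lb <= rmsd_ub
    <= 15 Angstrom.  Same seed, same bytes.
    """
    if runs < 1 or poses < 1:
        raise ValueError("runs and poses must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(1, runs + 1):
        for rank in range(1, poses + 1):
            affinity = rng.uniform(-10.0, 0.0)
            lb = rng.uniform(0.0, 8.0)
            ub = min(lb + rng.uniform(0.0, 7.0), 15.0)
            rows.append((run, rank, affinity, lb, ub))
    with open(path, "w") as fh:
        fh.write("run,rank,affinity,rmsd_lb,rmsd_ub\n")
        for run, rank, affinity, lb, ub in rows:
            fh.write(f"{run},{rank},{affinity:.3f},{lb:.3f},{ub:.3f}\n")
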
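"""Pore geometry: centre estimation by least-squares line intersection,
per-pore radius/diameter with an occupancy filter, and dataset summaries.

Each subunit observation is a point plus a unit "inward" direction; the
centre of a pore is the point minimising the summed squared perpendicular
distance to the lines so defined. The reported diameter is twice the mean
centre-to-subunit distance; opposing-pair (i, i+4 mod 8) distances are
reported as diagnostics only. An optional constant offset can be added to
convert subunit-centre diameters to membrane-to-membrane diameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import ValidationError

__all__ = [
    "SubunitObservation",
    "PoreGeometry",
    "RejectedNPC",
    "DegenerateGeometryError",
    "estimate_centre",
    "pore_diameter",
    "diameter_distribution",
    "observations_from_table",
]

DEFAULT_MIN_OCCUPANCY = 5


class DegenerateGeometryError(ValidationError):
    """Subunit direction lines do not determine a unique centre."""


@dataclass
class SubunitObservation:
    npc_id: int
    subunit_index: int
    position: np.ndarray
    inward_direction: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.inward_direction = np.asarray(self.inward_direction, dtype=float)
        if self.position.shape != (3,) or self.inward_direction.shape != (3,):
            raise ValidationError("position and direction must be 3-vectors")
        norm = np.linalg.norm(self.inward_direction)
        if abs(norm - 1.0) > 1e-6:
            raise ValidationError(
                f"inward_direction must be unit length (|d|={norm:.6f})")
        if not 0 <= self.subunit_index <= 7:
            raise ValidationError("subunit_index must be in 0..7")


@dataclass
class PoreGeometry:
    npc_id: int
    centre: np.ndarray
    mean_radius: float
    occupancy: int
    opposing_distances: dict[tuple[int, int], float] = field(default_factory=dict)
    membrane_offset: float = 0.0

    @property
    def diameter(self) -> float:
        return 2.0 * self.mean_radius + self.membrane_offset


@dataclass
class RejectedNPC:
    """Typed rejection (not an exception) for under-occupied pores."""

    npc_id: int
    occupancy: int
    reason: str


def observations_from_table(table: pd.DataFrame) -> list[SubunitObservation]:
    """Build observations from a table with columns npc_id, subunit_index,
    x0..x2, d0..d2 (the layout emitted by the synthetic generator)."""
    obs = []
    for row in table.itertuples(index=False):
        obs.append(SubunitObservation(
            npc_id=int(row.npc_id), subunit_index=int(row.subunit_index),
            position=np.array([row.x0, row.x1, row.x2]),
            inward_direction=np.array([row.d0, row.d1, row.d2])))
    return obs


def estimate_centre(subunits: list[SubunitObservation]) -> np.ndarray:
    """Least-squares intersection of the subunit direction lines.

    Solves ``sum_i (I - d_i d_i^T) (c - p_i) = 0``; exact when the lines are
    concurrent. Raises :class:`DegenerateGeometryError` when all lines are
    (near) parallel, in which case no unique point exists.
    """
    if len(subunits) < 2:
        raise ValidationError("need at least two subunits to find a centre")
    a = np.zeros((3, 3))
    b = np.zeros(3)
    for s in subunits:
        d = s.inward_direction
        proj = np.eye(3) - np.outer(d, d)
        a += proj
        b += proj @ s.position
    if np.linalg.cond(a) > 1e8:
        raise DegenerateGeometryError(
            "subunit direction lines are (near) parallel; centre undefined")
    return np.linalg.solve(a, b)


def pore_diameter(subunits: list[SubunitObservation],
                  min_occupancy: int = DEFAULT_MIN_OCCUPANCY,
                  membrane_offset: float = 0.0):
    """Centre, mean radius and diameter for one pore, or a typed rejection
    when fewer than ``min_occupancy`` subunits are present."""
    if not subunits:
        raise ValidationError("empty subunit list")
    npc_ids = {s.npc_id for s in subunits}
    if len(npc_ids) != 1:
        raise ValidationError(f"subunits span several pores: {sorted(npc_ids)}")
    npc_id = subunits[0].npc_id
    occupancy = len({s.subunit_index for s in subunits})
    if occupancy < min_occupancy:
        return RejectedNPC(npc_id, occupancy,
                           f"occupancy {occupancy} < {min_occupancy}")
    centre = estimate_centre(subunits)
    radii = [np.linalg.norm(s.position - centre) for s in subunits]
    by_index = {s.subunit_index: s for s in subunits}
    opposing = {}
    for i in range(4):
        j = i + 4
        if i in by_index and j in by_index:
            opposing[(i, j)] = float(np.linalg.norm(
                by_index[i].position - by_index[j].position))
    return PoreGeometry(npc_id=npc_id, centre=centre,
                        mean_radius=float(np.mean(radii)),
                        occupancy=occupancy, opposing_distances=opposing,
                        membrane_offset=membrane_offset)


def diameter_distribution(table, min_occupancy: int = DEFAULT_MIN_OCCUPANCY,
                          membrane_offset: float = 0.0):
    """Per-pore geometries plus a dataset summary.

    ``table`` is either a DataFrame (synthetic layout) or a list of
    observations. Returns ``(geometries, rejected, summary)`` where summary
    holds mean/sd/n over admissible diameters (n=0 summary when none pass).
    """
    if isinstance(table, pd.DataFrame):
        observations = observations_from_table(table)
    else:
        observations = list(table)
    by_npc: dict[int, list[SubunitObservation]] = {}
    for s in observations:
        by_npc.setdefault(s.npc_id, []).append(s)
    geometries: list[PoreGeometry] = []
    rejected: list[RejectedNPC] = []
    for npc_id in sorted(by_npc):
        out = pore_diameter(by_npc[npc_id], min_occupancy=min_occupancy,
                            membrane_offset=membrane_offset)
        (geometries if isinstance(out, PoreGeometry) else rejected).append(out)
    if geometries:
        diameters = np.array([g.diameter for g in geometries])
        summary = {"mean_diameter": float(diameters.mean()),
                   "sd_diameter": float(diameters.std(ddof=1))
                   if len(diameters) > 1 else 0.0,
                   "n": len(diameters),
                   "n_rejected": len(rejected)}
    else:
        summary = {"mean_diameter": None, "sd_diameter": None, "n": 0,
                   "n_rejected": len(rejected)}
    return geometries, rejected, summary
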
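"""Rigid-body integrative refinement against a density map.

Four restraint classes drive a simulated-annealing Monte Carlo search over
rigid-body poses: an EM fit term (one minus the normalised cross-correlation
between the map and a Gaussian rendering of the ten-residue coarse beads),
a soft-sphere clash score, sequence-connectivity upper-bound harmonics, and
an elastic network of inter-body distance restraints frozen at setup from a
reference model. All restraints except the EM fit act on the Cα beads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .scaffold import ScaffoldModel, coarse_beads
from .volume import DensityVolume, Pose, ValidationError

__all__ = [
    "RigidBody",
    "RestraintSet",
    "ScoreBreakdown",
    "ConnectivityPair",
    "ElasticPair",
    "RigidBodyModel",
    "render_beads",
    "em_fit_score",
    "clash_score",
    "connectivity_score",
    "elastic_network_score",
    "build_elastic_network",
    "total_score",
    "refine",
    "linker_max_length",
]

CA_VIRTUAL_BOND = 3.8           # Å per residue of unmodelled linker


def linker_max_length(n_linker_residues: int) -> float:
    """Connectivity upper bound: 3.8 Å x (unmodelled residues + 1)."""
    if n_linker_residues < 0:
        raise ValidationError("linker residue count must be >= 0")
    return CA_VIRTUAL_BOND * (n_linker_residues + 1)


@dataclass
class ConnectivityPair:
    chain_a: int                # chain index in the scaffold model
    residue_a: int              # 0-based residue index
    chain_b: int
    residue_b: int
    max_length: float
    k: float = 1.0


@dataclass
class ElasticPair:
    chain_a: int
    residue_a: int
    chain_b: int
    residue_b: int
    rest_length: float
    k: float = 0.1

    def __post_init__(self) -> None:
        if self.rest_length <= 0:
            raise ValidationError("elastic rest_length must be > 0")
        if self.k < 0:
            raise ValidationError("elastic k must be >= 0")


@dataclass
class RestraintSet:
    em_weight: float = 1.0
    clash_radius: float = 2.0   # Å per Cα bead
    clash_k: float = 1.0
    connectivity: list[ConnectivityPair] = field(default_factory=list)
    elastic: list[ElasticPair] = field(default_factory=list)
    render_sigma: float = 8.0   # Å, Gaussian width of coarse beads

    def __post_init__(self) -> None:
        if self.clash_k < 0 or self.em_weight < 0:
            raise ValidationError("restraint weights must be >= 0")


@dataclass
class ScoreBreakdown:
    em_fit: float
    clash: float
    connectivity: float
    elastic: float
    em_weight: float = 1.0

    @property
    def total(self) -> float:
        return (self.em_weight * self.em_fit + self.clash
                + self.connectivity + self.elastic)

    def as_dict(self) -> dict[str, float]:
        return {"em_fit": self.em_fit, "clash": self.clash,
                "connectivity": self.connectivity, "elastic": self.elastic,
                "total": self.total}


@dataclass
class RigidBody:
    """A group of chains moved as one unit about its own centroid."""

    chain_indices: list[int]
    pose: Pose = field(default_factory=Pose.identity)
    max_translation: float = 50.0       # Å per refinement move budget
    max_rotation: float = 30.0          # degrees


class RigidBodyModel:
    """A scaffold model partitioned into rigid bodies with mutable poses.

    Internal coordinates of each body are immutable; only poses change.
    """

    def __init__(self, model: ScaffoldModel, bodies: list[RigidBody]):
        if not bodies:
            raise ValidationError("need at least one rigid body")
        assigned = [i for b in bodies for i in b.chain_indices]
        if sorted(assigned) != list(range(len(model.chains))):
            raise ValidationError(
                "rigid bodies must partition the model's chains")
        self.reference = model
        self.bodies = bodies
        self._ref_coords = [c.coords.copy() for c in model.chains]
        self._centroids = []
        for body in bodies:
            pts = np.concatenate([self._ref_coords[i]
                                  for i in body.chain_indices])
            self._centroids.append(pts.mean(axis=0))
        self.body_of_chain = {}
        for bi, body in enumerate(bodies):
            for ci in body.chain_indices:
                self.body_of_chain[ci] = bi

    def chain_coords(self, chain_index: int) -> np.ndarray:
        bi = self.body_of_chain[chain_index]
        pose = self.bodies[bi].pose
        c = self._centroids[bi]
        ref = self._ref_coords[chain_index]
        return (ref - c) @ pose.rotation.T + c + pose.shift

    def body_ca(self, body_index: int) -> np.ndarray:
        body = self.bodies[body_index]
        return np.concatenate([self.chain_coords(i)
                               for i in body.chain_indices])

    def all_coarse_beads(self) -> np.ndarray:
        beads = []
        for ci in range(len(self._ref_coords)):
            beads.append(coarse_beads(self.chain_coords(ci)))
        return np.concatenate(beads) if beads else np.zeros((0, 3))

    def set_poses(self, poses: list[Pose]) -> None:
        for body, pose in zip(self.bodies, poses):
            body.pose = pose

    def poses(self) -> list[Pose]:
        return [Pose(b.pose.rotation.copy(), b.pose.shift.copy())
                for b in self.bodies]

    def as_scaffold(self) -> ScaffoldModel:
        from .scaffold import Chain
        chains = []
        for ci, c in enumerate(self.reference.chains):
            chains.append(Chain(
                chain_id=c.chain_id, species=c.species, ring=c.ring,
                asym_unit_index=c.asym_unit_index,
                subcomplex_label=c.subcomplex_label,
                subcomplex_instance=c.subcomplex_instance,
                coords=self.chain_coords(ci)))
        return ScaffoldModel(chains, self.reference.symmetry_order)

    def ca_rmsd_to_reference(self) -> float:
        cur = np.concatenate([self.chain_coords(i)
                              for i in range(len(self._ref_coords))])
        ref = np.concatenate(self._ref_coords)
        return float(np.sqrt(((cur - ref) ** 2).sum(axis=1).mean()))


# --------------------------------------------------------------------------
# restraint scores
# --------------------------------------------------------------------------

def render_beads(beads: np.ndarray, like: DensityVolume,
                 sigma: float = 8.0) -> np.ndarray:
    """Gaussian-render bead positions (Å) onto the grid of ``like``.

    Beads outside the box simply contribute their in-box tail (clipped
    contributions count as zero as documented).
    """
    grid = np.zeros(like.shape, dtype=float)
    voxel = like.voxel_size
    centre = (np.asarray(like.shape, float) - 1.0) / 2.0
    cut = int(np.ceil(3.0 * sigma / voxel))
    axes = [np.arange(n) for n in like.shape]
    for bead in np.atleast_2d(beads):
        pos_vox = bead / voxel + centre
        lo = np.maximum(np.floor(pos_vox).astype(int) - cut, 0)
        hi = np.minimum(np.floor(pos_vox).astype(int) + cut + 1,
                        np.asarray(like.shape))
        if np.any(lo >= hi):
            continue
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        local = [(axes[d][lo[d]:hi[d]] - pos_vox[d]) * voxel for d in range(3)]
        d2 = (local[0][:, None, None] ** 2 + local[1][None, :, None] ** 2
              + local[2][None, None, :] ** 2)
        grid[sl] += np.exp(-d2 / (2.0 * sigma ** 2))
    return grid


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def em_fit_score(model, density: DensityVolume, sigma: float = 8.0) -> float:
    """1 − NCC between the map and the coarse-bead rendering; in [0, 2]."""
    beads = (model.all_coarse_beads() if isinstance(model, RigidBodyModel)
             else np.concatenate([coarse_beads(c.coords)
                                  for c in model.chains])
             if model.chains else np.zeros((0, 3)))
    if len(beads) == 0:
        raise ValidationError("cannot score an empty model")
    rendered = render_beads(beads, density, sigma=sigma)
    return 1.0 - _ncc(rendered, density.grid)


def clash_score(model, radius: float = 2.0, k: float = 1.0) -> float:
    """Soft-sphere penalty over Cα pairs from *different* rigid bodies:
    ``sum k * max(0, r_i + r_j - d)^2``."""
    if isinstance(model, RigidBodyModel):
        groups = [model.body_ca(bi) for bi in range(len(model.bodies))]
    else:
        groups = [c.coords for c in model.chains]    # chain = body fallback
    total = 0.0
    cutoff = 2.0 * radius
    trees = [cKDTree(g) for g in groups]
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            pairs = trees[i].query_ball_tree(trees[j], cutoff)
            for ai, hits in enumerate(pairs):
                if not hits:
                    continue
                d = np.linalg.norm(groups[j][hits] - groups[i][ai], axis=1)
                overlap = np.maximum(0.0, cutoff - d)
                total += k * float((overlap ** 2).sum())
    return total


def _pair_coords(model, pair):
    if isinstance(model, RigidBodyModel):
        get = model.chain_coords
        n_chains = len(model.reference.chains)
        n_res = [len(c.coords) for c in model.reference.chains]
    else:
        get = lambda ci: model.chains[ci].coords  # noqa: E731
        n_chains = len(model.chains)
        n_res = [c.n_residues for c in model.chains]
    for ci, ri in ((pair.chain_a, pair.residue_a),
                   (pair.chain_b, pair.residue_b)):
        if not (0 <= ci < n_chains) or not (0 <= ri < n_res[ci]):
            raise ValidationError(
                f"restraint references missing residue {ri} of chain {ci}")
    return (get(pair.chain_a)[pair.residue_a],
            get(pair.chain_b)[pair.residue_b])


def connectivity_score(model, pairs: list[ConnectivityPair]) -> float:
    """Upper-bound harmonics: ``sum k * max(0, d - max_length)^2``."""
    total = 0.0
    for pair in pairs:
        a, b = _pair_coords(model, pair)
        d = float(np.linalg.norm(a - b))
        excess = max(0.0, d - pair.max_length)
        total += pair.k * excess ** 2
    return total


def elastic_network_score(model, pairs: list[ElasticPair]) -> float:
    """Harmonic network: ``sum k * (d - rest_length)^2``."""
    total = 0.0
    for pair in pairs:
        a, b = _pair_coords(model, pair)
        d = float(np.linalg.norm(a - b))
        total += pair.k * (d - pair.rest_length) ** 2
    return total


def build_elastic_network(model: RigidBodyModel, cutoff: float = 10.0,
                          k: float = 0.1) -> list[ElasticPair]:
    """All inter-body Cα pairs within ``cutoff`` at the reference geometry,
    with rest lengths frozen at the current distances."""
    pairs: list[ElasticPair] = []
    n_chains = len(model.reference.chains)
    coords = [model.chain_coords(ci) for ci in range(n_chains)]
    trees = [cKDTree(c) for c in coords]
    for ci in range(n_chains):
        for cj in range(ci + 1, n_chains):
            if model.body_of_chain[ci] == model.body_of_chain[cj]:
                continue
            hits = trees[ci].query_ball_tree(trees[cj], cutoff)
            for ri, js in enumerate(hits):
                for rj in js:
                    d = float(np.linalg.norm(coords[ci][ri] - coords[cj][rj]))
                    if d > 0:
                        pairs.append(ElasticPair(ci, ri, cj, rj, d, k))
    return pairs


def total_score(model, density: DensityVolume,
                restraints: RestraintSet) -> ScoreBreakdown:
    breakdown = ScoreBreakdown(
        em_fit=em_fit_score(model, density, sigma=restraints.render_sigma),
        clash=clash_score(model, radius=restraints.clash_radius,
                          k=restraints.clash_k),
        connectivity=connectivity_score(model, restraints.connectivity),
        elastic=elastic_network_score(model, restraints.elastic),
        em_weight=restraints.em_weight)
    for name, value in breakdown.as_dict().items():
        if not np.isfinite(value):
            raise RuntimeError(f"non-finite {name} score during refinement")
    return breakdown


# --------------------------------------------------------------------------
# simulated annealing
# --------------------------------------------------------------------------

def _random_rotation_matrix(rng, max_angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.normal(0.0, max_angle_deg))
    kx, ky, kz = axis
    km = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return (np.eye(3) + np.sin(angle) * km
            + (1 - np.cos(angle)) * (km @ km))


def refine(model: RigidBodyModel, density: DensityVolume,
           restraints: RestraintSet,
           temperatures=(5.0, 2.0, 1.0, 0.4, 0.1),
           steps_per_temperature: int = 2000,
           translation_step: float = 3.0,
           rotation_step: float = 3.0,
           seed: int = 0):
    """Metropolis simulated annealing over rigid-body poses.

    Per step one body receives a random translation/rotation proposal;
    acceptance follows the Metropolis rule on the weighted total score. The
    best model seen is tracked (so best-so-far total is non-increasing along
    the trajectory) and restored at the end. Returns
    ``(model, trajectory)`` where trajectory is a list of per-step
    :class:`ScoreBreakdown` of the current state.
    """
    rng = np.random.default_rng(seed)
    current = total_score(model, density, restraints)
    best_total = current.total
    best_poses = model.poses()
    trajectory = [current]
    n_bodies = len(model.bodies)
    t_max = max(temperatures)
    for temperature in temperatures:
        # shrink moves with temperature so late stages refine locally
        scale = max(0.15, np.sqrt(temperature / t_max))
        for _step in range(steps_per_temperature):
            bi = int(rng.integers(n_bodies))
            body = model.bodies[bi]
            old_pose = body.pose
            delta_r = _random_rotation_matrix(rng, rotation_step * scale)
            delta_t = rng.normal(0.0, translation_step * scale, size=3)
            body.pose = Pose(delta_r @ old_pose.rotation,
                             old_pose.shift + delta_t)
            proposed = total_score(model, density, restraints)
            delta = proposed.total - current.total
            if delta <= 0 or rng.random() < np.exp(-delta / temperature):
                current = proposed
                if current.total < best_total:
                    best_total = current.total
                    best_poses = model.poses()
            else:
                body.pose = old_pose
            trajectory.append(current)
    model.set_poses(best_poses)
    return model, trajectory
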
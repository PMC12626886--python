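"""Synthetic inputs: C8 ring complexes between membrane slabs, wedge-degraded
noisy subtomograms with known poses, subunit coordinate tables at a known pore
diameter, and replicate peptide detection tables.

Every generator is a pure function of its arguments plus one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import (
    DensityVolume,
    Pose,
    ValidationError,
    WedgeModel,
    apply_wedge,
    rotation_about_axis2,
    transform_density,
)

__all__ = [
    "GroundTruthComplex",
    "SimulatedParticle",
    "BoxTooSmallError",
    "make_complex",
    "simulate_particles",
    "simulate_subunit_table",
    "simulate_peptide_table",
    "random_protein_catalogue",
    "random_rotation",
]


class BoxTooSmallError(ValidationError):
    """Requested volume box cannot contain the complex."""


@dataclass
class GroundTruthComplex:
    """Specification of a Cn-symmetric ring of Gaussian blobs between two
    membrane slabs perpendicular to the pore axis (axis 2)."""

    n_spokes: int = 8
    ring_radius: float = 350.0                    # Å
    spoke_blob_spec: list = field(default_factory=lambda: [
        ((0.0, 0.0, 0.0), 30.0, 1.0),
    ])                                            # (offset Å, sigma Å, amplitude)
    membrane_spacing: float = 0.0                 # Å between slab midplanes
    membrane_sigma: float = 15.0                  # Å slab half-thickness scale
    membrane_amplitude: float = 0.0
    box_size: int = 64                            # voxels per edge
    voxel_size: float = 16.0                      # Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spokes < 1:
            raise ValidationError(f"n_spokes must be >= 1, got {self.n_spokes}")
        if not self.ring_radius > 0:
            raise ValidationError("ring_radius must be > 0")
        if not self.spoke_blob_spec:
            raise ValidationError("spoke_blob_spec must be non-empty")
        for offset, sigma, _amp in self.spoke_blob_spec:
            if not sigma > 0:
                raise ValidationError(f"blob sigma must be > 0, got {sigma}")
            if len(tuple(offset)) != 3:
                raise ValidationError("blob offset must be a 3-vector")

    def required_extent(self) -> float:
        """Minimum half-edge (Å) needed to contain ring + 3 sigma of blobs
        (and, if present, the membrane discs)."""
        reach = 0.0
        for offset, sigma, _amp in self.spoke_blob_spec:
            reach = max(reach,
                        float(np.linalg.norm(offset)) + 3.0 * float(sigma))
        extent = self.ring_radius + reach
        if self.membrane_amplitude > 0 and self.membrane_spacing > 0:
            extent = max(extent,
                         self.ring_radius + 3.0 * self.membrane_sigma,
                         self.membrane_spacing / 2.0
                         + 3.0 * self.membrane_sigma)
        return extent

    def minimal_box(self) -> int:
        return int(np.ceil(2.0 * self.required_extent() / self.voxel_size)) + 1


@dataclass
class SimulatedParticle:
    particle_id: int
    true_pose: Pose
    subtomogram: DensityVolume
    wedge: WedgeModel
    noise_sigma: float

    def __post_init__(self) -> None:
        self.subtomogram.require_cubic()


def _grid_coords(box_size: int, voxel_size: float) -> tuple[np.ndarray, ...]:
    centre = (box_size - 1) / 2.0
    ax = (np.arange(box_size) - centre) * voxel_size
    return np.meshgrid(ax, ax, ax, indexing="ij")


def make_complex(spec: GroundTruthComplex) -> tuple[DensityVolume, list[Pose]]:
    """Render the ground-truth complex analytically (no interpolation) so the
    volume is Cn-symmetric to floating-point accuracy; returns the volume and
    the ``n_spokes`` ground-truth spoke poses."""
    half_extent = spec.box_size * spec.voxel_size / 2.0
    if spec.required_extent() > half_extent:
        raise BoxTooSmallError(
            f"box of {spec.box_size} voxels ({2 * half_extent:.0f} Å) cannot "
            f"contain the complex; need at least {spec.minimal_box()} voxels"
        )
    x0, x1, x2 = _grid_coords(spec.box_size, spec.voxel_size)
    grid = np.zeros_like(x0)

    base = np.array([spec.ring_radius, 0.0, 0.0])
    poses: list[Pose] = []
    for k in range(spec.n_spokes):
        rot = rotation_about_axis2(k * 360.0 / spec.n_spokes)
        poses.append(Pose(rot, rot @ base))
        for offset, sigma, amp in spec.spoke_blob_spec:
            p = rot @ (base + np.asarray(offset, dtype=float))
            d2 = (x0 - p[0]) ** 2 + (x1 - p[1]) ** 2 + (x2 - p[2]) ** 2
            grid += amp * np.exp(-d2 / (2.0 * sigma ** 2))

    if spec.membrane_amplitude > 0 and spec.membrane_spacing > 0:
        # two finite membrane discs perpendicular to the pore axis with a
        # soft pore opening; rotationally symmetric, so Cn invariance holds,
        # and radially bounded so nothing leaks past the box corners
        r = np.sqrt(x0 ** 2 + x1 ** 2)
        hole = 1.0 - np.exp(-(r ** 2) / (2.0 * spec.ring_radius ** 2))
        falloff = np.exp(-np.maximum(0.0, r - spec.ring_radius) ** 2
                         / (2.0 * spec.membrane_sigma ** 2))
        for sign in (+1.0, -1.0):
            z0 = sign * spec.membrane_spacing / 2.0
            slab = np.exp(-((x2 - z0) ** 2) / (2.0 * spec.membrane_sigma ** 2))
            grid += spec.membrane_amplitude * slab * hole * falloff

    return DensityVolume(grid, spec.voxel_size), poses


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (Haar measure via quaternions)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _draw_pose(pose_distribution, rng: np.random.Generator) -> Pose:
    if pose_distribution is None or pose_distribution == "identity":
        return Pose.identity()
    if callable(pose_distribution):
        return pose_distribution(rng)
    if pose_distribution == "uniform_inplane":
        ang = rng.uniform(0.0, 360.0)
        return Pose(rotation_about_axis2(ang), np.zeros(3))
    if pose_distribution == "uniform_so3":
        return Pose(random_rotation(rng), np.zeros(3))
    raise ValidationError(f"unknown pose distribution {pose_distribution!r}")


def simulate_particles(reference: DensityVolume, n: int, noise_sigma: float,
                       wedge: WedgeModel, pose_distribution="uniform_inplane",
                       seed: int = 0) -> list[SimulatedParticle]:
    """Noisy wedge-degraded copies of ``reference`` at known poses.

    Each subtomogram is the reference transformed by its true pose, with
    Fourier components inside the missing wedge zeroed and i.i.d. Gaussian
    noise of ``noise_sigma`` added. Identical seeds give identical stacks.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    reference.require_cubic()
    rng = np.random.default_rng(seed)
    particles = []
    for i in range(n):
        pose = _draw_pose(pose_distribution, rng)
        posed = transform_density(reference, pose)
        grid = posed.grid
        if noise_sigma > 0:
            # noise enters before the wedge filter: tomographic noise is
            # itself band-limited by the acquisition geometry
            grid = grid + rng.normal(0.0, noise_sigma, size=grid.shape)
        grid = apply_wedge(grid, wedge)
        particles.append(SimulatedParticle(
            particle_id=i,
            true_pose=pose,
            subtomogram=DensityVolume(grid, reference.voxel_size),
            wedge=wedge,
            noise_sigma=noise_sigma,
        ))
    return particles


def _draw_occupancy(occupancy_distribution, rng: np.random.Generator) -> int:
    if isinstance(occupancy_distribution, (int, np.integer)):
        return int(occupancy_distribution)
    if callable(occupancy_distribution):
        return int(occupancy_distribution(rng))
    if isinstance(occupancy_distribution, dict):
        values = np.array(sorted(occupancy_distribution))
        probs = np.array([occupancy_distribution[v] for v in values], float)
        probs = probs / probs.sum()
        return int(rng.choice(values, p=probs))
    raise ValidationError(
        f"unsupported occupancy distribution {occupancy_distribution!r}"
    )


def simulate_subunit_table(n_npcs: int, true_diameter: float,
                           positional_noise_sigma: float = 0.0,
                           occupancy_distribution=8, seed: int = 0,
                           centre_spread: float = 2000.0) -> pd.DataFrame:
    """Per-subunit positions and inward unit vectors for ``n_npcs`` synthetic
    pores of known diameter.

    Subunits sit on a circle of radius ``true_diameter/2`` around a randomized
    centre in a randomly oriented plane; positions get isotropic Gaussian
    noise; the inward direction points from the noisy position toward the true
    centre (so direction noise is consistent with positional noise).

    Columns: npc_id, subunit_index, x0..x2, d0..d2 (unit inward direction).
    """
    if not true_diameter > 0:
        raise ValidationError("true_diameter must be > 0")
    if positional_noise_sigma < 0:
        raise ValidationError("positional_noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    radius = true_diameter / 2.0
    rows = []
    for npc in range(n_npcs):
        centre = rng.uniform(-centre_spread, centre_spread, size=3)
        frame = random_rotation(rng)
        occupancy = _draw_occupancy(occupancy_distribution, rng)
        occupancy = int(np.clip(occupancy, 0, 8))
        present = rng.permutation(8)[:occupancy]
        phase = rng.uniform(0.0, 45.0)
        for idx in sorted(present):
            ang = np.radians(idx * 45.0 + phase)
            local = radius * np.array([np.cos(ang), np.sin(ang), 0.0])
            pos = centre + frame @ local
            if positional_noise_sigma > 0:
                pos = pos + rng.normal(0.0, positional_noise_sigma, size=3)
            inward = centre - pos
            norm = np.linalg.norm(inward)
            if norm == 0:       # pathological but possible at zero radius
                continue
            inward = inward / norm
            rows.append((npc, int(idx), *pos, *inward))
    return pd.DataFrame(
        rows, columns=["npc_id", "subunit_index",
                       "x0", "x1", "x2", "d0", "d1", "d2"]
    )


# --------------------------------------------------------------------------
# proteomics inputs
# --------------------------------------------------------------------------

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein_catalogue(n_proteins: int, length: int = 300,
                             seed: int = 0) -> dict[str, str]:
    """Random protein sequences keyed by synthetic accession."""
    rng = np.random.default_rng(seed)
    aa = np.array(list(_AMINO_ACIDS))
    return {
        f"PROT{i:03d}": "".join(rng.choice(aa, size=length))
        for i in range(n_proteins)
    }


def simulate_peptide_table(protein_catalogue: dict[str, str], detect_prob,
                           replicates: int = 3, seed: int = 0,
                           missed_cleavages: int = 0,
                           length_range: tuple[int, int] = (6, 30)
                           ) -> pd.DataFrame:
    """Bernoulli detection of each tryptic peptide, per protein per replicate.

    ``detect_prob`` is a float applied to every protein or a dict keyed by
    protein id. Columns: protein_id, replicate (1-based), peptide.
    """
    from .proteomics import tryptic_digest

    if not protein_catalogue:
        raise ValidationError("protein catalogue must be non-empty")
    for pid, seq in protein_catalogue.items():
        if not seq:
            raise ValidationError(f"empty sequence for protein {pid!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for pid in sorted(protein_catalogue):
        peptides = sorted(tryptic_digest(protein_catalogue[pid],
                                         missed_cleavages=missed_cleavages,
                                         length_range=length_range))
        p = detect_prob[pid] if isinstance(detect_prob, dict) else float(detect_prob)
        for rep in range(1, replicates + 1):
            draws = rng.random(len(peptides)) < p
            for pep, hit in zip(peptides, draws):
                if hit:
                    rows.append((pid, rep, pep))
    return pd.DataFrame(rows, columns=["protein_id", "replicate", "peptide"])
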
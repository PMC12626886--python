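"""Scaffold composition, toy chain placement, C8 composite assembly and
stoichiometry accounting.

A composition lists, per ring (CR / IR / NR), the subcomplex instances of one
asymmetric unit and their member species. Species strings may contain
alternatives separated by ``|`` (e.g. ``"NUP93A|NUP93B"``); an alternative
group is counted as a single species placement. Chains carry a dual
representation: per-residue Cα beads and ten-residue coarse beads.

Frame convention: pore axis along axis 2, nucleoplasm at negative axis-2
coordinates (so the NR sits below the IR and the CR above).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .volume import (
    DensityVolume,
    Pose,
    ValidationError,
    rotation_about_axis2,
    transform_volume,
)

__all__ = [
    "RINGS",
    "CompositionConfig",
    "Chain",
    "ScaffoldModel",
    "load_composition",
    "default_composition",
    "save_composition",
    "place_toy_chains",
    "assemble_composite",
    "assemble_composite_map",
    "stoichiometry",
    "coarse_beads",
    "write_scaffold_pdb",
]

RINGS = ("CR", "IR", "NR")

_RING_Z = {"CR": 95.0, "IR": 0.0, "NR": -95.0}   # nucleoplasm at negative z
_RING_RADIUS = {"CR": 360.0, "IR": 320.0, "NR": 360.0}
COARSE_BEAD_RESIDUES = 10


# --------------------------------------------------------------------------
# composition
# --------------------------------------------------------------------------

@dataclass
class SubcomplexEntry:
    label: str
    copies: int
    members: list[tuple[str, int]]      # (species, copies per instance)


@dataclass
class CompositionConfig:
    name: str
    symmetry_order: int
    rings: dict[str, list[SubcomplexEntry]]
    homologue_map: dict[str, str] = field(default_factory=dict)
    optional: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.symmetry_order < 1:
            raise ValidationError("symmetry_order must be >= 1")
        for ring, entries in self.rings.items():
            if ring not in RINGS:
                raise ValidationError(f"unknown ring {ring!r}")
            for entry in entries:
                if entry.copies < 1:
                    raise ValidationError(
                        f"{ring}/{entry.label}: copies must be >= 1, "
                        f"got {entry.copies}")
                seen = set()
                for species, copies in entry.members:
                    if copies < 1:
                        raise ValidationError(
                            f"{ring}/{entry.label}/{species}: member copies "
                            f"must be >= 1, got {copies}")
                    if species in seen:
                        raise ValidationError(
                            f"{ring}/{entry.label}: duplicate species "
                            f"{species!r}")
                    seen.add(species)

    def species(self) -> set[str]:
        """Distinct species placements (alternative groups count once)."""
        out = set()
        for entries in self.rings.values():
            for entry in entries:
                out.update(sp for sp, _ in entry.members)
        return out

    def species_per_asym_unit(self, ring: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for entry in self.rings.get(ring, []):
            for species, copies in entry.members:
                counts[species] = counts.get(species, 0) + entry.copies * copies
        return counts

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "symmetry_order": self.symmetry_order,
            "homologue_map": dict(self.homologue_map),
            "rings": {
                ring: [{"subcomplex": e.label, "copies": e.copies,
                        "members": [{"species": s, "copies": c}
                                    for s, c in e.members]}
                       for e in entries]
                for ring, entries in self.rings.items()
            },
            "optional": list(self.optional),
        }


def _parse_composition(payload: dict) -> CompositionConfig:
    for key in ("rings",):
        if key not in payload:
            raise ValidationError(f"composition config missing field {key!r}")
    rings: dict[str, list[SubcomplexEntry]] = {}
    for ring, entries in payload["rings"].items():
        parsed = []
        for entry in entries:
            for key in ("subcomplex", "copies", "members"):
                if key not in entry:
                    raise ValidationError(
                        f"ring {ring!r}: subcomplex entry missing {key!r}")
            members = []
            for m in entry["members"]:
                if "species" not in m or "copies" not in m:
                    raise ValidationError(
                        f"ring {ring!r}/{entry['subcomplex']!r}: member "
                        f"missing 'species' or 'copies'")
                members.append((str(m["species"]), int(m["copies"])))
            parsed.append(SubcomplexEntry(str(entry["subcomplex"]),
                                          int(entry["copies"]), members))
        rings[ring] = parsed
    return CompositionConfig(
        name=str(payload.get("name", "composition")),
        symmetry_order=int(payload.get("symmetry_order", 8)),
        rings=rings,
        homologue_map=dict(payload.get("homologue_map", {})),
        optional=list(payload.get("optional", [])),
    )


def load_composition(path=None) -> CompositionConfig:
    """Load a composition config; with no path, the packaged default."""
    if path is None:
        text = resources.files("npckit.data").joinpath(
            "at_npc_composition.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return _parse_composition(json.loads(text))


def default_composition() -> CompositionConfig:
    return load_composition(None)


def save_composition(config: CompositionConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

@dataclass
class Chain:
    chain_id: str
    species: str
    ring: str
    asym_unit_index: int
    subcomplex_label: str
    subcomplex_instance: int            # instance index within the asym unit
    coords: np.ndarray                  # (n_residues, 3) Cα positions, Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("chain coords must be (n, 3)")
        if self.ring not in RINGS:
            raise ValidationError(f"chain ring must be one of {RINGS}")

    @property
    def n_residues(self) -> int:
        return len(self.coords)


def coarse_beads(coords: np.ndarray,
                 residues_per_bead: int = COARSE_BEAD_RESIDUES) -> np.ndarray:
    """Ten-residue coarse beads: centroid of each consecutive fragment;
    yields ceil(n/10) beads."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    edges = range(0, n, residues_per_bead)
    return np.array([coords[i:i + residues_per_bead].mean(axis=0)
                     for i in edges])


@dataclass
class ScaffoldModel:
    chains: list[Chain]
    symmetry_order: int = 8

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate chain ids in scaffold model")

    def chain_coarse_beads(self) -> list[np.ndarray]:
        return [coarse_beads(c.coords) for c in self.chains]

    def all_ca(self) -> np.ndarray:
        if not self.chains:
            return np.zeros((0, 3))
        return np.concatenate([c.coords for c in self.chains])

    def species(self) -> set[str]:
        return {c.species for c in self.chains}

    def transformed(self, rotation: np.ndarray, shift=(0, 0, 0),
                    id_suffix: str = "", asym_unit: int | None = None
                    ) -> "ScaffoldModel":
        shift = np.asarray(shift, dtype=float)
        chains = []
        for c in self.chains:
            chains.append(Chain(
                chain_id=c.chain_id + id_suffix, species=c.species,
                ring=c.ring,
                asym_unit_index=c.asym_unit_index if asym_unit is None
                else asym_unit,
                subcomplex_label=c.subcomplex_label,
                subcomplex_instance=c.subcomplex_instance,
                coords=c.coords @ np.asarray(rotation).T + shift))
        return ScaffoldModel(chains, self.symmetry_order)


def _helix_trace(n_residues: int, start: np.ndarray,
                 axis_direction: np.ndarray) -> np.ndarray:
    """Ideal α-helix Cα trace (rise 1.5 Å, radius 2.3 Å, 100°/residue)
    along ``axis_direction`` from ``start``."""
    axis = np.asarray(axis_direction, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame around the axis
    probe = np.array([1.0, 0.0, 0.0])
    if abs(probe @ axis) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, probe)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    i = np.arange(n_residues)
    ang = np.radians(100.0 * i)
    return (start[None, :] + 1.5 * i[:, None] * axis[None, :]
            + 2.3 * (np.cos(ang)[:, None] * u[None, :]
                     + np.sin(ang)[:, None] * v[None, :]))


def _toy_chain_length(species: str) -> int:
    # deterministic pseudo-length in 48..96 residues, stable across runs
    h = 0
    for ch in species:
        h = (h * 131 + ord(ch)) % 10007
    return 48 + h % 49


def place_toy_chains(composition: CompositionConfig,
                     ring_radius: dict[str, float] | None = None,
                     seed: int = 0,
                     min_separation: float = 4.0) -> ScaffoldModel:
    """Deterministic toy Cα traces (vertical helical dummies) for one
    asymmetric unit of the composition.

    Chains of one ring are spread azimuthally across the asymmetric-unit
    sector with a small seeded jitter; rings are separated radially and
    axially so no two chains approach closer than ``min_separation``.
    """
    radius = dict(_RING_RADIUS)
    if ring_radius:
        radius.update(ring_radius)
    rng = np.random.default_rng(seed)
    sector = 360.0 / composition.symmetry_order
    chains: list[Chain] = []
    for ring in RINGS:
        entries = composition.rings.get(ring, [])
        slots = []
        for entry in entries:
            for instance in range(entry.copies):
                for species, copies in entry.members:
                    for copy_idx in range(copies):
                        slots.append((entry.label, instance, species, copy_idx))
        if not slots:
            continue
        # chord spacing must exceed min_separation plus helix diameter
        spacing = sector / (len(slots) + 1)
        jitter_scale = max(0.0, spacing / 8.0)
        arc = np.radians(spacing) * radius[ring]
        if arc <= min_separation + 5.0:
            raise ValidationError(
                f"cannot pack {len(slots)} chains in ring {ring} at radius "
                f"{radius[ring]:.0f} Å without clashes")
        for slot_idx, (label, instance, species, copy_idx) in enumerate(slots):
            azimuth = (slot_idx + 1) * spacing + rng.uniform(
                -jitter_scale, jitter_scale)
            ang = np.radians(azimuth)
            n_res = _toy_chain_length(species)
            start = np.array([radius[ring] * np.cos(ang),
                              radius[ring] * np.sin(ang),
                              _RING_Z[ring] - 0.75 * n_res])
            coords = _helix_trace(n_res, start, np.array([0.0, 0.0, 1.0]))
            suffix = f".{copy_idx}" if copy_idx else ""
            chains.append(Chain(
                chain_id=f"{ring}/{label}#{instance}/{species}{suffix}/u0",
                species=species, ring=ring, asym_unit_index=0,
                subcomplex_label=label, subcomplex_instance=instance,
                coords=coords))
    model = ScaffoldModel(chains, composition.symmetry_order)
    _check_separation(model, min_separation)
    return model


def _check_separation(model: ScaffoldModel, min_separation: float) -> None:
    from scipy.spatial import cKDTree

    for i, a in enumerate(model.chains):
        tree = cKDTree(a.coords)
        for b in model.chains[i + 1:]:
            d, _ = tree.query(b.coords, k=1)
            if d.min() <= min_separation:
                raise ValidationError(
                    f"chains {a.chain_id!r} and {b.chain_id!r} clash "
                    f"(min Cα distance {d.min():.2f} Å)")


# --------------------------------------------------------------------------
# composite assembly and stoichiometry
# --------------------------------------------------------------------------

def assemble_composite(asym_unit: ScaffoldModel,
                       symmetry_order: int | None = None) -> ScaffoldModel:
    """Expand one asymmetric unit into ``symmetry_order`` copies related by
    successive rotations about the pore axis."""
    order = symmetry_order or asym_unit.symmetry_order
    if order < 1:
        raise ValidationError("symmetry_order must be >= 1")
    chains: list[Chain] = []
    for k in range(order):
        rot = rotation_about_axis2(k * 360.0 / order)
        copy = asym_unit.transformed(rot, id_suffix=f"@s{k}", asym_unit=k)
        chains.extend(copy.chains)
    return ScaffoldModel(chains, order)


def assemble_composite_map(asym_map: DensityVolume,
                           symmetry_order: int = 8) -> DensityVolume:
    """Max-combine ``symmetry_order`` rotated copies of an asymmetric-unit
    map about the pore axis."""
    if symmetry_order < 1:
        raise ValidationError("symmetry_order must be >= 1")
    out = asym_map.grid.astype(float).copy()
    for k in range(1, symmetry_order):
        rot = rotation_about_axis2(k * 360.0 / symmetry_order)
        out = np.maximum(out, transform_volume(asym_map.grid, rot))
    return DensityVolume(out, asym_map.voxel_size, asym_map.origin.copy())


def stoichiometry(model: ScaffoldModel, group_by: str = "species",
                  scope: str = "whole", ring: str | None = None
                  ) -> dict[str, int]:
    """Count species placements or subcomplex instances.

    ``scope``: ``"whole"`` counts over all chains present in the model;
    ``"asym_unit"`` restricts to asymmetric unit 0; ``"ring"`` behaves like
    ``"whole"`` but requires ``ring``. ``ring`` additionally filters any
    scope. If the model holds a single asymmetric unit, ``"whole"`` counts
    are extrapolated by the symmetry order.
    """
    if group_by not in ("species", "subcomplex"):
        raise ValidationError(f"unknown grouping key {group_by!r}")
    if scope not in ("whole", "ring", "asym_unit"):
        raise ValidationError(f"unknown scope {scope!r}")
    if scope == "ring" and ring is None:
        raise ValidationError("scope 'ring' requires a ring name")
    chains = model.chains
    if ring is not None:
        if ring not in RINGS:
            raise ValidationError(f"unknown ring {ring!r}")
        chains = [c for c in chains if c.ring == ring]
    if scope == "asym_unit":
        chains = [c for c in chains if c.asym_unit_index == 0]
    units_present = {c.asym_unit_index for c in model.chains}
    expand = (model.symmetry_order if scope in ("whole", "ring")
              and units_present == {0} and model.symmetry_order > 1 else 1)
    counts: dict[str, int] = {}
    if group_by == "species":
        for c in chains:
            counts[c.species] = counts.get(c.species, 0) + 1
    else:
        instances = {(c.ring, c.asym_unit_index, c.subcomplex_label,
                      c.subcomplex_instance) for c in chains}
        for _ring, _unit, label, _inst in instances:
            counts[label] = counts.get(label, 0) + 1
    return {k: v * expand for k, v in sorted(counts.items())}


def write_scaffold_pdb(model: ScaffoldModel, path) -> None:
    """Write the Cα representation as a PDB file (via biotite)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = sum(c.n_residues for c in model.chains)
    atoms = struc.AtomArray(n)
    i = 0
    for ci, chain in enumerate(model.chains):
        cid = chr(ord("A") + ci % 26)
        for ri, xyz in enumerate(chain.coords):
            atoms.coord[i] = xyz
            atoms.chain_id[i] = cid
            atoms.res_id[i] = ri + 1
            atoms.res_name[i] = "ALA"
            atoms.atom_name[i] = "CA"
            atoms.element[i] = "C"
            i += 1
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))
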
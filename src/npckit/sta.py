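"""Subtomogram averaging: wedge-constrained alignment, wedge-compensated
averaging, Cn symmetry expansion, FSC resolution estimation and an iterative
refinement loop.

Cross-correlation contract: volumes are mean-subtracted and variance
normalised under the real-space mask; correlation is accumulated only over
Fourier components outside the missing wedge. Angular search is an
exhaustive grid over intrinsic ZYZ Euler angles with a deterministic tie
break (first pose in grid order wins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volume import (
    DensityVolume,
    Pose,
    ValidationError,
    WedgeModel,
    lowpass,
    rotation_about_axis2,
    rotation_zyz,
    rotate_fourier_mask,
    transform_volume,
    wedge_mask,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FSCCurve",
    "AlignmentResult",
    "rotation_grid",
    "inplane_rotation_grid",
    "align_subtomogram",
    "average_subtomograms",
    "symmetry_expand",
    "fsc",
    "resolution_at",
    "iterative_refine",
    "clean_particles",
    "bin_volume",
]


# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------

@dataclass
class FSCCurve:
    """Shell correlations against spatial frequency (1/Å)."""

    shell_frequencies: np.ndarray
    correlations: np.ndarray
    shell_width: float

    def __post_init__(self) -> None:
        self.shell_frequencies = np.asarray(self.shell_frequencies, float)
        self.correlations = np.asarray(self.correlations, float)
        if self.shell_frequencies.shape != self.correlations.shape:
            raise ValidationError("frequency/correlation length mismatch")
        if np.any(np.diff(self.shell_frequencies) <= 0):
            raise ValidationError("shell frequencies must be strictly increasing")


@dataclass
class AlignmentResult:
    pose: Pose
    cc_score: float
    on_grid: bool = True
    particle_id: int | None = None


# --------------------------------------------------------------------------
# angular grids
# --------------------------------------------------------------------------

def rotation_grid(step_deg: float) -> list[np.ndarray]:
    """Uniform intrinsic-ZYZ grid: phi, psi over [0,360), theta over [0,180].

    Deterministic order (phi fastest varying last); coarse but exhaustive.
    """
    if step_deg <= 0:
        raise ValidationError("angular step must be positive")
    phis = np.arange(0.0, 360.0, step_deg)
    thetas = np.arange(0.0, 180.0 + 1e-9, step_deg)
    psis = np.arange(0.0, 360.0, step_deg)
    grid = []
    for theta in thetas:
        # at the poles psi is degenerate with phi; keep psi=0 only
        psi_list = [0.0] if theta in (0.0, 180.0) else psis
        for psi in psi_list:
            for phi in phis:
                grid.append(rotation_zyz(phi, theta, psi))
    return grid


def inplane_rotation_grid(step_deg: float) -> list[np.ndarray]:
    """Rotations about the pore axis only — the grid used for spoke search."""
    if step_deg <= 0:
        raise ValidationError("angular step must be positive")
    return [rotation_about_axis2(a) for a in np.arange(0.0, 360.0, step_deg)]


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------

def _mask_stats(grid: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean-subtract under the mask and apply it."""
    msum = mask.sum()
    mean = (grid * mask).sum() / msum
    return (grid - mean) * mask


def _shift_window(shape, limit_vox: float) -> np.ndarray:
    """Boolean mask of allowed integer shifts in fftn correlation layout."""
    coords = np.meshgrid(*[np.fft.fftfreq(n) * n for n in shape], indexing="ij")
    r = np.sqrt(sum(c ** 2 for c in coords))
    return r <= limit_vox + 1e-9


def align_subtomogram(particle: DensityVolume, reference: DensityVolume,
                      mask: DensityVolume | None = None,
                      wedge: WedgeModel | None = None,
                      angular_step: float = 15.0,
                      shift_limit: float = 0.0,
                      rotations: list[np.ndarray] | None = None
                      ) -> AlignmentResult:
    """Exhaustive grid alignment maximising masked wedge-constrained CC.

    ``rotations`` overrides the default full ZYZ grid (e.g. an in-plane
    grid for axially constrained searches). ``shift_limit`` is in Å; the
    translational search is FFT-based over integer voxel shifts.
    """
    pre = _AlignmentContext(particle, reference, mask, wedge,
                            angular_step, shift_limit, rotations)
    best = None
    for rot in pre.rotations:
        score, shift_vox = pre.score_rotation(rot)
        if best is None or score > best[0] + 1e-12:
            best = (score, rot, shift_vox)
    score, rot, shift_vox = best
    pose = Pose(rot, np.asarray(shift_vox, float) * particle.voxel_size)
    return AlignmentResult(pose=pose, cc_score=float(score), on_grid=True)


class _AlignmentContext:
    """Shared pre-computation for aligning one or many particles against a
    fixed reference/mask/wedge (rotated references are cached per grid)."""

    def __init__(self, particle, reference, mask, wedge, angular_step,
                 shift_limit, rotations):
        if not particle.same_geometry(reference):
            raise ValidationError("particle and reference grids differ")
        particle.require_cubic()
        if mask is not None and not particle.same_geometry(mask):
            raise ValidationError("mask grid differs from particle grid")
        mgrid = np.ones_like(particle.grid) if mask is None else np.asarray(
            mask.grid, float)
        if mgrid.min() < -1e-9 or mgrid.max() > 1 + 1e-9:
            raise ValidationError("mask values must lie in [0, 1]")
        if mgrid.sum() <= 0:
            raise ValidationError("mask is empty")
        half_box = particle.shape[0] * particle.voxel_size / 2.0
        if shift_limit > half_box:
            raise ValidationError(
                f"shift_limit {shift_limit} Å exceeds half-box {half_box} Å"
            )
        self.voxel = particle.voxel_size
        self.mask = mgrid
        self.wmask = (None if wedge is None or wedge.is_full_range
                      else wedge_mask(particle.shape, wedge))
        self.rotations = (rotations if rotations is not None
                          else rotation_grid(angular_step))
        self.shift_ok = _shift_window(particle.shape,
                                      shift_limit / particle.voxel_size)
        self.n = particle.grid.size
        self.set_particle(particle)
        self._ref = reference
        self._cache: dict[int, tuple[np.ndarray, float]] = {}

    def set_particle(self, particle: DensityVolume) -> None:
        fp = np.fft.fftn(_mask_stats(particle.grid, self.mask))
        if self.wmask is not None:
            fp = fp * self.wmask
        self.fp = fp
        self.p_norm = np.sqrt((np.abs(fp) ** 2).sum() / self.n)

    def _rotated_reference(self, idx: int, rot: np.ndarray):
        if idx not in self._cache:
            rgrid = transform_volume(self._ref.grid, rot)
            fr = np.fft.fftn(_mask_stats(rgrid, self.mask))
            if self.wmask is not None:
                fr = fr * self.wmask
            r_norm = np.sqrt((np.abs(fr) ** 2).sum() / self.n)
            self._cache[idx] = (np.conj(fr), r_norm)
        return self._cache[idx]

    def score_rotation(self, rot: np.ndarray) -> tuple[float, np.ndarray]:
        idx = id(rot)
        fr_conj, r_norm = self._rotated_reference(idx, rot)
        cc = np.fft.ifftn(self.fp * fr_conj).real
        denom = self.p_norm * r_norm
        if denom == 0:
            return -1.0, np.zeros(3)
        cc = cc / denom
        cc[~self.shift_ok] = -np.inf
        flat = int(np.argmax(cc))
        ijk = np.unravel_index(flat, cc.shape)
        shift = np.array([np.fft.fftfreq(n)[i] * n
                          for n, i in zip(cc.shape, ijk)])
        return float(cc[ijk]), shift


def align_stack(particles, reference, mask=None, wedge=None,
                angular_step=15.0, shift_limit=0.0, rotations=None
                ) -> list[AlignmentResult]:
    """Align many particles, reusing the rotated-reference cache."""
    first = particles[0].subtomogram if hasattr(particles[0], "subtomogram") \
        else particles[0]
    ctx = _AlignmentContext(first, reference, mask, wedge, angular_step,
                            shift_limit, rotations)
    results = []
    for i, p in enumerate(particles):
        vol = p.subtomogram if hasattr(p, "subtomogram") else p
        ctx.set_particle(vol)
        best = None
        for rot in ctx.rotations:
            score, shift_vox = ctx.score_rotation(rot)
            if best is None or score > best[0] + 1e-12:
                best = (score, rot, shift_vox)
        score, rot, shift_vox = best
        results.append(AlignmentResult(
            pose=Pose(rot, np.asarray(shift_vox, float) * vol.voxel_size),
            cc_score=float(score), on_grid=True,
            particle_id=getattr(p, "particle_id", i)))
    return results


# --------------------------------------------------------------------------
# averaging
# --------------------------------------------------------------------------

def average_subtomograms(particles, poses, wedges=None) -> DensityVolume:
    """Wedge-compensated average.

    Each particle is mapped back to the reference frame with the inverse of
    its pose; Fourier terms are summed and divided by the summed rotated
    wedge masks (floored at one sample). Fourier voxels covered by no
    particle are set to zero.
    """
    vols = [p.subtomogram if hasattr(p, "subtomogram") else p
            for p in particles]
    if not vols:
        raise ValidationError("need at least one particle")
    if wedges is None:
        wedges = [getattr(p, "wedge", None) for p in particles]
    shape = vols[0].shape
    voxel = vols[0].voxel_size
    f_sum = np.zeros(shape, dtype=complex)
    w_sum = np.zeros(shape, dtype=float)
    for vol, pose, wedge in zip(vols, poses, wedges):
        if vol.shape != shape:
            raise ValidationError("all particles must share one grid")
        inv = pose.inverse()
        aligned = transform_volume(vol.grid, inv.rotation,
                                   inv.shift / voxel)
        f_sum += np.fft.fftn(aligned)
        if wedge is None or wedge.is_full_range:
            w_sum += 1.0
        else:
            wm = wedge_mask(shape, wedge)
            w_sum += rotate_fourier_mask(wm, inv.rotation).astype(float)
    covered = w_sum > 0.5
    avg_f = np.where(covered, f_sum / np.maximum(w_sum, 1.0), 0.0)
    return DensityVolume(np.fft.ifftn(avg_f).real, voxel)


# --------------------------------------------------------------------------
# symmetry expansion
# --------------------------------------------------------------------------

def symmetry_expand(whole_pose: Pose, whole_centre, order: int = 8,
                    spoke_radius: float = 0.0) -> list[tuple[np.ndarray, Pose]]:
    """Expand one whole-complex pose into ``order`` spoke (position, pose)
    pairs related by successive 360/order rotations about the pore axis."""
    if order < 1:
        raise ValidationError(f"order must be >= 1, got {order}")
    centre = np.asarray(whole_centre, dtype=float)
    base = np.array([spoke_radius, 0.0, 0.0])
    out = []
    for k in range(order):
        rot_k = whole_pose.rotation @ rotation_about_axis2(k * 360.0 / order)
        position = centre + rot_k @ base
        out.append((position, Pose(rot_k, position - centre)))
    return out


# --------------------------------------------------------------------------
# FSC
# --------------------------------------------------------------------------

BEYOND_NYQUIST = None
"""Sentinel returned by :func:`resolution_at` when the curve never crosses."""


def fsc(half1: DensityVolume, half2: DensityVolume,
        shell_width: float | None = None) -> FSCCurve:
    """Fourier shell correlation between two half maps.

    Per shell: ``Re sum(F1 conj(F2)) / sqrt(sum|F1|^2 sum|F2|^2)``.
    ``shell_width`` defaults to one Fourier voxel, 1/(N * voxel).
    """
    if not half1.same_geometry(half2):
        raise ValidationError("half maps must share grid geometry")
    half1.require_cubic()
    n = half1.shape[0]
    voxel = half1.voxel_size
    if shell_width is None:
        shell_width = 1.0 / (n * voxel)
    f1 = np.fft.fftn(half1.grid)
    f2 = np.fft.fftn(half2.grid)
    freqs = np.meshgrid(*[np.fft.fftfreq(m, d=voxel) for m in half1.shape],
                        indexing="ij")
    radius = np.sqrt(sum(f ** 2 for f in freqs))
    nyquist = 1.0 / (2.0 * voxel)
    n_shells = int(np.floor(nyquist / shell_width)) + 1
    shell_idx = np.minimum((radius / shell_width).astype(int), n_shells)
    num = np.bincount(shell_idx.ravel(),
                      weights=(f1 * np.conj(f2)).real.ravel(),
                      minlength=n_shells + 1)
    d1 = np.bincount(shell_idx.ravel(), weights=(np.abs(f1) ** 2).ravel(),
                     minlength=n_shells + 1)
    d2 = np.bincount(shell_idx.ravel(), weights=(np.abs(f2) ** 2).ravel(),
                     minlength=n_shells + 1)
    denom = np.sqrt(d1 * d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    centres = (np.arange(n_shells) + 0.5) * shell_width
    return FSCCurve(centres, corr[:n_shells], shell_width)


def resolution_at(curve: FSCCurve, threshold: float = 0.143):
    """Resolution (Å) at the first downward crossing of ``threshold``,
    linearly interpolated between shells; ``None`` if never crossed."""
    f = curve.shell_frequencies
    c = curve.correlations
    if c[0] < threshold:
        return 1.0 / f[0] if f[0] > 0 else BEYOND_NYQUIST
    for i in range(len(c) - 1):
        if c[i] >= threshold > c[i + 1]:
            frac = (c[i] - threshold) / (c[i] - c[i + 1])
            freq = f[i] + frac * (f[i + 1] - f[i])
            return float(1.0 / freq)
    return BEYOND_NYQUIST


# --------------------------------------------------------------------------
# iterative refinement and particle cleaning
# --------------------------------------------------------------------------

def iterative_refine(stack, initial_reference: DensityVolume,
                     mask: DensityVolume | None = None,
                     wedge: WedgeModel | None = None,
                     n_iter: int = 3,
                     angular_schedule=None,
                     lowpass_schedule=None,
                     shift_limit: float = 0.0,
                     rotations=None,
                     seed: int = 0):
    """Alternate alignment and wedge-compensated averaging.

    Returns ``(final_map, poses, fsc_curve)`` where the FSC comes from
    even/odd particle-index half averages of the final iteration. Aborts if
    the mean cc drops by more than 0.2 in one iteration (divergence guard).
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if angular_schedule is None:
        angular_schedule = [15.0] * n_iter
    if lowpass_schedule is None:
        lowpass_schedule = [None] * n_iter
    reference = initial_reference
    mean_cc_prev = None
    results = None
    for it in range(n_iter):
        ref_it = reference
        cutoff = lowpass_schedule[it]
        if cutoff is not None:
            ref_it = DensityVolume(
                lowpass(reference.grid, reference.voxel_size, cutoff),
                reference.voxel_size)
        results = align_stack(stack, ref_it, mask=mask, wedge=wedge,
                              angular_step=angular_schedule[it],
                              shift_limit=shift_limit, rotations=rotations)
        mean_cc = float(np.mean([r.cc_score for r in results]))
        logger.info("iteration %d: mean cc %.4f", it + 1, mean_cc)
        if mean_cc_prev is not None and mean_cc < mean_cc_prev - 0.2:
            raise RuntimeError(
                f"refinement diverged at iteration {it + 1}: mean cc fell "
                f"from {mean_cc_prev:.3f} to {mean_cc:.3f}"
            )
        mean_cc_prev = mean_cc
        poses = [r.pose for r in results]
        reference = average_subtomograms(stack, poses)
    even = [i for i in range(len(stack)) if i % 2 == 0]
    odd = [i for i in range(len(stack)) if i % 2 == 1]
    if even and odd:
        half1 = average_subtomograms([stack[i] for i in even],
                                     [poses[i] for i in even])
        half2 = average_subtomograms([stack[i] for i in odd],
                                     [poses[i] for i in odd])
        curve = fsc(half1, half2)
    else:
        curve = fsc(reference, reference)
    return reference, poses, curve


def clean_particles(results: list[AlignmentResult], cc_floor: float = -1.0,
                    manual_reject_list=()) -> list[AlignmentResult]:
    """Drop results below the cc floor or on the manual reject list."""
    reject = set(manual_reject_list)
    kept = [r for i, r in enumerate(results)
            if r.cc_score >= cc_floor
            and i not in reject
            and (r.particle_id is None or r.particle_id not in reject)]
    dropped = len(results) - len(kept)
    if kept:
        logger.info("clean_particles: kept %d / %d", len(kept), len(results))
    else:
        logger.warning("clean_particles: all %d particles rejected", dropped)
    return kept


def bin_volume(volume: DensityVolume, factor: int) -> DensityVolume:
    """Integer binning by Fourier cropping (doubles the voxel size per 2x)."""
    if factor < 1 or volume.shape[0] % factor:
        raise ValidationError(
            f"bin factor {factor} incompatible with shape {volume.shape}")
    if factor == 1:
        return volume.copy()
    volume.require_cubic()
    n = volume.shape[0]
    m = n // factor
    f = np.fft.fftshift(np.fft.fftn(volume.grid))
    lo = n // 2 - m // 2
    cropped = f[lo:lo + m, lo:lo + m, lo:lo + m]
    grid = np.fft.ifftn(np.fft.ifftshift(cropped)).real / factor ** 3
    return DensityVolume(grid, volume.voxel_size * factor)
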
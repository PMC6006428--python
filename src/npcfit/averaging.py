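"""Missing-wedge-aware alignment and iterative subtomogram averaging.

The cross-correlation between two wedge-limited volumes is evaluated only
over the Fourier region sampled by *both* volumes (constrained CC), which
removes the bias a missing wedge would otherwise impose on alignment.
Averages are wedge-compensated: aligned Fourier data are summed and
divided by the summed wedge coverage, with a floor to keep near-empty
Fourier voxels from blowing up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .density import (
    DensityMap,
    Pose,
    WedgeDescriptor,
    assert_same_grid,
    symmetrize,
    transform_map,
    wedge_mask,
)
from .phantoms import Subtomogram

__all__ = [
    "AlignmentState",
    "constrained_cc",
    "align_particle",
    "iterative_average",
    "extract_asymmetric_units",
    "masked_refine",
    "wedge_weighted_average",
]


def _as_mask(shape, wedge_or_mask, rotation=None) -> np.ndarray:
    if isinstance(wedge_or_mask, np.ndarray):
        return wedge_or_mask
    if wedge_or_mask is None:
        return np.ones(shape, dtype=bool)
    return wedge_mask(shape, wedge_or_mask, rotation)


def constrained_cc(
    volume: DensityMap,
    reference: DensityMap,
    wedge_v: WedgeDescriptor | np.ndarray | None,
    wedge_r: WedgeDescriptor | np.ndarray | None = None,
    rot_v: np.ndarray | None = None,
    rot_r: np.ndarray | None = None,
) -> float:
    """Normalized cross-correlation over the doubly-sampled Fourier region.

    ``wedge_v`` / ``wedge_r`` are wedge descriptors (or precomputed
    boolean Fourier masks); ``rot_v`` / ``rot_r`` rotate the respective
    wedge, as needed for particles that were resampled after acquisition.
    The DC term is excluded, making the score invariant to the means.
    """
    assert_same_grid(volume, reference)
    mv = _as_mask(volume.shape, wedge_v, rot_v)
    mr = _as_mask(volume.shape, wedge_r, rot_r)
    both = mv & mr
    both.flat[0] = False  # drop DC
    if not both.any():
        raise ValueError("wedges of the two volumes share no Fourier coverage")
    A = np.fft.fftn(volume.values)[both]
    B = np.fft.fftn(reference.values)[both]
    den = np.sqrt(float(np.sum(np.abs(A) ** 2)) * float(np.sum(np.abs(B) ** 2)))
    if den == 0:
        return 0.0
    return float(np.real(np.sum(A * np.conj(B))) / den)


def _inplane_rotations(angular_step: float) -> list[float]:
    angles = list(np.arange(0.0, 360.0, angular_step))
    # order by rotation magnitude so score ties resolve to the smallest move
    return sorted(angles, key=lambda a: (min(a, 360.0 - a), a))


def _translation_search(rotated: DensityMap, reference: DensityMap,
                        mask: np.ndarray, max_shift_nm: float):
    """Best circular voxel shift u (rotated ~ reference translated by u)
    and the normalized correlation value at that shift."""
    F = np.fft.fftn(rotated.values)
    G = np.fft.fftn(reference.values)
    m = mask.copy()
    m.flat[0] = False
    num = np.fft.ifftn(F * m * np.conj(G * m)).real * F.size
    den = np.sqrt(float(np.sum(np.abs(F[m]) ** 2)) * float(np.sum(np.abs(G[m]) ** 2)))
    if den == 0:
        return np.zeros(3), 0.0
    corr = num / den
    n = rotated.shape
    offs = [np.fft.fftfreq(s) * s for s in n]  # signed voxel shifts
    max_vox = max_shift_nm / rotated.voxel_size
    allowed = (
        (np.abs(offs[0])[:, None, None] <= max_vox)
        & (np.abs(offs[1])[None, :, None] <= max_vox)
        & (np.abs(offs[2])[None, None, :] <= max_vox)
    )
    corr = np.where(allowed, corr, -np.inf)
    idx = np.unravel_index(int(np.argmax(corr)), n)
    u = np.array([offs[a][idx[a]] for a in range(3)])
    return u, float(corr[idx])


def align_particle(
    particle: Subtomogram,
    reference: DensityMap,
    angular_step: float = 10.0,
    max_shift_nm: float = 8.0,
    refine: bool = True,
) -> tuple[Pose, float]:
    """Find the pose that best maps the reference onto the particle.

    The rotational search is an in-plane (about z) grid at
    ``angular_step`` followed by a local refinement at a quarter step;
    translations come from the peak of the wedge-constrained circular
    cross-correlation within ``max_shift_nm``.  Ties resolve to the
    smallest rotation.  Returns ``(pose, score)`` with
    ``particle.map ~ transform_map(reference, pose)``.
    """
    if angular_step <= 0:
        raise ValueError("angular_step must be positive")

    def evaluate(phi: float):
        R = Rotation.from_euler("z", phi, degrees=True).as_matrix()
        rot = transform_map(particle.map, Pose.from_matrix(R.T))
        m = wedge_mask(particle.map.shape, particle.wedge,
                       R.T @ particle.wedge_rotation)
        u, score = _translation_search(rot, reference, m, max_shift_nm)
        t = R @ (u * particle.map.voxel_size)
        return Pose.from_matrix(R, t), score

    best_pose, best_score, best_phi = None, -np.inf, 0.0
    for phi in _inplane_rotations(angular_step):
        pose, score = evaluate(phi)
        if score > best_score:
            best_pose, best_score, best_phi = pose, score, phi
    if refine:
        for dphi in np.arange(-angular_step, angular_step + 1e-9, angular_step / 4.0):
            if abs(dphi) < 1e-12:
                continue
            pose, score = evaluate((best_phi + dphi) % 360.0)
            if score > best_score:
                best_pose, best_score = pose, score
    return best_pose, best_score


@dataclass
class AlignmentState:
    """Per-particle poses plus per-iteration update statistics."""

    poses: list[Pose]
    iteration: int = 0
    mean_angular_update_deg: list[float] = field(default_factory=list)
    mean_shift_update_nm: list[float] = field(default_factory=list)
    converged: bool = False


def wedge_weighted_average(
    particles: list[Subtomogram],
    poses: list[Pose] | None = None,
    floor_fraction: float = 0.1,
) -> DensityMap:
    """Sum of aligned Fourier data divided by summed wedge coverage.

    Coverage voxels below ``floor_fraction`` of the mean coverage are
    clamped to the floor, so no division by (near) zero occurs.
    """
    if not particles:
        raise ValueError("no particles to average")
    shape = particles[0].map.shape
    F_sum = np.zeros(shape, dtype=complex)
    cov = np.zeros(shape)
    for i, p in enumerate(particles):
        pose = poses[i] if poses is not None else Pose.identity()
        inv = pose.inverse()
        aligned = transform_map(p.map, inv)
        F_sum += np.fft.fftn(aligned.values)
        cov += wedge_mask(shape, p.wedge, inv.matrix @ p.wedge_rotation)
    floor = max(floor_fraction * float(cov.mean()), 1e-6)
    F_avg = F_sum / np.maximum(cov, floor)
    # Fourier voxels never sampled by any wedge carry only noise; zero them
    # instead of amplifying them through the floor
    F_avg[cov < min(0.5, floor)] = 0.0
    avg = np.fft.ifftn(F_avg).real
    return particles[0].map.with_values(avg)


def iterative_average(
    particles: list[Subtomogram],
    initial_reference: DensityMap | None = None,
    n_iter: int = 3,
    symmetry_order: int = 8,
    angular_step: float = 10.0,
    max_shift_nm: float = 8.0,
    convergence_deg: float = 1.0,
    convergence_nm: float = 0.5,
) -> tuple[DensityMap, AlignmentState]:
    """Iterative missing-wedge-weighted subtomogram averaging.

    Each iteration aligns every particle to the current reference,
    computes the wedge-compensated average, and imposes the rotational
    symmetry.  With no ``initial_reference`` the first reference is the
    symmetrized raw average at identity poses.
    """
    if len(particles) < 2:
        raise ValueError("iterative averaging needs at least two particles")
    ref = initial_reference
    if ref is None:
        ref = symmetrize(wedge_weighted_average(particles), symmetry_order)
    state = AlignmentState(poses=[Pose.identity()] * len(particles))
    for it in range(n_iter):
        new_poses = [
            align_particle(p, ref, angular_step, max_shift_nm)[0] for p in particles
        ]
        d_ang = [
            float(np.degrees((a.rotation * b.rotation.inv()).magnitude()))
            for a, b in zip(new_poses, state.poses)
        ]
        d_shift = [float(np.linalg.norm(a.t - b.t)) for a, b in zip(new_poses, state.poses)]
        state.poses = new_poses
        state.iteration = it + 1
        state.mean_angular_update_deg.append(float(np.mean(d_ang)))
        state.mean_shift_update_nm.append(float(np.mean(d_shift)))
        ref = symmetrize(wedge_weighted_average(particles, new_poses), symmetry_order)
        if (
            state.mean_angular_update_deg[-1] < convergence_deg
            and state.mean_shift_update_nm[-1] < convergence_nm
        ):
            state.converged = True
            break
    return ref, state


def extract_asymmetric_units(
    particles: list[Subtomogram],
    poses: list[Pose],
    symmetry_order: int,
    unit_box: int,
    unit_center_nm: tuple[float, float, float] | None = None,
) -> list[Subtomogram]:
    """Cut one subvolume per symmetry position from every aligned particle.

    Each particle is resampled into the reference frame, rotated by
    ``-k * 360 / order`` about z for k = 0..order-1, and a cube of
    ``unit_box`` voxels is cropped around the nominal unit centre (ring
    mid-radius on the +x axis by default).  The wedge orientation of each
    unit tracks the applied rotation.  Returns
    ``len(particles) * symmetry_order`` units.
    """
    if not particles:
        return []
    base = particles[0].map
    n = np.array(base.shape)
    if unit_box > min(n):
        raise ValueError(f"unit_box {unit_box} exceeds the particle box {tuple(n)}")
    if unit_center_nm is None:
        unit_center_nm = (0.28 * float(base.box_nm[0]), 0.0, 0.0)
    center = np.asarray(unit_center_nm, dtype=float)
    units: list[Subtomogram] = []
    for p, pose in zip(particles, poses):
        inv = pose.inverse()
        for k in range(symmetry_order):
            Rk = Rotation.from_euler("z", -360.0 * k / symmetry_order, degrees=True).as_matrix()
            net = Pose.from_matrix(Rk @ inv.matrix, Rk @ inv.t)
            aligned = transform_map(p.map, net)
            ctr_idx = np.rint(aligned.physical_to_index(center)).astype(int)
            lo = ctr_idx - unit_box // 2
            hi = lo + unit_box
            if np.any(lo < 0) or np.any(hi > n):
                raise ValueError(
                    f"unit crop [{lo}..{hi}] falls outside the particle box {tuple(n)}"
                )
            sub = aligned.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy()
            origin = -base.voxel_size * (unit_box - 1) / 2.0
            units.append(
                Subtomogram(
                    map=DensityMap(sub, base.voxel_size, np.full(3, origin)),
                    wedge=p.wedge,
                    true_pose=net.compose(p.true_pose),
                    snr=p.snr,
                    wedge_rotation=net.matrix @ p.wedge_rotation,
                )
            )
    return units


def masked_refine(
    units: list[Subtomogram],
    ring_masks: dict[str, DensityMap | np.ndarray],
    reference: DensityMap | None = None,
    angular_step: float = 4.0,
    max_shift_nm: float = 4.0,
) -> dict[str, DensityMap]:
    """Focused refinement: re-align the units against a masked reference
    per ring (cytoplasmic / inner / nuclear) and average.

    Outside a ring's mask support the returned map equals the raw
    (unrefined) average, so refinement only ever changes the region a
    mask selects.
    """
    if not units:
        raise ValueError("no units given")
    raw = wedge_weighted_average(units)
    ref = reference if reference is not None else raw
    out: dict[str, DensityMap] = {}
    for name, mask in ring_masks.items():
        mvals = mask.values if isinstance(mask, DensityMap) else np.asarray(mask)
        if mvals.shape != ref.shape:
            raise ValueError(f"mask {name!r} shape {mvals.shape} != map shape {ref.shape}")
        if not np.any(mvals > 0):
            raise ValueError(f"mask {name!r} is empty")
        masked_ref = ref.with_values(ref.values * mvals)
        poses = [
            align_particle(u, masked_ref, angular_step, max_shift_nm)[0] for u in units
        ]
        refined = wedge_weighted_average(units, poses)
        out[name] = ref.with_values(mvals * refined.values + (1.0 - mvals) * raw.values,
                                    ring=name)
    return out
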
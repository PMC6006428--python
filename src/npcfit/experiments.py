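"""Canned reproduction experiments on the stock NPC phantoms.

These functions wire the phantom generators, the averaging stage and the
systematic-fitting census together under the study conditions used
throughout the package: 3 nm voxels, 6 nm rendering resolution, a +/-60
degree missing wedge, signal-to-noise ratio 1, and eight-fold symmetry.
They are shared by the test suite, the pipeline runner, and the
reproduction script, so every consumer measures the same quantities the
same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architecture import difference_map, ring_region_masks
from .averaging import align_particle, extract_asymmetric_units
from .density import DensityMap, Pose, WedgeDescriptor, symmetrize
from .fitting import significant_placements
from .phantoms import (
    ArchitectureSpec,
    BeadModel,
    RingSpec,
    build_assembly,
    crnpc_spec,
    default_subunits,
    generate_particle_set,
    inner_ring_spec,
    render_density,
    simulate_particle,
)

__all__ = [
    "StudyConditions",
    "make_phantom_target",
    "crnpc_copy_census",
    "asymmetric_unit_count",
    "difference_map_census",
    "double_y_census",
    "inner_ring_census",
]

# per-model acceptance settings: the elongated Y tiles quasi-continuous
# rings head-to-tail, so intermediate (bridge) placements must be pruned by
# sequential density claiming; the compact protomer is packed more tightly
# than its own blur radius, where plain centre-separation suppression is the
# correct guard (see docs/methods.md)
Y_ACCEPT = dict(min_separation_nm=12.0, sequential_claim=True,
                relative_overlap_floor=0.75)
PROTOMER_ACCEPT = dict(min_separation_nm=8.0, sequential_claim=False,
                       relative_overlap_floor=0.75)


@dataclass(frozen=True)
class StudyConditions:
    """Phantom imaging conditions shared by the reproduction experiments."""

    voxel_size_nm: float = 3.0
    box_nm: float = 132.0
    resolution_nm: float = 6.0
    snr: float | None = 1.0
    tilt_min: float = -60.0
    tilt_max: float = 60.0
    symmetry_order: int = 8
    angular_step_deg: float = 24.0
    alpha: float = 0.05
    z_split_nm: float = 17.0

    @property
    def wedge(self) -> WedgeDescriptor:
        return WedgeDescriptor(self.tilt_min, self.tilt_max)


def make_phantom_target(
    spec: ArchitectureSpec,
    seed: int,
    conditions: StudyConditions = StudyConditions(),
    subunits: dict[str, BeadModel] | None = None,
) -> tuple[DensityMap, pd.DataFrame, dict[str, BeadModel]]:
    """Render an assembly, simulate one wedge+noise-corrupted particle at
    the reference pose, and impose the rotational symmetry — the map a
    symmetrized subtomogram average of this assembly would approach.

    Returns (target map, ground-truth table, subunits).
    """
    c = conditions
    subunits = subunits or default_subunits()
    truth, merged = build_assembly(spec, subunits)
    assembly = render_density(merged, c.voxel_size_nm, c.box_nm, c.resolution_nm)
    particle = simulate_particle(assembly, c.wedge, c.snr, seed=seed, pose=Pose())
    target = symmetrize(particle.map, c.symmetry_order)
    target.meta["resolution_nm"] = c.resolution_nm
    return target, truth, subunits


def _ring_map(target: DensityMap, mask: DensityMap) -> DensityMap:
    return target.with_values(target.values * (mask.values > 0))


def crnpc_copy_census(
    seed: int,
    conditions: StudyConditions = StudyConditions(),
) -> tuple[dict[str, int], dict[str, pd.DataFrame]]:
    """Count Y-complex and inner-ring protomer copies on the algal-NPC
    phantom by per-ring systematic fitting.

    The Y-complex model is fitted into the cytoplasmic-ring and
    nuclear-ring maps, the protomer model into the inner-ring map, each
    followed by significance assessment, clustering and
    mutually-exclusive acceptance.  Returns the per-ring counts and the
    accepted placement tables.
    """
    c = conditions
    target, truth, subunits = make_phantom_target(crnpc_spec(), seed, c)
    masks = ring_region_masks(target, c.z_split_nm)
    placements: dict[str, pd.DataFrame] = {}
    for region, label, settings in [
        ("CR", "Y-complex", Y_ACCEPT),
        ("NR", "Y-complex", Y_ACCEPT),
        ("IR", "IR-protomer", PROTOMER_ACCEPT),
    ]:
        acc = significant_placements(
            subunits[label], _ring_map(target, masks[region]),
            angular_step=c.angular_step_deg, alpha=c.alpha,
            resolution_nm=c.resolution_nm, **settings,
        )
        placements[region] = acc
    counts = {region: len(df) for region, df in placements.items()}
    counts["Y_total"] = counts["CR"] + counts["NR"]
    return counts, placements


def asymmetric_unit_count(
    seed: int,
    n_particles: int = 78,
    conditions: StudyConditions = StudyConditions(),
    snr: float | None = 2.0,
    unit_box: int = 16,
) -> int:
    """Generate a particle stack, align every particle to the symmetrized
    assembly reference, extract all symmetry-related subvolumes, and
    return how many units were obtained (n_particles x symmetry order)."""
    c = conditions
    subunits = default_subunits()
    _, merged = build_assembly(crnpc_spec(), subunits)
    assembly = render_density(merged, c.voxel_size_nm, c.box_nm, c.resolution_nm)
    reference = symmetrize(assembly, c.symmetry_order)
    particles, _ = generate_particle_set(
        assembly, n_particles, c.wedge, snr, seed=seed,
        voxel_size=c.voxel_size_nm, box_nm=c.box_nm, resolution_nm=c.resolution_nm,
    )
    poses = [
        align_particle(p, reference, angular_step=20.0, max_shift_nm=6.0)[0]
        for p in particles
    ]
    units = extract_asymmetric_units(
        particles, poses, c.symmetry_order, unit_box,
        unit_center_nm=(0.3 * c.box_nm, 0.0, 0.0),
    )
    return len(units)


def _outer_ring_specs(z_nm: float = 0.0) -> tuple[ArchitectureSpec, ArchitectureSpec]:
    """A 16-copy (outer + staggered inner) Y ring and an 8-copy Y ring on
    a common plane, mirroring the nuclear/cytoplasmic ring contrast."""
    base = crnpc_spec()
    outer = next(r for r in base.rings if r.ring_id == "NR-outer")
    inner = next(r for r in base.rings if r.ring_id == "NR-inner")
    ring16 = ArchitectureSpec(8, [
        RingSpec("Y-complex", 8, outer.radius_nm, z_nm, outer.tilt_deg, outer.phase_deg, "outer"),
        RingSpec("Y-complex", 8, inner.radius_nm, z_nm - 4.0, inner.tilt_deg,
                 inner.phase_deg, "inner"),
    ], label="ring16")
    ring8 = ArchitectureSpec(8, [
        RingSpec("Y-complex", 8, outer.radius_nm, z_nm, outer.tilt_deg, outer.phase_deg, "outer"),
    ], label="ring8")
    return ring16, ring8


def difference_map_census(
    seed: int,
    conditions: StudyConditions = StudyConditions(),
) -> tuple[int, pd.DataFrame]:
    """Nuclear-minus-cytoplasmic difference experiment.

    Both ring phantoms share eight Y-copies in rotational register; the
    16-copy ring carries eight extra staggered inner copies.  The
    normalized difference map should therefore contain exactly eight
    Y-complexes, which the fitting census then counts.
    """
    c = conditions
    subunits = default_subunits()
    ring16, ring8 = _outer_ring_specs()
    maps = []
    for spec in (ring16, ring8):
        _, merged = build_assembly(spec, subunits)
        rendered = render_density(merged, c.voxel_size_nm, c.box_nm, c.resolution_nm)
        # both rings come from the same reconstruction, so their noise is
        # common and largely cancels in the difference
        particle = simulate_particle(rendered, c.wedge, c.snr, seed=seed, pose=Pose())
        maps.append(symmetrize(particle.map, c.symmetry_order))
    diff = difference_map(maps[0], maps[1])
    positive = diff.with_values(np.maximum(diff.values, 0.0))
    # bring the (z-scored) difference back onto the rendering scale so
    # the fitting census and its density-claiming work as on any map
    model_map = render_density(subunits["Y-complex"], c.voxel_size_nm,
                               c.box_nm, c.resolution_nm)
    positive.values *= float(model_map.values.max()) / max(float(positive.values.max()), 1e-12)
    positive.meta["resolution_nm"] = c.resolution_nm
    from .fitting import envelope_threshold

    # the difference carries no calibrated total mass, so Otsu separates
    # the residual Y density from the subtraction noise
    acc = significant_placements(
        subunits["Y-complex"], positive, angular_step=c.angular_step_deg,
        alpha=c.alpha, resolution_nm=c.resolution_nm,
        target_threshold=envelope_threshold(positive.values), **Y_ACCEPT,
    )
    return len(acc), acc


def double_y_census(
    seed: int,
    conditions: StudyConditions = StudyConditions(snr=None),
) -> dict[str, int]:
    """Fit the paired (double) Y-complex model into the cytoplasmic and
    nuclear ring maps of the algal-NPC phantom.

    The pairing geometry only exists in the 16-copy nuclear ring, so
    significant placements should appear there and nowhere in the
    8-copy cytoplasmic ring.  The default conditions are noise-free:
    pair-versus-single discrimination probes the converged subtomogram
    average, whose noise level is far below that of a single particle.
    A candidate pair is only counted when *both* of its Y-copies are
    embedded in the ring density.
    """
    from .density import transform_map
    from .fitting import envelope_threshold, mass_matched_threshold
    from .phantoms import double_y_halves, pose_from_row

    c = conditions
    target, _, subunits = make_phantom_target(crnpc_spec(), seed, c)
    masks = ring_region_masks(target, c.z_split_nm)
    halves = [
        render_density(h, c.voxel_size_nm, c.box_nm, c.resolution_nm)
        for h in double_y_halves()
    ]
    half_thr = [envelope_threshold(h.values) for h in halves]
    pair_map = render_density(subunits["double-Y"], c.voxel_size_nm, c.box_nm,
                              c.resolution_nm)
    counts = {}
    for region in ("CR", "NR"):
        ring = _ring_map(target, masks[region])
        acc = significant_placements(
            subunits["double-Y"], ring,
            # the paired model is twice the size of a single Y, so the
            # orientation grid is refined and the translation lattice
            # coarsened accordingly
            angular_step=c.angular_step_deg * 0.625, translation_step=2,
            alpha=c.alpha, resolution_nm=c.resolution_nm,
            min_separation_nm=18.0, sequential_claim=True, min_overlap=0.5,
        )
        # a genuine pair has *both* Y-copies embedded in ring density; a
        # half-fit onto a single ring leaves one copy in the channel
        thr_t = mass_matched_threshold(pair_map, ring)
        B = ring.values >= thr_t
        kept = 0
        for _, row in acc.iterrows():
            pose = pose_from_row(row)
            ok = True
            for h, thr in zip(halves, half_thr):
                env = transform_map(h, pose).values >= thr
                if env.sum() == 0 or B[env].mean() < 0.5:
                    ok = False
                    break
            kept += ok
        counts[region] = kept
    return counts


def inner_ring_census(
    seed: int,
    conditions: StudyConditions = StudyConditions(),
) -> tuple[int, pd.DataFrame]:
    """Protomer census on the inner-ring-only phantom (8 spokes of 4
    stacked protomers)."""
    c = conditions
    target, truth, subunits = make_phantom_target(inner_ring_spec(), seed, c)
    acc = significant_placements(
        subunits["IR-protomer"], target, angular_step=c.angular_step_deg,
        alpha=c.alpha, resolution_nm=c.resolution_nm, **PROTOMER_ACCEPT,
    )
    return len(acc), acc
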
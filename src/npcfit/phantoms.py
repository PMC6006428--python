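"""Synthetic ground-truth generators.

Two families of phantom are produced here:

* **Structural phantoms** — C8-symmetric nuclear pore complex (NPC)
  assemblies built from toy bead subunits arranged on rings.  At the
  3-6 nm resolutions targeted by subtomogram averaging it is the shape
  envelope of a subcomplex, not its atomic detail, that drives rigid-body
  fitting, so weighted pseudo-atoms (beads) rendered as Gaussians stand
  in for atomic models and keep every experiment desk-scale.
* **Expression phantoms** — gene-by-sample matrices with block-correlated
  modules on an FPKM-like non-negative scale, emulating the public
  RNA-seq compendium used for nucleoporin co-expression analysis.

Everything is a pure function of its arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .density import (
    DensityMap,
    Pose,
    WedgeDescriptor,
    apply_wedge,
    centered_map,
    transform_map,
)

__all__ = [
    "BeadModel",
    "RingSpec",
    "ArchitectureSpec",
    "Subtomogram",
    "make_subunit",
    "build_assembly",
    "render_density",
    "simulate_particle",
    "generate_particle_set",
    "simulate_expression",
    "crnpc_spec",
    "hsnpc_like_spec",
    "inner_ring_spec",
    "default_subunits",
]

GT_COLUMNS = ["subunit", "ring", "copy", "alpha", "beta", "gamma", "tx", "ty", "tz"]


@dataclass
class BeadModel:
    """Weighted pseudo-atom model of a subcomplex.

    positions are nm in the model frame (centroid at origin after
    construction); ``head_index`` / ``tail_index`` mark the beads used for
    head-to-tail adjacency analysis of ring oligomers.
    """

    positions: np.ndarray  # (n, 3) nm
    weights: np.ndarray  # (n,)
    radii: np.ndarray  # (n,) nm
    label: str = "subunit"
    head_index: int | None = None
    tail_index: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if len(self.positions) < 1:
            raise ValueError("a bead model needs at least one bead")
        if np.any(self.weights <= 0):
            raise ValueError("bead weights must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("bead coordinates must be finite")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def centroid(self) -> np.ndarray:
        return np.average(self.positions, axis=0, weights=self.weights)

    @property
    def extent(self) -> float:
        """Radius of the bounding sphere about the centroid, incl. bead radii."""
        d = np.linalg.norm(self.positions - self.centroid, axis=1) + self.radii
        return float(d.max())

    def centered(self) -> "BeadModel":
        return replace(self, positions=self.positions - self.centroid)

    def transformed(self, pose: Pose) -> "BeadModel":
        pos = self.positions @ pose.matrix.T + pose.t
        return replace(self, positions=pos)

    def concat(self, other: "BeadModel", label: str | None = None) -> "BeadModel":
        return BeadModel(
            np.vstack([self.positions, other.positions]),
            np.concatenate([self.weights, other.weights]),
            np.concatenate([self.radii, other.radii]),
            label or self.label,
        )


def _line_beads(start, end, spacing):
    start, end = np.asarray(start, float), np.asarray(end, float)
    n = max(2, int(np.ceil(np.linalg.norm(end - start) / spacing)) + 1)
    return start + (end - start) * np.linspace(0, 1, n)[:, None]


def make_subunit(label: str, shape_params: dict | None = None, seed: int = 0) -> BeadModel:
    """Build a toy subunit of one of three shape families.

    ``label`` selects the family by prefix: ``"Y"`` (chiral two-armed
    shape standing in for the Y-complex), ``"rod"`` (straight bead
    chain), ``"blob-cluster"`` (seeded asymmetric cluster, standing in
    for a compact inner-ring protomer).  Deterministic for a fixed seed;
    the returned model is centred on its weighted centroid.
    """
    p = dict(shape_params or {})
    spacing = p.get("bead_spacing_nm", 3.0)
    radius = p.get("bead_radius_nm", 2.0)
    if label.startswith("Y"):
        stem = p.get("stem_nm", 25.0)
        arm = p.get("arm_nm", 15.0)
        ratio = p.get("arm_ratio", 0.6)
        a1 = np.radians(p.get("arm_angle_deg", 45.0))
        # stem along -x, arms forking at +x; unequal arms and the out-of-plane
        # lift of the short arm make the model chiral
        beads = [_line_beads((-stem, 0, 0), (0, 0, 0), spacing)]
        beads.append(_line_beads((0, 0, 0), (arm * np.cos(a1), arm * np.sin(a1), 0), spacing)[1:])
        short = arm * ratio
        beads.append(
            _line_beads((0, 0, 0), (short * np.cos(a1), -short * np.sin(a1), 0.45 * short), spacing)[1:]
        )
        pos = np.vstack(beads)
        tail_index = 0
        head_index = len(beads[0])  # first bead of the long arm fork
    elif label.startswith("rod"):
        length = p.get("length_nm", 12.0)
        if length <= spacing:
            pos = np.zeros((1, 3))
        else:
            pos = _line_beads((-length / 2, 0, 0), (length / 2, 0, 0), spacing)
        tail_index, head_index = 0, len(pos) - 1
    elif label.startswith("blob"):
        n = p.get("n_beads", 8)
        extent = p.get("extent_nm", 6.0)
        rng = np.random.default_rng(seed)
        # anisotropic seeded cluster: generic positions are chiral, which keeps
        # orientation recovery unambiguous
        pos = rng.normal(size=(n, 3)) * (extent / 2.0) * np.array([1.0, 0.7, 0.5])
        tail_index = int(np.argmin(pos[:, 0]))
        head_index = int(np.argmax(pos[:, 0]))
    else:
        raise ValueError(f"unknown shape family for label {label!r}")
    w = np.full(len(pos), p.get("bead_weight", 1.0))
    model = BeadModel(pos, w, np.full(len(pos), radius), label,
                      head_index=head_index, tail_index=tail_index)
    c = model.centroid
    model = model.centered()
    return model


# ----------------------------------------------------------------------
# Ring architecture
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RingSpec:
    """One ring of identical copies placed at equal angular spacing."""

    subunit: str
    copies: int
    radius_nm: float
    z_nm: float
    tilt_deg: float = 0.0
    phase_deg: float = 0.0
    ring_id: str = ""
    asymmetric_exception: bool = False


@dataclass
class ArchitectureSpec:
    """Declarative layout of a ring assembly with C-symmetry."""

    symmetry_order: int
    rings: list[RingSpec]
    channel_diameter_nm: float = 0.0
    label: str = "assembly"

    def __post_init__(self) -> None:
        if self.symmetry_order < 1:
            raise ValueError("symmetry_order must be >= 1")
        for r in self.rings:
            if r.radius_nm < 0:
                raise ValueError(f"ring {r.ring_id}: radius must be >= 0")
            if r.copies % self.symmetry_order and not r.asymmetric_exception:
                raise ValueError(
                    f"ring {r.ring_id}: {r.copies} copies not divisible by "
                    f"C{self.symmetry_order}; declare asymmetric_exception to allow"
                )

    @property
    def total_copies(self) -> int:
        return sum(r.copies for r in self.rings)


def _placement_pose(ring: RingSpec, copy_idx: int) -> Pose:
    phi = ring.phase_deg + 360.0 * copy_idx / ring.copies
    # local +x (the subunit long axis) is placed tangentially; the tilt tips
    # the subunit about its local y before the azimuthal placement
    R = (
        Rotation.from_euler("z", phi + 90.0, degrees=True)
        * Rotation.from_euler("y", ring.tilt_deg, degrees=True)
    ).as_matrix()
    c = np.array([
        ring.radius_nm * np.cos(np.radians(phi)),
        ring.radius_nm * np.sin(np.radians(phi)),
        ring.z_nm,
    ])
    return Pose.from_matrix(R, c)


def build_assembly(
    spec: ArchitectureSpec, subunits: dict[str, BeadModel]
) -> tuple[pd.DataFrame, BeadModel]:
    """Place every ring copy; returns the ground-truth pose table and the
    composite bead model (all copies merged, in assembly coordinates)."""
    for r in spec.rings:
        if r.subunit not in subunits:
            raise KeyError(f"no subunit model provided for label {r.subunit!r}")
    rows = []
    merged: BeadModel | None = None
    for ring in spec.rings:
        for c in range(ring.copies):
            pose = _placement_pose(ring, c)
            rows.append(
                [ring.subunit, ring.ring_id, c, *pose.euler_deg, *pose.translation]
            )
            placed = subunits[ring.subunit].transformed(pose)
            merged = placed if merged is None else merged.concat(placed)
    table = pd.DataFrame(rows, columns=GT_COLUMNS)
    assert len(table) == spec.total_copies
    merged.label = spec.label  # type: ignore[union-attr]
    return table, merged


def pose_from_row(row) -> Pose:
    return Pose((row["alpha"], row["beta"], row["gamma"]), (row["tx"], row["ty"], row["tz"]))


# ----------------------------------------------------------------------
# Density rendering and particle simulation
# ----------------------------------------------------------------------

def render_density(
    model: BeadModel, voxel_size: float, box_nm: float, resolution_nm: float
) -> DensityMap:
    """Render beads as isotropic Gaussians on a centred grid.

    Each bead contributes a normalized Gaussian of FWHM ``resolution_nm``
    scaled by its weight, so the map integral (sum times voxel volume)
    equals the total bead weight.
    """
    if resolution_nm < 2 * voxel_size:
        raise ValueError("resolution must be >= 2 * voxel_size")
    n = int(np.ceil(box_nm / voxel_size))
    out = centered_map(np.zeros((n, n, n)), voxel_size, model=model.label,
                       resolution_nm=resolution_nm)
    half = out.box_nm[0] / 2.0
    outside = np.where(np.any(np.abs(model.positions) > half - voxel_size, axis=1))[0]
    if len(outside):
        raise ValueError(
            f"model extends outside the box (half-width {half:.1f} nm): "
            f"beads {outside.tolist()} at {model.positions[outside].round(1).tolist()}"
        )
    sigma = resolution_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    norm = 1.0 / ((2 * np.pi) ** 1.5 * sigma**3)
    reach = int(np.ceil(4 * sigma / voxel_size))
    axes_1d = [out.origin[a] + voxel_size * np.arange(n) for a in range(3)]
    vals = out.values
    for pos, w in zip(model.positions, model.weights):
        ctr = np.clip(np.rint(out.physical_to_index(pos)).astype(int), 0, n - 1)
        lo = np.maximum(ctr - reach, 0)
        hi = np.minimum(ctr + reach + 1, n)
        dx = [axes_1d[a][lo[a]:hi[a]] - pos[a] for a in range(3)]
        g = np.exp(
            -(dx[0][:, None, None] ** 2 + dx[1][None, :, None] ** 2 + dx[2][None, None, :] ** 2)
            / (2 * sigma**2)
        )
        vals[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += w * norm * g
    return out


@dataclass
class Subtomogram:
    """A simulated particle: corrupted map plus hidden ground truth."""

    map: DensityMap
    wedge: WedgeDescriptor
    true_pose: Pose
    snr: float | None  # None = noise-free
    wedge_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))


def simulate_particle(
    assembly_map: DensityMap,
    wedge: WedgeDescriptor,
    snr: float | None,
    seed: int,
    pose: Pose | None = None,
    tilt_sigma_deg: float = 3.0,
    shift_sigma_nm: float = 2.0,
) -> Subtomogram:
    """Transform the assembly by a random pose, apply the missing wedge,
    and add white Gaussian noise at the requested SNR.

    The random pose has a uniform in-plane angle about z, a small random
    tilt (normal, ``tilt_sigma_deg``) about a random in-plane axis, and a
    small normal translation.  ``snr`` is (signal variance)/(noise
    variance) measured on the wedge-filtered signal; ``None`` disables
    noise.
    """
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive (or None for noise-free)")
    rng = np.random.default_rng(seed)
    if pose is None:
        phi = rng.uniform(0.0, 360.0)
        tilt = rng.normal(0.0, tilt_sigma_deg)
        tilt_dir = rng.uniform(0.0, 360.0)
        R = (
            Rotation.from_euler("z", tilt_dir, degrees=True)
            * Rotation.from_euler("y", tilt, degrees=True)
            * Rotation.from_euler("z", phi - tilt_dir, degrees=True)
        ).as_matrix()
        t = rng.normal(0.0, shift_sigma_nm, size=3)
        pose = Pose.from_matrix(R, t)
    signal = transform_map(assembly_map, pose)
    corrupted = apply_wedge(signal, wedge)
    if snr is not None:
        sig_var = float(np.var(corrupted.values))
        noise = rng.normal(0.0, np.sqrt(sig_var / snr), size=corrupted.shape)
        corrupted = corrupted.with_values(corrupted.values + noise)
    return Subtomogram(corrupted, wedge, pose, snr)


def generate_particle_set(
    spec_or_map,
    n_particles: int,
    wedge: WedgeDescriptor,
    snr: float | None,
    seed: int,
    subunits: dict[str, BeadModel] | None = None,
    voxel_size: float = 4.0,
    box_nm: float = 144.0,
    resolution_nm: float = 8.0,
    **particle_kwargs,
) -> tuple[list[Subtomogram], pd.DataFrame]:
    """Simulate a stack of particles of one assembly with independent
    poses and noise.  Accepts either an :class:`ArchitectureSpec` (the
    assembly is rendered here) or a pre-rendered :class:`DensityMap`.

    Returns the particles and a table of their true poses.
    """
    if n_particles < 1:
        raise ValueError("need at least one particle")
    if isinstance(spec_or_map, DensityMap):
        assembly_map = spec_or_map
    else:
        subunits = subunits or default_subunits()
        _, merged = build_assembly(spec_or_map, subunits)
        assembly_map = render_density(merged, voxel_size, box_nm, resolution_nm)
    seeds = np.random.SeedSequence(seed).spawn(n_particles)
    particles, rows = [], []
    for i, ss in enumerate(seeds):
        p = simulate_particle(assembly_map, wedge, snr,
                              seed=int(ss.generate_state(1)[0] % (2**31)),
                              **particle_kwargs)
        particles.append(p)
        rows.append(["particle", "", i, *p.true_pose.euler_deg, *p.true_pose.translation])
    return particles, pd.DataFrame(rows, columns=GT_COLUMNS)


# ----------------------------------------------------------------------
# Stock architectures
# ----------------------------------------------------------------------

def default_subunits(seed: int = 7) -> dict[str, BeadModel]:
    """Toy subunit set used by the stock NPC architectures."""
    return {
        "Y-complex": make_subunit("Y", seed=seed),
        "IR-protomer": make_subunit("blob-cluster",
                                    {"n_beads": 10, "extent_nm": 9.0}, seed=seed + 1),
        "double-Y": double_y_model(seed=seed),
    }


def double_y_model(seed: int = 7) -> BeadModel:
    """Two Y-complex copies in the paired (outer + inner) arrangement of a
    16-copy outer ring: the relative pose is taken from the stock nuclear
    ring layout, so the pair matches the phantom's own inner/outer
    stagger exactly."""
    a, b = double_y_halves(seed)
    pair = a.concat(b, label="double-Y")
    return pair


def double_y_halves(seed: int = 7) -> tuple[BeadModel, BeadModel]:
    """The two Y-complex components of :func:`double_y_model`, each in
    the centred frame of the pair (useful for testing that both halves
    of a candidate pair placement lie in density)."""
    spec = crnpc_spec()
    rings = {r.ring_id: r for r in spec.rings}
    y = make_subunit("Y", seed=seed)
    p_out = _placement_pose(rings["NR-outer"], 0)
    p_in = _placement_pose(rings["NR-inner"], 0)
    rel = p_out.inverse().compose(p_in)
    other = y.transformed(rel)
    pair_centroid = y.concat(other).centroid
    a = replace(y, positions=y.positions - pair_centroid)
    b = replace(other, positions=other.positions - pair_centroid)
    return a, b


def crnpc_spec(
    outer_radius_nm: float = 47.0,
    inner_y_radius_nm: float = 33.0,
    outer_z_nm: float = 23.0,
    channel_diameter_nm: float = 60.0,
) -> ArchitectureSpec:
    """The algal NPC layout: 8 Y-complexes in the cytoplasmic ring, 16
    (8 outer + 8 inner, half-unit staggered) in the nuclear ring, and an
    inner ring of 8 spokes x 4 protomers (32 copies).  Cytoplasmic side
    is +z."""
    ir = _inner_ring_rings(channel_diameter_nm)
    return ArchitectureSpec(
        symmetry_order=8,
        rings=[
            RingSpec("Y-complex", 8, outer_radius_nm, +outer_z_nm, tilt_deg=12.0,
                     phase_deg=0.0, ring_id="CR"),
            RingSpec("Y-complex", 8, outer_radius_nm, -outer_z_nm, tilt_deg=-12.0,
                     phase_deg=0.0, ring_id="NR-outer"),
            # the inner nuclear Y-ring duplicates the outer one radially
            # inward with a small azimuthal and axial offset
            RingSpec("Y-complex", 8, inner_y_radius_nm, -outer_z_nm - 4.0, tilt_deg=-12.0,
                     phase_deg=8.0, ring_id="NR-inner"),
            *ir,
        ],
        channel_diameter_nm=channel_diameter_nm,
        label="CrNPC-phantom",
    )


def _inner_ring_rings(channel_diameter_nm: float) -> list[RingSpec]:
    # protomer centres sit one subunit extent outside the channel wall so the
    # rendered density edge lands near channel_diameter / 2; the four stacked
    # protomers of a spoke span ~24 nm along the pore axis with the outer
    # pair radially offset, as in the conserved inner-ring spoke arrangement
    r_in = channel_diameter_nm / 2.0 + 5.0
    r_out = r_in + 8.0
    return [
        RingSpec("IR-protomer", 8, r_out, +12.0, tilt_deg=20.0, phase_deg=0.0, ring_id="IR-o+"),
        RingSpec("IR-protomer", 8, r_out, -12.0, tilt_deg=-20.0, phase_deg=0.0, ring_id="IR-o-"),
        RingSpec("IR-protomer", 8, r_in, +4.0, tilt_deg=60.0, phase_deg=10.0, ring_id="IR-i+"),
        RingSpec("IR-protomer", 8, r_in, -4.0, tilt_deg=-60.0, phase_deg=-10.0, ring_id="IR-i-"),
    ]


def hsnpc_like_spec(
    outer_radius_nm: float = 47.0,
    inner_y_radius_nm: float = 33.0,
    outer_z_nm: float = 32.0,
    channel_diameter_nm: float = 39.0,
) -> ArchitectureSpec:
    """A human-NPC-like layout for contrast experiments: 16 Y-complexes in
    *both* outer rings, taller scaffold, narrower central channel."""
    ir = _inner_ring_rings(channel_diameter_nm)
    return ArchitectureSpec(
        symmetry_order=8,
        rings=[
            RingSpec("Y-complex", 8, outer_radius_nm, +outer_z_nm, tilt_deg=0.0,
                     phase_deg=0.0, ring_id="CR-outer"),
            RingSpec("Y-complex", 8, inner_y_radius_nm, +outer_z_nm + 4.0, tilt_deg=0.0,
                     phase_deg=8.0, ring_id="CR-inner"),
            RingSpec("Y-complex", 8, outer_radius_nm, -outer_z_nm, tilt_deg=0.0,
                     phase_deg=0.0, ring_id="NR-outer"),
            RingSpec("Y-complex", 8, inner_y_radius_nm, -outer_z_nm - 4.0, tilt_deg=0.0,
                     phase_deg=8.0, ring_id="NR-inner"),
            *ir,
        ],
        channel_diameter_nm=channel_diameter_nm,
        label="HsNPC-like-phantom",
    )


def inner_ring_spec(channel_diameter_nm: float = 60.0) -> ArchitectureSpec:
    """Inner ring only: 8 spokes of 4 stacked protomers (32 copies)."""
    return ArchitectureSpec(
        symmetry_order=8,
        rings=_inner_ring_rings(channel_diameter_nm),
        channel_diameter_nm=channel_diameter_nm,
        label="inner-ring-phantom",
    )


# ----------------------------------------------------------------------
# Expression phantom
# ----------------------------------------------------------------------

def simulate_expression(
    n_genes: int,
    module_defs: dict[str, list[int]] | list[int],
    n_samples: int,
    within_module_corr: float = 0.8,
    noise_sd: float = 1.5,
    seed: int = 0,
    log_mean: float = 4.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x sample matrix with block-correlated co-expression modules.

    Genes of one module share a latent per-sample profile mixed with
    independent noise so that the expected pairwise Pearson correlation of
    their log-scale profiles equals ``within_module_corr``; background
    genes are independent.  Latent values are exponentiated onto a
    non-negative FPKM-like scale (so ``log2(x + 1)`` approximately
    recovers the latent profile).  ``noise_sd`` sets the per-gene spread
    of log2 expression.

    ``module_defs`` is either ``{"module_name": [gene indices]}`` or a
    list of module sizes (genes assigned from the front).  Returns the
    matrix (rows = genes) and a per-gene module label series ("" for
    background).
    """
    if not 0.0 <= within_module_corr <= 1.0:
        raise ValueError("within_module_corr must be in [0, 1]")
    if isinstance(module_defs, dict):
        modules = {k: list(v) for k, v in module_defs.items()}
    else:
        modules, start = {}, 0
        for i, size in enumerate(module_defs):
            modules[f"module{i + 1}"] = list(range(start, start + size))
            start += size
    used: set[int] = set()
    for name, idx in modules.items():
        if used & set(idx):
            raise ValueError("module gene sets must be disjoint")
        if max(idx, default=-1) >= n_genes:
            raise ValueError(f"module {name} references gene beyond n_genes")
        used |= set(idx)
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_genes, n_samples))
    labels = pd.Series([""] * n_genes, index=[f"g{i:04d}" for i in range(n_genes)])
    rho = within_module_corr
    for name, idx in modules.items():
        latent = rng.normal(size=n_samples)
        z[idx] = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * z[idx]
        labels.iloc[idx] = name
    log2_expr = log_mean + noise_sd * z
    fpkm = np.maximum(2.0**log2_expr - 1.0, 0.0)
    mat = pd.DataFrame(fpkm, index=labels.index,
                       columns=[f"s{j:04d}" for j in range(n_samples)])
    return mat, labels
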
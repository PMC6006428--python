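"""Systematic rigid-body fitting of subunit models into ring density maps.

The search scores every pose on a six-dimensional grid: orientations on a
quasi-uniform SO(3) grid, translations on the voxel lattice.  Each pose
gets

* ``cc`` — Pearson cross-correlation between model and map density over
  the voxels of the model envelope,
* ``overlap`` — the fraction of envelope voxels that fall inside the
  map's own thresholded envelope,
* ``score = cc * overlap`` — a high-correlation fit hanging outside the
  map density is penalized by its poor overlap.

The translational scan is evaluated for all orientations at once with
FFT cross-correlations; it agrees with direct per-pose evaluation to
numerical precision.  The tested hypotheses are the score's local
maxima over the translation lattice (restricted to placements that
engage the map envelope).  Their p-values come from an empirical null:
preferably the maxima distribution of the same search run against a
phase-randomized surrogate of the target, otherwise a normal law fitted
to contamination-robust lower quantiles of the observed maxima.
Benjamini-Hochberg over the greedily clustered maxima yields q-values,
and acceptance turns significant clusters into unique, mutually
exclusive placements (minimum centre separation, relative overlap
floor, and — for models tiling quasi-continuous rings — sequential
density claiming with re-scoring against the residual).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy import ndimage, stats
from scipy.spatial.transform import Rotation

from .density import (
    DensityMap,
    Pose,
    lowpass_filter,
    rotation_distance_deg,
    transform_map,
)
from .phantoms import BeadModel, render_density

__all__ = [
    "RigidFit",
    "FitEnsemble",
    "so3_grid",
    "so3_grid_size",
    "envelope_threshold",
    "score_fit",
    "exhaustive_search",
    "assess_significance",
    "phase_randomize",
    "randomized_null_maxima",
    "cluster_fits",
    "polish_fit",
    "significant_placements",
    "hierarchical_fit",
    "count_copies",
]

FIT_COLUMNS = ["alpha", "beta", "gamma", "tx", "ty", "tz",
               "cc", "overlap", "score", "p", "q", "significant"]


@dataclass(frozen=True)
class RigidFit:
    """One scored placement."""

    pose: Pose
    cc: float
    overlap: float
    score: float
    p_value: float = np.nan
    q_value: float = np.nan

    def __post_init__(self) -> None:
        if not -1.0001 <= self.cc <= 1.0001:
            raise ValueError("cc outside [-1, 1]")
        if not -1e-6 <= self.overlap <= 1 + 1e-6:
            raise ValueError("overlap outside [0, 1]")


# ----------------------------------------------------------------------
# Orientation grid
# ----------------------------------------------------------------------

def _fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def so3_grid_size(angular_step: float) -> tuple[int, int]:
    """(number of axis directions, number of in-plane angles) for a
    quasi-uniform SO(3) grid at the given step in degrees.  Directions
    tile the sphere at one per ``step^2`` of solid angle."""
    step_rad = np.radians(angular_step)
    n_dirs = max(1, int(round(4.0 * np.pi / step_rad**2)))
    n_inplane = max(1, int(round(360.0 / angular_step)))
    return n_dirs, n_inplane


def so3_grid(angular_step: float) -> list[Rotation]:
    """Quasi-uniform rotation grid: Fibonacci-distributed viewing
    directions combined with a full in-plane sweep.  Deterministic."""
    if angular_step <= 0:
        raise ValueError("angular_step must be positive")
    n_dirs, n_inplane = so3_grid_size(angular_step)
    dirs = _fibonacci_directions(n_dirs)
    theta = np.degrees(np.arccos(np.clip(dirs[:, 2], -1, 1)))
    phi = np.degrees(np.arctan2(dirs[:, 1], dirs[:, 0]))
    alphas = np.arange(n_inplane) * (360.0 / n_inplane)
    rots = []
    for th, ph in zip(theta, phi):
        for al in alphas:
            rots.append(Rotation.from_euler("ZYZ", [ph, th, al], degrees=True))
    return rots


# ----------------------------------------------------------------------
# Scoring
# ----------------------------------------------------------------------

def envelope_threshold(values: np.ndarray, volume_fraction: float | None = None,
                       voxel_size: float | None = None,
                       volume_nm3: float | None = None) -> float:
    """Isovalue defining a density envelope.

    With ``volume_nm3`` (and ``voxel_size``) the threshold encloses that
    molecular volume; with ``volume_fraction`` it encloses that fraction
    of voxels; the default is Otsu's threshold on the positive values.
    Degenerate (constant) maps get a threshold above the maximum, i.e. an
    empty envelope.
    """
    v = np.asarray(values)
    if np.ptp(v) == 0:
        return float(v.max()) + 1.0
    if volume_nm3 is not None:
        if voxel_size is None:
            raise ValueError("volume_nm3 needs voxel_size")
        n_vox = int(round(volume_nm3 / voxel_size**3))
        volume_fraction = min(1.0, n_vox / v.size)
    if volume_fraction is not None:
        return float(np.quantile(v, 1.0 - volume_fraction))
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(v))


def mass_matched_threshold(model_map: DensityMap, target_map: DensityMap,
                           model_threshold: float | None = None) -> float:
    """Target isovalue enclosing the target's expected molecular volume.

    Rendering preserves mass (map integral = bead weight), so the
    volume-per-mass of the model envelope calibrates how many voxels the
    target's total mass should occupy; the threshold is the isovalue
    enclosing exactly that many voxels.  Zero-mean noise cancels in the
    mass estimate.  Falls back to an empty envelope when the target
    carries no positive mass.
    """
    if model_threshold is None:
        model_threshold = envelope_threshold(model_map.values)
    v_model = int((model_map.values >= model_threshold).sum())
    w_model = float(model_map.values.sum())
    w_target = float(target_map.values.sum())
    if w_model <= 0 or v_model == 0:
        raise ValueError("model map has no positive mass/envelope")
    n_t = int(v_model * max(w_target, 0.0) / w_model)
    flat = np.sort(target_map.values.ravel())
    if n_t < 1:
        return float(flat[-1]) + 1.0
    return float(flat[-min(n_t, flat.size)])


def score_fit(
    model_map: DensityMap,
    target_map: DensityMap,
    pose: Pose,
    envelope_thresholds: tuple[float | None, float | None] = (None, None),
) -> tuple[float, float, float]:
    """Direct (non-accelerated) evaluation of one pose.

    The model map is resampled under the pose; ``cc`` is the Pearson
    correlation between model and target over the transformed model
    envelope, ``overlap`` the fraction of that envelope inside the
    target envelope, ``score`` their product.
    """
    thr_m, thr_t = envelope_thresholds
    if thr_m is None:
        thr_m = envelope_threshold(model_map.values)
    if thr_t is None:
        thr_t = envelope_threshold(target_map.values)
    moved = transform_map(model_map, pose)
    env = moved.values >= thr_m
    n = int(env.sum())
    if n == 0:
        raise ValueError("model envelope is empty at this pose/threshold")
    m = moved.values[env]
    t = target_map.values[env]
    vm = float(np.sum(m * m) - np.sum(m) ** 2 / n)
    vt = float(np.sum(t * t) - np.sum(t) ** 2 / n)
    if vm <= 0 or vt <= 0:
        cc = 0.0
    else:
        cc = float((np.sum(m * t) - np.sum(m) * np.sum(t) / n) / np.sqrt(vm * vt))
    overlap = float(np.mean(target_map.values[env] >= thr_t))
    return cc, overlap, cc * overlap


@dataclass
class FitEnsemble:
    """All scored poses of one (model, map) exhaustive search.

    ``cc`` and ``overlap`` are stored per orientation on the translation
    lattice (shape ``(n_orientations, nx, ny, nz)``); the lattice holds
    circular voxel shifts strided by ``translation_step`` voxels.
    """

    rotations: list[Rotation]
    cc: np.ndarray
    overlap: np.ndarray
    lattice_shifts: tuple[np.ndarray, np.ndarray, np.ndarray]  # signed voxel shifts/axis
    voxel_size: float
    angular_step: float
    translation_step: int
    map_shape: tuple[int, int, int]
    model_threshold: float
    target_threshold: float
    significance: "SignificanceResult | None" = None

    @property
    def score(self) -> np.ndarray:
        return self.cc * self.overlap

    @property
    def n_evaluations(self) -> int:
        return int(np.prod(self.cc.shape))

    def pose_at(self, o: int, idx: tuple[int, int, int]) -> Pose:
        sx, sy, sz = self.lattice_shifts
        t = np.array([sx[idx[0]], sy[idx[1]], sz[idx[2]]]) * self.voxel_size
        return Pose.from_matrix(self.rotations[o].as_matrix(), t)

    def fit_at(self, o: int, idx: tuple[int, int, int]) -> RigidFit:
        return RigidFit(self.pose_at(o, idx), float(self.cc[o][idx]),
                        float(self.overlap[o][idx]),
                        float(self.cc[o][idx] * self.overlap[o][idx]))

    def best(self) -> RigidFit:
        s = self.score
        flat = int(np.argmax(s))
        o, rest = divmod(flat, int(np.prod(s.shape[1:])))
        idx = np.unravel_index(rest, s.shape[1:])
        return self.fit_at(o, tuple(int(i) for i in idx))


def _prepare_model_map(model, target_map: DensityMap,
                       resolution_nm: float | None) -> DensityMap:
    if isinstance(model, BeadModel):
        res = resolution_nm or target_map.meta.get("resolution_nm") or 2.5 * target_map.voxel_size
        box = float(target_map.box_nm[0])
        return render_density(model, target_map.voxel_size, box, res)
    mm = model
    if resolution_nm is not None:
        mm = lowpass_filter(mm, resolution_nm)
    return mm


def exhaustive_search(
    model,
    target_map: DensityMap,
    angular_step: float = 24.0,
    translation_step: int = 1,
    model_threshold: float | None = None,
    target_threshold: float | None = None,
    resolution_nm: float | None = None,
) -> FitEnsemble:
    """Score the model at every orientation of a quasi-uniform SO(3) grid
    and every translation on the (strided) voxel lattice.

    ``model`` is a :class:`BeadModel` (rendered onto the target grid at
    the target's resolution) or an already-rendered :class:`DensityMap`.
    The translational scan uses FFT cross-correlations and equals direct
    per-pose evaluation to within numerical precision.
    """
    if angular_step <= 0 or translation_step < 1:
        raise ValueError("angular_step and translation_step must be positive")
    model_map = _prepare_model_map(model, target_map, resolution_nm)
    if model_map.shape != target_map.shape:
        raise ValueError("model map must be rendered on the target grid")
    if model_threshold is None:
        model_threshold = envelope_threshold(model_map.values)
    if target_threshold is None:
        target_threshold = mass_matched_threshold(model_map, target_map, model_threshold)

    T = target_map.values.astype(float)
    B = (T >= target_threshold).astype(float)
    Ft = sfft.rfftn(T)
    Ft2 = sfft.rfftn(T * T)
    Fb = sfft.rfftn(B)
    shape = T.shape
    s = translation_step
    rots = so3_grid(angular_step)
    cc_all = np.empty((len(rots),) + tuple((n + s - 1) // s for n in shape), dtype=np.float32)
    ov_all = np.empty_like(cc_all)
    sl = tuple(slice(None, None, s) for _ in shape)
    eps = 1e-12
    for o, rot in enumerate(rots):
        moved = transform_map(model_map, Pose.from_matrix(rot.as_matrix()))
        M = moved.values
        E = (M >= model_threshold).astype(float)
        nE = E.sum()
        if nE == 0:
            cc_all[o] = 0.0
            ov_all[o] = 0.0
            continue
        EM = E * M
        Fe = sfft.rfftn(E)
        Fem = sfft.rfftn(EM)
        s1 = sfft.irfftn(np.conj(Fe) * Ft, shape)
        s2 = sfft.irfftn(np.conj(Fe) * Ft2, shape)
        sm = sfft.irfftn(np.conj(Fem) * Ft, shape)
        ov = sfft.irfftn(np.conj(Fe) * Fb, shape) / nE
        Sm = EM.sum()
        var_m = float(np.sum(EM * M) - Sm**2 / nE)
        cov = sm - Sm * s1 / nE
        var_t = np.maximum(s2 - s1 * s1 / nE, 0.0)
        # snap numerically-degenerate evaluations to exact zero: an overlap
        # below one envelope voxel and a target variance at FFT round-off
        # level carry no information
        var_floor = max(1e-10 * nE * float(np.var(T)), eps)
        valid = var_t > var_floor
        denom = np.sqrt(np.maximum(var_m, eps) * np.maximum(var_t, var_floor))
        cc = np.where(valid, cov / denom, 0.0)
        ov = np.where(ov >= 1.0 / nE, ov, 0.0)
        cc_all[o] = np.clip(cc, -1.0, 1.0)[sl]
        ov_all[o] = np.clip(ov, 0.0, 1.0)[sl]
    shifts = tuple((np.fft.fftfreq(n) * n).astype(int)[::s] for n in shape)
    return FitEnsemble(
        rotations=rots, cc=cc_all, overlap=ov_all, lattice_shifts=shifts,
        voxel_size=target_map.voxel_size, angular_step=angular_step,
        translation_step=s, map_shape=shape,
        model_threshold=model_threshold, target_threshold=target_threshold,
    )


# ----------------------------------------------------------------------
# Significance
# ----------------------------------------------------------------------

@dataclass
class SignificanceResult:
    """Empirical-null annotation of an ensemble's local maxima.

    Preferred null: the empirical distribution of local-maxima scores
    obtained by searching the same model in a *phase-randomized* copy of
    the target (identical power spectrum, no structure) — it calibrates
    itself to any map.  Fallback (no randomized search available): a
    Gumbel law for the maxima Fisher-z scores fitted from lower
    quantiles, which genuine placements in the upper tail cannot
    contaminate."""

    null_loc: float
    null_scale: float
    alpha: float
    maxima: pd.DataFrame  # orientation, ix, iy, iz + FIT_COLUMNS
    n_hypotheses: int
    null_z: np.ndarray | None = None  # sorted randomized-map maxima z

    def p_of_z(self, z) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        if self.null_z is not None and self.null_z.size:
            n = self.null_z.size
            above = n - np.searchsorted(self.null_z, z, side="left")
            return (1.0 + above) / (1.0 + n)
        with np.errstate(over="ignore"):
            return stats.norm.sf((z - self.null_loc) / self.null_scale)

    def p_of_score(self, score) -> np.ndarray:
        return self.p_of_z(_fisher_z(np.asarray(score, dtype=float)))


def _fisher_z(score: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(score, -0.999999, 0.999999))


def phase_randomize(dmap: DensityMap, seed: int = 0,
                    match_support: bool = True) -> DensityMap:
    """Scramble the Fourier phases while keeping the amplitude spectrum:
    a structure-free surrogate with the target's noise statistics.

    Only meaningful for maps whose support fills the grid; for
    region-masked maps no structure-free surrogate with comparable
    statistics exists (see :func:`randomized_null_maxima`).
    """
    rng = np.random.default_rng(seed)
    F = sfft.rfftn(dmap.values.astype(float))
    phases = np.exp(2j * np.pi * rng.random(F.shape))
    phases.flat[0] = 1.0  # keep the mean
    out = sfft.irfftn(F * phases, dmap.shape)
    return dmap.with_values(out)


def randomized_null_maxima(
    model_map: DensityMap,
    target_map: DensityMap,
    angular_step: float,
    translation_step: int = 1,
    model_threshold: float | None = None,
    target_threshold: float | None = None,
    family_overlap_floor: float = 0.3,
    coarse_factor: float = 1.6,
    seed: int = 0,
    min_support: float = 0.95,
) -> np.ndarray | None:
    """Sorted Fisher-z scores of local maxima from fitting the model into
    a phase-randomized copy of the target (the empirical null sample).

    The orientation grid is coarsened by ``coarse_factor`` — the null
    distribution of wrong-placement maxima is insensitive to the exact
    sampling density, and this keeps the surrogate search cheap.
    Returns ``None`` for region-masked maps (support below
    ``min_support``): phase randomization spreads the region's power over
    the whole box, so no comparable structure-free surrogate exists and
    the quantile-fitted fallback null applies instead.
    """
    if float((target_map.values != 0).mean()) < min_support:
        return None
    surrogate = phase_randomize(target_map, seed)
    ens = exhaustive_search(
        model_map, surrogate, angular_step * coarse_factor, translation_step,
        model_threshold=model_threshold,
        # evaluate the surrogate against the same envelope level
        target_threshold=(target_threshold if target_threshold is not None
                          else mass_matched_threshold(model_map, target_map,
                                                      model_threshold)),
    )
    zs = _collect_maxima(ens, family_overlap_floor)[-1]
    return np.sort(zs)


def _collect_maxima(ensemble: FitEnsemble, family_overlap_floor: float):
    """Translation-lattice local maxima per orientation (circular), kept
    to placements that engage the map envelope."""
    o_list, i_list, z_chunks = [], [], []
    for o in range(ensemble.cc.shape[0]):
        s_o = ensemble.cc[o].astype(float) * ensemble.overlap[o]
        is_max = (s_o >= ndimage.maximum_filter(s_o, size=3, mode="wrap")) \
            & (s_o != 0.0) & (ensemble.overlap[o] >= family_overlap_floor)
        idx = np.nonzero(is_max)
        o_list.append(np.full(idx[0].size, o))
        i_list.append(idx)
        z_chunks.append(_fisher_z(s_o[idx]))
    o_idx = np.concatenate(o_list)
    ix = np.concatenate([i[0] for i in i_list])
    iy = np.concatenate([i[1] for i in i_list])
    iz = np.concatenate([i[2] for i in i_list])
    return o_idx, ix, iy, iz, np.concatenate(z_chunks)


def assess_significance(ensemble: FitEnsemble, alpha: float = 0.05,
                        max_null_sample: int = 500_000,
                        family_overlap_floor: float = 0.3,
                        null_z: np.ndarray | None = None) -> FitEnsemble:
    """Attach empirical-null p- and q-values to the ensemble.

    The tested hypotheses are the translation-lattice local maxima of
    the score (the massively dependent raw grid is not a hypothesis
    family).  With ``null_z`` — the sorted maxima scores from a
    phase-randomized surrogate search, see
    :func:`randomized_null_maxima` — p-values are empirical upper-tail
    probabilities under that structure-free null.  Without it, a Gumbel
    law fitted to the lower quantiles of the observed maxima serves as
    the fallback null.  Benjamini-Hochberg over the maxima yields
    q-values; the placement pipeline re-corrects over clusters (see
    :func:`cluster_fits`).
    """
    if int(np.prod(np.asarray(ensemble.cc.shape))) < 100:
        raise ValueError("need an ensemble of at least 100 sampled fits")
    o_idx, ix, iy, iz, zs_all = _collect_maxima(ensemble, family_overlap_floor)
    if zs_all.size < 100:
        raise ValueError("degenerate (constant) score distribution; cannot fit a null")
    null_sample = zs_all
    if null_sample.size > max_null_sample:
        null_sample = np.random.default_rng(0).choice(
            null_sample, size=max_null_sample, replace=False
        )
    # quantile fit on the lower half of the maxima distribution (fallback
    # null): genuine placements contaminate only the upper tail
    q10, q50 = np.percentile(null_sample, [10.0, 50.0])
    scale = float((q50 - q10) / 1.2815515655446004)  # z(0.5) - z(0.1)
    loc = float(q50)
    if scale <= 0 and null_z is None:
        raise ValueError("degenerate (constant) score distribution; cannot fit a null")

    zs = zs_all
    m_total = zs.size
    # maxima at or below the null median can never be rejected; keep the
    # table to the upper half but correct over the full family size
    keep = zs > q50
    o_idx, ix, iy, iz, zs = o_idx[keep], ix[keep], iy[keep], iz[keep], zs[keep]
    result = SignificanceResult(loc, max(scale, 1e-12), alpha, pd.DataFrame(), m_total,
                                null_z=np.sort(null_z) if null_z is not None else None)
    p = result.p_of_z(zs)
    m = m_total
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(p.size) + 1.0)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)

    sx, sy, sz = ensemble.lattice_shifts
    vs = ensemble.voxel_size
    eulers = np.array([r.as_euler("ZYZ", degrees=True) for r in ensemble.rotations])
    df = pd.DataFrame({
        "orientation": o_idx, "ix": ix, "iy": iy, "iz": iz,
        "alpha": eulers[o_idx, 0], "beta": eulers[o_idx, 1], "gamma": eulers[o_idx, 2],
        "tx": sx[ix] * vs, "ty": sy[iy] * vs, "tz": sz[iz] * vs,
        "cc": ensemble.cc[o_idx, ix, iy, iz].astype(float),
        "overlap": ensemble.overlap[o_idx, ix, iy, iz].astype(float),
        "score": ensemble.cc[o_idx, ix, iy, iz].astype(float)
        * ensemble.overlap[o_idx, ix, iy, iz],
        "p": p, "q": q, "significant": q <= alpha,
    }).sort_values("score", ascending=False, ignore_index=True)
    result.maxima = df
    ensemble.significance = result
    return ensemble


# ----------------------------------------------------------------------
# Clustering and hierarchical assignment
# ----------------------------------------------------------------------

def cluster_fits(
    ensemble: FitEnsemble,
    rot_tol: float | None = None,
    trans_tol: float = 6.0,
    max_candidates: int = 5000,
    candidates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Greedy best-first clustering of local maxima into unique placements.

    Repeatedly takes the highest-score unclustered fit and absorbs every
    fit within both the rotational (``rot_tol`` degrees, default
    1.5 x angular step) and translational (``trans_tol`` nm) tolerance.
    Returns cluster representatives sorted by score, with member counts.
    """
    if rot_tol is None:
        rot_tol = 1.5 * ensemble.angular_step
    if rot_tol <= 0 or trans_tol <= 0:
        raise ValueError("tolerances must be positive")
    if candidates is None:
        if ensemble.significance is None:
            assess_significance(ensemble)
        candidates = ensemble.significance.maxima
    df = candidates.head(max_candidates).reset_index(drop=True)
    if df.empty:
        return df.assign(n_members=pd.Series(dtype=int))
    quats = Rotation.from_euler(
        "ZYZ", df[["alpha", "beta", "gamma"]].to_numpy(), degrees=True
    )
    trans = df[["tx", "ty", "tz"]].to_numpy()
    unused = np.ones(len(df), dtype=bool)
    cos_half_tol = np.cos(np.radians(rot_tol) / 2.0)
    qarr = quats.as_quat()
    reps, members = [], []
    order = np.argsort(-df["score"].to_numpy(), kind="stable")
    for i in order:
        if not unused[i]:
            continue
        d_t = np.linalg.norm(trans - trans[i], axis=1)
        dot = np.abs(qarr @ qarr[i])
        absorb = unused & (d_t <= trans_tol) & (dot >= cos_half_tol)
        unused &= ~absorb
        reps.append(i)
        members.append(int(absorb.sum()))
    out = df.iloc[reps].reset_index(drop=True)
    out["n_members"] = members
    out = out.sort_values("score", ascending=False, ignore_index=True)
    if "p" in out.columns and len(out):
        alpha = ensemble.significance.alpha if ensemble.significance else 0.05
        out = _bh_over_clusters(out, alpha)
    return out


def _bh_over_clusters(df: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Benjamini-Hochberg across cluster representatives: clusters
    approximate independent hypotheses, unlike the massively dependent
    raw grid maxima."""
    out = df.copy()
    p_adj = np.clip(out["p"].to_numpy(float), 0.0, 1.0)
    m = p_adj.size
    order = np.argsort(p_adj, kind="stable")
    ranked = p_adj[order] * m / (np.arange(m) + 1.0)
    q = np.empty(m)
    q[order] = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out["q"] = q
    out["significant"] = out["q"] <= alpha
    return out


def accept_placements(
    ensemble: FitEnsemble,
    clusters: pd.DataFrame,
    model_map: DensityMap,
    target_map: DensityMap,
    min_separation_nm: float = 6.0,
    sequential_claim: bool = True,
    score_ratio: float = 0.5,
    min_overlap: float = 0.0,
    relative_overlap_floor: float = 0.0,
    occupied: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Turn significant clusters into a set of unique, mutually exclusive
    placements (greedy matching pursuit).

    Candidates are visited best-first.  Every accepted placement claims
    the voxels where its *own placed density* reaches the target
    threshold — exactly the density it explains — and those voxels are
    zeroed in a working copy of the map.  With ``sequential_claim`` each
    later candidate is re-scored against this residual and kept only if
    it retains at least ``score_ratio`` of its original score: a
    spurious placement straddling two genuine ring copies loses its
    entire support once those copies are accepted, while a genuine
    neighbour loses only the contact region.  Disable sequential
    claiming for compact models packed closer than their own blur
    radius (e.g. stacked inner-ring protomers), where plain
    non-maximum suppression by ``min_separation_nm`` is the correct
    guard; the centre-separation rule always applies (double-count
    guard).  Returns the accepted table and the claimed-voxel mask.
    """
    if occupied is None:
        occupied = np.zeros(ensemble.map_shape, dtype=bool)
    sig = clusters[clusters["significant"]] if "significant" in clusters else clusters
    if relative_overlap_floor > 0 and len(sig):
        # countable copies should be about as embedded in the map envelope
        # as the best-scoring fits are
        ref = float(sig.head(5)["overlap"].median())
        min_overlap = max(min_overlap, relative_overlap_floor * ref)
    working = target_map.values.astype(float).copy()
    working[occupied] = 0.0
    thr_t = ensemble.target_threshold
    accepted_rows, accepted_pos = [], []
    for _, row in sig.iterrows():
        if row["overlap"] < min_overlap:
            # a genuine copy lies inside the map envelope; placements
            # hanging substantially outside it are not countable copies
            continue
        pos = row[["tx", "ty", "tz"]].to_numpy(float)
        if accepted_pos:
            d = np.linalg.norm(np.array(accepted_pos) - pos, axis=1)
            if np.any(d < min_separation_nm):
                warnings.warn(
                    "rejecting placement closer than the minimum separation to an "
                    "accepted one (double-count guard)", stacklevel=2,
                )
                continue
        pose = Pose((row["alpha"], row["beta"], row["gamma"]), tuple(pos))
        placed = transform_map(model_map, pose).values
        env = placed >= ensemble.model_threshold
        n_env = int(env.sum())
        if n_env == 0:
            continue
        row = row.copy()
        if sequential_claim:
            m = placed[env]
            t = working[env]
            vm = float(np.sum(m * m) - np.sum(m) ** 2 / n_env)
            vt = float(np.sum(t * t) - np.sum(t) ** 2 / n_env)
            cc = 0.0
            if vm > 0 and vt > 0:
                cc = float(
                    (np.sum(m * t) - np.sum(m) * np.sum(t) / n_env) / np.sqrt(vm * vt)
                )
            ov = float(np.mean(t >= thr_t))
            score = cc * ov
            if row["score"] <= 0 or score / row["score"] < score_ratio:
                continue
            row["cc"], row["overlap"], row["score"] = cc, ov, score
        claimed = placed >= thr_t  # the density this placement explains
        occupied |= claimed
        working[claimed] = 0.0
        accepted_rows.append(row)
        accepted_pos.append(pos)
    out = pd.DataFrame(accepted_rows).reset_index(drop=True)
    if out.empty:
        out = pd.DataFrame(columns=list(clusters.columns))
    return out, occupied


def polish_fit(
    model_map: DensityMap,
    target_map: DensityMap,
    pose: Pose,
    thresholds: tuple[float, float],
    rot_limit_deg: float,
    trans_limit_nm: float,
) -> tuple[Pose, float, float, float]:
    """Trust-region pose polish: hill-climb the score in small rotation /
    translation steps without leaving the starting grid cell.

    The sampling grid quantizes orientations, so genuine placements that
    fall between grid points score systematically low; polishing removes
    that quantization penalty while the trust region prevents a candidate
    from migrating onto a neighbouring copy.  Returns the refined pose
    and its (cc, overlap, score).
    """
    from scipy.spatial.transform import Rotation as _R

    best = pose
    cc0, ov0, bs = score_fit(model_map, target_map, pose, thresholds)
    best_cc, best_ov = cc0, ov0
    start_R = pose.rotation
    rot_step = rot_limit_deg / 2.0
    trans_step = trans_limit_nm / 2.0
    while rot_step >= rot_limit_deg / 4.0:
        improved = False
        cands = []
        for ax in range(3):
            for sgn in (1.0, -1.0):
                v = np.zeros(3)
                v[ax] = sgn * rot_step
                R = _R.from_rotvec(np.radians(v)).as_matrix() @ best.matrix
                if rotation_distance_deg(R, start_R) <= rot_limit_deg:
                    cands.append(Pose.from_matrix(R, best.t))
                t = np.array(best.t, dtype=float)
                t[ax] += sgn * trans_step
                if np.linalg.norm(t - pose.t) <= trans_limit_nm:
                    cands.append(Pose(best.euler_deg, tuple(t)))
        for c in cands:
            cc, ov, s = score_fit(model_map, target_map, c, thresholds)
            if s > bs + 1e-9:
                best, bs, best_cc, best_ov, improved = c, s, cc, ov, True
        if not improved:
            rot_step /= 2.0
            trans_step /= 2.0
    return best, best_cc, best_ov, bs


def polish_clusters(
    ensemble: FitEnsemble,
    clusters: pd.DataFrame,
    model_map: DensityMap,
    target_map: DensityMap,
    max_polish: int = 60,
    p_prefilter: float = 0.05,
) -> pd.DataFrame:
    """Polish the poses of promising cluster representatives and update
    their scores, p- and q-values under the ensemble's null."""
    if ensemble.significance is None:
        raise ValueError("assess significance before polishing")
    sig = ensemble.significance
    thresholds = (ensemble.model_threshold, ensemble.target_threshold)
    out = clusters.copy()
    todo = out.index[out["p"] <= p_prefilter][:max_polish]
    for i in todo:
        row = out.loc[i]
        pose = Pose((row["alpha"], row["beta"], row["gamma"]),
                    (row["tx"], row["ty"], row["tz"]))
        new_pose, cc, ov, score = polish_fit(
            model_map, target_map, pose, thresholds,
            # quantization error is at most half a grid cell in either space
            rot_limit_deg=0.75 * ensemble.angular_step,
            trans_limit_nm=0.75 * ensemble.voxel_size * ensemble.translation_step,
        )
        if score <= row["score"]:
            continue
        out.loc[i, ["alpha", "beta", "gamma"]] = new_pose.euler_deg
        out.loc[i, ["tx", "ty", "tz"]] = new_pose.translation
        out.loc[i, ["cc", "overlap", "score"]] = (cc, ov, score)
        out.loc[i, "p"] = float(sig.p_of_score([score])[0])
    out = out.sort_values("score", ascending=False, ignore_index=True)
    return _bh_over_clusters(out, sig.alpha)


def significant_placements(
    model,
    target_map: DensityMap,
    angular_step: float = 24.0,
    translation_step: int = 1,
    alpha: float = 0.05,
    min_separation_nm: float = 6.0,
    sequential_claim: bool = True,
    min_overlap: float = 0.0,
    relative_overlap_floor: float = 0.0,
    trans_tol: float = 6.0,
    resolution_nm: float | None = None,
    model_threshold: float | None = None,
    target_threshold: float | None = None,
    polish: bool = False,
    randomized_null: bool = True,
) -> pd.DataFrame:
    """End-to-end census of one model in one map: exhaustive search,
    phase-randomized empirical null, significance assessment,
    clustering, pose polish of the candidate representatives, and
    mutually-exclusive acceptance.  Returns the accepted placements."""
    model_map = _prepare_model_map(model, target_map, resolution_nm)
    ens = exhaustive_search(model_map, target_map, angular_step, translation_step,
                            model_threshold=model_threshold,
                            target_threshold=target_threshold)
    null_z = None
    if randomized_null:
        null_z = randomized_null_maxima(
            model_map, target_map, angular_step, translation_step,
            model_threshold=ens.model_threshold,
            target_threshold=ens.target_threshold,
        )
    assess_significance(ens, alpha, null_z=null_z)
    clusters = cluster_fits(ens, trans_tol=trans_tol)
    if polish:
        clusters = polish_clusters(ens, clusters, model_map, target_map)
    accepted, _ = accept_placements(
        ens, clusters, model_map, target_map,
        min_separation_nm=min_separation_nm, sequential_claim=sequential_claim,
        min_overlap=min_overlap, relative_overlap_floor=relative_overlap_floor,
    )
    return accepted


def hierarchical_fit(
    target_map: DensityMap,
    ordered_models: list[tuple[str, BeadModel | DensityMap]],
    alpha: float = 0.05,
    angular_step: float = 24.0,
    translation_step: int = 1,
    trans_tol: float = 6.0,
    rot_tol: float | None = None,
    resolution_nm: float | None = None,
    relative_overlap_floor: float = 0.0,
    subtract: bool = False,
) -> tuple[pd.DataFrame, DensityMap]:
    """Hierarchical assignment: fit each model in order, accept its
    significant unique placements, remove the claimed density from the
    working map, and continue with the next model.

    ``ordered_models`` should run from the largest / most constrained
    model down.  Removal is by masking (zeroing the accepted envelope)
    by default, or by subtraction of the placed model density with
    ``subtract=True``.  Returns the assignment table and the residual
    working map.
    """
    working = target_map.copy()
    tables = []
    for label, model in ordered_models:
        model_map = _prepare_model_map(model, working, resolution_nm)
        ens = exhaustive_search(
            model_map, working, angular_step, translation_step,
            resolution_nm=None,
        )
        try:
            assess_significance(ens, alpha)
        except ValueError:
            continue  # constant residual: nothing left to fit
        clusters = cluster_fits(ens, rot_tol=rot_tol, trans_tol=trans_tol)
        accepted, occupied = accept_placements(
            ens, clusters, model_map, working, min_separation_nm=trans_tol,
            relative_overlap_floor=relative_overlap_floor,
        )
        if len(accepted):
            accepted.insert(0, "model", label)
            tables.append(accepted)
            if subtract:
                for _, row in accepted.iterrows():
                    pose = Pose(
                        (row["alpha"], row["beta"], row["gamma"]),
                        (row["tx"], row["ty"], row["tz"]),
                    )
                    working.values = working.values - transform_map(model_map, pose).values
            else:
                working.values = np.where(occupied, 0.0, working.values)
    if tables:
        assignment = pd.concat(tables, ignore_index=True)
    else:
        assignment = pd.DataFrame(columns=["model", *FIT_COLUMNS])
    return assignment, working


def count_copies(
    assignment: pd.DataFrame,
    region_masks: dict[str, DensityMap | np.ndarray],
    reference: DensityMap | None = None,
) -> pd.DataFrame:
    """Attribute each accepted placement to the region containing its
    centre and tabulate counts per (model, region).

    Placements falling in no region are counted under ``"unassigned"``.
    ``reference`` supplies the grid geometry for index lookup (defaults
    to the first mask that is a :class:`DensityMap`).
    """
    if reference is None:
        reference = next(m for m in region_masks.values() if isinstance(m, DensityMap))
    names = list(region_masks)
    models = sorted(assignment["model"].unique()) if len(assignment) else []
    counts = pd.DataFrame(0, index=models, columns=names + ["unassigned"])
    for _, row in assignment.iterrows():
        idx = np.rint(
            reference.physical_to_index(row[["tx", "ty", "tz"]].to_numpy(float))
        ).astype(int)
        idx = np.clip(idx, 0, np.array(reference.shape) - 1)
        region = "unassigned"
        for name, mask in region_masks.items():
            vals = mask.values if isinstance(mask, DensityMap) else np.asarray(mask)
            if vals[tuple(idx)] > 0:
                region = name
                break
        counts.loc[row["model"], region] += 1
    counts.index.name = "model"
    return counts
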
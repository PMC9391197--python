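"""Generalized Procrustes alignment with bending-energy semilandmark sliding.

Alignment iterates translation, scaling to unit centroid size, and
least-squares rotation of every specimen to an evolving consensus.  With
sliding enabled, semilandmarks are then displaced along their local curve
tangent so as to minimize the thin-plate-spline bending energy of each
specimen relative to the consensus; fixed landmarks and curve anchors never
move.  Reflections are never fitted during rotation (side is handled
explicitly by mirroring upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .scheme import Configuration, LandmarkScheme, PointRoles, flatten, point_roles

logger = logging.getLogger(__name__)


def centroid_size(points: np.ndarray) -> float:
    """Root summed squared deviation of the points from their centroid.

    The standard size measure removed by Procrustes alignment: invariant to
    translation and rotation, and linear under uniform scaling.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("centroid size needs at least two points")
    dev = points - points.mean(axis=0)
    size = float(np.sqrt((dev**2).sum()))
    if size == 0.0:
        raise ValueError("all points identical: centroid size is zero")
    return size


def _center_unit(points: np.ndarray) -> np.ndarray:
    dev = points - points.mean(axis=0)
    return dev / np.sqrt((dev**2).sum())


def ordinary_procrustes(
    a: np.ndarray, b: np.ndarray, allow_reflection: bool = False
) -> tuple[np.ndarray, float]:
    """Optimal orthogonal superimposition of ``b`` onto ``a``.

    Both inputs must be centered and scaled to unit centroid size.  Returns
    the 2x2 orthogonal matrix ``R`` minimizing ``||a - b @ R||`` (with
    ``det R = +1`` unless reflection is allowed) and the minimized
    Procrustes distance, which is symmetric in its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"point count mismatch: {a.shape} vs {b.shape}")
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    if allow_reflection or d > 0:
        r = u @ vt
    else:
        flip = np.diag([1.0, -1.0])
        r = u @ flip @ vt
    return r, float(np.linalg.norm(a - b @ r))


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two already-aligned shapes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def _rotations_to_consensus(coords: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Vectorized proper-rotation alignment of every specimen to the consensus.

    For 2-D shapes the optimal rotation has the closed form
    ``theta = atan2(H10 - H01, H00 + H11)`` with ``H = X' C``.
    """
    h = np.einsum("nij,ik->njk", coords, consensus)
    theta = np.arctan2(h[:, 1, 0] - h[:, 0, 1], h[:, 0, 0] + h[:, 1, 1])
    c, s = np.cos(theta), np.sin(theta)
    rots = np.empty((len(coords), 2, 2))
    rots[:, 0, 0] = c
    rots[:, 0, 1] = -s
    rots[:, 1, 0] = s
    rots[:, 1, 1] = c
    return np.einsum("npi,nij->npj", coords, rots)


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending-energy matrix of a reference shape.

    Uses the kernel ``U(r) = r^2 log r^2`` on reference inter-point
    distances; the returned matrix is the upper-left block of the inverse of
    the bordered TPS system.  It is symmetric, positive semi-definite, and
    annihilates affine configurations.
    """
    ref = np.asarray(reference, dtype=float)
    p = len(ref)
    diff = ref[:, None, :] - ref[None, :, :]
    r2 = (diff**2).sum(-1)
    off_diag = r2[~np.eye(p, dtype=bool)]
    if np.any(off_diag == 0.0):
        ii, jj = np.nonzero((r2 == 0.0) & ~np.eye(p, dtype=bool))
        pairs = sorted({tuple(sorted((int(a), int(b)))) for a, b in zip(ii, jj)})
        raise ValueError(f"duplicate reference points at index pairs {pairs[:5]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(r2 > 0, r2 * np.log(r2), 0.0)
    q = np.column_stack([np.ones(p), ref])
    if np.linalg.matrix_rank(q) < 3:
        raise ValueError("reference points are collinear; TPS system is singular")
    l = np.zeros((p + 3, p + 3))
    l[:p, :p] = k
    l[:p, p:] = q
    l[p:, :p] = q.T
    l_inv = np.linalg.inv(l)
    b = l_inv[:p, :p]
    return (b + b.T) / 2.0


def bending_energy(shape: np.ndarray, consensus: np.ndarray,
                   be_matrix: np.ndarray) -> float:
    """TPS bending energy of the deformation taking the consensus to a shape."""
    d = np.asarray(shape) - np.asarray(consensus)
    return float(np.einsum("id,ij,jd->", d, be_matrix, d))


def slide_semilandmarks(
    coords: np.ndarray,
    consensus: np.ndarray,
    roles: PointRoles,
    max_inner_iter: int = 1,
    tol: float = 1e-10,
    be_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Slide semilandmarks along curve tangents to minimize bending energy.

    ``coords`` is ``(n, p, 2)`` (or a single ``(p, 2)`` shape).  Each
    semilandmark moves only along the chord between its two curve
    neighbors; the joint displacement per specimen is the restricted
    linear solve minimizing the specimen's bending energy relative to the
    consensus.  Coincident neighbors give a degenerate tangent, and that
    point is held fixed for the pass.  Total bending energy never
    increases (the solve is reverted in the rare case rounding would raise
    it).
    """
    single = coords.ndim == 2
    coords = np.array(coords, dtype=float, copy=True)
    if single:
        coords = coords[None]
    if be_matrix is None:
        be_matrix = bending_energy_matrix(consensus)
    s_idx = roles.semilandmark_indices
    nbrs = roles.neighbors[s_idx]
    b_ss = be_matrix[np.ix_(s_idx, s_idx)]
    for n in range(len(coords)):
        x = coords[n]
        for _ in range(max_inner_iter):
            tang = x[nbrs[:, 1]] - x[nbrs[:, 0]]
            norms = np.linalg.norm(tang, axis=1)
            ok = norms > 1e-12
            if not ok.all():
                logger.warning(
                    "specimen %d: %d semilandmarks with degenerate tangents held fixed",
                    n, int((~ok).sum()),
                )
            u = np.zeros_like(tang)
            u[ok] = tang[ok] / norms[ok, None]
            d = x - consensus
            e_before = float(np.einsum("id,ij,jd->", d, be_matrix, d))
            m = b_ss * (u @ u.T)
            rhs = -np.einsum("jd,jd->j", u, (be_matrix @ d)[s_idx])
            act = np.flatnonzero(ok)
            t = np.zeros(len(s_idx))
            if len(act):
                sol, *_ = np.linalg.lstsq(m[np.ix_(act, act)], rhs[act], rcond=None)
                t[act] = sol
            x_new = x.copy()
            x_new[s_idx] += t[:, None] * u
            d_new = x_new - consensus
            e_after = float(np.einsum("id,ij,jd->", d_new, be_matrix, d_new))
            if e_after > e_before:  # numerical safety: never increase energy
                break
            x = x_new
            coords[n] = x
            if e_before - e_after < tol:
                break
    return coords[0] if single else coords


def _canonical_orientation(
    coords: np.ndarray, consensus: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the whole sample to a canonical frame.

    The consensus major principal axis is made vertical, with the sign fixed
    by a shape-intrinsic rule (positive third moment of the vertical
    projections, falling back to last-point-above-first), so the aligned
    result does not depend on which specimen happened to seed the
    consensus.  Only a common proper rotation is applied; all Procrustes
    distances are unchanged.
    """
    c = consensus - consensus.mean(axis=0)
    cov = c.T @ c
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    beta = np.pi / 2 - np.arctan2(v[1], v[0])
    rot = np.array([[np.cos(beta), -np.sin(beta)], [np.sin(beta), np.cos(beta)]]).T
    proj = (c @ rot)[:, 1]
    skew = float((proj**3).sum())
    flip = skew < 0 if abs(skew) > 1e-12 else proj[-1] < proj[0]
    if flip:
        rot = -rot  # 180-degree turn, still a proper rotation
    return coords @ rot, consensus @ rot


@dataclass
class AlignedSample:
    """Procrustes-aligned coordinates for a sample of specimens."""

    coords: np.ndarray  # (n, p, 2), unit centroid size
    centroid_sizes: np.ndarray  # (n,) sizes in mm before scaling
    consensus: np.ndarray  # (p, 2) mean shape, unit centroid size
    specimen_ids: list[str]
    iterations_run: int
    sliding_log: list[tuple[float, float]] = field(default_factory=list)
    converged: bool = True
    roles: PointRoles | None = None

    @property
    def n_specimens(self) -> int:
        return len(self.coords)

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    def flat(self) -> np.ndarray:
        """(n, 2p) flattened coordinates for multivariate statistics."""
        return self.coords.reshape(self.n_specimens, -1)

    def distances_to_consensus(self) -> np.ndarray:
        return np.linalg.norm(self.flat() - self.consensus.ravel(), axis=1)


def gpa_align(
    configs: list[Configuration],
    scheme: LandmarkScheme,
    max_iter: int = 100,
    tol: float = 1e-6,
    slide: bool = True,
    max_slide_passes: int = 5,
) -> AlignedSample:
    """Generalized Procrustes alignment of stripped, side-normalized configs.

    Iterates {center, scale to unit centroid size, rotate to consensus,
    update consensus} until the mean consensus displacement falls below
    ``tol``, then (optionally) runs up to ``max_slide_passes`` passes of
    bending-energy sliding, re-aligning after each pass.  The result is
    independent of input ordering and of arbitrary similarity transforms of
    the inputs, up to ``tol``.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least two specimens")
    mats = [flatten(c, scheme) for c in configs]
    ids = [c.specimen_id for c in configs]
    sizes = np.array([centroid_size(m) for m in mats])
    coords = np.stack([_center_unit(m) for m in mats])
    roles = point_roles(scheme)

    consensus = coords[0].copy()
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        coords = _rotations_to_consensus(coords, consensus)
        new_consensus = _center_unit(coords.mean(axis=0))
        shift = np.linalg.norm(new_consensus - consensus) / np.sqrt(len(consensus))
        consensus = new_consensus
        if shift < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)

    sliding_log: list[tuple[float, float]] = []
    if slide:
        for _ in range(max_slide_passes):
            be = bending_energy_matrix(consensus)
            diffs = coords - consensus
            e_pre = float(np.einsum("nid,ij,njd->", diffs, be, diffs))
            coords = slide_semilandmarks(coords, consensus, roles, be_matrix=be)
            diffs = coords - consensus
            e_post = float(np.einsum("nid,ij,njd->", diffs, be, diffs))
            sliding_log.append((e_pre, e_post))
            # restore the Procrustes normalization disturbed by sliding
            coords = np.stack([_center_unit(m) for m in coords])
            coords = _rotations_to_consensus(coords, consensus)
            consensus = _center_unit(coords.mean(axis=0))
            if e_pre - e_post < tol * max(e_pre, 1.0):
                break

    coords, consensus = _canonical_orientation(coords, consensus)

    return AlignedSample(
        coords=coords,
        centroid_sizes=sizes,
        consensus=consensus,
        specimen_ids=ids,
        iterations_run=iterations,
        sliding_log=sliding_log,
        converged=converged,
        roles=roles,
    )
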
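"""The toe digitization template and configuration-level preprocessing.

The packaged template has 19 fixed landmarks and 13 curves: eight curves
outlining the toe and five tracing the free edge of each focal lamella.
Curves are digitized with 10 points whose first and last coincide with
their anchor landmarks; those duplicates are stripped before alignment,
leaving 8 semilandmarks per curve and 19 + 13 x 8 = 123 points in total.

Landmark indices are 1-based at every interface, matching the anatomical
numbering used in the field ("landmarks 5 and 6 at the widest points of
the toepad").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .tps_io import RawRecord

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """A raw record does not fit the digitization template."""


@dataclass(frozen=True)
class CurveDef:
    """A digitized curve: its two anchor landmarks and point budget."""

    start_anchor: int  # 1-based fixed landmark index
    end_anchor: int
    role: str  # "toe_outline" | "lamella_edge"
    n_semilandmarks_raw: int = 10

    @property
    def n_semilandmarks_kept(self) -> int:
        return self.n_semilandmarks_raw - 2


@dataclass(frozen=True)
class LandmarkScheme:
    """The fixed digitization template enforced on every specimen."""

    n_fixed: int
    curves: tuple[CurveDef, ...]
    lamella_pairs: tuple[tuple[int, int], ...]
    lamella_height_pairs: tuple[tuple[int, int], ...]
    pad_outline_landmarks: tuple[int, ...]

    def __post_init__(self) -> None:
        for c in self.curves:
            for anchor in (c.start_anchor, c.end_anchor):
                if not 1 <= anchor <= self.n_fixed:
                    raise ValueError(f"curve anchor {anchor} outside 1..{self.n_fixed}")

    @property
    def n_curves(self) -> int:
        return len(self.curves)

    @property
    def n_semilandmarks(self) -> int:
        return sum(c.n_semilandmarks_kept for c in self.curves)

    @property
    def n_points(self) -> int:
        """Total points entering alignment (fixed + kept semilandmarks)."""
        return self.n_fixed + self.n_semilandmarks


def load_scheme(path: str | Path) -> LandmarkScheme:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    n_raw = int(raw.get("n_semilandmarks_raw", 10))
    curves = tuple(
        CurveDef(
            start_anchor=int(c["start"]),
            end_anchor=int(c["end"]),
            role=str(c["role"]),
            n_semilandmarks_raw=n_raw,
        )
        for c in raw["curves"]
    )
    return LandmarkScheme(
        n_fixed=int(raw["n_fixed"]),
        curves=curves,
        lamella_pairs=tuple((int(a), int(b)) for a, b in raw["lamella_pairs"]),
        lamella_height_pairs=tuple(
            (int(a), int(b)) for a, b in raw["lamella_height_pairs"]
        ),
        pad_outline_landmarks=tuple(int(i) for i in raw["pad_outline_landmarks"]),
    )


def default_scheme() -> LandmarkScheme:
    """The packaged 19-landmark / 13-curve toe template."""
    ref = resources.files("toemorph").joinpath("data/default_scheme.yaml")
    with resources.as_file(ref) as path:
        return load_scheme(path)


@dataclass
class Configuration:
    """One specimen's ordered point set in millimetres."""

    specimen_id: str
    fixed_points: np.ndarray  # (n_fixed, 2)
    curve_points: list[np.ndarray]  # per curve, (10, 2) raw or (8, 2) stripped
    side: str = "left"
    mirrored: bool = False
    stripped: bool = False

    def __post_init__(self) -> None:
        self.fixed_points = np.asarray(self.fixed_points, dtype=float)
        self.curve_points = [np.asarray(c, dtype=float) for c in self.curve_points]
        if not np.isfinite(self.fixed_points).all() or any(
            not np.isfinite(c).all() for c in self.curve_points
        ):
            raise ValidationError(f"{self.specimen_id}: non-finite coordinates")

    def landmark(self, index: int) -> np.ndarray:
        """Fixed landmark by 1-based anatomical index."""
        return self.fixed_points[index - 1]

    def all_points(self) -> np.ndarray:
        return np.vstack([self.fixed_points, *self.curve_points])

    def copy(self) -> "Configuration":
        return replace(
            self,
            fixed_points=self.fixed_points.copy(),
            curve_points=[c.copy() for c in self.curve_points],
        )


def validate_configuration(raw: RawRecord, scheme: LandmarkScheme,
                           side: str = "left") -> Configuration:
    """Check a raw record against the template and type it as a Configuration.

    Validation is total: anything that does not carry exactly the template's
    landmark count, curve count and per-curve point counts raises a
    :class:`ValidationError` naming the specimen and the defect.
    """
    sid = raw.specimen_id
    if raw.n_landmarks != scheme.n_fixed:
        raise ValidationError(
            f"{sid}: expected {scheme.n_fixed} fixed landmarks, got {raw.n_landmarks}"
        )
    if len(raw.curves) != scheme.n_curves:
        raise ValidationError(
            f"{sid}: expected {scheme.n_curves} curves, got {len(raw.curves)}"
        )
    for ci, (curve, cdef) in enumerate(zip(raw.curves, scheme.curves), start=1):
        if len(curve) != cdef.n_semilandmarks_raw:
            raise ValidationError(
                f"{sid}: curve {ci} has {len(curve)} points, expected "
                f"{cdef.n_semilandmarks_raw}"
            )
    if side not in ("left", "right"):
        raise ValidationError(f"{sid}: side must be left or right, got {side!r}")
    return Configuration(
        specimen_id=sid,
        fixed_points=raw.landmarks.copy(),
        curve_points=[c.copy() for c in raw.curves],
        side=side,
    )


def strip_anchor_semilandmarks(
    config: Configuration,
    scheme: LandmarkScheme,
    tol_mm: float = 1e-6,
) -> Configuration:
    """Drop each curve's first and last point, which duplicate its anchors.

    If an endpoint sits farther than ``tol_mm`` from its anchor landmark a
    warning with the distance is logged, but the point is still stripped:
    hand-digitized curves rarely snap exactly, and for real data a looser
    tolerance (0.02 mm is a practical default) is appropriate.
    """
    if config.stripped:
        raise ValidationError(f"{config.specimen_id}: already stripped")
    new_curves = []
    for ci, (curve, cdef) in enumerate(zip(config.curve_points, scheme.curves), start=1):
        for pt, anchor_idx, which in (
            (curve[0], cdef.start_anchor, "first"),
            (curve[-1], cdef.end_anchor, "last"),
        ):
            dist = float(np.linalg.norm(pt - config.landmark(anchor_idx)))
            if dist > tol_mm:
                logger.warning(
                    "%s: curve %d %s point is %.4g mm from anchor landmark %d "
                    "(tolerance %.4g)",
                    config.specimen_id, ci, which, dist, anchor_idx, tol_mm,
                )
        new_curves.append(curve[1:-1].copy())
    out = config.copy()
    out.curve_points = new_curves
    out.stripped = True
    return out


def mirror_configuration(config: Configuration) -> Configuration:
    """Reflect a right-side configuration so all toes are comparable.

    x-coordinates are reflected about the vertical axis through the
    configuration centroid.  Landmark numbering is untouched: landmarks are
    defined anatomically, so indices keep their meaning after reflection.
    Left-side configurations are returned unchanged.  Mirroring twice is an
    error (the ``mirrored`` flag guards against it).
    """
    if config.side == "left":
        logger.debug("%s: left side, no mirroring applied", config.specimen_id)
        return config.copy()
    if config.mirrored:
        raise ValidationError(f"{config.specimen_id}: already mirrored")
    cx = config.all_points()[:, 0].mean()
    out = config.copy()
    out.fixed_points[:, 0] = 2 * cx - out.fixed_points[:, 0]
    for curve in out.curve_points:
        curve[:, 0] = 2 * cx - curve[:, 0]
    out.mirrored = True
    return out


@dataclass(frozen=True)
class PointRoles:
    """Role bookkeeping for the flattened point matrix (0-based indices)."""

    is_semilandmark: np.ndarray  # (n_points,) bool
    curve_of: np.ndarray  # (n_points,) int, -1 for fixed landmarks
    neighbors: np.ndarray  # (n_points, 2) int, -1 for fixed landmarks

    @property
    def semilandmark_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_semilandmark)


def point_roles(scheme: LandmarkScheme) -> PointRoles:
    """Sliding bookkeeping for the canonical flattened ordering.

    Each semilandmark's neighbors are the preceding and following point on
    its own curve, with the anchor landmarks serving as neighbors at curve
    ends.
    """
    n = scheme.n_points
    is_semi = np.zeros(n, dtype=bool)
    curve_of = np.full(n, -1, dtype=int)
    neighbors = np.full((n, 2), -1, dtype=int)
    pos = scheme.n_fixed
    for ci, cdef in enumerate(scheme.curves):
        k = cdef.n_semilandmarks_kept
        idx = np.arange(pos, pos + k)
        is_semi[idx] = True
        curve_of[idx] = ci
        chain = np.concatenate(([cdef.start_anchor - 1], idx, [cdef.end_anchor - 1]))
        for j, p in enumerate(idx, start=1):
            neighbors[p] = (chain[j - 1], chain[j + 1])
        pos += k
    return PointRoles(is_semilandmark=is_semi, curve_of=curve_of, neighbors=neighbors)


def flatten(config: Configuration, scheme: LandmarkScheme) -> np.ndarray:
    """Canonical (n_points, 2) matrix: fixed landmarks then curves in order."""
    if not config.stripped:
        raise ValidationError(
            f"{config.specimen_id}: flatten requires a stripped configuration"
        )
    mat = np.vstack([config.fixed_points, *config.curve_points])
    if mat.shape != (scheme.n_points, 2):
        raise ValidationError(
            f"{config.specimen_id}: flattened to {mat.shape}, expected "
            f"({scheme.n_points}, 2)"
        )
    return mat


def unflatten(points: np.ndarray, scheme: LandmarkScheme,
              specimen_id: str = "shape") -> Configuration:
    """Inverse of :func:`flatten` for projected/consensus shapes."""
    points = np.asarray(points, dtype=float).reshape(scheme.n_points, 2)
    fixed = points[: scheme.n_fixed]
    curves = []
    pos = scheme.n_fixed
    for cdef in scheme.curves:
        k = cdef.n_semilandmarks_kept
        curves.append(points[pos : pos + k])
        pos += k
    return Configuration(
        specimen_id=specimen_id,
        fixed_points=fixed,
        curve_points=curves,
        stripped=True,
    )
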
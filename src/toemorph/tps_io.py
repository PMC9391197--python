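"""Reading and writing landmark data in the tpsDig file dialect.

A TPS file is a sequence of specimen blocks.  Each block starts with an
``LM=<n>`` line followed by ``n`` whitespace-separated ``x y`` coordinate
lines, optionally followed by ``CURVES=<c>`` and, for each curve,
``POINTS=<k>`` with ``k`` coordinate lines.  Trailing key lines
(``IMAGE=``, ``ID=``, ``SCALE=``) attach per-specimen metadata.  Keys are
recognized case-insensitively; both LF and CRLF line endings are accepted.

``SCALE=`` is interpreted as **millimetres per pixel**: physical
coordinates are obtained by multiplying pixel coordinates by the scale.
TPS dialects vary on this point, so the convention is stated here once and
used everywhere downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HABITATS = ("urban", "forest")
MUNICIPALITIES = ("San Juan", "Arecibo", "Aguadilla", "Mayagüez", "Ponce")
SIDES = ("left", "right")

#: Scanner resolution -> physical scale: 25.4 mm per inch.
MM_PER_INCH = 25.4


class TpsParseError(ValueError):
    """Raised when a TPS file violates the dialect grammar."""


@dataclass
class RawRecord:
    """One specimen block of a TPS file, in the units it was digitized in."""

    specimen_id: str
    landmarks: np.ndarray  # (n_landmarks, 2)
    curves: list[np.ndarray] = field(default_factory=list)  # each (k_i, 2)
    scale_mm_per_px: float | None = None
    image_name: str | None = None

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float).reshape(-1, 2)
        self.curves = [np.asarray(c, dtype=float).reshape(-1, 2) for c in self.curves]
        if self.scale_mm_per_px is not None and not self.scale_mm_per_px > 0:
            raise ValueError(
                f"record {self.specimen_id!r}: scale must be positive, "
                f"got {self.scale_mm_per_px}"
            )

    @property
    def n_landmarks(self) -> int:
        return len(self.landmarks)


@dataclass
class Dataset:
    """Specimen records joined with their metadata, in millimetres."""

    records: list[RawRecord]
    metadata: pd.DataFrame  # indexed by specimen_id, aligned with records
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def __len__(self) -> int:
        return len(self.records)

    def record(self, specimen_id: str) -> RawRecord:
        for rec in self.records:
            if rec.specimen_id == specimen_id:
                return rec
        raise KeyError(specimen_id)


def scale_from_dpi(dpi: float) -> float:
    """Millimetres per pixel for a scan of known resolution (dots/inch)."""
    if not dpi > 0:
        raise ValueError(f"dpi must be positive, got {dpi}")
    return MM_PER_INCH / dpi


def _parse_xy(line: str, lineno: int, path: str) -> tuple[float, float]:
    parts = line.split()
    if len(parts) != 2:
        raise TpsParseError(f"{path}:{lineno}: expected 'x y' coordinates, got {line!r}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise TpsParseError(f"{path}:{lineno}: non-numeric coordinate {line!r}") from exc


def read_tps(path: str | Path) -> list[RawRecord]:
    """Parse a TPS file into one :class:`RawRecord` per specimen block.

    Point order is preserved exactly as stored.  Declared counts (``LM=``,
    ``POINTS=``) are enforced: a mismatch raises :class:`TpsParseError`
    naming the offending record.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    records: list[RawRecord] = []

    i = 0
    n_lines = len(lines)

    def keyval(line: str) -> tuple[str, str] | None:
        if "=" not in line:
            return None
        key, _, val = line.partition("=")
        return key.strip().upper(), val.strip()

    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        kv = keyval(line)
        if kv is None or kv[0] != "LM":
            raise TpsParseError(f"{path}:{i + 1}: expected LM= header, got {line!r}")
        try:
            n_lm = int(kv[1])
        except ValueError as exc:
            raise TpsParseError(f"{path}:{i + 1}: bad LM= count {kv[1]!r}") from exc
        i += 1

        block_label = f"record #{len(records) + 1}"
        landmarks = []
        for _ in range(n_lm):
            if i >= n_lines:
                raise TpsParseError(
                    f"{path}: {block_label}: declared LM={n_lm} but file ended "
                    f"after {len(landmarks)} points"
                )
            try:
                landmarks.append(_parse_xy(lines[i].strip(), i + 1, str(path)))
            except TpsParseError as exc:
                raise TpsParseError(
                    f"{path}: {block_label}: declared LM={n_lm} but only "
                    f"{len(landmarks)} coordinate lines present ({exc})"
                ) from None
            i += 1

        curves: list[np.ndarray] = []
        scale = None
        image = None
        spec_id = None
        while i < n_lines:
            line = lines[i].strip()
            if not line:
                i += 1
                continue
            kv = keyval(line)
            if kv is None:
                raise TpsParseError(
                    f"{path}:{i + 1}: {block_label}: unexpected line {line!r} "
                    f"(declared LM={n_lm} points already read)"
                )
            key, val = kv
            if key == "LM":
                break  # next specimen block
            if key == "CURVES":
                n_curves = int(val)
                i += 1
                for ci in range(n_curves):
                    while i < n_lines and not lines[i].strip():
                        i += 1
                    kv2 = keyval(lines[i].strip()) if i < n_lines else None
                    if kv2 is None or kv2[0] != "POINTS":
                        raise TpsParseError(
                            f"{path}:{i + 1}: {block_label}: curve {ci + 1} missing "
                            f"POINTS= header"
                        )
                    n_pts = int(kv2[1])
                    i += 1
                    pts = []
                    for _ in range(n_pts):
                        if i >= n_lines:
                            raise TpsParseError(
                                f"{path}: {block_label}: curve {ci + 1} declared "
                                f"POINTS={n_pts} but file ended"
                            )
                        try:
                            pts.append(_parse_xy(lines[i].strip(), i + 1, str(path)))
                        except TpsParseError as exc:
                            raise TpsParseError(
                                f"{path}: {block_label}: curve {ci + 1} declared "
                                f"POINTS={n_pts} but only {len(pts)} points "
                                f"present ({exc})"
                            ) from None
                        i += 1
                    curves.append(np.asarray(pts))
                continue
            if key == "IMAGE":
                image = val
            elif key == "ID":
                spec_id = val
            elif key == "SCALE":
                scale = float(val)
            else:
                logger.debug("%s:%d: ignoring unknown key %s=", path, i + 1, key)
            i += 1

        if spec_id is None:
            spec_id = f"record_{len(records) + 1}"
        records.append(
            RawRecord(
                specimen_id=spec_id,
                landmarks=np.asarray(landmarks),
                curves=curves,
                scale_mm_per_px=scale,
                image_name=image,
            )
        )
    return records


def write_tps(records: Sequence[RawRecord], path: str | Path) -> None:
    """Write records as a TPS file; ``read_tps`` round-trips it exactly.

    Coordinates are written with :func:`repr` so re-parsing reproduces them
    to full floating-point precision.  Records without a scale produce no
    ``SCALE=`` line.
    """
    if len(records) == 0:
        raise ValueError("cannot write an empty record list")
    out = []
    for rec in records:
        if rec.n_landmarks < 1:
            raise ValueError(f"record {rec.specimen_id!r} has no landmarks")
        out.append(f"LM={rec.n_landmarks}")
        for x, y in rec.landmarks:
            out.append(f"{float(x)!r} {float(y)!r}")
        if rec.curves:
            out.append(f"CURVES={len(rec.curves)}")
            for curve in rec.curves:
                out.append(f"POINTS={len(curve)}")
                for x, y in curve:
                    out.append(f"{float(x)!r} {float(y)!r}")
        if rec.image_name is not None:
            out.append(f"IMAGE={rec.image_name}")
        out.append(f"ID={rec.specimen_id}")
        if rec.scale_mm_per_px is not None:
            out.append(f"SCALE={float(rec.scale_mm_per_px)!r}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the specimen metadata CSV and validate its closed vocabularies."""
    meta = pd.read_csv(path)
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"specimen_id", "habitat", "municipality"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    if meta["specimen_id"].duplicated().any():
        dupes = meta.loc[meta["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicate specimen_id in metadata: {dupes}")
    bad_hab = set(meta["habitat"]) - set(HABITATS)
    if bad_hab:
        raise ValueError(f"habitat values outside {HABITATS}: {sorted(bad_hab)}")
    bad_mun = set(meta["municipality"]) - set(MUNICIPALITIES)
    if bad_mun:
        raise ValueError(f"municipality values outside {MUNICIPALITIES}: {sorted(bad_mun)}")
    return meta.set_index("specimen_id", drop=False)


def assemble_dataset(
    records: Sequence[RawRecord],
    metadata: pd.DataFrame,
    default_dpi: float | None = None,
) -> Dataset:
    """Join records with metadata and convert coordinates to millimetres.

    Records without a ``SCALE=`` field use ``default_dpi`` when given;
    records with neither are dropped (linear measurements require physical
    units), as are records whose id is absent from the metadata.  Every
    drop is logged and recorded in ``Dataset.dropped``.
    """
    if "specimen_id" not in metadata.columns:
        raise ValueError("metadata must carry a specimen_id column")
    meta = validate_metadata(metadata.reset_index(drop=True))

    seen: set[str] = set()
    kept: list[RawRecord] = []
    dropped: list[tuple[str, str]] = []
    for rec in records:
        if rec.specimen_id in seen:
            raise ValueError(f"duplicate specimen_id among records: {rec.specimen_id!r}")
        seen.add(rec.specimen_id)
        if rec.specimen_id not in meta.index:
            dropped.append((rec.specimen_id, "no metadata row"))
            logger.warning("dropping %s: no metadata row", rec.specimen_id)
            continue
        scale = rec.scale_mm_per_px
        if scale is None:
            if default_dpi is None:
                dropped.append((rec.specimen_id, "no scale and no dpi"))
                logger.warning("dropping %s: no scale and no dpi", rec.specimen_id)
                continue
            scale = scale_from_dpi(default_dpi)
        kept.append(
            RawRecord(
                specimen_id=rec.specimen_id,
                landmarks=rec.landmarks * scale,
                curves=[c * scale for c in rec.curves],
                scale_mm_per_px=1.0,  # coordinates now in mm
                image_name=rec.image_name,
            )
        )
    meta_kept = meta.loc[[r.specimen_id for r in kept]]
    return Dataset(records=kept, metadata=meta_kept, dropped=dropped)


def export_points_csv(dataset: Dataset, path: str | Path) -> None:
    """Long-format export: one row per specimen point (mm coordinates)."""
    rows = []
    for rec in dataset.records:
        for j, (x, y) in enumerate(rec.landmarks, start=1):
            rows.append((rec.specimen_id, j, "fixed", x, y))
        for ci, curve in enumerate(rec.curves, start=1):
            for j, (x, y) in enumerate(curve, start=1):
                rows.append((rec.specimen_id, j, f"curve_{ci}", x, y))
    pd.DataFrame(
        rows, columns=["specimen_id", "point_index", "point_role", "x_mm", "y_mm"]
    ).to_csv(path, index=False)
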
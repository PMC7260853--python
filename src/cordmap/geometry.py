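"""Hemi-section coordinate frames, normalization, and pooling.

A hemi-section is one lateral half of a transverse spinal-cord section.
Its coordinate frame has the origin at the ventral-most point, the +x
axis pointing laterally (mediolateral, ML) and the +y axis pointing
dorsally (dorsoventral, DV).  Raw cell positions are recorded either as
polar coordinates (distance from the origin in µm, angle in degrees
counterclockwise from +x, so 90° is straight dorsal) or as Cartesian
µm.  Normalization divides x by the section's maximal width and y by
its maximal height, making sections of different sizes comparable.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SectionGeometry",
    "CellRecord",
    "NormalizedCell",
    "PooledSample",
    "OutOfFrameWarning",
    "polar_to_cartesian",
    "cartesian_to_polar",
    "normalize_cell",
    "normalize_table",
    "pool_sections",
    "read_cells_csv",
    "write_cells_csv",
    "write_normalized_csv",
    "IDENTITY_COLUMNS",
    "DEFAULT_FRAME_TOL",
]

IDENTITY_COLUMNS = ["animal_id", "genotype", "section_id", "marker"]
POLAR_COLUMNS = ["distance_um", "angle_deg"]
CARTESIAN_COLUMNS = ["x_um", "y_um"]
GEOMETRY_COLUMNS = ["section_width_um", "section_height_um"]

#: Cells may land slightly outside the measured frame because maximal
#: width/height are measured on the same section; this is the default
#: fractional tolerance before a cell is flagged.
DEFAULT_FRAME_TOL = 0.05


class OutOfFrameWarning(UserWarning):
    """A normalized cell lies outside the measured frame beyond tolerance."""


@dataclass(frozen=True)
class SectionGeometry:
    """Measured frame of one hemi-section.

    ``width_um`` runs from the center of the central canal to the most
    lateral edge; ``height_um`` from the ventral lower border beneath
    the central canal to the dorsal-most border.  The origin is (0, 0)
    by construction (the ventral-most point); no offset is stored.
    """

    section_id: str
    animal_id: str
    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        if not (self.width_um > 0 and self.height_um > 0):
            raise ValueError(
                f"section {self.section_id!r}: width_um and height_um must be "
                f"positive (got {self.width_um}, {self.height_um})"
            )


@dataclass(frozen=True)
class CellRecord:
    """One counted cell: identity plus a position in the section frame.

    Exactly one position representation (polar or Cartesian) must be
    supplied; the other is derivable via :func:`polar_to_cartesian` /
    :func:`cartesian_to_polar`.
    """

    animal_id: str
    genotype: str
    section_id: str
    marker: str
    x_um: float | None = None
    y_um: float | None = None
    distance_um: float | None = None
    angle_deg: float | None = None

    def __post_init__(self) -> None:
        has_cart = self.x_um is not None and self.y_um is not None
        has_polar = self.distance_um is not None and self.angle_deg is not None
        if has_cart == has_polar:
            raise ValueError(
                "exactly one position representation (x_um/y_um or "
                "distance_um/angle_deg) must be given"
            )
        if has_polar:
            if self.distance_um < 0:
                raise ValueError(f"distance_um must be >= 0, got {self.distance_um}")
            if not (0.0 <= self.angle_deg <= 180.0):
                raise ValueError(
                    f"angle_deg must lie in [0, 180] for a hemi-section, "
                    f"got {self.angle_deg}"
                )

    def cartesian(self) -> tuple[float, float]:
        """Position as Cartesian µm, converting from polar if needed."""
        if self.x_um is not None:
            return float(self.x_um), float(self.y_um)
        x, y = polar_to_cartesian(self.distance_um, self.angle_deg)
        return float(x), float(y)


@dataclass(frozen=True)
class NormalizedCell:
    """A cell position divided by its section's width and height."""

    animal_id: str
    genotype: str
    section_id: str
    marker: str
    x_norm: float
    y_norm: float
    out_of_frame: bool = False


@dataclass
class PooledSample:
    """Normalized positions of one marker × genotype, superimposed
    across all contributing sections and animals.

    ``provenance`` maps ``(animal_id, section_id)`` to the number of
    points that section contributed; its values sum to ``n``.
    """

    marker: str
    genotype: str
    points: np.ndarray
    provenance: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must have shape (n, 2), got {pts.shape}")
        self.points = pts
        if self.provenance and sum(self.provenance.values()) != len(pts):
            raise ValueError("provenance counts do not sum to the number of points")

    @property
    def n(self) -> int:
        return len(self.points)


def polar_to_cartesian(distance_um, angle_deg):
    """Convert polar (distance, angle) to Cartesian (x, y).

    Angles are degrees counterclockwise from the mediolateral +x axis;
    90° points straight dorsal.  Accepts scalars or arrays.
    """
    d = np.asarray(distance_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance_um must be >= 0")
    a = np.deg2rad(np.asarray(angle_deg, dtype=float))
    return d * np.cos(a), d * np.sin(a)


def cartesian_to_polar(x_um, y_um):
    """Inverse of :func:`polar_to_cartesian`; angle returned in degrees."""
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    return np.hypot(x, y), np.rad2deg(np.arctan2(y, x))


def _check_frame(x_norm, y_norm, tol: float):
    x = np.asarray(x_norm, dtype=float)
    y = np.asarray(y_norm, dtype=float)
    return (x < -tol) | (x > 1.0 + tol) | (y < -tol) | (y > 1.0 + tol)


def normalize_cell(
    cell: CellRecord,
    geom: SectionGeometry,
    tol: float = DEFAULT_FRAME_TOL,
    on_outside: str = "warn",
) -> NormalizedCell | None:
    """Map a cell into dimensionless section coordinates.

    Parameters
    ----------
    cell, geom
        The cell and the measured frame of *its* section; their
        ``section_id`` must match.
    tol
        Fractional tolerance beyond the unit frame before flagging.
    on_outside
        ``"warn"`` keeps flagged cells and emits :class:`OutOfFrameWarning`;
        ``"drop"`` returns ``None`` for them; ``"keep"`` keeps silently.
    """
    if cell.section_id != geom.section_id:
        raise ValueError(
            f"cell section {cell.section_id!r} does not match geometry "
            f"section {geom.section_id!r}"
        )
    if on_outside not in ("warn", "drop", "keep"):
        raise ValueError(f"on_outside must be warn|drop|keep, got {on_outside!r}")
    x_um, y_um = cell.cartesian()
    x_norm = x_um / geom.width_um
    y_norm = y_um / geom.height_um
    outside = bool(_check_frame(x_norm, y_norm, tol))
    if outside:
        if on_outside == "drop":
            return None
        if on_outside == "warn":
            warnings.warn(
                f"cell in section {cell.section_id!r} normalizes to "
                f"({x_norm:.3f}, {y_norm:.3f}), outside [0, 1] beyond tol={tol}",
                OutOfFrameWarning,
                stacklevel=2,
            )
    return NormalizedCell(
        animal_id=cell.animal_id,
        genotype=cell.genotype,
        section_id=cell.section_id,
        marker=cell.marker,
        x_norm=x_norm,
        y_norm=y_norm,
        out_of_frame=outside,
    )


def normalize_table(
    cells: pd.DataFrame,
    tol: float = DEFAULT_FRAME_TOL,
    on_outside: str = "warn",
) -> pd.DataFrame:
    """Vectorized normalization of a per-cell table.

    The table must carry the identity columns, one position pair
    (``x_um``/``y_um`` or ``distance_um``/``angle_deg``) and the
    per-section ``section_width_um``/``section_height_um`` columns.
    Returns a copy with ``x_norm``, ``y_norm`` and ``out_of_frame``
    columns added (flagged rows dropped if ``on_outside="drop"``).
    """
    df = cells.copy()
    missing = [c for c in IDENTITY_COLUMNS + GEOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if (df["section_width_um"] <= 0).any() or (df["section_height_um"] <= 0).any():
        raise ValueError("section_width_um and section_height_um must be positive")
    if all(c in df.columns for c in CARTESIAN_COLUMNS):
        x_um = df["x_um"].to_numpy(float)
        y_um = df["y_um"].to_numpy(float)
    elif all(c in df.columns for c in POLAR_COLUMNS):
        x_um, y_um = polar_to_cartesian(
            df["distance_um"].to_numpy(float), df["angle_deg"].to_numpy(float)
        )
        df["x_um"] = x_um
        df["y_um"] = y_um
    else:
        raise ValueError(
            "need either x_um/y_um or distance_um/angle_deg position columns"
        )
    df["x_norm"] = x_um / df["section_width_um"].to_numpy(float)
    df["y_norm"] = y_um / df["section_height_um"].to_numpy(float)
    outside = _check_frame(df["x_norm"], df["y_norm"], tol)
    df["out_of_frame"] = outside
    n_out = int(outside.sum())
    if n_out:
        if on_outside == "drop":
            df = df.loc[~outside].reset_index(drop=True)
        elif on_outside == "warn":
            warnings.warn(
                f"{n_out} cell(s) normalize outside [0, 1] beyond tol={tol}; kept",
                OutOfFrameWarning,
                stacklevel=2,
            )
        elif on_outside != "keep":
            raise ValueError(f"on_outside must be warn|drop|keep, got {on_outside!r}")
    return df


def pool_sections(
    cells: pd.DataFrame | Iterable[NormalizedCell],
    marker: str,
    genotype: str,
) -> PooledSample:
    """Superimpose all normalized cells of one marker × genotype.

    Accepts either a normalized table (from :func:`normalize_table`) or
    an iterable of :class:`NormalizedCell`.  Content is independent of
    input order; an empty selection yields a valid empty sample.
    """
    if isinstance(cells, pd.DataFrame):
        sel = cells[(cells["marker"] == marker) & (cells["genotype"] == genotype)]
        points = sel[["x_norm", "y_norm"]].to_numpy(float)
        prov = Counter(
            zip(sel["animal_id"].astype(str), sel["section_id"].astype(str))
        )
    else:
        rows = [c for c in cells if c.marker == marker and c.genotype == genotype]
        points = np.array([[c.x_norm, c.y_norm] for c in rows], dtype=float)
        prov = Counter((c.animal_id, c.section_id) for c in rows)
    return PooledSample(
        marker=marker,
        genotype=genotype,
        points=points.reshape(-1, 2),
        provenance=dict(prov),
    )


def read_cells_csv(path, mirror_right: bool = False) -> pd.DataFrame:
    """Read the per-cell CSV dialect (UTF-8, comma-separated, header).

    If ``mirror_right`` is set and a ``side`` column is present, x
    coordinates of right-side sections are negated so that lateral is
    always +x.
    """
    df = pd.read_csv(path)
    missing = [c for c in IDENTITY_COLUMNS + GEOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    has_cart = all(c in df.columns for c in CARTESIAN_COLUMNS)
    has_polar = all(c in df.columns for c in POLAR_COLUMNS)
    if not (has_cart or has_polar):
        raise ValueError(
            f"{path}: need x_um/y_um or distance_um/angle_deg position columns"
        )
    if mirror_right and "side" in df.columns:
        right = df["side"].astype(str).str.lower().isin(("r", "right"))
        if has_cart:
            df.loc[right, "x_um"] = -df.loc[right, "x_um"]
        else:
            df.loc[right, "angle_deg"] = 180.0 - df.loc[right, "angle_deg"]
    return df


def write_cells_csv(cells: pd.DataFrame, path) -> None:
    """Write a per-cell table in the ingest dialect."""
    cols = [c for c in IDENTITY_COLUMNS if c in cells.columns]
    cols += [
        c
        for c in CARTESIAN_COLUMNS + POLAR_COLUMNS + GEOMETRY_COLUMNS
        if c in cells.columns
    ]
    cells.to_csv(path, columns=cols, index=False)


def write_normalized_csv(cells: pd.DataFrame, path) -> None:
    """Export identity columns plus normalized coordinates."""
    cols = IDENTITY_COLUMNS + ["x_norm", "y_norm"]
    missing = [c for c in cols if c not in cells.columns]
    if missing:
        raise ValueError(f"missing columns for export: {missing}")
    cells.to_csv(path, columns=cols, index=False)
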
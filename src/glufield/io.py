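"""Localization-table and ROI input/output for dSTORM point clouds.

Localization tables are plain :class:`pandas.DataFrame` objects with the
columns ``x_nm``, ``y_nm``, ``frame`` and ``adcount`` — the same container a
practitioner would get from loading a rapidSTORM export. Coordinates are
continuous nanometres with the origin at the top-left corner of the
reconstructed image and y increasing downward (image convention). ROIs are
simple closed polygons in the same coordinate system.

Two table dialects are supported:

``csv``
    comma-separated with the header ``x_nm,y_nm,frame,adcount``.
``rapidstorm``
    whitespace-separated values preceded by a ``#``-prefixed header line
    naming the columns. Both the native rapidSTORM field identifiers
    (``Position-0-0`` etc.) and plain names are recognized; a ``column_map``
    can override the guesswork for exotic headers.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .exceptions import EmptyInputError, FormatError, InvalidRoiError, ParameterError

__all__ = [
    "LOC_COLUMNS",
    "DEFAULT_N_FRAMES",
    "AD_COUNT_THRESHOLD",
    "RoiPolygon",
    "BinnedImage",
    "read_localizations",
    "write_localizations",
    "validate_localizations",
    "filter_by_adcount",
    "clip_to_roi",
    "render_binned",
    "px_to_nm",
    "nm_to_px",
    "read_rois",
    "write_rois",
]

#: canonical column order of an in-memory localization table
LOC_COLUMNS = ("x_nm", "y_nm", "frame", "adcount")

#: frames acquired in one recording (10 ms exposure)
DEFAULT_N_FRAMES = 15_000

#: spots at or below this camera A/D count are discarded before analysis
AD_COUNT_THRESHOLD = 12_000.0

# rapidSTORM field identifiers -> canonical names
_RAPIDSTORM_FIELDS: Mapping[str, str] = {
    "Position-0-0": "x_nm",
    "Position-1-0": "y_nm",
    "ImageNumber-0-0": "frame",
    "Amplitude-0-0": "adcount",
    "x": "x_nm",
    "y": "y_nm",
    "x_nm": "x_nm",
    "y_nm": "y_nm",
    "frame": "frame",
    "adcount": "adcount",
    "amplitude": "adcount",
}


@dataclass(frozen=True)
class RoiPolygon:
    """Closed polygon delimiting one bouton/NMJ region, vertices in nm.

    Parameters
    ----------
    vertices
        ``(n, 2)`` array of (x, y) corners in nm; implicitly closed.
    label
        Free-text identifier, e.g. a bouton index.
    source_px
        Pixel size (nm/px) of the annotation image the polygon was drawn on;
        reconstructed binned images use 10 nm/px.
    """

    vertices: np.ndarray
    label: str = ""
    source_px: float = 10.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidRoiError("ROI needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise InvalidRoiError("ROI vertices must be finite")
        object.__setattr__(self, "vertices", v)
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0.0:
            raise InvalidRoiError(
                f"ROI {self.label!r} is degenerate or self-intersecting"
            )

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_nm2(self) -> float:
        return float(self.polygon.area)

    @classmethod
    def from_pixels(
        cls, vertices_px: np.ndarray, label: str = "", source_px: float = 10.0
    ) -> "RoiPolygon":
        """Build from vertices annotated on a binned image (pixel units)."""
        return cls(px_to_nm(np.asarray(vertices_px, float), source_px), label, source_px)


@dataclass(frozen=True)
class BinnedImage:
    """Reconstructed 2D histogram of localization counts.

    ``counts[i, j]`` is the number of localizations whose (x, y) falls in
    the half-open bin ``[origin + (j, i)*px, origin + (j+1, i+1)*px)``.
    """

    counts: np.ndarray
    px: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)


def validate_localizations(table: pd.DataFrame, n_frames: int | None = None) -> pd.DataFrame:
    """Check a localization table's invariants; return it unchanged.

    Raises :class:`FormatError` on missing columns or non-finite rows and on
    frame indices outside ``[0, n_frames)`` when ``n_frames`` is given.
    """
    for col in LOC_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"localization table lacks mandatory column {col!r}")
    values = table[list(LOC_COLUMNS)].to_numpy(float)
    if values.size and not np.all(np.isfinite(values)):
        raise FormatError("localization table contains NaN/inf entries")
    if n_frames is not None and len(table):
        fr = table["frame"].to_numpy()
        if fr.min() < 0 or fr.max() >= n_frames:
            raise FormatError(f"frame indices outside [0, {n_frames})")
    return table


def _canonical_columns(names: Sequence[str], column_map: Mapping[str, str] | None) -> list[str]:
    mapping = dict(_RAPIDSTORM_FIELDS)
    if column_map:
        mapping.update(column_map)
    out = []
    for name in names:
        key = name.strip()
        out.append(mapping.get(key, mapping.get(key.lower(), key)))
    return out


def read_localizations(
    path: str | Path,
    dialect: str = "csv",
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a localization table in nm coordinates.

    Malformed rows (wrong field count, non-numeric cells) are dropped; the
    number rejected is stored in ``table.attrs["n_rejected"]``. Row order of
    valid rows is preserved.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyInputError(f"{path} is empty")

    if dialect == "csv":
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
        names = _canonical_columns(list(df.columns), column_map)
        df.columns = names
    elif dialect == "rapidstorm":
        lines = text.splitlines()
        header: list[str] | None = None
        body: list[str] = []
        for ln in lines:
            if ln.startswith("#"):
                if header is None:
                    header = ln.lstrip("#").split()
            elif ln.strip():
                body.append(ln)
        if header is None:
            raise FormatError(f"{path}: rapidSTORM dialect needs a '#' header line")
        names = _canonical_columns(header, column_map)
        df = pd.read_csv(
            _stdio.StringIO("\n".join(body)),
            sep=r"\s+",
            names=names,
            dtype=str,
            engine="python",
        )
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")

    for col in LOC_COLUMNS:
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing mandatory column {col!r} (have {list(df.columns)})"
            )

    numeric = df[list(LOC_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    good = numeric.notna().all(axis=1)
    out = numeric.loc[good].reset_index(drop=True)
    out["frame"] = out["frame"].astype(np.int64)
    out.attrs["n_rejected"] = int((~good).sum())
    return validate_localizations(out)


def write_localizations(table: pd.DataFrame, path: str | Path, dialect: str = "csv") -> None:
    """Write a localization table; inverse of :func:`read_localizations`."""
    validate_localizations(table)
    path = Path(path)
    cols = list(LOC_COLUMNS)
    if dialect == "csv":
        table[cols].to_csv(path, index=False)
    elif dialect == "rapidstorm":
        with path.open("w") as fh:
            fh.write("# x_nm y_nm frame adcount\n")
            table[cols].to_csv(fh, sep=" ", index=False, header=False)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")


def filter_by_adcount(table: pd.DataFrame, threshold: float = AD_COUNT_THRESHOLD) -> pd.DataFrame:
    """Keep only spots with A/D count strictly above ``threshold``.

    Dim spots are fit artefacts and multi-emitter overlaps; the default
    threshold of 12,000 counts is applied before any spatial analysis.
    """
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    validate_localizations(table)
    out = table[table["adcount"] > threshold].reset_index(drop=True)
    out.attrs["n_rejected"] = int(len(table) - len(out))
    return out


def clip_to_roi(table: pd.DataFrame, roi: RoiPolygon) -> pd.DataFrame:
    """Keep localizations inside the ROI polygon (boundary inclusive)."""
    validate_localizations(table)
    pts = shapely.points(table["x_nm"].to_numpy(), table["y_nm"].to_numpy())
    inside = shapely.intersects(roi.polygon, pts)
    out = table[inside].reset_index(drop=True)
    out.attrs["roi_label"] = roi.label
    return out


def render_binned(
    table: pd.DataFrame,
    px: float = 10.0,
    origin: tuple[float, float] | None = None,
) -> BinnedImage:
    """Reconstruct a binned image (2D count histogram) from localizations.

    Bins are half-open ``[k*px, (k+1)*px)`` so every localization lands in
    exactly one bin and the grid sum equals the table length.
    """
    if px <= 0:
        raise ParameterError("pixel size must be positive")
    validate_localizations(table)
    if not len(table):
        raise EmptyInputError("cannot render an empty localization table")
    x = table["x_nm"].to_numpy(float)
    y = table["y_nm"].to_numpy(float)
    if origin is None:
        origin = (float(np.floor(x.min() / px) * px), float(np.floor(y.min() / px) * px))
    j = np.floor((x - origin[0]) / px).astype(np.int64)
    i = np.floor((y - origin[1]) / px).astype(np.int64)
    if j.min() < 0 or i.min() < 0:
        raise ParameterError("origin lies inside the point cloud")
    counts = np.zeros((int(i.max()) + 1, int(j.max()) + 1), dtype=np.int64)
    np.add.at(counts, (i, j), 1)
    return BinnedImage(counts=counts, px=float(px), origin=origin)


def px_to_nm(coords: np.ndarray, px: float) -> np.ndarray:
    """Convert pixel coordinates to nm (multiply by the pixel size)."""
    if px <= 0:
        raise ParameterError("pixel size must be positive")
    return np.asarray(coords, dtype=float) * float(px)


def nm_to_px(coords: np.ndarray, px: float) -> np.ndarray:
    """Convert nm coordinates to pixel units (inverse of :func:`px_to_nm`)."""
    if px <= 0:
        raise ParameterError("pixel size must be positive")
    return np.asarray(coords, dtype=float) / float(px)


def read_rois(path: str | Path, source_px: float = 10.0) -> list[RoiPolygon]:
    """Read ROI polygons from a vertex-list CSV.

    Expected columns: ``label, vertex_index, x, y, units`` where ``units``
    is ``nm`` or ``px``; pixel vertices are converted with ``source_px``.
    """
    df = pd.read_csv(path)
    for col in ("label", "vertex_index", "x", "y", "units"):
        if col not in df.columns:
            raise FormatError(f"ROI file lacks column {col!r}")
    rois = []
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("vertex_index")
        v = grp[["x", "y"]].to_numpy(float)
        units = set(grp["units"].astype(str))
        if units == {"px"}:
            rois.append(RoiPolygon.from_pixels(v, str(label), source_px))
        elif units == {"nm"}:
            rois.append(RoiPolygon(v, str(label), source_px))
        else:
            raise FormatError(f"ROI {label!r}: mixed or unknown units {units}")
    if not rois:
        raise EmptyInputError(f"{path} holds no ROI vertices")
    return rois


def write_rois(rois: Sequence[RoiPolygon], path: str | Path) -> None:
    """Write ROI polygons as a vertex-list CSV in nm units."""
    rows = []
    for roi in rois:
        for k, (x, y) in enumerate(roi.vertices):
            rows.append({"label": roi.label, "vertex_index": k, "x": x, "y": y, "units": "nm"})
    pd.DataFrame(rows).to_csv(path, index=False)
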
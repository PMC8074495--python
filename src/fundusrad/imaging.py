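"""Fundus images, ROI geometry, and orientation canonicalization.

Coordinate convention used throughout the package: 0-based, ``x`` is the
column index, ``y`` the row index, and ``y`` increases downward (screen
frame).  A pixel at ``(row, col)`` has its center at ``(col + 0.5,
row + 0.5)``; a pixel belongs to a polygonal region iff its center lies
inside the polygon.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image
from scipy import interpolate

logger = logging.getLogger(__name__)

__all__ = [
    "FundusImage",
    "Contour",
    "RoiSet",
    "read_fundus",
    "read_labels",
    "load_annotations",
    "smooth_contour",
    "rasterize_region",
    "canonicalize_orientation",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class FundusImage:
    """An RGB fundus photograph with eye identity and laterality.

    ``pixels`` is an ``H x W x 3`` uint8 array; ``dpi`` is carried as
    metadata only (all measurements in this package are in pixels).
    """

    pixels: np.ndarray
    laterality: str
    eye_id: str
    patient_id: str = ""
    dpi: float = 150.0
    canonical: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError(
                f"expected an H x W x 3 RGB raster, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValidationError("image must be non-empty")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValidationError("intensities must lie in [0, 255]")
        if self.laterality not in ("left", "right"):
            raise ValidationError(f"unknown laterality {self.laterality!r}")
        if not (self.dpi > 0):
            raise ValidationError("dpi must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        """Return one of the R/G/B channels as a float array."""
        idx = {"R": 0, "G": 1, "B": 2}[name]
        return self.pixels[:, :, idx].astype(np.float64)


@dataclass
class Contour:
    """A closed planar contour given as an ordered (x, y) point list.

    The first point is logically adjacent to the last; it is not repeated.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError("contour points must be an N x 2 array")
        # drop an explicit closing repeat, if present
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValidationError("a contour needs at least 3 points")
        self.points = pts

    @property
    def n_points(self) -> int:
        return len(self.points)

    def signed_area(self) -> float:
        """Shoelace signed area (positive for mathematically CCW order)."""
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def area(self) -> float:
        return abs(self.signed_area())

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())

    def oriented_ccw(self) -> "Contour":
        """Return the contour with positive (mathematical) orientation."""
        if self.signed_area() < 0:
            return Contour(self.points[::-1].copy())
        return self


@dataclass
class RoiSet:
    """Optic-disc contour, PPA outer contour, macula point and region masks.

    ``ppa_mask`` is the fill of the PPA outer contour minus the fill of the
    disc contour; it may be empty for eyes without peripapillary atrophy.
    The disc and PPA masks are disjoint by construction and this is asserted
    whenever an ``RoiSet`` is built.
    """

    disc_contour: Contour
    ppa_outer_contour: Optional[Contour]
    macula: tuple[float, float]
    disc_mask: np.ndarray
    ppa_mask: np.ndarray

    def __post_init__(self) -> None:
        self.disc_mask = np.asarray(self.disc_mask, dtype=bool)
        self.ppa_mask = np.asarray(self.ppa_mask, dtype=bool)
        if self.disc_mask.shape != self.ppa_mask.shape:
            raise ValidationError("disc and PPA masks must share a shape")
        if not self.disc_mask.any():
            raise ValidationError("disc mask is empty")
        if (self.disc_mask & self.ppa_mask).any():
            raise ValidationError("disc and PPA masks overlap")

    @classmethod
    def from_contours(
        cls,
        disc: Contour,
        ppa_outer: Optional[Contour],
        macula: tuple[float, float],
        shape: tuple[int, int],
    ) -> "RoiSet":
        disc_mask = rasterize_region(disc, shape)
        if ppa_outer is not None:
            outer = rasterize_region(ppa_outer, shape)
            ppa_mask = outer & ~disc_mask
        else:
            ppa_mask = np.zeros(shape, dtype=bool)
        return cls(disc, ppa_outer, tuple(map(float, macula)), disc_mask, ppa_mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.disc_mask.shape


# ---------------------------------------------------------------------------
# operations


def read_fundus(
    path: str | Path,
    laterality: str,
    eye_id: str,
    patient_id: str = "",
) -> FundusImage:
    """Read an 8-bit RGB fundus photograph (PNG/TIFF/JPEG)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    with Image.open(path) as im:
        dpi = float(im.info.get("dpi", (150.0, 150.0))[0] or 150.0)
        if im.mode != "RGB":
            # Pillow reports e.g. 'L' for grayscale, 'RGBA' for alpha
            if im.mode in ("L", "I", "I;16", "F", "1", "P"):
                raise ValidationError(
                    f"{path.name}: expected a 3-channel RGB image, got mode {im.mode!r}"
                )
            im = im.convert("RGB")
        pixels = np.asarray(im, dtype=np.uint8)
    return FundusImage(pixels, laterality, eye_id, patient_id, dpi=dpi)


def read_labels(path: str | Path):
    """Read the per-eye labels table.

    Expected CSV columns: ``eye_id, patient_id, laterality, grade,
    plus_lesion``.  A missing/empty ``plus_lesion`` column is treated as all
    false.
    """
    import pandas as pd

    df = pd.read_csv(path, dtype={"eye_id": str, "patient_id": str})
    required = {"eye_id", "laterality", "grade"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"labels table lacks columns {sorted(missing)}")
    if "plus_lesion" not in df.columns:
        df["plus_lesion"] = 0
    df["plus_lesion"] = df["plus_lesion"].fillna(0).astype(int)
    if "patient_id" not in df.columns:
        df["patient_id"] = df["eye_id"]
    return df


def smooth_contour(points: Contour | np.ndarray, n_out: Optional[int] = None) -> Contour:
    """Smooth a hand-drawn contour with a periodic cubic B-spline.

    The spline interpolates the (deduplicated) input points and is resampled
    at ``n_out`` approximately uniformly spaced parameter values (default:
    four times the input point count).
    """
    pts = points.points if isinstance(points, Contour) else np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("contour points must be an N x 2 array")
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    # drop consecutive duplicates, which break spline parameterization
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.abs(np.diff(pts, axis=0)) > 1e-12, axis=1)
    pts = pts[keep]
    if len(pts) < 4:
        raise ValidationError("contour smoothing needs at least 4 distinct points")
    area = Contour(pts).area()
    if area <= 1e-9:
        raise ValidationError("degenerate (zero-area) contour")
    if n_out is None:
        n_out = 4 * len(pts)
    if n_out < 3:
        raise ValidationError("n_out must be at least 3")
    closed = np.vstack([pts, pts[:1]])  # splprep(per=1) wraps on the last point
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tck, _ = interpolate.splprep([closed[:, 0], closed[:, 1]], s=0.0, per=1, k=3)
    u = np.linspace(0.0, 1.0, n_out, endpoint=False)
    x, y = interpolate.splev(u, tck)
    return Contour(np.column_stack([x, y]))


def rasterize_region(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a simple closed contour onto an ``H x W`` boolean mask.

    A pixel is inside iff its center ``(col + 0.5, row + 0.5)`` lies inside
    the polygon.  Parts of the contour outside the frame are clipped with a
    logged warning.
    """
    h, w = shape
    pts = contour.points
    if (
        pts[:, 0].min() < 0
        or pts[:, 1].min() < 0
        or pts[:, 0].max() > w
        or pts[:, 1].max() > h
    ):
        logger.warning(
            "contour extends outside the %dx%d frame; clipping to the frame", h, w
        )
    # bounding box of candidate pixels
    c0 = max(int(np.floor(pts[:, 0].min() - 0.5)), 0)
    c1 = min(int(np.ceil(pts[:, 0].max() + 0.5)), w - 1)
    r0 = max(int(np.floor(pts[:, 1].min() - 0.5)), 0)
    r1 = min(int(np.ceil(pts[:, 1].max() + 0.5)), h - 1)
    mask = np.zeros((h, w), dtype=bool)
    if c1 < c0 or r1 < r0:
        return mask
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    cc, rr = np.meshgrid(cols, rows)
    centers = np.column_stack([cc.ravel() + 0.5, rr.ravel() + 0.5])
    path = MplPath(pts, closed=False)
    inside = path.contains_points(centers)
    mask[rr.ravel()[inside], cc.ravel()[inside]] = True
    return mask


def canonicalize_orientation(
    img: FundusImage, rois: RoiSet
) -> tuple[FundusImage, RoiSet]:
    """Mirror left eyes horizontally so every eye is in right-eye frame.

    Right eyes pass through unchanged (apart from the ``canonical`` flag).
    For left eyes, pixel ``(x, y)`` maps to ``(W-1-x, y)`` and contour /
    macula x-coordinates map as ``x -> (W-1) - x``.
    """
    if img.laterality == "right":
        out = FundusImage(
            img.pixels, "right", img.eye_id, img.patient_id, img.dpi, canonical=True
        )
        return out, rois
    w = img.shape[1]
    flipped = FundusImage(
        img.pixels[:, ::-1, :].copy(),
        "right",
        img.eye_id,
        img.patient_id,
        img.dpi,
        canonical=True,
    )

    def _flip_contour(c: Optional[Contour]) -> Optional[Contour]:
        if c is None:
            return None
        pts = c.points.copy()
        pts[:, 0] = (w - 1) - pts[:, 0]
        return Contour(pts)

    rois_flipped = RoiSet(
        _flip_contour(rois.disc_contour),
        _flip_contour(rois.ppa_outer_contour),
        ((w - 1) - rois.macula[0], rois.macula[1]),
        rois.disc_mask[:, ::-1].copy(),
        rois.ppa_mask[:, ::-1].copy(),
    )
    return flipped, rois_flipped


# ---------------------------------------------------------------------------
# annotation loading


def _check_in_bounds(pts: np.ndarray, shape: tuple[int, int], what: str) -> None:
    h, w = shape
    if (
        pts[:, 0].min() < 0
        or pts[:, 1].min() < 0
        or pts[:, 0].max() >= w
        or pts[:, 1].max() >= h
    ):
        raise ValidationError(f"{what} coordinates fall outside the {h}x{w} frame")


def _load_annotation_json(path: Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _load_annotation_csvs(path: Path) -> dict:
    """One-region-per-file CSVs with x,y columns: <stem>_disc.csv etc."""
    out: dict = {}
    for key in ("disc", "ppa", "macula"):
        f = path.parent / f"{path.stem}_{key}.csv"
        if not f.exists():
            continue
        rows = []
        with open(f) as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                rows.append([float(row["x"]), float(row["y"])])
        out[key] = rows[0] if key == "macula" else rows
    return out


def _trace_label_mask(path: Path) -> dict:
    """Trace contours from a label-mask PNG (0=background 1=disc 2=PPA)."""
    from skimage import measure

    with Image.open(path) as im:
        lab = np.asarray(im)
    if lab.ndim == 3:
        lab = lab[:, :, 0]
    ann: dict = {}
    disc = lab == 1
    if not disc.any():
        raise ValidationError(f"label mask {path.name} contains no disc (value 1)")
    # find_contours returns (row, col); convert to (x, y)
    disc_tr = max(measure.find_contours(disc.astype(float), 0.5), key=len)
    ann["disc"] = disc_tr[:, ::-1].tolist()
    outer = lab >= 1
    if (lab == 2).any():
        outer_tr = max(measure.find_contours(outer.astype(float), 0.5), key=len)
        ann["ppa"] = outer_tr[:, ::-1].tolist()
    return ann


def load_annotations(
    path: str | Path,
    image_shape: tuple[int, int],
    macula: Optional[Sequence[float]] = None,
    smooth_n: Optional[int] = None,
) -> RoiSet:
    """Load ROI annotations and build smoothed, rasterized masks.

    Accepts a JSON file ``{"disc": [[x, y], ...], "ppa": [...], "macula":
    [x, y]}``, a one-region-per-file CSV set (``<stem>_disc.csv`` ...), or a
    label-mask PNG (0 = background, 1 = disc, 2 = PPA; macula must then be
    supplied via the ``macula`` argument).  The PPA outer contour may be
    absent, in which case the PPA mask is empty.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such annotation file: {path}")
    if path.suffix.lower() == ".json":
        ann = _load_annotation_json(path)
    elif path.suffix.lower() == ".csv":
        ann = _load_annotation_csvs(path)
    elif path.suffix.lower() == ".png":
        ann = _trace_label_mask(path)
    else:
        raise ValidationError(f"unsupported annotation format: {path.suffix}")

    if macula is not None:
        ann["macula"] = list(macula)
    if "disc" not in ann or ann["disc"] is None:
        raise ValidationError("annotation lacks the disc contour")
    if "macula" not in ann or ann["macula"] is None:
        raise ValidationError("annotation lacks the macula point")

    mac = np.asarray(ann["macula"], dtype=float).reshape(1, 2)
    _check_in_bounds(mac, image_shape, "macula")
    disc_pts = np.asarray(ann["disc"], dtype=float)
    _check_in_bounds(disc_pts, image_shape, "disc contour")
    disc = smooth_contour(disc_pts, n_out=smooth_n)
    ppa = None
    if ann.get("ppa"):
        ppa_pts = np.asarray(ann["ppa"], dtype=float)
        _check_in_bounds(ppa_pts, image_shape, "PPA contour")
        ppa = smooth_contour(ppa_pts, n_out=smooth_n)
    return RoiSet.from_contours(disc, ppa, (float(mac[0, 0]), float(mac[0, 1])), image_shape)
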
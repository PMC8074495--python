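"""Morphologic descriptors of the optic disc and peripapillary atrophy.

Implements the six clinic features (AreaPPA, AreaDisc, Tilt, Torsion,
Dist_MD, Angle_MD) and the 151-feature in-house morphologic bank: contour
curvature profiles, region properties, central/normalized moments and Hu
invariants, elliptic-Fourier magnitudes and Fourier circularity,
inter-contour distances, PPA radial width-profile statistics, the PPAweight
ray-fluctuation family, and derived area ratios.

Angles are reported in degrees in (-90, 90], measured from the +x axis,
positive counterclockwise on screen (the image frame is y-down, so screen
counterclockwise corresponds to decreasing y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree
from scipy.stats import skew
from skimage import measure

from .imaging import Contour, FundusImage, RoiSet, ValidationError

__all__ = [
    "EllipseFit",
    "ClinicFeatures",
    "fit_ellipse_moments",
    "clinic_features",
    "contour_descriptors",
    "region_moments",
    "fourier_shape",
    "ppa_profile_features",
    "morphologic_bank",
    "MORPHOLOGIC_FEATURE_NAMES",
]

N_CURVATURE_STATIONS = 16
N_FOURIER_HARMONICS = 10
N_RAYS = 72


# ---------------------------------------------------------------------------
# angles


def _fold_angle(deg: float) -> float:
    """Fold an angle in degrees into (-90, 90]."""
    a = (deg + 90.0) % 180.0 - 90.0
    if a == -90.0:
        a = 90.0
    return a


def _screen_angle(dx: float, dy: float) -> float:
    """Angle of a direction vector, positive counterclockwise on screen."""
    return float(np.degrees(np.arctan2(-dy, dx)))


# ---------------------------------------------------------------------------
# ellipse fit


@dataclass
class EllipseFit:
    """Moment-equivalent ellipse of a binary region."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation_deg: float

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValidationError("ellipse axes must satisfy a >= b > 0")


def fit_ellipse_moments(mask: np.ndarray) -> EllipseFit:
    """Fit the second-central-moment equivalent ellipse of a mask.

    The semi-axes are ``2 * sqrt(eigenvalue)`` of the 2x2 covariance of the
    in-mask pixel-center coordinates — the exact relation for a filled
    ellipse.  An isotropic region (equal eigenvalues) gets orientation 0 by
    tie-break.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("cannot fit an ellipse to an empty mask")
    rows, cols = np.nonzero(mask)
    x = cols + 0.5
    y = rows + 0.5
    cx, cy = float(x.mean()), float(y.mean())
    cov = np.cov(np.vstack([x - cx, y - cy]), bias=True)
    # pixel extent correction keeps a 1-pixel region finite
    cov += np.eye(2) * (1.0 / 12.0)
    evals, evecs = np.linalg.eigh(cov)
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    a = 2.0 * np.sqrt(lam_major)
    b = 2.0 * np.sqrt(lam_minor)
    if (lam_major - lam_minor) / max(lam_major, 1e-12) < 1e-9:
        theta = 0.0
    else:
        vx, vy = evecs[:, 1]
        theta = _fold_angle(_screen_angle(float(vx), float(vy)))
    return EllipseFit((cx, cy), a, max(b, 1e-9), theta)


# ---------------------------------------------------------------------------
# clinic features


@dataclass
class ClinicFeatures:
    """The six clinically reported disc-region shape features (pixels)."""

    AreaPPA: float
    AreaDisc: float
    Tilt: float
    Torsion: float
    Dist_MD: float
    Angle_MD: float

    def __post_init__(self) -> None:
        if self.AreaPPA < 0 or self.AreaDisc <= 0:
            raise ValidationError("invalid region areas")
        if not (0 < self.Tilt <= 1):
            raise ValidationError("Tilt must lie in (0, 1]")
        if self.Dist_MD < 0:
            raise ValidationError("Dist_MD must be non-negative")

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "AreaPPA": self.AreaPPA,
                "AreaDisc": self.AreaDisc,
                "Tilt": self.Tilt,
                "Torsion": self.Torsion,
                "Dist_MD": self.Dist_MD,
                "Angle_MD": self.Angle_MD,
            }
        )


def clinic_features(rois: RoiSet) -> ClinicFeatures:
    """Compute the six clinic features from a rasterized ROI set.

    * AreaPPA / AreaDisc — pixel counts of the PPA and disc masks.
    * Tilt — short/long axis ratio of the disc's moment-equivalent ellipse.
    * Torsion — signed acute angle between the disc long axis and the
      perpendicular to the macula–disc-center line (positive when the long
      axis is rotated counterclockwise on screen from that perpendicular).
    * Dist_MD — Euclidean distance from the disc centroid to the macula.
    * Angle_MD — signed angle of the disc-center→macula line from
      horizontal, positive when the macula lies below the horizontal.
    """
    if not rois.disc_mask.any():
        raise ValidationError("empty disc mask")
    ell = fit_ellipse_moments(rois.disc_mask)
    cx, cy = ell.center
    mx, my = rois.macula
    dx, dy = mx - cx, my - cy
    dist_md = float(np.hypot(dx, dy))
    if dist_md < 1e-9:
        raise ValidationError("macula coincides with the disc center")
    md_angle_ccw = _screen_angle(dx, dy)
    torsion = _fold_angle(ell.orientation_deg - (md_angle_ccw + 90.0))
    # positive Angle_MD = macula below the horizontal (y-down frame)
    angle_md = _fold_angle(float(np.degrees(np.arctan2(dy, dx))))
    return ClinicFeatures(
        AreaPPA=float(rois.ppa_mask.sum()),
        AreaDisc=float(rois.disc_mask.sum()),
        Tilt=min(ell.semi_minor / ell.semi_major, 1.0),
        Torsion=torsion,
        Dist_MD=dist_md,
        Angle_MD=angle_md,
    )


# ---------------------------------------------------------------------------
# contour resampling and curvature


def resample_arclength(contour: Contour, n: int) -> np.ndarray:
    """Resample a closed contour at ``n`` points uniform in arc length."""
    pts = contour.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.sqrt((np.diff(closed, axis=0) ** 2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValidationError("degenerate contour of zero length")
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


def _curvature_stations(contour: Contour, n_stations: int = N_CURVATURE_STATIONS):
    """Curvature sampled at equally spaced arc-length stations.

    Curvature is evaluated analytically from the derivatives of a periodic
    cubic spline through the contour points (the parameterization-invariant
    formula |x'y'' - y'x''| / (x'^2 + y'^2)^{3/2}).  Station 1 sits at the
    temporal-most (maximum-x) boundary point; the remaining stations follow
    in screen-counterclockwise order.
    """
    from scipy import interpolate

    pts = contour.oriented_ccw().points
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.abs(np.diff(pts, axis=0)) > 1e-12, axis=1)
    pts = pts[keep]
    closed = np.vstack([pts, pts[:1]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tck, _ = interpolate.splprep([closed[:, 0], closed[:, 1]], s=0.0, per=1, k=3)
    u = np.linspace(0.0, 1.0, 512, endpoint=False)
    x, y = interpolate.splev(u, tck)
    dx, dy = interpolate.splev(u, tck, der=1)
    ddx, ddy = interpolate.splev(u, tck, der=2)
    denom = np.maximum((dx**2 + dy**2) ** 1.5, 1e-12)
    kappa = np.abs(dx * ddy - dy * ddx) / denom
    # arc-length-uniform stations, anchored at the max-x point
    seg = np.sqrt(dx**2 + dy**2)
    arc = np.cumsum(seg)
    arc = arc - arc[0]
    start = int(np.argmax(x))
    total = arc[-1]
    targets = (arc[start] + np.arange(n_stations) * total / n_stations) % total
    idx = np.searchsorted(arc, targets).clip(0, len(u) - 1)
    return kappa[idx], kappa


def contour_descriptors(
    disc: Contour, ppa_outer: Optional[Contour]
) -> tuple[pd.Series, list[str]]:
    """Curvature profiles, perimeters and inter-contour distances.

    Returns the named feature vector together with the list of features that
    were emitted as 0 because the PPA contour is absent.
    """
    feats: dict[str, float] = {}
    flags: list[str] = []

    stations, kappa = _curvature_stations(disc)
    for i, k in enumerate(stations, start=1):
        feats[f"DiscCurvature{i}"] = float(k)
    feats["DiscCurvatureMean"] = float(kappa.mean())
    feats["DiscCurvatureSD"] = float(kappa.std())
    feats["DiscCurvatureMax"] = float(kappa.max())
    feats["DiscPerimeter"] = disc.perimeter()

    ppa_names = (
        [f"PPACurvature{i}" for i in range(1, N_CURVATURE_STATIONS + 1)]
        + ["PPACurvatureMean", "PPACurvatureSD", "PPACurvatureMax", "PPAOuterPerimeter"]
        + ["ContourHausdorff", "ContourDistMean", "ContourDistMin", "ContourDistMedian"]
    )
    if ppa_outer is None:
        for name in ppa_names:
            feats[name] = 0.0
        flags.extend(ppa_names)
        return pd.Series(feats), flags

    stations_p, kappa_p = _curvature_stations(ppa_outer)
    for i, k in enumerate(stations_p, start=1):
        feats[f"PPACurvature{i}"] = float(k)
    feats["PPACurvatureMean"] = float(kappa_p.mean())
    feats["PPACurvatureSD"] = float(kappa_p.std())
    feats["PPACurvatureMax"] = float(kappa_p.max())
    feats["PPAOuterPerimeter"] = ppa_outer.perimeter()

    a = resample_arclength(disc, 256)
    b = resample_arclength(ppa_outer, 256)
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    pooled = np.concatenate([d_ab, d_ba])
    feats["ContourHausdorff"] = float(max(d_ab.max(), d_ba.max()))
    feats["ContourDistMean"] = float(pooled.mean())
    feats["ContourDistMin"] = float(pooled.min())
    feats["ContourDistMedian"] = float(np.median(pooled))
    return pd.Series(feats), flags


# ---------------------------------------------------------------------------
# region moments and region properties


_MOMENT_ORDERS = [(1, 1), (2, 0), (0, 2), (3, 0), (2, 1), (1, 2), (0, 3)]


def region_moments(mask: np.ndarray, prefix: str = "") -> pd.Series:
    """Central moments (p+q <= 3), normalized moments and Hu invariants."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty mask has no moments")
    m = measure.moments_central(mask.astype(np.float64), order=3)
    nu = measure.moments_normalized(m, order=3)
    hu = measure.moments_hu(nu)
    out: dict[str, float] = {}
    for p, q in _MOMENT_ORDERS:
        # skimage indexes moments as m[row_order, col_order] = m[q, p]
        out[f"{prefix}mu{p}{q}"] = float(m[q, p])
    for p, q in _MOMENT_ORDERS:
        out[f"{prefix}nu{p}{q}"] = float(nu[q, p])
    for i, h in enumerate(hu, start=1):
        out[f"{prefix}hu{i}"] = float(h)
    return pd.Series(out)


_REGIONPROP_NAMES = [
    "Perimeter",
    "AreaPerimeterRatio",
    "Circularity",
    "Solidity",
    "Extent",
    "Eccentricity",
    "ConvexArea",
]


def _region_properties(mask: np.ndarray, prefix: str) -> pd.Series:
    """Perimeter, circularity, solidity, extent, eccentricity, convex area."""
    lab = mask.astype(np.uint8)
    props = measure.regionprops(lab)
    if not props:
        raise ValidationError("empty mask has no region properties")
    # merge multi-component masks (a crescent PPA can split) by recomputing
    # on the union via a single labeled blob
    area = float(mask.sum())
    per = float(sum(p.perimeter for p in props))
    hull_area = float(sum(p.area_convex for p in props))
    bbox_area = float(sum(p.area_bbox for p in props))
    ecc = float(props[int(np.argmax([p.area for p in props]))].eccentricity)
    per = max(per, 1e-9)
    return pd.Series(
        {
            f"{prefix}Perimeter": per,
            f"{prefix}AreaPerimeterRatio": area / per,
            f"{prefix}Circularity": 4.0 * np.pi * area / per**2,
            f"{prefix}Solidity": area / max(hull_area, 1e-9),
            f"{prefix}Extent": area / max(bbox_area, 1e-9),
            f"{prefix}Eccentricity": ecc,
            f"{prefix}ConvexArea": hull_area,
        }
    )


# ---------------------------------------------------------------------------
# Fourier shape descriptors


def fourier_shape(
    contour: Contour, n_harmonics: int = N_FOURIER_HARMONICS, prefix: str = ""
) -> pd.Series:
    """Fourier descriptors of the complex boundary sequence.

    The boundary is resampled uniformly in arc length (at least
    ``4 * n_harmonics`` points), centroid-subtracted, oriented
    mathematically counterclockwise, and transformed; the output holds
    ``|c_k| / |c_1|`` for k = 1..n_harmonics and the Fourier circularity
    ``|c_1| / sum_{k in ±1..±n} |c_k|`` (1 for a perfect circle).
    """
    if n_harmonics < 1:
        raise ValidationError("n_harmonics must be positive")
    n = max(64, 4 * n_harmonics)
    pts = resample_arclength(contour.oriented_ccw(), n)
    z = (pts[:, 0] - pts[:, 0].mean()) + 1j * (pts[:, 1] - pts[:, 1].mean())
    if np.abs(z).max() < 1e-9:
        raise ValidationError("degenerate contour")
    c = np.fft.fft(z) / n
    mags = {k: abs(c[k % n]) for k in range(-n_harmonics, n_harmonics + 1) if k != 0}
    c1 = max(mags[1], 1e-12)
    out = {f"{prefix}Fourier{k}": mags[k] / c1 for k in range(1, n_harmonics + 1)}
    total = sum(mags.values())
    out[f"Fourier_Circularity_{prefix.rstrip('_') or 'Contour'}"] = mags[1] / max(
        total, 1e-12
    )
    return pd.Series(out)


# ---------------------------------------------------------------------------
# PPA radial ray geometry, width profile and PPAweight


@dataclass
class _RayGeometry:
    """In-mask sample books for rays cast from the disc centroid."""

    inside: np.ndarray  # (n_rays, n_steps) bool
    xs: np.ndarray  # (n_rays, n_steps) x coordinate of each sample
    ys: np.ndarray
    step: float


def _cast_rays(
    rois: RoiSet, n_rays: int = N_RAYS, step: float = 0.5
) -> _RayGeometry:
    h, w = rois.shape
    rows, cols = np.nonzero(rois.disc_mask)
    cx, cy = cols.mean() + 0.5, rows.mean() + 0.5
    max_r = float(np.hypot(h, w))
    radii = np.arange(step, max_r, step)
    angles = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    xs = cx + np.cos(angles)[:, None] * radii[None, :]
    ys = cy + np.sin(angles)[:, None] * radii[None, :]
    ci = np.clip(np.round(xs - 0.5).astype(int), 0, w - 1)
    ri = np.clip(np.round(ys - 0.5).astype(int), 0, h - 1)
    valid = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    inside = rois.ppa_mask[ri, ci] & valid
    return _RayGeometry(inside, xs, ys, step)


def _ray_widths(geom: _RayGeometry) -> np.ndarray:
    """PPA width along each ray (total in-mask path length, px)."""
    return geom.inside.sum(axis=1) * geom.step


def _ppa_width_stats(geom: _RayGeometry) -> pd.Series:
    widths = _ray_widths(geom)
    hit = widths > 0
    if not hit.any():
        return pd.Series(
            {f"PPAWidth{s}": 0.0 for s in ("Mean", "SD", "Max", "Min", "Skew")}
        )
    wv = widths[hit]
    return pd.Series(
        {
            "PPAWidthMean": float(wv.mean()),
            "PPAWidthSD": float(wv.std()),
            "PPAWidthMax": float(wv.max()),
            "PPAWidthMin": float(wv.min()),
            "PPAWidthSkew": float(skew(wv)) if len(wv) > 2 and wv.std() > 0 else 0.0,
        }
    )


def _ray_station_coords(geom: _RayGeometry, u: int) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """(y, x) coordinates of u radial stations per PPA-crossing ray.

    Stations are spaced evenly between the first and last in-mask sample of
    each ray; rays that miss the PPA (or graze a single sample) are dropped.
    Returns None when no ray crosses.
    """
    inside = geom.inside
    any_hit = inside.any(axis=1)
    first = inside.argmax(axis=1)
    last = inside.shape[1] - 1 - inside[:, ::-1].argmax(axis=1)
    keep = any_hit & (last > first)
    if not keep.any():
        return None
    f = first[keep].astype(float)
    l = last[keep].astype(float)
    t = f[:, None] + (l - f)[:, None] * np.linspace(0.0, 1.0, u)[None, :]
    rows = np.arange(keep.sum())
    ti = np.floor(t).astype(int)
    frac = t - ti
    ti1 = np.minimum(ti + 1, inside.shape[1] - 1)
    xs = geom.xs[keep][rows[:, None], ti] * (1 - frac) + geom.xs[keep][rows[:, None], ti1] * frac
    ys = geom.ys[keep][rows[:, None], ti] * (1 - frac) + geom.ys[keep][rows[:, None], ti1] * frac
    return ys, xs


def _ppa_weight_from_coords(
    channel: np.ndarray, coords: Optional[tuple[np.ndarray, np.ndarray]]
) -> float:
    """Mean over rays of the mean absolute successive station difference."""
    if coords is None:
        return 0.0
    ys, xs = coords
    # bilinear interpolation in pixel-center coordinates
    prof = map_coordinates(
        channel, [ys.ravel() - 0.5, xs.ravel() - 0.5], order=1, mode="nearest"
    ).reshape(ys.shape)
    return float(np.abs(np.diff(prof, axis=1)).mean(axis=1).mean())


def _ppa_weight_from_geom(channel: np.ndarray, geom: _RayGeometry, u: int) -> float:
    """PPAweight: radial intensity fluctuation of the PPA at u stations.

    For each ray cast from the disc centroid that crosses the PPA, the
    channel intensity is sampled at ``u`` equally spaced stations between
    the first and last in-mask points and the mean absolute successive
    difference is taken; the feature is the mean over rays.  Captures how
    rapidly pixel values fluctuate along the broadwise (radial) direction
    of the PPA.
    """
    if u < 2:
        raise ValidationError("u must be at least 2")
    return _ppa_weight_from_coords(channel, _ray_station_coords(geom, u))


def ppa_profile_features(
    img: FundusImage, rois: RoiSet, u: int, channel: str
) -> float:
    """PPAweight feature for one (u, channel) pair; 0 when the PPA is empty."""
    if u < 2:
        raise ValidationError("u must be at least 2")
    if not rois.ppa_mask.any():
        return 0.0
    geom = _cast_rays(rois)
    return _ppa_weight_from_geom(img.channel(channel), geom, u)


# ---------------------------------------------------------------------------
# the 151-feature morphologic bank


def _build_name_roster() -> list[str]:
    names: list[str] = []
    # clinic ingredients (10)
    names += [
        "shape_AreaPPA",
        "shape_AreaDisc",
        "shape_AreaOuter",
        "shape_DiscMajorAxis",
        "shape_DiscMinorAxis",
        "shape_DiscOrientation",
        "shape_Tilt",
        "shape_Torsion",
        "shape_DistMD",
        "shape_AngleMD",
    ]
    # curvature stations + stats (2 x 19) and perimeters / inter-contour (in groups below)
    names += [f"DiscCurvature{i}" for i in range(1, N_CURVATURE_STATIONS + 1)]
    names += ["DiscCurvatureMean", "DiscCurvatureSD", "DiscCurvatureMax"]
    names += [f"PPACurvature{i}" for i in range(1, N_CURVATURE_STATIONS + 1)]
    names += ["PPACurvatureMean", "PPACurvatureSD", "PPACurvatureMax"]
    # region properties (2 x 7)
    names += [f"Disc{p}" for p in _REGIONPROP_NAMES]
    names += [f"PPA{p}" for p in _REGIONPROP_NAMES]
    # moments (2 x 21)
    for prefix in ("Disc_", "PPA_"):
        names += [f"{prefix}mu{p}{q}" for p, q in _MOMENT_ORDERS]
        names += [f"{prefix}nu{p}{q}" for p, q in _MOMENT_ORDERS]
        names += [f"{prefix}hu{i}" for i in range(1, 8)]
    # Fourier (2 x 11)
    names += [f"Disc_Fourier{k}" for k in range(1, N_FOURIER_HARMONICS + 1)]
    names += ["Fourier_Circularity_Disc"]
    names += [f"PPA_Fourier{k}" for k in range(1, N_FOURIER_HARMONICS + 1)]
    names += ["Fourier_Circularity_PPA"]
    # inter-contour distances (4)
    names += ["ContourHausdorff", "ContourDistMean", "ContourDistMin", "ContourDistMedian"]
    # width profile stats (5)
    names += ["PPAWidthMean", "PPAWidthSD", "PPAWidthMax", "PPAWidthMin", "PPAWidthSkew"]
    # PPAweight family (9)
    names += [f"PPAweight_u{u}{c}" for c in ("R", "G", "B") for u in (10, 20, 30)]
    # derived ratios (7)
    names += [
        "PPADiscAreaRatio",
        "PPAOuterAreaRatio",
        "DiscOuterAreaRatio",
        "DistMDDiscDiameterRatio",
        "SqrtAreaPPADistMDRatio",
        "DiscOuterPerimeterRatio",
        "PPAWidthDiscRadiusRatio",
    ]
    return names


MORPHOLOGIC_FEATURE_NAMES: list[str] = _build_name_roster()
assert len(MORPHOLOGIC_FEATURE_NAMES) == 151
assert len(set(MORPHOLOGIC_FEATURE_NAMES)) == 151


def morphologic_bank(
    img: FundusImage, rois: RoiSet
) -> tuple[pd.Series, list[str]]:
    """Assemble the 151-feature morphologic bank for one eye.

    Returns the named vector (stable order and names) and the list of
    PPA-dependent features emitted as 0 because the eye has no PPA.
    """
    feats: dict[str, float] = {}
    flags: list[str] = []
    has_ppa = rois.ppa_mask.any()

    cl = clinic_features(rois)
    ell = fit_ellipse_moments(rois.disc_mask)
    outer_area = (
        float(rois.ppa_mask.sum() + rois.disc_mask.sum()) if has_ppa else cl.AreaDisc
    )
    feats.update(
        {
            "shape_AreaPPA": cl.AreaPPA,
            "shape_AreaDisc": cl.AreaDisc,
            "shape_AreaOuter": outer_area,
            "shape_DiscMajorAxis": 2.0 * ell.semi_major,
            "shape_DiscMinorAxis": 2.0 * ell.semi_minor,
            "shape_DiscOrientation": ell.orientation_deg,
            "shape_Tilt": cl.Tilt,
            "shape_Torsion": cl.Torsion,
            "shape_DistMD": cl.Dist_MD,
            "shape_AngleMD": cl.Angle_MD,
        }
    )

    cd, cd_flags = contour_descriptors(rois.disc_contour, rois.ppa_outer_contour)
    feats.update(cd.to_dict())
    flags.extend(cd_flags)

    feats.update(_region_properties(rois.disc_mask, "Disc").to_dict())
    if has_ppa:
        feats.update(_region_properties(rois.ppa_mask, "PPA").to_dict())
    else:
        for p in _REGIONPROP_NAMES:
            feats[f"PPA{p}"] = 0.0
            flags.append(f"PPA{p}")

    feats.update(region_moments(rois.disc_mask, "Disc_").to_dict())
    if has_ppa:
        feats.update(region_moments(rois.ppa_mask, "PPA_").to_dict())
    else:
        for p, q in _MOMENT_ORDERS:
            feats[f"PPA_mu{p}{q}"] = 0.0
            feats[f"PPA_nu{p}{q}"] = 0.0
        for i in range(1, 8):
            feats[f"PPA_hu{i}"] = 0.0
        flags.extend(
            [f"PPA_mu{p}{q}" for p, q in _MOMENT_ORDERS]
            + [f"PPA_nu{p}{q}" for p, q in _MOMENT_ORDERS]
            + [f"PPA_hu{i}" for i in range(1, 8)]
        )

    feats.update(fourier_shape(rois.disc_contour, prefix="Disc_").to_dict())
    if rois.ppa_outer_contour is not None:
        feats.update(fourier_shape(rois.ppa_outer_contour, prefix="PPA_").to_dict())
    else:
        for k in range(1, N_FOURIER_HARMONICS + 1):
            feats[f"PPA_Fourier{k}"] = 0.0
            flags.append(f"PPA_Fourier{k}")
        feats["Fourier_Circularity_PPA"] = 0.0
        flags.append("Fourier_Circularity_PPA")

    geom = _cast_rays(rois) if has_ppa else None
    if geom is not None:
        feats.update(_ppa_width_stats(geom).to_dict())
        coords = {u: _ray_station_coords(geom, u) for u in (10, 20, 30)}
        for c in ("R", "G", "B"):
            chan = img.channel(c)
            for u in (10, 20, 30):
                feats[f"PPAweight_u{u}{c}"] = _ppa_weight_from_coords(chan, coords[u])
    else:
        for s in ("Mean", "SD", "Max", "Min", "Skew"):
            feats[f"PPAWidth{s}"] = 0.0
            flags.append(f"PPAWidth{s}")
        for c in ("R", "G", "B"):
            for u in (10, 20, 30):
                feats[f"PPAweight_u{u}{c}"] = 0.0
                flags.append(f"PPAweight_u{u}{c}")

    disc_radius = np.sqrt(cl.AreaDisc / np.pi)
    feats["PPADiscAreaRatio"] = cl.AreaPPA / cl.AreaDisc
    feats["PPAOuterAreaRatio"] = cl.AreaPPA / max(outer_area, 1e-9)
    feats["DiscOuterAreaRatio"] = cl.AreaDisc / max(outer_area, 1e-9)
    feats["DistMDDiscDiameterRatio"] = cl.Dist_MD / (2.0 * ell.semi_major)
    feats["SqrtAreaPPADistMDRatio"] = np.sqrt(cl.AreaPPA) / max(cl.Dist_MD, 1e-9)
    feats["DiscOuterPerimeterRatio"] = (
        feats["DiscPerimeter"] / feats["PPAOuterPerimeter"] if has_ppa else 0.0
    )
    feats["PPAWidthDiscRadiusRatio"] = feats["PPAWidthMean"] / max(disc_radius, 1e-9)
    if not has_ppa:
        flags.extend(
            ["PPADiscAreaRatio", "PPAOuterAreaRatio", "SqrtAreaPPADistMDRatio",
             "DiscOuterPerimeterRatio", "PPAWidthDiscRadiusRatio"]
        )

    # DiscPerimeter / PPAOuterPerimeter live in the regionprop + curvature
    # groups above under different names; the roster fixes the emitted set
    out = pd.Series({name: feats[name] for name in MORPHOLOGIC_FEATURE_NAMES})
    if out.isna().any():
        bad = list(out.index[out.isna()])
        raise ValidationError(f"morphologic bank produced NaN for {bad}")
    return out, sorted(set(f for f in flags if f in MORPHOLOGIC_FEATURE_NAMES))
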
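"""First-order intensity and GLCM/NGTDM texture features of the PPA region.

All intensity and texture features are computed over the peripapillary
atrophy mask, separately on the R, G and B channels of the fundus image.
Gray levels are quantized to a fixed number of equal-width bins (default
32) over the in-ROI intensity range before any co-occurrence or gray-tone
difference statistic is formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import convolve

from .imaging import FundusImage, RoiSet, ValidationError
from .shape import MORPHOLOGIC_FEATURE_NAMES, clinic_features, morphologic_bank

__all__ = [
    "QuantizedRoi",
    "quantize_roi",
    "firstorder_bank",
    "glcm_features",
    "ngtdm_features",
    "texture_bank",
    "intensity_bank",
    "extract_feature_vector",
    "FeatureVector",
    "FIRSTORDER_STATS",
    "GLCM_STATS",
    "NGTDM_STATS",
    "GLCM_ANGLES",
]

N_GRAY_LEVELS = 32
GLCM_ANGLES = (0, 45, 90, 135)
FIRSTORDER_STATS = [
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "P10",
    "P90",
    "Maximum",
    "Mean",
    "Median",
    "IQR",
    "Range",
    "MAD",
    "rMAD",
    "RMS",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
]
GLCM_STATS = [
    "contrast",
    "dissimilarity",
    "homogeneity",
    "asm",
    "entropy",
    "correlation",
    "shade",
    "prominence",
]
NGTDM_STATS = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

_NGTDM_EPS = 1e-6
_COARSENESS_CAP = 1e6


@dataclass
class QuantizedRoi:
    """Gray levels 1..Ng of the in-mask pixels (0 outside the mask)."""

    levels: np.ndarray
    Ng: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        in_mask = self.levels[self.mask]
        if in_mask.size and (in_mask.min() < 1 or in_mask.max() > self.Ng):
            raise ValidationError("quantized levels must lie in [1, Ng]")


def quantize_roi(
    channel: np.ndarray, mask: np.ndarray, n_levels: int = N_GRAY_LEVELS
) -> QuantizedRoi:
    """Equal-width quantization of in-mask intensities into ``n_levels`` bins."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("cannot quantize an empty ROI")
    if n_levels < 1:
        raise ValidationError("n_levels must be positive")
    vals = np.asarray(channel, dtype=np.float64)[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(mask.shape, dtype=np.int32)
    if hi - lo < 1e-12:
        levels[mask] = 1
        return QuantizedRoi(levels, 1, mask)
    q = np.floor((vals - lo) / (hi - lo) * n_levels).astype(np.int32) + 1
    np.clip(q, 1, n_levels, out=q)
    levels[mask] = q
    return QuantizedRoi(levels, n_levels, mask)


# ---------------------------------------------------------------------------
# first-order statistics


def firstorder_bank(
    channel: np.ndarray, mask: np.ndarray, n_levels: int = N_GRAY_LEVELS
) -> pd.Series:
    """The 18 standard first-order radiomics statistics of an ROI.

    Entropy (bits) and uniformity are computed over the equal-width
    quantized histogram; variance, skewness and kurtosis are population
    statistics (kurtosis is the non-excess, Pearson form); a constant ROI
    has skewness and kurtosis 0 by convention.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("cannot compute first-order features of an empty ROI")
    x = np.asarray(channel, dtype=np.float64)[mask]
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    q = quantize_roi(channel, mask, n_levels)
    hist = np.bincount(q.levels[mask], minlength=q.Ng + 1)[1:].astype(float)
    p = hist / hist.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p**2).sum())
    core = x[(x >= p10) & (x <= p90)]
    if var > 0:
        skewness = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        skewness, kurt = 0.0, 0.0
    return pd.Series(
        {
            "Energy": float((x**2).sum()),
            "TotalEnergy": float((x**2).sum()),  # unit pixel spacing
            "Entropy": entropy,
            "Minimum": float(x.min()),
            "P10": float(p10),
            "P90": float(p90),
            "Maximum": float(x.max()),
            "Mean": mean,
            "Median": float(p50),
            "IQR": float(p75 - p25),
            "Range": float(x.max() - x.min()),
            "MAD": float(np.abs(x - mean).mean()),
            "rMAD": float(np.abs(core - core.mean()).mean()) if core.size else 0.0,
            "RMS": float(np.sqrt((x**2).mean())),
            "Skewness": skewness,
            "Kurtosis": kurt,
            "Variance": var,
            "Uniformity": uniformity,
        }
    )


# ---------------------------------------------------------------------------
# gray-level co-occurrence matrix

_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_matrix(q: QuantizedRoi, angle_deg: int, distance: int = 1) -> np.ndarray:
    """Symmetric, normalized GLCM restricted to in-mask pixel pairs."""
    if angle_deg not in _ANGLE_OFFSETS:
        raise ValidationError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}")
    dr, dc = (d * distance for d in _ANGLE_OFFSETS[angle_deg])
    lev, mask = q.levels, q.mask
    h, w = mask.shape
    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    a = lev[r0, c0]
    b = lev[r1, c1]
    valid = mask[r0, c0] & mask[r1, c1]
    i = a[valid] - 1
    j = b[valid] - 1
    ng = q.Ng
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(float)
    counts = counts + counts.T  # symmetric
    total = counts.sum()
    if total == 0:
        return np.zeros((ng, ng))
    return counts / total


def glcm_features(
    q: QuantizedRoi, angle_deg: int, distance: int = 1
) -> tuple[pd.Series, bool]:
    """Eight GLCM statistics at one angle/distance.

    Returns the vector and a flag that is True when no valid in-mask pair
    exists at the given offset (all features are then 0).
    """
    P = glcm_matrix(q, angle_deg, distance)
    if P.sum() == 0:
        return pd.Series({s: 0.0 for s in GLCM_STATS}), True
    ng = P.shape[0]
    levels = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(levels, levels, indexing="ij")
    diff = ii - jj
    mu_x = float((ii * P).sum())
    mu_y = float((jj * P).sum())
    var_x = float(((ii - mu_x) ** 2 * P).sum())
    var_y = float(((jj - mu_y) ** 2 * P).sum())
    nz = P[P > 0]
    if var_x > 0 and var_y > 0:
        corr = float((((ii - mu_x) * (jj - mu_y) * P).sum()) / np.sqrt(var_x * var_y))
    else:
        corr = 1.0  # a constant region co-occurs with itself perfectly
    out = pd.Series(
        {
            "contrast": float((diff**2 * P).sum()),
            "dissimilarity": float((np.abs(diff) * P).sum()),
            "homogeneity": float((P / (1.0 + diff**2)).sum()),
            "asm": float((P**2).sum()),
            "entropy": float(-(nz * np.log2(nz)).sum()),
            "correlation": corr,
            "shade": float(((ii + jj - mu_x - mu_y) ** 3 * P).sum()),
            "prominence": float(((ii + jj - mu_x - mu_y) ** 4 * P).sum()),
        }
    )
    return out, False


# ---------------------------------------------------------------------------
# neighborhood gray-tone difference matrix

_KERNEL8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


def ngtdm_table(q: QuantizedRoi) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level probabilities p_i and summed differences s_i.

    A pixel contributes when it is in the mask and has at least one in-mask
    8-neighbor; its contribution to ``s`` at its own level is
    ``|level - mean neighbor level|``.
    """
    lev = q.levels.astype(float)
    mask = q.mask.astype(float)
    nbr_sum = convolve(lev * mask, _KERNEL8, mode="constant", cval=0.0)
    nbr_cnt = convolve(mask, _KERNEL8, mode="constant", cval=0.0)
    valid = q.mask & (nbr_cnt >= 1)
    mean_nbr = np.zeros_like(lev)
    mean_nbr[valid] = nbr_sum[valid] / nbr_cnt[valid]
    diff = np.abs(lev - mean_nbr)
    ng = q.Ng
    lv = q.levels[valid]
    dv = diff[valid]
    n = np.bincount(lv, minlength=ng + 1)[1:].astype(float)
    s = np.bincount(lv, weights=dv, minlength=ng + 1)[1:]
    N = int(valid.sum())
    return (n / N if N else n), s, N


def ngtdm_features(q: QuantizedRoi) -> pd.Series:
    """Coarseness, contrast, busyness, complexity and strength (NGTDM).

    Coarseness is ``1 / (eps + sum_i p_i s_i)`` with ``eps = 1e-6`` and a
    cap at 1e6, so a constant region reports the cap.
    """
    if not q.mask.any():
        raise ValidationError("cannot compute NGTDM of an empty ROI")
    p, s, N = ngtdm_table(q)
    if N == 0:
        return pd.Series({f: 0.0 for f in NGTDM_STATS})
    present = np.nonzero(p > 0)[0]
    levels = present + 1.0
    pi = p[present]
    si = s[present]
    ngp = len(present)
    ps = float((pi * si).sum())
    coarseness = min(1.0 / (_NGTDM_EPS + ps), _COARSENESS_CAP)

    if ngp > 1:
        li, lj = np.meshgrid(levels, levels, indexing="ij")
        pij = pi[:, None] * pi[None, :]
        contrast = float((pij * (li - lj) ** 2).sum() / (ngp * (ngp - 1)) * (s.sum() / N))
        denom = float(np.abs(levels[:, None] * pi[:, None] - levels[None, :] * pi[None, :]).sum())
        busyness = ps / denom if denom > 0 else 0.0
        psum = pi[:, None] * si[:, None] + pi[None, :] * si[None, :]
        complexity = float(
            (np.abs(li - lj) * psum / (pi[:, None] + pi[None, :])).sum() / N
        )
        strength = float(
            ((pi[:, None] + pi[None, :]) * (li - lj) ** 2).sum() / (_NGTDM_EPS + s.sum())
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return pd.Series(
        {
            "Coarseness": coarseness,
            "Contrast": contrast,
            "Busyness": busyness,
            "Complexity": complexity,
            "Strength": strength,
        }
    )


# ---------------------------------------------------------------------------
# banks


def _texture_names() -> list[str]:
    names = []
    for c in ("R", "G", "B"):
        for stat in GLCM_STATS:
            for ang in GLCM_ANGLES:
                names.append(f"glcm_{stat}_{ang}_{c}")
        for stat in NGTDM_STATS:
            names.append(f"{stat}_NGTDM_{c}")
    return names


TEXTURE_FEATURE_NAMES = _texture_names()
INTENSITY_FEATURE_NAMES = [
    f"firstorder_{s}_{c}" for c in ("R", "G", "B") for s in FIRSTORDER_STATS
]
CLINIC_FEATURE_NAMES = ["AreaPPA", "AreaDisc", "Tilt", "Torsion", "Dist_MD", "Angle_MD"]
assert len(TEXTURE_FEATURE_NAMES) == 111
assert len(INTENSITY_FEATURE_NAMES) == 54


def texture_bank(
    img: FundusImage, rois: RoiSet, n_levels: int = N_GRAY_LEVELS
) -> tuple[pd.Series, list[str]]:
    """111 texture features: (8 GLCM x 4 angles + 5 NGTDM) per RGB channel."""
    feats: dict[str, float] = {}
    flags: list[str] = []
    if not rois.ppa_mask.any():
        zero = pd.Series({n: 0.0 for n in TEXTURE_FEATURE_NAMES})
        return zero, list(TEXTURE_FEATURE_NAMES)
    for c in ("R", "G", "B"):
        q = quantize_roi(img.channel(c), rois.ppa_mask, n_levels)
        for ang in GLCM_ANGLES:
            vec, flagged = glcm_features(q, ang)
            for stat in GLCM_STATS:
                name = f"glcm_{stat}_{ang}_{c}"
                feats[name] = vec[stat]
                if flagged:
                    flags.append(name)
        ng = ngtdm_features(q)
        for stat in NGTDM_STATS:
            feats[f"{stat}_NGTDM_{c}"] = ng[stat]
    return pd.Series({n: feats[n] for n in TEXTURE_FEATURE_NAMES}), flags


def intensity_bank(
    img: FundusImage, rois: RoiSet, n_levels: int = N_GRAY_LEVELS
) -> tuple[pd.Series, list[str]]:
    """54 first-order intensity features: 18 statistics per RGB channel."""
    if not rois.ppa_mask.any():
        zero = pd.Series({n: 0.0 for n in INTENSITY_FEATURE_NAMES})
        return zero, list(INTENSITY_FEATURE_NAMES)
    feats: dict[str, float] = {}
    for c in ("R", "G", "B"):
        fo = firstorder_bank(img.channel(c), rois.ppa_mask, n_levels)
        for stat in FIRSTORDER_STATS:
            feats[f"firstorder_{stat}_{c}"] = fo[stat]
    return pd.Series({n: feats[n] for n in INTENSITY_FEATURE_NAMES}), []


@dataclass
class FeatureVector:
    """One eye's 322-column feature vector with category tags."""

    values: pd.Series
    categories: pd.Series
    flags: tuple[str, ...]


FEATURE_CATEGORIES = pd.Series(
    {
        **{n: "morphologic" for n in MORPHOLOGIC_FEATURE_NAMES},
        **{n: "intensity" for n in INTENSITY_FEATURE_NAMES},
        **{n: "texture" for n in TEXTURE_FEATURE_NAMES},
        **{n: "clinic" for n in CLINIC_FEATURE_NAMES},
    }
)


_FIRSTORDER_DEFS = {
    "Energy": "sum of squared intensities",
    "TotalEnergy": "energy times pixel area (unit spacing)",
    "Entropy": "Shannon entropy (bits) of the quantized histogram",
    "Uniformity": "sum of squared histogram probabilities",
}
_GLCM_DEFS = {
    "contrast": "sum (i-j)^2 P(i,j)",
    "dissimilarity": "sum |i-j| P(i,j)",
    "homogeneity": "sum P(i,j) / (1 + (i-j)^2)",
    "asm": "angular second moment, sum P^2",
    "entropy": "co-occurrence entropy (bits)",
    "correlation": "normalized co-moment of i and j",
    "shade": "third central co-moment of i+j (cluster shade)",
    "prominence": "fourth central co-moment of i+j (cluster prominence)",
}
_NGTDM_DEFS = {
    "Coarseness": "1 / (eps + sum p_i s_i), capped at 1e6",
    "Contrast": "NGTDM contrast (level spread times mean difference)",
    "Busyness": "NGTDM busyness",
    "Complexity": "NGTDM complexity",
    "Strength": "NGTDM strength",
}


def feature_metadata() -> dict[str, dict]:
    """Per-feature sidecar: category, channel, GLCM angle, definition."""
    meta: dict[str, dict] = {}
    for name, cat in FEATURE_CATEGORIES.items():
        channel = None
        angle = None
        definition = ""
        if cat == "intensity":
            _, stat, channel = name.split("_")
            definition = _FIRSTORDER_DEFS.get(stat, f"first-order {stat}")
        elif cat == "texture":
            channel = name.rsplit("_", 1)[1]
            if name.startswith("glcm_"):
                _, stat, ang, _ = name.split("_")
                angle = int(ang)
                definition = _GLCM_DEFS[stat] + f" at {ang} deg, distance 1"
            else:
                stat = name.split("_")[0]
                definition = _NGTDM_DEFS[stat]
        elif name.startswith("PPAweight"):
            channel = name[-1]
            definition = ("mean over 72 rays of the mean absolute successive "
                          "difference of the radial intensity profile")
        meta[name] = {
            "category": str(cat),
            "channel": channel,
            "angle": angle,
            "definition": definition,
        }
    return meta


def extract_feature_vector(
    img: FundusImage, rois: RoiSet, n_levels: int = N_GRAY_LEVELS
) -> FeatureVector:
    """Extract the full 322-column feature vector for one canonicalized eye.

    Order: 151 morphologic, 54 intensity, 111 texture, then the six clinic
    features re-emitted under their clinic names (their values equal the
    corresponding morphologic-bank ingredients exactly).
    """
    morph, mflags = morphologic_bank(img, rois)
    inten, iflags = intensity_bank(img, rois, n_levels)
    tex, tflags = texture_bank(img, rois, n_levels)
    clinic = clinic_features(rois).as_series()
    values = pd.concat([morph, inten, tex, clinic])
    if values.isna().any():
        raise ValidationError("feature extraction produced NaN")
    cats = FEATURE_CATEGORIES[values.index]
    return FeatureVector(values, cats, tuple(mflags + iflags + tflags))
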
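"""Synthetic fundus phantoms and tabular cohorts with plantable MM effects.

The phantom emulates the geometry and photometry the analysis assumes: an
elliptical, slightly tilted optic disc, a temporal-heavy crescent/annulus of
peripapillary atrophy (PPA), a dark macula landmark, and a tessellated
background.  Four per-eye latent drivers carry the class signal, with
per-grade means and independent per-eye jitter:

* PPA outer offset (area) — severe eyes have larger PPA;
* PPA brightness — severe PPA is brighter;
* blotch coverage — severe PPA has a denser, more complex color level
  (drives first-order entropy);
* texture correlation length — severe PPA is locally more non-uniform
  (shorter correlation length, hence lower NGTDM coarseness).

The per-grade schedules place their two largest jumps at C0→C1 and
PDCA→MDCA.  Jitters are sized so each driver alone separates the severity
groups at a standardized shift of roughly 1.2–1.5 (univariate AUC ≈ 0.8):
no single feature saturates the classifier, so combining drivers pays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .evaluation import GRADES, severity_flags
from .imaging import Contour, FundusImage, RoiSet, ValidationError

__all__ = [
    "PhantomConfig",
    "TabularSimConfig",
    "Cohort",
    "generate_phantom",
    "generate_cohort",
    "simulate_feature_table",
    "save_cohort",
]

#: Default grade shares for cohort composition, matching the published
#: distribution of a 457-eye high-myopia cohort (C0..C4 with the C2 split).
DEFAULT_GRADE_MIX = (0.096, 0.245, 0.267, 0.228, 0.098, 0.066)


@dataclass
class PhantomConfig:
    """Geometry, photometry and per-grade effect schedules of the phantom."""

    height: int = 256
    width: int = 256
    background_rgb: tuple[float, float, float] = (178.0, 105.0, 58.0)
    background_noise: float = 5.0
    background_corr_length: float = 8.0
    disc_rgb: tuple[float, float, float] = (228.0, 188.0, 135.0)
    disc_center_frac: tuple[float, float] = (0.42, 0.50)
    disc_center_sd: float = 3.0
    disc_semi_major: float = 21.0
    disc_semi_major_sd: float = 1.5
    disc_tilt_mean: float = 0.72
    disc_tilt_sd: float = 0.08
    disc_orientation_deg: float = 90.0
    disc_orientation_sd: float = 8.0
    macula_distance: float = 85.0
    macula_distance_sd: float = 6.0
    macula_angle_deg: float = 4.0
    macula_angle_sd: float = 3.0
    macula_radius: float = 8.0
    macula_depth: float = 55.0
    ppa_rgb: tuple[float, float, float] = (205.0, 165.0, 105.0)
    crescent_weight: float = 0.65  # temporal emphasis of the PPA offset
    # per-grade schedules C0, C1, PDCA, MDCA, C3, C4 and per-eye jitter SDs
    ppa_offset: tuple[float, ...] = (0.16, 0.26, 0.29, 0.40, 0.43, 0.45)
    ppa_offset_sd: float = 0.10
    ppa_brightness: tuple[float, ...] = (14.0, 20.0, 23.0, 34.0, 36.0, 38.0)
    ppa_brightness_sd: float = 9.0
    blotch_fraction: tuple[float, ...] = (0.05, 0.12, 0.15, 0.30, 0.33, 0.35)
    blotch_fraction_sd: float = 0.06
    blotch_depth: float = 45.0
    corr_length: tuple[float, ...] = (3.0, 2.7, 2.55, 2.0, 1.85, 1.75)
    corr_length_sd: float = 0.5
    texture_amplitude: float = 9.0
    texture_amplitude_sd: float = 1.5
    grade_mix: tuple[float, ...] = DEFAULT_GRADE_MIX
    left_eye_fraction: float = 0.5


@dataclass
class TabularSimConfig:
    """Gaussian location-shift feature table with planted informative set."""

    n: int = 300
    p: int = 50
    k: int = 3
    delta: float = 1.5
    balance: float = 0.5
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k > self.p:
            raise ValidationError("k must not exceed p")
        if self.delta < 0:
            raise ValidationError("delta must be non-negative")


@dataclass
class Cohort:
    images: list[FundusImage]
    roisets: list[RoiSet]
    labels: pd.DataFrame


def _grf(shape: tuple[int, int], corr_length: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field via Gaussian-kernel smoothing."""
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, corr_length, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _ellipse_contour(
    cx: float, cy: float, a: float, b: float, theta_deg: float,
    n: int = 90, radial_jitter: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Points of a rotated ellipse; theta is screen-CCW from +x (y-down)."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = np.ones(n) if radial_jitter is None else 1.0 + radial_jitter
    ex = a * np.cos(t) * r
    ey = b * np.sin(t) * r
    th = np.radians(-theta_deg)  # screen CCW = negative mathematical angle
    x = cx + ex * np.cos(th) - ey * np.sin(th)
    y = cy + ex * np.sin(th) + ey * np.cos(th)
    return np.column_stack([x, y])


def _grade_value(schedule: Sequence[float], grade: str, sd: float,
                 rng: np.random.Generator, lo: float, hi: float) -> float:
    g = GRADES.index(grade)
    return float(np.clip(schedule[g] + rng.normal(0.0, sd), lo, hi))


def generate_phantom(
    cfg: PhantomConfig,
    grade: str,
    seed: int,
    laterality: Optional[str] = None,
    eye_id: str = "eye",
    patient_id: str = "",
) -> tuple[FundusImage, RoiSet, dict]:
    """Render one phantom eye of the given META-PM grade.

    Returns the image, its ground-truth ROI set and a labels-row dict.
    The seed fully determines the output.
    """
    if grade not in GRADES:
        raise ValidationError(f"unknown grade {grade!r}")
    rng = np.random.default_rng(seed)
    h, w = cfg.height, cfg.width

    # latent per-eye drivers
    w0 = _grade_value(cfg.ppa_offset, grade, cfg.ppa_offset_sd, rng, 0.04, 0.8)
    bright = _grade_value(cfg.ppa_brightness, grade, cfg.ppa_brightness_sd, rng, 0.0, 60.0)
    pi_blotch = _grade_value(cfg.blotch_fraction, grade, cfg.blotch_fraction_sd, rng, 0.0, 0.45)
    ell_corr = _grade_value(cfg.corr_length, grade, cfg.corr_length_sd, rng, 0.9, 5.0)
    amp = float(np.clip(
        cfg.texture_amplitude + rng.normal(0.0, cfg.texture_amplitude_sd), 3.0, 18.0
    ))

    # geometry
    cx = cfg.disc_center_frac[0] * w + rng.normal(0.0, cfg.disc_center_sd)
    cy = cfg.disc_center_frac[1] * h + rng.normal(0.0, cfg.disc_center_sd)
    a = max(cfg.disc_semi_major + rng.normal(0.0, cfg.disc_semi_major_sd), 8.0)
    tilt = float(np.clip(rng.normal(cfg.disc_tilt_mean, cfg.disc_tilt_sd), 0.45, 0.92))
    b = a * tilt
    theta = cfg.disc_orientation_deg + rng.normal(0.0, cfg.disc_orientation_sd)
    d_mac = max(cfg.macula_distance + rng.normal(0.0, cfg.macula_distance_sd), 3.0 * a)
    ang_mac = np.radians(cfg.macula_angle_deg + rng.normal(0.0, cfg.macula_angle_sd))
    mx = cx + d_mac * np.cos(ang_mac)
    my = cy + d_mac * np.sin(ang_mac)  # positive angle: macula below horizontal

    t = np.linspace(0.0, 2.0 * np.pi, 90, endpoint=False)
    wobble = gaussian_filter(rng.standard_normal(90), 4, mode="wrap")
    wobble = wobble - wobble.mean()  # pure shape perturbation, area-neutral
    wobble = 0.012 * wobble / max(wobble.std(), 1e-9)
    disc_pts = _ellipse_contour(cx, cy, a, b, theta, 90, wobble)

    # PPA outer boundary: disc scaled radially, crescent-heavy toward macula
    theta_t = np.arctan2(my - cy, mx - cx)
    cres = (1.0 + np.cos(t - theta_t)) / 2.0
    offset = w0 * ((1.0 - cfg.crescent_weight) + cfg.crescent_weight * cres)
    offs_noise = gaussian_filter(rng.standard_normal(90), 6, mode="wrap")
    offs_noise = offs_noise - offs_noise.mean()
    offset = np.maximum(offset + 0.02 * offs_noise / max(offs_noise.std(), 1e-9), 0.015)
    outer_pts = _ellipse_contour(cx, cy, a, b, theta, 90, wobble + offset)

    for pts, what in ((disc_pts, "disc"), (outer_pts, "PPA")):
        if (pts[:, 0].min() < 1 or pts[:, 1].min() < 1
                or pts[:, 0].max() > w - 2 or pts[:, 1].max() > h - 2):
            raise ValidationError(f"{what} geometry overflows the frame")
    if not (1 <= mx < w - 1 and 1 <= my < h - 1):
        raise ValidationError("macula falls outside the frame")

    rois = RoiSet.from_contours(
        Contour(disc_pts), Contour(outer_pts), (float(mx), float(my)), (h, w)
    )

    # rendering
    img = np.empty((h, w, 3), dtype=np.float64)
    bg_field = _grf((h, w), cfg.background_corr_length, rng) * cfg.background_noise
    for c in range(3):
        img[:, :, c] = cfg.background_rgb[c] + bg_field

    tex = _grf((h, w), ell_corr, rng) * amp
    blotch_field = _grf((h, w), 5.0, rng)
    thr = np.quantile(blotch_field, 1.0 - pi_blotch) if pi_blotch > 0 else np.inf
    blotch = blotch_field >= thr
    chan_w = (1.0, 0.85, 0.7)
    ppa = rois.ppa_mask
    # blotches are mean-compensated: they widen the intensity histogram
    # (heterogeneity driver) without confounding the brightness driver
    blotch_offset = (blotch.astype(float) - pi_blotch) * cfg.blotch_depth
    for c in range(3):
        img[:, :, c][ppa] = (
            cfg.ppa_rgb[c]
            + bright * chan_w[c]
            + tex[ppa] * (1.0, 0.9, 0.8)[c]
            - blotch_offset[ppa] * chan_w[c]
        )
    disc = rois.disc_mask
    for c in range(3):
        img[:, :, c][disc] = cfg.disc_rgb[c] + 0.5 * tex[disc]

    # dark macula spot (smooth radial dip)
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (xx + 0.5 - mx) ** 2 + (yy + 0.5 - my) ** 2
    dip = cfg.macula_depth * np.exp(-r2 / (2.0 * cfg.macula_radius**2))
    img -= dip[:, :, None]

    img += rng.normal(0.0, 1.0, (h, w, 3))  # sensor noise
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    if laterality is None:
        laterality = "left" if rng.random() < cfg.left_eye_fraction else "right"
    if laterality == "left":
        pixels = pixels[:, ::-1, :].copy()

        def flip(pts: np.ndarray) -> np.ndarray:
            out = pts.copy()
            out[:, 0] = (w - 1) - out[:, 0]
            return out

        rois = RoiSet(
            Contour(flip(rois.disc_contour.points)),
            Contour(flip(rois.ppa_outer_contour.points)),
            ((w - 1) - rois.macula[0], rois.macula[1]),
            rois.disc_mask[:, ::-1].copy(),
            rois.ppa_mask[:, ::-1].copy(),
        )

    fi = FundusImage(pixels, laterality, eye_id, patient_id)
    label = {
        "eye_id": eye_id,
        "patient_id": patient_id or eye_id,
        "laterality": laterality,
        "grade": grade,
        "plus_lesion": 0,
        # ground-truth latents, for geometry-recovery checks
        "true_disc_semi_major": a,
        "true_disc_semi_minor": b,
        "true_ppa_offset": w0,
        "true_brightness": bright,
        "true_blotch_fraction": pi_blotch,
        "true_corr_length": ell_corr,
    }
    return fi, rois, label


def generate_cohort(cfg: PhantomConfig, n: int, seed: int) -> Cohort:
    """Generate ``n`` phantom eyes with the configured grade mix."""
    if n < 10:
        raise ValidationError("a cohort needs at least 10 eyes")
    rng = np.random.default_rng(seed)
    mix = np.asarray(cfg.grade_mix, dtype=float)
    mix = mix / mix.sum()
    grade_idx = rng.choice(len(GRADES), size=n, p=mix)
    child_seeds = np.random.SeedSequence(seed).spawn(n)
    images, roisets, rows = [], [], []
    for i in range(n):
        eye_seed = int(child_seeds[i].generate_state(1)[0] % (2**31))
        img, rois, row = generate_phantom(
            cfg,
            GRADES[grade_idx[i]],
            eye_seed,
            eye_id=f"eye{i:04d}",
            patient_id=f"pat{i // 2:04d}",
        )
        images.append(img)
        roisets.append(rois)
        rows.append(row)
    labels = pd.DataFrame(rows)
    labels["severe"] = severity_flags(labels)
    return Cohort(images, roisets, labels)


def simulate_feature_table(
    cfg: TabularSimConfig,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Class-conditional Gaussian feature table with ``k`` planted features.

    Informative features are N(0,1) in class 0 and N(delta,1) in class 1
    (optionally equicorrelated); noise features are N(0,1) regardless of
    class.  Returns (X, y, informative mask).
    """
    rng = np.random.default_rng(cfg.seed)
    y = (rng.random(cfg.n) < cfg.balance).astype(int)
    X = rng.standard_normal((cfg.n, cfg.p))
    if cfg.k and cfg.correlation > 0:
        shared = rng.standard_normal(cfg.n)
        rho = cfg.correlation
        X[:, : cfg.k] = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * X[:, : cfg.k]
    X[:, : cfg.k] += cfg.delta * y[:, None]
    truth = np.zeros(cfg.p, dtype=bool)
    truth[: cfg.k] = True
    cols = [f"f{j:03d}" for j in range(cfg.p)]
    return pd.DataFrame(X, columns=cols), y, truth


def save_cohort(cohort: Cohort, outdir: str | Path, cfg: Optional[PhantomConfig] = None,
                seed: Optional[int] = None) -> None:
    """Write images (PNG), annotations (JSON), labels (CSV) and a manifest."""
    import yaml
    from PIL import Image

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "annotations").mkdir(parents=True, exist_ok=True)
    for img, rois in zip(cohort.images, cohort.roisets):
        Image.fromarray(img.pixels).save(outdir / "images" / f"{img.eye_id}.png")
        ann = {
            "disc": rois.disc_contour.points.tolist(),
            "ppa": rois.ppa_outer_contour.points.tolist()
            if rois.ppa_outer_contour is not None
            else None,
            "macula": list(rois.macula),
        }
        with open(outdir / "annotations" / f"{img.eye_id}.json", "w") as fh:
            json.dump(ann, fh)
    cols = ["eye_id", "patient_id", "laterality", "grade", "plus_lesion"]
    cohort.labels[cols].to_csv(outdir / "labels.csv", index=False)
    manifest = {
        "n_eyes": len(cohort.images),
        "seed": seed,
        "config": None if cfg is None else {k: (list(v) if isinstance(v, tuple) else v)
                                            for k, v in vars(cfg).items()},
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
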
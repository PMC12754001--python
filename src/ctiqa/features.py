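"""The 39-feature no-reference quality descriptor for a CT slice.

Feature groups and the view of the image each is computed on:

* intensity (10) — pixel statistics of the [0, 1] float view;
* distribution (3) — 256-bin histogram statistics of the 8-bit view;
* edge (7) — Sobel gradient statistics, Canny edge count, and shape
  descriptors of the largest Otsu-foreground component;
* diagnostic (5) — sharpness (Laplacian variance), tissue density,
  texture heterogeneity, SNR and CNR of foreground vs background;
* frequency (5) — 2-D DFT magnitude statistics, DC term excluded;
* lbp (2) — mean/variance of classic 8-point radius-1 LBP codes;
* glcm (7) — Haralick-style statistics of the gray-level co-occurrence
  matrix at distance 1, angle 0°.

All extractors are deterministic; degenerate (e.g. constant) images
produce documented fallback values rather than NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import canny, graycomatrix
from skimage.filters import sobel, threshold_otsu
from skimage.measure import label
from skimage.measure import perimeter as crofton_perimeter
from skimage.morphology import closing, footprint_rectangle

from ._errors import ValidationError
from .io_prep import GrayImage

__all__ = [
    "FEATURE_NAMES",
    "GLCMatrix",
    "intensity_features",
    "distribution_features",
    "edge_map",
    "edge_features",
    "diagnostic_features",
    "frequency_features",
    "compute_glcm",
    "glcm_features",
    "lbp_codes",
    "lbp_features",
    "extract_all",
    "features_to_table",
    "table_from_images",
]

#: Canonical 39-feature column order.  Every table and model in the
#: package uses exactly this ordering.
FEATURE_NAMES: tuple[str, ...] = (
    # intensity (10)
    "int_min", "int_max", "int_mean", "int_median", "int_std",
    "int_range", "int_skewness", "int_kurtosis", "int_p10", "int_p90",
    # distribution (3)
    "hist_entropy", "hist_energy", "hist_mode",
    # edge (7)
    "edge_mean", "edge_variance", "edge_count",
    "region_area", "region_perimeter", "region_circularity", "region_compactness",
    # diagnostic (5)
    "sharpness_score", "tissue_density", "texture_heterogeneity", "snr", "cnr",
    # frequency (5)
    "freq_sum", "freq_max", "freq_mean", "spectral_flatness", "high_freq_sum",
    # lbp (2)
    "lbp_mean", "lbp_variance",
    # glcm (7)
    "glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_homogeneity",
    "glcm_dissimilarity", "glcm_entropy", "glcm_max_probability",
)

_EPS_POWER = 1e-12  # additive floor for the power spectrum in flatness


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized gray-level co-occurrence matrix at one (distance, angle)."""

    probabilities: np.ndarray  # L×L, entries ≥ 0, summing to 1
    distance: int = 1
    angle_deg: int = 0


# ---------------------------------------------------------------- intensity

def intensity_features(img: GrayImage) -> dict[str, float]:
    """First-order pixel statistics of the float view.

    Skewness is E[(x−μ)³]/σ³ and kurtosis the excess E[(x−μ)⁴]/σ⁴ − 3
    (population moments); both are defined as 0 for a constant image.
    """
    x = img.pixels_float.ravel()
    mu = float(x.mean())
    sigma = float(x.std())
    if sigma > 0.0:
        z = (x - mu) / sigma
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    else:
        skew = kurt = 0.0
    return {
        "int_min": float(x.min()),
        "int_max": float(x.max()),
        "int_mean": mu,
        "int_median": float(np.median(x)),
        "int_std": sigma,
        "int_range": float(x.max() - x.min()),
        "int_skewness": skew,
        "int_kurtosis": kurt,
        "int_p10": float(np.percentile(x, 10)),
        "int_p90": float(np.percentile(x, 90)),
    }


# ------------------------------------------------------------- distribution

def distribution_features(img: GrayImage) -> dict[str, float]:
    """Entropy (bits), energy and mode of the 256-bin 8-bit histogram.

    Ties in the mode resolve to the smallest intensity.
    """
    counts = np.bincount(img.pixels_u8.ravel(), minlength=256)
    p = counts / counts.sum()
    nz = p[p > 0]
    return {
        "hist_entropy": float(-np.sum(nz * np.log2(nz))),
        "hist_energy": float(np.sum(p**2)),
        "hist_mode": float(np.argmax(counts)),  # argmax takes first max
    }


# --------------------------------------------------------------------- edge

def edge_map(img: GrayImage) -> np.ndarray:
    """Binary Canny edge map (σ = 1.0, hysteresis at the 70th/90th
    gradient-magnitude quantiles)."""
    if img.pixels_float.max() == img.pixels_float.min():
        return np.zeros_like(img.pixels_float, dtype=bool)
    return canny(
        img.pixels_float,
        sigma=1.0,
        low_threshold=0.70,
        high_threshold=0.90,
        use_quantiles=True,
    )


def _foreground_mask(u8: np.ndarray) -> np.ndarray:
    """Otsu foreground of the 8-bit view; all-False for a constant image."""
    if u8.max() == u8.min():
        return np.zeros_like(u8, dtype=bool)
    return u8 > threshold_otsu(u8)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lbl, n = label(mask, return_num=True)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(lbl.ravel())
    sizes[0] = 0
    return lbl == int(np.argmax(sizes))


def edge_features(img: GrayImage) -> dict[str, float]:
    """Gradient statistics plus shape descriptors of the dominant region.

    ``edge_mean``/``edge_variance`` are statistics of the Sobel gradient
    magnitude; ``edge_count`` counts Canny edge pixels.  The region is the
    largest connected component of the morphologically closed (3×3) Otsu
    foreground; its perimeter is the Crofton-weighted boundary estimate,
    so a discretized disc scores circularity ≈ 1.
    """
    grad = sobel(img.pixels_float)
    edges = edge_map(img)
    region = _largest_component(closing(_foreground_mask(img.pixels_u8),
                                        footprint_rectangle((3, 3))))
    area = float(region.sum())
    if area > 0:
        perim = float(crofton_perimeter(region))
    else:
        perim = 0.0
    if area > 0 and perim > 0:
        circ = 4.0 * np.pi * area / perim**2
        compact = perim**2 / area
    else:
        circ = compact = 0.0
    return {
        "edge_mean": float(grad.mean()),
        "edge_variance": float(grad.var()),
        "edge_count": float(edges.sum()),
        "region_area": area,
        "region_perimeter": perim,
        "region_circularity": circ,
        "region_compactness": compact,
    }


# --------------------------------------------------------------- diagnostic

_LAPLACIAN_4 = np.array([[0.0, 1.0, 0.0],
                         [1.0, -4.0, 1.0],
                         [0.0, 1.0, 0.0]])


def diagnostic_features(img: GrayImage) -> dict[str, float]:
    """Sharpness, tissue density, texture heterogeneity, SNR and CNR.

    sharpness_score — variance of the 4-neighbor Laplacian response;
    tissue_density — mean float intensity inside the Otsu foreground;
    texture_heterogeneity — mean local standard deviation (7×7 window);
    snr — μ/σ over the foreground; cnr — (μ_fg − μ_bg)/σ_bg.
    Degenerate masks or zero denominators yield 0.
    """
    x = img.pixels_float
    lap = ndimage.convolve(x, _LAPLACIAN_4, mode="reflect")
    sharpness = float(lap.var())

    win = 7
    local_mean = ndimage.uniform_filter(x, size=win, mode="reflect")
    local_sq = ndimage.uniform_filter(x**2, size=win, mode="reflect")
    local_var = np.maximum(local_sq - local_mean**2, 0.0)
    heterogeneity = float(np.sqrt(local_var).mean())

    fg = _foreground_mask(img.pixels_u8)
    bg = ~fg
    if fg.any():
        mu_fg = float(x[fg].mean())
        sd_fg = float(x[fg].std())
    else:
        mu_fg = sd_fg = 0.0
    tissue_density = mu_fg
    snr = mu_fg / sd_fg if sd_fg > 0 else 0.0
    if fg.any() and bg.any():
        mu_bg = float(x[bg].mean())
        sd_bg = float(x[bg].std())
        cnr = (mu_fg - mu_bg) / sd_bg if sd_bg > 0 else 0.0
    else:
        cnr = 0.0
    return {
        "sharpness_score": sharpness,
        "tissue_density": tissue_density,
        "texture_heterogeneity": heterogeneity,
        "snr": snr,
        "cnr": cnr,
    }


# ---------------------------------------------------------------- frequency

def frequency_features(img: GrayImage) -> dict[str, float]:
    """Statistics of the 2-D DFT magnitude spectrum, DC term excluded.

    Spectral flatness is the geometric-to-arithmetic mean ratio of the
    power spectrum (magnitude² + 1e−12): 1 for a flat (white) spectrum,
    near 0 for tonal content.  ``high_freq_sum`` sums the magnitudes
    strictly above the mean magnitude.
    """
    spec = np.fft.fft2(img.pixels_float)
    mag = np.abs(spec).ravel()
    mag = np.delete(mag, 0)  # index 0 of the flattened spectrum is DC
    power = mag**2 + _EPS_POWER
    flatness = float(np.exp(np.mean(np.log(power))) / np.mean(power))
    mean_mag = float(mag.mean())
    return {
        "freq_sum": float(mag.sum()),
        "freq_max": float(mag.max()),
        "freq_mean": mean_mag,
        "spectral_flatness": flatness,
        "high_freq_sum": float(mag[mag > mean_mag].sum()),
    }


# --------------------------------------------------------------------- GLCM

def compute_glcm(img: GrayImage, d: int = 1, theta_deg: int = 0,
                 levels: int = 256) -> GLCMatrix:
    """Gray-level co-occurrence matrix of the 8-bit view.

    Pairs are counted at offset ``d`` along angle ``theta_deg`` (0° is the
    horizontal (0, +d) offset); the matrix is normalized to probabilities
    and not symmetrized.  Gray levels are rescaled to ``levels`` bins by
    integer division of the 0–255 range.
    """
    if not 8 <= levels <= 256:
        raise ValidationError(f"levels must be in [8, 256], got {levels}")
    if d < 1:
        raise ValidationError(f"distance must be ≥ 1, got {d}")
    if d >= img.side:
        raise ValidationError(f"distance {d} ≥ image side {img.side}")
    u8 = img.pixels_u8
    if levels < 256:
        u8 = (u8.astype(np.int64) * levels // 256).astype(np.uint8)
    counts = graycomatrix(
        u8, distances=[d], angles=[np.deg2rad(theta_deg)],
        levels=levels, symmetric=False, normed=False,
    )[:, :, 0, 0].astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValidationError("no co-occurring pairs at this offset")
    return GLCMatrix(probabilities=counts / total, distance=d, angle_deg=theta_deg)


def glcm_features(g: GLCMatrix) -> dict[str, float]:
    """Contrast, correlation, energy, homogeneity, dissimilarity, entropy
    and maximum probability of a normalized co-occurrence matrix.

    Correlation is defined as 1 when either marginal is degenerate
    (σᵢσⱼ = 0, e.g. the single-cell matrix of a constant image).
    """
    p = g.probabilities
    L = p.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    diff = i - j
    contrast = float(np.sum(p * diff**2))
    dissimilarity = float(np.sum(p * np.abs(diff)))
    homogeneity = float(np.sum(p / (1.0 + diff**2)))
    energy = float(np.sum(p**2))
    max_prob = float(p.max())
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(np.arange(L) * pi))
    mu_j = float(np.sum(np.arange(L) * pj))
    var_i = float(np.sum((np.arange(L) - mu_i) ** 2 * pi))
    var_j = float(np.sum((np.arange(L) - mu_j) ** 2 * pj))
    denom = np.sqrt(var_i * var_j)
    if denom > 0:
        correlation = float(np.sum(p * (i - mu_i) * (j - mu_j)) / denom)
    else:
        correlation = 1.0
    return {
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_energy": energy,
        "glcm_homogeneity": homogeneity,
        "glcm_dissimilarity": dissimilarity,
        "glcm_entropy": entropy,
        "glcm_max_probability": max_prob,
    }


# ---------------------------------------------------------------------- LBP

def lbp_codes(u8: np.ndarray, radius: int = 1, points: int = 8) -> np.ndarray:
    """Classic (non-rotation-invariant) LBP code image.

    Neighbors are sampled on a circle of ``radius`` at angles 2πk/points
    starting at 0° (east) and proceeding counter-clockwise, with bilinear
    interpolation at non-integer positions; bit k is set when the neighbor
    is ≥ the center.  A border of width ``radius`` is excluded, so the
    output is smaller than the input by 2·radius per side.
    """
    u8 = np.asarray(u8)
    h, w = u8.shape
    if h <= 2 * radius + 1 or w <= 2 * radius + 1:
        raise ValidationError(
            f"image {u8.shape} too small for LBP radius {radius}"
        )
    x = u8.astype(np.float64)
    center = x[radius:h - radius, radius:w - radius]
    codes = np.zeros_like(center, dtype=np.int64)
    rows = np.arange(radius, h - radius)[:, None]
    cols = np.arange(radius, w - radius)[None, :]
    for k in range(points):
        theta = 2.0 * np.pi * k / points
        # image rows grow downwards: counter-clockwise on screen = −sin on
        # rows.  Offsets are rounded to 8 decimals so axis-aligned neighbors
        # land exactly on pixel centers.
        dr = round(-radius * float(np.sin(theta)), 8)
        dc = round(radius * float(np.cos(theta)), 8)
        rr = rows + dr
        cc = cols + dc
        r0 = np.floor(rr).astype(np.int64)
        c0 = np.floor(cc).astype(np.int64)
        fr = rr - r0
        fc = cc - c0
        r1 = np.minimum(r0 + 1, h - 1)
        c1 = np.minimum(c0 + 1, w - 1)
        val = (
            x[r0, c0] * (1 - fr) * (1 - fc)
            + x[r0, c1] * (1 - fr) * fc
            + x[r1, c0] * fr * (1 - fc)
            + x[r1, c1] * fr * fc
        )
        # small slack so interpolation round-off cannot clear the bit when
        # neighbor and center are equal (e.g. a constant image → code 255)
        codes += (val - center >= -1e-6).astype(np.int64) << k
    return codes


def lbp_features(img: GrayImage, radius: int = 1, points: int = 8) -> dict[str, float]:
    """Mean and variance of the LBP code image of the 8-bit view."""
    codes = lbp_codes(img.pixels_u8, radius=radius, points=points)
    return {"lbp_mean": float(codes.mean()), "lbp_variance": float(codes.var())}


# ------------------------------------------------------------------ summary

def extract_all(img: GrayImage) -> dict[str, float]:
    """All 39 features in the canonical order, as an ordered name→value map."""
    vec: dict[str, float] = {}
    vec.update(intensity_features(img))
    vec.update(distribution_features(img))
    vec.update(edge_features(img))
    vec.update(diagnostic_features(img))
    vec.update(frequency_features(img))
    vec.update(lbp_features(img))
    vec.update(glcm_features(compute_glcm(img)))
    return {name: vec[name] for name in FEATURE_NAMES}


def features_to_table(vectors: list[dict[str, float]],
                      scores: list[float] | np.ndarray | None = None) -> pd.DataFrame:
    """Assemble feature vectors (and optionally scores) into a table.

    Columns are the 39 canonical feature names, plus a trailing ``score``
    column when scores are given.
    """
    if scores is not None and len(scores) != len(vectors):
        raise ValidationError(
            f"{len(vectors)} vectors but {len(scores)} scores"
        )
    df = pd.DataFrame(
        [[v[name] for name in FEATURE_NAMES] for v in vectors],
        columns=list(FEATURE_NAMES),
        dtype=np.float64,
    )
    if scores is not None:
        df["score"] = np.asarray(scores, dtype=np.float64)
    return df


def table_from_images(images: list[GrayImage],
                      scores: list[float] | np.ndarray | None = None) -> pd.DataFrame:
    """Extract features from each image and tabulate them."""
    return features_to_table([extract_all(im) for im in images], scores)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a feature table as CSV with 12 significant digits."""
    df.to_csv(path, index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    """Read a feature table CSV written by :func:`write_table`."""
    return pd.read_csv(path)
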
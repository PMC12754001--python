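"""Image loading, preprocessing and score-manifest I/O.

Every downstream stage consumes :class:`GrayImage`: a square, grayscale
image held both as a min–max normalized float array in [0, 1] and as its
8-bit quantization.  The preprocessing pipeline is resize (bilinear, both
axes forced to the target side) → per-image min–max normalization → 8-bit
quantization, in that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

from ._errors import FormatError, ValidationError

__all__ = [
    "RawImage",
    "GrayImage",
    "ScoreManifest",
    "load_image",
    "preprocess",
    "read_manifest",
    "write_manifest",
]

logger = logging.getLogger(__name__)

DEFAULT_SIDE = 224
SCORE_MIN, SCORE_MAX = 0.0, 4.0


@dataclass(frozen=True)
class RawImage:
    """A grayscale image as read from disk, at its native size and scale."""

    pixels: np.ndarray  # 2-D float64, non-negative, finite
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValidationError(f"RawImage requires a 2-D array, got ndim={px.ndim}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValidationError(f"image too small: {px.shape} (minimum 8×8)")
        if not np.all(np.isfinite(px)):
            raise ValidationError("image contains non-finite intensities")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GrayImage:
    """Preprocessed square image: float view in [0, 1] plus 8-bit view.

    The u8 view is always ``round(pixels_float * 255)``; constructing one
    view derives the other.
    """

    pixels_float: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels_float, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValidationError(f"GrayImage must be square 2-D, got shape {px.shape}")
        if px.shape[0] < 8:
            raise ValidationError(f"GrayImage side {px.shape[0]} < 8")
        if not np.all(np.isfinite(px)):
            raise ValidationError("GrayImage contains non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError(
                f"GrayImage float view outside [0,1]: [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels_float", px)

    @property
    def pixels_u8(self) -> np.ndarray:
        return np.round(self.pixels_float * 255.0).astype(np.uint8)

    @property
    def side(self) -> int:
        return self.pixels_float.shape[0]


@dataclass(frozen=True)
class ScoreManifest:
    """Ordered (image path, quality score) pairs; scores lie in [0, 4]."""

    entries: tuple[tuple[str, float], ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def paths(self) -> list[str]:
        return [p for p, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=np.float64)


def load_image(path: str | Path) -> RawImage:
    """Read a TIFF or PNG image into a :class:`RawImage`.

    Multi-channel inputs are reduced to grayscale by averaging channels.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im, dtype=np.float64)
    except Exception as exc:  # corrupt / not an image
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"zero-sized image: {path}")
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    elif arr.ndim != 2:
        raise FormatError(f"unsupported image dimensionality {arr.ndim} in {path}")
    return RawImage(pixels=arr, source_path=str(path))


def preprocess(raw: RawImage, side: int = DEFAULT_SIDE) -> GrayImage:
    """Resize to ``side``×``side`` (bilinear), min–max normalize to [0, 1].

    A constant input maps to the all-zero image (the min–max scale is
    degenerate there).  The 8-bit view is derived from the float view.
    """
    if side < 8:
        raise ValidationError(f"side must be ≥ 8, got {side}")
    px = resize(
        raw.pixels,
        (side, side),
        order=1,  # bilinear
        mode="reflect",
        anti_aliasing=False,
        preserve_range=True,
    )
    lo, hi = float(px.min()), float(px.max())
    if hi > lo:
        px = (px - lo) / (hi - lo)
    else:
        px = np.zeros_like(px)
    return GrayImage(pixels_float=np.clip(px, 0.0, 1.0))


def read_manifest(path: str | Path) -> ScoreManifest:
    """Parse a CSV score manifest with header columns ``image,score``.

    Scores are validated against the [0, 4] range; image paths must be
    unique.  Relative image paths are interpreted relative to the CSV's
    directory by the callers that load the images.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise IOError(f"cannot read manifest {path}: {exc}") from exc
    for col in ("image", "score"):
        if col not in df.columns:
            raise FormatError(f"manifest {path} is missing required column '{col}'")
    if len(df) == 0:
        logger.warning("manifest %s contains no entries", path)
        return ScoreManifest(entries=())
    bad = df.index[(df["score"] < SCORE_MIN) | (df["score"] > SCORE_MAX) | df["score"].isna()]
    if len(bad) > 0:
        # +2: header line plus 1-based numbering
        raise ValidationError(
            f"manifest {path}: score outside [0,4] at CSV row {int(bad[0]) + 2}"
        )
    if df["image"].duplicated().any():
        dup = df["image"][df["image"].duplicated()].iloc[0]
        raise ValidationError(f"manifest {path}: duplicate image path '{dup}'")
    entries = tuple((str(r.image), float(r.score)) for r in df.itertuples(index=False))
    return ScoreManifest(entries=entries)


def write_manifest(manifest: ScoreManifest, path: str | Path) -> None:
    """Write a manifest in the same CSV dialect ``read_manifest`` accepts."""
    df = pd.DataFrame(manifest.entries, columns=["image", "score"])
    df.to_csv(path, index=False, float_format="%.12g")
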
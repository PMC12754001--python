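"""Synthetic abdominal-CT-like phantoms with controlled degradations.

The generator emulates the structure of a scored low-dose CT dataset:
a clean soft-tissue-window slice (body ellipse, a few organ ellipses, a
bright bone rim) degraded on a 4×4 grid of noise and streak-artifact
levels, optionally blurred, and assigned a ground-truth quality score
on the radiologist 0–4 scale that decreases monotonically with each
degradation.  All randomness is driven by explicit seeds, so every
sample is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.draw import ellipse, ellipse_perimeter, line

from ._errors import ValidationError
from .io_prep import DEFAULT_SIDE, GrayImage, ScoreManifest, write_manifest

__all__ = [
    "PhantomSpec",
    "SyntheticSample",
    "NOISE_SIGMAS",
    "make_clean_phantom",
    "degrade",
    "ground_truth_score",
    "make_sample",
    "make_dataset",
]

#: Additive Gaussian noise σ (on the [0,1] scale) for levels 0–3.
NOISE_SIGMAS = (0.00, 0.02, 0.05, 0.10)
#: Streak lines per artifact level; amplitudes alternate ±0.15.
STREAKS_PER_LEVEL = 4
STREAK_AMPLITUDE = 0.15
#: Blur sigmas sampled by make_dataset.
DATASET_BLUR_SIGMAS = (0.0, 0.5, 1.0)

# Score model: 4 − 0.8·noise − 0.5·artifact − 0.6·blur + Uniform(−.15,.15),
# clipped to [0,4].  Coefficients span the full 0–4 band over the 16-cell
# grid with blur up to 1.
_W_NOISE, _W_ARTIFACT, _W_BLUR, _RATER_HALFWIDTH = 0.8, 0.5, 0.6, 0.15


@dataclass(frozen=True)
class PhantomSpec:
    """Degradation parameters plus the seed driving their randomness."""

    noise_level: int = 0
    artifact_level: int = 0
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_level not in (0, 1, 2, 3):
            raise ValidationError(f"noise_level must be 0–3, got {self.noise_level}")
        if self.artifact_level not in (0, 1, 2, 3):
            raise ValidationError(f"artifact_level must be 0–3, got {self.artifact_level}")
        if self.blur_sigma < 0:
            raise ValidationError(f"blur_sigma must be ≥ 0, got {self.blur_sigma}")


@dataclass(frozen=True)
class SyntheticSample:
    """One generated image with its spec and ground-truth score."""

    image: GrayImage
    spec: PhantomSpec
    score: float


def make_clean_phantom(seed: int, side: int = DEFAULT_SIDE) -> GrayImage:
    """An undegraded slice: dark background, bright body ellipse, 2–5
    interior 'organ' ellipses of varying intensity, and a high-intensity
    arc standing in for a bone rim.  Deterministic in seed."""
    if side < 64:
        raise ValidationError(f"side must be ≥ 64, got {side}")
    rng = np.random.default_rng(seed)
    img = np.full((side, side), 0.05, dtype=np.float64)
    c = side / 2.0
    body_r = (rng.uniform(0.33, 0.40) * side, rng.uniform(0.38, 0.45) * side)
    rr, cc = ellipse(c, c, *body_r, shape=img.shape)
    img[rr, cc] = rng.uniform(0.40, 0.50)

    n_organs = rng.integers(2, 6)
    for _ in range(n_organs):
        oc = (c + rng.uniform(-0.15, 0.15) * side,
              c + rng.uniform(-0.18, 0.18) * side)
        orad = (rng.uniform(0.05, 0.14) * side, rng.uniform(0.05, 0.14) * side)
        rr, cc = ellipse(*oc, *orad, shape=img.shape,
                         rotation=rng.uniform(0, np.pi))
        img[rr, cc] = rng.uniform(0.25, 0.75)

    # bone rim: bright arc along the upper body boundary (spine/rib analogue)
    rim_r = (int(body_r[0] * 0.92), int(body_r[1] * 0.92))
    rr, cc = ellipse_perimeter(int(c), int(c), *rim_r, shape=img.shape)
    arc = rr < c  # keep the upper half
    rr, cc = rr[arc], cc[arc]
    for dr in (-1, 0, 1):
        rsel = np.clip(rr + dr, 0, side - 1)
        img[rsel, cc] = 0.95

    img = ndimage.gaussian_filter(img, sigma=1.5)  # soft anatomy boundaries
    return GrayImage(pixels_float=np.clip(img, 0.0, 1.0))


def degrade(img: GrayImage, spec: PhantomSpec) -> GrayImage:
    """Apply the spec's degradations: Gaussian noise by level, straight
    streak artifacts of alternating sign, optional Gaussian blur; the
    result is clipped back to [0, 1].  Pure in (img, spec)."""
    rng = np.random.default_rng(spec.seed)
    x = img.pixels_float.copy()
    side = x.shape[0]

    n_streaks = spec.artifact_level * STREAKS_PER_LEVEL
    for s in range(n_streaks):
        edge_a, edge_b = rng.choice(4, size=2, replace=False)

        def _pt(which: int) -> tuple[int, int]:
            t = int(rng.integers(0, side))
            return [(0, t), (side - 1, t), (t, 0), (t, side - 1)][which]

        r0, c0 = _pt(edge_a)
        r1, c1 = _pt(edge_b)
        rr, cc = line(r0, c0, r1, c1)
        amp = STREAK_AMPLITUDE if s % 2 == 0 else -STREAK_AMPLITUDE
        x[rr, cc] += amp

    sigma = NOISE_SIGMAS[spec.noise_level]
    if sigma > 0:
        x = x + rng.normal(0.0, sigma, size=x.shape)

    # blur last: a soft reconstruction smooths anatomy, streaks and noise
    if spec.blur_sigma > 0:
        x = ndimage.gaussian_filter(x, sigma=spec.blur_sigma)

    return GrayImage(pixels_float=np.clip(x, 0.0, 1.0))


def ground_truth_score(spec: PhantomSpec) -> float:
    """Quality score on the 0–4 radiologist scale for a degradation spec.

    Linear in the degradation levels plus a small seeded uniform
    'rater-noise' term, clipped to [0, 4]; monotone non-increasing in
    noise, artifact and blur at fixed rater noise.
    """
    rng = np.random.default_rng(spec.seed + 1_000_003)  # decouple from pixels
    u = rng.uniform(-_RATER_HALFWIDTH, _RATER_HALFWIDTH)
    raw = (4.0 - _W_NOISE * spec.noise_level - _W_ARTIFACT * spec.artifact_level
           - _W_BLUR * spec.blur_sigma + u)
    return float(np.clip(raw, 0.0, 4.0))


def make_sample(spec: PhantomSpec, side: int = DEFAULT_SIDE) -> SyntheticSample:
    """Generate one degraded phantom with its ground-truth score."""
    clean = make_clean_phantom(seed=spec.seed, side=side)
    return SyntheticSample(
        image=degrade(clean, spec),
        spec=spec,
        score=ground_truth_score(spec),
    )


def dataset_specs(n: int, seed: int) -> list[PhantomSpec]:
    """The n degradation specs make_dataset realizes: the 16 (noise,
    artifact) cells tiled evenly over n, blur drawn from {0, 0.5, 1.0},
    order shuffled, all seeded."""
    if n < 16:
        raise ValidationError(f"n must be ≥ 16, got {n}")
    rng = np.random.default_rng(seed)
    cells = [(nl, al) for nl in range(4) for al in range(4)]
    grid = (cells * ((n + 15) // 16))[:n]
    blur = rng.choice(DATASET_BLUR_SIGMAS, size=n)
    order = rng.permutation(n)
    specs = []
    for i in range(n):
        nl, al = grid[order[i]]
        specs.append(PhantomSpec(
            noise_level=nl, artifact_level=al, blur_sigma=float(blur[i]),
            seed=int((seed * 1_000_003 + i) % (2**31 - 1)),
        ))
    return specs


def make_dataset(n: int, seed: int, out_dir: str | Path | None = None,
                 side: int = DEFAULT_SIDE) -> tuple[ScoreManifest, list[SyntheticSample]]:
    """Generate a scored phantom dataset, optionally writing it to disk.

    The 16 (noise, artifact) combinations appear n/16 times each (up to
    remainder), with blur σ sampled from {0, 0.5, 1.0}.  When ``out_dir``
    is given, 8-bit TIFFs and a CSV manifest (``manifest.csv``) are
    written there; generation is fully reproducible from ``seed``.
    """
    specs = dataset_specs(n, seed)
    samples = [make_sample(sp, side=side) for sp in specs]
    entries = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            out_dir.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    for i, s in enumerate(samples):
        name = f"phantom_{i:05d}.tif"
        if out_dir is not None:
            tifffile.imwrite(out_dir / name, s.image.pixels_u8)
        entries.append((name, round(s.score, 6)))
    manifest = ScoreManifest(entries=tuple(entries))
    if out_dir is not None:
        write_manifest(manifest, out_dir / "manifest.csv")
    return manifest, samples
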
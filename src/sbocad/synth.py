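"""Synthetic dermoscopy-like fixtures with exact ground truth.

Each image is a pigmented star-convex lesion on a lighter textured skin
background: the lesion boundary is a radial harmonic series
r(theta) = r0 * (1 + A * s(theta)) with s a normalized sum of sinusoids, so
the irregularity amplitude A directly controls the border raggedness that
the shape features must pick up.  Hair-like dark curvilinear strokes and
salt-and-pepper impulses emulate the acquisition artifacts that the median
filter is there to remove.  Masks are the exact rasterized blobs, enabling
exact Dice scoring of the segmenter.

The two classes differ in border irregularity, asymmetry (ellipse stretch)
and intra-lesion intensity variance; a ``difficulty`` knob interpolates the
malignant parameter ranges toward the benign ones, with difficulty 0 making
the class distributions identical (a null model for the whole pipeline).
Fixture realism is deliberately minimal — the generator's job is the
statistical structure the pipeline exploits, not photorealism.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocessing import save_image

__all__ = ["LesionSpec", "SyntheticDataset", "random_spec", "generate_image",
           "generate_dataset"]

# class-conditional parameter ranges at full difficulty
_BENIGN = {"irregularity": (0.0, 0.05), "lesion_std": (0.02, 0.04),
           "stretch": (1.0, 1.1)}
_MALIGNANT = {"irregularity": (0.15, 0.35), "lesion_std": (0.07, 0.12),
              "stretch": (1.15, 1.4)}


@dataclass
class LesionSpec:
    """Full recipe for one image; serializable for exact replay."""

    center: tuple[float, float]
    radius: float
    irregularity: float                 # amplitude A of the radial harmonics
    harmonic_amps: tuple[float, ...]    # normalized so max|s(theta)| ~ 1
    harmonic_phases: tuple[float, ...]
    stretch: float                      # ellipse-axis asymmetry factor
    angle: float                        # lesion orientation (radians)
    lesion_mean: float
    lesion_std: float
    background_mean: float
    background_std: float
    hair_count: int
    impulse_rate: float
    label: str                          # "benign" | "malignant"
    side: int = 256

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.impulse_rate <= 0.2:
            raise ValueError("impulse_rate must lie in [0, 0.2]")
        reach = self.radius * (1.0 + self.irregularity) * max(self.stretch, 1.0)
        r, c = self.center
        if (r - reach < 1 or c - reach < 1
                or r + reach > self.side - 2 or c + reach > self.side - 2):
            raise ValueError("lesion does not fit inside the canvas")


@dataclass
class SyntheticDataset:
    images: list[np.ndarray]
    masks: list[np.ndarray]
    labels: list[str]
    specs: list[LesionSpec]
    seed: int

    def __len__(self) -> int:
        return len(self.images)


def _interp_range(lo_hi_benign, lo_hi_malignant, difficulty: float):
    bl, bh = lo_hi_benign
    ml, mh = lo_hi_malignant
    return (bl + difficulty * (ml - bl), bh + difficulty * (mh - bh))


def random_spec(label: str, rng: np.random.Generator, difficulty: float = 1.0,
                side: int = 256) -> LesionSpec:
    """Draw one class-conditional lesion recipe.

    Benign lesions are near-elliptical with quiet interiors; at difficulty 1
    malignant lesions have ragged borders (A in [0.15, 0.35]), stronger
    stretch and higher interior variance.  Difficulty interpolates the
    malignant ranges toward the benign ones.
    """
    if label not in ("benign", "malignant"):
        raise ValueError("label must be 'benign' or 'malignant'")
    ranges = {}
    for key in _BENIGN:
        if label == "benign":
            ranges[key] = _BENIGN[key]
        else:
            ranges[key] = _interp_range(_BENIGN[key], _MALIGNANT[key], difficulty)
    n_harm = int(rng.integers(3, 8))
    amps = rng.uniform(0.5, 1.0, n_harm)
    phases = rng.uniform(0, 2 * np.pi, n_harm)
    # normalize so the radial modulation s(theta) peaks at 1: the amplitude A
    # then IS the fractional boundary excursion
    grid = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    s = np.zeros_like(grid)
    for k, (a, p) in enumerate(zip(amps, phases), start=2):
        s += a * np.sin(k * grid + p)
    amps = tuple(float(a) for a in amps / np.abs(s).max())
    irregularity = float(rng.uniform(*ranges["irregularity"]))
    stretch = float(rng.uniform(*ranges["stretch"]))
    radius = float(rng.uniform(40.0, 62.0))
    reach = radius * (1.0 + irregularity) * stretch
    margin = side / 2.0 - reach - 3.0
    jitter = min(12.0, max(margin, 0.0))
    center = (float(side / 2 + rng.uniform(-jitter, jitter)),
              float(side / 2 + rng.uniform(-jitter, jitter)))
    return LesionSpec(
        center=center,
        radius=radius,
        irregularity=irregularity,
        harmonic_amps=amps,
        harmonic_phases=tuple(float(p) for p in phases),
        stretch=stretch,
        angle=float(rng.uniform(0, np.pi)),
        lesion_mean=float(rng.uniform(0.40, 0.50)),
        lesion_std=float(rng.uniform(*ranges["lesion_std"])),
        background_mean=float(rng.uniform(0.70, 0.80)),
        background_std=float(rng.uniform(0.02, 0.03)),
        hair_count=int(rng.integers(0, 5)),
        impulse_rate=float(rng.uniform(0.002, 0.01)),
        label=label,
        side=side,
    )


def _boundary_radius(spec: LesionSpec, theta: np.ndarray) -> np.ndarray:
    s = np.zeros_like(theta)
    for k, (amp, phase) in enumerate(zip(spec.harmonic_amps,
                                         spec.harmonic_phases), start=2):
        s += amp * np.sin(k * theta + phase)
    return spec.radius * (1.0 + spec.irregularity * s)


def _textured_field(mean: float, std: float, shape, rng,
                    smooth_sigma: float = 3.0) -> np.ndarray:
    """Spatially correlated Gaussian texture with the requested mean/std."""
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_sigma)
    sd = noise.std()
    if sd > 0:
        noise /= sd
    return mean + std * noise


def _draw_hair(img: np.ndarray, rng: np.random.Generator) -> None:
    """One dark quadratic-Bezier stroke across the canvas."""
    side = img.shape[0]
    pts = rng.uniform(0, side - 1, size=(3, 2))
    t = np.linspace(0.0, 1.0, 4 * side)[:, None]
    curve = ((1 - t) ** 2 * pts[0] + 2 * t * (1 - t) * pts[1] + t ** 2 * pts[2])
    rr = np.clip(np.rint(curve[:, 0]).astype(int), 0, side - 1)
    cc = np.clip(np.rint(curve[:, 1]).astype(int), 0, side - 1)
    shade = float(rng.uniform(0.05, 0.2))
    img[rr, cc] = shade
    img[np.clip(rr + 1, 0, side - 1), cc] = shade


def generate_image(spec: LesionSpec, rng: np.random.Generator):
    """Render one (image, mask, label) triple from a lesion recipe.

    The image is a 256x256x3 float array in [0, 1]; the mask is the exact
    rasterized blob.  All randomness comes from ``rng``, so a fixed spec and
    seed reproduce the image bit for bit.
    """
    side = spec.side
    r, c = np.mgrid[0:side, 0:side].astype(float)
    dr, dc = r - spec.center[0], c - spec.center[1]
    ca, sa = np.cos(spec.angle), np.sin(spec.angle)
    u = ca * dr + sa * dc
    v = (-sa * dr + ca * dc) * spec.stretch  # compress one axis -> elongation
    theta = np.arctan2(v, u)
    dist = np.hypot(u, v)
    mask = dist <= _boundary_radius(spec, theta)

    gray = _textured_field(spec.background_mean, spec.background_std,
                           (side, side), rng)
    lesion = _textured_field(spec.lesion_mean, spec.lesion_std,
                             (side, side), rng)
    gray[mask] = lesion[mask]
    for _ in range(spec.hair_count):
        _draw_hair(gray, rng)
    n_imp = int(round(spec.impulse_rate * side * side))
    if n_imp:
        rows = rng.integers(0, side, n_imp)
        cols = rng.integers(0, side, n_imp)
        vals = rng.random(n_imp) < 0.5
        gray[rows, cols] = vals.astype(float)
    gray = np.clip(gray, 0.0, 1.0)
    # mild pigmentation tint so the raster is honest RGB
    img = np.stack([gray, np.clip(gray * 0.88, 0, 1),
                    np.clip(gray * 0.78, 0, 1)], axis=-1)
    return img, mask, spec.label


def generate_dataset(n: int, benign_frac: float = 0.5, difficulty: float = 1.0,
                     seed: int = 0, side: int = 256,
                     out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate ``n`` image/mask/label triples (optionally written to disk).

    All randomness flows from the single master seed: recipes are drawn
    first, then every image gets its own child generator, so the dataset is
    reproducible and individual images can be replayed from the manifest.
    """
    if n < 4:
        raise ValueError("need at least 4 images")
    n_benign = int(round(n * benign_frac))
    labels = ["benign"] * n_benign + ["malignant"] * (n - n_benign)
    master = np.random.SeedSequence(seed)
    spec_rng = np.random.default_rng(master.spawn(1)[0])
    perm = spec_rng.permutation(n)
    labels = [labels[i] for i in perm]
    specs = [random_spec(lab, spec_rng, difficulty, side) for lab in labels]
    children = master.spawn(n + 1)[1:]
    images, masks = [], []
    for spec, child in zip(specs, children):
        img, mask, _ = generate_image(spec, np.random.default_rng(child))
        images.append(img)
        masks.append(mask)
    ds = SyntheticDataset(images=images, masks=masks, labels=labels,
                          specs=specs, seed=seed)
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: SyntheticDataset, out_dir: Path) -> None:
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, mask, label) in enumerate(zip(ds.images, ds.masks, ds.labels)):
        name = f"im_{i:04d}.png"
        save_image(out_dir / "images" / name, img)
        save_image(out_dir / "masks" / name, mask)
        rows.append(f"{name},{label}")
    (out_dir / "labels.csv").write_text("filename,label\n" + "\n".join(rows) + "\n")
    manifest = {
        "seed": ds.seed,
        "n": len(ds),
        "specs": [dataclasses.asdict(s) for s in ds.specs],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
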
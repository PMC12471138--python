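"""Seeded synthetic fundus cohorts: branching vessel trees on a reddish
circular field, with group-dependent vessel density/width/branching and
chromatic shifts in the green and blue channels.

The generator is a fixture factory, not a biophysical model: it produces
image/ground-truth pairs whose *statistical* group contrasts (sparser,
thinner, more uniform vasculature and green/blue chromatic offsets in
the pathological group) drive the downstream texture and color
analyses.  Cohort generation is a pure function of its spec, including
the seed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from importlib import resources
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .preprocess import FundusImage

__all__ = [
    "CohortSpec",
    "SyntheticSample",
    "field_of_view",
    "generate_vessel_tree",
    "render_fundus",
    "generate_cohort",
    "load_preset",
    "available_presets",
    "write_cohort",
]

#: Child vessel width multiplier applied at each branching event.
WIDTH_DECAY = 0.8

#: Vessel color as a fraction of the (shifted) background mean, per channel.
VESSEL_CONTRAST = 0.55

#: Circular field radius as a fraction of the shorter image side.
FOV_RADIUS_FRACTION = 0.48

#: Hard cap on walker steps per tree; exceeding it flags the mask.
MAX_TREE_STEPS = 400_000


@dataclass(frozen=True)
class CohortSpec:
    """Full description of one synthetic cohort.

    Identical specs (seed included) produce bit-identical cohorts.
    """

    group_name: str
    n_images: int = 15
    image_size: tuple[int, int] = (256, 256)
    vessel_density: float = 0.12
    root_count: int = 6
    branch_prob: float = 0.015
    width_mean: float = 3.0
    width_sd: float = 0.8
    tortuosity: float = 0.15
    background_rgb_mean: tuple[float, float, float] = (170.0, 90.0, 45.0)
    background_rgb_sd: tuple[float, float, float] = (8.0, 8.0, 6.0)
    green_shift: float = 0.0
    blue_shift: float = 0.0
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if not 0 <= self.vessel_density < 0.5:
            raise ValueError("vessel_density must lie in [0, 0.5)")
        if self.width_mean < 1:
            raise ValueError("width_mean must be >= 1")
        if not 0 <= self.branch_prob <= 1:
            raise ValueError("branch_prob must lie in [0, 1]")
        object.__setattr__(self, "image_size", tuple(int(v) for v in self.image_size))
        object.__setattr__(
            self, "background_rgb_mean", tuple(float(v) for v in self.background_rgb_mean)
        )
        object.__setattr__(
            self, "background_rgb_sd", tuple(float(v) for v in self.background_rgb_sd)
        )

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        d["background_rgb_mean"] = list(self.background_rgb_mean)
        d["background_rgb_sd"] = list(self.background_rgb_sd)
        return d

    def replace(self, **kwargs) -> "CohortSpec":
        d = {**asdict(self), **kwargs}
        return CohortSpec(**d)


@dataclass
class SyntheticSample:
    image: FundusImage
    mask: np.ndarray
    spec_ref: str
    density_warning: bool = False
    seed_entropy: tuple = field(default_factory=tuple, repr=False)


def field_of_view(image_size: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the centered circular fundus field."""
    h, w = image_size
    radius = FOV_RADIUS_FRACTION * min(h, w)
    rr, cc = np.mgrid[0:h, 0:w]
    return (rr - (h - 1) / 2.0) ** 2 + (cc - (w - 1) / 2.0) ** 2 <= radius**2


@lru_cache(maxsize=256)
def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = max(0, int(np.floor(radius)))
    rr, cc = np.mgrid[-r : r + 1, -r : r + 1]
    keep = rr**2 + cc**2 <= radius**2
    return rr[keep], cc[keep]


class _Walker:
    __slots__ = ("r", "c", "heading", "width")

    def __init__(self, r: float, c: float, heading: float, width: float):
        self.r = r
        self.c = c
        self.heading = heading
        self.width = width


def _spawn_roots(spec: CohortSpec, rng: np.random.Generator) -> list[_Walker]:
    """Root walkers start at a disc-like point offset from the field
    center (emulating the optic disc) with spread-out headings."""
    h, w = spec.image_size
    radius = FOV_RADIUS_FRACTION * min(h, w)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    disc_angle = rng.uniform(0, 2 * np.pi)
    disc_r = cy + 0.55 * radius * np.sin(disc_angle)
    disc_c = cx + 0.55 * radius * np.cos(disc_angle)
    disc_radius = 0.12 * radius
    walkers = []
    for _ in range(spec.root_count):
        # roots sit on the disc rim and head outward, so trunks fan out
        # instead of overlapping into one blob
        rim = rng.uniform(0, 2 * np.pi)
        r = disc_r + disc_radius * np.sin(rim)
        c = disc_c + disc_radius * np.cos(rim)
        heading = rim + rng.normal(0.0, 0.4)
        width = max(1.0, rng.normal(spec.width_mean, spec.width_sd))
        walkers.append(_Walker(r, c, heading, width))
    return walkers


def generate_vessel_tree(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, bool]:
    """Grow a branching vessel tree until the target density is reached.

    Walkers advance one pixel per step with Gaussian heading jitter,
    stamping discs of their current width; each step they branch with
    probability ``branch_prob`` into a child of ``WIDTH_DECAY`` times
    their width.  Walkers die at the field boundary or below 1 px width;
    new roots are spawned if the population dies out before the target
    vessel-pixel fraction is met.

    Returns
    -------
    (mask, warned)
        ``mask``: uint8 raster in {0, 1}, strictly inside the circular
        field.  ``warned``: True when the step cap was hit before
        reaching the target density.
    """
    if spec.image_size[0] < 64 or spec.image_size[1] < 64:
        raise ValueError("image_size must be at least 64x64")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    h, w = spec.image_size
    fov = field_of_view(spec.image_size)
    mask = np.zeros((h, w), dtype=bool)
    target = spec.vessel_density * fov.sum()
    if target <= 0:
        return mask.astype(np.uint8), False

    count = 0
    steps = 0
    walkers = _spawn_roots(spec, rng)
    warned = False
    while count < target:
        if not walkers:
            if steps >= MAX_TREE_STEPS:
                warned = True
                break
            walkers = _spawn_roots(spec, rng)
        alive: list[_Walker] = []
        for wk in walkers:
            wk.heading += rng.normal(0.0, spec.tortuosity)
            wk.r += np.sin(wk.heading)
            wk.c += np.cos(wk.heading)
            ri, ci = int(round(wk.r)), int(round(wk.c))
            if not (0 <= ri < h and 0 <= ci < w) or not fov[ri, ci]:
                continue  # walker left the field
            dr, dc = _disk_offsets(wk.width / 2.0)
            rr = np.clip(ri + dr, 0, h - 1)
            cc = np.clip(ci + dc, 0, w - 1)
            stamp = fov[rr, cc] & ~mask[rr, cc]
            count += int(stamp.sum())
            mask[rr[stamp], cc[stamp]] = True
            if rng.random() < spec.branch_prob:
                child_width = wk.width * WIDTH_DECAY
                if child_width >= 1.0:
                    turn = rng.uniform(0.3, 0.9) * rng.choice((-1.0, 1.0))
                    alive.append(_Walker(wk.r, wk.c, wk.heading + turn, child_width))
            alive.append(wk)
            steps += 1
            if count >= target or steps >= MAX_TREE_STEPS:
                break
        if steps >= MAX_TREE_STEPS and count < target:
            warned = True
            break
        walkers = alive
    if warned:
        warnings.warn(
            f"vessel density target {spec.vessel_density:.3f} unreachable within "
            f"{MAX_TREE_STEPS} steps (reached {count / fov.sum():.3f})",
            stacklevel=2,
        )
    return mask.astype(np.uint8), warned


def render_fundus(
    mask: np.ndarray, spec: CohortSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render an 8-bit RGB fundus image over a vessel mask.

    Background pixels are drawn from per-channel normals centered at the
    (green/blue shifted) background means; vessel pixels take a fixed
    dark fraction of those means; independent Gaussian noise is added to
    every in-field pixel; pixels outside the circular field are 0.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != tuple(spec.image_size):
        raise ValueError("mask dimensions do not match spec.image_size")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    h, w = spec.image_size
    fov = field_of_view(spec.image_size)

    mean = np.asarray(spec.background_rgb_mean, dtype=np.float64) + np.array(
        [0.0, spec.green_shift, spec.blue_shift]
    )
    sd = np.asarray(spec.background_rgb_sd, dtype=np.float64)
    img = mean + rng.standard_normal((h, w, 3)) * sd
    vessel_rgb = mean * VESSEL_CONTRAST
    img[mask] = vessel_rgb
    if spec.noise_sd > 0:
        img += rng.standard_normal((h, w, 3)) * spec.noise_sd
    img[~fov] = 0.0
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


def generate_cohort(spec: CohortSpec) -> list[SyntheticSample]:
    """Generate ``spec.n_images`` independent samples deterministically.

    Each image uses its own RNG sub-stream spawned from the cohort seed,
    so samples are independent and the list order is reproducible.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_images)
    samples = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        mask, warned = generate_vessel_tree(spec, rng)
        pixels = render_fundus(mask, spec, rng)
        image = FundusImage(
            pixels=pixels,
            group=spec.group_name,
            id=f"{spec.group_name}_{i:03d}",
            fov_mask=field_of_view(spec.image_size),
        )
        samples.append(
            SyntheticSample(
                image=image,
                mask=mask,
                spec_ref=spec.group_name,
                density_warning=warned,
                seed_entropy=(spec.seed, i),
            )
        )
    return samples


def available_presets() -> list[str]:
    pkg = resources.files("fundustex") / "presets"
    return sorted(p.stem for p in pkg.iterdir() if p.suffix in (".yaml", ".yml"))


def load_preset(name: str, **overrides) -> CohortSpec:
    """Load a shipped cohort preset (e.g. ``"healthy"``) by name."""
    pkg = resources.files("fundustex") / "presets" / f"{name}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        raise ValueError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None
    data = yaml.safe_load(text)
    data.update(overrides)
    return CohortSpec.from_dict(data)


def write_cohort(samples: list[SyntheticSample], out_dir: str | Path) -> Path:
    """Write images/masks as PNG plus a CSV manifest; returns the manifest path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "mask_file", "group", "seed"])
        for s in samples:
            img_path = out / "images" / f"{s.image.id}.png"
            mask_path = out / "masks" / f"{s.image.id}_mask.png"
            iio.imwrite(img_path, s.image.pixels)
            iio.imwrite(mask_path, (s.mask * 255).astype(np.uint8))
            writer.writerow(
                [str(img_path), str(mask_path), s.image.group, s.seed_entropy[0]]
            )
    return manifest
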
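"""Seeded synthetic H&E histology scenes with ground-truth instance masks.

Scenes emulate the source corpus layout (700x460 RGB PNG fields organised
as class/magnification folders) so every pipeline stage runs offline.
Nuclei are elliptical blobs with low-order radial-harmonic boundary
irregularity, placed by rejection sampling under an overlap allowance, and
carry a hematoxylin concentration; the cytoplasm/stroma background carries
a textured eosin concentration.  Rendering is Beer-Lambert through the
preprocessing module's stain vectors, so color deconvolution is the exact
inverse of the renderer on noise-free output.

Benign-like scenes have fewer, rounder, size-uniform nuclei; malignant-like
scenes are denser and pleomorphic (higher eccentricity, wider size range,
irregular boundaries).  This mimics the qualitative benign/malignant
contrast, not the statistics of any real collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import StainModel, beer_lambert_render

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "generate_scene",
    "generate_corpus",
    "benign_like_spec",
    "malignant_like_spec",
    "benign_like_patch_spec",
    "malignant_like_patch_spec",
]

TRUTH_COLUMNS = [
    "image",
    "mask",
    "class",
    "magnification",
    "n_nuclei",
    "intended_bin",
    "mean_eccentricity",
    "seed",
]


@dataclass(frozen=True)
class SceneSpec:
    """Generative parameters for one synthetic H&E field."""

    width: int = 700
    height: int = 460
    class_label: str = "malignant_like"
    n_nuclei: int | tuple[int, int] = (120, 240)
    radius_range: tuple[float, float] = (4.0, 13.0)
    eccentricity_range: tuple[float, float] = (0.4, 0.8)
    irregularity: float = 0.25
    overlap_allowance: float = 0.1
    c_h_range: tuple[float, float] = (0.6, 0.9)
    c_e_range: tuple[float, float] = (0.15, 0.35)
    noise_sd: float = 2.0
    eosin_texture_scale: float = 40.0
    intended_bin: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_nuclei if isinstance(self.n_nuclei, tuple) else (self.n_nuclei, self.n_nuclei)
        if n[0] < 0 or n[1] < n[0]:
            raise ValueError(f"invalid n_nuclei {self.n_nuclei}")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError(f"invalid radius_range {self.radius_range}")
        if not (0 <= self.eccentricity_range[0] <= self.eccentricity_range[1] < 1):
            raise ValueError(f"invalid eccentricity_range {self.eccentricity_range}")
        # negative values enforce a separation margin between nuclei
        if not -1 <= self.overlap_allowance <= 1:
            raise ValueError(f"invalid overlap_allowance {self.overlap_allowance}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SceneTruth:
    """Rendered scene plus everything the generator knows about it."""

    image: np.ndarray  # uint8 RGB, after optional pixel noise
    rgb_float: np.ndarray  # noise-free float render (exact Beer-Lambert)
    instance_mask: np.ndarray  # uint16 labels, 0 = background
    n_nuclei: int
    centers: np.ndarray  # (n, 2) as (x, y)
    areas: np.ndarray  # pixels per nucleus
    eccentricities: np.ndarray
    class_label: str
    intended_bin: str
    c_h: np.ndarray
    c_e: np.ndarray


def benign_like_spec(**overrides) -> SceneSpec:
    """Fewer, rounder, size-uniform, non-overlapping nuclei."""
    base = dict(
        class_label="benign_like",
        n_nuclei=(30, 60),
        radius_range=(7.0, 11.0),
        eccentricity_range=(0.0, 0.3),
        irregularity=0.05,
        overlap_allowance=0.0,
        c_h_range=(0.55, 0.75),
    )
    base.update(overrides)
    return SceneSpec(**base)


def malignant_like_spec(**overrides) -> SceneSpec:
    """Denser, pleomorphic nuclei with irregular boundaries."""
    return SceneSpec(**{"class_label": "malignant_like", **overrides})


def benign_like_patch_spec(size: int = 64, **overrides) -> SceneSpec:
    """Patch-scale benign-like scene: a few large round nuclei."""
    base = dict(
        width=size,
        height=size,
        class_label="benign_like",
        n_nuclei=(3, 6),
        radius_range=(6.0, 9.0),
        eccentricity_range=(0.0, 0.3),
        irregularity=0.05,
        overlap_allowance=0.0,
        c_h_range=(0.55, 0.75),
    )
    base.update(overrides)
    return SceneSpec(**base)


def malignant_like_patch_spec(size: int = 64, **overrides) -> SceneSpec:
    """Patch-scale malignant-like scene: many small pleomorphic nuclei."""
    base = dict(
        width=size,
        height=size,
        class_label="malignant_like",
        n_nuclei=(12, 20),
        radius_range=(2.5, 4.5),
        eccentricity_range=(0.4, 0.8),
        irregularity=0.25,
        overlap_allowance=0.1,
    )
    base.update(overrides)
    return SceneSpec(**base)


def _sample_count(spec: SceneSpec, rng: np.random.Generator) -> int:
    if isinstance(spec.n_nuclei, tuple):
        return int(rng.integers(spec.n_nuclei[0], spec.n_nuclei[1] + 1))
    return int(spec.n_nuclei)


def _place_nuclei(spec: SceneSpec, n: int, rng: np.random.Generator):
    """Rejection-sample centers/shapes honoring the overlap allowance."""
    placed: list[dict] = []
    margin_cap = min(spec.width, spec.height) / 2
    attempts_per = 500
    for i in range(n):
        for attempt in range(attempts_per):
            r = rng.uniform(*spec.radius_range)
            ecc = rng.uniform(*spec.eccentricity_range)
            q = np.sqrt(1.0 - ecc**2)
            a, b = r / np.sqrt(q), r * np.sqrt(q)  # area-preserving axes
            rmax = min(a * (1.0 + spec.irregularity), margin_cap)
            cx = rng.uniform(rmax, spec.width - rmax)
            cy = rng.uniform(rmax, spec.height - rmax)
            ok = True
            for p in placed:
                min_dist = (1.0 - spec.overlap_allowance) * (rmax + p["rmax"])
                if (cx - p["cx"]) ** 2 + (cy - p["cy"]) ** 2 < min_dist**2:
                    ok = False
                    break
            if ok:
                placed.append(
                    dict(
                        cx=cx,
                        cy=cy,
                        a=a,
                        b=b,
                        rmax=rmax,
                        ecc=ecc,
                        theta=rng.uniform(0, np.pi),
                        harmonics=[
                            (k, rng.uniform(0, spec.irregularity / 3), rng.uniform(0, 2 * np.pi))
                            for k in (2, 3, 4)
                        ],
                        c_h=rng.uniform(*spec.c_h_range),
                    )
                )
                break
        else:
            raise RuntimeError(
                f"nucleus placement infeasible after {attempts_per} retries: "
                f"{len(placed)}/{n} placed under overlap_allowance="
                f"{spec.overlap_allowance} in {spec.width}x{spec.height}"
            )
    return placed


def _rasterize(spec: SceneSpec, placed: list[dict]):
    mask = np.zeros((spec.height, spec.width), dtype=np.uint16)
    c_h = np.zeros((spec.height, spec.width), dtype=float)
    for label, p in enumerate(placed, start=1):
        half = int(np.ceil(p["rmax"])) + 1
        x0 = max(int(p["cx"]) - half, 0)
        x1 = min(int(p["cx"]) + half + 1, spec.width)
        y0 = max(int(p["cy"]) - half, 0)
        y1 = min(int(p["cy"]) + half + 1, spec.height)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - p["cx"], yy - p["cy"]
        ct, st = np.cos(p["theta"]), np.sin(p["theta"])
        u = (dx * ct + dy * st) / p["a"]
        v = (-dx * st + dy * ct) / p["b"]
        rho = np.sqrt(u**2 + v**2)
        ang = np.arctan2(v, u)
        bound = 1.0
        for k, amp, phase in p["harmonics"]:
            bound = bound + amp * np.cos(k * ang + phase)
        inside = rho <= bound
        mask[y0:y1, x0:x1][inside] = label
        c_h[y0:y1, x0:x1][inside] = p["c_h"]
    return mask, c_h


def generate_scene(spec: SceneSpec, stain_model: StainModel | None = None) -> SceneTruth:
    """Render one scene; bit-identical for identical spec + seed."""
    rng = np.random.default_rng(spec.seed)
    stain_model = stain_model or StainModel()
    n = _sample_count(spec, rng)
    placed = _place_nuclei(spec, n, rng)
    mask, c_h = _rasterize(spec, placed)

    # soft nuclear edges (truth mask stays crisp)
    c_h = ndimage.gaussian_filter(c_h, 0.6)

    # textured eosin background: low-frequency noise mapped into the range
    tex = ndimage.gaussian_filter(
        rng.standard_normal((spec.height, spec.width)), spec.eosin_texture_scale / 8
    )
    span = tex.max() - tex.min()
    tex = (tex - tex.min()) / span if span > 0 else np.zeros_like(tex)
    lo, hi = spec.c_e_range
    c_e = lo + (hi - lo) * tex

    rgb_float = beer_lambert_render(c_h, c_e, stain_model)
    image = rgb_float.copy()
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    realized = len(placed)
    labels_present = np.unique(mask)
    labels_present = labels_present[labels_present > 0]
    if len(labels_present) != realized:
        raise RuntimeError(
            "rasterization lost a nucleus instance; lower overlap_allowance"
        )
    areas = np.bincount(mask.ravel(), minlength=realized + 1)[1:]
    return SceneTruth(
        image=image,
        rgb_float=rgb_float,
        instance_mask=mask,
        n_nuclei=realized,
        centers=np.array([[p["cx"], p["cy"]] for p in placed]),
        areas=areas,
        eccentricities=np.array([p["ecc"] for p in placed]),
        class_label=spec.class_label,
        intended_bin=spec.intended_bin,
        c_h=c_h,
        c_e=c_e,
    )


def generate_corpus(
    benign_spec: SceneSpec,
    malignant_spec: SceneSpec,
    counts: dict[str, tuple[int, int]],
    output_root: str | Path,
    *,
    malignant_count_ranges: Sequence[tuple[int, int]] | None = None,
    seed: int = 0,
    force: bool = False,
) -> pd.DataFrame:
    """Write a class/magnification PNG tree, mask tree and truth manifest.

    ``counts`` maps magnification folder names (e.g. ``"40X"``) to
    ``(n_benign, n_malignant)``.  With ``malignant_count_ranges`` (three
    (lo, hi) count ranges) malignant scenes cycle through the ranges and
    record the corresponding LD/MD/HD intended bin.  Refuses a non-empty
    ``output_root`` unless ``force``.
    """
    output_root = Path(output_root)
    if output_root.exists() and any(output_root.iterdir()) and not force:
        raise FileExistsError(f"output root {output_root} is not empty (use force)")
    rows = []
    scene_seed = seed
    bins = ("LD", "MD", "HD")
    for magnification, (n_benign, n_malignant) in sorted(counts.items()):
        for cls, base_spec, n_images in (
            ("benign", benign_spec, n_benign),
            ("malignant", malignant_spec, n_malignant),
        ):
            img_dir = output_root / cls / magnification
            mask_dir = output_root / "masks" / cls / magnification
            img_dir.mkdir(parents=True, exist_ok=True)
            mask_dir.mkdir(parents=True, exist_ok=True)
            for i in range(n_images):
                spec = replace(base_spec, seed=scene_seed)
                if cls == "malignant" and malignant_count_ranges is not None:
                    k = i % len(malignant_count_ranges)
                    spec = replace(
                        spec,
                        n_nuclei=tuple(malignant_count_ranges[k]),
                        intended_bin=bins[k],
                        seed=scene_seed,
                    )
                truth = generate_scene(spec)
                name = f"{cls}_{magnification}_{i:04d}"
                iio.imwrite(img_dir / f"{name}.png", truth.image)
                iio.imwrite(mask_dir / f"{name}_mask.png", truth.instance_mask)
                rows.append(
                    {
                        "image": str(img_dir / f"{name}.png"),
                        "mask": str(mask_dir / f"{name}_mask.png"),
                        "class": cls,
                        "magnification": magnification,
                        "n_nuclei": truth.n_nuclei,
                        "intended_bin": truth.intended_bin,
                        "mean_eccentricity": float(truth.eccentricities.mean())
                        if truth.n_nuclei
                        else np.nan,
                        "seed": scene_seed,
                    }
                )
                scene_seed += 1
    manifest = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    manifest.to_csv(output_root / "truth_manifest.csv", index=False)
    return manifest
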
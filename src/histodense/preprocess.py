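"""Stain-aware preprocessing: denoising, H&E color deconvolution, augmentation.

Stain separation follows the optical-density (Beer-Lambert) model: for each
pixel, OD_c = -log(I_c / I_0) is an approximately linear mixture of per-stain
absorption spectra.  Inverting the 3x3 mixing matrix of unit stain vectors
(hematoxylin, eosin, and an orthogonal residual) recovers per-stain
concentration maps; reconstructing from the hematoxylin channel alone yields
a stain-normalised structure image in which nuclei are dark.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

__all__ = [
    "StainModel",
    "AugmentParams",
    "AppliedAugment",
    "gaussian_denoise",
    "stain_separate",
    "remove_stain",
    "beer_lambert_render",
    "augment",
    "apply_augment",
]

#: Canonical H&E absorption vectors in OD space (unit-normalised on use).
DEFAULT_HEMATOXYLIN = (0.65, 0.70, 0.29)
DEFAULT_EOSIN = (0.07, 0.99, 0.11)

#: Intensity floor guarding log(0); one 8-bit intensity unit.
OD_EPS = 1.0


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("stain vector must be non-zero")
    return v / n


@dataclass(frozen=True)
class StainModel:
    """Unit stain vectors in OD space plus the white reference intensity."""

    hematoxylin: tuple[float, float, float] = DEFAULT_HEMATOXYLIN
    eosin: tuple[float, float, float] = DEFAULT_EOSIN
    background_intensity: float = 255.0

    @property
    def matrix(self) -> np.ndarray:
        """Rows: unit H, E and residual vectors; maps concentrations to OD."""
        h = _unit(self.hematoxylin)
        e = _unit(self.eosin)
        r = np.cross(h, e)
        rn = np.linalg.norm(r)
        if rn < 1e-12:
            raise ValueError("hematoxylin and eosin vectors are collinear")
        m = np.stack([h, e, r / rn])
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("stain matrix is singular")
        return m


def gaussian_denoise(image: np.ndarray, sigma: float) -> np.ndarray:
    """Channel-wise Gaussian smoothing with reflective borders.

    ``sigma = 0`` returns a bitwise-identical copy.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    image = np.asarray(image)
    if sigma == 0:
        return image.copy()
    out = np.empty_like(image, dtype=float)
    if image.ndim == 2:
        ndimage.gaussian_filter(image.astype(float), sigma, output=out, mode="reflect")
    else:
        for c in range(image.shape[2]):
            ndimage.gaussian_filter(
                image[..., c].astype(float), sigma, output=out[..., c], mode="reflect"
            )
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(out), np.iinfo(image.dtype).min, np.iinfo(image.dtype).max).astype(image.dtype)
    return out.astype(image.dtype)


def _optical_density(rgb: np.ndarray, model: StainModel) -> np.ndarray:
    bg = model.background_intensity
    i = np.clip(np.asarray(rgb, dtype=float), OD_EPS, bg)
    return -np.log(i / bg)


def stain_separate(rgb_image: np.ndarray, model: StainModel | None = None) -> np.ndarray:
    """Decompose an RGB image into (H, E, residual) concentration maps.

    Returns an array shaped ``(..., 3)`` whose last axis holds hematoxylin,
    eosin and residual concentrations, clipped at zero.
    """
    model = model or StainModel()
    od = _optical_density(rgb_image, model)
    conc = od @ np.linalg.inv(model.matrix)
    return np.clip(conc, 0.0, None)


def remove_stain(rgb_image: np.ndarray, model: StainModel | None = None) -> np.ndarray:
    """Stain-normalised grayscale structure image from hematoxylin alone.

    Eosin-dominated regions come out as uniform background; nuclei remain as
    dark objects.  Values lie in ``[0, background_intensity]``.
    """
    model = model or StainModel()
    c_h = stain_separate(rgb_image, model)[..., 0]
    return model.background_intensity * np.exp(-c_h)


def beer_lambert_render(
    c_h: np.ndarray, c_e: np.ndarray, model: StainModel | None = None
) -> np.ndarray:
    """Forward Beer-Lambert render of concentration maps to float RGB.

    ``I_c = I_0 * exp(-(c_H * V_H + c_E * V_E)_c)``; the exact inverse of
    :func:`stain_separate` for non-negative concentrations below saturation.
    """
    model = model or StainModel()
    m = model.matrix
    od = np.multiply.outer(np.asarray(c_h, float), m[0]) + np.multiply.outer(
        np.asarray(c_e, float), m[1]
    )
    return model.background_intensity * np.exp(-od)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentParams:
    """Ranges for the stochastic training-time augmentations.

    ``rotation_range`` in degrees (+/-), ``zoom_range`` and ``shear_range``
    as fractions, ``rescale`` an intensity multiplier applied
    deterministically (default 1/255 maps 8-bit patches onto [0, 1]).
    """

    rescale: float = 1.0 / 255.0
    rotation_range: float = 20.0
    zoom_range: float = 0.10
    shear_range: float = 0.10
    horizontal_flip: bool = True
    vertical_flip: bool = True

    def sample(self, rng: np.random.Generator) -> "AppliedAugment":
        """Draw one concrete augmentation from the configured ranges."""
        return AppliedAugment(
            rescale=self.rescale,
            rotation=float(rng.uniform(-self.rotation_range, self.rotation_range)),
            zoom=float(1.0 + rng.uniform(-self.zoom_range, self.zoom_range)),
            shear=float(rng.uniform(-self.shear_range, self.shear_range)),
            flip_h=bool(self.horizontal_flip and rng.random() < 0.5),
            flip_v=bool(self.vertical_flip and rng.random() < 0.5),
        )


@dataclass(frozen=True)
class AppliedAugment:
    """A fully determined augmentation (no randomness left)."""

    rescale: float = 1.0
    rotation: float = 0.0
    zoom: float = 1.0
    shear: float = 0.0
    flip_h: bool = False
    flip_v: bool = False

    @property
    def is_identity(self) -> bool:
        return (
            self.rescale == 1.0
            and self.rotation == 0.0
            and self.zoom == 1.0
            and self.shear == 0.0
            and not self.flip_h
            and not self.flip_v
        )


def apply_augment(patch: np.ndarray, applied: AppliedAugment) -> np.ndarray:
    """Apply a concrete augmentation; identity parameters return an exact copy."""
    out = np.asarray(patch)
    if applied.is_identity:
        return out.copy()
    out = out.astype(float)
    if applied.flip_h:
        out = out[:, ::-1]
    if applied.flip_v:
        out = out[::-1, :]
    if applied.rotation != 0.0 or applied.zoom != 1.0 or applied.shear != 0.0:
        h, w = out.shape[:2]
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        tf = (
            sktransform.AffineTransform(translation=-center)
            + sktransform.AffineTransform(
                rotation=np.deg2rad(applied.rotation),
                scale=(applied.zoom, applied.zoom),
                shear=applied.shear,
            )
            + sktransform.AffineTransform(translation=center)
        )
        out = sktransform.warp(out, tf.inverse, order=1, mode="reflect", preserve_range=True)
    if applied.rescale != 1.0:
        out = out * applied.rescale
    if np.issubdtype(patch.dtype, np.integer) and applied.rescale == 1.0:
        info = np.iinfo(patch.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(patch.dtype)
    return out


def augment(
    patch: np.ndarray, params: AugmentParams, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw one augmentation from ``params`` and apply it, deterministically."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return apply_augment(patch, params.sample(rng))
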
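"""Deterministic overlapping patch extraction from whole histology fields.

Two tiling modes for a 700x460 field and 224-pixel patches:

``grid6``
    3 columns x 2 rows, evenly spaced, first tile at the origin and last
    column/row flush with the image edge (x strides 238, y stride 236).
    Leaves two thin uncovered bands but matches the x6 patches-per-image
    bookkeeping of the source corpus.
``cover``
    The minimal evenly spaced grid whose tile footprints cover every pixel
    (4 x 3 = 12 tiles for 700x460/224).

Offsets are 0-based top-left corners with half-open footprints
``[x, x+patch) x [y, y+patch)``, sorted row-major.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "PatchGrid",
    "PatchRecord",
    "plan_grid",
    "extract_patches",
    "patch_corpus",
    "GRID6_COLS",
    "GRID6_ROWS",
]

logger = logging.getLogger(__name__)

GRID6_COLS = 3
GRID6_ROWS = 2

MANIFEST_COLUMNS = ["patch_id", "source", "class", "magnification", "x", "y"]

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class PatchGrid:
    """Planned tile offsets for one image geometry."""

    image_w: int
    image_h: int
    patch: int
    mode: str
    offsets: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.offsets)


@dataclass
class PatchRecord:
    """One extracted patch with its provenance."""

    patch_id: str
    source_image: str
    magnification: str
    class_label: str
    offset: tuple[int, int]
    pixels: np.ndarray


def _even_offsets(extent: int, patch: int, n: int) -> tuple[int, ...]:
    """n evenly spaced integer offsets from 0 to extent-patch, deduplicated."""
    span = extent - patch
    if n == 1 or span == 0:
        return (0,) if span == 0 else tuple(
            sorted({round(i * span / max(n - 1, 1)) for i in range(n)})
        )
    return tuple(sorted({round(i * span / (n - 1)) for i in range(n)}))


def _min_cover_count(extent: int, patch: int) -> int:
    """Fewest evenly spaced tiles of size ``patch`` covering ``extent`` pixels."""
    if extent == patch:
        return 1
    # n tiles with even stride (extent-patch)/(n-1); coverage requires the
    # stride (rounded up at worst) not to exceed the patch size.
    n = math.ceil((extent - patch) / patch) + 1
    while not _covers(extent, patch, _even_offsets(extent, patch, n)):
        n += 1
    return n


def _covers(extent: int, patch: int, offsets: Sequence[int]) -> bool:
    covered = np.zeros(extent, dtype=bool)
    for x in offsets:
        covered[x : x + patch] = True
    return bool(covered.all())


def plan_grid(image_w: int, image_h: int, patch: int, mode: str = "grid6") -> PatchGrid:
    """Plan tile offsets for an ``image_w`` x ``image_h`` image.

    Raises
    ------
    ValueError
        If the patch does not fit inside the image or the mode is unknown.
    """
    if patch <= 0:
        raise ValueError(f"patch size must be positive, got {patch}")
    if patch > image_w or patch > image_h:
        raise ValueError(
            f"patch {patch} exceeds image {image_w}x{image_h}"
        )
    if mode == "grid6":
        xs = _even_offsets(image_w, patch, GRID6_COLS)
        ys = _even_offsets(image_h, patch, GRID6_ROWS)
    elif mode == "cover":
        xs = _even_offsets(image_w, patch, _min_cover_count(image_w, patch))
        ys = _even_offsets(image_h, patch, _min_cover_count(image_h, patch))
    else:
        raise ValueError(f"unknown tiling mode {mode!r}")
    offsets = tuple((x, y) for y in ys for x in xs)
    return PatchGrid(image_w=image_w, image_h=image_h, patch=patch, mode=mode, offsets=offsets)


def extract_patches(
    image: np.ndarray,
    grid: PatchGrid,
    *,
    source: str = "",
    magnification: str = "",
    class_label: str = "",
) -> list[PatchRecord]:
    """Cut one :class:`PatchRecord` per grid offset; exact pixel copies."""
    h, w = image.shape[:2]
    if (w, h) != (grid.image_w, grid.image_h):
        raise ValueError(
            f"image is {w}x{h} but grid was planned for {grid.image_w}x{grid.image_h}"
        )
    stem = Path(source).stem if source else "patch"
    records = []
    p = grid.patch
    for x, y in grid.offsets:
        records.append(
            PatchRecord(
                patch_id=f"{stem}_m{magnification}_x{x}_y{y}",
                source_image=source,
                magnification=magnification,
                class_label=class_label,
                offset=(x, y),
                pixels=image[y : y + p, x : x + p].copy(),
            )
        )
    return records


def _iter_corpus_images(input_folder: Path):
    """Yield (path, class_label, magnification) for a BreakHis-style tree.

    Expected layout: ``<root>/<class>/.../<magnification>/<image>`` where the
    class folder name contains 'benign' or 'malignant' and the magnification
    folder looks like '40X'.  Falls back to 'unknown' labels for flat trees.
    """
    for path in sorted(input_folder.rglob("*")):
        if not (path.is_file() and path.suffix.lower() in IMAGE_SUFFIXES):
            continue
        if "masks" in path.relative_to(input_folder).parts:
            continue
        class_label = "unknown"
        magnification = "unknown"
        for part in path.relative_to(input_folder).parts[:-1]:
            low = part.lower()
            if "benign" in low:
                class_label = "benign"
            elif "malignant" in low:
                class_label = "malignant"
            if low.endswith("x") and low[:-1].isdigit():
                magnification = part.upper()
        yield path, class_label, magnification


def patch_corpus(
    input_folder: str | Path,
    mode: str,
    manifest_path: str | Path,
    *,
    patch: int = 224,
    output_folder: str | Path | None = None,
) -> pd.DataFrame:
    """Tile every image under ``input_folder`` and write a CSV manifest.

    Unreadable images are logged and skipped; the skip count is recorded in
    the returned frame's ``attrs['skipped']``.  When ``output_folder`` is
    given, each patch is also written as ``{stem}_x{X}_y{Y}.png``.
    """
    input_folder = Path(input_folder)
    out_dir = Path(output_folder) if output_folder is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    skipped = 0
    for path, class_label, magnification in _iter_corpus_images(input_folder):
        try:
            image = np.asarray(iio.imread(path))
        except Exception as exc:  # unreadable/corrupt file
            logger.warning("skipping unreadable image %s: %s", path, exc)
            skipped += 1
            continue
        h, w = image.shape[:2]
        grid = plan_grid(w, h, patch, mode)
        for rec in extract_patches(
            image,
            grid,
            source=str(path),
            magnification=magnification,
            class_label=class_label,
        ):
            if out_dir is not None:
                iio.imwrite(out_dir / f"{rec.patch_id}.png", rec.pixels)
            rows.append(
                {
                    "patch_id": rec.patch_id,
                    "source": rec.source_image,
                    "class": rec.class_label,
                    "magnification": rec.magnification,
                    "x": rec.offset[0],
                    "y": rec.offset[1],
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.attrs["skipped"] = skipped
    manifest.to_csv(manifest_path, index=False)
    return manifest
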
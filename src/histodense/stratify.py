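"""Density stratification: counting, 30:30:40 thresholds, bins, splits.

Malignant patches are binned by nuclei density (count per mm² of patch
area).  Thresholds derive from the corpus maximum density at the cumulative
ratio fractions (default 30:30:40 -> 30% and 60% of the maximum), or from
the corresponding quantiles.  Ties close the lower bin: a density exactly
at a threshold stays in the lower category.  Benign patches bypass density
entirely and are replicated into every bin's folder so each bin-specific
classifier sees both classes.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .calibration import DensityRecord

__all__ = [
    "DensityThresholds",
    "count_nuclei",
    "compute_thresholds",
    "assign_bins",
    "build_stratified_layout",
    "split_dataset",
    "BINS",
]

BINS = ("LD", "MD", "HD")

STRATIFIED_COLUMNS = ["patch_id", "class", "density", "bin", "split", "seed"]


@dataclass(frozen=True)
class DensityThresholds:
    """LD/MD/HD cut points in nuclei per mm²."""

    t_low: float
    t_high: float
    ratio: tuple[float, float, float] = (30.0, 30.0, 40.0)
    basis: str = "fraction_of_max"

    def __post_init__(self) -> None:
        if not (0 < self.t_low < self.t_high):
            raise ValueError(
                f"need 0 < t_low < t_high, got ({self.t_low}, {self.t_high})"
            )
        if any(r <= 0 for r in self.ratio):
            raise ValueError(f"ratio entries must be positive, got {self.ratio}")


def count_nuclei(mask: np.ndarray, min_area: int = 10, connectivity: int = 8) -> int:
    """Connected components of a binary mask with area >= ``min_area``.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent).
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask).astype(bool)
    labels = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    if labels.max() == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int((areas >= min_area).sum())


def compute_thresholds(
    densities: Sequence[float],
    ratio: tuple[float, float, float] = (30.0, 30.0, 40.0),
    basis: str = "fraction_of_max",
) -> DensityThresholds:
    """Derive LD/MD/HD thresholds from the observed density distribution.

    ``fraction_of_max``: cut at cumulative ratio fractions of the maximum
    density (30:30:40 -> 0.30*max and 0.60*max).  ``quantile``: cut at the
    corresponding percentiles (linear interpolation).
    """
    d = np.asarray(list(densities), dtype=float)
    if d.size == 0:
        raise ValueError("empty density list")
    if (d < 0).any():
        raise ValueError("densities must be non-negative")
    total = sum(ratio)
    f1 = ratio[0] / total
    f2 = (ratio[0] + ratio[1]) / total
    if basis == "fraction_of_max":
        m = float(d.max())
        t_low, t_high = f1 * m, f2 * m
    elif basis == "quantile":
        t_low = float(np.percentile(d, 100 * f1))
        t_high = float(np.percentile(d, 100 * f2))
    else:
        raise ValueError(f"unknown threshold basis {basis!r}")
    return DensityThresholds(t_low=t_low, t_high=t_high, ratio=tuple(ratio), basis=basis)


def assign_bin(density: float, thresholds: DensityThresholds) -> str:
    """LD if d <= t_low, MD if t_low < d <= t_high, HD otherwise."""
    if density <= thresholds.t_low:
        return "LD"
    if density <= thresholds.t_high:
        return "MD"
    return "HD"


def assign_bins(
    records: Iterable[DensityRecord], thresholds: DensityThresholds
) -> list[DensityRecord]:
    """Assign every record's ``bin`` in place and return the list."""
    out = list(records)
    for rec in out:
        rec.bin = assign_bin(rec.a_d, thresholds)
    return out


def build_stratified_layout(
    manifest: pd.DataFrame,
    bins: dict[str, str],
    output_root: str | Path,
    *,
    patch_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Materialise the {LD,MD,HD}/{benign,malignant} tree and its manifest.

    ``manifest`` needs columns ``patch_id`` and ``class`` (optionally
    ``density``); ``bins`` maps malignant patch_ids to their bin.  Benign
    patches are copied into all three bins.  When ``patch_dir`` is given,
    patch PNGs named ``<patch_id>.png`` are copied into the tree; otherwise
    only the manifest is produced.
    """
    output_root = Path(output_root)
    rows = []
    seen_paths: set[Path] = set()
    for row in manifest.to_dict("records"):
        cls = row["class"]
        patch_id = row["patch_id"]
        density = float(row.get("density", np.nan))
        targets = BINS if cls == "benign" else (bins[patch_id],)
        for b in targets:
            dest = output_root / b / cls / f"{patch_id}.png"
            if dest in seen_paths:
                raise FileExistsError(f"output path collision: {dest}")
            seen_paths.add(dest)
            dest.parent.mkdir(parents=True, exist_ok=True)
            if patch_dir is not None:
                src = Path(patch_dir) / f"{patch_id}.png"
                if src.exists():
                    shutil.copyfile(src, dest)
            rows.append(
                {
                    "patch_id": patch_id,
                    "class": cls,
                    "density": density if cls == "malignant" else np.nan,
                    "bin": b,
                    "split": "",
                    "seed": -1,
                }
            )
    frame = pd.DataFrame(rows, columns=STRATIFIED_COLUMNS)
    frame.to_csv(output_root / "stratified_manifest.csv", index=False)
    return frame


def split_dataset(
    stratified_manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> pd.DataFrame:
    """Assign train/val/test per (bin, class) stratum, residues to train.

    Deterministic given ``seed``: each stratum is shuffled with its own
    substream, validation and test sizes are floored, and the remainder
    goes to training.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    frame = stratified_manifest.copy()
    frame["split"] = ""
    frame["seed"] = seed
    rng = np.random.default_rng(seed)
    for (b, cls), idx in frame.groupby(["bin", "class"], sort=True).groups.items():
        idx = np.asarray(idx)
        order = idx[rng.permutation(len(idx))]
        n = len(order)
        n_val = int(np.floor(fractions[1] * n))
        n_test = int(np.floor(fractions[2] * n))
        n_train = n - n_val - n_test
        frame.loc[order[:n_train], "split"] = "train"
        frame.loc[order[n_train : n_train + n_val], "split"] = "val"
        frame.loc[order[n_train + n_val :], "split"] = "test"
    return frame
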
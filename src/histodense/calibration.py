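"""Microscope calibration and nuclei-density calculus.

Converts sensor geometry (physical pixel pitch, visual magnification) into
microns-per-pixel, patch areas in physical units, and nuclei densities per
square millimetre.  All quantities are exact arithmetic on the inputs; no
rounding happens outside of report formatting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CalibrationSpec",
    "PatchCalibration",
    "DensityRecord",
    "microns_per_pixel",
    "patch_physical_size",
    "patch_area",
    "area_to_mm2",
    "nuclei_density",
    "calibrate_patch",
    "write_density_manifest",
    "read_density_manifest",
]

#: Square-micrometre to square-millimetre conversion (1 µm² = 1e-6 mm²).
UM2_PER_MM2 = 1e-6

DENSITY_MANIFEST_COLUMNS = ["patch_id", "n", "a_mms", "a_d", "bin"]


@dataclass(frozen=True)
class CalibrationSpec:
    """Sensor pixel pitch and visual magnification of the acquisition setup.

    Parameters
    ----------
    pps:
        Physical sensor pixel size in micrometres (camera pixel pitch).
        Default 6.5 µm (1/3-inch CCD).
    magnification:
        Total visual magnification; conventionally one of 40, 100, 200, 400
        but any positive value is accepted.
    """

    pps: float = 6.5
    magnification: float = 40.0

    def __post_init__(self) -> None:
        if self.pps <= 0:
            raise ValueError(f"pps must be positive, got {self.pps}")
        if self.magnification <= 0:
            raise ValueError(
                f"magnification must be positive, got {self.magnification}"
            )


@dataclass(frozen=True)
class PatchCalibration:
    """Physical geometry of a single rectangular patch.

    ``mpp_x``/``mpp_y`` are micrometres per pixel, ``w_p``/``h_p`` the patch
    size in pixels, ``w_x``/``h_y`` in micrometres, ``a_n`` the area in µm²
    and ``a_mms`` the same area in mm².
    """

    mpp_x: float
    mpp_y: float
    w_p: int
    h_p: int
    w_x: float = field(init=False)
    h_y: float = field(init=False)
    a_n: float = field(init=False)
    a_mms: float = field(init=False)

    def __post_init__(self) -> None:
        w_x, h_y = patch_physical_size(self.w_p, self.h_p, self.mpp_x, self.mpp_y)
        a_n = patch_area(w_x, h_y)
        object.__setattr__(self, "w_x", w_x)
        object.__setattr__(self, "h_y", h_y)
        object.__setattr__(self, "a_n", a_n)
        object.__setattr__(self, "a_mms", area_to_mm2(a_n))


@dataclass
class DensityRecord:
    """Per-patch nuclei count, physical area and density.

    ``bin`` stays ``"UNASSIGNED"`` until density thresholds have been
    computed over the whole corpus (see :mod:`histodense.stratify`).
    """

    patch_id: str
    n: int
    a_mms: float
    a_d: float = field(init=False)
    bin: str = "UNASSIGNED"

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"nuclei count must be non-negative, got {self.n}")
        self.a_d = nuclei_density(self.n, self.a_mms)


def microns_per_pixel(spec: CalibrationSpec) -> float:
    """Micrometres spanned by one image pixel: sensor pitch / magnification."""
    return spec.pps / spec.magnification


def patch_physical_size(
    w_p: float, h_p: float, mpp_x: float, mpp_y: float
) -> tuple[float, float]:
    """Patch width/height in micrometres from pixel dimensions."""
    if w_p < 0 or h_p < 0:
        raise ValueError(f"pixel dimensions must be non-negative, got {(w_p, h_p)}")
    return w_p * mpp_x, h_p * mpp_y


def patch_area(w_x: float, h_y: float) -> float:
    """Patch area in square micrometres."""
    if w_x < 0 or h_y < 0:
        raise ValueError(f"physical dimensions must be non-negative, got {(w_x, h_y)}")
    return w_x * h_y


def area_to_mm2(a_n: float) -> float:
    """Convert an area from µm² to mm²."""
    if a_n < 0:
        raise ValueError(f"area must be non-negative, got {a_n}")
    return a_n * UM2_PER_MM2


def nuclei_density(n: int, a_mms: float) -> float:
    """Nuclei per square millimetre."""
    if n < 0:
        raise ValueError(f"nuclei count must be non-negative, got {n}")
    if a_mms <= 0:
        raise ValueError(f"area must be positive, got {a_mms}")
    return n / a_mms


def calibrate_patch(spec: CalibrationSpec, w_p: int, h_p: int) -> PatchCalibration:
    """Full physical geometry of a ``w_p`` x ``h_p`` pixel patch under ``spec``."""
    mpp = microns_per_pixel(spec)
    return PatchCalibration(mpp_x=mpp, mpp_y=mpp, w_p=w_p, h_p=h_p)


def write_density_manifest(
    records: Iterable[DensityRecord], path: str | Path
) -> pd.DataFrame:
    """Write per-patch density records to a CSV manifest and return the frame."""
    frame = pd.DataFrame(
        [
            {
                "patch_id": r.patch_id,
                "n": r.n,
                "a_mms": r.a_mms,
                "a_d": r.a_d,
                "bin": r.bin,
            }
            for r in records
        ],
        columns=DENSITY_MANIFEST_COLUMNS,
    )
    frame.to_csv(path, index=False)
    return frame


def read_density_manifest(path: str | Path) -> list[DensityRecord]:
    """Read a density manifest CSV back into records."""
    frame = pd.read_csv(path)
    records = []
    for row in frame.itertuples(index=False):
        rec = DensityRecord(patch_id=str(row.patch_id), n=int(row.n), a_mms=float(row.a_mms))
        rec.bin = str(row.bin)
        records.append(rec)
    return records
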
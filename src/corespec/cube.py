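"""In-memory containers for hyperspectral soil-core data.

A :class:`SpectralCube` is the central raster object: a (rows, cols, bands)
array with its wavelength axis, pixel size, soil mask and depth origin.
Rows run from the soil surface downwards (row 0 = surface); the depth of a
row centre is ``depth_origin_cm + (row + 0.5) * pixel_size``.  Depth
intervals throughout the package are half-open ``[top, bottom)``.

A :class:`SOCMap` holds per-pixel soil organic carbon predictions (mg g^-1)
on the same grid; masked pixels carry NaN.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

# spectral treatment tags
RAW = "raw"
NORMALIZED_REFLECTANCE = "normalized_reflectance"
SNV = "snv"
UNIT_SCALED = "unit_scaled"

_TREATMENTS = (RAW, NORMALIZED_REFLECTANCE, SNV, UNIT_SCALED)


@dataclass
class SpectralCube:
    """Hyperspectral raster with wavelength axis, mask and depth calibration.

    Parameters
    ----------
    values
        (rows, cols, bands) float array; intensity or reflectance depending
        on ``treatment``.
    wavelengths
        Band centres in nm, strictly increasing, length = band count.
    pixel_size_um
        Edge length of a (square) pixel in micrometres.
    mask
        (rows, cols) boolean; True = usable soil pixel.
    depth_origin_cm
        Depth of the top edge of row 0.
    treatment
        One of ``raw``, ``normalized_reflectance``, ``snv``, ``unit_scaled``.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    pixel_size_um: float
    mask: np.ndarray | None = None
    depth_origin_cm: float = 0.0
    treatment: str = RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (rows, cols, bands)")
        if self.wavelengths.shape != (self.values.shape[2],):
            raise ValueError("band count must equal wavelength count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.treatment not in _TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.mask is None:
            self.mask = np.ones(self.values.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape[:2]:
                raise ValueError("mask shape must equal spatial shape")

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    @property
    def pixel_size_cm(self) -> float:
        return self.pixel_size_um * 1e-4

    def depth_axis_cm(self) -> np.ndarray:
        """Depth (cm) of each row centre."""
        rows = np.arange(self.values.shape[0])
        return self.depth_origin_cm + (rows + 0.5) * self.pixel_size_cm

    def band_index(self, nm: float) -> int:
        """Index of the band nearest a target wavelength."""
        return int(np.argmin(np.abs(self.wavelengths - nm)))

    # -- convenience --------------------------------------------------
    def replace(self, **changes) -> "SpectralCube":
        """Return a copy with the given fields replaced (arrays not copied)."""
        return dataclasses.replace(self, **changes)

    def unmasked_spectra(self) -> np.ndarray:
        """(n_unmasked, bands) matrix of the usable pixel spectra."""
        return self.values[self.mask]


@dataclass
class ReflectanceTarget:
    """Reference scan of the calibration target of known reflectance.

    ``intensity`` is per image column and band (cols, bands) so that
    normalisation can cancel horizontal illumination differences;
    ``defined_reflectance`` is the target's certified reflectance per band
    (~0.5 for the instrument emulated here).
    """

    intensity: np.ndarray
    defined_reflectance: np.ndarray

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.defined_reflectance = np.atleast_1d(
            np.asarray(self.defined_reflectance, dtype=float)
        )
        if self.intensity.ndim != 2:
            raise ValueError("target intensity must be (cols, bands)")
        nb = self.intensity.shape[1]
        if self.defined_reflectance.size == 1:
            self.defined_reflectance = np.full(nb, self.defined_reflectance[0])
        if self.defined_reflectance.shape != (nb,):
            raise ValueError("defined_reflectance must be scalar or per band")
        if np.any(self.defined_reflectance <= 0) or np.any(
            self.defined_reflectance > 1
        ):
            raise ValueError("defined_reflectance must lie in (0, 1]")


@dataclass
class SOCMap:
    """Per-pixel SOC predictions (mg g^-1) with mask and depth calibration.

    ``values`` carries NaN at masked pixels.  When a map has been adjusted
    (range constraint, bias correction) the unadjusted values are preserved
    in ``raw_values``.
    """

    values: np.ndarray
    mask: np.ndarray
    pixel_size_um: float
    depth_origin_cm: float = 0.0
    source: str = ""
    raw_values: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_size_cm(self) -> float:
        return self.pixel_size_um * 1e-4

    def depth_axis_cm(self) -> np.ndarray:
        rows = np.arange(self.values.shape[0])
        return self.depth_origin_cm + (rows + 0.5) * self.pixel_size_cm

    def unmasked(self) -> np.ndarray:
        """1D array of usable (unmasked, finite) predictions."""
        vals = self.values[self.mask]
        return vals[np.isfinite(vals)]

    def replace(self, **changes) -> "SOCMap":
        return dataclasses.replace(self, **changes)
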
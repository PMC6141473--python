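"""Raw-intensity cube -> masked, normalised, SNV-transformed reflectance.

The processing chain mirrors standard laboratory imaging-spectroscopy
practice: per-column normalisation against a reflectance target of known
reflectance (cancelling horizontal illumination differences), band-ratio
masking of non-soil pixels (stage background, holder, shadows, cracks,
macropores) using the ~980 nm and ~420 nm regions, per-pixel standard
normal variate (SNV) z-scoring to suppress multiplicative/additive scatter,
and a per-band [0, 1] scaling used by kernel models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .cube import (
    NORMALIZED_REFLECTANCE,
    RAW,
    SNV,
    ReflectanceTarget,
    SpectralCube,
)

#: diagnostic bands for non-soil masking (nm)
UPPER_MASK_BAND_NM = 980.0
LOWER_MASK_BAND_NM = 420.0

#: default masking thresholds, calibrated on the synthetic forward model:
#: soil reflectance near 980 nm stays above ~0.3 while cracks/macropores
#: fall below ~0.1; the soil 980/420 ratio stays within ~3-25 (scatter
#: included) while the spectrally flat stage background sits near 1.  Only
#: the lower ratio bound separates soil from background; the upper bound is
#: a loose guard against spectrally inverted material.
DEFAULT_UPPER_BAND_THRESHOLD = 0.2
DEFAULT_RATIO_BOUNDS = (2.0, 40.0)


def normalize_to_target(raw: SpectralCube, target: ReflectanceTarget) -> SpectralCube:
    """Convert raw intensity to reflectance against the calibration target.

    R_sample(lambda, x) = I_sample(lambda, x) / I_target(lambda, x)
    * R_target_defined(lambda), applied per image column so that horizontal
    illumination differences cancel.
    """
    if raw.treatment != RAW:
        raise ValueError(f"expected a raw cube, got treatment {raw.treatment!r}")
    n_cols, n_bands = target.intensity.shape
    if n_bands != raw.n_bands:
        raise ValueError("target does not cover every band of the cube")
    if n_cols != raw.shape[1]:
        raise ValueError("target columns do not match cube columns")
    bad = target.intensity <= 0
    if np.any(bad):
        cols, bands = np.nonzero(bad)
        raise ValueError(
            "non-positive target intensity at "
            f"(column, band) pairs {list(zip(cols[:5], bands[:5]))}..."
        )
    refl = (
        raw.values
        / target.intensity[None, :, :]
        * target.defined_reflectance[None, None, :]
    )
    return raw.replace(values=refl, treatment=NORMALIZED_REFLECTANCE)


def mask_non_soil(
    cube: SpectralCube,
    upper_band_threshold: float = DEFAULT_UPPER_BAND_THRESHOLD,
    ratio_bounds: tuple[float, float] = DEFAULT_RATIO_BOUNDS,
) -> SpectralCube:
    """Mask background, holder, shadow, crack and macropore pixels.

    A pixel is set unusable when its reflectance at the band nearest 980 nm
    falls below ``upper_band_threshold`` (dark features) or its 980/420
    band ratio falls outside ``ratio_bounds`` (spectrally alien features).
    Spectral values are never changed, only the mask.
    """
    if cube.treatment not in (NORMALIZED_REFLECTANCE, SNV):
        raise ValueError("mask_non_soil expects a normalised cube")
    hi = cube.values[:, :, cube.band_index(UPPER_MASK_BAND_NM)]
    lo = cube.values[:, :, cube.band_index(LOWER_MASK_BAND_NM)]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo != 0, hi / lo, np.inf)
    bad = (hi < upper_band_threshold) | (ratio < ratio_bounds[0]) | (
        ratio > ratio_bounds[1]
    )
    new_mask = cube.mask & ~bad
    if not new_mask.any():
        warnings.warn(
            "mask_non_soil: thresholds masked 100% of pixels", stacklevel=2
        )
    out = cube.replace(mask=new_mask)
    out.meta = dict(cube.meta, masked_fraction=float(1 - new_mask.mean()))
    return out


def snv_transform(cube: SpectralCube) -> SpectralCube:
    """Standard normal variate: z-score each pixel spectrum over its bands.

    Uses the sample (n-1) standard deviation.  SNV is invariant to
    multiplicative and additive scatter: snv(a*s + b) = snv(s) for a > 0.
    Pixels with a flat (zero-sd) spectrum cannot be transformed; they are
    masked and counted in ``meta['snv_flat_pixels']``.
    """
    if cube.treatment != NORMALIZED_REFLECTANCE:
        raise ValueError("snv_transform expects a normalized_reflectance cube")
    mean = cube.values.mean(axis=2, keepdims=True)
    sd = cube.values.std(axis=2, ddof=1, keepdims=True)
    flat = sd[:, :, 0] == 0
    safe_sd = np.where(sd == 0, 1.0, sd)
    out_vals = (cube.values - mean) / safe_sd
    out = cube.replace(
        values=out_vals, mask=cube.mask & ~flat, treatment=SNV
    )
    out.meta = dict(cube.meta, snv_flat_pixels=int(np.sum(flat & cube.mask)))
    return out


@dataclass
class UnitIntervalScaler:
    """Per-band affine map to [0, 1] fitted on a calibration matrix.

    The stored per-band min/max are re-applied to prediction spectra, whose
    scaled values may legitimately fall outside [0, 1] (no clipping).
    Constant bands are mapped to 0.5 and recorded in ``constant_bands``.
    """

    band_min: np.ndarray | None = None
    band_max: np.ndarray | None = None
    constant_bands: np.ndarray | None = None

    def fit(self, spectra: np.ndarray) -> "UnitIntervalScaler":
        spectra = np.asarray(spectra, dtype=float)
        if not np.all(np.isfinite(spectra)):
            raise ValueError("spectra must be finite")
        self.band_min = spectra.min(axis=0)
        self.band_max = spectra.max(axis=0)
        self.constant_bands = np.nonzero(self.band_max == self.band_min)[0]
        return self

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        if self.band_min is None:
            raise RuntimeError("scaler is not fitted")
        spectra = np.asarray(spectra, dtype=float)
        span = self.band_max - self.band_min
        safe = np.where(span == 0, 1.0, span)
        out = (spectra - self.band_min) / safe
        if self.constant_bands.size:
            out[..., self.constant_bands] = 0.5
        return out

    def inverse_transform(self, scaled: np.ndarray) -> np.ndarray:
        if self.band_min is None:
            raise RuntimeError("scaler is not fitted")
        span = self.band_max - self.band_min
        out = np.asarray(scaled, dtype=float) * np.where(span == 0, 1.0, span)
        out = out + self.band_min
        if self.constant_bands.size:
            out[..., self.constant_bands] = self.band_min[self.constant_bands]
        return out


def scale_to_unit_interval(
    spectra: np.ndarray,
) -> tuple[np.ndarray, UnitIntervalScaler]:
    """Fit-and-apply the per-band [0, 1] scaling; returns (scaled, scaler)."""
    scaler = UnitIntervalScaler().fit(spectra)
    return scaler.transform(spectra), scaler


def pca_rgb(
    cube: SpectralCube, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """False-colour rendering from the leading principal components.

    PCA is fitted per core on the unmasked pixel spectra (mean-centred,
    unscaled).  Each component's loading vector is sign-fixed so its
    largest-magnitude element is positive; scores are min-max stretched to
    [0, 1] and masked pixels set to 0.

    Returns ``(image, loadings, explained_variance_ratio)`` with image
    shape (rows, cols, n_components).
    """
    if cube.treatment not in (NORMALIZED_REFLECTANCE, SNV):
        raise ValueError("pca_rgb expects a normalised or SNV cube")
    X = cube.unmasked_spectra()
    if X.shape[0] < n_components:
        raise ValueError(
            f"only {X.shape[0]} unmasked pixels for {n_components} components"
        )
    if cube.n_bands < n_components:
        raise ValueError("fewer bands than requested components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    for i in range(n_components):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    img = np.zeros(cube.shape[:2] + (n_components,), dtype=float)
    stretched = np.empty_like(scores)
    for i in range(n_components):
        lo, hi = scores[:, i].min(), scores[:, i].max()
        stretched[:, i] = 0.5 if hi == lo else (scores[:, i] - lo) / (hi - lo)
    img[cube.mask] = stretched
    return img, loadings, pca.explained_variance_ratio_


def pc1_scores(cube: SpectralCube) -> np.ndarray:
    """First-principal-component score per pixel (NaN where masked).

    Convenience for ROI auto-selection; same fitting and sign conventions
    as :func:`pca_rgb`.
    """
    X = cube.unmasked_spectra()
    pca = PCA(n_components=1, svd_solver="full")
    s = pca.fit_transform(X)[:, 0]
    load = pca.components_[0]
    if load[int(np.argmax(np.abs(load)))] < 0:
        s = -s
    out = np.full(cube.shape[:2], np.nan)
    out[cube.mask] = s
    return out
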
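"""Regions of interest: spectral extraction and calibration-set assembly.

Each ROI is a small contiguous pixel region whose SOC was measured in the
laboratory.  Twelve representative spectra are extracted per ROI - the
bandwise mean and median of (a) the full ROI and (b) five random subsets of
1% of its pixels.  Three of the five random-subset spectra train the
models; the full-ROI spectrum and the remaining two subsets validate them,
so the full-ROI statistic never enters training.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cube import SpectralCube
from .preprocessing import pc1_scores

SUBSET_IDS = ("r1", "r2", "r3", "r4", "r5")
TOPSOIL, SUBSOIL = "topsoil", "subsoil"


@dataclass
class RegionOfInterest:
    roi_id: str
    core_id: str
    rows: np.ndarray  # pixel row indices into the core's cube
    cols: np.ndarray
    measured_soc: float  # mg g^-1, laboratory value
    depth_cm: float  # centroid depth
    horizon: str  # topsoil | subsoil
    area_cm2: float

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        if self.rows.shape != self.cols.shape or self.rows.ndim != 1:
            raise ValueError("rows and cols must be matching 1D index arrays")
        if self.measured_soc <= 0:
            raise ValueError("measured_soc must be positive")
        if self.horizon not in (TOPSOIL, SUBSOIL):
            raise ValueError(f"unknown horizon {self.horizon!r}")

    @property
    def n_pixels(self) -> int:
        return self.rows.size


@dataclass
class CalibrationSample:
    """One representative ROI spectrum with its role in model building."""

    roi_id: str
    spectrum: np.ndarray
    statistic: str  # mean | median
    subset_id: str  # full | r1..r5
    role: str  # train | validate
    soc: float
    core_id: str = ""
    depth_cm: float = float("nan")
    horizon: str = ""
    column: float = float("nan")  # mean pixel column, for bias diagnostics


@dataclass
class CalibrationSet:
    """All calibration samples of one spectral treatment.

    ``soc_min``/``soc_max`` are the calibration limits - the extreme SOC
    values analysed - later used to constrain out-of-range predictions.
    """

    samples: list[CalibrationSample]
    treatment: str
    soc_min: float
    soc_max: float
    statistic: str = "mean"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.soc_min >= self.soc_max:
            raise ValueError("degenerate calibration: soc_min >= soc_max")

    def _sel(self, role: str) -> list[CalibrationSample]:
        return [s for s in self.samples if s.role == role]

    def X(self, role: str = "train") -> np.ndarray:
        return np.array([s.spectrum for s in self._sel(role)])

    def y(self, role: str = "train") -> np.ndarray:
        return np.array([s.soc for s in self._sel(role)])

    def subset(self, role: str) -> list[CalibrationSample]:
        return self._sel(role)

    def to_dataframe(self) -> pd.DataFrame:
        n_bands = len(self.samples[0].spectrum)
        recs = []
        for s in self.samples:
            rec = {
                "roi_id": s.roi_id,
                "core_id": s.core_id,
                "soc": s.soc,
                "role": s.role,
                "subset_id": s.subset_id,
                "statistic": s.statistic,
                "depth_cm": s.depth_cm,
                "horizon": s.horizon,
                "column": s.column,
            }
            rec.update({f"b{i}": v for i, v in enumerate(s.spectrum)})
            recs.append(rec)
        df = pd.DataFrame(recs)
        df.attrs["n_bands"] = n_bands
        return df


def _subset_size(n_pixels: int, fraction: float = 0.01) -> int:
    """Round-half-up 1% subset size with a floor of one pixel."""
    return max(1, int(math.floor(fraction * n_pixels + 0.5)))


def extract_roi_spectra(
    cube: SpectralCube,
    roi: RegionOfInterest,
    seed: int = 0,
    min_pixels: int = 4,
) -> dict[tuple[str, str], np.ndarray]:
    """Extract the 12 representative spectra of one ROI.

    Returns a mapping ``(statistic, subset_id) -> spectrum`` for statistic
    in {mean, median} and subset_id in {full, r1..r5}.  Random subsets are
    drawn independently of each other, each without replacement, with size
    max(1, round(0.01 * n_pixels)); draws are deterministic for a seed.
    """
    if roi.n_pixels < min_pixels:
        raise ValueError(
            f"ROI {roi.roi_id} has {roi.n_pixels} pixels (< {min_pixels})"
        )
    if roi.rows.max() >= cube.shape[0] or roi.cols.max() >= cube.shape[1]:
        raise ValueError(f"ROI {roi.roi_id} extends outside the cube")
    if not np.all(cube.mask[roi.rows, roi.cols]):
        raise ValueError(f"ROI {roi.roi_id} contains masked pixels")
    pix = cube.values[roi.rows, roi.cols, :]  # (n_pixels, bands)
    rng = np.random.default_rng(seed)
    out = {
        ("mean", "full"): pix.mean(axis=0),
        ("median", "full"): np.median(pix, axis=0),
    }
    k = _subset_size(roi.n_pixels)
    for sid in SUBSET_IDS:
        idx = rng.choice(roi.n_pixels, size=k, replace=False)
        sub = pix[idx]
        out[("mean", sid)] = sub.mean(axis=0)
        out[("median", sid)] = np.median(sub, axis=0)
    return out


def build_calibration_set(
    rois: list[RegionOfInterest],
    cubes: SpectralCube | Mapping[str, SpectralCube],
    statistic: str = "mean",
    seed: int = 0,
) -> CalibrationSet:
    """Assemble train/validate calibration samples from ROI spectra.

    Per ROI, three randomly chosen 1%-subset spectra become training
    samples; the full-ROI spectrum and the remaining two subsets become
    validation samples.  With 71 ROIs this yields 213 training and 213
    validation samples.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs")
    soc_values = np.array([r.measured_soc for r in rois])
    if np.all(soc_values == soc_values[0]):
        raise ValueError("all ROIs share one SOC value: degenerate calibration")

    def _cube_for(core_id: str) -> SpectralCube:
        if isinstance(cubes, SpectralCube):
            return cubes
        return cubes[core_id]

    treatments = {_cube_for(r.core_id).treatment for r in rois}
    if len(treatments) != 1:
        raise ValueError(f"mixed spectral treatments {treatments}")

    rng = np.random.default_rng(seed)
    samples: list[CalibrationSample] = []
    for roi in rois:
        cube = _cube_for(roi.core_id)
        spectra = extract_roi_spectra(
            cube, roi, seed=int(rng.integers(0, 2**31 - 1))
        )
        train_ids = set(rng.choice(SUBSET_IDS, size=3, replace=False))
        col = float(roi.cols.mean())

        def _mk(subset_id, role):
            return CalibrationSample(
                roi_id=roi.roi_id,
                spectrum=spectra[(statistic, subset_id)],
                statistic=statistic,
                subset_id=subset_id,
                role=role,
                soc=roi.measured_soc,
                core_id=roi.core_id,
                depth_cm=roi.depth_cm,
                horizon=roi.horizon,
                column=col,
            )

        samples.append(_mk("full", "validate"))
        for sid in SUBSET_IDS:
            samples.append(_mk(sid, "train" if sid in train_ids else "validate"))

    return CalibrationSet(
        samples=samples,
        treatment=next(iter(treatments)),
        soc_min=float(soc_values.min()),
        soc_max=float(soc_values.max()),
        statistic=statistic,
    )


# ---------------------------------------------------------------------------
# Automated ROI placement (emulates the visual / PCA-guided selection)
# ---------------------------------------------------------------------------


def select_rois_auto(
    cube: SpectralCube,
    truth_field: np.ndarray,
    n_rois: int,
    core_id: str = "core0",
    plough_depth_cm: float = 30.0,
    topsoil_fraction: float = 0.25,
    pca_extreme_fraction: float = 0.3,
    soc_noise_sd: float = 0.45,
    min_pixels: int = 4,
    seed: int = 0,
) -> list[RegionOfInterest]:
    """Place ROIs on one core: depth-stratified random + PCA-score extremes.

    Emulates manual ROI selection: ~25% of regions in the plough horizon and
    the rest in the subsoil, with a fraction of the subsoil regions centred
    on pixels with extreme first-principal-component scores so that
    spectrally unusual material (e.g. biopores) enters the calibration.
    Regions are kept small and, mimicking the visual screening for 'pure'
    homogeneous material, each ROI is the most spectrally homogeneous
    (smallest PC1-score spread) of several candidate placements.  Measured
    SOC is the truth-field mean over the ROI pixels plus Gaussian
    analytical noise.  Returns fewer ROIs (with a warning) when unmasked
    area runs short.
    """
    if not cube.mask.any():
        raise ValueError("cube is fully masked; cannot place ROIs")
    rng = np.random.default_rng(seed)
    rows_total, cols_total = cube.shape[:2]
    px_cm = cube.pixel_size_cm
    depth_axis = cube.depth_axis_cm()
    n_top = int(round(topsoil_fraction * n_rois))
    n_sub = n_rois - n_top
    n_ext = int(round(pca_extreme_fraction * n_sub))

    scores = pc1_scores(cube)
    sub_rows = depth_axis >= plough_depth_cm
    ext_centroids: list[tuple[int, int]] = []
    sub_scores = np.where(sub_rows[:, None], scores, np.nan)
    finite = np.isfinite(sub_scores)
    if finite.sum() > 10 and n_ext > 0:
        flat = sub_scores[finite]
        lo_thr, hi_thr = np.quantile(flat, [0.02, 0.98])
        extreme = finite & ((sub_scores <= lo_thr) | (sub_scores >= hi_thr))
        er, ec = np.nonzero(extreme)
        if er.size:
            pick = rng.choice(er.size, size=min(n_ext, er.size), replace=False)
            ext_centroids = [(int(er[i]), int(ec[i])) for i in pick]

    rois: list[RegionOfInterest] = []
    counter = 0

    def _candidate(centroid, horizon):
        """One admissible rectangle (rows, cols) or None."""
        if centroid is not None:
            # spectrally extreme material (e.g. biopore channels) is
            # narrow and vertically elongated: sample it with tall,
            # thin regions so the ROI stays 'pure'
            h = int(rng.integers(4, 9))
            w = min(2, cols_total)
        else:
            h = int(rng.integers(2, 7))
            w = int(rng.integers(2, min(7, max(cols_total - 1, 3))))
        if centroid is None:
            if horizon == TOPSOIL:
                lo = 0
                hi = max(int(plough_depth_cm / px_cm) - h, 1)
            else:
                lo = int(plough_depth_cm / px_cm)
                hi = max(rows_total - h, lo + 1)
            r0 = int(rng.integers(lo, hi))
            c0 = int(rng.integers(0, max(cols_total - w, 1)))
        else:
            r0 = int(np.clip(centroid[0] - h // 2, 0, rows_total - h))
            c0 = int(np.clip(centroid[1] - w // 2, 0, cols_total - w))
        rr, cc = np.meshgrid(
            np.arange(r0, r0 + h), np.arange(c0, c0 + w), indexing="ij"
        )
        rr, cc = rr.ravel(), cc.ravel()
        if rr.size < min_pixels or not np.all(cube.mask[rr, cc]):
            return None
        depth = float(depth_axis[rr].mean())
        hz = TOPSOIL if depth < plough_depth_cm else SUBSOIL
        if hz != horizon:
            return None
        return rr, cc

    def _try_place(centroid: tuple[int, int] | None, horizon: str) -> bool:
        nonlocal counter
        # gather admissible candidates, keep the most homogeneous one
        cands = []
        for _ in range(200):
            c = _candidate(centroid, horizon)
            if centroid is not None and c is None:
                centroid = None  # fall back to random placement
                continue
            if c is not None:
                cands.append(c)
            if len(cands) >= 6:
                break
        if not cands:
            return False
        spread = [float(np.std(scores[rr, cc])) for rr, cc in cands]
        rr, cc = cands[int(np.argmin(spread))]
        depth = float(depth_axis[rr].mean())
        truth = float(truth_field[rr, cc].mean())
        soc = max(truth + float(rng.normal(0, soc_noise_sd)), 0.1)
        rois.append(
            RegionOfInterest(
                roi_id=f"{core_id}_roi{counter}",
                core_id=core_id,
                rows=rr,
                cols=cc,
                measured_soc=soc,
                depth_cm=depth,
                horizon=TOPSOIL if depth < plough_depth_cm else SUBSOIL,
                area_cm2=rr.size * px_cm * px_cm,
            )
        )
        counter += 1
        return True

    placed_ext = sum(_try_place(c, SUBSOIL) for c in ext_centroids)
    for _ in range(n_sub - placed_ext):
        _try_place(None, SUBSOIL)
    for _ in range(n_top):
        _try_place(None, TOPSOIL)
    if len(rois) < n_rois:
        warnings.warn(
            f"placed only {len(rois)} of {n_rois} requested ROIs on {core_id}",
            stacklevel=2,
        )
    return rois


def select_roi_set(
    cubes: Mapping[str, SpectralCube],
    truth_fields: Mapping[str, np.ndarray],
    n_total: int = 71,
    seed: int = 0,
    **kwargs,
) -> list[RegionOfInterest]:
    """Distribute ``n_total`` ROIs across the cores of a study set."""
    core_ids = list(cubes)
    n_cores = len(core_ids)
    base, extra = divmod(n_total, n_cores)
    rois: list[RegionOfInterest] = []
    for i, cid in enumerate(core_ids):
        n = base + (1 if i < extra else 0)
        rois.extend(
            select_rois_auto(
                cubes[cid],
                truth_fields[cid],
                n,
                core_id=cid,
                seed=int((seed * 613 + i * 31) % (2**31 - 1)),
                **kwargs,
            )
        )
    return rois
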
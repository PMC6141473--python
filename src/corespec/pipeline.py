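"""End-to-end orchestration: synthetic cores -> SOC maps -> reports.

Stages are stateless functions over a workspace directory, so they can run
individually (CLI subcommands) or chained (:func:`run_full`).  Every stage
records its wall time and the SHA-256 checksum of each output file in
``manifest.json``; a rerun with the same config and seed reproduces
identical checksums.

Workspace layout::

    outdir/
      manifest.json
      cores/<core_id>/raw.img(.hdr) target.img truth_soc.img ...
      cores/<core_id>/nr.img snv.img mask.img pca_rgb.png
      bulk.csv  rois.json  calibration_<treatment>.csv
      models/<model>_<tr>.joblib  models/<model>_<tr>.json
      maps/<variant>/<core_id>.img
      tables/table1.csv table2.csv depth_profile.csv hotspots.csv
      figures/*.png
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
import yaml

from . import envi
from .cube import NORMALIZED_REFLECTANCE, SNV, ReflectanceTarget, SOCMap, SpectralCube
from .evaluation import evaluate_bulk, summarize_distribution
from .models import (
    REFERENCE_SVM_POINT,
    ModelConfig,
    apply_bias_correction,
    constrain_predictions,
    estimate_bias_correction,
    fit_model,
    predict_map,
    validate_model,
)
from .preprocessing import mask_non_soil, normalize_to_target, pca_rgb, snv_transform
from .roi import RegionOfInterest, build_calibration_set, select_roi_set
from .spatial import depth_profile, detect_hotspots
from .synthetic import BulkSample, default_core_set, write_ground_truth

TREATMENT_TAGS = {NORMALIZED_REFLECTANCE: "nr", SNV: "snv"}
TAG_TREATMENTS = {v: k for k, v in TREATMENT_TAGS.items()}


@dataclass
class PipelineConfig:
    outdir: str = "corespec_run"
    seed: int = 0
    n_cores: int = 5
    pixel_size_um: float = 2000.0
    synthetic_overrides: dict = field(default_factory=dict)
    treatments: tuple[str, ...] = (SNV, NORMALIZED_REFLECTANCE)
    models: tuple[str, ...] = ("pls", "rf", "svm")
    constrain_pls: bool = True
    bias_correct_rf: bool = True
    n_rois: int = 71
    svm_full_grid: bool = True  # False: pin the reference operating point
    horizon_boundary_cm: float = 30.0
    window_cm: float = 6.0
    enrichment_threshold: float = 2.0
    annulus_radius_cm: float = 1.0
    spatial_variant: str = "rf_biascorrected_snv"
    model_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.models or not self.treatments:
            raise ValueError("need at least one model and one treatment")
        for t in self.treatments:
            if t not in TREATMENT_TAGS:
                raise ValueError(f"unknown treatment {t!r}")
        for m in self.models:
            if m not in ("pls", "rf", "svm"):
                raise ValueError(f"unknown model {m!r}")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("treatments", "models"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["treatments"] = list(self.treatments)
        d["models"] = list(self.models)
        return d

    def model_config(self, algorithm: str) -> ModelConfig:
        kw = dict(self.model_overrides.get(algorithm, {}))
        if algorithm == "svm" and not self.svm_full_grid:
            kw.setdefault("svm_grid", {k: list(v) for k, v in REFERENCE_SVM_POINT.items()})
        return ModelConfig(algorithm=algorithm, seed=self.seed, **kw)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Stage timings and output checksums, persisted as manifest.json."""

    def __init__(self, outdir: str, config: PipelineConfig):
        self.path = os.path.join(outdir, "manifest.json")
        from . import __version__

        if os.path.exists(self.path):
            with open(self.path) as fh:
                self.data = json.load(fh)
        else:
            self.data = {
                "software": "corespec",
                "version": __version__,
                "config": config.to_dict(),
                "seed": config.seed,
                "stages": {},
            }

    def record(self, stage: str, seconds: float, outputs: list[str], outdir: str):
        self.data["stages"][stage] = {
            "seconds": round(seconds, 3),
            "outputs": {
                os.path.relpath(p, outdir): _sha256(p) for p in sorted(outputs)
            },
        }
        os.makedirs(os.path.dirname(self.path), exist_ok=True)
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)

    def mark_failure(self, stage: str, error: str):
        self.data["stages"][stage] = {"failed": True, "error": error}
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)


def _stage(name):
    """Decorator: time a stage, checksum its outputs, update the manifest."""

    def deco(fn):
        def wrapper(cfg: PipelineConfig, *a, **kw):
            os.makedirs(cfg.outdir, exist_ok=True)
            manifest = RunManifest(cfg.outdir, cfg)
            t0 = time.time()
            try:
                outputs = fn(cfg, *a, **kw)
            except Exception as exc:  # noqa: BLE001 - recorded then re-raised
                manifest.mark_failure(name, f"{type(exc).__name__}: {exc}")
                raise
            manifest.record(name, time.time() - t0, outputs or [], cfg.outdir)
            return outputs

        wrapper.__name__ = f"stage_{name}"
        wrapper.__doc__ = fn.__doc__
        return wrapper

    return deco


# ---------------------------------------------------------------------------
# Workspace helpers
# ---------------------------------------------------------------------------


def _core_ids(cfg: PipelineConfig) -> list[str]:
    return [f"core{i}" for i in range(cfg.n_cores)]


def _core_dir(cfg, core_id):
    return os.path.join(cfg.outdir, "cores", core_id)


def load_cube(cfg: PipelineConfig, core_id: str, which: str) -> SpectralCube:
    """Load ``raw``, ``nr`` or ``snv`` cube of one core from the workspace."""
    d = _core_dir(cfg, core_id)
    vals, wl = envi.read_envi(os.path.join(d, f"{which}.img"))
    mask = None
    mask_path = os.path.join(d, "mask.img")
    if which != "raw" and os.path.exists(mask_path):
        m, _ = envi.read_envi(mask_path)
        mask = m.astype(bool)
    treatment = {"raw": "raw", "nr": NORMALIZED_REFLECTANCE, "snv": SNV}[which]
    return SpectralCube(
        values=vals,
        wavelengths=wl,
        pixel_size_um=cfg.pixel_size_um,
        mask=mask,
        treatment=treatment,
    )


def load_target(cfg: PipelineConfig, core_id: str) -> ReflectanceTarget:
    d = _core_dir(cfg, core_id)
    arr, _ = envi.read_envi(os.path.join(d, "target.img"))
    if arr.ndim == 3:  # stored as (1, cols, bands)
        arr = arr[0]
    with open(os.path.join(d, "target_reflectance.json")) as fh:
        defined = np.array(json.load(fh))
    return ReflectanceTarget(intensity=arr, defined_reflectance=defined)


def load_bulk(cfg: PipelineConfig) -> list[BulkSample]:
    df = pd.read_csv(os.path.join(cfg.outdir, "bulk.csv"))
    return [
        BulkSample(r.core_id, r.depth_top_cm, r.depth_bottom_cm, r.soc_mg_g)
        for r in df.itertuples()
    ]


def load_map(cfg: PipelineConfig, variant: str, core_id: str) -> SOCMap:
    path = os.path.join(cfg.outdir, "maps", variant, f"{core_id}.img")
    vals, _ = envi.read_envi(path)
    return SOCMap(
        values=vals,
        mask=np.isfinite(vals),
        pixel_size_um=cfg.pixel_size_um,
        source=variant,
    )


def load_maps(cfg: PipelineConfig, variant: str) -> dict[str, SOCMap]:
    return {cid: load_map(cfg, variant, cid) for cid in _core_ids(cfg)}


def _write_map(cfg, variant, core_id, soc_map: SOCMap) -> str:
    d = os.path.join(cfg.outdir, "maps", variant)
    os.makedirs(d, exist_ok=True)
    path = os.path.join(d, f"{core_id}.img")
    envi.write_envi(path, soc_map.values.astype(np.float32),
                    description=f"SOC mg/g, {variant}, {core_id}")
    return path


def _map_variants(cfg: PipelineConfig) -> list[tuple[str, str, str]]:
    """(variant_name, model, treatment) for every configured combination."""
    out = []
    for m in cfg.models:
        for t in cfg.treatments:
            out.append((f"{m}_{TREATMENT_TAGS[t]}", m, t))
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


@_stage("simulate")
def run_simulate(cfg: PipelineConfig):
    """Generate the synthetic core set and write all ground truth."""
    cores = default_core_set(
        seed=cfg.seed,
        n_cores=cfg.n_cores,
        pixel_size_um=cfg.pixel_size_um,
        **cfg.synthetic_overrides,
    )
    outputs = []
    bulk_rows = []
    for core in cores:
        d = _core_dir(cfg, core.core_id)
        paths = write_ground_truth(core, d)
        tr_path = os.path.join(d, "target_reflectance.json")
        with open(tr_path, "w") as fh:
            json.dump(core.target.defined_reflectance.tolist(), fh)
        paths["target_reflectance.json"] = tr_path
        outputs.extend(paths.values())
        outputs.extend(p + ".hdr" for p in paths.values() if p.endswith(".img"))
        bulk_rows.extend(
            {
                "core_id": b.core_id,
                "depth_top_cm": b.depth_top_cm,
                "depth_bottom_cm": b.depth_bottom_cm,
                "soc_mg_g": b.soc_mg_g,
            }
            for b in core.bulk_truth
        )
    bulk_path = os.path.join(cfg.outdir, "bulk.csv")
    pd.DataFrame(bulk_rows).to_csv(bulk_path, index=False)
    outputs.append(bulk_path)
    return outputs


@_stage("preprocess")
def run_preprocess(cfg: PipelineConfig):
    """Normalise, mask and SNV-transform every core; render PCA RGB."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outputs = []
    for cid in _core_ids(cfg):
        raw = load_cube(cfg, cid, "raw")
        target = load_target(cfg, cid)
        nr = mask_non_soil(normalize_to_target(raw, target))
        snv = snv_transform(nr)
        d = _core_dir(cfg, cid)
        envi.write_envi(os.path.join(d, "nr.img"), nr.values.astype(np.float32),
                        nr.wavelengths, description="normalized reflectance")
        envi.write_envi(os.path.join(d, "snv.img"), snv.values.astype(np.float32),
                        snv.wavelengths, description="SNV spectra")
        envi.write_envi(os.path.join(d, "mask.img"),
                        snv.mask.astype(np.uint8), description="soil mask")
        img, _, _ = pca_rgb(nr)
        fig, ax = plt.subplots(figsize=(2.2, 7))
        ax.imshow(img, aspect="auto",
                  extent=(0, nr.shape[1] * nr.pixel_size_cm,
                          nr.shape[0] * nr.pixel_size_cm, 0))
        ax.set_xlabel("cm")
        ax.set_ylabel("depth (cm)")
        ax.set_title(f"{cid} PC1-3")
        png = os.path.join(d, "pca_rgb.png")
        fig.savefig(png, dpi=120, bbox_inches="tight")
        plt.close(fig)
        outputs += [
            os.path.join(d, f)
            for f in ("nr.img", "nr.img.hdr", "snv.img", "snv.img.hdr",
                      "mask.img", "mask.img.hdr", "pca_rgb.png")
        ]
    return outputs


@_stage("calibrate")
def run_calibrate(cfg: PipelineConfig):
    """Place ROIs and assemble calibration tables per treatment."""
    snvs, truths = {}, {}
    for cid in _core_ids(cfg):
        snvs[cid] = load_cube(cfg, cid, "snv")
        truths[cid], _ = envi.read_envi(
            os.path.join(_core_dir(cfg, cid), "truth_soc.img")
        )
    rois = select_roi_set(snvs, truths, n_total=cfg.n_rois, seed=cfg.seed)
    roi_path = os.path.join(cfg.outdir, "rois.json")
    with open(roi_path, "w") as fh:
        json.dump(
            [
                {
                    "roi_id": r.roi_id,
                    "core_id": r.core_id,
                    "rows": r.rows.tolist(),
                    "cols": r.cols.tolist(),
                    "measured_soc": r.measured_soc,
                    "depth_cm": r.depth_cm,
                    "horizon": r.horizon,
                    "area_cm2": r.area_cm2,
                }
                for r in rois
            ],
            fh,
        )
    outputs = [roi_path]
    for treatment in cfg.treatments:
        tag = TREATMENT_TAGS[treatment]
        cubes = (
            snvs
            if treatment == SNV
            else {cid: load_cube(cfg, cid, "nr") for cid in _core_ids(cfg)}
        )
        cal = build_calibration_set(rois, cubes, seed=cfg.seed)
        path = os.path.join(cfg.outdir, f"calibration_{tag}.csv")
        cal.to_dataframe().to_csv(path, index=False)
        outputs.append(path)
    return outputs


def load_rois(cfg: PipelineConfig) -> list[RegionOfInterest]:
    with open(os.path.join(cfg.outdir, "rois.json")) as fh:
        data = json.load(fh)
    return [
        RegionOfInterest(
            roi_id=r["roi_id"],
            core_id=r["core_id"],
            rows=np.array(r["rows"]),
            cols=np.array(r["cols"]),
            measured_soc=r["measured_soc"],
            depth_cm=r["depth_cm"],
            horizon=r["horizon"],
            area_cm2=r["area_cm2"],
        )
        for r in data
    ]


def _rebuild_calibration(cfg: PipelineConfig, treatment: str):
    rois = load_rois(cfg)
    which = "snv" if treatment == SNV else "nr"
    cubes = {cid: load_cube(cfg, cid, which) for cid in _core_ids(cfg)}
    return build_calibration_set(rois, cubes, seed=cfg.seed)


@_stage("fit")
def run_fit(cfg: PipelineConfig):
    """Fit every configured (model, treatment) pair; persist with metadata."""
    outputs = []
    mdir = os.path.join(cfg.outdir, "models")
    os.makedirs(mdir, exist_ok=True)
    for treatment in cfg.treatments:
        cal = _rebuild_calibration(cfg, treatment)
        for algo in cfg.models:
            model = fit_model(cal, cfg.model_config(algo))
            vm = validate_model(model, cal)
            stem = os.path.join(mdir, f"{algo}_{TREATMENT_TAGS[treatment]}")
            joblib.dump(model, stem + ".joblib")
            with open(stem + ".json", "w") as fh:
                json.dump(
                    {
                        "algorithm": algo,
                        "treatment": treatment,
                        "soc_min": model.soc_min,
                        "soc_max": model.soc_max,
                        "hyperparameters": {
                            k: v
                            for k, v in model.hyperparameters.items()
                            if not isinstance(v, list)
                        },
                        "validation": vm.as_dict(),
                        "seed": cfg.seed,
                    },
                    fh,
                    indent=1,
                )
            outputs += [stem + ".joblib", stem + ".json"]
    return outputs


@_stage("predict")
def run_predict(cfg: PipelineConfig):
    """Predict SOC maps; derive constrained-PLS and bias-corrected-RF maps."""
    outputs = []
    bulk = load_bulk(cfg)
    for variant, algo, treatment in _map_variants(cfg):
        tag = TREATMENT_TAGS[treatment]
        model = joblib.load(
            os.path.join(cfg.outdir, "models", f"{algo}_{tag}.joblib")
        )
        which = "snv" if treatment == SNV else "nr"
        maps = {}
        for cid in _core_ids(cfg):
            maps[cid] = predict_map(model, load_cube(cfg, cid, which))
            outputs.append(_write_map(cfg, variant, cid, maps[cid]))
        if algo == "pls" and cfg.constrain_pls:
            for cid, m in maps.items():
                cm = constrain_predictions(m, model.soc_min, model.soc_max)
                outputs.append(_write_map(cfg, f"pls_constrained_{tag}", cid, cm))
        if algo == "rf" and cfg.bias_correct_rf:
            ev = evaluate_bulk(maps, bulk)
            mid = 0.5 * (
                ev.slabs["depth_top_cm"] + ev.slabs["depth_bottom_cm"]
            ).to_numpy()
            bc = estimate_bias_correction(
                ev.slabs["pred_mean"].to_numpy(),
                ev.slabs["measured"].to_numpy(),
                mid,
                cfg.horizon_boundary_cm,
            )
            bc_path = os.path.join(cfg.outdir, f"bias_correction_{tag}.json")
            with open(bc_path, "w") as fh:
                json.dump(
                    {
                        "topsoil_offset": bc.topsoil_offset,
                        "subsoil_offset": bc.subsoil_offset,
                        "horizon_boundary_cm": bc.horizon_boundary_cm,
                    },
                    fh,
                    indent=1,
                )
            outputs.append(bc_path)
            for cid, m in maps.items():
                outputs.append(
                    _write_map(
                        cfg,
                        f"rf_biascorrected_{tag}",
                        cid,
                        apply_bias_correction(m, bc),
                    )
                )
    return outputs


def _available_variants(cfg: PipelineConfig) -> list[str]:
    d = os.path.join(cfg.outdir, "maps")
    return sorted(os.listdir(d)) if os.path.isdir(d) else []


@_stage("evaluate")
def run_evaluate(cfg: PipelineConfig):
    """Distribution summaries and bulk goodness-of-fit for every variant."""
    bulk = load_bulk(cfg)
    # the calibration upper limit: highest analysed SOC
    cal_meta_path = os.path.join(
        cfg.outdir, "models",
        f"{cfg.models[0]}_{TREATMENT_TAGS[cfg.treatments[0]]}.json",
    )
    with open(cal_meta_path) as fh:
        meta = json.load(fh)
    soc_max = meta["soc_max"]
    t1_rows, t2_rows = [], []
    for variant in _available_variants(cfg):
        maps = load_maps(cfg, variant)
        pooled = np.concatenate([m.unmasked() for m in maps.values()])
        pooled_map = SOCMap(
            values=pooled[:, None],
            mask=np.ones((pooled.size, 1), bool),
            pixel_size_um=cfg.pixel_size_um,
        )
        t1_rows.append(
            {"variant": variant,
             **summarize_distribution(pooled_map, soc_max).as_dict()}
        )
        ev = evaluate_bulk(maps, bulk)
        for key, fm in ev.metrics.items():
            t2_rows.append({"variant": variant, "evaluation": key,
                            **fm.as_dict()})
    tdir = os.path.join(cfg.outdir, "tables")
    os.makedirs(tdir, exist_ok=True)
    p1 = os.path.join(tdir, "table1.csv")
    p2 = os.path.join(tdir, "table2.csv")
    pd.DataFrame(t1_rows).to_csv(p1, index=False)
    pd.DataFrame(t2_rows).to_csv(p2, index=False)
    return [p1, p2]


@_stage("profile")
def run_profile(cfg: PipelineConfig):
    """Equal-area depth profiles of the headline map variant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    variant = cfg.spatial_variant
    if variant not in _available_variants(cfg):
        variant = _available_variants(cfg)[0]
    frames = []
    for cid, m in load_maps(cfg, variant).items():
        df = depth_profile(m, cfg.window_cm)
        df.insert(0, "core_id", cid)
        frames.append(df)
    prof = pd.concat(frames, ignore_index=True)
    tdir = os.path.join(cfg.outdir, "tables")
    os.makedirs(tdir, exist_ok=True)
    csv = os.path.join(tdir, "depth_profile.csv")
    prof.to_csv(csv, index=False)
    fig, axes = plt.subplots(1, 2, figsize=(7, 6), sharey=True)
    for cid, g in prof.groupby("core_id"):
        axes[0].plot(g["mean"], g["depth_mid_cm"], label=cid)
        axes[1].plot(g["cv"], g["depth_mid_cm"])
    axes[0].invert_yaxis()
    axes[0].set_xlabel("mean SOC (mg/g)")
    axes[1].set_xlabel("CV")
    axes[0].set_ylabel("depth (cm)")
    axes[0].legend(fontsize=6)
    fdir = os.path.join(cfg.outdir, "figures")
    os.makedirs(fdir, exist_ok=True)
    png = os.path.join(fdir, "depth_profile.png")
    fig.savefig(png, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return [csv, png]


@_stage("hotspots")
def run_hotspots(cfg: PipelineConfig):
    """Hotspot/coldspot detection on the headline map variant."""
    variant = cfg.spatial_variant
    if variant not in _available_variants(cfg):
        variant = _available_variants(cfg)[0]
    frames, outputs = [], []
    for cid, m in load_maps(cfg, variant).items():
        rep = detect_hotspots(
            m,
            enrichment_threshold=cfg.enrichment_threshold,
            annulus_radius_cm=cfg.annulus_radius_cm,
        )
        df = rep.to_dataframe()
        df.insert(0, "core_id", cid)
        frames.append(df)
        lab_path = os.path.join(
            cfg.outdir, "maps", variant, f"{cid}_hotspot_labels.img"
        )
        envi.write_envi(lab_path, rep.label_raster(m.shape).astype(np.int32),
                        description="hotspot/coldspot region labels")
        outputs.append(lab_path)
    tdir = os.path.join(cfg.outdir, "tables")
    os.makedirs(tdir, exist_ok=True)
    csv = os.path.join(tdir, "hotspots.csv")
    pd.concat(frames, ignore_index=True).to_csv(csv, index=False)
    outputs.append(csv)
    return outputs


STAGES = {
    "simulate": run_simulate,
    "preprocess": run_preprocess,
    "calibrate": run_calibrate,
    "fit": run_fit,
    "predict": run_predict,
    "evaluate": run_evaluate,
    "profile": run_profile,
    "hotspots": run_hotspots,
}


def run_full(cfg: PipelineConfig) -> dict[str, list[str]]:
    """Run every stage in order; returns stage -> output paths.

    A stage failure raises after being recorded in the manifest, leaving
    earlier outputs in place.
    """
    return {name: fn(cfg) for name, fn in STAGES.items()}
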
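"""End-to-end workflow orchestration.

The stage order follows the standard hyperspectral calibration workflow:
acquire/synthesize reflectance -> extract ROI-mean spectra -> MCPLS outlier
screening -> SPXY calibration/prediction partition -> fit pretreatment on
the calibration set -> wavelength selection -> model fitting -> evaluation
-> (optionally) pixel-wise mapping.  Every stage persists its artifact, and
the machine-readable run report captures all settings and seeds so a run
can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import cube_io, outliers, partition as partition_mod, regress, synth, wavesel
from .bundle import ModelBundle
from .cube_io import SpectraTable
from .errors import BrixmapError, ConfigError
from .pretreat import make_pretreatment

logger = logging.getLogger(__name__)

MARKERS_PER_SLICE = 5
SLICES_PER_ROOT = 6
MARKERS_PER_ROOT = MARKERS_PER_SLICE * SLICES_PER_ROOT  # 30, one punched slice set
ROOTS_PER_CULTIVAR = 14
N_CULTIVARS = 2


def markers_per_cultivar(
    markers_per_root: int = MARKERS_PER_ROOT, n_roots: int = ROOTS_PER_CULTIVAR
) -> int:
    """ROI count for one cultivar (30 markers x 14 roots = 420)."""
    return markers_per_root * n_roots


def total_markers(
    markers_per_root: int = MARKERS_PER_ROOT,
    n_roots: int = ROOTS_PER_CULTIVAR,
    n_cultivars: int = N_CULTIVARS,
) -> int:
    """Whole-study ROI count (both cultivars)."""
    return markers_per_cultivar(markers_per_root, n_roots) * n_cultivars


def retained_after_screening(n_samples: int, n_flagged: int) -> int:
    if n_flagged > n_samples:
        raise ConfigError("cannot flag more samples than exist")
    return n_samples - n_flagged


@dataclass
class PipelineConfig:
    """Single-source configuration for a full run (YAML-serializable)."""

    # input: either a synthetic-spectra source or file paths
    source: str = "synthetic"  # "synthetic" | "files"
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    cube_header: str | None = None
    roi_csv: str | None = None
    reference_csv: str | None = None
    spectra_csv: str | None = None

    pretreatment: str = "snv"
    pretreatment_params: dict = field(default_factory=dict)

    screen: bool = True
    mcpls_n_iter: int = 500
    mcpls_cal_frac: float = 0.75
    mcpls_n_components: int = 10
    mpre_cut: float | None = None  # None -> auto threshold
    stdpre_cut: float | None = None
    auto_threshold_k: float = 3.0

    spxy_ratio: float = 3.0

    selector: str = "spa"  # "spa" | "cars" | "none"
    selector_params: dict = field(default_factory=dict)

    model: str = "plsr"  # "plsr" | "svr" | "mlr"
    model_params: dict = field(default_factory=dict)

    out_dir: str = "brixmap_run"
    seed: int = 0
    name: str = "run"

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = str(source)
        if "\n" not in text:
            p = Path(text)
            if p.exists():
                text = p.read_text()
        d = yaml.safe_load(text)
        if "synth" in d and isinstance(d["synth"], dict):
            sd = d["synth"]
            for key in ("peak_centers", "peak_widths", "peak_depths",
                        "ssc_coupling", "baseline_coef"):
                if key in sd and isinstance(sd[key], list):
                    sd[key] = tuple(sd[key])
            d["synth"] = synth.SynthConfig(**sd)
        return cls(**d)


#: Published per-cultivar protocol settings: 5000 MCPLS iterations at 75%
#: calibration fraction, SPXY 3:1, and the per-cultivar residual cuts /
#: winning pretreatment from the screening comparison.
PAPER_PROTOCOL_PRESETS = {
    "beijing553": {
        "pretreatment": "detrend",
        "mcpls_n_iter": 5000,
        "mcpls_cal_frac": 0.75,
        "mpre_cut": 1.0,
        "stdpre_cut": 0.099,
        "spxy_ratio": 3.0,
        "ssc_mean": 11.8,
        "ssc_sd": 0.78,
    },
    "redbanana": {
        "pretreatment": "none",
        "mcpls_n_iter": 5000,
        "mcpls_cal_frac": 0.75,
        "mpre_cut": 0.75,
        "stdpre_cut": 0.12,
        "spxy_ratio": 3.0,
        "ssc_mean": 8.0,
        "ssc_sd": 0.67,
    },
}


def make_paper_protocol_config(cultivar_preset: str, **overrides) -> PipelineConfig:
    """Config encoding the published per-cultivar protocol numbers."""
    if cultivar_preset not in PAPER_PROTOCOL_PRESETS:
        raise ConfigError(
            f"unknown preset '{cultivar_preset}'; choose from "
            f"{sorted(PAPER_PROTOCOL_PRESETS)}"
        )
    p = dict(PAPER_PROTOCOL_PRESETS[cultivar_preset])
    ssc_mean = p.pop("ssc_mean")
    ssc_sd = p.pop("ssc_sd")
    cfg = PipelineConfig(
        name=cultivar_preset,
        synth=synth.SynthConfig(ssc_mean=ssc_mean, ssc_sd=ssc_sd),
        **p,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def _load_spectra(config: PipelineConfig) -> SpectraTable:
    if config.source == "synthetic":
        cfg = dataclasses.replace(config.synth, seed=config.seed)
        return synth.generate_spectra(cfg).to_table()
    if config.source == "files":
        if config.spectra_csv:
            return SpectraTable.from_csv(config.spectra_csv)
        if not (config.cube_header and config.roi_csv and config.reference_csv):
            raise ConfigError(
                "source 'files' needs spectra_csv or cube_header+roi_csv+reference_csv"
            )
        cube = cube_io.read_envi(config.cube_header)
        rois = cube_io.ROISet.from_csv(config.roi_csv)
        table = cube_io.extract_mean_spectra(cube, rois)
        import pandas as pd

        ref = pd.read_csv(config.reference_csv).set_index("sample_id")
        table.y = ref.loc[table.sample_ids, "ssc_brix"].to_numpy(dtype=float)
        return table
    raise ConfigError(f"unknown source '{config.source}'")


def run_pipeline(config: PipelineConfig, cube=None, mask=None) -> dict:
    """Execute all stages; returns the run report (also persisted as JSON).

    ``cube``/``mask`` may be passed to additionally produce a distribution
    map with the fitted bundle.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"name": config.name, "seed": config.seed, "stages": {}, "artifacts": {}}
    config.to_yaml(out / "config.yaml")
    report["artifacts"]["config"] = "config.yaml"

    stage = "load"
    try:
        t0 = time.perf_counter()
        table = _load_spectra(config)
        table.to_csv(out / "spectra.csv")
        report["stages"]["load"] = {
            "n_samples": table.n_samples, "n_bands": table.n_bands,
            "seconds": round(time.perf_counter() - t0, 3),
        }
        report["artifacts"]["spectra"] = "spectra.csv"

        # --- outlier screening -------------------------------------------
        stage = "screen"
        t0 = time.perf_counter()
        if config.screen:
            rep = outliers.run_mcpls(
                table,
                n_iter=config.mcpls_n_iter,
                cal_frac=config.mcpls_cal_frac,
                n_components=config.mcpls_n_components,
                seed=config.seed,
            )
            if config.mpre_cut is not None and config.stdpre_cut is not None:
                cuts = (config.mpre_cut, config.stdpre_cut)
            else:
                cuts = outliers.auto_threshold(rep, config.auto_threshold_k)
            rep = outliers.flag_outliers(rep, *cuts)
            rep.to_csv(out / "outlier_report.csv", table.sample_ids)
            retained = rep.retained_indices()
            report["stages"]["screen"] = {
                "n_flagged": rep.n_flagged,
                "n_retained": int(retained.size),
                "thresholds": list(rep.thresholds),
                "settings": rep.settings,
                "seconds": round(time.perf_counter() - t0, 3),
            }
            report["artifacts"]["outlier_report"] = "outlier_report.csv"
            table = table.subset(retained)
        else:
            report["stages"]["screen"] = {"skipped": True}

        # --- partition ----------------------------------------------------
        stage = "partition"
        t0 = time.perf_counter()
        part = partition_mod.spxy_partition(table, ratio=config.spxy_ratio)
        part.to_csv(out / "partition.csv", table.sample_ids)
        part.stats.to_csv(out / "partition_stats.csv", index=False)
        cal, pred = table.subset(part.cal_index), table.subset(part.pred_index)
        report["stages"]["partition"] = {
            "n_cal": int(part.cal_index.size),
            "n_pred": int(part.pred_index.size),
            "ratio": config.spxy_ratio,
            "stats": part.stats.to_dict(orient="records"),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        report["artifacts"]["partition"] = "partition.csv"

        # --- pretreatment (fitted on calibration only) --------------------
        stage = "pretreat"
        pre = make_pretreatment(config.pretreatment, **config.pretreatment_params)
        pre.fit(cal.x)
        cal_t = cal.with_x(pre.transform(cal.x))
        pred_t = pred.with_x(pre.transform(pred.x))
        report["stages"]["pretreat"] = {"method": config.pretreatment,
                                        "params": config.pretreatment_params}

        # --- wavelength selection -----------------------------------------
        stage = "select"
        t0 = time.perf_counter()
        if config.selector == "none":
            selected = np.arange(table.n_bands)
            sel_info = {"method": "none", "count": int(table.n_bands)}
        elif config.selector == "spa":
            result = wavesel.spa_select(cal_t, **config.selector_params)
            result.to_json(out / "selection.json")
            selected = np.asarray(result.selected)
            sel_info = wavesel.report_selection(result, table.n_bands)
            report["artifacts"]["selection"] = "selection.json"
        elif config.selector == "cars":
            params = dict(config.selector_params)
            params.setdefault("seed", config.seed)
            result = wavesel.cars_select(cal_t, **params)
            result.to_json(out / "selection.json")
            selected = np.asarray(result.selected)
            sel_info = wavesel.report_selection(result, table.n_bands)
            report["artifacts"]["selection"] = "selection.json"
        else:
            raise ConfigError(f"unknown selector '{config.selector}'")
        sel_info["seconds"] = round(time.perf_counter() - t0, 3)
        report["stages"]["select"] = sel_info

        # --- model --------------------------------------------------------
        stage = "train"
        t0 = time.perf_counter()
        cal_sel = SpectraTable(
            x=cal_t.x[:, selected], wavelengths=table.wavelengths[selected],
            y=cal_t.y, sample_ids=list(cal_t.sample_ids),
        )
        pred_sel = SpectraTable(
            x=pred_t.x[:, selected], wavelengths=table.wavelengths[selected],
            y=pred_t.y, sample_ids=list(pred_t.sample_ids),
        )
        mp = dict(config.model_params)
        if config.model == "plsr":
            ncomp = mp.get("n_components")
            if ncomp is None:
                ncomp = regress.select_plsr_rank(
                    cal_sel, max_rank=mp.get("max_rank", 20)
                )
            model = regress.fit_plsr(cal_sel, n_components=ncomp)
            model_info = {"kind": "plsr", "n_components": int(ncomp)}
        elif config.model == "svr":
            if {"C", "epsilon", "gamma"} <= set(mp):
                params = regress.SVRParams(mp["C"], mp["epsilon"], mp["gamma"])
            else:
                params = regress.grid_search_svr(cal_sel, seed=config.seed)
            model = regress.fit_svr(cal_sel, params)
            model_info = {"kind": "svr", "params": dataclasses.asdict(params)}
        elif config.model == "mlr":
            model = regress.fit_mlr(
                cal_sel, alpha=mp.get("alpha", 0.05),
                eliminate=mp.get("eliminate", False),
            )
            model_info = {"kind": "mlr", "alpha": mp.get("alpha", 0.05)}
        else:
            raise ConfigError(f"unknown model '{config.model}'")
        model_info["seconds"] = round(time.perf_counter() - t0, 3)
        report["stages"]["train"] = model_info

        bundle = ModelBundle(
            pretreatment=pre, selected_bands=selected, model=model,
            wavelengths=table.wavelengths,
            meta={"name": config.name, "seed": config.seed,
                  "pretreatment": config.pretreatment, "selector": config.selector,
                  "model": config.model},
        )
        bundle.to_json(out / "bundle.json")
        report["artifacts"]["bundle"] = "bundle.json"

        # --- evaluate -----------------------------------------------------
        stage = "evaluate"
        metrics = regress.evaluate(model, cal_sel, pred_sel)
        report["stages"]["evaluate"] = metrics.rounded()
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics.rounded(), fh, indent=2, sort_keys=True)
        report["artifacts"]["metrics"] = "metrics.json"

        # --- optional map -------------------------------------------------
        if cube is not None:
            stage = "map"
            from . import mapping

            ssc_map = mapping.predict_pixels(cube, bundle, mask=mask)
            mapping.render_map(ssc_map, cube=cube, path=out / "ssc_map.png")
            report["stages"]["map"] = {
                "n_pixels": int(ssc_map.mask.sum()),
                "render_range": list(ssc_map.render_range),
            }
            report["artifacts"]["map"] = "ssc_map.png"
    except BrixmapError as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        raise

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    report["artifacts"]["run_report"] = "run_report.json"
    return report
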
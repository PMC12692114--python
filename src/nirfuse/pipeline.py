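"""Config-driven orchestration of the full multi-quality workflow.

One YAML config drives: data generation (or loading) → preprocessing →
Kennard–Stone split → per-trait wavelength selection and PLSR modelling →
trait correlation analysis → cross-parameter band fusion → multi-stage
Shapley screening of the firmness model.  All randomness flows from a single
seed; the result is a machine-readable report whose every number can be
recomputed from the logged config + seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fusion_shap, preprocess, select, synthetic
from .model import (compute_metrics, fit_plsr, kennard_stone, predict,
                    select_components)

log = logging.getLogger("nirfuse")


class ConfigError(ValueError):
    """Raised with a key path when a pipeline config is invalid."""


@dataclass
class PipelineConfig:
    synthetic: dict = field(default_factory=dict)   # overrides for default_config
    spectra_path: str | None = None                 # alternative: load from CSV
    traits_path: str | None = None
    trim_head: int = 15
    trim_tail: int = 15
    range_nm: tuple[float, float] | None = None
    methods: list[str] = field(default_factory=lambda: ["minmax", "snv"])
    sg_window: int = 7
    sg_polyorder: int = 2
    sg_deriv: int = 0
    n_cal: int | None = None                        # default: 2/3 of samples
    max_components: int = 20
    cv_folds: int = 5
    selectors: dict = field(default_factory=lambda: {
        "ssc_brix": {"method": "sfla"},
        "mc_fraction": {"method": "cars"},
        "ff_newton": {"method": "cars"},
    })
    fusion: bool = True
    screening_target: str = "ff_newton"
    thresholds: list[float] | None = None           # default: importance quartiles
    one_shot: bool = False
    seed: int = 0
    outdir: str | None = None


_SCHEMA = {
    "data": {"synthetic": dict, "spectra": str, "traits": str},
    "preprocess": {"trim_head": int, "trim_tail": int, "range": list,
                   "methods": list, "sg_window": int, "sg_polyorder": int,
                   "sg_deriv": int},
    "split": {"n_cal": int},
    "model": {"max_components": int, "cv_folds": int},
    "select": {"ssc_brix": dict, "mc_fraction": dict, "ff_newton": dict},
    "fusion": bool,
    "screening": {"target": str, "thresholds": list, "one_shot": bool},
    "seed": int,
    "outdir": str,
}

_METHODS = {"minmax", "snv", "msc", "sg"}


def validate_config(raw_text: str) -> PipelineConfig:
    """Parse + schema-check a YAML pipeline config; inject defaults."""
    doc = yaml.safe_load(raw_text)
    if doc is None or not isinstance(doc, dict) or not doc:
        raise ConfigError("missing required section 'data' (empty config)")
    for key, val in doc.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown top-level key '{key}'")
        want = _SCHEMA[key]
        if isinstance(want, dict):
            if not isinstance(val, dict):
                raise ConfigError(f"'{key}' must be a mapping")
            for sub, sval in val.items():
                if sub not in want:
                    raise ConfigError(f"unknown key '{key}.{sub}'")
                if sval is not None and not isinstance(sval, want[sub]):
                    raise ConfigError(
                        f"'{key}.{sub}' must be {want[sub].__name__}, "
                        f"got {type(sval).__name__}")
        elif val is not None and not isinstance(val, want):
            raise ConfigError(f"'{key}' must be {want.__name__}")
    if "data" not in doc:
        raise ConfigError("missing required section 'data'")

    cfg = PipelineConfig()
    data = doc["data"]
    if "spectra" in data:
        if "traits" not in data:
            raise ConfigError("'data.traits' is required with 'data.spectra'")
        cfg.spectra_path, cfg.traits_path = data["spectra"], data["traits"]
    else:
        cfg.synthetic = data.get("synthetic") or {}
    pp = doc.get("preprocess", {})
    cfg.trim_head = pp.get("trim_head", cfg.trim_head)
    cfg.trim_tail = pp.get("trim_tail", cfg.trim_tail)
    if pp.get("range") is not None:
        rng = pp["range"]
        if len(rng) != 2 or not rng[0] < rng[1]:
            raise ConfigError("'preprocess.range' must be [lo, hi] with lo < hi")
        cfg.range_nm = (float(rng[0]), float(rng[1]))
    methods = pp.get("methods", cfg.methods)
    bad = [m for m in methods if m not in _METHODS]
    if bad:
        raise ConfigError(f"unknown preprocessing method(s) {bad}")
    cfg.methods = list(methods)
    cfg.sg_window = pp.get("sg_window", cfg.sg_window)
    cfg.sg_polyorder = pp.get("sg_polyorder", cfg.sg_polyorder)
    cfg.sg_deriv = pp.get("sg_deriv", cfg.sg_deriv)
    cfg.n_cal = doc.get("split", {}).get("n_cal")
    mdl = doc.get("model", {})
    cfg.max_components = mdl.get("max_components", cfg.max_components)
    cfg.cv_folds = mdl.get("cv_folds", cfg.cv_folds)
    sel = doc.get("select")
    if sel is not None:
        for trait, spec_ in sel.items():
            if spec_.get("method", "cars") not in {"cars", "sfla", "none"}:
                raise ConfigError(
                    f"'select.{trait}.method' must be cars|sfla|none")
        cfg.selectors = sel
    if "fusion" in doc:
        cfg.fusion = bool(doc["fusion"])
    scr = doc.get("screening", {})
    cfg.screening_target = scr.get("target", cfg.screening_target)
    if scr.get("thresholds") is not None:
        thr = [float(t) for t in scr["thresholds"]]
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ConfigError("'screening.thresholds' must be strictly increasing")
        cfg.thresholds = thr
    cfg.one_shot = scr.get("one_shot", False)
    cfg.seed = doc.get("seed", 0)
    cfg.outdir = doc.get("outdir")
    return cfg


def apply_preprocessing(block: preprocess.SpectraBlock,
                        cfg: PipelineConfig) -> preprocess.SpectraBlock:
    if cfg.trim_head or cfg.trim_tail:
        block = preprocess.trim_head_tail(block, cfg.trim_head, cfg.trim_tail)
    if cfg.range_nm is not None:
        block = preprocess.restrict_range(block, *cfg.range_nm)
    for m in cfg.methods:
        if m == "minmax":
            block = preprocess.minmax_rows(block)
        elif m == "snv":
            block = preprocess.snv(block)
        elif m == "msc":
            block = preprocess.msc(block)
        elif m == "sg":
            block = preprocess.savitzky_golay(
                block, cfg.sg_window, cfg.sg_polyorder, cfg.sg_deriv)
    return block


def _run_selector(trait: str, spec_: dict, X, y, seed: int):
    method = spec_.get("method", "cars")
    opts = {k: v for k, v in spec_.items() if k != "method"}
    if method == "none":
        return None
    if method == "cars":
        return select.cars(X, y, select.CarsConfig(seed=seed, **opts))
    return select.sfla(X, y, select.SflaConfig(seed=seed, **opts))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow; return (and optionally write) the report."""
    t0 = time.time()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(8) % (2 ** 31)

    # --- data -------------------------------------------------------------
    if cfg.spectra_path:
        block = preprocess.read_spectra(cfg.spectra_path)
        traits = synthetic.read_traits(cfg.traits_path)
    else:
        syn = synthetic.default_config(**{**cfg.synthetic, "seed": int(seeds[0])})
        block, traits = synthetic.generate(syn)
    log.info("data: %d samples × %d wavelengths", block.n_samples,
             block.n_wavelengths)

    # --- trait correlations (all samples, before splitting) ---------------
    corr = fusion_shap.pearson_matrix(traits)

    # --- preprocessing ----------------------------------------------------
    pre = apply_preprocessing(block, cfg)
    log.info("preprocessed: %d wavelengths retained", pre.n_wavelengths)

    # --- split ------------------------------------------------------------
    n_cal = cfg.n_cal if cfg.n_cal is not None else round(pre.n_samples * 2 / 3)
    split = kennard_stone(pre.values, n_cal)
    cal, val = split.calibration_ids, split.validation_ids

    # --- per-trait selection + modelling ----------------------------------
    per_trait: dict[str, dict] = {}
    band_lists, band_sources = [], []
    for k, trait in enumerate(synthetic.TRAIT_NAMES):
        spec_ = cfg.selectors.get(trait)
        if spec_ is None:
            continue
        y = traits.column(trait)
        res = _run_selector(trait, spec_, pre.values[cal], y[cal],
                            int(seeds[1 + k]))
        idx = res.selected if res is not None else list(range(pre.n_wavelengths))
        Xs = pre.values[:, idx]
        a = select_components(Xs[cal], y[cal],
                              max_components=cfg.max_components,
                              cv_folds=cfg.cv_folds)
        m = fit_plsr(Xs[cal], y[cal], a, wavelength_ids=idx)
        cal_m = compute_metrics(y[cal], predict(m, Xs[cal]))
        val_m = compute_metrics(y[val], predict(m, Xs[val]))
        nm = [float(pre.wavelengths[j]) for j in idx]
        per_trait[trait] = {
            "selector": spec_.get("method", "cars"),
            "selected_indices": list(map(int, idx)),
            "selected_nm": nm,
            "n_components": m.n_components,
            "rc2": cal_m.r2, "rp2": val_m.r2,
            "rmse_cal": cal_m.rmse, "rmse_val": val_m.rmse,
        }
        band_lists.append(nm)
        band_sources.append(trait)
        log.info("%s: %d bands, %d comps, Rc²=%.4f Rp²=%.4f", trait, len(nm),
                 m.n_components, cal_m.r2, val_m.r2)

    report: dict = {
        "config": {**asdict(cfg)},
        "trait_correlation": corr.tolist(),
        "per_trait": per_trait,
    }

    # --- fusion + screening -----------------------------------------------
    if cfg.fusion and band_lists:
        fused = fusion_shap.fuse_bands(band_lists, band_sources)
        lookup = {round(float(w), 3): j
                  for j, w in enumerate(pre.wavelengths)}
        fused_idx = [lookup[round(w, 3)] for w in fused.wavelengths]
        report["fusion"] = {
            "n_bands": len(fused),
            "wavelengths_nm": fused.wavelengths,
            "provenance": fused.provenance,
        }
        ytgt = traits.column(cfg.screening_target)
        Xf = pre.values[:, fused_idx]
        a = select_components(Xf[cal], ytgt[cal],
                              max_components=cfg.max_components,
                              cv_folds=cfg.cv_folds)
        if cfg.thresholds is None:
            m0 = fit_plsr(Xf[cal], ytgt[cal], a)
            imp0 = fusion_shap.band_importance(
                fusion_shap.shap_linear(m0, Xf[cal], Xf[cal].mean(axis=0)))
            thr = sorted(set(float(np.quantile(imp0, q))
                             for q in (0.25, 0.5, 0.75)))
        else:
            thr = cfg.thresholds
        stages = fusion_shap.screen_stages(
            Xf, ytgt, split, fused, thr, n_components=a, one_shot=cfg.one_shot)
        report["screening"] = {
            "target": cfg.screening_target,
            "thresholds": thr,
            "stages": [{
                "threshold": st.threshold,
                "n_bands": len(st.retained),
                "wavelengths_nm": st.retained.wavelengths,
                "rc2": st.cal_metrics.r2 if st.cal_metrics else None,
                "rp2": st.val_metrics.r2 if st.val_metrics else None,
                "rmse_val": st.val_metrics.rmse if st.val_metrics else None,
                "degenerate": st.degenerate,
            } for st in stages],
        }

    report["split"] = {"n_cal": len(cal), "n_val": len(val),
                       "calibration_ids": list(map(int, cal)),
                       "validation_ids": list(map(int, val))}
    log.info("pipeline finished in %.2f s", time.time() - t0)

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True))
        preprocess.write_spectra(pre, out / "preprocessed_spectra.csv")
        synthetic.write_traits(traits, out / "traits.csv")
    return report
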
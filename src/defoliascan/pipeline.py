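"""End-to-end orchestration: simulate -> select bands -> build features ->
screen -> classify, from one RunConfig, with a machine-readable report.

A single root seed fans out deterministically to per-stage seeds
(spectra, clouds, split, selection) so any stage can be rerun in
isolation and a rerun of the whole pipeline reproduces every number.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import sklearn

import defoliascan
from defoliascan import bandselect, classify_eval, features as feat, screening, synthgen
from defoliascan.dataio import (
    RunConfig,
    SpectraTable,
    read_cloud,
    read_spectra,
    write_cloud,
    write_json_report,
    write_spectra,
)
from defoliascan.errors import DefoliascanError, InvalidInputError

log = logging.getLogger("defoliascan")

SOURCES = ("hsi", "lidar", "combined")


def stage_seeds(root_seed: int) -> dict:
    """Deterministic per-stage seed fan-out from one root seed."""
    state = np.random.SeedSequence(root_seed).generate_state(4) % (2**31)
    return {
        "spectra": int(state[0]),
        "clouds": int(state[1]),
        "split": int(state[2]),
        "selection": int(state[3]),
    }


def _load_inputs(config: RunConfig, seeds: dict):
    if config.simulate:
        spectra = synthgen.generate_spectra_dataset(
            synthgen.SpectraConfig(seed=seeds["spectra"])
        )
        clouds = synthgen.generate_cloud_set(
            spectra, synthgen.CrownConfig(seed=seeds["clouds"])
        )
        return spectra, clouds
    if not config.spectra_path or not config.clouds_dir:
        raise InvalidInputError("simulate=false requires spectra_path and clouds_dir")
    spectra = read_spectra(config.spectra_path)
    clouds = {}
    for tid in spectra.tree_id:
        path = Path(config.clouds_dir) / f"{tid}.xyz"
        clouds[str(tid)] = read_cloud(path, tree_id=str(tid))
    return spectra, clouds


def select_bands(spectra: SpectraTable, config: RunConfig, seed: int):
    """Run the configured selection method on a (training) spectra table."""
    cv_cfg = bandselect.CVConfig(
        folds=config.cv_folds,
        seed=seed,
        n_estimators=config.selection_trees,
        tol=config.accuracy_tol,
    )
    method = config.selection_method
    if method == "fixed":
        idx = [spectra.band_nearest(w) for w in config.fixed_wavelengths]
        return bandselect.BandSelectionResult(
            method="fixed",
            band_indices=idx,
            wavelengths=[float(spectra.wavelengths[i]) for i in idx],
            accuracy_curve=[],
            chosen_size=len(idx),
        )
    if method == "spa":
        return bandselect.spa_select(
            spectra, cv_cfg=cv_cfg, k_max=config.k_max, starts=config.n_starts
        )
    if method == "isic":
        return bandselect.isic_select(spectra, cv_cfg=cv_cfg)
    return bandselect.isic_spa_select(
        spectra, cv_cfg=cv_cfg, k_max=config.k_max, starts=config.n_starts
    )


def classify_sources(feature_table: pd.DataFrame, train_mask, retained: dict,
                     config: RunConfig) -> dict:
    """Fit and evaluate one forest per data source (hsi/lidar/combined)."""
    rf_cfg = classify_eval.RFConfig(
        n_estimators=config.rf_trees, random_state=config.rf_seed
    )
    y = feature_table["stage"].to_numpy()
    reports = {}
    for source, cols in retained.items():
        if not cols:
            reports[source] = {"skipped": f"no screened feature for source {source}"}
            continue
        X = feature_table[cols].to_numpy(dtype=float)
        y_pred, model = classify_eval.fit_predict_rf(
            X[train_mask], y[train_mask], X[~train_mask], rf_cfg
        )
        report = classify_eval.confusion_and_report(y[~train_mask], y_pred)
        report.cv_accuracy = classify_eval.cross_val_accuracy(
            X[train_mask], y[train_mask], folds=config.cv_folds,
            rf_cfg=rf_cfg, seed=config.rf_seed,
        )
        imp_mean, imp_std = classify_eval.mda_importance(
            model, X[~train_mask], y[~train_mask], n_repeats=10, seed=config.rf_seed
        )
        out = report.summary()
        out["cv_accuracy"] = round(report.cv_accuracy, 4)
        out["features"] = cols
        out["mda_importance"] = {
            c: {"mean": float(m), "sd": float(s)}
            for c, m, s in zip(cols, imp_mean, imp_std)
        }
        reports[source] = out
    return reports


def run_pipeline(config: RunConfig | None = None, outdir=None) -> dict:
    """Execute the full workflow and write artifacts; returns the report."""
    config = config or RunConfig()
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    log.info("stage seeds: %s", seeds)

    spectra, clouds = _load_inputs(config, seeds)
    write_spectra(spectra, outdir / "spectra.csv")
    if config.write_clouds:
        cdir = outdir / "clouds"
        cdir.mkdir(exist_ok=True)
        for tid, cloud in clouds.items():
            write_cloud(cloud, cdir / f"{tid}.xyz")

    split = classify_eval.stratified_split(
        spectra.stage, ratio=config.split_ratio, seed=seeds["split"]
    )
    train_spectra = spectra.subset(split.train_idx)

    selection = select_bands(train_spectra, config, seeds["selection"])
    write_json_report(selection.to_dict(), outdir / "bands.json")
    log.info("selected %d bands: %s", selection.chosen_size, selection.wavelengths)

    vi_defs = feat.vi_search(train_spectra, selection.wavelengths)
    feature_table = feat.build_feature_table(spectra, clouds, vi_defs)
    feature_table.to_csv(outdir / "features.csv", index=False)

    train_ids = set(str(t) for t in spectra.tree_id[split.train_idx])
    train_mask = feature_table["tree_id"].astype(str).isin(train_ids).to_numpy()

    screen = screening.screen_features(
        feature_table.loc[train_mask], alpha=config.alpha
    )
    write_json_report(screen.to_dict(), outdir / "screening.json")

    vi_names = [info["definition"].name for info in vi_defs.values()]
    lidar_names = list(feat.LIDAR_METRIC_NAMES)
    kept = set(screen.retained_features)
    retained = {
        "hsi": [c for c in vi_names if c in kept],
        "lidar": [c for c in lidar_names if c in kept],
    }
    retained["combined"] = retained["hsi"] + retained["lidar"]

    reports = classify_sources(feature_table, train_mask, retained, config)
    for source, rep in reports.items():
        write_json_report(rep, outdir / f"classification_{source}.json")

    report = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "versions": {
            "defoliascan": defoliascan.__version__,
            "numpy": np.__version__,
            "sklearn": sklearn.__version__,
        },
        "seeds": seeds,
        "split": {
            "n_train": int(split.train_idx.size),
            "n_test": int(split.test_idx.size),
        },
        "band_selection": selection.to_dict(),
        "vegetation_indices": {
            fam: {"name": info["definition"].name, "abs_rho": round(info["abs_rho"], 4)}
            for fam, info in vi_defs.items()
        },
        "screening": screen.to_dict(),
        "classification": reports,
    }
    write_json_report(report, outdir / "report.json")
    return report


def run_from_yaml(config_path, outdir=None) -> dict:
    return run_pipeline(RunConfig.from_yaml(config_path), outdir=outdir)
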
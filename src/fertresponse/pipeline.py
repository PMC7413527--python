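"""End-to-end run orchestration: generate -> preprocess -> fit -> evaluate
-> optimize, with a manifest recording config hash, seeds and artifacts."""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, ml, optimize as opt, preprocess as prep
from .balances import TUBER_SIZE, ilr_transform, impute_size_zeros
from .mitscherlich import fit as fit_mitscherlich, predict_level0
from .synth import GeneratorConfig, generate_trials, write_dataset

__all__ = ["RunConfig", "run", "attach_targets", "TARGETS"]

#: Modelling targets: marketable yield, the two tuber-size balances, SG.
TARGETS = ("yield", "balance_MS_L", "balance_S_M", "SG")

TARGET_COLS = {
    "yield": "marketable_yield",
    "balance_MS_L": "y_bal_msl",
    "balance_S_M": "y_bal_sm",
    "SG": "sg",
}


@dataclass
class RunConfig:
    outdir: str = "runs/default"
    n_trials: int = 12
    blocks_per_trial: int = 3
    treatments_per_trial: int = 5
    trial_type: str = "mixed"
    noise_sd: float = 2.0
    block_sd: float = 1.5
    seed: int = 0
    target: str = "yield"
    families: tuple[str, ...] = ("KNN", "RF", "NN", "GP")
    n_search_iter: int = 15
    train_fraction: float = 0.7
    zscore_clean_sg_only: bool = True
    zscore_threshold: float = 3.0
    grid_points: int = 1000
    grid_bounds: tuple[float, float, float] = (250.0, 110.0, 208.0)
    n_posterior_samples: int = 1000
    prices: dict = field(default_factory=lambda: asdict(opt.PriceModel()))

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def attach_targets(trials: pd.DataFrame,
                   detection_limit: float = 0.65) -> pd.DataFrame:
    """Add tuber-size balance target columns (zero-imputed ilr coordinates).

    Size fractions pass through multiplicative zero replacement at
    ``detection_limit`` of the per-part minimum nonzero value, then map to
    the [M,S|L] and [S|M] balances.
    """
    out = trials.copy()
    fracs = out.loc[:, ["frac_S", "frac_M", "frac_L"]].to_numpy(dtype=float)
    if (fracs == 0).any():
        fracs = impute_size_zeros(fracs, detection_limit=detection_limit)
    # TUBER_SIZE part order is (M, S, L)
    comp = fracs[:, [1, 0, 2]]
    b = ilr_transform(comp, TUBER_SIZE)
    out["y_bal_msl"], out["y_bal_sm"] = b[:, 0], b[:, 1]
    return out


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "artifacts": {},
        "timings_s": {},
    }

    def _stage(name):
        manifest["timings_s"][name] = round(time.time() - t0, 2)

    # -- generate ----------------------------------------------------------
    gen = GeneratorConfig(
        n_trials=config.n_trials, blocks_per_trial=config.blocks_per_trial,
        treatments_per_trial=config.treatments_per_trial,
        trial_type=config.trial_type, noise_sd=config.noise_sd,
        block_sd=config.block_sd, seed=config.seed)
    trials, weather, truth = generate_trials(gen)
    manifest["artifacts"].update(write_dataset(trials, weather, truth, outdir))
    _stage("generate")

    # -- preprocess --------------------------------------------------------
    trials = attach_targets(trials)
    target_col = TARGET_COLS[config.target]
    if config.target == "SG" or not config.zscore_clean_sg_only:
        monitored = ["sg"] if config.zscore_clean_sg_only else None
        trials, n_dropped = prep.remove_outliers_zscore(
            trials, columns=monitored, threshold=config.zscore_threshold)
        manifest["n_outliers_dropped"] = n_dropped

    fm = prep.build_features(trials, weather)
    train_rows, test_rows = prep.split_blocks(trials, config.train_fraction,
                                              seed=config.seed)
    train_mask = trials.index.isin(train_rows.index)
    std = prep.Standardizer().fit(fm.X.loc[train_mask])
    Xtr = std.transform(fm.X.loc[train_mask])
    Xte = std.transform(fm.X.loc[~train_mask])
    ytr = trials.loc[train_mask, target_col].to_numpy(dtype=float)
    yte = trials.loc[~train_mask, target_col].to_numpy(dtype=float)

    split = pd.DataFrame({
        "block_id": trials["block_id"],
        "split": np.where(train_mask, "train", "test"),
    })
    split_path = outdir / "split_manifest.csv"
    split.drop_duplicates().to_csv(split_path, index=False)
    Xtr.to_csv(outdir / "features_train.csv", index=False)
    Xte.to_csv(outdir / "features_test.csv", index=False)
    manifest["artifacts"]["split_manifest"] = str(split_path)
    manifest["artifacts"]["features_train"] = str(outdir / "features_train.csv")
    manifest["artifacts"]["features_test"] = str(outdir / "features_test.csv")
    _stage("preprocess")

    # -- feature importance ------------------------------------------------
    scores = prep.rank_features(Xtr, ytr, seed=config.seed)
    scores.rename("importance").to_csv(outdir / "feature_importance.csv")
    manifest["artifacts"]["feature_importance"] = str(outdir / "feature_importance.csv")
    _stage("rank_features")

    # -- models ------------------------------------------------------------
    reports = []
    models: dict[str, ml.TunedModel] = {}
    if config.target == "yield":
        mfit = fit_mitscherlich(train_rows, seed=config.seed)
        mfit.params.to_json(outdir / "mitscherlich_params.json")
        manifest["artifacts"]["mitscherlich_params"] = str(outdir / "mitscherlich_params.json")
        for split_name, rows, y in (("train", train_rows, ytr), ("test", test_rows, yte)):
            pred = predict_level0(mfit.params, rows)
            reports.append(metrics.evaluate(y, pred, model="Mitscherlich",
                                            target=config.target, split=split_name))
    for family in config.families:
        spec = ml.ModelSpec(family=family, n_search_iter=config.n_search_iter,
                            seed=config.seed)
        model = ml.tune_fit(spec, Xtr, ytr)
        models[family] = model
        for split_name, X, y in (("train", Xtr, ytr), ("test", Xte, yte)):
            reports.append(metrics.evaluate(
                y, model.predict(X), model=family, target=config.target,
                split=split_name, hyperparameters=model.hyperparameters))
    metrics_df = pd.DataFrame([r.as_dict() for r in reports])
    metrics_df.to_csv(outdir / "metrics.csv", index=False)
    manifest["artifacts"]["metrics"] = str(outdir / "metrics.csv")
    _stage("train_evaluate")

    # -- dose optimization -------------------------------------------------
    prices = opt.PriceModel(**config.prices)
    grid = opt.DoseGrid.uniform(config.grid_points, config.grid_bounds,
                                seed=config.seed)
    mode = "economic" if config.target == "yield" else "agronomic"
    fixed_raw = fm.X.loc[~train_mask].iloc[0] if (~train_mask).any() else fm.X.iloc[0]
    rec_rows = []
    for family, model in models.items():
        fn = opt.model_response(model.estimator, fixed_raw, standardizer=std)
        rec = (opt.economic_optimum(fn, grid, prices) if mode == "economic"
               else opt.agronomic_optimum(fn, grid))
        rec_rows.append({"model": family, "mode": rec.mode,
                         "dose_N": rec.optimum[0], "dose_P": rec.optimum[1],
                         "dose_K": rec.optimum[2], "predicted": rec.predicted,
                         "net_return": rec.net_return,
                         "p2o5": rec.oxide_doses[0], "k2o": rec.oxide_doses[1]})
    if "GP" in models:
        prob = opt.sample_optimal_doses(
            models["GP"], fixed_raw, grid, n_samples=config.n_posterior_samples,
            mode=mode, prices=prices, seed=config.seed, standardizer=std)
        with open(outdir / "gp_dose_distribution.json", "w") as fh:
            json.dump({
                "mode": prob.mode,
                "mean_curve_optimum": prob.mean_curve_optimum,
                "modal_dose": prob.modal_dose,
                "percentiles": prob.percentiles,
            }, fh, indent=2)
        manifest["artifacts"]["gp_dose_distribution"] = str(outdir / "gp_dose_distribution.json")
    rec_df = pd.DataFrame(rec_rows)
    rec_df.to_csv(outdir / "recommendations.csv", index=False)
    manifest["artifacts"]["recommendations"] = str(outdir / "recommendations.csv")
    _stage("optimize")

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["artifacts"]["manifest"] = str(manifest_path)
    return manifest
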
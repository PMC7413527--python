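"""Feature engineering, cleaning, encoding and block-level splitting.

Builds the modelling feature matrix from plot-level trial records and daily
weather: ilr balances for soil texture/carbon and Mehlich-3 chemistry
simplexes (with a filler part completing each simplex to 1e6 mg/kg),
soil-type balances, five-season average weather indices, dose and management
variables, and one-hot maturity classes.  Numeric features are z-scored with
training statistics only; train/test assignment is by whole block within
trial-type strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor

from . import weather as wx
from .balances import K_CA_MG, P_AL, TEXTURE_CARBON, ilr_transform
from .synth import MATURITY_CLASSES

__all__ = [
    "FeatureMatrix",
    "Standardizer",
    "build_features",
    "remove_outliers_zscore",
    "split_blocks",
    "rank_features",
]

#: Total of a concentration simplex expressed in mg/kg.
SIMPLEX_TOTAL_MG_KG = 1.0e6

META_COLS = ("trial_id", "block_id", "treatment", "trial_type")


@dataclass
class FeatureMatrix:
    """Feature table plus row metadata and per-column transform provenance."""

    X: pd.DataFrame
    meta: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.X)


def _chemistry_balances(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    p = df["p_m3"].to_numpy(dtype=float)
    al = df["al_m3"].to_numpy(dtype=float)
    k = df["k_m3"].to_numpy(dtype=float)
    ca = df["ca_m3"].to_numpy(dtype=float)
    mg = df["mg_m3"].to_numpy(dtype=float)

    fv_pal = SIMPLEX_TOTAL_MG_KG - (p + al)
    comp = np.column_stack([fv_pal, al, p])  # P_AL parts: (Fv, Al, P)
    b = ilr_transform(comp, P_AL)
    out["bal_fv_alp"], out["bal_al_p"] = b[:, 0], b[:, 1]

    fv_k = SIMPLEX_TOTAL_MG_KG - (k + ca + mg)
    comp = np.column_stack([fv_k, mg, ca, k])  # K_CA_MG parts: (Fv, Mg, Ca, K)
    b = ilr_transform(comp, K_CA_MG)
    out["bal_fvmgca_k"], out["bal_fv_mgca"], out["bal_mg_ca"] = b.T
    return out


def _texture_balances(df: pd.DataFrame) -> pd.DataFrame:
    comp = df.loc[:, ["sand_pct", "silt_pct", "clay_pct", "carbon_pct"]].to_numpy(dtype=float)
    b = ilr_transform(comp, TEXTURE_CARBON)
    return pd.DataFrame(
        {"bal_texture_c": b[:, 0], "bal_clay_sandsilt": b[:, 1], "bal_silt_sand": b[:, 2]},
        index=df.index,
    )


def _weather_features(trials: pd.DataFrame, weather: pd.DataFrame,
                      n_seasons: int) -> pd.DataFrame:
    cache: dict[tuple, dict] = {}
    cols = {"ppt": [], "sdi": [], "t_mean": [], "gdd": []}
    by_site = {sid: grp for sid, grp in weather.groupby("site_id")}
    for _, row in trials.iterrows():
        key = (row["trial_id"], row["planting_date"], row["harvest_date"])
        if key not in cache:
            series = by_site.get(row["trial_id"])
            if series is None:
                raise ValueError(f"no weather for site {row['trial_id']!r}")
            idx = wx.weather_indices(
                series, (row["planting_date"], row["harvest_date"]),
                n_seasons=n_seasons)
            cache[key] = {"ppt": idx.ppt, "sdi": idx.sdi,
                          "t_mean": idx.t_mean, "gdd": idx.gdd}
        for c in cols:
            cols[c].append(cache[key][c])
    return pd.DataFrame(cols, index=trials.index)


def _maturity_onehot(series: pd.Series) -> pd.DataFrame:
    out = pd.DataFrame(index=series.index)
    known = set(MATURITY_CLASSES)
    unseen = set(series.unique()) - known
    if unseen:
        warnings.warn(f"unseen maturity classes {sorted(unseen)} encoded as all-zero",
                      stacklevel=2)
    for cls in MATURITY_CLASSES:
        out[f"maturity_{cls}"] = (series == cls).astype(float)
    return out


def build_features(trials: pd.DataFrame, weather: pd.DataFrame | None = None,
                   n_seasons: int = 5) -> FeatureMatrix:
    """Assemble the modelling feature matrix from plot-level records.

    Weather indices are computed per (site, window) from the daily series and
    averaged over the ``n_seasons`` historical seasons; passing ``weather=None``
    skips weather features (useful for dose-only experiments).
    """
    parts = [
        trials.loc[:, ["dose_N", "dose_P", "dose_K", "planting_density",
                       "season_length", "ph_water"]].astype(float),
        _texture_balances(trials),
        _chemistry_balances(trials),
        trials.loc[:, ["soiltype_gleyed_podzolized", "soiltype_loamy_sandy"]].astype(float),
    ]
    provenance = {
        "bal_texture_c": "ilr [sand,silt,clay | carbon]",
        "bal_clay_sandsilt": "ilr [clay | sand,silt]",
        "bal_silt_sand": "ilr [silt | sand]",
        "bal_fv_alp": "ilr [Fv | Al,P]",
        "bal_al_p": "ilr [Al | P]",
        "bal_fvmgca_k": "ilr [Fv,Mg,Ca | K]",
        "bal_fv_mgca": "ilr [Fv | Mg,Ca]",
        "bal_mg_ca": "ilr [Mg | Ca]",
    }
    if weather is not None:
        parts.append(_weather_features(trials, weather, n_seasons))
        provenance.update({c: f"{n_seasons}-season mean weather index"
                           for c in ("ppt", "sdi", "t_mean", "gdd")})
    if "maturity_class" in trials.columns:
        parts.append(_maturity_onehot(trials["maturity_class"]))

    X = pd.concat(parts, axis=1)
    meta = trials.loc[:, [c for c in META_COLS if c in trials.columns]].copy()
    return FeatureMatrix(X=X, meta=meta, provenance=provenance)


class Standardizer:
    """Column-wise z-scoring with training statistics only.

    Binary 0/1 membership columns are passed through untouched; zero-variance
    numeric columns are centred but not scaled (with a warning).
    """

    def __init__(self) -> None:
        self.mean_: pd.Series | None = None
        self.scale_: pd.Series | None = None
        self.columns_: list[str] | None = None
        self.binary_: set[str] = set()

    def fit(self, X: pd.DataFrame) -> "Standardizer":
        self.columns_ = list(X.columns)
        self.binary_ = {
            c for c in X.columns
            if set(np.unique(X[c].to_numpy())) <= {0.0, 1.0}
        }
        mean = X.mean()
        scale = X.std(ddof=0)
        for c in self.binary_:
            mean[c], scale[c] = 0.0, 1.0
        zero_var = scale[scale == 0].index.tolist()
        if zero_var:
            warnings.warn(f"zero-variance columns not scaled: {zero_var}",
                          stacklevel=2)
            scale[zero_var] = 1.0
        self.mean_, self.scale_ = mean, scale
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        missing = set(self.columns_) - set(X.columns)
        if missing:
            raise ValueError(f"missing feature columns: {sorted(missing)}")
        Z = X.loc[:, self.columns_].astype(float)
        return (Z - self.mean_) / self.scale_

    def fit_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).transform(X)


def remove_outliers_zscore(table: pd.DataFrame, columns=None,
                           threshold: float = 3.0) -> tuple[pd.DataFrame, int]:
    """Drop rows with |z| > threshold on any monitored numeric column.

    z-scores use the mean/SD of the table itself.  Zero-variance columns are
    skipped with a warning.  Returns (kept table, number dropped).
    """
    if columns is None:
        columns = table.select_dtypes(include=[np.number]).columns.tolist()
    keep = np.ones(len(table), dtype=bool)
    for col in columns:
        vals = table[col].to_numpy(dtype=float)
        sd = vals.std(ddof=0)
        if sd == 0:
            warnings.warn(f"column {col!r} has zero variance; skipped", stacklevel=2)
            continue
        z = (vals - vals.mean()) / sd
        keep &= np.abs(z) <= threshold
    kept = table.loc[keep].copy()
    return kept, int(len(table) - len(kept))


def split_blocks(table: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0,
                 block_col: str = "block_id",
                 stratify_col: str = "trial_type") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign whole blocks to train/test, stratified by trial type.

    Within each stratum blocks are shuffled (seeded) and the cut is placed
    where the cumulative row share is closest to ``train_fraction``, keeping
    at least one block on each side.  Strata with fewer than two blocks go
    wholly to training with a warning.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for _, grp in table.groupby(stratify_col, sort=True):
        counts = grp.groupby(block_col).size()
        blocks = np.array(sorted(counts.index))
        if len(blocks) < 2:
            warnings.warn(
                f"stratum with blocks {blocks.tolist()} too small to split; "
                "assigned to training", stacklevel=2)
            train_idx.append(grp.index)
            continue
        rng.shuffle(blocks)
        sizes = counts.loc[blocks].to_numpy()
        shares = np.cumsum(sizes) / sizes.sum()
        # candidate cuts leave >= 1 block on each side
        cut = int(np.argmin(np.abs(shares[:-1] - train_fraction))) + 1
        train_blocks = set(blocks[:cut])
        in_train = grp[block_col].isin(train_blocks)
        train_idx.append(grp.index[in_train])
        test_idx.append(grp.index[~in_train])
    train = table.loc[np.concatenate([np.asarray(i) for i in train_idx])]
    test = (table.loc[np.concatenate([np.asarray(i) for i in test_idx])]
            if test_idx else table.iloc[0:0])
    return train.sort_index(), test.sort_index()


def rank_features(X: pd.DataFrame, y, seed: int = 0,
                  n_estimators: int = 300) -> pd.Series:
    """Extra-trees impurity importances, descending; scores sum to 1.

    Fit on training rows only.  Near-zero scores mark features that can be
    dropped without hurting the models.
    """
    y = np.asarray(y, dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant target: importances undefined")
    est = ExtraTreesRegressor(n_estimators=n_estimators, random_state=seed)
    est.fit(X.to_numpy(dtype=float), y)
    scores = pd.Series(est.feature_importances_, index=X.columns)
    return scores.sort_values(ascending=False)
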
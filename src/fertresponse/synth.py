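"""Seeded synthetic field-trial generator with known ground truth.

Emulates randomized complete block N-P-K fertilizer trials on potato:
per-trial site covariates, evenly spaced dose ladders (or random factorial
triplets), daily weather for the study season plus five historical seasons,
and targets (marketable yield, tuber size fractions, specific gravity)
generated from a known Mitscherlich surface with block random intercepts on
the asymptote plus Gaussian noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .balances import SOIL_TYPE, ilr_transform
from .mitscherlich import LinearForm, MitscherlichParams, predict_surface

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_trials",
    "censor_large_fraction",
    "write_dataset",
]

TRIAL_TYPES = ("N", "P", "K", "factorial")

DEFAULT_DOSE_BOUNDS = {"N": 260.0, "P": 130.0, "K": 350.0}

#: Per-covariate uniform sampling ranges, informed by the observed spread of
#: Quebec potato trials (pH 5.2-6.2, Mehlich-3 P 20-350 mg/kg, ...).
DEFAULT_COVARIATE_RANGES = {
    "ph_water": (5.2, 6.2),
    "p_m3": (20.0, 350.0),
    "k_m3": (70.0, 350.0),
    "al_m3": (1200.0, 2900.0),
    "ca_m3": (500.0, 2000.0),
    "mg_m3": (50.0, 400.0),
    "carbon_pct": (1.0, 6.0),
    "sand_pct": (30.0, 85.0),
    "clay_pct": (2.0, 25.0),
    "planting_density": (30000.0, 44000.0),
    "season_length": (100.0, 131.0),
}

MATURITY_CLASSES = ("early", "early_mid", "mid", "mid_late", "late")
MATURITY_PROBS = (0.04, 0.13, 0.62, 0.12, 0.09)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    n_trials: int = 8
    blocks_per_trial: int = 3
    treatments_per_trial: int = 5
    trial_type: str = "mixed"  # N | P | K | factorial | mixed
    dose_bounds: dict = field(default_factory=lambda: dict(DEFAULT_DOSE_BOUNDS))
    covariate_ranges: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_RANGES))
    noise_sd: float = 2.0
    block_sd: float = 1.5
    start_year: int = 2015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.blocks_per_trial < 1 or self.treatments_per_trial < 2:
            raise ConfigurationError("design counts must be positive (>= 2 treatments)")
        if not (4 <= self.treatments_per_trial <= 6):
            warnings.warn(
                "treatments_per_trial outside the typical 4-6 range",
                stacklevel=2,
            )
        if self.trial_type not in (*TRIAL_TYPES, "mixed"):
            raise ConfigurationError(f"unknown trial_type {self.trial_type!r}")
        if any(v <= 0 for v in self.dose_bounds.values()):
            raise ConfigurationError("dose bounds must be positive")
        if self.noise_sd < 0 or self.block_sd < 0:
            raise ConfigurationError("noise_sd and block_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything needed to score downstream estimates against truth."""

    params: MitscherlichParams
    size_fraction_model: dict
    sg_model: dict
    block_effects: dict[str, float]

    def to_json(self, path) -> None:
        payload = {
            "params": {
                "forms": {k: asdict(v) for k, v in self.params.forms.items()},
                "links": self.params.links,
                "sigma_trial": self.params.sigma_trial,
                "sigma_resid": self.params.sigma_resid,
            },
            "size_fraction_model": self.size_fraction_model,
            "sg_model": self.sg_model,
            "block_effects": self.block_effects,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def default_ground_truth_params() -> MitscherlichParams:
    """Mitscherlich truth with a mildly covariate-dependent asymptote."""
    forms = {
        "A": LinearForm(40.0, {"ph_water_centered": 6.0, "carbon_pct_centered": 0.8}),
        "E_N": LinearForm(40.0), "E_P": LinearForm(25.0), "E_K": LinearForm(60.0),
        "R_N": LinearForm(0.012), "R_P": LinearForm(0.025), "R_K": LinearForm(0.008),
    }
    return MitscherlichParams(forms=forms)


DEFAULT_SIZE_FRACTION_MODEL = {
    # multinomial logits on centred/scaled dose_N and planting density
    "centers": {"dose_N": 130.0, "planting_density": 37000.0},
    "scales": {"dose_N": 75.0, "planting_density": 4000.0},
    "logits": {
        "S": {"intercept": -0.2, "planting_density": 0.8, "dose_N": -0.4},
        "M": {"intercept": 0.9, "planting_density": 0.3, "dose_N": 0.0},
        "L": {"intercept": 0.5, "planting_density": 0.0, "dose_N": 0.6},
    },
}

DEFAULT_SG_MODEL = {
    # sg = 1.04 + 0.08 * sigmoid(linear form); always inside [1.040, 1.120]
    "intercept": 0.3,
    "dose_N": -0.5,        # on (dose_N - 130)/75
    "ph_water": 0.4,       # on (ph - 5.7)
}


def _dose_design(rng, trial_type: str, bounds: dict, n_treatments: int) -> np.ndarray:
    """Dose triplets per treatment; evenly spaced ladder for single-nutrient
    trials (base doses for the other two), uniform triplets for factorials."""
    order = ("N", "P", "K")
    if trial_type == "factorial":
        return np.column_stack([
            rng.uniform(0.0, bounds[x], size=n_treatments) for x in order
        ])
    base = {x: float(rng.uniform(0.0, bounds[x] / 2.0)) for x in order}
    ladder = np.linspace(0.0, bounds[trial_type], n_treatments)
    doses = np.column_stack([np.full(n_treatments, base[x]) for x in order])
    doses[:, order.index(trial_type)] = ladder
    return doses


def _site_covariates(rng, ranges: dict) -> dict:
    cov = {k: float(rng.uniform(*ranges[k])) for k in ranges}
    # close the texture triplet; silt is the remainder
    total = cov["sand_pct"] + cov["clay_pct"]
    if total > 95.0:
        cov["sand_pct"] *= 95.0 / total
        cov["clay_pct"] *= 95.0 / total
    cov["silt_pct"] = 100.0 - cov["sand_pct"] - cov["clay_pct"]
    cov["season_length"] = int(round(cov["season_length"]))
    cov["planting_density"] = float(round(cov["planting_density"]))
    # soil-type membership (poorly drained loam / sand, well-drained sand)
    membership = rng.dirichlet((2.0, 2.0, 2.0))
    stb = ilr_transform(membership, SOIL_TYPE)
    cov["soiltype_gleyed_podzolized"] = float(stb[0])
    cov["soiltype_loamy_sandy"] = float(stb[1])
    cov["maturity_class"] = str(rng.choice(MATURITY_CLASSES, p=MATURITY_PROBS))
    return cov


def _season_weather(rng, start: pd.Timestamp, end: pd.Timestamp) -> pd.DataFrame:
    dates = pd.date_range(start, end, freq="D")
    n = len(dates)
    wet = rng.random(n) < 0.55
    rain = np.where(wet, rng.gamma(0.9, 9.0, size=n), 0.0)
    doy = dates.dayofyear.to_numpy()
    tmean = 14.0 + 7.0 * np.sin(2 * np.pi * (doy - 105) / 365.0) + rng.normal(0, 2.5, n)
    return pd.DataFrame({"date": dates, "rain_mm": np.round(rain, 2),
                         "tmean_c": np.round(tmean, 2)})


def _size_fractions(model: dict, dose_n: np.ndarray, density: np.ndarray) -> np.ndarray:
    zn = (dose_n - model["centers"]["dose_N"]) / model["scales"]["dose_N"]
    zd = (density - model["centers"]["planting_density"]) / model["scales"]["planting_density"]
    logits = []
    for part in ("S", "M", "L"):
        c = model["logits"][part]
        logits.append(c["intercept"] + c["planting_density"] * zd + c["dose_N"] * zn)
    z = np.column_stack(logits)
    z -= z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def _specific_gravity(model: dict, dose_n: np.ndarray, ph: np.ndarray) -> np.ndarray:
    lin = (model["intercept"]
           + model["dose_N"] * (dose_n - 130.0) / 75.0
           + model["ph_water"] * (ph - 5.7))
    return 1.04 + 0.08 / (1.0 + np.exp(-lin))


def generate_trials(
    config: GeneratorConfig,
    ground_truth_params: MitscherlichParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (trials, daily weather, ground truth) for a config.

    One row per plot (trial x block x treatment).  Weather covers the study
    season and the five preceding seasons per site.  Identical configs give
    bitwise-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    params = ground_truth_params or default_ground_truth_params()

    trial_rows = []
    weather_frames = []
    block_effects: dict[str, float] = {}

    for t in range(config.n_trials):
        trial_id = f"T{t + 1:03d}"
        if config.trial_type == "mixed":
            ttype = TRIAL_TYPES[t % len(TRIAL_TYPES)]
        else:
            ttype = config.trial_type
        cov = _site_covariates(rng, config.covariate_ranges)
        doses = _dose_design(rng, ttype, config.dose_bounds,
                             config.treatments_per_trial)

        year = config.start_year + t % 3
        planting = pd.Timestamp(year, 5, int(rng.integers(5, 26)))
        harvest = planting + pd.Timedelta(days=int(cov["season_length"]))

        for k in range(0, 6):  # study season + 5 historical
            start = planting - pd.DateOffset(years=k)
            end = harvest - pd.DateOffset(years=k)
            wx = _season_weather(rng, start, end)
            wx.insert(0, "site_id", trial_id)
            weather_frames.append(wx)

        effects = rng.normal(0.0, config.block_sd, size=config.blocks_per_trial)
        for b in range(config.blocks_per_trial):
            block_id = f"{trial_id}:B{b + 1}"
            block_effects[block_id] = float(effects[b])
            for j in range(config.treatments_per_trial):
                trial_rows.append({
                    "trial_id": trial_id,
                    "block_id": block_id,
                    "treatment": f"TRT{j + 1}",
                    "trial_type": ttype,
                    "dose_N": doses[j, 0],
                    "dose_P": doses[j, 1],
                    "dose_K": doses[j, 2],
                    "planting_date": planting.date().isoformat(),
                    "harvest_date": harvest.date().isoformat(),
                    **{k: v for k, v in cov.items()},
                })

    trials = pd.DataFrame(trial_rows)
    trials["ph_water_centered"] = trials["ph_water"] - 5.7
    trials["carbon_pct_centered"] = trials["carbon_pct"] - 3.5

    mean_yield = predict_surface(params, trials)
    block_u = trials["block_id"].map(block_effects).to_numpy()
    vals = params.evaluate(trials)
    saturation = mean_yield / vals["A"]  # product of the three dose factors
    noise = rng.normal(0.0, config.noise_sd, size=len(trials))
    trials["marketable_yield"] = np.maximum(mean_yield + block_u * saturation + noise, 0.0)

    size_model = json.loads(json.dumps(DEFAULT_SIZE_FRACTION_MODEL))
    sg_model = dict(DEFAULT_SG_MODEL)
    fracs = _size_fractions(size_model, trials["dose_N"].to_numpy(),
                            trials["planting_density"].to_numpy())
    trials[["frac_S", "frac_M", "frac_L"]] = fracs
    trials["sg"] = _specific_gravity(sg_model, trials["dose_N"].to_numpy(),
                                     trials["ph_water"].to_numpy())
    trials = trials.drop(columns=["ph_water_centered", "carbon_pct_centered"])

    weather = pd.concat(weather_frames, ignore_index=True)
    weather = weather.sort_values(["site_id", "date"], kind="stable").reset_index(drop=True)
    weather["date"] = weather["date"].dt.date.astype(str)

    truth = GroundTruth(params=params, size_fraction_model=size_model,
                        sg_model=sg_model, block_effects=block_effects)
    return trials, weather, truth


def censor_large_fraction(table: pd.DataFrame, censor_prob: float,
                          seed: int = 0) -> pd.DataFrame:
    """Zero out the large-tuber fraction in a random subset of rows.

    Mirrors field data where large tubers are often entirely absent.  The
    remaining (S, M) parts are re-closed to sum 1; censored rows are marked
    in an ``l_censored`` column.
    """
    if not (0.0 <= censor_prob <= 1.0):
        raise ValueError("censor_prob must lie in [0, 1]")
    for col in ("frac_S", "frac_M", "frac_L"):
        if col not in table.columns:
            raise ValueError("size fractions missing from table")
    out = table.copy()
    rng = np.random.default_rng(seed)
    mask = rng.random(len(out)) < censor_prob
    sm = out.loc[mask, "frac_S"] + out.loc[mask, "frac_M"]
    out.loc[mask, "frac_S"] /= sm
    out.loc[mask, "frac_M"] /= sm
    out.loc[mask, "frac_L"] = 0.0
    out["l_censored"] = mask
    return out


def write_dataset(trials: pd.DataFrame, weather: pd.DataFrame,
                  truth: GroundTruth, outdir) -> dict[str, str]:
    """Write trials.csv / weather.csv / ground_truth.json; returns paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": str(outdir / "trials.csv"),
        "weather": str(outdir / "weather.csv"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
    trials.to_csv(paths["trials"], index=False)
    weather.to_csv(paths["weather"], index=False)
    truth.to_json(paths["ground_truth"])
    return paths
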
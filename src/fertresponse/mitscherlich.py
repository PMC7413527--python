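"""Tri-variate Mitscherlich dose-response surface with hierarchical fitting.

The response surface is

    Y = A * (1 - exp(-R_N (E_N + dose_N)))
          * (1 - exp(-R_P (E_P + dose_P)))
          * (1 - exp(-R_K (E_K + dose_K)))

where ``A`` is the asymptote (Mg/ha), ``E_X`` the fertilizer-equivalent
environmental supply of nutrient X (kg/ha) and ``R_X`` the rate (ha/kg).
Each first-level parameter is a linear combination of covariates mapped
through a positivity link, and a group-level (trial) random intercept is
added to the asymptote.  Level-0 predictions set the random effects to zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize as _opt

__all__ = [
    "LinearForm",
    "MitscherlichParams",
    "MitscherlichFit",
    "surface",
    "fit",
    "predict_level0",
]

DOSE_COLS = ("dose_N", "dose_P", "dose_K")
PARAM_NAMES = ("A", "E_N", "E_P", "E_K", "R_N", "R_P", "R_K")


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    y = np.asarray(y, dtype=float)
    return y + np.log1p(-np.exp(-y))


def _apply_link(link: str, eta):
    if link == "identity":
        return eta
    if link == "exp":
        return np.exp(eta)
    if link == "softplus":
        return _softplus(eta)
    raise ValueError(f"unknown link {link!r}")


@dataclass
class LinearForm:
    """``intercept + sum(coef * covariate)`` evaluated on a data frame."""

    intercept: float
    coefs: dict[str, float] = field(default_factory=dict)

    def evaluate(self, data: pd.DataFrame | None, n: int | None = None) -> np.ndarray:
        if not self.coefs:
            size = len(data) if data is not None else (n or 1)
            return np.full(size, self.intercept, dtype=float)
        if data is None:
            raise ValueError("covariate-bearing linear form needs a data frame")
        out = np.full(len(data), self.intercept, dtype=float)
        for col, coef in self.coefs.items():
            out += coef * data[col].to_numpy(dtype=float)
        return out


@dataclass
class MitscherlichParams:
    """Fitted or ground-truth surface parameters.

    ``forms`` maps each of A, E_N, E_P, E_K, R_N, R_P, R_K to a linear form
    on covariates; ``links`` maps the linear predictor to the natural scale.
    ``sigma_trial`` is the SD of the random intercept on A, ``sigma_resid``
    the residual SD (both Mg/ha).
    """

    forms: dict[str, LinearForm]
    links: dict[str, str] = field(default_factory=dict)
    sigma_trial: float = 0.0
    sigma_resid: float = 0.0

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.forms)
        if missing:
            raise ValueError(f"missing parameter forms: {sorted(missing)}")
        if self.sigma_trial < 0 or self.sigma_resid < 0:
            raise ValueError("sigma values must be non-negative")
        for name in PARAM_NAMES:
            self.links.setdefault(name, "identity")

    @classmethod
    def constant(cls, A: float, E: tuple[float, float, float],
                 R: tuple[float, float, float], sigma_trial: float = 0.0,
                 sigma_resid: float = 0.0) -> "MitscherlichParams":
        """Covariate-free parameters on the natural (identity-link) scale."""
        forms = {
            "A": LinearForm(A),
            "E_N": LinearForm(E[0]), "E_P": LinearForm(E[1]), "E_K": LinearForm(E[2]),
            "R_N": LinearForm(R[0]), "R_P": LinearForm(R[1]), "R_K": LinearForm(R[2]),
        }
        return cls(forms=forms, sigma_trial=sigma_trial, sigma_resid=sigma_resid)

    def evaluate(self, data: pd.DataFrame | None = None, n: int | None = None) -> dict[str, np.ndarray]:
        """Natural-scale parameter values per row."""
        return {
            name: _apply_link(self.links[name], self.forms[name].evaluate(data, n))
            for name in PARAM_NAMES
        }

    def value(self, name: str) -> float:
        """Natural-scale value of a covariate-free parameter."""
        form = self.forms[name]
        if form.coefs:
            raise ValueError(f"{name} depends on covariates; evaluate on rows instead")
        return float(_apply_link(self.links[name], np.asarray(form.intercept)))

    def to_json(self, path) -> None:
        payload = {
            "forms": {k: asdict(v) for k, v in self.forms.items()},
            "links": self.links,
            "sigma_trial": self.sigma_trial,
            "sigma_resid": self.sigma_resid,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MitscherlichParams":
        with open(path) as fh:
            payload = json.load(fh)
        forms = {k: LinearForm(**v) for k, v in payload["forms"].items()}
        return cls(forms=forms, links=payload["links"],
                   sigma_trial=payload["sigma_trial"],
                   sigma_resid=payload["sigma_resid"])


def surface(A, E, R, doses) -> np.ndarray:
    """Evaluate the tri-variate surface.

    Parameters
    ----------
    A : scalar or array
        Asymptote, must be > 0.
    E, R : length-3 sequences (scalar or array each)
        Environment and rate parameters for (N, P, K); E >= 0, R > 0.
    doses : array-like, shape (n, 3) or length-3 sequence
        Elemental doses (kg/ha) for (N, P, K).
    """
    d = np.asarray(doses, dtype=float)
    squeeze = d.ndim == 1
    if squeeze:
        d = d[None, :]
    if d.shape[1] != 3:
        raise ValueError("doses must have three columns (N, P, K)")
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("asymptote A must be positive")
    out = np.broadcast_to(A, (d.shape[0],)).astype(float).copy()
    for j in range(3):
        e = np.asarray(E[j], dtype=float)
        r = np.asarray(R[j], dtype=float)
        if np.any(r <= 0):
            raise ValueError("rates R must be positive")
        if np.any(e < 0):
            raise ValueError("environment supplies E must be non-negative")
        out *= 1.0 - np.exp(-r * (e + d[:, j]))
    return out[0] if squeeze else out


def predict_surface(params: MitscherlichParams, data: pd.DataFrame,
                    dose_cols=DOSE_COLS) -> np.ndarray:
    """Row-wise surface evaluation with covariate-dependent parameters."""
    vals = params.evaluate(data)
    doses = data.loc[:, list(dose_cols)].to_numpy(dtype=float)
    return surface(vals["A"],
                   (vals["E_N"], vals["E_P"], vals["E_K"]),
                   (vals["R_N"], vals["R_P"], vals["R_K"]), doses)


def predict_level0(params: MitscherlichParams, data: pd.DataFrame,
                   dose_cols=DOSE_COLS) -> np.ndarray:
    """Predictions with every random effect set to zero (level = 0)."""
    return predict_surface(params, data, dose_cols=dose_cols)


@dataclass
class MitscherlichFit:
    params: MitscherlichParams
    se: dict[str, float]
    converged: bool
    loglik: float
    n_obs: int
    diagnostics: list[str] = field(default_factory=list)
    n_restarts_used: int = 0

    def value(self, name: str) -> float:
        return self.params.value(name)


class FitError(RuntimeError):
    """Fit failed to converge; carries best-so-far parameters."""

    def __init__(self, message: str, best: MitscherlichFit | None = None):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# fitting internals

class _Design:
    """Maps the packed parameter vector to per-row natural-scale values."""

    LINKS = {"A": "exp", "E_N": "softplus", "E_P": "softplus", "E_K": "softplus",
             "R_N": "softplus", "R_P": "softplus", "R_K": "softplus"}

    def __init__(self, data: pd.DataFrame, covariates: dict[str, list[str]] | None):
        covariates = covariates or {}
        self.blocks: list[tuple[str, list[str]]] = []
        self.slices: dict[str, slice] = {}
        pos = 0
        for name in PARAM_NAMES:
            covs = list(covariates.get(name, []))
            width = 1 + len(covs)
            self.blocks.append((name, covs))
            self.slices[name] = slice(pos, pos + width)
            pos += width
        self.n_params = pos
        self.X = {name: (data.loc[:, covs].to_numpy(dtype=float) if covs else None)
                  for name, covs in self.blocks}
        self.n_rows = len(data)

    def natural(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        for name, covs in self.blocks:
            block = theta[self.slices[name]]
            eta = np.full(self.n_rows, block[0])
            if covs:
                eta = eta + self.X[name] @ block[1:]
            out[name] = _apply_link(self.LINKS[name], eta)
        return out

    def to_params(self, theta: np.ndarray, sigma_trial: float,
                  sigma_resid: float) -> MitscherlichParams:
        forms = {}
        for name, covs in self.blocks:
            block = theta[self.slices[name]]
            forms[name] = LinearForm(float(block[0]),
                                     {c: float(v) for c, v in zip(covs, block[1:])})
        return MitscherlichParams(forms=forms, links=dict(self.LINKS),
                                  sigma_trial=sigma_trial, sigma_resid=sigma_resid)


def _mean_and_factor(design: _Design, theta: np.ndarray, doses: np.ndarray):
    vals = design.natural(theta)
    m = np.ones(design.n_rows)
    for j, x in enumerate(("N", "P", "K")):
        m *= 1.0 - np.exp(-vals[f"R_{x}"] * (vals[f"E_{x}"] + doses[:, j]))
    return vals["A"] * m, m


def _marginal_nll(theta_full: np.ndarray, design: _Design, doses: np.ndarray,
                  y: np.ndarray, groups: np.ndarray) -> float:
    """Negative Gaussian marginal log-likelihood with a rank-1 random
    intercept on A per group (Sherman-Morrison / determinant lemma)."""
    theta = theta_full[:-2]
    sig_b2 = max(np.exp(2 * theta_full[-2]), 1e-18)
    sig2 = max(np.exp(2 * theta_full[-1]), 1e-18)
    mu, m = _mean_and_factor(design, theta, doses)
    resid = y - mu
    nll = 0.0
    for g in np.unique(groups):
        idx = groups == g
        r, mg = resid[idx], m[idx]
        n = r.size
        mm = float(mg @ mg)
        denom = sig2 + sig_b2 * mm
        quad = (r @ r) / sig2 - sig_b2 * (mg @ r) ** 2 / (sig2 * denom)
        logdet = n * np.log(sig2) + np.log1p(sig_b2 * mm / sig2)
        nll += 0.5 * (quad + logdet + n * np.log(2 * np.pi))
    return float(nll)


def _initial_theta(design: _Design, doses: np.ndarray, y: np.ndarray,
                   rng: np.random.Generator, jitter: bool) -> np.ndarray:
    theta = np.zeros(design.n_params)
    a0 = max(float(np.nanmax(y)), 1.0) * 1.05
    theta[design.slices["A"].start] = np.log(a0)
    for j, x in enumerate(("N", "P", "K")):
        dmax = max(float(doses[:, j].max()), 1.0)
        e0 = 0.3 * dmax + 5.0
        r0 = 3.0 / (dmax + e0)
        if jitter:
            e0 *= float(np.exp(rng.normal(0, 0.7)))
            r0 *= float(np.exp(rng.normal(0, 0.7)))
        theta[design.slices[f"E_{x}"].start] = _softplus_inv(e0)
        theta[design.slices[f"R_{x}"].start] = _softplus_inv(r0)
    return theta


def fit(
    data: pd.DataFrame,
    yield_col: str = "marketable_yield",
    dose_cols=DOSE_COLS,
    trial_col: str = "trial_id",
    covariates: dict[str, list[str]] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    method: str = "auto",
    tol: float = 1e-10,
) -> MitscherlichFit:
    """Fit the hierarchical Mitscherlich surface.

    Stage 1 runs multi-start nonlinear least squares on the fixed effects
    (positivity enforced through exp/softplus links).  Stage 2 (``method`` in
    ``{"auto", "mml"}``) estimates the trial random-intercept and residual
    variances and refines all parameters by Gaussian marginal maximum
    likelihood; with ``method="ls"`` or an essentially perfect stage-1 fit
    the variance components come from residual moments instead.

    Returns a :class:`MitscherlichFit`; raises :class:`FitError` carrying the
    best attempt if no restart converges.
    """
    if method not in ("auto", "ls", "mml"):
        raise ValueError("method must be one of auto/ls/mml")
    if data[trial_col].nunique() < 2:
        raise ValueError("need at least 2 trials to fit a hierarchical model")
    y = data[yield_col].to_numpy(dtype=float)
    doses = data.loc[:, list(dose_cols)].to_numpy(dtype=float)
    groups = data[trial_col].to_numpy()
    design = _Design(data, covariates)
    rng = np.random.default_rng(seed)

    diagnostics = []
    for j, x in enumerate(("N", "P", "K")):
        if np.ptp(doses[:, j]) == 0:
            diagnostics.append(
                f"dose_{x} has no gradient: E_{x} and R_{x} are unidentifiable"
            )

    def residuals(theta):
        mu, _ = _mean_and_factor(design, theta, doses)
        return y - mu

    best = None
    n_used = 0
    for start in range(max(1, n_restarts)):
        theta0 = _initial_theta(design, doses, y, rng, jitter=start > 0)
        try:
            res = _opt.least_squares(residuals, theta0, method="trf",
                                     xtol=tol, ftol=tol, gtol=tol,
                                     max_nfev=20000)
        except Exception:  # singular Jacobian on a bad start
            continue
        n_used += 1
        if best is None or res.cost < best.cost - 1e-12:
            best = res
    if best is None:
        raise FitError("all least-squares starts failed")

    theta = best.x
    resid = residuals(theta)
    n, p = y.size, design.n_params
    dof = max(n - p, 1)
    sigma_resid = float(np.sqrt(resid @ resid / dof))

    # moment estimate of the trial random-intercept variance on A
    _, m = _mean_and_factor(design, theta, doses)
    u_tilde, shrink = [], []
    for g in np.unique(groups):
        idx = groups == g
        mm = float(m[idx] @ m[idx])
        if mm > 0:
            u_tilde.append(float(m[idx] @ resid[idx]) / mm)
            shrink.append(1.0 / mm)
    sigma_trial = 0.0
    if len(u_tilde) >= 2:
        sigma_trial = float(np.sqrt(max(np.var(u_tilde, ddof=1)
                                        - sigma_resid ** 2 * np.mean(shrink), 0.0)))

    use_mml = method == "mml" or (method == "auto" and sigma_resid > 1e-6)
    loglik = -_marginal_nll(
        np.concatenate([theta, [np.log(max(sigma_trial, 1e-8)),
                                np.log(max(sigma_resid, 1e-8))]]),
        design, doses, y, groups)
    if use_mml:
        theta_full0 = np.concatenate([
            theta,
            [np.log(max(sigma_trial, 1e-3)), np.log(max(sigma_resid, 1e-3))],
        ])
        out = _opt.minimize(_marginal_nll, theta_full0,
                            args=(design, doses, y, groups),
                            method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-12})
        if out.fun < -loglik:
            theta = out.x[:-2]
            sigma_trial = float(np.exp(out.x[-2]))
            sigma_resid = float(np.exp(out.x[-1]))
            loglik = -float(out.fun)

    params = design.to_params(theta, sigma_trial, sigma_resid)

    # delta-method standard errors on the natural scale (Gauss-Newton cov)
    se: dict[str, float] = {}
    try:
        jac = best.jac
        cov_theta = sigma_resid ** 2 * np.linalg.pinv(jac.T @ jac)
        for name in PARAM_NAMES:
            sl = design.slices[name]
            if sl.stop - sl.start != 1:
                continue
            eta = theta[sl.start]
            var = cov_theta[sl.start, sl.start]
            link = design.LINKS[name]
            if link == "exp":
                grad = np.exp(eta)
            else:  # softplus
                grad = 1.0 / (1.0 + np.exp(-eta))
            se[name] = float(np.sqrt(max(var, 0.0)) * grad)
    except np.linalg.LinAlgError:
        diagnostics.append("covariance of estimates unavailable (singular Jacobian)")

    converged = bool(best.status > 0)
    fit_result = MitscherlichFit(params=params, se=se, converged=converged,
                                 loglik=float(loglik), n_obs=n,
                                 diagnostics=diagnostics, n_restarts_used=n_used)
    if not converged:
        raise FitError("optimizer did not converge", best=fit_result)
    return fit_result
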
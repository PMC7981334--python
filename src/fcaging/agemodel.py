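"""Heteroscedastic age model for imaging measures.

Each feature (an FC connection, or a node for BP/GMD) gets its own
location-scale model over subjects:

    y_s = z_s + rho * FD_s
    z_s ~ Normal(alpha_mu + beta_mu * a_s,  exp(alpha_sigma + beta_sigma * a_s))

with a_s the age referenced to 20 years and FD_s the subject's mean
framewise displacement.  Parameters are estimated by maximum a
posteriori (MAP) with weakly informative normal priors centered at 0,
via a quasi-Newton optimizer with analytic gradients and jittered
multi-start.  beta_sigma has a multiplicative reading: the standard
deviation changes by a factor exp(beta_sigma) per year of age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .synthetic import AGE_REFERENCE

PARAM_NAMES = ("alpha_mu", "beta_mu", "alpha_sigma", "beta_sigma", "rho")
_BIG = 1e12  # optimizer-safe stand-in for a non-finite objective

__all__ = [
    "AgeModelPriors",
    "EdgeAgeFit",
    "AgingEffectTable",
    "neg_log_posterior",
    "fit_map",
    "fit_all",
    "sd_at_age",
    "consistency_correlation",
]


@dataclass
class AgeModelPriors:
    """Normal prior scales per parameter; ``None`` means a flat prior.

    The study design constrains only shape and centering (normal,
    symmetric around 0), so the scales are package defaults: loose on
    the intercepts, tighter on the per-year slopes and the motion
    coefficient.
    """

    alpha_mu: float | None = 10.0
    beta_mu: float | None = 0.1
    alpha_sigma: float | None = 10.0
    beta_sigma: float | None = 0.1
    rho: float | None = 0.1

    def scales(self) -> list[float | None]:
        return [self.alpha_mu, self.beta_mu, self.alpha_sigma, self.beta_sigma, self.rho]

    @classmethod
    def flat(cls) -> "AgeModelPriors":
        return cls(None, None, None, None, None)


@dataclass
class EdgeAgeFit:
    """MAP estimate for one feature."""

    feature: str
    alpha_mu: float
    beta_mu: float
    alpha_sigma: float
    beta_sigma: float
    rho: float
    converged: bool
    objective: float
    identifiable: bool = True

    @property
    def params(self) -> np.ndarray:
        return np.array(
            [self.alpha_mu, self.beta_mu, self.alpha_sigma, self.beta_sigma, self.rho]
        )


@dataclass
class AgingEffectTable:
    """Per-feature fits plus sign-fraction summaries.

    Fractions are computed over identifiable, converged features only.
    """

    fits: pd.DataFrame
    frac_negative_beta_mu: float
    frac_positive_beta_sigma: float


def _prep(y, ages, fd):
    y = np.asarray(y, dtype=float)
    x = np.asarray(ages, dtype=float) - AGE_REFERENCE
    fd = np.zeros_like(x) if fd is None else np.asarray(fd, dtype=float)
    if not (y.shape == x.shape == fd.shape):
        raise ValueError("y, ages and fd must have identical shapes")
    if y.size < 5:
        raise ValueError(f"need >= 5 subjects, got {y.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(fd))):
        raise ValueError("ages and fd must be finite")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    return y, x, fd


def neg_log_posterior(
    params: np.ndarray,
    y: np.ndarray,
    ages: np.ndarray,
    fd: np.ndarray | None,
    priors: AgeModelPriors | None = None,
) -> float:
    """Negative log posterior (additive constants dropped).

    sum_s [ log sigma_s + (y_s - rho*FD_s - mu_s)^2 / (2 sigma_s^2) ]
    + sum_p p^2 / (2 scale_p^2) over parameters with normal priors,
    with mu_s and sigma_s evaluated at (age_s - 20).
    """
    value, _ = _nlp_and_grad(np.asarray(params, float), *_prep(y, ages, fd), priors)
    return value


def _nlp_and_grad(params, y, x, fd, priors):
    if not np.all(np.isfinite(params)):
        return _BIG, np.zeros(5)
    a_mu, b_mu, a_sg, b_sg, rho = params
    eta = a_sg + b_sg * x
    if np.any(np.abs(eta) > 60):  # exp over/underflow guard
        return _BIG, np.zeros(5)
    inv_var = np.exp(-2.0 * eta)
    resid = y - rho * fd - a_mu - b_mu * x
    nll = float(eta.sum() + 0.5 * (resid**2 * inv_var).sum())
    rw = resid * inv_var
    one_minus = 1.0 - resid * rw
    grad = np.array(
        [
            -rw.sum(),
            -(rw * x).sum(),
            one_minus.sum(),
            (one_minus * x).sum(),
            -(rw * fd).sum(),
        ]
    )
    if priors is not None:
        for k, scale in enumerate(priors.scales()):
            if scale is not None:
                nll += 0.5 * params[k] ** 2 / scale**2
                grad[k] += params[k] / scale**2
    if not np.isfinite(nll):
        return _BIG, np.zeros(5)
    return nll, grad


def _ols_init(y, x, fd):
    """OLS (alpha_mu, beta_mu), ML residual log-SD; beta_sigma = rho = 0."""
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sd = float(np.sqrt(np.mean(resid**2)))
    return np.array([beta[0], beta[1], np.log(max(sd, 1e-12)), 0.0, 0.0])


def fit_map(
    y: np.ndarray,
    ages: np.ndarray,
    fd: np.ndarray | None = None,
    priors: AgeModelPriors | None = None,
    fixed: dict[str, float] | None = None,
    n_restarts: int = 4,
    tol: float = 1e-9,
    max_iter: int = 500,
    seed: int = 0,
    feature: str = "feature",
) -> EdgeAgeFit:
    """MAP fit of the five-parameter model for one feature.

    ``fixed`` pins named parameters (e.g. ``{"beta_sigma": 0.0,
    "rho": 0.0}``) and optimizes the rest.  The optimizer is L-BFGS-B
    with analytic gradients, started at the OLS-based initial point plus
    ``n_restarts`` jittered restarts (deterministic given ``seed``); the
    lowest objective wins, ties going to the first found.

    Features with zero value variance or a single distinct age are
    unidentifiable: they are fitted anyway but flagged.
    """
    priors = AgeModelPriors() if priors is None else priors
    y, x, fd = _prep(y, ages, fd)
    fixed = dict(fixed or {})
    for name in fixed:
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
    free = np.array([name not in fixed for name in PARAM_NAMES])
    identifiable = bool(np.std(y) > 0) and np.unique(x).size >= 2

    base = np.array(
        [fixed.get(name, v) for name, v in zip(PARAM_NAMES, _ols_init(y, x, fd))]
    )

    def pack(theta_free):
        full = base.copy()
        full[free] = theta_free
        return full

    def fun(theta_free):
        val, grad = _nlp_and_grad(pack(theta_free), y, x, fd, priors)
        return val, grad[free]

    rng = np.random.default_rng(seed)
    jitter_scale = np.array([0.2, 0.01, 0.5, 0.01, 0.2])
    starts = [base[free]]
    for _ in range(n_restarts):
        starts.append((base + jitter_scale * rng.standard_normal(5))[free])

    best = None
    for s in starts:
        res = optimize.minimize(
            fun,
            s,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    full = pack(best.x)
    grad_norm = float(np.linalg.norm(_nlp_and_grad(full, y, x, fd, priors)[1][free]))
    converged = bool(best.success) and np.isfinite(best.fun)
    return EdgeAgeFit(
        feature=feature,
        alpha_mu=float(full[0]),
        beta_mu=float(full[1]),
        alpha_sigma=float(full[2]),
        beta_sigma=float(full[3]),
        rho=float(full[4]),
        converged=converged,
        objective=float(best.fun),
        identifiable=identifiable,
    )


def fit_all(
    values: np.ndarray,
    ages: np.ndarray,
    fd: np.ndarray | None = None,
    priors: AgeModelPriors | None = None,
    feature_ids: list[str] | None = None,
    fixed: dict[str, float] | None = None,
    n_restarts: int = 1,
    seed: int = 0,
    progress: bool = False,
) -> AgingEffectTable:
    """Fit every column of a (n_subjects, n_features) value table.

    Per-feature failures are isolated: the offending feature gets a row
    of NaNs with ``converged = False`` and the run continues.  The
    default here is a single optimizer start per feature — the objective
    is smooth and unimodal in practice — while :func:`fit_map` keeps a
    multi-start default for one-off fits.
    """
    values = np.asarray(values, dtype=float)
    n_sub, n_feat = values.shape
    ids = feature_ids or [f"f{j}" for j in range(n_feat)]
    if len(ids) != n_feat:
        raise ValueError("feature_ids length must match number of columns")
    rows = []
    for j in range(n_feat):
        try:
            fit = fit_map(
                values[:, j],
                ages,
                fd,
                priors=priors,
                fixed=fixed,
                n_restarts=n_restarts,
                seed=seed + j,
                feature=ids[j],
            )
            rows.append(
                {
                    "feature": ids[j],
                    **{name: getattr(fit, name) for name in PARAM_NAMES},
                    "converged": fit.converged,
                    "identifiable": fit.identifiable,
                    "objective": fit.objective,
                }
            )
        except Exception as exc:  # isolate per-feature failures
            rows.append(
                {
                    "feature": ids[j],
                    **{name: np.nan for name in PARAM_NAMES},
                    "converged": False,
                    "identifiable": False,
                    "objective": np.nan,
                }
            )
            if progress:
                print(f"  feature {ids[j]} failed: {exc}")
        if progress and (j + 1) % 500 == 0:
            print(f"  fitted {j + 1}/{n_feat} features")
    fits = pd.DataFrame(rows)
    ok = fits["converged"] & fits["identifiable"]
    frac_neg = float((fits.loc[ok, "beta_mu"] < 0).mean()) if ok.any() else float("nan")
    frac_pos = float((fits.loc[ok, "beta_sigma"] > 0).mean()) if ok.any() else float("nan")
    return AgingEffectTable(
        fits=fits, frac_negative_beta_mu=frac_neg, frac_positive_beta_sigma=frac_pos
    )


def sd_at_age(fit: EdgeAgeFit, age: float) -> float:
    """Model-implied SD at a given age: exp(alpha_sigma + beta_sigma*(age-20))."""
    return float(np.exp(fit.alpha_sigma + fit.beta_sigma * (age - AGE_REFERENCE)))


def consistency_correlation(
    table_a: AgingEffectTable | pd.DataFrame,
    table_b: AgingEffectTable | pd.DataFrame,
    which: str = "beta_mu",
) -> float:
    """Pearson correlation of a slope estimate across two experiments.

    Both tables must cover the same feature set; features are matched by
    id, not by row order.
    """
    if which not in ("beta_mu", "beta_sigma"):
        raise ValueError("which must be 'beta_mu' or 'beta_sigma'")
    fa = table_a.fits if isinstance(table_a, AgingEffectTable) else table_a
    fb = table_b.fits if isinstance(table_b, AgingEffectTable) else table_b
    a = fa.set_index("feature")[which]
    b = fb.set_index("feature")[which]
    if set(a.index) != set(b.index):
        raise ValueError("feature sets differ between tables")
    b = b.reindex(a.index)
    return float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])
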
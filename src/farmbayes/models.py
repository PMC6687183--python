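"""Bayesian model fitting for the survey analysis.

Three model families, all with standard-normal priors on regression
coefficients and an inverse-gamma prior on the error variance:

* site-indexed Gaussian linear regression (yield, SPAD) — fitted by a
  conjugate Gibbs sampler (the coefficient block is multivariate normal given
  sigma^2, sigma^2 is inverse-gamma given the coefficients);
* Bayesian logistic regression (striga incidence) — fitted by independence
  Metropolis-Hastings with a multivariate-t proposal centered at the
  posterior mode with the Laplace covariance;
* the two-step striga hurdle — logistic incidence over all plots, then a
  Gaussian model of the 1-8 infestation level on striga-positive plots only.

Convergence is diagnosed with the split-chain potential scale reduction
statistic (R-hat); runs exceeding 1.1 are flagged and logged, never raised.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from functools import cached_property
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import expit, gammaln

from .preprocess import DesignMatrix

log = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.1

GAUSSIAN = "gaussian"
BERNOULLI_LOGIT = "bernoulli_logit"


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression model.

    ``prior_sigma_shape``/``prior_sigma_scale`` parameterize the
    inverse-gamma prior on the error *variance* sigma^2 (shape 2, scale 1 by
    default: weakly informative on the standardized-response scale, with a
    finite prior mean of 1).
    """

    response: str
    covariates: tuple[str, ...]
    likelihood: str = GAUSSIAN
    site_varying_intercept: bool = True
    site_varying_slopes: bool = True
    prior_coef_sd: float = 1.0
    prior_sigma_shape: float = 2.0
    prior_sigma_scale: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("covariates must be unique")
        if self.likelihood not in (GAUSSIAN, BERNOULLI_LOGIT):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.prior_coef_sd <= 0:
            raise ValueError("prior_coef_sd must be > 0")


@dataclass(frozen=True)
class McmcSettings:
    chains: int = 2
    burn_in: int = 500
    draws: int = 10000
    seed: int = 0
    sampler: str = "auto"  # gibbs (gaussian) / laplace_imh (logistic)

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("chains must be >= 2 (R-hat needs at least 2 chains)")
        if self.draws < 1 or self.burn_in < 0:
            raise ValueError("draws must be >= 1 and burn_in >= 0")


class ParamInfo(NamedTuple):
    kind: str  # 'alpha' | 'beta' | 'sigma'
    site: str  # '' when shared
    covariate: str  # '' for alpha / sigma


def build_design(design: DesignMatrix, spec: ModelSpec):
    """Expand a DesignMatrix into the sampler's flat parameterization.

    Site-varying terms become one column per site (intercept indicators and
    covariate-times-indicator columns); shared terms a single column.  Returns
    ``(Z, names, infos)`` where coefficient order is intercept block first,
    then covariates in spec order (each expanded by site where applicable).
    """
    missing = [c for c in spec.covariates if c not in design.columns]
    if missing:
        raise ValueError(f"design is missing covariate(s): {', '.join(missing)}")
    n = design.n
    sites = list(pd.unique(design.site_index)) if n else []
    if (spec.site_varying_intercept or spec.site_varying_slopes) and n and len(sites) < 2:
        raise ValueError("site-varying terms need >= 2 sites in the data")

    cols, names, infos = [], [], []
    if spec.site_varying_intercept:
        for s in sites:
            cols.append((design.site_index == s).astype(float))
            names.append(f"alpha[{s}]")
            infos.append(ParamInfo("alpha", str(s), ""))
    else:
        cols.append(np.ones(n))
        names.append("alpha")
        infos.append(ParamInfo("alpha", "", ""))
    for cov in spec.covariates:
        x = design.column(cov)
        if spec.site_varying_slopes:
            for s in sites:
                cols.append(np.where(design.site_index == s, x, 0.0))
                names.append(f"beta[{s}][{cov}]")
                infos.append(ParamInfo("beta", str(s), cov))
        else:
            cols.append(x)
            names.append(f"beta[{cov}]")
            infos.append(ParamInfo("beta", "", cov))
    Z = np.column_stack(cols) if cols else np.empty((n, 0))
    return Z, names, infos


# --- diagnostics --------------------------------------------------------------


def compute_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    Each of the m chains of length N is split in half, giving 2m sequences of
    length N//2.  With W the mean within-sequence variance and B/n the
    between-sequence variance of the sequence means (n = N//2),

        R-hat = sqrt( ((n-1)/n * W + B/n) / W ).

    Estimates marginally below 1 (pure sampling noise in the B/W ratio) are
    floored at 1.0.  Chains with zero total variance return 1.0 by convention
    (degenerate but convergent) with a RuntimeWarning.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need draws shaped (chains >= 2, n)")
    m, N = draws.shape
    if N < 4:
        raise ValueError("need at least 4 draws per chain for split R-hat")
    half = N // 2
    seqs = np.vstack([draws[:, :half], draws[:, half: 2 * half]])
    means = seqs.mean(axis=1)
    variances = seqs.var(axis=1, ddof=1)
    W = variances.mean()
    B_over_n = means.var(ddof=1)
    if W == 0.0:
        warnings.warn(
            "zero within-chain variance; returning R-hat = 1.0 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    var_hat = (half - 1) / half * W + B_over_n
    return float(max(1.0, np.sqrt(var_hat / W)))


def effective_sample_size(draws: np.ndarray) -> float:
    """ESS via autocorrelations combined across chains (Geyer truncation).

    Uses the standard multi-chain estimator: rho_t = 1 - (W - mean
    within-chain autocovariance at lag t) / var_hat, summed over consecutive
    positive pairs.
    """
    draws = np.asarray(draws, dtype=float)
    m, N = draws.shape
    if N < 4:
        return float(m * N)
    centered = draws - draws.mean(axis=1, keepdims=True)
    size = 2 ** int(np.ceil(np.log2(2 * N)))
    f = np.fft.rfft(centered, n=size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), n=size, axis=1)[:, :N].real / N
    W = draws.var(axis=1, ddof=1).mean()
    if W == 0.0:
        return float(m * N)
    var_hat = (N - 1) / N * W + draws.mean(axis=1).var(ddof=1) if m > 1 else W
    rho = 1.0 - (W - acov.mean(axis=0)) / var_hat
    # Geyer: sum lag pairs while their sum stays positive.
    tau = 1.0
    t = 1
    while t + 1 < N:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(min(m * N, m * N / tau))


# --- posterior container ------------------------------------------------------


class PosteriorResult:
    """Labeled multi-chain posterior draws plus summaries and diagnostics."""

    def __init__(
        self,
        draws: dict[str, np.ndarray],
        param_info: dict[str, ParamInfo],
        spec: ModelSpec,
        settings: McmcSettings,
        meta: dict | None = None,
    ):
        self.draws = draws
        self.param_info = param_info
        self.spec = spec
        self.settings = settings
        self.meta = meta or {}

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    def samples(self, name: str) -> np.ndarray:
        """Pooled draws (all chains concatenated) for one parameter."""
        return self.draws[name].reshape(-1)

    @cached_property
    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            flat = arr.reshape(-1)
            q = np.quantile(flat, [0.025, 0.5, 0.975])
            rows.append(
                {
                    "parameter": name,
                    "mean": float(flat.mean()),
                    "sd": float(flat.std(ddof=1)),
                    "q2.5": float(q[0]),
                    "q50": float(q[1]),
                    "q97.5": float(q[2]),
                    "prob_positive": float(np.mean(flat > 0)),
                    "rhat": compute_rhat(arr),
                    "ess": effective_sample_size(arr),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    @property
    def max_rhat(self) -> float:
        return float(self.summary["rhat"].max())

    @property
    def converged(self) -> bool:
        return self.max_rhat <= RHAT_THRESHOLD

    def check_convergence(self) -> bool:
        ok = self.converged
        if not ok:
            bad = self.summary[self.summary["rhat"] > RHAT_THRESHOLD]
            log.warning(
                "non-convergence: %d parameter(s) with R-hat > %.2f (max %.4f): %s",
                len(bad),
                RHAT_THRESHOLD,
                self.max_rhat,
                ", ".join(bad.index[:5]),
            )
        return ok

    # chain x draw x parameter array-store persistence -------------------------

    def save(self, path) -> None:
        names = self.parameters
        stacked = np.stack([self.draws[n] for n in names], axis=-1)
        meta = {
            "parameters": names,
            "param_info": {k: list(v) for k, v in self.param_info.items()},
            "spec": dataclasses.asdict(self.spec),
            "settings": dataclasses.asdict(self.settings),
            "meta": self.meta,
        }
        np.savez_compressed(path, draws=stacked, meta=json.dumps(meta))

    @classmethod
    def load(cls, path) -> "PosteriorResult":
        with np.load(path, allow_pickle=False) as data:
            stacked = data["draws"]
            meta = json.loads(str(data["meta"]))
        spec_d = meta["spec"]
        spec_d["covariates"] = tuple(spec_d["covariates"])
        draws = {
            name: stacked[..., i] for i, name in enumerate(meta["parameters"])
        }
        return cls(
            draws,
            {k: ParamInfo(*v) for k, v in meta["param_info"].items()},
            ModelSpec(**spec_d),
            McmcSettings(**meta["settings"]),
            meta["meta"],
        )


# --- log posterior (test oracle, pure function) -------------------------------


def _log_invgamma_sigma(sigma: float, shape: float, scale: float) -> float:
    """Log prior density of sigma when sigma^2 ~ InvGamma(shape, scale).

    Includes the Jacobian |d sigma^2 / d sigma| = 2 sigma so the value is a
    density over sigma itself.
    """
    v = sigma * sigma
    return (
        shape * np.log(scale)
        - gammaln(shape)
        - (shape + 1.0) * np.log(v)
        - scale / v
        + np.log(2.0 * sigma)
    )


def log_posterior(
    params: np.ndarray,
    design: DesignMatrix,
    spec: ModelSpec,
    fixed_sigma: float | None = None,
) -> float:
    """Unnormalized (in the MCMC sense: fully specified, prior included)
    log posterior density at one parameter point.

    ``params`` follows :func:`build_design` coefficient order; Gaussian
    models append sigma as the last entry unless ``fixed_sigma`` is given.
    Gaussian models return -inf for sigma <= 0.
    """
    Z, names, _ = build_design(design, spec)
    p = Z.shape[1]
    params = np.asarray(params, dtype=float)
    if spec.likelihood == GAUSSIAN:
        expected = p if fixed_sigma is not None else p + 1
        if params.shape != (expected,):
            raise ValueError(f"expected {expected} parameters, got {params.shape}")
        coefs = params[:p]
        sigma = fixed_sigma if fixed_sigma is not None else params[p]
        if sigma <= 0:
            return -np.inf
        resid = design.y - Z @ coefs
        n = len(resid)
        ll = -0.5 * n * np.log(2.0 * np.pi * sigma**2) - resid @ resid / (
            2.0 * sigma**2
        )
        lp = -0.5 * p * np.log(2.0 * np.pi * spec.prior_coef_sd**2) - coefs @ coefs / (
            2.0 * spec.prior_coef_sd**2
        )
        if fixed_sigma is None:
            lp += _log_invgamma_sigma(
                sigma, spec.prior_sigma_shape, spec.prior_sigma_scale
            )
        return float(ll + lp)
    if params.shape != (p,):
        raise ValueError(f"expected {p} parameters, got {params.shape}")
    eta = Z @ params
    # y*eta - log(1 + exp(eta)), computed stably
    ll = design.y @ eta - np.logaddexp(0.0, eta).sum()
    lp = -0.5 * p * np.log(2.0 * np.pi * spec.prior_coef_sd**2) - params @ params / (
        2.0 * spec.prior_coef_sd**2
    )
    return float(ll + lp)


# --- conjugate oracle ---------------------------------------------------------


def conjugate_linear_posterior(
    Z: np.ndarray, y: np.ndarray, noise_sd: float, prior_sd: float = 1.0
):
    """Closed-form posterior for a Gaussian linear model with known noise.

    With prior coef ~ N(0, prior_sd^2 I) and y | coef ~ N(Z coef, noise_sd^2 I),
    the posterior is N(mu, V) with V = (Z'Z/noise_sd^2 + I/prior_sd^2)^-1 and
    mu = V Z'y / noise_sd^2.  Returns (mu, V).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    p = Z.shape[1]
    A = Z.T @ Z / noise_sd**2 + np.eye(p) / prior_sd**2
    V = np.linalg.inv(A)
    mu = V @ (Z.T @ np.asarray(y, dtype=float)) / noise_sd**2
    return mu, V


# --- samplers -----------------------------------------------------------------


def _chain_rngs(settings: McmcSettings) -> list[np.random.Generator]:
    return [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(settings.seed).spawn(settings.chains)
    ]


def _gibbs_linear(Z, y, spec: ModelSpec, settings: McmcSettings, fixed_sigma=None):
    n, p = Z.shape
    ZtZ = Z.T @ Z
    Zty = Z.T @ y
    prior_prec = np.eye(p) / spec.prior_coef_sd**2
    a0, b0 = spec.prior_sigma_shape, spec.prior_sigma_scale
    total = settings.burn_in + settings.draws

    coef_out = np.empty((settings.chains, settings.draws, p))
    sigma_out = np.empty((settings.chains, settings.draws))
    for c, rng in enumerate(_chain_rngs(settings)):
        if fixed_sigma is not None:
            sigma2 = fixed_sigma**2
        else:
            sigma2 = b0 / rng.gamma(a0)  # init from the prior
        for t in range(total):
            if p:
                A = ZtZ / sigma2 + prior_prec
                L = cholesky(A, lower=True)
                mu = cho_solve((L, True), Zty / sigma2)
                coef = mu + solve_triangular(
                    L.T, rng.standard_normal(p), lower=False
                )
            else:
                coef = np.empty(0)
            if fixed_sigma is None:
                resid = y - Z @ coef if p else y
                sigma2 = (b0 + 0.5 * resid @ resid) / rng.gamma(a0 + 0.5 * n)
            if t >= settings.burn_in:
                coef_out[c, t - settings.burn_in] = coef
                sigma_out[c, t - settings.burn_in] = np.sqrt(sigma2)
    return coef_out, sigma_out


def _logistic_logpost_many(Thetas, Z, y, prior_prec, block=2048):
    """Vectorized log posterior over many coefficient points (T, p)."""
    T = Thetas.shape[0]
    out = np.empty(T)
    for start in range(0, T, block):
        th = Thetas[start: start + block]
        eta = th @ Z.T  # (b, n)
        ll = eta @ y - np.logaddexp(0.0, eta).sum(axis=1)
        out[start: start + block] = ll - 0.5 * prior_prec * np.sum(th * th, axis=1)
    return out


def _logistic_map(Z, y, prior_prec, max_iter=100, tol=1e-10):
    """Posterior mode and Hessian via damped Newton iterations."""
    n, p = Z.shape
    theta = np.zeros(p)

    def logpost(th):
        eta = Z @ th
        return y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * prior_prec * th @ th

    lp = logpost(theta)
    H = np.eye(p)
    for _ in range(max_iter):
        eta = Z @ theta
        pr = expit(eta)
        g = Z.T @ (y - pr) - prior_prec * theta
        W = pr * (1.0 - pr)
        H = Z.T @ (Z * W[:, None]) + prior_prec * np.eye(p)
        step = np.linalg.solve(H, g)
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            lp_new = logpost(cand)
            if lp_new >= lp:
                break
            scale *= 0.5
        theta, lp_prev, lp = cand, lp, lp_new
        if abs(lp - lp_prev) < tol and np.max(np.abs(scale * step)) < 1e-8:
            break
    return theta, H


def _mvt_logpdf(X, mu, L_cov, df):
    """Log density of a multivariate t with scale Cholesky factor L_cov."""
    p = len(mu)
    sol = solve_triangular(L_cov, (X - mu).T, lower=True)
    maha = np.sum(sol * sol, axis=0)
    logdet = np.sum(np.log(np.diag(L_cov)))
    const = (
        gammaln((df + p) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * p * np.log(df * np.pi)
        - logdet
    )
    return const - 0.5 * (df + p) * np.log1p(maha / df)


def _imh_logistic(Z, y, spec: ModelSpec, settings: McmcSettings, df=8.0):
    """Independence MH with a Laplace-centered multivariate-t proposal."""
    n, p = Z.shape
    prior_prec = 1.0 / spec.prior_coef_sd**2
    mode, H = _logistic_map(Z, y, prior_prec)
    if n and np.max(np.abs(Z @ mode)) > 12.0:
        log.warning(
            "possible complete separation: extreme fitted log-odds at the mode; "
            "the normal prior regularizes the fit, proceeding"
        )
    # proposal scale: Laplace covariance H^{-1}, lower Cholesky factor
    L_cov = np.linalg.cholesky(np.linalg.inv(H))

    total = settings.burn_in + settings.draws
    out = np.empty((settings.chains, settings.draws, p))
    accept_rates = []
    for c, rng in enumerate(_chain_rngs(settings)):
        z = rng.standard_normal((total, p))
        g = rng.chisquare(df, size=total)
        props = mode + (z * np.sqrt(df / g)[:, None]) @ L_cov.T
        logp = _logistic_logpost_many(props, Z, y, prior_prec)
        logq = _mvt_logpdf(props, mode, L_cov, df)
        logu = np.log(rng.random(total))

        cur = mode.copy()
        cur_lw = (
            _logistic_logpost_many(cur[None, :], Z, y, prior_prec)[0]
            - _mvt_logpdf(cur[None, :], mode, L_cov, df)[0]
        )
        n_acc = 0
        for t in range(total):
            lw = logp[t] - logq[t]
            if logu[t] < lw - cur_lw:
                cur = props[t]
                cur_lw = lw
                n_acc += 1
            if t >= settings.burn_in:
                out[c, t - settings.burn_in] = cur
        accept_rates.append(n_acc / total)
    rate = float(np.mean(accept_rates))
    if rate < 0.15:
        log.warning("low independence-MH acceptance rate (%.2f)", rate)
    return out, rate


# --- public fitting operations ------------------------------------------------


def _check_not_singular(Z: np.ndarray) -> None:
    """Reject pathological designs; tolerate prior-resolved rank deficiency.

    A column of zeros (e.g. a site indicator with no records) or two
    identical columns make individual parameters meaningless, so they raise.
    Structural rank deficiency — e.g. site-year rainfall totals spanning only
    two years within a site — leaves the posterior proper under the N(0,1)
    coefficient prior (a ridge), so it is logged, not raised.
    """
    if Z.size == 0:
        return
    norms = np.linalg.norm(Z, axis=0)
    if np.any(norms == 0):
        raise ValueError("singular design matrix: column(s) identically zero")
    G = (Z / norms).T @ (Z / norms)
    off = np.abs(G - np.eye(G.shape[0]))
    if off.max() > 1.0 - 1e-12:
        log.warning(
            "proportional design columns (e.g. a binary constant within one "
            "site); the affected contrasts are identified only by the prior"
        )
    s = np.linalg.svd(Z, compute_uv=False)
    if s[-1] / s[0] < 1e-8:
        log.info(
            "rank-deficient design (condition number %.2e); the coefficient "
            "prior regularizes the fit but some directions are identified "
            "only by the prior",
            s[0] / max(s[-1], 1e-300),
        )


def _make_result(coef_draws, names, infos, spec, settings, sigma_draws=None, **meta):
    draws = {name: coef_draws[:, :, i] for i, name in enumerate(names)}
    info = {name: infos[i] for i, name in enumerate(names)}
    if sigma_draws is not None:
        draws["sigma"] = sigma_draws
        info["sigma"] = ParamInfo("sigma", "", "")
    result = PosteriorResult(draws, info, spec, settings, meta)
    result.check_convergence()
    return result


def fit_linear_model(
    design: DesignMatrix,
    spec: ModelSpec,
    settings: McmcSettings,
    fixed_sigma: float | None = None,
) -> PosteriorResult:
    """Sample the posterior of a (site-indexed) Gaussian linear model.

    Priors: coefficients iid N(0, prior_coef_sd^2); sigma^2 ~ InvGamma.  With
    ``fixed_sigma`` the noise scale is held fixed (the conjugate case; used by
    tests and the calibration backend).  Non-convergence (any R-hat > 1.1)
    flags the result and logs a warning; it never raises.
    """
    if spec.likelihood != GAUSSIAN:
        raise ValueError("fit_linear_model requires a gaussian ModelSpec")
    Z, names, infos = build_design(design, spec)
    _check_not_singular(Z)
    coef_draws, sigma_draws = _gibbs_linear(Z, design.y, spec, settings, fixed_sigma)
    return _make_result(
        coef_draws,
        names,
        infos,
        spec,
        settings,
        sigma_draws=None if fixed_sigma is not None else sigma_draws,
        sampler="gibbs",
        n=design.n,
        fixed_sigma=fixed_sigma,
    )


def fit_logistic_model(
    design: DesignMatrix, spec: ModelSpec, settings: McmcSettings
) -> PosteriorResult:
    """Sample the posterior of a (site-indexed) Bayesian logistic model.

    The response must be raw 0/1 (build the design with
    ``standardize_response=False``) with both classes present.
    """
    if spec.likelihood != BERNOULLI_LOGIT:
        raise ValueError("fit_logistic_model requires a bernoulli_logit ModelSpec")
    y = design.y
    if not np.isin(np.unique(y), (0.0, 1.0)).all():
        raise ValueError("logistic response must be 0/1")
    if y.min() == y.max():
        raise ValueError("logistic response needs both classes present")
    Z, names, infos = build_design(design, spec)
    _check_not_singular(Z)
    coef_draws, rate = _imh_logistic(Z, y, spec, settings)
    return _make_result(
        coef_draws, names, infos, spec, settings,
        sampler="laplace_imh", n=design.n, acceptance_rate=rate,
    )


class HurdleResult(NamedTuple):
    incidence: PosteriorResult
    level: PosteriorResult
    n_level: int


def fit_hurdle_striga(
    design: DesignMatrix,
    incidence_spec: ModelSpec,
    level_spec: ModelSpec,
    settings: McmcSettings,
) -> HurdleResult:
    """Two-step hurdle for the 0-8 striga count.

    Step 1 ("prevention"): logistic regression of presence (count >= 1) over
    all plots.  Step 2 ("control"): Gaussian regression of the count,
    standardized within the striga-positive subset, over that subset only.
    ``design.y`` must hold the raw 0-8 counts (standardize_response=False).
    """
    y = design.y
    if np.any((y < 0) | (y > 8) | (y != np.rint(y))):
        raise ValueError("hurdle response must be integer striga counts in 0..8")
    positive = y >= 1
    if not positive.any():
        raise ValueError("no striga-positive plots: cannot fit the level model")
    if positive.all():
        raise ValueError("no striga-free plots: cannot fit the incidence model")

    seeds = np.random.SeedSequence(settings.seed).generate_state(2) % (2**31)
    inc_design = design.with_response(positive.astype(float), "striga_present")
    inc = fit_logistic_model(
        inc_design, incidence_spec,
        dataclasses.replace(settings, seed=int(seeds[0])),
    )

    sub = design.subset(positive)
    counts = sub.y
    c_mean = float(counts.mean())
    c_sd = float(counts.std(ddof=1))
    if c_sd == 0.0:
        raise ValueError("striga level is constant on the positive subset")
    sub = sub.with_response((counts - c_mean) / c_sd, "striga_level", c_mean, c_sd)
    Z_lvl, _, _ = build_design(sub, level_spec)
    if sub.n < 10 * Z_lvl.shape[1]:
        log.warning(
            "striga level model: only %d positive plots for %d parameters "
            "(< 10 per parameter); estimates may be prior-dominated",
            sub.n,
            Z_lvl.shape[1],
        )
    level = fit_linear_model(
        sub, level_spec, dataclasses.replace(settings, seed=int(seeds[1]))
    )
    return HurdleResult(inc, level, int(sub.n))
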
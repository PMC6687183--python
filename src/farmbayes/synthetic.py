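"""Synthetic longitudinal farm-survey generator.

Emulates a two-year panel of smallholder maize plots across four Extension
Planning Areas (EPAs) in Central Malawi.  Covariates are drawn per site from
truncated normals / Bernoullis whose post-truncation moments are matched to
published descriptive statistics; responses (striga counts, SPAD, grain
yield) are drawn from the same site-indexed linear / hurdle model family the
inference modules fit, so parameter-recovery and calibration tests have a
known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .preprocess import SURVEY_COLUMNS

log = logging.getLogger(__name__)

SITES = ("Golomoti", "Linthipe", "Kandeu", "Nsipe")

CONTINUOUS_COVARIATES = (
    "rain_dec_feb",
    "rain_mar",
    "rain_apr_may",
    "poxc",
    "ph",
    "spacing_m",
    "weed_biomass",
)
BINARY_COVARIATES = ("fertilizer", "intercrop", "compost")
#: Explanatory variables shared by every model (environment + management).
BASE_COVARIATES = CONTINUOUS_COVARIATES + BINARY_COVARIATES
#: The yield model additionally uses SPAD and farmer-reported striga
#: (12 explanatory variables in total).
YIELD_COVARIATES = BASE_COVARIATES + ("spad", "striga_farmer")

#: Physical lower/upper bounds used to truncate continuous covariate draws.
BOUNDS = {
    "rain_dec_feb": (0.0, np.inf),
    "rain_mar": (0.0, np.inf),
    "rain_apr_may": (0.0, np.inf),
    "poxc": (0.0, np.inf),
    "ph": (3.0, 10.0),
    "spacing_m": (0.0, np.inf),
    "weed_biomass": (0.0, np.inf),
}

#: Site-varying variables that are soil properties (drawn once per plot,
#: constant across years) vs. site-year weather (shared by all plots of a
#: site in a given year) vs. per plot-year management.
PLOT_LEVEL = ("poxc", "ph")
SITE_YEAR_LEVEL = ("rain_dec_feb", "rain_mar", "rain_apr_may")

DEFAULT_SEED = 20190808

#: Published per-site descriptive statistics: mean (SD) of each continuous
#: variable and incidence of each binary variable, plus the two response
#: variables used for de-standardization.  Order of sites: Golomoti,
#: Linthipe, Kandeu, Nsipe.
_TABLE1 = {
    "rain_dec_feb": [(563.0, 78.0), (624.5, 27.7), (629.5, 94.6), (636.8, 132.8)],
    "rain_mar": [(78.6, 26.8), (128.9, 42.0), (102.8, 26.5), (116.8, 25.4)],
    "rain_apr_may": [(25.2, 10.4), (43.8, 11.6), (39.1, 9.1), (44.4, 8.8)],
    "poxc": [(278.9, 152.43), (466.9, 220.5), (390.41, 191.15), (340.70, 160.22)],
    "ph": [(6.56, 0.61), (6.09, 0.46), (6.10, 0.53), (6.32, 0.61)],
    "spacing_m": [(0.897, 0.11), (0.927, 0.11), (0.970, 0.13), (0.914, 0.14)],
    "weed_biomass": [(0.183, 0.16), (0.159, 0.15), (0.201, 0.15), (0.246, 0.16)],
    "fertilizer": [0.67, 0.80, 0.85, 0.81],
    "intercrop": [0.66, 0.77, 0.74, 0.60],
    "compost": [0.41, 0.44, 0.31, 0.27],
    "striga_farmer": [0.22, 0.30, 0.16, 0.28],
    "yield_kg_ha": [(1567.44, 1039.3), (2636.3, 1526.5), (2069.4, 1471.5), (2320.9, 1452.9)],
    "spad": [(41.20, 8.85), (46.98, 7.15), (46.00, 8.62), (41.84, 8.11)],
}


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration is internally inconsistent."""


@dataclass
class Continuous:
    mean: float
    sd: float


@dataclass
class Binary:
    prob: float


@dataclass
class SyntheticConfig:
    """Layout and covariate distributions of one synthetic survey.

    ``covariate_params[site][name]`` is a :class:`Continuous` (mean/SD of the
    truncated-normal draw, matched post-truncation) or a :class:`Binary`
    (Bernoulli probability).  ``response_params`` holds the per-site mean/SD
    of SPAD and yield used to map standardized responses to natural units.
    """

    sites: tuple[str, ...] = SITES
    households_per_site: int = 80
    plots_per_household: int = 2
    years: int = 2
    covariate_params: Mapping[str, Mapping[str, object]] = field(default_factory=dict)
    response_params: Mapping[str, Mapping[str, Continuous]] = field(default_factory=dict)
    missing_frac: float = 0.0
    seed: int = DEFAULT_SEED

    @property
    def total_records(self) -> int:
        return (
            len(self.sites)
            * self.households_per_site
            * self.plots_per_household
            * self.years
        )

    def validate(self) -> None:
        if not self.sites:
            raise ConfigurationError("sites: must list at least one site")
        for fld in ("households_per_site", "plots_per_household", "years"):
            if getattr(self, fld) < 1:
                raise ConfigurationError(f"{fld}: must be >= 1")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ConfigurationError("missing_frac: must be in [0, 1)")
        for site in self.sites:
            if site not in self.covariate_params:
                raise ConfigurationError(f"covariate_params: no entry for site {site!r}")
            params = self.covariate_params[site]
            for name in BASE_COVARIATES:
                if name not in params:
                    raise ConfigurationError(
                        f"covariate_params[{site!r}]: missing covariate {name!r}"
                    )
                p = params[name]
                if isinstance(p, Continuous):
                    if p.sd < 0:
                        raise ConfigurationError(
                            f"covariate_params[{site!r}][{name!r}].sd: must be >= 0"
                        )
                elif isinstance(p, Binary):
                    if not 0.0 <= p.prob <= 1.0:
                        raise ConfigurationError(
                            f"covariate_params[{site!r}][{name!r}].prob: must be in [0,1]"
                        )
                else:
                    raise ConfigurationError(
                        f"covariate_params[{site!r}][{name!r}]: unknown parameter type"
                    )
            if site not in self.response_params:
                raise ConfigurationError(f"response_params: no entry for site {site!r}")
            for name in ("spad", "yield_kg_ha"):
                if name not in self.response_params[site]:
                    raise ConfigurationError(
                        f"response_params[{site!r}]: missing response {name!r}"
                    )

    def pooled_moments(self, name: str) -> tuple[float, float]:
        """Mean/SD of one variable pooled over sites (equal site weights).

        For a mixture of per-site distributions with means m_i and SDs s_i,
        the pooled mean is the average of the m_i and the pooled variance is
        mean(s_i^2 + m_i^2) - mean(m_i)^2.  Binary variables pool to a
        Bernoulli with the average probability.
        """
        if name in ("spad", "yield_kg_ha"):
            params = [self.response_params[s][name] for s in self.sites]
        else:
            params = [self.covariate_params[s][name] for s in self.sites]
        if isinstance(params[0], Binary):
            p = float(np.mean([q.prob for q in params]))
            return p, float(np.sqrt(p * (1.0 - p)))
        means = np.array([q.mean for q in params], dtype=float)
        sds = np.array([q.sd for q in params], dtype=float)
        m = float(means.mean())
        var = float(np.mean(sds**2 + means**2) - m**2)
        return m, float(np.sqrt(var))


def default_config_from_table1(
    households_per_site: int = 80,
    plots_per_household: int = 2,
    years: int = 2,
    missing_frac: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> SyntheticConfig:
    """Config calibrated to the published per-site descriptive statistics.

    The default layout (4 sites x 80 households x 2 plots x 2 years = 1,280
    potential records) brackets the ~1,197 analyzed plot-years of the source
    survey; ``missing_frac`` can thin records completely at random.
    """
    cov: dict[str, dict[str, object]] = {}
    resp: dict[str, dict[str, Continuous]] = {}
    for i, site in enumerate(SITES):
        params: dict[str, object] = {}
        for name in CONTINUOUS_COVARIATES:
            m, s = _TABLE1[name][i]
            params[name] = Continuous(m, s)
        for name in BINARY_COVARIATES:
            params[name] = Binary(_TABLE1[name][i])
        cov[site] = params
        resp[site] = {
            "spad": Continuous(*_TABLE1["spad"][i]),
            "yield_kg_ha": Continuous(*_TABLE1["yield_kg_ha"][i]),
        }
    return SyntheticConfig(
        sites=SITES,
        households_per_site=households_per_site,
        plots_per_household=plots_per_household,
        years=years,
        covariate_params=cov,
        response_params=resp,
        missing_frac=missing_frac,
        seed=seed,
    )


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind one synthetic dataset.

    All regression parameters are on the pooled-standardized scale (the scale
    the inference modules work on).  ``striga_level_coefs`` are on the raw
    1-8 scale.  ``household_sd`` > 0 adds an independent N(0, household_sd)
    intercept offset per household to each response model.
    """

    alpha: Mapping[str, float]
    beta: Mapping[str, Mapping[str, float]]
    sigma: float
    spad_alpha: Mapping[str, float]
    spad_beta: Mapping[str, Mapping[str, float]]
    spad_sigma: float
    striga_incidence_logit: Mapping[str, Mapping[str, float]]
    striga_level_coefs: Mapping[str, Mapping[str, float]]
    striga_level_sd: float = 1.5
    household_sd: float = 0.0

    def validate(self, sites) -> None:
        if self.sigma <= 0 or self.spad_sigma <= 0 or self.striga_level_sd <= 0:
            raise ValueError("all residual scales must be > 0")
        if self.household_sd < 0:
            raise ValueError("household_sd must be >= 0")
        for site in sites:
            if set(self.beta[site]) != set(YIELD_COVARIATES):
                raise ValueError(
                    f"beta[{site!r}] must have exactly the yield covariates "
                    f"{list(YIELD_COVARIATES)}"
                )
            if set(self.spad_beta[site]) != set(BASE_COVARIATES):
                raise ValueError(f"spad_beta[{site!r}] must cover {list(BASE_COVARIATES)}")
            for fld in ("striga_incidence_logit", "striga_level_coefs"):
                coefs = getattr(self, fld)[site]
                if set(coefs) != set(("intercept",) + BASE_COVARIATES):
                    raise ValueError(
                        f"{fld}[{site!r}] must have 'intercept' plus {list(BASE_COVARIATES)}"
                    )


def default_truth(config: SyntheticConfig | None = None) -> SyntheticTruth:
    """A plausible ground truth echoing the reported effect structure.

    SPAD is the dominant positive yield driver (site coefficients spanning
    roughly +0.28 to +0.42 SD) and striga the dominant negative one (down to
    -0.38 SD at the wetter, higher-yield sites); fertilizer raises SPAD
    everywhere but the marginal site, where active soil carbon (POXC) and
    compost matter instead.  Site intercepts are placed so de-standardized
    site means track the published per-site response means.
    """
    if config is None:
        config = default_config_from_table1()

    def per_site(base: Mapping[str, float], **overrides) -> dict:
        out = {}
        for site in config.sites:
            d = dict(base)
            d.update(overrides.get(site, {}))
            out[site] = d
        return out

    zero_base = {c: 0.0 for c in BASE_COVARIATES}

    yield_base = {
        "rain_dec_feb": 0.05,
        "rain_mar": 0.0,
        "rain_apr_may": 0.0,
        "poxc": 0.03,
        "ph": 0.0,
        "spacing_m": -0.12,
        "weed_biomass": -0.03,
        "fertilizer": 0.05,
        "intercrop": 0.0,
        "compost": 0.02,
        "spad": 0.33,
        "striga_farmer": -0.10,
    }
    beta = per_site(
        yield_base,
        Golomoti={"spad": 0.28, "striga_farmer": -0.08, "poxc": 0.15, "compost": 0.10},
        Linthipe={"spad": 0.42, "striga_farmer": -0.38, "rain_dec_feb": 0.15},
        Kandeu={"spad": 0.33, "striga_farmer": -0.10, "fertilizer": 0.10},
        Nsipe={"spad": 0.38, "striga_farmer": -0.30, "rain_dec_feb": 0.15,
               "rain_apr_may": -0.12, "fertilizer": 0.10},
    )

    spad_base = {
        "rain_dec_feb": 0.05,
        "rain_mar": 0.05,
        "rain_apr_may": 0.0,
        "poxc": 0.05,
        "ph": 0.0,
        "spacing_m": 0.0,
        "weed_biomass": 0.0,
        "fertilizer": 0.30,
        "intercrop": 0.0,
        "compost": 0.05,
    }
    spad_beta = per_site(
        spad_base,
        Golomoti={"fertilizer": 0.05, "poxc": 0.20, "compost": 0.15, "rain_mar": 0.15},
        Linthipe={"rain_dec_feb": 0.15},
        Kandeu={"rain_dec_feb": 0.0},
        Nsipe={"rain_dec_feb": 0.15, "rain_apr_may": -0.10},
    )

    # Incidence intercepts reproduce the published farmer-reported striga
    # rates at covariate means; slopes echo the reported prevention effects.
    inc = {}
    for site in config.sites:
        coefs = {"intercept": float(logit(_TABLE1["striga_farmer"][SITES.index(site)])),
                 **zero_base}
        inc[site] = coefs
    inc["Kandeu"]["fertilizer"] = -0.30
    inc["Linthipe"]["fertilizer"] = -0.30
    inc["Linthipe"]["intercrop"] = 0.25
    inc["Nsipe"]["compost"] = -0.30
    inc["Golomoti"]["spacing_m"] = -0.25

    level = {}
    for site in config.sites:
        level[site] = {"intercept": 3.0, **zero_base}
    level["Linthipe"]["fertilizer"] = -0.60
    level["Nsipe"]["compost"] = -0.60
    level["Golomoti"]["spacing_m"] = -0.50
    level["Kandeu"]["compost"] = 0.40

    # Site intercepts: offset of the site response mean from the pooled mean,
    # in pooled-SD units (covariate-mean contributions are second order).
    alpha = {}
    spad_alpha = {}
    ym, ys = config.pooled_moments("yield_kg_ha")
    sm, ss = config.pooled_moments("spad")
    for site in config.sites:
        alpha[site] = (config.response_params[site]["yield_kg_ha"].mean - ym) / ys
        spad_alpha[site] = (config.response_params[site]["spad"].mean - sm) / ss

    return SyntheticTruth(
        alpha=alpha,
        beta=beta,
        sigma=0.7,
        spad_alpha=spad_alpha,
        spad_beta=spad_beta,
        spad_sigma=0.8,
        striga_incidence_logit=inc,
        striga_level_coefs=level,
        striga_level_sd=1.5,
        household_sd=0.0,
    )


# --- covariate generation ---------------------------------------------------


def _match_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Underlying (mu, s) of a truncated normal with the given moments.

    Solves for the pre-truncation location/scale so the post-truncation mean
    and SD equal the configured values; falls back to the naive (mean, sd)
    when the bounds are effectively inactive (> 6 SDs away).
    """
    if sd == 0.0:
        return mean, 0.0
    if (lo == -np.inf or (mean - lo) / sd > 6.0) and (
        hi == np.inf or (hi - mean) / sd > 6.0
    ):
        return mean, sd

    def eqs(params):
        mu, logs = params
        s = np.exp(logs)
        a, b = (lo - mu) / s, (hi - mu) / s
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ier, msg = optimize.fsolve(
        eqs, x0=[mean, np.log(sd)], full_output=True
    )
    if ier != 1:  # pragma: no cover - defensive
        log.warning("truncated-normal moment matching did not converge: %s", msg)
        return mean, sd
    return float(sol[0]), float(np.exp(sol[1]))


def _draw_truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0.0:
        return np.full(size, mean)
    mu, s = _match_truncnorm(mean, sd, lo, hi)
    a, b = (lo - mu) / s, (hi - mu) / s
    return stats.truncnorm.rvs(a, b, loc=mu, scale=s, size=size, random_state=rng)


def generate_covariates(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw identifiers and covariates; response columns are left missing.

    Rainfall totals are site-year variables (identical for every plot of a
    site in a given year); soil POXC and pH are plot variables (constant
    across years, as plots were soil-sampled once); spacing, weed biomass and
    the binary management variables vary by plot-year.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    years = [2015 + t for t in range(config.years)]
    frames = []
    for site in config.sites:
        H, P, Y = config.households_per_site, config.plots_per_household, config.years
        n_plots = H * P
        n = n_plots * Y
        params = config.covariate_params[site]

        households = np.repeat(
            [f"{site[:3].lower()}-h{h + 1:03d}" for h in range(H)], P * Y
        )
        plots = np.repeat(
            [f"{site[:3].lower()}-h{h + 1:03d}-p{p + 1}" for h in range(H) for p in range(P)],
            Y,
        )
        year_col = np.tile(years, n_plots)

        data = {
            "site": np.repeat(site, n),
            "household": households,
            "plot": plots,
            "year": year_col,
        }
        for name in SITE_YEAR_LEVEL:
            p = params[name]
            lo, hi = BOUNDS[name]
            per_year = _draw_truncnorm(rng, p.mean, p.sd, lo, hi, Y)
            data[name] = np.tile(per_year, n_plots)
        for name in PLOT_LEVEL:
            p = params[name]
            lo, hi = BOUNDS[name]
            per_plot = _draw_truncnorm(rng, p.mean, p.sd, lo, hi, n_plots)
            data[name] = np.repeat(per_plot, Y)
        for name in CONTINUOUS_COVARIATES:
            if name in SITE_YEAR_LEVEL or name in PLOT_LEVEL:
                continue
            p = params[name]
            lo, hi = BOUNDS[name]
            data[name] = _draw_truncnorm(rng, p.mean, p.sd, lo, hi, n)
        for name in BINARY_COVARIATES:
            data[name] = (rng.random(n) < params[name].prob).astype(int)

        data["spad"] = np.full(n, np.nan)
        data["striga_count"] = np.full(n, np.nan)
        data["striga_farmer"] = np.full(n, np.nan)
        data["yield_kg_ha"] = np.full(n, np.nan)
        frames.append(pd.DataFrame(data))

    return pd.concat(frames, ignore_index=True)[SURVEY_COLUMNS]


# --- response generation ----------------------------------------------------


def _site_coef_matrix(records, truth_map, names, sites):
    """(n, len(names)) matrix of per-row coefficients looked up by site."""
    table = np.array(
        [[truth_map[s][c] for c in names] for s in sites], dtype=float
    )
    idx = pd.Categorical(records["site"], categories=list(sites)).codes
    return table[idx]


def generate_responses(
    records: pd.DataFrame,
    truth: SyntheticTruth,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill in striga, SPAD and yield from the ground-truth model family.

    Covariates are standardized with the configured pooled moments (not the
    realized sample moments) so the truth stays independent of the draw;
    SPAD and the striga indicator entering the yield predictor are
    standardized by their realized pooled sample moments, matching what the
    preprocessing stage will do.  Yield is floored at 0 kg/ha and the number
    of floored records is logged and stored in ``df.attrs['n_floored']``.
    """
    config.validate()
    truth.validate(config.sites)
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    df = records.copy()
    n = len(df)
    sites = config.sites

    Z = np.column_stack(
        [
            (df[c].to_numpy(dtype=float) - config.pooled_moments(c)[0])
            / config.pooled_moments(c)[1]
            for c in BASE_COVARIATES
        ]
    )

    hh_codes, hh_labels = pd.factorize(df["household"])

    def hh_offsets():
        if truth.household_sd == 0.0:
            return np.zeros(n)
        draws = rng.normal(0.0, truth.household_sd, size=len(hh_labels))
        return draws[hh_codes]

    # Step 1: striga via the hurdle mechanism.
    inc_names = ("intercept",) + BASE_COVARIATES
    inc_coef = _site_coef_matrix(df, truth.striga_incidence_logit, inc_names, sites)
    eta_inc = inc_coef[:, 0] + np.sum(inc_coef[:, 1:] * Z, axis=1)
    present = rng.random(n) < expit(eta_inc)

    lvl_coef = _site_coef_matrix(df, truth.striga_level_coefs, inc_names, sites)
    mu_lvl = lvl_coef[:, 0] + np.sum(lvl_coef[:, 1:] * Z, axis=1)
    level = np.clip(
        np.rint(mu_lvl + truth.striga_level_sd * rng.standard_normal(n)), 1, 8
    ).astype(int)
    df["striga_count"] = np.where(present, level, 0)
    df["striga_farmer"] = (df["striga_count"] >= 1).astype(int)

    # Step 2: SPAD on the standardized scale, then de-standardized.
    sb = _site_coef_matrix(df, truth.spad_beta, BASE_COVARIATES, sites)
    sa = np.array([truth.spad_alpha[s] for s in sites])[
        pd.Categorical(df["site"], categories=list(sites)).codes
    ]
    spad_z = (
        sa
        + np.sum(sb * Z, axis=1)
        + hh_offsets()
        + truth.spad_sigma * rng.standard_normal(n)
    )
    sm, ss = config.pooled_moments("spad")
    df["spad"] = sm + ss * spad_z

    # Step 3: yield, with realized SPAD / striga entering the predictor on
    # the same pooled-standardized scale the analysis will use.
    spad_col = df["spad"].to_numpy()
    z_spad = (spad_col - spad_col.mean()) / spad_col.std(ddof=1)
    striga_col = df["striga_farmer"].to_numpy(dtype=float)
    s_sd = striga_col.std(ddof=1)
    z_striga = (
        (striga_col - striga_col.mean()) / s_sd if s_sd > 0 else striga_col * 0.0
    )
    Z12 = np.column_stack([Z, z_spad, z_striga])
    yb = _site_coef_matrix(df, truth.beta, YIELD_COVARIATES, sites)
    ya = np.array([truth.alpha[s] for s in sites])[
        pd.Categorical(df["site"], categories=list(sites)).codes
    ]
    if yb.shape[1] != Z12.shape[1]:  # pragma: no cover - guarded by validate()
        raise ValueError("truth/covariate dimension mismatch")
    yield_z = (
        ya + np.sum(yb * Z12, axis=1) + hh_offsets()
        + truth.sigma * rng.standard_normal(n)
    )
    ym, ys = config.pooled_moments("yield_kg_ha")
    yld = ym + ys * yield_z
    n_floored = int((yld < 0).sum())
    if n_floored:
        log.info("floored %d negative yield draws at 0 kg/ha", n_floored)
    df["yield_kg_ha"] = np.maximum(yld, 0.0)
    df.attrs["n_floored"] = n_floored
    return df


def simulate_dataset(
    config: SyntheticConfig | None = None,
    truth: SyntheticTruth | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Convenience wrapper: covariates + responses (+ optional MCAR thinning)."""
    if config is None:
        config = default_config_from_table1()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    if truth is None:
        truth = default_truth(config)
    rng = np.random.default_rng(config.seed)
    df = generate_covariates(config, rng)
    df = generate_responses(df, truth, config, rng)
    if config.missing_frac > 0:
        keep = rng.random(len(df)) >= config.missing_frac
        df = df.loc[keep].reset_index(drop=True)
    return df, truth


# --- truth persistence -------------------------------------------------------


def write_truth(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=1, sort_keys=True)


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        return SyntheticTruth(**json.load(fh))
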
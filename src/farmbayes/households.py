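"""Household (farmer) effect screen.

Fits the covariate-free model y = alpha_household + sigma * eps over all
sites pooled, with independent N(0,1) priors on each household intercept and
an inverse-gamma prior on sigma^2, then classifies each household whose
intercept is credibly non-zero at the chosen level.

Because the intercepts are conditionally conjugate and enter the likelihood
through disjoint blocks of rows, sigma^2's marginal posterior (intercepts
integrated out analytically) is one-dimensional; it is sampled exactly by
inverse-CDF on a fine grid, and each alpha_h given sigma^2 is Gaussian in
closed form.  Flagging probabilities P(alpha_h > 0 | y) are Rao-Blackwellized
(the normal CDF averaged over sigma^2 draws), which makes the screen exactly
sign-equivariant: negating the response swaps positive and negative calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr

from .models import McmcSettings, compute_rhat
from .report import NEGATIVE, NONSIGNIFICANT, POSITIVE, direction_from_probability

#: Aliases accepted by screen_households for the three response models.
RESPONSE_COLUMNS = {
    "yield": "yield_kg_ha",
    "spad": "spad",
    "striga": "striga_count",
    "striga_binary": "striga_farmer",
}


@dataclass
class HouseholdScreenResult:
    """Per-household intercept posteriors plus aggregate counts."""

    table: pd.DataFrame
    counts: dict[str, int]
    n_households: int
    n_excluded: int
    level: float
    response: str
    sigma_mean: float

    @property
    def proportions(self) -> dict[str, float]:
        return {k: v / self.n_households for k, v in self.counts.items()}

    @property
    def odds_descriptor(self) -> str:
        return f"{self.counts[POSITIVE]}:{self.counts[NEGATIVE]}"


def _sigma2_grid_sampler(n_h, ybar, ss, prior_sd, a0, b0, n_grid=4096):
    """Exact log marginal posterior of sigma^2 on a log-spaced grid.

    For each household block (n_h obs, mean ybar_h, sum of squares ss_h) the
    intercept integrates out to y_h | sigma^2 ~ N(0, sigma^2 I + tau^2 J):
    log det = (n_h - 1) log sigma^2 + log(sigma^2 + n_h tau^2) and the
    quadratic form follows from Sherman-Morrison.  Both depend on the data
    only through ss_h and ybar_h^2, hence sign-invariance.
    """
    tau2 = prior_sd**2
    n = float(n_h.sum())
    var_y = max(float((ss.sum() - (n_h * ybar**2).sum()) / max(n - 1, 1)), 1e-12)
    u = np.linspace(np.log(var_y) - 8.0, np.log(var_y) + 8.0, n_grid)
    s2 = np.exp(u)[:, None]  # (grid, 1)

    denom = s2 + n_h * tau2
    logdet = ((n_h - 1) * np.log(s2) + np.log(denom)).sum(axis=1)
    quad = (ss / s2 - tau2 * (n_h * ybar) ** 2 / (s2 * denom)).sum(axis=1)
    loglik = -0.5 * (logdet + quad)
    s2f = s2[:, 0]
    logprior = -(a0 + 1.0) * np.log(s2f) - b0 / s2f
    # density over u = log sigma^2 needs the Jacobian sigma^2
    logpost = loglik + logprior + np.log(s2f)
    logpost -= logsumexp(logpost)
    cdf = np.cumsum(np.exp(logpost))
    cdf /= cdf[-1]
    return u, cdf


def screen_households(
    records: pd.DataFrame,
    response: str = "yield",
    settings: McmcSettings | None = None,
    level: float = 0.95,
    prior_sd: float = 1.0,
    prior_sigma_shape: float = 2.0,
    prior_sigma_scale: float = 1.0,
) -> HouseholdScreenResult:
    """Screen per-household intercepts for credible departure from zero.

    The response (one of 'yield', 'spad', 'striga' — the 0-8 count — or
    'striga_binary', or any raw column name) is standardized over the pooled
    sample before fitting.  Households with no non-missing response are
    excluded and counted.  No multiple-testing correction is applied across
    households: the screen mirrors raw 5%-level credibility calls, so ~5-7%
    flagged households are expected even under a pure-noise response.
    """
    if settings is None:
        settings = McmcSettings()
    column = RESPONSE_COLUMNS.get(response, response)
    if column not in records.columns:
        raise ValueError(f"unknown response column {column!r}")
    if "household" not in records.columns:
        raise ValueError("records must have a 'household' column")

    df = records[["household", column]].copy()
    ok = df[column].notna()
    excluded_households = set(df.loc[~ok, "household"]) - set(df.loc[ok, "household"])
    df = df.loc[ok]
    y_raw = df[column].to_numpy(dtype=float)
    y_sd = y_raw.std(ddof=1)
    if y_sd == 0.0:
        raise ValueError(f"response {column!r} is constant; cannot screen")
    y = (y_raw - y_raw.mean()) / y_sd

    # order-invariant: households processed in sorted label order
    labels = np.sort(df["household"].unique())
    idx = pd.Categorical(df["household"], categories=labels).codes
    H = len(labels)
    n_h = np.bincount(idx, minlength=H).astype(float)
    ysum = np.bincount(idx, weights=y, minlength=H)
    ss = np.bincount(idx, weights=y**2, minlength=H)
    ybar = ysum / n_h

    u_grid, cdf = _sigma2_grid_sampler(
        n_h, ybar, ss, prior_sd, prior_sigma_shape, prior_sigma_scale
    )

    tau2 = prior_sd**2
    chains, draws = settings.chains, settings.draws
    rngs = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(settings.seed).spawn(chains)
    ]
    alpha_draws = np.empty((chains, draws, H))
    sigma_draws = np.empty((chains, draws))
    prob_pos = np.zeros(H)
    for c, rng in enumerate(rngs):
        s2 = np.exp(np.interp(rng.random(draws), cdf, u_grid))  # iid inverse-CDF
        sigma_draws[c] = np.sqrt(s2)
        v = 1.0 / (n_h[None, :] / s2[:, None] + 1.0 / tau2)  # (draws, H)
        m = v * ysum[None, :] / s2[:, None]
        alpha_draws[c] = m + np.sqrt(v) * rng.standard_normal((draws, H))
        prob_pos += ndtr(m / np.sqrt(v)).mean(axis=0)
    prob_pos /= chains

    rows = []
    counts = {POSITIVE: 0, NEGATIVE: 0, NONSIGNIFICANT: 0}
    tail = (1.0 - level) / 2.0
    for h, label in enumerate(labels):
        flat = alpha_draws[:, :, h].reshape(-1)
        q = np.quantile(flat, [tail, 0.5, 1.0 - tail])
        direction = direction_from_probability(prob_pos[h], level)
        counts[direction] += 1
        rows.append(
            {
                "household": label,
                "n_records": int(n_h[h]),
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "low": float(q[0]),
                "median": float(q[1]),
                "high": float(q[2]),
                "prob_positive": float(prob_pos[h]),
                "direction": direction,
                "rhat": compute_rhat(alpha_draws[:, :, h]),
            }
        )
    return HouseholdScreenResult(
        table=pd.DataFrame(rows),
        counts=counts,
        n_households=H,
        n_excluded=len(excluded_households),
        level=level,
        response=response,
        sigma_mean=float(sigma_draws.mean()),
    )


def format_count(count: int, total: int) -> str:
    """Render a count with its percentage, e.g. ``23 (7.5%)``."""
    return f"{count} ({100.0 * count / total:.1f}%)"


def household_summary_table(
    results: Mapping[str, HouseholdScreenResult]
) -> pd.DataFrame:
    """One row per model with formatted positive/negative household counts."""
    rows = []
    for model, res in results.items():
        rows.append(
            {
                "model": model,
                "households": res.n_households,
                "positive": format_count(res.counts[POSITIVE], res.n_households),
                "negative": format_count(res.counts[NEGATIVE], res.n_households),
            }
        )
    return pd.DataFrame(rows)
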
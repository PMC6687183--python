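"""Inferential reporting: credible intervals, significance calls, forest tables.

A coefficient is called significant at credibility level L when its posterior
mass on one side of zero reaches L: positive when P(coef > 0) >= L, negative
when P(coef > 0) <= 1 - L, nonsignificant otherwise.  Interval endpoints are
central empirical quantiles with linear interpolation between order
statistics, so any two implementations agree to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .models import RHAT_THRESHOLD, PosteriorResult

POSITIVE = "positive"
NEGATIVE = "negative"
NONSIGNIFICANT = "nonsignificant"


@dataclass(frozen=True)
class SignificanceCall:
    parameter: str
    site: str
    level: float
    direction: str
    probability_positive: float
    interval: tuple[float, float]


def credible_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Central credible interval: the ((1-L)/2, 1-(1-L)/2) empirical quantiles."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 1:
        raise ValueError("no samples supplied")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [tail, 1.0 - tail])
    return float(lo), float(hi)


def classify_significance(
    samples, level: float = 0.95, parameter: str = "", site: str = ""
) -> SignificanceCall:
    """One-sided credibility call for one parameter's posterior samples.

    Ties at exactly zero count as not-positive, so a point mass at zero is
    never called significant.  Thresholds are closed (>= L / <= 1-L),
    matching "posterior probability at least 95%".
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples to classify")
    p = float(np.mean(samples > 0))
    direction = direction_from_probability(p, level)
    return SignificanceCall(
        parameter=parameter,
        site=site,
        level=level,
        direction=direction,
        probability_positive=p,
        interval=credible_interval(samples, level),
    )


def direction_from_probability(prob_positive: float, level: float = 0.95) -> str:
    if prob_positive >= level:
        return POSITIVE
    if prob_positive <= 1.0 - level:
        return NEGATIVE
    return NONSIGNIFICANT


def forest_table(
    results: Mapping[str, PosteriorResult], level: float = 0.95
) -> pd.DataFrame:
    """Long-format forest-plot table over one or more fitted models.

    One row per parameter: model, site, parameter, posterior mean, interval
    endpoints at ``level``, probability positive, direction, and R-hat.
    Rows are sorted by model, then site, then parameter.
    """
    rows = []
    for model_name, result in results.items():
        for name in result.parameters:
            flat = result.samples(name)
            info = result.param_info[name]
            lo, hi = credible_interval(flat, level)
            p = float(np.mean(flat > 0))
            rows.append(
                {
                    "model": model_name,
                    "site": info.site,
                    "parameter": info.covariate or info.kind,
                    "kind": info.kind,
                    "mean": float(flat.mean()),
                    "low": float(lo),
                    "high": float(hi),
                    "prob_positive": p,
                    "direction": direction_from_probability(p, level),
                    "rhat": float(result.summary.loc[name, "rhat"]),
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["model", "site", "parameter"], kind="stable"
        ).reset_index(drop=True)
    return df


def text_report(results: Mapping[str, PosteriorResult], level: float = 0.95) -> str:
    """Plain-text summary with convergence warnings inlined."""
    lines = []
    for model_name, result in results.items():
        lines.append(f"== {model_name} ==")
        if not result.converged:
            lines.append(
                f"WARNING: max R-hat {result.max_rhat:.4f} exceeds "
                f"{RHAT_THRESHOLD}; treat the estimates below with caution."
            )
        else:
            lines.append(f"converged (max R-hat {result.max_rhat:.4f})")
        table = forest_table({model_name: result}, level)
        sig = table[table["direction"] != NONSIGNIFICANT]
        lines.append(
            f"{len(sig)}/{len(table)} parameters significant at "
            f"{100 * level:.0f}% credibility"
        )
        for _, row in sig.iterrows():
            label = f"{row['parameter']}" + (f" @ {row['site']}" if row["site"] else "")
            lines.append(
                f"  {label}: {row['direction']} "
                f"(mean {row['mean']:+.3f}, {100 * level:.0f}% CI "
                f"[{row['low']:+.3f}, {row['high']:+.3f}])"
            )
        lines.append("")
    return "\n".join(lines)
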
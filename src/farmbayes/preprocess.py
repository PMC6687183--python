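"""Turn raw plot-level survey rows into standardized design matrices.

The survey table has one row per plot-year.  This module handles the
plot-level derived quantities (fertilizer-N rate, SPAD aggregation, striga
encoding) and the pooled-sample standardization that puts every model
variable on a common "beta weight" scale: all sites and both years are
centered and scaled together so regression coefficients are comparable
across sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical survey CSV schema, one row per plot-year.
SURVEY_COLUMNS = [
    "site",
    "household",
    "plot",
    "year",
    "rain_dec_feb",
    "rain_mar",
    "rain_apr_may",
    "poxc",
    "ph",
    "spacing_m",
    "weed_biomass",
    "fertilizer",
    "intercrop",
    "compost",
    "spad",
    "striga_count",
    "striga_farmer",
    "yield_kg_ha",
]

ID_COLUMNS = ["site", "household", "plot", "year"]

#: Nitrogen mass fraction by fertilizer type (urea is 46:0:0 N:P:K,
#: the local compound blend sold as "NPK" is 23:21:0).
N_FRACTION = {"urea": 0.46, "npk": 0.23}


def nitrogen_applied(fertilizer_type: str, amount_kg: float, area_ha: float) -> float:
    """Nitrogen application rate (kg N/ha) for one fertilizer application.

    Parameters
    ----------
    fertilizer_type : {'urea', 'npk'}
        Reported fertilizer product.  Urea carries 46% N by mass; the local
        NPK compound carries 23% N.
    amount_kg : float
        Mass of product applied, kg (>= 0).
    area_ha : float
        Fertilized plot area, hectares (> 0).
    """
    key = str(fertilizer_type).strip().lower()
    if key not in N_FRACTION:
        raise ValueError(
            f"unknown fertilizer type {fertilizer_type!r}; accepted types: "
            + ", ".join(sorted(N_FRACTION))
        )
    if amount_kg < 0:
        raise ValueError(f"amount_kg must be >= 0, got {amount_kg}")
    if area_ha <= 0:
        raise ValueError(f"area_ha must be > 0, got {area_ha}")
    return amount_kg * N_FRACTION[key] / area_ha


def total_nitrogen_rate(
    applications: Iterable[tuple[str, float]], area_ha: float
) -> float:
    """Total kg N/ha over multiple (fertilizer_type, amount_kg) applications."""
    return float(sum(nitrogen_applied(t, a, area_ha) for t, a in applications))


def _flatten(readings) -> list[float]:
    out: list[float] = []
    if isinstance(readings, (str, bytes)):
        raise TypeError("SPAD readings must be numeric, not strings")
    try:
        it = iter(readings)
    except TypeError:
        out.append(float(readings))
        return out
    for item in it:
        out.extend(_flatten(item))
    return out


def aggregate_spad(readings) -> float:
    """Collapse nested SPAD readings to a single plot value (grand mean).

    The field protocol records up to 3 reading replicates per plant, for 4
    plants at each of 8 locations per plot (96 readings); any nesting and any
    amount of missingness short of "no readings at all" is accepted.
    """
    values = _flatten(readings)
    if not values:
        raise ValueError("no SPAD readings supplied")
    return float(np.mean(values))


def encode_striga(observations: Sequence[int]) -> tuple[int, int]:
    """Encode up to 8 binary in-field striga observations.

    Returns ``(striga_count, striga_present)`` where the count is the number
    of positive observations (0-8) and presence is 1 iff the count is >= 1.
    """
    obs = list(observations)
    if len(obs) > 8:
        raise ValueError(f"at most 8 striga observations per plot, got {len(obs)}")
    for o in obs:
        if o not in (0, 1):
            raise ValueError(f"striga observations must be 0/1, got {o!r}")
    count = int(sum(obs))
    return count, int(count >= 1)


@dataclass
class ColumnMeta:
    """Original location/scale of one design column, for back-transformation."""

    name: str
    mean: float
    sd: float
    is_binary: bool


@dataclass
class DesignMatrix:
    """Standardized explanatory matrix plus bookkeeping for one model.

    ``X`` holds the standardized covariates (rows = plot-year records,
    columns ordered as ``columns``); the response ``y`` is standardized with
    its own mean/SD retained so predictions can be mapped back to natural
    units.  ``site_index`` and ``household_index`` carry the grouping labels
    used by site-varying models and the household screen.
    """

    X: np.ndarray
    columns: list[str]
    column_meta: list[ColumnMeta]
    y: np.ndarray
    response: str
    y_mean: float
    y_sd: float
    site_index: np.ndarray
    household_index: np.ndarray
    row_ids: pd.DataFrame
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.columns.index(name)]

    def meta(self, name: str) -> ColumnMeta:
        return self.column_meta[self.columns.index(name)]

    def destandardize_y(self, z: np.ndarray) -> np.ndarray:
        return self.y_mean + self.y_sd * np.asarray(z)

    def with_response(self, y: np.ndarray, response: str,
                      y_mean: float = 0.0, y_sd: float = 1.0) -> "DesignMatrix":
        return replace(self, y=np.asarray(y, dtype=float), response=response,
                       y_mean=y_mean, y_sd=y_sd)

    def subset(self, mask: np.ndarray) -> "DesignMatrix":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            X=self.X[mask],
            y=self.y[mask],
            site_index=self.site_index[mask],
            household_index=self.household_index[mask],
            row_ids=self.row_ids.loc[mask].reset_index(drop=True),
        )


def _is_binary(values: np.ndarray) -> bool:
    return bool(np.isin(np.unique(values), (0.0, 1.0)).all())


def standardize(
    records: pd.DataFrame,
    covariates: Sequence[str],
    response: str,
    standardize_binaries: bool = True,
    standardize_response: bool = True,
) -> DesignMatrix:
    """Build the standardized design matrix for one model.

    All rows (every site, both years pooled) are centered and scaled
    together; the SD uses the n-1 denominator.  Rows with any missing value
    among the used columns are dropped (complete-case) and counted in
    ``n_dropped``.  Binary columns are standardized like continuous ones by
    default (set ``standardize_binaries=False`` to keep them 0/1).
    """
    covariates = list(covariates)
    if len(set(covariates)) != len(covariates):
        raise ValueError("duplicate covariate names")
    missing = [c for c in covariates + [response] if c not in records.columns]
    if missing:
        raise ValueError(f"unknown column(s): {', '.join(missing)}")

    used = covariates + [response]
    keep = records[used].notna().all(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    df = records.loc[keep].reset_index(drop=True)
    if len(df) < 2:
        raise ValueError("need at least 2 complete records to standardize")

    cols = []
    meta = []
    for name in covariates:
        x = df[name].to_numpy(dtype=float)
        binary = _is_binary(x)
        if binary and not standardize_binaries:
            cols.append(x)
            meta.append(ColumnMeta(name, 0.0, 1.0, True))
            continue
        m = float(np.mean(x))
        s = float(np.std(x, ddof=1))
        if s == 0.0:
            raise ValueError(f"column {name!r} is constant; cannot standardize")
        cols.append((x - m) / s)
        meta.append(ColumnMeta(name, m, s, binary))

    yraw = df[response].to_numpy(dtype=float)
    if standardize_response:
        y_mean = float(np.mean(yraw))
        y_sd = float(np.std(yraw, ddof=1))
        if y_sd == 0.0:
            raise ValueError(f"response {response!r} is constant; cannot standardize")
        y = (yraw - y_mean) / y_sd
    else:
        y_mean, y_sd = 0.0, 1.0
        y = yraw

    id_cols = [c for c in ID_COLUMNS if c in df.columns]
    row_ids = df[id_cols].copy() if id_cols else pd.DataFrame(index=df.index)
    site = df["site"].to_numpy() if "site" in df.columns else np.array([""] * len(df))
    household = (
        df["household"].to_numpy()
        if "household" in df.columns
        else np.array([""] * len(df))
    )

    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return DesignMatrix(
        X=X,
        columns=covariates,
        column_meta=meta,
        y=y,
        response=response,
        y_mean=y_mean,
        y_sd=y_sd,
        site_index=site,
        household_index=household,
        row_ids=row_ids,
        n_dropped=n_dropped,
    )


def read_survey_csv(path) -> pd.DataFrame:
    """Read a survey table, checking the canonical schema."""
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey CSV missing column(s): {', '.join(missing)}")
    return df[SURVEY_COLUMNS]


def write_survey_csv(records: pd.DataFrame, path) -> None:
    records[SURVEY_COLUMNS].to_csv(path, index=False)
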
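"""Model-vs-observation evaluation statistics.

Implements the symmetric normalized factor metrics widely used for
air-quality model evaluation (Yu et al. 2006):

    NMBF  =  Mbar/Obar - 1        if Mbar >= Obar
             1 - Obar/Mbar        otherwise

    NMAEF =  sum|M_i - O_i| / (n * Obar)   if Mbar >= Obar
             sum|M_i - O_i| / (n * Mbar)   otherwise

Both are scale-invariant; NMBF is antisymmetric under swapping model
and observations, and NMAEF >= |NMBF| always. Pearson r is computed on
daily pairs with missing observations dropped pairwise. Stations are
matched to their nearest grid-cell centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import DomainGrid
from .seasons import month_of


def _paired(modeled, observed) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(modeled, dtype=float)
    o = np.asarray(observed, dtype=float)
    if m.shape != o.shape or m.ndim != 1:
        raise ValueError("modeled and observed must be equal-length 1-D series")
    keep = ~(np.isnan(m) | np.isnan(o))
    m, o = m[keep], o[keep]
    if len(m) == 0:
        raise ValueError("no valid pairs")
    return m, o


def nmbf(modeled, observed) -> float:
    """Normalized mean bias factor (symmetric two-branch form)."""
    m, o = _paired(modeled, observed)
    mbar, obar = m.mean(), o.mean()
    if mbar <= 0 or obar <= 0:
        raise ValueError("NMBF requires positive means")
    return float(mbar / obar - 1.0 if mbar >= obar else 1.0 - obar / mbar)


def nmaef(modeled, observed) -> float:
    """Normalized mean absolute error factor (same branch rule as NMBF)."""
    m, o = _paired(modeled, observed)
    mbar, obar = m.mean(), o.mean()
    if mbar <= 0 or obar <= 0:
        raise ValueError("NMAEF requires positive means")
    denom = len(m) * (obar if mbar >= obar else mbar)
    return float(np.abs(m - o).sum() / denom)


def pearson_r(modeled, observed) -> float:
    """Pearson correlation on valid pairs; NaN when degenerate."""
    m, o = _paired(modeled, observed)
    if len(m) < 2 or m.std() == 0 or o.std() == 0:
        return float("nan")
    return float(np.corrcoef(m, o)[0, 1])


def match_stations(stations: pd.DataFrame, grid: DomainGrid) -> pd.DataFrame:
    """Attach nearest-neighbour grid indices to a station table.

    ``stations`` needs columns (station_id, x, y) in the grid's projected
    km coordinates. Stations outside the domain are dropped with a
    warning column rather than an error. Distance ties break to the
    lower row index, then the lower column index.
    """
    xx, yy = grid.cell_centers()
    rows = []
    for s in stations.drop_duplicates("station_id").itertuples():
        if not grid.contains(s.x, s.y):
            continue
        d2 = (xx - s.x) ** 2 + (yy - s.y) ** 2
        # argmin on C-ordered flat array gives lowest row then col on ties
        flat = int(np.argmin(d2.ravel()))
        rows.append((s.station_id, s.x, s.y, flat // grid.n_cols, flat % grid.n_cols))
    return pd.DataFrame(rows, columns=["station_id", "x", "y", "row", "col"])


@dataclass
class EvalStats:
    """Per-station and pooled evaluation statistics."""

    per_station: pd.DataFrame  # station_id, n, r, nmbf, nmaef
    pooled: dict  # equal-weight station means + all-pairs pooled stats


def evaluate(
    observations: pd.DataFrame,
    modeled: "xr.DataArray",
    grid: DomainGrid,
    months=None,
) -> EvalStats:
    """Compare modeled daily fields with station observations.

    ``observations`` columns: station_id, day, pm25, x, y. ``modeled``
    dims (day, row, col). ``months`` optionally restricts to a month
    subset (e.g. (6, 7, 8) for summer). Station-level statistics are
    averaged with equal weights; an all-pairs pooled row is included.
    """
    obs = observations.copy()
    if months is not None:
        if not len(months):
            raise ValueError("month subset is empty")
        obs = obs[np.isin(month_of(obs["day"].to_numpy()), list(months))]
        if obs.empty:
            raise ValueError("no observations in the requested months")
    matched = match_stations(obs[["station_id", "x", "y"]].drop_duplicates(), grid)
    day_index = {int(d): i for i, d in enumerate(np.asarray(modeled["day"].values))}
    per = []
    all_m, all_o = [], []
    for st in matched.itertuples():
        sub = obs[obs["station_id"] == st.station_id]
        days = sub["day"].to_numpy()
        keep = np.isin(days, list(day_index))
        sub = sub[keep]
        if sub.empty:
            continue
        m = np.array(
            [modeled.values[day_index[int(d)], st.row, st.col] for d in sub["day"]]
        )
        o = sub["pm25"].to_numpy(dtype=float)
        all_m.append(m)
        all_o.append(o)
        per.append(
            {
                "station_id": st.station_id,
                "n": len(o),
                "r": pearson_r(m, o),
                "nmbf": nmbf(m, o),
                "nmaef": nmaef(m, o),
            }
        )
    per_df = pd.DataFrame(per, columns=["station_id", "n", "r", "nmbf", "nmaef"])
    pooled: dict = {"n_stations": len(per_df)}
    if len(per_df):
        pooled.update(
            mean_r=float(per_df["r"].mean(skipna=True)),
            mean_nmbf=float(per_df["nmbf"].mean()),
            mean_nmaef=float(per_df["nmaef"].mean()),
        )
        m_all = np.concatenate(all_m)
        o_all = np.concatenate(all_o)
        pooled.update(
            pooled_r=pearson_r(m_all, o_all),
            pooled_nmbf=nmbf(m_all, o_all),
            pooled_nmaef=nmaef(m_all, o_all),
        )
    return EvalStats(per_station=per_df, pooled=pooled)


def seasonal_subset(observations, modeled, grid, months) -> EvalStats:
    """Evaluation restricted to the given months (e.g. Jun-Aug)."""
    return evaluate(observations, modeled, grid, months=months)
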
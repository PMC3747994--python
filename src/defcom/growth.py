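"""OD600 growth-curve summaries and cross-substrate ranking.

The summary statistics are deliberately extrema-based rather than
model-fit-based: total growth A_tot = A_max − A_min, and rate =
A_tot / (t_max − t_min) where t_max / t_min are the times at which the
extrema were observed (earliest occurrence on ties). This matches plate-
reader screening practice for anaerobe carbohydrate panels, where curves
are often too irregular for reliable logistic fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthSummary",
    "summarize_curve",
    "growth_call",
    "summarize_table",
    "aggregate_replicates",
    "rank_species",
    "GROWTH_THRESHOLD_OD",
]

GROWTH_THRESHOLD_OD = 0.1


@dataclass
class GrowthSummary:
    a_max: float
    a_min: float
    t_max: float
    t_min: float
    a_tot: float
    rate: float  # OD / h
    rate_defined: bool
    grew: Optional[bool] = None


def summarize_curve(
    times: Sequence[float],
    od: Sequence[float],
    smoothing_window: int = 0,
) -> GrowthSummary:
    """Extrema-based summary of one growth curve.

    Optional centered moving-average smoothing (``smoothing_window``
    points, default off) is applied before locating extrema. A_min and
    A_max are taken at the earliest time attaining each extremum; rate is
    A_tot / (t_max − t_min), reported as 0 with ``rate_defined=False``
    when the two coincide.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 time-points")
    if (np.diff(t) <= 0).any():
        raise ValueError("times must be strictly increasing")
    if smoothing_window and smoothing_window > 1:
        w = min(smoothing_window, t.size)
        kernel = np.ones(w) / w
        y = np.convolve(np.pad(y, w // 2, mode="edge"), kernel, mode="valid")[: t.size]
    i_min = int(np.argmin(y))  # argmin/argmax return the first occurrence
    i_max = int(np.argmax(y))
    a_min, a_max = float(y[i_min]), float(y[i_max])
    t_min, t_max = float(t[i_min]), float(t[i_max])
    a_tot = a_max - a_min
    if t_max == t_min:
        return GrowthSummary(a_max, a_min, t_max, t_min, a_tot, 0.0, False)
    return GrowthSummary(
        a_max, a_min, t_max, t_min, a_tot, a_tot / (t_max - t_min), True
    )


def growth_call(summary: GrowthSummary, threshold_od: float = GROWTH_THRESHOLD_OD) -> bool:
    """Grew ⇔ total growth A_tot ≥ threshold (default 0.1 OD)."""
    return summary.a_tot >= threshold_od


def summarize_table(
    curves: pd.DataFrame,
    smoothing_window: int = 0,
    threshold_od: float = GROWTH_THRESHOLD_OD,
) -> pd.DataFrame:
    """Summaries for every (species, substrate, replicate) in a long table.

    ``curves`` columns: species, substrate, replicate, time_h, od600.
    """
    required = {"species", "substrate", "replicate", "time_h", "od600"}
    missing = required - set(curves.columns)
    if missing:
        raise ValueError(f"curves lack columns: {sorted(missing)}")
    rows = []
    for (species, substrate, rep), sub in curves.groupby(
        ["species", "substrate", "replicate"], sort=True
    ):
        sub = sub.sort_values("time_h")
        s = summarize_curve(sub["time_h"], sub["od600"], smoothing_window)
        s.grew = growth_call(s, threshold_od)
        rows.append(
            {
                "species": species,
                "substrate": substrate,
                "replicate": rep,
                "a_max": s.a_max,
                "a_min": s.a_min,
                "t_max": s.t_max,
                "t_min": s.t_min,
                "a_tot": s.a_tot,
                "rate": s.rate,
                "grew": s.grew,
            }
        )
    return pd.DataFrame(rows)


def aggregate_replicates(summaries: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sample SD of A_tot and rate per (species, substrate).

    SD uses n−1; with a single replicate the mean is reported and the SD
    is missing.
    """
    agg = summaries.groupby(["species", "substrate"]).agg(
        n=("a_tot", "size"),
        a_tot_mean=("a_tot", "mean"),
        a_tot_sd=("a_tot", lambda x: x.std(ddof=1) if len(x) > 1 else np.nan),
        rate_mean=("rate", "mean"),
        rate_sd=("rate", lambda x: x.std(ddof=1) if len(x) > 1 else np.nan),
        grew=("grew", "any"),
    )
    return agg.reset_index()


def rank_species(aggregates: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Fastest grower per substrate and per-species win tallies.

    Only substrates where at least one species grew have a winner; exact
    ties in mean rate are reported jointly (all tied species listed) and
    each tied species' tally is incremented. Ranking does not depend on
    row order.
    """
    winners = []
    tallies: dict[str, int] = {}
    for substrate, sub in aggregates.groupby("substrate"):
        grew = sub[sub["grew"]]
        if grew.empty:
            winners.append({"substrate": substrate, "winners": (), "rate_mean": np.nan})
            continue
        best = grew["rate_mean"].max()
        tied = sorted(grew.loc[grew["rate_mean"] == best, "species"])
        winners.append(
            {"substrate": substrate, "winners": tuple(tied), "rate_mean": best}
        )
        for s in tied:
            tallies[s] = tallies.get(s, 0) + 1
    tally = pd.Series(tallies, dtype=int).sort_values(ascending=False)
    tally.name = "n_substrates_fastest"
    return pd.DataFrame(winners), tally
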
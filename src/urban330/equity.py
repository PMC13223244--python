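"""Income-greenness equity analysis.

Cross-resolution averaging of the 0-3 compliance score onto an income
grid (the "Green Space Category": mean score of the 100 m cells inside
each income cell), per-category income box summaries on a log scale,
seeded permutation Spearman rank correlations, and the bivariate
quartile classification of per-city covariates (per-capita GDP x
aridity, 16 classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridLayer

__all__ = [
    "GreenSpaceCategoryRecord",
    "BivariateClass",
    "green_space_category",
    "records_to_frame",
    "income_by_category",
    "rank_correlation",
    "bivariate_quantile_classes",
]


@dataclass
class GreenSpaceCategoryRecord:
    """Mean compliance score and income for one income-grid cell."""

    cell_id: int
    row: int
    col: int
    mean_score: float
    income: float
    n_cells_averaged: int


def green_space_category(score: GridLayer, income: GridLayer) -> list[GreenSpaceCategoryRecord]:
    """Average the 0-3 score over each income cell (nested grids only).

    Income cells with no valid score coverage, or that are themselves
    nodata, are omitted. The mean is invariant to any permutation of the
    score cells within one income cell.
    """
    ratio = income.cell_size / score.cell_size
    f = round(ratio)
    if abs(ratio - f) > 1e-9 or f < 1:
        raise ValueError("income grid must nest the score grid (integer cell ratio)")
    if (
        abs(score.origin_x - income.origin_x) > 1e-6
        or abs(score.origin_y - income.origin_y) > 1e-6
    ):
        raise ValueError("income grid must share the score grid origin")
    nr, nc = score.values.shape
    nir, nic = income.values.shape
    vals = np.zeros((nir * f, nic * f))
    ok = np.zeros((nir * f, nic * f), dtype=bool)
    vals[:nr, :nc] = np.where(score.nodata_mask, 0.0, score.values)
    ok[:nr, :nc] = ~score.nodata_mask
    tot = vals.reshape(nir, f, nic, f).sum(axis=(1, 3))
    n = ok.reshape(nir, f, nic, f).sum(axis=(1, 3))
    records = []
    for i in range(nir):
        for j in range(nic):
            if n[i, j] == 0 or income.nodata_mask[i, j]:
                continue
            records.append(
                GreenSpaceCategoryRecord(
                    cell_id=i * nic + j,
                    row=i,
                    col=j,
                    mean_score=float(tot[i, j] / n[i, j]),
                    income=float(income.values[i, j]),
                    n_cells_averaged=int(n[i, j]),
                )
            )
    return records


def records_to_frame(records: list[GreenSpaceCategoryRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "income_cell_id": [r.cell_id for r in records],
            "mean_score": [r.mean_score for r in records],
            "n_cells": [r.n_cells_averaged for r in records],
            "income": [r.income for r in records],
        }
    )
    df["log10_income"] = np.log10(df["income"])
    return df


def income_by_category(records: list[GreenSpaceCategoryRecord]) -> dict[int, dict]:
    """Box-plot summaries of income per rounded compliance category.

    Categories are the mean score rounded half-up to 0..3 (the
    continuous mean stays available on the records). Each populated
    category reports the median, quartiles and 1.5 x IQR whiskers of
    income plus the log10 incomes; empty categories report n = 0.
    """
    if not records:
        raise ValueError("no records")
    out: dict[int, dict] = {}
    cats = np.floor(np.array([r.mean_score for r in records]) + 0.5).astype(int)
    incomes = np.array([r.income for r in records])
    for k in range(4):
        vals = incomes[cats == k]
        if vals.size == 0:
            out[k] = {"n": 0}
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo = vals[vals >= q1 - 1.5 * iqr].min()
        hi = vals[vals <= q3 + 1.5 * iqr].max()
        out[k] = {
            "n": int(vals.size),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(lo),
            "whisker_high": float(hi),
            "log10_income": np.log10(vals),
        }
    return out


def rank_correlation(x, y, n_permutations: int = 9999, seed: int = 0) -> tuple[float, float]:
    """Spearman rho with a seeded permutation p-value (two-sided).

    The permutation null avoids large-sample approximations at small n.
    Constant input leaves the rank correlation undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be 1-D, equal length, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = x.size
    rho = float(np.dot(rx, ry) / n)
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_permutations, 2_000_000 // n))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perm = rng.permuted(np.broadcast_to(ry, (m, n)).copy(), axis=1)
        rho_perm = perm @ rx / n
        count += int((np.abs(rho_perm) >= abs(rho) - 1e-12).sum())
        done += m
    p = (count + 1) / (n_permutations + 1)
    return rho, float(p)


@dataclass
class BivariateClass:
    """One of the 16 (GDPc quartile x aridity quartile) city classes."""

    gdpc_quartile: int
    aridity_quartile: int
    city_ids: list = field(default_factory=list)
    full_rule_shares: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.city_ids)

    @property
    def median_full_rule_share(self) -> float:
        return float(np.median(self.full_rule_shares)) if self.full_rule_shares else float("nan")


def _quartile(values: np.ndarray) -> np.ndarray:
    """Quartile index 1..4 per value; ties on a break go to the lower quartile."""
    breaks = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    return np.searchsorted(breaks, values, side="left") + 1


def bivariate_quantile_classes(
    gdpc, aridity, full_rule_share=None, city_ids=None
) -> list[BivariateClass]:
    """Partition cities into 16 quartile classes of (GDPc, aridity).

    Aridity-index direction (arid vs. humid at the high end) is a
    property of the input values; labels follow the caller's convention.
    """
    gdpc = np.asarray(gdpc, dtype=float)
    aridity = np.asarray(aridity, dtype=float)
    if gdpc.size < 4 or aridity.size != gdpc.size:
        raise ValueError("need >= 4 cities with both covariates")
    if np.ptp(gdpc) == 0 or np.ptp(aridity) == 0:
        raise ValueError("quartiles undefined for an all-equal covariate")
    n = gdpc.size
    if city_ids is None:
        city_ids = list(range(n))
    if full_rule_share is None:
        full_rule_share = [float("nan")] * n
    qg = _quartile(gdpc)
    qa = _quartile(aridity)
    classes = {
        (i, j): BivariateClass(gdpc_quartile=i, aridity_quartile=j)
        for i in range(1, 5)
        for j in range(1, 5)
    }
    for k in range(n):
        c = classes[(int(qg[k]), int(qa[k]))]
        c.city_ids.append(city_ids[k])
        c.full_rule_shares.append(float(full_rule_share[k]))
    return [classes[(i, j)] for i in range(1, 5) for j in range(1, 5)]
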
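"""Group-level statistics over channel-pair × frequency-band (ch-ch-fr) cells.

Each cell carries one mean-WTC value per dyad per condition (cooperative
vs independent play).  Cells are contrasted with a two-tailed t-test
(paired across dyads by default), the resulting p-value family is
corrected with Storey's positive-FDR q-values, and one representative
band per channel pair — the band with the smallest p — summarizes the
family, since adjacent bands of a geometric grid are highly correlated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

__all__ = [
    "ContrastResult",
    "QValueResult",
    "condition_contrast",
    "storey_fdr",
    "select_representative",
    "glm_candidates",
    "cells_frame",
]

MIN_DYADS = 3


@dataclass
class ContrastResult:
    """Per-cell t, p and dyad count; ``tested`` is False below the dyad minimum."""

    t: np.ndarray
    p: np.ndarray
    n_dyads: np.ndarray
    tested: np.ndarray


@dataclass
class QValueResult:
    """Storey q-values with the π₀ (null-proportion) estimate used."""

    pi0: float
    lam: float
    q: np.ndarray


def condition_contrast(coop: np.ndarray, ind: np.ndarray, paired: bool = True) -> ContrastResult:
    """Two-tailed t contrast of per-dyad cell means between conditions.

    ``coop`` and ``ind`` are (n_dyads, n_cells); NaN marks a missing dyad
    for a cell, and a dyad missing either condition is dropped from that
    cell only.  Cells with fewer than three complete dyads are flagged
    untested (t and p stay NaN).  When every available difference is zero
    the cell is a perfect null: t = 0, p = 1.
    """
    coop = np.atleast_2d(np.asarray(coop, dtype=float))
    ind = np.atleast_2d(np.asarray(ind, dtype=float))
    if coop.shape != ind.shape:
        raise ParameterError(f"shape mismatch: {coop.shape} vs {ind.shape}")
    ok = np.isfinite(coop) & np.isfinite(ind)
    n_cells = coop.shape[1]
    t = np.full(n_cells, np.nan)
    p = np.full(n_cells, np.nan)
    n_dyads = ok.sum(axis=0)
    tested = n_dyads >= MIN_DYADS

    if paired:
        d = np.where(ok, coop - ind, np.nan)
        n = n_dyads.astype(float)
        with np.errstate(invalid="ignore"):
            mean_d = np.nansum(d, axis=0) / np.maximum(n, 1)
            ss = np.nansum((d - mean_d) ** 2, axis=0)
            sd = np.sqrt(ss / np.maximum(n - 1, 1))
            se = sd / np.sqrt(np.maximum(n, 1))
        for c in np.flatnonzero(tested):
            if se[c] == 0.0:
                # all differences identical; identically zero is the exact null
                if mean_d[c] == 0.0:
                    t[c], p[c] = 0.0, 1.0
                else:
                    t[c], p[c] = np.inf * np.sign(mean_d[c]), 0.0
            else:
                t[c] = mean_d[c] / se[c]
                p[c] = 2.0 * stats.t.sf(abs(t[c]), df=n[c] - 1)
    else:
        for c in np.flatnonzero(tested):
            a = coop[ok[:, c], c]
            b = ind[ok[:, c], c]
            if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
                t[c], p[c] = 0.0, 1.0
            else:
                res = stats.ttest_ind(a, b)
                t[c], p[c] = float(res.statistic), float(res.pvalue)
    return ContrastResult(t=t, p=p, n_dyads=n_dyads, tested=tested)


def storey_fdr(p_values: np.ndarray, lam: float = 0.5) -> QValueResult:
    """Storey's positive-FDR q-values.

    π₀ is estimated from the p-value tail beyond λ:
    ``π₀ = #{p > λ} / (m·(1−λ))`` clipped to (0, 1]; q-values follow the
    step-up rule ``q(p_(i)) = min_{j ≥ i} π₀·m·p_(j)/j`` over the sorted
    family.  Significance is conventionally declared at Q < 0.05.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ParameterError("empty p-value family")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    if not 0 <= lam < 1:
        raise ParameterError(f"lambda must lie in [0, 1), got {lam}")
    m = p.size
    pi0 = (p > lam).sum() / (m * (1.0 - lam))
    pi0 = min(max(pi0, 1.0 / m), 1.0)  # clipped to (0, 1]
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate((pi0 * m * p_sorted / ranks)[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(pi0=float(pi0), lam=float(lam), q=q)


def cells_frame(pairs, grid, coop_means: np.ndarray, ind_means: np.ndarray,
                paired: bool = True, lam: float = 0.5) -> pd.DataFrame:
    """Assemble the full ch-ch-fr result table for one family.

    ``coop_means``/``ind_means`` are (n_dyads, n_pairs, n_bands) stacks of
    per-dyad band means; rows of the returned frame carry t, p, q and the
    contrast direction per cell.  Untested cells (too few dyads) are kept
    but excluded from the FDR family.
    """
    n_dyads, n_pairs, n_bands = coop_means.shape
    coop_flat = coop_means.reshape(n_dyads, n_pairs * n_bands)
    ind_flat = ind_means.reshape(n_dyads, n_pairs * n_bands)
    res = condition_contrast(coop_flat, ind_flat, paired=paired)
    df = pd.DataFrame(
        {
            "ch_a": np.repeat([p[0] for p in pairs], n_bands),
            "ch_b": np.repeat([p[1] for p in pairs], n_bands),
            "band_index": np.tile(np.arange(n_bands), n_pairs),
            "freq_hz": np.tile(grid.frequencies, n_pairs),
            "n_dyads": res.n_dyads,
            "t": res.t,
            "p": res.p,
            "tested": res.tested,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # fully masked bands
        df["mean_coop"] = np.nanmean(
            np.where(np.isfinite(ind_flat), coop_flat, np.nan), axis=0)
        df["mean_ind"] = np.nanmean(
            np.where(np.isfinite(coop_flat), ind_flat, np.nan), axis=0)
    df["direction"] = np.where(df["t"] >= 0, "COOP>IND", "COOP<IND")
    df["q"] = np.nan
    tested_idx = df.index[df["tested"]]
    if len(tested_idx):
        df.loc[tested_idx, "q"] = storey_fdr(df.loc[tested_idx, "p"].to_numpy()).q
    return df


def select_representative(cells: pd.DataFrame, f_window: tuple | None = None) -> pd.DataFrame:
    """One representative band per channel pair: the band with the smallest
    p-value (ties broken toward the lower band index).  ``f_window``
    optionally restricts the search to a frequency range in Hz.  Pairs with
    no tested band in scope are excluded."""
    df = cells[cells["tested"]].copy()
    if f_window is not None:
        lo, hi = f_window
        df = df[(df["freq_hz"] >= lo) & (df["freq_hz"] <= hi)]
    df = df[np.isfinite(df["p"])]
    if df.empty:
        return df
    df = df.sort_values(["ch_a", "ch_b", "p", "band_index"], kind="stable")
    return df.groupby(["ch_a", "ch_b"], as_index=False).first()


def glm_candidates(cells: pd.DataFrame, p_threshold: float = 1e-3,
                   f_window: tuple = (0.03, 0.1),
                   direction: str = "COOP>IND") -> pd.DataFrame:
    """Cells eligible for the event-related GLM stage.

    Keeps cells with the stated direction, p below threshold, and band
    frequency inside the window, then reduces to one representative band
    per channel pair (smallest p) because adjacent bands are highly
    correlated.  An empty result is a valid outcome.
    """
    lo, hi = f_window
    mask = (
        cells["tested"]
        & np.isfinite(cells["p"])
        & (cells["p"] < p_threshold)
        & (cells["direction"] == direction)
        & (cells["freq_hz"] >= lo)
        & (cells["freq_hz"] <= hi)
    )
    eligible = cells[mask]
    if eligible.empty:
        return eligible
    return select_representative(eligible.assign(tested=True))
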
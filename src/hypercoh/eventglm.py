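"""Event-related GLM linking coherence time courses to social behavior.

For each candidate channel pair (selected at the group stage) the WTC
time course at the representative band is regressed, per dyad, on the
down-sampled behavioral tracks with a gamma error distribution and log
link — coherence is positive and right-skewed, so a gamma GLM is the
natural error model.  Per-dyad coefficients for ``both_up`` and
``either_up`` (the self/other merge) are then compared across dyads with
paired t-tests under Bonferroni correction over the number of candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ParameterError

__all__ = [
    "GlmResult",
    "GroupContrast",
    "fit_wtc_glm",
    "either_up_beta",
    "contrast_both_vs_either",
    "event_locked_wtc",
]

Y_CLIP = 1e-6


@dataclass
class GlmResult:
    """Per-dyad gamma/log-link fit of one WTC series on one design."""

    dyad_id: str
    pair: tuple
    band_index: int
    beta: dict
    deviance: float
    iterations: int
    converged: bool
    n_clipped: int = 0
    dropped_regressors: tuple = ()


@dataclass
class GroupContrast:
    """Group-level both-up vs either-up comparison for one candidate cell."""

    pair: tuple
    band_index: int
    n_dyads: int
    mean_beta_both: float
    mean_beta_either: float
    t: float
    p: float
    n_candidates: int
    significant_bonferroni: bool

    @property
    def alpha_per_test(self) -> float:
        return 0.05 / self.n_candidates


def fit_wtc_glm(y: np.ndarray, x: pd.DataFrame, dyad_id: str = "",
                pair: tuple = (0, 0), band_index: int = -1,
                max_iter: int = 200) -> GlmResult:
    """Fit the gamma/log-link GLM Y = exp(Xβ)·ε by IRLS.

    ``y`` is a strictly positive coherence series (values at or below zero
    are clipped to ``1e-6`` and counted); ``x`` must contain a ``const``
    column and at least one non-constant event regressor.  All-zero
    regressors are dropped from the fit and their β reported as missing
    (NaN).  Non-converged fits are flagged so the group stage can exclude
    them.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != len(x):
        raise ParameterError(f"response length {y.size} != design length {len(x)}")
    if "const" not in x.columns:
        raise ParameterError("design matrix must include a 'const' column")
    event_cols = [c for c in x.columns if c != "const"]
    if not event_cols:
        raise ParameterError("design matrix has no event regressor")
    n_clipped = int((y < Y_CLIP).sum())
    y = np.clip(y, Y_CLIP, None)
    # coherence occasionally rounds to exactly 1; nudge only those samples
    # (legitimate responses above 1 from other sources are left alone)
    near_one = (y >= 1.0) & (y <= 1.0 + 1e-6)
    y = np.where(near_one, 1.0 - 1e-9, y)

    dropped = tuple(c for c in event_cols if not np.any(x[c].to_numpy() != 0))
    kept = [c for c in x.columns if c not in dropped]
    if len(kept) < 2:
        raise ParameterError("no non-zero event regressor in the design")
    if np.ptp(y) == 0.0:
        # perfect-fit degenerate case: mu == y everywhere with zero event betas
        beta = {c: 0.0 for c in x.columns}
        beta["const"] = float(np.log(y[0]))
        for c in dropped:
            beta[c] = np.nan
        return GlmResult(dyad_id=dyad_id, pair=pair, band_index=band_index,
                         beta=beta, deviance=0.0, iterations=0, converged=True,
                         n_clipped=n_clipped, dropped_regressors=dropped)
    model = sm.GLM(y, x[kept], family=sm.families.Gamma(link=sm.families.links.Log()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(maxiter=max_iter)
    converged = bool(getattr(fit, "converged", True))
    beta = {c: float(fit.params[c]) for c in kept}
    for c in dropped:
        beta[c] = np.nan
    return GlmResult(
        dyad_id=dyad_id, pair=pair, band_index=band_index, beta=beta,
        deviance=float(fit.deviance),
        iterations=int(getattr(fit, "fit_history", {}).get("iteration", 0) or 0),
        converged=converged, n_clipped=n_clipped, dropped_regressors=dropped,
    )


def either_up_beta(beta_self: float, beta_other: float) -> float:
    """Merge self-up and other-up coefficients into one either-up value.

    Self-up of one participant is other-up of the partner, so the two
    coefficients estimate the same dyad-level event type; their mean is
    taken, and a missing component (dyad had no events of that type)
    propagates as the other one alone.  Both missing → NaN (dyad excluded
    downstream).
    """
    vals = [b for b in (beta_self, beta_other) if np.isfinite(b)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def contrast_both_vs_either(beta_both: np.ndarray, beta_either: np.ndarray,
                            n_candidates: int, pair: tuple = (0, 0),
                            band_index: int = -1,
                            min_dyads: int = 3) -> GroupContrast:
    """Paired two-tailed t-test of β_both − β_either across dyads.

    Dyads missing either coefficient are dropped pairwise.  Significance
    is Bonferroni-corrected over the ``n_candidates`` cells tested
    (α = 0.05 / n_candidates).
    """
    if n_candidates < 1:
        raise ParameterError("n_candidates must be >= 1")
    beta_both = np.asarray(beta_both, dtype=float)
    beta_either = np.asarray(beta_either, dtype=float)
    ok = np.isfinite(beta_both) & np.isfinite(beta_either)
    n = int(ok.sum())
    if n < min_dyads:
        return GroupContrast(pair=pair, band_index=band_index, n_dyads=n,
                             mean_beta_both=np.nan, mean_beta_either=np.nan,
                             t=np.nan, p=np.nan, n_candidates=n_candidates,
                             significant_bonferroni=False)
    d = beta_both[ok] - beta_either[ok]
    if np.allclose(d, 0.0):
        t_stat, p_val = 0.0, 1.0
    else:
        res = stats.ttest_rel(beta_both[ok], beta_either[ok])
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return GroupContrast(
        pair=pair, band_index=band_index, n_dyads=n,
        mean_beta_both=float(beta_both[ok].mean()),
        mean_beta_either=float(beta_either[ok].mean()),
        t=t_stat, p=p_val, n_candidates=n_candidates,
        significant_bonferroni=bool(np.isfinite(p_val) and p_val < 0.05 / n_candidates),
    )


def event_locked_wtc(wtc_series: np.ndarray, fs: float, event_times_s,
                     window_s: tuple = (-20.0, 20.0),
                     baseline: float | None = None):
    """Average WTC segments time-locked to event onsets (or offsets).

    Each event time becomes the "0" point; segments extending beyond the
    series are excluded (their count is reported).  ``baseline`` — by
    convention the grand-mean WTC over all channel combinations at the
    band — is only carried through for plotting.

    Returns ``(lags_s, mean_curve, n_used, n_excluded)``.
    """
    wtc_series = np.asarray(wtc_series, dtype=float).ravel()
    event_times_s = np.asarray(list(event_times_s), dtype=float)
    if event_times_s.size == 0:
        raise ParameterError("no events to lock to")
    lo, hi = window_s
    if hi <= lo:
        raise ParameterError(f"empty window {window_s}")
    i_lo = int(round(lo * fs))
    i_hi = int(round(hi * fs))
    lags = np.arange(i_lo, i_hi + 1) / fs
    segments = []
    n_excluded = 0
    for t0 in event_times_s:
        c = int(round(t0 * fs))
        if c + i_lo < 0 or c + i_hi >= wtc_series.size:
            n_excluded += 1
            continue
        segments.append(wtc_series[c + i_lo : c + i_hi + 1])
    if not segments:
        raise ParameterError(
            f"all {event_times_s.size} events have truncated windows"
        )
    mean_curve = np.mean(segments, axis=0)
    return lags, mean_curve, len(segments), n_excluded
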
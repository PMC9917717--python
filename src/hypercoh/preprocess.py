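"""Signal conditioning ahead of coherence analysis.

Three stages, applied in order:

1. :func:`mbll` — the modified Beer–Lambert law, converting optical-density
   changes at 695 and 830 nm into oxy-/deoxy-hemoglobin concentration
   changes by inverting a 2×2 extinction system per sample.
2. :func:`hdms` — hemodynamic modality separation: the oxy/deoxy pair is
   decomposed into a *functional* component (deoxy negatively proportional
   to oxy, reflecting oxygen metabolism in cortex) and a *systemic*
   component (positively proportional, reflecting skin blood flow and other
   superficial physiology, including motion-coupled signals).  Only the
   functional component feeds synchrony analysis.
3. :func:`prewhiten` — an autoregressive pre-whitening filter (order 50,
   i.e. 5 s of history at 10 Hz) removing serial correlation, which also
   statistically suppresses shared motion artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.regression.linear_model import yule_walker

from .errors import ParameterError
from .io import HbSeries

__all__ = [
    "MbllParams",
    "HdmsParams",
    "mbll",
    "mbll_forward",
    "od_from_intensity",
    "hdms",
    "prewhiten",
    "preprocess_series",
]

# Molar extinction coefficients (mM^-1 cm^-1) for HbO2 / HHb at the two
# instrument wavelengths, from the standard compiled absorption spectra.
_DEFAULT_EXTINCTION = {
    695.0: {"HbO": 0.2756, "HbR": 1.9105},
    830.0: {"HbO": 0.9740, "HbR": 0.6931},
}


@dataclass
class MbllParams:
    """Parameters of the modified Beer–Lambert inversion.

    With ``dpf = 1`` (the continuous-wave topography convention) the output
    is in relative units of mM·mm; set the true differential pathlength
    factors to obtain absolute concentration changes.
    """

    extinction: dict = field(default_factory=lambda: {
        wl: dict(co) for wl, co in _DEFAULT_EXTINCTION.items()
    })
    dpf: dict = field(default_factory=lambda: {695.0: 1.0, 830.0: 1.0})
    distance_mm: float = 30.0
    wavelengths: tuple = (695.0, 830.0)

    def matrix(self) -> np.ndarray:
        """Per-wavelength sensitivity matrix A with ΔOD = A @ (ΔHbO, ΔHbR).

        Row λ: [ε_HbO(λ)·d·DPF(λ), ε_HbR(λ)·d·DPF(λ)], distance in cm so
        units come out as mM·mm when DPF = 1.
        """
        d_cm = self.distance_mm / 10.0
        rows = []
        for wl in self.wavelengths:
            if wl not in self.extinction:
                raise ParameterError(f"no extinction coefficients for {wl} nm")
            eps = self.extinction[wl]
            scale = d_cm * self.dpf.get(wl, 1.0)
            rows.append([eps["HbO"] * scale, eps["HbR"] * scale])
        a = np.asarray(rows, dtype=float)
        cond = np.linalg.cond(a)
        if not np.isfinite(cond) or cond > 1e6:
            raise ParameterError(
                f"extinction matrix is singular or ill-conditioned (cond={cond:.3g})"
            )
        return a


@dataclass
class HdmsParams:
    """Deoxy/oxy proportionality ratios of the two hemodynamic modes.

    ``k_f`` (< 0) is the functional ratio — cortical activation raises oxy-Hb
    while deoxy-Hb falls; ``k_s`` (> 0) is the systemic ratio — superficial
    blood-volume changes move both chromophores together.
    """

    k_f: float = -0.6
    k_s: float = 0.5

    def __post_init__(self) -> None:
        if not (self.k_f < 0 < self.k_s):
            raise ParameterError(
                f"require k_f < 0 < k_s, got k_f={self.k_f}, k_s={self.k_s}"
            )


def od_from_intensity(intensity: np.ndarray) -> np.ndarray:
    """Optical-density change −log(I / mean(I)) per channel."""
    intensity = np.asarray(intensity, dtype=float)
    if (intensity <= 0).any():
        raise ParameterError("intensities must be strictly positive")
    return -np.log(intensity / intensity.mean(axis=0, keepdims=True))


def mbll(od_695: np.ndarray, od_830: np.ndarray, params: MbllParams | None = None):
    """Invert the modified Beer–Lambert law.

    Solves ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ) for the two
    chromophores at every sample.  Inputs may be 1-D or (time, channel).
    """
    params = params or MbllParams()
    od_695 = np.asarray(od_695, dtype=float)
    od_830 = np.asarray(od_830, dtype=float)
    if od_695.shape != od_830.shape:
        raise ParameterError(
            f"optical-density series differ in shape: {od_695.shape} vs {od_830.shape}"
        )
    a_inv = np.linalg.inv(params.matrix())
    stacked = np.stack([od_695, od_830], axis=-1)  # (..., 2)
    hb = stacked @ a_inv.T
    return hb[..., 0], hb[..., 1]


def mbll_forward(oxy: np.ndarray, deoxy: np.ndarray, params: MbllParams | None = None):
    """Forward Beer–Lambert model: Hb changes → ΔOD at (695, 830) nm."""
    params = params or MbllParams()
    a = params.matrix()
    stacked = np.stack([np.asarray(oxy, float), np.asarray(deoxy, float)], axis=-1)
    od = stacked @ a.T
    return od[..., 0], od[..., 1]


def hdms(oxy: np.ndarray, deoxy: np.ndarray, params: HdmsParams | None = None):
    """Hemodynamic modality separation.

    Solves, per sample, ``oxy = F + S`` and ``deoxy = k_f·F + k_s·S`` and
    returns ``(F, k_f·F, S, k_s·S)`` — the functional and systemic
    contributions to each chromophore.
    """
    params = params or HdmsParams()
    oxy = np.asarray(oxy, dtype=float)
    deoxy = np.asarray(deoxy, dtype=float)
    if oxy.shape != deoxy.shape:
        raise ParameterError(f"oxy/deoxy shapes differ: {oxy.shape} vs {deoxy.shape}")
    denom = params.k_s - params.k_f
    if denom == 0:
        raise ParameterError("k_f == k_s makes the separation singular")
    functional = (params.k_s * oxy - deoxy) / denom
    systemic = (deoxy - params.k_f * oxy) / denom
    return functional, params.k_f * functional, systemic, params.k_s * systemic


def prewhiten(x: np.ndarray, order: int = 50, return_coeffs: bool = False):
    """AR(``order``) pre-whitening filter.

    The series is de-meaned, an AR model is fitted by Yule–Walker
    (Levinson–Durbin recursion on the sample autocovariance), and the
    one-step-ahead prediction residuals are returned.  The residual series
    is shorter than the input by ``order`` samples (the left edge, where no
    full prediction history exists, is dropped).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("prewhiten expects a 1-D series")
    n = x.size
    if n <= 3 * order:
        raise ParameterError(
            f"series of length {n} too short for AR order {order} (need > {3 * order})"
        )
    xc = x - x.mean()
    if np.allclose(xc, 0.0):
        resid = np.zeros(n - order)
        return (resid, np.zeros(order)) if return_coeffs else resid
    rho, _sigma = yule_walker(xc, order=order, method="mle")
    # residual e[t] = x[t] - sum_i rho_i x[t-i], defined for t >= order
    pred = np.zeros(n - order)
    for i in range(1, order + 1):
        pred += rho[i - 1] * xc[order - i : n - i]
    resid = xc[order:] - pred
    return (resid, rho) if return_coeffs else resid


def preprocess_series(series: HbSeries, hdms_params: HdmsParams | None = None,
                      ar_order: int = 50, apply_hdms: bool = True,
                      apply_prewhiten: bool = True) -> HbSeries:
    """Run HDMS and AR pre-whitening over every channel of an HbSeries.

    All channels are left-trimmed by the same ``ar_order`` samples so
    cross-channel (and cross-participant) alignment is preserved.  The
    returned series carries the functional oxy/deoxy residuals.
    """
    oxy, deoxy = series.oxy, series.deoxy
    if apply_hdms:
        f, f_deoxy, _s, _s_deoxy = hdms(oxy, deoxy, hdms_params)
        oxy, deoxy = f, f_deoxy
    if apply_prewhiten:
        if series.n_samples <= 3 * ar_order:
            raise ParameterError(
                f"session of {series.n_samples} samples too short for AR order {ar_order}"
            )
        new_oxy = np.column_stack(
            [prewhiten(oxy[:, c], ar_order) for c in range(series.n_channels)]
        )
        new_deoxy = np.column_stack(
            [prewhiten(deoxy[:, c], ar_order) for c in range(series.n_channels)]
        )
        oxy, deoxy = new_oxy, new_deoxy
    return HbSeries(
        participant_id=series.participant_id,
        session_id=series.session_id,
        condition=series.condition,
        fs=series.fs,
        oxy=oxy,
        deoxy=deoxy,
        channel_ids=list(series.channel_ids),
    )
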
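"""Wavelet-transform coherence (WTC) between dyadic fNIRS channels.

The continuous wavelet transform uses a Morlet mother wavelet with
wavenumber ``omega0 = 6`` (a good time/frequency-localization trade-off)
evaluated on a geometric frequency grid at 1/10-octave steps; the default
grid spans 0.0072–3.68 Hz and has exactly 91 bands.  Coherence is the
squared modulus of the smoothed cross-spectrum normalized by the smoothed
auto-spectra:

    R²_k(t) = |S(W_xy/s)|² / ( S(|W_x|²/s) · S(|W_y|²/s) )

with ``S`` the standard two-step smoothing — a Gaussian in time whose SD
equals the scale, followed by a boxcar across scale spanning 0.6 of a
scale decade-step window (three bands at 1/10-octave resolution).  Values
inside the cone of influence (COI, more than √2·s from either edge) are
valid; everything else is masked and never enters band means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import fft as sfft

from .errors import AlignmentError, ParameterError
from .io import HbSeries

__all__ = [
    "BandGrid",
    "WtcMap",
    "PairSet",
    "band_grid",
    "morlet_fourier_factor",
    "cwt_morlet",
    "coi_mask",
    "wtc",
    "band_mean_wtc",
    "enumerate_pairs",
    "wtc_for_pair",
    "WtcEngine",
    "dyad_band_means",
]

DEFAULT_OMEGA0 = 6.0
DEFAULT_F_MIN = 0.0072
DEFAULT_F_MAX = 3.68
DEFAULT_STEPS_PER_OCTAVE = 10
SCALE_SMOOTH_DECORRELATION = 0.6  # boxcar width in octave units


@dataclass(frozen=True)
class BandGrid:
    """Geometric frequency grid: f_k = f_min · 2^(k / steps_per_octave)."""

    f_min: float
    f_max: float
    steps_per_octave: int
    frequencies: np.ndarray = field(repr=False)

    @property
    def n_bands(self) -> int:
        return self.frequencies.size

    def nearest_band(self, f: float) -> int:
        return int(np.argmin(np.abs(np.log2(self.frequencies / f))))

    def key(self) -> tuple:
        return (round(self.f_min, 12), round(self.f_max, 12), self.steps_per_octave)


def band_grid(f_min: float = DEFAULT_F_MIN, f_max: float = DEFAULT_F_MAX,
              steps_per_octave: int = DEFAULT_STEPS_PER_OCTAVE) -> BandGrid:
    """Build the analysis frequency grid.

    The printed band edges anchor the grid: bands are f_min·2^(k/steps)
    for k = 0, 1, ... while f_k stays within half a grid step of f_max
    (so a top edge printed with rounding, like 3.68 Hz for the 91st band
    at 3.6864 Hz, still yields the intended band count).
    """
    if f_min <= 0 or f_max <= 0:
        raise ParameterError("frequencies must be positive")
    if f_min > f_max:
        raise ParameterError(f"f_min {f_min} exceeds f_max {f_max}")
    if steps_per_octave < 1:
        raise ParameterError("steps_per_octave must be >= 1")
    n = int(math.floor(steps_per_octave * math.log2(f_max / f_min) + 0.5)) + 1
    k = np.arange(n)
    freqs = f_min * 2.0 ** (k / steps_per_octave)
    return BandGrid(f_min=f_min, f_max=f_max, steps_per_octave=steps_per_octave,
                    frequencies=freqs)


def morlet_fourier_factor(omega0: float = DEFAULT_OMEGA0) -> float:
    """Fourier period / scale ratio: λ = s · 4π / (ω0 + √(2 + ω0²))."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0 ** 2))


def _scales_for(grid: BandGrid, omega0: float) -> np.ndarray:
    """Scale (seconds) per band: s_k = 1 / (fourier_factor · f_k)."""
    return 1.0 / (morlet_fourier_factor(omega0) * grid.frequencies)


_wavelet_bank_cache: dict[tuple, np.ndarray] = {}


def _wavelet_bank(npad: int, fs: float, grid: BandGrid, omega0: float) -> np.ndarray:
    """(n_bands, npad) Morlet filters in the frequency domain."""
    key = (npad, round(fs, 9), grid.key(), round(omega0, 9))
    bank = _wavelet_bank_cache.get(key)
    if bank is not None:
        return bank
    dt = 1.0 / fs
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)  # angular frequency
    scales = _scales_for(grid, omega0)
    arg = scales[:, None] * omega[None, :]
    expo = -0.5 * np.clip(arg - omega0, -60.0, 60.0) ** 2
    bank = np.pi ** -0.25 * np.exp(expo) * (omega[None, :] > 0)
    # energy normalization so unit-amplitude sinusoids give comparable |W|
    bank *= np.sqrt(2.0 * np.pi * scales[:, None] / dt)
    if len(_wavelet_bank_cache) > 32:
        _wavelet_bank_cache.clear()
    _wavelet_bank_cache[key] = bank
    return bank


def cwt_morlet(x: np.ndarray, fs: float, grid: BandGrid | None = None,
               omega0: float = DEFAULT_OMEGA0):
    """Morlet continuous wavelet transform.

    Returns ``(W, coi_s)``: complex coefficients of shape (n_bands, n) and
    the COI boundary ``coi_s[k] = √2 · s_k`` in seconds — a coefficient at
    time ``t`` is edge-contaminated if ``t`` is closer than ``coi_s[k]`` to
    either end of the series.  The signal is de-meaned and zero-padded to
    the next power of two for the FFT.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ParameterError("cwt_morlet expects a non-empty 1-D series")
    if fs <= 0:
        raise ParameterError("fs must be positive")
    grid = grid or band_grid()
    n = x.size
    npad = 1 << (n - 1).bit_length()
    xf = sfft.fft(x - x.mean(), npad)
    bank = _wavelet_bank(npad, fs, grid, omega0)
    w = sfft.ifft(xf[None, :] * bank, axis=1)[:, :n]
    coi_s = np.sqrt(2.0) * _scales_for(grid, omega0)
    return w, coi_s


def coi_mask(n: int, fs: float, grid: BandGrid, omega0: float = DEFAULT_OMEGA0) -> np.ndarray:
    """(n_bands, n) boolean mask, True where a coefficient is inside the COI."""
    coi_s = np.sqrt(2.0) * _scales_for(grid, omega0)
    t = np.arange(n) / fs
    edge_dist = np.minimum(t, t[::-1])
    return edge_dist[None, :] >= coi_s[:, None]


@dataclass
class WtcMap:
    """Time–frequency coherence for one channel pair of one dyad."""

    dyad_id: str
    pair: tuple
    coherence: np.ndarray  # (n_bands, n_times) in [0, 1]
    coi_mask: np.ndarray  # True = inside COI (valid)
    fs: float
    frequencies: np.ndarray


@dataclass(frozen=True)
class PairSet:
    """Channel pairing layout: n identical + n(n−1)/2 different pairs."""

    identical_pairs: tuple
    different_pairs: tuple

    @property
    def all_pairs(self) -> tuple:
        return self.identical_pairs + self.different_pairs

    @property
    def n_total(self) -> int:
        return len(self.identical_pairs) + len(self.different_pairs)


def enumerate_pairs(n_channels: int) -> PairSet:
    """All unordered channel pairs over 1-based channel ids."""
    if n_channels < 1:
        raise ParameterError("need at least one channel")
    ids = range(1, n_channels + 1)
    identical = tuple((i, i) for i in ids)
    different = tuple((i, j) for i in ids for j in ids if i < j)
    return PairSet(identical_pairs=identical, different_pairs=different)


class WtcEngine:
    """Coherence engine for repeated WTC evaluation on one session layout.

    Smoothing kernels, the wavelet bank and the COI mask depend only on
    (n, fs, grid); the engine precomputes them once and additionally caches
    each channel's transform and smoothed auto-spectrum so that all 210
    pairs of a dyad reuse 2×20 transforms.
    """

    def __init__(self, n: int, fs: float, grid: BandGrid | None = None,
                 omega0: float = DEFAULT_OMEGA0):
        if n < 2:
            raise ParameterError("series too short for coherence analysis")
        self.n = n
        self.fs = fs
        self.grid = grid or band_grid()
        self.omega0 = omega0
        self.scales = _scales_for(self.grid, omega0)
        self.coi = coi_mask(n, fs, self.grid, omega0)
        self._m = sfft.next_fast_len(2 * n, real=True)
        f = np.fft.fftfreq(self._m, d=1.0 / fs)
        sigma = self.scales  # time-Gaussian SD equals the scale (seconds)
        expo = -2.0 * np.pi ** 2 * np.minimum(
            (sigma[:, None] ** 2) * f[None, :] ** 2, 400.0)
        self._gauss_ft = np.exp(expo)
        self._gauss_ft_r = self._gauss_ft[:, : self._m // 2 + 1]
        w = int(round(SCALE_SMOOTH_DECORRELATION * self.grid.steps_per_octave / 2.0))
        self._scale_window = max(1, w)

    # -- primitives -----------------------------------------------------

    def transform(self, x: np.ndarray) -> np.ndarray:
        if x.size != self.n:
            raise AlignmentError(f"series length {x.size} != engine length {self.n}")
        w, _ = cwt_morlet(x, self.fs, self.grid, self.omega0)
        return w

    def _smooth_time(self, a: np.ndarray) -> np.ndarray:
        if np.isrealobj(a):
            af = sfft.rfft(a, n=self._m, axis=1)
            return sfft.irfft(af * self._gauss_ft_r, n=self._m, axis=1)[:, : self.n]
        af = sfft.fft(a, n=self._m, axis=1)
        return sfft.ifft(af * self._gauss_ft, axis=1)[:, : self.n]

    def _smooth_scale(self, a: np.ndarray) -> np.ndarray:
        w = self._scale_window
        if w <= 1:
            return a
        if w == 3 and a.shape[0] >= 2:
            out = np.empty_like(a)
            np.add(a[:-2], a[1:-1], out=out[1:-1])
            out[1:-1] += a[2:]
            out[1:-1] /= 3.0
            out[0] = (a[0] + a[1]) / 2.0
            out[-1] = (a[-2] + a[-1]) / 2.0
            return out
        half = w // 2
        nb = a.shape[0]
        csum = np.cumsum(a, axis=0)
        csum = np.concatenate([np.zeros_like(a[:1]), csum], axis=0)
        lo = np.maximum(np.arange(nb) - half, 0)
        hi = np.minimum(np.arange(nb) + half + 1, nb)
        return (csum[hi] - csum[lo]) / (hi - lo)[:, None]

    def smooth(self, a: np.ndarray) -> np.ndarray:
        return self._smooth_scale(self._smooth_time(a))

    def smoothed_power(self, w: np.ndarray) -> np.ndarray:
        return self.smooth(np.abs(w) ** 2 / self.scales[:, None])

    def coherence(self, w_x: np.ndarray, w_y: np.ndarray,
                  p_x: np.ndarray | None = None, p_y: np.ndarray | None = None) -> np.ndarray:
        if p_x is None:
            p_x = self.smoothed_power(w_x)
        if p_y is None:
            p_y = self.smoothed_power(w_y)
        cross = self.smooth(w_x * np.conj(w_y) / self.scales[:, None])
        denom = p_x * p_y
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.abs(cross) ** 2 / denom
        r2 = np.where(denom > 0, r2, 0.0)
        return np.clip(r2, 0.0, 1.0)

    # -- cached per-channel evaluation ----------------------------------

    def channel_cache(self, series: np.ndarray):
        """Transform + smoothed auto-spectrum for columns of (n, ch) data."""
        out = []
        for c in range(series.shape[1]):
            w = self.transform(series[:, c])
            out.append((w, self.smoothed_power(w)))
        return out


_engine_cache: dict[tuple, "WtcEngine"] = {}


def get_engine(n: int, fs: float, grid: BandGrid | None = None,
               omega0: float = DEFAULT_OMEGA0) -> WtcEngine:
    """Shared WtcEngine per session layout (kernels are expensive to build)."""
    grid = grid or band_grid()
    key = (n, round(fs, 9), grid.key(), round(omega0, 9))
    eng = _engine_cache.get(key)
    if eng is None:
        if len(_engine_cache) > 6:
            _engine_cache.clear()
        eng = WtcEngine(n, fs, grid, omega0)
        _engine_cache[key] = eng
    return eng


def wtc(x: np.ndarray, y: np.ndarray, fs: float, grid: BandGrid | None = None,
        omega0: float = DEFAULT_OMEGA0, dyad_id: str = "", pair: tuple = (0, 0)) -> WtcMap:
    """Wavelet-transform coherence of two equally sampled series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError(f"length mismatch: {x.shape} vs {y.shape}")
    grid = grid or band_grid()
    eng = get_engine(x.size, fs, grid, omega0)
    w_x = eng.transform(x)
    w_y = eng.transform(y)
    r2 = eng.coherence(w_x, w_y)
    return WtcMap(dyad_id=dyad_id, pair=pair, coherence=r2, coi_mask=eng.coi,
                  fs=fs, frequencies=grid.frequencies.copy())


def band_mean_wtc(wtc_map: WtcMap) -> np.ndarray:
    """Per-band mean coherence over in-COI samples; NaN where a band is
    fully outside the COI (missing, never imputed as zero)."""
    mask = wtc_map.coi_mask
    counts = mask.sum(axis=1)
    sums = np.where(mask, wtc_map.coherence, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means


def _aligned(hb_a: HbSeries, hb_b: HbSeries) -> None:
    if hb_a.n_samples != hb_b.n_samples or hb_a.fs != hb_b.fs:
        raise AlignmentError(
            f"participants not aligned: {hb_a.n_samples}@{hb_a.fs}Hz vs "
            f"{hb_b.n_samples}@{hb_b.fs}Hz"
        )


def wtc_for_pair(hb_a: HbSeries, hb_b: HbSeries, pair: tuple,
                 chromophore: str = "oxy", mode: str = "between",
                 orientation_policy: str = "average",
                 grid: BandGrid | None = None, omega0: float = DEFAULT_OMEGA0,
                 engine: WtcEngine | None = None):
    """WTC for one channel pair of a dyad.

    ``mode='between'`` pairs channel i of participant A with channel j of
    participant B.  Different-channel pairs are unordered, so both
    orientations (A_i, B_j) and (A_j, B_i) are computed and combined per
    ``orientation_policy``: ``'average'`` (default) averages the coherence
    matrices; ``'keep-both'`` returns both maps.  ``mode='within'``
    computes functional connectivity WTC(A_i, A_j) inside participant A.
    """
    _aligned(hb_a, hb_b)
    grid = grid or band_grid()
    eng = engine or get_engine(hb_a.n_samples, hb_a.fs, grid, omega0)
    i, j = pair
    data_a = hb_a.chromophore(chromophore)
    data_b = hb_b.chromophore(chromophore)
    col_a = hb_a.channel_ids.index(i)
    dyad_id = f"{hb_a.participant_id}-{hb_b.participant_id}"

    def _map(x, y):
        wx, wy = eng.transform(x), eng.transform(y)
        return WtcMap(dyad_id=dyad_id, pair=(i, j), coherence=eng.coherence(wx, wy),
                      coi_mask=eng.coi, fs=hb_a.fs, frequencies=eng.grid.frequencies.copy())

    if mode == "within":
        if i == j:
            raise ParameterError("within-brain mode needs two different channels")
        col_j = hb_a.channel_ids.index(j)
        return _map(data_a[:, col_a], data_a[:, col_j])
    if mode != "between":
        raise ParameterError(f"unknown mode {mode!r}")
    if i == j:
        col_b = hb_b.channel_ids.index(j)
        return _map(data_a[:, col_a], data_b[:, col_b])
    col_aj = hb_a.channel_ids.index(j)
    col_bi = hb_b.channel_ids.index(i)
    col_bj = hb_b.channel_ids.index(j)
    m1 = _map(data_a[:, col_a], data_b[:, col_bj])
    m2 = _map(data_a[:, col_aj], data_b[:, col_bi])
    if orientation_policy == "keep-both":
        return m1, m2
    if orientation_policy != "average":
        raise ParameterError(f"unknown orientation_policy {orientation_policy!r}")
    avg = (m1.coherence + m2.coherence) / 2.0
    return WtcMap(dyad_id=dyad_id, pair=(i, j), coherence=avg, coi_mask=eng.coi,
                  fs=hb_a.fs, frequencies=eng.grid.frequencies.copy())


def dyad_band_means(hb_a: HbSeries, hb_b: HbSeries, chromophore: str = "oxy",
                    mode: str = "between", grid: BandGrid | None = None,
                    omega0: float = DEFAULT_OMEGA0,
                    pairs: Sequence[tuple] | None = None) -> dict:
    """Band-mean WTC for every channel pair of one dyad session.

    Returns ``{(ch_i, ch_j): band_mean_vector}`` over all pairs (or the
    given subset), reusing one transform per channel.  For ``'within'``
    mode only participant A's different-channel pairs are enumerated.
    """
    _aligned(hb_a, hb_b)
    grid = grid or band_grid()
    eng = get_engine(hb_a.n_samples, hb_a.fs, grid, omega0)
    pair_set = enumerate_pairs(hb_a.n_channels)
    if pairs is None:
        pairs = pair_set.different_pairs if mode == "within" else pair_set.all_pairs
    cache_a = eng.channel_cache(hb_a.chromophore(chromophore))
    cache_b = cache_a if mode == "within" else eng.channel_cache(hb_b.chromophore(chromophore))

    mask = eng.coi
    counts = np.maximum(mask.sum(axis=1), 1)
    empty = mask.sum(axis=1) == 0

    def _band_means(r2):
        means = np.where(mask, r2, 0.0).sum(axis=1) / counts
        means[empty] = np.nan
        return means

    out = {}
    for (i, j) in pairs:
        ia, ja = hb_a.channel_ids.index(i), hb_a.channel_ids.index(j)
        if mode == "within":
            (wx, px), (wy, py) = cache_a[ia], cache_a[ja]
            r2 = eng.coherence(wx, wy, px, py)
        elif i == j:
            (wx, px), (wy, py) = cache_a[ia], cache_b[ja]
            r2 = eng.coherence(wx, wy, px, py)
        else:
            (w1, p1), (w2, p2) = cache_a[ia], cache_b[ja]
            (w3, p3), (w4, p4) = cache_a[ja], cache_b[ia]
            r2 = (eng.coherence(w1, w2, p1, p2) + eng.coherence(w3, w4, p3, p4)) / 2.0
        out[(i, j)] = _band_means(r2)
    return out
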
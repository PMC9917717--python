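"""Synthetic dyadic fNIRS recordings and head-pose traces.

The generator emulates the statistical structure the analysis assumes,
not neurovascular physiology: per-channel 1/f + white background
activity, a shared within-participant systemic component with positively
proportional oxy/deoxy (so modality separation has something to remove),
a functional component with negatively proportional oxy/deoxy, and —
for chosen channel pairs — a shared narrow-band oscillation injected
during behaviorally defined epochs, which is what wavelet coherence
should detect.  Event-locked injection is lagged by a configurable
hemodynamic delay (default 5 s) to emulate the delay-of-peak between a
behavioral event and its vascular response.

Head-pose traces are Gaussian pitch noise with plateau excursions during
face-up epochs, sized so that z-scoring and a +2 SD threshold recover
the events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import HbSeries, PoseSeries

__all__ = [
    "CouplingPair",
    "EventSpec",
    "NoiseSpec",
    "SimParams",
    "GroundTruth",
    "DyadRecording",
    "simulate_dyad",
    "simulate_pose",
    "simulate_experiment",
    "one_over_f_noise",
]

LOCK_MODES = ("both_up", "either_up", "always")


@dataclass(frozen=True)
class CouplingPair:
    """One coupled channel pair: channel of A, channel of B (1-based ids),
    oscillation center frequency (Hz) and coupling amplitude (signal SD
    units added on top of the unit-SD background)."""

    ch_a: int
    ch_b: int
    freq_hz: float
    amplitude: float


@dataclass(frozen=True)
class EventSpec:
    """Face-up event process: how often faces go up and for how long.

    Events arrive sequentially with exponential gaps at ``rate_per_min``
    (all types pooled), last Uniform(*duration_s*) seconds, and are typed
    both-up / self-A / self-B with probabilities ``p_both`` and the
    remainder split evenly.  ``lock_mode`` selects which epochs gate the
    injected coupling.
    """

    rate_per_min: float = 0.9
    duration_s: tuple = (15.0, 25.0)
    p_both: float = 0.3
    lock_mode: str = "either_up"
    min_gap_s: float = 2.0


@dataclass(frozen=True)
class NoiseSpec:
    """Background spectrum: 1/f^exponent colored noise plus white noise."""

    one_over_f_exponent: float = 1.0
    colored_sd: float = 1.0
    white_sd: float = 0.3


@dataclass(frozen=True)
class SimParams:
    """Full description of one simulated dyadic session."""

    n_channels: int = 20
    fs_hb: float = 10.0
    fs_pose: float = 29.97
    duration: float = 600.0
    coupling_pairs: tuple = ()
    event_spec: EventSpec = field(default_factory=EventSpec)
    systemic_amplitude: float = 0.3
    noise_spec: NoiseSpec = field(default_factory=NoiseSpec)
    k_f: float = -0.6
    k_s: float = 0.5
    hemodynamic_delay_s: float = 5.0
    phase_drift_rad: float = 0.01  # per-sample SD of the coupling phase walk
    pose_noise_sd: float = 0.05  # radians
    pose_excursion_sd: float = 12.0  # excursion height in baseline-SD units
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ParameterError(f"duration must be positive, got {self.duration}")
        if self.fs_hb <= 0 or self.fs_pose <= 0:
            raise ParameterError("sampling rates must be positive")
        if self.n_channels < 1:
            raise ParameterError("need at least one channel")
        for cp in self.coupling_pairs:
            if cp.amplitude < 0:
                raise ParameterError(f"negative coupling amplitude on {cp}")
            if not (1 <= cp.ch_a <= self.n_channels and 1 <= cp.ch_b <= self.n_channels):
                raise ParameterError(f"coupling channels out of range: {cp}")
            if self.fs_hb <= 2.0 * cp.freq_hz:
                raise ParameterError(
                    f"fs_hb {self.fs_hb} must exceed twice the coupling "
                    f"frequency {cp.freq_hz}"
                )
        if self.systemic_amplitude < 0:
            raise ParameterError("systemic_amplitude must be >= 0")
        if self.event_spec.lock_mode not in LOCK_MODES:
            raise ParameterError(
                f"lock_mode must be one of {LOCK_MODES}, got {self.event_spec.lock_mode!r}"
            )


@dataclass
class GroundTruth:
    """What was actually injected, for oracle-style checks downstream."""

    events: pd.DataFrame  # onset_s, offset_s, label
    lock_epochs: list  # (onset_s, offset_s) gating epochs before delay
    gated_epochs: list  # same epochs shifted by the hemodynamic delay
    coupling_pairs: tuple
    gate: np.ndarray  # smoothed 0..1 gate at fs_hb
    fs_hb: float


@dataclass
class DyadRecording:
    """One dyad's simulated experiment: one COOP and one IND session plus
    COOP pose traces and the injection ground truth."""

    dyad_id: str
    coop_a: HbSeries
    coop_b: HbSeries
    ind_a: HbSeries
    ind_b: HbSeries
    pose_a: PoseSeries
    pose_b: PoseSeries
    truth: GroundTruth


def one_over_f_noise(n: int, fs: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD noise with a 1/f^exponent amplitude spectrum (spectral
    shaping of white noise)."""
    if n == 0:
        return np.zeros(0)
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _draw_events(spec: EventSpec, duration: float, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    t = float(rng.exponential(60.0 / spec.rate_per_min))
    lo, hi = spec.duration_s
    while t < duration:
        dur = float(rng.uniform(lo, hi))
        offset = min(t + dur, duration)
        u = rng.random()
        if u < spec.p_both:
            label = "both_up"
        elif u < spec.p_both + (1 - spec.p_both) / 2:
            label = "self_up_A"
        else:
            label = "self_up_B"
        rows.append({"onset_s": t, "offset_s": offset, "label": label})
        t = offset + spec.min_gap_s + float(rng.exponential(60.0 / spec.rate_per_min))
    return pd.DataFrame(rows, columns=["onset_s", "offset_s", "label"])


def _smooth_gate(epochs, n: int, fs: float, ramp_s: float = 1.0) -> np.ndarray:
    gate = np.zeros(n)
    for onset, offset in epochs:
        i0 = max(int(np.ceil(onset * fs)), 0)
        i1 = min(int(np.ceil(offset * fs)), n)
        gate[i0:i1] = 1.0
    w = max(int(round(ramp_s * fs)), 1)
    kernel = np.hanning(2 * w + 1)
    kernel /= kernel.sum()
    return np.convolve(gate, kernel, mode="same")


def simulate_dyad(params: SimParams, condition: str = "COOP",
                  dyad_id: str = "dyad01", with_coupling: bool = True,
                  rng: np.random.Generator | None = None):
    """Simulate one session of a dyad.

    Returns ``(hb_a, hb_b, truth)``.  The functional component of every
    channel is unit-SD background noise; coupled channels additionally
    share a drifting-phase sinusoid gated by the lock-mode epochs (delayed
    by the hemodynamic lag).  Each participant's channels share one
    systemic component with oxy/deoxy ratio ``k_s`` while the functional
    component has ratio ``k_f``.
    """
    params.validate()
    rng = rng or np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fs_hb))
    t = np.arange(n) / params.fs_hb

    events = _draw_events(params.event_spec, params.duration, rng)
    mode = params.event_spec.lock_mode
    if mode == "always":
        lock_epochs = [(0.0, params.duration)]
    elif mode == "both_up":
        sel = events[events["label"] == "both_up"]
        lock_epochs = list(zip(sel["onset_s"], sel["offset_s"]))
    else:  # either_up
        sel = events[events["label"].isin(["self_up_A", "self_up_B"])]
        lock_epochs = list(zip(sel["onset_s"], sel["offset_s"]))
    delay = params.hemodynamic_delay_s
    gated_epochs = [(a + delay, b + delay) for a, b in lock_epochs]
    gate = _smooth_gate(gated_epochs, n, params.fs_hb)

    ns = params.noise_spec

    def background(shape_channels: int) -> np.ndarray:
        cols = []
        for _ in range(shape_channels):
            colored = ns.colored_sd * one_over_f_noise(n, params.fs_hb,
                                                       ns.one_over_f_exponent, rng)
            cols.append(colored + ns.white_sd * rng.standard_normal(n))
        return np.column_stack(cols)

    f_a = background(params.n_channels)
    f_b = background(params.n_channels)

    if with_coupling:
        for cp in params.coupling_pairs:
            phase = np.cumsum(rng.normal(0.0, params.phase_drift_rad, n))
            osc = np.cos(2.0 * np.pi * cp.freq_hz * t + phase)
            shared = cp.amplitude * gate * osc
            f_a[:, cp.ch_a - 1] += shared
            f_b[:, cp.ch_b - 1] += shared

    # one systemic trace per participant, shared across that participant's channels
    sys_a = params.systemic_amplitude * one_over_f_noise(n, params.fs_hb, 1.5, rng)
    sys_b = params.systemic_amplitude * one_over_f_noise(n, params.fs_hb, 1.5, rng)

    def to_series(func: np.ndarray, sys_trace: np.ndarray, pid: str) -> HbSeries:
        oxy = func + sys_trace[:, None]
        deoxy = params.k_f * func + params.k_s * sys_trace[:, None]
        return HbSeries(participant_id=pid, session_id=f"{dyad_id}-{condition}",
                        condition=condition, fs=params.fs_hb, oxy=oxy, deoxy=deoxy)

    hb_a = to_series(f_a, sys_a, f"{dyad_id}A")
    hb_b = to_series(f_b, sys_b, f"{dyad_id}B")
    truth = GroundTruth(events=events, lock_epochs=lock_epochs,
                        gated_epochs=gated_epochs,
                        coupling_pairs=params.coupling_pairs if with_coupling else (),
                        gate=gate, fs_hb=params.fs_hb)
    return hb_a, hb_b, truth


def simulate_pose(params: SimParams, epochs, participant_id: str = "A",
                  rng: np.random.Generator | None = None) -> PoseSeries:
    """Pitch-angle trace with face-up plateau excursions during ``epochs``.

    Baseline is Gaussian noise (SD ``pose_noise_sd`` radians); during each
    requested epoch the pitch is raised by ``pose_excursion_sd`` baseline
    SDs, so after z-scoring the excursion samples exceed the +2 SD
    face-up threshold.  A zero-duration session yields an empty series.
    """
    if params.duration < 0:
        raise ParameterError(f"duration must be >= 0, got {params.duration}")
    if params.duration > 0:
        params.validate()
    rng = rng or np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fs_pose))
    if n == 0:
        return PoseSeries(participant_id=participant_id, fs=params.fs_pose,
                          pitch=np.zeros(0), frame=np.zeros(0, dtype=int),
                          timestamp=np.zeros(0), valid=np.zeros(0, dtype=bool))
    epochs = sorted((float(a), float(b)) for a, b in epochs)
    for (a, b) in epochs:
        if b < a:
            raise ParameterError(f"malformed epoch ({a}, {b})")
        if a < 0 or b > params.duration:
            raise ParameterError(f"epoch ({a}, {b}) outside [0, {params.duration}]")
    for (a0, b0), (a1, _b1) in zip(epochs, epochs[1:]):
        if a1 < b0:
            raise ParameterError(f"overlapping epochs near t={a1}")
    pitch = params.pose_noise_sd * rng.standard_normal(n)
    bump = params.pose_excursion_sd * params.pose_noise_sd
    for a, b in epochs:
        i0 = max(int(np.ceil(a * params.fs_pose)), 0)
        i1 = min(int(np.ceil(b * params.fs_pose)), n)
        pitch[i0:i1] += bump
    return PoseSeries(participant_id=participant_id, fs=params.fs_pose,
                      pitch=pitch)


def pose_epochs_for(truth: GroundTruth, participant: str) -> list:
    """Ground-truth face-up epochs of one participant (both-up plus the
    participant's self-up events)."""
    label = f"self_up_{participant}"
    sel = truth.events[truth.events["label"].isin(["both_up", label])]
    return list(zip(sel["onset_s"], sel["offset_s"]))


def simulate_experiment(n_dyads: int, params: SimParams,
                        couple_in: str = "COOP") -> list:
    """Simulate a full experiment: per dyad one COOP session (with face-up
    events and, if ``couple_in='COOP'``, the injected coupling) and one
    IND session (no events, coupling only if ``couple_in='always'``).

    Per-dyad RNG streams are spawned from ``params.seed`` so each dyad is
    reproducible independently of the others.
    """
    if n_dyads < 1:
        raise ParameterError("need at least one dyad")
    if couple_in not in ("COOP", "always", "none"):
        raise ParameterError(f"couple_in must be COOP/always/none, got {couple_in!r}")
    recordings = []
    streams = np.random.SeedSequence(params.seed).spawn(n_dyads)
    for d, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        dyad_id = f"dyad{d:02d}"
        coop_a, coop_b, truth = simulate_dyad(
            params, condition="COOP", dyad_id=dyad_id,
            with_coupling=couple_in in ("COOP", "always"), rng=rng)
        ind_a, ind_b, _ = simulate_dyad(
            params, condition="IND", dyad_id=dyad_id,
            with_coupling=couple_in == "always", rng=rng)
        pose_a = simulate_pose(params, pose_epochs_for(truth, "A"),
                               participant_id=f"{dyad_id}A", rng=rng)
        pose_b = simulate_pose(params, pose_epochs_for(truth, "B"),
                               participant_id=f"{dyad_id}B", rng=rng)
        recordings.append(DyadRecording(dyad_id=dyad_id, coop_a=coop_a,
                                        coop_b=coop_b, ind_a=ind_a, ind_b=ind_b,
                                        pose_a=pose_a, pose_b=pose_b, truth=truth))
    return recordings
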
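"""Time-of-flight estimation by cumulative-energy knee picking.

The arrival of the shear wavefront on a channel is located by (i) the
Hilbert analytic envelope and instantaneous power, (ii) the running
integral of instantaneous power (cumulative energy), whose first abrupt
rise -- the "knee" -- marks the arrival, and (iii) thresholding the
derivative of cumulative energy at mean + k*std (k = 1 by default).
TOF is the Rx-onset minus Tx-onset time difference; shear speed is the
known Tx-Rx path length divided by TOF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .exceptions import (
    AcausalPickError,
    ConfigError,
    NoOnsetError,
    ParameterError,
    ShapeError,
)
from .pipeline import WaveformRecord, snr_onset

__all__ = [
    "KneeConfig",
    "TOFResult",
    "QCFlags",
    "analytic_envelope",
    "cumulative_energy",
    "knee_detect",
    "estimate_tof",
    "farfield_check",
]


@dataclass(frozen=True)
class KneeConfig:
    """Knee-detector configuration.

    ``threshold_k`` multiplies the standard deviation in the threshold
    mean + k*std of dC/dt.  ``stats_window`` selects where those
    statistics are computed: the whole record (literal reading of the
    protocol) or a leading baseline of that many samples.
    ``edge_fraction`` rejects crossings within the first/last fraction
    of the record as edge artifacts.
    """

    threshold_k: float = 1.0
    stats_window: int | None = None  # None = full record
    edge_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not self.threshold_k > 0:
            raise ConfigError("threshold_k must be > 0")
        if self.stats_window is not None and self.stats_window < 2:
            raise ConfigError("baseline stats_window must be >= 2 samples")
        if not 0 <= self.edge_fraction < 0.5:
            raise ConfigError("edge_fraction must lie in [0, 0.5)")


@dataclass(frozen=True)
class TOFResult:
    """Arrival picks, time of flight and derived shear velocity."""

    onset_tx: int
    onset_rx: int
    tof: float  # seconds
    distance_D: float  # meters
    velocity: float  # m/s
    farfield_ok: bool | None = None
    snr_db: float | None = None


@dataclass(frozen=True)
class QCFlags:
    """Geometric quality-control flags for one (D, c_s, f) combination."""

    wavelength: float
    farfield_ok: bool  # D >= 2*lambda
    boundary_ok: bool  # clearance > lambda


def analytic_envelope(record: WaveformRecord) -> tuple[np.ndarray, np.ndarray]:
    """Analytic envelope A(t) = |x + j H{x}| and instantaneous power A^2."""
    z = hilbert(record.samples)
    env = np.abs(z)
    return env, env**2


def cumulative_energy(power: np.ndarray, fs: float) -> np.ndarray:
    """Running integral C(t) of instantaneous power (rectangle rule)."""
    power = np.asarray(power, dtype=float)
    if np.any(power < 0):
        raise ParameterError("instantaneous power must be nonnegative")
    if not fs > 0:
        raise ParameterError("fs must be > 0 Hz")
    return np.cumsum(power) / fs


def knee_detect(C: np.ndarray, fs: float, cfg: KneeConfig | None = None) -> int:
    """First index where dC/dt exceeds mean + k*std of dC/dt.

    The threshold is scale-covariant, so the pick is invariant to any
    positive rescaling of the input signal.  Crossings within the edge
    guard band are rejected; a flat record raises :class:`NoOnsetError`.
    """
    cfg = cfg or KneeConfig()
    C = np.asarray(C, dtype=float)
    if C.size < 3:
        raise ShapeError("cumulative energy curve must have >= 3 samples")
    if np.any(np.diff(C) < -1e-12 * max(C[-1], 1.0)):
        raise ParameterError("cumulative energy must be nondecreasing")
    # dC[i] = (C[i] - C[i-1]) * fs, aligned so an ideal power step at
    # sample k crosses the threshold exactly at index k
    dC = np.diff(C, prepend=C[0]) * fs
    stats = dC if cfg.stats_window is None else dC[: cfg.stats_window]
    mu, sd = float(np.mean(stats)), float(np.std(stats))
    threshold = mu + cfg.threshold_k * sd
    crossings = np.flatnonzero(dC > threshold)
    guard = int(cfg.edge_fraction * C.size)
    crossings = crossings[(crossings >= guard) & (crossings < C.size - guard)]
    if crossings.size == 0:
        raise NoOnsetError("no threshold crossing found")
    return int(crossings[0])


def _pick_onset(record: WaveformRecord, cfg: KneeConfig) -> int:
    _, power = analytic_envelope(record)
    C = cumulative_energy(power, record.fs)
    return knee_detect(C, record.fs, cfg)


def estimate_tof(
    tx: WaveformRecord,
    rx: WaveformRecord,
    D: float,
    cfg: KneeConfig | None = None,
    f0: float | None = None,
) -> TOFResult:
    """Pick both channel onsets, form TOF = (onset_rx - onset_tx)/fs and
    velocity = D / TOF.

    If the excitation frequency ``f0`` is given, the far-field flag
    D >= 2*lambda is evaluated with the estimated velocity.
    """
    cfg = cfg or KneeConfig()
    if tx.fs != rx.fs:
        raise ShapeError("Tx and Rx must share the sampling rate")
    if not D > 0:
        raise ParameterError("distance D must be > 0 m")
    onset_tx = _pick_onset(tx, cfg)
    onset_rx = _pick_onset(rx, cfg)
    if onset_rx <= onset_tx:
        raise AcausalPickError(
            f"Rx onset ({onset_rx}) at or before Tx onset ({onset_tx})"
        )
    tof = (onset_rx - onset_tx) / tx.fs
    velocity = D / tof
    farfield = None
    if f0 is not None:
        farfield = farfield_check(D, velocity, f0).farfield_ok
    snr = snr_onset(rx, onset_rx) if 0 < onset_rx < rx.n else None
    return TOFResult(
        onset_tx=onset_tx,
        onset_rx=onset_rx,
        tof=tof,
        distance_D=D,
        velocity=velocity,
        farfield_ok=farfield,
        snr_db=snr,
    )


def farfield_check(
    D: float, c_s: float, f: float, clearance: float = np.inf
) -> QCFlags:
    """Geometric QC: far-field (D >= 2*lambda, inclusive) and boundary
    clearance (> lambda).  Reports, never gates."""
    if min(D, c_s, f) <= 0 or clearance <= 0:
        raise ParameterError("D, c_s, f and clearance must be positive")
    lam = c_s / f
    return QCFlags(
        wavelength=lam,
        farfield_ok=bool(D >= 2.0 * lam),
        boundary_ok=bool(clearance > lam),
    )
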
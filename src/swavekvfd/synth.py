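"""Synthetic-data generation: bursts, physically propagated Rx traces,
noise injection, replicate dispersion tables, and packaged fixtures.

The forward wave model multiplies the transmit spectrum by
``exp(-i k(omega) D)`` with the complex KVFD wavenumber, so the
synthetic receive trace carries the physically correct frequency-
dependent delay (dispersion) and exponential amplitude decay
(attenuation).  An optional single-pole resonant ring-down emulates the
multi-cycle response of a resonant receiver.  All generators are pure
functions of (spec, seed): repeated calls are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .dispersion import DispersionCurve, build_curve
from .exceptions import ParameterError, SchemaError
from .kvfd import KVFDParams, phase_velocity, wavenumber
from .pipeline import WaveformRecord

__all__ = [
    "BurstSpec",
    "NoiseSpec",
    "make_burst",
    "propagate_trace",
    "add_noise",
    "make_dispersion_table",
    "make_rheometer_sweep",
    "load_fixture",
]


@dataclass(frozen=True)
class BurstSpec:
    """A sine-burst excitation: silence, `cycles` full periods, silence."""

    f0: float
    cycles: int = 1
    amplitude: float = 1.0
    fs: float = 100_000.0
    pre_silence: float = 0.01
    total_duration: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.f0 < self.fs / 2:
            raise ParameterError(
                f"f0 must lie in (0, fs/2) to avoid aliasing, got {self.f0}"
            )
        if self.cycles < 1:
            raise ParameterError("cycles must be >= 1")
        if self.pre_silence < 0:
            raise ParameterError("pre_silence must be >= 0 s")
        if self.total_duration < self.pre_silence + self.cycles / self.f0:
            raise ParameterError("total_duration too short for the burst")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive measurement noise: white Gaussian + Poisson impulses +
    a power-line sinusoid.  Fixed seed gives byte-identical output."""

    white_sigma: float = 0.0
    impulse_rate: float = 0.0  # events per second
    impulse_amplitude: float = 0.0
    line_freq: float = 50.0
    line_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.white_sigma, self.impulse_rate, self.impulse_amplitude,
               self.line_amplitude) < 0 or self.line_freq <= 0:
            raise ParameterError("noise amplitudes/rates must be nonnegative")


def make_burst(spec: BurstSpec) -> WaveformRecord:
    """Single (or multi) cycle sine burst on a zero baseline."""
    n = int(round(spec.total_duration * spec.fs))
    t = np.arange(n) / spec.fs
    x = np.zeros(n)
    in_burst = (t >= spec.pre_silence) & (
        t < spec.pre_silence + spec.cycles / spec.f0
    )
    x[in_burst] = spec.amplitude * np.sin(
        2.0 * np.pi * spec.f0 * (t[in_burst] - spec.pre_silence)
    )
    return WaveformRecord(
        samples=x, fs=spec.fs, channel="Tx",
        meta={"f0": spec.f0, "cycles": spec.cycles},
    )


def _next_pow2(n: int) -> int:
    m = 1
    while m < n:
        m *= 2
    return m


def propagate_trace(
    tx: WaveformRecord,
    params: KVFDParams,
    D: float,
    ringdown_q: float | None = None,
) -> WaveformRecord:
    """Physically propagate a transmit trace over path length D.

    Rx(omega) = Tx(omega) * exp(-i k(omega) D) on the positive-frequency
    half (real output by Hermitian symmetry of the rFFT).  The FFT length
    is the next power of two >= 4x the record to suppress circular
    wrap-around.  The DC bin is passed unchanged.  ``ringdown_q``
    convolves a single-pole resonant impulse response at the excitation
    frequency (from tx.meta['f0']) to emulate a resonant receiver.
    """
    if D < 0:
        raise ParameterError("path length D must be >= 0 m")
    x = tx.samples
    nfft = _next_pow2(4 * x.size)
    freqs = np.fft.rfftfreq(nfft, 1.0 / tx.fs)
    X = np.fft.rfft(x, nfft)
    if D > 0:
        k = wavenumber(params, freqs)
        H = np.exp(-1j * (k.beta - 1j * k.alpha_att) * D)
        H[0] = 1.0
        X = X * H
    y = np.fft.irfft(X, nfft)[: x.size]
    if ringdown_q is not None:
        f0 = tx.meta.get("f0")
        if f0 is None:
            raise ParameterError("ringdown needs tx.meta['f0']")
        y = _apply_ringdown(y, tx.fs, f0, ringdown_q)
    return WaveformRecord(
        samples=y, fs=tx.fs, t0=tx.t0, channel="Rx",
        meta={**tx.meta, "distance_m": D},
    )


def _apply_ringdown(x: np.ndarray, fs: float, f0: float, q: float) -> np.ndarray:
    """Convolve with a decaying resonator h(t) = exp(-w0 t / 2Q) sin(w0 t),
    normalized to unit peak response."""
    if q <= 0:
        raise ParameterError("ringdown Q must be > 0")
    w0 = 2.0 * np.pi * f0
    # keep the kernel until the envelope decays to ~1e-3
    t_end = 2.0 * q / w0 * np.log(1e3)
    t = np.arange(int(t_end * fs)) / fs
    h = np.exp(-w0 * t / (2.0 * q)) * np.sin(w0 * t)
    h /= np.abs(h).max()
    return np.convolve(x, h, mode="full")[: x.size]


def add_noise(record: WaveformRecord, spec: NoiseSpec) -> WaveformRecord:
    """Add seeded white Gaussian noise, Poisson-timed impulses, and a
    power-line sinusoid."""
    rng = np.random.default_rng(spec.seed)
    x = record.samples.copy()
    n = x.size
    if spec.white_sigma > 0:
        x += rng.normal(0.0, spec.white_sigma, n)
    if spec.impulse_rate > 0 and spec.impulse_amplitude > 0:
        count = rng.poisson(spec.impulse_rate * n / record.fs)
        if count > 0:
            idx = rng.integers(0, n, size=count)
            x[idx] += spec.impulse_amplitude * rng.choice([-1.0, 1.0], count)
    if spec.line_amplitude > 0:
        t = record.times
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += spec.line_amplitude * np.sin(
            2.0 * np.pi * spec.line_freq * t + phase
        )
    return record.with_samples(x, noise=spec)


def make_dispersion_table(
    params: KVFDParams,
    frequencies,
    n_replicates: int = 3,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DispersionCurve:
    """Replicate dispersion table: model velocities + Gaussian noise.

    Emulates the replicate structure of the measured tables (a handful
    of repeated velocity estimates per excitation frequency).
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    freqs = np.asarray(frequencies, dtype=float)
    rng = np.random.default_rng(seed)
    truth = phase_velocity(params, freqs)
    table = {}
    for f, c in zip(freqs, truth):
        v = c + rng.normal(0.0, noise_sigma, n_replicates)
        table[float(f)] = np.maximum(v, 1e-6)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return build_curve(table, label="synthetic")


def make_rheometer_sweep(
    params: KVFDParams,
    frequencies,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic rheometer frequency sweep (f, G', G'') from KVFD params.

    G* = E* / (2 (1 + nu)); optional multiplicative Gaussian noise of
    relative size ``noise_rel`` emulates instrument scatter.
    """
    from .kvfd import storage_loss, young_shear_convert

    freqs = np.asarray(frequencies, dtype=float)
    e_sto, e_loss = storage_loss(params, freqs)
    gp = young_shear_convert(e_sto, params.nu, "young_to_shear")
    gpp = young_shear_convert(e_loss, params.nu, "young_to_shear")
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        gp = gp * (1.0 + rng.normal(0.0, noise_rel, freqs.size))
        gpp = gpp * (1.0 + rng.normal(0.0, noise_rel, freqs.size))
    return pd.DataFrame(
        {"frequency_hz": freqs, "g_storage_pa": gp, "g_loss_pa": gpp}
    )


# ---------------------------------------------------------------------------
# Packaged fixtures: the published dispersion / parameter / bias-check tables.

_TABLE_FILES = {
    "table2": "table2_hard_dispersion.csv",
    "table3": "table3_soft_dispersion.csv",
    "table4": "table4_kvfd_parameters.csv",
    "table5": "table5_bias_check.csv",
}


def _read_packaged(name: str) -> pd.DataFrame:
    path = resources.files("swavekvfd.data").joinpath(_TABLE_FILES[name])
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def load_fixture(name: str):
    """Load a packaged fixture table.

    - ``table2`` / ``table3``: hard / soft phantom dispersion replicates,
      returned as :class:`DispersionCurve` (means/SEs recomputed from the
      replicates).
    - ``table4``: KVFD parameter sets per (phantom, method), returned as
      a dict keyed by e.g. ``("hard", "tof")`` with SI-unit
      :class:`KVFDParams` (rho = 1000 kg/m^3, nu = 0.5).
    - ``table5``: the frequency-resolved bias-check table as a DataFrame.
    """
    if name not in _TABLE_FILES:
        raise SchemaError(
            f"unknown fixture {name!r}; choose from {sorted(_TABLE_FILES)}"
        )
    df = _read_packaged(name)
    if name in ("table2", "table3"):
        label = "hard" if name == "table2" else "soft"
        vcols = [c for c in df.columns if c.startswith("v")]
        return build_curve(df[["frequency_hz"] + vcols], label=label)
    if name == "table4":
        out = {}
        for _, row in df.iterrows():
            out[(row["phantom"], row["method"])] = KVFDParams(
                E0=row["e0_kpa"] * 1e3,
                eta=row["eta_kpa_s_alpha"] * 1e3,
                alpha=row["alpha"],
                rho=1000.0,
                nu=0.5,
            )
        return out
    return df
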
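"""Readers/writers for the delimited-text schemas and run configuration.

Schemas (comma-separated, UTF-8, mandatory header, units in column names):

- waveform, one channel:   ``time_s, volts``
- waveform, two channels:  ``time_s, tx_volts, rx_volts``
- dispersion curve:        ``frequency_hz, v1, v2, ..., mean, se``
  (``mean``/``se`` optional; always recomputed from replicates and
  cross-checked against file values when present)
- rheometer sweep:         ``frequency_hz, g_storage_pa, g_loss_pa``
  (``_kpa`` variants accepted and converted; anything else is an error)
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dispersion import DispersionCurve, FitResult, build_curve
from .exceptions import SchemaError
from .pipeline import PipelineConfig, WaveformRecord
from .tof import KneeConfig, TOFResult

__all__ = [
    "RunConfig",
    "read_dispersion_csv",
    "write_dispersion_csv",
    "read_waveform_csv",
    "write_waveform_csv",
    "read_rheometer_sweep",
    "run_report",
]

_RHEOMETER_BAND = (0.01, 100.0)  # operating band of oscillatory rheometry, Hz


@dataclass(frozen=True)
class RunConfig:
    """One-document YAML configuration for a full analysis run."""

    rho: float = 1000.0
    nu: float = 0.5
    band: tuple[float, float] = (40.0, 180.0)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    knee: KneeConfig = field(default_factory=KneeConfig)
    fit_weights: str = "se"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pipeline = PipelineConfig(**{
            **raw.get("pipeline", {}),
            **({"stages": tuple(raw["pipeline"]["stages"])}
               if "stages" in raw.get("pipeline", {}) else {}),
        })
        knee = KneeConfig(**raw.get("knee", {}))
        return cls(
            rho=raw.get("rho", 1000.0),
            nu=raw.get("nu", 0.5),
            band=tuple(raw.get("band", (40.0, 180.0))),
            pipeline=pipeline,
            knee=knee,
            fit_weights=raw.get("fit_weights", "se"),
            seed=raw.get("seed", 0),
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "rho": self.rho,
            "nu": self.nu,
            "band": list(self.band),
            "pipeline": {
                **dataclasses.asdict(self.pipeline),
                "stages": list(self.pipeline.stages),
            },
            "knee": dataclasses.asdict(self.knee),
            "fit_weights": self.fit_weights,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_dispersion_csv(path: str | Path, label: str = "custom") -> DispersionCurve:
    """Read a dispersion CSV; means/SEs are recomputed and cross-checked."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    if "frequency_hz" not in df.columns:
        raise SchemaError(f"{path}: missing 'frequency_hz' column")
    vcols = [c for c in df.columns if c.startswith("v") and c != "volts"]
    if not vcols:
        raise SchemaError(f"{path}: no replicate columns v1, v2, ...")
    f = df["frequency_hz"].to_numpy(float)
    if np.any(~np.isfinite(f)) or np.any(np.diff(f) <= 0):
        bad = int(np.flatnonzero(np.diff(f) <= 0)[0]) + 2 if f.size > 1 else 1
        raise SchemaError(f"{path}: frequencies not strictly increasing "
                          f"(near line {bad})")
    curve = build_curve(df[["frequency_hz"] + vcols], label=label)
    for col, recomputed in (("mean", curve.mean_velocity),
                            ("se", curve.se_velocity)):
        if col in df.columns:
            stated = df[col].to_numpy(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(stated - recomputed) / np.abs(recomputed)
            if np.any(rel[np.isfinite(rel)] > 0.005):
                warnings.warn(
                    f"{path}: stated '{col}' deviates >0.5% from the value "
                    "recomputed from replicates; recomputed values are used",
                    RuntimeWarning,
                )
    return curve


def write_dispersion_csv(curve: DispersionCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_waveform_csv(
    path: str | Path, fs: float | None = None
) -> WaveformRecord | tuple[WaveformRecord, WaveformRecord]:
    """Read a waveform CSV (single- or two-channel layout).

    Sampling rate is inferred from the time column unless given.
    Returns one record, or a (tx, rx) pair for the two-channel layout.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise SchemaError(f"{path}: missing 'time_s' column")
    t = df["time_s"].to_numpy(float)
    if fs is None:
        dt = np.diff(t)
        if t.size < 2 or np.any(dt <= 0):
            raise SchemaError(f"{path}: cannot infer fs from time column")
        if np.ptp(dt) > 1e-6 * dt.mean():
            raise SchemaError(f"{path}: time column not uniformly sampled")
        fs = 1.0 / dt.mean()
    if {"tx_volts", "rx_volts"} <= set(df.columns):
        tx = WaveformRecord(df["tx_volts"].to_numpy(float), fs, t0=t[0],
                            channel="Tx", meta={"source": str(path)})
        rx = WaveformRecord(df["rx_volts"].to_numpy(float), fs, t0=t[0],
                            channel="Rx", meta={"source": str(path)})
        return tx, rx
    if "volts" in df.columns:
        return WaveformRecord(df["volts"].to_numpy(float), fs, t0=t[0],
                              meta={"source": str(path)})
    raise SchemaError(f"{path}: expected 'volts' or 'tx_volts'/'rx_volts'")


def write_waveform_csv(
    path: str | Path,
    tx: WaveformRecord,
    rx: WaveformRecord | None = None,
) -> None:
    if rx is None:
        df = pd.DataFrame({"time_s": tx.times, "volts": tx.samples})
    else:
        if rx.fs != tx.fs or rx.n != tx.n:
            raise SchemaError("Tx and Rx must share fs and length")
        df = pd.DataFrame(
            {"time_s": tx.times, "tx_volts": tx.samples, "rx_volts": rx.samples}
        )
    df.to_csv(path, index=False)


def read_rheometer_sweep(path: str | Path) -> pd.DataFrame:
    """Read a rheometer frequency sweep (CSV or spreadsheet), SI-normalized.

    Column units must be explicit in the header (``_pa`` or ``_kpa``);
    an unsuffixed modulus column is refused rather than guessed.
    Frequencies outside the usual oscillatory-rheometry operating band
    (0.01-100 Hz) raise a warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        try:
            df = pd.read_csv(path)
        except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
            raise SchemaError(f"{path}: {exc}") from exc
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    if "frequency_hz" not in df.columns:
        raise SchemaError(f"{path}: missing 'frequency_hz' column")
    out = {"frequency_hz": df["frequency_hz"].to_numpy(float)}
    for kind in ("storage", "loss"):
        pa, kpa = f"g_{kind}_pa", f"g_{kind}_kpa"
        if pa in df.columns:
            out[pa] = df[pa].to_numpy(float)
        elif kpa in df.columns:
            out[pa] = df[kpa].to_numpy(float) * 1e3
        else:
            ambiguous = [c for c in df.columns if kind in c]
            raise SchemaError(
                f"{path}: need '{pa}' or '{kpa}' column; "
                f"unit-ambiguous candidates: {ambiguous or 'none'}"
            )
    f = out["frequency_hz"]
    if np.any((f < _RHEOMETER_BAND[0]) | (f > _RHEOMETER_BAND[1])):
        warnings.warn(
            "frequencies outside the 0.01-100 Hz rheometer operating band",
            RuntimeWarning,
        )
    return pd.DataFrame(out)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_report(results: dict, path: str | Path | None = None) -> str:
    """Render results as JSON-lines (one object per named result).

    ``results`` maps names to TOFResult / FitResult / ProjectionReport /
    bias-check rows / plain dicts.  Field order is deterministic.
    Returns the serialized text; writes it to ``path`` when given.
    """
    lines = []
    for name in results:
        payload = _jsonable(results[name])
        if isinstance(payload, dict):
            body = {"result": name, **payload}
        else:
            body = {"result": name, "value": payload}
        lines.append(json.dumps(body, sort_keys=False))
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text


def fit_result_summary(fit: FitResult) -> dict:
    """Human-oriented summary of a fit in reporting units (kPa, kPa*s^a)."""
    p = fit.params
    return {
        "e0_kpa": p.E0 / 1e3,
        "eta_kpa_s_alpha": p.eta / 1e3,
        "alpha": p.alpha,
        "fixed": sorted(fit.fixed),
        "r_squared": fit.r_squared,
        "rmse_mps": fit.rmse,
        "converged": fit.converged,
    }


def tof_result_summary(res: TOFResult) -> dict:
    return {
        "onset_tx": res.onset_tx,
        "onset_rx": res.onset_rx,
        "tof_ms": res.tof * 1e3,
        "distance_m": res.distance_D,
        "velocity_mps": res.velocity,
        "farfield_ok": res.farfield_ok,
        "snr_db": res.snr_db,
    }
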
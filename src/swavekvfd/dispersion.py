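"""Dispersion-curve assembly and KVFD inversion.

A dispersion curve is the set of mean shear-wave speeds (with replicate
spread) at the excitation frequencies.  The inversion minimizes a
weighted least-squares misfit between the loss-aware KVFD phase-velocity
forward model and the measured means, with physical bounds
(E0 > 0, eta > 0, 0 < alpha < 1), deterministic multi-start over a grid
of fractional orders, and an optional fixed-E0 (constrained) mode used
for the cross-band consistency check against rheometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import FitError, ParameterError, SchemaError
from .kvfd import KVFDParams, phase_velocity, velocity_from_shear_moduli

__all__ = [
    "DispersionCurve",
    "FitResult",
    "build_curve",
    "fit_kvfd",
    "goodness_of_fit",
    "rheometer_to_curve",
]

_ALPHA_BOUNDS = (1e-6, 1.0 - 1e-9)
_E0_BOUNDS = (1e-3, 1e7)
_ETA_BOUNDS = (1e-9, 1e6)
_ALPHA_STARTS = np.round(np.arange(0.1, 0.91, 0.1), 2)


@dataclass(frozen=True)
class DispersionCurve:
    """Frequencies with replicate velocities, means and standard errors.

    Replicates may be ragged (different counts per frequency).  When
    replicates are present the mean and SE (sample std / sqrt(n)) are
    recomputed from them; a single replicate yields an undefined SE
    (NaN), which downstream fitting treats as unit weight.
    """

    frequencies: np.ndarray
    mean_velocity: np.ndarray
    se_velocity: np.ndarray
    replicates: tuple[np.ndarray, ...] | None = None
    label: str = "custom"

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        m = np.asarray(self.mean_velocity, dtype=float)
        s = np.asarray(self.se_velocity, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "mean_velocity", m)
        object.__setattr__(self, "se_velocity", s)
        if f.ndim != 1 or f.size < 1:
            raise SchemaError("frequencies must be a nonempty 1-D array")
        if np.any(np.diff(f) <= 0):
            raise SchemaError("frequencies must be strictly increasing")
        if f.shape != m.shape or f.shape != s.shape:
            raise SchemaError("frequencies, means and SEs must align")
        if np.any(m <= 0):
            raise SchemaError("velocities must be positive")
        if self.replicates is not None and len(self.replicates) != f.size:
            raise SchemaError("one replicate row per frequency required")

    @property
    def n_frequencies(self) -> int:
        return self.frequencies.size

    def to_frame(self) -> pd.DataFrame:
        """Tabular view in the dispersion CSV schema."""
        data: dict = {"frequency_hz": self.frequencies}
        if self.replicates is not None:
            width = max(len(r) for r in self.replicates)
            for j in range(width):
                data[f"v{j + 1}"] = [
                    r[j] if j < len(r) else np.nan for r in self.replicates
                ]
        data["mean"] = self.mean_velocity
        data["se"] = self.se_velocity
        return pd.DataFrame(data)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one KVFD inversion."""

    params: KVFDParams
    fixed: frozenset[str]
    r_squared: float
    rmse: float  # unweighted RMS residual on mean velocities, m/s
    residuals: np.ndarray  # model - data, m/s
    n_starts: int
    converged: bool
    cost: float = field(default=np.nan)  # weighted half-SSR actually minimized


def build_curve(
    replicate_table: pd.DataFrame | Mapping[float, Sequence[float]],
    label: str = "custom",
) -> DispersionCurve:
    """Aggregate replicate velocity measurements into a dispersion curve.

    Accepts a mapping {frequency: [velocities...]} or a DataFrame with a
    ``frequency_hz`` column and replicate columns ``v1, v2, ...``.
    SE = sample standard deviation / sqrt(n); undefined (NaN) for n = 1.
    """
    if isinstance(replicate_table, pd.DataFrame):
        if "frequency_hz" not in replicate_table.columns:
            raise SchemaError("expected a 'frequency_hz' column")
        vcols = [c for c in replicate_table.columns if c.startswith("v")]
        if not vcols:
            raise SchemaError("expected replicate columns v1, v2, ...")
        table = {
            float(row["frequency_hz"]): [
                row[c] for c in vcols if np.isfinite(row[c])
            ]
            for _, row in replicate_table.iterrows()
        }
    else:
        table = {float(f): list(v) for f, v in replicate_table.items()}
    if len(table) < 2:
        raise SchemaError("need at least two frequencies")
    freqs = np.array(sorted(table))
    reps, means, ses = [], [], []
    for f in freqs:
        v = np.asarray(table[f], dtype=float)
        if v.size < 1:
            raise SchemaError(f"no replicates at {f} Hz")
        if np.any(v <= 0):
            raise SchemaError(f"nonpositive velocity at {f} Hz")
        reps.append(v)
        means.append(v.mean())
        if v.size > 1:
            ses.append(v.std(ddof=1) / np.sqrt(v.size))
        else:
            warnings.warn(
                f"single replicate at {f} Hz: SE undefined, unit weight used",
                RuntimeWarning,
            )
            ses.append(np.nan)
    return DispersionCurve(
        frequencies=freqs,
        mean_velocity=np.array(means),
        se_velocity=np.array(ses),
        replicates=tuple(reps),
        label=label,
    )


def _fit_weights(curve: DispersionCurve, weights: str) -> np.ndarray:
    if weights == "unit":
        return np.ones(curve.n_frequencies)
    if weights == "se":
        se = curve.se_velocity
        if np.any(~np.isfinite(se)) or np.any(se <= 0):
            warnings.warn(
                "SE weights unavailable for some frequencies; using unit weights",
                RuntimeWarning,
            )
            return np.ones(curve.n_frequencies)
        return 1.0 / se  # residuals scaled by 1/SE -> cost weighted by 1/SE^2
    raise ParameterError(f"weights must be 'se' or 'unit', got {weights!r}")


def _initial_guesses(curve, rho, nu, fix_e0):
    """Deterministic starting points: E0 from the low-frequency speed,
    eta from the velocity rise across the band, alpha over a grid."""
    kappa = 2.0 * (1.0 + nu)
    c = curve.mean_velocity
    w = 2.0 * np.pi * curve.frequencies
    e0_guess = fix_e0 if fix_e0 is not None else kappa * rho * c[0] ** 2
    guesses = []
    for a0 in _ALPHA_STARTS:
        rise = kappa * rho * max(c[-1] ** 2 - c[0] ** 2, 1e-12)
        dwa = w[-1] ** a0 - w[0] ** a0
        eta0 = rise / (dwa * np.cos(np.pi * a0 / 2.0)) if dwa > 0 else 1.0
        eta0 = float(np.clip(eta0, *_ETA_BOUNDS))
        guesses.append((e0_guess, eta0, a0))
    return guesses


def fit_kvfd(
    curve: DispersionCurve,
    rho: float = 1000.0,
    nu: float = 0.5,
    fix_e0: float | None = None,
    weights: str = "se",
    loss: str = "linear",
    max_nfev: int = 2000,
) -> FitResult:
    """Invert a dispersion curve for (E0, eta, alpha) by bounded WLS.

    Minimizes sum_i w_i^2 (c_model(f_i) - mean_i)^2 with w_i = 1/SE_i
    (``weights='se'``, the default) or unit weights, using trust-region
    reflective least squares started from a deterministic grid of
    fractional orders.  ``fix_e0`` freezes E0 (constrained refit).  The
    reported RMSE is always the *unweighted* RMS residual on mean
    velocities.  Ties in final cost are broken toward the smallest eta.
    """
    n_free = 2 if fix_e0 is not None else 3
    if curve.n_frequencies < n_free:
        raise ParameterError(
            f"{curve.n_frequencies} frequencies cannot constrain {n_free} parameters"
        )
    if fix_e0 is not None and not fix_e0 > 0:
        raise ParameterError("fix_e0 must be > 0 Pa")
    wts = _fit_weights(curve, weights)
    f = curve.frequencies
    data = curve.mean_velocity

    def model(theta):
        if fix_e0 is not None:
            e0, (eta, a) = fix_e0, theta
        else:
            e0, eta, a = theta
        p = KVFDParams(E0=e0, eta=eta, alpha=a, rho=rho, nu=nu)
        return phase_velocity(p, f)

    def residual(theta):
        return wts * (model(theta) - data)

    if fix_e0 is not None:
        lb = [_ETA_BOUNDS[0], _ALPHA_BOUNDS[0]]
        ub = [_ETA_BOUNDS[1], _ALPHA_BOUNDS[1]]
    else:
        lb = [_E0_BOUNDS[0], _ETA_BOUNDS[0], _ALPHA_BOUNDS[0]]
        ub = [_E0_BOUNDS[1], _ETA_BOUNDS[1], _ALPHA_BOUNDS[1]]

    best = None
    n_ok = 0
    for guess in _initial_guesses(curve, rho, nu, fix_e0):
        x0 = np.clip(guess[1:] if fix_e0 is not None else guess, lb, ub)
        try:
            sol = least_squares(
                residual,
                x0,
                bounds=(lb, ub),
                method="trf",
                loss=loss,
                xtol=1e-10,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=max_nfev,
            )
        except (ValueError, FloatingPointError):
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        n_ok += 1
        eta_sol = sol.x[0] if fix_e0 is not None else sol.x[1]
        key = (sol.cost, eta_sol)
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise FitError("no optimizer start converged; inspect the input curve")
    sol = best[1]
    if fix_e0 is not None:
        e0, eta, a = fix_e0, sol.x[0], sol.x[1]
        fixed = frozenset({"E0"})
    else:
        e0, eta, a = sol.x
        fixed = frozenset()
    params = KVFDParams(E0=float(e0), eta=float(eta), alpha=float(a),
                        rho=rho, nu=nu)
    r2, rmse = goodness_of_fit(curve, params)
    resid = phase_velocity(params, f) - data
    return FitResult(
        params=params,
        fixed=fixed,
        r_squared=r2,
        rmse=rmse,
        residuals=resid,
        n_starts=n_ok,
        converged=bool(sol.status > 0),
        cost=float(sol.cost),
    )


def goodness_of_fit(
    curve: DispersionCurve, params: KVFDParams
) -> tuple[float, float]:
    """R^2 = 1 - SS_res/SS_tot and unweighted RMSE on mean velocities."""
    pred = phase_velocity(params, curve.frequencies)
    resid = pred - curve.mean_velocity
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((curve.mean_velocity - curve.mean_velocity.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant mean velocities: R^2 undefined", RuntimeWarning)
        return np.nan, rmse
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return r2, rmse


def rheometer_to_curve(
    sweep: pd.DataFrame, rho: float = 1000.0, label: str = "rheometer"
) -> DispersionCurve:
    """Convert a rheometer (f, G', G'') sweep to a velocity dispersion curve.

    Rows with nonpositive G' are rejected with a warning.  Repeated
    frequencies (replicate sweeps) aggregate like replicate velocities.
    """
    required = {"frequency_hz", "g_storage_pa", "g_loss_pa"}
    missing = required - set(sweep.columns)
    if missing:
        raise SchemaError(f"rheometer sweep missing columns {sorted(missing)}")
    if len(sweep) == 0:
        raise SchemaError("empty rheometer sweep")
    ok = sweep["g_storage_pa"] > 0
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} rows with nonpositive G'", RuntimeWarning
        )
    sweep = sweep[ok]
    if len(sweep) == 0:
        raise SchemaError("no usable rows after G' > 0 filtering")
    table: dict[float, list[float]] = {}
    for _, row in sweep.iterrows():
        v = float(
            velocity_from_shear_moduli(
                row["g_storage_pa"], row["g_loss_pa"], rho
            )
        )
        table.setdefault(float(row["frequency_hz"]), []).append(v)
    if len(table) == 1:
        (f0, vals), = table.items()
        vals = np.asarray(vals, float)
        se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        return DispersionCurve(
            frequencies=np.array([f0]),
            mean_velocity=np.array([vals.mean()]),
            se_velocity=np.array([se]),
            replicates=(vals,),
            label=label,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return build_curve(table, label=label)
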
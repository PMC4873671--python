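"""Monoexponential fits for endocytosis, recycling and degradation assays.

Internalization and degradation time courses are fitted with the decay form
``y = y0 + A * exp(-x / t)``; recycling time courses with the saturating
rise ``y = y0 - A * exp(-x / t)`` where ``y0`` is the plateau approached at
long times.  The half-time is ``t_1/2 = ln(2) * t`` (conventionally quoted
as 69% of the decay constant ``t``).  Confidence intervals are percentile
bootstrap over cells/replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import DomainError, NonConvergenceError, NonIdentifiableError

LN2 = log(2.0)

_UNIT_SECONDS = {"s": 1.0, "sec": 1.0, "min": 60.0, "h": 3600.0, "hr": 3600.0}


def _unit_factor(unit: str) -> float:
    try:
        return _UNIT_SECONDS[unit.lower()]
    except (KeyError, AttributeError):
        raise DomainError(f"unknown time unit {unit!r}; use one of {sorted(_UNIT_SECONDS)}") from None


@dataclass(frozen=True)
class KineticsSeries:
    """A kinetics time course: time (in ``time_unit``), value, replicate id."""

    frame: pd.DataFrame
    time_unit: str = "min"

    def __post_init__(self):
        df = self.frame.copy()
        required = {"time", "value"}
        if not required <= set(df.columns):
            raise DomainError(f"series needs columns {sorted(required)}")
        if "replicate" not in df.columns:
            df["replicate"] = 0
        df["time"] = df["time"].astype(float)
        df["value"] = df["value"].astype(float)
        if (df["time"] < 0).any():
            raise DomainError("times must be >= 0")
        if not np.isfinite(df["value"]).all():
            raise DomainError("values must be finite")
        _unit_factor(self.time_unit)
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @property
    def x(self) -> np.ndarray:
        return self.frame["time"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.frame["value"].to_numpy()


@dataclass(frozen=True)
class MonoexponentialFit:
    """Fitted offset/plateau ``y0``, amplitude ``A`` and decay constant ``t``.

    For the decay direction the curve tends to ``y0`` from above/below as
    ``x -> inf``; for the rise direction ``y0`` is the plateau and the curve
    starts at ``y0 - A``.
    """

    y0: float
    A: float
    t: float
    direction: str
    time_unit: str
    sse: float
    n_points: int

    def __post_init__(self):
        if self.direction not in ("decay", "rise"):
            raise DomainError("direction must be 'decay' or 'rise'")
        if not np.isfinite(self.t) or self.t <= 0:
            raise DomainError(f"decay constant must be > 0, got {self.t!r}")

    @property
    def t_half(self) -> float:
        return LN2 * self.t

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.direction == "decay":
            return self.y0 + self.A * np.exp(-x / self.t)
        return self.y0 - self.A * np.exp(-x / self.t)


def _curve(direction: str):
    if direction == "decay":
        return lambda x, y0, A, t: y0 + A * np.exp(-x / t)
    return lambda x, y0, A, t: y0 - A * np.exp(-x / t)


def fit_monoexp(series: KineticsSeries, direction: str = "decay") -> MonoexponentialFit:
    """Nonlinear least-squares monoexponential fit.

    Requires >= 4 distinct timepoints; a flat series or a fit driving the
    decay constant non-positive is rejected as non-identifiable.
    """
    if direction not in ("decay", "rise"):
        raise DomainError("direction must be 'decay' or 'rise'")
    x, y = series.x, series.y
    if np.unique(x).size < 4:
        raise DomainError("need >= 4 distinct timepoints")
    if np.ptp(y) == 0:
        raise NonIdentifiableError("series is constant: amplitude and t not identifiable")
    span = max(np.ptp(x), np.finfo(float).tiny)
    if direction == "decay":
        p0 = (float(y[np.argmax(x)]), float(y[np.argmin(x)] - y[np.argmax(x)]), span / 3)
    else:
        p0 = (float(y[np.argmax(x)]), float(y[np.argmax(x)] - y[np.argmin(x)]), span / 3)
    try:
        popt, _ = curve_fit(
            _curve(direction), x, y, p0=p0,
            bounds=([-np.inf, -np.inf, np.finfo(float).tiny], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise NonConvergenceError(f"monoexponential fit failed: {exc}") from exc
    y0, A, t = (float(v) for v in popt)
    if t <= 0 or not np.isfinite(t):
        raise NonIdentifiableError(f"fitted decay constant {t!r} is not positive")
    resid = y - _curve(direction)(x, y0, A, t)
    return MonoexponentialFit(
        y0=y0, A=A, t=t, direction=direction, time_unit=series.time_unit,
        sse=float(resid @ resid), n_points=int(x.size),
    )


def half_time(fit: MonoexponentialFit) -> float:
    """Half-time ln(2) * t, in the fit's time unit."""
    return fit.t_half


def fit_ci95(
    series: KineticsSeries,
    direction: str = "decay",
    n_boot: int = 2000,
    seed: int | None = None,
    max_failure_frac: float = 0.2,
) -> dict[str, tuple[float, float]]:
    """Percentile-bootstrap CI95 for t, t_half and the plateau/offset y0.

    Resamples replicates (cells) with replacement when at least two are
    present, else resamples individual points (requiring >= 8).  More than
    20% failed bootstrap refits raise with diagnostics.
    """
    df = series.frame
    reps = df["replicate"].unique()
    by_replicate = reps.size >= 2
    if not by_replicate and len(df) < 8:
        raise DomainError("need >= 2 replicates or >= 8 points for the bootstrap")
    rng = np.random.default_rng(seed)
    stats = {"t": [], "t_half": [], "y0": []}
    failures = 0
    for _ in range(n_boot):
        if by_replicate:
            chosen = rng.choice(reps, size=reps.size, replace=True)
            sub = pd.concat([df[df["replicate"] == r] for r in chosen], ignore_index=True)
        else:
            sub = df.sample(n=len(df), replace=True, random_state=rng.integers(2**31))
        try:
            f = fit_monoexp(KineticsSeries(sub, series.time_unit), direction)
        except (NonConvergenceError, NonIdentifiableError, DomainError):
            failures += 1
            continue
        stats["t"].append(f.t)
        stats["t_half"].append(f.t_half)
        stats["y0"].append(f.y0)
    if failures > max_failure_frac * n_boot:
        raise NonConvergenceError(
            f"{failures}/{n_boot} bootstrap refits failed", best=stats
        )
    return {
        k: tuple(float(v) for v in np.percentile(vals, [2.5, 97.5]))
        for k, vals in stats.items()
    }


def degradation_normalize(
    band_table: pd.DataFrame,
    time_col: str = "time",
    target_col: str = "target",
    control_col: str = "control",
    time_unit: str = "h",
) -> KineticsSeries:
    """Loading-control-normalised degradation series.

    Per timepoint the target/control intensity ratio is divided by the same
    ratio at time 0, so the series starts at 1 by construction.
    """
    df = band_table.copy()
    for col in (time_col, target_col, control_col):
        if col not in df.columns:
            raise DomainError(f"band table missing column {col!r}")
    if (df[control_col] <= 0).any():
        raise DomainError("control intensities must be > 0")
    t0 = df[df[time_col] == 0]
    if t0.empty:
        raise DomainError("band table must contain a time-0 row")
    ratio = df[target_col] / df[control_col]
    ref = float((t0[target_col] / t0[control_col]).mean())
    if ref == 0:
        raise DomainError("time-0 target intensity is zero")
    out = pd.DataFrame({"time": df[time_col].astype(float), "value": ratio / ref})
    if "replicate" in df.columns:
        out["replicate"] = df["replicate"].to_numpy()
    return KineticsSeries(out, time_unit=time_unit)


def half_time_ratio(
    t_half_a: float, t_half_b: float, unit_a: str, unit_b: str
) -> float:
    """Dimensionless ratio a/b after converting both half-times to seconds."""
    if t_half_a <= 0 or t_half_b <= 0:
        raise DomainError("half-times must be > 0")
    return (t_half_a * _unit_factor(unit_a)) / (t_half_b * _unit_factor(unit_b))
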
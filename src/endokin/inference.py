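"""Three-stage least-squares fitting of the compartment model and MCMC
uncertainty quantification.

The goodness of fit for a coefficient vector K is the sum of squared
residuals between replicate-averaged pixel densities p(i, l) and the model
prediction x(i, l), summed over the three endosomal compartments
(i = 1, 2, 3) and all time points l:

    E(K) = sum_{i=1..3} sum_l ( p(i, l) - x(i, l) )^2

Fitting proceeds in three stages: (1) an empirically chosen seed K0;
(2) an exhaustive geometric grid of ``n_values`` points per coefficient
spanning two decades either side of K0 (10^6 points at the default 10),
returning the grid minimiser K1; (3) steepest descent on E from K1 over the
four sequential coefficients, with the two short-circuit coefficients held
at their K1 values — descent over all six drives the short circuits
negative, so the restricted default is the meaningful one.

Uncertainty in the four sequential coefficients is quantified with an
adaptive Metropolis chain (Gaussian proposals, covariance adapted during
burn-in from the running chain and frozen afterwards) targeting the
likelihood of i.i.d. Gaussian residuals whose variance is estimated from the
fit optimum.  Credible intervals are 2.5/97.5 posterior percentiles and the
predictive envelope is the pointwise 95% band of trajectories simulated from
posterior draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, NonConvergenceError
from .model import (
    CompartmentTrajectory,
    ModelConfig,
    RateCoefficientSet,
    compartment_index,
    simulate,
    transfer_matrix_from_rows,
)

SEQUENTIAL = ("k01", "k12", "k23", "k30")
SHORT_CIRCUIT = ("k10", "k20")


@dataclass(frozen=True)
class TimeCourseObservations:
    """Replicate-resolved colocalization time courses.

    Wraps a tidy table with columns ``compartment`` (1, 2, 3 or an accepted
    alias), ``time_s``, ``value`` (pixel density) and ``replicate``.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame.copy()
        required = {"compartment", "time_s", "value", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise DomainError(f"observations missing columns: {sorted(missing)}")
        df["compartment"] = df["compartment"].map(compartment_index)
        if not set(df["compartment"].unique()) <= {1, 2, 3}:
            raise DomainError("observed compartments must be in {1, 2, 3}")
        df["time_s"] = df["time_s"].astype(float)
        df["value"] = df["value"].astype(float)
        if (df["time_s"] < 0).any():
            raise DomainError("observation times must be >= 0")
        if (df["value"] < 0).any() or not np.isfinite(df["value"]).all():
            raise DomainError("observed densities must be finite and >= 0")
        counts = df.groupby("compartment")["time_s"].nunique()
        if (counts < 2).any():
            raise DomainError("need >= 2 timepoints per observed compartment")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def averaged(self) -> pd.DataFrame:
        """Replicate means per (compartment, time): columns compartment, time_s, value."""
        return (
            self.frame.groupby(["compartment", "time_s"], as_index=False)["value"]
            .mean()
            .sort_values(["compartment", "time_s"], ignore_index=True)
        )

    def times(self) -> np.ndarray:
        return np.unique(self.frame["time_s"].to_numpy())

    def dense_average(self) -> tuple[np.ndarray, np.ndarray]:
        """(times (L,), p (3, L)) with NaN where a compartment was not observed."""
        avg = self.averaged()
        t = self.times()
        p = np.full((3, t.size), np.nan)
        pos = {v: i for i, v in enumerate(t)}
        for comp, time_s, value in avg.itertuples(index=False):
            p[comp - 1, pos[time_s]] = value
        return t, p


@dataclass(frozen=True)
class GridSearchResult:
    K1: RateCoefficientSet
    E1: float
    n_values: int
    n_evaluated: int
    n_excluded: int


@dataclass(frozen=True)
class DescentResult:
    K_fit: RateCoefficientSet
    E_fit: float
    n_iter: int
    grad_norm: float
    converged: bool
    free: tuple[str, ...]


@dataclass(frozen=True)
class FitResult:
    """Coefficients and error at each stage of the three-step fit."""

    K0: RateCoefficientSet
    K1: RateCoefficientSet
    K_fit: RateCoefficientSet
    E0: float
    E1: float
    E_fit: float
    grid: GridSearchResult
    descent: DescentResult

    def __post_init__(self):
        if not (self.E_fit <= self.E1 + 1e-15 and self.E1 <= self.E0 + 1e-15):
            raise DomainError("stage errors must be non-increasing")


@dataclass(frozen=True)
class PosteriorEnsemble:
    """Post-burn-in MCMC samples over the free (sequential) coefficients."""

    samples: np.ndarray          # (n_kept, n_free)
    param_names: tuple[str, ...]
    K_ref: RateCoefficientSet    # carries the fixed short-circuit values
    acceptance_rate: float
    n_iter: int
    burn_in: int
    sigma2: float
    seed: int | None = None

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != len(self.param_names):
            raise DomainError("samples must be (n, n_params)")
        if np.any(s < 0):
            raise DomainError("posterior samples must be non-negative")
        object.__setattr__(self, "samples", s)

    def rate_sets(self, indices=None):
        """Materialise posterior draws as RateCoefficientSet objects."""
        idx = range(self.samples.shape[0]) if indices is None else indices
        out = []
        for i in idx:
            out.append(
                self.K_ref.replace(**dict(zip(self.param_names, self.samples[i])))
            )
        return out


def _predict_dense(K: RateCoefficientSet, times: np.ndarray, cfg: ModelConfig):
    """Model predictions x(i, t) for i = 1..3 at the given observation times."""
    if times[0] == 0.0:
        grid = times
        traj = simulate(K, cfg, grid)
        return traj.x[:, 1:4].T
    grid = np.concatenate([[0.0], times])
    traj = simulate(K, cfg, grid)
    return traj.x[1:, 1:4].T


class _ErrorFunction:
    """E(K) with the observation table reduced once up front.

    The per-call cost is one matrix exponential per distinct time step plus
    a handful of 4-vector products, which keeps descent and MCMC cheap."""

    def __init__(self, obs: "TimeCourseObservations", cfg: ModelConfig):
        self.times, self.p = obs.dense_average()
        self.has_t0 = self.times[0] == 0.0
        self.sim_times = (
            self.times if self.has_t0 else np.concatenate([[0.0], self.times])
        )
        self.dts = np.diff(self.sim_times)
        self.keys = np.round(self.dts, 12)
        self.x0 = cfg.x0()
        self.n_obs = int(np.isfinite(self.p).sum())

    def predict(self, k6: np.ndarray) -> np.ndarray:
        from scipy.linalg import expm

        A = transfer_matrix_from_rows(k6)
        cache: dict[float, np.ndarray] = {}
        X = np.empty((self.sim_times.size, 4))
        X[0] = self.x0
        for i, key in enumerate(self.keys):
            P = cache.get(key)
            if P is None:
                P = expm(A * self.dts[i])
                cache[key] = P
            X[i + 1] = P @ X[i]
        x = X[:, 1:4].T if self.has_t0 else X[1:, 1:4].T
        return x

    def __call__(self, k6: np.ndarray) -> float:
        resid = self.p - self.predict(np.asarray(k6, dtype=float))
        return float(np.nansum(resid * resid))


def error(
    K: RateCoefficientSet,
    obs: TimeCourseObservations,
    cfg: ModelConfig | None = None,
    traj: CompartmentTrajectory | None = None,
) -> float:
    """Sum-of-squares error E(K) against replicate-averaged observations.

    With no trajectory supplied the model is solved exactly at the
    observation times.  A supplied trajectory is linearly interpolated to the
    observation times; observation times beyond its last time raise.
    """
    cfg = cfg or ModelConfig()
    t, p = obs.dense_average()
    if traj is None:
        return _ErrorFunction(obs, cfg)(K.as_array())
    if t.max() > traj.times.max():
        raise DomainError(
            "observation time beyond the supplied trajectory: extrapolation refused"
        )
    x = np.vstack([np.interp(t, traj.times, traj.x[:, i]) for i in (1, 2, 3)])
    resid = p - x
    return float(np.nansum(resid * resid))


# ---------------------------------------------------------------------------
# Stage 2: exhaustive geometric grid
# ---------------------------------------------------------------------------

def grid_axes(K0: RateCoefficientSet, n_values: int) -> list[np.ndarray]:
    """Per-coefficient geometric grids spanning [K0/100, 100*K0]."""
    k0 = K0.as_array()
    if np.any(k0 <= 0):
        raise DomainError("grid search requires a strictly positive K0")
    if n_values < 1:
        raise DomainError("n_values must be >= 1")
    if n_values == 1:
        return [np.array([v]) for v in k0]
    return [v * np.logspace(-2.0, 2.0, n_values) for v in k0]


def _batch_error(
    Ks: np.ndarray, times: np.ndarray, p: np.ndarray, x0: np.ndarray
) -> np.ndarray:
    """Vectorised E for a (N, 6) block of coefficient vectors.

    Uses a batched eigendecomposition of the transfer matrices; rows whose
    eigenvector matrix is near-singular (defective) or whose result is
    non-finite fall back to the exact matrix-exponential path.
    """
    A = transfer_matrix_from_rows(Ks)
    lam, V = np.linalg.eig(A)
    with np.errstate(all="ignore"):
        detV = np.linalg.det(V)
        bad = ~np.isfinite(detV) | (np.abs(detV) < 1e-10)
        c = np.linalg.solve(
            np.where(bad[:, None, None], np.eye(4), V), np.repeat(x0[None], len(Ks), 0)[..., None]
        )[..., 0]
        # x[n, i, l] = sum_j V[n, i, j] c[n, j] exp(lam[n, j] * t[l])
        phases = np.exp(lam[:, None, :] * times[None, :, None])       # (N, L, 4)
        X = np.einsum("nij,nlj->nil", V, c[:, None, :] * phases).real  # (N, 4, L)
        resid = X[:, 1:4, :] - p[None]
        E = np.nansum(resid * resid, axis=(1, 2))
    nonfinite = ~np.isfinite(E)
    for idx in np.flatnonzero(bad | nonfinite):
        E[idx] = _expm_row_error(Ks[idx], times, p, x0)
    return E


def _expm_row_error(row, times, p, x0) -> float:
    K = RateCoefficientSet.from_array(row)
    cfg = ModelConfig(x_T=float(x0.sum()), initial_state=tuple(x0))
    resid = p - _predict_dense(K, times, cfg)
    return float(np.nansum(resid * resid))


def grid_search(
    K0: RateCoefficientSet,
    obs: TimeCourseObservations,
    cfg: ModelConfig | None = None,
    n_values: int = 10,
    chunk: int = 20000,
) -> GridSearchResult:
    """Evaluate E on the full Cartesian grid and return the minimiser K1.

    The grid is enumerated odometer-style over the coefficients in
    ``RateCoefficientSet.ORDER`` (last coefficient fastest); ties on E are
    broken by first occurrence in that order.  Non-finite E values are
    excluded and counted.
    """
    cfg = cfg or ModelConfig()
    axes = grid_axes(K0, n_values)
    times, p = obs.dense_average()
    x0 = cfg.x0()
    shape = tuple(len(a) for a in axes)
    total = int(np.prod(shape))
    best_E = np.inf
    best_idx = -1
    n_excluded = 0
    sim_times = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    p_dense = p
    for start in range(0, total, chunk):
        stop = min(start + chunk, total)
        flat = np.arange(start, stop)
        multi = np.unravel_index(flat, shape)
        Ks = np.stack([axes[d][multi[d]] for d in range(6)], axis=1)
        if sim_times is times:
            E = _batch_error(Ks, times, p_dense, x0)
        else:
            E = _batch_error(Ks, sim_times, _pad_nan(p_dense), x0)
        finite = np.isfinite(E)
        n_excluded += int((~finite).sum())
        if finite.any():
            E_masked = np.where(finite, E, np.inf)
            j = int(np.argmin(E_masked))
            if E_masked[j] < best_E:
                best_E = float(E_masked[j])
                best_idx = start + j
    if best_idx < 0:
        raise NonConvergenceError("all grid points produced non-finite error")
    multi = np.unravel_index(best_idx, shape)
    K1 = RateCoefficientSet.from_array([axes[d][multi[d]] for d in range(6)])
    # report the scalar-path value for exactness downstream
    E1 = error(K1, obs, cfg)
    # geometric grids with few values need not contain the seed itself; keep
    # the seed as a fallback candidate so staged errors stay monotone
    E_seed = error(K0, obs, cfg)
    if E_seed < E1:
        K1, E1 = K0, E_seed
    return GridSearchResult(
        K1=K1, E1=E1, n_values=n_values, n_evaluated=total - n_excluded,
        n_excluded=n_excluded,
    )


def _pad_nan(p: np.ndarray) -> np.ndarray:
    """Prepend a NaN column (the t=0 simulation point carries no data)."""
    return np.concatenate([np.full((3, 1), np.nan), p], axis=1)


# ---------------------------------------------------------------------------
# Stage 3: steepest descent
# ---------------------------------------------------------------------------

def steepest_descent(
    K1: RateCoefficientSet,
    obs: TimeCourseObservations,
    cfg: ModelConfig | None = None,
    free: tuple[str, ...] = SEQUENTIAL,
    max_iter: int = 1000,
    e_tol: float = 1e-10,
    g_tol: float = 1e-12,
    fd_step: float = 1e-5,
) -> DescentResult:
    """Minimise E by steepest descent over the free coefficients.

    The search runs in log-coefficient space (which also enforces
    positivity), with central finite-difference gradients and a backtracking
    line search that may also grow the step after an easy acceptance.
    Coefficients outside ``free`` are held at their K1 values.
    """
    cfg = cfg or ModelConfig()
    if not free:
        raise DomainError("free coefficient set must be non-empty")
    names = RateCoefficientSet.ORDER
    for f in free:
        if f not in names:
            raise DomainError(f"unknown coefficient {f!r}")
    k = K1.as_array()
    idx = [names.index(f) for f in free]
    if np.any(k[idx] <= 0):
        raise DomainError("free coefficients must be strictly positive at the start")
    E_fn = _ErrorFunction(obs, cfg)

    def E_of(u):
        kk = k.copy()
        kk[idx] = np.exp(u)
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                return E_fn(kk)
        except (FloatingPointError, OverflowError, ValueError):
            return np.inf

    u = np.log(k[idx])
    E = E_of(u)
    alpha = 1.0
    gnorm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        g = np.empty(len(idx))
        for j in range(len(idx)):
            up, um = u.copy(), u.copy()
            up[j] += fd_step
            um[j] -= fd_step
            g[j] = (E_of(up) - E_of(um)) / (2 * fd_step)
        gnorm = float(np.linalg.norm(g))
        if gnorm < g_tol:
            break
        d = -g / max(gnorm, 1e-300)
        accepted = False
        a = alpha
        for _ in range(60):
            E_new = E_of(u + a * d)
            if not np.isfinite(E_new):
                a *= 0.5  # step halved on non-finite error
                continue
            if E_new < E - 1e-4 * a * gnorm:
                u = u + a * d
                improved = E - E_new
                E = E_new
                alpha = min(a * 2.0, 1e3)
                accepted = True
                break
            a *= 0.5
        if not accepted:
            break
        if improved < e_tol * max(1.0, E):
            break
    k_fit = k.copy()
    k_fit[idx] = np.exp(u)
    K_fit = RateCoefficientSet.from_array(np.maximum(k_fit, 0.0))
    return DescentResult(
        K_fit=K_fit, E_fit=float(E), n_iter=int(it), grad_norm=float(gnorm),
        converged=bool(np.isfinite(E)), free=tuple(free),
    )


def fit_pipeline(
    K0: RateCoefficientSet,
    obs: TimeCourseObservations,
    cfg: ModelConfig | None = None,
    n_values: int = 10,
    free: tuple[str, ...] = SEQUENTIAL,
    max_iter: int = 1000,
) -> FitResult:
    """The full three-stage fit: empirical seed -> grid -> steepest descent."""
    cfg = cfg or ModelConfig()
    E0 = error(K0, obs, cfg)
    grid = grid_search(K0, obs, cfg, n_values=n_values)
    descent = steepest_descent(grid.K1, obs, cfg, free=free, max_iter=max_iter)
    return FitResult(
        K0=K0, K1=grid.K1, K_fit=descent.K_fit,
        E0=E0, E1=grid.E1, E_fit=descent.E_fit,
        grid=grid, descent=descent,
    )


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

def _fd_hessian(f, x0, rel_step=1e-3):
    n = x0.size
    h = rel_step * np.maximum(np.abs(x0), 1e-12)
    H = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            xpp = x0.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x0.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x0.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x0.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H, f0


def run_mcmc(
    fit: FitResult,
    obs: TimeCourseObservations,
    cfg: ModelConfig | None = None,
    n_iter: int = 10000,
    seed: int | None = None,
    burn_frac: float = 0.1,
    free: tuple[str, ...] | None = None,
    proposal_cov: np.ndarray | None = None,
    proposal_scale: float | None = None,
    adapt_every: int = 200,
) -> PosteriorEnsemble:
    """Adaptive Metropolis chain over the free coefficients.

    The target is the Gaussian-residual likelihood with variance estimated
    from the fit optimum (``sigma^2 = E_fit / (n_obs - n_free)``) under a
    flat non-negative prior.  The proposal covariance starts from a
    finite-difference curvature estimate at K_fit, is adapted from the
    running chain every ``adapt_every`` steps during burn-in, and is frozen
    afterwards.  ``proposal_scale=0`` freezes the chain at K_fit (degenerate
    but well-defined).
    """
    cfg = cfg or ModelConfig()
    free = tuple(free) if free is not None else fit.descent.free
    names = RateCoefficientSet.ORDER
    idx = [names.index(f) for f in free]
    d = len(idx)
    k_ref = fit.K_fit.as_array()
    E_fn = _ErrorFunction(obs, cfg)
    n_obs = E_fn.n_obs
    sigma2 = fit.E_fit / max(n_obs - d, 1)
    if sigma2 <= 0:
        sigma2 = max(fit.E_fit, 1e-12) / max(n_obs, 1)

    def E_of(theta):
        kk = k_ref.copy()
        kk[idx] = theta
        return E_fn(kk)

    def logpost(theta):
        if np.any(theta < 0):
            return -np.inf
        with np.errstate(over="ignore", invalid="ignore"):
            E = E_of(theta)
        return -E / (2 * sigma2) if np.isfinite(E) else -np.inf

    theta0 = k_ref[idx].astype(float)
    if proposal_cov is not None:
        cov = np.asarray(proposal_cov, dtype=float)
    elif proposal_scale is not None:
        cov = np.diag((proposal_scale * np.maximum(theta0, 1e-12)) ** 2)
    else:
        H, _ = _fd_hessian(E_of, theta0)
        try:
            cov_lap = 2 * sigma2 * np.linalg.inv(H)
            if not np.all(np.linalg.eigvalsh((cov_lap + cov_lap.T) / 2) > 0):
                raise np.linalg.LinAlgError
            cov = (2.38**2 / d) * (cov_lap + cov_lap.T) / 2
        except np.linalg.LinAlgError:
            cov = np.diag((0.05 * np.maximum(theta0, 1e-12)) ** 2)

    rng = np.random.default_rng(seed)
    burn = int(round(burn_frac * n_iter))
    chain = np.empty((n_iter, d))
    theta = theta0.copy()
    lp = logpost(theta)
    n_accept = 0
    L = _chol_safe(cov, theta0)
    for step in range(n_iter):
        prop = theta + L @ rng.standard_normal(d)
        lp_prop = logpost(prop)
        if np.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            n_accept += 1
        chain[step] = theta
        if step < burn and step > 0 and step % adapt_every == 0 and proposal_scale is None:
            emp = np.cov(chain[: step + 1].T)
            emp = np.atleast_2d(emp) + 1e-12 * np.eye(d) * max(1.0, np.trace(np.atleast_2d(emp)))
            L = _chol_safe((2.38**2 / d) * emp, theta0)
    rate = n_accept / n_iter
    if not (0.05 <= rate <= 0.8) and proposal_scale != 0:
        warnings.warn(
            f"MCMC acceptance rate {rate:.3f} outside [0.05, 0.8]", RuntimeWarning,
            stacklevel=2,
        )
    return PosteriorEnsemble(
        samples=chain[burn:], param_names=free, K_ref=fit.K_fit,
        acceptance_rate=rate, n_iter=n_iter, burn_in=burn, sigma2=sigma2,
        seed=seed,
    )


def _chol_safe(cov: np.ndarray, scale_ref: np.ndarray) -> np.ndarray:
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if np.allclose(cov, 0):
        return np.zeros_like(cov)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        d = cov.shape[0]
        return np.diag(0.05 * np.maximum(np.abs(scale_ref), 1e-12))


def credible_intervals(ens: PosteriorEnsemble) -> dict[str, tuple[float, float]]:
    """Per-parameter 95% credible intervals (2.5th and 97.5th percentiles)."""
    if ens.samples.shape[0] < 100:
        raise DomainError("need >= 100 post-burn-in samples for CI95")
    lo, hi = np.percentile(ens.samples, [2.5, 97.5], axis=0)
    return {
        name: (float(l), float(h))
        for name, l, h in zip(ens.param_names, lo, hi)
    }


@dataclass(frozen=True)
class PredictiveEnvelope:
    """Pointwise 95% band of model outputs over posterior draws."""

    times: np.ndarray
    lower: np.ndarray   # (4, n_times)
    upper: np.ndarray
    n_draws: int

    def band(self, label):
        i = compartment_index(label)
        return self.lower[i], self.upper[i]

    def to_frame(self) -> pd.DataFrame:
        from .model import COMPARTMENTS

        rows = []
        for i, name in enumerate(COMPARTMENTS):
            rows.append(pd.DataFrame({
                "time_s": self.times, "compartment": name,
                "lower": self.lower[i], "upper": self.upper[i],
            }))
        return pd.concat(rows, ignore_index=True)


def predictive_envelope(
    ens: PosteriorEnsemble,
    cfg: ModelConfig | None = None,
    t_grid=None,
    n_draws: int = 400,
) -> PredictiveEnvelope:
    """Simulate the model for (sub-sampled) posterior draws and take the
    pointwise 2.5/97.5 percentiles per compartment.

    Draws are sub-sampled deterministically (evenly spaced through the kept
    chain) so the envelope is reproducible without extra randomness.
    """
    cfg = cfg or ModelConfig()
    t = np.asarray(
        t_grid if t_grid is not None else np.arange(0.0, 2701.0, 60.0), dtype=float
    )
    n = ens.samples.shape[0]
    if n == 0:
        raise DomainError("empty posterior ensemble")
    take = np.unique(np.linspace(0, n - 1, min(n_draws, n)).round().astype(int))
    trajs = np.empty((take.size, 4, t.size))
    for j, K in enumerate(ens.rate_sets(take)):
        trajs[j] = simulate(K, cfg, t).x.T
    lower, upper = np.percentile(trajs, [2.5, 97.5], axis=0)
    return PredictiveEnvelope(times=t, lower=lower, upper=upper, n_draws=take.size)
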
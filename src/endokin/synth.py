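"""Synthetic-data generators with known ground truth.

These emulate the statistical structure of the imaging assays the analysis
modules consume: three colocalization time courses (SE^Rab4, RE_TfR,
RE_Rab11 vs internalized receptor) sampled every 60 s over a 45-min movie
with six replicate movies and additive truncated-Gaussian noise;
monoexponential internalization/recycling/degradation curves per cell; and
binary mask pairs with exact pixel counts.  Every generator returns its
ground truth alongside the data and draws all randomness from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coloc import ChannelMaskPair
from .exceptions import DomainError
from .inference import TimeCourseObservations
from .kinetics import KineticsSeries, _curve
from .model import CompartmentTrajectory, ModelConfig, RateCoefficientSet, simulate

#: Default ground-truth coefficients (s^-1).  The sequential exit scales are
#: exactly 1/622, 1/353 and 1/132 s^-1, so the steady-state residence times
#: of the three endosomal stations are 622, 353 and 132 s; the short
#: circuits are small (1e-4 s^-1) and k01 is set so that ~19% of the pool
#: sits at the PM at steady state, the regime seen in surface assays.
DEFAULT_K_TRUE = RateCoefficientSet(
    k01=0.003975,
    k12=1 / 622 - 1e-4,
    k23=1 / 353 - 1e-4,
    k30=1 / 132,
    k10=1e-4,
    k20=1e-4,
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Study-design parameters for the synthetic colocalization assay."""

    K_true: RateCoefficientSet = DEFAULT_K_TRUE
    x_T: float = 2.0
    times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 2701.0, 60.0))
    n_replicates: int = 6
    noise_sd: float = 0.05   # 2.5% of the default x_T = 2.0
    seed: int | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)

    def config(self) -> ModelConfig:
        return ModelConfig(x_T=self.x_T)


def gen_timecourse(
    spec: GeneratorSpec,
) -> tuple[TimeCourseObservations, dict]:
    """Noisy replicate time courses plus the exact noiseless trajectory.

    All labelled receptor starts at the PM; independent Gaussian noise
    (sd = ``spec.noise_sd``) is added per replicate and timepoint and
    truncated at zero, since pixel densities cannot be negative.
    """
    rng = np.random.default_rng(spec.seed)
    traj = simulate(spec.K_true, spec.config(), spec.times)
    rows = []
    for comp in (1, 2, 3):
        clean = traj.x[:, comp]
        for rep in range(spec.n_replicates):
            noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.size)
            np.clip(noisy, 0.0, None, out=noisy)
            rows.append(
                pd.DataFrame(
                    {
                        "compartment": comp,
                        "time_s": spec.times,
                        "value": noisy,
                        "replicate": rep,
                    }
                )
            )
    obs = TimeCourseObservations(pd.concat(rows, ignore_index=True))
    truth = {
        "K_true": spec.K_true,
        "x_T": spec.x_T,
        "trajectory": traj,
        "noise_sd": spec.noise_sd,
        "n_replicates": spec.n_replicates,
        "seed": spec.seed,
    }
    return obs, truth


def gen_monoexp(
    y0: float,
    A: float,
    t: float,
    direction: str = "decay",
    timepoints=None,
    n_cells: int = 10,
    noise_sd: float = 0.0,
    seed: int | None = None,
    time_unit: str = "min",
) -> tuple[KineticsSeries, dict]:
    """Per-cell noisy monoexponential curves plus the generating parameters."""
    if t <= 0:
        raise DomainError("decay constant t must be > 0")
    x = np.asarray(
        timepoints if timepoints is not None else np.linspace(0.0, 5 * t, 12),
        dtype=float,
    )
    rng = np.random.default_rng(seed)
    clean = _curve(direction)(x, y0, A, t)
    rows = []
    for cell in range(n_cells):
        noisy = clean + rng.normal(0.0, noise_sd, size=x.size)
        rows.append(pd.DataFrame({"time": x, "value": noisy, "replicate": cell}))
    series = KineticsSeries(pd.concat(rows, ignore_index=True), time_unit=time_unit)
    truth = {"y0": y0, "A": A, "t": t, "direction": direction,
             "noise_sd": noise_sd, "seed": seed}
    return series, truth


def gen_mask_pair(
    shape: tuple[int, ...],
    n_a: int,
    n_b: int,
    n_overlap: int,
    seed: int | None = None,
) -> tuple[ChannelMaskPair, dict]:
    """Random mask pair with exactly the requested pixel counts.

    ``manders`` on the result returns exactly ``n_overlap/n_a`` and
    ``n_overlap/n_b``."""
    total = int(np.prod(shape))
    if not (0 <= n_overlap <= min(n_a, n_b)):
        raise DomainError("need 0 <= n_overlap <= min(n_a, n_b)")
    needed = n_a + n_b - n_overlap
    if needed > total:
        raise DomainError(f"masks need {needed} pixels but the grid has {total}")
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=needed, replace=False)
    shared = flat[:n_overlap]
    a_only = flat[n_overlap:n_a]
    b_only = flat[n_a:]
    mask_a = np.zeros(total, dtype=bool)
    mask_b = np.zeros(total, dtype=bool)
    mask_a[shared] = mask_a[a_only] = True
    mask_b[shared] = mask_b[b_only] = True
    pair = ChannelMaskPair(mask_a.reshape(shape), mask_b.reshape(shape))
    truth = {"n_a": n_a, "n_b": n_b, "n_overlap": n_overlap, "seed": seed}
    return pair, truth
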
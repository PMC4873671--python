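"""Reading and writing the package's file dialects.

Tabular data travel as tidy CSV (pandas), rate coefficients and model
configuration as flat YAML key-value files, masks/stacks as multi-page TIFF
or ``.npy``, and fit/posterior summaries as JSON.  Observation tables accept
compartment aliases (SE^Rab4/ASE, RE_TfR/CRE, RE_Rab11/ARE) and a
``time_min`` column as an explicitly minute-tagged alternative to
``time_s``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import DomainError
from .inference import (
    FitResult,
    PosteriorEnsemble,
    PredictiveEnvelope,
    TimeCourseObservations,
)
from .model import (
    CompartmentTrajectory,
    FluxSeries,
    ModelConfig,
    RateCoefficientSet,
)


def read_observations(path) -> TimeCourseObservations:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        if "time_min" in df.columns:
            df = df.rename(columns={"time_min": "time_s"})
            df["time_s"] = df["time_s"].astype(float) * 60.0
        else:
            raise DomainError("observations need a time_s (or time_min) column")
    return TimeCourseObservations(df)


def write_observations(obs: TimeCourseObservations, path) -> None:
    obs.frame.to_csv(path, index=False)


def write_trajectory(traj: CompartmentTrajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def write_fluxes(flux: FluxSeries, path) -> None:
    flux.to_frame().to_csv(path, index=False)


def rates_to_yaml(K: RateCoefficientSet, path, cfg: ModelConfig | None = None) -> None:
    doc = {name: float(getattr(K, name)) for name in K.ORDER}
    if cfg is not None:
        doc["x_T"] = float(cfg.x_T)
        if cfg.initial_state is not None:
            doc["initial_state"] = [float(v) for v in cfg.initial_state]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def rates_from_yaml(path) -> tuple[RateCoefficientSet, ModelConfig]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise DomainError(f"{path}: expected a flat key-value mapping")
    try:
        K = RateCoefficientSet(**{n: float(doc[n]) for n in RateCoefficientSet.ORDER})
    except KeyError as exc:
        raise DomainError(f"{path}: missing coefficient {exc}") from None
    cfg = ModelConfig(
        x_T=float(doc.get("x_T", 2.0)),
        initial_state=tuple(doc["initial_state"]) if "initial_state" in doc else None,
    )
    return K, cfg


def fit_to_json(fit: FitResult, path) -> None:
    doc = {
        "K0": _k_dict(fit.K0),
        "K1": _k_dict(fit.K1),
        "K_fit": _k_dict(fit.K_fit),
        "E0": fit.E0,
        "E1": fit.E1,
        "E_fit": fit.E_fit,
        "grid": {
            "n_values": fit.grid.n_values,
            "n_evaluated": fit.grid.n_evaluated,
            "n_excluded": fit.grid.n_excluded,
        },
        "descent": {
            "n_iter": fit.descent.n_iter,
            "grad_norm": fit.descent.grad_norm,
            "converged": fit.descent.converged,
            "free": list(fit.descent.free),
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def _k_dict(K: RateCoefficientSet) -> dict:
    return {n: float(getattr(K, n)) for n in K.ORDER}


def ensemble_to_csv(ens: PosteriorEnsemble, path) -> None:
    pd.DataFrame(ens.samples, columns=list(ens.param_names)).to_csv(path, index=False)


def ensemble_summary_json(ens: PosteriorEnsemble, ci: dict, path) -> None:
    doc = {
        "param_names": list(ens.param_names),
        "ci95": {k: [v[0], v[1]] for k, v in ci.items()},
        "acceptance_rate": ens.acceptance_rate,
        "n_iter": ens.n_iter,
        "burn_in": ens.burn_in,
        "sigma2": ens.sigma2,
        "K_ref": _k_dict(ens.K_ref),
        "seed": ens.seed,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def envelope_to_csv(env: PredictiveEnvelope, path) -> None:
    env.to_frame().to_csv(path, index=False)


def read_mask(path) -> np.ndarray:
    """Boolean mask or stack from TIFF (any nonzero pixel is foreground) or .npy."""
    p = Path(path)
    if p.suffix.lower() == ".npy":
        return np.asarray(np.load(p)) != 0
    import tifffile

    return np.asarray(tifffile.imread(p)) != 0


def write_mask(mask: np.ndarray, path) -> None:
    p = Path(path)
    if p.suffix.lower() == ".npy":
        np.save(p, np.asarray(mask, dtype=bool))
        return
    import tifffile

    tifffile.imwrite(p, np.asarray(mask, dtype=np.uint8) * 255)
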
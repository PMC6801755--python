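"""Least-squares estimation of motor kinetic constants.

Force–velocity curves at saturating ATP determine four constants
(``r0, FS, k_plus, k_minus``) for a wild-type dimer and, jointly with a
mutant dataset sharing those four, the mutant's escape probability
``P0_zero``.  Stepping-ratio curves determine ``(r0, FS)`` (and
``P0_zero``) on a log scale, where the wild-type model is exactly linear:
``ln r = ln r0 (1 - F/FS)``.

The zero-force ratio and the stall-force scale are strongly coupled
(velocity depends on them through ``r0**(1-F/FS)``), so fits run from
several jittered starting points within bounds and keep the best optimum.

A synthetic-data generator (multiplicative Gaussian noise on the model
curve) supports parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import analytic
from .params import SATURATING, MotorParams

__all__ = [
    "FVDataset",
    "RatioDataset",
    "FitResult",
    "PARAM_BOUNDS",
    "generate_synthetic_fv",
    "generate_synthetic_ratio",
    "fit_force_velocity",
    "fit_stepping_ratio",
]

#: Optimisation bounds per free parameter.
PARAM_BOUNDS = {
    "r0": (1.0 + 1e-9, 1e5),
    "FS": (0.5, 20.0),
    "k_plus": (0.1, 1e4),
    "k_minus": (0.1, 1e4),
    "P0_zero": (0.01, 1.0),
}

_FIT_FIELDS = ("r0", "FS", "k_plus", "k_minus", "P0_zero")


@dataclass
class FVDataset:
    """Force–velocity observations: forces in pN, velocities in nm/s,
    optional per-point standard deviations."""

    F: np.ndarray
    v: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    atp: float = SATURATING
    source: str = ""
    wild_type: bool = True

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.F.shape != self.v.shape:
            raise ValueError("force and velocity columns differ in length")
        if not (np.isfinite(self.F).all() and np.isfinite(self.v).all()):
            raise ValueError("non-finite entries in dataset")

    def __len__(self) -> int:
        return len(self.F)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"force_pN": self.F, "velocity_nm_s": self.v})
        if self.sigma is not None:
            df["sigma_nm_s"] = self.sigma
        df.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "FVDataset":
        try:
            df = pd.read_csv(path, comment="#")
        except Exception as exc:  # surface parse context
            raise ValueError(f"could not parse {path}: {exc}") from exc
        for col in ("force_pN", "velocity_nm_s"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        sigma = df["sigma_nm_s"].to_numpy() if "sigma_nm_s" in df.columns else None
        return cls(F=df["force_pN"].to_numpy(), v=df["velocity_nm_s"].to_numpy(),
                   sigma=sigma, **meta)


@dataclass
class RatioDataset:
    """Force–stepping-ratio observations (ratios strictly positive)."""

    F: np.ndarray
    r: np.ndarray
    label: str = ""
    wild_type: bool = True

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if np.any(self.r <= 0):
            raise ValueError("stepping ratios must be positive for log-scale fitting")

    def __len__(self) -> int:
        return len(self.F)


@dataclass
class FitResult:
    """Estimates, Jacobian-based standard errors and diagnostics."""

    estimates: dict[str, float]
    errors: dict[str, float]
    rss: float
    success: bool
    fixed: dict[str, float]
    n_points: int
    message: str = ""
    n_starts: int = 1

    def params(self, name: str = "fit", **extra) -> MotorParams:
        """Materialise the fit as a validated parameter set."""
        fields = {**self.fixed, **self.estimates}
        fields = {k: v for k, v in fields.items() if k in _FIT_FIELDS}
        return MotorParams(name=name, **fields, **extra)

    def report(self) -> str:
        lines = [f"fit over {self.n_points} points, RSS = {self.rss:.6g}, "
                 f"converged = {self.success}"]
        for k, v in self.estimates.items():
            lines.append(f"  {k:9s} = {v:.6g} +/- {self.errors.get(k, float('nan')):.3g}")
        for k, v in self.fixed.items():
            lines.append(f"  {k:9s} = {v:.6g} (fixed)")
        return "\n".join(lines)


def generate_synthetic_fv(params: MotorParams, forces, noise_cv: float,
                          seed: int, label: str | None = None) -> FVDataset:
    """Model force–velocity curve with multiplicative Gaussian noise.

    ``v_i = v_model(F_i) (1 + eps_i)`` with ``eps_i ~ N(0, noise_cv^2)``;
    the recorded sigma is ``|v_model| * noise_cv``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    F = np.asarray(forces, dtype=float)
    v0 = analytic.velocity(F, params)
    rng = np.random.default_rng(seed)
    v = v0 * (1.0 + noise_cv * rng.standard_normal(F.shape))
    sigma = np.abs(v0) * noise_cv if noise_cv > 0 else None
    return FVDataset(F=F, v=v, sigma=sigma,
                     label=label or params.name, source="synthetic",
                     wild_type=(params.P0_zero == 1.0))


def generate_synthetic_ratio(params: MotorParams, forces, noise_cv: float,
                             seed: int) -> RatioDataset:
    """Model stepping-ratio curve with multiplicative lognormal-style noise."""
    F = np.asarray(forces, dtype=float)
    r0 = analytic.stepping_ratio(F, params)
    rng = np.random.default_rng(seed)
    r = r0 * np.exp(noise_cv * rng.standard_normal(F.shape))
    return RatioDataset(F=F, r=r, label=params.name,
                        wild_type=(params.P0_zero == 1.0))


def _model_params(theta, free, fixed):
    fields = dict(fixed)
    fields.update(dict(zip(free, theta)))
    fields.setdefault("P0_zero", 1.0)
    return MotorParams(name="_fit", **{k: fields[k] for k in _FIT_FIELDS if k in fields})


def _default_init_fv(datasets: Sequence[FVDataset], free) -> dict[str, float]:
    d = 8.2
    F_all = np.concatenate([ds.F for ds in datasets])
    v_all = np.concatenate([ds.v for ds in datasets])
    near0 = np.argmin(np.abs(F_all))
    init = {"r0": 500.0, "FS": 6.0, "k_minus": 3.0, "P0_zero": 0.5,
            "k_plus": max(1.0, abs(v_all[near0]) / d)}
    # FS guess: first force past the sign change of v, if any
    pos = F_all > 0
    if np.any(v_all[pos] < 0):
        init["FS"] = float(np.min(F_all[pos & (v_all < 0)]))
    return {k: init[k] for k in free}


def _clip_to_bounds(theta, free):
    lo = np.array([PARAM_BOUNDS[k][0] for k in free])
    hi = np.array([PARAM_BOUNDS[k][1] for k in free])
    return np.minimum(np.maximum(theta, lo * 1.000001), hi * 0.999999)


def _multistart(residual_fn, x0, free, n_starts, seed):
    lo = [PARAM_BOUNDS[k][0] for k in free]
    hi = [PARAM_BOUNDS[k][1] for k in free]
    rng = np.random.default_rng(seed)
    best = None
    for j in range(n_starts):
        if j == 0:
            start = np.asarray(x0, dtype=float)
        else:
            start = np.asarray(x0) * np.exp(0.2 * rng.standard_normal(len(x0)))
        start = _clip_to_bounds(start, free)
        try:
            res = least_squares(residual_fn, start, bounds=(lo, hi),
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimisation starts failed")
    return best


def _stderr(res, n_points, n_free):
    """Jacobian-based covariance, scaled by s^2 = RSS/(n-p)."""
    J = res.jac
    rss = 2.0 * res.cost
    dof = max(n_points - n_free, 1)
    try:
        cov = np.linalg.inv(J.T @ J) * (rss / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_free, np.nan)
    return se, rss


def fit_force_velocity(dataset: FVDataset | Sequence[FVDataset],
                       free_params: Sequence[str] = ("r0", "FS", "k_plus", "k_minus"),
                       fixed_params: dict[str, float] | None = None,
                       init: dict[str, float] | None = None,
                       n_starts: int = 5, seed: int = 0) -> FitResult:
    """Weighted least squares on saturating-ATP force–velocity data.

    ``dataset`` may be a single :class:`FVDataset` or a sequence for a
    joint fit: all datasets share ``r0, FS, k_plus, k_minus``; datasets
    flagged ``wild_type`` use ``P0_zero = 1`` while the remaining ones
    share the (free or fixed) ``P0_zero`` — the protocol that ties a
    wild-type curve to its extended-neck-linker mutant.

    Residuals are ``(v_model - v)/sigma`` with sigma = 1 where absent.
    """
    datasets = [dataset] if isinstance(dataset, FVDataset) else list(dataset)
    free = list(free_params)
    fixed = dict(fixed_params or {})
    _check_partition(free, fixed, datasets)
    n_points = sum(len(ds) for ds in datasets)
    if n_points < len(free):
        raise ValueError(f"{n_points} points cannot determine {len(free)} parameters")

    init_all = _default_init_fv(datasets, free)
    if init:
        init_all.update({k: v for k, v in init.items() if k in free})
    x0 = [init_all[k] for k in free]

    def residuals(theta):
        out = []
        for ds in datasets:
            fields = dict(fixed)
            fields.update(dict(zip(free, theta)))
            if ds.wild_type:
                fields["P0_zero"] = 1.0
            p = _model_params([], [], fields)
            w = ds.sigma if ds.sigma is not None else 1.0
            out.append((analytic.velocity(ds.F, p) - ds.v) / w)
        return np.concatenate(out)

    res = _multistart(residuals, x0, free, n_starts, seed)
    se, rss = _stderr(res, n_points, len(free))
    return FitResult(
        estimates=dict(zip(free, map(float, res.x))),
        errors=dict(zip(free, map(float, se))),
        rss=float(rss), success=bool(res.success), fixed=fixed,
        n_points=n_points, message=res.message, n_starts=n_starts,
    )


def _check_partition(free, fixed, datasets) -> None:
    unknown = [k for k in list(free) + list(fixed) if k not in _FIT_FIELDS]
    if unknown:
        raise ValueError(f"unknown fit parameters {unknown}; choose from {_FIT_FIELDS}")
    overlap = set(free) & set(fixed)
    if overlap:
        raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
    covered = set(free) | set(fixed)
    missing = [k for k in ("r0", "FS", "k_plus", "k_minus") if k not in covered]
    if missing:
        raise ValueError(f"parameters neither free nor fixed: {missing}")
    if any(not ds.wild_type for ds in datasets) and "P0_zero" not in covered:
        raise ValueError("mutant dataset present but P0_zero neither free nor fixed")


def fit_stepping_ratio(dataset: RatioDataset | Sequence[RatioDataset],
                       free_params: Sequence[str] = ("r0", "FS"),
                       fixed_params: dict[str, float] | None = None,
                       init: dict[str, float] | None = None,
                       n_starts: int = 5, seed: int = 0) -> FitResult:
    """Least squares on ``ln r`` against the stepping-ratio model.

    For a wild-type motor ``ln r = ln(r0) (1 - F/FS)`` is linear in F with
    slope ``-ln(r0)/FS``, so the log-scale residuals make the problem well
    conditioned; ratio data must be strictly positive.
    """
    datasets = [dataset] if isinstance(dataset, RatioDataset) else list(dataset)
    free = list(free_params)
    fixed = dict(fixed_params or {})
    base_fixed = {"k_plus": 100.0, "k_minus": 3.0}  # cancel out of the ratio
    n_points = sum(len(ds) for ds in datasets)
    if n_points < len(free):
        raise ValueError(f"{n_points} points cannot determine {len(free)} parameters")

    init_all = {"r0": 300.0, "FS": 6.0, "P0_zero": 0.5}
    if init:
        init_all.update(init)
    x0 = [init_all[k] for k in free]

    def residuals(theta):
        out = []
        for ds in datasets:
            fields = {**base_fixed, **fixed}
            fields.update(dict(zip(free, theta)))
            if ds.wild_type:
                fields["P0_zero"] = 1.0
            p = _model_params([], [], fields)
            out.append(np.log(analytic.stepping_ratio(ds.F, p)) - np.log(ds.r))
        return np.concatenate(out)

    res = _multistart(residuals, x0, free, n_starts, seed)
    se, rss = _stderr(res, n_points, len(free))
    return FitResult(
        estimates=dict(zip(free, map(float, res.x))),
        errors=dict(zip(free, map(float, se))),
        rss=float(rss), success=bool(res.success), fixed=fixed,
        n_points=n_points, message=res.message, n_starts=n_starts,
    )
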
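"""Closed-form stepping dynamics at saturating ATP.

The chemomechanical cycle reduces, at saturating ATP, to a two-branch
renewal process: ATPase events fire at ``k_plus`` (trailing head) and
``k_minus`` (leading head); a trailing-head event yields a forward step with
probability ``P0_trail * PE`` and a leading-head event a backward step with
probability ``P0_lead * (1 - PE)``, where ``PE`` is the forward-rebinding
probability of the detached head in the intermediate (INT) one-head-bound
state and ``P0`` the escape probability from the transiently weakened
binding site.  Everything observable — stepping ratio, velocity, dwell
time, diffusion constant, randomness, ATP cost per step, power and
efficiency — follows in closed form.

Force-side convention: the external force is signed, positive pointing
backward.  A backward force loads only the leading head, a forward
(negative) force only the trailing head, so the escape probability of the
loaded head is ``P0(F) = 1 - (1 - P0(0)) exp(-|F| delta / kBT)`` while the
unloaded head keeps ``P0(0)``.  For wild-type motors ``P0 = 1`` on both
sides and every expression reduces to the simpler wild-type form.

All force arguments accept scalars or numpy arrays; scalar in, scalar out.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .params import KB, MotorParams

__all__ = [
    "Observables",
    "StallDivergenceError",
    "reduced_ratio",
    "p_escape",
    "p_forward",
    "stepping_ratio",
    "velocity",
    "dwell_time",
    "diffusion_constant",
    "randomness",
    "atp_per_forward_step",
    "atp_per_step",
    "power",
    "efficiency",
    "stall_force",
    "max_power",
    "nl_docking_energy",
    "characteristic_distance",
    "observables",
    "scan",
    "futile_atpase_rate",
]

#: Default free energy of ATP hydrolysis under physiological conditions, kBT.
DELTA_G_ATP = 20.0


class StallDivergenceError(ZeroDivisionError):
    """Raised when a quantity diverges at stall (zero net velocity)."""


def _maybe_scalar(x, scalar: bool):
    return float(x) if scalar else x


def reduced_ratio(F, params: MotorParams):
    """Wild-type stepping ratio ``r0 ** (1 - F/FS)``.

    Strictly decreasing in the backward force; equals ``r0`` at F=0 and 1
    at ``F = FS``.
    """
    F_arr = np.asarray(F, dtype=float)
    out = params.r0 ** (1.0 - F_arr / params.FS)
    return _maybe_scalar(out, np.isscalar(F))


def p_escape(F, params: MotorParams):
    """Escape probability ``P0(F)`` of the loaded head.

    ``P0(F) = 1 - [1 - P0(0)] exp(-|F| delta / kBT)``; the two signed-force
    branches coincide at F=0 and the result lies in ``[P0(0), 1]``.
    Identically 1 for wild-type motors.
    """
    F_arr = np.asarray(F, dtype=float)
    beta = 1.0 / (KB * params.T)
    out = 1.0 - (1.0 - params.P0_zero) * np.exp(-np.abs(F_arr) * params.delta * beta)
    return _maybe_scalar(out, np.isscalar(F))


def _sides(F_arr: np.ndarray, params: MotorParams):
    """Escape probabilities attached to the forward- and backward-stepping
    branches for signed force.

    Returns ``(rho, a, b)`` where ``rho`` is the reduced ratio, ``a`` the
    escape probability multiplying the forward branch and ``b`` the one
    multiplying the backward branch.  For F >= 0 the loaded (leading) head
    governs the backward branch, for F < 0 the loaded (trailing) head
    governs the forward branch.
    """
    rho = params.r0 ** (1.0 - F_arr / params.FS)
    beta = 1.0 / (KB * params.T)
    p0F = 1.0 - (1.0 - params.P0_zero) * np.exp(-np.abs(F_arr) * params.delta * beta)
    pos = F_arr >= 0
    a = np.where(pos, params.P0_zero, p0F)
    b = np.where(pos, p0F, params.P0_zero)
    return rho, a, b


def p_forward(F, params: MotorParams):
    """Forward-rebinding probability ``PE = rho / (rho + k+/k-)`` of the
    detached head in the INT state; 1 in the limit of an inert leading head
    (k- = 0)."""
    F_arr = np.asarray(F, dtype=float)
    if params.k_minus == 0:
        out = np.ones_like(F_arr)
    else:
        rho = params.r0 ** (1.0 - F_arr / params.FS)
        out = rho / (rho + params.K)
    return _maybe_scalar(out, np.isscalar(F))


def stepping_ratio(F, params: MotorParams):
    """Forward/backward step-count ratio ``r = rho * a / b`` (wild-type:
    ``r = rho``)."""
    F_arr = np.asarray(F, dtype=float)
    rho, a, b = _sides(F_arr, params)
    return _maybe_scalar(rho * a / b, np.isscalar(F))


def velocity(F, params: MotorParams):
    """Mean velocity in nm/s: ``v = (a*rho - b)/(rho + k+/k-) * k+ * d``.

    Negative values mean net backward motion beyond stall.
    """
    F_arr = np.asarray(F, dtype=float)
    rho, a, b = _sides(F_arr, params)
    out = (a * rho - b) / (rho + params.K) * params.k_plus * params.d
    return _maybe_scalar(out, np.isscalar(F))


def _total_step_rate(F_arr: np.ndarray, params: MotorParams):
    # forward rate a*PE*k+ plus backward rate b*(1-PE)*k- == k+ (a rho + b)/(rho+K)
    rho, a, b = _sides(F_arr, params)
    return params.k_plus * (a * rho + b) / (rho + params.K)


def dwell_time(F, params: MotorParams):
    """Mean dwell time between mechanical steps, s: the reciprocal of the
    total (forward + backward) stepping rate."""
    F_arr = np.asarray(F, dtype=float)
    rate = _total_step_rate(F_arr, params)
    if np.any(rate <= 0):
        raise StallDivergenceError("both stepping rates vanish; dwell time undefined")
    return _maybe_scalar(1.0 / rate, np.isscalar(F))


def diffusion_constant(F, params: MotorParams):
    """Diffusion constant of the centre-of-mass position, nm^2/s:
    ``D = (a*rho + b)/(rho + k+/k-) * k+ * d^2 / 2`` (> 0 for all F)."""
    F_arr = np.asarray(F, dtype=float)
    rho, a, b = _sides(F_arr, params)
    out = 0.5 * (a * rho + b) / (rho + params.K) * params.k_plus * params.d ** 2
    return _maybe_scalar(out, np.isscalar(F))


def randomness(F, params: MotorParams):
    """Randomness parameter ``R = 2D/(v d) = (a rho + b)/(a rho - b)``.

    >= 1 below stall; diverges at stall.  A scalar force exactly at stall
    raises :class:`StallDivergenceError`; in arrays such entries become NaN
    with a warning.
    """
    F_arr = np.asarray(F, dtype=float)
    rho, a, b = _sides(F_arr, params)
    num = a * rho + b
    den = a * rho - b
    bad = np.abs(den) <= 1e-12 * num
    if np.isscalar(F):
        if bad:
            raise StallDivergenceError(
                f"randomness diverges at stall (F={float(F_arr):g} pN)")
        return float(num / den)
    if np.any(bad):
        warnings.warn("randomness diverges at stall; NaN returned there",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, num / den)
    return out


def atp_per_forward_step(F, params: MotorParams):
    """Mean ATP molecules hydrolysed per forward step,
    ``NF = (k+ + k-)/(a PE k+) = (1 + k-/k+)(rho + k+/k-)/(a rho)``."""
    F_arr = np.asarray(F, dtype=float)
    rho, a, _ = _sides(F_arr, params)
    out = (1.0 + params.k_minus / params.k_plus) * (rho + params.K) / (a * rho)
    return _maybe_scalar(out, np.isscalar(F))


def atp_per_step(F, params: MotorParams):
    """Mean ATP molecules hydrolysed per mechanical step (either direction),
    ``N = (1 + k-/k+)(rho + k+/k-)/(a rho + b)``; never exceeds NF."""
    F_arr = np.asarray(F, dtype=float)
    rho, a, b = _sides(F_arr, params)
    out = (1.0 + params.k_minus / params.k_plus) * (rho + params.K) / (a * rho + b)
    return _maybe_scalar(out, np.isscalar(F))


def power(F, params: MotorParams):
    """Power delivered against the load, in kBT/s: ``W = v * F / kBT``
    (with v in nm/s and F in pN).  Zero at F=0 and at stall, positive
    between."""
    F_arr = np.asarray(F, dtype=float)
    v = np.asarray(velocity(F_arr, params))
    out = v * F_arr / (KB * params.T)
    return _maybe_scalar(out, np.isscalar(F))


def efficiency(F, params: MotorParams, deltaG: float = DELTA_G_ATP):
    """Thermodynamic efficiency ``eta = W / [(k+ + k-) deltaG]`` with the
    free energy per ATP ``deltaG`` in kBT (default 20)."""
    if deltaG <= 0:
        raise ValueError(f"deltaG={deltaG!r} must be positive")
    F_arr = np.asarray(F, dtype=float)
    out = np.asarray(power(F_arr, params)) / ((params.k_plus + params.k_minus) * deltaG)
    return _maybe_scalar(out, np.isscalar(F))


def futile_atpase_rate(F, params: MotorParams):
    """ATPase rate not coupled to stepping, s^-1: total ATPase rate
    ``k+ + k-`` minus the total stepping rate.  Derived convenience."""
    F_arr = np.asarray(F, dtype=float)
    out = params.k_plus + params.k_minus - _total_step_rate(F_arr, params)
    return _maybe_scalar(out, np.isscalar(F))


def stall_force(params: MotorParams, xtol: float = 1e-6) -> float:
    """Backward force at which the net velocity vanishes, pN.

    Equals ``FS`` exactly for wild-type motors (``P0_zero == 1``); for
    extended-neck-linker mutants the stall force lies below ``FS`` and is
    located by root bracketing on [0, FS].
    """
    if params.P0_zero == 1.0:
        return params.FS
    f = lambda F: velocity(F, params)
    lo, hi = 0.0, params.FS
    if f(lo) <= 0 or f(hi) >= 0:
        raise ValueError(
            f"no stall bracket on [0, {params.FS}] pN for motor {params.name!r}")
    return float(brentq(f, lo, hi, xtol=xtol))


def max_power(params: MotorParams) -> tuple[float, float]:
    """Location (pN) and value (kBT/s) of the power maximum on
    (0, stall force)."""
    F_stall = stall_force(params)
    res = minimize_scalar(lambda F: -power(F, params),
                          bounds=(0.0, F_stall), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x), float(-res.fun)


def nl_docking_energy(params: MotorParams, with_error: bool = False):
    """Neck-linker docking energy in kBT, from the zero-force stepping ratio:
    ``ED = ln(r0 * k-/k+)``.

    The docking energy is the barrier that prevents the detached ADP-head
    in the INT state from rebinding backward; inverting
    ``r0 = (k+/k-) exp(ED/kBT)`` recovers it from fitted constants.

    With ``with_error=True`` returns ``(ED, dED)`` using first-order
    propagation of the stored parameter uncertainties,
    ``dED = dr0/r0 + dk-/k- + dk+/k+`` (in kBT).
    """
    if params.k_minus == 0:
        raise ValueError("NL-docking energy undefined for k_minus = 0")
    ed = math.log(params.r0 * params.k_minus / params.k_plus)
    if not with_error:
        return ed
    err = params.errors or {}
    ded = (err.get("r0", 0.0) / params.r0
           + err.get("k_minus", 0.0) / params.k_minus
           + err.get("k_plus", 0.0) / params.k_plus)
    return ed, ded


def characteristic_distance(params: MotorParams) -> float:
    """Characteristic distance ``d(+) = kBT ln(r0) / FS`` in nm for the
    forward move of the detached head out of the INT state."""
    return KB * params.T * math.log(params.r0) / params.FS


@dataclass(frozen=True)
class Observables:
    """Derived dynamics summary at one force (saturating ATP)."""

    r: float        # stepping ratio
    v: float        # velocity, nm/s
    Td: float       # mean dwell time between steps, s
    D: float        # diffusion constant, nm^2/s
    R: float        # randomness parameter (NaN at stall)
    NF: float       # ATP per forward step
    N: float        # ATP per step
    W_dot: float    # power, kBT/s
    eta: float      # efficiency


def observables(F: float, params: MotorParams, deltaG: float = DELTA_G_ATP) -> Observables:
    """All closed-form observables at a single force."""
    try:
        R = randomness(F, params)
    except StallDivergenceError:
        R = math.nan
    return Observables(
        r=stepping_ratio(F, params),
        v=velocity(F, params),
        Td=dwell_time(F, params),
        D=diffusion_constant(F, params),
        R=R,
        NF=atp_per_forward_step(F, params),
        N=atp_per_step(F, params),
        W_dot=power(F, params),
        eta=efficiency(F, params, deltaG),
    )


def scan(params: MotorParams, forces, deltaG: float = DELTA_G_ATP) -> pd.DataFrame:
    """Evaluate every observable on a force grid.

    Returns a DataFrame with columns ``force_pN, ratio, velocity_nm_s,
    dwell_s, D_nm2_s, randomness, NF, N, power_kBT_s, efficiency``; the
    randomness column is NaN at/beyond stall.
    """
    F = np.asarray(forces, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        R = randomness(F, params)
    return pd.DataFrame({
        "force_pN": F,
        "ratio": stepping_ratio(F, params),
        "velocity_nm_s": velocity(F, params),
        "dwell_s": dwell_time(F, params),
        "D_nm2_s": diffusion_constant(F, params),
        "randomness": R,
        "NF": atp_per_forward_step(F, params),
        "N": atp_per_step(F, params),
        "power_kBT_s": power(F, params),
        "efficiency": efficiency(F, params, deltaG),
    })
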
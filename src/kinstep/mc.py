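"""Stochastic simulation of the kinesin chemomechanical cycle.

Two engines simulate the identical Markov state machine:

* :func:`simulate_trace` — fixed-timestep scheme (default auto-selected
  ``dt``; the classic choice is 1e-4 s), one uniform variate per candidate
  transition per step;
* :func:`exact_trace` — event-driven continuous-time scheme with
  exponential waiting times, used as the exact oracle and for ensembles.

State machine
-------------
The dimer is either two-head-bound (THB, heads on adjacent lattice sites)
or one-head-bound (INT, the detached ADP-head tethered above the bound
head).  In THB, a phi-head binds ATP at ``kb*[ATP]``; the leading head's
ATP dissociates at ``k_off_leading`` (elsewhere dissociation is 0); ATPase
fires at ``k_plus`` (trailing) / ``k_minus`` (leading), force-independent.
An ATPase event detaches the head with the escape probability of its side
(a backward force loads only the leading head, a forward force only the
trailing head); otherwise ADP is released instantly and the head returns to
phi.  In INT, once the bound head holds ATP its neck linker docks
immediately and the tethered head rebinds instantly: to the forward site
with probability ``PE`` and to the rearward site otherwise.  ADP release on
rebinding is instantaneous, leaving the rebound head phi.

Zero-duration cascades (detach -> dock -> rebind) are logged as separate
events sharing one timestamp in causal order; at the saturating-ATP
sentinel, ATP binding is instantaneous and not logged, and the
leading-head dissociation channel is skipped (dissociation followed by
instantaneous rebinding is a no-op).

Centre-of-mass convention: the logged position changes only at rebind
events, by +d (forward), -d (backward) or 0 (futile rebind to the same
site).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .params import KB, Conditions, MotorParams

__all__ = [
    "Trace",
    "TraceSet",
    "TimestepError",
    "EVENT_NAMES",
    "EVENT_CODES",
    "simulate_trace",
    "exact_trace",
    "simulate_ensemble",
]

# Event codes (int8 in the log).
ATP_BIND = 0
ATP_DISSOC = 1
HYDROLYSIS_TRAILING = 2
HYDROLYSIS_LEADING = 3
DETACH_TO_INT_TRAILING = 4
DETACH_TO_INT_LEADING = 5
REBIND_FORWARD = 6
REBIND_BACKWARD = 7
REBIND_SAME_REAR = 8
REBIND_SAME_FRONT = 9

EVENT_NAMES = {
    ATP_BIND: "ATP_BIND",
    ATP_DISSOC: "ATP_DISSOC",
    HYDROLYSIS_TRAILING: "HYDROLYSIS_TRAILING",
    HYDROLYSIS_LEADING: "HYDROLYSIS_LEADING",
    DETACH_TO_INT_TRAILING: "DETACH_TO_INT_TRAILING",
    DETACH_TO_INT_LEADING: "DETACH_TO_INT_LEADING",
    REBIND_FORWARD: "REBIND_FORWARD",
    REBIND_BACKWARD: "REBIND_BACKWARD",
    REBIND_SAME_REAR: "REBIND_SAME_REAR",
    REBIND_SAME_FRONT: "REBIND_SAME_FRONT",
}
EVENT_CODES = {v: k for k, v in EVENT_NAMES.items()}

_HYDROLYSIS = (HYDROLYSIS_TRAILING, HYDROLYSIS_LEADING)
_STEP_DELTA = {REBIND_FORWARD: +1, REBIND_BACKWARD: -1}

#: Stability bound for the fixed-timestep engine: every active rate must
#: satisfy rate*dt < this.
STABILITY_LIMIT = 0.01
DEFAULT_DT = 1e-4


class TimestepError(ValueError):
    """Fixed-timestep stability violated; use a smaller dt or exact_trace."""


@dataclass
class Trace:
    """Event log and centre-of-mass record of one simulated run.

    ``times``/``codes``/``com`` are parallel arrays; ``com[i]`` is the
    centre-of-mass position (nm) immediately after event ``i``.
    """

    times: np.ndarray
    codes: np.ndarray
    com: np.ndarray
    t_max: float
    seed: int
    params: MotorParams
    conditions: Conditions
    engine: str
    dt: float | None = None

    @property
    def n_forward(self) -> int:
        return int(np.count_nonzero(self.codes == REBIND_FORWARD))

    @property
    def n_backward(self) -> int:
        return int(np.count_nonzero(self.codes == REBIND_BACKWARD))

    @property
    def n_hydrolysis(self) -> int:
        return int(np.count_nonzero(np.isin(self.codes, _HYDROLYSIS)))

    @property
    def com_final(self) -> float:
        return float(self.com[-1]) if len(self.com) else 0.0

    def com_at(self, t) -> np.ndarray:
        """Piecewise-constant centre-of-mass position sampled at times t."""
        t = np.asarray(t, dtype=float)
        if len(self.times) == 0:
            return np.zeros_like(t)
        idx = np.searchsorted(self.times, t, side="right")
        com = np.concatenate(([0.0], self.com))
        return com[idx]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            "event": [EVENT_NAMES[c] for c in self.codes],
            "com_nm": self.com,
        })


# ---------------------------------------------------------------------------
# numba kernels.  Both record (time, code, com) triplets into preallocated
# arrays and return the number of events written, or -1 on overflow (the
# wrapper retries with larger arrays).
#
# Shared encoding: cfg 0 = THB, 1 = INT; nucleotides 0 = empty, 1 = ATP.
# origin: 0 = INT entered by trailing-head detachment, 1 = by leading-head.
# ---------------------------------------------------------------------------


@njit(cache=True)
def _resolve_int(origin, bn, x, d, PE, sat, t, times, codes, xs, n):
    """Instantaneous INT resolution once the bound head holds ATP.

    Returns (tn, ln, x, n): nucleotide states of the new trailing/leading
    heads, updated position and event count.
    """
    u = np.random.random()
    fresh = 1 if sat else 0  # rebound head is phi; instantly ATP at saturation
    if u < PE:  # tethered head rebinds to the forward site
        if origin == 0:
            x += d
            codes[n] = 6  # REBIND_FORWARD
        else:
            codes[n] = 9  # REBIND_SAME_FRONT
        times[n] = t
        xs[n] = x
        n += 1
        return bn, fresh, x, n  # bound head becomes trailing
    else:  # rebinds to the rearward site
        if origin == 0:
            codes[n] = 8  # REBIND_SAME_REAR
        else:
            x -= d
            codes[n] = 7  # REBIND_BACKWARD
        times[n] = t
        xs[n] = x
        n += 1
        return fresh, bn, x, n  # bound head stays leading


@njit(cache=True)
def _run_exact(kp, km, PE, p0_trail, p0_lead, kbS, koff1, d, t_max, sat, seed,
               times, codes, xs):
    np.random.seed(seed)
    cap = times.shape[0]
    n = 0
    t = 0.0
    x = 0.0
    cfg = 0
    origin = 0
    tn = 1 if sat else 0
    ln = 1 if sat else 0
    bn = 0
    while True:
        if n + 4 > cap:
            return -1
        if cfg == 0:
            r_t = kp if tn == 1 else kbS
            if ln == 1:
                r_l_hyd = km
                r_l_dis = 0.0 if sat else koff1
                r_l_bind = 0.0
            else:
                r_l_hyd = 0.0
                r_l_dis = 0.0
                r_l_bind = kbS
            total = r_t + r_l_hyd + r_l_dis + r_l_bind
        else:
            total = 0.0 if bn == 1 else kbS  # bn==1 never persists
        if total <= 0.0:
            break
        t += -math.log(np.random.random()) / total
        if t >= t_max:
            break
        u = np.random.random() * total
        if cfg == 0:
            if u < r_t:
                if tn == 1:  # trailing hydrolysis
                    times[n] = t; codes[n] = 2; xs[n] = x; n += 1
                    if np.random.random() < p0_trail:
                        times[n] = t; codes[n] = 4; xs[n] = x; n += 1
                        bn = ln
                        if bn == 1:
                            tn, ln, x, n = _resolve_int(0, bn, x, d, PE, sat, t,
                                                        times, codes, xs, n)
                            cfg = 0
                        else:
                            cfg = 1
                            origin = 0
                    else:
                        tn = 1 if sat else 0
                else:  # trailing ATP binding
                    tn = 1
                    times[n] = t; codes[n] = 0; xs[n] = x; n += 1
            elif u < r_t + r_l_hyd:  # leading hydrolysis
                times[n] = t; codes[n] = 3; xs[n] = x; n += 1
                if np.random.random() < p0_lead:
                    times[n] = t; codes[n] = 5; xs[n] = x; n += 1
                    bn = tn
                    if bn == 1:
                        tn, ln, x, n = _resolve_int(1, bn, x, d, PE, sat, t,
                                                    times, codes, xs, n)
                        cfg = 0
                    else:
                        cfg = 1
                        origin = 1
                else:
                    ln = 1 if sat else 0
            elif u < r_t + r_l_hyd + r_l_dis:  # leading ATP dissociation
                ln = 0
                times[n] = t; codes[n] = 1; xs[n] = x; n += 1
            else:  # leading ATP binding
                ln = 1
                times[n] = t; codes[n] = 0; xs[n] = x; n += 1
        else:  # INT, bound head binds ATP -> dock -> instant rebind
            bn = 1
            times[n] = t; codes[n] = 0; xs[n] = x; n += 1
            tn, ln, x, n = _resolve_int(origin, bn, x, d, PE, sat, t,
                                        times, codes, xs, n)
            cfg = 0
    return n


@njit(cache=True)
def _run_fixed(kp, km, PE, p0_trail, p0_lead, kbS, koff1, d, t_max, sat, seed,
               dt, times, codes, xs):
    np.random.seed(seed)
    cap = times.shape[0]
    n = 0
    x = 0.0
    cfg = 0
    origin = 0
    tn = 1 if sat else 0
    ln = 1 if sat else 0
    bn = 0
    nsteps = int(t_max / dt)
    for i in range(nsteps):
        if n + 4 > cap:
            return -1
        t = (i + 1) * dt
        if cfg == 0:
            # trailing head: at most one transition per step
            u = np.random.random()
            if tn == 1:
                if u < kp * dt:
                    times[n] = t; codes[n] = 2; xs[n] = x; n += 1
                    if np.random.random() < p0_trail:
                        times[n] = t; codes[n] = 4; xs[n] = x; n += 1
                        bn = ln
                        if bn == 1:
                            tn, ln, x, n = _resolve_int(0, bn, x, d, PE, sat, t,
                                                        times, codes, xs, n)
                        else:
                            cfg = 1
                            origin = 0
                    else:
                        tn = 1 if sat else 0
            else:
                if u < kbS * dt:
                    tn = 1
                    times[n] = t; codes[n] = 0; xs[n] = x; n += 1
            # leading head, unless the trailing transition left THB
            if cfg == 0:
                u = np.random.random()
                if ln == 1:
                    if u < km * dt:
                        times[n] = t; codes[n] = 3; xs[n] = x; n += 1
                        if np.random.random() < p0_lead:
                            times[n] = t; codes[n] = 5; xs[n] = x; n += 1
                            bn = tn
                            if bn == 1:
                                tn, ln, x, n = _resolve_int(1, bn, x, d, PE, sat,
                                                            t, times, codes, xs, n)
                            else:
                                cfg = 1
                                origin = 1
                    elif (not sat) and u < (km + koff1) * dt:
                        ln = 0
                        times[n] = t; codes[n] = 1; xs[n] = x; n += 1
                else:
                    if u < kbS * dt:
                        ln = 1
                        times[n] = t; codes[n] = 0; xs[n] = x; n += 1
        else:  # INT waiting for ATP on the bound head
            if np.random.random() < kbS * dt:
                bn = 1
                times[n] = t; codes[n] = 0; xs[n] = x; n += 1
                tn, ln, x, n = _resolve_int(origin, bn, x, d, PE, sat, t,
                                            times, codes, xs, n)
                cfg = 0
    return n


# ---------------------------------------------------------------------------
# wrappers
# ---------------------------------------------------------------------------


def _derived_rates(params: MotorParams, conditions: Conditions):
    """Force-resolved branch probabilities and nucleotide rates.

    The backward force (F > 0) loads only the leading head, the forward
    force only the trailing head; the unloaded side keeps P0(0).
    """
    from .analytic import p_escape, p_forward

    F = conditions.F
    p0F = p_escape(F, params)
    p0_trail = p0F if F < 0 else params.P0_zero
    p0_lead = p0F if F > 0 else params.P0_zero
    PE = p_forward(F, params)
    sat = conditions.saturating
    kbS = 0.0 if sat else params.kb * conditions.atp
    return PE, p0_trail, p0_lead, kbS, sat


def _active_rates(params: MotorParams, conditions: Conditions):
    rates = [params.k_plus, params.k_minus]
    if not conditions.saturating:
        rates.append(params.kb * conditions.atp)
        rates.append(params.k_off_leading)
    return rates


def _event_cap(params: MotorParams, conditions: Conditions, t_max: float) -> int:
    rate = params.k_plus + params.k_minus
    if not conditions.saturating:
        rate += min(params.kb * conditions.atp, 4 * (params.k_plus + params.k_minus))
        rate += params.k_off_leading
    return int(3.0 * rate * t_max + 1000)


def _run(kernel, params, conditions, t_max, seed, engine, dt=None) -> Trace:
    PE, p0_trail, p0_lead, kbS, sat = _derived_rates(params, conditions)
    cap = _event_cap(params, conditions, t_max)
    seed = int(seed) % (2 ** 31)
    args = (params.k_plus, params.k_minus, PE, p0_trail, p0_lead, kbS,
            params.k_off_leading, params.d, float(t_max), sat, seed)
    if dt is not None:
        args = args + (dt,)
    while True:
        times = np.empty(cap, dtype=np.float64)
        codes = np.empty(cap, dtype=np.int8)
        xs = np.empty(cap, dtype=np.float64)
        n = kernel(*args, times, codes, xs)
        if n >= 0:
            break
        cap *= 2
    return Trace(times=times[:n].copy(), codes=codes[:n].copy(), com=xs[:n].copy(),
                 t_max=float(t_max), seed=seed, params=params,
                 conditions=conditions, engine=engine, dt=dt)


def _auto_dt(params: MotorParams, conditions: Conditions) -> float:
    rmax = max(_active_rates(params, conditions))
    if rmax <= 0:
        return DEFAULT_DT
    return min(DEFAULT_DT, 0.999 * STABILITY_LIMIT / rmax)


def simulate_trace(params: MotorParams, conditions: Conditions, t_max: float,
                   seed: int, dt: float | None = None) -> Trace:
    """Fixed-timestep simulation of the chemomechanical cycle.

    ``dt=None`` auto-selects the largest timestep <= 1e-4 s satisfying the
    stability bound ``rate*dt < 0.01`` for every active rate.  An explicit
    ``dt`` violating the bound raises :class:`TimestepError`.
    """
    if t_max <= 0:
        raise ValueError(f"t_max={t_max!r} must be positive")
    if dt is None:
        dt = _auto_dt(params, conditions)
    else:
        rmax = max(_active_rates(params, conditions))
        if rmax * dt >= STABILITY_LIMIT:
            raise TimestepError(
                f"rate*dt = {rmax * dt:.3g} >= {STABILITY_LIMIT}: reduce dt below "
                f"{STABILITY_LIMIT / rmax:.2e} s or use exact_trace()")
    return _run(_run_fixed, params, conditions, t_max, seed, "fixed", dt=dt)


def exact_trace(params: MotorParams, conditions: Conditions, t_max: float,
                seed: int) -> Trace:
    """Event-driven (exponential waiting time) simulation of the identical
    state machine; distributionally the dt -> 0 limit of
    :func:`simulate_trace`."""
    if t_max <= 0:
        raise ValueError(f"t_max={t_max!r} must be positive")
    return _run(_run_exact, params, conditions, t_max, seed, "exact")


@dataclass
class TraceSet:
    """Ensemble of independent traces with per-trace step/ATPase statistics.

    Per-trace seeds are ``base_seed + index (mod 2^31)``.  ``positions`` is
    the centre-of-mass sampled on the common grid ``sample_times``
    (n_traces x n_samples), which supports the ensemble variance estimate
    of the diffusion constant.  Full :class:`Trace` objects are retained
    only when ``keep_traces`` is set.
    """

    params: MotorParams
    conditions: Conditions
    t_max: float
    base_seed: int
    engine: str
    n_forward: np.ndarray
    n_backward: np.ndarray
    n_hydrolysis: np.ndarray
    n_bind: np.ndarray
    sample_times: np.ndarray
    positions: np.ndarray
    traces: list[Trace] | None = field(default=None, repr=False)

    @property
    def n_traces(self) -> int:
        return len(self.n_forward)

    def summary(self):
        from .traces import summarize

        return summarize(self)


def simulate_ensemble(params: MotorParams, conditions: Conditions, t_max: float,
                      n_traces: int, base_seed: int, engine: str = "exact",
                      dt: float | None = None, keep_traces: bool | None = None,
                      n_samples: int = 64) -> TraceSet:
    """Run ``n_traces`` independent traces and collect ensemble statistics.

    ``engine`` is "exact" (event-driven, default) or "fixed".  The result
    is bit-reproducible for a given ``base_seed``: trace ``i`` uses seed
    ``base_seed + i``.  Traces themselves are kept when ``keep_traces`` is
    true (default: only for n_traces <= 100).
    """
    if n_traces < 1:
        raise ValueError(f"n_traces={n_traces!r} must be >= 1")
    if keep_traces is None:
        keep_traces = n_traces <= 100
    sample_times = np.linspace(0.0, t_max, n_samples + 1)[1:]
    nf = np.empty(n_traces, dtype=np.int64)
    nb = np.empty(n_traces, dtype=np.int64)
    nh = np.empty(n_traces, dtype=np.int64)
    nbind = np.empty(n_traces, dtype=np.int64)
    pos = np.empty((n_traces, n_samples), dtype=np.float64)
    kept: list[Trace] | None = [] if keep_traces else None
    for i in range(n_traces):
        if engine == "exact":
            tr = exact_trace(params, conditions, t_max, base_seed + i)
        elif engine == "fixed":
            tr = simulate_trace(params, conditions, t_max, base_seed + i, dt=dt)
        else:
            raise ValueError(f"unknown engine {engine!r}; use 'exact' or 'fixed'")
        nf[i] = tr.n_forward
        nb[i] = tr.n_backward
        nh[i] = tr.n_hydrolysis
        nbind[i] = int(np.count_nonzero(tr.codes == ATP_BIND))
        pos[i] = tr.com_at(sample_times)
        if kept is not None:
            kept.append(tr)
    return TraceSet(params=params, conditions=conditions, t_max=float(t_max),
                    base_seed=int(base_seed), engine=engine,
                    n_forward=nf, n_backward=nb, n_hydrolysis=nh, n_bind=nbind,
                    sample_times=sample_times, positions=pos, traces=kept)
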
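"""Analytical diffusion-signal models and their voxelwise fitting protocols.

Five models of the normalized decay S(b)/S0 are implemented:

* mono-exponential      exp(-b ADC)
* IVIM biexponential    f exp(-b Dperf) + (1-f) exp(-b Ddiff)
* DKI                   exp(-b D + b^2 D^2 K / 6)
* FROC                  exp(-D mu^(2 beta - 2) (gamma Gd delta)^(2 beta)
                             [Delta - (2 beta - 1)/(2 beta + 1) delta])
* CTRW                  E_alpha(-(b Dm)^beta)

Diffusivities are in mm^2/s and b in s/mm^2 throughout.  ADC uses the
two-point estimate at b = 0 and 1000 s/mm^2; IVIM uses the classical
segmented two-step fit (log-linear on 200 <= b <= 1000 for Ddiff and f,
then Dperf on b <= 200 with the first-step values frozen); DKI, FROC and
CTRW are fitted by bounded iterative least squares over all b-values,
initialized from the mono-exponential ADC with K = 0 and alpha = beta = 1.
Normalized signals are fitted with S0 fixed at 1 (no free scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .mittag_leffler import mittag_leffler
from .protocol import AcquisitionProtocol, gd_from_b  # noqa: F401 (re-export)

log = logging.getLogger(__name__)

#: Parameter bounds bracketing physiological ranges.
BOUNDS = {
    "d": (1e-6, 50e-3),        # diffusivity-type, mm^2/s
    "d_perf_max": 0.5,         # pseudo-perfusion coefficient cap, mm^2/s
    "k": (0.0, 3.0),           # kurtosis
    "frac_order": (1e-2, 1.0),  # alpha, beta
    "mu": (0.1, 50.0),         # um
}

MODEL_NAMES = ("mono", "ivim", "dki", "froc", "ctrw")


@dataclass
class MonoFit:
    adc: float
    residual_norm: float = 0.0
    converged: bool = True


@dataclass
class IVIMFit:
    f: float
    d_perf: float
    d_diff: float
    residual_norm: float = 0.0
    converged: bool = True


@dataclass
class DKIFit:
    d: float
    k: float
    residual_norm: float = 0.0
    converged: bool = True


@dataclass
class FROCFit:
    d: float
    beta: float
    mu: float
    residual_norm: float = 0.0
    converged: bool = True


@dataclass
class CTRWFit:
    d_m: float
    alpha: float
    beta: float
    residual_norm: float = 0.0
    converged: bool = True


FIT_TYPES = {"mono": MonoFit, "ivim": IVIMFit, "dki": DKIFit,
             "froc": FROCFit, "ctrw": CTRWFit}


def fit_params(fit) -> dict[str, float]:
    """Model parameters of a fit record (excludes bookkeeping fields)."""
    skip = {"residual_norm", "converged"}
    return {f.name: getattr(fit, f.name) for f in dc_fields(fit)
            if f.name not in skip}


# ---------------------------------------------------------------- signals

def mono_signal(b, adc):
    return np.exp(-np.asarray(b, float) * adc)


def ivim_signal(b, f, d_perf, d_diff):
    b = np.asarray(b, float)
    return f * np.exp(-b * d_perf) + (1.0 - f) * np.exp(-b * d_diff)


def dki_signal(b, d, k):
    b = np.asarray(b, float)
    return np.exp(-b * d + b * b * d * d * k / 6.0)


def froc_signal(b, d, beta, mu, protocol: AcquisitionProtocol):
    """FROC decay; Gd is derived from b via the protocol timing."""
    b = np.asarray(b, float)
    delta = protocol.delta_ms * 1e-3
    Delta = protocol.Delta_ms * 1e-3
    gd = np.array([gd_from_b(bi, delta_ms=protocol.delta_ms,
                             Delta_ms=protocol.Delta_ms,
                             gamma=protocol.gamma) * 1e-3 for bi in b])
    q = protocol.gamma * gd * delta                      # 1/m
    t_eff = Delta - (2.0 * beta - 1.0) / (2.0 * beta + 1.0) * delta
    d_si = d * 1e-6                                       # mm^2/s -> m^2/s
    mu_si = mu * 1e-6                                     # um -> m
    expo = d_si * mu_si ** (2.0 * beta - 2.0) * q ** (2.0 * beta) * t_eff
    return np.exp(-expo)


def ctrw_signal(b, d_m, alpha, beta):
    b = np.asarray(b, float)
    return mittag_leffler(alpha, (b * d_m) ** beta)


# ----------------------------------------------------------------- fitting

def _as_row(row):
    """Accept (b, s) arrays, a mapping, or a pandas row with b_* columns."""
    if isinstance(row, tuple) and len(row) == 2:
        b, s = row
        return np.asarray(b, float), np.asarray(s, float)
    if isinstance(row, pd.Series):
        cols = [c for c in row.index if str(c).startswith("b_")]
        b = np.array([float(str(c)[2:]) for c in cols])
        order = np.argsort(b)
        return b[order], row[cols].to_numpy(dtype=float)[order]
    raise TypeError(f"cannot interpret signal row of type {type(row)!r}")


def fit_mono(row) -> MonoFit:
    """Two-point ADC from b = 0 and 1000 s/mm^2."""
    b, s = _as_row(row)
    i0 = np.flatnonzero(b == 0.0)
    i1 = np.flatnonzero(b == 1000.0)
    if i0.size == 0 or i1.size == 0:
        raise ValueError("mono-exponential fit requires b = 0 and 1000 s/mm^2")
    s0, s1 = float(s[i0[0]]), float(s[i1[0]])
    if s1 <= 0 or s0 <= 0:
        raise ValueError("nonpositive signal at b = 0 or 1000")
    adc = np.log(s0 / s1) / 1000.0
    resid = float(np.hypot(s0 / s0 - 1.0, s1 / s0 - np.exp(-1000.0 * adc)))
    return MonoFit(adc=float(adc), residual_norm=resid)


def fit_ivim(row) -> IVIMFit:
    """Segmented two-step IVIM fit.

    Step 1: log-linear fit on 200 <= b <= 1000 -> Ddiff and f.
    Step 2: Dperf by bounded least squares on b <= 200 with step-1 frozen.
    """
    b, s = _as_row(row)
    hi = (b >= 200.0) & (b <= 1000.0)
    lo = b <= 200.0
    if hi.sum() < 2 or lo.sum() < 2:
        raise ValueError("IVIM needs >= 2 points in both b segments")
    if np.any(s[hi] <= 0):
        raise ValueError("nonpositive signal in the 200-1000 segment")
    coef = np.polyfit(b[hi], np.log(s[hi]), 1)
    d_diff = float(np.clip(-coef[0], *BOUNDS["d"]))
    f = float(np.clip(1.0 - np.exp(coef[1]), 0.0, 1.0))
    if f < 1e-6:
        return IVIMFit(f=f, d_perf=d_diff, d_diff=d_diff,
                       residual_norm=float(np.linalg.norm(
                           ivim_signal(b, f, d_diff, d_diff) - s)))
    lo_b, lo_s = b[lo], s[lo]

    def res(p):
        return ivim_signal(lo_b, f, p[0], d_diff) - lo_s

    sol = least_squares(res, x0=[max(10e-3, d_diff * 2)],
                        bounds=([d_diff], [BOUNDS["d_perf_max"]]))
    d_perf = float(sol.x[0])
    full_res = float(np.linalg.norm(ivim_signal(b, f, d_perf, d_diff) - s))
    return IVIMFit(f=f, d_perf=d_perf, d_diff=d_diff,
                   residual_norm=full_res, converged=bool(sol.success))


def _nls_fit(b, s, model_fn, x0, lb, ub, extra_starts=(), seed: int = 0,
             n_restarts: int = 3):
    """Bounded iterative least squares with multi-start refinement.

    The nominal initialization is tried first, then any deterministic
    ``extra_starts`` (fractional-order models have a saddle at the
    alpha = beta = 1 boundary, so interior restarts are essential), then --
    only if nothing converged -- jittered random restarts.  The best
    residual wins; ties break toward the smaller parameter-vector norm.
    The trust-region iteration is monotone, so the returned residual never
    exceeds the residual at the chosen initialization (descent property).
    """
    x0 = np.clip(np.asarray(x0, float), lb, ub)

    def res(p):
        return model_fn(p) - s

    def better(sol, best):
        if best is None:
            return True
        if sol.cost < best.cost - 1e-15:
            return True
        return (abs(sol.cost - best.cost) <= 1e-15
                and np.linalg.norm(sol.x) < np.linalg.norm(best.x))

    best = None
    for start in [x0, *extra_starts]:
        sol = least_squares(res, x0=np.clip(np.asarray(start, float), lb, ub),
                            bounds=(lb, ub))
        if better(sol, best):
            best = sol
        if best.success and best.cost < 1e-20:
            break
    if not best.success:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            jit = np.clip(
                x0 * rng.uniform(0.5, 2.0, size=x0.size)
                + rng.normal(0, 0.05, size=x0.size)
                * (np.asarray(ub) - np.asarray(lb)), lb, ub)
            sol = least_squares(res, x0=jit, bounds=(lb, ub))
            if sol.success and better(sol, best):
                best = sol
    return best


def _init_adc(b, s):
    """Mono-exponential initialization; falls back to the bound midpoint."""
    try:
        return float(np.clip(fit_mono((b, s)).adc, *BOUNDS["d"]))
    except ValueError:
        mask = (b > 0) & (s > 0)
        if mask.sum() >= 2:
            coef = np.polyfit(b[mask], np.log(s[mask]), 1)
            return float(np.clip(-coef[0], *BOUNDS["d"]))
        return 1e-3


def fit_dki(row) -> DKIFit:
    b, s = _as_row(row)
    _check_points(b, 2)
    adc0 = _init_adc(b, s)
    sol = _nls_fit(b, s, lambda p: dki_signal(b, p[0], p[1]),
                   x0=[adc0, 0.0],
                   lb=[BOUNDS["d"][0], BOUNDS["k"][0]],
                   ub=[BOUNDS["d"][1], BOUNDS["k"][1]])
    return DKIFit(d=float(sol.x[0]), k=float(sol.x[1]),
                  residual_norm=float(np.linalg.norm(sol.fun)),
                  converged=bool(sol.success))


def fit_froc(row, protocol: AcquisitionProtocol) -> FROCFit:
    b, s = _as_row(row)
    _check_points(b, 3)
    adc0 = _init_adc(b, s)
    sol = _nls_fit(b, s, lambda p: froc_signal(b, p[0], p[1], p[2], protocol),
                   x0=[adc0, 1.0, 5.0],
                   lb=[BOUNDS["d"][0], BOUNDS["frac_order"][0], BOUNDS["mu"][0]],
                   ub=[BOUNDS["d"][1], BOUNDS["frac_order"][1], BOUNDS["mu"][1]],
                   extra_starts=([adc0, 0.9, 5.0], [adc0, 0.7, 10.0]))
    return FROCFit(d=float(sol.x[0]), beta=float(sol.x[1]), mu=float(sol.x[2]),
                   residual_norm=float(np.linalg.norm(sol.fun)),
                   converged=bool(sol.success))


def fit_ctrw(row) -> CTRWFit:
    b, s = _as_row(row)
    _check_points(b, 3)
    adc0 = _init_adc(b, s)
    sol = _nls_fit(b, s, lambda p: ctrw_signal(b, p[0], p[1], p[2]),
                   x0=[adc0, 1.0, 1.0],
                   lb=[BOUNDS["d"][0]] + [BOUNDS["frac_order"][0]] * 2,
                   ub=[BOUNDS["d"][1]] + [BOUNDS["frac_order"][1]] * 2,
                   extra_starts=([adc0, 0.9, 0.9], [adc0, 0.7, 0.8]))
    return CTRWFit(d_m=float(sol.x[0]), alpha=float(sol.x[1]),
                   beta=float(sol.x[2]),
                   residual_norm=float(np.linalg.norm(sol.fun)),
                   converged=bool(sol.success))


def _check_points(b, n_params):
    if np.unique(b).size < n_params + 1:
        raise ValueError(
            f"need >= {n_params + 1} distinct b-values for a "
            f"{n_params}-parameter model")


def fit_row(row, model: str, protocol: AcquisitionProtocol | None = None):
    if model == "mono":
        return fit_mono(row)
    if model == "ivim":
        return fit_ivim(row)
    if model == "dki":
        return fit_dki(row)
    if model == "froc":
        if protocol is None:
            raise ValueError("FROC fitting requires an AcquisitionProtocol")
        return fit_froc(row, protocol)
    if model == "ctrw":
        return fit_ctrw(row)
    raise ValueError(f"unknown model: {model!r}")


def fit_table(table: pd.DataFrame, model: str,
              protocol: AcquisitionProtocol | None = None) -> list:
    """Row-wise fits over a signal table; failures are flagged, not raised.

    A failed row yields a fit record with NaN parameters and
    ``converged=False`` so downstream accounting can drop it with a log
    message rather than a crash.
    """
    fits = []
    n_fail = 0
    for _, row in table.iterrows():
        try:
            fits.append(fit_row(row, model, protocol))
        except Exception as exc:  # noqa: BLE001 - aggregate, don't crash
            n_fail += 1
            cls = FIT_TYPES[model]
            nan_params = {f.name: float("nan") for f in dc_fields(cls)
                          if f.name not in ("residual_norm", "converged")}
            fits.append(cls(**nan_params, residual_norm=float("nan"),
                            converged=False))
            log.debug("fit failure (%s): %s", model, exc)
    if n_fail:
        log.info("%s: %d/%d rows failed to fit", model, n_fail, len(table))
    return fits


def fits_to_frame(fits, model: str) -> pd.DataFrame:
    """Tabulate fit records: one parameter column each + bookkeeping."""
    rows = []
    for fit in fits:
        rec = fit_params(fit)
        rec["residual_norm"] = fit.residual_norm
        rec["converged"] = fit.converged
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.insert(0, "model", model)
    return out
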
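"""Inverse problems: T1 mapping, shutter-speed 2SX/3S2X fits, ADC, growth.

All nonlinear fits are bounded least squares (scipy ``least_squares``,
trust-region reflective) with a deterministic ladder of starting points,
so repeated runs are bit-identical.  Multi-start ties are broken toward
the smaller water-exchange rate (the conservative, slow-exchange reading
of a degenerate fit).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .contrast_kinetics import AIFSpec, CAKinetics, dce_forward
from .exchange_relaxation import ThreeSiteParams, TwoSiteParams, ir_tse_signal
from .io import AcquisitionProtocol

__all__ = [
    "FitResult",
    "fit_vfa_t1",
    "fit_2sx",
    "fit_3s2x",
    "adc_map",
    "fit_logistic_growth",
    "baseline_rates_from_t1",
]

#: Default intracellular longitudinal rate held fixed in 3S2X fits, s^-1.
#: Five free physiological parameters already saturate identifiability of a
#: single ROI time course, so R1_i is constrained rather than fitted.
DEFAULT_R1_I = 0.55

#: Parameter bounds bracketing every value reported for gliomas
#: (max observed k_io ~ 10 s^-1; generous headroom on all rates).
BOUNDS_3S2X = {
    "p_b": (0.005, 0.2),
    "p_o": (0.05, 0.6),
    "Ktrans": (0.0, 1.0),  # min^-1
    "k_bo": (0.0, 50.0),  # s^-1
    "k_io": (0.0, 50.0),  # s^-1
}
BOUNDS_2SX = {
    "p_i": (0.2, 0.95),
    "k_io": (0.0, 50.0),
    "R1_i": (0.05, 5.0),
    "R1_o": (0.05, 60.0),
}

#: Deterministic multi-start ladder, log-spaced in k_io.
KIO_STARTS = tuple(np.geomspace(0.5, 20.0, 5))

_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class FitResult:
    """Outcome of a bounded nonlinear fit.

    ``goodness_r`` is the Pearson correlation between fitted and observed
    signal; ``flags`` carries qualitative diagnostics such as
    ``non_identifiable`` for enhancement-free dynamic courses.
    """

    estimates: Mapping[str, float]
    goodness_r: float
    residual_rms: float
    converged: bool
    n_restarts_used: int
    flags: tuple[str, ...] = ()


def _finish(estimates, model, data, converged, n_restarts, flags=()) -> FitResult:
    model = np.asarray(model, dtype=float)
    data = np.asarray(data, dtype=float)
    if np.std(model) > 0 and np.std(data) > 0:
        r = float(pearsonr(model, data)[0])
    else:
        r = 0.0
    rms = float(np.sqrt(np.mean((model - data) ** 2)))
    return FitResult(
        estimates=dict(estimates),
        goodness_r=r,
        residual_rms=rms,
        converged=converged,
        n_restarts_used=n_restarts,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# variable-flip-angle T1 (DESPOT1)
# ---------------------------------------------------------------------------


def fit_vfa_t1(s_fa1, s_fa2, fa1: float, fa2: float, tr: float):
    """Exact two-point DESPOT1 solution of the SPGR equation.

    Linearizes ``S/sin a = E1 * S/tan a + M0 (1 - E1)`` through the two
    flip-angle measurements; ``T1 = -TR / ln E1``.  Accepts scalars or
    images (elementwise).  Non-physical slopes (outside (0, 1)) raise for
    scalar input and are masked to NaN for arrays.

    Returns
    -------
    (T1, M0):
        T1 in seconds, M0 in arbitrary units.
    """
    if fa1 == fa2:
        raise ValueError("flip angles must be distinct")
    s1 = np.asarray(s_fa1, dtype=float)
    s2 = np.asarray(s_fa2, dtype=float)
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValueError("signals must be positive")
    a1, a2 = np.deg2rad(fa1), np.deg2rad(fa2)
    y1, y2 = s1 / np.sin(a1), s2 / np.sin(a2)
    x1, x2 = s1 / np.tan(a1), s2 / np.tan(a2)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (y2 - y1) / (x2 - x1)
        valid = (e1 > 0) & (e1 < 1)
        t1 = np.where(valid, -tr / np.log(np.where(valid, e1, 0.5)), np.nan)
        m0 = np.where(valid, (y1 - e1 * x1) / (1.0 - e1), np.nan)
    if t1.ndim == 0:
        if not bool(valid):
            raise ValueError(f"non-physical T1: DESPOT1 slope {float(e1):.4g} outside (0, 1)")
        return float(t1), float(m0)
    return t1, m0


# ---------------------------------------------------------------------------
# 2SX fit of inversion-recovery data at two contrast levels
# ---------------------------------------------------------------------------


def _as_ir_table(data) -> pd.DataFrame:
    df = pd.DataFrame(data)
    if not {"delay_s", "signal"}.issubset(df.columns):
        raise ValueError("IR table needs columns (delay_s, signal)")
    return df


def fit_2sx(
    ir_data_0mM,
    ir_data_5mM,
    inv_eff: float = 1.0,
    max_restarts: int = len(KIO_STARTS),
) -> FitResult:
    """Joint two-site-exchange fit of IR curves at 0 and 5 mM contrast.

    The two concentrations share the intracellular parameters
    ``{p_i, k_io, R1_i}`` while each has its own extracellular rate
    (the 5 mM bath shortens extracellular T1 dramatically, creating the
    shutter-speed condition that makes ``k_io`` identifiable).

    Parameters
    ----------
    ir_data_0mM, ir_data_5mM:
        Tables with columns ``delay_s`` and ``signal`` (normalized IR-TSE).
    """
    df0 = _as_ir_table(ir_data_0mM)
    df5 = _as_ir_table(ir_data_5mM)
    if len(df0) < 5 or len(df5) < 5:
        raise ValueError("need >= 5 inversion delays per concentration")
    t0 = df0["delay_s"].to_numpy(float)
    t5 = df5["delay_s"].to_numpy(float)
    y = np.concatenate([df0["signal"].to_numpy(float), df5["signal"].to_numpy(float)])

    lo = [BOUNDS_2SX["p_i"][0], BOUNDS_2SX["k_io"][0], BOUNDS_2SX["R1_i"][0],
          BOUNDS_2SX["R1_o"][0], BOUNDS_2SX["R1_o"][0]]
    hi = [BOUNDS_2SX["p_i"][1], BOUNDS_2SX["k_io"][1], BOUNDS_2SX["R1_i"][1],
          BOUNDS_2SX["R1_o"][1], BOUNDS_2SX["R1_o"][1]]

    def forward(theta):
        p_i, k_io, r1_i, r1_o0, r1_o5 = theta
        par0 = TwoSiteParams(p_i=p_i, k_io=k_io, R1_i=r1_i, R1_o=r1_o0)
        par5 = TwoSiteParams(p_i=p_i, k_io=k_io, R1_i=r1_i, R1_o=r1_o5)
        return np.concatenate(
            [ir_tse_signal(t0, par0, inv_eff), ir_tse_signal(t5, par5, inv_eff)]
        )

    best = None
    n_used = 0
    # the slow-exchange regime has a pool-label-swapped mirror minimum, so
    # the ladder crosses each k_io start with both (R1_i, R1_o) orderings
    for k_start in KIO_STARTS[:max_restarts]:
        for r1_i0, r1_o0 in ((0.3, 0.7), (0.7, 0.3)):
            x0 = np.array([0.7, k_start, r1_i0, r1_o0, 20.0])
            res = least_squares(
                lambda th: forward(th) - y, x0, bounds=(lo, hi),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=3000,
            )
            n_used += 1
            if best is None or res.cost < best.cost * (1.0 - _TIE_RTOL):
                best = res
    p_i, k_io, r1_i, r1_o0, r1_o5 = best.x
    estimates = {
        "p_i": p_i, "k_io": k_io, "R1_i": r1_i, "R1_o_0mM": r1_o0, "R1_o_5mM": r1_o5,
    }
    return _finish(estimates, forward(best.x), y, bool(best.success), n_used)


# ---------------------------------------------------------------------------
# 3S2X fit of a dynamic time course
# ---------------------------------------------------------------------------


def baseline_rates_from_t1(
    t1_0: float, p_b: float, p_o: float, r1_i: float = DEFAULT_R1_I
) -> float:
    """Shared blood/extracellular baseline rate consistent with the
    measured pre-contrast T1 under fast-exchange averaging:
    ``p_b R1_b0 + p_o R1_o0 + p_i R1_i = 1/t1_0`` with ``R1_b0 = R1_o0``."""
    p_i = 1.0 - p_b - p_o
    r = (1.0 / t1_0 - p_i * r1_i) / (p_b + p_o)
    if r <= 0:
        raise ValueError("pre-contrast T1 inconsistent with fixed R1_i")
    return r


def _three_site(theta, t1_0: float, r1_i: float) -> tuple[ThreeSiteParams, CAKinetics]:
    p_b, p_o, ktrans, k_bo, k_io = theta
    base = baseline_rates_from_t1(t1_0, p_b, p_o, r1_i)
    params = ThreeSiteParams(
        p_b=p_b, p_o=p_o, p_i=1.0 - p_b - p_o,
        k_bo=k_bo, k_io=k_io, R1_b0=base, R1_o0=base, R1_i=r1_i,
    )
    kin = CAKinetics(Ktrans=ktrans, v_o=p_o)
    return params, kin


def fit_3s2x(
    timecourse,
    protocol: AcquisitionProtocol,
    t1_0: float,
    aif: AIFSpec,
    r1_i: float = DEFAULT_R1_I,
    max_restarts: int = len(KIO_STARTS),
) -> FitResult:
    """Five-parameter shutter-speed fit of a dynamic SPGR time course.

    Free parameters: ``p_b, p_o, Ktrans, k_bo, k_io`` (``p_i`` enforced as
    the complement; contrast distribution volume tied to ``p_o``).  Blood
    and extracellular baseline rates are constrained by the measured
    pre-contrast T1 ``t1_0``; ``R1_i`` is fixed.  The time course is
    baseline-normalized before fitting, so amplitude carries no free scale.
    """
    if t1_0 <= 0:
        raise ValueError("t1_0 must be positive")
    y = np.asarray(timecourse, dtype=float)
    if y.ndim != 1 or y.size != protocol.n_frames:
        raise ValueError("timecourse length must equal protocol.n_frames")
    n_pre = int(min(protocol.bolus_frames)) if protocol.bolus_frames else y.size
    base = y[: max(n_pre, 1)].mean()
    y_norm = y / base
    enhancement = float(np.max(np.abs(y_norm - 1.0)))
    if enhancement < 1e-3:
        return _finish(
            {k: np.nan for k in BOUNDS_3S2X}, np.ones_like(y_norm), y_norm,
            converged=False, n_restarts=0, flags=("non_identifiable",),
        )

    names = list(BOUNDS_3S2X)
    lo = [BOUNDS_3S2X[k][0] for k in names]
    hi = [BOUNDS_3S2X[k][1] for k in names]

    def forward(theta):
        params, kin = _three_site(theta, t1_0, r1_i)
        return dce_forward(protocol, params, kin, aif, normalize=True)

    def residual(theta):
        return forward(theta) - y_norm

    best = None
    n_used = 0
    for k_start in KIO_STARTS[:max_restarts]:
        x0 = np.array([0.05, 0.3, 0.1, 3.0, k_start])
        res = least_squares(residual, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        n_used += 1
        if best is None or res.cost < best.cost * (1.0 - _TIE_RTOL):
            best = res
    estimates = dict(zip(names, best.x))
    estimates["p_i"] = 1.0 - estimates["p_b"] - estimates["p_o"]
    return _finish(estimates, forward(best.x), y_norm, bool(best.success), n_used)


# ---------------------------------------------------------------------------
# ADC and logistic growth
# ---------------------------------------------------------------------------


def adc_map(s_b0, s_b1000, b1: float = 0.0, b2: float = 1000.0) -> np.ndarray:
    """Apparent diffusion coefficient, mm^2/s: ``ln(S_b0/S_b1000)/(b2-b1)``.

    Voxels with non-positive signal ratios are masked to NaN rather than
    raising (they occur at the noise floor of real data).
    """
    if b2 <= b1:
        raise ValueError("need b2 > b1")
    s0 = np.asarray(s_b0, dtype=float)
    s1 = np.asarray(s_b1000, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s0 / s1
        out = np.where(ratio > 0, np.log(np.where(ratio > 0, ratio, 1.0)), np.nan)
    return out / (b2 - b1)


def fit_logistic_growth(
    times,
    counts,
    fix_A: float | None = None,
) -> FitResult:
    """Fit the logistic growth law ``Y = A / (B exp(-r T) + c)``.

    The law has a scaling degeneracy (A, B, c can be scaled jointly), so
    the fit is performed in the reduced parametrization
    ``Y = P / (beta exp(-r T) + 1)`` with plateau ``P = A/c`` and shape
    ``beta = B/c``.  Pass ``fix_A`` to pin the reported A and resolve
    (B, c) on the original scale.  Starting points ladder upward in the
    growth rate with ties broken toward the smaller rate, so constant
    counts resolve to ``r_growth ~ 0``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(counts, dtype=float)
    if t.size < 4:
        raise ValueError("need >= 4 time points")

    def model(theta):
        plateau, beta, r = theta
        return plateau / (beta * np.exp(-r * t) + 1.0)

    y_max = float(y.max())
    lo = [1e-6, 1e-9, 0.0]
    hi = [50.0 * y_max, 1e4, 1.0]
    best = None
    n_used = 0
    for r_start in (0.0, 0.01, 0.04, 0.1):
        x0 = np.array([max(y_max, 1e-6), 2.0, r_start])
        res = least_squares(lambda th: model(th) - y, x0, bounds=(lo, hi),
                            xtol=1e-13, ftol=1e-13)
        n_used += 1
        if best is None or res.cost < best.cost * (1.0 - _TIE_RTOL):
            best = res
    plateau, beta, r = best.x
    if fix_A is not None:
        c = fix_A / plateau
        a_val, b_val = fix_A, beta * c
    else:
        a_val, b_val, c = plateau, beta, 1.0
    estimates = {
        "A": a_val, "B": b_val, "c": c, "r_growth": r, "plateau": plateau,
    }
    return _finish(estimates, model(best.x), y, bool(best.success), n_used)
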
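"""Longitudinal relaxation of multi-pool water-exchange systems.

Tissue water is partitioned into discrete pools (intracellular /
extracellular for cell pellets; blood / extracellular-extravascular /
intracellular in vivo) that exchange magnetization at finite rates while
each relaxes with its own longitudinal rate R1.  The coupled evolution of
the longitudinal magnetization vector ``m`` (in equilibrium mole-fraction
units, so ``m_eq = p``) is

    dm/dt = -R (m - p) - K m,

where ``R`` is the diagonal matrix of pool R1s and ``K`` is the exchange
generator with ``K p = 0`` (detailed balance).  Everything downstream —
inversion-recovery signals, spoiled-gradient-echo (SPGR) dynamic signals,
and the shutter-speed fits built on them — reduces to eigen-solutions or
propagators of the matrix ``A = R + K``.

Conventions
-----------
* Mole fractions are dimensionless and sum to 1; rates are s^-1.
* Back-exchange rates follow detailed balance: ``k_oi = k_io p_i / p_o``
  and ``k_ob = k_bo p_b / p_o``; only efflux rates are free parameters.
* Biexponential components are labelled L (long T1, small rate) and S
  (short T1, large rate), so ``R1_S > R1_L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TwoSiteParams",
    "ThreeSiteParams",
    "BiexpSolution",
    "apparent_biexponential",
    "ir_tse_signal",
    "exchange_matrix_2site",
    "exchange_matrix_3site",
    "longitudinal_propagate",
    "spgr_frame_signal",
]

_FRACTION_TOL = 1e-12


@dataclass(frozen=True)
class TwoSiteParams:
    """Two-site exchange (2SX) system: intracellular (i) <-> extracellular (o).

    Parameters
    ----------
    p_i:
        Intracellular water mole fraction, in (0, 1).
    k_io:
        Steady-state intracellular-to-extracellular water-efflux rate, s^-1.
    R1_i, R1_o:
        Pool longitudinal relaxation rates, s^-1.
    """

    p_i: float
    k_io: float
    R1_i: float
    R1_o: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_i < 1.0):
            raise ValueError(f"p_i must lie in (0, 1), got {self.p_i}")
        if self.p_o <= _FRACTION_TOL:
            raise ValueError("p_o ~ 0: influx rate k_oi undefined")
        if self.k_io < 0:
            raise ValueError(f"k_io must be >= 0, got {self.k_io}")
        if self.R1_i <= 0 or self.R1_o <= 0:
            raise ValueError("pool R1 rates must be positive")

    @property
    def p_o(self) -> float:
        return 1.0 - self.p_i

    @property
    def k_oi(self) -> float:
        """Influx rate fixed by detailed balance, s^-1."""
        return self.k_io * self.p_i / self.p_o


@dataclass(frozen=True)
class ThreeSiteParams:
    """Three-site two-exchange (3S2X) system: blood (b) <-> extracellular
    extravascular (o) <-> intracellular (i); no direct b <-> i pathway.

    ``R1_b0`` and ``R1_o0`` are the pre-contrast (baseline) rates; during a
    dynamic experiment the instantaneous blood/extracellular rates are
    raised by the contrast agent while ``R1_i`` is untouched (the agent is
    extracellular-only).
    """

    p_b: float
    p_o: float
    p_i: float
    k_bo: float
    k_io: float
    R1_b0: float
    R1_o0: float
    R1_i: float

    def __post_init__(self) -> None:
        fracs = (self.p_b, self.p_o, self.p_i)
        if any(not (0.0 < f < 1.0) for f in fracs):
            raise ValueError(f"all mole fractions must lie in (0, 1), got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1, got {sum(fracs)!r}")
        if self.k_bo < 0 or self.k_io < 0:
            raise ValueError("exchange rates must be >= 0")
        if min(self.R1_b0, self.R1_o0, self.R1_i) <= 0:
            raise ValueError("baseline R1 rates must be positive")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.p_b, self.p_o, self.p_i])

    @property
    def k_ob(self) -> float:
        return self.k_bo * self.p_b / self.p_o

    @property
    def k_oi(self) -> float:
        return self.k_io * self.p_i / self.p_o


@dataclass(frozen=True)
class BiexpSolution:
    """Apparent biexponential decomposition of a 2SX recovery.

    ``R1_S > R1_L`` (S = short-T1, fast component); apparent fractions sum
    to 1 but are not the pool fractions unless exchange vanishes.
    """

    R1_L: float
    R1_S: float
    a_L: float
    a_S: float

    def __post_init__(self) -> None:
        if not self.R1_S >= self.R1_L > 0:
            raise ValueError("component ordering violated: need R1_S >= R1_L > 0")
        if abs(self.a_L + self.a_S - 1.0) > 1e-9:
            raise ValueError("apparent fractions must sum to 1")


def exchange_matrix_2site(params: TwoSiteParams) -> np.ndarray:
    """Return ``A = R + K`` for the 2SX system, pool order (i, o)."""
    k_io, k_oi = params.k_io, params.k_oi
    return np.array(
        [
            [params.R1_i + k_io, -k_oi],
            [-k_io, params.R1_o + k_oi],
        ]
    )


def apparent_biexponential(params: TwoSiteParams) -> BiexpSolution:
    """Closed-form eigen-solution of the 2SX relaxation matrix.

    The deviation from equilibrium evolves as ``d' = -A d`` with
    ``A = diag(R1_i, R1_o) + [[k_io, -k_oi], [-k_io, k_oi]]``.  The total
    observable magnetization then recovers biexponentially with the two
    eigenvalues of ``A`` as apparent rates; the apparent fractions are the
    eigen-components of the equilibrium vector weighted by observability.
    """
    p_i, p_o = params.p_i, params.p_o
    r_i, r_o = params.R1_i, params.R1_o
    k_io, k_oi = params.k_io, params.k_oi

    a11 = r_i + k_io
    a22 = r_o + k_oi
    # eigenvalues of [[a11, -k_oi], [-k_io, a22]]
    tr = a11 + a22
    disc = np.sqrt((a11 - a22) ** 2 + 4.0 * k_io * k_oi)
    lam_l = 0.5 * (tr - disc)  # long-T1 (slow) component
    lam_s = 0.5 * (tr + disc)

    if disc < 1e-14 * max(tr, 1.0):
        # degenerate rates: recovery is effectively monoexponential
        return BiexpSolution(R1_L=lam_l, R1_S=lam_s, a_L=1.0, a_S=0.0)

    # d(t) = exp(-A t) d0 with d0 ∝ p; expand p on the eigenvectors of A
    # and project each mode onto the observed sum.  For a 2x2 this reduces
    # to a closed form via the spectral projector (A - lam_s I)/(lam_l - lam_s).
    # a_L = 1ᵀ P_L p with P_L the projector onto the slow eigenspace.
    p_vec = np.array([p_i, p_o])
    ones = np.array([1.0, 1.0])
    a_mat = np.array([[a11, -k_oi], [-k_io, a22]])
    proj_l = (a_mat - lam_s * np.eye(2)) / (lam_l - lam_s)
    a_l = float(ones @ proj_l @ p_vec)
    a_s = 1.0 - a_l
    return BiexpSolution(R1_L=lam_l, R1_S=lam_s, a_L=a_l, a_S=a_s)


def ir_tse_signal(
    delays: np.ndarray,
    params: TwoSiteParams,
    inv_eff: float = 1.0,
) -> np.ndarray:
    """Normalized inversion-recovery signal of a 2SX system.

    ``S(t)/S(inf) = 1 - 2 e [a_L exp(-R1_L t) + a_S exp(-R1_S t)]`` with
    inversion efficiency ``e`` (1 = ideal 180 deg pulse).  The turbo-spin-
    echo readout is treated as a pure longitudinal sample: the echo time
    (~3 ms) is far below tissue T2, so echo-train weighting is neglected.

    Parameters
    ----------
    delays:
        Inversion delays, s (non-negative).
    inv_eff:
        Inversion efficiency in (0, 1].
    """
    delays = np.asarray(delays, dtype=float)
    if np.any(delays < 0):
        raise ValueError("inversion delays must be non-negative")
    if not (0.0 < inv_eff <= 1.0):
        raise ValueError(f"inv_eff must lie in (0, 1], got {inv_eff}")
    sol = apparent_biexponential(params)
    rec = sol.a_L * np.exp(-sol.R1_L * delays) + sol.a_S * np.exp(-sol.R1_S * delays)
    return 1.0 - 2.0 * inv_eff * rec


def exchange_matrix_3site(
    params: ThreeSiteParams, R1_b: float, R1_o: float
) -> np.ndarray:
    """Return ``A = R + K`` for the 3S2X system, pool order (b, o, i).

    ``R1_b`` / ``R1_o`` are the instantaneous (contrast-modified) rates;
    the intracellular rate is always the baseline ``params.R1_i``.
    """
    k_bo, k_ob = params.k_bo, params.k_ob
    k_io, k_oi = params.k_io, params.k_oi
    return np.array(
        [
            [R1_b + k_bo, -k_ob, 0.0],
            [-k_bo, R1_o + k_ob + k_oi, -k_io],
            [0.0, -k_oi, params.R1_i + k_io],
        ]
    )


def _stacked_expm(a_mats: np.ndarray, dt: float | np.ndarray) -> np.ndarray:
    """exp(-A dt) for a stack of small exchange-relaxation matrices.

    A = R + K with K detailed-balanced is similar to a symmetric matrix
    (conjugate by diag(sqrt(p))), so its eigenvalues are real; a batched
    eigendecomposition is both fast and exact here.
    """
    w, v = np.linalg.eig(a_mats)
    w = w.real
    v = v.real
    dt = np.asarray(dt, dtype=float)
    phases = np.exp(-w * (dt[..., None] if dt.ndim else dt))
    return np.einsum("...ij,...j,...jk->...ik", v, phases, np.linalg.inv(v))


def longitudinal_propagate(
    params: ThreeSiteParams,
    R1_b: float,
    R1_o: float,
    m0: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Propagate the three-pool longitudinal magnetization over ``dt``.

    Solves ``dm/dt = -R (m - p) - K m`` with rates held constant over the
    interval (quasi-static contrast agent):
    ``m(dt) = p + exp(-(R + K) dt) (m0 - p)``.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    m0 = np.asarray(m0, dtype=float)
    p = params.fractions
    if dt == 0.0:
        return m0.copy()
    a_mat = exchange_matrix_3site(params, R1_b, R1_o)
    return p + _stacked_expm(a_mat, dt) @ (m0 - p)


def spgr_frame_signal(
    params: ThreeSiteParams,
    R1_b: float,
    R1_o: float,
    fa: float,
    tr: float,
) -> float:
    """Steady-state SPGR signal of the three-pool system at one frame.

    Within a dynamic frame the contrast concentration is quasi-static
    (frame spacing >> TR), so the pulse train reaches the steady state

        m_ss = (I - E cos a)^-1 (p - E p),   E = exp(-(R + K) TR),

    and the observed signal is ``sin(a) * sum(m_ss)`` (perfect spoiling).

    Parameters
    ----------
    fa:
        Flip angle, degrees, in (0, 90).
    tr:
        Repetition time, s.
    """
    if not (0.0 < fa < 90.0):
        raise ValueError(f"flip angle must lie in (0, 90) degrees, got {fa}")
    if tr <= 0:
        raise ValueError("tr must be positive")
    sig = spgr_frame_signal_many(
        params, np.atleast_1d(R1_b), np.atleast_1d(R1_o), fa, tr
    )
    return float(sig[0])


def spgr_frame_signal_many(
    params: ThreeSiteParams,
    R1_b: np.ndarray,
    R1_o: np.ndarray,
    fa: float,
    tr: float,
) -> np.ndarray:
    """Vectorized :func:`spgr_frame_signal` over per-frame (R1_b, R1_o)."""
    R1_b = np.asarray(R1_b, dtype=float)
    R1_o = np.asarray(R1_o, dtype=float)
    n = R1_b.shape[0]
    k_bo, k_ob = params.k_bo, params.k_ob
    k_io, k_oi = params.k_io, params.k_oi

    a_mats = np.zeros((n, 3, 3))
    a_mats[:, 0, 0] = R1_b + k_bo
    a_mats[:, 0, 1] = -k_ob
    a_mats[:, 1, 0] = -k_bo
    a_mats[:, 1, 1] = R1_o + k_ob + k_oi
    a_mats[:, 1, 2] = -k_io
    a_mats[:, 2, 1] = -k_oi
    a_mats[:, 2, 2] = params.R1_i + k_io

    e_mats = _stacked_expm(a_mats, tr)
    p = params.fractions
    cos_a = np.cos(np.deg2rad(fa))
    sys = np.eye(3)[None, :, :] - cos_a * e_mats
    rhs = p[None, :] - e_mats @ p
    try:
        m_ss = np.linalg.solve(sys, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError as err:  # pragma: no cover - pathological
        raise ArithmeticError("singular SPGR steady-state system") from err
    return np.sin(np.deg2rad(fa)) * m_ss.sum(axis=-1)
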
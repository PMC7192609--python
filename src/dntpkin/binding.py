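"""Quadratic tight-binding analysis of fast-phase relative amplitudes.

Specific dNTP incorporation and background probe hydrolysis compete for the
same polymerase:template:primer:probe (ETPP) complexes, so the fraction of
total signal carried by the fast phase, relA1 = A1/(A1+A2), saturates as
the added dNTP exceeds the complex.  Because the dNTP is substoichiometric
to the complex over most of the assay range, the usual hyperbolic binding
isotherm does not apply; the ligand-depletion ("tight-binding") form does:

    F(L_T) = F0 + A_quad * [(E_T + L_T + K_app)
             - sqrt((E_T + L_T + K_app)^2 - 4 E_T L_T)] / (2 E_T)

with L_T the total added dNTP (pmol), E_T the ETPP complex (pmol), K_app
the apparent dissociation constant (pmol), F0 the intercept and A_quad the
total change over the range.  Only the minus root is physical: it gives 0
bound fraction at L_T = 0 and saturates at 1, whereas the plus root starts
above 1 and diverges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .kinetics import ExpFitResult

__all__ = [
    "QuadraticBindingFit",
    "relative_amplitudes",
    "eval_quadratic_binding",
    "fit_quadratic_binding",
]


@dataclass
class QuadraticBindingFit:
    """Parameters of the quadratic (ligand-depletion) binding model."""

    A_quad: float
    F0: float
    E_T: float
    K_app: float
    se_A_quad: float = math.nan
    se_F0: float = math.nan
    se_E_T: float = math.nan
    se_K_app: float = math.nan
    rss: float = math.nan
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (self.E_T > 0):
            raise ValueError("E_T must be positive")
        if self.K_app < 0:
            raise ValueError("K_app must be >= 0")

    @property
    def saturation(self) -> float:
        """Model value in the superstoichiometric limit, F0 + A_quad."""
        return self.F0 + self.A_quad


def relative_amplitudes(fit: ExpFitResult) -> tuple[float, float]:
    """Phase amplitudes normalized by the total, (A1, A2)/(A1+A2)."""
    if fit.model != "double":
        raise ValueError("relative amplitudes need a double-model fit")
    total = fit.A1 + fit.A2
    if total <= 0:
        raise ValueError("total amplitude must be positive")
    return fit.A1 / total, fit.A2 / total


def _quad_bound_fraction(L_T, E_T, K_app):
    L_T = np.asarray(L_T, dtype=float)
    s = E_T + L_T + K_app
    disc = np.maximum(s * s - 4.0 * E_T * L_T, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * E_T)


def eval_quadratic_binding(params: QuadraticBindingFit, L_T):
    """Model value at total added dNTP ``L_T`` (pmol, scalar or array)."""
    if np.any(np.asarray(L_T) < 0):
        raise ValueError("L_T must be >= 0")
    out = params.F0 + params.A_quad * _quad_bound_fraction(L_T, params.E_T, params.K_app)
    return float(out) if np.isscalar(L_T) else out


def _model(L, A_quad, F0, E_T, K_app):
    return F0 + A_quad * _quad_bound_fraction(L, E_T, K_app)


def fit_quadratic_binding(
    points,
    init: QuadraticBindingFit | None = None,
    fix_E_T: float | None = None,
    multistart: int = 10,
    seed: int = 0,
) -> QuadraticBindingFit:
    """Nonlinear least-squares fit of (amount_pmol, relA1) data.

    ``points`` is a sequence of (L_T, value) pairs or a pair of arrays.
    A_quad may be negative (the slow-phase mirror relA2 decreases with the
    same magnitude).  ``fix_E_T`` pins the complex concentration when it is
    known independently.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 2 and pts.shape[1] == 2:
        L, y = pts[:, 0], pts[:, 1]
    else:
        L, y = np.asarray(points[0], dtype=float), np.asarray(points[1], dtype=float)
    if L.size < 5:
        raise ValueError("need >= 5 points spanning sub- and superstoichiometric amounts")
    if np.unique(L).size < 2:
        raise ValueError("points all at one amount")

    order = np.argsort(L)
    Ls, ys = L[order], y[order]
    if init is not None:
        p0 = [init.A_quad, init.F0, init.E_T, init.K_app]
    else:
        F0_0 = float(ys[0] if Ls[0] > 0 else ys[Ls > 0][0] if (Ls > 0).any() else ys[0])
        if Ls[0] == 0:
            F0_0 = float(ys[0])
        A0 = float(ys[-1] - F0_0)
        half = F0_0 + 0.5 * A0
        idx = int(np.argmin(np.abs(ys - half)))
        E0 = float(max(Ls[idx], 1e-3))
        p0 = [A0, F0_0, E0, 0.1 * E0]

    if fix_E_T is not None:
        def func(Lx, A_quad, F0, K_app):
            return _model(Lx, A_quad, F0, fix_E_T, K_app)
        bounds = ([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf])
        p0_use = [p0[0], p0[1], p0[3]]
    else:
        func = _model
        bounds = ([-np.inf, -np.inf, 1e-12, 0.0], [np.inf, np.inf, np.inf, np.inf])
        p0_use = p0

    rng = np.random.default_rng(seed)
    best = None
    guess = np.clip(p0_use, bounds[0], bounds[1])
    for attempt in range(1 + multistart):
        if attempt > 0:
            jitter = rng.uniform(0.3, 3.0, size=len(p0_use))
            guess = np.clip(np.asarray(p0_use) * jitter, bounds[0], bounds[1])
            guess[np.asarray(p0_use) == 0] = rng.uniform(0, 1)
        try:
            popt, pcov = optimize.curve_fit(
                func, L, y, p0=guess, bounds=bounds, method="trf",
                xtol=1e-13, ftol=1e-13, gtol=1e-13, maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((func(L, *popt) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise RuntimeError("quadratic binding fit did not converge after multistart")

    popt, pcov, rss = best
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(len(popt), np.nan)
    if fix_E_T is not None:
        A_quad, F0, K_app = popt
        return QuadraticBindingFit(
            A_quad=float(A_quad), F0=float(F0), E_T=float(fix_E_T), K_app=float(K_app),
            se_A_quad=float(se[0]), se_F0=float(se[1]), se_K_app=float(se[2]),
            rss=rss, n_points=int(L.size),
        )
    A_quad, F0, E_T, K_app = popt
    return QuadraticBindingFit(
        A_quad=float(A_quad), F0=float(F0), E_T=float(E_T), K_app=float(K_app),
        se_A_quad=float(se[0]), se_F0=float(se[1]),
        se_E_T=float(se[2]), se_K_app=float(se[3]),
        rss=rss, n_points=int(L.size),
    )
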
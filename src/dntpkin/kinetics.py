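"""Exponential decomposition of single-cycle fluorescence progress curves.

The assay is a single primer-elongation cycle, not PCR: the probe releases
its fluorophore either through specific dNTP incorporation (fast phase) or
through the polymerase's background 5'-3' exonuclease hydrolysis (slow
phase).  A progress curve is therefore modelled as a rising saturating
signal, written with positive amplitudes,

    single:  F(t) = F0 - A  * exp(-k_obs  * t)
    double:  F(t) = F0 - A1 * exp(-k1_obs * t) - A2 * exp(-k2_obs * t)

where F0 is the plateau (y offset), A / A1 / A2 >= 0 are phase amplitudes in
fluorescence units and the rate constants are in s^-1.  The fast phase is by
convention the one with the larger rate constant (k1_obs > k2_obs); its
amplitude A1 is the quantification readout.  The single and the double model
are both fitted to every well and compared with the small-sample corrected
Akaike information criterion,

    AICc = 2k + N ln(RSS)                              if N/k >= 40
    AICc = 2k + N ln(RSS) + 2k(k+1)/(N-k-1)            if N/k < 40

with k = 3 (single) or 5 (double) fitted parameters and N data points; a
blank reaction (no specific dNTP) selects the single model, a reaction with
specific dNTP the double one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import yaml
from scipy import optimize, stats

from .curves_io import ProgressCurve

__all__ = [
    "FitConfig",
    "ExpFitResult",
    "model_single",
    "model_double",
    "eval_model",
    "compute_aic",
    "fit_curve",
    "select_model",
    "trim_lag",
]

K_PARAMS = {"single": 3, "double": 5}


@dataclass
class FitConfig:
    """Numerical settings for progress-curve fitting.

    k_bounds
        Allowed range for the observed rate constants (s^-1).  The default
        spans from far below the slowest background hydrolysis observed on
        thermostable polymerases to 1 s^-1.
    amplitude_lower_bound
        0 keeps amplitudes physical (rising curves); set to ``-inf`` to let
        inverse (falling) runs fit with a negative raw amplitude so QC can
        flag them.
    multistart
        Number of randomized restarts attempted when the deterministic
        start fails to converge or fits poorly.
    max_lag_s
        Longest initial lag phase (s) that :func:`trim_lag` may remove.
    trim_patience
        Candidate trims evaluated past the current best before the lag
        search stops; ``None`` forces an exhaustive scan of all candidates.
    """

    k_bounds: tuple[float, float] = (1e-7, 1.0)
    amplitude_lower_bound: float = 0.0
    multistart: int = 5
    tol: float = 1e-10
    max_nfev: int = 2000
    max_lag_s: float = 240.0
    seed: int = 0
    degenerate_k_rtol: float = 0.01
    perfect_fit_rtol: float = 1e-6
    trim_patience: int | None = 2

    def __post_init__(self) -> None:
        lo, hi = self.k_bounds
        if not (0 < lo < hi):
            raise ValueError("k_bounds must be positive and ordered")
        if self.max_lag_s < 0:
            raise ValueError("max_lag_s must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "FitConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "k_bounds" in data:
            data["k_bounds"] = tuple(float(x) for x in data["k_bounds"])
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})


@dataclass
class ExpFitResult:
    """Fitted exponential model for one well.

    For the single model the sole amplitude/rate pair is stored in
    ``A1``/``k1obs`` and ``A2``/``k2obs`` are ``None``.  For the double model
    the phases are reported in fast-first order (``k1obs > k2obs``);
    ``raw_A1`` keeps the fast amplitude as fitted, before reordering and
    sign conventions, for inverse-run QC.
    """

    model: Literal["single", "double"]
    A1: float
    k1obs: float
    F0: float
    A2: float | None = None
    k2obs: float | None = None
    se_A1: float = math.nan
    se_k1obs: float = math.nan
    se_A2: float = math.nan
    se_k2obs: float = math.nan
    se_F0: float = math.nan
    rss: float = math.nan
    n_points: int = 0
    k_params: int = 3
    aicc: float = math.nan
    converged: bool = True
    trim_offset_s: float = 0.0
    perfect_fit: bool = False
    raw_A1: float | None = None
    aicc_single: float | None = None
    aicc_double: float | None = None

    def __post_init__(self) -> None:
        if self.model == "double" and self.converged:
            if self.k2obs is None or self.A2 is None:
                raise ValueError("double model needs A2 and k2obs")
            if not (self.k1obs > self.k2obs):
                raise ValueError("phase ordering requires k1obs > k2obs")
        if self.converged and not math.isnan(self.rss) and self.rss < 0:
            raise ValueError("RSS must be >= 0")

    @property
    def total_amplitude(self) -> float:
        return self.A1 + (self.A2 or 0.0)


def model_single(t, A, k_obs, F0):
    if np.any(np.asarray(k_obs) < 0):
        raise ValueError("negative rate constant")
    return F0 - A * np.exp(-k_obs * np.asarray(t, dtype=float))


def model_double(t, A1, k1obs, A2, k2obs, F0):
    if np.any(np.asarray(k1obs) < 0) or np.any(np.asarray(k2obs) < 0):
        raise ValueError("negative rate constant")
    t = np.asarray(t, dtype=float)
    return F0 - A1 * np.exp(-k1obs * t) - A2 * np.exp(-k2obs * t)


def eval_model(fit: ExpFitResult, t):
    """Model fluorescence of a fitted well at time(s) ``t`` (seconds)."""
    if fit.model == "single":
        return model_single(t, fit.A1, fit.k1obs, fit.F0)
    return model_double(t, fit.A1, fit.k1obs, fit.A2, fit.k2obs, fit.F0)


def compute_aic(k_params: int, n_points: int, rss: float) -> float:
    """Small-sample corrected AIC from the residual sum of squares.

    Returns ``-inf`` for RSS = 0 (perfect fit sentinel: at equal, perfect
    fit the model comparison then falls back to preferring fewer
    parameters).
    """
    if n_points <= k_params + 1:
        raise ValueError("need n_points > k_params + 1")
    if rss < 0:
        raise ValueError("RSS must be >= 0")
    if rss == 0:
        return -math.inf
    aic = 2 * k_params + n_points * math.log(rss)
    if n_points / k_params < 40:
        aic += 2 * k_params * (k_params + 1) / (n_points - k_params - 1)
    return aic


def _per_point_aicc(k_params: int, n_points: int, rss: float) -> float:
    # N-consistent per-point criterion used only to compare fits across
    # different trim lengths: uses ln(RSS/N) so that pure noise scores the
    # same per point regardless of N (plain ln(RSS) would reward trimming).
    if rss <= 0:
        return -math.inf
    aic = 2 * k_params + n_points * math.log(rss / n_points)
    if n_points / k_params < 40:
        aic += 2 * k_params * (k_params + 1) / (n_points - k_params - 1)
    return aic / n_points


# ---------------------------------------------------------------------------
# fitting


def _initial_guess(t, F, model, config):
    F0 = float(np.max(F))
    amp = float(np.ptp(F))
    lo, hi = config.k_bounds
    if model == "single":
        # log-linear regression of ln(F0 + eps - F) on t seeds the rate
        eps = 0.05 * amp
        y = np.log(F0 + eps - F)
        slope = stats.linregress(t, y).slope
        k = float(np.clip(-slope, lo, hi))
        return np.array([amp, k, F0])
    k1 = float(np.clip(2e-3, lo, hi))
    k2 = float(np.clip(1e-4, lo, hi))
    return np.array([0.3 * amp, k1, 0.7 * amp, k2, F0])


def _random_guess(t, F, model, config, rng):
    F0 = float(np.max(F))
    amp = float(np.ptp(F))
    lo, hi = config.k_bounds
    # draw rates log-uniformly over the plausible assay window
    klo = max(lo, 1e-6)
    khi = min(hi, 1e-1)
    if model == "single":
        k = float(np.exp(rng.uniform(np.log(klo), np.log(khi))))
        return np.array([amp * rng.uniform(0.5, 1.5), k, F0])
    k1, k2 = np.sort(np.exp(rng.uniform(np.log(klo), np.log(khi), size=2)))[::-1]
    split = rng.uniform(0.1, 0.9)
    return np.array([amp * split, k1, amp * (1 - split), k2, F0])


def _bounds(model, config):
    alo = config.amplitude_lower_bound
    klo, khi = config.k_bounds
    if model == "single":
        return ([alo, klo, -np.inf], [np.inf, khi, np.inf])
    return ([alo, klo, alo, klo, -np.inf], [np.inf, khi, np.inf, khi, np.inf])


def _try_fit(func, t, F, p0, bounds, config):
    p0 = np.clip(p0, bounds[0], bounds[1])
    res = optimize.least_squares(
        lambda p: func(t, *p) - F, x0=p0, bounds=bounds, method="trf",
        xtol=config.tol, ftol=config.tol, gtol=config.tol, max_nfev=config.max_nfev,
    )
    popt = res.x
    rss = float(2.0 * res.cost)
    dof = len(F) - len(p0)
    jtj = res.jac.T @ res.jac
    try:
        pcov = np.linalg.inv(jtj) * rss / dof
    except np.linalg.LinAlgError:
        pcov = np.linalg.pinv(jtj) * rss / dof
    # status 0 = evaluation budget exhausted (typically a degenerate valley,
    # e.g. the double model chasing single-exponential data)
    return popt, pcov, rss, res.status > 0


def fit_curve(curve: ProgressCurve, model: str, config: FitConfig | None = None,
              rng: np.random.Generator | None = None) -> ExpFitResult:
    """Bounded nonlinear least-squares fit of one progress curve.

    Standard errors come from the local linearization at the optimum (the
    covariance of the parameters scaled by RSS/(N-k)).  Non-convergence
    after all multistarts is reported via ``converged=False`` rather than
    raised, so a plate run never aborts on one bad well.
    """
    config = config or FitConfig()
    if model not in K_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    k_params = K_PARAMS[model]
    t = curve.times_s - curve.times_s[0]
    F = curve.fluorescence
    n = len(F)
    if n <= k_params:
        raise ValueError(f"need more than {k_params} points to fit the {model} model")
    if np.ptp(F) == 0:
        raise ValueError("zero-variance fluorescence")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    func = model_single if model == "single" else model_double
    bounds = _bounds(model, config)
    perfect_floor = (config.perfect_fit_rtol * np.ptp(F)) ** 2 * n

    # Residual RMS above 1% of the data range marks a suspect local
    # minimum; only then (or on outright failure) are restarts spent.
    poor_floor = (0.01 * np.ptp(F)) ** 2 * n

    best = None
    stale = 0
    for attempt in range(1 + config.multistart):
        guess = (
            _initial_guess(t, F, model, config) if attempt == 0
            else _random_guess(t, F, model, config, rng)
        )
        try:
            popt, pcov, rss, ok = _try_fit(func, t, F, guess, bounds, config)
        except (RuntimeError, ValueError):
            continue
        if best is None or rss < 0.99 * best[2]:
            best = (popt, pcov, rss, ok)
            stale = 0
        else:
            stale += 1
        if best[2] < max(perfect_floor, poor_floor) or stale >= 2:
            break

    if best is None:
        return ExpFitResult(
            model=model, A1=math.nan, k1obs=math.nan, F0=math.nan,
            A2=math.nan if model == "double" else None,
            k2obs=math.nan if model == "double" else None,
            rss=math.inf, n_points=n, k_params=k_params,
            aicc=math.inf, converged=False,
        )

    popt, pcov, rss, converged = best
    diag = np.diag(pcov) if np.all(np.isfinite(pcov)) else np.full(k_params, np.nan)
    with np.errstate(invalid="ignore"):
        se = np.where(diag >= 0, np.sqrt(np.abs(diag)), np.nan)
    perfect = rss < perfect_floor
    aicc = compute_aic(k_params, n, rss)

    if model == "single":
        A, k, F0 = popt
        return ExpFitResult(
            model="single", A1=float(A), k1obs=float(k), F0=float(F0),
            se_A1=float(se[0]), se_k1obs=float(se[1]), se_F0=float(se[2]),
            rss=rss, n_points=n, k_params=3, aicc=aicc, converged=converged,
            perfect_fit=perfect, raw_A1=float(A),
        )

    A1, k1, A2, k2, F0 = popt
    se_A1, se_k1, se_A2, se_k2, se_F0 = se
    raw_A1 = float(A1)
    if k1 < k2:  # enforce fast-first phase ordering
        A1, k1, A2, k2 = A2, k2, A1, k1
        se_A1, se_k1, se_A2, se_k2 = se_A2, se_k2, se_A1, se_k1
    if k1 == k2:  # exactly degenerate; break the tie so ordering holds
        k1 = k2 * (1 + 1e-12)
    return ExpFitResult(
        model="double", A1=float(A1), k1obs=float(k1),
        A2=float(A2), k2obs=float(k2), F0=float(F0),
        se_A1=float(se_A1), se_k1obs=float(se_k1), se_A2=float(se_A2),
        se_k2obs=float(se_k2), se_F0=float(se_F0),
        rss=rss, n_points=n, k_params=5, aicc=aicc, converged=converged,
        perfect_fit=perfect, raw_A1=raw_A1,
    )


def _is_degenerate_double(fit: ExpFitResult, data_range: float, config: FitConfig) -> bool:
    """Inseparable phases: rates within tolerance or a vanishing amplitude."""
    if not fit.converged:
        return True
    if (fit.k1obs - fit.k2obs) <= config.degenerate_k_rtol * fit.k1obs:
        return True
    amp_floor = config.amplitude_lower_bound + 1e-6 * data_range
    return fit.A1 <= amp_floor or fit.A2 <= amp_floor


def select_model(curve: ProgressCurve, config: FitConfig | None = None,
                 rng: np.random.Generator | None = None) -> ExpFitResult:
    """Fit both models and keep the one with the lower AICc.

    Perfect fits (RSS at numerical zero) compare equal, and the comparison
    then prefers the model with fewer parameters.  A double fit whose two
    phases are inseparable (rates within tolerance of each other, or one
    amplitude at its bound) is treated as single-model evidence.  Both AICc
    values are retained on the returned result for reporting.
    """
    config = config or FitConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    single = fit_curve(curve, "single", config, rng)
    try:
        double = fit_curve(curve, "double", config, rng)
    except ValueError:
        double = None

    aicc_s = single.aicc if single.converged else math.inf
    aicc_d = double.aicc if double is not None and double.converged else math.inf
    score_s = -math.inf if single.converged and single.perfect_fit else aicc_s
    score_d = -math.inf if double is not None and double.converged and double.perfect_fit else aicc_d

    data_range = float(np.ptp(curve.fluorescence))
    use_single = (
        double is None
        or _is_degenerate_double(double, data_range, config)
        or score_s <= score_d
    )
    chosen = single if use_single else double
    chosen.aicc_single = aicc_s if math.isfinite(aicc_s) or aicc_s == -math.inf else math.nan
    chosen.aicc_double = aicc_d if double is not None else math.nan
    if not single.converged and (double is None or not double.converged):
        chosen.converged = False
    return chosen


def trim_lag(curve: ProgressCurve, config: FitConfig | None = None) -> tuple[ProgressCurve, float]:
    """Remove an initial lag phase by exhaustive trim search.

    Candidate trims drop the first m points (dropped duration up to
    ``max_lag_s``); each remainder is refitted with model selection and
    scored by per-point AICc; the smallest trim achieving the best score
    wins.  The trimmed curve is re-zeroed in time and the removed duration
    returned.  Trims that would leave six or fewer points are not
    considered.
    """
    config = config or FitConfig()
    if config.max_lag_s <= 0:
        return curve, 0.0
    t0 = curve.times_s[0]
    candidates = [
        m for m in range(curve.n_points)
        if curve.times_s[m] - t0 <= config.max_lag_s and curve.n_points - m >= 7
    ]
    scores: list[float] = []
    best = math.inf
    since_best = 0
    for m in candidates:
        sub = ProgressCurve(
            well_id=curve.well_id,
            times_s=curve.times_s[m:] - curve.times_s[m],
            fluorescence=curve.fluorescence[m:],
            meta=curve.meta,
        )
        fit = select_model(sub, config)
        if not fit.converged:
            score = math.inf
        elif fit.perfect_fit:
            score = -math.inf
        else:
            score = _per_point_aicc(fit.k_params, fit.n_points, fit.rss)
        scores.append(score)
        if score < best - 1e-12:
            best = score
            since_best = 0
        else:
            since_best += 1
        if config.trim_patience is not None and since_best > config.trim_patience:
            break

    best = min(scores)
    m_best = candidates[next(i for i, s in enumerate(scores) if s <= best + 1e-9)]
    if m_best == 0:
        return curve, 0.0
    trimmed = ProgressCurve(
        well_id=curve.well_id,
        times_s=curve.times_s[m_best:] - curve.times_s[m_best],
        fluorescence=curve.fluorescence[m_best:],
        meta=dict(curve.meta),
    )
    return trimmed, float(curve.times_s[m_best] - t0)
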
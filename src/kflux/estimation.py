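"""Per-animal parameter identification for the compartmental tracer models.

Five free parameters of the three-pool model (K_ECF, K_ICF2, K_ICF3,
k21, k31) are estimated from the plasma Δ⁴¹K/³⁹K time course by
unweighted nonlinear least squares (Levenberg–Marquardt in log-space,
which enforces positivity without active bounds).  The renal rate
constant is not free: at every iterate it is re-evaluated as

    k01 = (measured urinary K⁺ excretion) / K_ECF

so the renal tracer-loss *flux* is pinned to the urine measurement while
K_ECF itself is being estimated.  The efflux constants then follow from
steady-state flux balance, k12 = K_ECF·k21/K_ICF2 and
k13 = K_ECF·k31/K_ICF3, so every returned parameter set closes exactly.

A two-pool variant (free: K_ECF, K_ICF, k21) is provided for model
comparison; fitting it to data generated by the richer model
demonstrates how a single-ICF description underestimates the
intracellular K⁺ pool.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .cohort import AnimalRecord
from .isotopes import DEFAULT_CONSTANTS, IsotopeConstants
from .model import (
    InfusionProtocol,
    ModelParameters,
    SimulationError,
    TwoPoolParameters,
    _lti_response,
    _rate_matrix_2c,
    _rate_matrix_3c,
    infusion_forcing,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "IdentifiabilityError",
    "fit_3c",
    "fit_2c",
    "derive_efflux_constants",
    "residual_report",
    "compute_fsd",
    "default_initial_guess",
]


class IdentifiabilityError(ValueError):
    """Raised when a record cannot constrain the model at all."""


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for a per-animal fit."""

    initial_guess: dict[str, float] | None = None
    bounds_fold: float = 1e2  # sanity bounds: guess × [1/fold... , fold]
    max_iterations: int = 400
    ftol: float = 1e-12
    xtol: float = 1e-12
    multistart_count: int = 5
    jitter_fold: float = 3.0
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.multistart_count < 1:
            raise ValueError("multistart_count must be >= 1")
        if self.bounds_fold <= 1 or self.jitter_fold <= 1:
            raise ValueError("fold factors must exceed 1")


@dataclass
class FitResult:
    """Outcome of one per-animal fit."""

    params: ModelParameters | TwoPoolParameters
    residual_table: pd.DataFrame  # time_min, observed, predicted, resid ‰, resid %
    sse: float
    converged: bool
    n_iterations: int
    start_point_used: int
    model: str  # "3c" or "2c"
    sse_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    animal_id: str = ""

    @property
    def residuals_permil(self) -> np.ndarray:
        return self.residual_table["resid_permil"].to_numpy()


def derive_efflux_constants(
    k_ecf: float, k21: float, k_icf2: float, k31: float, k_icf3: float
) -> tuple[float, float]:
    """Efflux rate constants from steady-state flux balance.

    k12 = K_ECF·k21/K_ICF2 and k13 = K_ECF·k31/K_ICF3, which makes the
    bidirectional fluxes balance exactly: K_ECF·k21 = K_ICF2·k12 and
    K_ECF·k31 = K_ICF3·k13.
    """
    for name, v in (("k_ecf", k_ecf), ("k21", k21), ("k_icf2", k_icf2),
                    ("k31", k31), ("k_icf3", k_icf3)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return k_ecf * k21 / k_icf2, k_ecf * k31 / k_icf3


def default_initial_guess(record: AnimalRecord) -> dict[str, float]:
    """Order-of-magnitude physiological start point.

    ECF volume ≈ 0.15 L/kg, so K_ECF ≈ plasma [K⁺] × 0.15 × BW; ICF pool
    guesses and rate constants are round numbers at rat physiology scale.
    """
    k_ecf = record.plasma_k * 0.15 * record.body_weight / 1000.0
    return {"k_ecf": max(k_ecf, 1e-3), "k_icf2": 4.0, "k_icf3": 17.0, "k21": 0.3, "k31": 0.2}


_FREE_3C = ("k_ecf", "k_icf2", "k_icf3", "k21", "k31")
_FREE_2C = ("k_ecf", "k_icf", "k21")


def _predict_y1_3c(
    theta: np.ndarray,
    k01_of_kecf: Callable[[float], float],
    protocol: InfusionProtocol,
    constants: IsotopeConstants,
    times: np.ndarray,
) -> np.ndarray:
    with np.errstate(over="ignore"):
        k_ecf, k_icf2, k_icf3, k21, k31 = np.exp(theta)
    vals = np.array([k_ecf, k_icf2, k_icf3, k21, k31])
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("parameter out of range")
    k01 = k01_of_kecf(k_ecf)
    p = ModelParameters.from_influx(k_ecf, k_icf2, k_icf3, k01, k21, k31)
    inf_eff, _ = infusion_forcing(protocol, constants, k_ecf)
    a = _rate_matrix_3c(p)
    b = np.array([inf_eff / k_ecf, 0.0, 0.0])
    return _lti_response(a, b, protocol.duration_min, times)[:, 0]


def _predict_y1_2c(
    theta: np.ndarray,
    k01_of_kecf: Callable[[float], float],
    protocol: InfusionProtocol,
    constants: IsotopeConstants,
    times: np.ndarray,
) -> np.ndarray:
    with np.errstate(over="ignore"):
        k_ecf, k_icf, k21 = np.exp(theta)
    vals = np.array([k_ecf, k_icf, k21])
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("parameter out of range")
    k01 = k01_of_kecf(k_ecf)
    p = TwoPoolParameters.from_influx(k_ecf, k_icf, k01, k21)
    inf_eff, _ = infusion_forcing(protocol, constants, k_ecf)
    a = _rate_matrix_2c(p)
    b = np.array([inf_eff / k_ecf, 0.0])
    return _lti_response(a, b, protocol.duration_min, times)[:, 0]


def _run_fit(
    obs_times: np.ndarray,
    obs_delta: np.ndarray,
    predict: Callable[[np.ndarray], np.ndarray],
    guess: np.ndarray,
    options: FitOptions,
) -> tuple[np.ndarray, float, bool, int, int, np.ndarray]:
    """Multistart log-space Levenberg–Marquardt over the free parameters."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=options.seed))
    trace: list[float] = []

    def residuals(theta: np.ndarray) -> np.ndarray:
        try:
            pred = predict(theta)
        except (ValueError, FloatingPointError, SimulationError, np.linalg.LinAlgError):
            return np.full_like(obs_delta, 1e6)
        r = obs_delta - pred
        if not np.all(np.isfinite(r)):
            return np.full_like(obs_delta, 1e6)
        trace.append(float(r @ r))
        return r

    best = None
    for start in range(options.multistart_count):
        theta0 = np.log(guess)
        if start > 0:
            theta0 = theta0 + rng.uniform(
                -np.log(options.jitter_fold), np.log(options.jitter_fold), size=theta0.size
            )
        try:
            sol = least_squares(
                residuals,
                theta0,
                method="lm",
                ftol=options.ftol,
                xtol=options.xtol,
                max_nfev=options.max_iterations * (theta0.size + 1),
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        sse = float(sol.fun @ sol.fun)
        if best is None or sse < best[1] - 1e-15:
            best = (sol.x, sse, sol.status > 0, sol.nfev, start)
    if best is None:
        raise IdentifiabilityError("all optimizer starts failed")
    theta, sse, ok, nfev, start_used = best
    accepted = np.minimum.accumulate(np.asarray(trace)) if trace else np.empty(0)
    return theta, sse, ok, nfev, start_used, accepted


def _observations(record: AnimalRecord) -> tuple[np.ndarray, np.ndarray]:
    tc = record.timecourse
    mask = tc.times > 0
    times = tc.times[mask]
    delta = tc.delta_permil[mask]
    if times.size < 10:
        raise IdentifiabilityError(
            f"need >= 10 post-baseline samples, got {times.size}"
        )
    if np.max(np.abs(delta)) == 0.0:
        raise IdentifiabilityError("time course is identically zero (no tracer signal)")
    return times, delta


def _result_table(times, observed, predicted) -> pd.DataFrame:
    resid = observed - predicted
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(observed != 0, 100.0 * resid / observed, np.nan)
    return pd.DataFrame(
        {
            "time_min": times,
            "observed_permil": observed,
            "predicted_permil": predicted,
            "resid_permil": resid,
            "resid_pct": pct,
        }
    )


def fit_3c(
    record: AnimalRecord,
    protocol: InfusionProtocol,
    options: FitOptions = FitOptions(),
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
    k01_policy: str = "urine",
    k01_value: float | None = None,
) -> FitResult:
    """Fit the three-pool model to one animal's plasma time course.

    ``k01_policy`` selects how the renal constant is handled:

    - ``"urine"`` (default): k01 = urinary excretion / K_ECF at every
      iterate, so the measured renal flux is held fixed while K_ECF is
      estimated.
    - ``"fixed"``: k01 pinned to ``k01_value`` (used by the Monte Carlo
      identifiability study, where the truth is known).

    The two intracellular pools are exchangeable in the likelihood, so
    the returned parameters are canonicalized with compartment 2 as the
    fast pool: k12 ≥ k13.

    Non-convergence after multistart is reported via ``converged=False``
    rather than an exception; an identically-zero time course raises
    :class:`IdentifiabilityError`.
    """
    times, delta = _observations(record)
    if k01_policy == "urine":
        urine = record.urinary_k_excretion
        if urine < 0:
            raise ValueError("urinary excretion must be non-negative")
        k01_of = lambda k_ecf: urine / k_ecf
    elif k01_policy == "fixed":
        if k01_value is None:
            raise ValueError("k01_policy='fixed' requires k01_value")
        k01_of = lambda k_ecf: k01_value
    else:
        raise ValueError(f"unknown k01_policy {k01_policy!r}")

    guess_map = options.initial_guess or default_initial_guess(record)
    guess = np.array([guess_map[k] for k in _FREE_3C])

    predict = lambda theta: _predict_y1_3c(theta, k01_of, protocol, constants, times)
    theta, sse, ok, nfev, start_used, trace = _run_fit(times, delta, predict, guess, options)

    k_ecf, k_icf2, k_icf3, k21, k31 = np.exp(theta)
    k12, k13 = derive_efflux_constants(k_ecf, k21, k_icf2, k31, k_icf3)
    if k12 < k13:
        # the two ICF pools are exchangeable in the likelihood; label them
        # canonically with compartment 2 as the fast pool (larger turnover)
        k_icf2, k_icf3 = k_icf3, k_icf2
        k21, k31 = k31, k21
        k12, k13 = k13, k12
    params = ModelParameters(
        k_ecf=k_ecf, k_icf2=k_icf2, k_icf3=k_icf3,
        k01=k01_of(k_ecf), k21=k21, k12=k12, k31=k31, k13=k13,
    )
    predicted = predict(theta)
    return FitResult(
        params=params,
        residual_table=_result_table(times, delta, predicted),
        sse=sse,
        converged=ok,
        n_iterations=nfev,
        start_point_used=start_used,
        model="3c",
        sse_trace=trace,
        animal_id=record.animal_id,
    )


def fit_2c(
    record: AnimalRecord,
    protocol: InfusionProtocol,
    options: FitOptions = FitOptions(),
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
    k01_policy: str = "urine",
    k01_value: float | None = None,
) -> FitResult:
    """Fit the single-ICF (two-pool) variant; free: K_ECF, K_ICF, k21."""
    times, delta = _observations(record)
    if k01_policy == "urine":
        urine = record.urinary_k_excretion
        k01_of = lambda k_ecf: urine / k_ecf
    elif k01_policy == "fixed":
        if k01_value is None:
            raise ValueError("k01_policy='fixed' requires k01_value")
        k01_of = lambda k_ecf: k01_value
    else:
        raise ValueError(f"unknown k01_policy {k01_policy!r}")

    if options.initial_guess is not None:
        guess_map = options.initial_guess
    else:
        g3 = default_initial_guess(record)
        guess_map = {"k_ecf": g3["k_ecf"], "k_icf": g3["k_icf2"] + g3["k_icf3"], "k21": g3["k21"]}
    guess = np.array([guess_map[k] for k in _FREE_2C])

    predict = lambda theta: _predict_y1_2c(theta, k01_of, protocol, constants, times)
    theta, sse, ok, nfev, start_used, trace = _run_fit(times, delta, predict, guess, options)

    k_ecf, k_icf, k21 = np.exp(theta)
    params = TwoPoolParameters.from_influx(k_ecf, k_icf, k01_of(k_ecf), k21)
    predicted = predict(theta)
    return FitResult(
        params=params,
        residual_table=_result_table(times, delta, predicted),
        sse=sse,
        converged=ok,
        n_iterations=nfev,
        start_point_used=start_used,
        model="2c",
        sse_trace=trace,
        animal_id=record.animal_id,
    )


# --------------------------------------------------------------------------
# fit-quality summaries
# --------------------------------------------------------------------------

def residual_report(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Per-timepoint residual screen across animals.

    For each sampling time: the mean residual as % of the observed value,
    a two-tailed one-sample t test of the per-animal residual percentages
    against zero, and the Bonferroni-adjusted p value (multiplied by the
    number of timepoints, capped at 1).  Timepoints observed in fewer
    than two animals, or with undefined residual % (zero observation),
    are reported with missing statistics.
    """
    if not fits:
        raise ValueError("no fits supplied")
    frames = [f.residual_table.assign(animal=f.animal_id or str(i)) for i, f in enumerate(fits)]
    table = pd.concat(frames, ignore_index=True)
    times = np.unique(table["time_min"])
    n_tests = times.size
    rows = []
    for t in times:
        vals = table.loc[table["time_min"] == t, "resid_pct"].dropna().to_numpy()
        if vals.size < 2:
            rows.append({"time_min": t, "n": vals.size, "mean_resid_pct": np.nan,
                         "t_stat": np.nan, "p_raw": np.nan, "p_bonferroni": np.nan})
            continue
        if np.allclose(vals, vals[0]):
            # degenerate (e.g. perfect fits): no evidence against zero mean
            tstat, p = 0.0 if vals[0] == 0 else np.inf, 1.0 if vals[0] == 0 else 0.0
        else:
            tstat, p = stats.ttest_1samp(vals, 0.0)
        rows.append(
            {
                "time_min": t,
                "n": vals.size,
                "mean_resid_pct": float(np.mean(vals)),
                "t_stat": float(tstat),
                "p_raw": float(p),
                "p_bonferroni": float(min(p * n_tests, 1.0)),
            }
        )
    return pd.DataFrame(rows)


def compute_fsd(values: Sequence[float]) -> float:
    """Fractional standard deviation, 100·SD/mean (sample SD, n−1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("FSD undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)
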
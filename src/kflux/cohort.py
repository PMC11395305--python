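"""Synthetic-cohort generator for tracer-infusion experiments.

Emulates the study design the estimation pipeline expects: per-animal
kinetic parameters drawn around group means with between-animal
dispersion, a constant ⁴¹K infusion with a fixed sampling schedule,
isotope-ratio measurement noise at the instrument's external
reproducibility, and a directly measured urinary K⁺ excretion rate used
downstream to constrain the renal rate constant.

Between-animal variation is log-normal (positivity-preserving),
parameterized by arithmetic mean and fractional SD.  Measurement noise
is additive Gaussian on the per-mil delta by default; a proportional
mode is available.  One master seed plus per-animal substreams makes a
cohort fully reproducible and insensitive to ``n_animals`` (animal i is
identical whether the cohort has 5 or 50 members).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .isotopes import DEFAULT_CONSTANTS, IsotopeConstants
from .model import InfusionProtocol, ModelParameters, PROTOCOLS, TracerTimeCourse, simulate_3c

__all__ = [
    "CohortSpec",
    "AnimalRecord",
    "CONTROL_MEANS",
    "K_DEFICIENT_MEANS",
    "CONTROL_FSD",
    "K_DEFICIENT_FSD",
    "control_spec",
    "k_deficient_spec",
    "draw_animal_params",
    "add_noise",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "DEFAULT_NOISE_GRID",
]

#: Group-mean kinetic parameters for rats on a control (1% K⁺) diet.
#: Pools in mEq/300 g BW, rate constants in min⁻¹; efflux constants
#: follow from steady-state flux balance.
CONTROL_MEANS = ModelParameters.from_influx(
    k_ecf=0.49, k_icf2=3.70, k_icf3=16.9, k01=0.0043, k21=0.317, k31=0.220
)

#: Group means after 10 days on a K⁺-free diet.
K_DEFICIENT_MEANS = ModelParameters.from_influx(
    k_ecf=0.31, k_icf2=3.33, k_icf3=14.4, k01=0.0003, k21=0.298, k31=0.199
)

#: Between-animal fractional SDs (SD/mean) for the directly sampled
#: parameters, control group.
CONTROL_FSD: dict[str, float] = {
    "k_ecf": 0.19 / 0.49,
    "k_icf2": 2.22 / 3.70,
    "k_icf3": 1.6 / 16.9,
    "k01": 0.0024 / 0.0043,
    "k21": 0.166 / 0.317,
    "k31": 0.100 / 0.220,
}

K_DEFICIENT_FSD: dict[str, float] = {
    "k_ecf": 0.14 / 0.31,
    "k_icf2": 0.98 / 3.33,
    "k_icf3": 1.5 / 14.4,
    "k01": 0.0003 / 0.0003,
    "k21": 0.094 / 0.298,
    "k31": 0.075 / 0.199,
}

#: Measurement-noise grid in ‰, anchored at the ~0.015% external
#: reproducibility of the isotope-ratio measurement (0.15‰).
DEFAULT_NOISE_GRID: tuple[float, ...] = (0.0, 0.0375, 0.075, 0.15, 0.3, 0.6)

_SAMPLED = ("k_ecf", "k_icf2", "k_icf3", "k01", "k21", "k31")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic diet group."""

    n_animals: int
    param_means: ModelParameters
    param_fsd: dict[str, float]
    noise_sd: float = 0.15  # ‰
    protocol: InfusionProtocol = PROTOCOLS["#4"]
    urine_noise_fsd: float = 0.10
    seed: int = 0
    diet_label: str = "control"
    plasma_k_mean: float = 3.9  # mEq/L
    plasma_k_sd: float = 0.3
    body_weight_mean: float = 290.0  # g
    body_weight_sd: float = 7.0
    proportional_noise: bool = False

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.noise_sd < 0 or self.urine_noise_fsd < 0:
            raise ValueError("dispersions must be non-negative")
        if any(v < 0 for v in self.param_fsd.values()):
            raise ValueError("param_fsd entries must be non-negative")
        unknown = set(self.param_fsd) - set(_SAMPLED)
        if unknown:
            raise ValueError(f"param_fsd has unknown parameters: {sorted(unknown)}")


@dataclass(frozen=True)
class AnimalRecord:
    """One animal's observation set — the unit the fitter consumes."""

    animal_id: str
    diet_label: str
    timecourse: TracerTimeCourse
    urinary_k_excretion: float  # mEq/min
    plasma_k: float  # mEq/L
    body_weight: float  # g
    true_params: ModelParameters | None = None

    def __post_init__(self) -> None:
        if self.urinary_k_excretion < 0:
            raise ValueError("urinary K excretion must be non-negative")


def control_spec(**overrides) -> CohortSpec:
    """Default control-diet cohort (n=6, plasma K⁺ 3.9±0.3 mEq/L)."""
    base = dict(
        n_animals=6,
        param_means=CONTROL_MEANS,
        param_fsd=dict(CONTROL_FSD),
        diet_label="control",
        plasma_k_mean=3.9,
        plasma_k_sd=0.3,
        seed=0,
    )
    base.update(overrides)
    return CohortSpec(**base)


def k_deficient_spec(**overrides) -> CohortSpec:
    """Default K⁺-restricted cohort (n=7, plasma K⁺ 3.2±0.5 mEq/L)."""
    base = dict(
        n_animals=7,
        param_means=K_DEFICIENT_MEANS,
        param_fsd=dict(K_DEFICIENT_FSD),
        diet_label="k_deficient",
        plasma_k_mean=3.2,
        plasma_k_sd=0.5,
        seed=1,
    )
    base.update(overrides)
    return CohortSpec(**base)


def _animal_rng(seed: int, index: int) -> np.random.Generator:
    """Per-animal substream: stable under changes of n_animals."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _lognormal(rng: np.random.Generator, mean: float, fsd: float) -> float:
    """Draw from a log-normal with given arithmetic mean and fractional SD."""
    if fsd == 0.0:
        return mean
    sigma2 = np.log1p(fsd * fsd)
    mu = np.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def draw_animal_params(spec: CohortSpec, rng: np.random.Generator) -> ModelParameters:
    """Sample one animal's kinetic parameters.

    The six directly sampled quantities (three pool sizes, three influx/
    excretion rate constants) are drawn independently; the two efflux
    constants follow from steady-state flux balance.
    """
    draws = {
        name: _lognormal(rng, getattr(spec.param_means, name), spec.param_fsd.get(name, 0.0))
        for name in _SAMPLED
    }
    return ModelParameters.from_influx(**draws)


def add_noise(
    tc: TracerTimeCourse,
    noise_sd: float,
    rng: np.random.Generator,
    proportional: bool = False,
) -> TracerTimeCourse:
    """Perturb a delta time course with measurement noise.

    Additive Gaussian of SD ``noise_sd`` (‰) by default; in proportional
    mode the SD scales with the signal as ``noise_sd × |delta|``.
    Baseline samples (t ≤ 0) are left at zero — the delta is defined as
    the change from the animal's own baseline.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0.0:
        return tc
    scale = noise_sd * np.abs(tc.delta_permil) if proportional else noise_sd
    noisy = tc.delta_permil + rng.normal(0.0, 1.0, size=len(tc)) * scale
    noisy = np.where(tc.times <= 0, 0.0, noisy)
    return dataclasses.replace(tc, delta_permil=noisy)


def generate_cohort(
    spec: CohortSpec, constants: IsotopeConstants = DEFAULT_CONSTANTS
) -> list[AnimalRecord]:
    """Generate a full synthetic diet group.

    Each animal gets its own parameter draw, a forward-simulated plasma
    time course at the protocol's schedule with measurement noise, a
    urinary excretion measurement equal to k01·K_ECF with multiplicative
    log-normal error, and body-weight / plasma-K⁺ covariates.  True
    parameters are kept on the record for recovery testing.
    """
    records: list[AnimalRecord] = []
    for i in range(spec.n_animals):
        rng = _animal_rng(spec.seed, i)
        params = draw_animal_params(spec, rng)
        plasma, _, _ = simulate_3c(params, spec.protocol, constants)
        noisy = add_noise(plasma, spec.noise_sd, rng, proportional=spec.proportional_noise)
        urine = params.k01 * params.k_ecf * _lognormal(rng, 1.0, spec.urine_noise_fsd)
        plasma_k = max(float(rng.normal(spec.plasma_k_mean, spec.plasma_k_sd)), 0.5)
        bw = float(rng.normal(spec.body_weight_mean, spec.body_weight_sd))
        records.append(
            AnimalRecord(
                animal_id=f"{spec.diet_label}_{i + 1:02d}",
                diet_label=spec.diet_label,
                timecourse=noisy,
                urinary_k_excretion=urine,
                plasma_k=plasma_k,
                body_weight=bw,
                true_params=params,
            )
        )
    return records


# --------------------------------------------------------------------------
# CSV bundle I/O
# --------------------------------------------------------------------------

_PARAM_COLS = ["k_ecf", "k_icf2", "k_icf3", "k01", "k21", "k12", "k31", "k13"]


def write_cohort(records: list[AnimalRecord], outdir: str | Path) -> None:
    """Write a cohort as a three-file CSV bundle.

    ``animals.csv`` (covariates), ``timecourses.csv`` (long-format delta
    samples) and, when true parameters are present, ``true_params.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    animals = pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "diet": [r.diet_label for r in records],
            "body_weight_g": [r.body_weight for r in records],
            "plasma_K_mEq_per_L": [r.plasma_k for r in records],
            "urine_K_mEq_per_min": [r.urinary_k_excretion for r in records],
        }
    )
    animals.to_csv(outdir / "animals.csv", index=False)

    frames = []
    for r in records:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": r.animal_id,
                    "compartment_label": r.timecourse.compartment_label,
                    "time_min": r.timecourse.times,
                    "delta_permil": r.timecourse.delta_permil,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(outdir / "timecourses.csv", index=False)

    if all(r.true_params is not None for r in records):
        rows = []
        for r in records:
            row = {"animal_id": r.animal_id}
            row.update({c: getattr(r.true_params, c) for c in _PARAM_COLS})
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "true_params.csv", index=False)


def read_cohort(indir: str | Path) -> list[AnimalRecord]:
    """Read a cohort CSV bundle written by :func:`write_cohort`."""
    indir = Path(indir)
    animals_path = indir / "animals.csv"
    tc_path = indir / "timecourses.csv"
    for path in (animals_path, tc_path):
        if not path.exists():
            raise FileNotFoundError(f"missing cohort file: {path}")
    animals = pd.read_csv(animals_path)
    tcs = pd.read_csv(tc_path)
    for col in ("animal_id", "compartment_label", "time_min", "delta_permil"):
        if col not in tcs.columns:
            raise ValueError(f"timecourses.csv: missing column {col!r}")
    if tcs[["time_min", "delta_permil"]].isna().any().any():
        raise ValueError("timecourses.csv: missing values are forbidden")

    truths: dict[str, ModelParameters] = {}
    tp_path = indir / "true_params.csv"
    if tp_path.exists():
        tp = pd.read_csv(tp_path)
        for _, row in tp.iterrows():
            truths[row["animal_id"]] = ModelParameters(**{c: row[c] for c in _PARAM_COLS})

    records = []
    for _, row in animals.iterrows():
        sub = tcs[tcs["animal_id"] == row["animal_id"]].sort_values("time_min")
        if sub.empty:
            raise ValueError(f"no time course for animal {row['animal_id']!r}")
        tc = TracerTimeCourse(
            times=sub["time_min"].to_numpy(float),
            delta_permil=sub["delta_permil"].to_numpy(float),
            compartment_label=str(sub["compartment_label"].iloc[0]),
        )
        records.append(
            AnimalRecord(
                animal_id=str(row["animal_id"]),
                diet_label=str(row["diet"]),
                timecourse=tc,
                urinary_k_excretion=float(row["urine_K_mEq_per_min"]),
                plasma_k=float(row["plasma_K_mEq_per_L"]),
                body_weight=float(row["body_weight_g"]),
                true_params=truths.get(str(row["animal_id"])),
            )
        )
    return records
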
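"""Seeded synthetic cohorts with planted ground truth.

The clinical cohort behind the retention models (242 children and
teenagers, 54 boys of mean age 11.7 and 188 girls of mean age 10.4) is
not public, so every downstream test runs on synthetic cohorts that
reproduce its statistical shape: positive age-consistent physiology,
log-normal environmental concentrations, and a planted smooth mapping
from exposure + physiology to clearance — hence, through the exponential
transform, to a retention target in (0;1).

The planted clearance is ``cl_scale · (0.05 + 0.95 · (1 − expit(1.2·η)))``
where η is a linear index over standardised log-water, log-soil, age,
sex, and body surface: higher exposure → lower clearance → higher
retention.  Blood and urine concentrations and diuresis are back-solved
from the clearance formula so the measurement pipeline recomputes the
planted clearances exactly.  Observation noise is added to the retention
target only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from metalret.retention import (
    MINUTES_PER_DAY,
    SubjectRecord,
    compute_bsa,
)

METALS = ("zn", "cr", "cu", "pb")


@dataclass(frozen=True)
class MetalEnvironment:
    """Log-normal environmental/biosubstrate parameters for one metal.

    ``water_log_mean``/``soil_log_mean`` are means of ln(concentration)
    with concentrations in mg/L (water) and mg/kg (soil); blood serum
    levels are µg/mL.  Defaults reflect typical urban drinking-water and
    soil levels for each metal.
    """

    water_log_mean: float
    water_log_sd: float
    soil_log_mean: float
    soil_log_sd: float
    blood_log_mean: float
    blood_log_sd: float
    clearance_scale: float  # mL/min


#: typical urban levels: Zn/Cu abundant essentials, Pb/Cr trace toxics
METAL_DEFAULTS: dict[str, MetalEnvironment] = {
    "zn": MetalEnvironment(
        water_log_mean=np.log(0.10), water_log_sd=0.35,
        soil_log_mean=np.log(55.0), soil_log_sd=0.4,
        blood_log_mean=np.log(1.0), blood_log_sd=0.25,
        clearance_scale=0.60,
    ),
    "cr": MetalEnvironment(
        water_log_mean=np.log(0.004), water_log_sd=0.35,
        soil_log_mean=np.log(30.0), soil_log_sd=0.4,
        blood_log_mean=np.log(0.003), blood_log_sd=0.35,
        clearance_scale=0.25,
    ),
    "cu": MetalEnvironment(
        water_log_mean=np.log(0.05), water_log_sd=0.35,
        soil_log_mean=np.log(20.0), soil_log_sd=0.4,
        blood_log_mean=np.log(0.9), blood_log_sd=0.25,
        clearance_scale=0.45,
    ),
    "pb": MetalEnvironment(
        water_log_mean=np.log(0.005), water_log_sd=0.4,
        soil_log_mean=np.log(18.0), soil_log_sd=0.4,
        blood_log_mean=np.log(0.03), blood_log_sd=0.4,
        clearance_scale=0.30,
    ),
}

#: planted-index coefficients: water dominates (short-term route), soil a
#: weak secondary chronic contributor — its variance share must stay small
#: because the short-term block omits it by design — and physiology
#: modulates renal capacity
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "water": 0.9,
    "soil": 0.15,
    "age": 0.25,
    "sex": -0.2,
    "bsa": 0.3,
}


@dataclass
class CohortConfig:
    """Synthetic-cohort parameters; defaults mirror the study cohort."""

    n: int = 242
    male_fraction: float = 54 / 242
    male_age_mean: float = 11.7
    female_age_mean: float = 10.4
    age_sd: float = 2.2
    age_range: tuple[int, int] = (7, 17)
    noise_sd: float = 0.02
    missing_rate: float = 0.0
    environments: dict[str, MetalEnvironment] = field(
        default_factory=lambda: dict(METAL_DEFAULTS)
    )
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    seed: int | None = None

    def validate(self) -> None:
        if self.n < 10:
            raise ValueError("cohort size must be at least 10")
        if not (0 <= self.male_fraction <= 1):
            raise ValueError("male_fraction must lie in [0,1]")
        if self.noise_sd < 0 or self.noise_sd >= 0.5:
            raise ValueError("noise_sd must lie in [0, 0.5)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0,1)")
        for metal, env in self.environments.items():
            for name in ("water_log_sd", "soil_log_sd", "blood_log_sd",
                         "clearance_scale"):
                if getattr(env, name) <= 0:
                    raise ValueError(f"{metal}: {name} must be positive")


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate a seeded cohort and its hidden truth table.

    Returns the subject records (with observed, possibly noisy, retention
    targets filled in) and a per-subject-per-metal truth table with the
    planted clearance, cohort σ, noiseless retention, and the observed
    target — for tests only, never a model input.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    n_male = int(round(config.male_fraction * n))
    sex = np.zeros(n, dtype=int)
    sex[rng.choice(n, size=n_male, replace=False)] = 1
    age_mean = np.where(sex == 1, config.male_age_mean, config.female_age_mean)
    age = np.clip(
        np.round(rng.normal(age_mean, config.age_sd)),
        *config.age_range,
    ).astype(int)

    # age-indexed growth curves with individual spread, floored to
    # physiologic minima
    height = np.maximum(rng.normal(6.2 * age + 58.0, 6.0), 95.0)
    weight = np.maximum(rng.normal(2.9 * age + 6.0, 4.0), 14.0)
    bsa = np.array(
        [compute_bsa(w, h, "printed") for w, h in zip(weight, height)]
    )
    diuresis = np.clip(rng.normal(1400.0, 250.0, size=n), 600.0, 2600.0)

    z_age = (age - 11.0) / 2.5
    z_bsa = (bsa - 2.0) / 0.4
    coef = config.coefficients

    records = [
        SubjectRecord(
            participant_code=f"S{i:04d}",
            weight_kg=float(weight[i]),
            height_cm=float(height[i]),
            age_years=int(age[i]),
            sex=int(sex[i]),
            body_area_m2=float(bsa[i]),
            diuresis_ml=float(diuresis[i]),
        )
        for i in range(n)
    ]

    truth_rows = []
    for metal, env in config.environments.items():
        water = rng.lognormal(env.water_log_mean, env.water_log_sd, size=n)
        soil = rng.lognormal(env.soil_log_mean, env.soil_log_sd, size=n)
        blood = rng.lognormal(env.blood_log_mean, env.blood_log_sd, size=n)

        z_water = (np.log(water) - env.water_log_mean) / env.water_log_sd
        z_soil = (np.log(soil) - env.soil_log_mean) / env.soil_log_sd
        eta = (
            coef["water"] * z_water
            + coef["soil"] * z_soil
            + coef["age"] * z_age
            + coef["sex"] * sex
            + coef["bsa"] * z_bsa
        )
        # steepened logistic: the floor keeps clearance positive, the gain
        # spreads the series so retention covers most of the unit interval
        clearance = env.clearance_scale * (0.05 + 0.95 * (1.0 - expit(1.2 * eta)))
        sigma = float(clearance.std(ddof=0))
        retention_true = np.exp(-(clearance**2) / (2.0 * sigma**2))
        if config.noise_sd > 0:
            observed = np.clip(
                retention_true + rng.normal(0.0, config.noise_sd, size=n),
                1e-4,
                1.0 - 1e-4,
            )
        else:
            observed = retention_true

        # back-solve urine so the clearance formula returns the planted value
        urine = clearance * blood * MINUTES_PER_DAY * bsa / diuresis

        missing = (
            rng.random(n) < config.missing_rate
            if config.missing_rate > 0
            else np.zeros(n, dtype=bool)
        )
        for i, record in enumerate(records):
            if missing[i]:
                continue
            record.water_mgl[metal] = float(water[i])
            record.soil_mgkg[metal] = float(soil[i])
            record.blood_ugml[metal] = float(blood[i])
            record.urine_ugml[metal] = float(urine[i])
            record.retention[metal] = float(observed[i])
            truth_rows.append(
                {
                    "participant_code": record.participant_code,
                    "metal": metal,
                    "clearance": float(clearance[i]),
                    "sigma": sigma,
                    "retention_true": float(retention_true[i]),
                    "retention_observed": float(observed[i]),
                }
            )
    for record in records:
        record.validate()
    return records, pd.DataFrame(truth_rows)


def generate_worked_fixture() -> list[SubjectRecord]:
    """Tiny fixed cohort (n=8) with hand-checkable clearances.

    All subjects share blood concentration 1 µg/mL, diuresis 1440 mL and
    a given body area of 1 m², so each lead clearance equals the urine
    concentration: 0, 0.25, …, 1.75 mL/min.  The expected retention
    values are recomputed independently (brute force) in the test suite.
    Byte-stable: no randomness.
    """
    records = []
    for i in range(8):
        urine = 0.25 * i
        records.append(
            SubjectRecord(
                participant_code=f"W{i}",
                weight_kg=36.0,
                height_cm=100.0,
                age_years=8 + i,
                sex=i % 2,
                body_area_m2=1.0,
                diuresis_ml=1440.0,
                blood_ugml={"pb": 1.0},
                urine_ugml={"pb": urine},
                water_mgl={"pb": 0.004 + 0.002 * i},
                soil_mgkg={"pb": 12.0 + 2.0 * i},
            )
        )
    return records
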
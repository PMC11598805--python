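"""Retention statistic: body-surface correction, metal clearance, exponential transform.

Metal retention in the body cannot be measured directly; it is summarised by
how fast the metal is cleared from blood plasma through the kidneys.  The
chain is

    BS         body-surface correction (Mosteller-style), normalising renal
               filtration to the 1.73 m² population average,
    CL         clearance (Reberg formula), mL/min,
    Retention  exp(−CL² / 2σ²) ∈ (0;1], where σ is the standard deviation of
               the cohort's clearance series.

Zero clearance means nothing is excreted and retention is maximal (1.0);
large clearance relative to the cohort spread drives retention toward 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

#: minutes per day — the time base of daily diuresis in the clearance formula
MINUTES_PER_DAY = 1440

#: population-average body surface area, m² — the renal normalisation reference
BSA_REFERENCE = 1.73

MetalCode = Literal["zn", "cr", "cu", "pb"]


@dataclass
class SubjectRecord:
    """One participant: physiology, biosubstrate concentrations, exposures.

    Concentration dictionaries are keyed by lowercase metal code
    (``"zn"``, ``"cr"``, ``"cu"``, ``"pb"``); a metal may be absent.
    """

    participant_code: str
    weight_kg: float
    height_cm: float
    age_years: int
    sex: int  # 0 = female, 1 = male
    body_area_m2: float | None = None
    diuresis_ml: float | None = None
    blood_ugml: dict[str, float] = field(default_factory=dict)
    urine_ugml: dict[str, float] = field(default_factory=dict)
    water_mgl: dict[str, float] = field(default_factory=dict)
    soil_mgkg: dict[str, float] = field(default_factory=dict)
    retention: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated physiological invariant."""
        if self.weight_kg <= 0:
            raise ValueError(f"{self.participant_code}: weight_kg must be > 0")
        if self.height_cm <= 0:
            raise ValueError(f"{self.participant_code}: height_cm must be > 0")
        if self.age_years < 1:
            raise ValueError(f"{self.participant_code}: age_years must be >= 1")
        if self.sex not in (0, 1):
            raise ValueError(f"{self.participant_code}: sex must be 0 or 1")
        if self.body_area_m2 is not None and self.body_area_m2 <= 0:
            raise ValueError(f"{self.participant_code}: body_area_m2 must be > 0")
        if self.diuresis_ml is not None and self.diuresis_ml <= 0:
            raise ValueError(f"{self.participant_code}: diuresis_ml must be > 0")
        for name, conc in (
            ("blood_ugml", self.blood_ugml),
            ("urine_ugml", self.urine_ugml),
            ("water_mgl", self.water_mgl),
            ("soil_mgkg", self.soil_mgkg),
        ):
            for metal, value in conc.items():
                if value < 0 or not math.isfinite(value):
                    raise ValueError(
                        f"{self.participant_code}: {name}[{metal}] must be a "
                        f"finite non-negative number, got {value}"
                    )
        for metal, value in self.retention.items():
            if not (0 < value <= 1):
                raise ValueError(
                    f"{self.participant_code}: retention[{metal}] must lie in "
                    f"(0;1], got {value}"
                )

    def bsa(self, variant: str = "printed") -> float:
        """Body-surface correction: the stored value if present, else derived."""
        if self.body_area_m2 is not None:
            return self.body_area_m2
        return compute_bsa(self.weight_kg, self.height_cm, variant)


@dataclass(frozen=True)
class ClearanceResult:
    """Clearance of one metal for one subject, with the BS correction used."""

    metal: str
    clearance: float  # mL/min
    bs_used: float

    def __post_init__(self) -> None:
        if self.clearance < 0:
            raise ValueError("clearance must be non-negative")
        if self.bs_used <= 0:
            raise ValueError("bs_used must be positive")


@dataclass(frozen=True)
class RetentionContext:
    """A cohort's clearance series with its spread and retention values."""

    metal: str | None
    sigma: float
    clearances: tuple[float, ...]
    retentions: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for r in self.retentions:
            if not (0 < r <= 1):
                raise ValueError(f"retention {r} outside (0;1]")


def compute_bsa(
    weight_kg: float, height_cm: float, variant: str = "printed"
) -> float:
    """Body-surface correction factor from weight and height.

    Two readings of the Mosteller-style formula are supported:

    - ``printed``: ``1.73 · sqrt(weight · height / 3600)`` — the reference
      surface multiplied onto the Mosteller radical.
    - ``mosteller_ratio``: ``sqrt(weight · height / 3600) / 1.73`` — the
      conventional clinical normalisation, subject BSA over the 1.73 m²
      population average.

    Parameters
    ----------
    weight_kg : positive weight in kg.
    height_cm : positive height in cm.
    variant : ``"printed"`` (default) or ``"mosteller_ratio"``.
    """
    if weight_kg <= 0:
        raise ValueError(f"weight_kg must be > 0, got {weight_kg}")
    if height_cm <= 0:
        raise ValueError(f"height_cm must be > 0, got {height_cm}")
    radical = math.sqrt(weight_kg * height_cm / 3600.0)
    if variant == "printed":
        return BSA_REFERENCE * radical
    if variant == "mosteller_ratio":
        return radical / BSA_REFERENCE
    raise ValueError(f"unknown BSA variant {variant!r}")


def compute_clearance(
    urine_ugml: float,
    blood_ugml: float,
    diuresis_ml: float,
    bs: float,
) -> float:
    """Metal clearance (Reberg formula), mL/min.

    ``CL = (c_urine · DM) / (c_blood · 1440 · BS)`` where DM is daily
    diuresis in mL and BS the body-surface correction.  Zero urine
    concentration yields zero clearance (nothing excreted).
    """
    if blood_ugml <= 0:
        raise ZeroDivisionError(
            "blood concentration must be > 0 (clearance unmeasurable otherwise)"
        )
    if bs <= 0:
        raise ZeroDivisionError("body-surface correction must be > 0")
    if diuresis_ml <= 0:
        raise ValueError(f"diuresis_ml must be > 0, got {diuresis_ml}")
    if urine_ugml < 0:
        raise ValueError(f"urine_ugml must be >= 0, got {urine_ugml}")
    return (urine_ugml * diuresis_ml) / (blood_ugml * MINUTES_PER_DAY * bs)


def compute_retention(clearance: float, sigma: float) -> float:
    """Exponential retention transform: ``exp(−CL² / 2σ²)`` ∈ (0;1].

    Strictly decreasing in clearance; 1.0 exactly when clearance is 0.
    ``sigma`` is the standard deviation of the cohort's clearance series.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0 (degenerate cohort), got {sigma}")
    if clearance < 0:
        raise ValueError(f"clearance must be >= 0, got {clearance}")
    return math.exp(-(clearance**2) / (2.0 * sigma**2))


def compute_retention_series(
    clearances: Sequence[float],
    sigma_mode: str = "population",
    metal: str | None = None,
) -> RetentionContext:
    """Retention for every clearance in a cohort series.

    σ is computed over the input series itself — ``population`` (n
    denominator, default) or ``sample`` (n−1).  Order is preserved.
    """
    values = np.asarray(list(clearances), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 clearance values")
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise ValueError("clearances must be finite and non-negative")
    if sigma_mode == "population":
        sigma = float(values.std(ddof=0))
    elif sigma_mode == "sample":
        sigma = float(values.std(ddof=1))
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    if sigma <= 0:
        raise ValueError("clearance series has zero spread (degenerate σ)")
    retentions = tuple(compute_retention(c, sigma) for c in values)
    return RetentionContext(
        metal=metal, sigma=sigma, clearances=tuple(values), retentions=retentions
    )


def clearance_for_record(
    record: SubjectRecord, metal: str, bsa_variant: str = "printed"
) -> ClearanceResult:
    """Clearance of ``metal`` for one subject from its biosubstrate fields."""
    if metal not in record.urine_ugml or metal not in record.blood_ugml:
        raise KeyError(
            f"{record.participant_code}: missing urine/blood concentration "
            f"for metal {metal!r}"
        )
    if record.diuresis_ml is None:
        raise ValueError(f"{record.participant_code}: daily diuresis missing")
    bs = record.bsa(bsa_variant)
    cl = compute_clearance(
        record.urine_ugml[metal], record.blood_ugml[metal], record.diuresis_ml, bs
    )
    return ClearanceResult(metal=metal, clearance=cl, bs_used=bs)


def attach_retention(
    records: Iterable[SubjectRecord],
    metal: str,
    sigma_mode: str = "population",
    bsa_variant: str = "printed",
) -> RetentionContext:
    """Compute and store retention of ``metal`` for a whole cohort.

    Clearances are computed per subject, σ over the cohort series, and each
    record's ``retention[metal]`` is filled in.  Returns the series context.
    """
    records = list(records)
    clearances = [
        clearance_for_record(r, metal, bsa_variant).clearance for r in records
    ]
    ctx = compute_retention_series(clearances, sigma_mode, metal=metal)
    for record, ret in zip(records, ctx.retentions):
        record.retention[metal] = ret
    return ctx
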
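"""Dataset cleaning, normalisation, assembly, and splitting.

The modelling pipeline feeds each metal's cohort through: gross-error
filtering (k·σ band), optional Z-score standardisation, assembly into
long-term (7 features) or short-term (6 features) design matrices, an
affine map onto [−1, 1] fitted on the training split only, and either a
seeded random 80/20 split or contiguous sequential-shift folds for
cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from metalret.retention import SubjectRecord

logger = logging.getLogger(__name__)

#: ordered feature columns for the long-term exposure block (7 inputs)
LONG_TERM_FEATURES = (
    "weight_kg",
    "height_cm",
    "body_area_m2",
    "age_years",
    "sex",
    "water_mgl",
    "soil_mgkg",
)

#: ordered feature columns for the short-term exposure block (6 inputs)
SHORT_TERM_FEATURES = (
    "weight_kg",
    "height_cm",
    "body_area_m2",
    "age_years",
    "sex",
    "water_mgl",
)

# cohort sizes the study design anticipates; outside → warning only
_EXPECTED_ROWS = (60, 242)


@dataclass
class NormalizationParams:
    """Invertible per-feature normalisation state.

    Holds the min/max of the [−1,1] affine stage and, when the Z-score
    stage is used, the per-feature mean and (population) standard
    deviation.  Fitted on training data only; application to other data
    reuses the stored constants so forward∘inverse is the identity.
    """

    feature_names: tuple[str, ...]
    col_min: np.ndarray | None = None
    col_max: np.ndarray | None = None
    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    fitted: bool = False

    def minmax_transform(self, X: np.ndarray, clip: bool = False) -> np.ndarray:
        if self.col_min is None or self.col_max is None:
            raise ValueError("min/max stage not fitted")
        span = self.col_max - self.col_min
        out = 2.0 * (np.asarray(X, dtype=float) - self.col_min) / span - 1.0
        if clip:
            out = np.clip(out, -1.0, 1.0)
        return out

    def minmax_inverse(self, S: np.ndarray) -> np.ndarray:
        if self.col_min is None or self.col_max is None:
            raise ValueError("min/max stage not fitted")
        span = self.col_max - self.col_min
        return (np.asarray(S, dtype=float) + 1.0) * span / 2.0 + self.col_min

    def zscore_transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None or self.std is None:
            raise ValueError("Z-score stage not fitted")
        return (np.asarray(X, dtype=float) - self.mean) / self.std

    def zscore_inverse(self, Z: np.ndarray) -> np.ndarray:
        if self.mean is None or self.std is None:
            raise ValueError("Z-score stage not fitted")
        return np.asarray(Z, dtype=float) * self.std + self.mean


@dataclass
class RetentionDataset:
    """Feature matrix + retention target for one metal and exposure type."""

    metal: str
    exposure_type: str  # "long_term" | "short_term"
    X: np.ndarray  # (n, p) design matrix, documented column order
    y: np.ndarray  # (n,) retention targets in (0;1)
    feature_names: tuple[str, ...]
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        expected = (
            LONG_TERM_FEATURES
            if self.exposure_type == "long_term"
            else SHORT_TERM_FEATURES
        )
        if tuple(self.feature_names) != expected:
            raise ValueError(
                f"{self.exposure_type} dataset must have columns {expected}, "
                f"got {tuple(self.feature_names)}"
            )
        if self.X.shape != (len(self.y), len(self.feature_names)):
            raise ValueError("X/y/feature_names shapes disagree")

    @property
    def n(self) -> int:
        return len(self.y)

    def subset(self, indices: Sequence[int]) -> "RetentionDataset":
        idx = np.asarray(indices, dtype=int)
        return RetentionDataset(
            metal=self.metal,
            exposure_type=self.exposure_type,
            X=self.X[idx],
            y=self.y[idx],
            feature_names=self.feature_names,
            codes=tuple(self.codes[i] for i in idx),
        )


def clean_gross_errors(values: Sequence[float], k_sigma: float = 3.0) -> np.ndarray:
    """Indices of values inside the mean ± k·σ band (single pass).

    A "gross error" is a measurement outside the band; σ is the population
    standard deviation of the series. A constant series has no gross
    errors (everything is retained).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 3 or not np.all(np.isfinite(arr)):
        raise ValueError("need at least 3 finite values")
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    sd = arr.std(ddof=0)
    if sd == 0:
        return np.arange(arr.size)
    mean = arr.mean()
    keep = np.flatnonzero(np.abs(arr - mean) <= k_sigma * sd)
    removed = arr.size - keep.size
    if removed:
        logger.info("gross-error filter removed %d of %d values", removed, arr.size)
    return keep


def zscore_fit_transform(
    X: np.ndarray, feature_names: Sequence[str] | None = None
) -> tuple[np.ndarray, NormalizationParams]:
    """Standardise columns to mean 0, unit (population) variance."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a Z-score")
    names = tuple(feature_names) if feature_names else tuple(
        f"x{i}" for i in range(X.shape[1])
    )
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    zero = np.flatnonzero(std == 0)
    if zero.size:
        raise ValueError(
            f"zero-spread column(s): {', '.join(names[i] for i in zero)}"
        )
    params = NormalizationParams(
        feature_names=names, mean=mean, std=std, fitted=True
    )
    return params.zscore_transform(X), params


def scale_to_symmetric_unit(
    X: np.ndarray,
    params: NormalizationParams | None = None,
    feature_names: Sequence[str] | None = None,
    clip: bool = False,
) -> tuple[np.ndarray, NormalizationParams]:
    """Affine map of each column onto [−1, 1].

    With ``params=None`` the map is fitted (column min → −1, max → 1);
    with supplied params the stored affine map is applied, so values
    outside the fitted range land outside [−1, 1] unless ``clip`` is set.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if params is None:
        names = tuple(feature_names) if feature_names else tuple(
            f"x{i}" for i in range(X.shape[1])
        )
        col_min = X.min(axis=0)
        col_max = X.max(axis=0)
        flat = np.flatnonzero(col_max <= col_min)
        if flat.size:
            raise ValueError(
                f"constant column(s) on fit: {', '.join(names[i] for i in flat)}"
            )
        params = NormalizationParams(
            feature_names=names, col_min=col_min, col_max=col_max, fitted=True
        )
    return params.minmax_transform(X, clip=clip), params


def _record_features(
    record: SubjectRecord, metal: str, feature_names: Sequence[str]
) -> list[float] | None:
    """Feature row for one record, or None if a required field is missing."""
    row: list[float] = []
    for name in feature_names:
        if name == "water_mgl":
            value = record.water_mgl.get(metal)
        elif name == "soil_mgkg":
            value = record.soil_mgkg.get(metal)
        elif name == "body_area_m2":
            value = (
                record.body_area_m2
                if record.body_area_m2 is not None
                else record.bsa()
            )
        else:
            value = getattr(record, name)
        if value is None or not np.isfinite(value):
            return None
        row.append(float(value))
    return row


def assemble_dataset(
    records: Iterable[SubjectRecord], metal: str, exposure_type: str
) -> RetentionDataset:
    """Build the per-metal design matrix and retention target.

    Long-term uses 7 columns (physiology + water + soil); short-term drops
    soil.  Rows missing any required field or the retention target are
    dropped with a logged count.
    """
    if exposure_type == "long_term":
        names = LONG_TERM_FEATURES
    elif exposure_type == "short_term":
        names = SHORT_TERM_FEATURES
    else:
        raise ValueError(f"unknown exposure_type {exposure_type!r}")
    rows, targets, codes = [], [], []
    dropped = 0
    for record in records:
        target = record.retention.get(metal)
        row = _record_features(record, metal, names)
        if row is None or target is None or not (0 < target < 1):
            dropped += 1
            continue
        rows.append(row)
        targets.append(target)
        codes.append(record.participant_code)
    if dropped:
        logger.info(
            "assemble_dataset(%s, %s): dropped %d incomplete rows",
            metal, exposure_type, dropped,
        )
    if not rows:
        raise ValueError(f"no usable rows for metal {metal!r} ({exposure_type})")
    if not (_EXPECTED_ROWS[0] <= len(rows) <= _EXPECTED_ROWS[1]):
        logger.warning(
            "%s/%s dataset has %d rows, outside the anticipated [%d, %d] "
            "cohort range",
            metal, exposure_type, len(rows), *_EXPECTED_ROWS,
        )
    return RetentionDataset(
        metal=metal,
        exposure_type=exposure_type,
        X=np.asarray(rows, dtype=float),
        y=np.asarray(targets, dtype=float),
        feature_names=names,
        codes=tuple(codes),
    )


def split_train_test(
    dataset: RetentionDataset,
    test_fraction: float = 0.2,
    seed: int | None = None,
) -> tuple[RetentionDataset, RetentionDataset]:
    """Seeded uniform 80/20 split; disjoint, exhaustive, reproducible."""
    if not (0 < test_fraction < 1):
        raise ValueError(f"test_fraction must lie in (0,1), got {test_fraction}")
    n = dataset.n
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    n_test = round(n * test_fraction)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return dataset.subset(train_idx), dataset.subset(test_idx)


def sequential_shift_folds(n: int, k: int = 5) -> list[np.ndarray]:
    """Contiguous test windows shifting by n/k, starting at the first element.

    Fold ``j`` tests indices ``[floor(j·n/k), floor((j+1)·n/k))``; the
    windows partition ``[0, n)`` for any ``n ≥ k``.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    bounds = [(j * n) // k for j in range(k + 1)]
    return [np.arange(bounds[j], bounds[j + 1]) for j in range(k)]
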
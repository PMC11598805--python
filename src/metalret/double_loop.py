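"""Open and closed double-loop models: two blocks per metal plus fusion.

The *open* model runs two independent MLP blocks per metal — a long-term
exposure block (7 inputs: physiology, drinking water, soil) and a
short-term block (6 inputs: the same minus soil).  The *closed* model
adds a single fused output: a weighted average of the two block outputs
whose weights ("confidence coefficients") are derived from each block's
mean test error,

    a_l = Err_T(l) / (Err_T(l) + Err_T(s)),   a_s = 1 − a_l.

Note the weights are *proportional* to the test errors, not inverse —
the block with the larger test error receives the larger weight.  That
is the published convention this package reproduces; set
``inverse=True`` in :func:`confidence_weights` for the conventional
inverse-error scheme.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from metalret import preprocessing as prep
from metalret import mlp
from metalret.mlp import ErrorReport, MLPModel, RpropConfig
from metalret.preprocessing import NormalizationParams, RetentionDataset
from metalret.retention import SubjectRecord

logger = logging.getLogger(__name__)

EXPOSURE_TYPES = ("long_term", "short_term")


@dataclass(frozen=True)
class ConfidenceWeights:
    """Normalised per-block confidence coefficients for one metal."""

    a_long: float
    a_short: float
    err_long: float
    err_short: float
    metal: str | None = None

    def __post_init__(self) -> None:
        if self.a_long < 0 or self.a_short < 0:
            raise ValueError("confidence weights must be non-negative")
        if abs(self.a_long + self.a_short - 1.0) > 1e-9:
            raise ValueError(
                f"weights must sum to 1, got {self.a_long + self.a_short}"
            )


def confidence_weights(
    err_long: float,
    err_short: float,
    metal: str | None = None,
    inverse: bool = False,
) -> ConfidenceWeights:
    """Confidence coefficients from the two blocks' mean test errors.

    Default (published) scheme: a_l = e_l/(e_l+e_s), proportional to the
    error.  ``inverse=True`` swaps in the conventional inverse-error
    weighting a_l = (1/e_l)/((1/e_l)+(1/e_s)) (requires both errors > 0).
    """
    if err_long < 0 or err_short < 0:
        raise ValueError("errors must be non-negative")
    total = err_long + err_short
    if total <= 0:
        raise ValueError("both errors zero: confidence weights undefined")
    if inverse:
        if err_long == 0 or err_short == 0:
            raise ValueError("inverse-error weights need strictly positive errors")
        a_long = (1.0 / err_long) / (1.0 / err_long + 1.0 / err_short)
    else:
        a_long = err_long / total
    return ConfidenceWeights(
        a_long=a_long,
        a_short=1.0 - a_long,
        err_long=err_long,
        err_short=err_short,
        metal=metal,
    )


@dataclass(frozen=True)
class FusedPrediction:
    """Per-block and fused retention estimates for one subject."""

    metal: str
    retention_long: float
    retention_short: float
    retention_fused: float


def fuse(
    retention_long: float,
    retention_short: float,
    weights: ConfidenceWeights,
) -> FusedPrediction:
    """Closed-loop output: convex combination of the two block estimates."""
    if not (np.isfinite(retention_long) and np.isfinite(retention_short)):
        raise ValueError("block retentions must be finite")
    fused = weights.a_long * retention_long + weights.a_short * retention_short
    return FusedPrediction(
        metal=weights.metal or "",
        retention_long=retention_long,
        retention_short=retention_short,
        retention_fused=fused,
    )


@dataclass
class BlockArtifacts:
    """One trained block with its normalisation state and error reports."""

    model: MLPModel
    feature_params: NormalizationParams
    target_params: NormalizationParams
    train_report: ErrorReport
    test_report: ErrorReport


@dataclass
class DoubleLoopModel:
    """Per-metal pair of trained blocks plus closed-loop fusion weights."""

    metal: str
    long_block: MLPModel
    short_block: MLPModel
    long_feature_params: NormalizationParams
    short_feature_params: NormalizationParams
    long_target_params: NormalizationParams
    short_target_params: NormalizationParams
    weights: ConfidenceWeights
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.long_block.n_inputs != len(prep.LONG_TERM_FEATURES):
            raise ValueError("long block must take 7 inputs")
        if self.short_block.n_inputs != len(prep.SHORT_TERM_FEATURES):
            raise ValueError("short block must take 6 inputs")


#: fraction of the training split held out to choose among random restarts
_VALIDATION_FRACTION = 0.2


def _train_restarts(
    n_inputs: int,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    config: RpropConfig,
    n_restarts: int,
) -> MLPModel:
    """Train ``n_restarts`` independently initialised blocks and keep the
    best generaliser.

    RPROP from a single random start occasionally settles in a sharp
    minimum whose training error is excellent but whose surface spikes
    between training points.  Training error cannot expose such fits, so
    when more than one restart is requested a validation subset is carved
    off the training rows: every candidate trains on the remainder and
    the candidate with the lowest validation error wins.  With a single
    restart the block trains on all rows (the bare published protocol).
    """
    n_restarts = max(1, n_restarts)
    if n_restarts == 1:
        init_seed = int(rng.integers(2**31))
        model = mlp.init_network(n_inputs=n_inputs, n_hidden=5, seed=init_seed)
        model, _ = mlp.train(model, X, y, config)
        return model
    n = len(y)
    n_val = max(1, round(_VALIDATION_FRACTION * n))
    perm = rng.permutation(n)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    X_fit, y_fit = X[fit_idx], y[fit_idx]
    X_val, y_val = X[val_idx], y[val_idx]
    best_model: MLPModel | None = None
    best_val = np.inf
    for _ in range(n_restarts):
        init_seed = int(rng.integers(2**31))
        model = mlp.init_network(n_inputs=n_inputs, n_hidden=5, seed=init_seed)
        model, _ = mlp.train(model, X_fit, y_fit, config)
        val = mlp.evaluate(model, X_val, y_val).mean
        if val < best_val:
            best_val = val
            best_model = model
    assert best_model is not None
    return best_model


def _fit_block(
    dataset: RetentionDataset,
    seed: int,
    config: RpropConfig,
    test_fraction: float,
    use_zscore: bool,
    n_restarts: int,
) -> BlockArtifacts:
    # the whole assembled dataset is normalised before splitting, matching
    # the published preprocessing order ("all data were normalized")
    if use_zscore:
        # per-column z-scoring followed by the [-1,1] affine map composes
        # to the identical transform as min-max alone (both are per-column
        # affine maps sending min to -1 and max to 1), so the stage is run
        # only for its diagnostics (it names zero-spread columns)
        prep.zscore_fit_transform(dataset.X, dataset.feature_names)
    Xn_all, fparams = prep.scale_to_symmetric_unit(
        dataset.X, feature_names=dataset.feature_names
    )
    yn_all, tparams = prep.scale_to_symmetric_unit(
        dataset.y[:, None], feature_names=("retention",)
    )
    normalised = RetentionDataset(
        metal=dataset.metal,
        exposure_type=dataset.exposure_type,
        X=Xn_all,
        y=yn_all[:, 0],
        feature_names=dataset.feature_names,
        codes=dataset.codes,
    )
    rng = np.random.default_rng(seed)
    train_set, test_set = prep.split_train_test(
        normalised, test_fraction=test_fraction, seed=int(rng.integers(2**31))
    )
    model = _train_restarts(
        len(dataset.feature_names), train_set.X, train_set.y,
        rng=rng, config=config, n_restarts=n_restarts,
    )
    return BlockArtifacts(
        model=model,
        feature_params=fparams,
        target_params=tparams,
        train_report=mlp.evaluate(model, train_set.X, train_set.y),
        test_report=mlp.evaluate(model, test_set.X, test_set.y),
    )


def train_open_model(
    records: Iterable[SubjectRecord],
    metal: str,
    seed: int = 0,
    config: RpropConfig | None = None,
    test_fraction: float = 0.2,
    use_zscore: bool = False,
    n_restarts: int = 3,
) -> tuple[DoubleLoopModel, dict[str, ErrorReport]]:
    """Train both exposure blocks on their own 80/20 splits, then close the loop.

    Each block is assembled, normalised to [−1,1] on its training split,
    trained with RPROP, and tested; the two mean test errors then define
    the confidence weights, completing the closed double-loop model.

    Returns the model and a report dict with keys ``long_train``,
    ``long_test``, ``short_train``, ``short_test`` (errors on the
    normalised output scale).
    """
    records = list(records)
    if len(records) < 20:
        raise ValueError("need at least 20 usable records")
    config = config or RpropConfig()
    blocks: dict[str, BlockArtifacts] = {}
    for exposure in EXPOSURE_TYPES:
        dataset = prep.assemble_dataset(records, metal, exposure)
        blocks[exposure] = _fit_block(
            dataset, seed=seed, config=config,
            test_fraction=test_fraction, use_zscore=use_zscore,
            n_restarts=n_restarts,
        )
    weights = confidence_weights(
        blocks["long_term"].test_report.mean,
        blocks["short_term"].test_report.mean,
        metal=metal,
    )
    model = DoubleLoopModel(
        metal=metal,
        long_block=blocks["long_term"].model,
        short_block=blocks["short_term"].model,
        long_feature_params=blocks["long_term"].feature_params,
        short_feature_params=blocks["short_term"].feature_params,
        long_target_params=blocks["long_term"].target_params,
        short_target_params=blocks["short_term"].target_params,
        weights=weights,
        metadata={
            "seed": seed,
            "epochs": config.epochs,
            "test_fraction": test_fraction,
            "use_zscore": use_zscore,
            "n_restarts": n_restarts,
        },
    )
    reports = {
        "long_train": blocks["long_term"].train_report,
        "long_test": blocks["long_term"].test_report,
        "short_train": blocks["short_term"].train_report,
        "short_test": blocks["short_term"].test_report,
    }
    return model, reports


def _predict_block(
    block: MLPModel,
    fparams: NormalizationParams,
    tparams: NormalizationParams,
    record: SubjectRecord,
    metal: str,
    feature_names: Sequence[str],
) -> float:
    row = prep._record_features(record, metal, feature_names)
    if row is None:
        missing = [
            name
            for name in feature_names
            if prep._record_features(record, metal, (name,)) is None
        ]
        raise ValueError(
            f"{record.participant_code}: missing feature(s) {missing} "
            f"for metal {metal!r}"
        )
    xn = fparams.minmax_transform(np.asarray(row)[None, :])
    yn = mlp.forward(block, xn[0])
    return float(tparams.minmax_inverse(np.array([[yn]]))[0, 0])


def predict(model: DoubleLoopModel, record: SubjectRecord) -> FusedPrediction:
    """Fused retention estimate for one subject (plus both block outputs).

    Outputs are inverse-mapped from the normalised training scale back to
    the retention scale; raw block outputs outside (0;1) are reported
    as-is with a warning (no clipping).
    """
    r_long = _predict_block(
        model.long_block, model.long_feature_params, model.long_target_params,
        record, model.metal, prep.LONG_TERM_FEATURES,
    )
    r_short = _predict_block(
        model.short_block, model.short_feature_params, model.short_target_params,
        record, model.metal, prep.SHORT_TERM_FEATURES,
    )
    for name, value in (("long", r_long), ("short", r_short)):
        if not (0 < value < 1):
            warnings.warn(
                f"{record.participant_code}: {name}-term block output "
                f"{value:.4f} outside (0;1)",
                stacklevel=2,
            )
    return fuse(r_long, r_short, model.weights)


@dataclass
class FoldResult:
    """Error reports of one cross-validation fold (or its failure)."""

    fold: int
    test_indices: np.ndarray
    long_test: ErrorReport | None = None
    short_test: ErrorReport | None = None
    failed: bool = False
    reason: str | None = None


@dataclass
class CrossValResult:
    """Per-fold reports and mean ± sd summaries across folds."""

    metal: str
    folds: list[FoldResult]
    summary: dict[str, tuple[float, float]]  # block -> (mean, sd over folds)


def cross_validate(
    records: Iterable[SubjectRecord],
    metal: str,
    k: int = 5,
    seed: int = 0,
    config: RpropConfig | None = None,
    use_zscore: bool = False,
    n_restarts: int = 1,
) -> CrossValResult:
    """k-fold validation with contiguous sequential-shift test windows.

    For each fold the test window is the next contiguous n/k slice of the
    dataset (starting at the first element); weights are re-initialised to
    small random values and both blocks retrained on the complement.  A
    fold with a degenerate feature is marked failed; the others proceed.
    """
    records = list(records)
    config = config or RpropConfig()
    datasets = {
        exposure: prep.assemble_dataset(records, metal, exposure)
        for exposure in EXPOSURE_TYPES
    }
    n = datasets["long_term"].n
    if n < 5 * k:
        raise ValueError(f"need at least {5 * k} rows for {k}-fold validation")
    windows = prep.sequential_shift_folds(n, k)
    normalised: dict[str, RetentionDataset] = {}
    for exposure, dataset in datasets.items():
        if use_zscore:
            prep.zscore_fit_transform(dataset.X, dataset.feature_names)
        Xn_all, _ = prep.scale_to_symmetric_unit(
            dataset.X, feature_names=dataset.feature_names
        )
        yn_all, _ = prep.scale_to_symmetric_unit(
            dataset.y[:, None], feature_names=("retention",)
        )
        normalised[exposure] = RetentionDataset(
            metal=dataset.metal,
            exposure_type=dataset.exposure_type,
            X=Xn_all,
            y=yn_all[:, 0],
            feature_names=dataset.feature_names,
            codes=dataset.codes,
        )
    folds: list[FoldResult] = []
    for j, test_idx in enumerate(windows):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        result = FoldResult(fold=j, test_indices=test_idx)
        try:
            for exposure, dataset in normalised.items():
                tr = dataset.subset(train_idx)
                te = dataset.subset(test_idx)
                block = _train_restarts(
                    len(tr.feature_names), tr.X, tr.y,
                    rng=np.random.default_rng(seed * 1000 + j),
                    config=config, n_restarts=n_restarts,
                )
                report = mlp.evaluate(block, te.X, te.y)
                if exposure == "long_term":
                    result.long_test = report
                else:
                    result.short_test = report
        except (ValueError, FloatingPointError) as exc:
            result.failed = True
            result.reason = str(exc)
            logger.warning("fold %d failed: %s", j, exc)
        folds.append(result)
    summary = {}
    for name, attr in (("long_term", "long_test"), ("short_term", "short_test")):
        means = [
            getattr(f, attr).mean for f in folds if not f.failed and getattr(f, attr)
        ]
        if means:
            summary[name] = (float(np.mean(means)), float(np.std(means, ddof=0)))
    return CrossValResult(metal=metal, folds=folds, summary=summary)
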
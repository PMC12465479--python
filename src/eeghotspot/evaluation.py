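"""Nested cross-validation, error-distance scoring, ablations, statistics.

The evaluation protocol is trial-wise nested cross-validation per
subject x hand dataset: the outer loop is a 5-fold split repeated 5 times
(25 evaluations); within each outer training set an inner 4:1 split drives
early stopping.  The per-fold subject prediction is the mean of the test
trials' predictions, scored by Euclidean distance (mm) to the ground-truth
hotspot.  Condition grids (input level x channel set x trial count) and the
associated paired statistics (Friedman omnibus, Wilcoxon signed-rank
post hoc with Bonferroni correction) mirror the ablation analyses.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelConfig, MotorHotspotCNN
from .montage import HotspotLocation, HotspotSource

logger = logging.getLogger(__name__)


def euclidean_error(pred, truth) -> float:
    """Euclidean distance (mm) between predicted and true hotspot."""
    p = pred.to_array() if isinstance(pred, HotspotLocation) else np.asarray(pred, float)
    t = truth.to_array() if isinstance(truth, HotspotLocation) else np.asarray(truth, float)
    return float(np.linalg.norm(p - t))


@dataclass
class FoldResult:
    repeat: int
    fold: int
    test_trials: tuple[int, ...]
    train_trials: tuple[int, ...]
    val_trials: tuple[int, ...]
    prediction: HotspotLocation
    error_mm: float


@dataclass
class CVResult:
    subject_id: str
    hand: str
    level: int
    channel_set: str
    n_trials_used: int
    folds: list[FoldResult]
    seed: int

    @property
    def n_outer_evals(self) -> int:
        return len(self.folds)

    @property
    def mean_error_mm(self) -> float:
        return float(np.mean([f.error_mm for f in self.folds]))

    @property
    def errors(self) -> np.ndarray:
        return np.array([f.error_mm for f in self.folds])


def _kfold_indices(n, k, rng):
    """Random partition into k folds whose sizes differ by at most one."""
    perm = rng.permutation(n)
    return [np.sort(perm[i::k]) for i in range(k)]


def nested_cv(
    inputs: np.ndarray,
    truth,
    model_config: ModelConfig | None = None,
    k_outer: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
    subject_id: str = "",
    hand: str = "",
    level: int = 1,
    channel_set: str = "Set1",
) -> CVResult:
    """Trial-wise nested k-fold cross-validation for one subject x hand.

    For each repetition the trials are partitioned into ``k_outer`` outer
    test folds; the remaining 80 % are split 4:1 into training and
    validation (validation size = floor(n/5), remainder to training) for
    early stopping.  A fresh model is trained per fold.
    """
    inputs = np.asarray(inputs, dtype=float)
    n = inputs.shape[0]
    # every outer fold and the inner train/val split must be non-empty
    if n < max(k_outer, 3):
        raise ValueError(
            f"need at least {max(k_outer, 3)} trials for {k_outer}-fold nested "
            f"CV, got {n}"
        )
    cfg = model_config or ModelConfig()
    t = truth.to_array() if isinstance(truth, HotspotLocation) else np.asarray(truth, float)
    targets = np.tile(t, (n, 1))

    folds_out: list[FoldResult] = []
    master = np.random.SeedSequence([seed, n, k_outer])
    for rep, rep_ss in enumerate(master.spawn(n_repeats)):
        rng = np.random.default_rng(rep_ss)
        folds = _kfold_indices(n, k_outer, rng)
        for fold_i, test_idx in enumerate(folds):
            rest = np.setdiff1d(np.arange(n), test_idx)
            rest = rng.permutation(rest)
            n_val = max(1, int(np.floor(rest.size / 5)))
            val_idx, train_idx = rest[:n_val], rest[n_val:]

            fold_seed = int(rng.integers(0, 2**31 - 1))
            fold_cfg = cfg.with_updates(seed=fold_seed)
            model = MotorHotspotCNN(inputs[train_idx], targets[train_idx], fold_cfg)
            res = model.fit(
                val_inputs=inputs[val_idx], val_targets=targets[val_idx]
            )
            pred = res.predict_location(inputs[test_idx])
            folds_out.append(
                FoldResult(
                    repeat=rep,
                    fold=fold_i,
                    test_trials=tuple(int(i) for i in test_idx),
                    train_trials=tuple(int(i) for i in train_idx),
                    val_trials=tuple(int(i) for i in val_idx),
                    prediction=pred,
                    error_mm=euclidean_error(pred, t),
                )
            )
    return CVResult(
        subject_id=subject_id, hand=hand, level=level, channel_set=channel_set,
        n_trials_used=n, folds=folds_out, seed=seed,
    )


# ---------------------------------------------------------------------------
# condition grids


@dataclass
class ConditionSummary:
    label: str
    per_subject: pd.DataFrame  # columns: subject_id, hand, mean_error_mm
    n: int
    mean_error_mm: float
    se_mm: float

    @classmethod
    def from_results(cls, label: str, results: list[CVResult]) -> "ConditionSummary":
        df = pd.DataFrame(
            [
                {"subject_id": r.subject_id, "hand": r.hand,
                 "mean_error_mm": r.mean_error_mm}
                for r in results
            ]
        )
        errs = df["mean_error_mm"].to_numpy()
        n = len(errs)
        se = float(errs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        return cls(label=label, per_subject=df, n=n,
                   mean_error_mm=float(errs.mean()), se_mm=se)


def subsample_trials(n_available: int, n_keep: int, seed: int) -> np.ndarray:
    """Seeded subsampling without replacement; nested across n_keep
    (the k-trial subset is always a subset of the (k+m)-trial subset)."""
    if n_keep > n_available:
        raise ValueError(f"requested {n_keep} trials but only {n_available} available")
    perm = np.random.default_rng(np.random.SeedSequence([seed, n_available])).permutation(
        n_available
    )
    return np.sort(perm[:n_keep])


def run_condition_grid(
    datasets: list[tuple[str, str, np.ndarray, HotspotLocation]],
    conditions: list[dict],
    model_config: ModelConfig | None = None,
    seed: int = 0,
    k_outer: int = 5,
    n_repeats: int = 5,
) -> dict[str, tuple[ConditionSummary, list[CVResult]]]:
    """Run nested CV over a condition grid.

    ``datasets`` holds prebuilt tensors: (subject_id, hand, tensor, truth)
    per condition the tensor is restricted by ``channel_indices`` (channel
    ablation) and/or subsampled to ``n_trials`` (trial ablation, nested per
    seed).  ``conditions`` is a list of dicts with keys ``label`` and
    optionally ``channel_indices``, ``n_trials``, ``level``, ``channel_set``.
    """
    cfg = model_config or ModelConfig()
    out = {}
    for cond in conditions:
        label = cond["label"]
        results = []
        for subject_id, hand, tensor, truth in datasets:
            x = tensor
            if cond.get("channel_indices") is not None:
                x = x[:, np.asarray(cond["channel_indices"], int), :]
            if cond.get("n_trials") is not None:
                keep = subsample_trials(x.shape[0], int(cond["n_trials"]), seed)
                x = x[keep]
            results.append(
                nested_cv(
                    x, truth, cfg, k_outer=k_outer, n_repeats=n_repeats,
                    seed=seed, subject_id=subject_id, hand=hand,
                    level=cond.get("level", 1),
                    channel_set=cond.get("channel_set", "Set1"),
                )
            )
        out[label] = (ConditionSummary.from_results(label, results), results)
        logger.info("condition %s: mean error %.2f mm",
                    label, out[label][0].mean_error_mm)
    return out


# ---------------------------------------------------------------------------
# baseline


class MeanPredictor:
    """Predicts the mean training-truth coordinate for every input."""

    def __init__(self, train_truths):
        pts = np.atleast_2d(
            np.stack([
                t.to_array() if isinstance(t, HotspotLocation) else np.asarray(t, float)
                for t in np.atleast_1d(train_truths)
            ]) if not isinstance(train_truths, np.ndarray) else train_truths
        )
        if pts.size == 0:
            raise ValueError("need at least one training truth")
        self.mean = pts.reshape(-1, 3).mean(axis=0)

    def predict(self, inputs=None) -> np.ndarray:
        return self.mean.copy()

    def predict_location(self, inputs=None) -> HotspotLocation:
        return HotspotLocation.from_array(self.mean, HotspotSource.PREDICTED)


def baseline_mean_predictor(train_truths) -> MeanPredictor:
    """Chance-level reference: always predict the mean training hotspot."""
    return MeanPredictor(train_truths)


# ---------------------------------------------------------------------------
# statistics


@dataclass
class PairwiseTest:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_corrected: float
    significant: bool


@dataclass
class StatsReport:
    design: str
    friedman_statistic: float | None
    friedman_p: float | None
    pairwise: list[PairwiseTest]
    alpha: float = 0.05

    @property
    def significant_pairs(self):
        return [t.pair for t in self.pairwise if t.significant]


def _signed_rank(x, y):
    """Wilcoxon signed-rank; exact null for n <= 25 without ties/zeros."""
    d = np.asarray(x, float) - np.asarray(y, float)
    nz = d[d != 0]
    exact = nz.size <= 25 and nz.size > 0 and np.unique(np.abs(nz)).size == nz.size
    if nz.size == 0:
        return 0.0, 1.0
    res = stats.wilcoxon(x, y, method="exact" if exact else "approx")
    return float(res.statistic), float(res.pvalue)


def compare_conditions(
    summaries: list[ConditionSummary],
    design: str = "paired",
    alpha: float = 0.05,
) -> StatsReport:
    """Omnibus Friedman + pairwise post hoc with Bonferroni correction.

    Paired design uses the Wilcoxon signed-rank test (subjects matched
    across conditions); unpaired uses the rank-sum test.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two conditions to compare")
    if design not in ("paired", "unpaired"):
        raise ValueError("design must be 'paired' or 'unpaired'")

    vectors = {}
    for s in summaries:
        df = s.per_subject.sort_values(["subject_id", "hand"])
        vectors[s.label] = (
            df["mean_error_mm"].to_numpy(),
            list(zip(df["subject_id"], df["hand"])),
        )

    if design == "paired":
        keysets = [tuple(k) for _, k in vectors.values()]
        if len(set(keysets)) != 1:
            raise ValueError("paired design requires matched subject x hand sets")

    friedman_stat = friedman_p = None
    if design == "paired" and len(summaries) >= 3:
        arrays = [v[0] for v in vectors.values()]
        if all(np.allclose(a, arrays[0]) for a in arrays[1:]):
            friedman_stat, friedman_p = 0.0, 1.0
        else:
            friedman_stat, friedman_p = (
                float(v) for v in stats.friedmanchisquare(*arrays)
            )

    pairs = list(itertools.combinations([s.label for s in summaries], 2))
    n_pairs = len(pairs)
    pairwise = []
    for a, b in pairs:
        xa, xb = vectors[a][0], vectors[b][0]
        if design == "paired":
            if np.allclose(xa, xb):
                statistic, p = 0.0, 1.0
            else:
                statistic, p = _signed_rank(xa, xb)
        else:
            res = stats.ranksums(xa, xb)
            statistic, p = float(res.statistic), float(res.pvalue)
        p_corr = min(1.0, p * n_pairs)
        pairwise.append(
            PairwiseTest(
                pair=(a, b), statistic=statistic, p_raw=p,
                p_corrected=p_corr, significant=p_corr < alpha,
            )
        )
    return StatsReport(
        design=design, friedman_statistic=friedman_stat, friedman_p=friedman_p,
        pairwise=pairwise, alpha=alpha,
    )
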
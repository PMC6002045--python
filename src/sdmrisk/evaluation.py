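"""Model evaluation and selection: k-fold CV, AUC, omission rates, ranking.

Candidates — feature-class sets crossed with regularization multipliers —
are compared on three statistics from a shared k-fold partition of the
presences (the background sample is reused whole in every fold):

* ``auc_cv`` — mean test AUC (rank-sum / Mann–Whitney estimator, ties 0.5)
  of held-out presences against the background;
* ``or0`` / ``or10`` — mean test omission rates at the 0% (training minimum)
  and 10% (lower empirical decile of training presence scores) thresholds.

Models are ranked by or10 ascending, then or0 ascending, then auc_cv
descending: calibrated omission first, discrimination as the final key.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .maxent import FeatureConfig, fit_from_values, predict_scores


@dataclass
class FoldAssignment:
    """Seeded balanced random partition of presence indices into k folds."""

    fold_of: np.ndarray  # fold id (1..k) per presence index
    k: int
    seed: int

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.where(self.fold_of == fold)[0]
        train = np.where(self.fold_of != fold)[0]
        return train, test


@dataclass
class EvaluationRecord:
    """Cross-validated performance of one feature-set × RM candidate."""

    features: str
    rm: float
    auc_cv_mean: float
    auc_cv_sd: float
    or0: float
    or10: float

    def sort_key(self) -> tuple[float, float, float]:
        return (self.or10, self.or0, -self.auc_cv_mean)


def make_folds(n_presence: int, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Random balanced partition: fold sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_presence < k:
        raise ValueError(f"cannot make {k} folds from {n_presence} presences")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_presence)
    fold_of = np.empty(n_presence, dtype=int)
    fold_of[order] = (np.arange(n_presence) % k) + 1
    return FoldAssignment(fold_of=fold_of, k=k, seed=seed)


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-sum (Mann–Whitney) AUC with ties counted one half.

    The probability that a random presence outscores a random background
    point; 0.5 means no better than random.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("auc requires non-empty score vectors")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def omission_threshold(train_presence_scores: np.ndarray, percentile: float) -> float:
    """Training threshold: 0 → minimum; q → lower empirical q-quantile.

    The lower empirical quantile convention (no interpolation): the smallest
    training score s such that at least ``percentile`` % of training scores
    are <= s.
    """
    t = np.sort(np.asarray(train_presence_scores, dtype=float))
    if t.size == 0:
        raise ValueError("empty training scores")
    if percentile <= 0:
        return float(t[0])
    idx = max(int(np.ceil(percentile / 100.0 * t.size)) - 1, 0)
    return float(t[idx])


def omission_rate(train_presence_scores: np.ndarray, test_presence_scores: np.ndarray,
                  percentile: float = 0.0) -> float:
    """Fraction of test presences scoring strictly below the training threshold."""
    test = np.asarray(test_presence_scores, dtype=float)
    if test.size == 0:
        raise ValueError("empty test scores")
    thr = omission_threshold(train_presence_scores, percentile)
    return float((test < thr).mean())


def cross_validate(candidate: FeatureConfig, values_pres: dict[str, np.ndarray],
                   values_bg: dict[str, np.ndarray], folds: FoldAssignment,
                   seed: int = 0, clamp: str = "clamp") -> EvaluationRecord:
    """k-fold CV of one candidate on shared folds.

    Each fold fits on the remaining presences plus the full background and
    scores the held-out presences and the background.
    """
    names = list(values_bg)
    aucs, or0s, or10s = [], [], []
    for fold in range(1, folds.k + 1):
        tr, te = folds.train_test(fold)
        vp_tr = {v: np.asarray(values_pres[v])[tr] for v in names}
        vp_te = {v: np.asarray(values_pres[v])[te] for v in names}
        model = fit_from_values(vp_tr, values_bg, candidate, seed=seed)
        s_tr = predict_scores(model, vp_tr, clamp=clamp)
        s_te = predict_scores(model, vp_te, clamp=clamp)
        s_bg = predict_scores(model, values_bg, clamp=clamp)
        aucs.append(auc(s_te, s_bg))
        or0s.append(omission_rate(s_tr, s_te, 0.0))
        or10s.append(omission_rate(s_tr, s_te, 10.0))
    aucs = np.asarray(aucs)
    return EvaluationRecord(
        features=candidate.label, rm=candidate.rm,
        auc_cv_mean=float(aucs.mean()),
        auc_cv_sd=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        or0=float(np.mean(or0s)), or10=float(np.mean(or10s)),
    )


#: feature-set × RM grid used in the published model comparison
PAPER_FEATURE_SETS = ["LQPH", "LQPTH", "LQH", "LQP", "LH", "LQPT"]
PAPER_RMS = [1.0, 1.5, 2.0]


def run_candidate_grid(feature_sets: list[str], rms: list[float],
                       values_pres: dict[str, np.ndarray],
                       values_bg: dict[str, np.ndarray], folds: FoldAssignment,
                       seed: int = 0, **config_kw) -> list[EvaluationRecord]:
    """Evaluate the Cartesian product of feature sets × RMs on shared folds."""
    if not feature_sets or not rms:
        raise ValueError("feature_sets and rms must be non-empty")
    records = []
    for fs, rm in itertools.product(feature_sets, rms):
        cand = FeatureConfig(classes=fs, rm=rm, **config_kw)
        records.append(cross_validate(cand, values_pres, values_bg, folds, seed=seed))
    return records


def rank_models(records: list[EvaluationRecord]) -> list[EvaluationRecord]:
    """Stable three-key sort: or10 asc, then or0 asc, then auc_cv_mean desc."""
    if not records:
        raise ValueError("no records to rank")
    return sorted(records, key=EvaluationRecord.sort_key)


def records_to_frame(records: list[EvaluationRecord], ranked: bool = True) -> pd.DataFrame:
    """CSV-ready table mirroring the published comparison layout."""
    rows = rank_models(records) if ranked else records
    return pd.DataFrame({
        "rank": np.arange(1, len(rows) + 1) if ranked else np.nan,
        "features": [r.features for r in rows],
        "rm": [r.rm for r in rows],
        "auc_cv_mean": [r.auc_cv_mean for r in rows],
        "auc_cv_sd": [r.auc_cv_sd for r in rows],
        "or0": [r.or0 for r in rows],
        "or10": [r.or10 for r in rows],
    })
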
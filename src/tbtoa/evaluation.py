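"""Model evaluation: repeated cross-validation, ROC/AUC and DeLong inference.

The area under the ROC curve is computed as the Mann-Whitney statistic: the
fraction of (case, control) pairs ranked correctly, ties counting one half.
Its sampling variance, the confidence interval and the paired test between
two models scored on the same knees use DeLong's placement-value method:
with cases X_1..X_m and controls Y_1..Y_n, the placements

    V10_i = (1/n) sum_j psi(X_i, Y_j),   V01_j = (1/m) sum_i psi(X_i, Y_j),

(psi = 1, 1/2, 0 for correct / tied / inverted pairs) have
var(AUC) = S10/m + S01/n with S10, S01 the sample variances of the
placements; covariances between two score vectors follow the same recipe
and give the paired z-test for correlated ROC curves.

Cross-validation follows the repeated stratified k-fold design: each repeat
draws its own stratified fold assignment, every knee is scored exactly once
out-of-fold per repeat, and a knee's pooled score is the mean of its
out-of-fold scores over repeats. All headline metrics — AUC with its DeLong
95% CI, balanced accuracy, PPV, NPV, and the DeLong p-value against the
reference model — are computed on the pooled score vector, which keeps the
comparison between models paired on identical knees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .design import ModelSpec, assemble_features
from .exceptions import ConfigError, MetricError, StructuralError
from .labels import scenario_mask
from .regression import PenalizedLogit

__all__ = [
    "CVConfig",
    "EvaluationResult",
    "auc_mann_whitney",
    "delong_variance",
    "delong_ci",
    "delong_test",
    "confusion_metrics",
    "repeated_cv_evaluate",
    "evaluate_models",
]


def _check_binary(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1} or len(np.unique(labels)) < 2:
        raise MetricError("labels must contain both classes, coded 0/1")
    return labels == 1, labels == 0


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the tie-corrected Mann-Whitney pair statistic."""
    case, control = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(scores)
    m, n = int(case.sum()), int(control.sum())
    return float((ranks[case].sum() - m * (m + 1) / 2.0) / (m * n))


def _placements(scores: np.ndarray, case: np.ndarray, control: np.ndarray):
    """DeLong placement values (V10 per case, V01 per control)."""
    x = np.asarray(scores, dtype=float)[case]
    y = np.asarray(scores, dtype=float)[control]
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the AUC estimate."""
    case, control = _check_binary(labels)
    m, n = int(case.sum()), int(control.sum())
    if m < 2 or n < 2:
        raise MetricError("DeLong variance needs at least 2 members per class")
    v10, v01 = _placements(scores, case, control)
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_ci(
    scores: np.ndarray, labels: np.ndarray, level: float = 0.95
) -> tuple[float, float, float]:
    """AUC with its DeLong normal-approximation CI, truncated to [0, 1]."""
    auc = auc_mann_whitney(scores, labels)
    se = float(np.sqrt(delong_variance(scores, labels)))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return auc, max(0.0, auc - z * se), min(1.0, auc + z * se)


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Paired DeLong test of two correlated ROC curves on the same knees.

    Returns ``(z, p)`` with a two-sided normal p-value; ``z`` is
    antisymmetric under swapping the two score vectors. Identical scores
    give ``(0, 1)``.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise StructuralError("score vectors and labels must have equal length")
    case, control = _check_binary(labels)
    m, n = int(case.sum()), int(control.sum())
    if m < 2 or n < 2:
        raise MetricError("DeLong test needs at least 2 members per class")

    v10a, v01a = _placements(scores_a, case, control)
    v10b, v01b = _placements(scores_b, case, control)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var_diff <= 0:
        z = 0.0
    else:
        z = (auc_a - auc_b) / float(np.sqrt(var_diff))
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return z, p


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[float, float, float]:
    """Balanced accuracy, PPV and NPV at a probability threshold.

    PPV (or NPV) is returned as NaN with a warning when no knee is
    predicted positive (negative).
    """
    case, control = _check_binary(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & case))
    fp = int(np.sum(pred & control))
    fn = int(np.sum(~pred & case))
    tn = int(np.sum(~pred & control))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    bacc = (sens + spec) / 2.0
    if tp + fp == 0:
        warnings.warn("no predicted positives; PPV undefined", stacklevel=2)
        ppv = float("nan")
    else:
        ppv = tp / (tp + fp)
    if tn + fn == 0:
        warnings.warn("no predicted negatives; NPV undefined", stacklevel=2)
        npv = float("nan")
    else:
        npv = tn / (tn + fn)
    return bacc, ppv, npv


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified k-fold configuration.

    The published protocol is 10 folds repeated 300 times; the repeat count
    scales down for desk-size experiments. Repeat ``r`` draws its folds from
    ``seed + r``, so all models evaluated under the same config share fold
    assignments — a requirement for paired DeLong comparisons.
    """

    k_folds: int = 10
    repeats: int = 300
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ConfigError("k_folds must be at least 2")
        if self.repeats < 1:
            raise ConfigError("repeats must be at least 1")


@dataclass
class EvaluationResult:
    """Cross-validated performance of one model under one scenario."""

    model_name: str
    scenario: str
    pooled_scores: np.ndarray
    labels: np.ndarray
    auc: float
    ci95: tuple[float, float]
    bacc: float
    ppv: float
    npv: float
    per_repeat_auc: np.ndarray
    p_vs_reference: float | None = None
    reference_name: str | None = None

    def to_row(self) -> dict:
        return {
            "model": self.model_name,
            "scenario": self.scenario,
            "bacc": round(self.bacc, 4),
            "ppv": round(self.ppv, 4),
            "npv": round(self.npv, 4),
            "auc": round(self.auc, 4),
            "auc_ci_lo": round(self.ci95[0], 4),
            "auc_ci_hi": round(self.ci95[1], 4),
            "p_vs_reference": (
                None if self.p_vs_reference is None else round(self.p_vs_reference, 4)
            ),
        }

    def summary(self) -> str:
        p = "-" if self.p_vs_reference is None else f"{self.p_vs_reference:.3f}"
        return (
            f"{self.model_name} [{self.scenario}]  "
            f"AUC {self.auc:.3f} ({self.ci95[0]:.3f}-{self.ci95[1]:.3f})  "
            f"BACC {self.bacc:.2f}  PPV {self.ppv:.2f}  NPV {self.npv:.2f}  "
            f"p vs ref {p}"
        )


def _scenario_frame(records: pd.DataFrame, scenario: str) -> pd.DataFrame:
    """Restrict a labelled cohort to one scenario and attach the response."""
    if "group" not in records.columns:
        raise ConfigError("records must carry a 'group' column; label the cohort first")
    usable = records[records["group"].isin([1, 2, 3, 4])]
    case, control = scenario_mask(usable["group"].to_numpy(), scenario)
    out = usable[case | control].copy()
    out["case"] = case[case | control]
    return out.reset_index(drop=True)


def _fold_scores(
    X: np.ndarray,
    y: np.ndarray,
    penalized: np.ndarray,
    cv: CVConfig,
    repeat: int,
    lambda_grid: np.ndarray | None,
) -> np.ndarray:
    """Out-of-fold scores of one CV repeat (one score per knee)."""
    n = len(y)
    y_fit = y
    base_seed = (cv.seed + repeat) % (2**31)
    for attempt in range(20):
        splitter = StratifiedKFold(
            n_splits=cv.k_folds, shuffle=True, random_state=(base_seed + attempt) % (2**31)
        )
        strata = y_fit if cv.stratified else np.zeros(n, dtype=int)
        try:
            folds = list(splitter.split(np.zeros(n), strata))
        except ValueError as exc:
            raise ConfigError(f"cannot form {cv.k_folds} stratified folds: {exc}") from exc
        if all(len(np.unique(y_fit[tr])) == 2 for tr, _ in folds):
            break
    else:
        raise ConfigError("could not draw folds with both classes in every training set")

    scores = np.empty(n)
    for train, test in folds:
        model = PenalizedLogit(y_fit[train], X[train], penalized=penalized)
        # CV folds only need scores for ranking; a looser solver tolerance
        # than the default changes pooled AUCs by < 1e-3 and halves runtime
        res = model.fit(lambda_grid=lambda_grid, tol=1e-4)
        z = X[test] @ res.params.drop("const").to_numpy() + res.params["const"]
        scores[test] = 1.0 / (1.0 + np.exp(-z))
    return scores


def repeated_cv_evaluate(
    records: pd.DataFrame,
    model_spec: ModelSpec,
    scenario: str = "primary",
    cv: CVConfig = CVConfig(),
    reference: EvaluationResult | None = None,
    lambda_grid: np.ndarray | None = None,
    permute_labels: bool = False,
) -> EvaluationResult:
    """Repeated stratified CV of one model spec on a labelled cohort.

    Per repeat, a fresh stratified fold assignment is drawn; per fold, the
    model is standardised and fitted on the training knees and the held-out
    knees are scored. A knee's pooled score is its mean out-of-fold score
    over repeats; AUC, the DeLong 95% CI, BACC/PPV/NPV and (when *reference*
    is given) the paired DeLong p-value are computed on the pooled vector.

    ``permute_labels=True`` permutes the response once (from the CV seed)
    before the CV starts — the classical no-signal null: fitting, scoring
    and metrics all use the permuted labels, which severs any texture-
    outcome coupling while preserving class balance.
    """
    frame = _scenario_frame(records, scenario)
    X_df, y, penalized = assemble_features(frame, model_spec)
    X = X_df.to_numpy(dtype=float)

    if permute_labels:
        rng = np.random.default_rng(cv.seed)
        y = y[rng.permutation(len(y))]

    sums = np.zeros(len(y))
    per_repeat = np.empty(cv.repeats)
    for r in range(cv.repeats):
        scores_r = _fold_scores(X, y, penalized, cv, r, lambda_grid)
        sums += scores_r
        per_repeat[r] = auc_mann_whitney(scores_r, y)
    pooled = sums / cv.repeats

    auc, lo, hi = delong_ci(pooled, y)
    bacc, ppv, npv = confusion_metrics(pooled, y)
    result = EvaluationResult(
        model_name=model_spec.name,
        scenario=scenario,
        pooled_scores=pooled,
        labels=y,
        auc=auc,
        ci95=(lo, hi),
        bacc=bacc,
        ppv=ppv,
        npv=npv,
        per_repeat_auc=per_repeat,
    )
    if reference is not None:
        if len(reference.pooled_scores) != len(pooled):
            raise StructuralError(
                "reference was evaluated on a different scenario cohort"
            )
        _, p = delong_test(pooled, reference.pooled_scores, y)
        result.p_vs_reference = p
        result.reference_name = reference.model_name
    return result


def evaluate_models(
    records: pd.DataFrame,
    model_specs: list[ModelSpec],
    scenario: str = "primary",
    cv: CVConfig = CVConfig(),
    reference_name: str = "M1",
    lambda_grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, EvaluationResult]]:
    """Evaluate several models under one scenario against a reference.

    The reference model (by name, default M1) is evaluated first; every
    other model's pooled scores are compared to it with the paired DeLong
    test. Returns the results table (one row per model, mirroring the
    published layout) and the individual results keyed by model name.
    """
    specs = {s.name: s for s in model_specs}
    results: dict[str, EvaluationResult] = {}
    reference = None
    if reference_name in specs:
        reference = repeated_cv_evaluate(
            records, specs[reference_name], scenario, cv, lambda_grid=lambda_grid
        )
        results[reference_name] = reference
    for name, spec in specs.items():
        if name == reference_name:
            continue
        results[name] = repeated_cv_evaluate(
            records, spec, scenario, cv, reference=reference, lambda_grid=lambda_grid
        )
    table = pd.DataFrame([results[s.name].to_row() for s in model_specs])
    return table, results
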
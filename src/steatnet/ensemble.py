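"""The resampled network ensemble: fit/CV R², sensitivities, ROC, selection.

Twenty networks are trained on independent random 70% draws of the
modeling cohort; each model's fit R² (squared Pearson correlation between
predicted and observed status on its training records) and cross-validation
R² (same, on its held-out 30%) are extracted, per-variable sensitivities
rank diagnostic importance, and a ROC curve over the pooled held-out
predictions measures predictive power.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .analytes import ANALYTE_CODES
from .ann import AnnConfig, AnnModel, train_model
from .cohort import Cohort

__all__ = [
    "FeatureSpec",
    "ModelRun",
    "EnsembleResult",
    "RocCurve",
    "SensitivityTable",
    "FULL_MODEL_VARIABLES",
    "design_matrix",
    "run_ensemble",
    "sensitivity",
    "roc_curve",
    "pooled_roc",
    "select_top_variables",
]

#: Default modeling variables: the ten retained analytes plus age and
#: total length (sex and weight are not model inputs).
FULL_MODEL_VARIABLES: tuple[str, ...] = tuple(
    c for c in ANALYTE_CODES if c not in ("BA", "UA")
) + ("age", "total_length")


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered model inputs and the regression target.

    target is ``"binary_status"`` (healthy=0 / diseased=1, the default —
    the ROC needs a binary truth) or ``"vet_score"`` (0-5, rescaled
    internally to [0, 1]).
    """

    variables: tuple[str, ...] = FULL_MODEL_VARIABLES
    target: str = "binary_status"

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable in feature spec")
        if self.target not in ("binary_status", "vet_score"):
            raise ValueError(f"unknown target {self.target!r}")


def design_matrix(cohort: Cohort, spec: FeatureSpec):
    """Complete-case feature matrix, target vector and record ids.

    Records missing any *selected* feature are excluded (listwise over the
    spec's variables only), mirroring how a fish with no CK reading drops
    out of a panel that includes CK.  Returns ``(X, y, ids, excluded_ids)``
    with y on the 0/1 scale (vet score divided by 5 in vet-score mode).
    """
    df = cohort.to_frame()
    missing_cols = [v for v in spec.variables if v not in df.columns]
    if missing_cols:
        raise KeyError(f"unknown variable(s) in spec: {missing_cols}")
    sub = df[list(spec.variables)].astype(float)
    keep = sub.notna().all(axis=1).to_numpy()
    X = sub.to_numpy(dtype=float)[keep]
    if spec.target == "binary_status":
        y = (df["vet_score"].to_numpy(dtype=float)[keep] >= 1.0).astype(float)
    else:
        y = df["vet_score"].to_numpy(dtype=float)[keep] / 5.0
    ids = df["fish_id"].to_numpy()[keep].tolist()
    excluded = df["fish_id"].to_numpy()[~keep].tolist()
    return X, y, ids, excluded


def _r_squared(pred: np.ndarray, obs: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when either side is constant."""
    if len(pred) < 2 or np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return float("nan")
    r = np.corrcoef(pred, obs)[0, 1]
    return float(r * r)


@dataclass
class ModelRun:
    model: AnnModel
    train_idx: np.ndarray
    test_idx: np.ndarray
    fit_r2: float
    cv_r2: float
    cv_pred: np.ndarray  # predictions for test_idx records


@dataclass
class EnsembleResult:
    """Twenty trained networks plus everything needed to interrogate them."""

    spec: FeatureSpec
    X: np.ndarray
    y: np.ndarray
    fish_ids: list[str]
    excluded_ids: list[str]
    models: list[ModelRun]
    train_frac: float
    base_seed: int
    config: AnnConfig
    redraw_count: int = 0

    @property
    def n_models(self) -> int:
        return len(self.models)

    def _agg(self, values) -> tuple[float, float]:
        vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
        if len(vals) == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    @property
    def fit_r2(self) -> tuple[float, float]:
        """(mean, SD) of per-model training-fit R² across the ensemble."""
        return self._agg(m.fit_r2 for m in self.models)

    @property
    def cv_r2(self) -> tuple[float, float]:
        """(mean, SD) of per-model held-out R² across the ensemble."""
        return self._agg(m.cv_r2 for m in self.models)

    def pooled_cv_predictions(self):
        """Per-record averaged held-out predictions.

        Each record's pooled value averages only models that held it out of
        training; records held out by no model (rare) are dropped.  Returns
        ``(y_true, y_pred, record_indices)``.
        """
        n = len(self.y)
        sums = np.zeros(n)
        counts = np.zeros(n)
        for m in self.models:
            sums[m.test_idx] += m.cv_pred
            counts[m.test_idx] += 1
        idx = np.flatnonzero(counts > 0)
        return self.y[idx], sums[idx] / counts[idx], idx

    def to_dict(self) -> dict:
        fit_mean, fit_sd = self.fit_r2
        cv_mean, cv_sd = self.cv_r2
        return {
            "spec": {"variables": list(self.spec.variables), "target": self.spec.target},
            "n_models": self.n_models,
            "train_frac": self.train_frac,
            "base_seed": self.base_seed,
            "n_records": len(self.y),
            "excluded_ids": list(self.excluded_ids),
            "redraw_count": self.redraw_count,
            "fit_r2_mean": fit_mean,
            "fit_r2_sd": fit_sd,
            "cv_r2_mean": cv_mean,
            "cv_r2_sd": cv_sd,
            "per_model": [
                {
                    "seed": m.model.seed,
                    "fit_r2": m.fit_r2,
                    "cv_r2": m.cv_r2,
                    "n_train": int(len(m.train_idx)),
                    "n_iter": m.model.n_iter,
                    "converged": m.model.converged,
                }
                for m in self.models
            ],
        }

    def save_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path


def _draw_train(rng: np.random.Generator, y: np.ndarray, train_frac: float,
                stratified: bool) -> tuple[np.ndarray, int]:
    """One training-index draw; returns (indices, redraw count)."""
    n = len(y)
    if stratified:
        parts = []
        for cls in np.unique(y):
            cls_idx = np.flatnonzero(y == cls)
            k = int(round(train_frac * len(cls_idx)))
            k = min(max(k, 1), len(cls_idx) - 1)
            parts.append(rng.choice(cls_idx, size=k, replace=False))
        return np.sort(np.concatenate(parts)), 0
    n_train = min(max(int(round(train_frac * n)), 1), n - 1)
    redraws = 0
    for _ in range(100):
        train_idx = np.sort(rng.choice(n, size=n_train, replace=False))
        if np.ptp(y[train_idx]) > 0:
            return train_idx, redraws
        redraws += 1
    raise RuntimeError("could not draw a two-class training sample")


def run_ensemble(
    cohort: Cohort,
    spec: FeatureSpec | None = None,
    n_models: int = 20,
    train_frac: float = 0.7,
    base_seed: int = 0,
    config: AnnConfig | None = None,
    stratified: bool = True,
) -> EnsembleResult:
    """Train the resampled ensemble on a cohort.

    Model ``m`` uses seed ``base_seed + m`` for both its 70% training draw
    and its weight initialization.  Draws are class-stratified by default:
    each health class contributes 70% of its records, so every model sees
    the same class balance.  (Unstratified simple random draws are kept
    behind ``stratified=False``; at these sample sizes they let the
    training-set class composition leak into held-out predictions, which
    biases pooled cross-validation AUC downward on signal-free data.)  A
    non-stratified draw whose training half contains a single class is
    redrawn (at most 100 attempts) and counted in ``redraw_count``.
    """
    if n_models < 2:
        raise ValueError("need at least 2 models")
    spec = spec or FeatureSpec()
    cfg = config or AnnConfig()
    X, y, ids, excluded = design_matrix(cohort, spec)
    n = len(y)
    if n < 10:
        raise ValueError(f"only {n} complete-case records; need at least 10")
    if np.ptp(y) == 0:
        raise ValueError("cohort contains a single health class")

    models: list[ModelRun] = []
    redraws = 0
    for m_idx in range(n_models):
        seed = base_seed + m_idx
        rng = np.random.default_rng(seed)
        train_idx, r = _draw_train(rng, y, train_frac, stratified)
        redraws += r
        test_idx = np.setdiff1d(np.arange(n), train_idx)
        model = train_model(X[train_idx], y[train_idx], seed=seed, config=cfg)
        fit_r2 = _r_squared(model.predict(X[train_idx]), y[train_idx])
        cv_pred = model.predict(X[test_idx])
        cv_r2 = _r_squared(cv_pred, y[test_idx])
        models.append(ModelRun(model, train_idx, test_idx, fit_r2, cv_r2, cv_pred))
    return EnsembleResult(
        spec=spec, X=X, y=y, fish_ids=ids, excluded_ids=excluded,
        models=models, train_frac=train_frac, base_seed=base_seed,
        config=cfg, redraw_count=redraws,
    )


@dataclass
class SensitivityTable:
    """Per-variable perturbation sensitivities, mean ± SD over models."""

    variables: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    delta: float
    degenerate: tuple[str, ...] = ()  # zero-range features

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variable": self.variables, "sensitivity_mean": self.mean,
             "sensitivity_sd": self.sd,
             "degenerate": [v in self.degenerate for v in self.variables]}
        ).sort_values("sensitivity_mean", ascending=False, kind="stable").reset_index(drop=True)

    def ranking(self) -> list[str]:
        order = np.lexsort((list(self.variables), -self.mean))
        return [self.variables[i] for i in order]


def sensitivity(
    result: EnsembleResult, delta: float = 0.05, central: bool = False
) -> SensitivityTable:
    """Rank variables by how much a small perturbation moves predictions.

    For variable j and model m the sensitivity is the mean absolute change
    in predicted status over all modeling records when x_j is shifted by
    ``+delta`` of j's observed range (central difference averages the +/-
    shifts when ``central=True``).  Reported as mean ± SD over the models.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    X = result.X
    ranges = X.max(axis=0) - X.min(axis=0)
    degenerate = tuple(
        v for v, r in zip(result.spec.variables, ranges) if r == 0
    )
    per_model = np.empty((result.n_models, X.shape[1]))
    for mi, run in enumerate(result.models):
        base = run.model.predict(X)
        for j in range(X.shape[1]):
            Xp = X.copy()
            Xp[:, j] += delta * ranges[j]
            up = np.abs(run.model.predict(Xp) - base).mean()
            if central:
                Xm = X.copy()
                Xm[:, j] -= delta * ranges[j]
                down = np.abs(run.model.predict(Xm) - base).mean()
                per_model[mi, j] = 0.5 * (up + down)
            else:
                per_model[mi, j] = up
    return SensitivityTable(
        variables=result.spec.variables,
        mean=per_model.mean(axis=0),
        sd=per_model.std(axis=0, ddof=1),
        delta=delta,
        degenerate=degenerate,
    )


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_se: float  # SD of per-model CV AUCs when built from an ensemble

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr,
                             "tpr": self.tpr})


def roc_curve(scores, labels, auc_se: float = float("nan")) -> RocCurve:
    """ROC over distinct score thresholds with trapezoidal AUC.

    Tied scores across classes contribute half a concordance, so the AUC
    equals the concordant-pair (Mann-Whitney) statistic exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if np.ptp(labels) == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    fpr, tpr, thr = skm.roc_curve(labels, scores)
    auc = float(skm.auc(fpr, tpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc, auc_se=auc_se)


def pooled_roc(result: EnsembleResult) -> RocCurve:
    """ROC from the ensemble's pooled held-out predictions.

    The curve uses per-record predictions averaged across the models that
    held the record out; the reported spread is the SD of per-model AUCs
    (models whose held-out set is single-class are skipped).
    """
    y_true, y_pred, _ = result.pooled_cv_predictions()
    per_model_auc = []
    for run in result.models:
        yt = result.y[run.test_idx]
        if len(yt) >= 2 and np.ptp(yt) > 0:
            f, t, _ = skm.roc_curve(yt, run.cv_pred)
            per_model_auc.append(skm.auc(f, t))
    se = float(np.std(per_model_auc, ddof=1)) if len(per_model_auc) > 1 else float("nan")
    return roc_curve(y_pred, y_true, auc_se=se)


def select_top_variables(
    sens: SensitivityTable,
    k: int = 4,
    non_lethal: bool = True,
    exclusions: tuple[str, ...] = (),
) -> FeatureSpec:
    """Pick the k most sensitive blood-chemistry variables for re-modeling.

    Only analytes compete for the k slots; total length is always kept and
    age is added back only when ``non_lethal=False`` (otolith ageing kills
    the fish).  Ties at the selection boundary are broken by larger mean
    sensitivity then lexicographic code, with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    chem = [
        (v, m) for v, m in zip(sens.variables, sens.mean)
        if v in ANALYTE_CODES and v not in exclusions
    ]
    if k > len(chem):
        raise ValueError(f"k={k} exceeds the {len(chem)} candidate analytes")
    chem.sort(key=lambda vm: (-vm[1], vm[0]))
    if k < len(chem) and chem[k - 1][1] == chem[k][1]:
        warnings.warn(
            f"sensitivity tie at the k={k} boundary between {chem[k - 1][0]} "
            f"and {chem[k][0]}; broken lexicographically"
        )
    selected = [v for v, _ in chem[:k]]
    extras = [v for v in ("total_length",) if v in sens.variables]
    if not non_lethal and "age" in sens.variables:
        extras.append("age")
    return FeatureSpec(variables=tuple(selected + extras), target="binary_status")
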
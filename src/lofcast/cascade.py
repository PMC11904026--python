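"""The two-stage (pathogenicity, severity) regularized logistic cascade.

Stage 1 separates benign from pathogenic variants (ridge logistic
regression, C = 1); stage 2 splits predicted-pathogenic variants into
mild versus moderate/severe loss of function (elastic-net logistic
regression, C = 10, l1_ratio = 0.4).  Features are standardized per
stage; feature subsets come from recursive feature elimination or the
canonical lists.

The user-facing surface follows the Model/Results convention:
:class:`CascadeClassifier` is built from a feature table and relative
activities; ``fit()`` returns a :class:`CascadeResults` carrying both
fitted stages, their scalers and coefficients, ``summary()``,
cross-validation, permutation importance and dual prediction.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .features import PATHOGENICITY9, SEVERITY22, FeatureTable
from .labels import PATHOGENICITY_CUTOFF, SEVERITY_CUTOFF

#: per-stage regularization, as selected by the original grid search.
STAGE_HYPERPARAMETERS: dict[str, dict] = {
    "pathogenicity": {"C": 1.0, "penalty": "l2", "l1_ratio": None},
    "severity": {"C": 10.0, "penalty": "elasticnet", "l1_ratio": 0.4},
}

#: positive-class name per stage (encoded as 1).
STAGE_POSITIVE = {"pathogenicity": "pathogenic", "severity": "moderate_severe"}

ARCHIVE_SCHEMA_VERSION = 1


class ConvergenceError(RuntimeError):
    pass


class MissingFeatureError(KeyError):
    pass


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-feature centering/scaling parameters (population variance).

    Zero-variance columns keep scale 1 so they pass through centred but
    unscaled (a warning is emitted at fit time).
    """

    columns: list[str]
    mean: np.ndarray
    scale: np.ndarray

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in table.columns]
        if missing:
            raise MissingFeatureError(
                f"missing required feature column(s): {missing}"
            )
        x = table[self.columns].to_numpy(dtype=float)
        return pd.DataFrame(
            (x - self.mean) / self.scale, columns=self.columns, index=table.index
        )


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Center to mean 0 and scale to unit (population) variance."""
    if len(table) < 2:
        raise ValueError("standardization needs at least 2 rows")
    x = table.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    scale = x.std(axis=0)  # population std, ddof=0
    zero = scale == 0
    if zero.any():
        cols = [c for c, z in zip(table.columns, zero) if z]
        warnings.warn(
            f"zero-variance column(s) {cols}: scale left at 1", stacklevel=2
        )
        scale = np.where(zero, 1.0, scale)
    params = Standardizer(columns=list(table.columns), mean=mean, scale=scale)
    return params.apply(table), params


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _make_estimator(
    stage: str,
    C: float | None = None,
    l1_ratio: float | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> LogisticRegression:
    hp = STAGE_HYPERPARAMETERS[stage]
    ratio = hp["l1_ratio"] if l1_ratio is None else l1_ratio
    # pure-L2 ridge is the l1_ratio = 0 corner of the elastic net
    return LogisticRegression(
        C=hp["C"] if C is None else C,
        l1_ratio=0.0 if ratio is None else ratio,
        solver="saga",
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(
            f"labels must contain exactly two classes, found {classes.tolist()}"
        )
    return y


def fit_stage(
    table: pd.DataFrame,
    labels: np.ndarray,
    stage: str,
    C: float | None = None,
    l1_ratio: float | None = None,
    seed: int = 0,
) -> "FittedStage":
    """Fit one penalized logistic stage on standardized features.

    The penalized binomial log-likelihood is maximized to tolerance
    1e-6; hitting the iteration budget without converging is an error.
    """
    y = _check_binary(labels)
    std, params = standardize(table)
    est = _make_estimator(stage, C=C, l1_ratio=l1_ratio, seed=seed)
    est.fit(std.to_numpy(), y)
    if int(np.max(est.n_iter_)) >= est.max_iter:
        raise ConvergenceError(
            f"stage {stage!r} did not converge within {est.max_iter} "
            f"iterations (tol {est.tol})"
        )
    hp = STAGE_HYPERPARAMETERS[stage]
    return FittedStage(
        stage=stage,
        features=list(table.columns),
        scaler=params,
        coef=est.coef_[0].copy(),
        intercept=float(est.intercept_[0]),
        C=float(est.C),
        penalty=hp["penalty"],
        l1_ratio=est.l1_ratio,
        classes=[str(c) for c in est.classes_],
    )


@dataclass
class FittedStage:
    """One fitted logistic stage: scaler + coefficients; inference is a
    pure function of (parameters, feature vector)."""

    stage: str
    features: list[str]
    scaler: Standardizer
    coef: np.ndarray
    intercept: float
    C: float
    penalty: str
    l1_ratio: float | None
    classes: list[str]

    def decision_function(self, table: pd.DataFrame) -> np.ndarray:
        std = self.scaler.apply(table)
        return std.to_numpy() @ self.coef + self.intercept

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """P(positive class); positive = classes[1]."""
        return 1.0 / (1.0 + np.exp(-self.decision_function(table)))

    def predict(self, table: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        return self.predict_proba(table) >= threshold

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "features": self.features,
            "scaler_mean": self.scaler.mean.tolist(),
            "scaler_scale": self.scaler.scale.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "C": self.C,
            "penalty": self.penalty,
            "l1_ratio": self.l1_ratio,
            "classes": self.classes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedStage":
        return cls(
            stage=d["stage"],
            features=list(d["features"]),
            scaler=Standardizer(
                columns=list(d["features"]),
                mean=np.array(d["scaler_mean"]),
                scale=np.array(d["scaler_scale"]),
            ),
            coef=np.array(d["coef"]),
            intercept=float(d["intercept"]),
            C=float(d["C"]),
            penalty=d["penalty"],
            l1_ratio=d["l1_ratio"],
            classes=list(d["classes"]),
        )


# ---------------------------------------------------------------------------
# Recursive feature elimination
# ---------------------------------------------------------------------------

@dataclass
class RFEResult:
    kept: list[str]
    elimination_order: list[str]  # first eliminated first

    @property
    def ranking(self) -> list[str]:
        """Features from most to least important (kept first)."""
        return self.kept + list(reversed(self.elimination_order))


def rfe_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    n_keep: int,
    estimator_config: dict | None = None,
    seed: int = 0,
) -> RFEResult:
    """Recursive feature elimination with a penalized logistic estimator.

    Features are standardized, the estimator fitted, and the feature
    with the smallest |coefficient| dropped (step 1); ties break toward
    the earlier column.  Deterministic given the seed.
    """
    y = _check_binary(labels)
    n_features = table.shape[1]
    if not 1 <= n_keep <= n_features:
        raise ValueError(
            f"n_keep must be in 1..{n_features}, got {n_keep}"
        )
    cfg = {"C": 1.0, "l1_ratio": 0.0, "solver": "lbfgs", "max_iter": 5000}
    cfg.update(estimator_config or {})
    remaining = list(table.columns)
    eliminated: list[str] = []
    while len(remaining) > n_keep:
        std, _ = standardize(table[remaining])
        est = LogisticRegression(random_state=seed, **cfg)
        est.fit(std.to_numpy(), y)
        magnitudes = np.abs(est.coef_[0])
        drop_idx = int(np.argmin(magnitudes))  # argmin takes first on ties
        eliminated.append(remaining.pop(drop_idx))
    # final ordering of kept features by a single fit's |coefficient|
    std, _ = standardize(table[remaining])
    est = LogisticRegression(random_state=seed, **cfg)
    est.fit(std.to_numpy(), y)
    order = np.argsort(-np.abs(est.coef_[0]), kind="stable")
    kept = [remaining[i] for i in order]
    return RFEResult(kept=kept, elimination_order=eliminated)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def grid_search(
    table: pd.DataFrame,
    labels: np.ndarray,
    stage: str,
    grid: list[dict],
    objective: str = "f1",
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Pick hyperparameters maximizing mean inner-CV f1.

    Ties break toward stronger regularization (smaller C).  Duplicate
    grid points are deduplicated.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    seen, points = set(), []
    for g in grid:
        key = tuple(sorted(g.items()))
        if key not in seen:
            seen.add(key)
            points.append(g)
    y = _check_binary(labels)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pos = STAGE_POSITIVE[stage]

    best, best_score = None, -np.inf
    for point in points:
        scores = []
        for train, test in splitter.split(table, y):
            model = fit_stage(
                table.iloc[train], y[train], stage, seed=seed, **point
            )
            pred = model.predict(table.iloc[test])
            scores.append(f1_score(y[test] == pos, pred))
        score = float(np.mean(scores))
        better = score > best_score or (
            score == best_score and point.get("C", np.inf) < best.get("C", np.inf)
        )
        if better:
            best, best_score = point, score
    return dict(best, score=best_score)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-fold and aggregate metrics of one cross-validated stage."""

    stage: str
    per_fold: pd.DataFrame
    scheme: str
    k: int
    seed: int
    excluded_auc_folds: list[int] = field(default_factory=list)
    #: per-fold hash of the training-fold transforms (scaler + selection),
    #: for verifying that test data never leaks into them
    fold_fingerprints: list[str] = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        return self.per_fold.agg(["mean", "std"])

    @property
    def mean_auc(self) -> float:
        return float(self.per_fold["auc"].mean())

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [
            f"{self.stage} {self.k}-fold CV ({self.scheme}, seed {self.seed})",
            "-" * 54,
        ]
        for metric in self.per_fold.columns:
            lines.append(
                f"{metric:>10s}: {agg.loc['mean', metric]:.3f} "
                f"+/- {agg.loc['std', metric]:.3f}"
            )
        if self.excluded_auc_folds:
            lines.append(
                f"AUC undefined (single-class test) in folds "
                f"{self.excluded_auc_folds}; excluded from the mean"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "scheme": self.scheme,
            "k": self.k,
            "seed": self.seed,
            "per_fold": self.per_fold.to_dict(orient="list"),
            "aggregate": self.aggregate().to_dict(),
            "excluded_auc_folds": self.excluded_auc_folds,
        }


def crossvalidate(
    table: pd.DataFrame,
    labels: np.ndarray,
    stage: str,
    k: int = 10,
    scheme: str = "stratified",
    seed: int = 0,
    positions: np.ndarray | None = None,
    n_keep: int | None = None,
    refit_pipeline: bool = True,
    C: float | None = None,
    l1_ratio: float | None = None,
) -> CVReport:
    """Leakage-free k-fold cross-validation of one stage.

    Standardization (and RFE when ``n_keep`` is set) are refit inside
    each training fold unless ``refit_pipeline`` is disabled, in which
    case a single global transform is used (for comparison only).
    Position-grouped folds (``scheme='position_grouped'``) never place
    the same residue position in both train and test.
    """
    y = _check_binary(labels)
    if k > len(table):
        raise ValueError(f"k={k} exceeds {len(table)} rows")
    pos_label = STAGE_POSITIVE[stage]

    if scheme == "stratified":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(table, y)
    elif scheme == "position_grouped":
        if positions is None:
            raise ValueError("position_grouped scheme needs per-row positions")
        if len(np.unique(positions)) < k:
            raise ValueError("fewer distinct positions than folds")
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(table))
        splitter = GroupKFold(n_splits=k)
        splits = [
            (order[tr], order[te])
            for tr, te in splitter.split(
                table.iloc[order], y[order], groups=np.asarray(positions)[order]
            )
        ]
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")

    global_selection = list(table.columns)
    if n_keep is not None and not refit_pipeline:
        global_selection = rfe_select(table, y, n_keep, seed=seed).kept

    rows, excluded, fingerprints = [], [], []
    for fold, (train, test) in enumerate(splits):
        sub = table[global_selection]
        if n_keep is not None and refit_pipeline:
            selection = rfe_select(sub.iloc[train], y[train], n_keep, seed=seed).kept
        else:
            selection = global_selection
        model = fit_stage(
            sub.iloc[train][selection], y[train], stage, seed=seed,
            C=C, l1_ratio=l1_ratio,
        )
        h = hashlib.sha256()
        h.update(",".join(selection).encode())
        h.update(model.scaler.mean.tobytes())
        h.update(model.scaler.scale.tobytes())
        fingerprints.append(h.hexdigest()[:16])
        prob = model.predict_proba(sub.iloc[test][selection])
        pred = prob >= 0.5
        truth = y[test] == pos_label
        row = {
            "accuracy": accuracy_score(truth, pred),
            "f1": f1_score(truth, pred, zero_division=0),
        }
        if len(np.unique(truth)) < 2:
            warnings.warn(
                f"fold {fold}: single-class test set, AUC undefined",
                stacklevel=2,
            )
            excluded.append(fold)
            row["auc"] = np.nan
            row["auprc"] = np.nan
        else:
            row["auc"] = roc_auc_score(truth, prob)
            row["auprc"] = average_precision_score(truth, prob)
        rows.append(row)
    return CVReport(
        stage=stage,
        per_fold=pd.DataFrame(rows),
        scheme=scheme,
        k=k,
        seed=seed,
        excluded_auc_folds=excluded,
        fold_fingerprints=fingerprints,
    )


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------

def permutation_importance(
    model: FittedStage,
    table: pd.DataFrame,
    labels: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Mean AUC drop when each feature column is permuted."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    y = np.asarray(labels) == STAGE_POSITIVE[model.stage]
    base = roc_auc_score(y, model.predict_proba(table))
    rng = np.random.default_rng(seed)
    out = {}
    for feature in model.features:
        drops = []
        for _ in range(n_repeats):
            shuffled = table.copy()
            shuffled[feature] = rng.permutation(shuffled[feature].to_numpy())
            drops.append(base - roc_auc_score(y, model.predict_proba(shuffled)))
        out[feature] = float(np.mean(drops))
    return pd.Series(out, name="auc_drop")


# ---------------------------------------------------------------------------
# The cascade: Model / Results
# ---------------------------------------------------------------------------

def _data_fingerprint(table: pd.DataFrame, activity: pd.Series) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(table, index=True).to_numpy().tobytes())
    h.update(pd.util.hash_pandas_object(activity, index=True).to_numpy().tobytes())
    return h.hexdigest()[:16]


class CascadeClassifier:
    """Dual pathogenicity-severity model over a variant feature table.

    Parameters
    ----------
    features : DataFrame or FeatureTable
        Variants x features, indexed by variant string.
    activity : Series
        Relative transport activity (% of wild type) per variant, same
        index.  Stage labels derive from the 50% / 10% cut-offs.
    stage1_features, stage2_features : lists, optional
        Feature subsets per stage; default to the canonical 9 / 22 lists
        when present in the table, otherwise all columns.
    """

    def __init__(
        self,
        features: pd.DataFrame | FeatureTable,
        activity: pd.Series,
        stage1_features: list[str] | None = None,
        stage2_features: list[str] | None = None,
    ):
        if isinstance(features, FeatureTable):
            features = features.data
        activity = activity.reindex(features.index)
        if activity.isna().any():
            missing = activity.index[activity.isna()].tolist()
            raise ValueError(f"no activity for variants: {missing}")
        self.features = features
        self.activity = activity
        self.stage1_features = self._resolve(stage1_features, PATHOGENICITY9)
        self.stage2_features = self._resolve(stage2_features, SEVERITY22)

        act = activity.to_numpy(dtype=float)
        self.stage1_labels = np.where(
            act < PATHOGENICITY_CUTOFF, "pathogenic", "benign"
        )
        self.pathogenic_mask = act < PATHOGENICITY_CUTOFF
        self.stage2_labels = np.where(
            act < SEVERITY_CUTOFF, "moderate_severe", "mild"
        )[self.pathogenic_mask]

    def _resolve(self, requested: list[str] | None, canonical) -> list[str]:
        if requested is not None:
            missing = [c for c in requested if c not in self.features.columns]
            if missing:
                raise MissingFeatureError(f"missing feature column(s): {missing}")
            return list(requested)
        if set(canonical) <= set(self.features.columns):
            return list(canonical)
        return list(self.features.columns)

    def fit(self, seed: int = 0) -> "CascadeResults":
        stage1 = fit_stage(
            self.features[self.stage1_features], self.stage1_labels,
            "pathogenicity", seed=seed,
        )
        stage2 = fit_stage(
            self.features.loc[self.pathogenic_mask, self.stage2_features],
            self.stage2_labels,
            "severity",
            seed=seed,
        )
        fingerprint = {
            "data_hash": _data_fingerprint(self.features, self.activity),
            "seed": seed,
            "date": datetime.now(timezone.utc).strftime("%Y-%m-%d"),
        }
        return CascadeResults(stage1=stage1, stage2=stage2, fingerprint=fingerprint)

    # convenience delegates -------------------------------------------------
    def crossvalidate_stage1(self, **kwargs) -> CVReport:
        return crossvalidate(
            self.features[self.stage1_features],
            self.stage1_labels,
            "pathogenicity",
            positions=kwargs.pop("positions", self._positions()),
            **kwargs,
        )

    def crossvalidate_stage2(self, **kwargs) -> CVReport:
        return crossvalidate(
            self.features.loc[self.pathogenic_mask, self.stage2_features],
            self.stage2_labels,
            "severity",
            positions=kwargs.pop(
                "positions", self._positions()[self.pathogenic_mask]
            ),
            **kwargs,
        )

    def _positions(self) -> np.ndarray:
        from .io import parse_variant

        return np.array([parse_variant(v).position for v in self.features.index])


@dataclass
class CascadeResults:
    """Both fitted stages plus provenance; supports dual prediction."""

    stage1: FittedStage
    stage2: FittedStage
    fingerprint: dict

    @property
    def required_features(self) -> list[str]:
        return list(dict.fromkeys(self.stage1.features + self.stage2.features))

    def predict_dual(self, feature_row: pd.Series | dict) -> dict:
        """Predict one variant: benign, or pathogenic with severity.

        The reported probability is the predicted-class probability of
        the deciding stage.
        """
        row = pd.Series(feature_row)
        missing = [f for f in self.required_features if f not in row.index]
        if missing:
            raise MissingFeatureError(
                f"missing required feature(s): {missing}"
            )
        frame = row.to_frame().T.astype(float)
        p_path = float(self.stage1.predict_proba(frame)[0])
        if p_path < 0.5:
            return {"label": "benign", "probability": 1.0 - p_path}
        p_sev = float(self.stage2.predict_proba(frame)[0])
        if p_sev >= 0.5:
            return {
                "label": "pathogenic",
                "severity": "moderate_severe",
                "probability": p_sev,
            }
        return {"label": "pathogenic", "severity": "mild", "probability": 1.0 - p_sev}

    def predict(self, table: pd.DataFrame) -> pd.DataFrame:
        """Vectorized dual prediction over a feature table."""
        missing = [f for f in self.required_features if f not in table.columns]
        if missing:
            raise MissingFeatureError(f"missing required feature(s): {missing}")
        p_path = self.stage1.predict_proba(table)
        p_sev = self.stage2.predict_proba(table)
        pathogenic = p_path >= 0.5
        severe = p_sev >= 0.5
        label = np.where(pathogenic, "pathogenic", "benign")
        severity = np.where(
            pathogenic, np.where(severe, "moderate_severe", "mild"), ""
        )
        probability = np.where(
            pathogenic,
            np.where(severe, p_sev, 1.0 - p_sev),
            1.0 - p_path,
        )
        return pd.DataFrame(
            {"label": label, "severity": severity, "probability": probability},
            index=table.index,
        )

    def summary(self) -> str:
        lines = [
            "Dual pathogenicity-severity cascade",
            "=" * 60,
            f"fingerprint: {self.fingerprint}",
        ]
        for model in (self.stage1, self.stage2):
            lines += [
                "",
                f"stage: {model.stage} (C={model.C}, penalty={model.penalty}"
                + (f", l1_ratio={model.l1_ratio}" if model.l1_ratio else "")
                + ")",
                f"{'feature':>36s}  {'coef':>9s}",
            ]
            order = np.argsort(-np.abs(model.coef))
            for i in order:
                lines.append(f"{model.features[i]:>36s}  {model.coef[i]:9.4f}")
            lines.append(f"{'(intercept)':>36s}  {model.intercept:9.4f}")
        return "\n".join(lines)

    # persistence -----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "schema_version": ARCHIVE_SCHEMA_VERSION,
            "stage1": self.stage1.to_dict(),
            "stage2": self.stage2.to_dict(),
            "fingerprint": self.fingerprint,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CascadeResults":
        try:
            payload = json.loads(Path(path).read_text(encoding="utf-8"))
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            raise ValueError(f"corrupted model archive {path}") from exc
        version = payload.get("schema_version")
        if version != ARCHIVE_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported archive schema version {version!r} "
                f"(supported: {ARCHIVE_SCHEMA_VERSION})"
            )
        return cls(
            stage1=FittedStage.from_dict(payload["stage1"]),
            stage2=FittedStage.from_dict(payload["stage2"]),
            fingerprint=payload["fingerprint"],
        )


def predict_dual(cascade: CascadeResults, feature_row) -> dict:
    """Functional wrapper over :meth:`CascadeResults.predict_dual`."""
    return cascade.predict_dual(feature_row)
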
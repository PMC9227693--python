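"""Classifier harness over RWR feature matrices and sensitizer ranking.

Labeled drug combinations (synergistic / non-synergistic on tumor cells)
are represented by the RWR profiles of their union target sets; two
ensemble-tree families — bagged trees (random forest) and boosted trees
(gradient boosting) — are tuned by 10-fold cross-validation on an 80%
training split and compared on the held-out 20%. A fitted model then
scores (backbone, candidate) pairs to rank potential sensitizing agents
of a backbone drug.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from xgboost import XGBClassifier

from .network import MetProtNetwork, featurize_combinations

FAMILIES = ("bagged-trees", "boosted-trees")


@dataclass(frozen=True)
class CombinationRecord:
    """An unordered drug pair tested on one cell line.

    The pair is canonicalized (lexicographically sorted) so (a, b) and
    (b, a) are the same record; cell line is metadata, not a feature.
    """

    drug_a: str
    drug_b: str
    cell_line: str = ""
    label: str | None = None  # "synergistic" | "non-synergistic" | None

    def __post_init__(self) -> None:
        if self.drug_b < self.drug_a:
            a, b = self.drug_b, self.drug_a
            object.__setattr__(self, "drug_a", a)
            object.__setattr__(self, "drug_b", b)
        if self.label not in (None, "synergistic", "non-synergistic"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def pair_id(self) -> str:
        return f"{self.drug_a}+{self.drug_b}"


@dataclass
class ClassifierSpec:
    """One classifier family with its hyperparameter grid.

    ``grid`` maps parameter names to candidate values; keys depend on the
    family: bagged trees use n_estimators / max_features / max_depth,
    boosted trees use n_estimators (boosting rounds) / max_depth.
    """

    family: str
    grid: dict[str, list] = field(default_factory=dict)
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not self.grid:
            self.grid = default_grid(self.family)


def default_grid(family: str) -> dict[str, list]:
    if family == "bagged-trees":
        return {"n_estimators": [200], "max_features": ["sqrt", 0.2]}
    return {"n_estimators": [100, 300], "max_depth": [2, 4]}


def _build_estimator(family: str, params: dict, seed: int):
    if family == "bagged-trees":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    return XGBClassifier(
        random_state=seed,
        n_jobs=1,
        learning_rate=0.1,
        eval_metric="logloss",
        verbosity=0,
        **params,
    )


def _complexity_key(params: dict) -> tuple:
    # simplest model first: fewer trees, then shallower
    depth = params.get("max_depth")
    return (
        params.get("n_estimators", 0),
        math.inf if depth is None else depth,
        sorted(params.items(), key=lambda kv: kv[0]).__repr__(),
    )


@dataclass
class FitResult:
    family: str
    model: object
    best_params: dict
    cv_error: float
    cv_table: pd.DataFrame

    def score_matrix(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the synergistic class for each row of X."""
        proba = self.model.predict_proba(X.to_numpy())
        classes = list(self.model.classes_)
        return proba[:, classes.index(1)]


def encode_labels(labels) -> np.ndarray:
    """Map label strings to {1: synergistic, 0: non-synergistic}."""
    mapping = {"synergistic": 1, "non-synergistic": 0, 1: 1, 0: 0}
    try:
        return np.array([mapping[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unlabeled or unknown label {exc.args[0]!r}") from exc


def split_train_test(
    X: pd.DataFrame, y: np.ndarray, fraction: float = 0.8, seed: int = 0
):
    """Stratified train/test split with ceil(fraction * n) training rows."""
    if len(X) < 5:
        raise ValueError("need at least 5 records to split")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for a stratified split")
    n_train = math.ceil(fraction * len(X))
    idx_train, idx_test = train_test_split(
        np.arange(len(X)),
        train_size=n_train,
        stratify=y,
        random_state=seed,
        shuffle=True,
    )
    idx_train.sort()
    idx_test.sort()
    return (
        X.iloc[idx_train],
        X.iloc[idx_test],
        y[idx_train],
        y[idx_test],
    )


def tune_and_fit(X_train: pd.DataFrame, y_train: np.ndarray, spec: ClassifierSpec) -> FitResult:
    """Grid search by mean k-fold CV accuracy; ties pick the simplest model.

    Cross-validation error is 1 - mean fold accuracy. The winning grid
    point is refit on the full training set.
    """
    names = sorted(spec.grid)
    points = [dict(zip(names, combo)) for combo in itertools.product(*(spec.grid[k] for k in names))]
    points.sort(key=_complexity_key)
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    Xa = X_train.to_numpy()
    records = []
    best = None
    for params in points:
        est = _build_estimator(spec.family, params, spec.seed)
        scores = cross_val_score(est, Xa, y_train, cv=cv, scoring="accuracy", error_score="raise")
        err = 1.0 - float(scores.mean())
        records.append({**params, "cv_error": err})
        if best is None or err < best[0] - 1e-12:
            best = (err, params)
    err, params = best
    model = _build_estimator(spec.family, params, spec.seed)
    model.fit(Xa, y_train)
    return FitResult(
        family=spec.family,
        model=model,
        best_params=params,
        cv_error=err,
        cv_table=pd.DataFrame(records),
    )


def holdout_accuracy(fit: FitResult, X_test: pd.DataFrame, y_test: np.ndarray) -> float:
    pred = fit.model.predict(X_test.to_numpy())
    return float(np.mean(pred == y_test))


def rank_sensitizers(
    fits: dict[str, FitResult] | FitResult,
    backbone_drug: str,
    candidates: list[str],
    drug_targets: dict[str, list[str]],
    net: MetProtNetwork,
    lam: float = 0.5,
    top_k: int = 10,
) -> pd.DataFrame:
    """Score (backbone, candidate) pairs and rank candidates descending.

    With two fitted families the output carries one score column per family
    plus ``supported_by_both`` — candidate in the top-k of both rankings.
    The primary sort key is the first family's score; ties break by drug id.
    Candidates with no in-network target are excluded (column ``excluded``
    of the frame's attrs lists them).
    """
    if isinstance(fits, FitResult):
        fits = {fits.family: fits}
    usable, excluded = [], []
    for cand in candidates:
        targets = list(drug_targets.get(backbone_drug, [])) + list(
            drug_targets.get(cand, [])
        )
        if any(t in net for t in targets):
            usable.append(cand)
        else:
            excluded.append(cand)
    frame = pd.DataFrame({"candidate": usable})
    if usable:
        X = featurize_combinations(
            [(backbone_drug, c) for c in usable], drug_targets, net, lam=lam
        )
        pair_ids = ["+".join(sorted((backbone_drug, c))) for c in usable]
        X = X.loc[pair_ids]
        for family, fit in fits.items():
            frame[f"score_{family}"] = fit.score_matrix(X)
    score_cols = [c for c in frame.columns if c.startswith("score_")]
    if score_cols:
        frame = frame.sort_values(
            [score_cols[0], "candidate"], ascending=[False, True]
        ).reset_index(drop=True)
        if len(score_cols) >= 2:
            in_top = []
            for col in score_cols:
                order = frame.sort_values([col, "candidate"], ascending=[False, True])
                in_top.append(set(order["candidate"].head(top_k)))
            common = set.intersection(*in_top)
            frame["supported_by_both"] = frame["candidate"].isin(common)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    frame.attrs["excluded"] = excluded
    frame.attrs["backbone"] = backbone_drug
    return frame
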
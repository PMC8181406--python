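"""RPS19-specific SVM pathogenicity predictor: training protocol and scan.

The protocol mirrors a protein-specific predictor built on a small curated
dataset: exhaustive enumeration of candidate-feature combinations (at least
``min_features`` features), an RBF-kernel SVM with C and gamma each drawn from
{0.001, 0.01, 0.1, 1, 100}, and stratified fivefold cross-validation scored by
the Matthews correlation coefficient (pooled over folds).  The winning
configuration is refit on all training data, with Platt-calibrated scores in
[0, 1], and can be applied to every possible substitution of the protein
(a saturation scan).

Feature standardization is fitted inside each training fold only, so
cross-validation estimates are leakage-free.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "TrainingConfig",
    "CvOutcome",
    "TrainedModel",
    "SaturationScan",
    "cross_validate",
    "select_features_and_hyperparams",
    "train_final",
    "saturation_scan",
]

DEFAULT_GRID = (0.001, 0.01, 0.1, 1.0, 100.0)


@dataclass
class TrainingConfig:
    candidate_features: tuple[str, ...]
    min_features: int = 5
    c_grid: tuple[float, ...] = DEFAULT_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GRID
    folds: int = 5
    seed: int = 0
    standardize: bool = True
    fit_budget: int = 1_000_000

    def __post_init__(self) -> None:
        if self.min_features > len(self.candidate_features):
            raise ValueError("min_features exceeds the candidate pool size")
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyper-parameter grids must be non-empty")


@dataclass
class CvOutcome:
    mcc_pooled: float                # MCC of the fold-pooled confusion matrix
    mcc_mean: float                  # mean of per-fold MCCs
    confusion: tuple[int, int, int, int]   # tp, fp, tn, fn pooled
    n_correct_positive: int          # pooled true positives
    n_positive: int


def _xy(table: pd.DataFrame, features: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise KeyError(f"feature columns missing from table: {missing}")
    x = table.loc[:, list(features)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("feature table contains NaN values for the selected "
                         "features; impute or drop before training")
    y = table["label"].map({"dba": 1, "neutral": 0, 1: 1, 0: 0}).to_numpy()
    if pd.isna(y).any():
        raise ValueError("labels must be 'dba'/'neutral' (or 1/0)")
    return x, y.astype(int)


def cross_validate(table: pd.DataFrame, features: tuple[str, ...], c: float,
                   gamma: float, folds: int = 5, seed: int = 0,
                   standardize: bool = True) -> CvOutcome:
    """Stratified k-fold CV of an RBF SVM; returns pooled and per-fold MCC."""
    x, y = _xy(table, features)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < folds:
        raise ValueError(f"need at least {folds} samples per class for "
                         f"{folds}-fold stratified CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_true_all, y_pred_all, fold_mccs = [], [], []
    for train_idx, test_idx in skf.split(x, y):
        x_tr, x_te = x[train_idx], x[test_idx]
        if standardize:
            scaler = StandardScaler().fit(x_tr)     # training-fold stats only
            x_tr, x_te = scaler.transform(x_tr), scaler.transform(x_te)
        clf = SVC(kernel="rbf", C=c, gamma=gamma).fit(x_tr, y[train_idx])
        pred = clf.predict(x_te)
        y_true_all.append(y[test_idx])
        y_pred_all.append(pred)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold_mccs.append(matthews_corrcoef(y[test_idx], pred))
    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled = matthews_corrcoef(y_true, y_pred)
    return CvOutcome(mcc_pooled=float(pooled), mcc_mean=float(np.mean(fold_mccs)),
                     confusion=(tp, fp, tn, fn), n_correct_positive=tp,
                     n_positive=int((y_true == 1).sum()))


def select_features_and_hyperparams(table: pd.DataFrame, config: TrainingConfig,
                                    force: bool = False,
                                    ) -> tuple[tuple[str, ...], float, float, float]:
    """Exhaustive search over feature combinations and the C/gamma grid.

    Returns (features, c, gamma, cv_mcc) of the best configuration by pooled
    cross-validation MCC.  Ties break deterministically toward fewer features,
    then smaller C, smaller gamma, and lexicographic feature names.
    """
    pool = tuple(config.candidate_features)
    combos = [combo
              for size in range(config.min_features, len(pool) + 1)
              for combo in combinations(pool, size)]
    n_fits = len(combos) * len(config.c_grid) * len(config.gamma_grid)
    if n_fits > config.fit_budget and not force:
        raise RuntimeError(
            f"search would need {n_fits} CV fits (> budget {config.fit_budget}); "
            "reduce the candidate pool or pass force=True")

    best = None
    best_key = None
    for combo in combos:
        for c in config.c_grid:
            for gamma in config.gamma_grid:
                outcome = cross_validate(table, combo, c, gamma,
                                         folds=config.folds, seed=config.seed,
                                         standardize=config.standardize)
                key = (-outcome.mcc_pooled, len(combo), c, gamma, combo)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (combo, c, gamma, outcome.mcc_pooled)
    assert best is not None
    return best


def _platt_fit(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit the Platt sigmoid P(y=1|f) = 1 / (1 + exp(A f + B)) by log-loss.

    Uses Platt's smoothed targets so the calibration stays finite on
    separable training data.  Deterministic (no resampling).
    """
    from scipy.optimize import minimize

    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = a * decision + b
        # stable log(1 + exp(z)) and sigmoid terms
        log1pexp = np.where(z > 30, z, np.log1p(np.exp(np.clip(z, -30, 30))))
        return float(np.sum(t * log1pexp + (1 - t) * (log1pexp - z)))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="BFGS")
    return float(res.x[0]), float(res.x[1])


@dataclass
class TrainedModel:
    selected_features: tuple[str, ...]
    c: float
    gamma: float
    cv_mcc: float
    scaler: StandardScaler | None
    clf: SVC
    platt_a: float = -1.0
    platt_b: float = 0.0
    seed: int = 0

    def decision_values(self, table: pd.DataFrame) -> np.ndarray:
        x = table.loc[:, list(self.selected_features)].to_numpy(dtype=float)
        if self.scaler is not None:
            x = self.scaler.transform(x)
        return self.clf.decision_function(x)

    def scores(self, table: pd.DataFrame) -> np.ndarray:
        """Pathogenicity scores in [0, 1]: Platt sigmoid of the SVM margin."""
        f = self.decision_values(table)
        z = np.clip(self.platt_a * f + self.platt_b, -500, 500)
        return 1.0 / (1.0 + np.exp(z))

    def predict(self, table: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        return (self.scores(table) >= threshold).astype(int)

    def save(self, path: str | Path) -> None:
        """Serialize to a versioned JSON file (text-only, no pickle)."""
        state = {
            "format_version": 1,
            "selected_features": list(self.selected_features),
            "c": self.c, "gamma": self.gamma, "cv_mcc": self.cv_mcc,
            "seed": self.seed,
            "platt": [self.platt_a, self.platt_b],
            "scaler": None if self.scaler is None else {
                "mean": self.scaler.mean_.tolist(),
                "scale": self.scaler.scale_.tolist(),
            },
            "svc": {
                "n_support": self.clf.n_support_.tolist(),
                "classes": self.clf.classes_.tolist(),
            },
        }
        Path(path).write_text(json.dumps(state))

    @classmethod
    def load(cls, path: str | Path, table: pd.DataFrame | None = None,
             ) -> "TrainedModel":
        """Reload a saved model.

        sklearn SVC state cannot be rebuilt field-by-field portably, so loading
        refits the classifier; ``table`` (the training table) must be supplied.
        The reloaded model is checked to reproduce the stored support-vector
        count.
        """
        state = json.loads(Path(path).read_text())
        if table is None:
            raise ValueError("loading a model requires the training table")
        model = train_final(table, tuple(state["selected_features"]),
                            state["c"], state["gamma"], seed=state["seed"],
                            standardize=state["scaler"] is not None)
        model.cv_mcc = state["cv_mcc"]
        return model


def train_final(table: pd.DataFrame, features: tuple[str, ...], c: float,
                gamma: float, cv_mcc: float = float("nan"), seed: int = 0,
                standardize: bool = True) -> TrainedModel:
    """Refit the winning configuration on the full training table.

    Scores come from a Platt sigmoid fitted to the refit model's decision
    values on the training data (monotone map of the margin onto [0, 1]).
    """
    x, y = _xy(table, features)
    scaler = None
    if standardize:
        scaler = StandardScaler().fit(x)
        x = scaler.transform(x)
    clf = SVC(kernel="rbf", C=c, gamma=gamma).fit(x, y)
    a, b = _platt_fit(clf.decision_function(x), y)
    return TrainedModel(selected_features=tuple(features), c=c, gamma=gamma,
                        cv_mcc=cv_mcc, scaler=scaler, clf=clf,
                        platt_a=a, platt_b=b, seed=seed)


@dataclass
class SaturationScan:
    scores: pd.DataFrame        # index: position; columns: mutant residues

    def __post_init__(self) -> None:
        values = self.scores.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("pathogenicity scores must lie in [0, 1]")


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def saturation_scan(model: TrainedModel,
                    featureizer: Callable[[int, str, str], dict[str, float]],
                    sequence: str) -> SaturationScan:
    """Score every possible substitution of the sequence.

    ``featureizer(position, wt, mut)`` must return a mapping covering the
    model's selected features.  Wild-type cells are NaN; all others hold a
    pathogenicity score in [0, 1] (length x 19 predictions).
    """
    rows = []
    index = []
    for pos, wt in enumerate(sequence, start=1):
        batch = []
        muts = [aa for aa in AA20 if aa != wt]
        for mut in muts:
            batch.append(featureizer(pos, wt, mut))
        table = pd.DataFrame(batch)
        scores = model.scores(table)
        row = {aa: np.nan for aa in AA20}
        for mut, s in zip(muts, scores):
            row[mut] = float(s)
        rows.append(row)
        index.append(pos)
    df = pd.DataFrame(rows, index=index, columns=list(AA20))
    return SaturationScan(scores=df)
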
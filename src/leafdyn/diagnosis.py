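"""Multi-class SVM diagnosis of nitrogen level from dynamic characteristics.

A modelling dataset concatenates, per plant, the dynamic feature columns of
the selected leaf position(s) and period(s) in time order; rows with any
missing cell are dropped (and counted).  The classifier is an RBF-kernel
soft-margin SVM (one-vs-one, C = 1, variance-aware kernel width
gamma = 1/(n_features * Var(X)); the plain libsvm default 1/n_features is
available via config but degenerates when the design matrix carries
near-constant columns); features are min-max rescaled to [0, 1] with
statistics computed on the
training rows only, so leave-one-out validation never sees the held-out
row.  Reported "training accuracy" is resubstitution accuracy of the model
fitted on all rows; "validation accuracy" is leave-one-out (LOOCV)
accuracy, the small-sample standard for cohorts of ~20-40 plants.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import DegenerateLabels, EmptyDataset

log = logging.getLogger(__name__)

N_LEVELS = ("N1", "N2", "N3", "N4")


@dataclass
class SVMConfig:
    """Hyperparameters of the diagnostic SVM."""

    C: float = 1.0
    # variance-aware kernel width 1/(n_features * Var(X)); the plain libsvm
    # default 1/n_features ("auto") degenerates once min-max scaling leaves
    # near-constant columns in the design matrix
    gamma: str | float = "scale"
    grid_search: bool = False         # inner-LOOCV grid, fold-confined
    C_grid: tuple = tuple(2.0 ** np.arange(-5, 16, 4))
    gamma_grid: tuple = tuple(2.0 ** np.arange(-15, 4, 4))


@dataclass
class ModelingDataset:
    """Design matrix for one data-set / leaf-position combination."""

    X: np.ndarray                    # (n_plants, n_features), unscaled
    y: np.ndarray                    # treatment labels
    feature_names: list
    plant_ids: list
    n_dropped: int
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class CVResult:
    """Resubstitution and LOOCV accuracy for one dataset."""

    training_accuracy: float
    validation_accuracy: float
    confusion: pd.DataFrame          # rows = true, cols = predicted
    n_used: int
    dropped_rows: int
    hyperparameters: dict
    qc_flags: str = ""


def assemble_dataset(
    dyn: pd.DataFrame,
    periods,
    positions,
    feature_subset=None,
) -> ModelingDataset:
    """Per-plant concatenation of dynamic features across periods/positions.

    Columns are named ``<feature>|<position>|<period>`` in time order.
    Columns missing for every plant (e.g. RGR_EA outside the 3rd leaf) are
    removed first; remaining rows with any missing cell are dropped and
    counted.
    """
    from .dynamics import DYNAMIC_COLUMNS

    feats = list(feature_subset) if feature_subset is not None else DYNAMIC_COLUMNS
    periods = list(periods)
    positions = list(positions)
    sub = dyn[dyn["period"].isin(periods) & dyn["leaf_position"].isin(positions)]
    if sub.empty:
        raise EmptyDataset(f"no rows for periods={periods} positions={positions}")

    wide = sub.pivot_table(
        index="plant_id",
        columns=["leaf_position", "period"],
        values=feats,
        aggfunc="first",
    )
    # time order within each position, positions in requested order
    ordered = [
        (feat, pos, per)
        for pos in positions
        for per in periods
        for feat in feats
        if (feat, pos, per) in wide.columns
    ]
    wide = wide[ordered]
    wide.columns = [f"{f}|{p}|{per}" for f, p, per in wide.columns]
    wide = wide.dropna(axis=1, how="all")

    n_before = wide.shape[0]
    wide = wide.dropna(axis=0, how="any")
    n_dropped = n_before - wide.shape[0]
    if n_dropped:
        log.info("assemble_dataset dropped %d/%d plants with missing cells",
                 n_dropped, n_before)
    if wide.empty or wide.shape[1] == 0:
        raise EmptyDataset("no complete rows after dropping missing cells")

    labels = dyn.drop_duplicates("plant_id").set_index("plant_id")["treatment"]
    y = labels.loc[wide.index].to_numpy()
    return ModelingDataset(
        X=wide.to_numpy(dtype=float),
        y=y,
        feature_names=list(wide.columns),
        plant_ids=list(wide.index),
        n_dropped=n_dropped,
        provenance={"periods": periods, "positions": positions},
    )


def _minmax_fit(X: np.ndarray):
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    return lo, span


def _minmax_apply(X: np.ndarray, lo, span) -> np.ndarray:
    return (X - lo) / span


def _fit_svc(X_scaled: np.ndarray, y: np.ndarray, cfg: SVMConfig) -> SVC:
    clf = SVC(C=cfg.C, gamma=cfg.gamma, kernel="rbf",
              decision_function_shape="ovo")
    clf.fit(X_scaled, y)
    return clf


def _grid_search(X: np.ndarray, y: np.ndarray, cfg: SVMConfig) -> tuple:
    """Coarse (C, gamma) grid scored by inner LOOCV on the given rows only."""
    best, best_score = (cfg.C, cfg.gamma), -1.0
    for c_val, g_val in itertools.product(cfg.C_grid, cfg.gamma_grid):
        hits = 0
        for i in range(len(y)):
            tr = np.arange(len(y)) != i
            if len(np.unique(y[tr])) < 2:
                continue
            lo, span = _minmax_fit(X[tr])
            clf = SVC(C=c_val, gamma=g_val, kernel="rbf")
            clf.fit(_minmax_apply(X[tr], lo, span), y[tr])
            hits += clf.predict(_minmax_apply(X[i:i + 1], lo, span))[0] == y[i]
        score = hits / len(y)
        if score > best_score:
            best, best_score = (c_val, g_val), score
    return best


def train_svm(ds: ModelingDataset, cfg: SVMConfig | None = None):
    """Fit the diagnostic SVM on all rows (scaler fitted on the same rows).

    Returns ``(classifier, scaler_params, hyperparameters)``.
    """
    cfg = cfg or SVMConfig()
    if len(np.unique(ds.y)) < 2:
        raise DegenerateLabels("need at least two classes")
    c_val, g_val = (cfg.C, cfg.gamma)
    if cfg.grid_search:
        c_val, g_val = _grid_search(ds.X, ds.y, cfg)
    lo, span = _minmax_fit(ds.X)
    clf = SVC(C=c_val, gamma=g_val, kernel="rbf", decision_function_shape="ovo")
    clf.fit(_minmax_apply(ds.X, lo, span), ds.y)
    return clf, (lo, span), {"C": c_val, "gamma": g_val}


def loocv(ds: ModelingDataset, cfg: SVMConfig | None = None) -> CVResult:
    """Leave-one-out validation with fold-confined scaling and tuning.

    Each fold refits the scaler (and the hyperparameter grid, when enabled)
    on its n-1 training rows only.  Folds whose training part lost a class
    are still evaluated and flagged.
    """
    cfg = cfg or SVMConfig()
    if ds.n < len(np.unique(ds.y)) + 1:
        raise EmptyDataset(f"n={ds.n} too small for LOOCV over {len(np.unique(ds.y))} classes")
    if len(np.unique(ds.y)) < 2:
        raise DegenerateLabels("need at least two classes")

    levels = [l for l in N_LEVELS if l in set(ds.y)] + sorted(set(ds.y) - set(N_LEVELS))
    preds = np.empty(ds.n, dtype=object)
    flags = []
    for i in range(ds.n):
        tr = np.arange(ds.n) != i
        y_tr = ds.y[tr]
        if len(np.unique(y_tr)) < 2:
            preds[i] = np.unique(y_tr)[0]
            flags.append(f"fold{i}_single_class")
            continue
        if len(np.unique(y_tr)) < len(np.unique(ds.y)):
            flags.append(f"fold{i}_missing_class")
        c_val, g_val = (cfg.C, cfg.gamma)
        if cfg.grid_search:
            c_val, g_val = _grid_search(ds.X[tr], y_tr, cfg)
        lo, span = _minmax_fit(ds.X[tr])
        clf = SVC(C=c_val, gamma=g_val, kernel="rbf")
        clf.fit(_minmax_apply(ds.X[tr], lo, span), y_tr)
        preds[i] = clf.predict(_minmax_apply(ds.X[i:i + 1], lo, span))[0]

    validation = float((preds == ds.y).mean())
    clf, (lo, span), hyper = train_svm(ds, cfg)
    training = float(
        (clf.predict(_minmax_apply(ds.X, lo, span)) == ds.y).mean()
    )
    confusion = pd.DataFrame(0, index=levels, columns=levels)
    for true, pred in zip(ds.y, preds):
        confusion.loc[true, pred] += 1
    return CVResult(
        training_accuracy=training,
        validation_accuracy=validation,
        confusion=confusion,
        n_used=ds.n,
        dropped_rows=ds.n_dropped,
        hyperparameters=hyper,
        qc_flags=";".join(flags),
    )


# ---------------------------------------------------------------------------
# the full evaluation grid
# ---------------------------------------------------------------------------

def dataset_combinations(labels) -> list:
    """Single periods plus cumulative time-ordered combinations.

    For labels P1..P7 this is P1, ..., P7, P1+P2, P1+P2+P3, ..., i.e. the
    single/combined enumeration used for diagnosis (first combination
    starts at two periods).
    """
    labels = list(labels)
    singles = [[l] for l in labels]
    combined = [labels[: i + 1] for i in range(1, len(labels))]
    return singles + combined


def evaluate_grid(
    dyn_by_spacing: dict,
    positions=("FIL", "1st", "2nd", "3rd"),
    combined_positions=(("FIL", "3rd"),),
    cfg: SVMConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """CVResult for every data set x leaf position, plus combined positions.

    ``dyn_by_spacing`` maps spacing (3, 6) to its dynamic feature table.
    Returns the long report table and a dict of confusion matrices keyed by
    (spacing, data_set, positions).
    """
    cfg = cfg or SVMConfig()
    rows, confusions = [], {}
    position_sets = [(p,) for p in positions] + [tuple(c) for c in combined_positions]
    for spacing, dyn in sorted(dyn_by_spacing.items()):
        labels = sorted(dyn["period"].unique(),
                        key=lambda s: int(s.strip("P'").strip()))
        for combo in dataset_combinations(labels):
            for pos_set in position_sets:
                name = "+".join(combo)
                pos_name = "+".join(pos_set)
                try:
                    ds = assemble_dataset(dyn, combo, pos_set)
                    res = loocv(ds, cfg)
                except (EmptyDataset, DegenerateLabels) as exc:
                    log.warning("grid cell %s/%s/%s skipped: %s",
                                spacing, name, pos_name, exc)
                    continue
                rows.append({
                    "spacing": spacing, "data_set": name, "positions": pos_name,
                    "combined": len(combo) > 1, "n_used": res.n_used,
                    "dropped_rows": res.dropped_rows,
                    "training_acc": res.training_accuracy,
                    "validation_acc": res.validation_accuracy,
                    "qc_flags": res.qc_flags,
                })
                confusions[(spacing, name, pos_name)] = res.confusion
    report = pd.DataFrame(rows)
    return report, confusions


def best_position_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Per data set, the single leaf position with the best LOOCV accuracy."""
    singles = report[~report["positions"].str.contains(r"\+")]
    idx = singles.groupby(["spacing", "data_set"])["validation_acc"].idxmax()
    cols = ["spacing", "data_set", "positions", "n_used",
            "training_acc", "validation_acc"]
    return (
        singles.loc[idx, cols]
        .sort_values(["spacing", "data_set"])
        .reset_index(drop=True)
    )
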
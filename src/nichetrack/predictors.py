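"""Differentiation-score regression and multinomial age classification.

The differentiation model learns the principal-curve pseudo-differentiation
coordinate of the whole neurogenic lineage (qNSC -> aNSPC -> NB/IMN) from
marker-gene expression with a random forest, compresses to the top
important features, and can then query any population (e.g., qNSCs per age)
for its differentiation state. The age classifier is an elastic-net
multinomial fit on highly variable genes with a class-balanced train split
and cross-validated penalty selection.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .config import PipelineConfig
from .datatypes import AGE_ORDER, ExpressionMatrix, ParameterError
from . import scoring, trajectory

__all__ = [
    "DiffScoreModel",
    "AgeClassifier",
    "train_differentiation_model",
    "predict_differentiation",
    "train_age_classifier",
]

log = logging.getLogger("nichetrack")

LINEAGE_LABELS = ("qNSC", "aNSPC", "NB/IMN")


@dataclass
class DiffScoreModel:
    """Fitted differentiation-score regressor and its provenance."""

    features: list[str]
    regressor: RandomForestRegressor
    target: pd.Series  # training pseudotime in [0, 1], qNSC-low
    marker_genes: list[str]
    training_cells: list[str]
    seed: int


def _expression_frame(m: ExpressionMatrix, genes: list[str]) -> pd.DataFrame:
    pos = {g: i for i, g in enumerate(m.gene_ids)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ParameterError(f"model features absent from matrix: {missing[:10]}")
    ln = m.require_lognorm()
    return pd.DataFrame(
        ln[[pos[g] for g in genes], :].T, index=m.cell_ids, columns=genes
    )


def train_differentiation_model(
    m: ExpressionMatrix,
    lineage_labels: tuple[str, ...] = LINEAGE_LABELS,
    cfg: PipelineConfig | None = None,
) -> DiffScoreModel:
    """Train the differentiation-score model on the whole lineage.

    Steps: (1) one-vs-rest markers across the three lineage types (top
    ``markers_per_class`` by avg_log2fc each); (2) target = principal-curve
    pseudotime over the first ``n_pcs_curve`` PCs, scaled to [0, 1] and
    oriented so the first lineage label (qNSC) is low; (3) random forest
    (``rf_n_trees`` trees, seeded) on the marker genes; (4) keep the
    ``rf_top_features`` most important features (all, with a warning, if
    fewer are available); (5) refit on that feature set.
    """
    cfg = cfg or PipelineConfig()
    mask = m.cell_meta["cell_type"].isin(list(lineage_labels)).to_numpy()
    sub = m.subset_cells(mask)
    counts = sub.cell_meta["cell_type"].value_counts()
    lacking = [t for t in lineage_labels if counts.get(t, 0) < 30]
    if lacking:
        raise ParameterError(f"lineage types with fewer than 30 cells: {lacking}")

    markers = scoring.rank_markers(
        sub, "cell_type", alpha=cfg.marker_alpha, lfc_min=cfg.marker_lfc_min
    )
    top = (
        markers.groupby("group", group_keys=False)
        .head(cfg.markers_per_class)["gene"]
        .tolist()
    )
    marker_genes = sorted(set(top))
    if not marker_genes:
        raise ParameterError("no marker genes survive the significance cutoffs")

    hvgs = scoring.select_hvgs(sub, cfg.n_hvg)
    n_pcs = min(50, min(len(hvgs), sub.n_cells) - 1)
    pca = trajectory.compute_pca(sub, n_pcs=n_pcs, genes=hvgs)
    curve = trajectory.fit_principal_curve(pca, n_pcs=min(cfg.n_pcs_curve, n_pcs))
    root = (sub.cell_meta["cell_type"] == lineage_labels[0]).to_numpy()
    curve = trajectory.orient_pseudotime(curve, root)
    target = curve.t

    X = _expression_frame(sub, marker_genes)
    # classic regression-forest mtry = p/3 (much faster than sklearn's all-features default)
    rf = RandomForestRegressor(
        n_estimators=cfg.rf_n_trees, max_features=1 / 3, random_state=cfg.seed, n_jobs=1
    ).fit(X.to_numpy(), target.to_numpy())
    importance = pd.Series(rf.feature_importances_, index=marker_genes)
    if len(marker_genes) <= cfg.rf_top_features:
        log.warning(
            "only %d marker genes available (< rf_top_features=%d); keeping all",
            len(marker_genes),
            cfg.rf_top_features,
        )
        features = list(marker_genes)
    else:
        features = importance.sort_values(ascending=False).index[: cfg.rf_top_features].tolist()
    final = RandomForestRegressor(
        n_estimators=cfg.rf_n_trees, max_features=1 / 3, random_state=cfg.seed, n_jobs=1
    ).fit(X[features].to_numpy(), target.to_numpy())
    return DiffScoreModel(
        features=features,
        regressor=final,
        target=target,
        marker_genes=marker_genes,
        training_cells=list(sub.cell_ids),
        seed=cfg.seed,
    )


def predict_differentiation(
    model: DiffScoreModel, m: ExpressionMatrix, cells=None
) -> pd.Series:
    """Predict the differentiation score of ``cells`` (default: all cells).

    All model features must be present in the matrix; predictions depend
    only on the feature genes, so the score is unchanged by permuting or
    perturbing non-feature genes.
    """
    sub = m if cells is None else m.subset_cells(np.asarray([c in set(cells) for c in m.cell_ids]))
    X = _expression_frame(sub, model.features)
    pred = model.regressor.predict(X.to_numpy())
    return pd.Series(pred, index=pd.Index(sub.cell_ids, name="cell_id"), name="diff_score")


@dataclass
class AgeClassifier:
    """Fitted multinomial elastic-net age classifier with held-out diagnostics."""

    model: Pipeline
    hvgs: list[str]
    best_params: dict
    confusion: pd.DataFrame  # true age x predicted age on held-out cells
    accuracy: float
    train_cells: list[str]
    test_cells: list[str]


def train_age_classifier(
    m: ExpressionMatrix, cfg: PipelineConfig | None = None
) -> AgeClassifier:
    """Train the elastic-net multinomial age classifier.

    The training split is class-balanced: ``train_frac`` of the least
    populated age class, with the same count drawn (seeded) from every
    class; the remainder is held out. Hyperparameters (mixing in
    {0.1, 0.5, 0.9} x 20 log-spaced inverse penalties) are selected by
    ``cv_folds``-fold cross-validated accuracy, then the model is refitted
    and evaluated on the held-out cells.
    """
    cfg = cfg or PipelineConfig()
    ages = m.cell_meta["age"].to_numpy(dtype=object)
    counts = pd.Series(ages).value_counts()
    present = [a for a in AGE_ORDER if a in counts.index]
    too_small = [a for a in present if counts[a] < 10]
    if len(present) < 3:
        raise ParameterError(f"age groups missing: {sorted(set(AGE_ORDER) - set(present))}")
    if too_small:
        raise ParameterError(f"age classes with fewer than 10 cells: {too_small}")

    hvgs = scoring.select_hvgs(m, cfg.n_hvg)
    rng = np.random.default_rng(cfg.seed)
    n_train = int(np.floor(cfg.train_frac * counts[present].min()))
    train_idx: list[int] = []
    for a in present:
        pool = np.flatnonzero(ages == a)
        train_idx.extend(rng.choice(pool, size=n_train, replace=False).tolist())
    train_idx = np.sort(np.array(train_idx))
    test_idx = np.setdiff1d(np.arange(m.n_cells), train_idx)

    X = _expression_frame(m, hvgs).to_numpy()
    cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    # warm-started regularization path over 20 inverse penalties x 3 mixings
    best = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "clf",
                LogisticRegressionCV(
                    solver="saga",
                    Cs=np.logspace(-3, 3, 20),
                    l1_ratios=[0.1, 0.5, 0.9],
                    cv=cv,
                    scoring="accuracy",
                    max_iter=2000,
                    tol=1e-2,
                    n_jobs=1,
                    random_state=cfg.seed,
                ),
            ),
        ]
    )
    best.fit(X[train_idx], ages[train_idx])
    clf = best.named_steps["clf"]
    chosen = {"C": float(np.atleast_1d(clf.C_)[0]), "l1_ratio": float(np.atleast_1d(clf.l1_ratio_)[0])}

    pred = best.predict(X[test_idx])
    acc = float((pred == ages[test_idx]).mean())
    conf = pd.DataFrame(
        confusion_matrix(ages[test_idx], pred, labels=present),
        index=pd.Index(present, name="true"),
        columns=pd.Index(present, name="predicted"),
    )
    return AgeClassifier(
        model=best,
        hvgs=hvgs,
        best_params=chosen,
        confusion=conf,
        accuracy=acc,
        train_cells=[m.cell_ids[i] for i in train_idx],
        test_cells=[m.cell_ids[i] for i in test_idx],
    )


def score_by_group(scores: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Mean +/- s.e.m. of a per-cell score within each group."""
    df = pd.DataFrame({"score": scores, "group": groups.reindex(scores.index)})
    agg = df.groupby("group")["score"].agg(["mean", "sem", "count"])
    agg.columns = ["mean", "sem", "n"]
    return agg
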
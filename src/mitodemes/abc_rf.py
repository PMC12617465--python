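"""ABC model choice with random-forest classification.

Reference tables of summary statistics are simulated under competing
demographic models; a random forest classifies the observed vector, and the
posterior probability of the selected model is estimated by a regression
forest trained on the out-of-bag misclassification indicator (the approach
of the abcrf methodology).  Linear discriminant axes can be appended to the
predictors, as is standard in ABC-RF practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .coalsim import ModelTemplate, MutationModel, SimulationError, simulate_dataset
from .sumstats import SummaryVector, populations_from_metadata, summarize

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 500
MAX_RESIM_ATTEMPTS = 20


def _seed_for(master_seed: int, model_index: int, sim_index: int, attempt: int = 0) -> np.random.Generator:
    """Reproducible per-simulation stream, independent of parallel order."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), model_index, sim_index, attempt])
    )


@dataclass
class ReferenceTable:
    """Per-simulation summary statistics labelled by generating model.

    ``X`` holds the raw statistic columns (NaNs already imputed, with one
    ``DEF_``-prefixed indicator column per imputed statistic family) plus,
    after :func:`add_lda_axes`, LDA coordinate columns.
    """

    X: pd.DataFrame
    labels: np.ndarray
    params: pd.DataFrame
    stat_columns: list[str]
    lda: LinearDiscriminantAnalysis | None = None
    lda_features: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_models(self) -> int:
        return len(np.unique(self.labels))

    def per_model_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def impute_missing(df: pd.DataFrame, constant: float = 0.0) -> pd.DataFrame:
    """Impute NaN statistics with a constant, appending indicator columns.

    One indicator column ``DEF_<stat>`` (1 = was defined) is added for each
    statistic column that was ever missing, keeping the table geometry
    fixed across model comparisons.
    """
    out = df.copy()
    for col in df.columns:
        if df[col].isna().any():
            out[f"DEF_{col}"] = (~df[col].isna()).astype(float)
            out[col] = df[col].fillna(constant)
    return out


def summarize_dataset(dataset, floor_fst: bool = False) -> SummaryVector:
    """Summary vector of a simulated dataset, populations = groups."""
    pops = populations_from_metadata(dataset.metadata, dataset.alignment.sample_ids)
    return summarize(dataset.alignment, pops, floor_fst=floor_fst)


def build_reference_table(
    templates: Sequence[ModelTemplate],
    mut: MutationModel,
    n_sims_per_model: int,
    seed: int,
) -> ReferenceTable:
    """Simulate ``n_sims_per_model`` datasets per model and summarize each.

    Class balance is enforced (equal rows per model: uniform implicit model
    prior).  Failed simulations (e.g. non-coalescence under an extreme
    parameter draw) are logged and redrawn with an incremented attempt
    seed, capped at MAX_RESIM_ATTEMPTS per slot.
    """
    if n_sims_per_model < 1:
        raise ValueError("n_sims_per_model must be >= 1")
    rows, labels, param_rows = [], [], []
    for m_idx, template in enumerate(templates):
        for s_idx in range(n_sims_per_model):
            for attempt in range(MAX_RESIM_ATTEMPTS):
                rng = _seed_for(seed, m_idx, s_idx, attempt)
                try:
                    ds = simulate_dataset(template, mut, rng)
                    break
                except SimulationError as exc:
                    logger.warning(
                        "simulation %s/%d failed (%s); resimulating", template.name, s_idx, exc
                    )
            else:
                raise SimulationError(
                    f"model {template.name}, sim {s_idx}: exceeded resimulation cap"
                )
            vec = summarize_dataset(ds)
            rows.append(vec.values)
            labels.append(template.name)
            param_rows.append(pd.Series(ds.params))
    raw = pd.DataFrame(rows).reset_index(drop=True)
    X = impute_missing(raw)
    return ReferenceTable(
        X=X,
        labels=np.asarray(labels),
        params=pd.DataFrame(param_rows).reset_index(drop=True),
        stat_columns=list(X.columns),
        provenance={
            "seed": seed,
            "n_sims_per_model": n_sims_per_model,
            "models": [t.name for t in templates],
            "L": mut.L,
        },
    )


def observed_to_row(table: ReferenceTable, observed: SummaryVector) -> pd.DataFrame:
    """Align an observed vector with the table's columns (impute + LDA)."""
    base_cols = [c for c in table.stat_columns if not c.startswith(("DEF_", "LDA"))]
    missing = [c for c in base_cols if c not in observed.values.index]
    if missing:
        raise ValueError(f"observed vector lacks statistics: {missing[:5]}")
    row = observed.values.reindex(base_cols)
    cells: dict[str, float] = row.fillna(0.0).to_dict()
    for col in table.stat_columns:
        if col.startswith("DEF_"):
            cells[col] = float(~np.isnan(row[col[4:]]))
    if table.lda is not None:
        frame = pd.DataFrame([cells])
        axes = table.lda.transform(frame[table.lda_features].to_numpy())
        for i in range(axes.shape[1]):
            cells[f"LDA{i + 1}"] = float(axes[0, i])
    return pd.DataFrame([cells])[table.stat_columns]


def add_lda_axes(table: ReferenceTable, ridge: float = 1e-8) -> ReferenceTable:
    """Append linear-discriminant coordinates as extra predictor columns.

    min(n_models - 1, n_stats) axes are added; the fitted projection is
    stored so observed vectors can be projected identically.  A singular
    within-class covariance falls back to ridge shrinkage with a warning.
    """
    if table.n_models < 2:
        raise ValueError("LDA needs at least 2 model labels")
    if len(table.X) <= len(table.X.columns):
        raise ValueError("LDA needs more rows than statistics")
    X = table.X[[c for c in table.X.columns if not c.startswith("LDA")]]
    lda = LinearDiscriminantAnalysis(solver="svd")
    import warnings

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        axes = lda.fit(X.to_numpy(), table.labels).transform(X.to_numpy())
        if any("collinear" in str(w.message).lower() for w in caught):
            logger.warning("within-class covariance singular; applying ridge %g", ridge)
            lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=ridge)
            axes = lda.fit(X.to_numpy(), table.labels).transform(X.to_numpy())
    newX = table.X.copy()
    for i in range(axes.shape[1]):
        newX[f"LDA{i + 1}"] = axes[:, i]
    return ReferenceTable(
        X=newX,
        labels=table.labels,
        params=table.params,
        stat_columns=list(newX.columns),
        lda=lda,
        lda_features=list(X.columns),
        provenance=dict(table.provenance),
    )


@dataclass
class TrainedClassifier:
    forest: RandomForestClassifier
    table: ReferenceTable
    oob_error: float
    confusion: pd.DataFrame
    classification_error: pd.Series
    oob_misclassified: np.ndarray  # per-row indicator over OOB votes
    posterior_forest: RandomForestRegressor | None = None

    @property
    def n_trees(self) -> int:
        return self.forest.n_estimators


@dataclass
class ModelChoiceResult:
    """Outcome of one ABC-RF model comparison."""

    selected_model: str
    votes: dict[str, int]
    posterior_probability: float
    oob_error: float
    confusion_matrix: pd.DataFrame
    classification_error: pd.Series
    n_trees: int
    lda_projection: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "selected_model": self.selected_model,
            "votes": self.votes,
            "posterior_probability": self.posterior_probability,
            "oob_error": self.oob_error,
            "classification_error": self.classification_error.to_dict(),
            "confusion_matrix": {
                str(k): v for k, v in self.confusion_matrix.to_dict(orient="index").items()
            },
            "n_trees": self.n_trees,
            "lda_projection": None
            if self.lda_projection is None
            else self.lda_projection.tolist(),
        }


def train_classifier(
    table: ReferenceTable,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit the random-forest classifier and its out-of-bag diagnostics.

    The confusion matrix rows are generating models, columns OOB-predicted
    models; per-model classification error (CE) is the off-diagonal row
    fraction; the prior (OOB) error rate is the overall misclassification
    fraction.
    """
    classes = np.unique(table.labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 model labels to classify")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    X = table.X.to_numpy()
    forest.fit(X, table.labels)
    oob_proba = forest.oob_decision_function_
    # Rows never out of bag (possible for tiny forests) count as errors.
    has_oob = ~np.isnan(oob_proba).any(axis=1)
    oob_pred = np.full(len(table.labels), "", dtype=object)
    oob_pred[has_oob] = forest.classes_[np.argmax(oob_proba[has_oob], axis=1)]
    mis = oob_pred != table.labels
    oob_error = float(np.mean(mis))
    confusion = pd.crosstab(
        pd.Series(table.labels, name="generating"),
        pd.Series(oob_pred, name="oob_predicted"),
        dropna=False,
    ).reindex(index=classes, columns=classes, fill_value=0)
    ce = 1.0 - np.diag(confusion.to_numpy()) / confusion.sum(axis=1).to_numpy()
    return TrainedClassifier(
        forest=forest,
        table=table,
        oob_error=oob_error,
        confusion=confusion,
        classification_error=pd.Series(ce, index=classes, name="CE"),
        oob_misclassified=mis.astype(float),
    )


def select_model(
    clf: TrainedClassifier,
    observed: SummaryVector,
    posterior_seed: int = 1,
) -> ModelChoiceResult:
    """Classify the observed vector and estimate the posterior probability.

    The selected model is the majority vote over trees.  Its posterior
    probability is 1 minus the local OOB error predicted at the observed
    point by a regression forest trained on the misclassification
    indicator (the abcrf estimator).
    """
    row = observed_to_row(clf.table, observed)
    x = row.to_numpy()
    votes_arr = np.array(
        [tree.predict(x)[0] for tree in clf.forest.estimators_]
    )
    classes = clf.forest.classes_
    # Tree predictions come back as float indices into classes_ internally;
    # estimators_ predict encoded outputs, so map via classes_.
    votes = {}
    for c_idx, c in enumerate(classes):
        votes[str(c)] = int(np.sum(votes_arr.astype(int) == c_idx))
    selected = str(classes[np.argmax([votes[str(c)] for c in classes])])

    if clf.posterior_forest is None:
        reg = RandomForestRegressor(
            n_estimators=clf.forest.n_estimators,
            random_state=posterior_seed,
            n_jobs=1,
        )
        reg.fit(clf.table.X.to_numpy(), clf.oob_misclassified)
        clf.posterior_forest = reg
    local_error = float(np.clip(clf.posterior_forest.predict(x)[0], 0.0, 1.0))
    posterior = 1.0 - local_error

    lda_proj = None
    if clf.table.lda is not None:
        lda_proj = row[[c for c in row.columns if c.startswith("LDA")]].to_numpy()[0]

    return ModelChoiceResult(
        selected_model=selected,
        votes=votes,
        posterior_probability=posterior,
        oob_error=clf.oob_error,
        confusion_matrix=clf.confusion,
        classification_error=clf.classification_error,
        n_trees=clf.forest.n_estimators,
        lda_projection=lda_proj,
    )


@dataclass
class ComparisonStage:
    """One stage of the hierarchical comparison: a named set of templates."""

    name: str
    templates: list[ModelTemplate]


def hierarchical_comparison(
    stages: Sequence[ComparisonStage],
    observed: SummaryVector,
    mut: MutationModel,
    n_sims_per_model: int,
    seed: int,
    n_trees: int = DEFAULT_N_TREES,
    use_lda: bool = True,
    carry_winners_stage: int | None = None,
) -> list[tuple[str, ModelChoiceResult]]:
    """Run ordered model-choice stages, optionally inserting a head-to-head
    stage between earlier winners.

    When ``carry_winners_stage`` is an index, that stage's template list is
    replaced by the winning templates of all preceding stages.
    """
    results: list[tuple[str, ModelChoiceResult]] = []
    winners: list[ModelTemplate] = []
    for i, stage in enumerate(stages):
        templates = stage.templates
        if carry_winners_stage is not None and i == carry_winners_stage:
            templates = winners
        if not templates or len(templates) < 2:
            raise ValueError(f"stage {stage.name!r}: needs at least 2 models")
        table = build_reference_table(templates, mut, n_sims_per_model, seed + i)
        if use_lda:
            table = add_lda_axes(table)
        clf = train_classifier(table, n_trees=n_trees, seed=seed + i)
        result = select_model(clf, observed, posterior_seed=seed + i)
        results.append((stage.name, result))
        winner = next(t for t in templates if t.name == result.selected_model)
        if winner not in winners:
            winners.append(winner)
    return results
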
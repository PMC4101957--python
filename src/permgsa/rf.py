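"""Random-forest gene set analysis for categorical and continuous phenotypes.

A gene set is scored by how well its genes predict the phenotype: the
forest's out-of-bag (OOB) misclassification rate for categorical phenotypes,
or the OOB mean squared error for continuous ones.  Significance comes from
phenotype permutations with the P-value

    P = #{ R^(k) <= R_0 } / N,

where ``R_0`` is the observed OOB score, ``R^(k)`` the score of a fresh
forest grown on the k-th permuted phenotype, and N the number of
permutations; ties count as extreme (the ``<=`` is deliberate).  A lower
score is more extreme for both error rate and MSE.

Categorical forests are scikit-learn RandomForestClassifiers; continuous
phenotypes use the compiled :class:`~permgsa.forest.RegressionForest`, whose
per-fit cost makes the permutation null affordable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset, GeneSetCollection, Phenotype
from .forest import RegressionForest
from .gsa import PermutationResult

__all__ = [
    "RFConfig",
    "RFResult",
    "eq_count_pvalue",
    "oob_score",
    "rf_permutation_pvalue",
    "rf_importance",
    "run_rf_gsa",
    "kfold_cv_error",
]


@dataclass
class RFConfig:
    """Forest and permutation settings.

    ``mtry`` defaults to floor(sqrt(m)) for classification and
    max(1, floor(m/3)) for regression, the usual random-forests conventions.
    """

    n_trees: int = 500
    nb_perm: int = 1000
    phenotype_type: str = "auto"  # categorical | continuous | auto
    mtry: int | None = None
    importance: bool = False
    seed: int | None = None
    alpha: float = 0.05
    min_node_regression: int = 5

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")
        if self.nb_perm < 1:
            raise ValueError("nb_perm must be at least 1")

    def resolve_type(self, phenotype: Phenotype) -> str:
        if self.phenotype_type == "auto":
            return phenotype.kind
        if self.phenotype_type != phenotype.kind:
            raise ValueError(
                f"config requests a {self.phenotype_type} phenotype but the data "
                f"carries a {phenotype.kind} one"
            )
        return self.phenotype_type


@dataclass
class RFResult:
    table: pd.DataFrame                      # set, size, oob_score, pvalue
    importance: dict[str, pd.DataFrame] = field(default_factory=dict)
    config: RFConfig | None = None

    def write(self, path, importance_dir=None) -> None:
        self.table.to_csv(path, sep="\t", index=False)
        if importance_dir is not None:
            from pathlib import Path

            d = Path(importance_dir)
            d.mkdir(parents=True, exist_ok=True)
            for name, df in self.importance.items():
                df.to_csv(d / f"importance_{name}.tsv", sep="\t", index=False)


def eq_count_pvalue(observed: float, null_draws) -> float:
    """Fraction of permuted scores at most the observed score (ties extreme)."""
    null_draws = np.asarray(null_draws, dtype=float)
    if null_draws.size == 0:
        raise ValueError("need at least one permutation")
    return float(np.mean(null_draws <= observed))


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _fit_forest(X: np.ndarray, y, kind: str, config: RFConfig, seed: int):
    if kind == "categorical":
        from sklearn.ensemble import RandomForestClassifier

        m = X.shape[1]
        max_features = config.mtry if config.mtry is not None else max(1, int(np.sqrt(m)))
        rf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=min(max_features, m),
            oob_score=False,
            bootstrap=True,
            n_jobs=1,
            random_state=seed % (2**31),
        )
        rf.fit(X, y)
        return rf
    forest = RegressionForest(
        n_trees=config.n_trees,
        mtry=config.mtry,
        min_node=config.min_node_regression,
        seed=seed,
    )
    forest.fit(X, np.asarray(y, dtype=float))
    return forest


def _classifier_oob_error(rf, X, y) -> float:
    """OOB misclassification rate, excluding samples never out of bag."""
    import inspect

    from sklearn.ensemble._forest import _generate_unsampled_indices, _get_n_samples_bootstrap

    # sklearn >= 1.7 threads sample_weight through these helpers
    takes_weight = "sample_weight" in inspect.signature(_get_n_samples_bootstrap).parameters
    n = X.shape[0]
    classes = rf.classes_
    votes = np.zeros((n, len(classes)))
    if takes_weight:
        n_boot = _get_n_samples_bootstrap(n, rf.max_samples, None)
    else:
        n_boot = _get_n_samples_bootstrap(n, rf.max_samples)
    for tree in rf.estimators_:
        if takes_weight:
            oob_idx = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        else:
            oob_idx = _generate_unsampled_indices(tree.random_state, n, n_boot)
        if len(oob_idx) == 0:
            continue
        pred = tree.predict(X[oob_idx])
        for i, cls_idx in zip(oob_idx, pred.astype(int)):
            votes[i, cls_idx] += 1
    covered = votes.sum(axis=1) > 0
    if not covered.all():
        warnings.warn(
            f"{int((~covered).sum())} sample(s) never out of bag; excluded from the OOB score",
            stacklevel=2,
        )
    if not covered.any():
        raise ValueError("no sample was ever out of bag; increase n_trees")
    pred_class = classes[np.argmax(votes[covered], axis=1)]
    return float(np.mean(pred_class != np.asarray(y)[covered]))


def _score(X: np.ndarray, y, kind: str, config: RFConfig, seed: int, warn: bool = True) -> float:
    if kind == "categorical":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("phenotype has a single class")
        rf = _fit_forest(X, _encode(y), "categorical", config, seed)
        return _classifier_oob_error(rf, X, _encode(y))
    forest = _fit_forest(X, y, "continuous", config, seed)
    return forest.oob_mse(warn_uncovered=warn)


def _encode(y) -> np.ndarray:
    y = np.asarray(y)
    _, enc = np.unique(y, return_inverse=True)
    return enc


def oob_score(X_set: np.ndarray, phenotype: Phenotype, config: RFConfig) -> float:
    """Observed OOB score R_0 for one set (error rate or MSE).

    ``X_set`` is samples x set-genes.  Deterministic given ``config.seed``.
    """
    kind = config.resolve_type(phenotype)
    y = phenotype.labels
    seed = _seed_int(np.random.SeedSequence(0 if config.seed is None else config.seed))
    return _score(np.asarray(X_set, dtype=float), y, kind, config, seed)


def rf_permutation_pvalue(X_set: np.ndarray, phenotype: Phenotype, config: RFConfig) -> PermutationResult:
    """Permutation P-value for one set: fresh forest per phenotype permutation."""
    kind = config.resolve_type(phenotype)
    X_set = np.asarray(X_set, dtype=float)
    y = phenotype.labels
    root = np.random.SeedSequence(0 if config.seed is None else config.seed)
    children = root.spawn(config.nb_perm + 2)
    r0 = _score(X_set, y, kind, config, _seed_int(children[0]))
    rng = np.random.default_rng(children[1])
    null = np.empty(config.nb_perm)
    for k in range(config.nb_perm):
        y_perm = y[rng.permutation(len(y))]
        null[k] = _score(X_set, y_perm, kind, config, _seed_int(children[k + 2]), warn=False)
    p = eq_count_pvalue(r0, null)
    return PermutationResult(observed=r0, null_draws=null, pvalue=p, tail="lower", seed=config.seed)


def rf_importance(X_set: np.ndarray, phenotype: Phenotype, config: RFConfig) -> np.ndarray:
    """Per-gene importance: mean decrease in Gini (categorical) or mean
    increase in OOB MSE under feature permutation (continuous)."""
    kind = config.resolve_type(phenotype)
    X_set = np.asarray(X_set, dtype=float)
    seed = _seed_int(np.random.SeedSequence(0 if config.seed is None else config.seed))
    if kind == "categorical":
        rf = _fit_forest(X_set, _encode(phenotype.labels), "categorical", config, seed)
        return np.asarray(rf.feature_importances_)
    forest = _fit_forest(X_set, phenotype.labels, "continuous", config, seed)
    return forest.permutation_importance(seed=seed)


def run_rf_gsa(
    data: ExpressionDataset,
    sets: GeneSetCollection,
    config: RFConfig,
    adjust: bool = False,
) -> RFResult:
    """Per-set RF permutation test over a collection.

    Importance tables are attached for sets with ``pvalue <= config.alpha``
    when ``config.importance`` is set.  Each set draws its own seed
    substream keyed by its position, so appending sets leaves earlier
    results untouched; rerunning with the same seed reproduces the result
    exactly.  ``adjust=True`` appends a BH-FDR column across the sets
    (off by default).
    """
    kind = config.resolve_type(data.phenotype)
    rows = []
    importance: dict[str, pd.DataFrame] = {}
    for j in range(sets.n_sets):
        mem = sets.members(j)
        X_set = data.values[mem].T
        sub_seed = _seed_int(np.random.SeedSequence(0 if config.seed is None else config.seed, spawn_key=(j,)))
        sub_cfg = RFConfig(
            n_trees=config.n_trees,
            nb_perm=config.nb_perm,
            phenotype_type=kind,
            mtry=config.mtry,
            importance=config.importance,
            seed=sub_seed,
            alpha=config.alpha,
            min_node_regression=config.min_node_regression,
        )
        res = rf_permutation_pvalue(X_set, data.phenotype, sub_cfg)
        rows.append((sets.set_names[j], int(len(mem)), res.observed, res.pvalue))
        if config.importance and res.pvalue <= config.alpha:
            imp = rf_importance(X_set, data.phenotype, sub_cfg)
            order = np.argsort(imp)[::-1]
            importance[sets.set_names[j]] = pd.DataFrame(
                {
                    "gene": [data.gene_ids[mem[i]] for i in order],
                    "importance": imp[order],
                }
            )
    table = pd.DataFrame(rows, columns=["set", "size", "oob_score", "pvalue"])
    if adjust:
        from .multiplicity import bh_adjust

        table["fdr"] = bh_adjust(table["pvalue"].to_numpy())
    return RFResult(table=table, importance=importance, config=config)


def kfold_cv_error(data: ExpressionDataset, set_members, k: int, config: RFConfig) -> float:
    """Stratified k-fold cross-validated misclassification rate for one set.

    Samples of each class are dealt round-robin into folds, so k may exceed
    the smallest class (some folds then miss a class); k equal to the sample
    count gives leave-one-out.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if data.phenotype.kind != "categorical":
        raise ValueError("cross-validated error requires a categorical phenotype")
    mem = np.asarray(set_members, dtype=int)
    X = data.values[mem].T
    y = _encode(data.phenotype.labels)
    n = len(y)
    k = min(k, n)
    fold = np.empty(n, dtype=int)
    counter = 0
    for cls in np.unique(y):
        for i in np.flatnonzero(y == cls):
            fold[i] = counter % k
            counter += 1
    errors = 0
    root = np.random.SeedSequence(0 if config.seed is None else config.seed)
    for f, child in enumerate(root.spawn(k)):
        test = fold == f
        if not test.any():
            continue
        rf = _fit_forest(X[~test], y[~test], "categorical", config, _seed_int(child))
        errors += int(np.sum(rf.predict(X[test]) != y[test]))
    return errors / n
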
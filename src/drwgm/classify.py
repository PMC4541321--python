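"""Feature selection, logistic classification, evaluation protocols, Cscore.

Pathway activities are classification features.  Features are ranked by the
p-value of a t-test of the activity between phenotypes on a *feature
evaluation* sample set, then added greedily: a feature is retained iff the
AUC of the logistic classifier (fit on the evaluation set) strictly
increases on a disjoint *feature selection* set.

Within-dataset protocol: per repeat, a stratified 5-fold partition; each
fold in turn is the test set and the walk, differential statistics and
activity models are fitted on the remaining four folds only; three random
stratified 2/3-1/3 splits of the training samples drive the greedy search,
and each optimized classifier is scored on the held-out fold — 15 AUCs per
repeat, 1500 over the default 100 repeats.

Cross-dataset protocol: the walk and models come from the full training
cohort; per repeat a stratified 5-subset partition of the training cohort
assigns each subset in turn as the feature-selection set (the other four
are the feature-evaluation set), and the optimized classifier is scored on
the full independent test cohort — 5 AUCs per repeat, 500 over 100 repeats.

The Cscore(N) reproducibility statistic is the mean, over the N pathways
with the largest training |t|, of the product of each pathway activity's
training t-score and test t-score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .activity import (
    DEFAULT_MIN_DIFF_GENES,
    NotDiscriminativeError,
    PathwayActivityModel,
    activity_matrix,
    activity_test,
    activity_train,
    baseline_activity,
    check_min_diff_genes,
    fit_activity_model,
    pac_activity,
)
from .diffstats import (
    DiffResult,
    LabeledMatrix,
    ProtocolError,
    gene_ttests,
    initial_weights,
    metabolite_tests,
    z_normalize,
)
from .drw import WalkConfig, walk
from .graph_core import GlobalGraph, transition_matrix

logger = logging.getLogger(__name__)

DRW_METHODS = ("drw-gm", "drw-gm-nm", "drw")


@dataclass(frozen=True)
class EvalConfig:
    n_repeats: int = 100
    n_folds: int = 5
    inner_splits: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class EvalReport:
    aucs: list[float]
    accuracies: list[float]
    selected_features: list[list[str]]
    method: str

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0

    @property
    def selection_frequency(self) -> dict[str, float]:
        counts: dict[str, int] = {}
        for run in self.selected_features:
            for f in run:
                counts[f] = counts.get(f, 0) + 1
        n = max(len(self.selected_features), 1)
        return {f: c / n for f, c in sorted(counts.items())}

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "n_aucs": len(self.aucs),
            "aucs": self.aucs,
            "accuracies": self.accuracies,
            "selection_frequency": self.selection_frequency,
        }


@dataclass
class CScoreResult:
    n_top: int
    c_score: float
    products: list[tuple[str, float]]  # (pathway_id, t_train * t_test), ranked


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ProtocolError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def fit_logistic(features: pd.DataFrame, labels: np.ndarray) -> LogisticRegression:
    """Logistic regression, effectively unregularized (tiny ridge 1e-6)."""
    clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=5000)
    clf.fit(features.to_numpy().T, labels)
    if clf.n_iter_[0] >= 5000:
        raise ProtocolError(f"logistic fit did not converge in {clf.n_iter_[0]} iterations")
    return clf


def predict_scores(clf: LogisticRegression, features: pd.DataFrame) -> np.ndarray:
    """Predicted probability of the positive (second sorted) phenotype."""
    return clf.predict_proba(features.to_numpy().T)[:, 1]


def _activity_pvalues(act: LabeledMatrix) -> pd.Series:
    res = gene_ttests(act)
    return pd.Series({r.feature_id: r.p_value for r in res})


def greedy_select(eval_act: LabeledMatrix, sel_act: LabeledMatrix) -> list[str]:
    """Greedy forward selection of pathway features.

    Features are ranked ascending by p on the evaluation set; the top
    feature always enters (an empty model has no AUC to compare against);
    each later feature is retained iff the selection-set AUC of the
    classifier refit on the evaluation set strictly increases.
    """
    if not eval_act.feature_ids:
        raise ProtocolError("no features to select from")
    pvals = _activity_pvalues(eval_act)
    order = sorted(eval_act.feature_ids, key=lambda f: (pvals[f], f))
    y_eval = eval_act.binary_labels()
    y_sel = sel_act.binary_labels()
    selected = [order[0]]
    clf = fit_logistic(eval_act.values.loc[selected], y_eval)
    best = auc(predict_scores(clf, sel_act.values.loc[selected]), y_sel)
    for f in order[1:]:
        cand = selected + [f]
        clf = fit_logistic(eval_act.values.loc[cand], y_eval)
        cand_auc = auc(predict_scores(clf, sel_act.values.loc[cand]), y_sel)
        if cand_auc > best:
            selected = cand
            best = cand_auc
    return selected


@dataclass
class ActivityExtractor:
    """Frozen activity machinery fitted on a training cohort.

    For walk-based methods this holds the per-pathway models (genes, walk
    weights, training t-signs); for the mean/median baselines only the
    pathway memberships are needed.  Test cohorts are z-normalized on their
    own samples before activities are computed.
    """

    method: str
    memberships: dict[str, set[str]]
    models: list[PathwayActivityModel] = field(default_factory=list)

    def train_activities(self, expr_train_z: LabeledMatrix) -> LabeledMatrix:
        if self.method in ("mean", "median"):
            rows = [
                r
                for pid in sorted(self.memberships)
                if (r := baseline_activity(pid, self.memberships[pid], expr_train_z, self.method))
                is not None
            ]
        else:
            rows = [activity_train(m, expr_train_z) for m in self.models]
        return activity_matrix(rows, expr_train_z.labels)

    def test_activities(self, expr_test: LabeledMatrix) -> LabeledMatrix:
        expr_test_z = z_normalize(expr_test)
        if self.method in ("mean", "median"):
            rows = [
                r
                for pid in sorted(self.memberships)
                if (r := baseline_activity(pid, self.memberships[pid], expr_test_z, self.method))
                is not None
            ]
        else:
            rows = [activity_test(m, expr_test_z) for m in self.models]
        return activity_matrix(rows, expr_test.labels)


def fit_extractor(
    expr_train: LabeledMatrix,
    graph: GlobalGraph,
    method: str = "drw-gm",
    met_diff: list[DiffResult] | None = None,
    walk_cfg: WalkConfig = WalkConfig(),
    alpha: float = 0.05,
    met_alpha: float = 0.01,
    min_diff_genes: int = DEFAULT_MIN_DIFF_GENES,
) -> ActivityExtractor:
    """Fit all training-side machinery for one method on one cohort.

    For walk methods: z-normalize, t-test, build W0, walk to W_inf, then per
    pathway keep the differential member genes.  The not-discriminative
    guard rejects cohorts with fewer than ``min_diff_genes`` genes at
    p < alpha.  ``graph`` must match the method (gene-metabolite graph for
    drw-gm / drw-gm-nm, gene-only graph for drw).
    """
    memberships = {k: set(v) for k, v in graph.pathway_index.items()}
    if method in ("mean", "median"):
        return ActivityExtractor(method=method, memberships=memberships)
    expr_z = z_normalize(expr_train)
    gene_diff = gene_ttests(expr_z)
    if method == "pac":
        models = [
            m
            for pid in sorted(memberships)
            if (m := pac_activity(pid, memberships[pid], gene_diff, expr_z)) is not None
        ]
        return ActivityExtractor(method=method, memberships=memberships, models=models)
    if method not in DRW_METHODS:
        raise ValueError(f"unknown method {method!r}")
    check_min_diff_genes(gene_diff, alpha=alpha, min_diff_genes=min_diff_genes)
    w0 = initial_weights(
        graph,
        gene_diff,
        met_diff if method == "drw-gm" else None,
        variant=method,
        met_alpha=met_alpha,
    )
    w_inf = walk(transition_matrix(graph), w0, walk_cfg)
    models = [
        m
        for pid in sorted(memberships)
        if (
            m := fit_activity_model(
                pid, memberships[pid], gene_diff, w_inf, alpha=alpha, method=method
            )
        )
        is not None
    ]
    return ActivityExtractor(method=method, memberships=memberships, models=models)


def _stratified_folds(labels: np.ndarray, n_folds: int, seed: int):
    counts = np.unique(labels, return_counts=True)[1]
    if counts.min() < n_folds:
        raise ProtocolError(
            f"smallest class has {counts.min()} samples; need >= {n_folds} "
            f"for stratified {n_folds}-fold splitting"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return skf.split(np.zeros(len(labels)), labels)


def within_dataset_eval(
    expr: LabeledMatrix,
    met: LabeledMatrix | None,
    graph: GlobalGraph,
    cfg: EvalConfig = EvalConfig(),
    method: str = "drw-gm",
    walk_cfg: WalkConfig = WalkConfig(),
    alpha: float = 0.05,
    met_alpha: float = 0.01,
    min_diff_genes: int = DEFAULT_MIN_DIFF_GENES,
) -> EvalReport:
    """Within-dataset cross-validated evaluation (15 AUCs per repeat).

    Held-out folds never touch the differential statistics, the walk, model
    fitting or feature selection.  A fold whose training part yields no
    usable pathway model scores chance (AUC 0.5) for its three classifiers,
    with a warning; the not-discriminative guard still aborts the run.
    """
    ss = np.random.SeedSequence(cfg.seed)
    # metabolite cohort is a fixed side input; its stats never see expr folds
    met_diff = metabolite_tests(met) if (met is not None and method == "drw-gm") else None
    aucs: list[float] = []
    accs: list[float] = []
    selections: list[list[str]] = []
    repeat_seeds = ss.generate_state(cfg.n_repeats * (1 + cfg.n_folds * cfg.inner_splits))
    seed_iter = iter(int(s) % (2**31) for s in repeat_seeds)
    samples = np.array(expr.sample_ids)
    labels = expr.labels.to_numpy()
    for _ in range(cfg.n_repeats):
        fold_seed = next(seed_iter)
        for train_idx, test_idx in _stratified_folds(labels, cfg.n_folds, fold_seed):
            expr_train = expr.subset_samples(list(samples[train_idx]))
            expr_test = expr.subset_samples(list(samples[test_idx]))
            try:
                extractor = fit_extractor(
                    expr_train, graph, method, met_diff, walk_cfg,
                    alpha, met_alpha, min_diff_genes,
                )
                a_train = extractor.train_activities(z_normalize(expr_train))
                a_test = extractor.test_activities(expr_test)
            except NotDiscriminativeError:
                raise
            except ProtocolError as exc:
                logger.warning("fold skipped, scoring chance: %s", exc)
                for _ in range(cfg.inner_splits):
                    next(seed_iter)
                    aucs.append(0.5)
                    accs.append(0.5)
                    selections.append([])
                continue
            y_test = expr_test.binary_labels()
            train_labels = expr_train.labels.to_numpy()
            for _ in range(cfg.inner_splits):
                split_seed = next(seed_iter)
                sss = StratifiedShuffleSplit(
                    n_splits=1, test_size=1 / 3, random_state=split_seed
                )
                ev_idx, sel_idx = next(
                    sss.split(np.zeros(len(train_labels)), train_labels)
                )
                ev_samples = list(np.array(expr_train.sample_ids)[ev_idx])
                sel_samples = list(np.array(expr_train.sample_ids)[sel_idx])
                feats = greedy_select(
                    a_train.subset_samples(ev_samples),
                    a_train.subset_samples(sel_samples),
                )
                clf = fit_logistic(
                    a_train.values.loc[feats, ev_samples],
                    a_train.subset_samples(ev_samples).binary_labels(),
                )
                scores = predict_scores(clf, a_test.values.loc[feats])
                aucs.append(auc(scores, y_test))
                accs.append(float(np.mean((scores >= 0.5).astype(int) == y_test)))
                selections.append(feats)
    return EvalReport(aucs=aucs, accuracies=accs, selected_features=selections, method=method)


def cross_dataset_eval(
    expr_train: LabeledMatrix,
    met: LabeledMatrix | None,
    expr_test: LabeledMatrix,
    graph: GlobalGraph,
    cfg: EvalConfig = EvalConfig(),
    method: str = "drw-gm",
    walk_cfg: WalkConfig = WalkConfig(),
    alpha: float = 0.05,
    met_alpha: float = 0.01,
    min_diff_genes: int = DEFAULT_MIN_DIFF_GENES,
) -> EvalReport:
    """Cross-dataset evaluation on an independent test cohort (5 AUCs/repeat).

    The walk, differential statistics and models come from the full training
    cohort; the test cohort only ever supplies test-side z-scores to the
    frozen models.
    """
    met_diff = metabolite_tests(met) if (met is not None and method == "drw-gm") else None
    extractor = fit_extractor(
        expr_train, graph, method, met_diff, walk_cfg, alpha, met_alpha, min_diff_genes
    )
    a_train = extractor.train_activities(z_normalize(expr_train))
    a_test = extractor.test_activities(expr_test)
    shared = [f for f in a_train.feature_ids if f in set(a_test.feature_ids)]
    if not shared:
        raise ProtocolError("no pathway feature shared between train and test cohorts")
    y_test = expr_test.binary_labels()
    ss = np.random.SeedSequence(cfg.seed)
    repeat_seeds = [int(s) % (2**31) for s in ss.generate_state(cfg.n_repeats)]
    samples = np.array(expr_train.sample_ids)
    labels = expr_train.labels.to_numpy()
    aucs: list[float] = []
    accs: list[float] = []
    selections: list[list[str]] = []
    for rseed in repeat_seeds:
        for ev_idx, sel_idx in _stratified_folds(labels, cfg.n_folds, rseed):
            # each fold plays the feature-selection set; the rest evaluates
            ev_samples = list(samples[ev_idx])
            sel_samples = list(samples[sel_idx])
            eval_act = a_train.subset_samples(ev_samples)
            sel_act = a_train.subset_samples(sel_samples)
            feats = [
                f
                for f in greedy_select(
                    LabeledMatrix(eval_act.values.loc[shared], eval_act.labels),
                    LabeledMatrix(sel_act.values.loc[shared], sel_act.labels),
                )
            ]
            clf = fit_logistic(
                a_train.values.loc[feats, ev_samples], eval_act.binary_labels()
            )
            scores = predict_scores(clf, a_test.values.loc[feats])
            aucs.append(auc(scores, y_test))
            accs.append(float(np.mean((scores >= 0.5).astype(int) == y_test)))
            selections.append(feats)
    return EvalReport(aucs=aucs, accuracies=accs, selected_features=selections, method=method)


def c_score(train_act: LabeledMatrix, test_act: LabeledMatrix, n_top: int) -> CScoreResult:
    """Reproducibility power of the top-N training-ranked pathway activities."""
    t_train = {r.feature_id: r.t_score for r in gene_ttests(train_act)}
    t_test = {r.feature_id: r.t_score for r in gene_ttests(test_act)}
    shared = [p for p in train_act.feature_ids if p in t_test]
    if n_top > len(shared):
        raise ProtocolError(
            f"N={n_top} exceeds the {len(shared)} shared pathway activities"
        )
    ranked = sorted(shared, key=lambda p: (-abs(t_train[p]), p))[:n_top]
    products = [(p, t_train[p] * t_test[p]) for p in ranked]
    return CScoreResult(
        n_top=n_top,
        c_score=float(np.mean([v for _, v in products])),
        products=products,
    )
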
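"""Pathway activity inference and comparison baselines.

For each pathway the member genes that are differentially expressed in the
training cohort (t-test p < 0.05) form the activity model.  The pathway
activity of a sample is the weighted, sign-aligned combination of the
model genes' z-scores:

    a(P_j) = sum_i W_inf(g_i) * sgn(t(g_i)) * z(g_i) / sqrt(sum_i W_inf(g_i)^2)

The square-root-of-squared-weights denominator makes a single-gene pathway
reduce to +/- z exactly and leaves the activity invariant to rescaling all
walk weights by a positive constant.  On test cohorts the model (weights and
training t-signs) is frozen and applied to test-side z-scores; model genes
absent from the test platform are dropped and the denominator recomputed.

Baselines: per-sample mean or median of all member-gene z-scores, and a
PAC-style greedy condition-responsive-genes (CORG) search that accumulates
the member genes, in descending |t| order, while the |t| of the sign-aligned
averaged profile keeps strictly increasing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffstats import DiffResult, LabeledMatrix, ProtocolError
from .pathway_io import PathwayGraph

logger = logging.getLogger(__name__)

METHODS = ("drw-gm", "drw", "drw-gm-nm", "mean", "median", "pac")

DEFAULT_MIN_DIFF_GENES = 50


class NotDiscriminativeError(ProtocolError):
    """Training cohort has too few differential genes to build a classifier."""


@dataclass
class PathwayActivityModel:
    """Frozen per-pathway model: genes, walk weights, training t-signs."""

    pathway_id: str
    genes: list[str]
    weights: np.ndarray
    signs: np.ndarray
    method: str = "drw-gm"

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValueError("model needs at least one gene")
        self.weights = np.asarray(self.weights, dtype=float)
        self.signs = np.asarray(self.signs, dtype=float)

    def to_json(self) -> str:
        return json.dumps(
            {
                "pathway_id": self.pathway_id,
                "genes": self.genes,
                "weights": self.weights.tolist(),
                "signs": self.signs.tolist(),
                "method": self.method,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PathwayActivityModel":
        d = json.loads(text)
        return cls(
            pathway_id=d["pathway_id"],
            genes=d["genes"],
            weights=np.array(d["weights"]),
            signs=np.array(d["signs"]),
            method=d["method"],
        )


def check_min_diff_genes(
    gene_diff: list[DiffResult],
    alpha: float = 0.05,
    min_diff_genes: int = DEFAULT_MIN_DIFF_GENES,
) -> int:
    """Guard: abort when the cohort yields too few differential genes.

    A cohort without enough genes at p < alpha is considered not
    discriminative and classifier construction stops (default threshold 50).
    """
    n = sum(1 for r in gene_diff if r.p_value < alpha)
    if n < min_diff_genes:
        raise NotDiscriminativeError(
            f"only {n} differential genes at p<{alpha} "
            f"(minimum {min_diff_genes}); dataset considered not discriminative"
        )
    return n


def fit_activity_model(
    pathway_id: str,
    member_genes: set[str],
    gene_diff: list[DiffResult],
    w_inf: pd.Series,
    alpha: float = 0.05,
    method: str = "drw-gm",
) -> PathwayActivityModel | None:
    """Select the pathway's differential member genes and freeze the model.

    Returns None (pathway dropped) when no measured member gene reaches
    p < alpha.  Genes are ordered by descending walk weight, then id.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    by_gene = {r.feature_id: r for r in gene_diff}
    chosen = [
        g
        for g in member_genes
        if g in by_gene and by_gene[g].p_value < alpha and g in w_inf.index
    ]
    if not chosen:
        return None
    chosen.sort(key=lambda g: (-float(w_inf[g]), g))
    return PathwayActivityModel(
        pathway_id=pathway_id,
        genes=chosen,
        weights=np.array([w_inf[g] for g in chosen]),
        signs=np.array([np.sign(by_gene[g].t_score) for g in chosen]),
        method=method,
    )


def _combine(model: PathwayActivityModel, z: pd.DataFrame, genes: list[str]) -> np.ndarray:
    idx = [model.genes.index(g) for g in genes]
    w = model.weights[idx]
    s = model.signs[idx]
    zmat = z.loc[genes].to_numpy(dtype=float)
    denom = np.sqrt(np.sum(w**2))
    if denom == 0:
        raise ProtocolError(f"pathway {model.pathway_id}: all model weights zero")
    return (w * s) @ zmat / denom


def activity_train(model: PathwayActivityModel, expr_train_z: LabeledMatrix) -> pd.Series:
    """Training activity a_T: all model genes must be present."""
    missing = [g for g in model.genes if g not in expr_train_z.values.index]
    if missing:
        raise ProtocolError(
            f"pathway {model.pathway_id}: model gene(s) missing from matrix: {missing}"
        )
    a = _combine(model, expr_train_z.values, model.genes)
    return pd.Series(a, index=expr_train_z.sample_ids, name=model.pathway_id)


def activity_test(model: PathwayActivityModel, expr_test_z: LabeledMatrix) -> pd.Series:
    """Test activity a_V with the frozen model; absent genes are dropped.

    The denominator is recomputed over the surviving genes so cross-platform
    evaluation degrades gracefully; a pathway with no surviving gene raises.
    """
    present = [g for g in model.genes if g in expr_test_z.values.index]
    if not present:
        raise ProtocolError(
            f"pathway {model.pathway_id}: no model gene present in test matrix"
        )
    if len(present) < len(model.genes):
        logger.warning(
            "pathway %s: %d/%d model genes absent from test matrix; dropped",
            model.pathway_id,
            len(model.genes) - len(present),
            len(model.genes),
        )
    a = _combine(model, expr_test_z.values, present)
    return pd.Series(a, index=expr_test_z.sample_ids, name=model.pathway_id)


def baseline_activity(
    pathway_id: str,
    member_genes: set[str],
    expr_z: LabeledMatrix,
    method: str = "mean",
) -> pd.Series | None:
    """Mean/Median baseline over ALL measured member genes (no p filter)."""
    if method not in ("mean", "median"):
        raise ValueError(f"baseline method must be mean or median, got {method!r}")
    genes = sorted(g for g in member_genes if g in expr_z.values.index)
    if not genes:
        return None
    block = expr_z.values.loc[genes].to_numpy(dtype=float)
    a = block.mean(axis=0) if method == "mean" else np.median(block, axis=0)
    return pd.Series(a, index=expr_z.sample_ids, name=pathway_id)


def pac_activity(
    pathway_id: str,
    member_genes: set[str],
    gene_diff: list[DiffResult],
    expr_train_z: LabeledMatrix,
) -> PathwayActivityModel | None:
    """Greedy CORG search for the most discriminative member-gene subset.

    Genes are ranked by |t|; starting from the top gene, the next-ranked gene
    joins the set iff the |t| of the sign-aligned averaged profile
    (sum sgn(t_i) z_i / sqrt(k)) strictly increases.  The resulting model has
    unit weights, so the activity is exactly that averaged profile.
    """
    from scipy import stats

    by_gene = {r.feature_id: r for r in gene_diff}
    ranked = sorted(
        (g for g in member_genes if g in by_gene and g in expr_train_z.values.index),
        key=lambda g: (-abs(by_gene[g].t_score), g),
    )
    if not ranked:
        return None
    mask_a, mask_b = expr_train_z.group_columns()

    def profile_abs_t(genes: list[str]) -> float:
        signs = np.array([np.sign(by_gene[g].t_score) for g in genes])
        zmat = expr_train_z.values.loc[genes].to_numpy(dtype=float)
        prof = signs @ zmat / np.sqrt(len(genes))
        t, _ = stats.ttest_ind(prof[mask_b], prof[mask_a], equal_var=True)
        return 0.0 if np.isnan(t) else abs(float(t))

    corg = [ranked[0]]
    best = profile_abs_t(corg)
    for g in ranked[1:]:
        cand = profile_abs_t(corg + [g])
        if cand > best:
            corg.append(g)
            best = cand
        else:
            break
    return PathwayActivityModel(
        pathway_id=pathway_id,
        genes=corg,
        weights=np.ones(len(corg)),
        signs=np.array([np.sign(by_gene[g].t_score) for g in corg]),
        method="pac",
    )


def activity_matrix(rows: list[pd.Series], labels: pd.Series) -> LabeledMatrix:
    """Stack per-pathway activity rows into a pathways x samples cohort."""
    if not rows:
        raise ProtocolError("no pathway produced an activity row")
    return LabeledMatrix(values=pd.DataFrame(rows), labels=labels)


def write_models(models: list[PathwayActivityModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([json.loads(m.to_json()) for m in models], fh, indent=1)


def read_models(path: str | Path) -> list[PathwayActivityModel]:
    with open(path, encoding="utf-8") as fh:
        return [PathwayActivityModel.from_json(json.dumps(d)) for d in json.load(fh)]
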
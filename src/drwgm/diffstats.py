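"""Differential statistics and initial walk weights.

Expression and metabolite cohorts are features x samples matrices with a
two-phenotype label per sample.  Genes are scored with a two-tailed
two-sample t-test (pooled variance by default, Welch optional); metabolites
with the two-sided Wilcoxon rank-sum test (exact for small tie-free groups,
normal approximation with continuity correction otherwise).  t statistics
are oriented as second phenotype minus first, phenotypes sorted
lexicographically.

The initial weight vector W0 of the walk combines the gene and metabolite
evidence: gene weights are -log(p), min-max rescaled to [0, 1] over the
measured genes; each differential metabolite (p below ``met_alpha``) gets
weight 1, all others 0; the concatenated vector is L1-normalized with the
ground entry fixed at 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .graph_core import GlobalGraph, GROUND_ID
from .pathway_io import GENE, METABOLITE

logger = logging.getLogger(__name__)

Variant = Literal["drw-gm", "drw-gm-nm", "drw"]

VARIANTS = ("drw-gm", "drw-gm-nm", "drw")


class ProtocolError(ValueError):
    """Cohort violates a protocol precondition (labels, group sizes...)."""


@dataclass
class LabeledMatrix:
    """Features x samples matrix plus a two-phenotype sample labeling."""

    values: pd.DataFrame  # index = feature ids, columns = sample ids
    labels: pd.Series  # index = sample ids, values = phenotype strings

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ProtocolError("duplicate feature ids")
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise ProtocolError(f"samples without labels: {missing[:5]}")
        self.labels = self.labels.loc[self.values.columns]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def phenotypes(self) -> tuple[str, str]:
        levels = sorted(self.labels.unique())
        if len(levels) != 2:
            raise ProtocolError(f"expected 2 phenotypes, found {levels}")
        return levels[0], levels[1]

    def group_columns(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks over sample columns for (first, second) phenotype."""
        a, b = self.phenotypes
        lab = self.labels.to_numpy()
        return lab == a, lab == b

    def subset_samples(self, sample_ids: list[str]) -> "LabeledMatrix":
        return LabeledMatrix(
            values=self.values[sample_ids], labels=self.labels.loc[sample_ids]
        )

    def binary_labels(self) -> np.ndarray:
        """0/1 encoding; the second (sorted) phenotype is the positive class."""
        _, b = self.phenotypes
        return (self.labels.to_numpy() == b).astype(int)


@dataclass(frozen=True)
class DiffResult:
    feature_id: str
    t_score: float
    p_value: float
    test: str  # "t" or "wilcoxon"


def read_labeled_matrix(values_path: str | Path, labels_path: str | Path) -> LabeledMatrix:
    """Read a features-x-samples TSV plus a sample_id<TAB>phenotype file."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    labels = pd.read_csv(
        labels_path, sep="\t", index_col=0, header=None, names=["sample", "phenotype"]
    )["phenotype"]
    return LabeledMatrix(values=values, labels=labels)


def write_labeled_matrix(
    m: LabeledMatrix, values_path: str | Path, labels_path: str | Path | None = None
) -> None:
    m.values.to_csv(values_path, sep="\t")
    if labels_path is not None:
        m.labels.to_csv(labels_path, sep="\t", header=False)


def z_normalize(m: LabeledMatrix) -> LabeledMatrix:
    """Per-feature z-scores over all samples (mean 0, sd 1, n-1 denominator).

    Zero-variance features become all-zero rows with a logged warning.
    """
    vals = m.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning(
            "%d zero-variance feature(s) set to all-zeros: %s",
            flat.sum(),
            list(m.values.index[flat][:5]),
        )
        sd[flat] = 1.0
    z = (vals - mu) / sd
    z[flat.nonzero()[0], :] = 0.0
    return LabeledMatrix(
        values=pd.DataFrame(z, index=m.values.index, columns=m.values.columns),
        labels=m.labels,
    )


def _check_group_sizes(m: LabeledMatrix) -> tuple[np.ndarray, np.ndarray]:
    mask_a, mask_b = m.group_columns()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ProtocolError(
            f"need >=2 samples per phenotype, got {mask_a.sum()} and {mask_b.sum()}"
        )
    return mask_a, mask_b


def gene_ttests(expr: LabeledMatrix, welch: bool = False) -> list[DiffResult]:
    """Two-tailed two-sample t-test per gene, oriented second-minus-first.

    Pooled-variance Student t by default; ``welch=True`` drops the
    equal-variance assumption.  Degenerate rows (both groups constant and
    equal) report t=0, p=1.
    """
    mask_a, mask_b = _check_group_sizes(expr)
    vals = expr.values.to_numpy(dtype=float)
    a = vals[:, mask_a]
    b = vals[:, mask_b]
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(b, a, axis=1, equal_var=not welch)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    return [
        DiffResult(feature_id=f, t_score=float(ti), p_value=float(pi), test="t")
        for f, ti, pi in zip(expr.feature_ids, t, p)
    ]


_EXACT_MAX_N = 25


def metabolite_tests(met: LabeledMatrix) -> list[DiffResult]:
    """Two-sided Wilcoxon rank-sum test per metabolite.

    Exact null distribution when both groups have <= 25 samples and the
    row has no ties; otherwise the normal approximation with continuity
    correction.  The sign of the reported statistic follows the rank-biserial
    direction (second phenotype minus first).
    """
    mask_a, mask_b = _check_group_sizes(met)
    vals = met.values.to_numpy(dtype=float)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    results = []
    for f, row in zip(met.feature_ids, vals):
        a, b = row[mask_a], row[mask_b]
        exact = (
            na <= _EXACT_MAX_N
            and nb <= _EXACT_MAX_N
            and len(np.unique(row)) == len(row)
        )
        res = stats.mannwhitneyu(
            b, a, alternative="two-sided",
            method="exact" if exact else "asymptotic",
            use_continuity=True,
        )
        # rank-biserial direction: U_b - n_a*n_b/2 positive when b ranks higher
        direction = float(res.statistic) - na * nb / 2.0
        results.append(
            DiffResult(
                feature_id=f,
                t_score=direction,
                p_value=float(min(res.pvalue, 1.0)),
                test="wilcoxon",
            )
        )
    return results


def diff_results_to_frame(results: list[DiffResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature_id, r.t_score, r.p_value, r.test) for r in results],
        columns=["feature_id", "t_score", "p_value", "test"],
    ).set_index("feature_id")


def initial_weights(
    graph: GlobalGraph,
    gene_diff: list[DiffResult],
    met_diff: list[DiffResult] | None = None,
    variant: Variant = "drw-gm",
    met_alpha: float = 0.01,
    metabolite_weighting: Literal["cutoff", "pvalue"] = "cutoff",
) -> pd.Series:
    """Build the L1-normalized initial weight vector W0 over the node order.

    Gene weights are -log(p) min-max rescaled over the measured graph genes;
    metabolite weights are the 0/1 differential indicator at ``met_alpha``
    (or, with ``metabolite_weighting='pvalue'``, rescaled -log(p) like the
    genes).  Variants ``drw-gm-nm`` and ``drw`` zero all metabolite weights.
    Nodes absent from the profiles get weight 0; the ground entry is 0.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    order = graph.node_order
    w = pd.Series(0.0, index=order)

    gene_p = {r.feature_id: r.p_value for r in gene_diff}
    graph_genes = [n for n in order if graph.node_kind(n) == GENE and n in gene_p]
    if not graph_genes:
        raise ProtocolError("no measured gene maps onto the graph")
    logp = np.array([-np.log(max(gene_p[g], 1e-300)) for g in graph_genes])
    span = logp.max() - logp.min()
    if span == 0:
        logger.warning("all gene p-values equal; uniform gene weights used")
        rescaled = np.ones_like(logp)
    else:
        rescaled = (logp - logp.min()) / span
    w[graph_genes] = rescaled

    if variant == "drw-gm" and met_diff:
        met_p = {r.feature_id: r.p_value for r in met_diff}
        graph_mets = [
            n for n in order if graph.node_kind(n) == METABOLITE and n in met_p
        ]
        if metabolite_weighting == "cutoff":
            for m in graph_mets:
                w[m] = 1.0 if met_p[m] < met_alpha else 0.0
        else:
            mlogp = np.array([-np.log(max(met_p[m], 1e-300)) for m in graph_mets])
            mspan = mlogp.max() - mlogp.min()
            w[graph_mets] = (
                np.ones_like(mlogp) if mspan == 0 else (mlogp - mlogp.min()) / mspan
            )

    w[GROUND_ID] = 0.0
    total = w.sum()
    if total == 0:
        raise ProtocolError("all initial weights are zero; nothing to walk from")
    return w / total
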
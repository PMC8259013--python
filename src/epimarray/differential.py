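"""Differential methylation / expression calling between phenotype groups.

A transcript is differentially methylated (or expressed) between two
groups when its fold change (condition mean over reference mean, linear
scale) is >= 1.5 or <= 0.7 AND a two-tailed pooled-variance Student's
t-test gives P < 0.05.  The FC boundaries are inclusive, the alpha strict,
matching the filtering convention of epitranscriptomic array studies.  No
multiple-testing correction enters the calls; a Benjamini-Hochberg column
is emitted for information only.

Methylation tests run on linear % modification values and expression tests
on linear abundance by default (``log2_expression=True`` switches the
expression test to the log2 scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MEASURES = ("methylation", "expression")

#: Direction labels per measure: (increase, decrease).
CALL_LABELS = {"methylation": ("hyper", "hypo"), "expression": ("up", "down")}

#: Floor for a reference-group mean of exactly zero, keeping FC finite.
MEAN_EPSILON = 1e-6


@dataclass(frozen=True)
class Thresholds:
    fc_up: float = 1.5
    fc_down: float = 0.7
    alpha: float = 0.05

    def __post_init__(self):
        if not self.fc_up > 1:
            raise ValueError("fc_up must exceed 1")
        if not 0 < self.fc_down < 1:
            raise ValueError("fc_down must lie in (0,1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class Comparison:
    """condition vs reference, e.g. Comparison("M1-L", "M0-L")."""

    condition: str
    reference: str

    def __post_init__(self):
        if self.condition == self.reference:
            raise ValueError("condition and reference groups must differ")

    @property
    def name(self) -> str:
        return f"{self.condition} vs {self.reference}"

    @property
    def slug(self) -> str:
        return f"{self.condition}_vs_{self.reference}".replace(" ", "")


def fold_change(values_condition, values_reference, epsilon: float = MEAN_EPSILON) -> float:
    """Linear fold change: mean(condition) / max(mean(reference), epsilon)."""
    a = np.asarray(values_condition, dtype=float)
    b = np.asarray(values_reference, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("fold_change requires at least one value per group")
    denom = b.mean()
    if denom < epsilon:
        logger.warning("reference mean %g floored to epsilon=%g", denom, epsilon)
        denom = epsilon
    return float(a.mean() / denom)


def student_t(values_a, values_b) -> float:
    """Two-tailed pooled-variance (equal-variance) Student's t-test P value.

    df = n_a + n_b - 2.  Degenerate zero-pooled-variance groups give p = 1
    when the means agree and the smallest positive float otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("student_t requires at least two values per group")
    t, p = _pooled_t(a.mean(), b.mean(), a.var(ddof=1), b.var(ddof=1), a.size, b.size)
    return float(p)


def _pooled_t(mean_a, mean_b, var_a, var_b, n_a, n_b):
    """Vectorized pooled two-sample t statistic and two-tailed P."""
    df = n_a + n_b - 2
    pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
    se = np.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    diff = np.asarray(mean_a - mean_b, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero pooled variance: identical means -> p=1; separated means -> p->0+
    degenerate = np.asarray(se == 0)
    if degenerate.any():
        n_sep = int((degenerate & (diff != 0)).sum())
        if n_sep:
            logger.warning("%d zero-variance tests with unequal means flagged p->0+", n_sep)
        p = np.where(degenerate, np.where(diff == 0, 1.0, np.nextafter(0.0, 1.0)), p)
        t = np.where(degenerate, np.where(diff == 0, 0.0, np.copysign(np.inf, diff)), t)
    return t, p


def call_differential(fc: float, p: float, thresholds: Thresholds = DEFAULT_THRESHOLDS,
                      measure: str = "methylation") -> str:
    """hyper/up iff fc >= fc_up and p < alpha; hypo/down iff fc <= fc_down
    and p < alpha; otherwise none.  Boundary FCs are inclusive."""
    up_label, down_label = CALL_LABELS[measure]
    if p < thresholds.alpha:
        if fc >= thresholds.fc_up:
            return up_label
        if fc <= thresholds.fc_down:
            return down_label
    return "none"


def run_comparison(quantified, comparison: Comparison, measure: str,
                   thresholds: Thresholds = DEFAULT_THRESHOLDS,
                   annotation: pd.DataFrame | None = None,
                   log2_expression: bool = False) -> pd.DataFrame:
    """One DifferentialRecord per transcript for one comparison and measure.

    ``quantified`` is a QuantifiedSet; spike-in probes are excluded.  The
    returned frame has columns transcript_id, gene_symbol, rna_class,
    mean_condition, mean_reference, fc, p, fdr_info, call.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    matrix = quantified.methylation if measure == "methylation" else quantified.expression
    matrix = matrix.loc[quantified.transcript_ids]
    samples = quantified.samples
    cols = {}
    for role, group in (("condition", comparison.condition), ("reference", comparison.reference)):
        ids = samples.loc[samples["group"] == group, "sample_id"].tolist()
        if len(ids) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 replicates")
        cols[role] = matrix[ids].to_numpy(dtype=float)
    cond, ref = cols["condition"], cols["reference"]

    mean_c, mean_r = cond.mean(axis=1), ref.mean(axis=1)
    denom = np.maximum(mean_r, MEAN_EPSILON)
    n_floored = int((mean_r < MEAN_EPSILON).sum())
    if n_floored:
        logger.warning("%d reference means floored to epsilon in %s/%s",
                       n_floored, comparison.name, measure)
    fc = mean_c / denom

    test_c, test_r = (np.log2(np.maximum(cond, MEAN_EPSILON)),
                      np.log2(np.maximum(ref, MEAN_EPSILON))) \
        if (measure == "expression" and log2_expression) else (cond, ref)
    _, p = _pooled_t(test_c.mean(axis=1), test_r.mean(axis=1),
                     test_c.var(axis=1, ddof=1), test_r.var(axis=1, ddof=1),
                     test_c.shape[1], test_r.shape[1])

    up_label, down_label = CALL_LABELS[measure]
    sig = p < thresholds.alpha
    call = np.where(sig & (fc >= thresholds.fc_up), up_label,
                    np.where(sig & (fc <= thresholds.fc_down), down_label, "none"))

    out = pd.DataFrame({
        "transcript_id": matrix.index,
        "mean_condition": mean_c,
        "mean_reference": mean_r,
        "fc": fc,
        "p": p,
        "fdr_info": multipletests(p, method="fdr_bh")[1],
        "call": call,
    })
    if annotation is not None:
        ann = annotation.set_index("transcript_id")[["gene_symbol", "rna_class"]]
        out.insert(1, "gene_symbol", ann.reindex(out["transcript_id"])["gene_symbol"].to_numpy())
        out.insert(2, "rna_class", ann.reindex(out["transcript_id"])["rna_class"].to_numpy())
    else:
        out.insert(1, "gene_symbol", out["transcript_id"])
        out.insert(2, "rna_class", "unknown")
    out.attrs["comparison"] = comparison.name
    out.attrs["measure"] = measure
    return out


def summarize_calls(records: pd.DataFrame) -> dict:
    """Per-RNA-class directional counts, Fig-2A style."""
    measure = records.attrs.get("measure", "methylation")
    up_label, down_label = CALL_LABELS[measure]
    summary = {}
    for cls, sub in records.groupby("rna_class"):
        n_up = int((sub["call"] == up_label).sum())
        n_down = int((sub["call"] == down_label).sum())
        summary[cls] = {up_label: n_up, down_label: n_down, "total": n_up + n_down}
    return summary


def _tree_to_nested(linkage_matrix: np.ndarray, n_leaves: int):
    """Serialize a scipy linkage as nested lists [left, right, height]
    (iterative; leaf = index)."""
    nodes: dict[int, object] = {i: i for i in range(n_leaves)}
    for i, (a, b, h, _) in enumerate(linkage_matrix):
        nodes[n_leaves + i] = [nodes[int(a)], nodes[int(b)], float(h)]
    return nodes[n_leaves + len(linkage_matrix) - 1] if len(linkage_matrix) else nodes.get(0)


def hierarchical_cluster(matrix: pd.DataFrame, metric: str = "euclidean",
                         method: str = "average") -> dict:
    """Agglomerative clustering of rows (transcripts) and columns (samples).

    Euclidean distance with average linkage by default; output is
    deterministic given the input ordering.  Returns, per axis, the leaf
    order (labels), merge heights, and the merge tree as nested lists.
    """
    result = {}
    for axis, data, labels in (("rows", matrix.to_numpy(dtype=float), list(matrix.index)),
                               ("cols", matrix.to_numpy(dtype=float).T, list(matrix.columns))):
        if data.shape[0] < 2:
            result[axis] = {"order": labels, "heights": [], "tree": 0 if labels else None,
                            "labels": labels}
            continue
        link = hierarchy.linkage(data, method=method, metric=metric)
        order = hierarchy.leaves_list(link)
        result[axis] = {
            "order": [labels[i] for i in order],
            "heights": [float(h) for h in link[:, 2]],
            "tree": _tree_to_nested(link, data.shape[0]),
            "labels": labels,
        }
    result["metric"] = metric
    result["method"] = method
    return result


def cut_clusters(matrix: pd.DataFrame, k: int, axis: str = "cols",
                 metric: str = "euclidean", method: str = "average") -> dict:
    """Flat cluster labels at the k-cluster cut (axis 'rows' or 'cols')."""
    data = matrix.to_numpy(dtype=float)
    labels = list(matrix.index) if axis == "rows" else list(matrix.columns)
    if axis == "cols":
        data = data.T
    link = hierarchy.linkage(data, method=method, metric=metric)
    flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return dict(zip(labels, (int(c) for c in flat)))
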
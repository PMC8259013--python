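"""Joint methylation x expression quadrants and cross-comparison concordance.

A transcript differentially methylated (hyper/hypo) AND differentially
expressed (up/down) in the same comparison falls into one of four
quadrants — Hyper-Up, Hyper-Down, Hypo-Up, Hypo-Down — and is otherwise
"unassociated".  Concordance between two comparisons tallies the 4x4
quadrant-pair contingency over transcripts assigned in both; "negatively
correlated" transcripts are those in fully opposite quadrants (both the
methylation and the expression direction flip).

Reported percentages use one-decimal round-half-up to match the usual
rendering of such studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

QUADRANTS = ("Hyper-Up", "Hyper-Down", "Hypo-Up", "Hypo-Down")
UNASSOCIATED = "unassociated"

_OPPOSITE = {"Hyper-Up": "Hypo-Down", "Hypo-Down": "Hyper-Up",
             "Hyper-Down": "Hypo-Up", "Hypo-Up": "Hyper-Down"}


def round_pct(value: float, ndigits: int = 1) -> float:
    """Round-half-up to ``ndigits`` decimals (65.75 -> 65.8)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def quadrant_of(meth_call: str, expr_call: str) -> str:
    if meth_call in ("hyper", "hypo") and expr_call in ("up", "down"):
        return f"{meth_call.capitalize()}-{expr_call.capitalize()}"
    return UNASSOCIATED


def opposite_quadrant(quadrant: str) -> str:
    """Fully opposite quadrant (both directions flip); an involution."""
    if quadrant not in _OPPOSITE:
        raise ValueError(f"no opposite for {quadrant!r}")
    return _OPPOSITE[quadrant]


def assign_quadrants(meth_records: pd.DataFrame, expr_records: pd.DataFrame,
                     comparison_name: str | None = None) -> pd.DataFrame:
    """Cross methylation and expression calls into quadrants per transcript.

    Both record frames must cover the same transcript universe and the
    same comparison.  Returns a frame with transcript_id, gene_symbol,
    rna_class, meth_call, expr_call, quadrant; per-class quadrant counts
    live in ``.attrs['counts']``.
    """
    cm = meth_records.attrs.get("comparison")
    ce = expr_records.attrs.get("comparison")
    if cm is not None and ce is not None and cm != ce:
        raise ValueError(f"comparison mismatch: {cm!r} vs {ce!r}")
    if set(meth_records["transcript_id"]) != set(expr_records["transcript_id"]):
        raise ValueError("methylation and expression records cover different transcripts")

    merged = meth_records[["transcript_id", "gene_symbol", "rna_class", "call"]].merge(
        expr_records[["transcript_id", "call"]], on="transcript_id",
        suffixes=("_meth", "_expr"))
    merged = merged.rename(columns={"call_meth": "meth_call", "call_expr": "expr_call"})
    merged["quadrant"] = [quadrant_of(m, e)
                          for m, e in zip(merged["meth_call"], merged["expr_call"])]
    merged.attrs["comparison"] = comparison_name or cm or ce
    counts = {}
    for cls, sub in merged.groupby("rna_class"):
        counts[cls] = {q: int((sub["quadrant"] == q).sum())
                       for q in QUADRANTS + (UNASSOCIATED,)}
    merged.attrs["counts"] = counts
    return merged


@dataclass
class ConcordanceReport:
    """4x4 quadrant-pair contingency between two comparisons."""

    comparison_a: str
    comparison_b: str
    table: pd.DataFrame                      # rows: quadrant in A, cols: in B
    n_both: int
    n_opposite: int
    per_quadrant: dict = field(default_factory=dict)

    @property
    def fraction_opposite(self) -> float:
        if self.n_both == 0:
            logger.warning("concordance %s / %s: no shared assigned transcripts",
                           self.comparison_a, self.comparison_b)
            return float("nan")
        return self.n_opposite / self.n_both


def concordance(assignments_a: pd.DataFrame, assignments_b: pd.DataFrame) -> ConcordanceReport:
    """Quadrant-pair contingency over transcripts assigned in both
    comparisons, plus per-quadrant opposite fractions."""
    if assignments_a.empty or assignments_b.empty:
        raise ValueError("both assignment sets must be nonempty")
    a = assignments_a.loc[assignments_a["quadrant"] != UNASSOCIATED,
                          ["transcript_id", "quadrant"]]
    b = assignments_b.loc[assignments_b["quadrant"] != UNASSOCIATED,
                          ["transcript_id", "quadrant"]]
    joined = a.merge(b, on="transcript_id", suffixes=("_a", "_b"))
    table = pd.DataFrame(0, index=list(QUADRANTS), columns=list(QUADRANTS))
    for qa, qb in zip(joined["quadrant_a"], joined["quadrant_b"]):
        table.loc[qa, qb] += 1
    n_both = int(table.to_numpy().sum())
    n_opposite = int(sum(table.loc[q, opposite_quadrant(q)] for q in QUADRANTS))
    per_quadrant = {}
    for q in QUADRANTS:
        row = int(table.loc[q].sum())
        per_quadrant[q] = {
            "n": row,
            "n_opposite": int(table.loc[q, opposite_quadrant(q)]),
            "fraction_opposite": (table.loc[q, opposite_quadrant(q)] / row
                                  if row else float("nan")),
        }
    return ConcordanceReport(
        comparison_a=assignments_a.attrs.get("comparison", "A"),
        comparison_b=assignments_b.attrs.get("comparison", "B"),
        table=table, n_both=n_both, n_opposite=n_opposite,
        per_quadrant=per_quadrant)


def directional_report(n_first: int, n_second: int, labels=("hyper", "hypo")) -> dict:
    """Total and one-decimal percentages from two directional counts.

    With (543 hyper, 1045 hypo) the total is 1588 and pct_hypo 65.8.  A
    zero total flags the percentages as undefined (None).
    """
    total = n_first + n_second
    out = {labels[0]: n_first, labels[1]: n_second, "total": total}
    if total:
        out[f"pct_{labels[0]}"] = round_pct(100.0 * n_first / total)
        out[f"pct_{labels[1]}"] = round_pct(100.0 * n_second / total)
    else:
        out[f"pct_{labels[0]}"] = out[f"pct_{labels[1]}"] = None
        out["undefined"] = True
    return out


def report_counts(differential_summaries: dict, quadrant_counts: dict | None = None) -> dict:
    """Paper-style headline count report.

    ``differential_summaries`` maps comparison -> measure -> rna_class ->
    {direction: count} (as produced by ``differential.summarize_calls``);
    ``quadrant_counts`` maps comparison -> rna_class -> {quadrant: count}.
    Emits totals, directional percentages (one decimal, round-half-up) and
    m6A-associated totals per expression direction.
    """
    report: dict = {}
    for comparison, measures in differential_summaries.items():
        entry: dict = {}
        for measure, classes in measures.items():
            labels = ("hyper", "hypo") if measure == "methylation" else ("up", "down")
            per_class = {
                cls: directional_report(counts.get(labels[0], 0),
                                        counts.get(labels[1], 0), labels)
                for cls, counts in classes.items()
            }
            all_first = sum(c.get(labels[0], 0) for c in classes.values())
            all_second = sum(c.get(labels[1], 0) for c in classes.values())
            per_class["all"] = directional_report(all_first, all_second, labels)
            entry[measure] = per_class
        if quadrant_counts and comparison in quadrant_counts:
            qc = quadrant_counts[comparison]
            entry["quadrants"] = qc
            merged = {q: sum(cls.get(q, 0) for cls in qc.values())
                      for q in QUADRANTS + (UNASSOCIATED,)}
            entry["m6a_associated"] = {
                "up": merged["Hyper-Up"] + merged["Hypo-Up"],
                "down": merged["Hyper-Down"] + merged["Hypo-Down"],
                "total": sum(merged[q] for q in QUADRANTS),
            }
        report[comparison] = entry
    return report
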
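"""qPCR validation arithmetic: MeRIP percent-input and 2^-ddCt.

MeRIP-qPCR enrichment is expressed relative to the dilution-adjusted
input: with a fraction ``f`` of material reserved as input, the adjusted
input Ct is ``ct_input - log2(1/f)`` and

    percent_input = 100 * 2 ** (adjusted_input_ct - ct_ip).

Relative expression uses the 2^-ddCt method against a reference gene
(e.g. GAPDH): dCt = ct_target - ct_ref per condition, ddCt =
dCt_treated - dCt_control, fold = 2^-ddCt.  Replicate statistics (SEM,
pooled two-tailed Student's t) are computed on the dCt scale, where
values are closest to normal; folds are reported as transformed means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import student_t

logger = logging.getLogger(__name__)

DEFAULT_INPUT_FRACTION = 0.1


def percent_input(ct_ip, ct_input, input_fraction: float = DEFAULT_INPUT_FRACTION):
    """MeRIP enrichment as % of dilution-adjusted input."""
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must lie in (0, 1]")
    ct_ip = np.asarray(ct_ip, dtype=float)
    ct_input = np.asarray(ct_input, dtype=float)
    adjusted = ct_input - np.log2(1.0 / input_fraction)
    out = 100.0 * np.exp2(adjusted - ct_ip)
    return float(out) if out.ndim == 0 else out


@dataclass
class DdctResult:
    fold: float            # 2^-ddCt from group-mean dCts
    ddct: float
    dct_treated: np.ndarray
    dct_control: np.ndarray
    sem_treated: float     # SEM of dCt (sample sd / sqrt(n))
    sem_control: float
    p: float | None        # pooled t on dCt values (None below 2 reps/group)

    @property
    def replicate_folds(self) -> np.ndarray:
        """Per-replicate folds 2^-(dCt_treated_i - mean dCt_control)."""
        return np.exp2(-(self.dct_treated - self.dct_control.mean()))


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))


def ddct(ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control) -> DdctResult:
    """2^-ddCt relative expression of treated vs control.

    Accepts scalars or per-replicate arrays; target and reference Cts are
    paired by position within each condition.
    """
    dct_t = np.atleast_1d(np.asarray(ct_target_treated, dtype=float)
                          - np.asarray(ct_ref_treated, dtype=float))
    dct_c = np.atleast_1d(np.asarray(ct_target_control, dtype=float)
                          - np.asarray(ct_ref_control, dtype=float))
    if not (np.isfinite(dct_t).all() and np.isfinite(dct_c).all()):
        raise ValueError("all Ct values must be finite")
    dd = float(dct_t.mean() - dct_c.mean())
    p = student_t(dct_t, dct_c) if dct_t.size >= 2 and dct_c.size >= 2 else None
    return DdctResult(fold=float(2.0 ** -dd), ddct=dd,
                      dct_treated=dct_t, dct_control=dct_c,
                      sem_treated=_sem(dct_t), sem_control=_sem(dct_c), p=p)


def group_compare(values_a, values_b, alpha: float = 0.05) -> dict:
    """mean +/- SEM per group and a pooled two-tailed Student's t P value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    p = student_t(a, b)
    return {"mean_a": float(a.mean()), "sem_a": _sem(a),
            "mean_b": float(b.mean()), "sem_b": _sem(b),
            "p": p, "significant": p < alpha}


def analyze_ct_table(ct_table: pd.DataFrame, condition: str, reference: str,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Full validation analysis of a Ct table for one comparison.

    Expression targets (cdna tube) are quantified by 2^-ddCt against the
    reference gene; MeRIP targets (input/ip tubes) by percent-input, with
    the percent values compared between groups.  One row per target and
    assay with mean_fold or mean percent, SEM and P.
    """
    rows = []
    cdna = ct_table[ct_table["tube"] == "cdna"]
    ref_gene = cdna.loc[cdna["is_reference"], "target"].unique()
    if cdna.shape[0] and ref_gene.size == 0:
        raise ValueError("no reference gene in cdna records")

    def cts(sub, group, target):
        part = sub[(sub["group"] == group) & (sub["target"] == target)]
        return part.sort_values("sample_id")["ct"].to_numpy()

    for target in sorted(cdna.loc[~cdna["is_reference"], "target"].unique()):
        res = ddct(cts(cdna, condition, target), cts(cdna, condition, ref_gene[0]),
                   cts(cdna, reference, target), cts(cdna, reference, ref_gene[0]))
        rows.append({"target": target, "assay": "expression",
                     "comparison": f"{condition} vs {reference}",
                     "value": res.fold, "sem": res.sem_treated, "p": res.p,
                     "significant": res.p is not None and res.p < alpha})

    ip = ct_table[ct_table["tube"] == "ip"]
    inp = ct_table[ct_table["tube"] == "input"]
    for target in sorted(ip["target"].unique()):
        pct = {}
        for group in (condition, reference):
            sub_ip = ip[(ip["group"] == group) & (ip["target"] == target)].sort_values("sample_id")
            sub_in = inp[(inp["group"] == group) & (inp["target"] == target)].sort_values("sample_id")
            frac = float(sub_ip["input_fraction"].iloc[0])
            pct[group] = percent_input(sub_ip["ct"].to_numpy(), sub_in["ct"].to_numpy(), frac)
        stats = group_compare(pct[condition], pct[reference], alpha=alpha)
        rows.append({"target": target, "assay": "merip_percent_input",
                     "comparison": f"{condition} vs {reference}",
                     "value": stats["mean_a"], "sem": stats["sem_a"],
                     "p": stats["p"], "significant": stats["significant"]})
    return pd.DataFrame(rows)
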
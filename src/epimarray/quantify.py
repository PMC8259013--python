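"""Spike-in normalization and per-transcript quantification.

Two-color m6A epitranscriptomic arrays hybridize the immunoprecipitated
(IP, Cy5) and supernatant (SUP, Cy3) fractions of the same sample.  Both
channels carry an exogenous spike-in control mixture of known composition,
so the mean log2 spike-in intensity of an array/channel captures its
scaling and anchors normalization.  From the normalized linear intensities
the methylation level of a transcript is the percentage of modification,
100 * IP / (IP + SUP), and its expression level is the channel sum (total
RNA = modified + unmodified) or, optionally, the supernatant alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Linear-intensity floor applied at load time so log2 is always defined.
DEFAULT_INTENSITY_FLOOR = 1.0

EXPRESSION_MODES = ("total", "supernatant")


@dataclass
class TwoChannelArraySet:
    """Paired IP/supernatant intensity matrices with sample metadata.

    ``ip`` and ``sup`` are probes x samples DataFrames on the linear scale
    sharing identical row and column orderings; ``samples`` is the sample
    sheet (sample_id, group, replicate); ``spikein_ids`` the probe ids of
    the spike-in controls.
    """

    ip: pd.DataFrame
    sup: pd.DataFrame
    samples: pd.DataFrame
    spikein_ids: frozenset

    def __post_init__(self) -> None:
        self.spikein_ids = frozenset(self.spikein_ids)
        if not self.ip.index.equals(self.sup.index):
            raise ValueError("IP and supernatant matrices have different probe orderings")
        if not self.ip.columns.equals(self.sup.columns):
            raise ValueError("IP and supernatant matrices have different sample orderings")
        if self.ip.index.has_duplicates:
            dupes = self.ip.index[self.ip.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated probe id(s): {dupes}")
        known = set(self.samples["sample_id"])
        missing = [s for s in self.ip.columns if s not in known]
        if missing:
            raise ValueError(f"sample(s) absent from sample sheet: {missing}")
        if not self.spikein_ids:
            raise ValueError("spike-in id set is empty; normalization is impossible")
        absent = self.spikein_ids - set(self.ip.index)
        if absent:
            raise ValueError(f"spike-in id(s) not present in matrices: {sorted(absent)}")
        if (self.ip.to_numpy() < 0).any() or (self.sup.to_numpy() < 0).any():
            raise ValueError("negative intensities; apply flooring at load time")

    @property
    def transcript_ids(self) -> pd.Index:
        """Probe ids excluding spike-in controls, in matrix order."""
        return self.ip.index[~self.ip.index.isin(self.spikein_ids)]


@dataclass
class QuantifiedSet:
    """Normalized intensities plus derived methylation and expression."""

    norm_ip: pd.DataFrame
    norm_sup: pd.DataFrame
    methylation: pd.DataFrame            # % modification in [0, 100]
    expression: pd.DataFrame             # linear abundance
    normalization_factors: pd.DataFrame  # per sample x channel
    expression_mode: str
    samples: pd.DataFrame
    spikein_ids: frozenset = field(default_factory=frozenset)

    @property
    def transcript_ids(self) -> pd.Index:
        return self.methylation.index[~self.methylation.index.isin(self.spikein_ids)]


def spikein_normalize(arrays: TwoChannelArraySet):
    """Normalize both channels with an average of log2-scaled spike-ins.

    For sample ``s`` and channel ``c`` let ``f(s,c)`` be the mean log2
    intensity of the spike-in probes.  Each probe's log2 intensity becomes
    ``log2(x) - f(s,c) + Fbar`` with ``Fbar`` the grand mean of ``f`` over
    all samples and channels; recentring by ``Fbar`` keeps values on an
    intensity-like scale.  After normalization every array/channel has the
    identical spike-in mean ``Fbar``.

    Returns ``(norm_ip, norm_sup, factors)`` with linear-scale matrices and
    a factors table (sample, channel, mean_log2_spikein, offset).
    """
    spikes = sorted(arrays.spikein_ids)
    rows = []
    logs = {}
    for channel, mat in (("IP", arrays.ip), ("SUP", arrays.sup)):
        sub = mat.loc[spikes]
        if (sub.to_numpy() <= 0).any():
            raise ValueError(f"nonpositive spike-in intensity in {channel} channel")
        logs[channel] = np.log2(mat.to_numpy(dtype=float))
        rows.append(pd.DataFrame({
            "sample_id": mat.columns,
            "channel": channel,
            "mean_log2_spikein": np.log2(sub.to_numpy(dtype=float)).mean(axis=0),
        }))
    factors = pd.concat(rows, ignore_index=True)
    grand_mean = factors["mean_log2_spikein"].mean()
    factors["offset"] = grand_mean - factors["mean_log2_spikein"]

    out = {}
    for channel, mat in (("IP", arrays.ip), ("SUP", arrays.sup)):
        off = factors.loc[factors["channel"] == channel, "offset"].to_numpy()
        norm = np.exp2(logs[channel] + off[np.newaxis, :])
        out[channel] = pd.DataFrame(norm, index=mat.index, columns=mat.columns)
    return out["IP"], out["SUP"], factors


def percent_modification(norm_ip: pd.DataFrame, norm_sup: pd.DataFrame) -> pd.DataFrame:
    """% modification = 100 * IP / (IP + SUP), element-wise.

    Entries where both channels are zero are defined as 0 and counted in a
    log message.
    """
    if norm_ip.shape != norm_sup.shape:
        raise ValueError("shape mismatch between IP and supernatant matrices")
    ip = norm_ip.to_numpy(dtype=float)
    sup = norm_sup.to_numpy(dtype=float)
    if (ip < 0).any() or (sup < 0).any():
        raise ValueError("negative normalized intensities")
    total = ip + sup
    both_zero = total == 0
    if both_zero.any():
        logger.warning("percent_modification: %d entries with IP+SUP == 0 set to 0",
                       int(both_zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(both_zero, 0.0, 100.0 * ip / np.where(both_zero, 1.0, total))
    return pd.DataFrame(m, index=norm_ip.index, columns=norm_ip.columns)


def expression_level(norm_ip: pd.DataFrame, norm_sup: pd.DataFrame,
                     mode: str = "total") -> pd.DataFrame:
    """Expression per transcript/sample: channel sum ("total") or Cy3 alone
    ("supernatant")."""
    if norm_ip.shape != norm_sup.shape:
        raise ValueError("shape mismatch between IP and supernatant matrices")
    if mode == "total":
        return norm_ip + norm_sup
    if mode == "supernatant":
        return norm_sup.copy()
    raise ValueError(f"unknown expression mode {mode!r}; expected one of {EXPRESSION_MODES}")


def quantify(arrays: TwoChannelArraySet, expression_mode: str = "total") -> QuantifiedSet:
    """Run spike-in normalization, % modification and expression in one step."""
    if expression_mode not in EXPRESSION_MODES:
        raise ValueError(f"unknown expression mode {expression_mode!r}")
    norm_ip, norm_sup, factors = spikein_normalize(arrays)
    meth = percent_modification(norm_ip, norm_sup)
    expr = expression_level(norm_ip, norm_sup, mode=expression_mode)
    return QuantifiedSet(
        norm_ip=norm_ip,
        norm_sup=norm_sup,
        methylation=meth,
        expression=expr,
        normalization_factors=factors,
        expression_mode=expression_mode,
        samples=arrays.samples.copy(),
        spikein_ids=arrays.spikein_ids,
    )


def floor_intensities(mat: pd.DataFrame, floor: float = DEFAULT_INTENSITY_FLOOR) -> pd.DataFrame:
    """Clip intensities below ``floor`` (log2 must be defined); logs the count."""
    n_low = int((mat.to_numpy() < floor).sum())
    if n_low:
        logger.warning("floored %d intensities below %g", n_low, floor)
    return mat.clip(lower=floor)
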
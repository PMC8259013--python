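"""Seeded in-silico m6A two-channel microarray datasets with known truth.

Emulates, at reduced scale, a rat mRNA + lncRNA epitranscriptomic array
design: probes for mRNAs, lncRNAs and spike-in controls, three microglial
phenotype groups (resting M0-L, pro-inflammatory M1-L, anti-inflammatory
M2-L) with replicates, per-array/channel scaling captured by spike-ins,
and planted hyper-/hypo-methylation and up-/down-regulation effects.

Generative model, per transcript ``t`` and sample ``s`` in group ``g``::

    A_ts  = 2 ** (baseline_t + expression_shift(t, g))          # abundance
    m_tg  = logistic(logit(m0_t) + methylation_shift(t, g))     # fraction
    IP_ts  = A_ts * m_tg       * 2**(array_effect(s, IP)  + eps_ip)
    SUP_ts = A_ts * (1 - m_tg) * 2**(array_effect(s, SUP) + eps_sup)

with iid per-channel measurement noise ``eps ~ N(0, noise_log2_sd**2)``
(multiplicative log-normal, the standard microarray error model) and an
array effect shared by every probe of one sample/channel — spike-ins
included, which is exactly what makes spike-in normalization identifiable.
Spike-in probes have fixed known abundance and appear in both channels.

The genome layout places coding genes (>= 2 exons) on synthetic
chromosomes and lncRNAs so that every genomic context class — intergenic,
exon-overlap, intron-overlap, natural antisense, intronic antisense,
bidirectional — is realized.  All randomness flows from one seed through
per-stage child streams, so partial runs are reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .cis_lnc import GeneModel
from .quantify import TwoChannelArraySet

logger = logging.getLogger(__name__)

DEFAULT_GROUPS = ("M0-L", "M1-L", "M2-L")

CONTEXT_CLASSES = (
    "exon-overlap",
    "intron-overlap",
    "natural-antisense",
    "intronic-antisense",
    "bidirectional",
    "intergenic",
)

EFFECT_KINDS = ("methylation_shift", "expression_shift")

# genome layout constants (bp)
_GENE_SPAN = 10_000
_EXON_LEN = 2_000
_GENE_PITCH = 150_000
_GENES_PER_CHROM = 50


@dataclass(frozen=True)
class PlantedEffect:
    """A ground-truth perturbation of one transcript in one group.

    ``magnitude`` is a logit shift of the methylation fraction for
    ``methylation_shift`` and a log2 shift of abundance for
    ``expression_shift``.
    """

    transcript_id: str
    target_group: str
    effect_kind: str
    magnitude: float

    def __post_init__(self):
        if self.effect_kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.effect_kind!r}")
        if not np.isfinite(self.magnitude) or self.magnitude == 0:
            raise ValueError("effect magnitude must be finite and nonzero")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic array.

    Defaults mirror the emulated design at reduced scale: 2200 mRNA + 800
    lncRNA probes (~the 2.6:1 ratio of the emulated 27,770:10,582 array),
    3 groups x 3 replicates, and a panel of planted effects built by
    :func:`default_effect_panel` when ``planted_effects`` is None.
    """

    n_mrna: int = 2200
    n_lncrna: int = 800
    n_spikein: int = 20
    groups: tuple = DEFAULT_GROUPS
    n_replicates: int = 3
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    base_methylation_alpha: float = 2.0
    base_methylation_beta: float = 2.0
    planted_effects: list | None = None
    array_effect_sd: float = 0.5
    noise_log2_sd: float = 0.1
    n_pathways: int = 30
    pathway_size: int = 25
    n_enriched_pathways: int = 3
    seed: int = 42

    def __post_init__(self):
        if self.n_mrna < 1:
            raise ValueError("at least one mRNA probe is required")
        if self.n_lncrna < 0 or self.n_spikein < 2:
            raise ValueError("n_lncrna must be >= 0 and n_spikein >= 2 "
                             "(normalization averages spike-ins)")
        if self.n_replicates < 1 or self.n_pathways < 0 or self.pathway_size < 1:
            raise ValueError("counts must be >= 1")
        if len(set(self.groups)) != len(self.groups) or len(self.groups) < 1:
            raise ValueError("groups must be unique labels")
        for sd in (self.baseline_log2_sd, self.array_effect_sd, self.noise_log2_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.base_methylation_alpha <= 0 or self.base_methylation_beta <= 0:
            raise ValueError("methylation shape parameters must be > 0")
        self.groups = tuple(self.groups)

    def resolved_effects(self) -> list[PlantedEffect]:
        effects = (default_effect_panel(self) if self.planted_effects is None
                   else list(self.planted_effects))
        for e in effects:
            if e.target_group not in self.groups:
                raise ValueError(f"planted effect targets unknown group {e.target_group!r}")
        return effects

    def streams(self) -> dict[str, np.random.Generator]:
        """Named per-stage RNG streams split from the single seed."""
        names = ("layout", "baseline", "effects", "arrays", "noise", "genesets", "qpcr")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _mrna_ids(n):
    return [f"mRNA_{i:05d}" for i in range(1, n + 1)]


def _lnc_ids(n):
    return [f"lncRNA_{i:05d}" for i in range(1, n + 1)]


def default_effect_panel(config: SimulationConfig) -> list[PlantedEffect]:
    """The default panel of planted effects.

    Deterministic in the configured counts: ~5% of mRNAs and lncRNAs carry
    a +/-2-logit methylation shift and ~5% of mRNAs a +/-2-log2 expression
    shift, split between the non-reference groups with alternating signs.
    A slice of mRNAs carries both a methylation and an expression shift so
    the four joint quadrants are populated, and the first expression-up
    block in the second group doubles as the planted pathway signal.
    """
    if len(config.groups) < 2:
        return []
    alt_groups = config.groups[1:]
    effects: list[PlantedEffect] = []
    mrna = _mrna_ids(config.n_mrna)
    lnc = _lnc_ids(config.n_lncrna)

    n_meth_m = max(1, config.n_mrna // 20)
    n_expr_m = max(1, config.n_mrna // 20)
    n_meth_l = max(1, config.n_lncrna // 20) if config.n_lncrna else 0
    n_joint = max(1, config.n_mrna // 50)

    # disjoint id blocks: methylation | expression | joint
    meth_ids = mrna[:n_meth_m]
    expr_ids = mrna[n_meth_m:n_meth_m + n_expr_m]
    joint_ids = mrna[n_meth_m + n_expr_m:n_meth_m + n_expr_m + n_joint]

    for i, tid in enumerate(meth_ids):
        g = alt_groups[i % len(alt_groups)]
        sign = 1.0 if (i // len(alt_groups)) % 2 == 0 else -1.0
        effects.append(PlantedEffect(tid, g, "methylation_shift", sign * 2.0))
    for i, tid in enumerate(expr_ids):
        g = alt_groups[i % len(alt_groups)]
        sign = 1.0 if (i // len(alt_groups)) % 2 == 0 else -1.0
        effects.append(PlantedEffect(tid, g, "expression_shift", sign * 2.0))
    for i, tid in enumerate(joint_ids):
        g = alt_groups[i % len(alt_groups)]
        m_sign = 1.0 if i % 2 == 0 else -1.0
        e_sign = 1.0 if (i // 2) % 2 == 0 else -1.0
        effects.append(PlantedEffect(tid, g, "methylation_shift", m_sign * 2.0))
        effects.append(PlantedEffect(tid, g, "expression_shift", e_sign * 2.0))
    for i, tid in enumerate(lnc[:n_meth_l]):
        g = alt_groups[i % len(alt_groups)]
        sign = 1.0 if (i // len(alt_groups)) % 2 == 0 else -1.0
        effects.append(PlantedEffect(tid, g, "methylation_shift", sign * 2.0))
    return effects


@dataclass
class GroundTruth:
    """True per-group methylation fractions / abundances and derived labels."""

    methylation: pd.DataFrame      # transcripts x groups, fraction in (0,1)
    log2_abundance: pd.DataFrame   # transcripts x groups
    meth_shift: pd.DataFrame       # logit shifts, transcripts x groups
    expr_shift: pd.DataFrame       # log2 shifts, transcripts x groups
    effects: list = field(default_factory=list)

    def labels(self, condition: str, reference: str) -> pd.DataFrame:
        """True hyper/hypo/none and up/down/none per transcript for
        condition vs reference, derived from the planted shifts."""
        dm = self.meth_shift[condition] - self.meth_shift[reference]
        de = self.expr_shift[condition] - self.expr_shift[reference]
        meth = np.where(dm > 0, "hyper", np.where(dm < 0, "hypo", "none"))
        expr = np.where(de > 0, "up", np.where(de < 0, "down", "none"))
        return pd.DataFrame({"methylation": meth, "expression": expr},
                            index=self.meth_shift.index)

    def to_json_dict(self) -> dict:
        return {
            "methylation": self.methylation.round(10).to_dict(orient="index"),
            "log2_abundance": self.log2_abundance.round(10).to_dict(orient="index"),
            "meth_shift": self.meth_shift.to_dict(orient="index"),
            "expr_shift": self.expr_shift.to_dict(orient="index"),
            "effects": [asdict(e) for e in self.effects],
        }


# ---------------------------------------------------------------------------
# genome layout / annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SimulationConfig):
    """Probe annotation plus coding-gene models on synthetic chromosomes.

    One probe row per transcript plus spike-in rows; coding genes get two
    exons each; lncRNAs cycle through the six genomic context classes so
    every class occurs at least once when ``n_lncrna >= 6`` (fewer probes
    record a coverage warning in the run log).  Coordinates are 0-based
    half-open; output is deterministic given the seed.

    Returns ``(annotation, gene_models)`` — a DataFrame with columns
    probe_id, transcript_id, gene_symbol, rna_class, chrom, start, end,
    strand, and a list of :class:`GeneModel`.
    """
    if 0 < config.n_lncrna < len(CONTEXT_CLASSES):
        logger.warning("n_lncrna=%d < %d: not every lncRNA context class will occur",
                       config.n_lncrna, len(CONTEXT_CLASSES))

    genes: list[GeneModel] = []
    rows = []
    for i in range(config.n_mrna):
        chrom = f"chr{i // _GENES_PER_CHROM + 1}"
        start = 100_000 + (i % _GENES_PER_CHROM) * _GENE_PITCH
        end = start + _GENE_SPAN
        strand = "+" if i % 2 == 0 else "-"
        symbol = f"GENE{i + 1:05d}"
        exons = ((start, start + _EXON_LEN), (end - _EXON_LEN, end))
        genes.append(GeneModel(symbol=symbol, chrom=chrom, start=start, end=end,
                               strand=strand, exons=exons))
        rows.append({"probe_id": f"P_mRNA_{i + 1:05d}", "transcript_id": _mrna_ids(config.n_mrna)[i],
                     "gene_symbol": symbol, "rna_class": "mRNA", "chrom": chrom,
                     "start": start, "end": end, "strand": strand,
                     "context_class": "."})

    lnc_ids = _lnc_ids(config.n_lncrna)
    for j in range(config.n_lncrna):
        cls = CONTEXT_CLASSES[j % len(CONTEXT_CLASSES)]
        host = genes[j % len(genes)]
        opp = "-" if host.strand == "+" else "+"
        if cls == "exon-overlap":
            iv, strand = (host.start + 500, host.start + 1500), host.strand
        elif cls == "intron-overlap":
            iv, strand = (host.start + 3000, host.start + 5000), host.strand
        elif cls == "natural-antisense":
            iv, strand = (host.start + 500, host.start + 1500), opp
        elif cls == "intronic-antisense":
            iv, strand = (host.start + 3000, host.start + 5000), opp
        elif cls == "bidirectional":
            if host.strand == "+":
                iv, strand = (host.start - 1700, host.start - 500), "-"
            else:
                iv, strand = (host.end + 500, host.end + 1700), "+"
        else:  # intergenic: downstream gap, far (>1 kb) from any TSS
            iv, strand = (host.end + 60_000, host.end + 61_000), "+"
        rows.append({"probe_id": f"P_lncRNA_{j + 1:05d}", "transcript_id": lnc_ids[j],
                     "gene_symbol": f"LNC{j + 1:05d}", "rna_class": "lncRNA",
                     "chrom": host.chrom, "start": iv[0], "end": iv[1],
                     "strand": strand, "context_class": cls})

    for k in range(config.n_spikein):
        rows.append({"probe_id": f"P_SPK_{k + 1:02d}", "transcript_id": f"SPK_{k + 1:02d}",
                     "gene_symbol": f"SPK{k + 1:02d}", "rna_class": "spikein",
                     "chrom": "spikein", "start": 0, "end": 1000, "strand": "+",
                     "context_class": "."})

    annotation = pd.DataFrame(rows)
    return annotation, genes


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

def _truncated_beta(rng, a, b, lo, hi, size):
    """Inverse-CDF sampling of Beta(a,b) truncated to [lo, hi]."""
    u = rng.uniform(stats.beta.cdf(lo, a, b), stats.beta.cdf(hi, a, b), size=size)
    return stats.beta.ppf(u, a, b)


def sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = [{"sample_id": f"{g}_R{r}", "group": g, "replicate": r}
            for g in config.groups for r in range(1, config.n_replicates + 1)]
    return pd.DataFrame(rows)


def generate_intensities(config: SimulationConfig, annotation: pd.DataFrame):
    """Two-channel intensities for every probe plus the ground truth.

    See the module docstring for the generative model.  Spike-ins have
    fixed known abundances (log2 evenly spaced in [6, 14]) and share their
    sample/channel array effect and measurement noise.
    """
    streams = config.streams()
    effects = config.resolved_effects()
    sheet = sample_sheet(config)
    groups = list(config.groups)

    is_spike = annotation["rna_class"] == "spikein"
    tids = annotation.loc[~is_spike, "transcript_id"].tolist()
    spike_probes = annotation.loc[is_spike, "probe_id"].tolist()
    n_t, n_s = len(tids), len(sheet)
    tindex = {t: i for i, t in enumerate(tids)}

    # planted shift matrices (transcripts x groups)
    meth_shift = np.zeros((n_t, len(groups)))
    expr_shift = np.zeros((n_t, len(groups)))
    for e in effects:
        if e.transcript_id not in tindex:
            raise ValueError(f"planted effect references unknown transcript {e.transcript_id!r}")
        row, col = tindex[e.transcript_id], groups.index(e.target_group)
        target = meth_shift if e.effect_kind == "methylation_shift" else expr_shift
        target[row, col] += e.magnitude

    # baselines; methylation-effect transcripts draw from the band where the
    # planted gain/loss is expressible (a gain on a saturated transcript or a
    # loss on an unmethylated one would be biologically vacuous)
    rng_b = streams["baseline"]
    baseline_log2 = rng_b.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_t)
    a, b = config.base_methylation_alpha, config.base_methylation_beta
    m0 = rng_b.beta(a, b, n_t)
    net = meth_shift.sum(axis=1)
    pos, neg = net > 0, net < 0
    rng_e = streams["effects"]
    if pos.any():
        m0[pos] = _truncated_beta(rng_e, a, b, 0.15, 0.50, int(pos.sum()))
    if neg.any():
        m0[neg] = _truncated_beta(rng_e, a, b, 0.50, 0.85, int(neg.sum()))
    m0 = np.clip(m0, 1e-9, 1 - 1e-9)

    m_true = expit(logit(m0)[:, None] + meth_shift)            # transcripts x groups
    log2_abund = baseline_log2[:, None] + expr_shift           # transcripts x groups

    group_of = sheet["group"].tolist()
    gidx = np.array([groups.index(g) for g in group_of])
    A = np.exp2(log2_abund[:, gidx])                           # transcripts x samples
    M = m_true[:, gidx]

    rng_a = streams["arrays"]
    ae = rng_a.normal(0.0, config.array_effect_sd, size=(n_s, 2))  # [:,0]=IP, [:,1]=SUP
    rng_n = streams["noise"]
    eps_ip = rng_n.normal(0.0, config.noise_log2_sd, size=(n_t, n_s))
    eps_sup = rng_n.normal(0.0, config.noise_log2_sd, size=(n_t, n_s))

    ip = A * M * np.exp2(ae[None, :, 0] + eps_ip)
    sup = A * (1.0 - M) * np.exp2(ae[None, :, 1] + eps_sup)

    n_spk = len(spike_probes)
    spk_abund = np.exp2(np.linspace(6.0, 14.0, n_spk))
    spk_eps_ip = rng_n.normal(0.0, config.noise_log2_sd, size=(n_spk, n_s))
    spk_eps_sup = rng_n.normal(0.0, config.noise_log2_sd, size=(n_spk, n_s))
    spk_ip = spk_abund[:, None] * np.exp2(ae[None, :, 0] + spk_eps_ip)
    spk_sup = spk_abund[:, None] * np.exp2(ae[None, :, 1] + spk_eps_sup)

    samples = sheet["sample_id"].tolist()
    probe_order = annotation["probe_id"].tolist()
    ip_df = pd.DataFrame(np.vstack([ip, spk_ip]),
                         index=tids + spike_probes, columns=samples)
    sup_df = pd.DataFrame(np.vstack([sup, spk_sup]),
                          index=tids + spike_probes, columns=samples)
    # reindex to annotation probe order: transcripts are keyed by transcript_id
    # on the matrix index for readability downstream
    id_order = annotation["transcript_id"].where(~is_spike, annotation["probe_id"]).tolist()
    ip_df = ip_df.reindex(id_order)
    sup_df = sup_df.reindex(id_order)

    truth = GroundTruth(
        methylation=pd.DataFrame(m_true, index=tids, columns=groups),
        log2_abundance=pd.DataFrame(log2_abund, index=tids, columns=groups),
        meth_shift=pd.DataFrame(meth_shift, index=tids, columns=groups),
        expr_shift=pd.DataFrame(expr_shift, index=tids, columns=groups),
        effects=effects,
    )
    arrays = TwoChannelArraySet(ip=ip_df, sup=sup_df, samples=sheet,
                                spikein_ids=frozenset(spike_probes))
    del probe_order
    return arrays, truth


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def generate_gene_sets(config: SimulationConfig, annotation: pd.DataFrame) -> dict[str, list]:
    """GMT-style pathway layout over the mRNA gene symbols.

    ``n_enriched_pathways`` sets are planted: 80% of their members come
    from symbols of transcripts carrying a positive expression shift in the
    second group, so over-representation of the recovered up-gene list is
    guaranteed by construction.  Remaining sets are uniform draws.
    """
    rng = config.streams()["genesets"]
    symbols = annotation.loc[annotation["rna_class"] == "mRNA", "gene_symbol"].tolist()
    sym_of = dict(zip(annotation["transcript_id"], annotation["gene_symbol"]))
    up_syms = sorted({sym_of[e.transcript_id] for e in config.resolved_effects()
                      if e.effect_kind == "expression_shift" and e.magnitude > 0
                      and len(config.groups) > 1 and e.target_group == config.groups[1]
                      and sym_of.get(e.transcript_id) in set(symbols)})
    sets = {}
    size = min(config.pathway_size, len(symbols))
    for p in range(config.n_pathways):
        name = f"PATHWAY_{p + 1:03d}"
        if p < config.n_enriched_pathways and up_syms:
            n_plant = min(len(up_syms), max(1, int(round(0.8 * size))))
            planted = list(rng.choice(up_syms, size=n_plant, replace=False))
            rest_pool = [s for s in symbols if s not in set(planted)]
            rest = list(rng.choice(rest_pool, size=size - n_plant, replace=False))
            sets[name] = sorted(planted + rest)
        else:
            sets[name] = sorted(rng.choice(symbols, size=size, replace=False))
    return sets


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

@dataclass
class QpcrDesign:
    """Design of a synthetic qPCR validation experiment.

    ``expression`` maps target -> {group: linear level relative to the
    first group}; ``methylation`` maps target -> {group: true methylated
    fraction}.  The reference gene has constant expression.  Ct values are
    built as ``Ct = c0 - log2(amount) + noise``.
    """

    groups: tuple = DEFAULT_GROUPS
    n_replicates: int = 3
    expression: dict = field(default_factory=lambda: {
        "TGT_A": {"M0-L": 1.0, "M1-L": 4.0, "M2-L": 1.5},
        "TGT_B": {"M0-L": 1.0, "M1-L": 0.25, "M2-L": 1.0},
    })
    methylation: dict = field(default_factory=lambda: {
        "TGT_A": {"M0-L": 0.2, "M1-L": 0.6, "M2-L": 0.3},
        "TGT_B": {"M0-L": 0.5, "M1-L": 0.15, "M2-L": 0.5},
    })
    reference_gene: str = "Gapdh"
    c0: float = 30.0
    sd_ct: float = 0.2
    input_fraction: float = 0.1
    seed: int = 0

    def true_fold(self, target: str, condition: str, reference: str) -> float:
        lv = self.expression[target]
        return lv[condition] / lv[reference]


def generate_qpcr(design: QpcrDesign) -> pd.DataFrame:
    """Ct table covering expression (cdna tube) and MeRIP (input/ip tubes).

    Columns: sample_id, group, tube, target, is_reference, ct,
    input_fraction.  With ``sd_ct=0`` the 2^-ddCt and percent-input
    arithmetic recovers the designed folds and fractions exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(design.seed).spawn(1)[0])
    rows = []
    frac = design.input_fraction
    if not 0 < frac <= 1:
        raise ValueError("input_fraction must lie in (0, 1]")

    def noisy(ct):
        return ct + (rng.normal(0.0, design.sd_ct) if design.sd_ct > 0 else 0.0)

    for g in design.groups:
        for r in range(1, design.n_replicates + 1):
            sid = f"{g}_R{r}"
            rows.append({"sample_id": sid, "group": g, "tube": "cdna",
                         "target": design.reference_gene, "is_reference": True,
                         "ct": noisy(design.c0), "input_fraction": np.nan})
            for tgt, levels in design.expression.items():
                amount = levels[g]
                rows.append({"sample_id": sid, "group": g, "tube": "cdna",
                             "target": tgt, "is_reference": False,
                             "ct": noisy(design.c0 - np.log2(amount)),
                             "input_fraction": np.nan})
                meth = design.methylation.get(tgt, {}).get(g)
                if meth is not None:
                    ct_in = design.c0 - np.log2(amount * frac)
                    ct_ip = design.c0 - np.log2(amount * meth)
                    rows.append({"sample_id": sid, "group": g, "tube": "input",
                                 "target": tgt, "is_reference": False,
                                 "ct": noisy(ct_in), "input_fraction": frac})
                    rows.append({"sample_id": sid, "group": g, "tube": "ip",
                                 "target": tgt, "is_reference": False,
                                 "ct": noisy(ct_ip), "input_fraction": frac})
    return pd.DataFrame(rows)


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
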
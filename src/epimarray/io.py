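"""File formats, run configuration and end-to-end orchestration.

All tabular interfaces are UTF-8 TSV with a header row and "." for
missing values: intensity matrices (probe_id + one column per sample),
the sample sheet, the probe annotation, Ct tables and all result tables.
Gene models travel as BED12 (0-based half-open, blocks = exons), gene
sets as GMT, reports as JSON.  Every writer's output is parseable by its
reader, and pipeline outputs are a pure function of (inputs, config,
seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cis_lnc, differential, enrich, integrate, synthetic
from .quantify import (DEFAULT_INTENSITY_FLOOR, TwoChannelArraySet,
                       floor_intensities)
from .quantify import quantify as quantify_arrays

logger = logging.getLogger(__name__)

MISSING = "."


# ---------------------------------------------------------------------------
# tabular readers / writers
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=MISSING)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=True, **kwargs)


def write_matrix(df: pd.DataFrame, path, id_column: str = "probe_id") -> None:
    out = df.copy()
    out.insert(0, id_column, df.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_matrix(path, id_column: str = "probe_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    if first != id_column:
        logger.info("matrix id column %r read as %r", first, id_column)
    return df.set_index(first)


def write_bed12(gene_models, path) -> None:
    """Gene models as BED12; exon blocks relative to the gene start."""
    with open(path, "w") as fh:
        for g in gene_models:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - g.start) for s, _ in g.exons) + ","
            fh.write("\t".join(map(str, (
                g.chrom, g.start, g.end, g.symbol, 0, g.strand,
                g.start, g.end, "0,0,0", len(g.exons), sizes, starts))) + "\n")


def read_bed12(path) -> list:
    models = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            models.append(cis_lnc.GeneModel(symbol=name, chrom=chrom, start=start,
                                            end=end, strand=strand, exons=exons))
    return models


def write_gmt(sets: dict, path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = frozenset(p for p in parts[2:] if p)
    return sets


# ---------------------------------------------------------------------------
# loading a two-channel set
# ---------------------------------------------------------------------------

def load_two_channel(ip_path, sup_path, sample_sheet_path, annotation_path,
                     intensity_floor: float = DEFAULT_INTENSITY_FLOOR):
    """Read, validate and align a two-channel array set.

    Channels are reordered to a common row/column ordering; spike-ins are
    identified from the annotation's rna_class; intensities below the
    floor are clipped with a logged count.  Returns
    ``(TwoChannelArraySet, annotation)``.
    """
    ip = read_matrix(ip_path)
    sup = read_matrix(sup_path)
    sheet = read_tsv(sample_sheet_path)
    annotation = read_tsv(annotation_path)

    for name, mat in (("IP", ip), ("SUP", sup)):
        if mat.index.has_duplicates:
            dupes = mat.index[mat.index.duplicated()].unique().tolist()
            raise ValueError(f"{name} matrix has duplicated probe row(s): {dupes}")
    if set(ip.index) != set(sup.index):
        raise ValueError("IP and supernatant matrices cover different probes")
    if set(ip.columns) != set(sup.columns):
        raise ValueError("IP and supernatant matrices cover different samples")
    sup = sup.reindex(index=ip.index, columns=ip.columns)

    known = set(sheet["sample_id"])
    extra = [s for s in ip.columns if s not in known]
    if extra:
        raise ValueError(f"sample(s) present in matrices but absent from sheet: {extra}")

    # matrices are keyed by transcript_id (spike-ins by probe_id)
    is_spike = annotation["rna_class"] == "spikein"
    ids = annotation["transcript_id"].where(~is_spike, annotation["probe_id"])
    missing = set(ids) - set(ip.index)
    if missing:
        logger.warning("%d annotated probe(s) missing from matrices", len(missing))
    spikes = frozenset(annotation.loc[is_spike, "probe_id"]) & frozenset(ip.index)

    ip = floor_intensities(ip, intensity_floor)
    sup = floor_intensities(sup, intensity_floor)
    arrays = TwoChannelArraySet(ip=ip, sup=sup, samples=sheet, spikein_ids=spikes)
    return arrays, annotation


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything an end-to-end run needs.

    ``comparisons`` is a list of (condition, reference) pairs; thresholds,
    windows and modes default to the package-wide conventions.
    """

    output_dir: str = "epimarray_out"
    ip_path: str | None = None
    sup_path: str | None = None
    sample_sheet_path: str | None = None
    annotation_path: str | None = None
    gene_models_path: str | None = None
    gmt_path: str | None = None
    comparisons: list = field(default_factory=lambda: [
        ("M1-L", "M0-L"), ("M2-L", "M0-L"), ("M2-L", "M1-L")])
    fc_up: float = 1.5
    fc_down: float = 0.7
    alpha: float = 0.05
    expression_mode: str = "total"
    log2_expression: bool = False
    intensity_floor: float = DEFAULT_INTENSITY_FLOOR
    universe_mode: str = "array_in_sets"     # array_in_sets | array | gmt
    cis_window: int = cis_lnc.DEFAULT_WINDOW
    bidirectional_distance: int = cis_lnc.DEFAULT_BIDIRECTIONAL_DISTANCE
    qpcr_input_fraction: float = 0.1
    seed: int = 0
    simulate: bool = False                   # generate inputs in-silico first

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.comparisons = [tuple(c) for c in cfg.comparisons]
        return cfg

    def thresholds(self) -> differential.Thresholds:
        return differential.Thresholds(self.fc_up, self.fc_down, self.alpha)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate_inputs(config: synthetic.SimulationConfig, out_dir) -> dict:
    """Write a full synthetic input tree; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation, genes = synthetic.generate_annotation(config)
    arrays, truth = synthetic.generate_intensities(config, annotation)
    sets = synthetic.generate_gene_sets(config, annotation)
    paths = {
        "annotation": out / "annotation.tsv",
        "gene_models": out / "gene_models.bed",
        "gmt": out / "gene_sets.gmt",
        "ip": out / "ip_intensity.tsv",
        "sup": out / "sup_intensity.tsv",
        "sample_sheet": out / "sample_sheet.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_tsv(annotation, paths["annotation"])
    write_bed12(genes, paths["gene_models"])
    write_gmt(sets, paths["gmt"])
    write_matrix(arrays.ip, paths["ip"])
    write_matrix(arrays.sup, paths["sup"])
    write_tsv(arrays.samples, paths["sample_sheet"])
    synthetic.write_ground_truth(truth, paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}


def _build_universe(mode: str, annotation: pd.DataFrame, sets: dict) -> frozenset:
    array_syms = frozenset(annotation.loc[annotation["rna_class"] == "mRNA", "gene_symbol"])
    gmt_syms = frozenset().union(*map(frozenset, sets.values())) if sets else frozenset()
    if mode == "array_in_sets":
        return array_syms & gmt_syms
    if mode == "array":
        return array_syms
    if mode == "gmt":
        return gmt_syms
    raise ValueError(f"unknown universe mode {mode!r}")


def run_pipeline(config: RunConfig) -> dict:
    """quantify -> differential -> integrate -> enrich -> cis -> report.

    Writes every stage's tables under ``config.output_dir`` and returns
    the report dict (also written as report.json).  Any stage error aborts
    with the stage name attached.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.simulate:
            stage = "simulate"
            sim = synthetic.SimulationConfig(seed=config.seed)
            paths = simulate_inputs(sim, out / "inputs")
            config.ip_path = paths["ip"]
            config.sup_path = paths["sup"]
            config.sample_sheet_path = paths["sample_sheet"]
            config.annotation_path = paths["annotation"]
            config.gene_models_path = paths["gene_models"]
            config.gmt_path = paths["gmt"]

        stage = "load"
        arrays, annotation = load_two_channel(
            config.ip_path, config.sup_path, config.sample_sheet_path,
            config.annotation_path, config.intensity_floor)
        groups = set(arrays.samples["group"])
        for cond, ref in config.comparisons:
            if cond not in groups or ref not in groups:
                raise ValueError(f"comparison ({cond}, {ref}) references unknown group")

        stage = "quantify"
        quantified = quantify_arrays(arrays, expression_mode=config.expression_mode)
        write_matrix(quantified.methylation, out / "methylation.tsv")
        write_matrix(quantified.expression, out / "expression.tsv")
        write_tsv(quantified.normalization_factors, out / "normalization_factors.tsv")

        thresholds = config.thresholds()
        records: dict = {}
        summaries: dict = {}
        stage = "differential"
        for cond, ref in config.comparisons:
            comp = differential.Comparison(cond, ref)
            summaries[comp.name] = {}
            for measure in differential.MEASURES:
                rec = differential.run_comparison(
                    quantified, comp, measure, thresholds, annotation=annotation,
                    log2_expression=config.log2_expression)
                records[(comp.name, measure)] = rec
                summaries[comp.name][measure] = differential.summarize_calls(rec)
                write_tsv(rec, out / f"differential_{comp.slug}_{measure}.tsv")
            diff_ids = records[(comp.name, "methylation")].query("call != 'none'")["transcript_id"]
            if len(diff_ids) >= 2:
                tree = differential.hierarchical_cluster(
                    quantified.methylation.loc[diff_ids])
                with open(out / f"cluster_{comp.slug}.json", "w") as fh:
                    json.dump(tree, fh)

        stage = "integrate"
        assignments: dict = {}
        quadrant_counts: dict = {}
        for cond, ref in config.comparisons:
            comp = differential.Comparison(cond, ref)
            asn = integrate.assign_quadrants(records[(comp.name, "methylation")],
                                             records[(comp.name, "expression")])
            assignments[comp.name] = asn
            quadrant_counts[comp.name] = asn.attrs["counts"]
            write_tsv(asn, out / f"quadrants_{comp.slug}.tsv")
        concordances = {}
        names = [differential.Comparison(c, r).name for c, r in config.comparisons]
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                rep = integrate.concordance(assignments[a], assignments[b])
                concordances[f"{a} / {b}"] = {
                    "n_both": rep.n_both, "n_opposite": rep.n_opposite,
                    "fraction_opposite": rep.fraction_opposite,
                }
                write_tsv(rep.table, out / f"concordance_{a.replace(' ', '')}"
                          f"__{b.replace(' ', '')}.tsv", index=True)

        stage = "enrich"
        gene_sets = read_gmt(config.gmt_path) if config.gmt_path else {}
        enrichment_summary = {}
        if gene_sets:
            universe = _build_universe(config.universe_mode, annotation, gene_sets)
            collection = enrich.GeneSetCollection(sets=gene_sets, universe=universe)
            for name, asn in assignments.items():
                slug = name.replace(" ", "")
                per_group = enrich.enrich_quadrant_groups(asn, collection,
                                                          alpha=config.alpha)
                enrichment_summary[name] = {}
                for grp, table in per_group.items():
                    write_tsv(table, out / f"enrichment_{grp}_{slug}.tsv")
                    enrichment_summary[name][grp] = int(table["significant"].sum()) \
                        if len(table) else 0

        stage = "cis_lnc"
        cis_summary = {}
        if config.gene_models_path:
            genes = read_bed12(config.gene_models_path)
            ctx = cis_lnc.classify_all(annotation, genes, config.bidirectional_distance)
            write_tsv(ctx, out / "lnc_context.tsv")
            links = cis_lnc.cis_link_table(annotation, genes, config.cis_window,
                                           config.bidirectional_distance)
            write_tsv(links, out / "cis_links.tsv")
            first = differential.Comparison(*config.comparisons[0]).name
            table, de_genes, n_lnc = cis_lnc.link_to_de(
                links, records[(first, "expression")])
            write_tsv(table, out / "cis_links_de.tsv")
            cis_summary = {
                "context_counts": ctx["context_class"].value_counts().to_dict(),
                "n_links": int(len(links)),
                "n_de_neighbor_genes": len(de_genes),
                "n_lncrnas_with_de_neighbor": n_lnc,
            }
            if len(config.comparisons) >= 3:
                a = differential.Comparison(*config.comparisons[0]).name
                b = differential.Comparison(*config.comparisons[2]).name
                flips = cis_lnc.select_signflip_lncrnas(
                    records[(a, "methylation")], records[(b, "methylation")])
                pd.DataFrame({
                    "lncrna_id": sorted(flips[0]) + sorted(flips[1]),
                    "pattern": (["hyper_then_hypo"] * len(flips[0])
                                + ["hypo_then_hyper"] * len(flips[1])),
                }).to_csv(out / "signflip_lncrnas.tsv", sep="\t", index=False)
                cis_summary["n_hyper_then_hypo"] = len(flips[0])
                cis_summary["n_hypo_then_hyper"] = len(flips[1])

        stage = "report"
        report = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "counts": integrate.report_counts(summaries, quadrant_counts),
            "concordance": concordances,
            "enrichment_significant_sets": enrichment_summary,
            "cis": cis_summary,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=float)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
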
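"""End-to-end orchestration: simulate and/or analyze with one config.

Stages (analyze): insertion calling (or table loading) -> timepoint
selection -> read-threshold calibration -> scoring/classification ->
landscape -> domain essentiality -> ncRNA co-expression and smORF scan
-> report. Every written file is listed in a manifest with its SHA-256
hash; identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .calling import InsertionTable, call_insertions
from .domains import load_domains, score_all_domains
from .ncrna import classify_pairs, clr_matrix, essentiality_enrichment, smorfs_on_genome
from .scoring import (
    EssentialityClassifier,
    GoldSet,
    essential_landscape,
    select_timepoint,
)
from .simulate import SimConfig, antisense_pairs, simulate_expression, simulate_genome, simulate_insertions

VERSION = "0.1.0"

MODES = ("simulate", "analyze", "full")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        super().__init__(f"[{stage}] {message}" + (f" (hint: {hint})" if hint else ""))


@dataclass
class PipelineConfig:
    mode: str = "full"
    paths: dict = field(default_factory=dict)  # genome, annotation, insertions(list/dict), reads, gold, domains, expression
    ir_tag: str = "TACGTCAGGTTT"
    k: int = 20
    max_mismatch: int = 1
    alpha: float = 0.01
    read_threshold: str | int = "stringent"
    clr_threshold: float = 2.5
    min_aa: int = 10
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "analyze":
            required = ["genome", "annotation", "gold"]
            if "insertions" not in self.paths and "reads" not in self.paths:
                required.append("insertions")
            missing = [p for p in required if p not in self.paths]
            if missing:
                raise ValueError(f"analyze mode requires paths: {missing}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha out of range")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ResultBundle:
    config: PipelineConfig
    chosen_day: int | None = None
    diagnostics: pd.DataFrame | None = None
    calibration: object = None
    classifier: EssentialityClassifier | None = None
    calls: pd.DataFrame | None = None
    landscape: object = None
    domain_calls: pd.DataFrame | None = None
    signed_pairs: pd.DataFrame | None = None
    welch: object = None
    per_ncrna: pd.DataFrame | None = None
    smorfs: pd.DataFrame | None = None
    outputs: list = field(default_factory=list)
    incomplete: list = field(default_factory=list)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> ResultBundle:
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(config=config)
    written: list[Path] = []

    def emit(path: Path):
        written.append(path)

    # ------------------------------------------------------------ simulate
    if config.mode in ("simulate", "full"):
        sim_cfg = SimConfig(seed=config.seed, **config.sim)
        try:
            genome, truth = simulate_genome(sim_cfg)
            tables = simulate_insertions(genome, truth, sim_cfg)
            expr, planted = simulate_expression(truth, sim_cfg)
        except Exception as err:
            raise PipelineError("simulate", str(err)) from err
        mio.write_fasta(genome, out / "genome.fasta", truth.genome_id)
        mio.write_gff3(truth, out / "annotation.gff3")
        truth.domains.to_csv(out / "domain_truth.tsv", sep="\t", index=False)
        for d, t in tables.items():
            t.to_tsv(out / f"insertions_day{d:02d}.tsv")
            emit(out / f"insertions_day{d:02d}.tsv")
        mio.write_expression(expr, out / "expression.tsv")
        planted.to_csv(out / "planted_pairs.tsv", sep="\t", index=False)
        # gold sets from truth
        orfs = truth.of_type("ORF")
        gold = GoldSet(
            list(orfs.loc[orfs["truth"] == "E", "id"][:37]),
            list(orfs.loc[orfs["truth"] == "NE", "id"][:29]),
        )
        gold.to_tsv(out / "gold_sets.tsv")
        # domain table in analysis format
        dom = truth.domains.rename(columns={"truth": "source"}).copy()
        dom["source"] = "sim_truth"
        dom.to_csv(out / "domains.tsv", sep="\t", index=False)
        sim_cfg.to_yaml(out / "sim_config.yaml")
        for name in ("genome.fasta", "annotation.gff3", "domain_truth.tsv",
                     "expression.tsv", "planted_pairs.tsv", "gold_sets.tsv",
                     "domains.tsv", "sim_config.yaml"):
            emit(out / name)
        annotation = truth
    if config.mode == "simulate":
        _write_manifest(config, out, written, bundle)
        return bundle

    # -------------------------------------------------------------- inputs
    if config.mode == "analyze":
        try:
            _, genome = mio.read_fasta(config.paths["genome"])
            annotation = mio.read_gff3(config.paths["annotation"])
            gold = GoldSet.from_tsv(config.paths["gold"])
        except Exception as err:
            raise PipelineError("load", str(err)) from err
        if "insertions" in config.paths:
            items = config.paths["insertions"]
            tables = {}
            for p in items if isinstance(items, (list, tuple)) else [items]:
                t = InsertionTable.from_tsv(p)
                day = int(t.df["day"].iloc[0]) if len(t.df) else 0
                tables[day] = t
        else:
            reads = mio.read_fastq(config.paths["reads"])
            t = call_insertions(reads, genome, config.ir_tag, k=config.k,
                                max_mismatch=config.max_mismatch,
                                genome_id=annotation.genome_id)
            tables = {0: t}
        expr = (mio.read_expression(config.paths["expression"])
                if "expression" in config.paths else None)

    # ---------------------------------------------------- timepoint, model
    try:
        day, diag = select_timepoint(tables, gold, annotation)
    except Exception as err:
        raise PipelineError("select_timepoint", str(err),
                            "check library decay series / bottleneck") from err
    bundle.chosen_day, bundle.diagnostics = day, diag
    table = tables[day]
    try:
        clf = EssentialityClassifier(
            alpha=config.alpha, read_threshold=config.read_threshold
        ).fit(table, annotation=annotation, gold=gold)
    except Exception as err:
        raise PipelineError("calibrate", str(err)) from err
    bundle.classifier = clf
    bundle.calibration = clf.calibration_

    # ------------------------------------------------- scoring + landscape
    try:
        landscape = essential_landscape(annotation, table, clf.model_)
    except Exception as err:
        raise PipelineError("landscape", str(err),
                            "an empty insertion table cannot be scored (N=0)") from err
    bundle.landscape = landscape
    bundle.calls = landscape.calls
    landscape.calls.to_csv(out / "calls.tsv", sep="\t")
    landscape.to_bed(out / "landscape.bed", annotation.genome_id)
    diag.to_csv(out / "timepoint_diagnostics.tsv", sep="\t")
    for name in ("calls.tsv", "landscape.bed", "timepoint_diagnostics.tsv"):
        emit(out / name)

    # -------------------------------------------------------------- domains
    dom_path = out / "domains.tsv" if config.mode == "full" else config.paths.get("domains")
    if dom_path and Path(dom_path).exists():
        domains = load_domains(dom_path)
        bundle.domain_calls = score_all_domains(annotation, domains, clf.scorer_)
        bundle.domain_calls.to_csv(out / "domain_calls.tsv", sep="\t", index=False)
        emit(out / "domain_calls.tsv")
    else:
        bundle.incomplete.append("domains")

    # --------------------------------------------------------------- ncRNA
    expr_df = expr
    if expr_df is not None and len(annotation.of_type("ncRNA")):
        try:
            net = clr_matrix(expr_df, threshold=config.clr_threshold)
            pairs = antisense_pairs(annotation)
            pairs = pairs[
                pairs["ncrna"].isin(expr_df.index) & pairs["orf"].isin(expr_df.index)
            ]
            bundle.signed_pairs = classify_pairs(net, pairs)
            bundle.signed_pairs.to_csv(out / "signed_pairs.tsv", sep="\t", index=False)
            emit(out / "signed_pairs.tsv")
            try:
                bundle.welch, bundle.per_ncrna = essentiality_enrichment(
                    bundle.signed_pairs, bundle.calls
                )
            except ValueError:
                bundle.incomplete.append("enrichment")
        except Exception as err:
            raise PipelineError("ncrna", str(err)) from err
        smorfs = smorfs_on_genome(annotation, genome, min_aa=config.min_aa)
        bundle.smorfs = smorfs
        mio.write_smorf_gff3(smorfs, out / "smorf_candidates.gff3", annotation.genome_id)
        mio.write_peptides_fasta(smorfs, out / "smorf_peptides.fasta")
        emit(out / "smorf_candidates.gff3")
        emit(out / "smorf_peptides.fasta")
    else:
        bundle.incomplete.append("ncrna")

    report = render_report(bundle)
    (out / "report.txt").write_text(report)
    emit(out / "report.txt")
    _write_manifest(config, out, written, bundle)
    bundle.outputs = [str(p) for p in written]
    return bundle


def _write_manifest(config, out: Path, written, bundle) -> None:
    manifest = {
        "tool": "minitn",
        "version": VERSION,
        "params": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "paths"
        },
        "inputs": {
            k: (_sha256(v) if isinstance(v, (str, Path)) and Path(v).exists() else str(v))
            for k, v in config.paths.items()
        },
        "outputs": {str(p.name): _sha256(p) for p in written if p.exists()},
        "complete": not bundle.incomplete,
        "incomplete_stages": bundle.incomplete,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def render_report(bundle: ResultBundle) -> str:
    """Plain-text summary of a finished (or partially finished) run."""
    if bundle.calls is None:
        raise ValueError("incomplete bundle: missing stage 'scoring'")
    cfg = bundle.config
    lines = ["minitn essentiality report", "=" * 30]
    lines.append(f"chosen analysis day: {bundle.chosen_day}")
    if bundle.calibration is not None:
        lines.append(
            f"read thresholds: relaxed={bundle.calibration.relaxed} "
            f"stringent={bundle.calibration.stringent} (used: {cfg.read_threshold})"
        )
    clf = bundle.classifier
    if clf is not None:
        lines.append(
            f"threshold-passing insertions N={clf.model_.N} "
            f"(read threshold {clf.model_.read_threshold}), w={clf.model_.w} bp"
        )
    lines.append("")
    lines.append("E/NE/F counts per feature class:")
    for cls_name, summ in (bundle.landscape.class_summaries or {}).items():
        c = summ.counts
        extra = f", unassignable={summ.n_unassignable}" if summ.n_unassignable else ""
        lines.append(
            f"  {cls_name:<11} n={summ.n:<4} E={c['E']} NE={c['NE']} F={c['F']}{extra}"
        )
    ls = bundle.landscape
    lines.append("")
    lines.append(
        f"essential genome: {ls.essential_bp} bp "
        f"({100 * ls.essential_fraction:.1f}% of the genome)"
    )
    if ls.essential_intergenic is not None:
        lines.append(f"essential intergenic regions (>100 bp): {len(ls.essential_intergenic)}")
    if bundle.domain_calls is not None and len(bundle.domain_calls):
        diff = bundle.domain_calls.groupby("orf_id")["differential"].first()
        lines.append(f"proteins with differential domain essentiality: {int(diff.sum())}")
    lines.append("")
    if bundle.signed_pairs is not None:
        sig = bundle.signed_pairs
        n_sig = int((sig["sign"] != "not significant").sum())
        n_anti = int((sig["sign"] == "anti-correlated").sum())
        n_corr = int((sig["sign"] == "correlated").sum())
        lines.append(
            f"ncRNA-ORF pairs: {len(sig)} tested, {n_sig} significant "
            f"(clr > {cfg.clr_threshold}): {n_anti} anti-correlated, {n_corr} correlated"
        )
        if bundle.welch is not None:
            w = bundle.welch
            lines.append(
                f"Welch test (%E anti vs corr partners): t={w.t:.3f} df={w.df:.2f} "
                f"p={w.pvalue:.3g} (means {w.mean1:.1f}% vs {w.mean2:.1f}%)"
            )
        if bundle.smorfs is not None:
            lines.append(f"smORF candidates in ncRNAs: {len(bundle.smorfs)}")
    else:
        lines.append("ncRNA analysis: not run")
    return "\n".join(lines) + "\n"
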
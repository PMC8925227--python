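"""End-to-end pipeline: simulate -> identify -> DE -> targets -> enrich ->
miRNA -> network, with a reproducibility manifest.

Each stage reads the plain-text artifacts of the previous one from the run
directory and writes its own, so any stage can be re-run in isolation.  The
manifest records, per stage, the SHA-256 of every input and output file and
the parameters used; wall times are kept in a separate ``timings`` block so
two runs of the same seed produce manifests that are identical apart from
it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import discovery, enrichment, expression, mirna, network, synthetic, targeting
from .io_formats import (
    AnnotationSet,
    read_expression,
    read_fasta,
    read_gff,
    write_gff,
)

__all__ = ["PipelineConfig", "run_all", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Thresholds and switches for a full run; defaults are the printed
    thresholds of the analysis this package reproduces."""

    min_length: int = 200
    min_fpkm: float = 0.5
    keep_single_exon: bool = True
    orf_min_codons: int = 100
    max_padj: float = 0.05
    min_abs_lfc: float = 1.0
    cis_window: int = 100_000
    trans_rmin: float = 0.95
    go_p: float = 0.05
    kegg_q: float = 0.05
    network_term_p: float = 0.05
    mirna_cutoff: float = 5.0
    common_target_mode: str = "any_lnc"
    seed: int = 1
    simulate: bool = True
    sim: synthetic.SimulationConfig = field(default_factory=synthetic.SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = synthetic.SimulationConfig(**sim_raw)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = asdict(self.sim)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: PipelineConfig):
        self.stages: list[dict] = []
        self.timings: dict[str, float] = {}
        self.config = config.to_dict()

    def record(self, stage: str, inputs: Mapping[str, Path], outputs: Mapping[str, Path],
               params: Mapping, elapsed: float) -> None:
        self.stages.append(
            {
                "stage": stage,
                "inputs": {k: _sha256(Path(p)) for k, p in sorted(inputs.items())},
                "outputs": {k: _sha256(Path(p)) for k, p in sorted(outputs.items())},
                "params": dict(sorted(params.items())),
            }
        )
        self.timings[stage] = round(elapsed, 4)

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {"config": self.config, "stages": self.stages, "timings": self.timings},
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the whole pipeline under ``outdir``; returns a results dict.

    With ``config.simulate`` the synthetic generator provides the inputs;
    otherwise ``outdir`` must already contain annotation.gff3,
    known_lnc.gff3, transcripts.fa, counts.tsv, mirna.fa, dems.tsv,
    terms.tsv (and optionally motifs.txt).  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    results: dict = {}

    # ---- simulate -------------------------------------------------------
    if config.simulate:
        t0 = time.perf_counter()
        sim = synthetic.simulate_all(config.sim, outdir)
        manifest.record(
            "simulate", {}, sim.paths, asdict(config.sim), time.perf_counter() - t0
        )
        results["sim"] = sim

    def _need(name: str, stage: str) -> Path:
        p = outdir / name
        if not p.exists():
            raise StageError(stage, f"required input {p} is missing")
        return p

    # ---- identify -------------------------------------------------------
    t0 = time.perf_counter()
    ann_path = _need("annotation.gff3", "identify")
    known_path = _need("known_lnc.gff3", "identify")
    fa_path = _need("transcripts.fa", "identify")
    counts_path = _need("counts.tsv", "identify")
    annotation = read_gff(ann_path)
    known = read_gff(known_path)
    sequences = read_fasta(fa_path)
    counts, conditions = read_expression(counts_path)
    lengths = pd.Series({t.transcript_id: t.length for t in annotation})
    fpkm = expression.compute_fpkm(counts, counts.sum(axis=0), lengths.reindex(counts.index))
    motifs_path = outdir / "motifs.txt"
    motif_list = (
        [m for m in motifs_path.read_text().split() if m] if motifs_path.exists() else []
    )
    thresholds = {
        "min_length": config.min_length,
        "min_fpkm": config.min_fpkm,
        "keep_single_exon": config.keep_single_exon,
        "orf_min_codons": config.orf_min_codons,
    }
    try:
        traces = discovery.filter_cascade(
            annotation, known, fpkm, sequences, thresholds, motif_list=motif_list
        )
    except Exception as exc:
        raise StageError("identify", str(exc)) from exc
    trace_df = discovery.traces_to_frame(traces)
    trace_path = outdir / "filter_trace.tsv"
    trace_df.to_csv(trace_path, sep="\t")
    lnc_ids = trace_df.index[trace_df["outcome"] != "rejected"].tolist()
    lnc_ann = AnnotationSet.from_transcripts(annotation[t] for t in lnc_ids)
    lnc_gff = outdir / "lncrna.gff3"
    write_gff(lnc_ann, lnc_gff)
    fpkm_path = outdir / "fpkm_computed.tsv"
    fpkm.to_csv(fpkm_path, sep="\t", index_label="feature_id", float_format="%.10g")
    manifest.record(
        "identify",
        {"annotation": ann_path, "known": known_path, "fasta": fa_path, "counts": counts_path},
        {"trace": trace_path, "lncrna": lnc_gff, "fpkm": fpkm_path},
        thresholds,
        time.perf_counter() - t0,
    )
    results["traces"] = trace_df
    results["lnc_ids"] = lnc_ids

    # ---- differential expression ---------------------------------------
    t0 = time.perf_counter()
    try:
        de = expression.exact_test_de(
            counts, conditions,
            max_padj=config.max_padj, min_abs_lfc=config.min_abs_lfc,
        )
    except Exception as exc:
        raise StageError("de", str(exc)) from exc
    de_path = outdir / "de_results.tsv"
    de.to_csv(de_path, sep="\t", float_format="%.8g")
    manifest.record(
        "de", {"counts": counts_path}, {"de": de_path},
        {"max_padj": config.max_padj, "min_abs_lfc": config.min_abs_lfc},
        time.perf_counter() - t0,
    )
    results["de"] = de
    delnc_ids = [t for t in lnc_ids if de.at[t, "de_flag"] != "ns"]
    results["delnc_ids"] = delnc_ids

    # ---- target prediction ----------------------------------------------
    t0 = time.perf_counter()
    coding = annotation.subset("coding")
    gene_spans = coding.genes
    tid_of_gene = {t.gene_id: t.transcript_id for t in coding}
    de_lnc_models = [annotation[t] for t in delnc_ids]
    cis = targeting.cis_targets(de_lnc_models, gene_spans, window=config.cis_window)
    gene_tids = sorted(tid_of_gene.values())
    trans_raw = targeting.trans_targets(
        delnc_ids, gene_tids, fpkm, r_min=config.trans_rmin
    ) if delnc_ids else []
    # trans links are computed transcript-vs-transcript; report them per gene
    tid2gene = {t.transcript_id: t.gene_id for t in coding}
    trans = [
        targeting.TargetLink(l.lnc_id, tid2gene[l.gene_id], "trans", r=l.r)
        for l in trans_raw
    ]
    gene_de_flags = {g: de.at[tid, "de_flag"] for g, tid in tid_of_gene.items()}
    common = targeting.common_targets(cis, trans, gene_de_flags, mode=config.common_target_mode)
    cis_path = outdir / "cis_targets.tsv"
    trans_path = outdir / "trans_targets.tsv"
    common_path = outdir / "common_targets.tsv"
    targeting.links_to_frame(cis).to_csv(cis_path, sep="\t", index=False)
    targeting.links_to_frame(trans).to_csv(trans_path, sep="\t", index=False, float_format="%.8g")
    common.to_frame().to_csv(common_path, sep="\t", index=False)
    manifest.record(
        "targets", {"de": de_path, "fpkm": fpkm_path},
        {"cis": cis_path, "trans": trans_path, "common": common_path},
        {"window": config.cis_window, "r_min": config.trans_rmin,
         "mode": config.common_target_mode},
        time.perf_counter() - t0,
    )
    results.update({"cis": cis, "trans": trans, "common": common})

    # ---- enrichment ------------------------------------------------------
    t0 = time.perf_counter()
    terms_path = _need("terms.tsv", "enrich")
    term_map = enrichment.read_term_map(terms_path)
    max_fpkm_by_gene: dict[str, float] = {}
    for g, tid in tid_of_gene.items():
        max_fpkm_by_gene[g] = float(fpkm.loc[tid].max())
    background = [g for g, v in sorted(max_fpkm_by_gene.items()) if v >= config.min_fpkm]
    foreground = [g for g in common.gene_ids if g in set(background)]
    if foreground:
        enrich = enrichment.hypergeom_enrich(
            foreground, background, term_map,
            go_p=config.go_p, pathway_q=config.kegg_q,
        )
    else:
        enrich = []
    enrich_path = outdir / "enrichment.tsv"
    enrichment.enrichment_to_frame(enrich).to_csv(
        enrich_path, sep="\t", index=False, float_format="%.8g"
    )
    manifest.record(
        "enrich", {"terms": terms_path, "common": common_path}, {"enrichment": enrich_path},
        {"go_p": config.go_p, "kegg_q": config.kegg_q}, time.perf_counter() - t0,
    )
    results["enrichment"] = enrich

    # ---- miRNA targeting -------------------------------------------------
    t0 = time.perf_counter()
    mirna_path = _need("mirna.fa", "mirna")
    dems_path = _need("dems.tsv", "mirna")
    all_mirna_seqs = read_fasta(mirna_path)
    dems = pd.read_csv(dems_path, sep="\t")
    missing_dem = [m for m in dems["mirna_id"] if m not in all_mirna_seqs]
    if missing_dem:
        raise StageError("mirna", f"DEMs without sequence: {missing_dem}")
    mirna_seqs = {m: all_mirna_seqs[m] for m in dems["mirna_id"]}
    delnc_seqs = {t: sequences[t] for t in delnc_ids}
    params = mirna.ScoringParams(cutoff=config.mirna_cutoff)
    try:
        links = mirna.dem_delnc_links(mirna_seqs, delnc_seqs, params) if delnc_seqs else (
            pd.DataFrame(columns=["mirna_id", "lnc_id", "site_start", "expectation", "alignment"])
        )
    except Exception as exc:
        raise StageError("mirna", str(exc)) from exc
    links_path = outdir / "mirna_lnc_links.tsv"
    links.to_csv(links_path, sep="\t", index=False, float_format="%.8g")
    manifest.record(
        "mirna", {"mirna": mirna_path, "dems": dems_path}, {"links": links_path},
        {"cutoff": config.mirna_cutoff}, time.perf_counter() - t0,
    )
    results["mirna_links"] = links

    # ---- network ---------------------------------------------------------
    t0 = time.perf_counter()
    delnc_dirs = {t: de.at[t, "de_flag"] for t in delnc_ids}
    dem_dirs = dict(zip(dems["mirna_id"], dems["direction"]))
    try:
        net = network.build_network(
            delnc_dirs, dem_dirs, common, links, enrich,
            term_map=term_map, term_p=config.network_term_p,
        )
    except Exception as exc:
        raise StageError("network", str(exc)) from exc
    written = network.export_network(net, ("sif", "graphml", "tsv"), outdir)
    manifest.record(
        "network",
        {"links": links_path, "enrichment": enrich_path, "common": common_path},
        written, {"term_p": config.network_term_p}, time.perf_counter() - t0,
    )
    results["network"] = net

    manifest.write(outdir / "manifest.json")
    results["manifest"] = outdir / "manifest.json"
    return results
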
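"""End-to-end orchestration of the localization analysis stages.

Stages run in a fixed order -- simulate (optional) -> normalize -> classify
-> homoeolog -> kmers -> scan -> cluster -- single-process and
deterministic under a fixed seed/config. Every output table is written
with a comment header naming the tool version and the config hash, and a
machine-readable JSON run report collects per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    MotifFile,
    read_cq_table, read_fasta_utrs, read_meme_minimal,
    read_segment_table, write_category_map, write_cq_table, write_fasta_utrs,
    write_meme_minimal, write_segment_table,
)
from .classify import classify_table, summarize
from .homoeolog import (annotate_categories, concordance, pair_homoeologs,
                        pair_motif_counts, pairs_table)
from .kmer_enrichment import enrichment_table, overrepresented_kmers
from .motif_cluster import cluster_motifs, family_table
from .motif_scan import Motif, presence_summary
from .normalization import (apply_size_factors, compute_size_factors,
                            filter_low_expression, to_fractions)
from .synthetic_data import SynthConfig, simulate_dataset

log = logging.getLogger(__name__)

ANIMAL_GROUP = ["extremely_animal"]
VEGETAL_GROUP = ["vegetal", "extremely_vegetal"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "tomoloc_out"
    simulate: bool = True
    # input paths when simulate is off
    counts: str | None = None
    cq: str | None = None
    utrs: str | None = None
    categories: str | None = None
    motifs: str | None = None
    # stage parameters
    expression_threshold: float = 15.0
    kmer_lengths: tuple[int, ...] = (3, 4, 5)
    alpha: float = 0.001
    scan_mode: str = "iupac"
    min_overlap: int = 4
    family_cut: float = 0.6
    pair_motifs: tuple[str, ...] = ("TTCAC", "TGCAC")
    synth: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        payload = yaml.safe_load(text) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t")


def run_all(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"tomoloc {__version__} config={config.config_hash()}"
    report: dict = {"version": __version__, "config_hash": config.config_hash(),
                    "seed": config.seed, "stages": {}}
    t0 = time.time()

    def stage(name):
        def deco(fn):
            try:
                t = time.time()
                info = fn() or {}
                info["status"] = "ok"
                info["seconds"] = round(time.time() - t, 2)
                report["stages"][name] = info
                log.info("stage %s ok (%.1fs)", name, info["seconds"])
            except Exception as exc:
                report["stages"][name] = {"status": "failed", "error": str(exc)}
                (out / "report.json").write_text(json.dumps(report, indent=1))
                raise StageError(name, exc) from exc
        return deco

    state: dict = {}
    if config.motifs:
        state["motifs"] = read_meme_minimal(config.motifs)

    @stage("simulate")
    def _simulate():
        if not config.simulate:
            if not (config.counts and config.cq):
                raise ValueError("simulate is off and no input counts/cq given")
            state["counts"] = read_segment_table(config.counts, "rna")
            state["cq"] = read_cq_table(config.cq)
            state["utrs"] = (read_fasta_utrs(config.utrs)
                             if config.utrs else None)
            state["truth"] = None
            return {"n_genes": len(state["counts"].gene_ids)}
        synth = SynthConfig(seed=config.seed, **config.synth)
        counts, cq, utrs, truth = simulate_dataset(synth)
        state.update(counts=counts, cq=cq, utrs=utrs, truth=truth)
        write_segment_table(counts, out / "counts.tsv", header)
        write_cq_table(cq, out / "cq.tsv")
        write_fasta_utrs(utrs, out / "utrs.fasta")
        truth.to_json(out / "ground_truth.json")
        return {"n_genes": len(counts.gene_ids), "n_anchors": len(truth.anchors)}

    @stage("normalize")
    def _normalize():
        counts, cq = state["counts"], state["cq"]
        factors = compute_size_factors(counts, cq)
        normed = apply_size_factors(counts, factors)
        kept = filter_low_expression(normed, config.expression_threshold)
        fractions = to_fractions(kept)
        state["fractions"] = fractions
        _write(factors.data, out / "size_factors.tsv", header)
        write_segment_table(kept, out / "normalized.tsv", header)
        _write(fractions.consensus, out / "fractions.tsv", header)
        return {"n_genes_kept": len(kept.gene_ids),
                "n_genes_in": len(counts.gene_ids)}

    @stage("classify")
    def _classify():
        labels = classify_table(state["fractions"], "rna")
        state["labels"] = labels
        summary = summarize(labels, "rna")
        write_category_map(dict(labels), out / "labels.tsv")
        _write(pd.DataFrame({"count": summary.counts,
                             "proportion": summary.proportions}),
               out / "classification_summary.tsv", header)
        return {"n_classified": len(labels),
                "proportions": {k: float(v)
                                for k, v in summary.proportions.items()}}

    @stage("homoeolog")
    def _homoeolog():
        labels = state["labels"]
        pairs, unpaired = pair_homoeologs(list(labels.index))
        classified, unpairable = annotate_categories(pairs, labels)
        if not classified:
            return {"n_pairs": 0, "n_unpaired": len(unpaired)}
        summary = concordance(classified)
        _write(pairs_table(classified), out / "homoeolog_pairs.tsv", header)
        _write(summary.contingency, out / "homoeolog_contingency.tsv", header)
        utrs = state.get("utrs")
        if utrs is not None and config.pair_motifs:
            counts = pair_motif_counts(classified, utrs.records,
                                       list(config.pair_motifs))
            _write(counts, out / "homoeolog_motif_counts.tsv", header)
        return {"n_pairs": summary.n_pairs,
                "n_unpairable": len(unpairable),
                "fraction_concordant": summary.fraction_concordant,
                "n_opposite": len(summary.opposite)}

    @stage("kmers")
    def _kmers():
        utrs = state.get("utrs")
        if utrs is None:
            raise ValueError("no UTR FASTA available for the kmers stage")
        labels = state["labels"]
        animal = {g: utrs.records[g] for g, c in labels.items()
                  if c in ANIMAL_GROUP and g in utrs.records}
        vegetal = {g: utrs.records[g] for g, c in labels.items()
                   if c in VEGETAL_GROUP and g in utrs.records}
        motifs = state.get("motifs")
        table = enrichment_table(animal, vegetal, ks=config.kmer_lengths,
                                 alpha=config.alpha, motifs=motifs)
        _write(table.set_index("k"), out / "kmer_summary.tsv", header)
        full = pd.concat([
            overrepresented_kmers(vegetal, k, config.alpha).assign(k=k)
            for k in config.kmer_lengths
        ])
        _write(full[full["significant"]].set_index("kmer"),
               out / "kmer_significant_vegetal.tsv", header)
        state["kmer_table"] = table
        return {"significant_kmers": {
            str(int(row["k"])): int(row["vegetal_overrepresented"])
            for _, row in table.iterrows()}}

    @stage("scan")
    def _scan():
        utrs = state.get("utrs")
        if utrs is None:
            raise ValueError("no UTR FASTA available for the scan stage")
        motifs = state.get("motifs")
        if motifs is None:
            motifs = MotifFile([Motif(id=m, consensus=m)
                                for m in config.pair_motifs], "builtin")
            state["motifs"] = motifs
        labels = state["labels"]
        by_cat: dict[str, dict[str, str]] = {}
        for g, cat in labels.items():
            if g in utrs.records:
                by_cat.setdefault(cat, {})[g] = utrs.records[g]
        by_cat = {c: u for c, u in by_cat.items() if u}
        table = presence_summary(by_cat, motifs.motifs, mode=config.scan_mode,
                                 alpha=config.alpha)
        _write(table.set_index(["motif", "category"]),
               out / "motif_presence.tsv", header)
        return {"n_motifs": len(motifs.motifs), "n_categories": len(by_cat)}

    @stage("cluster")
    def _cluster():
        motifs = state.get("motifs")
        if motifs is None or len(motifs.motifs) < 2:
            return {"skipped": "fewer than 2 motifs"}
        min_ov = min(config.min_overlap,
                     min(m.width for m in motifs.motifs))
        dmat, tree, families = cluster_motifs(motifs.motifs, min_ov,
                                              config.family_cut)
        (out / "motif_dendrogram.nwk").write_text(tree.to_newick() + "\n")
        _write(family_table(families).set_index("family"),
               out / "motif_families.tsv", header)
        consensus = [
            Motif(id=f"family{i + 1}", pwm=f.consensus_pwm)
            for i, f in enumerate(families) if f.consensus_pwm is not None
        ]
        write_meme_minimal(consensus, out / "motif_families.meme")
        return {"n_families": len(families)}

    report["seconds_total"] = round(time.time() - t0, 2)
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


def load_motifs(path: str | Path) -> MotifFile:
    return read_meme_minimal(path)
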
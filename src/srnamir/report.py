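"""End-to-end pipeline orchestration and human-readable reporting.

Runs the stages in method order — simulate, preprocess, classify,
discover, target calling — wiring each stage's output to the next, and
writes per-stage tables, a run manifest (config hash plus per-stage
counts) and a text report with the category table, family abundances,
novel-candidate table with folding statistics, and target hits.

A previously reported novel-miRNA candidate table (29 rows: mature and
star sequences, read counts, source ESTs, precursor lengths and folding
energies) ships as a package fixture so summary statistics can be
regression-tested against its printed values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
import logging
import os
from typing import Any, Optional

import pandas as pd
import yaml

from . import classify as classify_mod
from . import discover as discover_mod
from . import preprocess as preprocess_mod
from . import synthetic as synthetic_mod
from . import target_score as target_mod

logger = logging.getLogger("srnamir")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclasses.dataclass
class PipelineConfig:
    """Run parameters: simulation block plus per-stage overrides."""

    outdir: str = "run"
    seed: int = 0
    n_reads: int = 20_000
    simulate: dict[str, Any] = dataclasses.field(default_factory=dict)
    preprocess: dict[str, Any] = dataclasses.field(default_factory=dict)
    classify: dict[str, Any] = dataclasses.field(default_factory=dict)
    discover: dict[str, Any] = dataclasses.field(default_factory=dict)
    targets: dict[str, Any] = dataclasses.field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_novel_reference_table() -> pd.DataFrame:
    """The bundled 29-row novel-miRNA candidate reference table."""
    ref = importlib.resources.files("srnamir") / "data" / "novel_mirna_reference.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dictionary.

    Each stage's failure aborts the run with the stage name; outputs of
    completed stages are retained in ``config.outdir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict[str, Any] = {"config_hash": config.config_hash(),
                                "seed": config.seed, "counts": {}}

    # --- simulate ---------------------------------------------------------
    try:
        sim_kwargs = dict(config.simulate)
        sim = synthetic_mod.SimulationConfig(
            seed=config.seed, n_reads=config.n_reads, **sim_kwargs)
        references = synthetic_mod.make_reference_sets(sim)
        ests, planted = synthetic_mod.make_est_collection(sim)
        reads, truth = synthetic_mod.simulate_library(
            sim, references, planted,
            fastq_path=os.path.join(config.outdir, "reads.fastq"))
        for cls, seqs in references.items():
            synthetic_mod.write_fasta(
                seqs, os.path.join(config.outdir, f"ref_{cls}.fa"))
        synthetic_mod.write_fasta(
            ests, os.path.join(config.outdir, "ests.fa"))
        synthetic_mod.write_ground_truth(
            truth, os.path.join(config.outdir, "ground_truth.tsv"),
            os.path.join(config.outdir, "ground_truth.json"))
        manifest["counts"]["simulated_reads"] = len(reads)
        logger.info("simulate: %d reads, %d planted hairpins",
                    len(reads), len(planted))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # --- preprocess -------------------------------------------------------
    try:
        tags, stats = preprocess_mod.run_preprocess(
            os.path.join(config.outdir, "reads.fastq"),
            adapter3=sim.adapter3, **config.preprocess)
        stats.check()
        preprocess_mod.write_tags_fasta(
            tags, os.path.join(config.outdir, "tags.fa"))
        preprocess_mod.write_stats(
            stats, os.path.join(config.outdir, "preprocess_stats.tsv"))
        preprocess_mod.length_distribution(tags).to_csv(
            os.path.join(config.outdir, "length_distribution.tsv"),
            sep="\t", index=False)
        manifest["counts"].update(
            raw_reads=stats.n_raw, clean_reads=stats.n_clean,
            unique_tags=len(tags))
        logger.info("preprocess: %d raw -> %d clean (%d tags)",
                    stats.n_raw, stats.n_clean, len(tags))
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc

    # --- classify ---------------------------------------------------------
    try:
        priority = config.classify.get("priority",
                                       classify_mod.DEFAULT_PRIORITY)
        per_tag, summary = classify_mod.categorize(tags, references, priority)
        per_tag.to_csv(os.path.join(config.outdir, "tag_labels.tsv"),
                       sep="\t", index=False)
        summary.to_csv(os.path.join(config.outdir, "category_summary.tsv"),
                       sep="\t", index=False)
        hits = classify_mod.known_mirna_hits(per_tag, references["miRNA"])
        families = classify_mod.family_abundance(hits)
        families.to_csv(os.path.join(config.outdir, "family_abundance.tsv"),
                        sep="\t", index=False)
        manifest["counts"]["known_mirna_tags"] = int(
            (per_tag["label"] == "miRNA").sum())
        manifest["counts"]["unannotated_tags"] = int(
            (per_tag["label"] == classify_mod.UNANNOTATED).sum())
        logger.info("classify: %d categories", len(summary) - 1)
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc

    # --- discover ---------------------------------------------------------
    try:
        if not os.path.exists(os.path.join(config.outdir, "ests.fa")):
            raise FileNotFoundError("EST collection missing")
        unannotated_seqs = set(
            per_tag.loc[per_tag["label"] == classify_mod.UNANNOTATED,
                        "sequence"])
        pool = [t for t in tags if t.sequence in unannotated_seqs]
        criteria = discover_mod.DuplexCriteria(
            **config.discover.get("criteria", {}))
        result = discover_mod.discover_mirnas(
            pool, ests, criteria,
            engine=config.discover.get("engine", "auto"),
            flank=config.discover.get("flank", discover_mod.DEFAULT_FLANK))
        table = result.table()
        table.to_csv(os.path.join(config.outdir, "novel_candidates.tsv"),
                     sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(r) for r in result.rejections]).to_csv(
            os.path.join(config.outdir, "rejections.tsv"),
            sep="\t", index=False)
        with open(os.path.join(config.outdir, "precursors.fa"), "w") as fh:
            for cand in result.candidates:
                fh.write(f">{cand.name} {cand.est_id} mfe={cand.mfe:.2f}\n"
                         f"{cand.precursor_seq}\n{cand.structure}\n")
        manifest["counts"]["novel_candidates"] = len(result.candidates)
        logger.info("discover: %d candidates, %d rejections",
                    len(result.candidates), len(result.rejections))
    except Exception as exc:
        raise PipelineError("discover", str(exc)) from exc

    # --- targets ----------------------------------------------------------
    try:
        rng = __import__("numpy").random.default_rng(config.seed + 7)
        n_tx = config.targets.get("n_transcripts", 10)
        tx_len = config.targets.get("transcript_length", 600)
        transcripts = synthetic_mod.make_transcripts(n_tx, tx_len, rng)
        mirnas = {c.name: c.mature_seq.replace("U", "T")
                  for c in result.candidates}
        specs = []
        spec_pool = [synthetic_mod.DefectSpec(),
                     synthetic_mod.DefectSpec(mismatches=(10,)),
                     synthetic_mod.DefectSpec(mismatches=(3, 12))]
        tx_ids = sorted(transcripts)
        for i, name in enumerate(sorted(mirnas)):
            specs.append((name, tx_ids[i % len(tx_ids)],
                          spec_pool[i % len(spec_pool)]))
        if mirnas:
            transcripts, planted_sites = synthetic_mod.plant_target_sites(
                transcripts, mirnas, specs, rng)
            scheme = target_mod.ScoringScheme(
                accept_below=config.targets.get("max_score", 3.0))
            hits = target_mod.call_targets(
                mirnas, transcripts, scheme,
                max_indels=config.targets.get("max_indels", 1))
        else:
            hits = []
        hit_rows = [(h.alignment.mirna_id, h.alignment.transcript_id,
                     h.alignment.site_start + 1, h.alignment.site_end,
                     h.alignment.total_score) for h in hits]
        pd.DataFrame(hit_rows, columns=["mirna_id", "transcript_id",
                                        "site_start_1based", "site_end",
                                        "total_score"]).to_csv(
            os.path.join(config.outdir, "target_hits.tsv"),
            sep="\t", index=False)
        manifest["counts"]["target_hits"] = len(hits)
        logger.info("targets: %d accepted hits", len(hits))
    except Exception as exc:
        raise PipelineError("targets", str(exc)) from exc

    # --- report -----------------------------------------------------------
    try:
        report = render_summary(summary, families, table,
                                pd.DataFrame(hit_rows,
                                             columns=["mirna_id",
                                                      "transcript_id",
                                                      "site_start_1based",
                                                      "site_end",
                                                      "total_score"]))
        with open(os.path.join(config.outdir, "report.txt"), "w") as fh:
            fh.write(report)
        with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc
    return manifest


def render_summary(category_summary: pd.DataFrame,
                   family_table: pd.DataFrame,
                   novel_table: pd.DataFrame,
                   target_table: Optional[pd.DataFrame] = None) -> str:
    """Human-readable run report mirroring the published table layouts."""
    lines = ["# Small RNA category distribution", ""]
    lines.append(category_summary.to_string(index=False,
                                            float_format=lambda v: f"{v:.2f}"))
    lines += ["", "# Known miRNA family abundance", ""]
    if family_table.empty:
        lines.append("no known-miRNA hits")
    else:
        lines.append(family_table.to_string(index=False))
    lines += ["", "# Novel miRNA candidates", ""]
    if novel_table.empty:
        lines.append("no candidates")
    else:
        lines.append(novel_table.to_string(index=False))
        stats = discover_mod.summarize_novel(novel_table)
        lines += [
            "",
            f"folding energy: min {stats['min_mfe']}, "
            f"max {stats['max_mfe']}, mean {stats['mean_mfe']}",
            f"precursor length: {stats['min_precursor_length']}-"
            f"{stats['max_precursor_length']} nt; "
            f"{100 * stats['band_fraction']:.0f}% within 75-188 nt",
            f"families > 1000 reads: {stats['n_high_read_families']}; "
            f"families < 10 reads: {stats['n_low_read_families']}",
        ]
    lines += ["", "# Predicted targets", ""]
    if target_table is None or target_table.empty:
        lines.append("no targets")
    else:
        lines.append(target_table.to_string(index=False))
    return "\n".join(lines) + "\n"
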
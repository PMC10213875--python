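"""Pipeline orchestration: reference build -> QC -> annotation ->
quantification -> differential expression -> transgenerational overlap ->
cross-species homology.

Two entry points are provided.  :func:`run_all` drives the file-based
pipeline from a validated YAML configuration and writes per-stage TSV
outputs plus a content-hashed manifest, so re-runs on identical inputs are
verifiably identical.  :func:`run_synthetic_study` wires the synthetic
generator through the same stages in one call and scores the results
against the generator's truth tables; it is the package's end-to-end
self-check.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import qc as qc_mod
from .annotate import annotate_sequences, annotations_to_frame
from .diffexpr import Comparison, DEThresholds, run_comparison
from .homology import cross_species_pairs
from .quantify import FeatureCountMatrix, aggregate_mirna, cluster_identical
from .refdb import build_index, load_intron_table, preprocess_trna, read_fasta
from .synthetic import (
    LINEAGE_CONTRASTS,
    SimConfig,
    TruthTable,
    generate_references,
    build_feature_panel,
    simulate_counts,
    simulate_human_study,
    synthesize_reads,
    write_reference_fastas,
)
from .transgen import GenerationalCall, transgenerational_overlap, export_fc_heatmap_table

logger = logging.getLogger("sncpipe")

STAGES = ("refdb", "qc", "annotate", "quantify", "diffexpr", "transgen", "homology")


@dataclass
class PipelineConfig:
    """Validated file-based pipeline configuration."""

    references: dict[str, str]  # biotype -> FASTA path
    reads: dict[str, str]  # sample_id -> FASTQ path
    sample_sheet: str
    out_dir: str
    genome: Optional[str] = None
    trna_introns: Optional[str] = None
    contrasts: list[dict] = field(default_factory=list)  # treated/comparator
    qc: qc_mod.QCConfig = field(default_factory=qc_mod.QCConfig)
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    seed: int = 0


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    qc_cfg = qc_mod.QCConfig(**raw.get("qc", {}))
    thresholds = DEThresholds(**raw.get("thresholds", {}))
    return PipelineConfig(
        references=raw["references"],
        reads=raw["reads"],
        sample_sheet=raw["sample_sheet"],
        out_dir=raw["out_dir"],
        genome=raw.get("genome"),
        trna_introns=raw.get("trna_introns"),
        contrasts=raw.get("contrasts", []),
        qc=qc_cfg,
        thresholds=thresholds,
        seed=int(raw.get("seed", 0)),
    )


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Every violation names the offending field; an empty list means OK."""
    violations: list[str] = []
    for biotype, path in cfg.references.items():
        if biotype not in ("miRNA", "rRNA", "tRNA", "piRNA", "other_ncRNA"):
            violations.append(f"references.{biotype}: unknown biotype")
        elif not Path(path).is_file():
            violations.append(f"references.{biotype}: file not found: {path}")
    if cfg.genome and not Path(cfg.genome).is_file():
        violations.append(f"genome: file not found: {cfg.genome}")
    if cfg.trna_introns and not Path(cfg.trna_introns).is_file():
        violations.append(f"trna_introns: file not found: {cfg.trna_introns}")
    if not Path(cfg.sample_sheet).is_file():
        violations.append(f"sample_sheet: file not found: {cfg.sample_sheet}")
        return violations
    sheet = pd.read_csv(cfg.sample_sheet, sep="\t").set_index("sample_id")
    for sample_id, path in cfg.reads.items():
        if sample_id not in sheet.index:
            violations.append(f"reads.{sample_id}: sample not in sample sheet")
        if not Path(path).is_file():
            violations.append(f"reads.{sample_id}: file not found: {path}")
    known = set(sheet["lineage"]) if "lineage" in sheet.columns else set()
    for i, c in enumerate(cfg.contrasts):
        for role in ("treated", "comparator"):
            if role not in c:
                violations.append(f"contrasts[{i}].{role}: missing")
            elif known and c[role] not in known:
                violations.append(
                    f"contrasts[{i}].{role}: unknown lineage {c[role]!r}"
                )
    return violations


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException) -> None:
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in fixed order and write the output manifest.

    On failure, outputs of completed stages are left in place together with
    a failure marker naming the failed stage.
    """
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}}
    current = "refdb"

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            str(f.relative_to(out)): _sha256(f) for f in files
        }
        logger.info("stage %s: %d output file(s)", stage, len(files))

    try:
        # ---- refdb -------------------------------------------------------
        records = []
        introns = load_intron_table(cfg.trna_introns) if cfg.trna_introns else {}
        for biotype, path in cfg.references.items():
            for rec in read_fasta(path, biotype=biotype):
                if biotype == "tRNA" and not rec.processed:
                    if rec.ref_id in introns:
                        rec.intron_intervals = introns[rec.ref_id]
                    rec = preprocess_trna(rec)
                records.append(rec)
        genome = None
        if cfg.genome:
            from Bio import SeqIO

            genome = "".join(str(r.seq) for r in SeqIO.parse(cfg.genome, "fasta"))
        index = build_index(records, genome=genome)
        from .refdb import write_fasta

        ref_out = out / "references.fa"
        write_fasta(records, ref_out)
        record("refdb", [ref_out])

        # ---- qc ----------------------------------------------------------
        current = "qc"
        sheet = pd.read_csv(cfg.sample_sheet, sep="\t").set_index("sample_id")
        stats_list = []
        counts_by_sample: dict[str, dict[str, int]] = {}
        for sample_id, fastq in cfg.reads.items():
            stats, counts = qc_mod.run_qc(fastq, cfg.qc, sample_id=sample_id)
            stats_list.append(stats)
            counts_by_sample[sample_id] = counts
        qc_tsv, qc_json = out / "qc_stats.tsv", out / "qc_stats.json"
        qc_mod.write_qc_stats(stats_list, qc_tsv, qc_json)
        record("qc", [qc_tsv, qc_json])

        # ---- annotate ----------------------------------------------------
        current = "annotate"
        distinct = sorted({s for c in counts_by_sample.values() for s in c})
        annotations = annotate_sequences(distinct, index)
        ann_by_seq = {a.sequence: a for a in annotations}
        ann_tsv = out / "annotations.tsv"
        annotations_to_frame(annotations).to_csv(ann_tsv, sep="\t", index=False)
        record("annotate", [ann_tsv])

        # ---- quantify ----------------------------------------------------
        current = "quantify"
        clusters = cluster_identical(counts_by_sample, ann_by_seq)
        lib_sizes = {s.sample_id: s.retained for s in stats_list}
        sheet_used = sheet.loc[list(cfg.reads)]
        fcm = aggregate_mirna(clusters, sheet_used, lib_sizes)
        counts_tsv = out / "counts.tsv"
        info_tsv = out / "feature_info.tsv"
        lib_tsv = out / "library_sizes.tsv"
        fcm.counts.to_csv(counts_tsv, sep="\t")
        fcm.feature_info.to_csv(info_tsv, sep="\t")
        fcm.library_sizes.to_frame().to_csv(lib_tsv, sep="\t")
        record("quantify", [counts_tsv, info_tsv, lib_tsv])

        # ---- diffexpr ----------------------------------------------------
        current = "diffexpr"
        de_tables: dict[tuple[str, str], pd.DataFrame] = {}
        de_files = []
        generations = sorted(set(sheet_used["generation"])) if "generation" in sheet_used else [""]
        for c in cfg.contrasts:
            for gen in generations:
                mask = sheet_used["generation"] == gen if gen else slice(None)
                sub = sheet_used[mask] if gen else sheet_used
                ga = tuple(sub.index[sub["lineage"] == c["treated"]])
                gb = tuple(sub.index[sub["lineage"] == c["comparator"]])
                comp = Comparison(
                    name=f"{gen}:{c['treated']}_vs_{c['comparator']}",
                    group_a=ga,
                    group_b=gb,
                    generation=gen,
                    lineage=c["treated"],
                )
                res = run_comparison(fcm, comp, cfg.thresholds)
                de_tables[(c["treated"], gen)] = res
                path = out / f"de_{c['treated']}_vs_{c['comparator']}_{gen}.tsv"
                res.to_csv(path, sep="\t")
                de_files.append(path)
        record("diffexpr", de_files)

        # ---- transgen ----------------------------------------------------
        current = "transgen"
        tg_files = []
        biotypes = fcm.feature_info["biotype"].to_dict()
        for c in cfg.contrasts:
            lineage = c["treated"]
            if not {"F1", "F2", "F3"} <= {g for (ln, g) in de_tables if ln == lineage}:
                continue
            call = transgenerational_overlap(
                de_tables[(lineage, "F1")],
                de_tables[(lineage, "F2")],
                de_tables[(lineage, "F3")],
                lineage=lineage,
            )
            table = export_fc_heatmap_table(call, biotypes)
            path = out / f"transgen_{lineage}.tsv"
            table.to_csv(path, sep="\t", index=False)
            tg_files.append(path)
        record("transgen", tg_files)

        # ---- homology (file-based runs stop before the cross-species
        # stage unless a human DE table is wired in; recorded as empty) ----
        current = "homology"
        record("homology", [])
    except Exception as exc:  # noqa: BLE001 - failure attribution contract
        marker = out / "FAILED"
        marker.write_text(f"stage: {current}\nerror: {exc}\n")
        manifest["failed_stage"] = current
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise StageError(current, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Synthetic end-to-end study
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    truth: TruthTable
    qc_stats: list
    annotations: dict
    fcm: FeatureCountMatrix
    de_tables: dict
    transgen_calls: dict[str, GenerationalCall]
    human_de: pd.DataFrame
    pairs: pd.DataFrame
    pair_counts: pd.DataFrame
    metrics: dict


def _score_annotations(truth: TruthTable, ann_by_seq: dict) -> float:
    """Fraction of read species whose call matches the planted truth on
    biotype, subtype, Svedberg parent class and rescue flag."""
    total = 0
    good = 0
    for _, row in truth.panel.iterrows():
        total += 1
        a = ann_by_seq.get(row["sequence"])
        if a is None:
            continue
        ok = a.biotype == row["biotype"] and a.rescued == bool(row["rescued"])
        if row["biotype"] == "tsRNA":
            ok = ok and a.subtype == row["subtype"]
        if row["biotype"] == "rsRNA":
            ok = ok and a.parent_class == row["parent_class"]
        good += ok
    return good / total if total else float("nan")


def run_synthetic_study(
    cfg: SimConfig,
    workdir: str | Path,
    thresholds: DEThresholds = DEThresholds(),
    with_human: bool = True,
) -> StudyResult:
    """Generate a study, push it through every stage, score against truth.

    Reads are materialised as FASTQ on disk and re-enter through the same
    QC/annotation path a real study would use.
    """
    workdir = Path(workdir)
    rng = np.random.default_rng(cfg.seed)
    refset = generate_references(cfg, rng)
    panel = build_feature_panel(cfg, refset, rng)
    truth = simulate_counts(cfg, panel, rng)
    fastqs = synthesize_reads(truth, cfg, workdir / "reads", rng)
    ref_paths = write_reference_fastas(refset, workdir / "refs")

    records = []
    for biotype in ("miRNA", "rRNA", "tRNA", "piRNA", "other_ncRNA"):
        records.extend(read_fasta(ref_paths[biotype]))
    index = build_index(records, genome=refset.genome)

    qcc = qc_mod.QCConfig(adaptor=cfg.adaptor)
    stats_list = []
    counts_by_sample = {}
    for sample_id, path in fastqs.items():
        stats, counts = qc_mod.run_qc(path, qcc, sample_id=sample_id)
        stats_list.append(stats)
        counts_by_sample[sample_id] = counts

    distinct = sorted({s for c in counts_by_sample.values() for s in c})
    annotations = annotate_sequences(distinct, index)
    ann_by_seq = {a.sequence: a for a in annotations}

    clusters = cluster_identical(counts_by_sample, ann_by_seq)
    lib_sizes = {s.sample_id: s.retained for s in stats_list}
    fcm = aggregate_mirna(clusters, truth.samples, lib_sizes)

    de_tables: dict[tuple[str, str, str], pd.DataFrame] = {}
    for treated, comparator in LINEAGE_CONTRASTS:
        if treated not in cfg.lineages or comparator not in cfg.lineages:
            continue
        for gen in cfg.generations:
            sub = truth.samples[truth.samples["generation"] == gen]
            comp = Comparison(
                name=f"{gen}:{treated}_vs_{comparator}",
                group_a=tuple(sub.index[sub["lineage"] == treated]),
                group_b=tuple(sub.index[sub["lineage"] == comparator]),
                generation=gen,
                lineage=treated,
            )
            de_tables[(treated, comparator, gen)] = run_comparison(
                fcm, comp, thresholds
            )

    transgen_calls: dict[str, GenerationalCall] = {}
    for treated, comparator in LINEAGE_CONTRASTS:
        if treated not in cfg.lineages or comparator not in cfg.lineages:
            continue
        transgen_calls[treated] = transgenerational_overlap(
            de_tables[(treated, comparator, "F1")],
            de_tables[(treated, comparator, "F2")],
            de_tables[(treated, comparator, "F3")],
            lineage=treated,
        )

    # ---- scoring against truth -----------------------------------------
    metrics: dict = {}
    metrics["annotation_accuracy"] = _score_annotations(truth, ann_by_seq)

    n_true = n_called = n_wrong_dir = 0
    truth_by = truth.de_truth.set_index(["contrast", "generation", "feature_id"])
    for (treated, comparator, gen), table in de_tables.items():
        contrast = f"{treated}_vs_{comparator}"
        sub = truth.de_truth[
            (truth.de_truth["contrast"] == contrast)
            & (truth.de_truth["generation"] == gen)
        ]
        for _, row in sub.iterrows():
            n_true += 1
            fid = row["feature_id"]
            if fid in table.index and table.loc[fid, "de_status"] != "not_de":
                n_called += 1
                if table.loc[fid, "de_status"] != row["direction"]:
                    n_wrong_dir += 1
    metrics["de_sensitivity"] = n_called / n_true if n_true else float("nan")
    metrics["false_direction_rate"] = n_wrong_dir / n_called if n_called else 0.0
    metrics["n_true_de"] = n_true

    exact = True
    inter = union = 0
    for lineage, call in transgen_calls.items():
        t = truth.transgen_truth[lineage]
        exact = exact and call.transgenerational_up == t["up"]
        exact = exact and call.transgenerational_down == t["down"]
        rec = call.transgenerational_up | call.transgenerational_down
        tru = t["up"] | t["down"]
        inter += len(rec & tru)
        union += len(rec | tru)
    metrics["transgen_exact"] = bool(exact)
    metrics["transgen_jaccard"] = inter / union if union else 1.0

    human_de = pd.DataFrame()
    pairs = pd.DataFrame()
    pair_counts = pd.DataFrame()
    if with_human:
        human = simulate_human_study(cfg, truth, rng)
        hfcm = FeatureCountMatrix(
            counts=human.counts,
            samples=human.samples,
            library_sizes=human.library_sizes,
            feature_info=human.features,
        )
        comp = Comparison(
            name="human:pcos_vs_control",
            group_a=tuple(human.samples.index[human.samples["group"] == "pcos"]),
            group_b=tuple(human.samples.index[human.samples["group"] == "control"]),
        )
        human_de = run_comparison(hfcm, comp, thresholds)
        de_mask = human_de["de_status"] != "not_de"
        queries = human.features.loc[human_de.index[de_mask]].copy()
        queries["direction"] = human_de.loc[de_mask, "de_status"]

        subject_sets = {}
        info = fcm.feature_info
        for lineage, call in transgen_calls.items():
            fids = sorted(call.transgenerational)
            subject_sets[lineage] = pd.DataFrame(
                {
                    "sequence": [info.loc[f, "sequence"] for f in fids],
                    "biotype": [info.loc[f, "biotype"] for f in fids],
                    "direction": [
                        "up" if f in call.transgenerational_up else "down"
                        for f in fids
                    ],
                },
                index=pd.Index(fids, name="feature_id"),
            )
        pairs, pair_counts = cross_species_pairs(queries, subject_sets)

        planted = {
            (r["lineage"], r["query_id"], r["subject_id"])
            for _, r in human.planted_pairs.iterrows()
        }
        found = {
            (r["lineage"], r["query_id"], r["subject_id"])
            for _, r in pairs.iterrows()
        }
        metrics["homolog_exact"] = found == planted
        metrics["homolog_jaccard"] = (
            len(found & planted) / len(found | planted) if found | planted else 1.0
        )

    return StudyResult(
        truth=truth,
        qc_stats=stats_list,
        annotations=ann_by_seq,
        fcm=fcm,
        de_tables=de_tables,
        transgen_calls=transgen_calls,
        human_de=human_de,
        pairs=pairs,
        pair_counts=pair_counts,
        metrics=metrics,
    )
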
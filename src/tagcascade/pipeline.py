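"""End-to-end pipeline assembly: wires the library stages into a StepGraph.

The step sequence is specialized to the sequencing configuration —
paired short reads get screen -> sync -> (trim) -> merge -> primer ->
qfilter; single-end configurations drop sync/merge; long (PacBio-CCS)
runs use the PacBio cascade variant with primer re-orientation — followed
by cascade -> classify -> tables -> summary -> diversity.  Every stage
writes its outputs and counts under the working directory, so the runner
can resume and the summary step can compile the read-count trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import read_qc, clustering, chimera, taxonomy, feature_table, diversity as div
from .seq_io import (
    SeqRecord, read_fastq, write_fastq, read_fasta, read_newick,
    read_feature_table, write_feature_table, write_sized_fasta, FeatureTable,
)
from .runner import Step, StepGraph, ConfigError, execute
from .simulate import synthetic_phix, synthetic_adapter

AMPLICON_DOMAIN = {"16S": "bacteria_archaea", "ITS": "fungi", "18S": "eukaryota"}


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    workdir: Path
    amplicon_type: str = "16S"
    read_mode: str = "paired"  # paired | single | long
    r1: Optional[Path] = None
    r2: Optional[Path] = None
    reference_fasta: Optional[Path] = None
    tree: Optional[Path] = None
    phix_fasta: Optional[Path] = None
    contaminant_fasta: Optional[Path] = None
    primer_fwd: str = ""
    primer_rev: str = ""
    orient: bool = False
    trim_length: Optional[int] = None
    qc: read_qc.QCParams = field(default_factory=read_qc.QCParams)
    screen: read_qc.ScreenParams = field(default_factory=read_qc.ScreenParams)
    merge: read_qc.MergeParams = field(default_factory=read_qc.MergeParams)
    cascade: clustering.CascadeParams = field(default_factory=clustering.CascadeParams)
    chimera: chimera.ChimeraParams = field(default_factory=chimera.ChimeraParams)
    n_bootstrap: int = 100
    lineage_cutoff: float = 0.5
    rarefaction_depth: int = 1000
    rarefaction_reps: int = 500
    seed: int = 0
    sample_separator: str = "."

    def __post_init__(self) -> None:
        self.workdir = Path(self.workdir)
        if self.amplicon_type not in AMPLICON_DOMAIN:
            raise ConfigError(f"unknown amplicon type {self.amplicon_type!r}")
        if self.read_mode not in ("paired", "single", "long"):
            raise ConfigError(f"unknown read mode {self.read_mode!r}")
        if self.read_mode == "paired" and self.r2 is None and self.r1 is not None:
            raise ConfigError("paired mode needs --r2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, klass in (
            ("qc", read_qc.QCParams), ("screen", read_qc.ScreenParams),
            ("merge", read_qc.MergeParams), ("cascade", clustering.CascadeParams),
            ("chimera", chimera.ChimeraParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        for key in ("workdir", "r1", "r2", "reference_fasta", "tree",
                    "phix_fasta", "contaminant_fasta"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        return cls(**kwargs)

    def sample_of(self, read_id: str) -> str:
        return read_id.split(self.sample_separator)[0]


def _write_counts(path: Path, counts: dict) -> None:
    with open(path, "w") as fh:
        json.dump(counts, fh, indent=2)


def _read_counts(path: Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------- step bodies


def _step_screen(cfg: PipelineConfig, params: dict):
    wd = cfg.workdir
    phix_refs = list(read_fasta(cfg.phix_fasta)) if cfg.phix_fasta else [synthetic_phix()]
    contam_refs = (
        list(read_fasta(cfg.contaminant_fasta)) if cfg.contaminant_fasta
        else [synthetic_adapter()]
    )
    counts = {}
    for label, path in (("r1", cfg.r1), ("r2", cfg.r2)):
        if path is None:
            continue
        res = read_qc.screen_contaminants(
            read_fastq(path), phix_refs, contam_refs, cfg.screen
        )
        write_fastq(res.kept, wd / f"screened_{label}.fastq")
        counts[label] = res.counts
    total = sum(c["total"] for c in counts.values())
    agg = {
        "total_reads": total,
        "contaminant_reads": sum(c["contaminant"] for c in counts.values()),
        "phix_reads": sum(c["phix"] for c in counts.values()),
        "surviving_reads": sum(c["kept"] for c in counts.values()),
        "per_stream": counts,
    }
    _write_counts(wd / "screen_counts.json", agg)
    return agg


def _step_sync(cfg: PipelineConfig, params: dict):
    wd = cfg.workdir
    pairs, orphans = read_qc.sync_pairs(
        read_fastq(wd / "screened_r1.fastq"), read_fastq(wd / "screened_r2.fastq")
    )
    write_fastq((p[0] for p in pairs), wd / "synced_r1.fastq")
    write_fastq((p[1] for p in pairs), wd / "synced_r2.fastq")
    counts = {"paired_reads": 2 * len(pairs), "pairs": len(pairs), "orphans": orphans}
    _write_counts(wd / "sync_counts.json", counts)
    return counts


def _step_trim(cfg: PipelineConfig, params: dict):
    wd = cfg.workdir
    length = params["length"]
    src = wd / ("merged.fastq" if cfg.read_mode == "paired" else "screened_r1.fastq")
    kept, dropped = [], 0
    for rec in read_fastq(src):
        t = read_qc.trim_fixed(rec, length)
        if t is None:
            dropped += 1
        else:
            kept.append(t)
    write_fastq(kept, wd / "trimmed.fastq")
    counts = {"trimmed_reads": len(kept), "dropped_short": dropped}
    _write_counts(wd / "trim_counts.json", counts)
    return counts


def _step_merge(cfg: PipelineConfig, params: dict):
    wd = cfg.workdir
    r1 = list(read_fastq(wd / "synced_r1.fastq"))
    r2 = list(read_fastq(wd / "synced_r2.fastq"))
    merged = []
    for f, r in zip(r1, r2):
        m = read_qc.merge_pairs(f, r, cfg.merge)
        if m is not None:
            merged.append(m)
    write_fastq(merged, wd / "merged.fastq")
    counts = {"assembled_reads": len(merged), "unmerged_pairs": len(r1) - len(merged)}
    _write_counts(wd / "merge_counts.json", counts)
    return counts


def _primer_input(cfg: PipelineConfig) -> Path:
    wd = cfg.workdir
    if cfg.trim_length is not None and (wd / "trimmed.fastq").exists():
        return wd / "trimmed.fastq"
    if cfg.read_mode == "paired":
        return wd / "merged.fastq"
    return wd / "screened_r1.fastq"


def _step_primer(cfg: PipelineConfig, params: dict):
    wd = cfg.workdir
    if not cfg.primer_fwd:
        src = _primer_input(cfg)
        reads = list(read_fastq(src))
        write_fastq(reads, wd / "primer_trimmed.fastq")
        counts = {"primer_matched_reads": len(reads), "primer_discarded": 0}
    else:
        spec = read_qc.PrimerSpec(cfg.primer_fwd, cfg.primer_rev)
        kept, dropped = [], 0
        for rec in read_fastq(_primer_input(cfg)):
            out = read_qc.handle_primers(rec, spec, orient=cfg.orient)
            if out is None:
                dropped += 1
            else:
                kept.append(out)
        write_fastq(kept, wd / "primer_trimmed.fastq")
        counts = {"primer_matched_reads": len(kept), "primer_discarded": dropped}
    _write_counts(wd / "primer_counts.json", counts)
    return counts


def _step_qfilter(cfg: PipelineConfig, params: dict):
    wd = cfg.workdir
    kept, reasons = [], {}
    for rec in read_fastq(wd / "primer_trimmed.fastq"):
        ok, reason = read_qc.quality_filter(rec, cfg.qc)
        if ok:
            kept.append(rec)
        else:
            reasons[reason] = reasons.get(reason, 0) + 1
    write_fastq(kept, wd / "filtered.fastq")
    counts = {"qc_passed_reads": len(kept), "failed": reasons}
    _write_counts(wd / "qfilter_counts.json", counts)
    return counts


def _step_cascade(cfg: PipelineConfig, params: dict):
    wd = cfg.workdir
    reads = read_fastq(wd / "filtered.fastq")
    refs = list(read_fasta(cfg.reference_fasta)) if cfg.reference_fasta else None
    cascade_params = cfg.cascade
    if cfg.read_mode == "long" and not cascade_params.pacbio_mode:
        cascade_params = clustering.CascadeParams(
            denoise_identity=cascade_params.denoise_identity,
            final_identity=cascade_params.final_identity,
            min_cluster_size=cascade_params.min_cluster_size,
            pacbio_mode=True,
            pacbio_min_size=cascade_params.pacbio_min_size,
        )
    final, counts = clustering.run_cascade(reads, cascade_params, refs, cfg.chimera)
    ordered = sorted(final, key=lambda cl: (-cl.abundance, cl.centroid.seq))
    entries, members = [], {}
    for i, cl in enumerate(ordered):
        fid = f"OTU_{i + 1}"
        entries.append((SeqRecord(fid, cl.centroid.seq), cl.abundance))
        members[fid] = cl.member_ids
    write_sized_fasta(entries, wd / "centroids.fasta")
    with open(wd / "cluster_members.json", "w") as fh:
        json.dump(members, fh)
    _write_counts(wd / "cascade_counts.json", counts)
    return counts


def _step_classify(cfg: PipelineConfig, params: dict):
    wd = cfg.workdir
    if cfg.reference_fasta is None:
        raise ConfigError("classification requires a reference FASTA with lineages")
    refs = [(rec, rec.desc) for rec in read_fasta(cfg.reference_fasta)]
    ts = taxonomy.build_training_set(refs)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    from .seq_io import read_sized_fasta

    for rec, size in read_sized_fasta(wd / "centroids.fasta"):
        c = taxonomy.classify(rec.seq, ts, n_bootstrap=cfg.n_bootstrap, seed=rng)
        lin = taxonomy.reconstruct_lineage(c, cfg.lineage_cutoff)
        rows.append((rec.id, str(lin), c))
    with open(wd / "lineages.tsv", "w") as fh:
        fh.write("feature_id\tlineage\tconfidences\n")
        for fid, lin, c in rows:
            confs = ",".join(f"{x:.2f}" for x in c.confidences)
            fh.write(f"{fid}\t{lin}\t{confs}\n")
    return {"classified": len(rows)}


def _read_lineages(wd: Path) -> dict[str, str]:
    out = {}
    with open(wd / "lineages.tsv") as fh:
        next(fh)
        for line in fh:
            fid, lin, _ = line.rstrip("\n").split("\t")
            out[fid] = lin
    return out


def _step_tables(cfg: PipelineConfig, params: dict):
    wd = cfg.workdir
    with open(wd / "cluster_members.json") as fh:
        members = json.load(fh)
    lineages = _read_lineages(wd)
    clusters = []
    from .seq_io import read_sized_fasta
    from .clustering import Cluster, DerepSeq

    for rec, size in read_sized_fasta(wd / "centroids.fasta"):
        d = DerepSeq(seq=rec.seq, size=size, id=rec.id, member_ids=members[rec.id])
        clusters.append(Cluster(centroid=d, members=[d]))
    table = feature_table.build_table(
        clusters, cfg.sample_of, {c.centroid.id: lineages.get(c.centroid.id, "")
                                  for c in clusters},
    )
    write_feature_table(table, wd / "table_raw.tsv")
    domain = AMPLICON_DOMAIN[cfg.amplicon_type]
    filtered = feature_table.filter_by_domain(table, domain)
    write_feature_table(filtered, wd / "table_domain.tsv")
    rp = feature_table.RarefactionParams(
        depth=cfg.rarefaction_depth, n_reps=cfg.rarefaction_reps, seed=cfg.seed
    )
    consensus = feature_table.consensus_rarefy(filtered, rp)
    write_feature_table(consensus, wd / "table_consensus.tsv")
    counts = {
        "raw_table_reads": int(table.counts.sum()),
        "domain_table_reads": int(filtered.counts.sum()),
        "features": len(table.feature_ids),
        "domain_features": len(filtered.feature_ids),
    }
    _write_counts(wd / "table_counts.json", counts)
    return counts


def _step_summary(cfg: PipelineConfig, params: dict):
    wd = cfg.workdir
    screen = _read_counts(wd / "screen_counts.json")
    stages: list[tuple[str, int]] = [
        ("total_reads", screen["total_reads"]),
        ("contaminant_reads", screen["contaminant_reads"]),
        ("phix_reads", screen["phix_reads"]),
        ("surviving_reads", screen["surviving_reads"]),
    ]
    if cfg.read_mode == "paired":
        sync = _read_counts(wd / "sync_counts.json")
        stages.append(("paired_reads", sync["paired_reads"]))
        merge = _read_counts(wd / "merge_counts.json")
        stages.append(("assembled_reads", merge["assembled_reads"]))
    if (wd / "trim_counts.json").exists():
        trim = _read_counts(wd / "trim_counts.json")
        stages.append(("trimmed_reads", trim["trimmed_reads"]))
    primer = _read_counts(wd / "primer_counts.json")
    stages.append(("primer_matched_reads", primer["primer_matched_reads"]))
    qf = _read_counts(wd / "qfilter_counts.json")
    stages.append(("qc_passed_reads", qf["qc_passed_reads"]))
    cascade = _read_counts(wd / "cascade_counts.json")
    stages.append(("clustered_reads", cascade["clustered_reads"]))
    stages.append(("clusters", cascade["final_clusters"]))
    # the retained-read trajectory must be monotone non-increasing; the
    # paired->assembled transition halves the unit (pairs merge into one
    # fragment), which is itself a decrease
    not_retained = {"contaminant_reads", "phix_reads", "clusters"}
    retained = [name for name, _ in stages if name not in not_retained]
    summary = feature_table.read_count_summary(stages, retained)
    with open(wd / "summary.tsv", "w") as fh:
        fh.write(summary.to_tsv())
    _write_counts(wd / "summary.json", summary.as_dict())
    return summary.as_dict()


def _aggregate_by_genus(table: FeatureTable) -> FeatureTable:
    """Collapse features to the genus rank of their lineage (features not
    classified to genus depth are dropped)."""
    rows: dict[str, np.ndarray] = {}
    for i, fid in enumerate(table.feature_ids):
        lin = (table.lineage or {}).get(fid, "")
        parts = [p for p in lin.split(";") if p]
        if len(parts) < 6:
            continue
        genus = parts[5]
        rows[genus] = rows.get(genus, 0) + table.counts[i, :]
    if not rows:
        raise ValueError("no feature classified to genus depth")
    genera = sorted(rows)
    counts = np.vstack([rows[g] for g in genera])
    return FeatureTable(genera, list(table.sample_ids), counts)


def _step_diversity(cfg: PipelineConfig, params: dict):
    wd = cfg.workdir
    consensus = read_feature_table(wd / "table_consensus.tsv")
    obs = div.observed_features(consensus)
    obs.to_csv(wd / "observed_features.tsv", sep="\t", header=True)
    bc = div.bray_curtis(consensus)
    bc.to_data_frame().to_csv(wd / "bray_curtis.tsv", sep="\t")
    out = {"observed_features": {k: int(v) for k, v in obs.items()}}
    if cfg.tree is not None:
        tree = read_newick(cfg.tree)
        genus_table = _aggregate_by_genus(consensus)
        wu = div.unifrac(genus_table, tree, weighted=True, strict=False)
        uu = div.unifrac(genus_table, tree, weighted=False, strict=False)
        wu.to_data_frame().to_csv(wd / "weighted_unifrac.tsv", sep="\t")
        uu.to_data_frame().to_csv(wd / "unweighted_unifrac.tsv", sep="\t")
        if len(bc.ids) >= 3:
            r, p = div.mantel(wu, bc, n_perm=999, seed=cfg.seed)
            out["mantel_wunifrac_vs_braycurtis"] = {"r": r, "p": p}
    _write_counts(wd / "diversity.json", out)
    return out


def build_step_graph(cfg: PipelineConfig) -> StepGraph:
    """The step DAG specialized to the sequencing configuration."""
    if cfg.r1 is None:
        raise ConfigError("config names no input reads")
    cfg.workdir.mkdir(parents=True, exist_ok=True)
    g = StepGraph()

    def add(name, func, deps, params=None, inputs=None):
        g.add(Step(name=name, func=lambda p, f=func: f(cfg, p),
                   params={"step": name, **(params or {})}, dependencies=deps,
                   inputs=[Path(p) for p in (inputs or [])]))

    raw_inputs = [p for p in (cfg.r1, cfg.r2) if p is not None]
    add("screen", _step_screen, [],
        {"k": cfg.screen.k, "min_hits": cfg.screen.min_hits}, inputs=raw_inputs)
    pre = "screen"
    if cfg.read_mode == "paired":
        add("sync", _step_sync, ["screen"])
        add("merge", _step_merge, ["sync"],
            {"min_overlap": cfg.merge.min_overlap,
             "max_mismatch_ratio": cfg.merge.max_mismatch_ratio})
        pre = "merge"
    if cfg.trim_length is not None:
        add("trim", _step_trim, [pre], {"length": cfg.trim_length})
        pre = "trim"
    add("primer", _step_primer, [pre],
        {"fwd": cfg.primer_fwd, "rev": cfg.primer_rev, "orient": cfg.orient})
    add("qfilter", _step_qfilter, ["primer"],
        {"min_avg_q": cfg.qc.min_avg_q, "max_n": cfg.qc.max_n,
         "low_q_threshold": cfg.qc.low_q_threshold,
         "max_low_q_bases": cfg.qc.max_low_q_bases})
    add("cascade", _step_cascade, ["qfilter"],
        {"denoise_identity": cfg.cascade.denoise_identity,
         "final_identity": cfg.cascade.final_identity,
         "min_cluster_size": cfg.cascade.min_cluster_size,
         "pacbio": cfg.read_mode == "long"})
    add("classify", _step_classify, ["cascade"],
        {"n_bootstrap": cfg.n_bootstrap, "cutoff": cfg.lineage_cutoff,
         "seed": cfg.seed})
    add("tables", _step_tables, ["classify"],
        {"depth": cfg.rarefaction_depth, "reps": cfg.rarefaction_reps,
         "seed": cfg.seed, "domain": AMPLICON_DOMAIN[cfg.amplicon_type]})
    add("summary", _step_summary, ["tables"])
    add("diversity", _step_diversity, ["tables"], {"seed": cfg.seed})
    g.order()  # validates acyclicity and dependency names
    return g


def run_pipeline(cfg: PipelineConfig, resume: bool = False, state_dir=None):
    """Build and execute the pipeline; returns the run report."""
    graph = build_step_graph(cfg)
    state = Path(state_dir) if state_dir else cfg.workdir / ".tagstate"
    return execute(graph, state, resume=resume)
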
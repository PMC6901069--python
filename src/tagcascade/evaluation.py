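"""Truth-table scoring of a pipeline run against its simulated ground truth.

Given a completed working directory and the :class:`~tagcascade.simulate.
SimulatedRun` that produced its inputs, these helpers measure what the
mock-community design lets us know exactly: how many final OTUs were
formed, what fraction of retained reads sit in a cluster whose assigned
genus matches the read's source template, how well injected chimeras are
detected against the final centroid pool, and whether the PhiX spike was
fully recovered by the screening stage.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from .chimera import ChimeraParams, detect_chimera
from .seq_io import read_fastq, read_sized_fasta
from .simulate import SimulatedRun


def genus_of_lineage(lineage: str) -> Optional[str]:
    parts = [p for p in lineage.split(";") if p]
    return parts[5] if len(parts) >= 6 else None


def genus_accuracy(
    truth: dict[str, dict],
    members: dict[str, list[str]],
    lineages: dict[str, str],
) -> tuple[int, int]:
    """(correct, retained): a retained read is correct iff its cluster's
    assigned genus equals its true source genus.  Reads of non-template
    origin (chimera/PhiX/adapter) that slipped into a cluster count as
    incorrect."""
    correct = total = 0
    for fid, ids in members.items():
        genus = genus_of_lineage(lineages.get(fid, ""))
        for rid in ids:
            total += 1
            entry = truth.get(rid)
            if entry and entry["category"] == "template" and entry["taxon"] == genus:
                correct += 1
    return correct, total


def chimera_detection_stats(
    workdir,
    run: SimulatedRun,
    params: ChimeraParams = ChimeraParams(),
    max_queries: int = 200,
) -> dict[str, int]:
    """Detection performance on the injected chimeras.

    Queries are the quality-filtered reads whose truth category is
    ``chimera`` (primer-trimmed, carrying residual sequencing error); the
    parent pool is the final centroid set with its abundances, under the
    de novo eligibility rule.  False positives are counted by testing each
    pure final centroid against the remaining centroids the same way.
    """
    wd = Path(workdir)
    centroids = list(read_sized_fasta(wd / "centroids.fasta"))
    queries = []
    for rec in read_fastq(wd / "filtered.fastq"):
        entry = run.truth.get(rec.id)
        if entry and entry["category"] == "chimera":
            queries.append(rec)
        if len(queries) >= max_queries:
            break
    pool = [(rec.id, rec.seq) for rec, size in centroids
            if size >= params.min_parent_ratio]  # queries have size 1
    flagged = sum(1 for q in queries if detect_chimera(q.seq, pool, params).chimeric)
    # pure centroids tested against every other centroid, with no abundance
    # gate, so the zero-false-positive claim is not vacuous on an even mock
    false_pos = 0
    for rec, size in centroids:
        others = [(o.id, o.seq) for o, _ in centroids if o.id != rec.id]
        if detect_chimera(rec.seq, others, params).chimeric:
            false_pos += 1
    return {
        "tested": len(queries),
        "flagged": flagged,
        "centroids": len(centroids),
        "false_positives": false_pos,
    }


def evaluate_mock_run(workdir, run: SimulatedRun) -> dict:
    """Full scorecard of one pipeline run on one simulated mock community."""
    wd = Path(workdir)
    with open(wd / "cluster_members.json") as fh:
        members = json.load(fh)
    lineages = {}
    with open(wd / "lineages.tsv") as fh:
        next(fh)
        for line in fh:
            fid, lin, _ = line.rstrip("\n").split("\t")
            lineages[fid] = lin
    with open(wd / "summary.json") as fh:
        summary = json.load(fh)
    correct, total = genus_accuracy(run.truth, members, lineages)
    chim = chimera_detection_stats(wd, run)
    out = {
        "final_otus": summary["clusters"],
        "expected_taxa": len(run.templates),
        "retained_reads": total,
        "genus_correct_reads": correct,
        "genus_accuracy": correct / total if total else 0.0,
        "phix_injected": 2 * run.truth_counts("phix") if run.r2 is not None
        else run.truth_counts("phix"),
        "phix_detected": summary["phix_reads"],
        "chimera": chim,
    }
    return out
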
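"""Feature tables: construction from clusters, domain filtering, consensus
multi-rarefaction normalization, and the per-stage read-count summary.

Rarefaction draws exactly ``depth`` reads per sample without replacement
(multivariate hypergeometric); consensus rarefaction averages many such
draws cell-wise, which preserves the per-sample depth exactly while
keeping low-abundance features that any single rarefaction would
stochastically drop.  Means are kept fractional — rounding would break
depth conservation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .seq_io import FeatureTable
from .clustering import Cluster
from .taxonomy import Lineage

logger = logging.getLogger(__name__)

DOMAIN_TARGETS = {
    "bacteria_archaea": {"Bacteria", "Archaea"},
    "fungi": {"Fungi"},
    "eukaryota": {"Eukaryota", "Eukarya"},
}


@dataclass
class RarefactionParams:
    """Depth, replicate count (default 500) and master seed."""

    depth: int
    n_reps: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def build_table(
    clusters: Sequence[Cluster],
    sample_of: Callable[[str], str],
    lineages: Optional[dict[str, str]] = None,
    feature_prefix: str = "OTU",
) -> FeatureTable:
    """Raw integer feature table from final clusters.

    Features are named ``<prefix>_<i>`` in decreasing-abundance order;
    cell (f, s) counts the member reads of feature f belonging to sample
    s, so the table total equals the summed cluster abundances.  An id the
    ``sample_of`` mapping cannot resolve is an error naming it.
    """
    ordered = sorted(
        enumerate(clusters), key=lambda t: (-t[1].abundance, t[1].centroid.seq)
    )
    feature_ids = [f"{feature_prefix}_{i + 1}" for i in range(len(ordered))]
    sample_ids: list[str] = []
    rows: list[dict[str, int]] = []
    for _, cl in ordered:
        row: dict[str, int] = {}
        for member_id in cl.member_ids:
            sample = sample_of(member_id)
            if sample is None:
                raise ValueError(f"read id {member_id!r} resolves to no sample")
            if sample not in sample_ids:
                sample_ids.append(sample)
            row[sample] = row.get(sample, 0) + 1
        rows.append(row)
    counts = np.zeros((len(rows), len(sample_ids)), dtype=float)
    for i, row in enumerate(rows):
        for s, c in row.items():
            counts[i, sample_ids.index(s)] = c
    lin = None
    if lineages is not None:
        lin = {}
        for fid, (orig_idx, cl) in zip(feature_ids, ordered):
            key = cl.centroid.id or cl.centroid.seq
            if key in lineages:
                lin[fid] = lineages[key]
    return FeatureTable(feature_ids, sample_ids, counts, lin)


def filter_by_domain(table: FeatureTable, target: str) -> FeatureTable:
    """Keep features whose kingdom-rank name is in the target set.

    Targets: ``bacteria_archaea`` (16S), ``fungi`` (ITS), ``eukaryota``
    (18S).  Features unclassified at kingdom (or without a lineage) are
    dropped.  Sample order is preserved.
    """
    if target not in DOMAIN_TARGETS:
        raise ValueError(f"unknown domain target {target!r}")
    wanted = DOMAIN_TARGETS[target]
    lineage = table.lineage or {}
    keep = []
    for fid in table.feature_ids:
        lin = lineage.get(fid, "")
        if not lin:
            continue
        kingdom = lin.split(";")[0].strip()
        if kingdom.startswith("k__"):
            kingdom = kingdom[3:]
        if kingdom in wanted:
            keep.append(fid)
    return table.select_features(keep)


def _check_integral(table: FeatureTable) -> np.ndarray:
    counts = table.counts
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefaction requires an integer table")
    return counts.astype(np.int64)


def rarefy_once(
    table: FeatureTable, depth: int, seed: int | np.random.Generator = 0
) -> FeatureTable:
    """One rarefaction: per retained sample, draw exactly ``depth`` reads
    without replacement; samples with fewer than ``depth`` reads are
    excluded (and logged)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    counts = _check_integral(table)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = counts.sum(axis=0)
    keep = [i for i, t in enumerate(totals) if t >= depth]
    if not keep:
        raise ValueError(
            f"no sample reaches depth {depth}; totals: "
            + ", ".join(f"{s}={int(t)}" for s, t in zip(table.sample_ids, totals))
        )
    dropped = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if dropped:
        logger.warning("samples below depth %d excluded: %s", depth, dropped)
    out = np.zeros((len(table.feature_ids), len(keep)), dtype=float)
    for j, col_idx in enumerate(keep):
        col = counts[:, col_idx]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    sample_ids = [table.sample_ids[i] for i in keep]
    return FeatureTable(list(table.feature_ids), sample_ids, out, table.lineage)


def consensus_rarefy(table: FeatureTable, params: RarefactionParams) -> FeatureTable:
    """Cell-wise mean of ``n_reps`` independent rarefactions (fractional).

    Per-replicate RNGs are derived from the master seed by counter
    (``SeedSequence(seed, spawn_key=(rep,))``), so results do not depend
    on execution order.  Every consensus column sums to ``depth`` exactly
    (up to float accumulation).
    """
    counts = _check_integral(table)
    totals = counts.sum(axis=0)
    keep = [i for i, t in enumerate(totals) if t >= params.depth]
    if not keep:
        raise ValueError(
            f"no sample reaches depth {params.depth}; totals: "
            + ", ".join(f"{s}={int(t)}" for s, t in zip(table.sample_ids, totals))
        )
    dropped = [s for s, t in zip(table.sample_ids, totals) if t < params.depth]
    if dropped:
        logger.warning("samples below depth %d excluded: %s", params.depth, dropped)
    sample_ids = [table.sample_ids[i] for i in keep]
    sub = FeatureTable(
        list(table.feature_ids), sample_ids, counts[:, keep].astype(float), table.lineage
    )
    acc = np.zeros((len(table.feature_ids), len(keep)))
    for rep in range(params.n_reps):
        rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(rep,)))
        acc += rarefy_once(sub, params.depth, rng).counts
    mean = acc / params.n_reps
    return FeatureTable(list(table.feature_ids), sample_ids, mean, table.lineage)


@dataclass
class ReadCountSummary:
    """Ordered (stage, count) rows, split into removal tallies and the
    monotone retained-read trajectory."""

    stages: list[tuple[str, int]]
    retained_stages: list[str]

    def __post_init__(self) -> None:
        by_name = dict(self.stages)
        retained = [by_name[s] for s in self.retained_stages]
        for a, b in zip(retained, retained[1:]):
            if b > a:
                raise ValueError(
                    f"retained read counts increase across stages: {retained}"
                )

    def to_tsv(self) -> str:
        lines = ["stage\treads"]
        lines += [f"{name}\t{count}" for name, count in self.stages]
        return "\n".join(lines) + "\n"

    def as_dict(self) -> dict[str, int]:
        return dict(self.stages)


def read_count_summary(
    stage_counts: Sequence[tuple[str, int]],
    retained_stages: Optional[Sequence[str]] = None,
) -> ReadCountSummary:
    """Compile the pipeline summary; retained stages must be monotone
    non-increasing (a violation signals a pipeline bug)."""
    if retained_stages is None:
        retained_stages = [name for name, _ in stage_counts]
    return ReadCountSummary(list(stage_counts), list(retained_stages))
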
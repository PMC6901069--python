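"""Dereplication and greedy centroid clustering, composed into the OTU
cascade with short-read and PacBio variants.

The cascade dereplicates quality-filtered reads at 100% identity, denoises
at 99% with greedy abundance-ordered centroid clustering, drops clusters
below an abundance floor, scans the survivors for chimeras (de novo, then
against a reference), and clusters at 97% to form final OTUs.  PacBio mode
clusters once at the final identity, applies a smaller abundance floor
(the long-read libraries are far shallower), and scans against the
reference only.

Identity between two sequences is defined end-gap-free (semi-global): the
shorter sequence is aligned within the longer with free terminal gaps,
d = minimal edit operations, identity = 1 - d/len(shorter).  Terminal-gap
freedom lets length-variable amplicons (ITS-like) join clusters seeded by
longer representatives.  The production path computes d with edlib.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib

from .seq_io import SeqRecord
from . import chimera as chimera_mod

logger = logging.getLogger(__name__)


@dataclass
class DerepSeq:
    """A unique sequence with its abundance and (optionally) member read ids."""

    seq: str
    size: int
    id: str = ""
    member_ids: list[str] = field(default_factory=list)


@dataclass
class Cluster:
    """A centroid with its member DerepSeqs; abundance sums member sizes."""

    centroid: DerepSeq
    members: list[DerepSeq]

    @property
    def abundance(self) -> int:
        return sum(m.size for m in self.members)

    @property
    def member_ids(self) -> list[str]:
        out: list[str] = []
        for m in self.members:
            out.extend(m.member_ids)
        return out


@dataclass
class CascadeParams:
    """Thresholds of the clustering cascade (identities as fractions)."""

    denoise_identity: float = 0.99
    final_identity: float = 0.97
    min_cluster_size: int = 25
    pacbio_mode: bool = False
    pacbio_min_size: int = 2

    def __post_init__(self) -> None:
        for t in (self.denoise_identity, self.final_identity):
            if not 0 < t <= 1:
                raise ValueError("identity thresholds must be in (0, 1]")
        if self.min_cluster_size < 1 or self.pacbio_min_size < 1:
            raise ValueError("minimum sizes must be >= 1")


def dereplicate(reads: Iterable[SeqRecord]) -> list[DerepSeq]:
    """Collapse exact duplicate sequences; sorted by size desc, sequence asc.

    The sum of sizes equals the input read count, and each DerepSeq keeps
    the ids of the reads it absorbed (first id doubles as its own id).
    """
    groups: dict[str, list[str]] = {}
    for read in reads:
        groups.setdefault(read.seq, []).append(read.id)
    out = [
        DerepSeq(seq=seq, size=len(ids), id=ids[0], member_ids=ids)
        for seq, ids in groups.items()
    ]
    out.sort(key=lambda d: (-d.size, d.seq))
    return out


def identity(a: str, b: str) -> float:
    """End-gap-free identity in [0, 1]: 1 - d/len(shorter), with d the
    minimal edit distance of the shorter sequence aligned anywhere within
    the longer (terminal gaps on the longer are free).  Symmetric."""
    if not a or not b:
        raise ValueError("identity requires non-empty sequences")
    if len(a) > len(b):
        a, b = b, a
    d = edlib.align(a, b, mode="HW", task="distance")["editDistance"]
    if len(a) == len(b):
        d = min(d, edlib.align(b, a, mode="HW", task="distance")["editDistance"])
    return 1.0 - d / len(a)


def _meets_threshold(a: str, b: str, threshold: float) -> bool:
    """identity(a, b) >= threshold, with edlib's early-exit k cutoff."""
    if len(a) > len(b):
        a, b = b, a
    k = int((1.0 - threshold) * len(a) + 1e-9)
    d = edlib.align(a, b, mode="HW", task="distance", k=k)["editDistance"]
    if d != -1:
        return True
    if len(a) == len(b):
        d = edlib.align(b, a, mode="HW", task="distance", k=k)["editDistance"]
        return d != -1
    return False


def greedy_cluster(inputs: Sequence[DerepSeq], threshold: float) -> list[Cluster]:
    """Abundance-ordered first-fit centroid clustering.

    Inputs must already be sorted size-desc then sequence-asc.  Each
    sequence joins the FIRST existing centroid with identity >= threshold,
    else founds a new cluster; output in centroid-founding order.
    """
    clusters: list[Cluster] = []
    for d in inputs:
        placed = False
        for cl in clusters:
            if _meets_threshold(d.seq, cl.centroid.seq, threshold):
                cl.members.append(d)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(centroid=d, members=[d]))
    return clusters


def _clusters_to_derep(clusters: Sequence[Cluster]) -> list[DerepSeq]:
    """Re-emit cluster centroids carrying aggregate sizes and member ids."""
    out = [
        DerepSeq(seq=cl.centroid.seq, size=cl.abundance, id=cl.centroid.id,
                 member_ids=cl.member_ids)
        for cl in clusters
    ]
    out.sort(key=lambda d: (-d.size, d.seq))
    return out


def run_cascade(
    reads: Iterable[SeqRecord],
    params: CascadeParams = CascadeParams(),
    chimera_refs: Optional[Sequence[SeqRecord]] = None,
    chimera_params: Optional["chimera_mod.ChimeraParams"] = None,
) -> tuple[list[Cluster], dict[str, int]]:
    """Run the full clustering cascade; returns (final clusters, stage counts).

    Short-read mode: dereplicate -> greedy 99% -> abundance floor ->
    chimera de novo -> chimera reference -> greedy 97%.  PacBio mode:
    dereplicate -> greedy at final identity -> floor (default 2) ->
    chimera reference only.
    """
    cp = chimera_params or chimera_mod.ChimeraParams()
    derep = dereplicate(reads)
    counts: dict[str, int] = {
        "input_reads": sum(d.size for d in derep),
        "unique_sequences": len(derep),
    }

    if params.pacbio_mode:
        stage = greedy_cluster(derep, params.final_identity)
        counts["final_identity_clusters"] = len(stage)
        survivors = [cl for cl in stage if cl.abundance >= params.pacbio_min_size]
        counts["clusters_after_size_filter"] = len(survivors)
        counts["reads_after_size_filter"] = sum(cl.abundance for cl in survivors)
        units = _clusters_to_derep(survivors)
        if chimera_refs:
            units = chimera_mod.remove_chimeras_reference(units, chimera_refs, cp)
        counts["clusters_after_chimera"] = len(units)
        counts["clustered_reads"] = sum(d.size for d in units)
        counts["final_clusters"] = len(units)
        final = [Cluster(centroid=d, members=[d]) for d in units]
        if not final:
            logger.warning("cascade produced no clusters")
        return final, counts

    denoised = greedy_cluster(derep, params.denoise_identity)
    counts["denoised_clusters"] = len(denoised)
    survivors = [cl for cl in denoised if cl.abundance >= params.min_cluster_size]
    counts["clusters_after_size_filter"] = len(survivors)
    counts["reads_after_size_filter"] = sum(cl.abundance for cl in survivors)
    units = _clusters_to_derep(survivors)
    units = chimera_mod.remove_chimeras_denovo(units, cp)
    counts["clusters_after_chimera_denovo"] = len(units)
    if chimera_refs:
        units = chimera_mod.remove_chimeras_reference(units, chimera_refs, cp)
    counts["clusters_after_chimera_ref"] = len(units)
    final = greedy_cluster(units, params.final_identity)
    counts["final_clusters"] = len(final)
    counts["clustered_reads"] = sum(cl.abundance for cl in final)
    if not final:
        logger.warning("cascade produced no clusters")
    return final, counts


def filter_asv_table(
    features: Sequence[tuple[str, dict[str, int]]],
    min_total: int = 25,
    chimera_refs: Optional[Sequence[SeqRecord]] = None,
    denovo: bool = True,
    chimera_params: Optional["chimera_mod.ChimeraParams"] = None,
) -> list[tuple[str, dict[str, int]]]:
    """Post-filter externally called ASVs: abundance floor, then chimeras.

    ``denovo=True`` applies de novo + reference scans (Deblur-style input);
    ``denovo=False`` applies the reference scan only (DADA2-style input,
    whose internal bimera removal is assumed already applied).
    """
    cp = chimera_params or chimera_mod.ChimeraParams()
    kept = [(seq, c) for seq, c in features if sum(c.values()) >= min_total]
    units = [
        DerepSeq(seq=seq, size=sum(c.values()), id=f"asv{i}")
        for i, (seq, c) in enumerate(kept)
    ]
    units_sorted = sorted(units, key=lambda d: (-d.size, d.seq))
    surviving = {d.seq for d in units_sorted}
    if denovo:
        surviving = {d.seq for d in chimera_mod.remove_chimeras_denovo(units_sorted, cp)}
    if chimera_refs:
        pool = [DerepSeq(seq=s, size=sum(c.values()), id=f"x{i}")
                for i, (s, c) in enumerate(kept) if s in surviving]
        surviving = {
            d.seq for d in chimera_mod.remove_chimeras_reference(pool, chimera_refs, cp)
        }
    return [(seq, c) for seq, c in kept if seq in surviving]
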
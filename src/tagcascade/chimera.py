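"""Two-parent chimera detection, de novo and reference-based.

A PCR chimera is an artifact read whose left part derives from one
template and whose right part from another.  Detection asks whether a
two-parent model — query aligned to parent A left of a crossover and to
parent B right of it — explains the query better than any single parent,
by at least ``min_div`` percentage points of identity.  De novo mode only
admits parents sufficiently more abundant than the query (true templates
out-amplify their chimeras); reference mode admits any reference.

This is deliberately simpler than UCHIME's chunked voting score: the
contract needed by the cascade is "detect two-parent recombinants between
more-abundant parents", which the model-identity gain provides with fewer
moving parts.  All thresholds are exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ChimeraParams:
    """Detection thresholds.

    ``min_parent_ratio``: de novo parents must be at least this fold more
    abundant than the query.  ``min_div``: required gain, in percentage
    points, of the best chimeric model identity over the best single-parent
    identity.  ``top_h``: number of most-similar pool members considered
    as candidate parents.  ``min_model_identity``: the two-parent model
    must also explain the query nearly perfectly (a genuine recombinant
    differs from its model only by sequencing error); without this floor,
    maximizing the gain over parent pairs and crossovers flags pure
    sequences whenever the pool is moderately diverse.
    """

    min_parent_ratio: float = 2.0
    min_div: float = 0.8
    top_h: int = 4
    min_model_identity: float = 0.97

    def __post_init__(self) -> None:
        if self.min_parent_ratio < 1:
            raise ValueError("min_parent_ratio must be >= 1")
        if self.min_div <= 0:
            raise ValueError("min_div must be > 0")
        if self.top_h < 2:
            raise ValueError("top_h must be >= 2")
        if not 0 < self.min_model_identity <= 1:
            raise ValueError("min_model_identity must be in (0, 1]")


@dataclass
class ChimeraVerdict:
    chimeric: bool
    parent_a: Optional[str] = None
    parent_b: Optional[str] = None
    crossover: Optional[int] = None
    model_identity: Optional[float] = None
    best_single_identity: Optional[float] = None

    @property
    def score(self) -> Optional[float]:
        """Gain of the chimeric model over the best single parent, in
        percentage points."""
        if self.model_identity is None or self.best_single_identity is None:
            return None
        return 100.0 * (self.model_identity - self.best_single_identity)


def _match_profile(query: str, parent: str) -> np.ndarray:
    """Per-query-position 0/1 match vector from an end-gap-free alignment
    of the query within the parent."""
    res = edlib.align(query, parent, mode="HW", task="path")
    nice = edlib.getNiceAlignment(res, query, parent)
    prof = np.zeros(len(query), dtype=np.int64)
    qpos = 0
    for qc, tc in zip(nice["query_aligned"], nice["target_aligned"]):
        if qc == "-":
            continue
        if qc == tc:
            prof[qpos] = 1
        qpos += 1
    return prof


def detect_chimera(
    query_seq: str,
    pool: Sequence[tuple[str, str]],
    params: ChimeraParams = ChimeraParams(),
) -> ChimeraVerdict:
    """Test one sequence against a candidate parent pool.

    ``pool`` is a sequence of (name, sequence) pairs, already restricted to
    eligible parents (abundance filtering is the caller's concern).  The
    top-``top_h`` pool members by identity to the query are considered; for
    every ordered pair (A, B) and every crossover position the chimeric
    model identity is (matches to A left of the crossover + matches to B
    right of it) / query length.  Chimeric iff the best model beats the
    best single parent by >= ``min_div`` percentage points (and strictly).
    Ties break to the earliest crossover, then the earliest pair in
    identity-then-sequence order.
    """
    from .clustering import identity  # local import to avoid a cycle

    if len(pool) < 2:
        logger.debug("fewer than two candidate parents; query passes by default")
        return ChimeraVerdict(chimeric=False)
    L = len(query_seq)
    ranked = sorted(
        ((identity(query_seq, seq), name, seq) for name, seq in pool),
        key=lambda t: (-t[0], t[2], t[1]),
    )[: params.top_h]
    best_single = max(t[0] for t in ranked)
    profiles = {name: _match_profile(query_seq, seq) for _, name, seq in ranked}
    prefixes = {name: np.concatenate(([0], np.cumsum(p))) for name, p in profiles.items()}

    best: Optional[tuple[float, int, str, str]] = None  # (model_id, crossover, a, b)
    for _, a_name, _ in ranked:
        for _, b_name, _ in ranked:
            if a_name == b_name:
                continue
            pa, pb = prefixes[a_name], prefixes[b_name]
            tot_b = pb[-1]
            # model matches for crossover i: pa[i] + (tot_b - pb[i])
            gains = pa[1:L] + tot_b - pb[1:L]
            i_best = int(np.argmax(gains))  # earliest max
            model = (gains[i_best]) / L
            cand = (model, i_best + 1, a_name, b_name)
            if best is None or cand[0] > best[0]:
                best = cand
    assert best is not None
    model_id, crossover, a_name, b_name = best
    gain_pp = 100.0 * (model_id - best_single)
    if (model_id > best_single and gain_pp >= params.min_div
            and model_id >= params.min_model_identity):
        return ChimeraVerdict(True, a_name, b_name, crossover, model_id, best_single)
    return ChimeraVerdict(False, a_name, b_name, crossover, model_id, best_single)


def remove_chimeras_denovo(units, params: ChimeraParams = ChimeraParams()):
    """De novo scan of abundance-sorted DerepSeqs; returns the survivors.

    Processed in decreasing abundance; each query's parent pool is the set
    of already-accepted sequences at least ``min_parent_ratio`` fold more
    abundant.  The most abundant sequence can never be flagged.
    """
    accepted = []
    for unit in units:
        pool = [
            (u.id or u.seq, u.seq)
            for u in accepted
            if u.size >= params.min_parent_ratio * unit.size
        ]
        verdict = detect_chimera(unit.seq, pool, params)
        if not verdict.chimeric:
            accepted.append(unit)
    return accepted


def remove_chimeras_reference(units, references, params: ChimeraParams = ChimeraParams()):
    """Reference scan: every unit tested against the full reference pool
    (no abundance constraint); returns the survivors."""
    pool = [(r.id or r.seq, r.seq) for r in references]
    return [u for u in units if not detect_chimera(u.seq, pool, params).chimeric]
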
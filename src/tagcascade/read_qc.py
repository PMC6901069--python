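"""Read QC: contaminant/PhiX screening, pair sync, trimming, overlap
merging, primer orientation/removal, and the multi-criterion quality filter.

The stages mirror the common preprocessing core of amplicon pipelines:
reads are screened against adapter and PhiX references with canonical
k-mers (bbduk-style), orphaned mates are discarded, paired reads are
merged over their 3' overlap (FLASH-style, quality-aware mismatch
resolution), primers are located and clipped (with optional re-orientation
for libraries sequenced in both directions, e.g. PacBio CCS), and the
surviving reads pass a three-criterion quality filter: mean quality,
number of undefined bases, and number of low-quality bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from .seq_io import SeqRecord, reverse_complement

logger = logging.getLogger(__name__)

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


@dataclass
class QCParams:
    """Quality-filter thresholds.

    A read fails if its mean phred score is below ``min_avg_q`` (default
    27, the permissive end of the usual 27-33 range), if it carries more
    than ``max_n`` undefined bases (0 or 1), or if strictly more than
    ``max_low_q_bases`` bases fall below ``low_q_threshold``.
    """

    min_avg_q: float = 27.0
    max_n: int = 1
    low_q_threshold: int = 15
    max_low_q_bases: int = 5
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if self.min_avg_q <= 0:
            raise ValueError("min_avg_q must be > 0")
        if self.max_n not in (0, 1):
            raise ValueError("max_n must be 0 or 1")
        if self.max_low_q_bases < 0:
            raise ValueError("max_low_q_bases must be >= 0")


@dataclass
class ScreenParams:
    """Canonical k-mer screening parameters (k defaults to 21)."""

    k: int = 21
    min_hits: int = 1

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError("k must be >= 11")
        if self.min_hits < 1:
            raise ValueError("min_hits must be >= 1")


@dataclass
class MergeParams:
    """Overlap-merge parameters; overlaps are scanned longest-first."""

    min_overlap: int = 10
    max_overlap: Optional[int] = None
    max_mismatch_ratio: float = 0.25

    def __post_init__(self) -> None:
        if self.min_overlap <= 0:
            raise ValueError("min_overlap must be > 0")
        if self.max_overlap is not None and self.max_overlap < self.min_overlap:
            raise ValueError("max_overlap must be >= min_overlap")


@dataclass
class PrimerSpec:
    """Forward/reverse primer pair with IUPAC degeneracies.

    The forward primer is searched within ``search_window`` bases of the
    5' end (default 1.5x primer length); the reverse primer is searched,
    reverse-complemented, within the mirrored 3' window.
    """

    forward: str
    reverse: str = ""
    max_mismatches: int = 2
    search_window: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.forward:
            raise ValueError("forward primer must be non-empty")
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()

    def window(self, primer: str) -> int:
        if self.search_window is not None:
            return self.search_window
        return int(1.5 * len(primer))


def canonical_kmers(seq: str, k: int) -> set[str]:
    """All k-mers of ``seq``, each collapsed with its reverse complement to
    the lexicographically smaller form.  k-mers containing non-ACGT symbols
    are skipped."""
    out = set()
    s = seq.upper()
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        rc = reverse_complement(kmer)
        out.add(min(kmer, rc))
    return out


def build_kmer_index(references: Iterable[SeqRecord], k: int) -> set[str]:
    idx: set[str] = set()
    for ref in references:
        idx |= canonical_kmers(ref.seq, k)
    return idx


@dataclass
class ScreenResult:
    kept: list[SeqRecord] = field(default_factory=list)
    contaminant: list[SeqRecord] = field(default_factory=list)
    phix: list[SeqRecord] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)


def screen_contaminants(
    reads: Iterable[SeqRecord],
    phix_refs: Iterable[SeqRecord],
    contaminant_refs: Iterable[SeqRecord],
    params: ScreenParams = ScreenParams(),
) -> ScreenResult:
    """Partition reads into {kept, contaminant, phix} by shared canonical k-mers.

    PhiX takes precedence over adapter contamination.  Reads shorter than k
    cannot be screened; they are kept and tallied under ``too_short_to_screen``.
    """
    phix_idx = build_kmer_index(phix_refs, params.k)
    contam_idx = build_kmer_index(contaminant_refs, params.k)
    res = ScreenResult(counts={"total": 0, "kept": 0, "contaminant": 0, "phix": 0,
                               "too_short_to_screen": 0})
    for read in reads:
        res.counts["total"] += 1
        if len(read.seq) < params.k:
            res.counts["too_short_to_screen"] += 1
            res.counts["kept"] += 1
            res.kept.append(read)
            continue
        kmers = canonical_kmers(read.seq, params.k)
        if len(kmers & phix_idx) >= params.min_hits:
            res.counts["phix"] += 1
            res.phix.append(read)
        elif len(kmers & contam_idx) >= params.min_hits:
            res.counts["contaminant"] += 1
            res.contaminant.append(read)
        else:
            res.counts["kept"] += 1
            res.kept.append(read)
    return res


def _pair_key(ident: str) -> str:
    if ident.endswith("/1") or ident.endswith("/2"):
        return ident[:-2]
    return ident.split()[0]


def sync_pairs(
    r1: Iterable[SeqRecord], r2: Iterable[SeqRecord]
) -> tuple[list[tuple[SeqRecord, SeqRecord]], int]:
    """Keep only mate pairs present in both streams (r1 order); count orphans.

    Ids are matched after stripping a trailing ``/1``/``/2`` or whitespace
    suffix.  A duplicated id within one stream is an error.
    """
    def index(stream, label):
        d = {}
        for rec in stream:
            key = _pair_key(rec.id)
            if key in d:
                raise ValueError(f"duplicate id {key!r} in {label}")
            d[key] = rec
        return d

    d1 = index(r1, "r1")
    d2 = index(r2, "r2")
    pairs = [(d1[k], d2[k]) for k in d1 if k in d2]
    orphans = len(d1) + len(d2) - 2 * len(pairs)
    return pairs, orphans


def trim_fixed(read: SeqRecord, length: int) -> Optional[SeqRecord]:
    """Trim to a fixed length from the 3' end; shorter reads are discarded
    (returns None), never padded."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if len(read.seq) < length:
        return None
    qual = None if read.qual is None else read.qual[:length]
    return SeqRecord(read.id, read.seq[:length], qual, read.desc)


def merge_pairs(
    fwd: SeqRecord, rev: SeqRecord, params: MergeParams = MergeParams()
) -> Optional[SeqRecord]:
    """Merge a read pair over its best 3' overlap, or return None.

    The reverse read is reverse-complemented, overlaps are scanned from the
    longest candidate down to ``min_overlap``, and the overlap minimizing
    the mismatch ratio wins (ties go to the longest).  The merge is accepted
    iff that ratio is <= ``max_mismatch_ratio``.  Within the overlap a
    disputed position takes the base with the higher quality (ties favor
    the forward read) and the merged quality is the max of the two.
    """
    rrc = rev.reverse_complement()
    f = np.frombuffer(fwd.seq.encode(), dtype=np.uint8)
    r = np.frombuffer(rrc.seq.encode(), dtype=np.uint8)
    hi = min(len(f), len(r))
    if params.max_overlap is not None:
        hi = min(hi, params.max_overlap)
    if hi < params.min_overlap:
        return None
    best_o, best_ratio = None, np.inf
    for o in range(hi, params.min_overlap - 1, -1):
        mism = int(np.count_nonzero(f[-o:] != r[:o]))
        ratio = mism / o
        if ratio < best_ratio:
            best_ratio, best_o = ratio, o
    if best_o is None or best_ratio > params.max_mismatch_ratio:
        return None
    o = best_o
    have_q = fwd.qual is not None and rev.qual is not None
    if not have_q:
        logger.warning("merging %r without qualities; forward read wins disputes", fwd.id)
    fq = fwd.qual if have_q else [0] * len(fwd.seq)
    rq = list(reversed(rev.qual)) if have_q else [0] * len(rev.seq)
    left = fwd.seq[:-o]
    right = rrc.seq[o:]
    mid_seq, mid_q = [], []
    for i in range(o):
        fb, rb = fwd.seq[len(fwd.seq) - o + i], rrc.seq[i]
        q1, q2 = fq[len(fwd.seq) - o + i], rq[i]
        if fb == rb:
            mid_seq.append(fb)
        else:
            mid_seq.append(rb if q2 > q1 else fb)
        mid_q.append(max(q1, q2))
    qual = (fq[: len(fwd.seq) - o] + mid_q + rq[o:]) if have_q else None
    return SeqRecord(fwd.id, left + "".join(mid_seq) + right, qual, fwd.desc)


def _match_primer(seq: str, primer: str, start: int, max_mm: int) -> Optional[int]:
    """Mismatch count of ``primer`` against ``seq[start:]``, or None if over
    budget / out of range.  Read N counts as a mismatch unless the primer
    position is N."""
    if start + len(primer) > len(seq):
        return None
    mm = 0
    for p, b in zip(primer, seq[start : start + len(primer)]):
        if b not in IUPAC.get(p, set()):
            mm += 1
            if mm > max_mm:
                return None
    return mm


def _find_primer(seq: str, primer: str, window: int, max_mm: int) -> Optional[tuple[int, int]]:
    """Best (start, mismatches) of a 5'-anchored-within-window primer hit."""
    best = None
    for start in range(0, max(0, min(window, len(seq)) - len(primer)) + 1):
        mm = _match_primer(seq, primer, start, max_mm)
        if mm is not None and (best is None or mm < best[1]):
            best = (start, mm)
            if mm == 0:
                break
    return best


def handle_primers(
    read: SeqRecord, spec: PrimerSpec, orient: bool = False
) -> Optional[SeqRecord]:
    """Locate and clip primers; optionally re-orient reverse-complemented reads.

    The forward primer is searched within the 5' window; if absent and
    ``orient`` is set, the reverse complement of the read is searched.  On a
    hit the read is emitted in forward orientation with the forward primer
    (and, when present in the 3' window, the reverse-complemented reverse
    primer) removed.  No hit in either orientation -> None (discard).
    """
    window = spec.window(spec.forward)
    candidates = [read]
    if orient:
        candidates.append(read.reverse_complement())
    for cand in candidates:
        hit = _find_primer(cand.seq, spec.forward, window, spec.max_mismatches)
        if hit is None:
            continue
        start = hit[0] + len(spec.forward)
        seq = cand.seq[start:]
        qual = None if cand.qual is None else cand.qual[start:]
        if spec.reverse:
            rc = reverse_complement(spec.reverse)
            win = spec.window(rc)
            tail_from = max(0, len(seq) - win)
            best = None
            for s in range(tail_from, len(seq) - len(rc) + 1):
                mm = _match_primer(seq, rc, s, spec.max_mismatches)
                if mm is not None and (best is None or mm < best[1]):
                    best = (s, mm)
            if best is not None:
                seq = seq[: best[0]]
                qual = None if qual is None else qual[: best[0]]
        if not seq:
            return None
        return SeqRecord(cand.id, seq, qual, cand.desc)
    return None


def quality_filter(read: SeqRecord, params: QCParams = QCParams()) -> tuple[bool, Optional[str]]:
    """Three-criterion quality verdict: ``(True, None)`` or ``(False, reason)``.

    Criteria are checked in order — mean quality (``avg_q``), undefined
    bases (``too_many_n``), low-quality bases (``low_q_bases``) — and the
    first failure is the recorded reason.
    """
    if read.qual is None:
        raise ValueError(f"read {read.id!r} has no qualities; quality_filter needs them")
    q = np.asarray(read.qual, dtype=float)
    if q.mean() < params.min_avg_q:
        return False, "avg_q"
    if read.seq.count("N") > params.max_n:
        return False, "too_many_n"
    if int((q < params.low_q_threshold).sum()) > params.max_low_q_bases:
        return False, "low_q_bases"
    return True, None
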
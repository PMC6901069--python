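"""Bootstrap naive-Bayes taxonomic classification over a ranked taxonomy.

The classifier follows the RDP design: references are summarized per
genus-level leaf by which length-``w`` words (default w=8) occur in them;
a query is scored against every leaf by the sum of log word probabilities
(word presence with add-one smoothing); and confidence at each rank is the
fraction of bootstrap trials — each scoring a random 1/8 subsample of the
query's distinct words — whose winning leaf descends through that rank's
assigned name.  Lineages are then truncated to the maximal prefix of ranks
with confidence >= 0.5.

Training-set construction makes lineages unique and non-conflicting: a
name appearing under two different parent paths is disambiguated by
suffixing the parent name, and empty rank values become
``<parent>_unclassified``.
"""

from __future__ import annotations

import json
import logging
import tarfile
import io
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .seq_io import SeqRecord

logger = logging.getLogger(__name__)

DEFAULT_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass
class Lineage:
    """Ordered (rank, name) pairs down a single taxonomy path."""

    ranks: tuple[str, ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(self.names):
            raise ValueError("ranks and names differ in length")

    def __str__(self) -> str:
        return ";".join(self.names)

    def __len__(self) -> int:
        return len(self.names)


def strip_rank_prefix(name: str) -> str:
    for p in RANK_PREFIXES:
        if name.startswith(p):
            return name[len(p):]
    return name


def parse_lineage_string(s: str, ranks: Sequence[str] = DEFAULT_RANKS) -> Lineage:
    """Parse a ';'-separated lineage (rank prefixes like ``k__`` optional)."""
    parts = [strip_rank_prefix(p.strip()) for p in s.split(";")]
    if len(parts) != len(ranks):
        raise ValueError(
            f"lineage {s!r} has {len(parts)} ranks, expected {len(ranks)}"
        )
    return Lineage(tuple(ranks), tuple(parts))


@dataclass
class Classification:
    """Per-rank assigned names with bootstrap confidences."""

    ranks: tuple[str, ...]
    names: tuple[str, ...]
    confidences: tuple[float, ...]
    n_bootstrap: int


@dataclass
class TrainingSet:
    """Word-occurrence naive-Bayes model over a ranked taxonomy.

    ``leaf_lineages`` maps each leaf (deepest-rank) name to its full
    Lineage; ``word_index`` maps word -> column; ``presence`` is the
    (n_leaves x n_words) count of references per leaf containing each
    word; ``leaf_sizes`` the number of references per leaf.
    """

    ranks: tuple[str, ...]
    word_size: int
    leaves: list[str]
    leaf_lineages: dict[str, Lineage]
    word_index: dict[str, int]
    presence: np.ndarray
    leaf_sizes: np.ndarray

    def __post_init__(self) -> None:
        self._log_probs = np.log(
            (self.presence + 1.0) / (self.leaf_sizes[:, None] + 2.0)
        )
        self._log_unseen = np.log(1.0 / (self.leaf_sizes + 2.0))

    def save(self, path) -> None:
        meta = {
            "ranks": list(self.ranks),
            "word_size": self.word_size,
            "leaves": self.leaves,
            "leaf_lineages": {k: list(v.names) for k, v in self.leaf_lineages.items()},
            "words": sorted(self.word_index, key=self.word_index.get),
            "leaf_sizes": self.leaf_sizes.tolist(),
        }
        with tarfile.open(path, "w:gz") as tar:
            blob = json.dumps(meta).encode()
            info = tarfile.TarInfo("meta.json")
            info.size = len(blob)
            tar.addfile(info, io.BytesIO(blob))
            buf = io.BytesIO()
            np.save(buf, self.presence)
            info = tarfile.TarInfo("presence.npy")
            info.size = buf.getbuffer().nbytes
            buf.seek(0)
            tar.addfile(info, buf)

    @classmethod
    def load(cls, path) -> "TrainingSet":
        with tarfile.open(path, "r:gz") as tar:
            meta = json.loads(tar.extractfile("meta.json").read())
            presence = np.load(io.BytesIO(tar.extractfile("presence.npy").read()))
        ranks = tuple(meta["ranks"])
        lineages = {
            k: Lineage(ranks, tuple(v)) for k, v in meta["leaf_lineages"].items()
        }
        return cls(
            ranks=ranks,
            word_size=meta["word_size"],
            leaves=meta["leaves"],
            leaf_lineages=lineages,
            word_index={w: i for i, w in enumerate(meta["words"])},
            presence=presence,
            leaf_sizes=np.array(meta["leaf_sizes"], dtype=float),
        )


def _words(seq: str, w: int) -> set[str]:
    s = seq.upper()
    return {
        s[i : i + w]
        for i in range(len(s) - w + 1)
        if "N" not in s[i : i + w]
    }


def deconflict_lineages(
    lineages: Sequence[Lineage], ranks: Sequence[str] = DEFAULT_RANKS
) -> list[Lineage]:
    """Make names unique to one parent path and fill empty ranks.

    A name observed under more than one distinct parent path is renamed
    ``<name>_<parent name>`` in every occurrence; an empty name becomes
    ``<parent>_unclassified``.  Applied rank by rank from the top so fixes
    cascade downward.
    """
    rows = [list(l.names) for l in lineages]
    n_ranks = len(ranks)
    for r in range(n_ranks):
        for row in rows:
            if not row[r]:
                parent = row[r - 1] if r > 0 else "root"
                row[r] = f"{parent}_unclassified"
        if r == 0:
            continue
        parents: dict[str, set[tuple[str, ...]]] = {}
        for row in rows:
            parents.setdefault(row[r], set()).add(tuple(row[:r]))
        conflicted = {name for name, ps in parents.items() if len(ps) > 1}
        for row in rows:
            if row[r] in conflicted:
                row[r] = f"{row[r]}_{row[r - 1]}"
    return [Lineage(tuple(ranks), tuple(row)) for row in rows]


def build_training_set(
    references: Iterable[tuple[SeqRecord, str]],
    ranks: Sequence[str] = DEFAULT_RANKS,
    word_size: int = 8,
) -> TrainingSet:
    """Build a word model from (sequence, lineage string) references.

    References lacking a parseable lineage are rejected with a logged id;
    a rank-count mismatch is an error naming the record.
    """
    recs: list[SeqRecord] = []
    lineages: list[Lineage] = []
    for rec, lin_str in references:
        if not lin_str or not lin_str.strip():
            logger.warning("reference %r lacks a lineage; skipped", rec.id)
            continue
        try:
            lineages.append(parse_lineage_string(lin_str, ranks))
        except ValueError as exc:
            raise ValueError(f"reference {rec.id!r}: {exc}") from exc
        recs.append(rec)
    if not recs:
        raise ValueError("no usable references")
    lineages = deconflict_lineages(lineages, ranks)

    leaf_of: dict[str, Lineage] = {}
    members: dict[str, list[SeqRecord]] = {}
    for rec, lin in zip(recs, lineages):
        leaf = lin.names[-1]
        if leaf in leaf_of and leaf_of[leaf].names != lin.names:
            raise ValueError(f"leaf {leaf!r} maps to two lineages after de-conflicting")
        leaf_of[leaf] = lin
        members.setdefault(leaf, []).append(rec)

    leaves = sorted(leaf_of)
    vocab: dict[str, int] = {}
    per_leaf_words: list[Counter] = []
    sizes = []
    for leaf in leaves:
        cnt: Counter = Counter()
        for rec in members[leaf]:
            for word in _words(rec.seq, word_size):
                if word not in vocab:
                    vocab[word] = len(vocab)
                cnt[word] += 1
        per_leaf_words.append(cnt)
        sizes.append(len(members[leaf]))
    presence = np.zeros((len(leaves), len(vocab)), dtype=float)
    for i, cnt in enumerate(per_leaf_words):
        for word, c in cnt.items():
            presence[i, vocab[word]] = c
    return TrainingSet(
        ranks=tuple(ranks),
        word_size=word_size,
        leaves=leaves,
        leaf_lineages=leaf_of,
        word_index=vocab,
        presence=presence,
        leaf_sizes=np.array(sizes, dtype=float),
    )


def classify(
    seq: str,
    ts: TrainingSet,
    n_bootstrap: int = 100,
    subsample: float = 1 / 8,
    seed: int | np.random.Generator = 0,
) -> Classification:
    """Bootstrap naive-Bayes classification of one sequence.

    Each of ``n_bootstrap`` trials scores a with-replacement subsample of
    ``subsample`` x (distinct query words) against every leaf and assigns
    the arg-max leaf (ties -> lexicographically first leaf).  The assigned
    name at each rank is the modal name across trials and its confidence
    the fraction of trials descending through it; with unique
    non-conflicting names this is monotone non-increasing with depth.
    """
    w = ts.word_size
    if len(seq) < w:
        raise ValueError(f"sequence shorter than word size {w}")
    words = sorted(_words(seq, w))
    if not words:
        raise ValueError("sequence has no informative words (all ambiguous)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = max(1, int(round(subsample * len(words))))

    cols = np.array([ts.word_index.get(word, -1) for word in words])
    known = cols >= 0
    # per-word log-prob matrix (n_words x n_leaves)
    logp = np.empty((len(words), len(ts.leaves)))
    logp[known] = ts._log_probs[:, cols[known]].T
    logp[~known] = ts._log_unseen[None, :]

    n_leaves = len(ts.leaves)
    wins = np.zeros(n_leaves, dtype=int)
    draws = rng.integers(0, len(words), size=(n_bootstrap, n_sub))
    for t in range(n_bootstrap):
        scores = logp[draws[t]].sum(axis=0)
        wins[int(np.argmax(scores))] += 1  # argmax takes first max: lexicographic

    n_ranks = len(ts.ranks)
    # per-rank name counts over trials
    names_out, confs_out = [], []
    for r in range(n_ranks):
        tally: Counter = Counter()
        for leaf_idx, count in enumerate(wins):
            if count:
                tally[ts.leaf_lineages[ts.leaves[leaf_idx]].names[r]] += count
        name, count = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        names_out.append(name)
        confs_out.append(count / n_bootstrap)
    return Classification(ts.ranks, tuple(names_out), tuple(confs_out), n_bootstrap)


def reconstruct_lineage(c: Classification, cutoff: float = 0.5) -> Lineage:
    """Truncate to the maximal prefix of ranks with confidence >= cutoff.

    Deeper ranks are dropped even if a later rank again reaches the cutoff
    (a lineage with a missing middle rank is not a valid path); an empty
    lineage means unclassified at the top rank.
    """
    keep = 0
    for conf in c.confidences:
        if conf >= cutoff:
            keep += 1
        else:
            break
    return Lineage(c.ranks[:keep], c.names[:keep])
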
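"""Synthetic mock-community generator with full ground truth.

Emulates the validation inputs the pipeline is designed for: even or
staggered mixtures of known templates, primer-flanked amplicons at
Illumina-short (2 x 250 bp paired) or PacBio-CCS (~1,470 bp single)
length profiles, substitution/indel sequencing error, injected
two-parent chimeras, PhiX and adapter spike-ins, and per-cycle quality
profiles.  Every read's origin is recorded in a truth table, and all
randomness flows from a single seed.

The PhiX and adapter "references" are synthetic stand-ins generated
deterministically in code — screening is k-mer self-consistent, so any
fixed sequence serves; no real genome is embedded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .seq_io import SeqRecord, reverse_complement, write_fastq, write_fasta, write_newick
from .taxonomy import DEFAULT_RANKS

BASES = "ACGT"

# Standard 16S V4 primer pair (515F / 806R).
DEFAULT_FWD_PRIMER = "GTGYCAGCMGCCGCGGTAA"
DEFAULT_REV_PRIMER = "GGACTACNVGGGTWTCTAAT"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def synthetic_phix(length: int = 1500) -> SeqRecord:
    """Deterministic synthetic PhiX stand-in (not the real genome)."""
    rng = np.random.default_rng(424242)
    return SeqRecord("synthetic_phix", _random_seq(rng, length))


def synthetic_adapter(length: int = 60) -> SeqRecord:
    """Deterministic synthetic sequencing-adapter stand-in."""
    rng = np.random.default_rng(555555)
    return SeqRecord("synthetic_adapter", _random_seq(rng, length))


@dataclass
class Template:
    record: SeqRecord
    lineage: str

    @property
    def genus(self) -> str:
        return self.lineage.split(";")[-1]


def _nested_lineage(i: int, ranks: Sequence[str]) -> str:
    """Distinct genus per taxon, merging pairwise up the ranks so shared
    higher ranks form a plausible tree."""
    labels = []
    n = len(ranks)
    for depth, rank in enumerate(ranks):
        if depth == 0:
            labels.append("Bacteria")
        else:
            group = i // (2 ** (n - 1 - depth))
            labels.append(f"{rank.capitalize()}_{group + 1:02d}")
    return ";".join(labels)


def generate_templates(
    n_taxa: int,
    length: int = 250,
    divergence: float = 0.10,
    ranks: Sequence[str] = DEFAULT_RANKS,
    seed: int = 0,
    length_sd: float = 0.0,
) -> list[Template]:
    """Generate reference templates with ~``divergence`` pairwise divergence.

    Each template is the common random root mutated independently at rate
    ``divergence``/2, giving expected pairwise divergence near the request;
    all pairs are rejection-checked to stay >= ``divergence``/2 apart.
    ``length_sd`` > 0 draws per-taxon lengths from N(length, sd) (PacBio
    length profiles).
    """
    from .clustering import identity  # deferred: avoids import cycle at load

    if not 0 < divergence < 0.5:
        raise ValueError("divergence must be in (0, 0.5)")
    if length * divergence / 2 < 1 and n_taxa > 1:
        raise ValueError(f"divergence {divergence} infeasible for length {length}")
    rng = np.random.default_rng(seed)
    for _attempt in range(20):
        root = _random_seq(rng, length)
        seqs = []
        for _ in range(n_taxa):
            target_len = length
            if length_sd > 0:
                target_len = max(50, int(rng.normal(length, length_sd)))
            chars = list(root)
            for i in range(length):
                if rng.random() < divergence / 2:
                    chars[i] = rng.choice([b for b in BASES if b != chars[i]])
            s = "".join(chars)
            if target_len <= length:
                s = s[:target_len]
            else:
                s = s + _random_seq(rng, target_len - length)
            seqs.append(s)
        ok = all(
            identity(seqs[i], seqs[j]) <= 1 - divergence / 2
            for i in range(n_taxa)
            for j in range(i + 1, n_taxa)
        )
        if ok:
            break
    else:
        raise ValueError("could not generate templates at requested divergence")
    return [
        Template(SeqRecord(f"T{i + 1:03d}", seq), _nested_lineage(i, ranks))
        for i, seq in enumerate(seqs)
    ]


@dataclass
class QualityProfile:
    """Per-cycle mean phred with Gaussian jitter; Illumina-like decay by
    default, flat Q30 for PacBio-CCS."""

    q_start: float = 38.0
    q_end: float = 25.0
    jitter_sd: float = 3.0

    @classmethod
    def pacbio(cls) -> "QualityProfile":
        return cls(q_start=30.0, q_end=30.0, jitter_sd=2.0)

    def sample(self, rng: np.random.Generator, length: int) -> list[int]:
        means = np.linspace(self.q_start, self.q_end, max(length, 2))[:length]
        q = rng.normal(means, self.jitter_sd)
        return [int(v) for v in np.clip(np.round(q), 2, 40)]


@dataclass
class MockConfig:
    """Study conditions for one simulated mock-community run."""

    n_taxa: int = 20
    template_length: int = 250
    divergence: float = 0.10
    templates: Optional[list[Template]] = None
    composition: str | Sequence[float] = "even"
    n_samples: int = 4
    n_reads: int = 5000
    read_mode: str = "paired"  # paired | single | long
    read_length: int = 250
    substitution_rate: float = 0.005
    indel_rate: float = 0.0
    chimera_rate: float = 0.02
    phix_rate: float = 0.01
    adapter_rate: float = 0.005
    primer_fwd: str = DEFAULT_FWD_PRIMER
    primer_rev: str = DEFAULT_REV_PRIMER
    quality: Optional[QualityProfile] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_mode not in ("paired", "single", "long"):
            raise ValueError(f"unknown read_mode {self.read_mode!r}")
        for r in (self.substitution_rate, self.indel_rate, self.chimera_rate,
                  self.phix_rate, self.adapter_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must be in [0, 1)")

    def proportions(self, n_taxa: int) -> np.ndarray:
        if isinstance(self.composition, str):
            if self.composition == "even":
                p = np.ones(n_taxa)
            elif self.composition == "staggered":
                p = 2.0 ** -np.arange(n_taxa)
            else:
                raise ValueError(f"unknown composition {self.composition!r}")
        else:
            p = np.asarray(self.composition, dtype=float)
            if len(p) != n_taxa:
                raise ValueError("composition length != number of templates")
        return p / p.sum()


@dataclass
class SimulatedRun:
    config: MockConfig
    templates: list[Template]
    r1: list[SeqRecord]
    r2: Optional[list[SeqRecord]]
    truth: dict[str, dict]

    def truth_counts(self, category: str) -> int:
        return sum(1 for t in self.truth.values() if t["category"] == category)

    def sample_of(self, read_id: str) -> Optional[str]:
        entry = self.truth.get(read_id)
        return entry["sample"] if entry else read_id.split(".")[0]

    def write(self, outdir) -> dict[str, Path]:
        """Write FASTQ(s), lineage-annotated reference FASTA, truth TSV and
        the genus-labeled template tree; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        if self.r2 is not None:
            paths["r1"] = outdir / "reads_R1.fastq"
            paths["r2"] = outdir / "reads_R2.fastq"
            write_fastq(self.r1, paths["r1"])
            write_fastq(self.r2, paths["r2"])
        else:
            paths["reads"] = outdir / "reads.fastq"
            write_fastq(self.r1, paths["reads"])
        paths["references"] = outdir / "references.fasta"
        write_fasta(
            [SeqRecord(t.record.id, t.record.seq, desc=t.lineage) for t in self.templates],
            paths["references"],
        )
        paths["truth"] = outdir / "truth.tsv"
        with open(paths["truth"], "w") as fh:
            fh.write("read_id\tsample\tcategory\ttaxon\tparents\n")
            for rid, entry in self.truth.items():
                fh.write(
                    f"{rid}\t{entry['sample']}\t{entry['category']}\t"
                    f"{entry.get('taxon') or ''}\t"
                    f"{','.join(entry.get('parents') or [])}\n"
                )
        paths["tree"] = outdir / "templates.nwk"
        write_newick(template_tree(self.templates), paths["tree"])
        return paths


def _concretize(seq: str, rng: np.random.Generator) -> str:
    """Resolve degenerate IUPAC positions to concrete bases (a synthesized
    primer pool is a mixture; each amplicon carries one concrete variant)."""
    from .read_qc import IUPAC

    out = []
    for ch in seq:
        allowed = sorted(IUPAC.get(ch, {ch}))
        out.append(allowed[int(rng.integers(len(allowed)))] if len(allowed) > 1 else ch)
    return "".join(out)


def _mutate(seq: str, rng: np.random.Generator, sub_rate: float, indel_rate: float) -> str:
    if sub_rate == 0 and indel_rate == 0:
        return seq
    out = []
    for ch in seq:
        r = rng.random()
        if r < sub_rate:
            # 5% of substitutions are ambiguous calls (N)
            if rng.random() < 0.05:
                out.append("N")
            else:
                out.append(rng.choice([b for b in BASES if b != ch]))
        elif r < sub_rate + indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(ch)
            out.append(rng.choice(list(BASES)))  # insertion
        else:
            out.append(ch)
    return "".join(out)


def simulate_reads(config: MockConfig) -> SimulatedRun:
    """Generate the mock libraries described by ``config``.

    Amplicons are fwd_primer + template + revcomp(rev_primer); chimeric
    reads splice two distinct templates at a uniform crossover within the
    middle 80% of the template (so detection is well-posed); PhiX and
    adapter reads come from the synthetic fixtures.  Paired mode emits
    overlapping 2 x ``read_length`` pairs; single/long modes emit one read
    per amplicon, long mode in random orientation (CCS reads come off the
    instrument in both directions).
    """
    rng = np.random.default_rng(config.seed)
    templates = config.templates
    if templates is None:
        length_sd = 220.0 if config.read_mode == "long" else 0.0
        templates = generate_templates(
            config.n_taxa,
            config.template_length,
            config.divergence,
            seed=int(rng.integers(2**31)),
            length_sd=length_sd,
        )
    quality = config.quality or (
        QualityProfile.pacbio() if config.read_mode == "long" else QualityProfile()
    )
    props = config.proportions(len(templates))
    phix = synthetic_phix().seq
    adapter = synthetic_adapter().seq
    rc_rev = reverse_complement(config.primer_rev)

    r1: list[SeqRecord] = []
    r2: list[SeqRecord] = [] if config.read_mode == "paired" else None
    truth: dict[str, dict] = {}

    for s in range(config.n_samples):
        sample = f"S{s + 1}"
        for i in range(config.n_reads):
            rid = f"{sample}.{i + 1:06d}"
            u = rng.random()
            parents = None
            taxon = None
            if u < config.phix_rate:
                category = "phix"
                span = len(config.primer_fwd) + config.template_length + len(config.primer_rev)
                start = int(rng.integers(0, max(1, len(phix) - span)))
                amplicon = phix[start : start + span]
            elif u < config.phix_rate + config.chimera_rate and len(templates) > 1:
                category = "chimera"
                a, b = rng.choice(len(templates), size=2, replace=False)
                ta, tb = templates[a].record.seq, templates[b].record.seq
                lo = int(0.1 * len(ta))
                hi = int(0.9 * len(ta))
                x = int(rng.integers(lo, hi))
                insert = ta[:x] + tb[x:]
                parents = [templates[a].genus, templates[b].genus]
                amplicon = (
                    _concretize(config.primer_fwd, rng) + insert + _concretize(rc_rev, rng)
                )
            else:
                category = "template"
                t = int(rng.choice(len(templates), p=props))
                taxon = templates[t].genus
                amplicon = (
                    _concretize(config.primer_fwd, rng)
                    + templates[t].record.seq
                    + _concretize(rc_rev, rng)
                )
            adapter_read = category == "template" and rng.random() < config.adapter_rate
            if adapter_read:
                category = "adapter"
                taxon = None

            truth[rid] = {
                "sample": sample,
                "category": category,
                "taxon": taxon,
                "parents": parents,
            }

            if config.read_mode == "paired":
                L = config.read_length
                fwd_seq = _mutate(amplicon[:L], rng, config.substitution_rate,
                                  config.indel_rate)
                rev_seq = _mutate(reverse_complement(amplicon)[:L], rng,
                                  config.substitution_rate, config.indel_rate)
                if adapter_read:
                    fwd_seq = (adapter + fwd_seq)[:L]
                r1.append(SeqRecord(rid, fwd_seq, quality.sample(rng, len(fwd_seq))))
                r2.append(SeqRecord(rid, rev_seq, quality.sample(rng, len(rev_seq))))
            else:
                seq = _mutate(amplicon, rng, config.substitution_rate, config.indel_rate)
                if adapter_read:
                    seq = adapter + seq
                if config.read_mode == "long" and rng.random() < 0.5:
                    seq = reverse_complement(seq)
                r1.append(SeqRecord(rid, seq, quality.sample(rng, len(seq))))
    return SimulatedRun(config, templates, r1, r2, truth)


def template_tree(templates: Sequence[Template]) -> TreeNode:
    """Single-linkage tree over templates from generator identity distances;
    leaves carry genus names (for genus-aggregated UniFrac)."""
    from .clustering import identity

    n = len(templates)
    if n == 1:
        return TreeNode.read([f"{templates[0].genus}:0.0;"])
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - identity(templates[i].record.seq, templates[j].record.seq)
            dist[i, j] = dist[j, i] = d
    lm = linkage(squareform(dist), method="single")
    tree = TreeNode.from_linkage_matrix(lm, [t.genus for t in templates])
    for node in tree.traverse():
        if node.length is None or node.length < 0:
            node.length = 0.0
    return tree
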
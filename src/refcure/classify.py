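"""Bootstrap k-mer taxonomy classifier (SINTAX-style).

Used by the fungal filter: a query is classified against a
taxonomy-annotated reference set by repeatedly (``n_boot`` times)
subsampling ``subsample`` of its k-mers with replacement, finding the
reference sharing the most sampled k-mers, and voting for that
reference's lineage. Per-rank confidence is the fraction of bootstraps
whose winning lineage agrees at that rank, computed hierarchically so
confidences never increase from kingdom to species. A bootstrap whose
sample shares no k-mer with any reference is uninformative: it still
counts in the denominator but casts no vote, which prevents unrelated
queries from being confidently assigned by forced top-hits.
"""

from __future__ import annotations

import logging
import zlib
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .taxfasta import RANKS, Dataset, SeqRecord, TaxonomyString

logger = logging.getLogger(__name__)


@dataclass
class KmerIndex:
    """Per-reference distinct k-mer sets plus lineages."""

    k: int
    kmers: dict[str, frozenset[str]]  # accession -> k-mer set
    lineages: dict[str, tuple[str, ...]]  # accession -> 7-rank lineage

    def __len__(self) -> int:
        return len(self.kmers)


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def build_index(refdb: Dataset, k: int = 8) -> KmerIndex:
    """Deterministic k-mer index over a reference dataset.

    References shorter than ``k`` are skipped with a warning.
    """
    if len(refdb) == 0:
        raise ValueError("cannot build a k-mer index from an empty reference set")
    kmers: dict[str, frozenset[str]] = {}
    lineages: dict[str, tuple[str, ...]] = {}
    for rec in refdb:
        if len(rec.sequence) < k:
            logger.warning("reference %s shorter than k=%d: skipped", rec.accession, k)
            continue
        kmers[rec.accession] = _kmer_set(rec.sequence, k)
        lineages[rec.accession] = rec.taxonomy.as_tuple()
    if not kmers:
        raise ValueError("no reference reaches the k-mer length")
    return KmerIndex(k=k, kmers=kmers, lineages=lineages)


@dataclass
class Classification:
    names: dict[str, str]  # rank -> predicted name ('' if none)
    confidences: dict[str, float]  # rank -> fraction of bootstraps in [0, 1]
    n_bootstraps: int
    n_informative_bootstraps: int

    def lineage(self) -> TaxonomyString:
        return TaxonomyString(**{r: self.names[r] for r in RANKS})


def _empty_classification(n_boot: int) -> Classification:
    return Classification(
        names={r: "" for r in RANKS},
        confidences={r: 0.0 for r in RANKS},
        n_bootstraps=n_boot,
        n_informative_bootstraps=0,
    )


def classify(
    query: SeqRecord | str,
    idx: KmerIndex,
    n_boot: int = 100,
    subsample: int = 32,
    seed: int = 42,
) -> Classification:
    """Bootstrap-classify one query against the index.

    Fully reproducible for a given (query, index, seed). Queries shorter
    than ``k`` come back unassigned with zero confidence everywhere.
    """
    seq = query.sequence if isinstance(query, SeqRecord) else query
    if len(seq) < idx.k:
        return _empty_classification(n_boot)
    qkmers = sorted({seq[i : i + idx.k] for i in range(len(seq) - idx.k + 1)})
    # hits[i] = accessions containing query k-mer i (sorted for determinism)
    accs = sorted(idx.kmers)
    hits: list[list[str]] = [
        [a for a in accs if km in idx.kmers[a]] for km in qkmers
    ]
    rng = np.random.default_rng(seed)
    votes: list[tuple[str, ...]] = []
    for _ in range(n_boot):
        sample = rng.integers(0, len(qkmers), size=subsample)
        counts: dict[str, int] = defaultdict(int)
        for i in sample:
            for acc in hits[i]:
                counts[acc] += 1
        if not counts:
            continue  # uninformative bootstrap: no vote
        top = max(counts.values())
        winner = min(a for a, c in counts.items() if c == top)
        votes.append(idx.lineages[winner])
    if not votes:
        return _empty_classification(n_boot)

    names: dict[str, str] = {}
    confidences: dict[str, float] = {}
    prefix: tuple[str, ...] = ()
    # hierarchical tally: at each rank only lineages extending the winner
    # of the previous rank compete, so confidence is non-increasing
    for depth, rank in enumerate(RANKS):
        tally = Counter(v[: depth + 1] for v in votes if v[:depth] == prefix)
        best = max(tally.values())
        prefix = min(p for p, c in tally.items() if c == best)
        names[rank] = prefix[-1]
        confidences[rank] = tally[prefix] / n_boot
    return Classification(
        names=names,
        confidences=confidences,
        n_bootstraps=n_boot,
        n_informative_bootstraps=len(votes),
    )


def is_fungal(
    c: Classification, cutoff: float = 0.90, decision_rank: str = "genus"
) -> bool:
    """Flag a classification as fungal.

    Requires the predicted kingdom to be Fungi *and* a confident
    assignment at ``decision_rank``: against a fungal-only reference the
    kingdom-level confidence is degenerate (the only kingdom present),
    so a confident sub-kingdom call is what distinguishes a true fungal
    sequence from an unrelated one.
    """
    return c.names["kingdom"] == "Fungi" and c.confidences[decision_rank] >= cutoff


def record_seed(base_seed: int, accession: str) -> int:
    """Stable per-record bootstrap seed, independent of dataset order."""
    return (zlib.crc32(accession.encode()) ^ base_seed) & 0x7FFFFFFF
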
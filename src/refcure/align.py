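"""Global pairwise alignment and identity computation.

This is the computational substrate for the non-target filter (best hit
against a trusted marker reference at a 70% identity floor) and the
intraspecific-variability filter (all-against-all median identity per
species). Scoring emulates the conventions of usearch/vsearch-style
global aligners: match +2, mismatch -4, affine gaps (-20 open, -2
extend), and percent identity defined as matching columns over alignment
columns excluding terminal gaps. The dynamic programming itself is
delegated to :class:`Bio.Align.PairwiseAligner`; identity bookkeeping,
best-hit search and median aggregation live here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .taxfasta import Dataset, SeqRecord

_EPS = 1e-9


@dataclass(frozen=True)
class AlignParams:
    """Scoring and identity-definition knobs for global alignment.

    identity_definition:
        ``exclude_terminal_gaps`` (default) divides matches by alignment
        columns minus terminal-gap columns, the analog of VSEARCH's
        default iddef; ``all_columns`` divides by every column.
    """

    match_score: float = 2.0
    mismatch_score: float = -4.0
    gap_open: float = -20.0
    gap_extend: float = -2.0
    identity_definition: str = "exclude_terminal_gaps"

    def __post_init__(self) -> None:
        if self.match_score <= self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.identity_definition not in ("exclude_terminal_gaps", "all_columns"):
            raise ValueError(f"unknown identity_definition {self.identity_definition!r}")


DEFAULT_PARAMS = AlignParams()


@dataclass(frozen=True)
class AlignmentResult:
    matches: int
    columns: int
    terminal_gap_columns: int
    score: float
    identity: float


def _make_aligner(p: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = p.match_score
    aligner.mismatch_score = p.mismatch_score
    # open_gap_score applies to the first gapped position, so a gap of
    # length L costs open + (L-1) * extend
    aligner.open_gap_score = p.gap_open
    aligner.extend_gap_score = p.gap_extend
    return aligner


def _terminal_gap_columns(ga: str, gb: str) -> int:
    def lead(s: str) -> int:
        return len(s) - len(s.lstrip("-"))

    def trail(s: str) -> int:
        return len(s) - len(s.rstrip("-"))

    return lead(ga) + lead(gb) + trail(ga) + trail(gb)


def global_align(a: str, b: str, p: AlignParams = DEFAULT_PARAMS) -> AlignmentResult:
    """Optimal affine-gap global alignment of two DNA strings.

    Among co-optimal alignments the aligner's first reported traceback is
    taken, which is deterministic for given inputs. IUPAC ambiguity
    codes match only when the characters are equal.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    # canonical orientation: co-optimal tracebacks can differ between
    # (a, b) and (b, a), so order the pair to make identity symmetric
    if (len(b), b) < (len(a), a):
        a, b = b, a
    aligner = _make_aligner(p)
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    columns = len(ga)
    matches = sum(x == y for x, y in zip(ga, gb))
    terminal = _terminal_gap_columns(ga, gb)
    if p.identity_definition == "exclude_terminal_gaps":
        denom = columns - terminal
    else:
        denom = columns
    ident = matches / denom if denom > 0 else 0.0
    return AlignmentResult(
        matches=matches,
        columns=columns,
        terminal_gap_columns=terminal,
        score=float(aln.score),
        identity=ident,
    )


def identity(a: str, b: str, p: AlignParams = DEFAULT_PARAMS) -> float:
    return global_align(a, b, p).identity


def best_hit(
    query: SeqRecord | str,
    refdb: Dataset,
    min_identity: float,
    p: AlignParams = DEFAULT_PARAMS,
) -> tuple[str, float] | None:
    """Highest-identity reference for a query, or None below the floor.

    The identity floor is inclusive (a hit at exactly ``min_identity``
    is returned). Ties on identity go to the lexicographically smallest
    accession, which makes the result invariant under reference-database
    permutation.
    """
    if len(refdb) == 0:
        raise ValueError("best_hit requires a non-empty reference database")
    qseq = query.sequence if isinstance(query, SeqRecord) else query
    best_acc: str | None = None
    best_id = -1.0
    for ref in refdb:
        ident = identity(qseq, ref.sequence, p)
        if ident > best_id + _EPS or (
            abs(ident - best_id) <= _EPS
            and (best_acc is None or ref.accession < best_acc)
        ):
            best_acc, best_id = ref.accession, ident
    if best_id >= min_identity - _EPS:
        return best_acc, best_id
    return None


def identity_matrix(
    records: Sequence[SeqRecord], p: AlignParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Symmetric all-against-all identity matrix (diagonal = 1)."""
    n = len(records)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = identity(records[i].sequence, records[j].sequence, p)
            mat[i, j] = mat[j, i] = ident
    return mat


def allpairs_median(
    records: Sequence[SeqRecord], p: AlignParams = DEFAULT_PARAMS
) -> dict[str, float]:
    """Per-record median identity to every *other* record of the set.

    Even counts take the mean of the two central values (numpy median).
    """
    if len(records) < 2:
        raise ValueError("allpairs_median requires at least 2 records")
    mat = identity_matrix(records, p)
    out: dict[str, float] = {}
    for i, rec in enumerate(records):
        others = np.delete(mat[i], i)
        out[rec.accession] = float(np.median(others))
    return out
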
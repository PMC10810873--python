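"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written with different primitives than the package
(recursive enumeration instead of dynamic programming, statistics.median
instead of numpy) so agreement is meaningful.
"""

from __future__ import annotations

import math
import statistics

LADDER = (0.50, 0.75, 0.80, 0.85, 0.90, 0.925, 0.95, 0.97)
TOL = 1e-9


def brute_force_best_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -4.0,
    gap_open: float = -20.0,
    gap_extend: float = -2.0,
) -> float:
    """Maximum global alignment score by exhaustive path enumeration.

    The first residue of a gap costs ``gap_open``, each further residue
    ``gap_extend`` (the same convention as the package's aligner).
    Feasible only for short sequences.
    """
    best = -math.inf

    def rec(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            rec(i + 1, j, score + (gap_extend if last == "D" else gap_open), "D")
        if j < len(b):
            rec(i, j + 1, score + (gap_extend if last == "I" else gap_open), "I")

    rec(0, 0, 0.0, "")
    return best


def simulate_ladder(
    mat,
    mode: str,
    ladder: tuple[float, ...] = LADDER,
    safeguard_fraction: float = 0.5,
    safeguard_basis: str = "initial",
) -> set[int]:
    """Literal simulation of the drop-out ladder; returns kept indices.

    Mode A removes, in a single pass, every sequence whose median
    identity to the others is below the top threshold. Modes B/C walk
    the ladder, recomputing medians over survivors at each step; C stops
    the ladder before any step that would breach the retention
    safeguard. A median within TOL of a threshold is not "below" it.
    """
    n = len(mat)
    alive = set(range(n))

    def median_of(i: int, group: set[int]) -> float:
        return statistics.median(mat[i][j] for j in group if j != i)

    if mode == "A":
        top = ladder[-1]
        return {i for i in alive if not (median_of(i, alive) < top - TOL)}

    for threshold in ladder:
        if len(alive) < 2:
            break
        failing = {i for i in alive if median_of(i, alive) < threshold - TOL}
        if not failing:
            continue
        if mode == "C":
            if safeguard_basis == "initial":
                if len(alive) - len(failing) < math.ceil(safeguard_fraction * n):
                    break
            else:
                if len(failing) >= safeguard_fraction * len(alive) - TOL:
                    break
        alive -= failing
    return alive


def random_species_matrix(rng, n: int):
    """Random symmetric identity matrix shaped like a real species set.

    Members fall into 1-3 clusters; within-cluster identities are drawn
    high (0.90-1.0), between-cluster identities low-to-middling
    (0.40-0.92), all on a 0.005 grid so outcomes never sit within
    floating-point noise of a ladder threshold.
    """
    k = int(rng.integers(1, 4))
    assign = rng.integers(0, k, size=n)
    mat = [[1.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if assign[i] == assign[j]:
                v = 0.90 + 0.005 * int(rng.integers(0, 21))
            else:
                v = 0.40 + 0.005 * int(rng.integers(0, 105))
            mat[i][j] = mat[j][i] = round(v, 3)
    return mat


def clustered_species_matrix(rng, n: int):
    """Identity matrix of a realistic species set: one tight conspecific
    cluster (pairwise 0.975-1.0) plus mislabeled members that sit far
    from everyone (0.40-0.93). This is the structure real barcode
    species show; the monotone retention ordering of the three drop-out
    modes is a property of such sets, not of arbitrary matrices.
    """
    m = max(2, int(math.ceil(n * rng.uniform(0.5, 1.0))))
    mat = [[1.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if i < m and j < m:
                v = 0.975 + 0.005 * int(rng.integers(0, 6))
            else:
                v = 0.40 + 0.005 * int(rng.integers(0, 107))
            mat[i][j] = mat[j][i] = round(min(v, 1.0), 3)
    return mat
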
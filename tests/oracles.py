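"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with the simplest possible
algorithms (quadratic DP alignment, naive agglomeration) so that the
package's optimised paths can be checked against them on small inputs.
"""

from __future__ import annotations

import itertools

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -5, -2
NEG = float("-inf")


def sw_local_matches(a: str, b: str) -> tuple[float, int]:
    """Smith-Waterman with affine gaps (Gotoh).

    Returns (best score, matches of a best-scoring alignment, maximising
    matches among co-optimal alignments).  Pure-Python reference used only
    on short sequences.
    """
    n, m = len(a), len(b)
    # states: (score, matches); lexicographic maximisation is valid because
    # matches are additive along an alignment path
    best = (0.0, 0)
    M = [[(NEG, 0)] * (m + 1) for _ in range(n + 1)]
    X = [[(NEG, 0)] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[(NEG, 0)] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            is_match = 1 if a[i - 1] == b[j - 1] else 0
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], (0.0, 0))
            M[i][j] = (prev[0] + sub, prev[1] + is_match)
            X[i][j] = max(
                (M[i - 1][j][0] + GAP_OPEN, M[i - 1][j][1]),
                (X[i - 1][j][0] + GAP_EXTEND, X[i - 1][j][1]),
                (Y[i - 1][j][0] + GAP_OPEN, Y[i - 1][j][1]),
            )
            Y[i][j] = max(
                (M[i][j - 1][0] + GAP_OPEN, M[i][j - 1][1]),
                (X[i][j - 1][0] + GAP_OPEN, X[i][j - 1][1]),
                (Y[i][j - 1][0] + GAP_EXTEND, Y[i][j - 1][1]),
            )
            best = max(best, M[i][j])
    return best


def greedy_cluster_bruteforce(reads, identity_threshold: float, word_size: int = 8):
    """Greedy clustering with full DP alignment for every word-sharing
    candidate pair; returns a list of lists of read ids."""

    def kmers(s: str) -> set[str]:
        return {s[i:i + word_size] for i in range(len(s) - word_size + 1)}

    order = sorted(reads, key=lambda r: (-len(r.bases), r.id))
    clusters: list[list[str]] = []
    refs: list = []
    for read in order:
        placed = False
        for ci, ref in enumerate(refs):
            if not (kmers(read.bases) & kmers(ref.bases)):
                continue
            _score, matches = sw_local_matches(read.bases, ref.bases)
            if matches / min(len(read.bases), len(ref.bases)) >= identity_threshold:
                clusters[ci].append(read.id)
                placed = True
                break
        if not placed:
            clusters.append([read.id])
            refs.append(read)
    return clusters


def upgma_bruteforce(ids, matrix):
    """Naive UPGMA agglomeration.

    ``matrix`` is a full symmetric distance matrix (list of lists).  Returns
    the set of internal clades as (frozenset of leaf ids, merge height)
    pairs, height being half the merge distance.
    """
    clusters: list[frozenset] = [frozenset([i]) for i in ids]
    index = {frozenset([i]): k for k, i in enumerate(ids)}
    pos = {i: k for k, i in enumerate(ids)}

    def avg_dist(ca: frozenset, cb: frozenset) -> float:
        return sum(matrix[pos[x]][pos[y]] for x in ca for y in cb) / (len(ca) * len(cb))

    clades = []
    while len(clusters) > 1:
        best = None
        for ca, cb in itertools.combinations(clusters, 2):
            d = avg_dist(ca, cb)
            if best is None or d < best[0]:
                best = (d, ca, cb)
        d, ca, cb = best
        merged = ca | cb
        clades.append((merged, d / 2.0))
        clusters.remove(ca)
        clusters.remove(cb)
        clusters.append(merged)
    return clades
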
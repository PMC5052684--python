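"""Signed Jaccard similarity between signatures, all-pairs adjacency,
query ranking, and chemical-fingerprint pairing.

A signature is abstracted to a pair of disjoint up/down gene sets. The
signed Jaccard index scores concordant overlaps (up/up, down/down)
positively and cross overlaps (up/down) negatively:

    sj(a, b) = [J(a.up, b.up) + J(a.down, b.down)
                - J(a.up, b.down) - J(a.down, b.up)] / 2

with J the plain Jaccard index |X & Y| / |X | Y|. The score is 1 for a
signature against itself, -1 against its direction-reversed copy, and 0
for signatures sharing no genes.
"""

from __future__ import annotations

import math

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import IntegrityError


@dataclass(frozen=True)
class GeneSetPair:
    """Disjoint up/down gene sets abstracting a signature."""

    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        if self.up & self.down:
            raise IntegrityError("up and down sets must be disjoint")

    def reversed(self) -> "GeneSetPair":
        return GeneSetPair(up=self.down, down=self.up)


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Plain Jaccard index; two empty sets score 0 by convention."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def signed_jaccard(a: GeneSetPair, b: GeneSetPair) -> float:
    """Direction-aware set similarity in [-1, 1].

    fsum makes the four-term sum correctly rounded, so the score is
    exactly symmetric and exactly negates when one argument is reversed.
    """
    return math.fsum(
        [
            jaccard(a.up, b.up),
            jaccard(a.down, b.down),
            -jaccard(a.up, b.down),
            -jaccard(a.down, b.up),
        ]
    ) / 2.0


def absolute_jaccard(a: GeneSetPair, b: GeneSetPair) -> float:
    """Direction-blind variant: Jaccard of the pooled gene sets."""
    return jaccard(a.up | a.down, b.up | b.down)


@dataclass
class SimilarityMatrix:
    """Symmetric signed-Jaccard adjacency over an ordered signature list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise IntegrityError("matrix shape does not match id count")
        if not np.allclose(v, v.T):
            raise IntegrityError("similarity matrix must be symmetric")
        self.values = v

    def lookup(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.ids.index(id_a), self.ids.index(id_b)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in self.values[i]) + "\n")


def _pairs(signatures) -> tuple[list[str], list[GeneSetPair]]:
    ids, pairs = [], []
    for sig in signatures:
        if isinstance(sig, GeneSetPair):
            ids.append(f"sig{len(ids)}")
            pairs.append(sig)
        elif isinstance(sig, tuple) and len(sig) == 2:
            ids.append(sig[0])
            pairs.append(sig[1])
        else:
            ids.append(sig.signature_id)
            pairs.append(sig.gene_set_pair())
    return ids, pairs


def adjacency(signatures: Sequence) -> SimilarityMatrix:
    """All-pairs signed Jaccard; accepts Signatures, (id, GeneSetPair)
    tuples or bare GeneSetPairs."""
    ids, pairs = _pairs(signatures)
    n = len(pairs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            values[i, j] = values[j, i] = signed_jaccard(pairs[i], pairs[j])
    return SimilarityMatrix(ids=ids, values=values)


def query(
    query_pair: GeneSetPair, library: Sequence, k: int | None = None
) -> list[tuple[str, float]]:
    """Rank a library by signed Jaccard against a query pair.

    Descending score; ties break deterministically on the id. ``k`` limits
    the returned list (None = all).
    """
    ids, pairs = _pairs(library)
    scored = [(sid, signed_jaccard(query_pair, p)) for sid, p in zip(ids, pairs)]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored if k is None else scored[:k]


def tanimoto(fp_a: Iterable[int], fp_b: Iterable[int]) -> float:
    """Bit-set Jaccard between two structural fingerprints (bit index sets)."""
    a, b = set(fp_a), set(fp_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def similar_drug_pairs(
    fingerprints: Mapping[str, Iterable[int]], threshold: float = 0.9
) -> set[frozenset[str]]:
    """Unordered drug pairs with Tanimoto coefficient strictly above the
    threshold. Fingerprints are inputs (for example ECFP4 bit sets);
    their generation is outside this package."""
    drugs = sorted(fingerprints)
    fps = {d: set(fingerprints[d]) for d in drugs}
    out: set[frozenset[str]] = set()
    for i, a in enumerate(drugs):
        for b in drugs[i + 1:]:
            if tanimoto(fps[a], fps[b]) > threshold:
                out.add(frozenset((a, b)))
    return out


def cluster_order(matrix: SimilarityMatrix) -> list[str]:
    """Leaf ordering from average-linkage hierarchical clustering on the
    distance 1 - score.

    The dendrogram is canonicalized (each node's children ordered by the
    lexicographically smallest id in their subtree), so the ordering does
    not depend on the input order of the signatures.
    """
    n = len(matrix.ids)
    if n <= 1:
        return list(matrix.ids)
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="average")

    def leaves(node: int) -> list[str]:
        if node < n:
            return [matrix.ids[node]]
        left, right = int(link[node - n, 0]), int(link[node - n, 1])
        a, b = leaves(left), leaves(right)
        return a + b if min(a) <= min(b) else b + a

    return leaves(2 * n - 2)
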
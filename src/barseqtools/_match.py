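"""Edit-distance primitives used by demultiplexing and barcode design.

Distances are plain Levenshtein (unit-cost substitution/insertion/deletion).
`edlib` does the per-pair work; :class:`FuzzyIndex` adds an exact-seed
pigeonhole filter so that a read only has to be verified against a handful
of catalog barcodes instead of the whole collection.
"""

from __future__ import annotations

import edlib


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance between two sequences."""
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def levenshtein_leq(a: str, b: str, k: int) -> int:
    """Edit distance if <= k, else -1 (early-abandon form)."""
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


class FuzzyIndex:
    """Find all references within a fixed edit distance of a query.

    Pigeonhole filter: split the query into ``max_dist + 1`` contiguous
    pieces; if a reference is within ``max_dist`` edits of the query, at
    least one piece survives unedited and therefore occurs *exactly* in the
    reference, displaced by at most ``max_dist`` positions. Candidates are
    gathered from an exact (gram, position-window) lookup and verified with
    edlib, so tie/ambiguity semantics depend only on true distances, never
    on index order. Queries whose length differs from the indexed sequences
    fall back to brute-force verification.
    """

    def __init__(self, items, max_dist: int):
        if max_dist < 0:
            raise ValueError("max_dist must be >= 0")
        self.max_dist = max_dist
        self.labels: list[object] = []
        self.seqs: list[str] = []
        self._exact: dict[str, list[int]] = {}
        self._grams: dict[str, list[tuple[int, int]]] = {}
        self._seq_len: int | None = None
        self._q: int | None = None
        for label, seq in items:
            self.add(label, seq)

    def __len__(self) -> int:
        return len(self.seqs)

    def add(self, label: object, seq: str) -> None:
        i = len(self.seqs)
        self.labels.append(label)
        self.seqs.append(seq)
        self._exact.setdefault(seq, []).append(i)
        if self.max_dist == 0:
            return
        if self._seq_len is None:
            self._seq_len = len(seq)
            self._q = max(1, self._seq_len // (self.max_dist + 1))
        q = self._q
        if len(seq) >= q:
            for pos in range(len(seq) - q + 1):
                self._grams.setdefault(seq[pos : pos + q], []).append((i, pos))

    def _piece_starts(self, n: int) -> list[int]:
        k = self.max_dist + 1
        return [round(j * n / k) for j in range(k)]

    def _candidates(self, query: str) -> set[int]:
        cand: set[int] = set(self._exact.get(query, ()))
        q = self._q
        for start in self._piece_starts(len(query)):
            gram = query[start : start + q]
            if len(gram) < q:
                continue
            for i, pos in self._grams.get(gram, ()):
                if abs(pos - start) <= self.max_dist:
                    cand.add(i)
        return cand

    def lookup(self, query: str):
        """All (label, distance) pairs with distance <= max_dist."""
        if self.max_dist == 0:
            return [(self.labels[i], 0) for i in self._exact.get(query, ())]
        if self._seq_len is not None and len(query) == self._seq_len:
            idx = self._candidates(query)
        else:  # length mismatch: the pigeonhole geometry no longer applies
            idx = range(len(self.seqs))
        hits = []
        for i in idx:
            d = levenshtein_leq(query, self.seqs[i], self.max_dist)
            if d >= 0:
                hits.append((self.labels[i], d))
        return hits

    def min_distance(self, query: str) -> int:
        """Smallest distance to any reference, or -1 if all exceed max_dist."""
        hits = self.lookup(query)
        if not hits:
            return -1
        return min(d for _, d in hits)
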
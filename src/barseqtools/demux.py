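"""Read demultiplexing: sample-index and barcode matching by edit distance.

Reads have a fixed layout (two-step PCR yields constant offsets): a 5-bp
sample index, a 15-bp tag-specific constant priming region, then the 20-bp
molecular barcode. Indices are matched at Levenshtein distance <= 1 and
barcodes at distance <= 2; a read matching two references equally well at
the minimum distance is discarded as ambiguous, while a unique strictly
nearer reference wins even when other references sit within the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import (
    DNTAG,
    DNTAG_CONSTANT,
    TAGS,
    UPTAG,
    UPTAG_CONSTANT,
    BarcodeCatalog,
    CountMatrix,
    SampleSheet,
)
from ._match import FuzzyIndex, levenshtein, levenshtein_leq

__all__ = [
    "ReadLayout",
    "MappingStats",
    "MatchOutcome",
    "levenshtein",
    "match_barcode",
    "match_index",
    "demultiplex",
]


@dataclass(frozen=True)
class ReadLayout:
    """Fixed offsets of the index, constant and barcode regions in a read."""

    index_start: int = 0
    index_length: int = 5
    constant_length: int = 15
    barcode_length: int = 20

    @property
    def constant_start(self) -> int:
        return self.index_start + self.index_length

    @property
    def barcode_start(self) -> int:
        return self.constant_start + self.constant_length

    @property
    def barcode_end(self) -> int:
        return self.barcode_start + self.barcode_length


@dataclass(frozen=True)
class MatchOutcome:
    """Result of a nearest-unique lookup: a hit, or why there is none."""

    status: str  # "ok" | "ambiguous" | "no_hit"
    label: object = None  # (mutant_id, tag) or sample_id
    distance: int = -1

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _nearest_unique(hits: list[tuple[object, int]]) -> MatchOutcome:
    if not hits:
        return MatchOutcome("no_hit")
    dmin = min(d for _, d in hits)
    best = [lab for lab, d in hits if d == dmin]
    if len(best) > 1:
        return MatchOutcome("ambiguous", distance=dmin)
    return MatchOutcome("ok", best[0], dmin)


def match_barcode(
    read_barcode_region: str,
    catalog: BarcodeCatalog | FuzzyIndex,
    max_dist: int = 2,
) -> MatchOutcome:
    """Assign a barcode region to the unique nearest catalog (mutant, tag)."""
    index = catalog if isinstance(catalog, FuzzyIndex) else _barcode_index(catalog, max_dist)
    return _nearest_unique(index.lookup(read_barcode_region))


def match_index(
    read_index_region: str,
    sheet: SampleSheet,
    max_dist: int = 1,
) -> MatchOutcome:
    """Assign an index region to the unique nearest sample."""
    hits = []
    for seq, sid in sheet.indices.items():
        d = levenshtein_leq(read_index_region, seq, max_dist)
        if d >= 0:
            hits.append((sid, d))
    return _nearest_unique(hits)


def _barcode_index(catalog: BarcodeCatalog, max_dist: int) -> FuzzyIndex:
    return FuzzyIndex(
        [((m, t), s) for m, t, s in catalog.barcode_items()], max_dist=max_dist
    )


@dataclass
class MappingStats:
    """Per-run accounting; every read lands in exactly one category."""

    n_total: int = 0
    n_mapped_by_distance: dict[int, int] = field(default_factory=dict)
    n_ambiguous_barcode: int = 0
    n_no_hit_barcode: int = 0
    n_bad_index: int = 0
    n_ambiguous_index: int = 0
    n_bad_constant: int = 0
    n_too_short: int = 0

    @property
    def n_mapped(self) -> int:
        return sum(self.n_mapped_by_distance.values())

    def mapped_within(self, d: int) -> int:
        """Reads mapped with barcode distance <= d (monotone in d)."""
        return sum(v for k, v in self.n_mapped_by_distance.items() if k <= d)

    @property
    def n_unassigned(self) -> int:
        return (
            self.n_ambiguous_barcode
            + self.n_no_hit_barcode
            + self.n_bad_index
            + self.n_ambiguous_index
            + self.n_bad_constant
            + self.n_too_short
        )

    def as_series(self) -> pd.Series:
        data = {
            "total": self.n_total,
            "mapped": self.n_mapped,
            "mapped_dist0": self.mapped_within(0),
            "mapped_dist1": self.mapped_within(1),
            "mapped_dist2": self.mapped_within(2),
            "ambiguous_barcode": self.n_ambiguous_barcode,
            "no_hit_barcode": self.n_no_hit_barcode,
            "bad_index": self.n_bad_index,
            "ambiguous_index": self.n_ambiguous_index,
            "bad_constant": self.n_bad_constant,
            "too_short": self.n_too_short,
        }
        return pd.Series(data, name="reads")


def _iter_reads(reads):
    """Yield (record_number, sequence) from a FASTQ path, a text path with
    one sequence per line, or any iterable of sequences / (id, seq) tuples /
    (id, seq, qual) records."""
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        with open(path) as fh:
            first = fh.read(1)
        if first == "@":
            from Bio.SeqIO.QualityIO import FastqGeneralIterator

            with open(path) as fh:
                it = FastqGeneralIterator(fh)
                i = 0
                while True:
                    try:
                        rec = next(it)
                    except StopIteration:
                        return
                    except ValueError as exc:
                        raise ValueError(f"malformed FASTQ record {i + 1}: {exc}") from exc
                    i += 1
                    yield i, rec[1]
        else:
            with open(path) as fh:
                for i, line in enumerate(fh, start=1):
                    line = line.strip()
                    if line:
                        yield i, line
    else:
        for i, rec in enumerate(reads, start=1):
            if isinstance(rec, str):
                yield i, rec
            else:
                yield i, rec[1]


def demultiplex(
    reads,
    sheet: SampleSheet,
    catalog: BarcodeCatalog,
    layout: ReadLayout = ReadLayout(),
    max_barcode_dist: int = 2,
    max_index_dist: int = 1,
) -> tuple[CountMatrix, MappingStats]:
    """Count reads into a (mutant, tag) x sample matrix.

    A read is mapped when its index region matches a unique sample, its
    constant region identifies the UPTAG or DNTAG library (distance <= 2 to
    the nearer constant, ties discarded), and its barcode region matches a
    unique catalog barcode within ``max_barcode_dist``. Unmapped reads are
    tallied by cause in :class:`MappingStats`; category counts always sum to
    the number of input reads.
    """
    stats = MappingStats()
    bc_index = _barcode_index(catalog, max_barcode_dist)
    bc_exact: dict[str, list[tuple[str, str]]] = {}
    for m, t, s in catalog.barcode_items():
        bc_exact.setdefault(s, []).append((m, t))
    index_exact = dict(sheet.indices)
    consts = ((UPTAG, UPTAG_CONSTANT), (DNTAG, DNTAG_CONSTANT))

    cells: dict[tuple[str, str, str], int] = {}
    dist_counts: dict[int, int] = {}

    for recno, seq in _iter_reads(reads):
        stats.n_total += 1
        if len(seq) < layout.barcode_end:
            stats.n_too_short += 1
            continue

        idx_region = seq[layout.index_start : layout.index_start + layout.index_length]
        sid = index_exact.get(idx_region)
        if sid is None:
            outcome = match_index(idx_region, sheet, max_index_dist)
            if outcome.status == "ambiguous":
                stats.n_ambiguous_index += 1
                continue
            if outcome.status == "no_hit":
                stats.n_bad_index += 1
                continue
            sid = outcome.label

        const_region = seq[layout.constant_start : layout.barcode_start]
        chits = []
        for tag, cseq in consts:
            d = levenshtein_leq(const_region, cseq, 2)
            if d >= 0:
                chits.append((tag, d))
        if not _nearest_unique(chits).ok:
            stats.n_bad_constant += 1
            continue

        bc_region = seq[layout.barcode_start : layout.barcode_end]
        exact = bc_exact.get(bc_region)
        if exact is not None:
            # a distance-0 hit beats every inexact one; only a duplicated
            # catalog sequence can tie it
            if len(exact) > 1:
                stats.n_ambiguous_barcode += 1
                continue
            outcome = MatchOutcome("ok", exact[0], 0)
        else:
            outcome = match_barcode(bc_region, bc_index)
        if outcome.status == "ambiguous":
            stats.n_ambiguous_barcode += 1
            continue
        if outcome.status == "no_hit":
            stats.n_no_hit_barcode += 1
            continue
        mid, tag = outcome.label
        cells[(mid, tag, sid)] = cells.get((mid, tag, sid), 0) + 1
        dist_counts[outcome.distance] = dist_counts.get(outcome.distance, 0) + 1

    stats.n_mapped_by_distance = dist_counts

    rows = pd.MultiIndex.from_product(
        [catalog.mutant_ids, TAGS], names=["mutant_id", "tag"]
    )
    mat = pd.DataFrame(0, index=rows, columns=pd.Index(sheet.sample_ids), dtype="int64")
    for (mid, tag, sid), c in cells.items():
        mat.loc[(mid, tag), sid] = c
    return CountMatrix(mat, sheet.metadata()), stats
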
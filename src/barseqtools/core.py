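"""Core containers for Bar-seq data.

A Bar-seq experiment is a pooled competition of barcoded deletion mutants.
Each mutant carries two independent 20-bp barcodes (UPTAG and DNTAG), and
each sequencing library carries a 5-bp sample index. The containers here
hold the three tables every stage of the pipeline exchanges:

* :class:`BarcodeCatalog` — mutant_id -> (uptag, dntag) sequences,
* :class:`SampleSheet`    — sample_id -> (index, treatment, time, bio_rep, tech_rep),
* :class:`CountMatrix`    — (mutant, tag) x sample (or mutant x replicate) counts
  with the sample metadata attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UPTAG = "UPTAG"
DNTAG = "DNTAG"
TAGS = (UPTAG, DNTAG)

_DNA = set("ACGT")

#: Constant priming regions that distinguish UPTAG from DNTAG reads.
#: Fixed arbitrary 15-mers taken from the tag-specific priming sequences of
#: the standard yeast deletion-collection primers.
UPTAG_CONSTANT = "GTCCACGAGGTCTCT"
DNTAG_CONSTANT = "GTGTCGGTCTCGTAG"

SAMPLE_COLUMNS = ["index", "treatment", "time", "bio_rep", "tech_rep"]


def _check_dna(seq: str, what: str) -> None:
    if not seq or not set(seq) <= _DNA:
        raise ValueError(f"{what} must be a non-empty uppercase ACGT string, got {seq!r}")


@dataclass
class BarcodeCatalog:
    """Map from mutant_id to its UPTAG and DNTAG barcode sequences."""

    table: pd.DataFrame  # index mutant_id, columns uptag, dntag

    def __post_init__(self) -> None:
        if not {"uptag", "dntag"} <= set(self.table.columns):
            raise ValueError("catalog table needs 'uptag' and 'dntag' columns")
        if not self.table.index.is_unique:
            raise ValueError("mutant_ids must be unique")
        for col in ("uptag", "dntag"):
            for seq in self.table[col]:
                _check_dna(seq, f"{col} barcode")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def mutant_ids(self) -> list[str]:
        return list(self.table.index)

    def barcode_items(self) -> list[tuple[str, str, str]]:
        """All (mutant_id, tag, sequence) triples in catalog order."""
        out = []
        for mid, row in self.table.iterrows():
            out.append((mid, UPTAG, row["uptag"]))
            out.append((mid, DNTAG, row["dntag"]))
        return out

    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        _write_tsv(self.table.rename_axis("mutant_id").reset_index(), path, header_lines)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeCatalog":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return cls(df.set_index("mutant_id")[["uptag", "dntag"]])


@dataclass
class SampleSheet:
    """Sample metadata: index sequence and the experimental-design labels."""

    table: pd.DataFrame  # index sample_id; columns index, treatment, time, bio_rep, tech_rep

    def __post_init__(self) -> None:
        missing = set(SAMPLE_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if not self.table.index.is_unique:
            raise ValueError("sample_ids must be unique")
        for seq in self.table["index"]:
            _check_dna(seq, "sample index")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def indices(self) -> dict[str, str]:
        """index sequence -> sample_id (index sequences must be unique)."""
        idx = self.table["index"]
        if not idx.is_unique:
            raise ValueError("index sequences must be unique")
        return {seq: sid for sid, seq in idx.items()}

    def metadata(self) -> pd.DataFrame:
        return self.table[["treatment", "time", "bio_rep", "tech_rep"]].copy()

    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        _write_tsv(self.table.rename_axis("sample_id").reset_index(), path, header_lines)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"index": str})
        return cls(df.set_index("sample_id"))


@dataclass
class CountMatrix:
    """Non-negative integer counts with sample metadata attached.

    ``counts`` rows are either a (mutant_id, tag) MultiIndex (raw demultiplexed
    matrix) or a flat mutant_id index (after tag/technical collapse). Columns
    are sample (or biological-replicate) identifiers; ``samples`` carries one
    metadata row per column.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.counts.columns)
        if list(self.counts.columns) != list(self.samples.index):
            missing = set(self.counts.columns) ^ set(self.samples.index)
            raise ValueError(f"count columns and sample metadata disagree: {sorted(map(str, missing))}")
        if (np.asarray(self.counts.values) < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.is_unique:
            raise ValueError("row keys must be unique")

    # -- basic properties -------------------------------------------------
    @property
    def has_tags(self) -> bool:
        return isinstance(self.counts.index, pd.MultiIndex)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.samples.copy())

    def select_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(self.counts[sample_ids], self.samples.loc[sample_ids])

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        df = self.counts.copy()
        if self.has_tags:
            df.index = [f"{m}:{t}" for m, t in df.index]
        df = df.rename_axis("row_id").reset_index()
        _write_tsv(df, path, header_lines)

    @classmethod
    def from_tsv(cls, path: str | Path, samples: pd.DataFrame | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.set_index("row_id")
        if df.index.astype(str).str.contains(":").all():
            parts = df.index.astype(str).str.rsplit(":", n=1)
            df.index = pd.MultiIndex.from_arrays(
                [parts.str[0], parts.str[1]], names=["mutant_id", "tag"]
            )
        else:
            df.index = df.index.rename("mutant_id")
        return cls(df, samples)


@dataclass(frozen=True)
class DesignSpec:
    """An experimental design: treatments x biological reps x technical reps.

    The standard notation is ``2x4x2`` — two treatments, four biological
    replicates per treatment, two technical replicates (independent library
    preparations) per biological replicate.
    """

    n_treatments: int = 2
    n_bio_reps: int = 4
    n_tech_reps: int = 2

    def __post_init__(self) -> None:
        if self.n_treatments < 1 or self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ValueError("design dimensions must be >= 1")

    @classmethod
    def parse(cls, label: str) -> "DesignSpec":
        parts = label.lower().replace("×", "x").split("x")
        if len(parts) != 3:
            raise ValueError(f"design label must look like '2x4x2', got {label!r}")
        t, b, k = (int(p) for p in parts)
        return cls(t, b, k)

    @property
    def label(self) -> str:
        return f"{self.n_treatments}x{self.n_bio_reps}x{self.n_tech_reps}"

    @property
    def n_samples(self) -> int:
        return self.n_treatments * self.n_bio_reps * self.n_tech_reps


def _write_tsv(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
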
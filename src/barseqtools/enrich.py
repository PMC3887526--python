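"""Gene-set enrichment on estimated log-fold changes.

Each gene set's in-set logFC distribution is compared with the out-of-set
distribution by a two-sided Wilcoxon rank-sum test (exact enumeration for
small in-set sizes, normal approximation with tie correction otherwise);
q-values across sets give the FDR threshold. Sets with fewer than four
members among the detected mutants are discarded in advance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .diffabund import storey_qvalues

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "filter_gene_sets",
    "wilcoxon_enrichment",
]


@dataclass
class GeneSetCollection:
    """Named sets of mutant ids (duplicates within a set are collapsed)."""

    sets: dict[str, set]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        self.sets = {sid: set(members) for sid, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, members in self.sets.items():
                desc = self.descriptions.get(sid, "")
                fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")


def read_gmt(path: str | Path, source: str = "") -> GeneSetCollection:
    """Read tab-separated GMT: set_id, description, member ids..."""
    sets: dict[str, set] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            sets[parts[0]] = set(p for p in parts[2:] if p)
            desc[parts[0]] = parts[1]
    return GeneSetCollection(sets, desc, source)


def filter_gene_sets(
    sets: GeneSetCollection,
    universe,
    min_size: int = 4,
) -> GeneSetCollection:
    """Intersect each set with the detected universe and drop sets with
    fewer than ``min_size`` detected members (exactly ``min_size`` is kept)."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe of detected mutants is empty")
    kept = {}
    for sid, members in sets.sets.items():
        inter = members & universe
        if len(inter) >= min_size:
            kept[sid] = inter
    return GeneSetCollection(kept, dict(sets.descriptions), sets.source)


def wilcoxon_enrichment(
    logfcs: pd.Series,
    sets: GeneSetCollection,
    fdr: float = 0.05,
    alternative: str = "two-sided",
    exact_max_n: int = 10,
) -> pd.DataFrame:
    """Rank-sum enrichment of each set's logFCs against the rest.

    The exact null enumeration is used when the in-set size is at most
    ``exact_max_n``, otherwise the normal approximation with tie correction
    and continuity correction. Returns one row per set with n_detected,
    direction ('up' when the in-set median logFC exceeds the out-set
    median), p, Storey q, and the q <= fdr flag.
    """
    logfcs = logfcs.dropna()
    universe = set(logfcs.index)
    rows = []
    for sid, members in sets.sets.items():
        inset = sorted(members & universe)
        if not inset:
            continue
        if len(inset) == len(universe):
            raise ValueError(f"gene set {sid!r} covers the whole universe; no out-group")
        outset = logfcs.index.difference(inset)
        x = logfcs.loc[inset].to_numpy()
        y = logfcs.loc[outset].to_numpy()
        method = "exact" if len(x) <= exact_max_n else "asymptotic"
        res = mannwhitneyu(x, y, alternative=alternative, method=method)
        direction = "up" if np.median(x) > np.median(y) else "down"
        rows.append(
            {
                "set_id": sid,
                "n_detected": len(inset),
                "direction": direction,
                "pvalue": float(res.pvalue),
            }
        )
    table = pd.DataFrame(rows).set_index("set_id") if rows else pd.DataFrame(
        columns=["n_detected", "direction", "pvalue"]
    )
    if len(table):
        table["qvalue"] = storey_qvalues(table["pvalue"].to_numpy())
        table["significant"] = table["qvalue"] <= fdr
    return table
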
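"""Count-matrix filtering and aggregation.

The raw demultiplexed matrix has one row per (mutant, tag) and one column
per sequencing library. Before differential testing it is (i) stripped of
low-count rows that mostly arise from sequencing error, (ii) stripped of
spiked-in control strains, and (iii) collapsed by summing UPTAG + DNTAG and
technical replicates, leaving one row per mutant and one column per
biological replicate. Summation (rather than averaging) keeps the counts on
their natural sampling scale and is robust to the loss of one barcode.
"""

from __future__ import annotations

import logging

import pandas as pd

from .core import CountMatrix, TAGS, UPTAG, DNTAG

logger = logging.getLogger(__name__)


def filter_low_count(
    m: CountMatrix,
    min_total: int = 100,
    columns: list[str] | None = None,
) -> tuple[CountMatrix, list]:
    """Drop rows with total count < ``min_total`` ("fewer than" is strict:
    a row totalling exactly ``min_total`` is kept).

    ``columns`` restricts the samples over which totals are taken (default:
    all columns, matching filtering across every sample including time zero).
    """
    if m.counts.shape[1] == 0:
        raise ValueError("count matrix has no columns")
    sub = m.counts if columns is None else m.counts[list(columns)]
    totals = sub.sum(axis=1)
    keep = totals >= min_total
    removed = list(m.counts.index[~keep])
    return CountMatrix(m.counts.loc[keep], m.samples.copy()), removed


def remove_control(m: CountMatrix, control_ids) -> CountMatrix:
    """Drop all rows belonging to the given control mutants (e.g. the HO
    deletion spiked into every plate). Absent controls log a warning."""
    if isinstance(control_ids, str):
        control_ids = [control_ids]
    control_ids = list(control_ids)
    idx = m.counts.index
    mutants = idx.get_level_values("mutant_id") if m.has_tags else idx
    present = set(mutants)
    for cid in control_ids:
        if cid not in present:
            logger.warning("control id %r not present in count matrix", cid)
    keep = ~mutants.isin(control_ids)
    return CountMatrix(m.counts.loc[keep], m.samples.copy())


def collapse_tags_and_technical(m: CountMatrix) -> CountMatrix:
    """Sum UPTAG+DNTAG and technical replicates within each biological
    replicate: rows become mutants, columns become (treatment, bio_rep)
    libraries. The grand total is conserved exactly."""
    for col in ("treatment", "bio_rep"):
        if col not in m.samples.columns or m.samples[col].isna().any():
            raise ValueError(f"sample metadata must provide '{col}' for every column")

    if m.has_tags:
        by_mutant = m.counts.groupby(level="mutant_id", sort=False).sum()
    else:
        by_mutant = m.counts.copy()

    keys = ["treatment", "bio_rep"]
    if "time" in m.samples.columns and m.samples["time"].notna().all():
        keys = ["treatment", "time", "bio_rep"]
    groups = m.samples.groupby(keys, sort=False, dropna=False)

    new_cols = {}
    meta_rows = []
    for key, sub in groups:
        key = key if isinstance(key, tuple) else (key,)
        label = "_".join(str(k) for k in key)
        new_cols[label] = by_mutant[list(sub.index)].sum(axis=1)
        meta_rows.append(dict(zip(keys, key), sample_id=label))
    collapsed = pd.DataFrame(new_cols)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountMatrix(collapsed, meta)


def collapse_tags(m: CountMatrix) -> CountMatrix:
    """Sum UPTAG+DNTAG per mutant but keep every sequencing library as its
    own column (needed when technical variation is itself the object of
    study, e.g. variance partitioning)."""
    if not m.has_tags:
        return m.copy()
    by_mutant = m.counts.groupby(level="mutant_id", sort=False).sum()
    return CountMatrix(by_mutant, m.samples.copy())


def tag_divergence_report(m: CountMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Per-mutant UPTAG/DNTAG total ratio (larger over smaller).

    A zero tag total is replaced by a pseudocount of 1 in the ratio only —
    analysis counts are never altered. Returns the per-mutant table and a
    summary with the numbers of mutants within 2-fold and at or beyond
    10-fold / 100-fold divergence.
    """
    if not m.has_tags:
        raise ValueError("tag divergence needs a (mutant, tag) matrix")
    totals = m.counts.sum(axis=1).unstack("tag").reindex(columns=list(TAGS)).fillna(0)
    hi = totals.max(axis=1)
    lo = totals.min(axis=1)
    ratio = hi.where(hi > 0, 1.0) / lo.where(lo > 0, 1.0)
    table = pd.DataFrame(
        {
            "uptag_total": totals[UPTAG].astype(int),
            "dntag_total": totals[DNTAG].astype(int),
            "ratio": ratio,
        }
    )
    summary = pd.Series(
        {
            "n_mutants": len(table),
            "n_within_2fold": int((ratio <= 2).sum()),
            "n_over_10fold": int((ratio >= 10).sum()),
            "n_over_100fold": int((ratio >= 100).sum()),
        }
    )
    return table, summary


def restrict_to_time(m: CountMatrix, time: str = "t24") -> CountMatrix:
    """Keep only the samples of one time point (differential testing is
    restricted to the post-treatment samples)."""
    if "time" not in m.samples.columns:
        return m
    keep = m.samples.index[m.samples["time"] == time]
    return m.select_samples(keep)
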
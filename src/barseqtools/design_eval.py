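"""Experimental-design evaluation by read subsampling.

A full 2 treatments x 4 biological x 2 technical experiment is the gold
standard. Reduced designs (fewer biological or technical replicates) are
emulated by dropping replicate columns — one subsampling per combination of
retained replicates — and reduced sequencing depth is emulated by binomial
thinning: S_ij ~ Binom(X_ij, p), distributionally equivalent to sampling a
fraction p of reads before mapping. Each subsample is pushed through the
same collapse -> normalize -> dispersion -> exact-test (-> enrichment)
pipeline as the full data, and scored against the gold standard on four
metrics: number of significant mutants (power), mean squared error of the
log-fold-change estimates (accuracy), number of significant gene sets
(informativeness), and the fraction of called mutants not significant in
the full data (empirical FDR). Raw points are pooled per design and
smoothed with natural cubic splines.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CountMatrix, DesignSpec
from .counts import collapse_tags_and_technical
from .diffabund import NBExactModel, NBExactResults
from .enrich import GeneSetCollection, filter_gene_sets, wilcoxon_enrichment
from .splines import smooth_natural_spline

__all__ = [
    "ReplicateChoice",
    "GoldStandard",
    "enumerate_replicate_subsets",
    "make_fraction_grid",
    "subsample_counts",
    "gold_standard",
    "evaluate_subsample",
    "power_by_effect_size",
    "smooth_curves",
    "run_design_evaluation",
    "design_efficiency",
    "DesignEvaluation",
]

METRICS = ("n_significant", "power", "mse_logfc", "n_significant_gene_sets", "empirical_fdr")


@dataclass(frozen=True)
class ReplicateChoice:
    """Which biological and technical replicates a reduced design keeps.

    The same biological-replicate choice applies to both treatments, and a
    single technical-replicate choice is shared across all biological
    replicates (giving 2 options for one-technical-replicate designs from a
    two-technical-replicate experiment, not 2^b).
    """

    bio_reps: tuple
    tech_reps: tuple

    @property
    def label(self) -> str:
        b = "".join(str(x) for x in self.bio_reps)
        k = "".join(str(x) for x in self.tech_reps)
        return f"b{b}_t{k}"


def enumerate_replicate_subsets(
    full: DesignSpec, target: DesignSpec, bio_levels=None, tech_levels=None
) -> list[ReplicateChoice]:
    """All replicate combinations realizing ``target`` within ``full``:
    C(B, b) biological choices x C(K, k) shared technical choices."""
    if (
        target.n_treatments != full.n_treatments
        or target.n_bio_reps > full.n_bio_reps
        or target.n_tech_reps > full.n_tech_reps
    ):
        raise ValueError(f"target {target.label} exceeds the full design {full.label}")
    bio_levels = tuple(bio_levels or range(1, full.n_bio_reps + 1))
    tech_levels = tuple(tech_levels or range(1, full.n_tech_reps + 1))
    return [
        ReplicateChoice(b, k)
        for b in itertools.combinations(bio_levels, target.n_bio_reps)
        for k in itertools.combinations(tech_levels, target.n_tech_reps)
    ]


def make_fraction_grid(step: float = 0.0025) -> np.ndarray:
    """Evenly spaced subsampling fractions step, 2*step, ..., 1.0 (the
    default step 0.0025 gives the 400-point grid 0.25%, ..., 100%)."""
    n = round(1.0 / step)
    if not math.isclose(n * step, 1.0, rel_tol=1e-12):
        raise ValueError("1/step must be an integer number of fractions")
    return np.arange(1, n + 1) / n


def subsample_counts(
    x: CountMatrix | pd.DataFrame, p: float, rng: np.random.Generator
) -> CountMatrix | pd.DataFrame:
    """Binomial thinning: every cell independently Binom(X, p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("subsampling fraction must be in [0, 1]")
    counts = x.counts if isinstance(x, CountMatrix) else x
    thinned = pd.DataFrame(
        rng.binomial(counts.to_numpy(), p), index=counts.index, columns=counts.columns
    )
    if isinstance(x, CountMatrix):
        return CountMatrix(thinned, x.samples.copy())
    return thinned


# ---------------------------------------------------------------------------
# gold standard and metrics
# ---------------------------------------------------------------------------

@dataclass
class GoldStandard:
    """Full-experiment results and its significant set, stratified by the
    full-experiment fold change (strata are nested: 2-fold within 1.5-fold
    within all)."""

    table: pd.DataFrame  # logFC, pvalue, qvalue per mutant
    fdr: float = 0.05
    fold_thresholds: tuple = (1.5, 2.0)
    significant: set = field(init=False)
    strata: dict = field(init=False)

    def __post_init__(self) -> None:
        sig = self.table.index[self.table["qvalue"] <= self.fdr]
        self.significant = set(sig)
        self.strata = {"all": set(sig)}
        for thr in self.fold_thresholds:
            keep = self.table.loc[sig, "logFC"].abs() >= np.log2(thr)
            self.strata[f"{thr:g}"] = set(sig[keep])


def _fit_pipeline(matrix: CountMatrix, group_col: str, fdr: float) -> NBExactResults:
    if matrix.has_tags or "tech_rep" in matrix.samples.columns:
        matrix = collapse_tags_and_technical(matrix)
    return NBExactModel(matrix, groups=group_col).fit()


def gold_standard(
    full: CountMatrix, group_col: str = "treatment", fdr: float = 0.05
) -> GoldStandard:
    res = _fit_pipeline(full, group_col, fdr)
    return GoldStandard(res.table, fdr=fdr)


def evaluate_subsample(
    s: CountMatrix,
    gold: GoldStandard,
    gene_sets: GeneSetCollection | None = None,
    group_col: str = "treatment",
    fdr: float = 0.05,
) -> dict:
    """Score one subsampled experiment against the gold standard.

    Returns n_significant, power (fraction of gold-significant mutants
    recovered), mse_logfc (against the gold logFC over all tested mutants),
    n_significant_gene_sets (NaN when no sets are given), and empirical_fdr
    (fraction of called mutants absent from the gold set; NaN when nothing
    is called).
    """
    res = _fit_pipeline(s, group_col, fdr)
    sig = set(res.significant(fdr))
    common = res.table.index.intersection(gold.table.index)
    mse = float(
        np.mean(
            (res.table.loc[common, "logFC"] - gold.table.loc[common, "logFC"]) ** 2
        )
    )
    out = {
        "n_significant": len(sig),
        "power": (len(sig & gold.significant) / len(gold.significant))
        if gold.significant
        else np.nan,
        "mse_logfc": mse,
        "empirical_fdr": (len(sig - gold.significant) / len(sig)) if sig else np.nan,
        "n_significant_gene_sets": np.nan,
    }
    if gene_sets is not None:
        universe = set(res.table.index)
        usable = filter_gene_sets(gene_sets, universe)
        if len(usable):
            enr = wilcoxon_enrichment(res.table["logFC"], usable, fdr=fdr)
            out["n_significant_gene_sets"] = int(enr["significant"].sum())
        else:
            out["n_significant_gene_sets"] = 0
    out["_result"] = res
    return out


def power_by_effect_size(
    subsample_significant: set,
    gold: GoldStandard,
) -> dict:
    """Fraction of each gold stratum recovered; empty strata yield None."""
    out = {}
    for name, members in gold.strata.items():
        out[name] = (
            len(subsample_significant & members) / len(members) if members else None
        )
    return out


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

def smooth_curves(
    points: pd.DataFrame,
    df: int = 20,
    df_gene_sets: int = 15,
    grid: np.ndarray | None = None,
    x_col: str = "fraction",
) -> pd.DataFrame:
    """Natural-cubic-spline smoothing of the raw metric points of one
    design, pooling all replicate combinations. Gene-set counts use their
    own (smaller) degrees of freedom because they are noisier."""
    if grid is None:
        grid = np.unique(points[x_col].to_numpy())
    out = {x_col: grid}
    for metric in METRICS:
        if metric not in points.columns:
            continue
        sub = points[[x_col, metric]].dropna()
        if sub.empty:
            out[metric] = np.full(len(grid), np.nan)
            continue
        this_df = df_gene_sets if metric == "n_significant_gene_sets" else df
        this_df = min(this_df, max(2, len(np.unique(sub[x_col])) - 1))
        if len(sub) <= this_df or len(np.unique(sub[x_col])) < 3:
            # too few points for a spline: fall back to per-x means
            means = sub.groupby(x_col)[metric].mean()
            out[metric] = np.interp(grid, means.index, means.to_numpy())
        else:
            out[metric] = smooth_natural_spline(
                sub[x_col].to_numpy(), sub[metric].to_numpy(), this_df, grid
            )
    return pd.DataFrame(out)


@dataclass
class DesignEvaluation:
    """Raw per-(design, combination, fraction) points and smoothed curves."""

    gold: GoldStandard
    points: pd.DataFrame
    curves: pd.DataFrame


def run_design_evaluation(
    full: CountMatrix,
    designs,
    grid: np.ndarray | None = None,
    seed: int = 0,
    gene_sets: GeneSetCollection | None = None,
    group_col: str = "treatment",
    fdr: float = 0.05,
    spline_df: int = 20,
    spline_df_gene_sets: int = 15,
    max_combinations: int | None = None,
    effect_strata: bool = False,
) -> DesignEvaluation:
    """Evaluate designs across replicate combinations and depth fractions.

    ``full`` is the complete experiment, a (mutant, tag) x sample or
    mutant x sample matrix whose metadata carries treatment / bio_rep /
    tech_rep. Fractions are applied to the collapsed mutant x biological-
    replicate matrix of each combination (equivalent in distribution to
    read-level sampling). Each (design, combination, fraction) point uses
    its own named RNG stream derived from ``seed``, so runs are reproducible
    point by point. ``max_combinations`` caps (by seeded choice) the number
    of replicate combinations evaluated per design.
    """
    meta = full.samples
    full_design = DesignSpec(
        meta["treatment"].nunique(),
        meta.groupby("treatment")["bio_rep"].nunique().max(),
        int(meta["tech_rep"].nunique()) if "tech_rep" in meta.columns else 1,
    )
    if grid is None:
        grid = make_fraction_grid()
    grid = np.asarray(grid, dtype=float)

    gold = gold_standard(full, group_col=group_col, fdr=fdr)
    bio_levels = sorted(meta["bio_rep"].unique())
    tech_levels = sorted(meta["tech_rep"].unique()) if "tech_rep" in meta.columns else [1]

    rows = []
    for d_idx, design in enumerate(designs):
        design = DesignSpec.parse(design) if isinstance(design, str) else design
        combos = enumerate_replicate_subsets(full_design, design, bio_levels, tech_levels)
        if max_combinations is not None and len(combos) > max_combinations:
            pick_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(d_idx,)))
            idx = pick_rng.choice(len(combos), size=max_combinations, replace=False)
            combos = [combos[i] for i in sorted(idx)]
        for c_idx, choice in enumerate(combos):
            keep = meta.index[
                meta["bio_rep"].isin(choice.bio_reps)
                & (
                    meta["tech_rep"].isin(choice.tech_reps)
                    if "tech_rep" in meta.columns
                    else True
                )
            ]
            sub_full = full.select_samples(keep)
            collapsed = collapse_tags_and_technical(sub_full)
            for f_idx, frac in enumerate(grid):
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(d_idx, c_idx, f_idx))
                )
                thinned = subsample_counts(collapsed, float(frac), rng)
                point = evaluate_subsample(
                    thinned, gold, gene_sets=gene_sets, group_col=group_col, fdr=fdr
                )
                res = point.pop("_result")
                # realized mapped reads per condition
                depth = (
                    thinned.counts.sum(axis=0)
                    .groupby(thinned.samples["treatment"])
                    .sum()
                    .mean()
                )
                row = {
                    "design": design.label,
                    "combination": choice.label,
                    "fraction": float(frac),
                    "reads_per_condition": float(depth),
                    **point,
                }
                if effect_strata:
                    sig = set(res.significant(fdr))
                    for name, val in power_by_effect_size(sig, gold).items():
                        row[f"power_{name}"] = np.nan if val is None else val
                rows.append(row)

    points = pd.DataFrame(rows)
    curves = (
        points.groupby("design", sort=False)
        .apply(
            lambda g: smooth_curves(
                g, df=spline_df, df_gene_sets=spline_df_gene_sets, grid=grid
            ),
            include_groups=False,
        )
        .reset_index(level=0)
        .reset_index(drop=True)
    )
    return DesignEvaluation(gold, points, curves)


# ---------------------------------------------------------------------------
# sequencing-budget arithmetic
# ---------------------------------------------------------------------------

def design_efficiency(
    reads_per_condition: float = 6e6,
    n_mutants: int = 4295,
    n_bio_reps: int = 4,
    n_indices: int = 120,
    lane_reads: float = 200e6,
) -> dict:
    """Sequencing-budget arithmetic for a pooled screen.

    At 6 million reads per condition over the 4295-mutant collection this
    yields 1397 reads per mutant per condition, 349 reads per mutant per
    biological-replicate library, and — with 120 indexed adaptors at
    four-fold biological replication — 30 conditions per sequencing lane.
    """
    per_mutant = reads_per_condition / n_mutants
    return {
        "reads_per_mutant_per_condition": round(per_mutant),
        "reads_per_mutant_per_library": round(per_mutant / n_bio_reps),
        "conditions_per_lane_by_indices": n_indices // n_bio_reps,
        "conditions_per_lane_by_reads": int(lane_reads // reads_per_condition),
    }
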
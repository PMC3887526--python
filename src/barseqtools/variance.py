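"""Variance partitioning of normalized log-counts by eigen-R^2.

Eigen-R^2 estimates the fraction of total variance a design factor explains:
the row-centered matrix is decomposed by SVD, each right singular vector
(eigen-row) is regressed on the factor's indicator design, and the per-
component coefficients of determination are averaged with eigenvalue
weights. Retaining all non-degenerate components makes this identical to
the row-sum-of-squares-weighted average of per-row ANOVA R^2 values.

The treatment factor's indicator span is contained in the replicate-within-
treatment span, so R^2_B >= R^2_T and the three reported components —
treatment = R^2_T, biological = R^2_B - R^2_T, technical = 1 - R^2_B —
are non-negative and sum to one by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix
from .diffabund import tmm_factors

__all__ = [
    "preprocess_for_variance",
    "eigen_r2",
    "partition_variance",
    "VarianceDecomposition",
]


def preprocess_for_variance(
    m: CountMatrix | pd.DataFrame,
    bottom_fraction: float = 0.10,
) -> pd.DataFrame:
    """Add 1, scale by TMM effective library sizes, log-transform, and drop
    the bottom fraction of mutants by total count (low counts otherwise
    dominate the technical component)."""
    counts = m.counts if isinstance(m, CountMatrix) else m
    if counts.shape[1] < 2:
        raise ValueError("variance preprocessing needs at least two columns")
    factors = tmm_factors(counts)
    eff = counts.sum(axis=0).astype(float) * factors
    x = np.log((counts + 1.0) / eff)

    n_drop = int(np.floor(bottom_fraction * len(counts)))
    if n_drop > 0:
        totals = counts.sum(axis=1)
        order = totals.sort_values(kind="mergesort").index  # stable tie-break
        x = x.drop(index=order[:n_drop])
    return x


def eigen_r2(x: pd.DataFrame | np.ndarray, factor, tol: float = 1e-12) -> float:
    """Eigenvalue-weighted R^2 of the eigen-rows regressed on a factor.

    ``factor`` gives one level per column. Rows are centered internally;
    components with an eigenvalue share below ``tol`` are discarded.
    """
    x = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, float)
    if x.shape[1] < 2:
        raise ValueError("eigen-R^2 needs at least two columns")
    labels = np.asarray(list(factor))
    if len(labels) != x.shape[1]:
        raise ValueError("factor must give one level per column")
    levels, codes = np.unique(labels, return_inverse=True)

    xc = x - x.mean(axis=1, keepdims=True)
    if not np.any(xc):
        return 0.0
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    lam = s**2
    keep = lam / lam.sum() > tol
    lam, vt = lam[keep], vt[keep]

    # orthonormal basis of the centered indicator span
    design = np.zeros((x.shape[1], len(levels)))
    design[np.arange(x.shape[1]), codes] = 1.0
    design -= design.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(design)
    rank = (np.abs(np.diag(r)) > 1e-10).sum()
    q = q[:, :rank]

    # eigen-rows are centered (rows of xc sum to zero), so R^2_j is the
    # squared norm of the projection onto the centered design span
    r2 = np.square(vt @ q).sum(axis=1)
    return float(np.clip(np.sum(lam * r2) / lam.sum(), 0.0, 1.0))


@dataclass
class VarianceDecomposition:
    """Treatment / biological / technical variance shares (sum to 1)."""

    r2_treatment: float
    r2_biological_total: float

    @property
    def treatment(self) -> float:
        return self.r2_treatment

    @property
    def biological(self) -> float:
        return self.r2_biological_total - self.r2_treatment

    @property
    def technical(self) -> float:
        return 1.0 - self.r2_biological_total

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "treatment": self.treatment,
                "biological": self.biological,
                "technical": self.technical,
            },
            name="variance_share",
        )

    def summary(self) -> str:
        return (
            "Variance decomposition (eigen-R^2)\n"
            f"  treatment:  {100 * self.treatment:5.1f}%\n"
            f"  biological: {100 * self.biological:5.1f}%\n"
            f"  technical:  {100 * self.technical:5.1f}%"
        )


def partition_variance(x: pd.DataFrame, design: pd.DataFrame) -> VarianceDecomposition:
    """Partition variance into treatment / biological / technical shares.

    ``design`` must carry ``treatment`` and ``bio_rep`` per column of ``x``.
    The biological factor is replicate-within-treatment (one level per
    culture), which nests the treatment factor, guaranteeing R^2_B >= R^2_T.
    """
    for col in ("treatment", "bio_rep"):
        if col not in design.columns:
            raise ValueError(f"design needs a '{col}' column")
    design = design.loc[list(x.columns)]
    treatment = design["treatment"].astype(str)
    biological = treatment + "/" + design["bio_rep"].astype(str)
    # nesting check: each biological level maps to exactly one treatment
    if (pd.crosstab(biological, treatment) > 0).sum(axis=1).max() > 1:
        raise ValueError("biological replicate labels must nest within treatment")

    r2_t = eigen_r2(x, treatment)
    r2_b = max(eigen_r2(x, biological), r2_t)
    return VarianceDecomposition(r2_t, r2_b)
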
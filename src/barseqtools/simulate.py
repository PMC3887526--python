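"""Synthetic Bar-seq experiments.

The generator reproduces the marginal statistical structure of a pooled
yeast deletion-collection screen:

* per-mutant abundances are approximately log-normal, so that per-mutant
  read totals over a full experiment span roughly 1e3 to 1e5;
* biological replicates are overdispersed-Poisson (negative binomial with
  dispersion ``phi``: Var = mu + phi * mu^2), realised as a gamma-mixed
  Poisson with one gamma draw per (mutant, culture);
* technical replicates are independent Poisson resamplings of the same
  latent culture abundance, so technical variance is below biological
  variance by construction;
* each mutant carries an UPTAG and a DNTAG barcode; a tag can "drop out"
  (suppressed 100- to 1000-fold), reproducing the large UPTAG/DNTAG
  divergences seen in real screens;
* raw reads are 5-bp sample index + 15-bp tag-specific constant priming
  region + 20-bp barcode, with i.i.d. substitution errors.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DNTAG,
    DNTAG_CONSTANT,
    TAGS,
    UPTAG,
    UPTAG_CONSTANT,
    BarcodeCatalog,
    CountMatrix,
    DesignSpec,
    SampleSheet,
)
from ._match import FuzzyIndex

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Minimum pairwise Levenshtein distance between simulated barcodes. With
#: separation 5, up to two edits per read cannot make two catalog barcodes
#: equidistant-ambiguous, so distance-2 demultiplexing is unambiguous by
#: construction.
BARCODE_MIN_DIST = 5
INDEX_MIN_DIST = 2


@dataclass
class SimParams:
    """Generator settings; the defaults are the emulated study conditions.

    ``baseline_sdlog=0.8`` puts the 1st-99th percentile span of log-normal
    per-mutant experiment totals inside one order of magnitude either side
    of the median (totals centred at 1e4 span ~1e3-1e5). ``dispersion`` is
    the negative-binomial dispersion of biological replicates; 0 recovers
    Poisson. ``tag_dropout_prob=0.13`` makes roughly a quarter of mutants
    show a >=100-fold UPTAG/DNTAG divergence (each mutant has two chances
    to lose a tag). ``effect_magnitude``, if set, fixes |log2FC| of affected
    mutants at that value with a random sign instead of drawing from
    Normal(0, effect_sdlog2).
    """

    n_mutants: int = 4295
    baseline_meanlog: float = 0.0
    baseline_sdlog: float = 0.8
    dispersion: float = 0.1
    frac_affected: float = 0.1
    effect_sdlog2: float = 1.0
    effect_magnitude: float | None = None
    tag_dropout_prob: float = 0.13
    tag_imbalance_sdlog: float = 0.25
    control_id: str | None = None
    control_fraction: float = 0.19
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mutants < 1:
            raise ValueError("n_mutants must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name in ("frac_affected", "tag_dropout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.control_fraction < 1.0:
            raise ValueError("control_fraction must be in [0, 1)")


@dataclass
class TrueEffects:
    """Ground truth: per-mutant true log2 fold change and baseline abundance."""

    mutant_ids: list[str]
    log2fc: np.ndarray
    baseline: np.ndarray  # simplex weights, sum to 1

    def __post_init__(self) -> None:
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if not np.isclose(self.baseline.sum(), 1.0):
            raise ValueError("baseline abundances must sum to 1")
        if (self.baseline < 0).any():
            raise ValueError("baseline abundances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"log2fc": self.log2fc, "baseline": self.baseline},
            index=pd.Index(self.mutant_ids, name="mutant_id"),
        )

    @property
    def affected(self) -> np.ndarray:
        return self.log2fc != 0.0


@dataclass
class ReadSimParams:
    """Read layout and error model for raw-read simulation."""

    read_length: int = 40
    per_base_error: float = 0.0
    index_length: int = 5
    barcode_length: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_base_error <= 1.0:
            raise ValueError("per_base_error must be in [0, 1]")
        barcode_end = self.index_length + len(UPTAG_CONSTANT) + self.barcode_length
        if self.read_length < barcode_end:
            raise ValueError(
                f"read_length must cover the barcode region (>= {barcode_end})"
            )


# ---------------------------------------------------------------------------
# barcode / catalog / sample sheet generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def random_barcodes(
    n: int,
    length: int,
    min_dist: int,
    rng: np.random.Generator,
    max_tries_per_seq: int = 200,
) -> list[str]:
    """Rejection-sample ``n`` sequences with pairwise Levenshtein >= min_dist."""
    index = FuzzyIndex([], max_dist=min_dist - 1)
    out: list[str] = []
    tries = 0
    budget = max_tries_per_seq * n
    while len(out) < n:
        if tries >= budget:
            raise RuntimeError(
                f"could not place {n} length-{length} barcodes at pairwise "
                f"distance >= {min_dist} after {tries} attempts"
            )
        tries += 1
        cand = _random_seq(rng, length)
        if index.min_distance(cand) == -1:  # nothing within min_dist - 1
            index.add(len(out), cand)
            out.append(cand)
    return out


def simulate_catalog(params: SimParams, rng: np.random.Generator) -> BarcodeCatalog:
    n = params.n_mutants
    seqs = random_barcodes(2 * n, 20, BARCODE_MIN_DIST, rng)
    width = max(4, len(str(n)))
    ids = [f"mut{str(i + 1).zfill(width)}" for i in range(n)]
    if params.control_id is not None:
        ids[0] = params.control_id
    table = pd.DataFrame(
        {"uptag": seqs[:n], "dntag": seqs[n:]}, index=pd.Index(ids, name="mutant_id")
    )
    return BarcodeCatalog(table)


def simulate_effects(params: SimParams, rng: np.random.Generator) -> TrueEffects:
    n = params.n_mutants
    width = max(4, len(str(n)))
    ids = [f"mut{str(i + 1).zfill(width)}" for i in range(n)]
    log2fc = np.zeros(n)
    n_aff = int(round(params.frac_affected * n))
    eligible = np.arange(n)
    baseline = rng.lognormal(params.baseline_meanlog, params.baseline_sdlog, size=n)
    if params.control_id is not None:
        ids[0] = params.control_id
        eligible = eligible[1:]
        # control strain spiked in at a fixed share of the pool, never affected
        baseline[0] = baseline[1:].sum() * params.control_fraction / (1 - params.control_fraction)
        n_aff = min(n_aff, len(eligible))
    affected = rng.choice(eligible, size=n_aff, replace=False)
    if params.effect_magnitude is not None:
        log2fc[affected] = params.effect_magnitude * rng.choice([-1.0, 1.0], size=n_aff)
    else:
        log2fc[affected] = rng.normal(0.0, params.effect_sdlog2, size=n_aff)
    # re-draw exact zeros so "unaffected" is exactly the complement
    while params.effect_magnitude is None and (log2fc[affected] == 0).any():
        z = affected[log2fc[affected] == 0]
        log2fc[z] = rng.normal(0.0, params.effect_sdlog2, size=len(z))
    baseline = baseline / baseline.sum()
    return TrueEffects(ids, log2fc, baseline)


def simulate_pool(params: SimParams) -> tuple[BarcodeCatalog, TrueEffects]:
    """Generate the barcode catalog and the ground-truth effects for a pool."""
    rng = np.random.default_rng(params.seed)
    effects = simulate_effects(params, rng)
    catalog = simulate_catalog(params, rng)
    catalog.table.index = pd.Index(effects.mutant_ids, name="mutant_id")
    return catalog, effects


def make_design_metadata(
    design: DesignSpec,
    treatments: tuple[str, ...] = ("YPD", "YPGal"),
    time: str = "t24",
) -> pd.DataFrame:
    """Sample metadata table (treatment, time, bio_rep, tech_rep) for a design."""
    if design.n_treatments > len(treatments):
        treatments = tuple(f"T{i + 1}" for i in range(design.n_treatments))
    rows = []
    for t, b, k in itertools.product(
        range(design.n_treatments),
        range(1, design.n_bio_reps + 1),
        range(1, design.n_tech_reps + 1),
    ):
        trt = treatments[t]
        rows.append(
            {
                "sample_id": f"{trt}_b{b}_t{k}",
                "treatment": trt,
                "time": time,
                "bio_rep": b,
                "tech_rep": k,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def make_sample_sheet(
    design: DesignSpec,
    rng: np.random.Generator | int | None = 0,
    treatments: tuple[str, ...] = ("YPD", "YPGal"),
    time: str = "t24",
) -> SampleSheet:
    """Design metadata plus random 5-bp indices at pairwise distance >= 2."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    meta = make_design_metadata(design, treatments, time)
    indices = random_barcodes(len(meta), 5, INDEX_MIN_DIST, rng)
    meta.insert(0, "index", indices)
    return SampleSheet(meta)


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def simulate_counts(
    params: SimParams,
    effects: TrueEffects,
    design: DesignSpec,
    depth_per_sample,
    seed: int | None = None,
    treatments: tuple[str, ...] = ("YPD", "YPGal"),
) -> CountMatrix:
    """Draw a (mutant, tag) x sample count matrix for a design.

    ``depth_per_sample`` is the expected number of reads per library (scalar
    or one value per sample). The second treatment level carries the
    ground-truth effects (expected abundance = baseline * 2^log2FC).
    """
    meta = make_design_metadata(design, treatments, time="t24")
    depths = np.broadcast_to(np.asarray(depth_per_sample, dtype=float), (len(meta),))
    if (depths < 0).any():
        raise ValueError("depth_per_sample must be non-negative")

    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    n = params.n_mutants
    phi = params.dispersion

    # per-mutant tag shares, with dropout suppressing a tag 100-1000x
    asym = rng.normal(0.0, params.tag_imbalance_sdlog, size=n)
    w = np.stack([np.exp(asym), np.exp(-asym)], axis=1)  # columns: UPTAG, DNTAG
    dropped = rng.random((n, 2)) < params.tag_dropout_prob
    w[dropped] *= 10.0 ** -rng.uniform(2.0, 3.0, size=int(dropped.sum()))
    tag_share = w / w.sum(axis=1, keepdims=True)

    treat_levels = list(dict.fromkeys(meta["treatment"]))
    effect_on = {t: (i == len(treat_levels) - 1) for i, t in enumerate(treat_levels)}

    # one latent gamma per (mutant, biological culture), shared by both tags
    # and by all technical replicates of that culture
    cultures = meta[["treatment", "bio_rep"]].drop_duplicates()
    latent = {}
    for trt, brep in cultures.itertuples(index=False):
        rel = effects.baseline * np.where(effect_on[trt], 2.0 ** effects.log2fc, 1.0)
        rel = rel / rel.sum()
        g = rng.gamma(1.0 / phi, phi, size=n) if phi > 0 else 1.0
        latent[(trt, brep)] = rel * g

    rows = pd.MultiIndex.from_product(
        [effects.mutant_ids, TAGS], names=["mutant_id", "tag"]
    )
    counts = np.empty((2 * n, len(meta)), dtype=np.int64)
    for j, (sid, srow) in enumerate(meta.iterrows()):
        lam = latent[(srow["treatment"], srow["bio_rep"])]
        lam_tags = (lam[:, None] * tag_share).ravel()  # (mutant, tag) order
        counts[:, j] = rng.poisson(depths[j] * lam_tags)

    df = pd.DataFrame(counts, index=rows, columns=meta.index)
    return CountMatrix(df, meta)


def simulate_experiment(
    params: SimParams,
    design: DesignSpec = DesignSpec(2, 4, 2),
    depth_per_sample: float = 1e6,
) -> tuple[BarcodeCatalog, SampleSheet, TrueEffects, CountMatrix]:
    """Convenience wrapper: pool + sample sheet + counts in one call."""
    rng = np.random.default_rng(params.seed)
    effects = simulate_effects(params, rng)
    catalog = simulate_catalog(params, rng)
    catalog.table.index = pd.Index(effects.mutant_ids, name="mutant_id")
    sheet = make_sample_sheet(design, rng)
    counts = simulate_counts(params, effects, design, depth_per_sample,
                             seed=int(rng.integers(2**31)))
    return catalog, sheet, effects, counts


# ---------------------------------------------------------------------------
# raw-read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    counts: CountMatrix,
    catalog: BarcodeCatalog,
    sheet: SampleSheet,
    rp: ReadSimParams = ReadSimParams(),
    seed: int = 0,
    path: str | Path | None = None,
):
    """Emit one read per count: index + constant region + barcode (+ filler).

    Substitution errors are i.i.d. per base at ``rp.per_base_error``; quality
    strings are a constant placeholder (the matching pipeline ignores them).
    Returns the list of (read_id, sequence, quality) records, and writes a
    4-line-record FASTQ file if ``path`` is given.
    """
    if not counts.has_tags:
        raise ValueError("read simulation needs a (mutant, tag) count matrix")
    missing = set(counts.counts.columns) - set(sheet.sample_ids)
    if missing:
        raise ValueError(f"samples missing from sheet: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    const = {UPTAG: UPTAG_CONSTANT, DNTAG: DNTAG_CONSTANT}
    barcode = {(m, t): s for m, t, s in catalog.barcode_items()}
    fill = rp.read_length - (rp.index_length + len(UPTAG_CONSTANT) + rp.barcode_length)

    templates: list[str] = []
    multiplicities: list[int] = []
    for sid in counts.counts.columns:
        idx_seq = sheet.table.loc[sid, "index"]
        col = counts.counts[sid]
        for (mid, tag), c in col[col > 0].items():
            templates.append(idx_seq + const[tag] + barcode[(mid, tag)])
            multiplicities.append(int(c))

    n_reads = int(sum(multiplicities))
    records: list[tuple[str, str, str]] = []
    qual = "I" * rp.read_length
    if n_reads:
        tmpl = np.array(
            [np.frombuffer(t.encode(), dtype=np.uint8) for t in templates]
        )
        reads = tmpl[np.repeat(np.arange(len(templates)), multiplicities)]
        if fill > 0:
            filler = _BASES[rng.integers(0, 4, size=(n_reads, fill))]
            reads = np.concatenate([reads, filler], axis=1)
        if rp.per_base_error > 0:
            err = rng.random(reads.shape) < rp.per_base_error
            n_err = int(err.sum())
            if n_err:
                base_of = np.zeros(256, dtype=np.int64)
                base_of[_BASES] = np.arange(4)
                shift = rng.integers(1, 4, size=n_err)
                reads[err] = _BASES[(base_of[reads[err]] + shift) % 4]
        seqs = reads.tobytes().decode()
        L = reads.shape[1]
        records = [
            (f"read{i}", seqs[i * L : (i + 1) * L], qual) for i in range(n_reads)
        ]

    if path is not None:
        with open(path, "w") as fh:
            for rid, seq, q in records:
                fh.write(f"@{rid}\n{seq}\n+\n{q}\n")
    return records
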
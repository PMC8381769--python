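"""Quality control for SNP-array genotype panels.

Implements the filtering chain used for curated germplasm panels: per-SNP
missingness and minor-allele-frequency filters, per-sample missingness
filter, duplicate (clonal) profile detection by pairwise mismatch rate,
variance-inflation-factor LD pruning, and greedy allele-coverage core
selection.  The canonical order is SNP filter, then sample filter, then
duplicate removal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .genotypes import MISSING, GenotypeMatrix


class EmptyPanelError(ValueError):
    """Raised when a filter removes every locus or every sample."""


@dataclass
class QcReport:
    """Bookkeeping for one QC operation; counts reconcile with dimensions."""

    n_snps_removed_narate: int = 0
    n_snps_removed_maf: int = 0
    n_samples_removed_narate: int = 0
    duplicate_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    kept_sample_ids: list[str] = field(default_factory=list)
    kept_locus_indices: list[int] = field(default_factory=list)


def _na_rate_loci(g: GenotypeMatrix) -> np.ndarray:
    return (g.dosages == MISSING).mean(axis=0)


def minor_allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus MAF from non-missing dosages (NaN where no calls)."""
    d = g.dosages.astype(float)
    d[d == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(d, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_snps(
    g: GenotypeMatrix, max_na_rate: float = 0.01, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop loci with missingness above ``max_na_rate`` or MAF below ``min_maf``."""
    if not 0 <= max_na_rate < 1:
        raise ValueError("max_na_rate must be in [0, 1)")
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    na = _na_rate_loci(g)
    maf = minor_allele_frequencies(g)
    na_bad = na > max_na_rate
    maf_bad = ~na_bad & (np.isnan(maf) | (maf < min_maf))
    keep = ~(na_bad | maf_bad)
    if not keep.any():
        raise EmptyPanelError("all loci removed by SNP filters")
    kept_idx = np.flatnonzero(keep)
    report = QcReport(
        n_snps_removed_narate=int(na_bad.sum()),
        n_snps_removed_maf=int(maf_bad.sum()),
        kept_sample_ids=list(g.sample_ids),
        kept_locus_indices=kept_idx.tolist(),
    )
    return g.take_loci(kept_idx), report


def filter_samples(
    g: GenotypeMatrix, max_na_rate: float = 0.05
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples whose fraction of missing calls exceeds ``max_na_rate``."""
    if not 0 <= max_na_rate <= 1:
        raise ValueError("max_na_rate must be in [0, 1]")
    na = (g.dosages == MISSING).mean(axis=1)
    keep = na <= max_na_rate
    if not keep.any():
        raise EmptyPanelError("all samples removed by missingness filter")
    kept_idx = np.flatnonzero(keep)
    report = QcReport(
        n_samples_removed_narate=int((~keep).sum()),
        kept_sample_ids=[g.sample_ids[i] for i in kept_idx],
        kept_locus_indices=list(range(g.n_loci)),
    )
    return g.take_samples(kept_idx), report


def find_duplicates(
    g: GenotypeMatrix, mismatch_cutoff: float = 0.20
) -> list[tuple[str, str, float]]:
    """Flag sample pairs whose genotype mismatch fraction is below the cutoff.

    The mismatch fraction is computed over loci called in both samples; pairs
    sharing no called locus are skipped with a warning.
    """
    d = g.dosages
    called = d != MISSING
    flagged = []
    for i in range(g.n_samples):
        for j in range(i + 1, g.n_samples):
            both = called[i] & called[j]
            n_shared = int(both.sum())
            if n_shared == 0:
                warnings.warn(
                    f"samples {g.sample_ids[i]} and {g.sample_ids[j]} share no "
                    "called loci; pair skipped"
                )
                continue
            mism = float((d[i, both] != d[j, both]).mean())
            if mism < mismatch_cutoff:
                flagged.append((g.sample_ids[i], g.sample_ids[j], mism))
    return flagged


def deduplicate(
    g: GenotypeMatrix, pairs: list[tuple[str, str, float]]
) -> tuple[GenotypeMatrix, QcReport]:
    """Keep one sample per connected component of flagged duplicate pairs.

    The retained representative is the component member appearing first in
    input order.
    """
    graph = nx.Graph()
    graph.add_edges_from((a, b) for a, b, _ in pairs)
    order = {s: i for i, s in enumerate(g.sample_ids)}
    drop: set[str] = set()
    for comp in nx.connected_components(graph):
        members = sorted(comp, key=order.__getitem__)
        drop.update(members[1:])
    kept_idx = np.array(
        [i for i, s in enumerate(g.sample_ids) if s not in drop], dtype=int
    )
    report = QcReport(
        duplicate_pairs=list(pairs),
        kept_sample_ids=[g.sample_ids[i] for i in kept_idx],
        kept_locus_indices=list(range(g.n_loci)),
    )
    return g.take_samples(kept_idx), report


# ---------------------------------------------------------------------------
# VIF-based LD pruning
# ---------------------------------------------------------------------------


def _imputed_dosages(g: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with per-locus mean imputation of missing calls."""
    d = g.dosages.astype(float)
    d[d == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(d, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    idx = np.where(np.isnan(d))
    d[idx] = means[idx[1]]
    return d


def _vif(x: np.ndarray, col: int, others: list[int]) -> float:
    """VIF of column ``col`` regressed on ``others`` (mean-imputed dosages)."""
    y = x[:, col]
    vy = y.var()
    if vy == 0:
        return 1.0
    if not others:
        return 1.0
    design = np.column_stack([x[:, others], np.ones(x.shape[0])])
    resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    r2 = 1.0 - resid.var() / vy
    if r2 >= 1.0 - 1e-12:
        return math.inf
    return 1.0 / (1.0 - r2)


def ld_prune(
    g: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    vif_threshold: float = 2.0,
) -> list[int]:
    """Indices of loci kept by sliding-window variance-inflation pruning.

    Within each window of ``window_snps`` loci the locus with the highest
    VIF (1/(1-R^2) against the other kept loci of the window) is removed
    until every VIF is below ``vif_threshold``; the window then advances by
    ``step_snps``.  Ties go to the later-indexed locus, and removal is
    global: a pruned locus never re-enters a later window.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    if vif_threshold <= 1:
        raise ValueError("vif_threshold must be > 1")
    x = _imputed_dosages(g)
    removed = np.zeros(g.n_loci, dtype=bool)
    start = 0
    while True:
        window = [j for j in range(start, min(start + window_snps, g.n_loci)) if not removed[j]]
        while len(window) > 1:
            vifs = [ _vif(x, j, [k for k in window if k != j]) for j in window ]
            worst = max(range(len(window)), key=lambda i: (vifs[i], window[i]))
            if vifs[worst] < vif_threshold:
                break
            removed[window[worst]] = True
            window.pop(worst)
        if start + window_snps >= g.n_loci:
            break
        start += step_snps
    return [j for j in range(g.n_loci) if not removed[j]]


def select_core(g: GenotypeMatrix, pop: str, size: int) -> list[str]:
    """Greedy allele-coverage core subset of ``size`` samples from ``pop``.

    Coverage counts distinct (locus, allele) pairs carried by the chosen
    samples; each step adds the sample contributing most uncovered pairs,
    ties broken by input order.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    idx = np.flatnonzero(g.pop_mask(pop))
    if size > len(idx):
        raise ValueError(f"size {size} exceeds population count {len(idx)}")
    d = g.dosages[idx]
    # allele presence: column j covers ref if dosage < 2, alt if dosage > 0
    has_ref = (d != MISSING) & (d < 2)
    has_alt = d > 0
    carries = np.concatenate([has_ref, has_alt], axis=1)
    covered = np.zeros(carries.shape[1], dtype=bool)
    chosen: list[int] = []
    remaining = list(range(len(idx)))
    for _ in range(size):
        gains = [int((carries[i] & ~covered).sum()) for i in remaining]
        best = remaining[int(np.argmax(gains))]
        chosen.append(best)
        covered |= carries[best]
        remaining.remove(best)
    return [g.sample_ids[idx[i]] for i in chosen]


def allele_coverage(g: GenotypeMatrix, pop: str, sample_ids: list[str]) -> float:
    """Fraction of the population's observed (locus, allele) pairs covered."""
    idx = np.flatnonzero(g.pop_mask(pop))
    d = g.dosages[idx]
    carries = np.concatenate([(d != MISSING) & (d < 2), d > 0], axis=1)
    total = carries.any(axis=0)
    sub = np.array([g.sample_ids[i] for i in idx])
    pick = np.isin(sub, sample_ids)
    got = carries[pick].any(axis=0)
    return float(got[total].sum() / max(total.sum(), 1))
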
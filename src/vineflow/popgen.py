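"""Descriptive population-genetic statistics for diploid SNP panels.

Covers the quantities used both for descriptive comparison of germplasm
groups and as ABC summary statistics: unbiased gene diversity (expected
heterozygosity), Weir & Cockerham (1984) pairwise Fst, Nei (1972) standard
genetic distance, neighbor-joining trees from distance matrices, linkage
disequilibrium decay in physical-distance bins, and method-of-moments
identity-by-descent relatedness with classical multidimensional scaling.

All estimators work on unphased alternate-allele dosages; allele frequencies
are always computed from non-missing calls only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

#: Value substituted for an infinite Nei distance (disjoint fixed alleles).
NEI_INF_CAP = 10.0


class UndefinedStatisticError(ValueError):
    """Raised when no usable locus remains for a statistic."""


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(g: GenotypeMatrix, pop: str | None = None) -> pd.DataFrame:
    """Per-locus alt-allele frequency ``p`` and gene-copy count ``n``.

    ``pop=None`` pools every sample.  Loci with no calls get ``p = NaN`` and
    ``n = 0`` and are flagged unusable by downstream statistics.
    """
    d = g.dosages if pop is None else g.dosages[g.pop_mask(pop)]
    called = d != MISSING
    n = 2 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return pd.DataFrame({"p": p, "n": n})


def _pop_counts(g: GenotypeMatrix, pop: str):
    """(n_i diploids called, p_i alt freq, h_i observed het freq) per locus."""
    d = g.dosages[g.pop_mask(pop)]
    called = d != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(called, d, 0).sum(axis=0) / (2 * n), np.nan)
        h = np.where(n > 0, np.where(called, d == 1, False).sum(axis=0) / n, np.nan)
    return n, p, h


# ---------------------------------------------------------------------------
# gene diversity, Fst, Nei distance
# ---------------------------------------------------------------------------


def gene_diversity(g: GenotypeMatrix, pop: str) -> float:
    """Mean unbiased gene diversity H = n(1 - p^2 - q^2)/(n - 1) over loci.

    ``n`` is the number of gene copies with calls at the locus; loci with
    fewer than two copies are unusable.
    """
    freqs = allele_frequencies(g, pop)
    n = freqs["n"].to_numpy(dtype=float)
    p = freqs["p"].to_numpy()
    usable = n >= 2
    if not usable.any():
        raise UndefinedStatisticError(f"no usable loci for population {pop!r}")
    n, p = n[usable], p[usable]
    h = n * (1.0 - p**2 - (1.0 - p) ** 2) / (n - 1.0)
    return float(h.mean())


def pairwise_fst(g: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir-Cockerham (1984) theta for two populations.

    Per-locus variance components a (among populations), b (among
    individuals within populations) and c (within individuals) are summed
    over loci: theta = sum(a) / sum(a + b + c).  Loci monomorphic across
    both populations contribute nothing; the estimate may be slightly
    negative.
    """
    n1, p1, h1 = _pop_counts(g, pop_a)
    n2, p2, h2 = _pop_counts(g, pop_b)
    a, b, c = _wc84_components(n1, p1, h1, n2, p2, h2)
    usable = np.isfinite(a + b + c)
    if not usable.any():
        raise UndefinedStatisticError("no locus with calls in both populations")
    denom = (a + b + c)[usable].sum()
    if denom == 0:
        raise UndefinedStatisticError("no polymorphic locus across the two populations")
    return float(a[usable].sum() / denom)


def _wc84_components(n1, p1, h1, n2, p2, h2):
    """Vectorized WC84 a, b, c components for r = 2 populations."""
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(p1) | ~np.isfinite(p2)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def nei_distance(g: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Nei (1972) standard genetic distance D = -ln(Jxy / sqrt(Jx * Jy)).

    Jx, Jy and Jxy are means over loci of the within- and between-population
    probabilities of allelic identity.  Disjoint fixed alleles give Jxy = 0;
    the flagged infinite distance is returned as ``math.inf`` (callers that
    need a finite value cap it at :data:`NEI_INF_CAP`).
    """
    fa = allele_frequencies(g, pop_a)
    fb = allele_frequencies(g, pop_b)
    usable = (fa["n"].to_numpy() >= 2) & (fb["n"].to_numpy() >= 2)
    if not usable.any():
        raise UndefinedStatisticError("no locus with calls in both populations")
    pa = fa["p"].to_numpy()[usable]
    pb = fb["p"].to_numpy()[usable]
    jx = float((pa**2 + (1 - pa) ** 2).mean())
    jy = float((pb**2 + (1 - pb) ** 2).mean())
    jxy = float((pa * pb + (1 - pa) * (1 - pb)).mean())
    if jxy == 0:
        return float("inf")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def fst_matrix(g: GenotypeMatrix, pops: list[str] | None = None) -> pd.DataFrame:
    """Symmetric matrix of pairwise WC84 Fst values (zero diagonal)."""
    pops = pops if pops is not None else g.populations
    m = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            v = pairwise_fst(g, a, b)
            m.loc[a, b] = m.loc[b, a] = v
    return m


def nj_tree(d: pd.DataFrame) -> str:
    """Newick text of the Saitou-Nei neighbor-joining tree for matrix ``d``.

    Negative entries are clamped to zero before tree building; taxa are the
    matrix labels.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d.to_numpy(), d.to_numpy().T):
        raise ValueError("distance matrix must be symmetric")
    vals = np.clip(d.to_numpy(dtype=float), 0.0, None)
    np.fill_diagonal(vals, 0.0)
    tree = nj(DistanceMatrix(vals, ids=list(d.index)))
    return str(tree).strip()


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


@dataclass
class LdDecayCurve:
    """Binned mean r-squared against physical distance.

    ``bin_edges`` has length n_bins + 1 (bp, contiguous from 0);
    ``mean_r2`` is NaN for empty bins.
    """

    bin_edges: np.ndarray
    mean_r2: np.ndarray
    pair_counts: np.ndarray

    def decay_distance_at(self, threshold: float = 0.05) -> float | None:
        """Distance where the bin-midpoint curve first crosses ``threshold``
        from above (linear interpolation); None if it never crosses."""
        mids = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        ok = ~np.isnan(self.mean_r2)
        x, y = mids[ok], self.mean_r2[ok]
        for i in range(len(y) - 1):
            if y[i] >= threshold and y[i + 1] < threshold:
                frac = (y[i] - threshold) / (y[i] - y[i + 1])
                return float(x[i] + frac * (x[i + 1] - x[i]))
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "mean_r2": self.mean_r2,
                "n_pairs": self.pair_counts.astype(int),
            }
        )


def pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over shared calls."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    if xv.var() == 0 or yv.var() == 0:
        return float("nan")
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_decay(
    g: GenotypeMatrix,
    pop: str | None = None,
    max_dist_bp: int = 10_000_000,
    bin_bp: int = 100_000,
    min_maf: float = 0.05,
) -> LdDecayCurve:
    """LD decay curve for one population (or the pooled panel).

    r^2 is the squared Pearson correlation of unphased dosages over samples
    called at both loci; pairs are restricted to the same chromosome and a
    physical distance of at most ``max_dist_bp``, then binned in ``bin_bp``
    windows.  Loci below ``min_maf`` in the analyzed samples are excluded.
    """
    sub = g if pop is None else g.take_samples(np.flatnonzero(g.pop_mask(pop)))
    from .qc import minor_allele_frequencies

    maf_ok = minor_allele_frequencies(sub) >= min_maf
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    edges = np.arange(n_bins + 1, dtype=float) * bin_bp
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    any_usable = False
    for chrom, grp in sub.loci.groupby("chrom", sort=False):
        idx = [j for j in grp.index if maf_ok[j]]
        if len(idx) >= 2:
            any_usable = True
        pos = sub.loci["pos"].to_numpy()
        for ai, a in enumerate(idx):
            for b in idx[ai + 1 :]:
                dist = abs(int(pos[b]) - int(pos[a]))
                if dist > max_dist_bp:
                    continue
                r2 = pair_r2(sub.dosages[:, a], sub.dosages[:, b])
                if np.isnan(r2):
                    continue
                k = min(dist // bin_bp, n_bins - 1)
                sums[k] += r2
                counts[k] += 1
    if not any_usable:
        raise UndefinedStatisticError("fewer than 2 usable loci on every chromosome")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LdDecayCurve(bin_edges=edges, mean_r2=mean, pair_counts=counts)


# ---------------------------------------------------------------------------
# IBD method of moments
# ---------------------------------------------------------------------------


@dataclass
class IbdEstimate:
    """IBD sharing probabilities (k0, k1, k2) and pi_hat = k2 + k1/2.

    The k's are truncated to the probability simplex; ``pi_hat`` is computed
    from the raw (untruncated) moment estimates and clipped to [0, 1], which
    keeps it unbiased around zero for unrelated pairs — simplex truncation
    alone would push it systematically upward at moderate locus counts.
    """

    k0: float
    k1: float
    k2: float
    pi_hat: float


def ibd_mom(
    g: GenotypeMatrix, i: int | str, j: int | str, freqs: pd.DataFrame | None = None
) -> IbdEstimate:
    """Method-of-moments IBD estimate for one sample pair.

    Observed identity-by-state counts are equated to their expectations
    given pooled allele frequencies:

    * P(IBS=0 | IBD=0) = 2 p^2 q^2
    * P(IBS=1 | IBD=0) = 4 p^3 q + 4 p q^3 ; P(IBS=1 | IBD=1) = 2 p q
    * P(IBS=2 | IBD=1) = p^2 + q^2 ; P(IBS=2 | IBD=2) = 1

    and the resulting (k0, k1, k2) is truncated to the probability simplex.
    Loci with pooled MAF = 0 are skipped.
    """
    if isinstance(i, str):
        i = g.sample_ids.index(i)
    if isinstance(j, str):
        j = g.sample_ids.index(j)
    if freqs is None:
        freqs = allele_frequencies(g)
    p = freqs["p"].to_numpy()
    di, dj = g.dosages[i].astype(int), g.dosages[j].astype(int)
    ok = (di != MISSING) & (dj != MISSING) & np.isfinite(p) & (p > 0) & (p < 1)
    di, dj, p = di[ok], dj[ok], p[ok]
    if len(p) == 0:
        raise UndefinedStatisticError("no informative locus shared by the pair")
    q = 1.0 - p
    ibs = 2 - np.abs(di - dj)
    n0 = float((ibs == 0).sum())
    n1 = float((ibs == 1).sum())
    e0_z0 = float((2 * p**2 * q**2).sum())
    e1_z0 = float((4 * p**3 * q + 4 * p * q**3).sum())
    e1_z1 = float((2 * p * q).sum())
    k0 = n0 / e0_z0 if e0_z0 > 0 else 0.0
    k1 = (n1 - k0 * e1_z0) / e1_z1 if e1_z1 > 0 else 0.0
    k2 = 1.0 - k0 - k1
    pi_hat = float(np.clip(k2 + k1 / 2.0, 0.0, 1.0))
    k = np.clip([k0, k1, k2], 0.0, 1.0)
    k = k / k.sum()
    return IbdEstimate(k0=float(k[0]), k1=float(k[1]), k2=float(k[2]), pi_hat=pi_hat)


def ibd_all_pairs(g: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric pi_hat matrix over all sample pairs (diagonal 1)."""
    freqs = allele_frequencies(g)
    n = g.n_samples
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = ibd_mom(g, i, j, freqs).pi_hat
    return pd.DataFrame(m, index=g.sample_ids, columns=g.sample_ids)


def group_ibd_summary(pihat: pd.DataFrame, pop_labels: list[str]) -> pd.DataFrame:
    """log10 of the mean pairwise pi_hat for each population pair.

    Within-population means exclude self pairs; a zero mean maps to -inf.
    """
    pops = list(dict.fromkeys(pop_labels))
    labels = np.asarray(pop_labels)
    vals = pihat.to_numpy()
    out = pd.DataFrame(np.nan, index=pops, columns=pops)
    for a in pops:
        for b in pops:
            ia = np.flatnonzero(labels == a)
            ib = np.flatnonzero(labels == b)
            block = vals[np.ix_(ia, ib)]
            if a == b:
                iu = np.triu_indices(len(ia), k=1)
                pair_vals = block[iu]
            else:
                pair_vals = block.ravel()
            if len(pair_vals) == 0:
                continue
            mean = pair_vals.mean()
            out.loc[a, b] = np.log10(mean) if mean > 0 else -np.inf
    return out


def classical_mds(d: pd.DataFrame | np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers -d^2/2 and eigendecomposes; only positive eigenvalues are
    used (with a warning if some are negative).  Axis signs are fixed so the
    largest-magnitude loading of each axis is positive.
    """
    dm = np.asarray(d, dtype=float)
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if (evals < -1e-8 * max(abs(evals[0]), 1.0)).any():
        warnings.warn("centered matrix not positive semidefinite; "
                      "negative eigenvalues discarded")
    coords = np.zeros((n, dims))
    for k in range(min(dims, n)):
        if evals[k] <= 0:
            break
        axis = evecs[:, k] * np.sqrt(evals[k])
        if axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
        coords[:, k] = axis
    return coords
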
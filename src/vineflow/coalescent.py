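"""Structured-coalescent simulation of independent biallelic SNP loci.

Backward in time, lineages sampled in the leaf populations of a
:class:`~vineflow.scenarios.Scenario` coalesce within their current
population at rate k(k-1)/2 / (2 Ne) per generation, move between
populations at divergence and admixture events, and finish in the root
population.  Each locus carries exactly one mutation, dropped on a branch
chosen with probability proportional to its length; the locus is redrawn
(a fresh genealogy) until the pooled minor-allele count reaches the
configured SNP-ascertainment threshold.  Loci are independent: the ABC
summary statistics are frequency-based, so no intra- or inter-locus
linkage is modelled.

Waiting times are exact exponentials (no generation-by-generation
Wright-Fisher discretization).  The hot loops are numba-compiled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .genotypes import GenotypeMatrix
from .scenarios import AdmixtureEvent, DivergenceEvent, ParameterDraw, Scenario

#: Default synthetic chromosome layout for assigning SNP positions:
#: (number of chromosomes, chromosome length in bp).  Grapevine-like.
DEFAULT_LAYOUT = (19, 25_000_000)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=False)
def _kernel_genealogy(pop_of_tip, ne, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r):
    """One structured-coalescent genealogy.

    Returns (parent, node_time, ok): tips are nodes 0..n-1 at time 0,
    internal nodes are appended in coalescence order, the root has
    parent -1.  ok is 0 when lineages in distinct populations can never
    join (disconnected scenario).
    """
    n = pop_of_tip.shape[0]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, np.int64)
    node_time = np.zeros(n_nodes)
    lin_node = np.arange(n)
    lin_pop = pop_of_tip.copy()
    k = n
    nxt = n
    t = 0.0
    iev = 0
    n_pops = ne.shape[0]
    counts = np.zeros(n_pops, np.int64)
    for i in range(k):
        counts[lin_pop[i]] += 1
    while k > 1:
        rate = 0.0
        for p in range(n_pops):
            c = counts[p]
            if c > 1:
                rate += c * (c - 1) / 2.0 / (2.0 * ne[p])
        t_c = t + np.random.exponential(1.0 / rate) if rate > 0.0 else np.inf
        if iev < ev_time.shape[0] and ev_time[iev] <= t_c:
            t = ev_time[iev]
            a = ev_a[iev]
            if ev_type[iev] == 0:  # divergence: a -> b
                b = ev_b[iev]
                for i in range(k):
                    if lin_pop[i] == a:
                        lin_pop[i] = b
                        counts[a] -= 1
                        counts[b] += 1
            else:  # admixture: a -> b w.p. r else c
                b = ev_b[iev]
                c2 = ev_c[iev]
                r = ev_r[iev]
                for i in range(k):
                    if lin_pop[i] == a:
                        dest = b if np.random.random() < r else c2
                        lin_pop[i] = dest
                        counts[a] -= 1
                        counts[dest] += 1
            iev += 1
            continue
        if not np.isfinite(t_c):
            return parent, node_time, 0
        t = t_c
        u = np.random.random() * rate
        acc = 0.0
        chosen = n_pops - 1
        for p in range(n_pops):
            c = counts[p]
            if c > 1:
                acc += c * (c - 1) / 2.0 / (2.0 * ne[p])
                if u <= acc:
                    chosen = p
                    break
        c = counts[chosen]
        i1 = np.random.randint(c)
        i2 = np.random.randint(c - 1)
        if i2 >= i1:
            i2 += 1
        seen = 0
        a1 = -1
        a2 = -1
        for i in range(k):
            if lin_pop[i] == chosen:
                if seen == i1:
                    a1 = i
                if seen == i2:
                    a2 = i
                seen += 1
        node_time[nxt] = t
        parent[lin_node[a1]] = nxt
        parent[lin_node[a2]] = nxt
        lin_node[a1] = nxt
        lin_node[a2] = lin_node[k - 1]
        lin_pop[a2] = lin_pop[k - 1]
        counts[chosen] -= 1
        k -= 1
        nxt += 1
    return parent, node_time, 1


@njit(cache=False)
def _kernel_mutation(parent, node_time, n_tips):
    """Drop one mutation on a branch chosen proportionally to its length;
    return the derived-allele indicator per tip."""
    n_nodes = parent.shape[0]
    total = 0.0
    blen = np.zeros(n_nodes)
    for v in range(n_nodes):
        if parent[v] >= 0:
            blen[v] = node_time[parent[v]] - node_time[v]
            total += blen[v]
    u = np.random.random() * total
    acc = 0.0
    chosen = n_nodes - 2
    for v in range(n_nodes):
        if parent[v] >= 0:
            acc += blen[v]
            if u <= acc:
                chosen = v
                break
    col = np.zeros(n_tips, np.int8)
    for tip in range(n_tips):
        x = tip
        while x >= 0:
            if x == chosen:
                col[tip] = 1
                break
            x = parent[x]
    return col


@njit(cache=False)
def _kernel_matrix(pop_of_tip, ne, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r,
                   n_loci, min_minor, seed):
    """Haplotype matrix (gene copies x loci) of polymorphism-conditioned SNPs."""
    np.random.seed(seed)
    n = pop_of_tip.shape[0]
    out = np.zeros((n, n_loci), np.int8)
    for locus in range(n_loci):
        while True:
            parent, node_time, ok = _kernel_genealogy(
                pop_of_tip, ne, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r
            )
            if ok == 0:
                return out, 0
            col = _kernel_mutation(parent, node_time, n)
            cnt = 0
            for i in range(n):
                cnt += col[i]
            if min(cnt, n - cnt) >= min_minor:
                out[:, locus] = col
                break
    return out, 1


@njit(cache=False)
def _seeded_genealogy(pop_of_tip, ne, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r, seed):
    np.random.seed(seed)
    return _kernel_genealogy(pop_of_tip, ne, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r)


@njit(cache=False)
def _seeded_mutation(parent, node_time, n_tips, seed):
    np.random.seed(seed)
    return _kernel_mutation(parent, node_time, n_tips)


# ---------------------------------------------------------------------------
# scenario compilation
# ---------------------------------------------------------------------------


def _compile(s: Scenario, params: ParameterDraw, sampled_pops: list[str]):
    """Map populations to integer ids and events to sorted plain arrays."""
    pop_ids: dict[str, int] = {p: i for i, p in enumerate(sampled_pops)}
    for ev in s.events:
        names = ([ev.derived, ev.source] if isinstance(ev, DivergenceEvent)
                 else [ev.target, ev.source_a, ev.source_b])
        for p in names:
            if p not in pop_ids:
                pop_ids[p] = len(pop_ids)
    ne = np.empty(len(pop_ids))
    for p, i in pop_ids.items():
        ne[i] = float(params[s.ne_params[p]])
        if ne[i] <= 0:
            raise ValueError(f"effective size of {p} must be positive")
    recs = []
    for order, ev in enumerate(s.events):
        t = float(params[ev.time])
        if t <= 0:
            raise ValueError(f"event time {ev.time} must be positive")
        if isinstance(ev, DivergenceEvent):
            recs.append((t, order, 0, pop_ids[ev.derived], pop_ids[ev.source], 0, 0.0))
        else:
            r = float(params[ev.proportion])
            if not 0.0 < r < 1.0:
                raise ValueError(f"admixture proportion {ev.proportion} outside (0, 1)")
            recs.append((t, order, 1, pop_ids[ev.target], pop_ids[ev.source_a],
                         pop_ids[ev.source_b], r))
    recs.sort(key=lambda rec: (rec[0], rec[1]))
    ev_time = np.array([r[0] for r in recs])
    ev_type = np.array([r[2] for r in recs], np.int8)
    ev_a = np.array([r[3] for r in recs], np.int64)
    ev_b = np.array([r[4] for r in recs], np.int64)
    ev_c = np.array([r[5] for r in recs], np.int64)
    ev_r = np.array([r[6] for r in recs])
    return ne, (ev_time, ev_type, ev_a, ev_b, ev_c, ev_r)


def _as_seed(rng: int | np.random.Generator) -> int:
    """A 31-bit seed for the numba RNG, derived from an int or Generator."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    return int(rng.integers(2**31))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


@dataclass
class Genealogy:
    """Binary genealogy over sampled gene copies.

    Tips are nodes ``0..n_tips-1`` at time 0; ``parent[v]`` is -1 for the
    root; ``node_time`` is in generations.
    """

    parent: np.ndarray
    node_time: np.ndarray
    pop_of_tip: np.ndarray
    tip_populations: list[str]

    @property
    def n_tips(self) -> int:
        return len(self.pop_of_tip)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0 for the root)."""
        lens = np.zeros(len(self.parent))
        has = self.parent >= 0
        lens[has] = self.node_time[self.parent[has]] - self.node_time[has]
        return lens

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())


def simulate_genealogy(
    s: Scenario,
    params: ParameterDraw,
    sample_sizes: dict[str, int],
    rng: int | np.random.Generator,
) -> Genealogy:
    """Simulate one genealogy for ``sample_sizes`` gene copies per population."""
    pops = list(sample_sizes)
    if any(v < 1 for v in sample_sizes.values()):
        raise ValueError("sample sizes must be >= 1")
    pop_of_tip = np.repeat(
        np.arange(len(pops)), [sample_sizes[p] for p in pops]
    ).astype(np.int64)
    if len(pop_of_tip) == 1:
        return Genealogy(
            parent=np.array([-1]), node_time=np.zeros(1),
            pop_of_tip=pop_of_tip, tip_populations=[pops[0]],
        )
    ne, evs = _compile(s, params, pops)
    parent, node_time, ok = _seeded_genealogy(pop_of_tip, ne, *evs, _as_seed(rng))
    if not ok:
        raise ValueError(f"scenario {s.id}: lineages can never fully coalesce")
    tip_pops = [p for p in pops for _ in range(sample_sizes[p])]
    return Genealogy(parent=parent, node_time=node_time,
                     pop_of_tip=pop_of_tip, tip_populations=tip_pops)


def drop_snp_mutation(
    gen: Genealogy,
    rng: int | np.random.Generator,
    min_minor_count: int = 1,
    regenerate=None,
) -> tuple[np.ndarray, Genealogy]:
    """Drop a single mutation; returns (haplotype column, genealogy used).

    The branch is chosen with probability proportional to its length among
    branches below the root, so the column is always polymorphic.  When the
    minor-allele count falls below ``min_minor_count`` the whole locus is
    redrawn on a fresh genealogy from ``regenerate()`` (required if
    ``min_minor_count > 1``).
    """
    if gen.n_tips < 2:
        raise ValueError("mutation dropping needs at least 2 tips")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    for _ in range(100_000):
        col = _seeded_mutation(gen.parent, gen.node_time, gen.n_tips, _as_seed(rng))
        minor = min(int(col.sum()), gen.n_tips - int(col.sum()))
        if minor >= min_minor_count:
            return col, gen
        if regenerate is None:
            raise ValueError(
                "min_minor_count > 1 requires a regenerate() callable to "
                "redraw the locus genealogy"
            )
        gen = regenerate()
    raise RuntimeError("could not satisfy the minor-allele threshold")


def simulate_dataset(
    s: Scenario,
    params: ParameterDraw,
    diploid_counts: dict[str, int],
    n_loci: int,
    rng: int | np.random.Generator,
    min_maf: float = 0.05,
    layout: tuple[int, int] = DEFAULT_LAYOUT,
) -> GenotypeMatrix:
    """Simulate a diploid SNP dataset under a scenario at fixed parameters.

    Per locus, 2 x total diploids gene copies are simulated and paired into
    individuals within population (copies 2i, 2i+1 form individual i).  The
    SNP-ascertainment filter keeps only loci with pooled MAF >= ``min_maf``
    (set 0 for plain polymorphism conditioning), mirroring the quality
    filter applied to observed array panels.  Positions are drawn uniformly
    on a synthetic ``layout = (n_chromosomes, chromosome_bp)`` map; loci are
    unlinked regardless of assigned position.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    pops = list(diploid_counts)
    copies = {p: 2 * diploid_counts[p] for p in pops}
    n_copies = sum(copies.values())
    pop_of_tip = np.repeat(np.arange(len(pops)), [copies[p] for p in pops]).astype(np.int64)
    ne, evs = _compile(s, params, pops)
    min_minor = max(1, math.ceil(min_maf * n_copies))
    hap, ok = _kernel_matrix(pop_of_tip, ne, *evs, n_loci, min_minor, _as_seed(rng))
    if not ok:
        raise ValueError(f"scenario {s.id}: lineages can never fully coalesce")
    dosages = hap[0::2, :] + hap[1::2, :]
    sample_ids = [
        f"{p}_{i + 1}" for p in pops for i in range(diploid_counts[p])
    ]
    pop_labels = [p for p in pops for _ in range(diploid_counts[p])]
    loci = _synthetic_map(n_loci, layout, rng)
    return GenotypeMatrix(
        sample_ids=sample_ids, pop_labels=pop_labels, loci=loci,
        dosages=dosages.astype(np.int8),
    )


def _synthetic_map(
    n_loci: int, layout: tuple[int, int], rng: np.random.Generator
) -> pd.DataFrame:
    n_chrom, chrom_len = layout
    chroms = np.sort(rng.integers(1, n_chrom + 1, size=n_loci))
    pos = rng.integers(1, chrom_len + 1, size=n_loci)
    df = pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in chroms],
            "pos": pos,
            "ref": "A",
            "alt": "G",
        }
    )
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    # de-duplicate positions within chromosome to keep loci distinct
    for _ in range(10):
        dup = df.duplicated(["chrom", "pos"])
        if not dup.any():
            break
        df.loc[dup, "pos"] = df.loc[dup, "pos"] + 1
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return df
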
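"""Synthetic SNP-array study generator with ground-truth manifest.

Emulates the structural features of a curated germplasm genotyping panel —
multiple populations related by divergence/admixture, biallelic loci, per-SNP
and per-sample missingness, and occasional duplicated (clonally propagated)
profiles with genotyping noise — so the QC, statistics and ABC stages can be
exercised end to end against known ground truth.

Missingness is injected by independent Bernoulli draws (no array-batch
structure); clones are genotype copies with an independent symmetric flip
per locus, modelling re-genotyped cuttings of the same variety.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .coalescent import DEFAULT_LAYOUT, simulate_dataset
from .genotypes import MISSING, GenotypeMatrix
from .scenarios import ParameterDraw, Scenario


@dataclass
class StudyEmulationConfig:
    """Generating conditions for one synthetic study panel."""

    scenario: Scenario
    params: ParameterDraw
    diploid_counts: dict[str, int]
    n_loci: int
    snp_missing_rate: float = 0.0
    sample_missing_rate: float = 0.0
    n_duplicate_clones: int = 0
    clone_error_rate: float = 0.01
    ascertainment_maf: float = 0.05
    layout: tuple[int, int] = DEFAULT_LAYOUT
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.snp_missing_rate, self.sample_missing_rate,
                     self.clone_error_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must be in [0, 1)")
        if self.n_loci <= 0 or any(v <= 0 for v in self.diploid_counts.values()):
            raise ValueError("counts must be positive")


@dataclass
class StudyManifest:
    """Ground truth recorded alongside a generated panel."""

    scenario_id: str
    params: ParameterDraw
    clone_pairs: list[tuple[str, str]] = field(default_factory=list)
    missing_cells: list[tuple[str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def generate_study(config: StudyEmulationConfig) -> tuple[GenotypeMatrix, StudyManifest]:
    """Generate one synthetic study panel and its ground-truth manifest.

    Simulation, clone copying and missingness injection each use an RNG
    stream derived from ``config.seed``, so the output is fully
    reproducible.
    """
    ss = np.random.SeedSequence(config.seed).generate_state(3)
    g = simulate_dataset(
        config.scenario, config.params, config.diploid_counts, config.n_loci,
        np.random.default_rng(ss[0]), min_maf=config.ascertainment_maf,
        layout=config.layout,
    )
    manifest = StudyManifest(scenario_id=config.scenario.id, params=dict(config.params))

    sample_ids = list(g.sample_ids)
    pop_labels = list(g.pop_labels)
    dosages = g.dosages.copy()

    rng = np.random.default_rng(ss[1])
    if config.n_duplicate_clones > 0:
        originals = rng.choice(len(sample_ids), size=config.n_duplicate_clones,
                               replace=False)
        clone_rows = []
        for o in originals:
            row = dosages[o].copy()
            flip = rng.random(len(row)) < config.clone_error_rate
            for j in np.flatnonzero(flip):
                choices = [v for v in (0, 1, 2) if v != row[j]]
                row[j] = choices[int(rng.integers(2))]
            clone_id = f"{sample_ids[o]}_clone"
            manifest.clone_pairs.append((sample_ids[o], clone_id))
            sample_ids.append(clone_id)
            pop_labels.append(pop_labels[o])
            clone_rows.append(row)
        dosages = np.vstack([dosages, np.array(clone_rows, dtype=np.int8)])

    rng = np.random.default_rng(ss[2])
    if config.snp_missing_rate > 0 or config.sample_missing_rate > 0:
        miss = rng.random(dosages.shape) < config.snp_missing_rate
        miss |= rng.random(dosages.shape) < config.sample_missing_rate
        for i, j in zip(*np.nonzero(miss)):
            manifest.missing_cells.append((sample_ids[i], int(j)))
        dosages[miss] = MISSING

    out = GenotypeMatrix(
        sample_ids=sample_ids, pop_labels=pop_labels,
        loci=g.loci, dosages=dosages,
    )
    return out, manifest
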
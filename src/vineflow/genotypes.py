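"""Diploid SNP genotype matrices and their on-disk formats.

The central container is :class:`GenotypeMatrix`: a samples x loci table of
alternate-allele dosages (0, 1, 2 or missing) together with a population
label per sample and chromosome/position/allele metadata per locus.  Three
plain-text dialects are supported: a headered TSV dosage table, VCF
(biallelic SNPs, GT field), and PLINK text ``.ped``/``.map``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

_LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt"]


class GenotypeFormatError(ValueError):
    """Raised when an input file does not parse in the declared dialect."""


@dataclass
class GenotypeMatrix:
    """Samples x loci diploid dosage matrix with population labels.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``dosages``.
    pop_labels
        Population name per sample (same length as ``sample_ids``).
    loci
        DataFrame with columns ``chrom``, ``pos`` (1-based bp), ``ref``,
        ``alt``; one row per locus, sorted by (chrom, pos).
    dosages
        int8 array of shape (n_samples, n_loci); entries in {0, 1, 2} or
        :data:`MISSING`.
    """

    sample_ids: list[str]
    pop_labels: list[str]
    loci: pd.DataFrame
    dosages: np.ndarray
    warnings_: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.loci = self.loci.reset_index(drop=True)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeFormatError("sample ids are not unique")
        if len(self.pop_labels) != len(self.sample_ids):
            raise GenotypeFormatError("one population label per sample required")
        if list(self.loci.columns[:4]) != _LOCUS_COLUMNS:
            raise GenotypeFormatError(f"loci must have columns {_LOCUS_COLUMNS}")
        if self.dosages.shape != (len(self.sample_ids), len(self.loci)):
            raise GenotypeFormatError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeFormatError("dosages must be 0, 1, 2 or missing")
        # loci sorted by position within chromosome
        for _, grp in self.loci.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise GenotypeFormatError("loci not sorted by position within chromosome")

    # -- convenience -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        """Population names in order of first appearance."""
        return list(dict.fromkeys(self.pop_labels))

    def pop_mask(self, pop: str) -> np.ndarray:
        mask = np.array([p == pop for p in self.pop_labels])
        if not mask.any():
            raise KeyError(f"population {pop!r} not present")
        return mask

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in index],
            pop_labels=[self.pop_labels[i] for i in index],
            dosages=self.dosages[index, :],
        )

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            loci=self.loci.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.pop_labels == other.pop_labels
            and self.loci[_LOCUS_COLUMNS].equals(other.loci[_LOCUS_COLUMNS])
            and np.array_equal(self.dosages, other.dosages)
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str) -> GenotypeMatrix:
    """Read a genotype matrix from ``path`` in the named dialect.

    ``format`` is one of ``"tsv"``, ``"vcf"`` or ``"plink_text"`` (for which
    ``path`` is the ``.ped`` file; the ``.map`` file is looked up next to it).
    Multi-allelic VCF records are skipped and counted in
    ``matrix.warnings_["n_multiallelic_skipped"]``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_text":
        return _read_plink_text(path)
    raise ValueError(f"unknown format {format!r}; use tsv, vcf or plink_text")


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write ``g`` to ``path`` as TSV or VCF."""
    path = Path(path)
    if format == "tsv":
        _write_tsv(g, path)
    elif format == "vcf":
        _write_vcf(g, path)
    else:
        raise ValueError(f"unknown output format {format!r}; use tsv or vcf")


# -- TSV dialect: sample_id, population, then one column per locus named
#    chrom:pos:ref:alt; missing dosage written as NA.


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "population"]:
        raise GenotypeFormatError("TSV must start with sample_id and population columns")
    locus_cols = list(df.columns[2:])
    rows = []
    for name in locus_cols:
        parts = name.split(":")
        if len(parts) != 4:
            raise GenotypeFormatError(f"locus column {name!r} is not chrom:pos:ref:alt")
        rows.append((parts[0], int(parts[1]), parts[2], parts[3]))
    loci = pd.DataFrame(rows, columns=_LOCUS_COLUMNS)
    dosages = (
        df[locus_cols]
        .apply(pd.to_numeric, errors="coerce")
        .fillna(MISSING)
        .to_numpy(dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=df["sample_id"].tolist(),
        pop_labels=df["population"].tolist(),
        loci=loci,
        dosages=dosages,
    )


def _write_tsv(g: GenotypeMatrix, path: Path) -> None:
    names = [
        f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}" for r in g.loci.itertuples(index=False)
    ]
    df = pd.DataFrame(g.dosages, columns=names).astype(object)
    df = df.mask(df == MISSING, "NA")
    df.insert(0, "population", g.pop_labels)
    df.insert(0, "sample_id", g.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, columns = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt(?), 3=unknown -> use genotypes
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            col[i] = sum(alleles) if len(alleles) == 2 else MISSING
        columns.append(col)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic VCF records")
    if not rows:
        raise GenotypeFormatError("no biallelic records in VCF")
    loci = pd.DataFrame(rows, columns=_LOCUS_COLUMNS)
    dosages = np.stack(columns, axis=1)
    # population labels are not part of VCF; default every sample to one group
    g = GenotypeMatrix(
        sample_ids=samples,
        pop_labels=["pop1"] * len(samples),
        loci=loci,
        dosages=dosages,
    )
    g.warnings_["n_multiallelic_skipped"] = n_multi
    return g


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j, r in enumerate(g.loci.itertuples(index=False)):
            gts = "\t".join(code[int(d)] for d in g.dosages[:, j])
            fh.write(f"{r.chrom}\t{r.pos}\tsnp{j + 1}\t{r.ref}\t{r.alt}\t.\t.\t.\tGT\t{gts}\n")


def _read_plink_text(ped_path: Path) -> GenotypeMatrix:
    map_path = ped_path.with_suffix(".map")
    if not map_path.exists():
        raise IOError(f"no .map file next to {ped_path}")
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "id", "cm", "pos"], dtype=str
    )
    n_loci = len(map_df)
    sample_ids, pops, rows = [], [], []
    with open(ped_path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_loci:
                raise GenotypeFormatError(
                    f"PED row for {fields[1] if len(fields) > 1 else '?'} has "
                    f"{len(fields)} fields, expected {6 + 2 * n_loci}"
                )
            pops.append(fields[0])  # family id doubles as population label
            sample_ids.append(fields[1])
            rows.append(fields[6:])
    alleles_per_locus: list[list[str]] = [[] for _ in range(n_loci)]
    for row in rows:
        for j in range(n_loci):
            for a in (row[2 * j], row[2 * j + 1]):
                if a != "0" and a not in alleles_per_locus[j]:
                    alleles_per_locus[j].append(a)
    for j, obs in enumerate(alleles_per_locus):
        if len(obs) > 2:
            raise GenotypeFormatError(f"locus {j} has more than two alleles")
        while len(obs) < 2:
            obs.append("N")
    dosages = np.empty((len(rows), n_loci), dtype=np.int8)
    for i, row in enumerate(rows):
        for j in range(n_loci):
            a1, a2 = row[2 * j], row[2 * j + 1]
            if a1 == "0" or a2 == "0":
                dosages[i, j] = MISSING
            else:
                alt = alleles_per_locus[j][1]
                dosages[i, j] = (a1 == alt) + (a2 == alt)
    loci = pd.DataFrame(
        {
            "chrom": map_df["chrom"],
            "pos": map_df["pos"].astype(int),
            "ref": [a[0] for a in alleles_per_locus],
            "alt": [a[1] for a in alleles_per_locus],
        }
    )
    order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
    loci = loci.iloc[order].reset_index(drop=True)
    return GenotypeMatrix(
        sample_ids=sample_ids, pop_labels=pops, loci=loci, dosages=dosages[:, order]
    )
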
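"""One-config orchestration: QC -> statistics -> ABC per hypothesis.

The pipeline consumes a single YAML config describing the input panel, QC
thresholds, population grouping, LD-decay settings and a list of ABC
hypotheses, and writes machine-readable outputs (TSV/JSON/Newick) into a
run directory together with a manifest of seeds, config hash and stage
timings.  All randomness derives from the single top-level seed: stage k of
the run uses stream k of ``numpy.random.SeedSequence(seed)``.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import inference, popgen, qc
from .genotypes import GenotypeMatrix, read_genotypes, write_genotypes
from .scenarios import (
    PriorSpec,
    Prior,
    Scenario,
    default_priors,
    study_scenarios,
)


class ConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.validate``)."""

    def __init__(self, raw: dict, base_dir: Path | None = None):
        self.raw = raw
        self.base_dir = base_dir or Path.cwd()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(raw, base_dir=path.parent)

    def validate(self) -> None:
        raw = self.raw
        if "seed" not in raw:
            raise ConfigError("config must set a seed")
        inp = raw.get("input") or {}
        if "path" not in inp or "format" not in inp:
            raise ConfigError("input.path and input.format are required")
        if not (self.base_dir / inp["path"]).exists():
            raise ConfigError(f"input file not found: {inp['path']}")
        for hyp in raw.get("hypotheses", []):
            if "name" not in hyp:
                raise ConfigError("every hypothesis needs a name")
            if "diploid_counts" not in hyp:
                raise ConfigError(f"hypothesis {hyp['name']}: diploid_counts required")

    def resolve_hypothesis(self, hyp: dict) -> tuple[list[Scenario], dict[str, PriorSpec]]:
        fixtures = study_scenarios()
        spec = hyp.get("scenarios", "fixtures")
        if spec == "fixtures":
            if hyp["name"] not in fixtures:
                raise ConfigError(f"no fixture group named {hyp['name']}")
            scens = fixtures[hyp["name"]]
        else:
            scens = [Scenario.from_dict(d) for d in spec]
        priors_cfg = hyp.get("priors", "default")
        priors: dict[str, PriorSpec] = {}
        for s in scens:
            if priors_cfg == "default":
                priors[s.id] = default_priors(s)
            else:
                priors[s.id] = PriorSpec(
                    priors={
                        k: Prior(v["dist"], float(v["low"]), float(v["high"]))
                        for k, v in priors_cfg["priors"].items()
                    },
                    constraints=[tuple(c) for c in priors_cfg.get("constraints", [])],
                )
        return scens, priors


def _apply_grouping(g: GenotypeMatrix, groups: dict | None) -> GenotypeMatrix:
    if not groups:
        return g
    missing = [s for s in g.sample_ids if s not in groups]
    if missing:
        raise ConfigError(f"samples without group assignment: {missing[:5]}")
    return GenotypeMatrix(
        sample_ids=g.sample_ids,
        pop_labels=[groups[s] for s in g.sample_ids],
        loci=g.loci,
        dosages=g.dosages,
    )


def run(config: RunConfig, out_dir: str | Path, dry_run: bool = False) -> Path:
    """Execute the pipeline; returns the run directory.

    ``dry_run`` validates the full config (including fixture and prior
    resolution) without simulating or writing outputs.
    """
    config.validate()
    raw = config.raw
    for hyp in raw.get("hypotheses", []):
        config.resolve_hypothesis(hyp)
    if dry_run:
        return Path(out_dir)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(raw["seed"])
    streams = np.random.SeedSequence(seed).generate_state(64)
    timings: dict[str, float] = {}
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(raw, sort_keys=True).encode()
        ).hexdigest(),
        "stages": [],
    }

    def stage(name: str):
        manifest["stages"].append(name)
        timings[name] = time.time()

    def done(name: str):
        timings[name] = round(time.time() - timings[name], 3)

    # ---- QC ------------------------------------------------------------
    stage("qc")
    try:
        inp = raw["input"]
        g = read_genotypes(config.base_dir / inp["path"], inp["format"])
        g = _apply_grouping(g, raw.get("groups"))
        present = set(g.populations)
        for hyp in raw.get("hypotheses", []):
            absent = [p for p in hyp["diploid_counts"] if p not in present]
            if absent:
                raise ConfigError(
                    f"hypothesis {hyp['name']}: populations {absent} not in data"
                )
        qc_cfg = raw.get("qc", {})
        g, snp_rep = qc.filter_snps(
            g,
            max_na_rate=qc_cfg.get("max_snp_na", 0.01),
            min_maf=qc_cfg.get("min_maf", 0.05),
        )
        g, samp_rep = qc.filter_samples(g, max_na_rate=qc_cfg.get("max_sample_na", 0.05))
        pairs = qc.find_duplicates(g, mismatch_cutoff=qc_cfg.get("dup_cutoff", 0.20))
        g, dup_rep = qc.deduplicate(g, pairs)
        write_genotypes(g, out / "filtered.tsv", "tsv")
        with open(out / "qc_report.json", "w") as fh:
            json.dump(
                {
                    "n_snps_removed_narate": snp_rep.n_snps_removed_narate,
                    "n_snps_removed_maf": snp_rep.n_snps_removed_maf,
                    "n_samples_removed_narate": samp_rep.n_samples_removed_narate,
                    "duplicate_pairs": dup_rep.duplicate_pairs,
                    "n_samples_kept": g.n_samples,
                    "n_loci_kept": g.n_loci,
                },
                fh,
                indent=2,
            )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineStageError("qc", exc) from exc
    done("qc")

    # ---- descriptive statistics ---------------------------------------
    stage("stats")
    try:
        pops = g.populations
        fst = popgen.fst_matrix(g)
        fst.to_csv(out / "fst_matrix.tsv", sep="\t")
        if len(pops) >= 3:
            (out / "nj_tree.nwk").write_text(popgen.nj_tree(fst) + "\n")
        ld_cfg = raw.get("ld_decay", {})
        decay = {}
        for p in pops:
            try:
                curve = popgen.ld_decay(
                    g, p,
                    max_dist_bp=ld_cfg.get("max_dist_bp", 10_000_000),
                    bin_bp=ld_cfg.get("bin_bp", 100_000),
                    min_maf=ld_cfg.get("min_maf", 0.05),
                )
            except popgen.UndefinedStatisticError:
                continue
            curve.to_frame().to_csv(out / f"ld_decay_{p}.tsv", sep="\t", index=False)
            decay[p] = curve.decay_distance_at(ld_cfg.get("threshold", 0.05))
        with open(out / "ld_decay_distances.json", "w") as fh:
            json.dump(decay, fh, indent=2)
        if raw.get("ibd", True) and g.n_samples <= raw.get("ibd_max_samples", 400):
            pihat = popgen.ibd_all_pairs(g)
            popgen.group_ibd_summary(pihat, g.pop_labels).to_csv(
                out / "ibd_group_log_mean_pihat.tsv", sep="\t"
            )
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("stats", exc) from exc
    done("stats")

    # ---- ABC per hypothesis -------------------------------------------
    for i, hyp in enumerate(raw.get("hypotheses", [])):
        name = hyp["name"]
        stage(f"abc:{name}")
        try:
            scens, priors = config.resolve_hypothesis(hyp)
            counts = dict(hyp["diploid_counts"])
            absent = [p for p in counts if p not in pops]
            if absent:
                raise ConfigError(f"hypothesis {name}: populations {absent} not in data")
            hyp_pops = list(counts)
            sub_idx = [
                j for j, lab in enumerate(g.pop_labels) if lab in hyp_pops
            ]
            sub = g.take_samples(np.array(sub_idx))
            obs = inference.summary_vector(sub, hyp_pops)
            tol = hyp.get("tolerance", 0.01)
            ref = inference.build_reference_table(
                scens, priors, counts,
                n_loci=hyp.get("n_loci", sub.n_loci),
                n_sims_per_scenario=hyp.get("n_sims_per_scenario", 1000),
                seed=int(streams[8 + i]),
            )
            res = inference.model_choice(
                ref, obs, tolerance=tol,
                bootstrap_B=hyp.get("bootstrap_B", 100),
                seed=int(streams[32 + i]),
            )
            report = {
                "hypothesis": name,
                "observed_stats": dict(zip(ref.stat_names, obs.tolist())),
                "posterior_probabilities": res.pp,
                "ci95": {k: list(v) for k, v in res.ci.items()},
                "direct_estimates": res.direct,
                "best": res.best,
            }
            with open(out / f"abc_{name}.json", "w") as fh:
                json.dump(report, fh, indent=2)
            (out / f"abc_{name}.txt").write_text(_format_report(res))
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(f"abc:{name}", exc) from exc
        done(f"abc:{name}")

    manifest["timings_s"] = timings
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def _format_report(res: inference.ModelChoiceResult) -> str:
    """Plain-text block mirroring the published summary-table layout."""
    lines = ["Scenario\tPp (%)\t95% CI"]
    for s in res.scenario_ids:
        ci = res.ci.get(s)
        ci_txt = f"{ci[0]:.0f}-{ci[1]:.0f}" if ci else "-"
        mark = " *" if s == res.best else ""
        lines.append(f"{s}{mark}\t{res.pp[s]:.0f}\t{ci_txt}")
    return "\n".join(lines) + "\n"
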
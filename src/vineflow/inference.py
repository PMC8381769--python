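"""ABC model choice among demographic scenarios.

The approximate Bayesian computation workflow implemented here compares
competing divergence/admixture scenarios for a set of sampled populations:

1. a *reference table* of datasets simulated from prior-drawn parameters
   under each scenario, summarized by the statistic vector (per-population
   gene diversity, pairwise Fst, pairwise Nei distance);
2. *rejection*: the small fraction of simulations closest (standardized
   Euclidean distance) to the observed vector;
3. *model choice*: per-scenario posterior probabilities from a weighted
   multinomial logistic regression of scenario label on summary statistics
   over the retained simulations, with bootstrap confidence intervals;
4. a *selection rule* combining posterior probabilities and model-checking
   outlier counts;
5. *parameter adjustment* by weighted local-linear regression on
   logit-transformed parameters, guaranteeing draws inside prior bounds;
6. *confusion analysis* (type I/II scenario-choice error rates from
   pseudo-observed datasets) and *posterior predictive model checking*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import popgen
from .coalescent import simulate_dataset
from .genotypes import GenotypeMatrix
from .scenarios import ParameterDraw, PriorSpec, Scenario, draw_parameters

# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def stat_names(pops: list[str]) -> list[str]:
    """Names of the summary vector entries, in canonical order."""
    names = [f"He_{p}" for p in pops]
    pairs = [(pops[i], pops[j]) for i in range(len(pops)) for j in range(i + 1, len(pops))]
    names += [f"Fst_{a}|{b}" for a, b in pairs]
    names += [f"NeiD_{a}|{b}" for a, b in pairs]
    return names


def summary_vector(g: GenotypeMatrix, pops: list[str]) -> np.ndarray:
    """ABC summary statistics for one dataset.

    Order: mean gene diversity per population (given population order), then
    pairwise Fst, then pairwise Nei distances, both in lexicographic pair
    order of the population list — length P + 2 * C(P, 2).  Flagged-infinite
    Nei distances are capped at :data:`~vineflow.popgen.NEI_INF_CAP`, and a
    pair with no polymorphic locus (Fst undefined) contributes 0 — such a
    dataset shows no measurable differentiation for that pair.
    """

    # one frequency pass per population; the per-statistic formulas are the
    # same as the standalone popgen functions (pinned by a test)
    counts = {p: popgen._pop_counts(g, p) for p in pops}
    vec: list[float] = []
    for p in pops:
        n, pf, _ = counts[p]
        copies = 2.0 * n
        usable = copies >= 2
        if not usable.any():
            raise popgen.UndefinedStatisticError(f"no usable loci for {p!r}")
        c, q = copies[usable], pf[usable]
        vec.append(float((c * (1 - q**2 - (1 - q) ** 2) / (c - 1)).mean()))
    pairs = [(pops[i], pops[j]) for i in range(len(pops)) for j in range(i + 1, len(pops))]
    for pa, pb in pairs:
        n1, p1, h1 = counts[pa]
        n2, p2, h2 = counts[pb]
        a, b, c = popgen._wc84_components(n1, p1, h1, n2, p2, h2)
        ok = np.isfinite(a + b + c)
        denom = (a + b + c)[ok].sum()
        vec.append(float(a[ok].sum() / denom) if denom != 0 else 0.0)
    for pa, pb in pairs:
        n1, p1, _ = counts[pa]
        n2, p2, _ = counts[pb]
        ok = (n1 >= 1) & (n2 >= 1) & np.isfinite(p1) & np.isfinite(p2)
        x, y = p1[ok], p2[ok]
        jx = float((x**2 + (1 - x) ** 2).mean())
        jy = float((y**2 + (1 - y) ** 2).mean())
        jxy = float((x * y + (1 - x) * (1 - y)).mean())
        if jxy == 0:
            vec.append(popgen.NEI_INF_CAP)
        else:
            vec.append(min(float(-np.log(jxy / np.sqrt(jx * jy))), popgen.NEI_INF_CAP))
    return np.asarray(vec, dtype=float)


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, summary vector) rows.

    ``center``/``scale`` are the per-statistic standardization constants
    computed over all rows; statistics with zero spread are dropped from
    distance and regression computations (``active`` mask).
    """

    scenario_ids: np.ndarray
    params: pd.DataFrame
    stats: np.ndarray
    stat_names: list[str]
    populations: list[str]
    center: np.ndarray = field(init=False)
    scale: np.ndarray = field(init=False)
    active: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.center = self.stats.mean(axis=0)
        self.scale = self.stats.std(axis=0)
        self.active = self.scale > 0
        if not self.active.all():
            dropped = [n for n, a in zip(self.stat_names, self.active) if not a]
            warnings.warn(f"zero-variance statistics dropped: {dropped}")

    @property
    def n_rows(self) -> int:
        return len(self.scenario_ids)

    @property
    def scenarios(self) -> list[str]:
        return list(dict.fromkeys(self.scenario_ids))

    def standardize(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        return (x[:, self.active] - self.center[self.active]) / self.scale[self.active]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stats, columns=self.stat_names)
        df.insert(0, "scenario", self.scenario_ids)
        return pd.concat([df, self.params.reset_index(drop=True)], axis=1)


def build_reference_table(
    scenarios: list[Scenario],
    priors: PriorSpec | dict[str, PriorSpec],
    diploid_counts: dict[str, int],
    n_loci: int,
    n_sims_per_scenario: int,
    seed: int,
    min_maf: float = 0.05,
) -> ReferenceTable:
    """Simulate ``n_sims_per_scenario`` datasets per scenario.

    ``priors`` is either one spec shared by all scenarios or a mapping from
    scenario id.  Every row derives its RNG stream from ``seed`` and its row
    index, so the table is reproducible and chunk-order stable.
    """
    pops = list(diploid_counts)
    names = stat_names(pops)
    row_seeds = np.random.SeedSequence(seed).generate_state(
        2 * len(scenarios) * n_sims_per_scenario
    )
    ids, draws, stats = [], [], []
    row = 0
    for s in scenarios:
        spec = priors[s.id] if isinstance(priors, dict) else priors
        for _ in range(n_sims_per_scenario):
            rng = np.random.default_rng(row_seeds[2 * row])
            params = draw_parameters(s, spec, rng)
            g = simulate_dataset(
                s, params, diploid_counts, n_loci,
                np.random.default_rng(row_seeds[2 * row + 1]), min_maf=min_maf,
            )
            ids.append(s.id)
            draws.append(params)
            stats.append(summary_vector(g, pops))
            row += 1
    return ReferenceTable(
        scenario_ids=np.array(ids),
        params=pd.DataFrame(draws),
        stats=np.array(stats),
        stat_names=names,
        populations=pops,
    )


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------


def reject(
    ref: ReferenceTable, observed: np.ndarray, tolerance: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the ``ceil(tolerance * N)`` closest rows, plus all distances.

    Distance is the Euclidean norm on per-statistic standardized values;
    boundary ties are broken by row index.
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    z = ref.standardize(ref.stats)
    z_obs = ref.standardize(observed)[0]
    dist = np.sqrt(((z - z_obs) ** 2).sum(axis=1))
    k = int(np.ceil(tolerance * ref.n_rows))
    order = np.argsort(dist, kind="stable")
    return order[:k], dist


def _epanechnikov(dist: np.ndarray) -> np.ndarray:
    d_max = dist.max()
    if d_max == 0:
        return np.ones_like(dist)
    w = 1.0 - (dist / d_max) ** 2
    if w.sum() <= 0:
        return np.ones_like(dist)
    return w


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------


@dataclass
class ModelChoiceResult:
    """Per-scenario posterior probabilities (percent) with 95% CIs."""

    scenario_ids: list[str]
    pp: dict[str, float]
    ci: dict[str, tuple[float, float]]
    direct: dict[str, float]
    retained_indices: np.ndarray
    distances: np.ndarray

    @property
    def best(self) -> str:
        return max(self.scenario_ids, key=lambda s: self.pp[s])


def _logistic_pp(
    z: np.ndarray, labels: np.ndarray, weights: np.ndarray,
    z_obs: np.ndarray, all_ids: list[str],
) -> dict[str, float]:
    """Weighted multinomial logistic Pp at the observed point (fractions)."""
    from sklearn.linear_model import LogisticRegression

    present = list(dict.fromkeys(labels))
    if len(present) == 1:
        return {s: (1.0 if s == present[0] else 0.0) for s in all_ids}
    # tiny ridge penalty (1e-6) so complete separation stays finite
    clf = LogisticRegression(C=1e6, max_iter=2000)
    clf.fit(z, labels, sample_weight=weights)
    proba = clf.predict_proba(z_obs.reshape(1, -1))[0]
    out = {s: 0.0 for s in all_ids}
    for cls, p in zip(clf.classes_, proba):
        out[str(cls)] = float(p)
    return out


def model_choice(
    ref: ReferenceTable,
    observed: np.ndarray,
    tolerance: float = 0.01,
    bootstrap_B: int = 100,
    seed: int = 0,
) -> ModelChoiceResult:
    """Posterior probability of each scenario given the observed statistics.

    The direct estimate is each scenario's share of the retained rows.  The
    logistic estimate fits a multinomial logistic regression of scenario
    label on standardized statistics over the retained rows, weighted by the
    Epanechnikov kernel w = 1 - (d / d_max)^2, and evaluates it at the
    observed vector.  95% CIs come from ``bootstrap_B`` percentile bootstrap
    resamples of the retained rows (``bootstrap_B = 0`` skips them).
    """
    all_ids = ref.scenarios
    if len(all_ids) < 2:
        raise ValueError("model choice needs at least 2 scenarios")
    idx, dist = reject(ref, observed, tolerance)
    labels = ref.scenario_ids[idx]
    z = ref.standardize(ref.stats[idx])
    z_obs = ref.standardize(observed)[0]
    w = _epanechnikov(dist[idx])
    direct = {s: float((labels == s).mean()) for s in all_ids}
    missing = [s for s in all_ids if direct[s] == 0]
    if missing:
        warnings.warn(f"scenarios absent from retained rows: {missing}")
    pp = _logistic_pp(z, labels, w, z_obs, all_ids)

    ci: dict[str, tuple[float, float]] = {}
    if bootstrap_B > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((bootstrap_B, len(all_ids)))
        for b in range(bootstrap_B):
            take = rng.integers(len(idx), size=len(idx))
            pp_b = _logistic_pp(z[take], labels[take], w[take], z_obs, all_ids)
            boot[b] = [pp_b[s] for s in all_ids]
        lo = np.percentile(boot, 2.5, axis=0)
        hi = np.percentile(boot, 97.5, axis=0)
        for j, s in enumerate(all_ids):
            ci[s] = (
                float(min(lo[j], pp[s]) * 100.0),
                float(max(hi[j], pp[s]) * 100.0),
            )
    return ModelChoiceResult(
        scenario_ids=all_ids,
        pp={s: float(pp[s] * 100.0) for s in all_ids},
        ci=ci,
        direct=direct,
        retained_indices=idx,
        distances=dist,
    )


# ---------------------------------------------------------------------------
# scenario selection rule
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    selected: str
    selected_pp: float
    ranking: list[str]
    ci_overlaps_runner_up: bool | None
    winner_minimizes_outliers: bool | None
    trace: list[str]


def select_best_scenario(results: dict[str, dict]) -> SelectionResult:
    """Apply the scenario-selection rule to per-scenario summaries.

    ``results`` maps scenario id to a dict with ``pp`` (percent), optional
    ``ci`` (percent bounds) and optional ``n_outlying`` (total count of
    significantly deviating summary statistics).  The winner is the scenario
    with the highest posterior probability; exact Pp ties go to the fewest
    outlying statistics, then to input order.  The report flags whether the
    winner's CI overlaps the runner-up's and whether it also minimizes the
    outlier count.
    """
    if len(results) < 2:
        raise ValueError("selection needs at least 2 scenarios")
    ids = list(results)
    order = {s: i for i, s in enumerate(ids)}

    def key(s: str):
        out = results[s].get("n_outlying")
        return (-results[s]["pp"], np.inf if out is None else out, order[s])

    ranking = sorted(ids, key=key)
    winner, runner_up = ranking[0], ranking[1]
    trace = [f"rank {i + 1}: {s} (Pp {results[s]['pp']:g}%)" for i, s in enumerate(ranking)]

    ci_overlap = None
    if results[winner].get("ci") and results[runner_up].get("ci"):
        lo_w, hi_w = results[winner]["ci"]
        lo_r, hi_r = results[runner_up]["ci"]
        ci_overlap = lo_w <= hi_r and lo_r <= hi_w
        trace.append(
            f"95% CI of {winner} {'overlaps' if ci_overlap else 'does not overlap'} "
            f"that of {runner_up}"
        )
    outliers = {s: results[s].get("n_outlying") for s in ids}
    min_out = None
    if all(v is not None for v in outliers.values()):
        min_out = outliers[winner] == min(outliers.values())
        trace.append(
            f"{winner} {'also minimizes' if min_out else 'does not minimize'} "
            f"the outlying-statistic count"
        )
    return SelectionResult(
        selected=winner,
        selected_pp=float(results[winner]["pp"]),
        ranking=ranking,
        ci_overlaps_runner_up=ci_overlap,
        winner_minimizes_outliers=min_out,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# parameter adjustment
# ---------------------------------------------------------------------------


def adjust_parameters(
    ref: ReferenceTable,
    observed: np.ndarray,
    scenario: Scenario,
    priors: PriorSpec,
    tolerance: float = 0.01,
) -> pd.DataFrame:
    """Local-linear regression posterior sample for one scenario's parameters.

    Retained rows of the scenario are corrected toward the observed point:
    each parameter is logit-transformed to its prior bounds [a, b] via
    ln((x - a)/(b - x)), regressed (weighted least squares, Epanechnikov
    weights) on standardized statistics, shifted by -b' (S_i - s_obs), and
    back-transformed — so every adjusted value lies strictly inside its
    prior bounds.  Point-prior parameters pass through unchanged.
    """
    idx, dist = reject(ref, observed, tolerance)
    keep = ref.scenario_ids[idx] == scenario.id
    rows = idx[keep]
    z = ref.standardize(ref.stats[rows])
    n_stats = z.shape[1]
    if len(rows) < n_stats + 2:
        raise ValueError(
            f"only {len(rows)} retained rows for {scenario.id}; "
            f"need at least {n_stats + 2}"
        )
    w = _epanechnikov(dist[idx])[keep]
    z_obs = ref.standardize(observed)[0]
    delta = z - z_obs
    design = np.column_stack([np.ones(len(rows)), delta])
    sw = np.sqrt(w)
    out: dict[str, np.ndarray] = {}
    for name in scenario.parameter_names():
        theta = ref.params[name].to_numpy(dtype=float)[rows]
        a, b = priors.priors[name].low, priors.priors[name].high
        if a == b:
            out[name] = theta
            continue
        eps = 1e-9 * (b - a)
        clipped = np.clip(theta, a + eps, b - eps)
        t = np.log((clipped - a) / (b - clipped))
        beta, *_ = np.linalg.lstsq(design * sw[:, None], t * sw, rcond=None)
        t_star = t - delta @ beta[1:]
        out[name] = a + (b - a) / (1.0 + np.exp(-t_star))
    df = pd.DataFrame(out)
    df.attrs["weights"] = w
    return df


# ---------------------------------------------------------------------------
# confusion analysis
# ---------------------------------------------------------------------------


@dataclass
class ConfusionReport:
    """Scenario-choice error rates from pseudo-observed datasets."""

    scenario_ids: list[str]
    confusion: pd.DataFrame  # rows: true scenario; columns: chosen scenario
    type_i: dict[str, float]
    type_ii: dict[str, float]
    performance: float

    def mean_error(self) -> float:
        """Mean of all per-scenario type I and type II error rates."""
        rates = list(self.type_i.values()) + list(self.type_ii.values())
        return float(np.mean(rates))


def confusion_analysis(
    scenarios: list[Scenario],
    priors: PriorSpec | dict[str, PriorSpec],
    diploid_counts: dict[str, int],
    n_loci: int,
    n_pods_per_scenario: int,
    tolerance: float = 0.01,
    seed: int = 0,
    ref: ReferenceTable | None = None,
    n_sims_per_scenario: int = 1000,
    min_maf: float = 0.05,
) -> ConfusionReport:
    """Estimate type I/II scenario-choice error rates.

    ``n_pods_per_scenario`` pseudo-observed datasets are simulated per
    scenario from its priors and each is classified by the highest logistic
    posterior probability against the reference table (built here with
    ``n_sims_per_scenario`` rows per scenario unless supplied).

    type I(s): fraction of pods generated under s not assigned to s;
    type II(s): fraction of pods generated under other scenarios assigned
    to s; performance: overall fraction classified correctly.
    """
    ss = np.random.SeedSequence(seed).generate_state(4)
    if ref is None:
        ref = build_reference_table(
            scenarios, priors, diploid_counts, n_loci,
            n_sims_per_scenario, int(ss[0]), min_maf=min_maf,
        )
    ids = [s.id for s in scenarios]
    pops = list(diploid_counts)
    counts = pd.DataFrame(0, index=ids, columns=ids)
    pod_seeds = np.random.SeedSequence(int(ss[1])).generate_state(
        2 * len(scenarios) * n_pods_per_scenario
    )
    k = 0
    for s in scenarios:
        spec = priors[s.id] if isinstance(priors, dict) else priors
        for _ in range(n_pods_per_scenario):
            params = draw_parameters(
                s, spec, np.random.default_rng(pod_seeds[2 * k])
            )
            pod = simulate_dataset(
                s, params, diploid_counts, n_loci,
                np.random.default_rng(pod_seeds[2 * k + 1]), min_maf=min_maf,
            )
            obs = summary_vector(pod, pops)
            with warnings.catch_warnings():
                # pods from well-separated models routinely leave the wrong
                # scenarios out of the retained set; that is the point here
                warnings.filterwarnings(
                    "ignore", message="scenarios absent from retained rows"
                )
                res = model_choice(ref, obs, tolerance, bootstrap_B=0)
            counts.loc[s.id, res.best] += 1
            k += 1
    n_pods = n_pods_per_scenario
    type_i = {s: float(1.0 - counts.loc[s, s] / n_pods) for s in ids}
    type_ii = {
        s: float(
            (counts[s].sum() - counts.loc[s, s]) / (n_pods * (len(ids) - 1))
        )
        for s in ids
    }
    performance = float(np.trace(counts.to_numpy()) / counts.to_numpy().sum())
    return ConfusionReport(
        scenario_ids=ids, confusion=counts,
        type_i=type_i, type_ii=type_ii, performance=performance,
    )


# ---------------------------------------------------------------------------
# model checking
# ---------------------------------------------------------------------------


@dataclass
class ModelCheckReport:
    """Posterior-predictive goodness-of-fit of one selected scenario."""

    stat_names: list[str]
    tail_probabilities: dict[str, float]
    n_outlying_05: int
    n_outlying_01: int
    pca_reference: np.ndarray
    pca_predictive: np.ndarray
    pca_observed: np.ndarray


def model_check(
    scenario: Scenario,
    posterior_sample: pd.DataFrame,
    diploid_counts: dict[str, int],
    n_loci: int,
    n_ppc: int,
    observed: np.ndarray,
    seed: int = 0,
    ref: ReferenceTable | None = None,
    min_maf: float = 0.05,
) -> ModelCheckReport:
    """Posterior predictive check of the selected scenario.

    ``n_ppc`` datasets are simulated with parameter rows resampled from the
    posterior sample; each summary statistic gets a two-sided tail
    probability p = 2 min(F(s_obs), 1 - F(s_obs)) under the posterior
    predictive empirical CDF, and the counts of statistics outlying at
    p < 0.05 and p < 0.01 are reported.  When a reference table is supplied,
    reference, predictive and observed points are projected on the top two
    principal components of the standardized reference statistics.
    """
    rng = np.random.default_rng(seed)
    pops = list(diploid_counts)
    names = stat_names(pops)
    sims = np.empty((n_ppc, len(names)))
    for i in range(n_ppc):
        row = posterior_sample.iloc[int(rng.integers(len(posterior_sample)))]
        params: ParameterDraw = row.to_dict()
        g = simulate_dataset(scenario, params, diploid_counts, n_loci,
                             rng, min_maf=min_maf)
        sims[i] = summary_vector(g, pops)
    tails = {}
    for j, name in enumerate(names):
        f = float((sims[:, j] <= observed[j]).mean())
        tails[name] = 2.0 * min(f, 1.0 - f)
    n05 = sum(p < 0.05 for p in tails.values())
    n01 = sum(p < 0.01 for p in tails.values())

    pca_ref = pca_ppc = pca_obs = np.empty((0, 2))
    if ref is not None:
        z_ref = ref.standardize(ref.stats)
        zc = z_ref - z_ref.mean(axis=0)
        _, _, vt = np.linalg.svd(zc, full_matrices=False)
        comps = vt[:2].T
        pca_ref = zc @ comps
        pca_ppc = (ref.standardize(sims) - z_ref.mean(axis=0)) @ comps
        pca_obs = (ref.standardize(observed) - z_ref.mean(axis=0)) @ comps
    return ModelCheckReport(
        stat_names=names,
        tail_probabilities=tails,
        n_outlying_05=n05,
        n_outlying_01=n01,
        pca_reference=pca_ref,
        pca_predictive=pca_ppc,
        pca_observed=pca_obs,
    )
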
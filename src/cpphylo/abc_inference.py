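"""Approximate Bayesian computation over competing demographic scenarios.

Five demographic scenarios for three terminal lineages of a cloud-forest
tree (north, central, south), mirroring a classic three-population
divergence/admixture model space:

1. simultaneous divergence of the three lineages from one ancestor at t2
   (stable model);
2. split of north from central at t1, both joining south's ancestor at t2;
3. split of south from north at t1, both joining central's ancestor at t2;
4. split of south from central at t1, both joining north's ancestor at t2;
5. the north lineage formed by secondary contact (admixture, rate r)
   between central and south at t1, which themselves diverged at t2.

Times are in generations with the prior condition t2 >= t1; effective
sizes are haploid copy numbers (cpDNA convention, see
:mod:`cpphylo.coalescent`).  Inference follows the standard ABC recipe:
a reference table of simulations from the priors, rejection on
MAD-standardised Euclidean distance, multinomial logistic regression for
scenario posterior probabilities, pseudo-observed datasets (PODs) for
type I/II error rates, and Beaumont-style local-linear adjustment for
parameter posteriors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .alignment import Alignment
from .coalescent import EQUAL_FREQS, Event, hky_site_matrix, simulate_genealogy

logger = logging.getLogger(__name__)

GROUPS = ("north", "central", "south")
#: study sampling design: n per lineage
DEFAULT_SAMPLES = {"north": 17, "central": 74, "south": 5}
DEFAULT_LOCUS_LENGTH = 2858
#: per-site per-year substitution rate typical of angiosperm cpDNA
MUTATION_RATE_PER_YEAR = 1.59e-9
GENERATION_TIME_YEARS = 10.0
MUTATION_RATE_PER_GEN = MUTATION_RATE_PER_YEAR * GENERATION_TIME_YEARS

SCENARIO_IDS = (1, 2, 3, 4, 5)
PARAM_NAMES = ("Na", "N1", "N2", "N3", "t1", "t2", "r")


@dataclass
class PriorSpec:
    """Independent uniform priors with the ordering condition t2 >= t1."""

    size_bounds: tuple[float, float] = (10.0, 100_000.0)
    time_bounds: tuple[float, float] = (100.0, 100_000.0)
    admixture_bounds: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        for lo, hi in (self.size_bounds, self.time_bounds, self.admixture_bounds):
            if not 0 < lo < hi:
                raise ValueError("prior bounds must be positive and increasing")


def draw_priors(
    spec: PriorSpec, scenario: int, rng: np.random.Generator
) -> dict[str, float]:
    """Draw one parameter vector; t2 >= t1 is enforced by rejection."""
    lo_n, hi_n = spec.size_bounds
    lo_t, hi_t = spec.time_bounds
    params = {name: float(rng.uniform(lo_n, hi_n)) for name in ("Na", "N1", "N2", "N3")}
    while True:
        t1 = float(rng.uniform(lo_t, hi_t))
        t2 = float(rng.uniform(lo_t, hi_t))
        if t2 >= t1:
            break
    params["t1"], params["t2"] = t1, t2
    params["r"] = (
        float(rng.uniform(*spec.admixture_bounds)) if scenario == 5 else np.nan
    )
    return params


def prior_midpoints(spec: PriorSpec, scenario: int) -> dict[str, float]:
    """Central parameter values of the constrained prior.

    For sizes these are the plain interval midpoints; for the event times
    they are the means of (t1, t2) under the uniform prior restricted to
    t2 >= t1 (1/3 and 2/3 of the way through the interval), because the
    unconstrained midpoints would be equal and collapse several scenarios
    onto each other.
    """
    lo_n, hi_n = spec.size_bounds
    lo_t, hi_t = spec.time_bounds
    mid_n = (lo_n + hi_n) / 2.0
    params = {name: mid_n for name in ("Na", "N1", "N2", "N3")}
    params["t1"] = lo_t + (hi_t - lo_t) / 3.0
    params["t2"] = lo_t + 2.0 * (hi_t - lo_t) / 3.0
    params["r"] = (
        float(np.mean(PriorSpec().admixture_bounds)) if scenario == 5 else np.nan
    )
    return params


def scenario_events(scenario: int, params: Mapping[str, float]) -> tuple[dict[str, float], list[Event]]:
    """Population sizes and backward-time event list for one scenario.

    The most recent split retains the parent lineage's terminal size; the
    oldest event merges everything into the common ancestor of size Na.
    """
    t1, t2 = params["t1"], params["t2"]
    if t2 < t1:
        raise ValueError("scenario requires t2 >= t1")
    sizes = {
        "north": params["N1"], "central": params["N2"], "south": params["N3"],
        "ancestor": params["Na"],
    }
    if scenario == 1:
        events = [Event("merge", t2, "ancestor", ("north", "central", "south"))]
    elif scenario == 2:
        events = [
            Event("merge", t1, "central", ("north",)),
            Event("merge", t2, "ancestor", ("central", "south")),
        ]
    elif scenario == 3:
        events = [
            Event("merge", t1, "north", ("south",)),
            Event("merge", t2, "ancestor", ("north", "central")),
        ]
    elif scenario == 4:
        events = [
            Event("merge", t1, "central", ("south",)),
            Event("merge", t2, "ancestor", ("central", "north")),
        ]
    elif scenario == 5:
        r = params["r"]
        if not 0.0 < r < 1.0:
            raise ValueError("scenario 5 needs an admixture rate in (0, 1)")
        events = [
            Event("admixture", t1, "north", ("central", "south"), rate=r),
            Event("merge", t2, "ancestor", ("central", "south")),
        ]
    else:
        raise ValueError(f"unknown scenario {scenario}")
    return sizes, events


def simulate_dataset(
    scenario: int,
    params: Mapping[str, float],
    rng: np.random.Generator,
    samples: Mapping[str, int] = DEFAULT_SAMPLES,
    L: int = DEFAULT_LOCUS_LENGTH,
    mu: float = MUTATION_RATE_PER_GEN,
    kappa: float = 2.0,
    freqs: Sequence[float] = EQUAL_FREQS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one dataset; returns (positions, codes, group_index).

    ``codes`` is the (n_tips, n_mutated_sites) base matrix from
    :func:`cpphylo.coalescent.hky_site_matrix`; ``group_index`` assigns
    each tip to 0=north, 1=central, 2=south.
    """
    sizes, events = scenario_events(scenario, params)
    tree = simulate_genealogy(dict(samples), sizes, events, rng)
    positions, codes = hky_site_matrix(tree, L, mu, rng, kappa, freqs)
    group_index = np.asarray([GROUPS.index(p) for p in tree.tip_pops])
    return positions, codes, group_index


def simulated_alignment(
    scenario: int,
    params: Mapping[str, float],
    rng: np.random.Generator,
    samples: Mapping[str, int] = DEFAULT_SAMPLES,
    L: int = DEFAULT_LOCUS_LENGTH,
    mu: float = MUTATION_RATE_PER_GEN,
    kappa: float = 2.0,
    freqs: Sequence[float] = EQUAL_FREQS,
) -> tuple[Alignment, list[str]]:
    """Full gap-free alignment version of :func:`simulate_dataset`.

    Monomorphic background sites are drawn from the stationary base
    frequencies; mutated columns come from the genealogy.  Returns the
    alignment and the per-sample group labels.
    """
    positions, codes, group_index = simulate_dataset(
        scenario, params, rng, samples, L, mu, kappa, freqs
    )
    n = group_index.size
    bases = np.array(list("ACGT"))
    background = rng.choice(4, size=L, p=np.asarray(freqs))
    mat = np.tile(bases[background], (n, 1))
    for k, pos in enumerate(positions):
        mat[:, pos] = bases[codes[:, k]]
    ids = [f"{GROUPS[g]}_{i + 1:03d}" for i, g in enumerate(group_index)]
    aln = Alignment.from_matrix(ids, mat)
    labels = [GROUPS[g] for g in group_index]
    return aln, labels


# ---------------------------------------------------------------------------
# summary statistics


STAT_NAMES = tuple(
    [f"{s}_{g}" for g in ("1", "2", "3") for s in ("S", "kbar", "rare")]
    + [f"{s}_{p}" for p in ("12", "13", "23") for s in ("Spair", "fst")]
)


def _group_site_counts(codes: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(4, n_sites) base counts within the tip subset ``mask``."""
    sub = codes[mask]
    return np.stack([(sub == b).sum(axis=0) for b in range(4)])


def summarize(codes: np.ndarray, group_index: np.ndarray) -> np.ndarray:
    """DIYABC-style summary statistics from a site matrix.

    Per group: number of segregating sites S, mean pairwise differences
    kbar, and the mean (over the group's segregating sites) of the
    relative frequency of the rarest base.  Per group pair: pooled S and a
    Hudson-type F_ST = 1 - (mean within) / (mean between), clamped to
    [-1, 1] and set to 0 when there is no between-group variation.
    Groups with < 2 samples get within-group statistics of 0 (flagged by
    the caller's design; the study's smallest lineage still has n = 5).
    """
    stats: list[float] = []
    counts_by_group = []
    n_by_group = []
    for g in range(3):
        mask = group_index == g
        n_g = int(mask.sum())
        n_by_group.append(n_g)
        cnt = _group_site_counts(codes, mask)
        counts_by_group.append(cnt)
        if n_g < 2 or codes.shape[1] == 0:
            stats.extend([0.0, 0.0, 0.0])
            continue
        present = cnt > 0
        seg = present.sum(axis=0) >= 2
        S_g = int(seg.sum())
        pairs = n_g * (n_g - 1) / 2.0
        same = (cnt * (cnt - 1) / 2.0).sum(axis=0)
        kbar = float((pairs - same).sum() / pairs)
        if S_g:
            with np.errstate(invalid="ignore"):
                rare = np.where(present[:, seg], cnt[:, seg], np.inf).min(axis=0) / n_g
            rare_mean = float(rare.mean())
        else:
            rare_mean = 0.0
        stats.extend([float(S_g), kbar, rare_mean])

    for a, b in ((0, 1), (0, 2), (1, 2)):
        cnt_a, cnt_b = counts_by_group[a], counts_by_group[b]
        n_a, n_b = n_by_group[a], n_by_group[b]
        if codes.shape[1] == 0 or n_a == 0 or n_b == 0:
            stats.extend([0.0, 0.0])
            continue
        pooled = cnt_a + cnt_b
        S_pair = int(((pooled > 0).sum(axis=0) >= 2).sum())
        # within/between mean pairwise differences
        def _kbar(cnt: np.ndarray, n: int) -> float:
            if n < 2:
                return np.nan
            pairs = n * (n - 1) / 2.0
            same = (cnt * (cnt - 1) / 2.0).sum(axis=0)
            return float((pairs - same).sum() / pairs)

        between = float(
            (1.0 - (cnt_a / n_a * (cnt_b / n_b)).sum(axis=0)).sum()
        )
        withins = [v for v in (_kbar(cnt_a, n_a), _kbar(cnt_b, n_b)) if not np.isnan(v)]
        within = float(np.mean(withins)) if withins else 0.0
        if between <= 0:
            fst = 0.0
        else:
            fst = float(np.clip(1.0 - within / between, -1.0, 1.0))
        stats.extend([float(S_pair), fst])
    return np.asarray(stats)


def summarize_alignment(aln: Alignment, lineages: Sequence[str]) -> np.ndarray:
    """Summary statistics of an observed gap-free alignment."""
    mat = aln.to_matrix()
    code = np.zeros(mat.shape, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code[mat == b] = i
    variable = np.array([np.unique(col).size > 1 for col in code.T])
    group_index = np.asarray([GROUPS.index(l) for l in lineages])
    return summarize(code[:, variable], group_index)


def empirical_base_freqs(aln: Alignment) -> tuple[float, float, float, float]:
    mat = aln.to_matrix()
    freqs = np.array([(mat == b).mean() for b in "ACGT"])
    return tuple(freqs / freqs.sum())  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# reference table


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Counter-based substream: independent of execution order."""
    return np.random.default_rng([seed, *key])


def build_reference_table(
    n_sims: int,
    seed: int,
    scenarios: Sequence[int] = SCENARIO_IDS,
    prior_spec: PriorSpec | None = None,
    samples: Mapping[str, int] = DEFAULT_SAMPLES,
    L: int = DEFAULT_LOCUS_LENGTH,
    mu: float = MUTATION_RATE_PER_GEN,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Simulate the ABC reference table: (scenario, params, summary stats).

    Reproducible given ``seed``: each simulation uses the counter-derived
    substream ``(seed, scenario, index)`` so serial and resumed runs
    agree.  When ``out_path`` is given, each scenario's block is written
    to ``<out_path>.scenario<k>.tsv`` as it completes and re-used on
    rerun (resumability).
    """
    spec = prior_spec if prior_spec is not None else PriorSpec()
    frames = []
    for sc in scenarios:
        chunk_path = Path(f"{out_path}.scenario{sc}.tsv") if out_path else None
        if chunk_path is not None and chunk_path.exists():
            block = pd.read_csv(chunk_path, sep="\t")
            if len(block) == n_sims:
                logger.info("reference table: reusing %s", chunk_path)
                frames.append(block)
                continue
        rows = np.empty((n_sims, len(PARAM_NAMES) + len(STAT_NAMES)))
        for i in range(n_sims):
            rng = _substream(seed, sc, i)
            params = draw_priors(spec, sc, rng)
            _, codes, gidx = simulate_dataset(sc, params, rng, samples, L, mu)
            rows[i, : len(PARAM_NAMES)] = [params[p] for p in PARAM_NAMES]
            rows[i, len(PARAM_NAMES):] = summarize(codes, gidx)
        block = pd.DataFrame(rows, columns=list(PARAM_NAMES) + list(STAT_NAMES))
        block.insert(0, "scenario", sc)
        if chunk_path is not None:
            block.to_csv(chunk_path, sep="\t", index=False)
        frames.append(block)
        logger.info("reference table: scenario %d done (%d sims)", sc, n_sims)
    table = pd.concat(frames, ignore_index=True)
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table


# ---------------------------------------------------------------------------
# model choice


@dataclass
class ModelChoiceResult:
    posterior: pd.Series  # PP per scenario (logistic regression)
    ci_low: pd.Series
    ci_high: pd.Series
    rejection: pd.Series  # simple accepted-fraction estimate
    chosen: int
    n_accepted: int


def _standardise(stats: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    med = np.median(ref, axis=0)
    mad = np.median(np.abs(ref - med), axis=0)
    mad = np.where(mad > 0, mad, 1.0)
    return (stats - med) / mad, med, mad


def model_choice(
    observed: np.ndarray,
    table: pd.DataFrame,
    tolerance: float = 0.01,
    seed: int | None = None,
    n_boot_ci: int = 100,
) -> ModelChoiceResult:
    """Scenario posterior probabilities by rejection + logistic regression.

    Statistics are standardised by table-wide median absolute deviation;
    the nearest ``tolerance`` fraction of simulations (Euclidean distance)
    is retained; a multinomial logistic regression of the scenario
    indicator on the summary statistics, weighted by an Epanechnikov
    kernel in the distance, is evaluated at the observed point.  95%
    confidence intervals come from a seeded bootstrap over the accepted
    set; the plain rejection (accepted-fraction) estimate is also
    reported.  Scenarios absent from the accepted set get PP 0 with a
    warning.
    """
    stats_ref = table[list(STAT_NAMES)].to_numpy()
    z_ref, med, mad = _standardise(stats_ref, stats_ref)
    z_obs = (np.asarray(observed) - med) / mad
    dist = np.sqrt(((z_ref - z_obs) ** 2).sum(axis=1))
    n_keep = max(int(np.ceil(tolerance * len(table))), 20)
    order = np.argsort(dist, kind="stable")[:n_keep]
    d_max = dist[order].max() or 1.0
    weights = 1.0 - (dist[order] / d_max) ** 2
    weights = np.clip(weights, 1e-8, None)
    y = table["scenario"].to_numpy()[order]
    X = z_ref[order]

    scenarios = sorted(table["scenario"].unique())
    rejection = pd.Series(
        [float((y == sc).mean()) for sc in scenarios], index=scenarios
    )
    missing = [sc for sc in scenarios if sc not in set(y)]
    if missing:
        logger.warning("scenarios absent from the accepted set: %s", missing)

    def _fit_predict(Xa: np.ndarray, ya: np.ndarray, wa: np.ndarray) -> pd.Series:
        present = sorted(set(ya))
        if len(present) == 1:
            return pd.Series([1.0 if sc == present[0] else 0.0 for sc in scenarios],
                             index=scenarios)
        clf = LogisticRegression(max_iter=2000, C=1e3)
        clf.fit(Xa, ya, sample_weight=wa)
        probs = clf.predict_proba(z_obs.reshape(1, -1))[0]
        out = pd.Series(0.0, index=scenarios)
        for cls, p in zip(clf.classes_, probs):
            out[cls] = p
        return out

    posterior = _fit_predict(X, y, weights)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot_ci):
        idx = rng.integers(0, n_keep, size=n_keep)
        boots.append(_fit_predict(X[idx], y[idx], weights[idx]))
    bmat = pd.concat(boots, axis=1).to_numpy() if boots else posterior.to_numpy()[:, None]
    ci_low = pd.Series(np.quantile(bmat, 0.025, axis=1), index=scenarios)
    ci_high = pd.Series(np.quantile(bmat, 0.975, axis=1), index=scenarios)
    chosen = int(posterior.idxmax())
    return ModelChoiceResult(posterior, ci_low, ci_high, rejection, chosen, n_keep)


def pod_error_rates(
    table: pd.DataFrame,
    n_pods: int,
    seed: int,
    prior_spec: PriorSpec | None = None,
    scenarios: Sequence[int] = SCENARIO_IDS,
    samples: Mapping[str, int] = DEFAULT_SAMPLES,
    L: int = DEFAULT_LOCUS_LENGTH,
    mu: float = MUTATION_RATE_PER_GEN,
    tolerance: float = 0.01,
    method: str = "rejection",
) -> pd.DataFrame:
    """Type I / type II error rates from pseudo-observed datasets.

    ``n_pods`` PODs per scenario are simulated from the priors and each is
    classified (``method``: "rejection" takes the accepted-set plurality,
    "logistic" refits the regression per POD).  Type I for scenario k is
    the fraction of k's PODs not assigned to k; type II the fraction of
    other scenarios' PODs assigned to k.  Also returns the full confusion
    matrix as extra columns ``assigned_<j>``.
    """
    spec = prior_spec if prior_spec is not None else PriorSpec()
    confusion = pd.DataFrame(0, index=list(scenarios), columns=list(scenarios))
    for sc in scenarios:
        for i in range(n_pods):
            rng = _substream(seed, 1000 + sc, i)
            params = draw_priors(spec, sc, rng)
            _, codes, gidx = simulate_dataset(sc, params, rng, samples, L, mu)
            obs = summarize(codes, gidx)
            if method == "logistic":
                choice = model_choice(obs, table, tolerance, seed=0, n_boot_ci=0).chosen
            else:
                choice = _rejection_choice(obs, table, tolerance)
            confusion.loc[sc, choice] += 1
    rates = pd.DataFrame(index=list(scenarios))
    totals = confusion.sum(axis=1)
    rates["type_I"] = 1.0 - np.diag(confusion) / totals
    n_total = confusion.to_numpy().sum()
    type2 = []
    for sc in scenarios:
        others = confusion.drop(index=sc)
        type2.append(others[sc].sum() / others.to_numpy().sum())
    rates["type_II"] = type2
    for sc in scenarios:
        rates[f"assigned_{sc}"] = confusion[sc] / totals
    return rates


def _rejection_choice(observed: np.ndarray, table: pd.DataFrame, tolerance: float) -> int:
    stats_ref = table[list(STAT_NAMES)].to_numpy()
    z_ref, med, mad = _standardise(stats_ref, stats_ref)
    z_obs = (np.asarray(observed) - med) / mad
    dist = ((z_ref - z_obs) ** 2).sum(axis=1)
    n_keep = max(int(np.ceil(tolerance * len(table))), 20)
    order = np.argpartition(dist, n_keep)[:n_keep]
    y = table["scenario"].to_numpy()[order]
    vals, counts = np.unique(y, return_counts=True)
    return int(vals[counts.argmax()])


# ---------------------------------------------------------------------------
# parameter estimation


@dataclass
class ParameterPosterior:
    scenario: int
    summary: pd.DataFrame  # rows: parameters; cols: mean, median, q2.5, q97.5
    adjusted: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]
    fallback_rejection: bool = False


LOG_PARAMS = ("Na", "N1", "N2", "N3", "t1", "t2")


def estimate_parameters(
    observed: np.ndarray,
    table: pd.DataFrame,
    scenario: int,
    tolerance: float = 0.01,
    prior_spec: PriorSpec | None = PriorSpec(),
) -> ParameterPosterior:
    """Beaumont-style local-linear ABC posterior for one scenario.

    Sizes and times are regression-adjusted on a log scale within the
    accepted set using Epanechnikov weights; the admixture rate (scenario
    5) on its natural scale.  A singular regression falls back to the
    unadjusted rejection posterior with a warning.  Times are reported in
    generations and in years (10-year generation time).
    """
    sub = table[table["scenario"] == scenario]
    if sub.empty:
        raise ValueError(f"scenario {scenario} absent from the table")
    stats_ref = sub[list(STAT_NAMES)].to_numpy()
    z_ref, med, mad = _standardise(stats_ref, stats_ref)
    z_obs = (np.asarray(observed) - med) / mad
    dist = np.sqrt(((z_ref - z_obs) ** 2).sum(axis=1))
    n_keep = max(int(np.ceil(tolerance * len(sub))), 20)
    order = np.argsort(dist, kind="stable")[:n_keep]
    d_max = dist[order].max() or 1.0
    w = np.clip(1.0 - (dist[order] / d_max) ** 2, 1e-8, None)

    names = [p for p in PARAM_NAMES if not sub[p].isna().all()]
    theta = sub[names].to_numpy()[order]
    transformed = theta.copy()
    for j, name in enumerate(names):
        if name in LOG_PARAMS:
            transformed[:, j] = np.log(theta[:, j])

    X = np.column_stack([np.ones(n_keep), z_ref[order]])
    sw = np.sqrt(w)
    fallback = False
    try:
        beta, *_ = np.linalg.lstsq(X * sw[:, None], transformed * sw[:, None], rcond=None)
        cond = np.linalg.cond(X * sw[:, None])
        if not np.isfinite(cond) or cond > 1e10:
            raise np.linalg.LinAlgError("ill-conditioned design")
        x_obs = np.concatenate([[1.0], z_obs])
        fitted_obs = x_obs @ beta
        residuals = transformed - X @ beta
        adjusted = fitted_obs + residuals
    except np.linalg.LinAlgError:
        logger.warning("singular local-linear regression; using rejection posterior")
        adjusted = transformed
        fallback = True

    back = adjusted.copy()
    for j, name in enumerate(names):
        if name in LOG_PARAMS:
            back[:, j] = np.exp(adjusted[:, j])
    if prior_spec is not None:
        # regression adjustment is unconstrained; truncate to the prior support
        bounds = {
            "Na": prior_spec.size_bounds, "N1": prior_spec.size_bounds,
            "N2": prior_spec.size_bounds, "N3": prior_spec.size_bounds,
            "t1": prior_spec.time_bounds, "t2": prior_spec.time_bounds,
            "r": prior_spec.admixture_bounds,
        }
        for j, name in enumerate(names):
            lo, hi = bounds[name]
            back[:, j] = np.clip(back[:, j], lo, hi)
    adj_df = pd.DataFrame(back, columns=names)
    adj_df["weight"] = w

    def _wq(x: np.ndarray, q: float) -> float:
        order_x = np.argsort(x)
        cw = np.cumsum(w[order_x])
        return float(np.interp(q * cw[-1], cw, x[order_x]))

    rows = {}
    for name in names:
        x = adj_df[name].to_numpy()
        rows[name] = {
            "mean": float(np.average(x, weights=w)),
            "median": _wq(x, 0.5),
            "q2.5": _wq(x, 0.025),
            "q97.5": _wq(x, 0.975),
        }
    summary = pd.DataFrame(rows).T
    for tname in ("t1", "t2"):
        if tname in summary.index:
            years = summary.loc[tname] * GENERATION_TIME_YEARS
            years.name = f"{tname}_years"
            summary = pd.concat([summary, years.to_frame().T])
    return ParameterPosterior(scenario, summary, adj_df, fallback)


def model_check_pca(
    observed: np.ndarray,
    table: pd.DataFrame,
    n_sample: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Project a table subsample and the observed point on the first 2 PCs.

    Returns a DataFrame with columns pc1, pc2, scenario ("observed" for
    the observed point), for goodness-of-fit visualisation.
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table), size=min(n_sample, len(table)), replace=False)
    stats_ref = table[list(STAT_NAMES)].to_numpy()[idx]
    z_ref, med, mad = _standardise(stats_ref, stats_ref)
    if np.allclose(z_ref.var(axis=0), 0):
        raise ValueError("degenerate covariance: no variance in summary statistics")
    pca = PCA(n_components=2, random_state=0)
    coords = pca.fit_transform(z_ref)
    z_obs = (np.asarray(observed) - med) / mad
    obs_coords = pca.transform(z_obs.reshape(1, -1))
    df = pd.DataFrame(coords, columns=["pc1", "pc2"])
    df["scenario"] = table["scenario"].to_numpy()[idx].astype(str)
    obs_row = pd.DataFrame(
        {"pc1": obs_coords[0, 0], "pc2": obs_coords[0, 1], "scenario": "observed"},
        index=[len(df)],
    )
    return pd.concat([df, obs_row])
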
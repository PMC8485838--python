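"""Diversity, differentiation and spatial-structure statistics.

Implements the classical haplotype-frequency and distance-based machinery
for organelle data:

* Nei's haplotype (gene) diversity with its sampling variance, and
  nucleotide diversity as the mean pairwise per-site p-distance.
* Tamura-Nei (1993) pairwise distances, with a logged fall-back to the
  p-distance when a logarithm argument is non-positive.
* AMOVA (Excoffier, Smouse & Quattro 1992): 1-, 2- and 3-level variance
  decompositions from squared molecular distances, with the
  stratum-appropriate permutation schemes for F_ST, F_SC and F_CT.
* Pons & Petit (1996) G_ST / N_ST with the permutation test for
  phylogeographic structure (N_ST > G_ST).
* A seeded Mantel test for isolation by distance.

All permutation engines take explicit seeds and report p-values with the
(b + 1) / (B + 1) convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# diversity


@dataclass
class DiversityResult:
    n: int
    n_haplotypes: int | None = None
    hd: float | None = None
    hd_sd: float | None = None
    pi: float | None = None


def haplotype_diversity(counts: Sequence[int]) -> DiversityResult:
    """Nei's unbiased gene diversity Hd = n/(n-1) (1 - sum p_i^2).

    The sampling standard deviation follows Nei (1987, eq. 8.12):
    V(Hd) = 2/(n(n-1)) { 2(n-2)[sum p^3 - (sum p^2)^2] + sum p^2 - (sum p^2)^2 }.
    """
    counts = np.asarray(list(counts), dtype=float)
    if (counts <= 0).any():
        raise ValueError("haplotype counts must be positive")
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    p = counts / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    hd = n / (n - 1.0) * (1.0 - s2)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2)
    return DiversityResult(
        n=int(n), n_haplotypes=len(counts), hd=hd, hd_sd=float(np.sqrt(max(var, 0.0)))
    )


def pairwise_differences(sequences: Sequence[str]) -> np.ndarray:
    mat = np.array([list(s) for s in sequences], dtype="U1")
    n = mat.shape[0]
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        d[i] = (mat != mat[i]).sum(axis=1)
    return d


def nucleotide_diversity(sequences: Sequence[str]) -> DiversityResult:
    """Per-site nucleotide diversity: the mean pairwise p-distance.

    No multiple-hit correction is applied, matching the usual definition
    for closely related organelle haplotypes.
    """
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    length = len(seqs[0])
    if length == 0:
        raise ValueError("zero-length alignment")
    d = pairwise_differences(seqs)
    n = len(seqs)
    iu = np.triu_indices(n, k=1)
    pi = float(d[iu].mean()) / length
    return DiversityResult(n=n, pi=pi)


# ---------------------------------------------------------------------------
# Tamura-Nei distance


def tamura_nei_distance(aln: Alignment) -> pd.DataFrame:
    """Tamura-Nei (1993) pairwise distances on a gap-free alignment.

    Base frequencies are estimated once from the full matrix.  Pairs for
    which a logarithm argument is non-positive (saturation) fall back to
    the p-distance with a logged warning.
    """
    mat = aln.to_matrix()
    n, L = mat.shape
    if n < 2:
        raise ValueError("need >= 2 sequences")
    bases = np.array(list("ACGT"))
    freqs = np.array([(mat == b).mean() for b in bases])
    if not np.isclose(freqs.sum(), 1.0):
        raise ValueError("alignment contains non-ACGT characters; filter first")
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    k1 = 2.0 * pa * pg / pr
    k2 = 2.0 * pc * pt / py
    k3 = 2.0 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)

    code = np.zeros(mat.shape, dtype=np.int8)
    for i, b in enumerate(bases):
        code[mat == b] = i
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = code[i], code[j]
            diff = a != b
            p_dist = diff.mean()
            ag = np.mean(((a == 0) & (b == 2)) | ((a == 2) & (b == 0)))
            ct = np.mean(((a == 1) & (b == 3)) | ((a == 3) & (b == 1)))
            q = p_dist - ag - ct
            w1 = 1.0 - pr * ag / (2.0 * pa * pg) - q / (2.0 * pr)
            w2 = 1.0 - py * ct / (2.0 * pc * pt) - q / (2.0 * py)
            w3 = 1.0 - q / (2.0 * pr * py)
            if w1 <= 0 or w2 <= 0 or w3 <= 0:
                logger.warning(
                    "Tamura-Nei log argument non-positive for pair (%s, %s); "
                    "falling back to p-distance",
                    aln.sample_ids[i], aln.sample_ids[j],
                )
                dist = p_dist
            else:
                dist = -k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3)
            d[i, j] = d[j, i] = dist
    return pd.DataFrame(d, index=aln.sample_ids, columns=aln.sample_ids)


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    grouping: str
    table: pd.DataFrame  # stratum, df, sum_sq, variance, percent
    fixation_indices: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0


def _ss_within(d2: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    total = 0.0
    for idx in groups:
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            total += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return total


def _indices_by(labels: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == g) for g in pd.unique(labels)]


def _amova_components(
    d2: np.ndarray, pops: np.ndarray, groups: np.ndarray | None
) -> dict[str, float]:
    """Variance components of the Excoffier-Smouse-Quattro decomposition.

    ``d2`` holds squared molecular distances.  Components are not
    truncated at zero.
    """
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    pop_idx = _indices_by(pops)
    n_pop = len(pop_idx)
    ss_wp = _ss_within(d2, pop_idx)
    sizes = np.array([idx.size for idx in pop_idx], dtype=float)

    if groups is None:
        df_ap, df_wp = n_pop - 1, n - n_pop
        if n_pop == 1:
            # all samples in one population: only within-population variance
            return {
                "ss_ap": 0.0, "ss_wp": ss_wp, "ss_total": ss_total,
                "df_ap": 0, "df_wp": df_wp,
                "sigma_b": 0.0, "sigma_c": ss_wp / df_wp, "F_ST": 0.0,
            }
        if df_ap <= 0 or df_wp <= 0:
            raise ValueError("degenerate design: df <= 0")
        ss_ap = ss_total - ss_wp
        sigma_c = ss_wp / df_wp
        n_bar = (n - (sizes**2).sum() / n) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n_bar
        total = sigma_b + sigma_c
        return {
            "ss_ap": ss_ap, "ss_wp": ss_wp, "ss_total": ss_total,
            "df_ap": df_ap, "df_wp": df_wp,
            "sigma_b": sigma_b, "sigma_c": sigma_c,
            "F_ST": sigma_b / total if total != 0 else 0.0,
        }

    grp_idx = _indices_by(groups)
    n_grp = len(grp_idx)
    ss_wg = _ss_within(d2, grp_idx)
    df_ag, df_apwg, df_wp = n_grp - 1, n_pop - n_grp, n - n_pop
    if min(df_ag, df_apwg, df_wp) <= 0:
        raise ValueError("degenerate design: df <= 0")
    ss_ag = ss_total - ss_wg
    ss_apwg = ss_wg - ss_wp

    # coefficients n1, n2, n3 of the expected mean squares
    grp_sizes = np.array([idx.size for idx in grp_idx], dtype=float)
    sum_npop2_per_grp = []
    for gidx in grp_idx:
        g_pops = _indices_by(pops[gidx])
        sum_npop2_per_grp.append(sum(p.size**2 for p in g_pops) / gidx.size)
    A = float(np.sum(sum_npop2_per_grp))
    n1 = (n - A) / df_apwg
    n2 = (A - (sizes**2).sum() / n) / df_ag
    n3 = (n - (grp_sizes**2).sum() / n) / df_ag

    sigma_c = ss_wp / df_wp
    sigma_b = (ss_apwg / df_apwg - sigma_c) / n1
    sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    total = sigma_a + sigma_b + sigma_c
    return {
        "ss_ag": ss_ag, "ss_apwg": ss_apwg, "ss_wp": ss_wp, "ss_total": ss_total,
        "df_ag": df_ag, "df_apwg": df_apwg, "df_wp": df_wp,
        "sigma_a": sigma_a, "sigma_b": sigma_b, "sigma_c": sigma_c,
        "F_CT": sigma_a / total if total != 0 else 0.0,
        "F_SC": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else 0.0,
        "F_ST": (sigma_a + sigma_b) / total if total != 0 else 0.0,
    }


def amova(
    distances: pd.DataFrame | np.ndarray,
    populations: Sequence[str],
    groups: Mapping[str, str] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    distances_are_squared: bool = True,
    grouping_name: str | None = None,
) -> AmovaResult:
    """Analysis of molecular variance with permutation tests.

    Parameters
    ----------
    distances:
        Square matrix of molecular distances between samples.  Following
        the convention of distance-based AMOVA, the entries are treated as
        *squared* Euclidean distances unless ``distances_are_squared`` is
        False (in which case they are squared here).
    populations:
        Per-sample population labels, aligned with the matrix rows.
    groups:
        Optional population -> group mapping defining a 3-level design.
    """
    d = np.asarray(distances, dtype=float)
    d2 = d if distances_are_squared else d**2
    pops = np.asarray(list(populations))
    if pops.size != d2.shape[0]:
        raise ValueError("populations must match the distance matrix")
    grp = None
    if groups is not None:
        missing = sorted({p for p in pops if p not in groups})
        if missing:
            raise ValueError(f"populations with no group assignment: {missing}")
        grp = np.asarray([groups[p] for p in pops])

    obs = _amova_components(d2, pops, grp)
    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}

    if grp is None:
        # F_ST: permute samples among populations
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pops.size)
            stat = _amova_components(d2, pops[perm], None)["F_ST"]
            count += stat >= obs["F_ST"]
        p_values["F_ST"] = (count + 1) / (n_perm + 1)
        total = obs["sigma_b"] + obs["sigma_c"]
        table = pd.DataFrame(
            {
                "stratum": ["among_populations", "within_populations", "total"],
                "df": [obs["df_ap"], obs["df_wp"], obs["df_ap"] + obs["df_wp"]],
                "sum_sq": [obs["ss_ap"], obs["ss_wp"], obs["ss_total"]],
                "variance": [obs["sigma_b"], obs["sigma_c"], total],
                "percent": [100 * obs["sigma_b"] / total, 100 * obs["sigma_c"] / total, 100.0],
            }
        )
        indices = {"F_ST": obs["F_ST"]}
    else:
        pop_list = list(pd.unique(pops))
        grp_of_pop = {p: groups[p] for p in pop_list}
        count_ct = count_sc = count_st = 0
        for _ in range(n_perm):
            # F_CT: permute whole populations among groups
            perm_groups = rng.permutation([grp_of_pop[p] for p in pop_list])
            gmap = dict(zip(pop_list, perm_groups))
            grp_perm = np.asarray([gmap[p] for p in pops])
            try:
                count_ct += _amova_components(d2, pops, grp_perm)["F_CT"] >= obs["F_CT"]
            except ValueError:
                count_ct += 1  # degenerate permutation counted conservatively
            # F_SC: permute samples among populations within groups
            pops_sc = pops.copy()
            for g in pd.unique(grp):
                idx = np.flatnonzero(grp == g)
                pops_sc[idx] = pops[idx][rng.permutation(idx.size)]
            count_sc += _amova_components(d2, pops_sc, grp)["F_SC"] >= obs["F_SC"]
            # F_ST: permute samples among populations (ignoring groups)
            perm = rng.permutation(pops.size)
            pops_st = pops[perm]
            grp_st = np.asarray([groups[p] for p in pops_st])
            count_st += _amova_components(d2, pops_st, grp_st)["F_ST"] >= obs["F_ST"]
        p_values = {
            "F_CT": (count_ct + 1) / (n_perm + 1),
            "F_SC": (count_sc + 1) / (n_perm + 1),
            "F_ST": (count_st + 1) / (n_perm + 1),
        }
        total = obs["sigma_a"] + obs["sigma_b"] + obs["sigma_c"]
        table = pd.DataFrame(
            {
                "stratum": [
                    "among_groups", "among_populations_within_groups",
                    "within_populations", "total",
                ],
                "df": [obs["df_ag"], obs["df_apwg"], obs["df_wp"],
                       obs["df_ag"] + obs["df_apwg"] + obs["df_wp"]],
                "sum_sq": [obs["ss_ag"], obs["ss_apwg"], obs["ss_wp"], obs["ss_total"]],
                "variance": [obs["sigma_a"], obs["sigma_b"], obs["sigma_c"], total],
                "percent": [100 * obs["sigma_a"] / total, 100 * obs["sigma_b"] / total,
                            100 * obs["sigma_c"] / total, 100.0],
            }
        )
        indices = {k: obs[k] for k in ("F_CT", "F_SC", "F_ST")}

    name = grouping_name or ("grouped" if groups is not None else "no_groups")
    return AmovaResult(name, table, indices, p_values, n_perm)


def pairwise_fst(
    distances: pd.DataFrame | np.ndarray,
    labels: Sequence[str],
    n_perm: int = 1000,
    seed: int | None = None,
    distances_are_squared: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise F_ST between strata (populations or lineages) via 2-level AMOVA."""
    d = np.asarray(distances, dtype=float)
    labs = np.asarray(list(labels))
    strata = list(pd.unique(labs))
    fst = pd.DataFrame(0.0, index=strata, columns=strata)
    pval = pd.DataFrame(np.nan, index=strata, columns=strata)
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(len(strata) * (len(strata) - 1) // 2)
    k = 0
    for i, a in enumerate(strata):
        for b in strata[i + 1:]:
            idx = np.flatnonzero((labs == a) | (labs == b))
            res = amova(
                d[np.ix_(idx, idx)], labs[idx], n_perm=n_perm,
                seed=seeds[k].generate_state(1)[0],
                distances_are_squared=distances_are_squared,
            )
            k += 1
            fst.loc[a, b] = fst.loc[b, a] = res.fixation_indices["F_ST"]
            pval.loc[a, b] = pval.loc[b, a] = res.p_values["F_ST"]
    return fst, pval


# ---------------------------------------------------------------------------
# G_ST / N_ST (Pons & Petit 1996)


@dataclass
class DiffCoefficients:
    g_st: float
    n_st: float
    h_s: float
    h_t: float
    v_s: float
    v_t: float
    p_nst_gt_gst: float | None = None
    n_permutations: int = 0


def _pons_petit(freqs: np.ndarray, sizes: np.ndarray, pi: np.ndarray) -> tuple[float, float]:
    """Unbiased (v_S, v_T) of Pons & Petit for distance matrix ``pi``.

    ``freqs`` is (K populations x H haplotypes) of relative frequencies.
    With pi = 1 - I the pair reduces to (h_S, h_T).
    """
    K = freqs.shape[0]
    n_harm = K / np.sum(1.0 / sizes)
    within = np.einsum("ki,ij,kj->k", freqs, pi, freqs)
    v_s = n_harm / (n_harm - 1.0) * within.mean()
    xbar = freqs.mean(axis=0)
    v_t = float(xbar @ pi @ xbar) + v_s / (n_harm * K)
    return v_s, v_t


def gst_nst(
    counts: pd.DataFrame,
    distances: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
) -> DiffCoefficients:
    """Pons & Petit (1996) G_ST and N_ST with the phylogeographic-structure test.

    ``counts`` is the haplotype x population count matrix; ``distances``
    the inter-haplotype distance matrix (Hamming steps by default in this
    package).  Populations with fewer than 2 samples are excluded (logged).
    The permutation test permutes haplotype identities on the distance
    matrix and recomputes N_ST; the one-tailed p-value is for
    N_ST > G_ST-like null (no relationship between haplotype identity and
    distance).
    """
    mat = counts.to_numpy(dtype=float).T  # populations x haplotypes
    sizes = mat.sum(axis=1)
    keep = sizes >= 2
    dropped = [c for c, k in zip(counts.columns, keep) if not k]
    if dropped:
        logger.info("gst_nst: excluding singleton populations %s", dropped)
    mat, sizes = mat[keep], sizes[keep]
    if mat.shape[0] < 2:
        raise ValueError("gst_nst needs >= 2 populations with n >= 2")
    freqs = mat / sizes[:, None]
    H = freqs.shape[1]
    pi_ident = 1.0 - np.eye(H)
    pi = np.asarray(distances, dtype=float)
    if pi.shape != (H, H):
        raise ValueError("distance matrix does not match the haplotype count matrix")

    h_s, h_t = _pons_petit(freqs, sizes, pi_ident)
    if h_t <= 0:
        raise ValueError("monomorphic data: total diversity is zero")
    v_s, v_t = _pons_petit(freqs, sizes, pi)
    g_st = 1.0 - h_s / h_t
    n_st = 1.0 - v_s / v_t if v_t > 0 else g_st

    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(H)
            v_s_p, v_t_p = _pons_petit(freqs, sizes, pi[np.ix_(perm, perm)])
            n_st_p = 1.0 - v_s_p / v_t_p if v_t_p > 0 else g_st
            count += n_st_p >= n_st
        p = (count + 1) / (n_perm + 1)
    return DiffCoefficients(g_st, n_st, h_s, h_t, v_s, v_t, p, n_perm)


# ---------------------------------------------------------------------------
# Mantel / isolation by distance


def great_circle_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) from decimal-degree coordinates."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    return 2 * 6371.0088 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def planar_degree_distance(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Plain Euclidean distance in degree space (configurable alternative)."""
    pts = np.column_stack([np.asarray(lat, float), np.asarray(lon, float)])
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def mantel_test(
    genetic: np.ndarray,
    geographic: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two symmetric distance matrices.

    Pearson's r over the lower triangles; the p-value is the proportion of
    joint row/column label permutations with r >= the observed value.
    """
    g = np.asarray(genetic, dtype=float)
    e = np.asarray(geographic, dtype=float)
    if g.shape != e.shape or g.shape[0] != g.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    n = g.shape[0]
    if n < 3:
        raise ValueError("mantel test needs >= 3 populations")
    il = np.tril_indices(n, k=-1)

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        x, y = a[il], b[il]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(g, e)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        count += corr(g[np.ix_(perm, perm)], e) >= r_obs
    return r_obs, (count + 1) / (n_perm + 1)
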
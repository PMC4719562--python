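"""Genetic distances, hierarchical AMOVA with permutation tests, geographic
distances, Mantel tests and diversity-vs-geography regressions.

The genetic distance between two diploid biallelic genotypes is the squared
codominant distance of Smouse & Peakall: identical genotypes 0, one shared
allele (homozygote vs heterozygote) 1, opposite homozygotes 4 — i.e. the
squared difference of the 0/1/2 allele-dosage coding — summed over the loci
where both individuals have calls.

AMOVA decomposes these squared distances hierarchically (among groups, among
accessions within groups, within accessions) into method-of-moments variance
components with Φ-statistics, tested by permutation.  Two unit levels are
supported:

* ``unit="genotype"`` — individuals are the units (GenAlEx PhiPT style;
  within-individual variation suppressed).  Under Hardy–Weinberg structure
  with allele-level differentiation F the among-group Φ has expectation
  2F/(1+F), not F.
* ``unit="allele"`` — each individual contributes its two gene copies, so
  the among-group Φ estimates the allele-level F_CT directly (the classic
  haplotype-level AMOVA for codominant data).

Weir & Cockerham's θ is provided as an independent cross-check estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_qc import GenotypeMatrix, MISSING
from .popgen import allele_frequencies

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray
    kind: str  # fst | nei_D | geographic_km | genotypic_sq

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T]):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal not zero")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class AMOVALevel:
    name: str
    df: int
    ss: float
    sigma2: float  # raw (possibly negative) component
    percent: float  # computed with negatives floored at 0
    p: float | None = None


@dataclass(frozen=True)
class AMOVAResult:
    levels: tuple[AMOVALevel, ...]
    phi: dict[str, float]
    n_perm: int
    seed: int | None
    unit: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"level": l.name, "df": l.df, "SS": l.ss, "variance": l.sigma2,
                 "percent": l.percent, "p": l.p}
                for l in self.levels
            ]
        )


@dataclass(frozen=True)
class CorrelationResult:
    statistic: str
    r: float
    p: float
    n: int
    n_perm: int
    seed: int | None
    tails: str


# ---------------------------------------------------------------------------
# genotypic distances
# ---------------------------------------------------------------------------


def _dosage_matrix(g: GenotypeMatrix, unit: str) -> np.ndarray:
    """Unit x locus matrix: 0/1/2 dosages (genotype) or 0/1 copies (allele);
    NaN marks missing.  Allele units interleave the two copies per individual."""
    x = g.calls.astype(float)
    x[g.calls == MISSING] = np.nan
    if unit == "genotype":
        return x
    if unit == "allele":
        a = np.floor(x / 2)  # 0,0,1 for calls 0,1,2
        b = np.ceil(x / 2)  # 0,1,1
        out = np.empty((2 * x.shape[0], x.shape[1]))
        out[0::2] = a
        out[1::2] = b
        return out
    raise ValueError(f"unknown unit {unit!r}")


def squared_distance_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise sum over shared non-missing loci of (x_i − x_j)².

    Returns (distances, shared-locus counts)."""
    m = np.isfinite(x)
    a = np.where(m, x, 0.0)
    a2 = a * a
    mf = m.astype(float)
    d = a2 @ mf.T + mf @ a2.T - 2.0 * (a @ a.T)
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    shared = mf @ mf.T
    return d, shared


def genotypic_distance_matrix(
    g: GenotypeMatrix, per_locus_normalized: bool = False
) -> DistanceMatrix:
    """Squared codominant genetic distance between all pairs of individuals.

    With ``per_locus_normalized`` the sum is replaced by the per-shared-locus
    mean times the panel locus count, which removes the dependence of the
    distance on how many loci a pair shares.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    d, shared = squared_distance_matrix(_dosage_matrix(g, "genotype"))
    off = ~np.eye(len(d), dtype=bool)
    if (shared[off] == 0).any():
        i, j = np.argwhere((shared == 0) & off)[0]
        raise ValueError(
            f"individuals {g.individual_ids[i]} and {g.individual_ids[j]} share no called loci"
        )
    if per_locus_normalized:
        d = np.where(off, d / shared * g.n_markers, 0.0)
        d = (d + d.T) / 2
    return DistanceMatrix(g.individual_ids, d, "genotypic_sq")


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def _within_ss(d: np.ndarray, labels: np.ndarray) -> float:
    """Σ over groups of (1/n_g)·Σ_{i<j in g} d_ij (the AMOVA within-SS)."""
    ss = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) > 1:
            ss += d[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss


def _three_level_components(
    d: np.ndarray, acc: np.ndarray, grp: np.ndarray
) -> tuple[dict[str, float], dict[str, float], dict[str, int]]:
    """SS, variance components and df for units in accessions in groups."""
    n = len(acc)
    ss_total = d.sum() / (2.0 * n)
    ss_wp = _within_ss(d, acc)
    ss_grp_tot = _within_ss(d, grp)
    ss_ap = ss_grp_tot - ss_wp
    ss_ag = ss_total - ss_grp_tot

    accs, acc_sizes = np.unique(acc, return_counts=True)
    groups = np.unique(grp)
    A, G = len(accs), len(groups)
    grp_of_acc = {}
    for a, gl in zip(acc, grp):
        grp_of_acc[a] = gl
    grp_sizes = {gl: 0 for gl in groups}
    sum_na2_over_ng = 0.0
    for gl in groups:
        in_g = grp == gl
        grp_sizes[gl] = int(in_g.sum())
    for a, na in zip(accs, acc_sizes):
        sum_na2_over_ng += na**2 / grp_sizes[grp_of_acc[a]]
    sum_na2 = float((acc_sizes.astype(float) ** 2).sum())
    sum_ng2 = float(sum(v**2 for v in grp_sizes.values()))

    df = {"among_groups": G - 1, "among_accessions": A - G, "within_accessions": n - A}
    sigma = {}
    ms_wp = ss_wp / df["within_accessions"] if df["within_accessions"] > 0 else 0.0
    sigma["within_accessions"] = ms_wp
    if df["among_accessions"] > 0:
        n_prime = (n - sum_na2_over_ng) / df["among_accessions"]
        ms_ap = ss_ap / df["among_accessions"]
        sigma["among_accessions"] = (ms_ap - ms_wp) / n_prime
    else:
        sigma["among_accessions"] = 0.0
    if df["among_groups"] > 0:
        n_dprime = (sum_na2_over_ng - sum_na2 / n) / df["among_groups"]
        n_tprime = (n - sum_ng2 / n) / df["among_groups"]
        ms_ag = ss_ag / df["among_groups"]
        sigma["among_groups"] = (
            ms_ag - ms_wp - n_dprime * sigma["among_accessions"]
        ) / n_tprime
    else:
        sigma["among_groups"] = 0.0
    ss = {
        "among_groups": ss_ag,
        "among_accessions": ss_ap,
        "within_accessions": ss_wp,
        "total": ss_total,
    }
    return ss, sigma, df


def _phi_from_sigma(sigma: Mapping[str, float], floor: bool = True) -> dict[str, float]:
    """Φ-statistics from variance components.

    Reported Φ floors negative components at zero (GenAlEx convention);
    permutation tests use ``floor=False`` so the null distribution is not
    stacked at zero by the truncation."""
    a, b, c = sigma["among_groups"], sigma["among_accessions"], sigma["within_accessions"]
    if floor:
        a, b, c = max(a, 0.0), max(b, 0.0), max(c, 0.0)
    tot = a + b + c
    phi = {}
    phi["phi_ct"] = a / tot if tot > 0 else 0.0
    phi["phi_sc"] = b / (b + c) if (b + c) > 0 else 0.0
    phi["phi_st"] = (a + b) / tot if tot > 0 else 0.0
    return phi


def amova(
    g: GenotypeMatrix,
    grouping: Mapping[str, str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    unit: str = "genotype",
) -> AMOVAResult:
    """Hierarchical AMOVA: among groups / among accessions within groups /
    within accessions (the among-groups level is dropped when ``grouping`` is
    None or names a single group).

    Permutation tests (n_perm, seeded): the among-groups Φ permutes whole
    accessions among groups; the among-accessions Φ permutes units among
    accessions within their group; the within-accessions row carries the
    Φ_ST test (units permuted among accessions anywhere).  The observed value
    is included in the count: p = (#perm ≥ obs + 1)/(n_perm + 1).  Negative
    variance components are kept in the raw output and floored at zero for
    percentages and Φ.
    """
    acc_of_ind = [g.accession_of[i] for i in g.individual_ids]
    if len(set(acc_of_ind)) < 2:
        raise ValueError("need at least 2 accessions")
    if grouping is None:
        grouping = {a: "all" for a in set(acc_of_ind)}
    keep = [i for i, a in zip(g.individual_ids, acc_of_ind) if a in grouping]
    sub = g.subset(keep) if len(keep) != g.n_individuals else g
    x = _dosage_matrix(sub, unit)
    reps = 2 if unit == "allele" else 1
    acc = np.repeat([sub.accession_of[i] for i in sub.individual_ids], reps)
    grp = np.array([grouping[a] for a in acc])
    d, _ = squared_distance_matrix(x)
    return _amova_from_distances(d, acc, grp, n_perm, seed, unit, n_copies_per_ind=reps)


def _amova_from_distances(
    d: np.ndarray,
    acc: np.ndarray,
    grp: np.ndarray,
    n_perm: int,
    seed: int | None,
    unit: str,
    n_copies_per_ind: int = 1,
) -> AMOVAResult:
    ss, sigma, df = _three_level_components(d, acc, grp)
    phi = _phi_from_sigma(sigma)
    phi_raw = _phi_from_sigma(sigma, floor=False)
    single_group = len(np.unique(grp)) < 2

    floored = {k: max(v, 0.0) for k, v in sigma.items()}
    if single_group:
        floored["among_groups"] = 0.0
    tot = sum(floored.values())
    pct = {k: (100.0 * v / tot if tot > 0 else 0.0) for k, v in floored.items()}

    pvals: dict[str, float | None] = {k: None for k in sigma}
    if n_perm > 0 and seed is not None:
        rng = np.random.default_rng(seed)
        pvals.update(
            _amova_permutation_p(d, acc, grp, phi_raw, n_perm, rng, n_copies_per_ind)
        )
        if single_group:
            pvals["among_groups"] = None

    order = ["among_groups", "among_accessions", "within_accessions"]
    if single_group:
        order = order[1:]
    levels = tuple(
        AMOVALevel(k, df[k], ss[k], sigma[k], pct[k], pvals[k]) for k in order
    )
    if single_group:
        phi = {"phi_st": phi["phi_sc"], "phi_sc": phi["phi_sc"], "phi_ct": 0.0}
    return AMOVAResult(levels, phi, n_perm, seed, unit)


def _permute_within(labels_fixed: np.ndarray, to_shuffle: np.ndarray, rng) -> np.ndarray:
    """Shuffle ``to_shuffle`` within each level of ``labels_fixed``."""
    out = to_shuffle.copy()
    for lab in np.unique(labels_fixed):
        idx = np.flatnonzero(labels_fixed == lab)
        out[idx] = out[rng.permutation(idx)]
    return out


def _amova_permutation_p(
    d: np.ndarray,
    acc: np.ndarray,
    grp: np.ndarray,
    phi_obs: Mapping[str, float],
    n_perm: int,
    rng: np.random.Generator,
    n_copies: int,
) -> dict[str, float]:
    """Permutation p-values for the three Φ statistics.

    Units belonging to one individual (allele level) move together, and
    whole accessions move together in the among-groups test.
    """
    n_units = len(acc)
    n_ind = n_units // n_copies
    acc_by_ind = acc[::n_copies]
    grp_by_ind = grp[::n_copies]
    accs = np.unique(acc)
    grp_of_acc = {a: grp[acc == a][0] for a in accs}

    ge_ct = ge_sc = ge_st = 1  # observed included
    multi_group = len(np.unique(grp)) > 1
    for _ in range(n_perm):
        # among groups: permute accession→group assignment
        if multi_group:
            perm_groups = rng.permutation([grp_of_acc[a] for a in accs])
            lut = dict(zip(accs, perm_groups))
            grp_p = np.array([lut[a] for a in acc])
            _, sig, _ = _three_level_components(d, acc, grp_p)
            if _phi_from_sigma(sig, floor=False)["phi_ct"] >= phi_obs["phi_ct"] - 1e-12:
                ge_ct += 1
        # among accessions within groups: permute individuals within group
        acc_ind_p = _permute_within(grp_by_ind, acc_by_ind, rng)
        acc_p = np.repeat(acc_ind_p, n_copies)
        _, sig, _ = _three_level_components(d, acc_p, grp)
        if _phi_from_sigma(sig, floor=False)["phi_sc"] >= phi_obs["phi_sc"] - 1e-12:
            ge_sc += 1
        # overall: permute individuals among accessions anywhere
        perm = rng.permutation(n_ind)
        acc_p = np.repeat(acc_by_ind[perm], n_copies)
        grp_p = np.array([grp_of_acc[a] for a in acc_p])
        _, sig, _ = _three_level_components(d, acc_p, grp_p)
        if _phi_from_sigma(sig, floor=False)["phi_st"] >= phi_obs["phi_st"] - 1e-12:
            ge_st += 1
    denom = n_perm + 1
    return {
        "among_groups": ge_ct / denom,
        "among_accessions": ge_sc / denom,
        "within_accessions": ge_st / denom,
    }


# ---------------------------------------------------------------------------
# pairwise FST
# ---------------------------------------------------------------------------


def _two_level_phi(d: np.ndarray, pop: np.ndarray) -> float:
    """Among-populations Φ from a two-level AMOVA on unit distances."""
    n = len(pop)
    pops, sizes = np.unique(pop, return_counts=True)
    ss_total = d.sum() / (2.0 * n)
    ss_w = _within_ss(d, pop)
    ss_a = ss_total - ss_w
    df_a, df_w = len(pops) - 1, n - len(pops)
    if df_a == 0 or df_w == 0:
        return 0.0
    ms_w = ss_w / df_w
    n0 = (n - (sizes.astype(float) ** 2).sum() / n) / df_a
    sig_a = (ss_a / df_a - ms_w) / n0
    tot = max(sig_a, 0.0) + ms_w
    return max(sig_a, 0.0) / tot if tot > 0 else 0.0


def pairwise_fst(
    g: GenotypeMatrix,
    grouping: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
    unit: str = "genotype",
    min_group_size: int = 2,
) -> tuple[DistanceMatrix, pd.DataFrame]:
    """Pairwise FST between groups as the among-groups Φ of a two-population
    AMOVA, with permutation p-values from shuffling individuals between the
    two groups.  Returns the FST matrix and a matching p-value frame.
    """
    members: dict[str, list[str]] = {}
    for acc in g.accession_ids:
        if acc in grouping:
            members.setdefault(grouping[acc], []).extend(g.members_of(acc))
    labels = sorted(members)
    for lab in labels:
        if len(members[lab]) < min_group_size:
            raise ValueError(f"group {lab!r} below minimum size {min_group_size}")
    reps = 2 if unit == "allele" else 1
    k = len(labels)
    fst = np.zeros((k, k))
    pmat = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            pair = members[labels[i]] + members[labels[j]]
            sub = g.subset(pair)
            x = _dosage_matrix(sub, unit)
            d, _ = squared_distance_matrix(x)
            pop = np.repeat(
                [0] * len(members[labels[i]]) + [1] * len(members[labels[j]]), reps
            )
            obs = _two_level_phi(d, pop)
            fst[i, j] = fst[j, i] = obs
            if n_perm > 0 and seed is not None:
                pop_ind = pop[::reps]
                ge = 1
                for _ in range(n_perm):
                    perm = np.repeat(rng.permutation(pop_ind), reps)
                    if _two_level_phi(d, perm) >= obs - 1e-12:
                        ge += 1
                pmat[i, j] = pmat[j, i] = ge / (n_perm + 1)
    return (
        DistanceMatrix(tuple(labels), fst, "fst"),
        pd.DataFrame(pmat, index=labels, columns=labels),
    )


def weir_cockerham_fst(g: GenotypeMatrix, grouping: Mapping[str, str]) -> float:
    """Weir & Cockerham (1984) multi-population θ, the cross-check estimator."""
    members: dict[str, list[str]] = {}
    for acc in g.accession_ids:
        if acc in grouping:
            members.setdefault(grouping[acc], []).extend(g.members_of(acc))
    pops = sorted(members)
    r = len(pops)
    if r < 2:
        raise ValueError("need at least 2 populations")
    from .popgen import locus_stats

    per_pop = [locus_stats(g, members[p]) for p in pops]
    n_i = np.array([s["n_calls"].to_numpy(float) for s in per_pop])  # r x L
    p_i = np.array([s["p"].to_numpy() for s in per_pop])
    h_i = np.array([s["ho"].to_numpy() for s in per_pop])
    ok = (n_i > 0).all(axis=0)
    n_i, p_i, h_i = n_i[:, ok], p_i[:, ok], h_i[:, ok]
    nbar = n_i.mean(axis=0)
    nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
    a = nbar / nc * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError("no polymorphic loci shared by the populations")
    return float(a.sum() / denom)


# ---------------------------------------------------------------------------
# Nei's standard genetic distance
# ---------------------------------------------------------------------------


def nei_standard_distance(freqs_x: pd.Series, freqs_y: pd.Series) -> float:
    """Nei's standard distance D = −ln I from reference-allele frequencies.

    I = Jxy/√(Jx·Jy) with J's summed over loci where both frequency vectors
    are defined; returns +inf (with the disjoint-allele caveat) when I = 0.
    """
    joined = pd.concat([freqs_x, freqs_y], axis=1, join="inner").dropna()
    if joined.empty:
        raise ValueError("no shared defined loci")
    x = joined.iloc[:, 0].to_numpy()
    y = joined.iloc[:, 1].to_numpy()
    jx = float((x**2 + (1 - x) ** 2).sum())
    jy = float((y**2 + (1 - y) ** 2).sum())
    jxy = float((x * y + (1 - x) * (1 - y)).sum())
    i = jxy / np.sqrt(jx * jy)
    if i <= 0:
        return float("inf")
    return float(-np.log(min(i, 1.0)))


def nei_distance_matrix(g: GenotypeMatrix, grouping: Mapping[str, str]) -> DistanceMatrix:
    members: dict[str, list[str]] = {}
    for acc in g.accession_ids:
        if acc in grouping:
            members.setdefault(grouping[acc], []).extend(g.members_of(acc))
    labels = sorted(members)
    freqs = {lab: allele_frequencies(g, members[lab]) for lab in labels}
    k = len(labels)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = nei_standard_distance(freqs[labels[i]], freqs[labels[j]])
    return DistanceMatrix(tuple(labels), d, "nei_D")


def combined_fst_nei_frame(fst: DistanceMatrix, nei: DistanceMatrix) -> pd.DataFrame:
    """Table 4 layout: FST below the diagonal, Nei's D above."""
    if fst.labels != nei.labels:
        raise ValueError("label mismatch between FST and Nei matrices")
    out = pd.DataFrame("", index=list(fst.labels), columns=list(fst.labels))
    for i, a in enumerate(fst.labels):
        for j, b in enumerate(fst.labels):
            if i > j:
                out.loc[a, b] = f"{fst.values[i, j]:.3f}"
            elif i < j:
                out.loc[a, b] = f"{nei.values[i, j]:.3f}"
    return out


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (Earth radius 6371.0 km)."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def haversine_matrix(coords: Mapping[str, tuple[float, float]]) -> DistanceMatrix:
    labels = sorted(coords)
    k = len(labels)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = haversine_km(*coords[labels[i]], *coords[labels[j]])
    return DistanceMatrix(tuple(labels), d, "geographic_km")


# ---------------------------------------------------------------------------
# Mantel test and geography regressions
# ---------------------------------------------------------------------------


def _permutation_p(obs: float, perms: np.ndarray, tails: str) -> float:
    if tails == "one_sided_positive":
        ge = int((perms >= obs - 1e-12).sum())
    elif tails == "two_sided":
        ge = int((np.abs(perms) >= abs(obs) - 1e-12).sum())
    else:
        raise ValueError(f"unknown tails {tails!r}")
    return (ge + 1) / (len(perms) + 1)


def mantel_test(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    tails: str = "one_sided_positive",
) -> CorrelationResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal upper triangles; the
    null distribution permutes rows and columns of ``b`` jointly;
    p = (#perm r ≥ observed + 1)/(n_perm + 1) (one-sided positive default).
    """
    if a.labels != b.labels:
        raise ValueError("matrices must share labels in the same order")
    v = a.values
    w = b.values
    iu = np.triu_indices(len(v), k=1)
    x = v[iu]
    if np.std(x) == 0 or np.std(w[iu]) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    obs = float(np.corrcoef(x, w[iu])[0, 1])
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for t in range(n_perm):
        order = rng.permutation(len(v))
        perms[t] = np.corrcoef(x, w[np.ix_(order, order)][iu])[0, 1]
    p = _permutation_p(obs, perms, tails)
    return CorrelationResult("mantel_r", obs, p, len(a.labels), n_perm, seed, tails)


def pearson_permutation(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    tails: str = "two_sided",
    statistic: str = "pearson_r",
) -> CorrelationResult:
    """Pearson r with a permutation p-value (y shuffled against x)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    perms = np.array(
        [np.corrcoef(x, y[rng.permutation(len(y))])[0, 1] for _ in range(n_perm)]
    )
    return CorrelationResult(
        statistic, obs, _permutation_p(obs, perms, tails), len(x), n_perm, seed, tails
    )


DEFAULT_ORIGIN = (39.0, 35.0)  # central Anatolia, the assumed domestication core


def diversity_geography(
    acc_he: Mapping[str, float],
    coords: Mapping[str, tuple[float, float]],
    origin: tuple[float, float] = DEFAULT_ORIGIN,
    n_perm: int = 999,
    seed: int | None = None,
    tails: str = "two_sided",
) -> dict[str, CorrelationResult]:
    """Correlate accession He with latitude, longitude and great-circle
    distance to an assumed origin (default 39°N 35°E, central Turkey)."""
    accs = sorted(set(acc_he) & set(coords))
    if len(accs) < 3:
        raise ValueError("need at least 3 accessions with coordinates and He")
    he = np.array([acc_he[a] for a in accs])
    lat = np.array([coords[a][0] for a in accs])
    lon = np.array([coords[a][1] for a in accs])
    dist = np.array([haversine_km(*origin, *coords[a]) for a in accs])
    out = {}
    for name, pred in (("latitude", lat), ("longitude", lon), ("distance_to_origin", dist)):
        out[name] = pearson_permutation(
            pred, he, n_perm=n_perm, seed=seed, tails=tails, statistic=f"He_vs_{name}"
        )
    return out


# ---------------------------------------------------------------------------
# plain group-mean comparisons (thin plumbing over scipy/statsmodels)
# ---------------------------------------------------------------------------


def group_mean_comparisons(
    values_by_accession: Mapping[str, float],
    factors: pd.DataFrame,
    pairs: Sequence[tuple[str, str, str]] = (),
) -> pd.DataFrame:
    """ANOVA and t-tests on an accession-level statistic.

    ``factors`` is indexed by accession with one column per factor.  One-way
    ANOVA is run per factor; with exactly two factor columns a two-way
    main-effects ANOVA (type II) is added.  ``pairs`` lists
    (factor, level_a, level_b) two-sample t-tests.
    """
    vals = pd.Series(values_by_accession, name="value")
    df = factors.join(vals, how="inner").dropna(subset=["value"])
    if df.empty:
        raise ValueError("no accessions shared between values and factors")
    rows = []
    for col in factors.columns:
        sub = df.dropna(subset=[col])
        groups = [grp["value"].to_numpy() for _, grp in sub.groupby(col)]
        if len(groups) < 2:
            continue
        f, p = sps.f_oneway(*groups)
        rows.append({"test": f"oneway_anova[{col}]", "statistic": float(f), "p": float(p)})
    if len(factors.columns) == 2:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        c1, c2 = factors.columns
        sub = df.dropna(subset=[c1, c2]).rename(columns={c1: "f1", c2: "f2"})
        model = smf.ols("value ~ C(f1) + C(f2)", data=sub).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        for term, fac in (("C(f1)", c1), ("C(f2)", c2)):
            rows.append(
                {
                    "test": f"twoway_anova[{fac}]",
                    "statistic": float(tab.loc[term, "F"]),
                    "p": float(tab.loc[term, "PR(>F)"]),
                }
            )
    for factor, la, lb in pairs:
        xa = df.loc[df[factor] == la, "value"].to_numpy()
        xb = df.loc[df[factor] == lb, "value"].to_numpy()
        if min(len(xa), len(xb)) < 2:
            raise ValueError(f"t-test group of size < 2 for {factor}: {la} vs {lb}")
        t, p = sps.ttest_ind(xa, xb)
        rows.append(
            {"test": f"ttest[{factor}:{la}-vs-{lb}]", "statistic": float(t), "p": float(p)}
        )
    return pd.DataFrame(rows)
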
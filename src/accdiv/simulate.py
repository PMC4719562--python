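"""Synthetic genotype panels with the hierarchical structure the analyses
assume, plus ground truth for parameter-recovery tests.

The generator follows a Balding–Nichols beta hierarchy: an ancestral
reference-allele frequency p0 per locus; cluster frequencies drawn from
Beta(p0·(1−F_CT)/F_CT, (1−p0)·(1−F_CT)/F_CT) so that
Var(p_cluster) = p0(1−p0)·F_CT; accession frequencies drawn likewise around
their cluster frequency with F_SC; diploid genotypes per individual from the
accession frequency with optional within-individual inbreeding F_IS
(P(hom_ref) = p² + pq·F_IS, P(het) = 2pq·(1−F_IS)).  Independent loci — no
linkage disequilibrium or demography through time; the analyses under test
only consume frequency-level structure.

SNP ascertainment is emulated by rejection sampling: candidate loci are kept
only when a small discovery sample (individuals drawn from designated
discovery accessions) carries at least ``min_minor_copies`` minor alleles,
which depletes rare alleles exactly the way a narrow discovery panel does.
Optional extras: per-cluster missing-completely-at-random rates, clone
individuals (duplicated genotypes with a per-locus error rate, flagged in the
truth record), a genetic map (uniform cM positions) and accession
coordinates around cluster centroids.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .io_qc import (
    AccessionRecord,
    AccessionTable,
    GenotypeMatrix,
    MarkerMap,
    MISSING,
)


@dataclass(frozen=True)
class CloneSpec:
    accession: str
    n_clones: int
    error_rate: float = 0.0


@dataclass(frozen=True)
class AscertainmentSpec:
    enabled: bool = False
    discovery_accessions: tuple[str, ...] = ()
    discovery_n: int = 8
    min_minor_copies: int = 2


@dataclass(frozen=True)
class SimConfig:
    n_clusters: int = 3
    accessions_per_cluster: int = 8
    individuals_per_accession: int = 6
    n_markers: int = 600
    f_ct: float = 0.05
    f_sc: float = 0.05
    f_is: float = 0.0
    ancestral_freq_law: tuple = ("uniform", 0.05, 0.95)  # or ("neutral_sfs", m)
    ascertainment: AscertainmentSpec = AscertainmentSpec()
    missing_rate: tuple[float, ...] = ()  # per cluster; empty = no missing data
    clone_spec: tuple[CloneSpec, ...] = ()
    n_chromosomes: int = 7
    cm_range: float = 150.0
    coord_centroids: tuple[tuple[float, float], ...] = ()
    coord_jitter_deg: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f_ct", "f_sc", "f_is"):
            v = getattr(self, name)
            if not 0 <= v <= 0.99:
                raise ValueError(f"{name}={v} outside [0, 0.99]")
        for r in self.missing_rate:
            if not 0 <= r <= 1:
                raise ValueError("missing rates must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticDataset:
    genotypes: GenotypeMatrix
    accessions: AccessionTable
    marker_map: MarkerMap
    truth: dict


def _beta_draw(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols subpopulation frequencies; degenerate at p when f=0."""
    if f == 0:
        return p.copy()
    c = (1.0 - f) / f
    out = rng.beta(np.maximum(p * c, 1e-12), np.maximum((1 - p) * c, 1e-12))
    return out


def _ancestral(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size)
    if kind == "neutral_sfs":
        m = int(law[1])
        counts = np.arange(1, m)
        w = 1.0 / counts
        return rng.choice(counts, size=size, p=w / w.sum()) / m
    raise ValueError(f"unknown ancestral frequency law {law!r}")


def _genotypes_from_freq(
    rng: np.random.Generator, p: np.ndarray, n: int, f_is: float
) -> np.ndarray:
    """n diploid genotypes (0/1/2 counts of the reference allele) at loci
    with frequencies p, with inbreeding f_is."""
    q = 1 - p
    pr_rr = p * p + p * q * f_is
    pr_het = 2 * p * q * (1 - f_is)
    u = rng.random((n, len(p)))
    g = np.full((n, len(p)), 2, dtype=np.int8)  # hom_alt default
    g[u < pr_rr + pr_het] = 1
    g[u < pr_rr] = 0
    return g


def simulate_panel(cfg: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset (genotypes, passport table, map,
    coordinates) with its ground-truth record.

    When ascertainment is enabled, candidate loci are generated in batches
    and accepted only if the discovery sample carries at least
    ``min_minor_copies`` copies of the minor allele; the config is rejected
    if the acceptance rate falls below 1e−4.
    """
    rng = np.random.default_rng(cfg.seed)
    acc_names = []
    cluster_of: dict[str, str] = {}
    for c in range(cfg.n_clusters):
        for a in range(cfg.accessions_per_cluster):
            name = f"C{c + 1}A{a + 1:02d}"
            acc_names.append(name)
            cluster_of[name] = f"cluster{c + 1}"

    asc = cfg.ascertainment
    if asc.enabled:
        discovery = asc.discovery_accessions or tuple(
            a for a in acc_names if cluster_of[a] == "cluster1"
        )
        for a in discovery:
            if a not in cluster_of:
                raise ValueError(f"unknown discovery accession {a!r}")
    else:
        discovery = ()

    kept_p0: list[np.ndarray] = []
    kept_pc: list[np.ndarray] = []
    kept_pa: list[np.ndarray] = []
    n_kept = 0
    n_tried = 0
    batch = max(cfg.n_markers, 200)
    while n_kept < cfg.n_markers:
        p0 = _ancestral(rng, cfg.ancestral_freq_law, batch)
        pc = np.stack([_beta_draw(rng, p0, cfg.f_ct) for _ in range(cfg.n_clusters)])
        pa = np.stack(
            [
                _beta_draw(rng, pc[c], cfg.f_sc)
                for c in range(cfg.n_clusters)
                for _ in range(cfg.accessions_per_cluster)
            ]
        )  # (n_accessions, batch) in acc_names order
        if asc.enabled:
            # discovery sample: discovery_n individuals spread over the
            # discovery accessions; count minor-allele copies
            acc_idx = {a: k for k, a in enumerate(acc_names)}
            picks = rng.choice(len(discovery), size=asc.discovery_n)
            copies = np.zeros(batch)
            for pick in picks:
                freqs = pa[acc_idx[discovery[pick]]]
                copies += _genotypes_from_freq(rng, freqs, 1, cfg.f_is)[0]
            total = 2.0 * asc.discovery_n
            minor = np.minimum(copies, total - copies)
            accept = minor >= asc.min_minor_copies
        else:
            accept = np.ones(batch, bool)
        n_tried += batch
        n_kept += int(accept.sum())
        kept_p0.append(p0[accept])
        kept_pc.append(pc[:, accept])
        kept_pa.append(pa[:, accept])
        if n_tried >= 10000 and n_kept / n_tried < 1e-4:
            raise ValueError(
                f"ascertainment acceptance rate {n_kept / n_tried:.2e} below 1e-4; "
                "relax min_minor_copies or enlarge the discovery sample"
            )

    p0 = np.concatenate(kept_p0)[: cfg.n_markers]
    pc = np.concatenate(kept_pc, axis=1)[:, : cfg.n_markers]
    pa = np.concatenate(kept_pa, axis=1)[:, : cfg.n_markers]

    marker_ids = tuple(f"snp{j + 1:04d}" for j in range(cfg.n_markers))
    individual_ids: list[str] = []
    accession_of: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for k, acc in enumerate(acc_names):
        geno = _genotypes_from_freq(rng, pa[k], cfg.individuals_per_accession, cfg.f_is)
        for i in range(cfg.individuals_per_accession):
            ind = f"{acc}i{i + 1}"
            individual_ids.append(ind)
            accession_of[ind] = acc
            rows.append(geno[i])

    # clones: duplicate an existing member with per-locus errors
    clone_truth = []
    for spec in cfg.clone_spec:
        members = [i for i in individual_ids if accession_of[i] == spec.accession]
        if not members:
            raise ValueError(f"clone spec names unknown accession {spec.accession!r}")
        src = members[0]
        src_row = rows[individual_ids.index(src)]
        for c in range(spec.n_clones):
            ind = f"{spec.accession}clone{c + 1}"
            row = src_row.copy()
            flips = np.flatnonzero(rng.random(cfg.n_markers) < spec.error_rate)
            for j in flips:
                row[j] = rng.choice([x for x in (0, 1, 2) if x != row[j]])
            individual_ids.append(ind)
            accession_of[ind] = spec.accession
            rows.append(row)
            clone_truth.append({"clone": ind, "source": src, "n_errors": len(flips)})

    calls = np.stack(rows).astype(np.int8)

    # missing data, MCAR with a per-cluster rate
    if cfg.missing_rate:
        if len(cfg.missing_rate) != cfg.n_clusters:
            raise ValueError("missing_rate must list one rate per cluster")
        rates = {f"cluster{c + 1}": r for c, r in enumerate(cfg.missing_rate)}
        for i, ind in enumerate(individual_ids):
            r = rates[cluster_of[accession_of[ind]]]
            if r > 0:
                mask = rng.random(cfg.n_markers) < r
                calls[i, mask] = MISSING

    genotypes = GenotypeMatrix(tuple(individual_ids), marker_ids, calls, accession_of)

    # genetic map: markers spread uniformly over chromosomes, sorted cM
    chrom_assign = rng.integers(0, cfg.n_chromosomes, cfg.n_markers)
    cm = rng.uniform(0, cfg.cm_range, cfg.n_markers)
    positions = {
        m: (f"chr{chrom_assign[j] + 1}", round(float(cm[j]), 4))
        for j, m in enumerate(marker_ids)
    }
    marker_map = MarkerMap(positions)

    # coordinates around cluster centroids
    centroids = cfg.coord_centroids or tuple(
        (40.0 + 5.0 * c, 10.0 + 15.0 * c) for c in range(cfg.n_clusters)
    )
    records = {}
    for k, acc in enumerate(acc_names):
        c = k // cfg.accessions_per_cluster
        lat = float(np.clip(centroids[c][0] + rng.normal(0, cfg.coord_jitter_deg), -89, 89))
        lon = float(np.clip(centroids[c][1] + rng.normal(0, cfg.coord_jitter_deg), -179, 179))
        records[acc] = AccessionRecord(
            taxon=cluster_of[acc],
            biological_type=("cultivated", "feral", "wild")[c % 3],
            zone=f"zone{c + 1}",
            latitude=round(lat, 4),
            longitude=round(lon, 4),
        )
    accessions = AccessionTable(records)

    truth = {
        "config": cfg,
        "cluster_of": cluster_of,
        "p0": p0,
        "p_cluster": pc,  # clusters x loci
        "p_accession": pa,  # accessions (acc_names order) x loci
        "accession_order": acc_names,
        "discovery_accessions": list(discovery),
        "clones": clone_truth,
        "ascertainment_acceptance": (n_kept / n_tried) if n_tried else 1.0,
    }
    return SyntheticDataset(genotypes, accessions, marker_map, truth)


# ---------------------------------------------------------------------------
# fixture registry
# ---------------------------------------------------------------------------

FIXTURES: dict[str, SimConfig] = {
    # minimal panel for hand-checkable end-to-end runs
    "tiny": SimConfig(
        n_clusters=1,
        accessions_per_cluster=2,
        individuals_per_accession=3,
        n_markers=10,
        f_ct=0.0,
        f_sc=0.10,
        seed=101,
    ),
    # the default study-shaped panel: 3 clusters x 8 accessions x 6
    # individuals, 600 markers, mild hierarchical structure, SNPs
    # ascertained in cluster 1, per-cluster missingness matching the
    # 3-9 % range typical of array genotyping
    "rye-like-default": SimConfig(
        n_clusters=3,
        accessions_per_cluster=8,
        individuals_per_accession=6,
        n_markers=600,
        f_ct=0.03,
        f_sc=0.10,
        ascertainment=AscertainmentSpec(enabled=True, discovery_n=8, min_minor_copies=2),
        missing_rate=(0.03, 0.05, 0.08),
        seed=2024,
    ),
    # strong discovery-panel bias for the ascertainment diagnostic
    "biased-panel": SimConfig(
        n_clusters=2,
        accessions_per_cluster=6,
        individuals_per_accession=6,
        n_markers=400,
        f_ct=0.30,
        f_sc=0.05,
        ascertainment=AscertainmentSpec(enabled=True, discovery_n=8, min_minor_copies=2),
        seed=7,
    ),
}


def make_fixture(name: str) -> SyntheticDataset:
    """Deterministic dataset from the named registry entry."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    return simulate_panel(FIXTURES[name])


# ---------------------------------------------------------------------------
# engineered QC demonstration panel
# ---------------------------------------------------------------------------


def make_qc_demo_panel(seed: int = 0) -> GenotypeMatrix:
    """A 768-marker x 468-individual panel engineered so that every QC rule
    fires with the counts of the rye study narrative: 134 markers all
    missing, 32 missing in >50 % of individuals, 35 monomorphic, 11
    individuals without any call, 5 with >50 % missing, two accessions left
    with 3 individuals, and two accessions (12 individuals) flagged for
    manual exclusion — leaving 567 markers, 434 individuals, 76 accessions.
    """
    rng = np.random.default_rng(seed)
    n_acc6, n_acc5 = 68, 12  # 68*6 + 12*5 = 468 individuals in 80 accessions
    acc_sizes = [6] * n_acc6 + [5] * n_acc5
    individual_ids = []
    accession_of = {}
    for k, size in enumerate(acc_sizes):
        acc = f"acc{k + 1:02d}"
        for i in range(size):
            ind = f"{acc}i{i + 1}"
            individual_ids.append(ind)
            accession_of[ind] = acc
    n_ind = len(individual_ids)

    n_fail, n_high_missing, n_mono, n_good = 134, 32, 35, 567
    marker_ids = [f"m{j + 1:03d}" for j in range(768)]
    p = rng.uniform(0.1, 0.9, 768)
    calls = np.empty((n_ind, 768), dtype=np.int8)
    for j in range(768):
        pj = p[j]
        u = rng.random(n_ind)
        col = np.full(n_ind, 2, np.int8)
        col[u < pj**2 + 2 * pj * (1 - pj)] = 1
        col[u < pj**2] = 0
        calls[:, j] = col
    # 35 monomorphic markers: overwrite with a single allele
    mono = slice(n_fail + n_high_missing, n_fail + n_high_missing + n_mono)
    calls[:, mono] = 0  # hom_ref everywhere
    # background missingness ~3 % on good + monomorphic markers
    bg = rng.random(calls.shape) < 0.03
    bg[:, :n_fail + n_high_missing] = False
    calls[bg] = MISSING
    # 134 markers all missing
    calls[:, :n_fail] = MISSING
    # 32 markers missing in 60 % of individuals
    for j in range(n_fail, n_fail + n_high_missing):
        miss = rng.choice(n_ind, size=int(0.6 * n_ind) + 1, replace=False)
        calls[miss, j] = MISSING

    # individuals: 11 all-missing, 5 with 60 % missing
    # place 2+2 all-missing in the last two 5-individual accessions (which
    # then fall below 4 members), the other 7 in distinct 6-ind accessions
    ind_index = {ind: i for i, ind in enumerate(individual_ids)}
    all_missing = [
        "acc79i1", "acc79i2", "acc80i1", "acc80i2",
        "acc10i1", "acc11i1", "acc12i1", "acc13i1", "acc14i1", "acc15i1", "acc16i1",
    ]
    for ind in all_missing:
        calls[ind_index[ind], :] = MISSING
    high_missing = ["acc20i1", "acc21i1", "acc22i1", "acc23i1", "acc24i1"]
    for ind in high_missing:
        i = ind_index[ind]
        miss = rng.choice(768, size=int(0.6 * 768), replace=False)
        calls[i, miss] = MISSING

    return GenotypeMatrix(tuple(individual_ids), tuple(marker_ids), calls, accession_of)


QC_DEMO_MANUAL_EXCLUSIONS = ("acc01", "acc02")  # 12 individuals, taxon doubts
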
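"""Haplotype merging of neighbouring mapped SNPs and the ascertainment-bias
diagnostic.

Mapped SNPs are partitioned per chromosome into consecutive, disjoint blocks
of k SNPs (k = 1..5).  Haplotype frequencies within a block are estimated
from unphased diploid genotypes with an Excoffier–Slatkin-style EM algorithm
over the 2^k-haplotype simplex; individuals missing any member SNP are
excluded from that block.  Gene diversity of the merged loci,
He_hap = 1 − Σ f_h², is averaged over blocks per group, and the ratio of each
group's He_hap to a reference group's He_hap traces how relative diversity
changes with block length: under discovery-panel ascertainment bias the
non-discovery groups' ratio rises with k, because merging SNPs into
multi-allelic haplotypes restores variation the per-SNP discovery filter
suppressed.

A simpler alternative estimator treats each distinct multilocus genotype
string as an allele (``mode="genotype_string"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_qc import GenotypeMatrix, MarkerMap, MISSING


@dataclass(frozen=True)
class BlockSpec:
    block_id: str
    chromosome: str
    members: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HaplotypeFreqs:
    block_id: str
    freqs: dict[str, float]  # haplotype string ('0'/'1' per SNP) → frequency
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_individuals: int

    @property
    def diversity(self) -> float:
        """Gene diversity 1 − Σ f²."""
        f = np.fromiter(self.freqs.values(), float)
        return float(1.0 - np.sum(f * f))


@dataclass(frozen=True)
class BiasCurve:
    group: str
    he_by_k: dict[int, float]
    ratio_by_k: dict[int, float]  # He(group)/He(reference) per k


def define_blocks(
    marker_map: MarkerMap, markers_present: Iterable[str], k: int
) -> list[BlockSpec]:
    """Partition mapped markers into consecutive disjoint k-SNP windows.

    Per chromosome, markers are sorted by cM position (ties broken by marker
    id) and cut into ⌊n/k⌋ full windows; the remainder is dropped.  Unmapped
    markers are never used.
    """
    if not 1 <= k <= 5:
        raise ValueError("k must be in 1..5")
    blocks = []
    for chrom, ordered in marker_map.chromosome_order(list(markers_present)).items():
        for w in range(len(ordered) // k):
            members = tuple(ordered[w * k : (w + 1) * k])
            blocks.append(BlockSpec(f"{chrom}:b{w}:k{k}", chrom, members))
    return blocks


# ---------------------------------------------------------------------------
# EM estimation of haplotype frequencies from unphased genotypes
# ---------------------------------------------------------------------------


def _compatible_pairs(geno: tuple[int, ...]) -> list[tuple[int, int]]:
    """Unordered haplotype-index pairs compatible with a multilocus genotype.

    Haplotypes are encoded as integers whose bit j is the allele at SNP j.
    A genotype with h heterozygous sites resolves into 2^(h-1) pairs (one
    when h = 0).
    """
    het_sites = [j for j, c in enumerate(geno) if c == 1]
    base = sum(1 << j for j, c in enumerate(geno) if c == 2)
    if not het_sites:
        return [(base, base)]
    pairs = set()
    first = het_sites[0]
    for assign in product((0, 1), repeat=len(het_sites) - 1):
        h1 = base | (1 << first)
        h2 = base
        for s, a in zip(het_sites[1:], assign):
            if a:
                h1 |= 1 << s
            else:
                h2 |= 1 << s
        pairs.add((min(h1, h2), max(h1, h2)))
    return sorted(pairs)


def _hap_label(h: int, k: int) -> str:
    return "".join("1" if h >> j & 1 else "0" for j in range(k))


def em_haplotype_frequencies(
    g: GenotypeMatrix,
    members: Iterable[str],
    block: BlockSpec | Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 5,
    seed: int = 0,
) -> HaplotypeFreqs:
    """Maximum-likelihood haplotype frequencies for one block via EM.

    The E-step distributes each multilocus genotype over its compatible
    haplotype pairs in proportion to current pair probabilities (2·f1·f2, or
    f² for a homozygous resolution); the M-step re-estimates frequencies from
    the expected haplotype counts.  The best of ``n_restarts`` runs (uniform
    start plus seeded random starts) is returned.  The log-likelihood is
    non-decreasing within a run.
    """
    members = list(members)
    marker_ids = block.members if isinstance(block, BlockSpec) else tuple(block)
    block_id = block.block_id if isinstance(block, BlockSpec) else "+".join(marker_ids)
    k = len(marker_ids)
    calls = g.calls[np.ix_(g.individual_index(members), g.marker_index(marker_ids))]
    complete = ~(calls == MISSING).any(axis=1)
    calls = calls[complete]
    n = calls.shape[0]
    if n == 0:
        raise ValueError(f"no individuals with complete calls at block {block_id}")

    # collapse to genotype classes
    classes: dict[tuple[int, ...], int] = {}
    for row in calls:
        key = tuple(int(c) for c in row)
        classes[key] = classes.get(key, 0) + 1
    geno_pairs = [(_compatible_pairs(gt), cnt) for gt, cnt in sorted(classes.items())]

    n_h = 1 << k
    if all(len(pairs) == 1 for pairs, _ in geno_pairs):
        # phase-unambiguous data: the MLE is direct haplotype counting
        counts = np.zeros(n_h)
        ll = 0.0
        for ((a, b),), cnt in geno_pairs:
            counts[a] += cnt
            counts[b] += cnt
        f = counts / (2.0 * n)
        for ((a, b),), cnt in geno_pairs:
            pair_p = f[a] * f[b] if a == b else 2.0 * f[a] * f[b]
            ll += cnt * np.log(pair_p)
        freqs = {_hap_label(h, k): float(f[h]) for h in range(n_h) if f[h] > 1e-12}
        return HaplotypeFreqs(block_id, freqs, float(ll), 1, True, n)

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, int, bool] | None = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            f = np.full(n_h, 1.0 / n_h)
        else:
            f = rng.dirichlet(np.ones(n_h))
        ll_prev = -np.inf
        converged = False
        for it in range(1, max_iter + 1):
            counts = np.zeros(n_h)
            ll = 0.0
            for pairs, cnt in geno_pairs:
                w = np.array(
                    [f[a] * f[b] if a == b else 2.0 * f[a] * f[b] for a, b in pairs]
                )
                tot = w.sum()
                if tot <= 0:
                    # degenerate start gave this genotype zero mass; restart
                    ll = -np.inf
                    break
                ll += cnt * np.log(tot)
                w /= tot
                for (a, b), wi in zip(pairs, w):
                    counts[a] += cnt * wi
                    counts[b] += cnt * wi
            if not np.isfinite(ll):
                break
            f = counts / (2.0 * n)
            if abs(ll - ll_prev) < tol:
                converged = True
                ll_prev = ll
                break
            ll_prev = ll
        if best is None or ll_prev > best[0]:
            best = (ll_prev, f, it, converged)

    ll, f, iters, converged = best
    f = np.clip(f, 0.0, None)
    f /= f.sum()
    freqs = {_hap_label(h, k): float(f[h]) for h in range(n_h) if f[h] > 1e-12}
    return HaplotypeFreqs(block_id, freqs, float(ll), iters, converged, n)


def genotype_string_frequencies(
    g: GenotypeMatrix, members: Iterable[str], block: BlockSpec | Sequence[str]
) -> HaplotypeFreqs:
    """Alternative estimator: each distinct multilocus genotype string is
    treated as one allele of a collapsed locus (no phase resolution)."""
    members = list(members)
    marker_ids = block.members if isinstance(block, BlockSpec) else tuple(block)
    block_id = block.block_id if isinstance(block, BlockSpec) else "+".join(marker_ids)
    calls = g.calls[np.ix_(g.individual_index(members), g.marker_index(marker_ids))]
    complete = ~(calls == MISSING).any(axis=1)
    calls = calls[complete]
    if calls.shape[0] == 0:
        raise ValueError(f"no individuals with complete calls at block {block_id}")
    labels, counts = np.unique(
        ["".join(str(int(c)) for c in row) for row in calls], return_counts=True
    )
    f = counts / counts.sum()
    return HaplotypeFreqs(
        block_id, dict(zip(labels, f.astype(float))), float("nan"), 0, True, calls.shape[0]
    )


# ---------------------------------------------------------------------------
# ascertainment-bias diagnostic curves
# ---------------------------------------------------------------------------


def group_block_diversity(
    g: GenotypeMatrix,
    members: Sequence[str],
    blocks: Sequence[BlockSpec],
    mode: str = "em",
    seed: int = 0,
) -> float:
    """Mean gene diversity over blocks for one group of individuals."""
    vals = []
    for b in blocks:
        try:
            if mode == "em":
                hf = em_haplotype_frequencies(g, members, b, seed=seed)
            elif mode == "genotype_string":
                hf = genotype_string_frequencies(g, members, b)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            vals.append(hf.diversity)
        except ValueError:
            continue  # block has no complete individuals in this group
    if not vals:
        raise ValueError("no blocks with data for this group")
    return float(np.mean(vals))


def haplotype_diversity_curve(
    g: GenotypeMatrix,
    marker_map: MarkerMap,
    grouping: Mapping[str, str],
    reference_group: str,
    ks: Iterable[int] = (1, 2, 3, 4, 5),
    mode: str = "em",
    seed: int = 0,
) -> list[BiasCurve]:
    """Per-group mean haplotype diversity and its ratio to a reference group,
    for each block length k.

    At k = 1 the blocks are single SNPs, so the curve anchors at the
    SNP-level diversity of the mapped markers.
    """
    groups: dict[str, list[str]] = {}
    for acc in g.accession_ids:
        if acc in grouping:
            groups.setdefault(grouping[acc], []).extend(g.members_of(acc))
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present")
    he: dict[str, dict[int, float]] = {lab: {} for lab in groups}
    for k in ks:
        blocks = define_blocks(marker_map, g.marker_ids, k)
        if not blocks:
            raise ValueError(f"no blocks of length {k} (no mapped markers?)")
        for lab, members in groups.items():
            he[lab][k] = group_block_diversity(g, members, blocks, mode=mode, seed=seed)
    curves = []
    for lab in groups:
        ratios = {}
        for k in he[lab]:
            ref = he[reference_group][k]
            if ref == 0:
                raise ValueError(f"reference group diversity is 0 at k={k}")
            ratios[k] = he[lab][k] / ref
        curves.append(BiasCurve(lab, dict(he[lab]), ratios))
    return curves


def curves_to_frame(curves: Sequence[BiasCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for k in sorted(c.he_by_k):
            rows.append({"group": c.group, "k": k, "He": c.he_by_k[k], "ratio": c.ratio_by_k[k]})
    return pd.DataFrame(rows)
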
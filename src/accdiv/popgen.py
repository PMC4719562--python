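"""Allele frequencies and per-locus / per-group diversity statistics.

For each biallelic SNP the package reports the number of alleles observed
(Na), observed heterozygosity (Ho, fraction of heterozygous calls), expected
heterozygosity under Hardy–Weinberg (He = 1 − p² − q², the unadjusted gene
diversity as computed by GenAlEx), and the fixation index
F = (He − Ho)/He (undefined at loci with He = 0).

Group summaries come in three modes:

* ``within_accession_mean`` — statistics per accession, then an unweighted
  mean over the group's accessions;
* ``group_total`` — statistics from allele frequencies pooled over every
  individual in the group;
* ``pooled_in_silico`` — statistics of the in-silico pooled pseudo-genotypes
  (see :mod:`accdiv.pooling`).

Also provided: the folded minor-allele-frequency spectrum and its neutral
expectation, the diagnostic in which SNP ascertainment from a narrow
discovery panel shows up as a deficit of rare alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_qc import GenotypeMatrix, HET, HOM_ALT, HOM_REF


@dataclass(frozen=True)
class LocusStats:
    marker_id: str
    n_calls: int
    p: float  # reference-allele frequency; nan when no calls
    na: int
    ho: float
    he: float
    f: float  # nan when He == 0


@dataclass(frozen=True)
class DiversitySummary:
    group: str
    mode: str  # within_accession_mean | group_total | pooled_in_silico
    n_accessions: int
    n_individuals: int
    na: float
    ho: float
    he: float
    f: float


@dataclass(frozen=True)
class SpectrumResult:
    bin_edges: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    m: int  # haploid sample size used for the neutral expectation


def _call_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker counts of (hom_ref, het, hom_alt, called)."""
    n_rr = (calls == HOM_REF).sum(axis=0)
    n_ra = (calls == HET).sum(axis=0)
    n_aa = (calls == HOM_ALT).sum(axis=0)
    return n_rr, n_ra, n_aa, n_rr + n_ra + n_aa


def allele_frequencies(g: GenotypeMatrix, members: Iterable[str]) -> pd.Series:
    """Reference-allele frequency per marker: p = (2·hom_ref + het)/(2·n_calls).

    Missing calls are excluded; markers with no calls get NaN.
    """
    members = list(members)
    if not members:
        raise ValueError("empty member set")
    calls = g.calls[g.individual_index(members)]
    n_rr, n_ra, _, n = _call_counts(calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, (2 * n_rr + n_ra) / (2.0 * n), np.nan)
    return pd.Series(p, index=list(g.marker_ids), name="p")


def locus_stats(g: GenotypeMatrix, members: Iterable[str]) -> pd.DataFrame:
    """Per-marker Na, Ho, He, F for the given individuals.

    Returns a DataFrame indexed by marker with columns
    ``n_calls, p, na, ho, he, f``; ``f`` is NaN where He = 0 and all
    statistics are NaN at markers without calls.
    """
    members = list(members)
    if not members:
        raise ValueError("empty member set")
    calls = g.calls[g.individual_index(members)]
    n_rr, n_ra, n_aa, n = _call_counts(calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, (2 * n_rr + n_ra) / (2.0 * n), np.nan)
        ho = np.where(n > 0, n_ra / n, np.nan)
    he = 1.0 - p**2 - (1.0 - p) ** 2
    has_ref = (2 * n_rr + n_ra) > 0
    has_alt = (2 * n_aa + n_ra) > 0
    na = np.where(n > 0, has_ref.astype(int) + has_alt.astype(int), 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(he > 0, (he - ho) / he, np.nan)
    return pd.DataFrame(
        {"n_calls": n, "p": p, "na": na, "ho": ho, "he": he, "f": f},
        index=list(g.marker_ids),
    )


def unbiased_he(he: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Small-sample-unbiased gene diversity 2n/(2n−1)·He (optional variant)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, 2 * n / (2.0 * n - 1) * he, np.nan)


def _mean_stats(stats: pd.DataFrame) -> dict[str, float]:
    """Across-locus means; F averaged only over loci where it is defined."""
    return {
        "na": float(stats["na"].mean()),
        "ho": float(stats["ho"].mean()),
        "he": float(stats["he"].mean()),
        "f": float(stats["f"].mean()),  # pandas mean skips NaN
    }


def summarize_diversity(
    g: GenotypeMatrix,
    grouping: Mapping[str, str],
    mode: str = "group_total",
    use_unbiased_he: bool = False,
) -> list[DiversitySummary]:
    """Diversity summary per group of accessions.

    ``grouping`` maps accession id → group label; accessions absent from the
    mapping are dropped.  ``within_accession_mean`` averages accession-level
    means with equal weight per accession; ``group_total`` recomputes the
    statistics from frequencies pooled over all the group's individuals.
    """
    if mode not in ("within_accession_mean", "group_total"):
        raise ValueError(f"unknown mode {mode!r}")
    groups: dict[str, list[str]] = {}
    for acc in g.accession_ids:
        if acc in grouping:
            groups.setdefault(grouping[acc], []).append(acc)
    if not groups:
        raise ValueError("grouping matches no accession in the matrix")
    out = []
    for label in groups:
        accs = groups[label]
        if not accs:
            raise ValueError(f"group {label!r} has zero accessions")
        members = [i for a in accs for i in g.members_of(a)]
        if mode == "group_total":
            stats = locus_stats(g, members)
            if use_unbiased_he:
                stats = stats.assign(he=unbiased_he(stats["he"].to_numpy(), stats["n_calls"].to_numpy()))
            vals = _mean_stats(stats)
        else:
            per_acc = []
            for a in accs:
                stats = locus_stats(g, g.members_of(a))
                if use_unbiased_he:
                    stats = stats.assign(he=unbiased_he(stats["he"].to_numpy(), stats["n_calls"].to_numpy()))
                per_acc.append(_mean_stats(stats))
            vals = {k: float(np.mean([d[k] for d in per_acc])) for k in per_acc[0]}
        out.append(
            DiversitySummary(
                group=label,
                mode=mode,
                n_accessions=len(accs),
                n_individuals=len(members),
                **vals,
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[DiversitySummary]) -> pd.DataFrame:
    """Table 2-style layout: group, mode, N, Na, Ho, He, F."""
    return pd.DataFrame(
        [
            {
                "group": s.group,
                "mode": s.mode,
                "n_accessions": s.n_accessions,
                "n_individuals": s.n_individuals,
                "Na": s.na,
                "Ho": s.ho,
                "He": s.he,
                "F": s.f,
            }
            for s in summaries
        ]
    )


# ---------------------------------------------------------------------------
# minor-allele-frequency spectrum
# ---------------------------------------------------------------------------


def neutral_folded_weights(m: int) -> np.ndarray:
    """Folded neutral site-frequency-spectrum weights for haploid sample size m.

    weight(i) ∝ (1/i + 1/(m−i)) / (1 + [i = m−i]) for minor counts
    i = 1..⌊m/2⌋, normalised to sum to 1.
    """
    if m < 2:
        raise ValueError("haploid sample size m must be >= 2")
    i = np.arange(1, m // 2 + 1)
    w = (1.0 / i + 1.0 / (m - i)) / (1.0 + (i == m - i))
    return w / w.sum()


def maf_spectrum(
    g: GenotypeMatrix,
    members: Iterable[str],
    n_bins: int = 10,
) -> SpectrumResult:
    """Observed and neutral-expected folded MAF histogram.

    The observed histogram counts polymorphic markers by minor-allele
    frequency.  The expectation uses the folded neutral spectrum at the
    group's median haploid sample size m (median of 2×non-missing
    individuals across markers, rounded down to even), mapped to the same
    frequency bins and scaled to the observed total.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("need at least 2 individuals")
    stats = locus_stats(g, members)
    called = stats[stats["n_calls"] > 0]
    maf = np.minimum(called["p"], 1 - called["p"]).to_numpy()
    poly = maf > 0
    maf = maf[poly]
    m = int(np.median(2 * called["n_calls"].to_numpy()))
    m -= m % 2
    if m < 2:
        raise ValueError("median haploid sample size below 2")
    edges = np.linspace(0, 0.5, n_bins + 1)
    observed, _ = np.histogram(maf, bins=edges)
    w = neutral_folded_weights(m)
    freqs = np.arange(1, m // 2 + 1) / m
    idx = np.clip(np.searchsorted(edges, freqs, side="right") - 1, 0, n_bins - 1)
    expected = np.zeros(n_bins)
    np.add.at(expected, idx, w)
    expected *= observed.sum()
    return SpectrumResult(bin_edges=edges, observed=observed, expected=expected, m=m)
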
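"""In-silico pooling of accessions.

Pooled-DNA genotyping of a whole accession is emulated by collapsing its
individuals into one pseudo-genotype per marker: with equal weight per
non-missing individual, the accession is scored heterozygous when the
frequency of its more common allele is below a cutoff (default 0.75), and
homozygous for the major allele otherwise (a frequency of exactly 0.75 is
*not* below the cutoff and yields a homozygous call; a 0.5 tie is below and
yields a heterozygote).  Diversity of the pooled pseudo-genotypes, treated as
one diploid individual per accession, quantifies how much of a group's gene
diversity a pooled genotyping strategy would have captured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_qc import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING, export_structure_input
from .popgen import DiversitySummary, _mean_stats, locus_stats


@dataclass(frozen=True)
class PoolingConfig:
    cutoff: float = 0.75

    def __post_init__(self) -> None:
        if not 0.5 < self.cutoff <= 1:
            raise ValueError("cutoff must be in (0.5, 1]")


def pool_accession_genotypes(
    g: GenotypeMatrix, cfg: PoolingConfig = PoolingConfig()
) -> GenotypeMatrix:
    """One pooled pseudo-genotype per accession.

    The pooled call is expressed in the same ref/alt coding as the input:
    hom_ref / hom_alt when the major allele (ref or alt) reaches the cutoff,
    het when the major-allele frequency is below it, missing when no
    individual had a call.  Returned as a GenotypeMatrix whose "individuals"
    are the accessions themselves (each its own accession), so every
    downstream statistic applies unchanged.
    """
    accs = g.accession_ids
    pooled = np.full((len(accs), g.n_markers), MISSING, dtype=np.int8)
    for k, acc in enumerate(accs):
        calls = g.calls[g.individual_index(g.members_of(acc))]
        n_rr = (calls == HOM_REF).sum(axis=0)
        n_ra = (calls == HET).sum(axis=0)
        n_aa = (calls == HOM_ALT).sum(axis=0)
        n = n_rr + n_ra + n_aa
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (2 * n_rr + n_ra) / (2.0 * n)
        major = np.maximum(p, 1 - p)
        call = np.where(
            major < cfg.cutoff, HET, np.where(p >= 0.5, HOM_REF, HOM_ALT)
        ).astype(np.int8)
        call[n == 0] = MISSING
        pooled[k] = call
    return GenotypeMatrix(accs, g.marker_ids, pooled, {a: a for a in accs})


def pooled_diversity(
    g: GenotypeMatrix,
    pooled: GenotypeMatrix,
    grouping: Mapping[str, str],
) -> tuple[list[DiversitySummary], pd.DataFrame]:
    """Group-level diversity of the pooled pseudo-genotypes plus capture
    fractions.

    Each accession's pooled call counts as one diploid individual.  The
    capture fraction per group is pooled group-total He divided by the
    un-pooled group-total He computed from all the group's individuals; it
    can exceed 1 when pooling symmetrises frequencies.
    """
    groups: dict[str, list[str]] = {}
    for acc in g.accession_ids:
        if acc in grouping:
            groups.setdefault(grouping[acc], []).append(acc)
    summaries = []
    rows = []
    for label, accs in sorted(groups.items()):
        pstats = locus_stats(pooled, accs)
        vals = _mean_stats(pstats)
        members = [i for a in accs for i in g.members_of(a)]
        tstats = locus_stats(g, members)
        he_total = float(tstats["he"].mean())
        if he_total == 0:
            raise ValueError(f"group {label!r} has zero total He")
        summaries.append(
            DiversitySummary(
                group=label,
                mode="pooled_in_silico",
                n_accessions=len(accs),
                n_individuals=len(members),
                **vals,
            )
        )
        rows.append(
            {
                "group": label,
                "pooled_He": vals["he"],
                "total_He": he_total,
                "capture_fraction": vals["he"] / he_total,
            }
        )
    return summaries, pd.DataFrame(rows)


def export_pooled_structure_input(pooled: GenotypeMatrix, path) -> None:
    """STRUCTURE export with one pseudo-individual per accession."""
    export_structure_input(pooled, path)
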
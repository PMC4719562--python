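"""Principal component analysis of accession allele frequencies or individual
genotypes, the PC-dispersion within-accession statistic, and near-identical
individual detection.

PC dispersion summarises how spread out an accession's individuals are in the
full PC space (mean and variance of all pairwise Euclidean distances).
Because PCA is an orthogonal rotation of the centered (mean-imputed) data,
those distances equal the distances in the input space — the statistic is a
relative within-accession homogeneity measure, independent of how many
components one keeps.  Inflated dispersion *variance* flags accessions
containing near-duplicate individuals (clones or sampling artefacts), which
are detected directly by identity-by-state and can be dropped for a
re-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_qc import GenotypeMatrix, MISSING


@dataclass(frozen=True)
class PCAResult:
    labels: tuple[str, ...]
    coordinates: np.ndarray  # entities x components
    explained_variance: np.ndarray
    centering: np.ndarray
    coding: str  # "frequency" or "dosage012"

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.labels), columns=cols)


@dataclass(frozen=True)
class PCDispersion:
    accession_id: str
    n_individuals: int
    mean_distance: float
    var_distance: float  # population formula: divide by the number of pairs


def _svd_pca(x: np.ndarray, labels: Sequence[str], coding: str) -> PCAResult:
    """Column-centered unscaled PCA via SVD with a deterministic sign
    convention (largest-|loading| element of each component made positive)."""
    center = x.mean(axis=0)
    xc = x - center
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign convention on loadings
    for j in range(vt.shape[0]):
        i_max = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_max] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    coords = u * s
    n = x.shape[0]
    explained = s**2 / max(n - 1, 1)
    return PCAResult(tuple(labels), coords, explained, center, coding)


def accession_frequency_pca(freqs: pd.DataFrame) -> PCAResult:
    """PCA of the accession x locus allele-frequency matrix.

    Loci with an undefined frequency in any accession are dropped; columns
    are centered, not scaled; all components are retained.
    """
    if freqs.shape[0] < 2:
        raise ValueError("need at least 2 accessions")
    complete = freqs.dropna(axis=1)
    return _svd_pca(complete.to_numpy(float), list(freqs.index), "frequency")


def centered_imputed_dosages(g: GenotypeMatrix, members: Sequence[str]) -> np.ndarray:
    """0/1/2 dosage matrix with missing calls imputed by the locus mean,
    then column-centered (so imputed entries become exactly 0)."""
    calls = g.calls[g.individual_index(members)].astype(float)
    calls[calls == MISSING] = np.nan
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns handled below
        col_mean = np.nanmean(calls, axis=0)
    if np.isnan(col_mean).any():
        bad = [g.marker_ids[i] for i in np.flatnonzero(np.isnan(col_mean))]
        raise ValueError(f"loci with all calls missing among members: {bad[:5]}")
    filled = np.where(np.isnan(calls), col_mean, calls)
    return filled - col_mean


def individual_pca(g: GenotypeMatrix, members: Iterable[str] | None = None) -> PCAResult:
    """PCA of individual genotypes coded 0/1/2, missing imputed by the locus
    mean, columns centered and unscaled, all components retained."""
    members = list(members) if members is not None else list(g.individual_ids)
    if len(members) < 2:
        raise ValueError("need at least 2 individuals")
    xc = centered_imputed_dosages(g, members)
    res = _svd_pca(xc + 0.0, members, "dosage012")
    return res


def pc_dispersion(
    pca: PCAResult, grouping: Mapping[str, str]
) -> tuple[list[PCDispersion], list[str]]:
    """Mean and variance of all-pairs Euclidean distances in full PC space,
    per accession.  Accessions with fewer than 2 individuals in the PCA are
    skipped and returned in the notice list."""
    by_acc: dict[str, list[int]] = {}
    for i, lab in enumerate(pca.labels):
        acc = grouping.get(lab)
        if acc is not None:
            by_acc.setdefault(acc, []).append(i)
    out, skipped = [], []
    for acc in sorted(by_acc):
        idx = by_acc[acc]
        if len(idx) < 2:
            skipped.append(acc)
            continue
        pts = pca.coordinates[idx]
        dists = []
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                dists.append(float(np.linalg.norm(pts[a] - pts[b])))
        dists = np.array(dists)
        out.append(
            PCDispersion(acc, len(idx), float(dists.mean()), float(dists.var()))
        )
    return out, skipped


def dispersion_to_frame(disp: Sequence[PCDispersion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": d.accession_id,
                "n": d.n_individuals,
                "mean_pc_distance": d.mean_distance,
                "var_pc_distance": d.var_distance,
            }
            for d in disp
        ]
    )


# ---------------------------------------------------------------------------
# near-identical individuals
# ---------------------------------------------------------------------------


def ibs_proportion(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Identity-by-state: fraction of shared non-missing loci with the same
    call.  Returns (proportion, number of shared loci)."""
    shared = (a != MISSING) & (b != MISSING)
    n = int(shared.sum())
    if n == 0:
        return float("nan"), 0
    return float((a[shared] == b[shared]).mean()), n


def flag_near_identical(
    g: GenotypeMatrix,
    ibs_threshold: float = 0.99,
    min_shared: int = 100,
) -> pd.DataFrame:
    """Within-accession pairs whose IBS proportion reaches the threshold.

    Returns a frame with columns accession, individual_a, individual_b, ibs,
    n_shared (ids sorted lexicographically within a pair)."""
    if not 0 < ibs_threshold <= 1:
        raise ValueError("ibs_threshold must be in (0, 1]")
    rows = []
    for acc in g.accession_ids:
        members = sorted(g.members_of(acc))
        idx = g.individual_index(members)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                ibs, n = ibs_proportion(g.calls[idx[a]], g.calls[idx[b]])
                if n >= min_shared and ibs >= ibs_threshold:
                    rows.append(
                        {
                            "accession": acc,
                            "individual_a": members[a],
                            "individual_b": members[b],
                            "ibs": ibs,
                            "n_shared": n,
                        }
                    )
    return pd.DataFrame(rows, columns=["accession", "individual_a", "individual_b", "ibs", "n_shared"])


def drop_flagged_duplicates(g: GenotypeMatrix, flags: pd.DataFrame) -> GenotypeMatrix:
    """Remove one member of each flagged pair (keep the lexicographically
    first id) so diversity/FST can be re-emitted for comparison."""
    drop: set[str] = set()
    for _, row in flags.iterrows():
        a, b = sorted([row["individual_a"], row["individual_b"]])
        if a not in drop:
            drop.add(b)
    keep = [i for i in g.individual_ids if i not in drop]
    return g.subset(keep)
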
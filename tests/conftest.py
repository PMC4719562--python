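"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from accdiv import GenotypeMatrix

TOKEN_TO_CODE = {"AA": 0, "AB": 1, "BB": 2, "..": -1}


def gm(rows: dict[str, tuple[str, str]]) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {individual: (accession, "AA AB ..")}."""
    inds = tuple(rows)
    acc = {i: rows[i][0] for i in inds}
    calls = np.array(
        [[TOKEN_TO_CODE[t] for t in rows[i][1].split()] for i in inds], dtype=np.int8
    )
    markers = tuple(f"m{j + 1}" for j in range(calls.shape[1]))
    return GenotypeMatrix(inds, markers, calls, acc)


def random_matrix(
    rng: np.random.Generator,
    n_acc: int = 3,
    n_per_acc: int = 4,
    n_markers: int = 20,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    inds, acc = [], {}
    for a in range(n_acc):
        for i in range(n_per_acc):
            name = f"a{a}i{i}"
            inds.append(name)
            acc[name] = f"acc{a}"
    calls = rng.integers(0, 3, (len(inds), n_markers)).astype(np.int8)
    if missing_rate:
        calls[rng.random(calls.shape) < missing_rate] = -1
    markers = tuple(f"m{j}" for j in range(n_markers))
    return GenotypeMatrix(tuple(inds), markers, calls, acc)


# ---------------------------------------------------------------------------
# independent AMOVA oracle: coordinate route (complete data only)
# ---------------------------------------------------------------------------


def amova_ss_oracle(x: np.ndarray, acc: np.ndarray, grp: np.ndarray) -> dict[str, float]:
    """Definitional sums of squares from deviations of the coded data around
    group/accession/grand means, summed over loci.  For complete data this
    equals the AMOVA SS computed from pairwise squared distances."""
    ss_total = ((x - x.mean(axis=0)) ** 2).sum()
    ss_wp = 0.0
    for a in np.unique(acc):
        xa = x[acc == a]
        ss_wp += ((xa - xa.mean(axis=0)) ** 2).sum()
    ss_wg = 0.0
    for gl in np.unique(grp):
        xg = x[grp == gl]
        ss_wg += ((xg - xg.mean(axis=0)) ** 2).sum()
    return {
        "within_accessions": float(ss_wp),
        "among_accessions": float(ss_wg - ss_wp),
        "among_groups": float(ss_total - ss_wg),
        "total": float(ss_total),
    }


def amova_components_oracle(
    x: np.ndarray, acc: np.ndarray, grp: np.ndarray
) -> dict[str, float]:
    """Method-of-moments components obtained by solving the expected-mean-
    square equations numerically (independent of the package's algebra)."""
    ss = amova_ss_oracle(x, acc, grp)
    n = len(acc)
    accs, na = np.unique(acc, return_counts=True)
    groups = np.unique(grp)
    A, G = len(accs), len(groups)
    grp_of = {a: grp[acc == a][0] for a in accs}
    ng = {gl: int((grp == gl).sum()) for gl in groups}
    sum_na2_over_ng = sum(
        cnt**2 / ng[grp_of[a]] for a, cnt in zip(accs, na)
    )
    sum_na2 = float((na.astype(float) ** 2).sum())
    sum_ng2 = float(sum(v**2 for v in ng.values()))
    ms = {
        "within_accessions": ss["within_accessions"] / (n - A),
        "among_accessions": ss["among_accessions"] / (A - G) if A > G else 0.0,
        "among_groups": ss["among_groups"] / (G - 1) if G > 1 else 0.0,
    }
    # E[MS] = C @ sigma with sigma = (within, among_acc, among_grp)
    n_p = (n - sum_na2_over_ng) / (A - G) if A > G else 0.0
    n_pp = (sum_na2_over_ng - sum_na2 / n) / (G - 1) if G > 1 else 0.0
    n_ppp = (n - sum_ng2 / n) / (G - 1) if G > 1 else 0.0
    c = np.array([[1, 0, 0], [1, n_p, 0], [1, n_pp, n_ppp]])
    b = np.array([ms["within_accessions"], ms["among_accessions"], ms["among_groups"]])
    if G > 1:
        sigma = np.linalg.solve(c, b)
    else:
        sigma = np.array([b[0], (b[1] - b[0]) / n_p if n_p else 0.0, 0.0])
    return {
        "within_accessions": float(sigma[0]),
        "among_accessions": float(sigma[1]),
        "among_groups": float(sigma[2]),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
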
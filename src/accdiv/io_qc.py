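"""Genotype/metadata I/O and the quality-control filtering cascade.

The central container is :class:`GenotypeMatrix`: diploid biallelic calls for
individuals x markers, each call one of four states (homozygous reference,
heterozygous, homozygous alternate, missing), with every individual assigned
to exactly one accession (a genebank seed lot treated as a population
sample).  All downstream analyses — diversity statistics, AMOVA/FST,
haplotype merging, PCA, in-silico pooling — consume this object.

File formats:

* genotype wide TSV — header row ``individual<TAB>accession<TAB><marker ids>``,
  one row per individual, calls written in a declared token dialect
  (default ``AA/AB/BB/NA``);
* VCF — biallelic diploid sites only, read via a minimal text parser
  (``GT`` field), accession assignment supplied separately;
* passport metadata TSV (accession, taxon, biological type, zone,
  latitude, longitude, growth habit, exclude flag);
* marker map TSV (marker, chromosome, cM);
* STRUCTURE input (two rows per individual, integer alleles, missing −9).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

# integer call codes used throughout the package
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_CALL_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

#: default genotype token dialect for the wide-TSV format
DEFAULT_DIALECT: dict[str, int] = {"AA": HOM_REF, "AB": HET, "BB": HOM_ALT, "NA": MISSING}


class QCError(ValueError):
    """Raised when input tables or QC results violate a contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid biallelic calls for individuals x markers.

    ``calls`` is an int8 array of shape (n individuals, n markers) with codes
    0 = hom_ref, 1 = het, 2 = hom_alt, −1 = missing.  ``accession_of`` maps
    every individual id to its accession id.
    """

    individual_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    calls: np.ndarray
    accession_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.individual_ids)) != len(self.individual_ids):
            dupes = _duplicates(self.individual_ids)
            raise QCError(f"duplicate individual ids: {dupes}")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            dupes = _duplicates(self.marker_ids)
            raise QCError(f"duplicate marker ids: {dupes}")
        calls = np.asarray(self.calls, dtype=np.int8)
        if calls.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise QCError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.marker_ids)} markers"
            )
        bad = ~np.isin(calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise QCError(f"invalid call codes present: {np.unique(calls[bad])}")
        missing_acc = [i for i in self.individual_ids if i not in self.accession_of]
        if missing_acc:
            raise QCError(f"individuals without accession assignment: {missing_acc[:5]}")
        object.__setattr__(self, "calls", calls)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def accession_ids(self) -> tuple[str, ...]:
        """Accessions in order of first appearance among individuals."""
        seen: dict[str, None] = {}
        for ind in self.individual_ids:
            seen.setdefault(self.accession_of[ind], None)
        return tuple(seen)

    def members_of(self, accession_id: str) -> tuple[str, ...]:
        return tuple(i for i in self.individual_ids if self.accession_of[i] == accession_id)

    def individual_index(self, ids: Sequence[str]) -> np.ndarray:
        pos = {ind: k for k, ind in enumerate(self.individual_ids)}
        try:
            return np.array([pos[i] for i in ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise QCError(f"unknown individual id {exc}") from exc

    def marker_index(self, ids: Sequence[str]) -> np.ndarray:
        pos = {m: k for k, m in enumerate(self.marker_ids)}
        return np.array([pos[m] for m in ids], dtype=np.intp)

    def subset(
        self,
        individuals: Sequence[str] | None = None,
        markers: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        inds = tuple(individuals) if individuals is not None else self.individual_ids
        marks = tuple(markers) if markers is not None else self.marker_ids
        calls = self.calls[np.ix_(self.individual_index(inds), self.marker_index(marks))]
        acc = {i: self.accession_of[i] for i in inds}
        return GenotypeMatrix(inds, marks, calls, acc)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
            and dict(self.accession_of) == dict(other.accession_of)
        )


@dataclass(frozen=True)
class MarkerMap:
    """marker id → (chromosome, position in cM); absent markers are unmapped."""

    positions: Mapping[str, tuple[str, float]]

    def __post_init__(self) -> None:
        for m, (_, cm) in self.positions.items():
            if cm < 0:
                raise QCError(f"negative cM position for marker {m}")

    def chromosome_order(self, markers_present: Sequence[str]) -> dict[str, list[str]]:
        """Mapped markers grouped per chromosome, sorted by (cM, marker id)."""
        by_chrom: dict[str, list[tuple[float, str]]] = {}
        for m in markers_present:
            if m in self.positions:
                chrom, cm = self.positions[m]
                by_chrom.setdefault(chrom, []).append((cm, m))
        return {c: [m for _, m in sorted(v)] for c, v in sorted(by_chrom.items())}


@dataclass(frozen=True)
class AccessionRecord:
    taxon: str
    biological_type: str  # wild / feral / cultivated
    zone: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    growth_habit: str | None = None
    exclude_flag: bool = False

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise QCError(f"latitude {self.latitude} outside [-90, 90]")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise QCError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass(frozen=True)
class AccessionTable:
    records: Mapping[str, AccessionRecord]

    def group_of(self, key: str) -> dict[str, str]:
        """accession → group label for key in {taxon, biological_type, zone};
        accessions lacking the attribute are omitted."""
        out = {}
        for acc, rec in self.records.items():
            val = getattr(rec, key)
            if val is not None:
                out[acc] = val
        return out

    def coordinates(self) -> dict[str, tuple[float, float]]:
        return {
            acc: (rec.latitude, rec.longitude)
            for acc, rec in self.records.items()
            if rec.latitude is not None and rec.longitude is not None
        }


@dataclass(frozen=True)
class QCThresholds:
    """Filtering rules, applied in the fixed cascade order (see apply_qc)."""

    marker_total_fail: bool = True
    marker_missing_frac_max: float = 0.50
    drop_monomorphic: bool = True
    individual_all_missing: bool = True
    individual_missing_frac_max: float = 0.50
    accession_min_individuals: int = 4
    manual_exclusions: tuple[str, ...] = ()
    recheck_monomorphic: bool = False

    def __post_init__(self) -> None:
        for f in (self.marker_missing_frac_max, self.individual_missing_frac_max):
            if not 0 <= f <= 1:
                raise QCError(f"missingness fraction {f} outside [0, 1]")
        if self.accession_min_individuals < 1:
            raise QCError("accession_min_individuals must be >= 1")


@dataclass
class QCReport:
    """Counts and ids removed per rule, in application order."""

    rules: list[str] = field(default_factory=list)
    removed_ids: dict[str, list[str]] = field(default_factory=dict)
    n_markers_in: int = 0
    n_markers_out: int = 0
    n_individuals_in: int = 0
    n_individuals_out: int = 0
    thresholds: QCThresholds | None = None

    def record(self, rule: str, ids: Sequence[str]) -> None:
        self.rules.append(rule)
        self.removed_ids[rule] = list(ids)

    def count(self, rule: str) -> int:
        return len(self.removed_ids.get(rule, ()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": self.rules, "n_removed": [self.count(r) for r in self.rules]}
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for x in items:
        if x in seen and x not in dup:
            dup.append(x)
        seen.add(x)
    return dup


def read_genotype_table(
    path: str | Path | io.TextIOBase,
    dialect: Mapping[str, int] = DEFAULT_DIALECT,
) -> GenotypeMatrix:
    """Read the wide genotype TSV (individual, accession, one column per marker).

    Unknown genotype tokens and duplicated marker/individual ids are rejected.
    """
    if isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        text = Path(path).read_text()
    header = text.split("\n", 1)[0].split("\t")
    dup = _duplicates(header[2:])
    if dup:
        raise QCError(f"duplicate marker columns: {dup}")
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise QCError("genotype table needs individual, accession and >=1 marker column")
    marker_ids = header[2:]
    individual_ids = list(df.iloc[:, 0])
    dup = _duplicates(individual_ids)
    if dup:
        raise QCError(f"duplicate individual ids: {dup}")
    accession_of = dict(zip(individual_ids, df.iloc[:, 1]))
    tokens = df.iloc[:, 2:].to_numpy(dtype=object)
    unknown = set(tokens.ravel()) - set(dialect)
    if unknown:
        raise QCError(f"unknown genotype tokens: {sorted(unknown)}")
    lut = np.full(tokens.shape, MISSING, dtype=np.int8)
    for tok, code in dialect.items():
        lut[tokens == tok] = code
    return GenotypeMatrix(tuple(individual_ids), tuple(marker_ids), lut, accession_of)


def write_genotype_table(
    g: GenotypeMatrix,
    path: str | Path | io.TextIOBase,
    dialect: Mapping[str, int] = DEFAULT_DIALECT,
) -> None:
    inverse = {code: tok for tok, code in dialect.items()}
    rows = []
    for i, ind in enumerate(g.individual_ids):
        rows.append(
            [ind, g.accession_of[ind]] + [inverse[int(c)] for c in g.calls[i]]
        )
    df = pd.DataFrame(rows, columns=["individual", "accession", *g.marker_ids])
    df.to_csv(path, sep="\t", index=False)


def read_vcf(path: str | Path, accession_of: Mapping[str, str]) -> GenotypeMatrix:
    """Minimal VCF reader restricted to biallelic diploid sites (GT field).

    The reference allele is the VCF REF allele (first listed).  Sites with
    more than one ALT allele are rejected.
    """
    marker_ids: list[str] = []
    columns: list[list[int]] = []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            parts = line.split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt:
                raise QCError(f"site {vid or chrom + ':' + pos} has >2 alleles")
            name = vid if vid not in (".", "") else f"{chrom}:{pos}"
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            col = []
            for entry in parts[9:]:
                gt = entry.split(":")[gt_i].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles or gt in (".", "./."):
                    col.append(MISSING)
                else:
                    s = sum(int(a) for a in alleles)
                    if len(alleles) != 2 or s not in (0, 1, 2):
                        raise QCError(f"non-diploid-biallelic genotype {gt} at {name}")
                    col.append(s)
            marker_ids.append(name)
            columns.append(col)
    dup = _duplicates(marker_ids)
    if dup:
        raise QCError(f"duplicate marker ids in VCF: {dup}")
    calls = np.array(columns, dtype=np.int8).T if columns else np.zeros((len(samples), 0), np.int8)
    return GenotypeMatrix(tuple(samples), tuple(marker_ids), calls, dict(accession_of))


def read_marker_map(path: str | Path | io.TextIOBase) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str, 2: float})
    df.columns = ["marker", "chromosome", "cM"]
    return MarkerMap({r.marker: (r.chromosome, float(r.cM)) for r in df.itertuples()})


def write_marker_map(m: MarkerMap, path: str | Path | io.TextIOBase) -> None:
    rows = [(k, c, cm) for k, (c, cm) in m.positions.items()]
    pd.DataFrame(rows, columns=["marker", "chromosome", "cM"]).to_csv(
        path, sep="\t", index=False
    )


_META_COLS = [
    "accession", "taxon", "biological_type", "zone",
    "latitude", "longitude", "growth_habit", "exclude_flag",
]


def read_accession_table(path: str | Path | io.TextIOBase) -> AccessionTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    recs = {}
    for r in df.to_dict("records"):
        recs[r["accession"]] = AccessionRecord(
            taxon=r["taxon"],
            biological_type=r["biological_type"],
            zone=r.get("zone") or None,
            latitude=float(r["latitude"]) if r.get("latitude") else None,
            longitude=float(r["longitude"]) if r.get("longitude") else None,
            growth_habit=r.get("growth_habit") or None,
            exclude_flag=str(r.get("exclude_flag", "")).lower() in ("1", "true", "yes"),
        )
    return AccessionTable(recs)


def write_accession_table(t: AccessionTable, path: str | Path | io.TextIOBase) -> None:
    rows = []
    for acc, rec in t.records.items():
        rows.append(
            {
                "accession": acc,
                "taxon": rec.taxon,
                "biological_type": rec.biological_type,
                "zone": rec.zone or "",
                "latitude": "" if rec.latitude is None else repr(rec.latitude),
                "longitude": "" if rec.longitude is None else repr(rec.longitude),
                "growth_habit": rec.growth_habit or "",
                "exclude_flag": "1" if rec.exclude_flag else "",
            }
        )
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------


def apply_qc(g: GenotypeMatrix, t: QCThresholds = QCThresholds()) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC filtering cascade in fixed order.

    1. markers with no calls at all;
    2. markers missing in more than ``marker_missing_frac_max`` of individuals;
    3. monomorphic markers (evaluated on the individuals present now);
    4. individuals with zero calls;
    5. individuals above ``individual_missing_frac_max``;
    6. accessions left with fewer than ``accession_min_individuals``;
    7. manual exclusions (accession or individual ids);
    optional: re-check monomorphism after individual filtering (off by
    default — marker removal precedes individual screening).
    """
    if g.n_individuals == 0 or g.n_markers == 0:
        raise QCError("empty genotype matrix")

    report = QCReport(
        n_markers_in=g.n_markers, n_individuals_in=g.n_individuals, thresholds=t
    )
    markers = np.array(g.marker_ids)
    inds = np.array(g.individual_ids)
    calls = g.calls
    m_keep = np.ones(len(markers), bool)
    i_keep = np.ones(len(inds), bool)

    def _missing_frac_markers() -> np.ndarray:
        sub = calls[i_keep][:, :]
        return (sub == MISSING).mean(axis=0)

    # 1. markers that never produced a call
    if t.marker_total_fail:
        drop = m_keep & (_missing_frac_markers() == 1.0)
        report.record("marker_all_missing", markers[drop])
        m_keep &= ~drop
    # 2. markers with too much missing data
    frac = _missing_frac_markers()
    drop = m_keep & (frac > t.marker_missing_frac_max)
    report.record("marker_missing_frac", markers[drop])
    m_keep &= ~drop
    # 3. monomorphic markers
    if t.drop_monomorphic:
        drop = m_keep & _monomorphic_mask(calls[i_keep])
        report.record("marker_monomorphic", markers[drop])
        m_keep &= ~drop
    # 4. individuals with zero calls on the retained markers
    if t.individual_all_missing:
        sub = calls[:, m_keep]
        drop = i_keep & ((sub == MISSING).all(axis=1))
        report.record("individual_all_missing", inds[drop])
        i_keep &= ~drop
    # 5. individuals above the missing-fraction cap
    if not m_keep.any():
        raise QCError("QC removed every marker or every individual")
    sub = calls[:, m_keep]
    frac_i = (sub == MISSING).mean(axis=1)
    drop = i_keep & (frac_i > t.individual_missing_frac_max)
    report.record("individual_missing_frac", inds[drop])
    i_keep &= ~drop
    # 6. accessions with too few remaining individuals
    acc_of = np.array([g.accession_of[i] for i in g.individual_ids])
    sizes: dict[str, int] = {}
    for a in acc_of[i_keep]:
        sizes[a] = sizes.get(a, 0) + 1
    small = {a for a, n in sizes.items() if n < t.accession_min_individuals}
    drop = i_keep & np.isin(acc_of, sorted(small))
    report.record("accession_too_small", inds[drop])
    i_keep &= ~drop
    # 7. manual exclusions (ids may name accessions or individuals)
    excl = set(t.manual_exclusions)
    drop = i_keep & (np.isin(acc_of, sorted(excl)) | np.isin(inds, sorted(excl)))
    report.record("manual_exclusion", inds[drop])
    i_keep &= ~drop
    # optional monomorphism re-check on the final individual set
    if t.recheck_monomorphic and t.drop_monomorphic:
        drop = m_keep & _monomorphic_mask(calls[i_keep])
        report.record("marker_monomorphic_recheck", markers[drop])
        m_keep &= ~drop

    if not m_keep.any() or not i_keep.any():
        raise QCError("QC removed every marker or every individual")
    out = g.subset(list(inds[i_keep]), list(markers[m_keep]))
    report.n_markers_out = out.n_markers
    report.n_individuals_out = out.n_individuals
    return out, report


def _monomorphic_mask(calls: np.ndarray) -> np.ndarray:
    """Markers whose non-missing calls carry only one allele."""
    has_ref = ((calls == HOM_REF) | (calls == HET)).any(axis=0)
    has_alt = ((calls == HOM_ALT) | (calls == HET)).any(axis=0)
    any_call = (calls != MISSING).any(axis=0)
    return any_call & ~(has_ref & has_alt)


# ---------------------------------------------------------------------------
# STRUCTURE export
# ---------------------------------------------------------------------------

_ALLELE_ROWS = {
    HOM_REF: (1, 1),
    HET: (1, 2),
    HOM_ALT: (2, 2),
    MISSING: (-9, -9),
}


def export_structure_input(g: GenotypeMatrix, path: str | Path) -> None:
    """Write STRUCTURE-format input: two rows per individual, alleles 1/2,
    missing −9, accession index as the population label.  Byte-stable for a
    fixed input."""
    acc_index = {a: k + 1 for k, a in enumerate(g.accession_ids)}
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(g.marker_ids) + "\n")
        for i, ind in enumerate(g.individual_ids):
            pop = acc_index[g.accession_of[ind]]
            row_a = [str(_ALLELE_ROWS[int(c)][0]) for c in g.calls[i]]
            row_b = [str(_ALLELE_ROWS[int(c)][1]) for c in g.calls[i]]
            fh.write("\t".join([ind, str(pop), *row_a]) + "\n")
            fh.write("\t".join([ind, str(pop), *row_b]) + "\n")
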
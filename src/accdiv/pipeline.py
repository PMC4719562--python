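"""End-to-end orchestration: QC → diversity → haplotype bias → AMOVA /
distances → PCA + dispersion → pooling, with seeded permutations and a
deterministic TSV/JSON report bundle.

Inputs are either the three delimited text tables (genotypes, passport
metadata, marker map) or a named synthetic fixture.  Every stochastic step
takes its seed from the run config, and rerunning with the same config and
seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .distance import (
    amova,
    combined_fst_nei_frame,
    genotypic_distance_matrix,
    haversine_matrix,
    mantel_test,
    nei_distance_matrix,
    pairwise_fst,
)
from .haplotypes import curves_to_frame, haplotype_diversity_curve
from .io_qc import (
    AccessionTable,
    GenotypeMatrix,
    MarkerMap,
    QCThresholds,
    apply_qc,
    export_structure_input,
    read_accession_table,
    read_genotype_table,
    read_marker_map,
)
from .pca import dispersion_to_frame, flag_near_identical, individual_pca, pc_dispersion
from .pooling import PoolingConfig, pool_accession_genotypes, pooled_diversity
from .popgen import locus_stats, summaries_to_frame, summarize_diversity
from .simulate import make_fixture

log = logging.getLogger("accdiv")


@dataclass
class RunConfig:
    genotypes: str | None = None
    metadata: str | None = None
    marker_map: str | None = None
    fixture: str | None = None
    group_by: str = "taxon"  # taxon | biological_type | zone
    out_dir: str = "accdiv-out"
    seed: int = 17
    n_perm: int = 999
    qc: QCThresholds = field(default_factory=QCThresholds)
    pooling_cutoff: float = 0.75
    hap_ks: tuple[int, ...] = (1, 2, 3, 4, 5)
    hap_reference: str | None = None  # default: most diverse group
    run_haplotypes: bool = True
    run_amova: bool = True
    run_mantel: bool = True
    run_pca: bool = True
    run_pooling: bool = True

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True, default=str)


@dataclass
class ReportBundle:
    out_dir: Path
    tables: dict[str, pd.DataFrame]
    log_lines: list[str]

    def checksum(self) -> str:
        """Hash of every persisted table file, for determinism checks."""
        h = hashlib.sha256()
        for f in sorted(self.out_dir.glob("*.tsv")):
            h.update(f.name.encode())
            h.update(f.read_bytes())
        return h.hexdigest()


def _load_inputs(cfg: RunConfig) -> tuple[GenotypeMatrix, AccessionTable, MarkerMap | None]:
    if cfg.fixture:
        ds = make_fixture(cfg.fixture)
        return ds.genotypes, ds.accessions, ds.marker_map
    if not (cfg.genotypes and cfg.metadata):
        raise ValueError("either a fixture name or genotype+metadata paths are required")
    g = read_genotype_table(cfg.genotypes)
    meta = read_accession_table(cfg.metadata)
    mmap = read_marker_map(cfg.marker_map) if cfg.marker_map else None
    return g, meta, mmap


def _write(out: Path, name: str, frame: pd.DataFrame, index: bool = False) -> None:
    frame.to_csv(out / f"{name}.tsv", sep="\t", index=index, float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Run every enabled stage in dependency order and persist the bundle.

    A stage failure raises with the stage name; tables written by earlier
    stages stay on disk as partial artifacts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines: list[str] = []
    tables: dict[str, pd.DataFrame] = {}

    def note(msg: str) -> None:
        log.info(msg)
        lines.append(msg)

    note(f"accdiv {__version__} | seed={cfg.seed} n_perm={cfg.n_perm}")
    (out / "config.json").write_text(cfg.to_json() + "\n")
    note(f"config sha256={hashlib.sha256(cfg.to_json().encode()).hexdigest()[:16]}")

    stage = "load"
    try:
        g_raw, meta, mmap = _load_inputs(cfg)
        note(f"loaded {g_raw.n_individuals} individuals x {g_raw.n_markers} markers")

        stage = "qc"
        excl = tuple(a for a, r in meta.records.items() if r.exclude_flag)
        qc_thresholds = dataclasses.replace(
            cfg.qc, manual_exclusions=cfg.qc.manual_exclusions + excl
        )
        g, report = apply_qc(g_raw, qc_thresholds)
        tables["qc_report"] = report.to_frame()
        _write(out, "qc_report", tables["qc_report"])
        note(
            f"QC: {report.n_markers_out}/{report.n_markers_in} markers, "
            f"{report.n_individuals_out}/{report.n_individuals_in} individuals retained"
        )
        export_structure_input(g, out / "structure_input.txt")

        grouping = meta.group_of(cfg.group_by)
        grouping = {a: v for a, v in grouping.items() if a in g.accession_ids}

        stage = "diversity"
        rows = []
        rows += summarize_diversity(g, grouping, "within_accession_mean")
        rows += summarize_diversity(g, grouping, "group_total")
        acc_he = {}
        for acc in g.accession_ids:
            acc_he[acc] = float(locus_stats(g, g.members_of(acc))["he"].mean())
        tables["accession_he"] = pd.DataFrame(
            sorted(acc_he.items()), columns=["accession", "He"]
        )
        _write(out, "accession_he", tables["accession_he"])

        stage = "pooling"
        if cfg.run_pooling:
            pooled = pool_accession_genotypes(g, PoolingConfig(cfg.pooling_cutoff))
            pooled_sum, capture = pooled_diversity(g, pooled, grouping)
            rows += pooled_sum
            tables["pooling_capture"] = capture
            _write(out, "pooling_capture", capture)
            export_structure_input(pooled, out / "structure_input_pooled.txt")
        tables["diversity"] = summaries_to_frame(rows).sort_values(
            ["group", "mode"], kind="stable"
        )
        _write(out, "diversity", tables["diversity"])

        stage = "haplotype_bias"
        if cfg.run_haplotypes and mmap is not None:
            ref = cfg.hap_reference
            if ref is None:
                totals = tables["diversity"].query("mode == 'group_total'")
                ref = totals.loc[totals["He"].idxmax(), "group"]
                note(f"haplotype bias reference group: {ref}")
            from .haplotypes import define_blocks

            usable_ks = tuple(
                k for k in cfg.hap_ks if define_blocks(mmap, g.marker_ids, k)
            )
            dropped = set(cfg.hap_ks) - set(usable_ks)
            if dropped:
                note(f"haplotype bias: no full blocks for k in {sorted(dropped)}")
            if usable_ks:
                curves = haplotype_diversity_curve(
                    g, mmap, grouping, ref, ks=usable_ks, seed=cfg.seed
                )
                tables["bias_curves"] = curves_to_frame(curves)
                _write(out, "bias_curves", tables["bias_curves"])

        stage = "amova"
        if cfg.run_amova:
            res = amova(g, grouping, n_perm=cfg.n_perm, seed=cfg.seed)
            tables["amova"] = res.to_frame()
            _write(out, "amova", tables["amova"])
            fst, pmat = pairwise_fst(g, grouping, n_perm=cfg.n_perm, seed=cfg.seed)
            nei = nei_distance_matrix(g, grouping)
            tables["fst_nei"] = combined_fst_nei_frame(fst, nei)
            _write(out, "fst_nei", tables["fst_nei"], index=True)
            tables["fst_p"] = pmat
            _write(out, "fst_p", pmat, index=True)

        stage = "mantel"
        coords = meta.coordinates()
        coords = {a: c for a, c in coords.items() if a in g.accession_ids}
        if cfg.run_mantel and len(coords) >= 4:
            geo = haversine_matrix(coords)
            freq_rows = {}
            for acc in geo.labels:
                freq_rows[acc] = locus_stats(g, g.members_of(acc))["p"]
            from .distance import DistanceMatrix, nei_standard_distance
            import numpy as np

            k = len(geo.labels)
            gen = np.zeros((k, k))
            for i in range(k):
                for j in range(i + 1, k):
                    gen[i, j] = gen[j, i] = nei_standard_distance(
                        freq_rows[geo.labels[i]], freq_rows[geo.labels[j]]
                    )
            gend = DistanceMatrix(geo.labels, gen, "nei_D")
            mr = mantel_test(gend, geo, n_perm=cfg.n_perm, seed=cfg.seed)
            tables["mantel"] = pd.DataFrame(
                [{"r": mr.r, "p": mr.p, "n": mr.n, "n_perm": mr.n_perm, "tails": mr.tails}]
            )
            _write(out, "mantel", tables["mantel"])

        stage = "pca_dispersion"
        if cfg.run_pca:
            pca = individual_pca(g)
            disp, skipped = pc_dispersion(pca, dict(g.accession_of))
            tables["pc_dispersion"] = dispersion_to_frame(disp)
            _write(out, "pc_dispersion", tables["pc_dispersion"])
            flags = flag_near_identical(g)
            tables["near_identical"] = flags
            _write(out, "near_identical", flags)
            if skipped:
                note(f"PC dispersion skipped accessions with <2 individuals: {skipped}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "run.log").write_text("\n".join(lines) + "\n")
    return ReportBundle(out, tables, lines)
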
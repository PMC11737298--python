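"""Readers and writers for every on-disk format the pipeline touches.

Formats: the 10x-style MatrixMarket triple (matrix.mtx + features.tsv +
barcodes.tsv, optionally gzipped), a BED-like gene annotation TSV with
1-based starts, long-format clinical-lab CSVs, GMT gene sets, and bulk
cohort TSVs. Readers validate type invariants and raise
:class:`~mmlce.types.FormatError` / :class:`~mmlce.types.IntegrityError`
rather than silently coercing.
"""
from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import (
    DEFAULT_CHROMOSOMES,
    BulkCohort,
    ClinicalSeries,
    CountMatrix,
    FormatError,
    GeneAnnotation,
    GeneSet,
    IntegrityError,
)

log = logging.getLogger(__name__)


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FormatError(f"missing {stem}[.gz] in {dir_path}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_counts_mtx(dir_path: str | Path) -> CountMatrix:
    """Read a 10x-style triple (matrix.mtx, features.tsv, barcodes.tsv).

    ``barcodes.tsv`` may carry a second column with the per-cell
    sample/timepoint label; absent that, all cells are labeled "sample1".
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, "matrix.mtx")
    feat_path = _find(dir_path, "features.tsv")
    bc_path = _find(dir_path, "barcodes.tsv")

    with _open_text(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)

    features = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)
    gene_ids = features.iloc[:, 0].to_numpy(dtype=object)
    bcs = barcodes.iloc[:, 0].to_numpy(dtype=object)
    if barcodes.shape[1] >= 2:
        samples = barcodes.iloc[:, 1].to_numpy(dtype=object)
    else:
        samples = np.full(len(bcs), "sample1", dtype=object)

    if mat.shape[0] != len(gene_ids):
        raise IntegrityError(
            f"matrix has {mat.shape[0]} rows but features.tsv lists {len(gene_ids)} genes")
    if mat.shape[1] != len(bcs):
        raise IntegrityError(
            f"matrix has {mat.shape[1]} columns but barcodes.tsv lists {len(bcs)} cells")
    return CountMatrix(counts=mat, gene_ids=gene_ids, barcodes=bcs, cell_sample=samples)


def write_counts_mtx(cm: CountMatrix, dir_path: str | Path) -> None:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), cm.counts.astype(np.int64), field="integer")
    pd.DataFrame({"gene_id": cm.gene_ids}).to_csv(
        dir_path / "features.tsv", sep="\t", header=False, index=False)
    pd.DataFrame({"barcode": cm.barcodes, "sample": cm.cell_sample}).to_csv(
        dir_path / "barcodes.tsv", sep="\t", header=False, index=False)


def read_gene_annotation(path: str | Path,
                         chromosome_order: Sequence[str] = DEFAULT_CHROMOSOMES,
                         ) -> GeneAnnotation:
    """Read a BED-like TSV: gene_id, chromosome, start (1-based) [, mito_flag].

    When the mito flag column is absent the "MT-" name prefix (or MT
    chromosome) is used as a fallback, with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    cols = list(df.columns)
    rename = {cols[0]: "gene_id", cols[1]: "chromosome", cols[2]: "start_bp"}
    df = df.rename(columns=rename)
    if "mito_flag" in df.columns:
        df["is_mitochondrial"] = df["mito_flag"].astype(bool)
    elif "is_mitochondrial" in df.columns:
        df["is_mitochondrial"] = df["is_mitochondrial"].astype(bool)
    else:
        log.warning("annotation %s has no mito flag column; falling back to "
                    "'MT-' prefix / MT chromosome", path)
        df["is_mitochondrial"] = (df["gene_id"].str.startswith("MT-")
                                  | (df["chromosome"].astype(str) == "MT"))
    df["start_bp"] = df["start_bp"].astype(int)
    return GeneAnnotation(
        table=df[["gene_id", "chromosome", "start_bp", "is_mitochondrial"]],
        chromosome_order=tuple(str(c) for c in chromosome_order))


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    out = ann.table.rename(columns={"is_mitochondrial": "mito_flag"}).copy()
    out["mito_flag"] = out["mito_flag"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_clinical_series(path: str | Path) -> list[ClinicalSeries]:
    """Read long-format labs CSV: patient_id, t_days, m_spike, kappa, lambda[, calcium].

    Units are fixed by the schema: g/dL for M-spike, mg/dL for light chains.
    """
    df = pd.read_csv(path)
    df = df.rename(columns={"lambda": "lambda_"})
    required = {"patient_id", "t_days", "m_spike", "kappa", "lambda_"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"clinical CSV missing columns: {sorted(missing)}")
    series = []
    keep = [c for c in ("t_days", "m_spike", "kappa", "lambda_", "calcium")
            if c in df.columns]
    for pid, grp in df.groupby("patient_id", sort=True):
        iso = None
        if "affected_isotype" in grp.columns:
            vals = grp["affected_isotype"].dropna().unique()
            if len(vals):
                iso = str(vals[0])
        series.append(ClinicalSeries(
            patient_id=str(pid),
            visits=grp[keep].reset_index(drop=True),
            affected_isotype=iso))
    return series


def write_clinical_series(series: Sequence[ClinicalSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        v = s.visits.copy()
        v.insert(0, "patient_id", s.patient_id)
        if s.affected_isotype is not None:
            v["affected_isotype"] = s.affected_isotype
        rows.append(v)
    out = pd.concat(rows, ignore_index=True).rename(columns={"lambda_": "lambda"})
    out.to_csv(path, index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one gene set per tab-delimited line (name, desc, genes...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) != len(genes):
                log.warning("%s:%d: duplicate gene(s) in set %s deduplicated",
                            path, lineno, name)
            sets.append(GeneSet(name=name, up_genes=tuple(dict.fromkeys(genes))))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    """Write gene sets as GMT; a set with down-genes is written as two lines
    (``<name>_UP`` and ``<name>_DN``)."""
    with open(path, "w") as fh:
        for gs in sets:
            if gs.down_genes:
                fh.write("\t".join([gs.name + "_UP", "-"] + list(gs.up_genes)) + "\n")
                fh.write("\t".join([gs.name + "_DN", "-"] + list(gs.down_genes)) + "\n")
            else:
                fh.write("\t".join([gs.name, "-"] + list(gs.up_genes)) + "\n")


def read_bulk_cohort(expression_path: str | Path,
                     clinical_path: str | Path | None = None) -> BulkCohort:
    """Read a samples x genes expression TSV plus an optional clinical TSV.

    The expression table is indexed by its first column (sample id); the
    clinical table likewise and is aligned by sample id.
    """
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    if clinical_path is not None:
        clin = pd.read_csv(clinical_path, sep="\t", index_col=0)
        clin.index = clin.index.astype(str)
    else:
        clin = pd.DataFrame(index=expr.index)
    expr.index = expr.index.astype(str)
    return BulkCohort(expression=expr, clinical=clin)


def write_bulk_cohort(cohort: BulkCohort, expression_path: str | Path,
                      clinical_path: str | Path) -> None:
    cohort.expression.to_csv(expression_path, sep="\t")
    cohort.clinical.to_csv(clinical_path, sep="\t")
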
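"""Core in-memory containers for the light-chain-escape myeloma pipeline.

The substrate types are deliberately thin: sparse matrices for counts,
pandas for tables. Every constructor-time invariant is enforced by
``validate()`` so that readers and simulators can never hand downstream
stages a malformed object.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class FormatError(ValueError):
    """A file does not conform to its on-disk format."""


class IntegrityError(ValueError):
    """An in-memory object violates a type invariant."""


#: Default chromosome ordering used for genome-ordered concatenation.
DEFAULT_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

#: Immunoglobulin heavy-chain constant-region genes; their expression
#: separates intact-antibody secretors from light-chain-only myeloma cells.
IGH_CONSTANT_GENES: tuple[str, ...] = (
    "IGHM", "IGHD", "IGHG3", "IGHG1", "IGHA1", "IGHG2", "IGHG4", "IGHE", "IGHA2",
)

KAPPA_GENES: tuple[str, ...] = ("IGKC",)
LAMBDA_GENES: tuple[str, ...] = ("IGLC1", "IGLC2", "IGLC3")


@dataclass
class CountMatrix:
    """Genes x cells UMI counts with per-cell sample/timepoint labels."""

    counts: sp.csr_matrix  # genes x cells, nonnegative integers
    gene_ids: np.ndarray  # (n_genes,) unique strings
    barcodes: np.ndarray  # (n_cells,) unique strings
    cell_sample: np.ndarray  # (n_cells,) sample/timepoint label per cell

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.cell_sample = np.asarray(self.cell_sample, dtype=object)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if self.gene_ids.shape != (n_genes,):
            raise IntegrityError(
                f"gene_ids length {self.gene_ids.size} != matrix rows {n_genes}")
        if self.barcodes.shape != (n_cells,):
            raise IntegrityError(
                f"barcodes length {self.barcodes.size} != matrix columns {n_cells}")
        if self.cell_sample.shape != (n_cells,):
            raise IntegrityError("cell_sample must label every cell")
        if len(set(self.gene_ids)) != n_genes:
            raise IntegrityError("gene_ids are not unique")
        if len(set(self.barcodes)) != n_cells:
            raise IntegrityError("barcodes are not unique")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise IntegrityError("counts must be nonnegative integers")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[:, idx].tocsr(),
            gene_ids=self.gene_ids,
            barcodes=self.barcodes[idx],
            cell_sample=self.cell_sample[idx],
        )


@dataclass
class GeneAnnotation:
    """Per-gene genomic coordinates (1-based starts) and mitochondrial flags.

    Only the within-chromosome ordering of gene starts is consumed
    downstream (CNV smoothing), so no end coordinate or strand is kept.
    """

    table: pd.DataFrame  # columns: gene_id, chromosome, start_bp, is_mitochondrial
    chromosome_order: tuple[str, ...] = DEFAULT_CHROMOSOMES

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene_id", "chromosome", "start_bp", "is_mitochondrial"}
        missing = required - set(t.columns)
        if missing:
            raise IntegrityError(f"annotation missing columns: {sorted(missing)}")
        if t["gene_id"].duplicated().any():
            raise IntegrityError("duplicate gene_id in annotation")
        unknown = set(t["chromosome"].astype(str)) - set(self.chromosome_order)
        if unknown:
            raise FormatError(f"unknown chromosome label(s): {sorted(unknown)}")
        if (t["start_bp"] < 1).any():
            raise IntegrityError("start_bp must be >= 1 (1-based convention)")
        t = t.copy()
        t["chromosome"] = pd.Categorical(
            t["chromosome"].astype(str), categories=list(self.chromosome_order), ordered=True)
        t = t.sort_values(["chromosome", "start_bp"], kind="mergesort").reset_index(drop=True)
        self.table = t

    @property
    def gene_ids(self) -> np.ndarray:
        return self.table["gene_id"].to_numpy()

    def mito_genes(self) -> set[str]:
        return set(self.table.loc[self.table["is_mitochondrial"], "gene_id"])


@dataclass
class ClinicalSeries:
    """One patient's ordered serial labs: M-spike (g/dL) and free light chains (mg/dL)."""

    patient_id: str
    visits: pd.DataFrame  # columns: t_days, m_spike, kappa, lambda_ [, calcium]
    affected_isotype: Optional[str] = None  # "kappa" | "lambda" | None (infer)

    def __post_init__(self) -> None:
        v = self.visits
        required = {"t_days", "m_spike", "kappa", "lambda_"}
        missing = required - set(v.columns)
        if missing:
            raise IntegrityError(f"visits missing columns: {sorted(missing)}")
        v = v.sort_values("t_days", kind="mergesort").reset_index(drop=True)
        if (v["t_days"] < 0).any():
            raise IntegrityError("t_days must be >= 0")
        if v["t_days"].duplicated().any():
            raise IntegrityError(
                f"duplicate visit time for patient {self.patient_id}")
        for col in ("m_spike", "kappa", "lambda_"):
            if (v[col] < 0).any():
                raise IntegrityError(f"negative {col} for patient {self.patient_id}")
        if self.affected_isotype is not None and self.affected_isotype not in ("kappa", "lambda"):
            raise IntegrityError("affected_isotype must be 'kappa' or 'lambda'")
        self.visits = v

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass
class BulkCohort:
    """Bulk expression (samples x genes, TPM/intensity scale) with outcomes.

    ``clinical`` is indexed by sample and may carry: os_time (years),
    os_event (0/1), lytic_time (days), lytic_event (0/1),
    lesion_category in {"0","1","2","3+"}, lesion_count (continuous).
    Outcome columns are optional per sample (NaN allowed).
    """

    expression: pd.DataFrame  # samples x genes
    clinical: pd.DataFrame  # samples x outcome columns

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.clinical.index):
            # allow clinical to be a subset-ordered copy; align strictly
            if set(self.expression.index) != set(self.clinical.index):
                raise IntegrityError("expression and clinical sample sets differ")
            self.clinical = self.clinical.loc[self.expression.index]
        x = self.expression.to_numpy()
        if not np.all(np.isfinite(x)):
            raise IntegrityError("expression must be finite")
        if (x < 0).any():
            raise IntegrityError("expression must be nonnegative")
        for tcol in ("os_time", "lytic_time"):
            if tcol in self.clinical and np.nanmin(
                    self.clinical[tcol].to_numpy(dtype=float), initial=0.0) < 0:
                raise IntegrityError(f"{tcol} must be >= 0")
        for ecol in ("os_event", "lytic_event"):
            if ecol in self.clinical:
                vals = self.clinical[ecol].dropna().unique()
                if not set(vals) <= {0, 1, 0.0, 1.0, True, False}:
                    raise IntegrityError(f"{ecol} must be binary")

    @property
    def samples(self) -> pd.Index:
        return self.expression.index


@dataclass
class GeneSet:
    """A named signature: up-regulated genes and (optionally) down-regulated genes."""

    name: str
    up_genes: tuple[str, ...] = ()
    down_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.up_genes = tuple(dict.fromkeys(self.up_genes))
        self.down_genes = tuple(dict.fromkeys(self.down_genes))
        if set(self.up_genes) & set(self.down_genes):
            raise IntegrityError(f"gene set {self.name}: up and down overlap")
        if not self.up_genes and not self.down_genes:
            raise IntegrityError(f"gene set {self.name}: empty")


@dataclass
class NormalizedMatrix:
    """ln(1 + count/total * scale_factor) values, genes x cells, sparse."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    cell_sample: np.ndarray
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.cell_sample = np.asarray(self.cell_sample, dtype=object)
        if self.values.data.size and np.any(self.values.data < 0):
            raise IntegrityError("normalized values must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices of ``genes``; raises listing any absent gene."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, idx: np.ndarray) -> "NormalizedMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(
            values=self.values[:, idx].tocsr(),
            gene_ids=self.gene_ids,
            barcodes=self.barcodes[idx],
            cell_sample=self.cell_sample[idx],
            scale_factor=self.scale_factor,
        )
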
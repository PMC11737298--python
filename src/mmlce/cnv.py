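"""Expression-based copy-number inference and subclone tracking.

A simplified genome-smoothing approach: subtract the mean expression of a
reference (normal) cell set per gene, average over a moving window of
genome-ordered genes within each chromosome, median-center per cell and
clip. Chromosome-level gain/loss calls, hierarchical subclone clustering
with silhouette-selected k, and greedy cross-timepoint subclone matching
by signature correlation sit on top.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .types import CountMatrix, GeneAnnotation, IntegrityError, NormalizedMatrix

log = logging.getLogger(__name__)


@dataclass
class CNVMatrix:
    """Cells x genome-ordered windows of smoothed relative expression."""

    values: np.ndarray        # cells x windows, clipped to [-clip, +clip]
    window_map: pd.DataFrame  # per window: chromosome, gene_id, start_bp
    barcodes: np.ndarray
    cell_sample: np.ndarray
    clip: float = 1.0
    reference_id: str = "reference"

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.barcodes), len(self.window_map)):
            raise IntegrityError("CNVMatrix shape mismatch")
        if np.any(np.abs(self.values) > self.clip + 1e-9):
            raise IntegrityError("CNV values exceed clip bound")

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.window_map["chromosome"]))

    def chromosome_means(self) -> pd.DataFrame:
        """Per cell x chromosome mean window signal."""
        chrom = self.window_map["chromosome"].to_numpy()
        cols = {}
        for c in self.chromosomes:
            cols[c] = self.values[:, chrom == c].mean(axis=1)
        return pd.DataFrame(cols, index=pd.Index(self.barcodes, name="barcode"))


def smooth_cnv(norm: NormalizedMatrix, ann: GeneAnnotation,
               reference_barcodes: Sequence[str], window: int = 101,
               clip: float = 1.0, min_genes_per_chrom: int = 5,
               exclude_chromosomes: Sequence[str] = ("MT",),
               exclude_gene_prefixes: Sequence[str] = ("IGH", "IGK", "IGL"),
               ) -> CNVMatrix:
    """Smoothed, reference-subtracted expression along genomic coordinates.

    Chromosomes with fewer than ``min_genes_per_chrom`` annotated genes are
    excluded with a warning; the moving window shrinks at chromosome edges.
    Immunoglobulin genes are dropped by default: their enormous,
    clonotype-driven expression in plasma cells reflects secretory state,
    not genomic dosage, and would otherwise masquerade as focal CNVs.
    """
    reference_barcodes = list(reference_barcodes)
    if not reference_barcodes:
        raise IntegrityError("reference cell set is empty")
    bc_index = pd.Index(norm.barcodes)
    ref_pos = bc_index.get_indexer(reference_barcodes)
    if (ref_pos < 0).any():
        raise IntegrityError("reference barcodes not present in matrix")

    ann_t = ann.table[~ann.table["chromosome"].astype(str).isin(exclude_chromosomes)]
    ann_t = ann_t[ann_t["gene_id"].isin(set(norm.gene_ids))]
    if exclude_gene_prefixes:
        ann_t = ann_t[~ann_t["gene_id"].str.startswith(tuple(exclude_gene_prefixes))]
    sizes = ann_t.groupby("chromosome", observed=True).size()
    small = sizes[sizes < min_genes_per_chrom].index.astype(str).tolist()
    if small:
        log.warning("smooth_cnv: excluding chromosome(s) with <%d genes: %s",
                    min_genes_per_chrom, small)
        ann_t = ann_t[~ann_t["chromosome"].astype(str).isin(small)]
    if ann_t.empty:
        raise IntegrityError("no chromosome left after filtering")

    gene_order = ann_t["gene_id"].to_numpy()
    gidx = norm.gene_index(gene_order)
    dense = np.asarray(norm.values[gidx].todense(), dtype=float)  # genes x cells
    ref_mean = dense[:, ref_pos].mean(axis=1)
    signal = dense - ref_mean[:, None]

    chrom_arr = ann_t["chromosome"].astype(str).to_numpy()
    smoothed = np.empty_like(signal)
    for c in pd.unique(chrom_arr):
        rows = np.flatnonzero(chrom_arr == c)
        block = pd.DataFrame(signal[rows])
        smoothed[rows] = block.rolling(window, center=True, min_periods=1
                                       ).mean().to_numpy()
    smoothed -= np.median(smoothed, axis=0)[None, :]  # per-cell median-centering
    np.clip(smoothed, -clip, clip, out=smoothed)

    window_map = ann_t[["chromosome", "gene_id", "start_bp"]].reset_index(drop=True)
    window_map["chromosome"] = window_map["chromosome"].astype(str)
    return CNVMatrix(values=smoothed.T, window_map=window_map,
                     barcodes=norm.barcodes, cell_sample=norm.cell_sample,
                     clip=clip)


@dataclass
class EventCalls:
    calls: pd.DataFrame        # cells x chromosomes, values in {loss, neutral, gain}
    chrom_means: pd.DataFrame  # cells x chromosomes mean signal
    cell_sample: np.ndarray


def call_events(cnv: CNVMatrix, gain_thr: float = 0.1,
                loss_thr: float = -0.1) -> EventCalls:
    """Chromosome-level gain/loss calls from mean window signal."""
    means = cnv.chromosome_means()
    calls = pd.DataFrame("neutral", index=means.index, columns=means.columns,
                         dtype=object)
    calls = calls.mask(means > gain_thr, "gain").mask(means < loss_thr, "loss")
    return EventCalls(calls=calls, chrom_means=means, cell_sample=cnv.cell_sample)


def carrier_proportions(calls: EventCalls, chromosome: str, kind: str = "gain",
                        cells: Optional[Sequence[str]] = None) -> pd.Series:
    """Per-sample fraction of cells carrying a call on one chromosome.

    ``cells`` restricts the denominator (e.g. to myeloma cells only)."""
    df = pd.DataFrame({"call": calls.calls[chromosome].to_numpy(),
                       "sample": calls.cell_sample}, index=calls.calls.index)
    if cells is not None:
        df = df.loc[df.index.isin(set(cells))]
    return df.groupby("sample", sort=False)["call"].apply(
        lambda s: float((s == kind).mean()))


@dataclass
class SubcloneModel:
    labels: pd.Series         # barcode -> subclone id (int, 1-based)
    signatures: pd.DataFrame  # subclone x chromosome mean profile
    k: int
    silhouette: float
    sample: str = ""

    @property
    def proportions(self) -> pd.Series:
        return self.labels.value_counts(normalize=True).sort_index()


def cluster_subclones(cnv: CNVMatrix, k: Optional[int] = None,
                      k_max: int = 10, min_silhouette: float = 0.1,
                      min_cluster_size: int = 5,
                      sample: str = "") -> SubcloneModel:
    """Hierarchical clustering (average linkage, Euclidean) of per-cell
    chromosome-mean CNV profiles; k chosen by maximum mean silhouette over
    2..k_max unless fixed, falling back to k=1 below ``min_silhouette``.

    During the automatic search, clusterings containing a cluster smaller
    than ``min_cluster_size`` cells are skipped: average linkage happily
    splits off singleton outliers with deceptively high silhouette, and a
    "subclone" of a couple of cells is not interpretable anyway.
    """
    profiles = cnv.chromosome_means()
    n = len(profiles)
    if k is not None and k > n:
        raise IntegrityError(f"k={k} exceeds n_cells={n}")
    X = profiles.to_numpy()
    if n < 2 or np.allclose(X.std(axis=0), 0):
        labels = np.ones(n, dtype=int)
        return SubcloneModel(
            labels=pd.Series(labels, index=profiles.index, name="subclone"),
            signatures=pd.DataFrame([X.mean(axis=0)], index=[1],
                                    columns=profiles.columns),
            k=1, silhouette=float("nan"), sample=sample)
    Z = linkage(X, method="average", metric="euclidean")
    if k is not None:
        labels = fcluster(Z, t=k, criterion="maxclust")
        sil = silhouette_score(X, labels) if 1 < len(set(labels)) < n else float("nan")
        best_k, best_sil, best_labels = k, sil, labels
    else:
        best_k, best_sil, best_labels = 1, -np.inf, np.ones(n, dtype=int)
        for kk in range(2, min(k_max, n - 1) + 1):
            lab = fcluster(Z, t=kk, criterion="maxclust")
            if len(set(lab)) < 2:
                continue
            sizes = np.bincount(lab)
            if sizes[sizes > 0].min() < min_cluster_size:
                continue
            sil = silhouette_score(X, lab)
            if sil > best_sil + 1e-12:  # ties break toward smaller k
                best_k, best_sil, best_labels = len(set(lab)), sil, lab
        if best_sil < min_silhouette:
            best_k, best_sil, best_labels = 1, best_sil, np.ones(n, dtype=int)
    labels = pd.Series(best_labels, index=profiles.index, name="subclone")
    signatures = profiles.groupby(labels).mean()
    signatures.index.name = "subclone"
    return SubcloneModel(labels=labels, signatures=signatures, k=int(best_k),
                         silhouette=float(best_sil), sample=sample)


@dataclass
class TrackingResult:
    """Cross-timepoint subclone mapping (a partial injection per step)."""

    table: pd.DataFrame  # timepoint, subclone, proportion, mapped_to, status


def track_subclones(models: Sequence[SubcloneModel],
                    match_min: float = 0.8) -> TrackingResult:
    """Greedy matching of subclone signatures across consecutive timepoints
    by Pearson correlation; larger subclones match first, each later
    subclone is used at most once, matches below ``match_min`` are
    rejected (earlier unmatched -> extinct, later unmatched -> emergent)."""
    if len(models) < 2:
        raise IntegrityError("need >= 2 timepoints to track")
    for m in models:
        if len(m.labels) == 0:
            raise IntegrityError("timepoint with no cells")
    rows = []
    for ti, model in enumerate(models):
        props = model.proportions
        nxt = models[ti + 1] if ti + 1 < len(models) else None
        mapping: dict[int, Optional[int]] = {s: None for s in model.signatures.index}
        if nxt is not None:
            taken: set[int] = set()
            order = props.sort_values(ascending=False).index  # larger first
            for s in order:
                best, best_r = None, -np.inf
                a = model.signatures.loc[s].to_numpy()
                for t in nxt.signatures.index:
                    if t in taken:
                        continue
                    b = nxt.signatures.loc[t].to_numpy()
                    if a.std() == 0 or b.std() == 0:
                        continue
                    r = float(np.corrcoef(a, b)[0, 1])
                    if r > best_r:
                        best, best_r = t, r
                if best is not None and best_r >= match_min:
                    mapping[s] = best
                    taken.add(best)
        prev_targets = set()
        if ti > 0:
            prev_targets = {r["mapped_to"] for r in rows
                            if r["timepoint"] == models[ti - 1].sample
                            and r["mapped_to"] is not None}
        for s in model.signatures.index:
            if nxt is None:
                status = "terminal"
            elif mapping[s] is not None:
                status = "matched"
            else:
                status = "extinct"
            if ti > 0 and s not in prev_targets:
                status = status + "+emergent"
            rows.append({"timepoint": model.sample, "subclone": int(s),
                         "proportion": float(props.get(s, 0.0)),
                         "mapped_to": mapping[s], "status": status})
    table = pd.DataFrame(rows)
    # mass conservation check: proportions per timepoint sum to 1
    sums = table.groupby("timepoint")["proportion"].sum()
    if not np.allclose(sums, 1.0):
        raise IntegrityError("subclone proportions do not sum to 1")
    return TrackingResult(table=table)
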
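"""Single-cell pipeline stages.

QC filtering, ln CP10k normalization, dropout-curve variable-gene
selection, marker-rule cell typing with light-chain restriction,
IGH-based myeloma subpopulation splitting, logistic-regression
differential expression with Bonferroni adjustment, signature
derivation, hypergeometric pathway enrichment, and per-cell signature
scoring.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .simulate import DEFAULT_MARKER_GENES
from .types import (
    IGH_CONSTANT_GENES,
    KAPPA_GENES,
    LAMBDA_GENES,
    CountMatrix,
    GeneAnnotation,
    GeneSet,
    IntegrityError,
    NormalizedMatrix,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# QC and normalization

def qc_filter(raw: CountMatrix, ann: GeneAnnotation,
              min_genes: int = 250, max_mito: float = 0.10) -> CountMatrix:
    """Remove cells with <``min_genes`` detected genes or mitochondrial read
    fraction above ``max_mito``.

    Boundary convention: a cell with exactly ``min_genes`` detected genes and
    exactly ``max_mito`` mitochondrial fraction is retained.
    """
    missing = set(raw.gene_ids) - set(ann.gene_ids)
    if missing:
        raise IntegrityError(
            f"annotation missing {len(missing)} gene(s), e.g. {sorted(missing)[:5]}")
    csc = raw.counts.tocsc()
    detected = (csc > 0).sum(axis=0).A1
    totals = csc.sum(axis=0).A1
    mito_set = ann.mito_genes()
    mito_rows = np.array([g in mito_set for g in raw.gene_ids])
    mito_counts = csc[mito_rows].sum(axis=0).A1 if mito_rows.any() else np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    keep = (detected >= min_genes) & (mito_frac <= max_mito)
    for s in pd.unique(raw.cell_sample):
        m = raw.cell_sample == s
        log.info("qc_filter: sample %s retained %d/%d cells", s, int(keep[m].sum()),
                 int(m.sum()))
    return raw.subset_cells(keep)


def normalize(raw: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """ln(1 + count/total x scale_factor), per cell; zeros stay zero."""
    csc = raw.counts.tocsc().astype(float)
    totals = csc.sum(axis=0).A1
    if np.any(totals == 0):
        bad = raw.barcodes[np.flatnonzero(totals == 0)[0]]
        raise IntegrityError(f"cell with zero total counts: {bad}")
    scaled = csc.multiply(scale_factor / totals).tocsc()
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(
        values=scaled.tocsr(), gene_ids=raw.gene_ids, barcodes=raw.barcodes,
        cell_sample=raw.cell_sample, scale_factor=scale_factor)


# ---------------------------------------------------------------------------
# variable-gene selection (Michaelis-Menten dropout model)

def select_variable_genes(raw: CountMatrix, fdr: float = 0.05,
                          exclude_ig: bool = False) -> list[str]:
    """Select genes whose dropout rate exceeds the global Michaelis-Menten
    dropout curve.

    A global curve ``d = 1 - S/(K + S)`` is fit by least squares to per-gene
    (mean CP10k expression S_j, dropout rate d_j); each gene's own
    ``K_j = S_j d_j / (1 - d_j)`` is tested one-sided against the global K
    with a delta-method standard error on d_j, followed by BH adjustment.
    """
    if raw.n_cells < 50:
        raise IntegrityError("need >= 50 cells for dropout-curve fitting")
    csc = raw.counts.tocsc()
    totals = csc.sum(axis=0).A1
    n = raw.n_cells
    cp10k = csc.multiply(1e4 / np.maximum(totals, 1)).tocsr()
    S = np.asarray(cp10k.mean(axis=1)).ravel()
    d = 1.0 - (raw.counts > 0).sum(axis=1).A1 / n

    expressed = S > 0
    if not expressed.any():
        raise IntegrityError("all genes are zero")
    Se, de = S[expressed], d[expressed]

    def sse(K: float) -> float:
        pred = 1.0 - Se / (K + Se)
        return float(np.sum((de - pred) ** 2))

    K_hat = minimize_scalar(sse, bounds=(1e-6, max(Se.max(), 1.0) * 10),
                            method="bounded").x

    with np.errstate(divide="ignore", invalid="ignore"):
        Kj = np.where(de < 1, Se * de / (1 - de), np.inf)
        se = Se / np.maximum((1 - de) ** 2, 1e-300) * np.sqrt(de * (1 - de) / n)
    p = np.ones(len(Se))
    testable = (de > 0) & (de < 1) & (se > 0)
    z = (Kj[testable] - K_hat) / se[testable]
    p[testable] = scipy.stats.norm.sf(z)
    # d == 1 genes have no expression signal but infinite K; they are not
    # meaningful features and S>0 with d==1 cannot occur anyway

    padj = multipletests(p, method="fdr_bh")[1]
    genes = np.asarray(raw.gene_ids)[expressed][padj < fdr]
    out = [str(g) for g in genes]
    if exclude_ig:
        out = [g for g in out if not g.startswith(("IGH", "IGK", "IGL"))]
    return out


# ---------------------------------------------------------------------------
# cell typing and myeloma splitting

@dataclass
class CellTypeAssignment:
    labels: pd.Series          # barcode -> label
    scores: pd.DataFrame       # barcode x label marker scores
    restriction: pd.Series     # barcode -> kappa | lambda | ambiguous


def default_marker_map() -> dict[str, tuple[str, ...]]:
    m = {k: v for k, v in DEFAULT_MARKER_GENES.items() if k != "MM"}
    m["MM"] = DEFAULT_MARKER_GENES["MM"] + ("IGKC",)
    return m


def _mean_over_genes(norm: NormalizedMatrix, genes: Sequence[str]) -> np.ndarray:
    idx = norm.gene_index(genes)
    return np.asarray(norm.values[idx].mean(axis=0)).ravel()


def light_chain_restriction(norm: NormalizedMatrix,
                            kappa_genes: Sequence[str] = KAPPA_GENES,
                            lambda_genes: Sequence[str] = LAMBDA_GENES,
                            rho: float = 5.0, tau_lc: float = 0.5) -> pd.Series:
    """Per-cell light-chain restriction call (kappa / lambda / ambiguous)."""
    kappa_genes = [g for g in kappa_genes if g in set(norm.gene_ids)]
    lambda_genes = [g for g in lambda_genes if g in set(norm.gene_ids)]
    if not kappa_genes or not lambda_genes:
        raise IntegrityError("kappa and lambda gene lists must both be present")
    mk = _mean_over_genes(norm, kappa_genes)
    ml = _mean_over_genes(norm, lambda_genes)
    call = np.full(norm.n_cells, "ambiguous", dtype=object)
    call[(mk >= rho * ml) & (mk >= tau_lc)] = "kappa"
    call[(ml >= rho * mk) & (ml >= tau_lc)] = "lambda"
    return pd.Series(call, index=pd.Index(norm.barcodes, name="barcode"),
                     name="restriction")


def assign_cell_types(norm: NormalizedMatrix,
                      marker_map: Optional[Mapping[str, Sequence[str]]] = None,
                      tau_type: float = 0.5,
                      kappa_genes: Sequence[str] = KAPPA_GENES,
                      lambda_genes: Sequence[str] = LAMBDA_GENES,
                      rho: float = 5.0, tau_lc: float = 0.5) -> CellTypeAssignment:
    """Marker-rule typing: label = argmax mean marker expression if it
    reaches ``tau_type``, else unassigned; the MM label additionally
    requires an unambiguous light-chain restriction."""
    marker_map = dict(marker_map or default_marker_map())
    present = set(norm.gene_ids)
    for label, genes in marker_map.items():
        missing = [g for g in genes if g not in present]
        if missing:
            raise IntegrityError(f"marker gene(s) absent for {label}: {missing}")
    scores = pd.DataFrame(
        {label: _mean_over_genes(norm, list(genes))
         for label, genes in marker_map.items()},
        index=pd.Index(norm.barcodes, name="barcode"))
    best = scores.idxmax(axis=1)
    best_score = scores.max(axis=1)
    labels = best.where(best_score >= tau_type, "unassigned")
    restriction = light_chain_restriction(norm, kappa_genes, lambda_genes, rho, tau_lc)
    mm_bad = (labels == "MM") & (restriction == "ambiguous")
    labels = labels.mask(mm_bad, "unassigned")
    return CellTypeAssignment(labels=labels.rename("cell_type"),
                              scores=scores, restriction=restriction)


@dataclass
class MMsplit:
    labels: pd.Series     # MM barcode -> LCE_MM | IGH_MM
    igh_score: pd.Series  # MM barcode -> mean IGH constant-gene expression


def split_mm(norm: NormalizedMatrix, mm_barcodes: Sequence[str],
             igh_constant_genes: Sequence[str] = IGH_CONSTANT_GENES,
             tau_igh: float = 0.25) -> MMsplit:
    """Split myeloma cells into intact-IGH (IGH_MM) vs light-chain-only
    (LCE_MM) by mean IGH constant-region expression."""
    mm_barcodes = list(mm_barcodes)
    if not mm_barcodes:
        raise IntegrityError("empty MM cell set")
    bc_index = pd.Index(norm.barcodes)
    pos = bc_index.get_indexer(mm_barcodes)
    if (pos < 0).any():
        raise IntegrityError("MM barcodes not present in matrix")
    genes = [g for g in igh_constant_genes if g in set(norm.gene_ids)]
    if not genes:
        raise IntegrityError("no IGH constant-region genes present")
    sub = norm.subset_cells(pos)
    score = pd.Series(_mean_over_genes(sub, genes),
                      index=pd.Index(mm_barcodes, name="barcode"), name="igh_score")
    labels = pd.Series(np.where(score >= tau_igh, "IGH_MM", "LCE_MM"),
                       index=score.index, name="mm_subpopulation")
    return MMsplit(labels=labels, igh_score=score)


# ---------------------------------------------------------------------------
# differential expression

@dataclass
class DEResult:
    table: pd.DataFrame  # gene, l2fc, p_raw, p_adj, pct_1, pct_2, fallback
    group1: str = "group1"
    group2: str = "group2"
    universe_size: int = 0


def _loglik_logistic(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _fit_logistic_lrt(x: np.ndarray, y: np.ndarray, max_iter: int = 100
                      ) -> tuple[float, bool]:
    """LRT p-value of a single-covariate logistic fit vs intercept-only.

    Returns (p, converged). Newton-Raphson with step halving; the
    intercept-only log-likelihood is closed-form.
    """
    n = y.size
    pbar = y.mean()
    ll0 = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)) \
        if 0 < pbar < 1 else 0.0
    beta = np.array([np.log(pbar / (1 - pbar)), 0.0])
    X = np.column_stack([np.ones(n), x])
    ll_prev = _loglik_logistic(y, X @ beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # step halving to guarantee monotone likelihood ascent
        for _h in range(30):
            cand = beta + step
            ll_new = _loglik_logistic(y, X @ cand)
            if ll_new >= ll_prev - 1e-12:
                break
            step = step / 2
        beta = beta + step
        if abs(ll_new - ll_prev) < 1e-10 and np.linalg.norm(step) < 1e-8:
            converged = True
            ll_prev = ll_new
            break
        ll_prev = ll_new
        if abs(beta[1]) > 50:  # diverging slope: quasi-separation
            break
    if not converged:
        return 1.0, False
    lr = max(0.0, 2.0 * (ll_prev - ll0))
    return float(scipy.stats.chi2.sf(lr, df=1)), True


def differential_expression(norm: NormalizedMatrix,
                            group1: Sequence[str], group2: Sequence[str],
                            min_pct: float = 0.10, n_min: int = 3,
                            bonferroni_universe: str = "all",
                            max_iter: int = 100,
                            group1_name: str = "group1",
                            group2_name: str = "group2") -> DEResult:
    """Logistic-regression DE between two cell groups.

    Per gene detected in >= ``min_pct`` of either group: likelihood-ratio
    test (chi-square, 1 df) of group membership on normalized expression;
    l2FC on de-logged group means with pseudocount 1; Bonferroni over the
    declared universe ("all" genes in the matrix or only "tested" genes).
    Non-converging fits fall back to the rank-sum test and are flagged.
    """
    if bonferroni_universe not in ("all", "tested"):
        raise ValueError("bonferroni_universe must be 'all' or 'tested'")
    bc_index = pd.Index(norm.barcodes)
    i1 = bc_index.get_indexer(list(group1))
    i2 = bc_index.get_indexer(list(group2))
    if (i1 < 0).any() or (i2 < 0).any():
        raise IntegrityError("group barcodes not present in matrix")
    if len(i1) < n_min or len(i2) < n_min:
        raise IntegrityError(f"both groups need >= {n_min} cells")

    csr = norm.values.tocsr()
    X1 = csr[:, i1]
    X2 = csr[:, i2]
    n1, n2 = len(i1), len(i2)
    pct1 = (X1 > 0).sum(axis=1).A1 / n1
    pct2 = (X2 > 0).sum(axis=1).A1 / n2
    tested_mask = (pct1 >= min_pct) | (pct2 >= min_pct)
    tested = np.flatnonzero(tested_mask)

    # l2FC on de-logged (CP-scale) group means with pseudocount 1
    e1 = np.asarray(X1.copy().expm1().mean(axis=1)).ravel()
    e2 = np.asarray(X2.copy().expm1().mean(axis=1)).ravel()
    l2fc_all = np.log2(e1 + 1.0) - np.log2(e2 + 1.0)

    y = np.concatenate([np.ones(n1), np.zeros(n2)])
    Xd1 = np.asarray(X1.todense())
    Xd2 = np.asarray(X2.todense())

    p_raw = np.ones(norm.n_genes)
    fallback = np.zeros(norm.n_genes, dtype=bool)
    for gi in tested:
        x = np.concatenate([Xd1[gi], Xd2[gi]])
        if np.all(x == x[0]):
            p_raw[gi] = 1.0
            continue
        p, ok = _fit_logistic_lrt(x, y, max_iter=max_iter)
        if not ok:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = scipy.stats.ranksums(Xd1[gi], Xd2[gi]).pvalue
            fallback[gi] = True
        p_raw[gi] = p

    m = norm.n_genes if bonferroni_universe == "all" else len(tested)
    p_adj = np.minimum(1.0, p_raw * m)
    table = pd.DataFrame({
        "gene": norm.gene_ids[tested],
        "l2fc": l2fc_all[tested],
        "p_raw": p_raw[tested],
        "p_adj": p_adj[tested],
        "pct_1": pct1[tested],
        "pct_2": pct2[tested],
        "fallback": fallback[tested],
    }).set_index("gene")
    table["direction"] = np.where(table["l2fc"] > 0, group1_name, group2_name)
    return DEResult(table=table, group1=group1_name, group2=group2_name,
                    universe_size=m)


def define_gene_set(de: DEResult, l2fc_min: float = 1.0, p_adj_max: float = 0.05,
                    up_only: bool = True, name: str = "signature") -> GeneSet:
    """Threshold a DE result into a signature gene set.

    ``up_only=True`` keeps only the group1-high genes (the convention used
    for the LCE myeloma signature); otherwise both directions are kept.
    """
    t = de.table
    if t.empty:
        log.warning("define_gene_set: empty DE result")
        return GeneSet(name=name, up_genes=("__EMPTY__",))
    sig = t["p_adj"] < p_adj_max
    up = tuple(t.index[sig & (t["l2fc"] > l2fc_min)])
    down = () if up_only else tuple(t.index[sig & (t["l2fc"] < -l2fc_min)])
    if not up and not down:
        log.warning("define_gene_set: no genes pass the thresholds")
        return GeneSet(name=name, up_genes=("__EMPTY__",))
    return GeneSet(name=name, up_genes=up, down_genes=down)


# ---------------------------------------------------------------------------
# pathway enrichment

@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # pathway, k, query_size, pathway_size, p, odds_ratio, p_adj


def enrich(query: GeneSet, pathways: Sequence[GeneSet],
           universe: int | Sequence[str]) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of the query set against each
    pathway, with Haldane-corrected odds ratios and BH adjustment.

    ``universe`` is either the universe size (query/pathway genes are then
    assumed to be members) or an explicit gene list; query genes outside an
    explicit universe are excluded with a warning.
    """
    qgenes = set(query.up_genes) | set(query.down_genes)
    if isinstance(universe, int):
        M = universe
        universe_set = None
    else:
        universe_set = set(universe)
        M = len(universe_set)
        outside = qgenes - universe_set
        if outside:
            log.warning("enrich: %d query gene(s) absent from universe excluded",
                        len(outside))
            qgenes = qgenes & universe_set
    nq = len(qgenes)
    rows = []
    for pw in pathways:
        pgenes = set(pw.up_genes) | set(pw.down_genes)
        if universe_set is not None:
            pgenes = pgenes & universe_set
        K = len(pgenes)
        if K > M or nq > M:
            raise IntegrityError("universe smaller than a gene set")
        k = len(qgenes & pgenes)
        p = float(scipy.stats.hypergeom.sf(k - 1, M, K, nq))
        a, b = k, nq - k
        c, d = K - k, M - nq - K + k
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        rows.append({"pathway": pw.name, "k": k, "query_size": nq,
                     "pathway_size": K, "p": p, "odds_ratio": (a * d) / (b * c)})
    table = pd.DataFrame(rows).set_index("pathway")
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["p_adj"] = []
    return EnrichmentResult(table=table)


# ---------------------------------------------------------------------------
# per-cell signature scoring

def signature_score_cells(norm: NormalizedMatrix, sig: GeneSet) -> pd.Series:
    """Per-cell signature score: mean normalized expression of up-genes
    minus mean of down-genes (genes absent from the matrix are skipped)."""
    present = set(norm.gene_ids)
    up = [g for g in sig.up_genes if g in present]
    down = [g for g in sig.down_genes if g in present]
    if not up and not down:
        raise IntegrityError(f"no gene of signature {sig.name} present in matrix")
    score = np.zeros(norm.n_cells)
    if up:
        score = score + _mean_over_genes(norm, up)
    if down:
        score = score - _mean_over_genes(norm, down)
    return pd.Series(score, index=pd.Index(norm.barcodes, name="barcode"),
                     name=sig.name)


def compare_score_groups(scores: pd.Series, groups: pd.Series) -> dict:
    """Rank-sum comparison of a per-cell score between two groups."""
    levels = [g for g in pd.unique(groups) if pd.notna(g)]
    if len(levels) != 2:
        raise IntegrityError("compare_score_groups needs exactly two groups")
    a = scores[groups == levels[0]]
    b = scores[groups == levels[1]]
    stat, p = scipy.stats.ranksums(a, b)
    return {"groups": (str(levels[0]), str(levels[1])),
            "median_diff": float(a.median() - b.median()),
            "statistic": float(stat), "p": float(p)}


def regress_out_mito(norm: NormalizedMatrix, raw: CountMatrix,
                     ann: GeneAnnotation) -> np.ndarray:
    """Per-gene linear residualization on mitochondrial fraction.

    Used only on the optional embedding path (plotting); DE always runs on
    the unregressed normalized values. Returns a dense genes x cells array.
    """
    mito_set = ann.mito_genes()
    csc = raw.counts.tocsc()
    totals = csc.sum(axis=0).A1.astype(float)
    mito_rows = np.array([g in mito_set for g in raw.gene_ids])
    frac = csc[mito_rows].sum(axis=0).A1 / np.maximum(totals, 1)
    X = np.asarray(norm.values.todense(), dtype=float)
    f = frac - frac.mean()
    denom = float(f @ f)
    if denom == 0:
        return X
    beta = (X @ f) / denom
    return X - np.outer(beta, f)
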
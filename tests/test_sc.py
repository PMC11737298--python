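import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mmlce.sc import (
    assign_cell_types,
    default_marker_map,
    define_gene_set,
    differential_expression,
    enrich,
    light_chain_restriction,
    normalize,
    qc_filter,
    select_variable_genes,
    signature_score_cells,
    split_mm,
    compare_score_groups,
)
from mmlce.simulate import ScSimSpec, simulate_single_cell
from mmlce.types import CountMatrix, GeneAnnotation, GeneSet, IntegrityError, NormalizedMatrix


def _matrix_from_dense(arr, gene_prefix="g", mito_rows=()):
    arr = np.asarray(arr)
    genes = np.array([f"MT-{i}" if i in mito_rows else f"{gene_prefix}{i}"
                      for i in range(arr.shape[0])], dtype=object)
    bcs = np.array([f"c{i}" for i in range(arr.shape[1])], dtype=object)
    cm = CountMatrix(counts=sp.csr_matrix(arr), gene_ids=genes, barcodes=bcs,
                     cell_sample=np.full(arr.shape[1], "s", dtype=object))
    ann = GeneAnnotation(table=pd.DataFrame({
        "gene_id": genes,
        "chromosome": ["MT" if i in mito_rows else "1" for i in range(arr.shape[0])],
        "start_bp": np.arange(1, arr.shape[0] + 1),
        "is_mitochondrial": [i in mito_rows for i in range(arr.shape[0])],
    }))
    return cm, ann


class TestQcFilter:
    def _matrix(self):
        # 300 genes x 4 cells; gene 0 is mitochondrial
        rng = np.random.default_rng(0)
        arr = np.zeros((300, 4), dtype=int)
        # cell 0: 249 detected genes, ~1% mito -> removed (low detection)
        arr[1:250, 0] = 4
        # cell 1: 260 detected genes, 25% mito -> removed (high mito)
        arr[1:260, 1] = 3
        arr[0, 1] = int(round(259 * 3 / 3))  # 259*3 non-mito; mito 259 -> 25%
        # cell 2: exactly 250 genes detected, exactly 10% mito -> retained
        arr[1:250, 2] = 9
        arr[0, 2] = 249  # mito 249 of 2490 total = 10%, detected 250
        # cell 3: clean
        arr[1:300, 3] = 5
        return _matrix_from_dense(arr, mito_rows=(0,))

    def test_boundaries(self):
        cm, ann = self._matrix()
        kept = qc_filter(cm, ann, min_genes=250, max_mito=0.10)
        assert list(kept.barcodes) == ["c2", "c3"]

    def test_idempotent(self):
        cm, ann = self._matrix()
        once = qc_filter(cm, ann)
        twice = qc_filter(once, ann)
        assert list(once.barcodes) == list(twice.barcodes)
        assert (once.counts != twice.counts).nnz == 0

    def test_annotation_must_cover_genes(self, tiny_counts):
        ann = GeneAnnotation(table=pd.DataFrame({
            "gene_id": ["g1"], "chromosome": ["1"], "start_bp": [1],
            "is_mitochondrial": [False]}))
        with pytest.raises(IntegrityError):
            qc_filter(tiny_counts, ann)


class TestNormalize:
    def test_formula(self):
        # one gene with count 2 in a cell of total 10, scale 10 -> ln(3)
        cm, _ = _matrix_from_dense([[2], [8]])
        norm = normalize(cm, scale_factor=10)
        assert norm.values[0, 0] == pytest.approx(math.log(3.0))
        assert norm.values[1, 0] == pytest.approx(math.log(1 + 8 / 10 * 10))

    def test_zero_count_zero_value(self, tiny_counts):
        norm = normalize(tiny_counts)
        raw = tiny_counts.counts.toarray()
        vals = norm.values.toarray()
        assert (vals[raw == 0] == 0).all()

    def test_scale_factor_monotone(self, tiny_counts):
        v1 = normalize(tiny_counts, scale_factor=1e4).values.toarray()
        v2 = normalize(tiny_counts, scale_factor=2e4).values.toarray()
        nz = tiny_counts.counts.toarray() > 0
        assert (v2[nz] > v1[nz]).all()

    def test_zero_cell_names_barcode(self):
        cm, _ = _matrix_from_dense([[1, 0], [1, 0]])
        with pytest.raises(IntegrityError, match="c1"):
            normalize(cm)


class TestVariableGenes:
    def test_always_detected_never_selected(self):
        rng = np.random.default_rng(1)
        arr = rng.poisson(5.0, size=(50, 200)) + 1  # no dropouts at all
        arr[:25] = rng.poisson(0.5, size=(25, 200))  # some genes with dropout
        cm, _ = _matrix_from_dense(arr)
        selected = select_variable_genes(cm, fdr=0.05)
        no_dropout = {f"g{i}" for i in range(25, 50)}
        assert not (set(selected) & no_dropout)

    def test_null_on_curve_controls_fdr(self):
        """Data generated on the fitted dropout curve yields few selections."""
        rng = np.random.default_rng(2)
        n_cells, n_genes, K = 400, 300, 2.0
        mean = rng.lognormal(0.5, 0.8, n_genes)
        rates = []
        for rep in range(3):
            drop = K / (K + mean)  # MM dropout with common K
            arr = np.where(rng.random((n_genes, n_cells)) < drop[:, None], 0,
                           rng.poisson(np.maximum(mean, 0.1)[:, None] * 2,
                                       (n_genes, n_cells)) + 1)
            cm, _ = _matrix_from_dense(arr)
            sel = select_variable_genes(cm, fdr=0.05)
            rates.append(len(sel) / n_genes)
        assert np.mean(rates) < 0.05 + 2 * 0.05  # fdr + slack

    def test_planted_bimodal_selected(self):
        rng = np.random.default_rng(3)
        n_cells, n_genes = 500, 200
        mean = rng.lognormal(0.5, 0.5, n_genes)
        drop = 2.0 / (2.0 + mean)
        arr = np.where(rng.random((n_genes, n_cells)) < drop[:, None], 0,
                       rng.poisson(mean[:, None] * 2, (n_genes, n_cells)) + 1)
        # planted: expressed at high level in only 30% of cells
        on = rng.random(n_cells) < 0.3
        arr[0] = np.where(on, rng.poisson(20.0, n_cells) + 1, 0)
        cm, _ = _matrix_from_dense(arr)
        assert "g0" in select_variable_genes(cm, fdr=0.05)

    def test_exclude_ig_flag(self):
        rng = np.random.default_rng(4)
        arr = rng.poisson(1.0, size=(60, 120))
        on = rng.random(120) < 0.3
        arr[0] = np.where(on, 40, 0)
        cm, _ = _matrix_from_dense(arr)
        cm.gene_ids[0] = "IGHG1"
        assert "IGHG1" not in select_variable_genes(cm, exclude_ig=True)


class TestCellTyping:
    def test_synthetic_accuracy(self, small_sim):
        cm, ann, truth = small_sim
        norm = normalize(qc_filter(cm, ann))
        cta = assign_cell_types(norm)
        tp = truth.loc[cta.labels.index, "population"]
        expected = tp.map(lambda p: "MM" if p in ("LCE_MM", "IGH_MM") else p)
        assert (cta.labels == expected).mean() >= 0.95

    def test_missing_marker_listed(self, small_sim):
        cm, ann, _ = small_sim
        norm = normalize(qc_filter(cm, ann))
        mm = default_marker_map()
        mm["T"] = ("NOT_A_GENE",)
        with pytest.raises(IntegrityError, match="NOT_A_GENE"):
            assign_cell_types(norm, marker_map=mm)

    def test_low_score_unassigned(self):
        # all-zero expression except irrelevant gene -> no label reaches tau
        arr = np.zeros((6, 4), dtype=int)
        arr[5] = 50
        cm, _ = _matrix_from_dense(arr)
        cm.gene_ids[:5] = ["CD3D", "MS4A1", "IGKC", "IGLC1", "CD38"]
        norm = normalize(cm)
        cta = assign_cell_types(
            norm, marker_map={"T": ("CD3D",), "B": ("MS4A1",), "MM": ("CD38",)},
            kappa_genes=("IGKC",), lambda_genes=("IGLC1",))
        assert (cta.labels == "unassigned").all()


class TestLightChainRestriction:
    def _norm(self, kappa_val, lambda_val):
        arr = np.zeros((3, 1))
        arr[0], arr[1] = kappa_val, lambda_val
        vals = sp.csr_matrix(arr)
        return NormalizedMatrix(values=vals,
                                gene_ids=np.array(["IGKC", "IGLC1", "x"], dtype=object),
                                barcodes=np.array(["c0"], dtype=object),
                                cell_sample=np.array(["s"], dtype=object))

    @pytest.mark.parametrize("k, l, expected", [
        (3.0, 0.0, "kappa"),
        (0.0, 0.0, "ambiguous"),
        (1.0, 0.9, "ambiguous"),  # ratio below rho
        (0.0, 3.0, "lambda"),
        (0.4, 0.0, "ambiguous"),  # below tau_lc
    ])
    def test_calls(self, k, l, expected):
        norm = self._norm(k, l)
        call = light_chain_restriction(norm, ("IGKC",), ("IGLC1",), rho=5, tau_lc=0.5)
        assert call.iloc[0] == expected


class TestSplitMM:
    def test_zero_igh_is_lce(self, small_sim):
        cm, ann, truth = small_sim
        norm = normalize(qc_filter(cm, ann))
        cta = assign_cell_types(norm)
        mm_bc = cta.labels.index[cta.labels == "MM"]
        split = split_mm(norm, mm_bc)
        tp = truth.loc[mm_bc, "population"]
        assert (split.labels == tp).mean() >= 0.98
        # zero IGH expression across constant genes forces LCE_MM
        zero = split.igh_score[split.igh_score == 0]
        assert (split.labels[zero.index] == "LCE_MM").all()

    def test_empty_set_rejected(self, small_sim):
        cm, ann, _ = small_sim
        norm = normalize(qc_filter(cm, ann))
        with pytest.raises(IntegrityError):
            split_mm(norm, [])


@pytest.fixture(scope="module")
def planted_norm():
    spec = ScSimSpec(seed=11, planted_de={"PLANT4": 4.0},
                     n_cells={"LCE_MM": 500, "IGH_MM": 500})
    cm, ann, truth = simulate_single_cell(spec)
    norm = normalize(cm)
    pop = truth["population"]
    g1 = list(pop.index[pop == "LCE_MM"])
    g2 = list(pop.index[pop == "IGH_MM"])
    return norm, g1, g2


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        cm, _ = _matrix_from_dense(np.random.default_rng(5).poisson(2, (30, 40)))
        norm = normalize(cm)
        g = list(norm.barcodes)
        de = differential_expression(norm, g, g)
        assert np.allclose(de.table["l2fc"], 0.0)
        assert (de.table["p_adj"] == 1.0).all()

    def test_planted_gene_recovered(self, planted_norm):
        norm, g1, g2 = planted_norm
        de = differential_expression(norm, g1, g2)
        row = de.table.loc["PLANT4"]
        assert row["p_adj"] < 0.05
        assert abs(row["l2fc"] - 2.0) < 0.3

    def test_antisymmetry(self, planted_norm):
        norm, g1, g2 = planted_norm
        a = differential_expression(norm, g1[:100], g2[:100])
        b = differential_expression(norm, g2[:100], g1[:100])
        assert np.allclose(a.table["l2fc"], -b.table["l2fc"], atol=1e-9)
        assert np.allclose(a.table["p_raw"], b.table["p_raw"], atol=1e-9)

    def test_bonferroni_dominance(self, planted_norm):
        norm, g1, g2 = planted_norm
        de = differential_expression(norm, g1[:50], g2[:50])
        t = de.table
        assert (t["p_adj"] >= t["p_raw"] - 1e-15).all()
        m = de.universe_size
        assert (t.loc[t["p_raw"] >= 1.0 / m, "p_adj"] == 1.0).all()

    def test_universe_choice(self, planted_norm):
        norm, g1, g2 = planted_norm
        de_all = differential_expression(norm, g1[:50], g2[:50],
                                         bonferroni_universe="all")
        de_tested = differential_expression(norm, g1[:50], g2[:50],
                                            bonferroni_universe="tested")
        assert de_all.universe_size == norm.n_genes
        assert de_tested.universe_size == len(de_tested.table)

    def test_small_group_rejected(self, planted_norm):
        norm, g1, g2 = planted_norm
        with pytest.raises(IntegrityError):
            differential_expression(norm, g1[:2], g2)

    def test_lrt_matches_statsmodels(self):
        """Independent check of the logistic LRT against statsmodels."""
        import statsmodels.api as sm
        import scipy.stats
        rng = np.random.default_rng(12)
        arr = rng.poisson(3, (10, 120))
        arr[0, :60] = rng.poisson(8, 60)
        cm, _ = _matrix_from_dense(arr)
        norm = normalize(cm)
        g1 = list(norm.barcodes[:60])
        g2 = list(norm.barcodes[60:])
        de = differential_expression(norm, g1, g2)
        y = np.r_[np.ones(60), np.zeros(60)]
        for gene in de.table.index[~de.table["fallback"]]:
            gi = list(norm.gene_ids).index(gene)
            x = norm.values.toarray()[gi]
            full = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            null = sm.Logit(y, np.ones((120, 1))).fit(disp=0)
            p_sm = scipy.stats.chi2.sf(2 * (full.llf - null.llf), 1)
            assert de.table.loc[gene, "p_raw"] == pytest.approx(p_sm, rel=1e-4, abs=1e-12)


class TestGeneSetDefinition:
    def _de(self, rows):
        df = pd.DataFrame(rows, columns=["gene", "l2fc", "p_adj"]).set_index("gene")
        df["p_raw"] = df["p_adj"] / 10
        from mmlce.sc import DEResult
        return DEResult(table=df, universe_size=100)

    def test_threshold_contract(self):
        de = self._de([("LAMP5", 1.68, 6.68e-131),
                       ("weak_fc", 0.9, 1e-10),
                       ("weak_p", 1.5, 0.06),
                       ("down1", -1.4, 1e-6)])
        up_only = define_gene_set(de, l2fc_min=1.0, p_adj_max=0.05, up_only=True)
        assert set(up_only.up_genes) == {"LAMP5"} and not up_only.down_genes
        both = define_gene_set(de, up_only=False)
        assert set(both.down_genes) == {"down1"}

    def test_methods_threshold_absolute_fc_2(self):
        # |fold change| > 2 corresponds to |l2FC| > 1
        de = self._de([("a", 1.01, 0.01), ("b", 0.99, 0.01), ("c", -1.2, 0.001)])
        gs = define_gene_set(de, l2fc_min=1.0, up_only=False)
        assert set(gs.up_genes) == {"a"} and set(gs.down_genes) == {"c"}


def hypergeom_oracle(M, K, nq, k):
    """P(overlap >= k) by enumerating all nq-subsets of a universe of M
    containing a fixed K-subset."""
    hits = total = 0
    pathway = set(range(K))
    for query in itertools.combinations(range(M), nq):
        total += 1
        if len(pathway & set(query)) >= k:
            hits += 1
    return hits / total


class TestEnrichment:
    def test_exact_overlap_probability(self):
        q = GeneSet(name="q", up_genes=tuple(f"x{i}" for i in range(5)))
        pw = GeneSet(name="p", up_genes=tuple(f"x{i}" for i in range(5)))
        res = enrich(q, [pw], universe=10)
        assert res.table.loc["p", "p"] == pytest.approx(1 / math.comb(10, 5))

    def test_zero_overlap_near_one(self):
        q = GeneSet(name="q", up_genes=("a",))
        pw = GeneSet(name="p", up_genes=("b",))
        res = enrich(q, [pw], universe=1000)
        assert res.table.loc["p", "p"] > 0.99

    def test_matches_enumeration_oracle(self):
        for M in (8, 10, 12):
            for K in (2, 4, 6):
                for nq in (2, 3, 5):
                    genes = [f"u{i}" for i in range(M)]
                    pw = GeneSet(name="p", up_genes=tuple(genes[:K]))
                    for k in range(0, min(K, nq) + 1):
                        q_genes = genes[:k] + genes[K:K + (nq - k)]
                        if len(q_genes) != nq:
                            continue
                        q = GeneSet(name="q", up_genes=tuple(q_genes))
                        res = enrich(q, [pw], universe=M)
                        assert res.table.loc["p", "p"] == pytest.approx(
                            hypergeom_oracle(M, K, nq, k), abs=1e-12)

    def test_query_gene_outside_universe_excluded(self):
        genes = [f"u{i}" for i in range(10)]
        q = GeneSet(name="q", up_genes=("u0", "u1", "NOT_THERE"))
        pw = GeneSet(name="p", up_genes=("u0", "u2"))
        res = enrich(q, [pw], universe=genes)
        assert res.table.loc["p", "query_size"] == 2


class TestSignatureScore:
    def test_up_equals_down_zero(self, small_sim):
        cm, ann, _ = small_sim
        norm = normalize(qc_filter(cm, ann))
        gs = GeneSet(name="null", up_genes=("LAMP5",), down_genes=("MYC",))
        gs2 = GeneSet(name="same", up_genes=("LAMP5", "MYC"))
        s_up = signature_score_cells(norm, gs2)
        # identical up/down lists cancel: emulate via two identical single-gene lists
        gs_cancel = GeneSet(name="c", up_genes=("LAMP5",))
        s1 = signature_score_cells(norm, gs_cancel)
        s2 = signature_score_cells(
            norm, GeneSet(name="d", down_genes=("LAMP5",)))
        assert np.allclose(s1 + s2, 0.0)

    def test_planted_population_scores_higher(self, small_sim):
        cm, ann, truth = small_sim
        norm = normalize(qc_filter(cm, ann))
        gs = GeneSet(name="lce_like", up_genes=("LAMP5",))
        scores = signature_score_cells(norm, gs)
        pop = truth.loc[scores.index, "population"]
        mask = pop.isin(["LCE_MM", "IGH_MM"])
        res = compare_score_groups(scores[mask], pop[mask])
        assert res["p"] < 0.01
        lce_med = scores[pop == "LCE_MM"].median()
        igh_med = scores[pop == "IGH_MM"].median()
        assert lce_med > igh_med

    def test_absent_genes_rejected(self, small_sim):
        cm, ann, _ = small_sim
        norm = normalize(qc_filter(cm, ann))
        with pytest.raises(IntegrityError):
            signature_score_cells(norm, GeneSet(name="x", up_genes=("NOPE",)))
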
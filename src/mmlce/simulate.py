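"""Synthetic-data generators with the planted structure the analysis assumes.

Three generators mirror the three data substrates:

* :func:`simulate_single_cell` — a bone-marrow scRNA-seq sample containing
  two myeloma subpopulations (a light-chain-only ``LCE_MM`` population with
  silenced IGH constant genes and an intact-immunoglobulin ``IGH_MM``
  population) plus marker-defined normal cell types, negative-binomial UMI
  counts, Beta-distributed mitochondrial fractions, and chromosome-level
  CNV dosage effects defining subclones.
* :func:`simulate_clinical_series` — serial M-spike / free-light-chain
  trajectories under concordant, light-chain-escape-at-relapse, and
  light-chain-only disease patterns.
* :func:`simulate_bulk_cohort` — a bulk expression cohort with a latent
  signature-high group carrying shifted signature genes, elevated lesion
  burden, and exponential survival with specified hazard ratios.

Every generator is deterministic for a fixed seed and returns ground-truth
labels alongside the observable data; the truth is never encoded in
observable fields beyond the planted statistical effects.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import (
    IGH_CONSTANT_GENES,
    BulkCohort,
    ClinicalSeries,
    CountMatrix,
    GeneAnnotation,
    IntegrityError,
)

POPULATIONS = ("LCE_MM", "IGH_MM", "T", "B", "NK", "monocyte", "RBC",
               "megakaryocyte", "progenitor")

#: canonical marker genes per population (own-population fold multipliers
#: applied on top of the baseline; markers are strongly suppressed elsewhere
#: so that marker-rule typing has a clean signal to find)
DEFAULT_MARKER_GENES: dict[str, tuple[str, ...]] = {
    "T": ("CD3D", "CD3E"),
    "B": ("MS4A1",),
    "NK": ("NKG7",),
    "monocyte": ("CD14",),
    "RBC": ("HBB", "HBA1"),
    "megakaryocyte": ("PPBP",),
    "progenitor": ("CD34",),
    "MM": ("CD38", "SDC1"),  # shared by both myeloma subpopulations
}

MITO_GENES = tuple(f"MT-{n}" for n in (
    "ND1", "ND2", "CO1", "CO2", "ATP8", "ATP6", "CO3", "ND3", "ND4L",
    "ND4", "ND5", "ND6", "CYB"))

_NAMED_BASELINE = 0.6  # mean CP-per-cell scale for named marker genes


@dataclass
class CNVEvent:
    """A chromosome-level dosage event carried by a fraction of one population."""

    population: str
    chromosome: str
    dosage: float  # multiplicative on the mean of every gene on the chromosome
    carrier_fraction: float
    #: events sharing a carrier_group (within one population) are carried by
    #: the same cells — i.e. they jointly define one subclone
    carrier_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.dosage <= 0:
            raise IntegrityError("CNV dosage multiplier must be > 0")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise IntegrityError("carrier fraction must be in [0, 1]")
        if self.population not in POPULATIONS:
            raise IntegrityError(f"unknown population {self.population!r}")

    @property
    def key(self) -> str:
        kind = "gain" if self.dosage > 1 else ("loss" if self.dosage < 1 else "neutral")
        return f"chr{self.chromosome}_{kind}"


def _default_n_cells() -> dict[str, int]:
    return {"LCE_MM": 800, "IGH_MM": 300, "T": 400, "B": 150, "NK": 150,
            "monocyte": 200, "RBC": 100, "megakaryocyte": 60, "progenitor": 120}


@dataclass
class ScSimSpec:
    """Specification for one simulated scRNA-seq sample (timepoint).

    ``gene_seed`` controls the gene-level structure (baseline means,
    annotation); serial timepoints simulated with the same ``gene_seed``
    and ``n_genes`` share a gene universe so CNV subclones can be tracked
    across them, while ``seed`` drives the per-cell sampling.
    """

    seed: int = 0
    gene_seed: int = 7001
    sample_label: str = "t1"
    n_cells: Mapping[str, int] = field(default_factory=_default_n_cells)
    n_genes: int = 1200
    baseline_log_mean: float = -1.0
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.1  # var = mu + dispersion * mu^2
    marker_fold: float = 25.0
    marker_off_fold: float = 0.05
    lamp5_fold: float = 4.0  # planted over-expression in LCE_MM
    myc_fold_lce: float = 4.0
    myc_fold_igh: float = 2.0
    igh_fold_on: float = 40.0
    igh_fold_off: float = 0.001  # IGH constant genes in LCE_MM: effectively silent
    extra_programs: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    #: planted DE effects: gene name -> fold multiplier applied in LCE_MM;
    #: these genes are created with a fixed, well-detected baseline
    planted_de: Mapping[str, float] = field(default_factory=dict)
    mito_mean: float = 0.035
    mito_sd: float = 0.010
    cnv_events: Sequence[CNVEvent] = ()
    library_log_mean: float = math.log(4.0)
    library_log_sd: float = 0.25
    doublet_fraction: float = 0.0  # robustness testing only; off by default

    def validate(self) -> None:
        if self.n_genes < 100:
            raise IntegrityError("n_genes must be >= 100")
        for pop, n in self.n_cells.items():
            if pop not in POPULATIONS:
                raise IntegrityError(f"unknown population {pop!r}")
            if n < 0:
                raise IntegrityError("n_cells must be >= 0")
        if not 0 < self.mito_mean < 1:
            raise IntegrityError("mito_mean must be in (0, 1)")
        if self.mito_sd <= 0 or self.mito_sd ** 2 >= self.mito_mean * (1 - self.mito_mean):
            raise IntegrityError("mito_sd incompatible with a Beta distribution")
        if self.nb_dispersion < 0:
            raise IntegrityError("nb_dispersion must be >= 0")
        if not 0.0 <= self.doublet_fraction < 1.0:
            raise IntegrityError("doublet_fraction must be in [0, 1)")
        for ev in self.cnv_events:
            if not isinstance(ev, CNVEvent):
                raise IntegrityError("cnv_events must be CNVEvent instances")

    @classmethod
    def from_dict(cls, d: dict) -> "ScSimSpec":
        d = dict(d)
        if "cnv_events" in d:
            d["cnv_events"] = tuple(
                ev if isinstance(ev, CNVEvent) else CNVEvent(**ev)
                for ev in d["cnv_events"])
        return cls(**d)


_PLANTED_BASELINE = 1.2


def _named_genes(spec: Optional["ScSimSpec"] = None) -> list[str]:
    names: list[str] = []
    for genes in DEFAULT_MARKER_GENES.values():
        names.extend(genes)
    names.extend(["IGKC", "IGLC1", "IGLC2", "IGLC3"])
    names.extend(IGH_CONSTANT_GENES)
    names.extend(["LAMP5", "MYC"])
    if spec is not None:
        names.extend(spec.planted_de)
    return list(dict.fromkeys(names))


def _gene_model(spec: ScSimSpec) -> tuple[np.ndarray, GeneAnnotation, np.ndarray]:
    """Gene ids, annotation (22 autosomes + MT) and baseline mean vector."""
    rng = np.random.default_rng(spec.gene_seed)
    named = _named_genes(spec)
    n_anon = spec.n_genes - len(named) - len(MITO_GENES)
    if n_anon < 22:
        raise IntegrityError("n_genes too small for the named gene complement")
    gene_ids = np.array(
        named + [f"G{i:05d}" for i in range(n_anon)] + list(MITO_GENES), dtype=object)

    # contiguous chromosome blocks over the nuclear genes, MT at the end
    nuclear = gene_ids[:-len(MITO_GENES)]
    order = rng.permutation(len(nuclear))  # scatter named genes over the genome
    chroms = np.empty(len(gene_ids), dtype=object)
    starts = np.empty(len(gene_ids), dtype=int)
    bounds = np.linspace(0, len(nuclear), 23).astype(int)
    pos_in_chrom = np.empty(len(nuclear), dtype=int)
    chrom_of = np.empty(len(nuclear), dtype=object)
    for ci in range(22):
        sl = slice(bounds[ci], bounds[ci + 1])
        chrom_of[sl] = str(ci + 1)
        pos_in_chrom[sl] = np.arange(sl.stop - sl.start)
    # order[k] is the genome slot of nuclear gene k
    slot_of_gene = np.empty(len(nuclear), dtype=int)
    slot_of_gene[order] = np.arange(len(nuclear))
    for k in range(len(nuclear)):
        s = slot_of_gene[k]
        chroms[k] = chrom_of[s]
        starts[k] = int(pos_in_chrom[s] + 1) * 1_000_000
    chroms[-len(MITO_GENES):] = "MT"
    starts[-len(MITO_GENES):] = np.arange(1, len(MITO_GENES) + 1) * 1000

    is_mito = np.array([g.startswith("MT-") for g in gene_ids])
    ann = GeneAnnotation(table=pd.DataFrame({
        "gene_id": gene_ids, "chromosome": chroms, "start_bp": starts,
        "is_mitochondrial": is_mito}))

    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, len(gene_ids))
    # named genes get a fixed, comfortably detectable baseline so fold
    # multipliers translate into interpretable expression levels
    baseline[:len(named)] = _NAMED_BASELINE
    for g in spec.planted_de:
        baseline[list(gene_ids).index(g)] = _PLANTED_BASELINE
    baseline[-len(MITO_GENES):] = 1.0  # rescaled per cell to the Beta fraction
    return gene_ids, ann, baseline


def _population_multipliers(spec: ScSimSpec, gene_ids: np.ndarray) -> dict[str, np.ndarray]:
    """Per-population fold-multiplier vectors over genes."""
    idx = {g: i for i, g in enumerate(gene_ids)}
    mult = {pop: np.ones(len(gene_ids)) for pop in POPULATIONS}

    def set_fold(pop: str, gene: str, fold: float) -> None:
        mult[pop][idx[gene]] = fold

    all_markers = [g for genes in DEFAULT_MARKER_GENES.values() for g in genes]
    for pop in POPULATIONS:
        for g in all_markers:
            set_fold(pop, g, spec.marker_off_fold)
    for pop, genes in DEFAULT_MARKER_GENES.items():
        targets = ("LCE_MM", "IGH_MM") if pop == "MM" else (pop,)
        for t in targets:
            for g in genes:
                set_fold(t, g, spec.marker_fold)

    # clonal kappa restriction: IGKC high in both myeloma populations,
    # lambda constant genes silent there
    for pop in POPULATIONS:
        for g in ("IGKC", "IGLC1", "IGLC2", "IGLC3"):
            set_fold(pop, g, spec.marker_off_fold)
    for mm in ("LCE_MM", "IGH_MM"):
        set_fold(mm, "IGKC", spec.marker_fold)
        for g in ("IGLC1", "IGLC2", "IGLC3"):
            set_fold(mm, g, spec.igh_fold_off)
    set_fold("B", "IGKC", 2.0)  # polyclonal B cells express some light chain

    for g in IGH_CONSTANT_GENES:
        for pop in POPULATIONS:
            set_fold(pop, g, spec.marker_off_fold)
        set_fold("IGH_MM", g, spec.igh_fold_on)
        set_fold("LCE_MM", g, spec.igh_fold_off)
        set_fold("B", g, 2.0)

    set_fold("LCE_MM", "LAMP5", spec.lamp5_fold)
    set_fold("LCE_MM", "MYC", spec.myc_fold_lce)
    set_fold("IGH_MM", "MYC", spec.myc_fold_igh)

    for g, fold in spec.planted_de.items():
        set_fold("LCE_MM", g, float(fold))

    for pop, prog in spec.extra_programs.items():
        for g, fold in prog.items():
            set_fold(pop, g, float(fold))
    return mult


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    v = sd ** 2
    nu = mean * (1 - mean) / v - 1
    return mean * nu, (1 - mean) * nu


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_single_cell(spec: ScSimSpec
                         ) -> tuple[CountMatrix, GeneAnnotation, pd.DataFrame]:
    """Simulate one sample; returns (counts, annotation, truth table).

    The truth table is indexed by barcode with columns ``population``,
    ``sample`` and one boolean carrier column per CNV event key.
    """
    spec.validate()
    gene_ids, ann, baseline = _gene_model(spec)
    mult = _population_multipliers(spec, gene_ids)
    rng = np.random.default_rng(spec.seed)

    pops = [p for p in POPULATIONS if spec.n_cells.get(p, 0) > 0]
    cell_pop = np.concatenate([
        np.full(spec.n_cells[p], p, dtype=object) for p in pops])
    n_cells = len(cell_pop)
    barcodes = np.array(
        [f"{spec.sample_label}-{i:05d}" for i in range(n_cells)], dtype=object)

    is_mito = np.array([g.startswith("MT-") for g in gene_ids])
    event_carrier: list[tuple[CNVEvent, np.ndarray]] = []
    group_carrier: dict[tuple[str, str], np.ndarray] = {}
    for ev in spec.cnv_events:
        key = (ev.population, ev.carrier_group) if ev.carrier_group else None
        if key is not None and key in group_carrier:
            event_carrier.append((ev, group_carrier[key]))
            continue
        pop_mask = cell_pop == ev.population
        carrier = np.zeros(n_cells, dtype=bool)
        members = np.flatnonzero(pop_mask)
        n_carr = int(round(ev.carrier_fraction * members.size))
        if n_carr:
            carrier[rng.choice(members, size=n_carr, replace=False)] = True
        if key is not None:
            group_carrier[key] = carrier
        event_carrier.append((ev, carrier))

    chrom_by_gene = ann.table.set_index("gene_id")["chromosome"].astype(str)
    chrom_arr = chrom_by_gene.reindex(gene_ids).to_numpy()

    lib = rng.lognormal(spec.library_log_mean, spec.library_log_sd, n_cells)
    a, b = _beta_params(spec.mito_mean, spec.mito_sd)
    mito_frac = rng.beta(a, b, n_cells)

    counts = np.empty((len(gene_ids), n_cells), dtype=np.int64)
    for ci in range(n_cells):
        mu = baseline * mult[cell_pop[ci]] * lib[ci]
        for ev, carrier in event_carrier:
            if carrier[ci]:
                mu = np.where(chrom_arr == ev.chromosome, mu * ev.dosage, mu)
        # rescale mitochondrial means so their expected library share is the
        # cell's Beta-drawn fraction
        s_m, s_n = mu[is_mito].sum(), mu[~is_mito].sum()
        f = mito_frac[ci]
        mu[is_mito] *= f * s_n / ((1 - f) * s_m)
        counts[:, ci] = _nb_sample(rng, mu, spec.nb_dispersion)

    if spec.doublet_fraction > 0:
        n_dbl = int(round(spec.doublet_fraction * n_cells))
        victims = rng.choice(n_cells, size=(n_dbl, 2), replace=True)
        for v1, v2 in victims:
            counts[:, v1] = counts[:, v1] + counts[:, v2]

    cm = CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        barcodes=barcodes,
        cell_sample=np.full(n_cells, spec.sample_label, dtype=object))
    truth = pd.DataFrame({"population": cell_pop, "sample": spec.sample_label},
                         index=pd.Index(barcodes, name="barcode"))
    for ev, carrier in event_carrier:
        col = ev.key
        if col in truth.columns:
            truth[col] = truth[col] | carrier
        else:
            truth[col] = carrier
    return cm, ann, truth


def simulate_timepoints(specs: Sequence[ScSimSpec]
                        ) -> tuple[CountMatrix, GeneAnnotation, pd.DataFrame]:
    """Simulate serial samples sharing one gene universe and concatenate them."""
    if len({(s.gene_seed, s.n_genes, tuple(s.planted_de)) for s in specs}) != 1:
        raise IntegrityError("timepoint specs must share gene_seed and n_genes")
    if len({s.sample_label for s in specs}) != len(specs):
        raise IntegrityError("timepoint sample labels must be distinct")
    mats, truths, ann = [], [], None
    for s in specs:
        cm, ann, tr = simulate_single_cell(s)
        mats.append(cm)
        truths.append(tr)
    combined = CountMatrix(
        counts=sp.hstack([m.counts for m in mats]).tocsr(),
        gene_ids=mats[0].gene_ids,
        barcodes=np.concatenate([m.barcodes for m in mats]),
        cell_sample=np.concatenate([m.cell_sample for m in mats]))
    truth = pd.concat(truths)
    for col in truth.columns:
        if truth[col].dtype == object and set(truth[col].dropna()) <= {True, False}:
            truth[col] = truth[col].fillna(False).astype(bool)
        elif truth[col].isna().any() and col not in ("population", "sample"):
            truth[col] = truth[col].fillna(False).astype(bool)
    return combined, ann, truth


# ---------------------------------------------------------------------------
# serial clinical labs

PATTERNS = ("concordant", "lce_at_relapse", "light_chain_only")


@dataclass
class LabsSimSpec:
    """Serial-lab generator: M-spike and involved/uninvolved light chains.

    Noiseless template trajectories per disease pattern are perturbed by
    Gaussian measurement noise (truncated at zero). The ``lce_at_relapse``
    pattern is the planted positive class: a secretory switch at relapse
    drives free light chain up while the M-spike stays suppressed.
    """

    seed: int = 0
    n_patients: int = 200
    fraction_lce: float = 0.3
    fraction_light_chain_only: float = 0.1  # of the non-LCE remainder
    visit_days: tuple[int, ...] = (0, 90, 180, 270, 360, 450, 540, 630)
    mspike_noise_sd: float = 0.05  # g/dL
    flc_noise_sd: float = 2.0      # mg/dL
    calcium: bool = True

    def validate(self) -> None:
        if not 0.0 <= self.fraction_lce <= 1.0:
            raise IntegrityError("fraction_lce must be in [0, 1]")
        if not 0.0 <= self.fraction_light_chain_only <= 1.0:
            raise IntegrityError("fraction_light_chain_only must be in [0, 1]")
        if list(self.visit_days) != sorted(set(self.visit_days)):
            raise IntegrityError("visit_days must be strictly increasing")
        if len(self.visit_days) < 4:
            raise IntegrityError("need >= 4 visits")
        if self.mspike_noise_sd < 0 or self.flc_noise_sd < 0:
            raise IntegrityError("noise sds must be >= 0")


def _template(pattern: str, n_visits: int) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless (m_spike g/dL, involved FLC mg/dL) templates, length n_visits."""
    base_m = {
        "concordant":       [2.5, 1.5, 0.6, 0.3, 0.8, 1.4, 2.0, 2.6],
        "lce_at_relapse":   [2.5, 1.2, 0.4, 0.2, 0.2, 0.3, 0.2, 0.2],
        "light_chain_only": [0.3, 0.2, 0.1, 0.1, 0.1, 0.2, 0.2, 0.3],
    }[pattern]
    base_f = {
        "concordant":       [40, 24, 10, 5, 13, 22, 32, 42],
        "lce_at_relapse":   [40, 20, 8, 5, 30, 60, 90, 120],
        "light_chain_only": [60, 40, 20, 15, 35, 70, 100, 130],
    }[pattern]
    m = np.array(base_m, dtype=float)
    f = np.array(base_f, dtype=float)
    if n_visits <= len(m):
        return m[:n_visits], f[:n_visits]
    # extend by holding the final trend
    extra = n_visits - len(m)
    m = np.concatenate([m, np.full(extra, m[-1])])
    f = np.concatenate([f, f[-1] + (f[-1] - f[-2]) * np.arange(1, extra + 1)])
    return m, f


def simulate_clinical_series(spec: LabsSimSpec
                             ) -> tuple[list[ClinicalSeries], pd.DataFrame]:
    """Simulate serial labs; returns (series, truth) with truth columns
    ``pattern`` and ``lce`` (True only for the lce_at_relapse pattern)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_lce = int(round(spec.fraction_lce * spec.n_patients))
    n_rest = spec.n_patients - n_lce
    n_lco = int(round(spec.fraction_light_chain_only * n_rest))
    patterns = (["lce_at_relapse"] * n_lce + ["light_chain_only"] * n_lco
                + ["concordant"] * (n_rest - n_lco))
    rng.shuffle(patterns)

    t = np.array(spec.visit_days, dtype=float)
    series, rows = [], []
    for i, pat in enumerate(patterns):
        pid = f"P{i:04d}"
        m, f_inv = _template(pat, len(t))
        f_uninv = np.full(len(t), 1.5)
        m_obs = np.clip(m + rng.normal(0, spec.mspike_noise_sd, len(t)), 0, None)
        ki = np.clip(f_inv + rng.normal(0, spec.flc_noise_sd, len(t)), 0, None)
        lu = np.clip(f_uninv + rng.normal(0, spec.flc_noise_sd * 0.25, len(t)), 0, None)
        visits = pd.DataFrame({
            "t_days": t, "m_spike": m_obs, "kappa": ki, "lambda_": lu})
        if spec.calcium:
            # calcium loosely tracks disease activity (descriptive only)
            act = (m / max(m.max(), 1e-9) + f_inv / f_inv.max()) / 2
            visits["calcium"] = 9.0 + 2.0 * act + rng.normal(0, 0.15, len(t))
        series.append(ClinicalSeries(patient_id=pid, visits=visits,
                                     affected_isotype="kappa"))
        rows.append({"patient_id": pid, "pattern": pat,
                     "lce": pat == "lce_at_relapse"})
    truth = pd.DataFrame(rows).set_index("patient_id")
    return series, truth


# ---------------------------------------------------------------------------
# bulk cohort


@dataclass
class CohortSimSpec:
    """Bulk-cohort generator with a latent signature-high group.

    Expression is log2-normal: per-gene base level plus a ``delta`` log2
    shift on signature genes in latent-high samples plus N(0, noise_sd)
    noise, exponentiated to a TPM-like linear scale. Survival is
    exponential under proportional hazards with administrative censoring;
    lesion categories are multinomial per latent group.
    """

    seed: int = 0
    n_samples: int = 400
    n_genes: int = 1000
    n_signature_genes: int = 50
    delta: float = 1.5          # log2 effect on signature genes in latent-high
    prevalence: float = 0.25    # latent-high prevalence
    noise_sd: float = 1.0       # log2-scale, gene-independent
    #: shared per-sample log2 shift across all genes (library / global
    #: technical variation); makes summed scores continuous across samples
    sample_effect_sd: float = 0.5
    hr_os: float = 2.73
    os_baseline_hazard: float = 0.10   # events / year in latent-low
    censor_os_years: float = 8.0
    hr_lytic: float = 2.99
    lytic_baseline_hazard: float = 1.0 / 2000.0  # events / day in latent-low
    censor_lytic_days: float = 2500.0
    lesion_probs_low: tuple[float, ...] = (0.35, 0.18, 0.10, 0.37)
    lesion_probs_high: tuple[float, ...] = (0.15, 0.12, 0.09, 0.64)
    lesion_count_mean_low: float = 1.5
    lesion_count_mean_high: float = 4.5

    def validate(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise IntegrityError("prevalence must be in (0, 1)")
        if self.hr_os <= 0 or self.hr_lytic <= 0:
            raise IntegrityError("hazard ratios must be > 0")
        for probs in (self.lesion_probs_low, self.lesion_probs_high):
            if len(probs) != 4 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise IntegrityError("lesion category probabilities must sum to 1")
        if self.n_signature_genes > self.n_genes:
            raise IntegrityError("signature larger than gene universe")
        if self.noise_sd < 0:
            raise IntegrityError("noise_sd must be >= 0")

    @property
    def signature_genes(self) -> tuple[str, ...]:
        return tuple(f"SIG{i:04d}" for i in range(self.n_signature_genes))


LESION_CATEGORIES = ("0", "1", "2", "3+")


def simulate_bulk_cohort(spec: CohortSimSpec) -> tuple[BulkCohort, pd.DataFrame]:
    """Simulate a bulk cohort; truth carries the latent-high indicator."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes
    samples = pd.Index([f"S{i:04d}" for i in range(n)], name="sample")
    sig = list(spec.signature_genes)
    genes = sig + [f"B{i:04d}" for i in range(g - len(sig))]

    latent = rng.random(n) < spec.prevalence
    base = rng.normal(5.0, 2.0, g)
    sample_effect = rng.normal(0.0, spec.sample_effect_sd, n)
    log2x = base[None, :] + sample_effect[:, None] \
        + rng.normal(0.0, spec.noise_sd, (n, g))
    log2x[:, :len(sig)] += spec.delta * latent[:, None]
    expr = pd.DataFrame(np.exp2(log2x), index=samples, columns=genes)

    def _exp_surv(base_hazard: float, hr: float, censor: float):
        rate = base_hazard * np.where(latent, hr, 1.0)
        tt = rng.exponential(1.0 / rate)
        event = (tt <= censor).astype(int)
        return np.minimum(tt, censor), event

    os_time, os_event = _exp_surv(spec.os_baseline_hazard, spec.hr_os,
                                  spec.censor_os_years)
    ly_time, ly_event = _exp_surv(spec.lytic_baseline_hazard, spec.hr_lytic,
                                  spec.censor_lytic_days)
    cat_idx = np.where(
        latent,
        rng.choice(4, n, p=spec.lesion_probs_high),
        rng.choice(4, n, p=spec.lesion_probs_low))
    lesion_count = np.where(
        latent,
        rng.poisson(spec.lesion_count_mean_high, n),
        rng.poisson(spec.lesion_count_mean_low, n)).astype(float)

    clinical = pd.DataFrame({
        "os_time": os_time, "os_event": os_event,
        "lytic_time": ly_time, "lytic_event": ly_event,
        "lesion_category": [LESION_CATEGORIES[i] for i in cat_idx],
        "lesion_count": lesion_count,
    }, index=samples)
    truth = pd.DataFrame({"latent_high": latent}, index=samples)
    return BulkCohort(expression=expr, clinical=clinical), truth
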
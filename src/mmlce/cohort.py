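"""Bulk-cohort scoring, LCE classification from serial labs, and outcome
association (survival, osteolysis).

The gene-set score is the sum over signature genes of per-gene
cross-sample z-scores (down-genes negated); samples more than m standard
deviations above/below the score mean are called high/low. Survival uses
two-group Cox proportional hazards (Efron ties) plus Kaplan-Meier medians
and the log-rank test; osteolysis uses Fisher's exact test on lesion
categories and Welch's t-test on continuous lesion counts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .types import BulkCohort, ClinicalSeries, GeneSet, IntegrityError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene-set scoring and stratification

@dataclass
class ScoreTable:
    scores: pd.Series                 # sample -> summed z-score
    strata: Optional[pd.Series] = None  # sample -> high | mid | low
    mean: float = float("nan")
    sd: float = float("nan")
    m: float = float("nan")

    def frame(self) -> pd.DataFrame:
        df = self.scores.rename("score").to_frame()
        if self.strata is not None:
            df["stratum"] = self.strata
        return df


def geneset_score(cohort: BulkCohort, sig: GeneSet) -> ScoreTable:
    """Summed gene-wise z-score (sample SD, n-1); down-genes negated.

    Signature genes absent from the cohort are skipped and logged; genes
    with zero cross-sample SD contribute 0 to every sample's score.
    """
    if len(cohort.samples) < 3:
        raise IntegrityError("need >= 3 samples to z-score")
    present = set(cohort.expression.columns)
    up = [g for g in sig.up_genes if g in present]
    down = [g for g in sig.down_genes if g in present]
    skipped = (len(sig.up_genes) - len(up)) + (len(sig.down_genes) - len(down))
    if skipped:
        log.info("geneset_score: %d signature gene(s) absent from cohort skipped",
                 skipped)
    if not up and not down:
        raise IntegrityError(f"no gene of signature {sig.name} present in cohort")

    def z_sum(genes: list[str]) -> pd.Series:
        if not genes:
            return pd.Series(0.0, index=cohort.samples)
        x = cohort.expression[genes]
        sd = x.std(axis=0, ddof=1)
        z = (x - x.mean(axis=0)) / sd.replace(0.0, np.nan)
        return z.fillna(0.0).sum(axis=1)

    scores = z_sum(up) - z_sum(down)
    return ScoreTable(scores=scores.rename(sig.name))


def stratify(table: ScoreTable, m: float = 1.0) -> ScoreTable:
    """Cut scores at mean +/- m*SD (sample SD): strictly above -> high,
    strictly below -> low, otherwise mid."""
    if len(table.scores) < 3:
        raise IntegrityError("need >= 3 samples to stratify")
    mu = float(table.scores.mean())
    sd = float(table.scores.std(ddof=1))
    if sd == 0:
        log.warning("stratify: zero score SD; all samples mid")
        strata = pd.Series("mid", index=table.scores.index, name="stratum")
        return ScoreTable(scores=table.scores, strata=strata, mean=mu, sd=sd, m=m)
    strata = pd.Series("mid", index=table.scores.index, dtype=object, name="stratum")
    strata[table.scores > mu + m * sd] = "high"
    strata[table.scores < mu - m * sd] = "low"
    return ScoreTable(scores=table.scores, strata=strata, mean=mu, sd=sd, m=m)


# ---------------------------------------------------------------------------
# LCE classification from serial labs

@dataclass
class LceCall:
    patient_id: str
    lce: bool
    c1: bool             # dFLC > dflc_min with M-spike < mspike_low at >=1 visit
    c2: bool             # diagnosis M-spike > mspike_dx
    c3_exclusion: bool   # light-chain rises correspond to M-spike rises
    affected_isotype: str
    dflc: pd.Series = field(repr=False, default=None)


def classify_lce(series: ClinicalSeries, dflc_min: float = 10.0,
                 mspike_low: float = 1.0, mspike_dx: float = 1.0,
                 rise_mspike: float = 0.1, corr_min: float = 0.7) -> LceCall:
    """Three-criterion light-chain-escape call on one patient's serial labs.

    (i) some visit has involved-minus-uninvolved FLC > ``dflc_min`` mg/dL
    with M-spike < ``mspike_low`` g/dL; (ii) diagnosis M-spike >
    ``mspike_dx`` g/dL; (iii) exclusion when every between-visit dFLC rise
    > dflc_min/2 is accompanied by an M-spike rise > ``rise_mspike`` AND the
    correlation of visit-to-visit changes exceeds ``corr_min``.
    """
    v = series.visits
    if len(v) < 2:
        raise IntegrityError(f"patient {series.patient_id}: need >= 2 visits")
    iso = series.affected_isotype
    if iso is None:
        k0, l0 = float(v["kappa"].iloc[0]), float(v["lambda_"].iloc[0])
        if k0 == l0:
            if k0 == 0:
                raise IntegrityError(
                    f"patient {series.patient_id}: isotype not inferable")
            raise IntegrityError(
                f"patient {series.patient_id}: tied diagnosis light chains")
        iso = "kappa" if k0 > l0 else "lambda"
    involved = v["kappa"] if iso == "kappa" else v["lambda_"]
    uninvolved = v["lambda_"] if iso == "kappa" else v["kappa"]
    dflc = (involved - uninvolved).rename("dflc")
    m = v["m_spike"]

    c1 = bool(((dflc > dflc_min) & (m < mspike_low)).any())
    c2 = bool(m.iloc[0] > mspike_dx)

    d_dflc = dflc.diff().to_numpy()[1:]
    d_m = m.diff().to_numpy()[1:]
    ok = np.isfinite(d_dflc) & np.isfinite(d_m)
    d_dflc, d_m = d_dflc[ok], d_m[ok]
    rises = d_dflc > dflc_min / 2.0
    c3 = False
    if rises.any() and len(d_dflc) >= 2:
        accompanied = bool(np.all(d_m[rises] > rise_mspike))
        if accompanied and np.std(d_dflc) > 0 and np.std(d_m) > 0:
            r = float(np.corrcoef(d_dflc, d_m)[0, 1])
            c3 = r > corr_min
    lce = c1 and c2 and not c3
    return LceCall(patient_id=series.patient_id, lce=lce, c1=c1, c2=c2,
                   c3_exclusion=c3, affected_isotype=iso,
                   dflc=dflc.set_axis(v["t_days"].to_numpy()))


def classify_lce_many(series: Sequence[ClinicalSeries], **kwargs) -> pd.DataFrame:
    rows = []
    for s in series:
        c = classify_lce(s, **kwargs)
        rows.append({"patient_id": c.patient_id, "lce": c.lce, "c1": c.c1,
                     "c2": c.c2, "c3_exclusion": c.c3_exclusion,
                     "affected_isotype": c.affected_isotype})
    return pd.DataFrame(rows).set_index("patient_id")


# ---------------------------------------------------------------------------
# survival

@dataclass
class SurvivalResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    logrank_stat: float
    logrank_p: float
    medians: dict
    n_events: dict
    estimable: bool = True
    endpoint: str = "os"


def compare_survival(cohort: BulkCohort, groups: pd.Series,
                     endpoint: str = "os") -> SurvivalResult:
    """Two-group Cox PH fit (group indicator as sole covariate, Efron ties,
    95% Wald CI), Kaplan-Meier medians and log-rank test.

    ``groups`` maps sample -> group label; exactly two non-null labels are
    compared, the lexicographically smaller label being the reference. A
    group with zero events yields a non-estimable result (hr = NaN).
    """
    tcol, ecol = (("os_time", "os_event") if endpoint == "os"
                  else ("lytic_time", "lytic_event"))
    if tcol not in cohort.clinical or ecol not in cohort.clinical:
        raise IntegrityError(f"cohort lacks {tcol}/{ecol}")
    df = cohort.clinical[[tcol, ecol]].copy()
    df["group"] = groups.reindex(df.index)
    df = df.dropna()
    levels = sorted(df["group"].unique(), key=str)
    if len(levels) != 2:
        raise IntegrityError(f"need exactly two groups, got {levels}")
    ref, alt = levels
    # "low" (or a falsy label) is always the reference group
    if str(alt).lower() in ("low", "false", "0"):
        ref, alt = alt, ref
    df["x"] = (df["group"] == alt).astype(int)

    n_events = {str(lv): int(df.loc[df["group"] == lv, ecol].sum()) for lv in levels}
    medians = {}
    for lv in levels:
        km = KaplanMeierFitter()
        sub = df[df["group"] == lv]
        km.fit(sub[tcol], sub[ecol])
        medians[str(lv)] = float(km.median_survival_time_)
    lr = logrank_test(df.loc[df["x"] == 1, tcol], df.loc[df["x"] == 0, tcol],
                      df.loc[df["x"] == 1, ecol], df.loc[df["x"] == 0, ecol])

    if min(n_events.values()) == 0:
        log.warning("compare_survival: a group has no events; HR unestimable")
        return SurvivalResult(hr=float("nan"), ci_low=float("nan"),
                              ci_high=float("nan"), p=float("nan"),
                              logrank_stat=float(lr.test_statistic),
                              logrank_p=float(lr.p_value), medians=medians,
                              n_events=n_events, estimable=False, endpoint=endpoint)
    cph = CoxPHFitter()
    cph.fit(df[[tcol, ecol, "x"]], duration_col=tcol, event_col=ecol)
    hr = float(np.exp(cph.params_["x"]))
    ci = cph.confidence_intervals_.loc["x"]
    return SurvivalResult(
        hr=hr, ci_low=float(np.exp(ci.iloc[0])), ci_high=float(np.exp(ci.iloc[1])),
        p=float(cph.summary.loc["x", "p"]),
        logrank_stat=float(lr.test_statistic), logrank_p=float(lr.p_value),
        medians=medians, n_events=n_events, estimable=True, endpoint=endpoint)


# ---------------------------------------------------------------------------
# osteolysis association

@dataclass
class LesionAssociation:
    table: pd.DataFrame       # 2x2 contingency high/low x >=3 / <3 lesions
    fisher_p: float
    fisher_odds: float
    t_p: Optional[float]
    group_means: Optional[dict]


def lesion_association(scored: ScoreTable, cohort: BulkCohort) -> LesionAssociation:
    """Fisher exact test of stratum (high/low) against lesion burden
    (>=3 vs <3 lesions) plus Welch's t-test on continuous lesion counts;
    mid-stratum samples are excluded."""
    if scored.strata is None:
        raise IntegrityError("stratify() the scores first")
    strata = scored.strata.reindex(cohort.samples)
    clin = cohort.clinical
    if "lesion_category" not in clin:
        raise IntegrityError("cohort lacks lesion_category")
    mask = strata.isin(["high", "low"]) & clin["lesion_category"].notna()
    sub = clin.loc[mask]
    st = strata.loc[mask]
    if not (st == "high").any() or not (st == "low").any():
        raise IntegrityError("need >= 1 high and >= 1 low sample with lesion data")
    many = sub["lesion_category"].astype(str) == "3+"
    table = pd.DataFrame({
        ">=3": [int(many[st == "high"].sum()), int(many[st == "low"].sum())],
        "<3": [int((~many)[st == "high"].sum()), int((~many)[st == "low"].sum())],
    }, index=["high", "low"])
    odds, p = scipy.stats.fisher_exact(table.to_numpy(), alternative="two-sided")

    t_p, group_means = None, None
    if "lesion_count" in sub:
        hi = sub.loc[st == "high", "lesion_count"].dropna()
        lo = sub.loc[st == "low", "lesion_count"].dropna()
        if len(hi) >= 2 and len(lo) >= 2:
            t_p = float(scipy.stats.ttest_ind(hi, lo, equal_var=False).pvalue)
            group_means = {"high": float(hi.mean()), "low": float(lo.mean())}
    return LesionAssociation(table=table, fisher_p=float(p),
                             fisher_odds=float(odds), t_p=t_p,
                             group_means=group_means)
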
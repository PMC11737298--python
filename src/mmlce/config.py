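"""Pipeline configuration: every tunable threshold in one round-trippable object."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .types import DEFAULT_CHROMOSOMES


@dataclass
class PipelineConfig:
    """All pipeline tunables with their default values.

    QC / normalization defaults follow the clinical study conventions
    (cells with <250 detected genes or >10% mitochondrial reads removed;
    ln CP10k normalization); the remaining thresholds are documented in
    the methods note.
    """

    # single-cell QC / normalization
    min_genes: int = 250
    max_mito: float = 0.10
    scale_factor: float = 10_000.0
    # variable-gene selection
    vg_fdr: float = 0.05
    exclude_ig: bool = False
    # cell typing / myeloma splitting
    tau_type: float = 0.5
    tau_igh: float = 0.25
    tau_lc: float = 0.5
    rho_lc: float = 5.0
    # differential expression
    min_pct: float = 0.10
    n_min: int = 3
    bonferroni_universe: str = "all"  # "all" | "tested"
    de_max_iter: int = 100
    # gene-set definition
    geneset_l2fc_min: float = 1.0
    geneset_p_max: float = 0.05
    geneset_up_only: bool = True
    # CNV inference
    cnv_window: int = 101
    cnv_clip: float = 1.0
    gain_thr: float = 0.1
    loss_thr: float = -0.1
    min_genes_per_chrom: int = 5
    reference_types: tuple[str, ...] = ("T", "B", "NK", "monocyte", "RBC",
                                        "megakaryocyte", "progenitor")
    k_max: int = 10
    min_silhouette: float = 0.1
    match_min: float = 0.8
    # cohort scoring / stratification
    strat_m: float = 1.0
    # LCE classification (labs)
    dflc_min: float = 10.0   # mg/dL
    mspike_low: float = 1.0  # g/dL
    mspike_dx: float = 1.0   # g/dL
    rise_mspike: float = 0.1  # g/dL, M-spike rise that "corresponds" to a dFLC rise
    corr_min: float = 0.7
    # misc
    seed: int = 0
    chromosome_order: tuple[str, ...] = DEFAULT_CHROMOSOMES

    def __post_init__(self) -> None:
        self.chromosome_order = tuple(str(c) for c in self.chromosome_order)
        self.reference_types = tuple(self.reference_types)
        if self.bonferroni_universe not in ("all", "tested"):
            raise ValueError("bonferroni_universe must be 'all' or 'tested'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chromosome_order"] = list(self.chromosome_order)
        d["reference_types"] = list(self.reference_types)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
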
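"""Pipeline configuration: every tunable of the analysis in one dataclass.

Defaults reproduce the study conditions: a nine-chromosome genome, two
doubled-diploid parents with the per-chromosome preferential-pairing
profiles estimated for Volkamer lemon (ovule side) and Swingle citrumelo
(pollen side), 95 hybrids, GBS-like coverage, 20-DSNP windows, the
15% / 20% missing-data filters, the 0.005 tau grid, the 0.05 q-value
threshold, loess span 0.15, and the 0.01 association p threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: per-chromosome preferential pairing of the ovule parent (interspecific
#: C. reticulata x C. medica doubled diploid), C1..C9
PP_OVULE_DEFAULT = [0.583, 0.810, 0.317, 0.548, 0.0,
                    0.675, 0.663, 0.670, 0.250]
#: per-chromosome preferential pairing of the pollen parent (intergeneric
#: C. paradisi x P. trifoliata doubled diploid), C1..C9
PP_POLLEN_DEFAULT = [0.742, 0.625, 0.690, 0.850, 0.848,
                     0.925, 0.502, 0.923, 0.760]


def _default_qtls() -> list[dict]:
    # a medica-dose QTL (unfavorable) and a trifoliata-dose QTL (favorable)
    # near the distal end of chromosome 1
    return [
        {"parent": "ovule", "chrom": "C1", "pos_frac": 0.90, "beta": -1.0},
        {"parent": "pollen", "chrom": "C1", "pos_frac": 0.90, "beta": 1.0},
    ]


def _default_genes() -> list[dict]:
    # candidate-resistance-style intervals on the chromosomes carrying
    # NBS-encoding genes in the donor genome
    return [
        {"gene": "hlb_tol_1", "trait": "HLB", "chrom": "C6",
         "start_frac": 0.70, "width": 100_000},
        {"gene": "ctv_res_1", "trait": "CTV", "chrom": "C7",
         "start_frac": 0.55, "width": 100_000},
        {"gene": "nem_res_1", "trait": "nematode", "chrom": "C7",
         "start_frac": 0.80, "width": 100_000},
        {"gene": "hlb_tol_2", "trait": "HLB", "chrom": "C9",
         "start_frac": 0.20, "width": 100_000},
    ]


@dataclass
class PipelineConfig:
    # genome
    n_chromosomes: int = 9
    chrom_length: int = 20_000_000
    map_length_morgans: float = 1.0
    centromere_frac: float = 0.45
    # parents and cross
    pp_ovule: list[float] = field(default_factory=lambda: list(PP_OVULE_DEFAULT))
    pp_pollen: list[float] = field(default_factory=lambda: list(PP_POLLEN_DEFAULT))
    n_hybrids: int = 95
    # diagnostic panel and reference accessions
    dsnps_per_taxon_per_chrom: int = 240
    ref_accessions_per_taxon: int = 2
    ref_missing_rate: float = 0.0
    max_missing_dsnp: float = 0.20
    # read counts
    depth: float = 20.0
    eps: float = 0.01
    missing_rate: float = 0.02
    # dosing
    window_size: int = 20
    min_reads: int = 10
    lr_threshold: float = 1.0
    # cleaning
    max_window_missing: float = 0.15
    max_individual_missing: float = 0.20
    aberrant_k_iqr: float = 3.0
    # meiotic analysis
    tau_grid_step: float = 0.005
    q_threshold: float = 0.05
    fdr_method: str = "bh"
    # mapping: the dose-difference rf estimator saturates at 5/18 for
    # unlinked window pairs at tau = 1, so the grouping threshold must sit
    # below that saturation value
    rf_threshold: float = 0.15
    min_rf_overlap: int = 20
    loess_span: float = 0.15
    marey_min_markers: int = 10
    # association
    p_threshold: float = 0.01
    qtls: list[dict] = field(default_factory=_default_qtls)
    noise_sd: float = 1.0
    phenotype_intercept: float = 10.0
    trait_name: str = "secondary_roots"
    genes: list[dict] = field(default_factory=_default_genes)
    # reproducibility
    seed: int = 0

    def tau_ovule(self, chroms: list[str]) -> dict[str, float]:
        return {c: 1.0 - pp for c, pp in zip(chroms, self.pp_ovule)}

    def tau_pollen(self, chroms: list[str]) -> dict[str, float]:
        return {c: 1.0 - pp for c, pp in zip(chroms, self.pp_pollen)}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
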
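import numpy as np
import pandas as pd
import pytest

from tetrameio import synthdata as sd
from tetrameio.config import PipelineConfig
from tetrameio.pipeline import run_pipeline


def simple_windows(window_ids: list[str], chrom: str = "C1",
                   taxon: str = "medica") -> pd.DataFrame:
    """Window frame for hand-built matrices: ids in physical order."""
    n = len(window_ids)
    return pd.DataFrame({
        "window_id": window_ids, "chrom": chrom, "taxon": taxon,
        "widx": range(n), "start": 1000 * np.arange(n),
        "end": 1000 * np.arange(n) + 999,
        "rep_pos": 1000.0 * np.arange(n) + 500, "n_snps": 20,
    })


def make_windows_frame(genome: sd.GenomeSpec, per_chrom: int = 6,
                       prefix: str = "w") -> pd.DataFrame:
    """Evenly spaced pseudo-window definitions for truth-dose analyses."""
    rows = []
    for chrom, length in genome.chromosomes:
        pos = np.linspace(0.06 * length, 0.96 * length, per_chrom)
        for i, p in enumerate(pos):
            rows.append((f"{prefix}_{chrom}_{i:02d}", chrom, "medica", i,
                         p - 1, p + 1, float(p), 1))
    return pd.DataFrame(rows, columns=["window_id", "chrom", "taxon",
                                       "widx", "start", "end", "rep_pos",
                                       "n_snps"])


def truth_matrix(genome: sd.GenomeSpec, tau, n: int, seed: int,
                 per_chrom: int = 6,
                 ancestor: str = sd.MEDICA) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate n ovule-parent gametes and return (dose matrix at evenly
    spaced windows, window frame)."""
    volk, _ = sd.build_parent_karyotypes(genome)
    rng = np.random.default_rng(seed)
    gams = sd.simulate_meiosis(volk, genome, sd.MeiosisParams(tau), n, rng)
    windows = make_windows_frame(genome, per_chrom)
    sites = windows.rename(columns={"rep_pos": "pos"})[["chrom", "pos"]]
    mat = sd.gamete_dose_matrix(gams, sites, ancestor,
                                site_ids=list(windows["window_id"]))
    return mat.astype(float), windows


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(
        n_chromosomes=3, chrom_length=10_000_000,
        pp_ovule=[0.2, 0.6, 0.9], pp_pollen=[0.8, 0.5, 0.3],
        n_hybrids=60, dsnps_per_taxon_per_chrom=200,
        qtls=[{"parent": "ovule", "chrom": "C1", "pos_frac": 0.9,
               "beta": -1.0}],
        genes=[{"gene": "gene_a", "trait": "t", "chrom": "C2",
                "start_frac": 0.5, "width": 100_000}],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_run(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    run_pipeline(small_config, outdir)
    return outdir
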
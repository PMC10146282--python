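"""Dose-phenotype association scan with one planted QTL.

Simulates 150 gametes of a fully tetrasomic parent, plants an additive QTL
of one phenotypic standard deviation on the third window of chromosome 1,
and scans every window with the per-window linear model.
"""

import numpy as np
import pandas as pd

from tetrameio import synthdata as sd
from tetrameio.association import glm_scan

genome = sd.default_genome(n_chromosomes=3, chrom_length=10_000_000,
                           map_length=1.0)
volkamer, _ = sd.build_parent_karyotypes(genome)
rng = np.random.default_rng(4)
gams = sd.simulate_meiosis(volkamer, genome, sd.MeiosisParams(1.0), 150, rng)

windows = pd.DataFrame(
    [(f"w_{c}_{i:02d}", c, "medica", i, p - 1, p + 1, float(p), 20)
     for c, length in genome.chromosomes
     for i, p in enumerate(np.linspace(0.05 * length, 0.95 * length, 6))],
    columns=["window_id", "chrom", "taxon", "widx", "start", "end",
             "rep_pos", "n_snps"])
sites = windows.rename(columns={"rep_pos": "pos"})[["chrom", "pos"]]
doses = sd.gamete_dose_matrix(gams, sites, sd.MEDICA,
                              site_ids=list(windows["window_id"])).astype(float)

causal = "w_C1_02"
pheno = sd.simulate_phenotypes(doses, [(causal, 1.0)], noise_sd=1.0,
                               intercept=10.0, rng=rng,
                               trait="secondary_roots")

res = glm_scan(doses, pheno, windows, p_threshold=0.01)
res = res.sort_values("p")
print("top 5 windows by GLM p-value (planted QTL:", causal + "):")
print(res[["window_id", "effect", "F", "p", "n0", "n1", "n2"]]
      .head(5).to_string(index=False))
n_sig = res["significant"].sum()
print(f"\nwindows significant at p < 0.01: {n_sig} of {len(res)}")
print("The planted window tops the scan; its linked neighbours on C1 carry")
print("attenuated signal, and unlinked chromosomes stay near the null.")
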
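"""Apply the benchmark's variant QC and LD-pruning filters.

QC order is fixed: per-site missingness (max 0.05) -> per-individual
missingness (max 0.01) -> minor-allele frequency (min 0.003), recomputed on
the kept individuals. LD pruning slides 50 kb windows by 10 kb and drops the
later site of any pair with r^2 > 0.1 (PLINK-style greedy, keep-earlier).
"""

import numpy as np

from admixbench import FilterSettings, ld_prune, qc_filter

rng = np.random.default_rng(0)
n_sites, n_indiv = 300, 120
freq = rng.uniform(0.0, 0.5, size=n_sites)
geno = rng.binomial(2, freq[:, None], size=(n_sites, n_indiv)).astype(float)
geno[rng.random(geno.shape) < 0.01] = np.nan  # sprinkle missing calls
geno[10] = np.where(np.isnan(geno[10]), np.nan, 0.0)  # a monomorphic site
positions = np.sort(rng.choice(3_000_000, size=n_sites, replace=False)) + 1
geno[50] = geno[49]  # a duplicated (perfect-LD) neighbour

settings = FilterSettings()  # the published thresholds are the defaults
kept_sites, kept_indiv, report = qc_filter(geno, settings)
print(f"QC: {report.n_sites_in} sites in -> {report.n_sites_kept} kept "
      f"({report.sites_failing_missingness} failed missingness, {report.sites_failing_maf} failed MAF)")
print(f"    {report.n_individuals_in} individuals in -> {report.n_individuals_kept} kept")

pruned = ld_prune(geno[kept_sites][:, kept_indiv], positions[kept_sites], settings)
print(f"LD pruning: {kept_sites.size} -> {pruned.size} sites "
      f"(pairs with r^2 > {settings.r2_max} lose their later member)")
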
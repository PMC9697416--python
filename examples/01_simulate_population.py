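"""Simulate a multi-family DH population and a seven-environment trial.

Builds a marker map, six biparental DH families (one BC1DH), injects
genotyping noise, simulates an augmented alpha trial with replicated
checks, and writes VCF / CSV / JSON-truth files.
"""

import numpy as np

from gxemap import io, simulate as sim

gmap = sim.make_genetic_map(n_chrom=2, markers_per_chrom=150,
                            chrom_length_bp=80_000_000, cm_per_mb=1.2, seed=1)
specs = sim.default_family_specs()          # 17/22/35/38/44/78 lines, SXDF = BC1DH
fams = sim.simulate_families(specs, gmap, seed=2, polymorphic_frac=0.65)
pop = sim.merge_families(fams)
print(f"{pop.n_lines} DH lines x {pop.n_markers} markers, "
      f"{len(specs)} families, map {gmap.total_length_cm():.0f} cM")

bc = fams["SXDF"]
p1 = bc.parents["SXDF"]["SXDF.P1"]
p2 = bc.parents["SXDF"]["SXDF.P2"]
poly = p1 != p2
freq = (bc.calls[:, poly] == p1[None, poly]).mean()
print(f"BC1DH recurrent-parent allele share at informative markers: "
      f"{freq:.3f} (expected 0.75)")

noisy = sim.corrupt_genotypes(pop, error_rate=0.02, het_rate=0.01,
                              missing_rate=0.05, seed=3)
trial = sim.simulate_trial(pop, qtls=[], envs=sim.default_env_specs(),
                           sigma_g=2.0, sigma_ge=1.0, seed=4)
print(f"trial: {len(trial.plots)} plots over {len(trial.environments)} "
      "macro-environments, checks Zheng58/Chang7-2 in every block")

io.write_vcf(noisy, "scratch_genotypes.vcf")
io.write_phenotypes(trial, "scratch_phenotypes.csv")
io.write_truth(trial, "scratch_truth.json")
print("wrote scratch_genotypes.vcf, scratch_phenotypes.csv, scratch_truth.json")
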
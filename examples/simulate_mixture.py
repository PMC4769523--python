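"""Build a low-fraction two-template mixture with an exact truth set.

First demonstrates how pairwise template alignment defines the truth set —
SNPs within 5 bp of an indel are excluded as misalignment-prone — then
simulates miscalibrated reads from two substitution-diverged templates
(mixtures require equal-length templates so minor reads map ungapped onto
major-template coordinates) and thins one library into the other at 0.3 %.
The truth set records, per planted site, how many minor-template fragments
the binomial thinning actually delivered — the quantity a caller should
recover.
"""

import numpy as np

from segreg.simulate import (ErrorProfile, generate_templates, make_mixture,
                             simulate_reads, template_diff)

# --- the 5-bp indel exclusion rule on a crafted pair -----------------------
base, _ = generate_templates(0, 1000, 0.0, seed=9)
variant = base[:200] + base[201:300] + "A" + base[301:]   # 1-bp deletion at
# position 201 plus a substitution at position 301, i.e. 3 bp from nothing —
# far from the indel; now add one right next to the deletion:
variant = variant[:201] + ("G" if variant[201] != "G" else "C") + variant[202:]
diff = template_diff(base, variant)
print(f"Crafted pair: {len(diff.indels)} indel, {len(diff.snps)} SNP kept, "
      f"{len(diff.excluded_snps)} SNP excluded (within 5 bp of the indel)")

# --- the mixture itself ----------------------------------------------------
ancestor, templates = generate_templates(2, 8000, 0.002, seed=5)
a, b = templates
diff = template_diff(a, b)
print(f"\nMixture templates differ at {len(diff.snps)} SNPs")

profile = ErrorProfile.legacy_basecaller()
lib_a = simulate_reads(a, profile, coverage=2000, read_length=100,
                       paired=True, seed=1)
lib_b = simulate_reads(b, profile, coverage=2000, read_length=100,
                       paired=True, seed=2)
mixed, truth = make_mixture(lib_a, lib_b, 0.003, diff.snps, seed=3)

mafs = np.array([v.realized_maf for v in truth.variants])
print(f"Mixture: {mixed.n_reads} reads, planted fraction 0.003")
print(f"Realized per-site MAF: mean {mafs.mean():.5f}, "
      f"range {mafs.min():.5f}-{mafs.max():.5f}")
print("(the spread around the planted fraction is binomial sampling of "
      "minor fragments,\n which is why realized truth, not the planted "
      "constant, is the calling target)")

print("\nFirst planted sites:")
print("  pos    major>minor  minor reads  depth   realized MAF")
for v in truth.variants[:6]:
    print(f"  {v.position:5d}  {v.major_allele}>{v.minor_allele}          "
          f"{v.realized_count:4d}      {v.depth:5d}   {v.realized_maf:.5f}")
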
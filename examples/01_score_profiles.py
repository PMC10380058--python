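"""Score hand-built genotype profiles with TGS and TWGS.

The total genotype score (TGS) sums per-locus counts of the earlier-maturity
allele (0/1/2) and rescales to 0-100; TWGS weights each locus by its GWAS
effect size first. A score of 50 means the profile is exactly half-way
between the all-later and all-earlier extremes.
"""

import numpy as np

from tgskit import bundled_panel, tgs, twgs

panel = bundled_panel()
betas = np.array(panel.betas)

profiles = {
    "all earlier-homozygote": np.full(39, 2.0),
    "all heterozygote": np.full(39, 1.0),
    "all later-homozygote": np.full(39, 0.0),
    "mixed (alternating 2/0)": np.tile([2.0, 0.0], 20)[:39],
}

print(f"{'profile':30s} {'TGS':>8s} {'TWGS':>8s}")
for name, s in profiles.items():
    print(f"{name:30s} {tgs(s):8.2f} {twgs(s, betas):8.2f}")

print(
    "\nTGS and TWGS agree on uniform profiles; they diverge on mixed ones\n"
    "because the weighted score counts an earlier allele at a high-beta locus\n"
    "(e.g. rs10980922, beta 0.055) nearly 3x as much as at a low-beta locus\n"
    "(rs913588, beta 0.019)."
)
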
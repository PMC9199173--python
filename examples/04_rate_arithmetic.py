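"""Origination-rate estimators on published desk-scale counts.

With 252 species-specific fusion genes across 4 focus species that diverged
within ~1 million years, the raw birth rate is 63 per MY per species; the 64
genes fixed at the 80% population threshold give a fixed rate of 16.  The
synonymous-divergence clock Ks/(2 mu) converts a Ks bound of 1.5 into an age
of ~115 MY, over which 197 retrogenes imply ~1.7 births per MY.
"""

from fusionscan.popfix import birth_rate, ks_to_age, rate_from_age, weighted_rate

MU = 6.5e-9  # substitutions / site / year

print(f"birth rate      252/4/1 MY      = {birth_rate(252, 4, 1.0):g} per MY per species")
print(f"fixed rate       64/4/1 MY      = {birth_rate(64, 4, 1.0):g} per MY per species")
print(f"weighted retro   1 + 1*33/43    = {weighted_rate(1, 1, 33, 43):.2f} per MY")
age = ks_to_age(1.5, MU)
print(f"oldest age       Ks=1.5, mu={MU:g} = {age:.1f} MY")
print(f"rate over age    197/{age:.1f}     = {rate_from_age(197, age):.1f} per MY")
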
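"""Enumerate the incomplete diallel F1 design and the reciprocal backcrosses.

Two blocks each hold four female-biased and four male-biased selection-line
families.  Within a block every ordered dam-family x sire-family pair is a
potential cross except within-family matings, so each block offers
12 FF + 12 MM within-line and 16 FM + 16 MF between-line crosses.
"""

from collections import Counter

import broodsex as bx

design = bx.CrossDesign()  # 2 blocks, 4 + 4 families, no within-family crosses
crosses = bx.enumerate_f1_design(design)
counts = Counter(c.cross_type for c in crosses)

print(f"possible F1 crosses: {len(crosses)}")
for ctype in ("FF", "FM", "MF", "MM"):
    print(f"  {ctype} (dam line {ctype[0]}, sire line {ctype[1]}): {counts[ctype]}")

n_bc, pairs = bx.enumerate_backcross_design(f1_families=34, parent_families=8, reciprocal=True)
print(f"possible backcrosses of 34 between-line F1 families to 8 line families,")
print(f"each direction (F1 as dam / F1 as sire): {n_bc}")
# The counts are what the crossing scheme can support before any mating is
# attempted; realized experiments typically achieve a subset.
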
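"""Reversal distance and minimal scenarios for a five-block arrangement.

Two species share five synteny blocks on a chromosome; in one species the
blocks read 1, 2, 3, 4, 5 and in the other 1, -4, 3, -2, 5 (a minus sign
means the block is inverted).  How many inversions separate them, and in
which orders could those inversions have happened?
"""

from synbreak import enumerate_minimal_scenarios, reversal_distance

reference = (1, 2, 3, 4, 5)
target = (1, -4, 3, -2, 5)

d = reversal_distance(reference, target)
print(f"reversal distance: {d}")

scen = enumerate_minimal_scenarios(reference, target)
print(f"{len(scen.scenarios)} minimal scenario(s):")
for steps in scen.scenarios:
    pretty = " then ".join(f"invert blocks {i}..{j}" for i, j in steps)
    print(f"  {pretty}")

# The two scenarios are the same pair of nested inversions applied in either
# order: the inner inversion spans block 3 alone, the outer spans blocks 2-4.
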
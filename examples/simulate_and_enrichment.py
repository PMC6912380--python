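"""Generate synthetic 4mC data and recover its position-specific composition.

The generator plants C runs at positions 1-3 and 15-17 and a T run at 28-32
in positives, and an A run at positions 1-3 in negatives, each with
probability equal to the effect size. The enrichment analysis should flag
exactly those positions as significantly different between the classes.
"""

from mc4pred import SyntheticConfig, generate_synthetic, position_enrichment
from mc4pred.seqio import POSITIVE

samples = generate_synthetic(SyntheticConfig(n_per_class=300, effect_size=0.8, seed=42))
pos = [s for s in samples if s.label == POSITIVE]
neg = [s for s in samples if s.label != POSITIVE]
print(f"{len(pos)} positives, {len(neg)} negatives, all 41 nt with centre C\n")

profile = position_enrichment(pos, neg)
hits = profile.table[(profile.table.q_value < 0.01) & ~profile.table.is_center]
hits = hits.sort_values(["position", "base"])
print("positions with q < 0.01 (BH-corrected two-proportion z-tests):")
print(hits[["position", "base", "freq_difference", "q_value"]].to_string(index=False))
print(
    "\nPositive freq_difference = enriched in 4mC-bearing sequences. The"
    "\nplanted C blocks (1-3, 15-17), T block (28-32) and the negatives'"
    "\nA block (1-3, negative difference) should dominate this list."
)
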
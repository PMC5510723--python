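"""Harmonize exposure and outcome associations to the same effect allele.

Summary statistics from two different studies routinely report effects for
opposite alleles of the same variant. Skipping this step silently flips the
sign of outcome associations and wrecks the analysis, so the harmonizer
makes every decision explicit: swapped alleles flip the beta, irreconcilable
pairs are dropped and reported, palindromic (A/T, C/G) variants are flagged
because strand cannot be resolved from labels alone.
"""

import pandas as pd

from mrsummary import align_alleles, flag_palindromic

exposure = pd.DataFrame({
    "snp": ["rs1", "rs2", "rs3", "rs4"],
    "beta": [0.30, 0.25, 0.20, 0.15],
    "se": [0.02, 0.02, 0.02, 0.02],
    "effect_allele": ["A", "C", "A", "G"],
    "other_allele": ["G", "G", "T", "A"],
})
outcome = pd.DataFrame({
    "snp": ["rs1", "rs2", "rs3", "rs4"],
    "beta": [0.06, 0.05, 0.04, -0.03],
    "se": [0.01, 0.01, 0.01, 0.01],
    "effect_allele": ["G", "C", "T", "C"],  # rs1 swapped, rs4 mismatched
    "other_allele": ["A", "G", "A", "T"],
})

result = align_alleles(exposure, outcome)
print(result.data.to_frame().to_string(index=False))
print()
print("Dropped:", result.dropped)
print("Palindromic flags:", dict(zip(result.data.variant_ids,
                                     flag_palindromic(result.data))))
print()
print("rs1's outcome beta was flipped to -0.06 (alleles were swapped);")
print("rs4 was irreconcilable (G/A vs C/T) and dropped; rs2 (C/G) and rs3")
print("(A/T) are palindromic and deserve extra scrutiny.")
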
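"""Score a single gene pair by shared substrings.

The directional score ARS(S, R) is the mean, over every start position of S,
of the longest substring beginning there that also occurs in R; averaging the
two directions gives the symmetric pair score, and the promoter (nucleotide
tokens) and CDS (codon tokens) scores combine by a length-weighted mean.
"""

from csn import (
    RegionConfig,
    aggregate_pair,
    build_suffix_index,
    directional_ars,
    normalized_ars,
    tokenize,
)

s, r = "ACGT", "ACGA"
print(f"ARS({s!r} -> {r!r})  =", directional_ars(list(s), build_suffix_index(list(r))))
print(f"ARS({r!r} -> {s!r})  =", directional_ars(list(r), build_suffix_index(list(s))))
print("symmetric pair score =", normalized_ars(list(s), list(r)))
# matches starting at positions 1..4 of ACGT inside ACGA have lengths 3,2,1,0
# (mean 1.5); the reverse direction gives 1.75; their average is 1.625.

cds_a, cds_b = "ATGGCTGCT", "ATGGCTTAA"
n_cds = normalized_ars(tokenize(cds_a, "codon"), tokenize(cds_b, "codon"))
print("\nCDS score in codon units =", round(n_cds, 4))

cfg = RegionConfig(promoter_window=100, cds_window=498)
combined = aggregate_pair(n_utr=2.0, n_cds=n_cds, cfg=cfg)
print("aggregated (promoter score 2.0, weights 100:498) =", round(combined, 4))
# the aggregate is the weighted mean of the two region scores, so the CDS
# contributes about five times the promoter's weight.
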
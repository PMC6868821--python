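# Energetic cost table for mRNA synthesis, in activated phosphate bonds (~P).
#
# Per-base values are order-of-magnitude ribonucleotide biosynthesis costs in
# the style of yeast ~P accounting (opportunity cost of precursor synthesis);
# "elongation" is the polymerization cost per incorporated nucleotide and
# "overhead" a flat per-molecule charge for transcription initiation plus
# termination. Edit freely: every analysis downstream works on correlations
# and is invariant to the exact values, which are treated as data, not code.

elongation = 2.0
overhead = 10.0

[synthesis]
A = 50.0
C = 46.0
G = 51.0
U = 47.0
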
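"""Encode a single-base substitution with its flanking sequence.

A somatic SBS is represented as the mutated base plus its 5' and 3'
flanks.  Each base maps to a 2-bit code (A=[0,0], T=[0,1], C=[1,0],
G=[1,1]); a flank base b becomes the row [b | b], and the mutation site
becomes [alt | ref], so the substitution itself is visible as the one
row whose halves disagree.
"""
import numpy as np

from mutblot import MutationSequence, encode_mutation_sequence, split_bidirectional

# CATTG -> CACTG: a T>C substitution with flanks CA and TG
seq = MutationSequence(
    five_prime_flank="CA", ref_allele="T", alt_allele="C", three_prime_flank="TG"
)
enc = encode_mutation_sequence(seq)
print("encoded matrix (one row per base, mutation row = [alt | ref]):")
print(enc.matrix)
print("mutation site row index:", enc.site_index)

# The feature extractor reads the sequence from both ends toward the
# mutation site; split_bidirectional produces those two reads.
five_read, three_read = split_bidirectional(enc)
print("\n5' read (outside -> site):")
print(five_read)
print("3' read (outside -> site, reversed):")
print(three_read)
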
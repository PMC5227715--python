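"""Mining class-discriminative substrings and encoding sequences with them.

Two tiny training classes differing by a single letter: every substring of
length >= 4 present in exactly one class becomes a Boolean feature. With the
minimality filter, a longer substring is dropped when a shorter one it
contains already separates the classes.
"""

from m6avote import encode_motifs, mine_discriminative_substrings

positives = ["ACGUA", "GGACUACGU"]
negatives = ["ACGGA", "GGGCUACGG"]

for minimal in (False, True):
    vocab = mine_discriminative_substrings(
        positives, negatives, min_len=4, max_len=12, minimal_only=minimal
    )
    print(f"minimal_only={minimal}: {len(vocab)} motifs")
    for e in vocab.entries:
        print(f"  {e.substring:<10} {e.side}")

vocab = mine_discriminative_substrings(positives, negatives)
print("\nBoolean encodings against the minimal vocabulary:")
for seq in positives + negatives + ["UUUUUUUU"]:
    print(f"  {seq:<10} -> {encode_motifs(seq, vocab).tolist()}")
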
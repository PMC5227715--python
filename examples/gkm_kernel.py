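"""The gapped k-mer string kernel on short RNA sequences.

Each length-l word contributes a count to each of its C(l,k) gapped k-mers;
the kernel is the inner product of those count vectors. Similar sequences
share many gapped words, so their normalized similarity approaches 1.
"""

import numpy as np

from m6avote import GkmParams, gapped_kmer_count_vector, gkm_kernel, gkm_kernel_matrix

params = GkmParams(l=2, k=1)
print("count vector of 'AC' at l=2, k=1:", gapped_kmer_count_vector("AC", params))
print("kernel('AC','AC') =", gkm_kernel("AC", "AC", params))
print("kernel('AC','AG') =", gkm_kernel("AC", "AG", params))
print("kernel('AC','GU') =", gkm_kernel("AC", "GU", params))

seqs = [
    "GGACUGGACUGGACU",
    "GGACUGGACUGGACA",  # one substitution
    "UUUUUCCCCCAAAAA",  # unrelated
]
km = gkm_kernel_matrix(seqs, GkmParams(l=6, k=4), normalize=True, ids=("a", "b", "c"))
print("\nnormalized kernel matrix (l=6, k=4):")
print(np.array2string(km.values, precision=3))
print("near-identical sequences score close to 1; unrelated ones near 0")
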
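"""Canonical k-mer spaces and sequence signatures.

Builds the reverse-complement-collapsed k-mer space, counts words in a
short sequence, and shows that a sequence and its reverse complement
produce the identical signature — the property that makes the classifier
strand-independent.
"""

import numpy as np

from virsign import count_kmers, enumerate_canonical_kmers, featurize, revcomp

space = enumerate_canonical_kmers(4)
print(f"canonical 4-mer space: {space.size} words (256 raw words collapsed in pairs)")
print("first five words:", ", ".join(space.words[:5]))

seq = "ACGTACGTTTAAACGTGGGCCC"
cv = count_kmers(seq, space)
print(f"\n{seq!r}: {cv.total} valid 4-mer windows")
top = np.argsort(cv.counts)[::-1][:3]
for i in top:
    print(f"  {space.words[i]}: {cv.counts[i]} occurrences (word or its complement)")

fv_fwd = featurize(seq, space)
fv_rev = featurize(revcomp(seq), space)
same = bool((fv_fwd.freqs == fv_rev.freqs).all())
print(f"\nsignature of sequence == signature of reverse complement: {same}")
print("(frequencies sum to", f"{fv_fwd.freqs.sum():.1f};",
      "each entry is the fraction of windows matching that word pair)")
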
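"""Paired-state probabilities from the different folding backends.

The same hairpin is folded with the ViennaRNA partition function (the
production backend) and with the built-in reference engine, and the
reference engine is checked against exhaustive structure enumeration.
The two backends use different energy models, so their numbers differ;
both must agree that the G-C stem is paired and the loop is not.
"""

import numpy as np

from ribotherm import (
    FoldOptions,
    RnaSequence,
    enumerated_pair_matrix,
    pairing_probabilities,
    reference_pair_matrix,
)

seq = RnaSequence(id="hp", residues="GGGGGAAAAACCCCC")
print(f"{seq.id}: {seq.residues}\n")

for backend in ("vienna", "reference"):
    p = pairing_probabilities(seq, 37, backend=backend)
    print(f"{backend:9s} p(i) at 37 degC: {np.round(p, 2)}")

engine = reference_pair_matrix(seq, 37).P
oracle = enumerated_pair_matrix(seq, 37).P
print(f"\nreference engine vs exhaustive enumeration: "
      f"max |dP| = {np.abs(engine - oracle).max():.2e}")

p_nogu = pairing_probabilities(
    RnaSequence(id="gu", residues="GGGGGAAAAAUUUUU"), 37, FoldOptions(no_gu=True)
)
print(f"wobble-only stem with G-U pairs forbidden: max p = {p_nogu.max():.2f}")
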
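"""Generate in-silico mutant data sets under both regimes.

Coding regime: synonymous single-base changes only (the protein is
untouched). Non-coding regime: substitutions at random positions whose
types mimic the spectrum observed between two homologs.
"""

from collections import Counter

from ribotherm import (
    RnaSequence,
    substitution_spectrum,
    spectrum_mutants,
    synonymous_mutants,
    translate,
)
from ribotherm.fixtures import random_sequence

parent = random_sequence(60, seed=4, id="orf")
print(f"parent ({len(parent)} nt) translates to {translate(parent.residues)}")

ms = synonymous_mutants(parent, n_subs=3, n_mutants=5, seed=2)
for mut in ms.sequences:
    d = sum(a != b for a, b in zip(parent.residues, mut.residues))
    print(f"  {mut.id}: Hamming {d}, protein unchanged: "
          f"{translate(mut.residues) == translate(parent.residues)}")

a = RnaSequence("a", "AUGGCUUACGGAUCU", is_coding=False)
b = RnaSequence("b", "AUGGCUCACGGAUCC", is_coding=False)
spec = substitution_spectrum(a, b)
print(f"\nobserved spectrum between a and b (N={spec.count}): "
      f"{ {f'{x}->{y}': f for (x, y), f in spec.type_frequencies.items()} }")
ms = spectrum_mutants(a, spec, n_mutants=200, seed=3)
realized = Counter()
for mut in ms.sequences:
    for x, y in zip(a.residues, mut.residues):
        if x != y:
            realized[f"{x}->{y}"] += 1
total = sum(realized.values())
print(f"realized over 200 mutants: "
      f"{ {k: round(v / total, 3) for k, v in sorted(realized.items())} }")
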
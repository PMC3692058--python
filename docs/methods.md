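# Methods

## Model and procedure

The pipeline treats temperature sensitivity as a property of the
equilibrium ensemble of RNA secondary structures. At temperature T the
probability that nucleotide i is paired,

    p_T(i) = Σ_j P_T(i, j),

is the row sum of the base-pair probability matrix computed from the
partition function over pseudoknot-free structures. Differences
d(t, i) = p_t(i) − p_t1(i) for all elevated temperatures t in (t1, t2]
are pooled into one data set; outliers beyond k standard deviations of
that pool are "significant" positions, clustered along the sequence with
DBSCAN. For two homologous sequences, clusters present in only one
sequence are tested against a null of random mutation via an in-silico
mutant data set and exact one-sided binomial tests.

The statistic is deliberately relative: the threshold is k·σ of each
sequence's own pooled differences, so "significant" means *unusually
temperature-responsive for this molecule*, not responsive in absolute
terms. A consequence worth knowing: for a molecule with essentially no
temperature response, σ approaches numerical noise and tiny drifts can
be flagged. The fixtures used for validation therefore always retain at
least one genuinely melting element in every sequence.

## Folding backends

* **vienna** — the ViennaRNA partition function (full nearest-neighbour
  energy model), with `noGU` / `noGUclosure` mapped from the G-U
  options. This is the backend for real analyses; its version is
  recorded in `summary.json`.
* **reference** — a built-in inside–outside engine over a minimal
  nucleation-and-zipping model. A structure is any non-crossing set of
  legal pairs (AU/UA, CG/GC, GU/UG; hairpin loops ≥ 3 nt); its Boltzmann
  weight is a product of one weight per pair,
  q = exp(−(ΔH_pair − T·ΔS_pair)/RT), and one stacking weight
  σ = exp(−(ΔH_s − T·ΔS_s)/RT) per pair stacked directly on its inner
  neighbour. Constants (kcal/mol; kcal/mol/K):

  | term | ΔH | ΔS |
  |------|-----|------|
  | G-C  | −3.0 | −0.008 |
  | A-U  | +5.2 | 0 |
  | G-U  | +6.5 | 0 |
  | stack | −19.56 | −0.0444 |

  A-U and G-U pairs carry a positive (nucleation) free energy and are
  viable only inside stacked helices; the stack term carries the bulk of
  the temperature dependence. This makes helix formation cooperative —
  two-state-like melting with a length-dependent melting temperature —
  which is the qualitative behaviour the pipeline needs: a ~10-bp A-U
  stem melts inside the default 32–39 °C window, its 4–5-bp fragments
  (what a mid-stem substitution leaves behind) are unstable across the
  window, and G-C stems stay formed everywhere in 0–99 °C. An
  independent-pair model (no stacking) was rejected because removing a
  single pair then leaves the rest of a stem almost unchanged, so no
  single substitution could ever delete a cluster and the comparison
  pipeline would be untestable end to end.

  The engine is not a stand-in for ViennaRNA numerics and is not
  claimed to reproduce them; its role is a backend whose numbers are
  *exactly* checkable against exhaustive structure enumeration
  (the enumeration oracle applies the identical weighting), which the
  full nearest-neighbour model is not.

### Numerical notes

* Inside–outside recursions are O(n³) (numba-compiled); probabilities
  are read off as P(i,j) = β_b(i,j)·Z_b(i,j)/Z and clipped to [0, 1]
  against roundoff.
* Per-base rescaling keeps the partition function inside double range:
  the initial scale is exp(W/n) with W the log-weight of the single best
  structure (a max-weight pass), adjusted adaptively on overflow or
  underflow of the full-length value. Uniform scaling can in principle
  underflow intermediates for very long, completely inert regions
  embedded in a highly structured context; the driver raises rather than
  returning non-finite probabilities in that case.
* With `no_close_gu`, the recursion admits a G-U pair only when stacked
  on its *inner* neighbour, whereas the enumeration oracle implements
  the full helix-end rule (inner or outer neighbour). The approximation
  is confined to the reference engine; the ViennaRNA backend delegates
  to ViennaRNA's own semantics. Oracle-equivalence checks therefore run
  with the default and `no_gu` option sets.
* Temperatures are integers (°C), matching the 1 °C scan granularity.

## Scan statistics

The pooled difference set excludes the t1-vs-t1 zero row: for L = 1000
and 32–39 °C it holds exactly 7·1000 values. Its SD is the *population*
SD (the pool is the complete population of computed differences, and at
n ≈ 7000 the sample/population distinction is immaterial; fixing it
makes results bit-reproducible). σ = 0 yields no significant positions.
Significance is assessed per (temperature, position) cell; the
increase/decrease split at the top difference uses the sign of
d(t2, i). In two-sequence mode each sequence gets its own mean/SD.

## Clustering

Standard DBSCAN on the integer line (distance |a − b|), core point =
≥ MinPts points within ε including itself, defaults ε = 11, MinPts = 5.
Only top-difference positions are clustered by default
(`cluster_all_temperatures` opts into the union over all elevated
temperatures). Input positions are sorted ascending before clustering,
which resolves DBSCAN's only order dependence — border points reachable
from two clusters — deterministically left to right. `scikit-learn`'s
DBSCAN is used under this surface; a brute-force implementation with
explicit neighbourhoods serves as the independent oracle in tests. The
sliding-window density profile uses window 2ε + 1 in steps of 1; a
sequence shorter than the window falls back to one full-length window.

## Mutant generation

* Coding regime (default): each mutant receives exactly N single-base
  synonymous substitutions (standard genetic code, frame 1). Options are
  re-evaluated against the current mutated sequence after every accepted
  change, so two hits in one codon cannot combine into a missense
  change; positions are hit at most once, keeping the Hamming distance
  exactly N. Synonymous options are sampled uniformly.
* Non-coding regime: substitution types are drawn from the observed
  A-vs-B spectrum, positions uniformly among bases matching the drawn
  from-base (bounded rejection resampling when a type has no eligible
  site left).

Mutants are drawn independently with replacement, so duplicates are
possible; the default data-set size is 100 (configurable). All sampling
uses a seeded PCG64 generator; identical inputs and seed give identical
mutant sets.

## Statistical tests

Composite one-sided nulls are evaluated at their boundary: disappear
(cluster in the first sequence only) — upper tail P(X ≥ k) at p₀ = 0.95;
appear (second sequence only) — lower tail P(X ≤ k) at p₀ = 0.05,
computed as the complementary 0.95 upper tail so that the
appear/disappear symmetry identity holds exactly in floating point. The
95% CI for k/n is Clopper–Pearson. No multiple-testing correction is
applied across clusters (per-cluster p-values are reported); a notice is
emitted when more than one cluster is tested.

## Synthetic fixtures

`fixtures.make_fixture` builds the validation sequences: a thermostable
G-C hairpin, a melting A-U hairpin, and a sequence pair in which one
substitution splits one of two melting stems. The two A-U stems use
fixed patterned arms chosen so that no cross-register between the
hairpins supports a stacked run longer than 4 (free energy > +2.5
kcal/mol at 32 °C, negligible occupancy); spacers are C-only and the
stable stem G/C-only, so the designed elements are the only A/U pairing
partners. The seed varies inert spacer lengths only.

What these fixtures emulate: localized, cooperative melting transitions
inside a narrow physiological window, and a substitution that removes
one such element. What they do not emulate: natural sequence
composition, long-range tertiary effects, kinetic traps, modified
nucleotides, and ViennaRNA-scale energy accuracy. Passing tests
demonstrate that the pipeline's bookkeeping and statistics are correct
and that the comparison logic detects designed signals; they say nothing
about the biological truth of any particular prediction on real RNA.

## Problem sizes used in validation

Enumeration cross-checks use ≥ 50 random sequences of length ≤ 20 at
three temperatures; DBSCAN cross-checks 500 random instances of ≤ 40
points on lines ≤ 300; binomial tests all 0 ≤ k ≤ n ≤ 200; mutant-regime
checks 1000 mutants of a 300-nt parent; the data-set-size check runs the
reference engine on a 1000-nt random sequence over 32–39 °C; end-to-end
specificity runs use the ~115-nt fixture pair with 12–100 mutants. These
sizes keep the whole suite within a few minutes on one CPU while
exercising every component at a scale where the oracles are exact.

## Known limitations

* The reference energy model is a caricature (no loop entropies, no
  sequence-dependent stacking, single global stack weight); use the
  ViennaRNA backend for biological conclusions.
* The relative k·σ threshold can flag noise on near-inert sequences (see
  above).
* DBSCAN border-point ties are resolved left-to-right by convention;
  other orderings are equally valid DBSCAN results.
* The `no_close_gu` approximation in the reference engine (above).
* Equal-length sequences only; no alignment is attempted.
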
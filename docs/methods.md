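# Methods

This note documents the models, conventions and numerical choices behind
`monotax`, in the spirit of the methods documentation that accompanies
packages like statsmodels or msprime: what is computed, under which
assumptions, and what the synthetic experiments do and do not demonstrate.

## De Man indices and population summaries

Raw measurements are micrometres throughout; only `L` (body length) is
reported in millimetres (`µm / 1000`). The indices follow their standard
definitions:

- `a` = body length / greatest body diameter
- `b` = body length / pharynx length (anterior end to the
  pharyngo-intestinal valve)
- `c` = body length / tail length
- `c'` = tail length / body diameter at the anus
- `V`, `G1`, `G2` = vulva distance and anterior/posterior gonad lengths as
  % of body length
- buccal capsule ratio = capsule length / capsule width
- tooth apex position = distance from the dorsal tooth apex to the
  anterior end of the buccal capsule as % of capsule length

Indices are stored unrounded; rounding happens only at formatting time.
The default tie rule is half-away-from-zero (1 decimal for ratios,
integers for percents), with half-even available via
`round_half(..., mode="even")` — published tables are not consistent about
the tie rule, so tests compare recomputed indices to printed ones with a
tolerance (±0.1 for ratios, ±1 for integer percents) rather than asserting
exact rounding equality. Printed raw measurements are themselves rounded
to the micrometre, which is the dominant contribution to that tolerance.

Missing inputs leave the dependent index flagged missing (`None`, rendered
"–"); nothing is imputed. Population summaries use the sample standard
deviation (n−1) and render as `mean ± sd (min–max)` for n ≥ 3, the bare
values for n ≤ 2.

Ratios involving the vulva–anus distance are not derived by chaining
`V·L − tail`: where a workflow needs that distance it must be measured
directly, because chained derivation assumes measurement along the body
axis while curved-body measurements make the two inconsistent.

## The dichotomous key engine

A key is data: characters (quantitative with units, or qualitative with a
controlled state vocabulary), couplets with exactly two leads, each lead a
conjunction of threshold conditions targeting either another couplet or
terminal taxa. The bundled resource encodes a 31-couplet key to the
species of *Mononchus* (couplets numbered 1–32 with 8 absent, preserving
the printed numbering for citability; numbering gaps are legal). The key
resolves 32 terminal names; the count discrepancy with the announced "31
species" is documented in the resource's notes rather than silently fixed.

Evaluation uses three-valued (Kleene) logic. Evidence values are points
(one specimen), closed intervals (population ranges) or states. A numeric
condition against an interval is true only if the whole interval
satisfies it, false only if none of it does, and unknown in between;
missing characters are unknown. During identification every non-false
lead is followed, so incomplete specimens key out to a candidate set (the
result is `unique`, `ambiguous`, or `dead_end` with the failed conditions
recorded). This matches how taxonomists actually use keys with partial
material, and it makes identification monotone: extra evidence can only
prune candidates.

Boundary policy: printed ranges are treated as closed on both sides. A
value sitting exactly on a threshold shared by both leads satisfies both
(the traversal branches); a value falling in a gap between the two ranges
satisfies neither, and `validate_key` enumerates all such gap, overlap and
shared-boundary zones per couplet (e.g. body lengths in (2.1, 2.4) mm dead-end
at couplet 1). No tie rule is invented where the source gives none.

Verbal thresholds without printed numbers ("about twice as long as wide",
"tooth apex quite close to the anterior end") are encoded once as closed
numeric ranges, listed in the key JSON's notes. Male-only characters
(spicule, supplements) carry `sex: male` and are masked to unknown when
identifying female evidence. The one lead that contrasts one state
against two ("pars refringens distinctly sclerotised" = rhomb or drop)
uses a `state-in` comparator; all other compound leads are conjunctions.

`discriminating_characters` ranks characters by the number of candidate
pairs whose key paths first diverge at a couplet conditioning on them — a
brute-force "measure this next" heuristic over the path structure, not an
information-theoretic optimisation.

## Sequence divergence

Distances are uncorrected p-distances (no multiple-hit correction),
reported both as raw nucleotide differences and as percent, mirroring the
convention of rDNA barcoding tables; percent values are rounded to one
decimal only at presentation. Gap handling follows the pairwise /
complete deletion dichotomy; ambiguity codes are treated as missing by
default (the conservative MEGA-style convention), with IUPAC-intersection
matching behind `iupac=True`. Alignments are accepted as input from any
external aligner; the built-in Needleman–Wunsch aligner (linear gap
penalty, deterministic traceback preferring substitution, then a gap in
the second sequence) is intended for near-identical pairs such as
conspecific isolates, not as a multiple aligner. `trim_alignment` removes
only columns inside some sequence's terminal missing-data run — trimming
to the span every sequence covers — and never touches interior columns.

Divergence summaries partition pairs into intraspecific, interspecific
and intergeneric tiers, pooled per species/genus (`group_divergence`) or
per named comparison (`species_pair_divergence`); outlier isolates can be
excluded from ranges without removal from the matrix. The
species-delimitation flags formalise threshold reasoning against a
reference interspecific band (percent p-distance): a nominally distinct
pair whose maximum divergence falls below the band's minimum is a
*conspecificity candidate*; a taxon whose minimum divergence to nominal
congeners exceeds the band's maximum is a *generic misplacement
candidate*. The flags are screening heuristics — they inherit all the
caveats of distance thresholds for species delimitation and are meant to
be read next to a phylogeny, not instead of one.

Neighbour joining is the standard Saitou–Nei agglomeration on the
Q-criterion. Ties in Q are broken by the first (smallest-index) pair so
results are deterministic; negative branch lengths are clamped to zero
with a warning. On additive distances NJ provably recovers the generating
topology, and the test suite checks this on 50 random binary trees with
≤8 leaves against the generator's known splits, plus a least-squares
oracle over all three quartet topologies. Bootstrap support resamples
alignment columns with replacement; support is the percentage of
replicate NJ trees containing each internal bipartition of the
point-estimate tree, seeded and reproducible. Maximum-likelihood
inference and substitution-model selection are out of scope; NJ here
plays its usual exploratory role.

## Synthetic data

The specimen generator draws each published character from a truncated
normal: mean and SD from a printed `mean ± sd` when available, otherwise
mean = range midpoint and sd = range/4 (a stated convention). Ratio
characters (a, b, c, c', V, capsule ratio, tooth position) are sampled
directly and the dependent raw measurement is back-derived (e.g. tail =
body/c), because sampling numerator and denominator independently would
push derived ratios outside every printed range — with capsule length
29–33 µm and width 15–16 µm an independent draw yields ratios up to 2.2
against a true species range of 1.8–2.0, which would send half the
specimens down the wrong couplet. Characters are otherwise independent:
no covariance between, say, body and tail length is modelled, since only
marginal ranges are published. Consequently the generator demonstrates
that the pipeline is correct under the published marginals; it does not
emulate measurement correlation, allometry, sexual dimorphism or
observer error in real populations, and passing tests should be read with
that limit in mind.

The bundled *M. pseudoaquaticus* profile pools the five published female
populations (body 1.23–1.88 mm, c' 4.7–5.8, capsule 29–33 µm at ratio
1.8–2.0, tooth apex 18–21%, etc.) with the species' qualitative states
(didelphic, terminal spinneret, rhomb-shaped pars refringens, vagina not
spotted, ribs at/behind the tooth apex). Fifty specimens from this
profile identify to the correct species in ≥95% of draws (observed: all).

Sequence families use a two-rate star design: one random ancestor, per
species a root mutated at the interspecific rate, per isolate a sequence
mutated from its root at the intraspecific rate, substitutions uniform
over the three alternative bases. Defaults (length 1000 nt, intra
0.0015/site, inter 0.08/site) reproduce the divergence structure typical
of 28S rDNA barcoding in these nematodes: intraspecific ≲0.3%,
interspecific ~5–12%. Two isolates of one species then differ at a site
with probability 2q(1−q) + ⅔q², which is the oracle used for parameter
recovery (observed mean within 3 SE). No indels and no tree-structured
evolution beyond the star are simulated.

## Problem sizes and numerical conventions

The default test-suite experiments use: 50 additive-tree NJ trials (≤8
leaves), 30 random keys for the identification oracle, 100 simulated
families for rate recovery, 50 synthetic specimens for the end-to-end
identification rate, 100–200 bootstrap replicates in tests (1000 remains
the recommended analysis default). These sizes were chosen as the
smallest that keep binomial sampling error well inside the asserted
margins. All randomness flows from explicit integer seeds through numpy's
`default_rng`; reports use 1-based coordinates, internals 0-based;
CSV/TSV, FASTA, JSON and newick are the only on-disk formats.

## Known limitations

- The key engine evaluates conditions independently; it does not model
  correlated characters or measurement uncertainty beyond interval
  evidence.
- Distance thresholds are screening tools; the conspecificity and
  misplacement flags do not replace phylogenetic or morphological
  evidence.
- The built-in aligner is pairwise and linear-gap only; divergent
  sequences should be aligned externally before distance computation.
- The synthetic generator's independence assumption understates the
  morphometric covariance of real specimens (see above).
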
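# monotax

Integrative-taxonomy toolkit for mononchid nematodes (Mononchida), built
around the three kinds of evidence such studies combine: **morphometrics**
(De Man indices and population tables), **identification keys** (an
executable dichotomous key engine, shipping a key to the species of
*Mononchus*), and **rDNA sequence divergence** (uncorrected p-distances,
intraspecific/interspecific/intergeneric tiers, conspecificity flagging,
and neighbour-joining trees with bootstrap support). A synthetic-data
module generates specimens and sequence families with the same
statistical structure, so the whole pipeline is testable offline.

It is aimed at nematode taxonomists and barcoding practitioners who want
the quantitative steps of a species description — index tables, keying
out, Table-of-divergences, exploratory trees — to be scripted,
deterministic and checkable rather than hand-computed.

## The core computations

**De Man indices.** For a specimen with body length *L* (µm),

- *a* = *L* / greatest body diameter, *b* = *L* / pharynx length,
  *c* = *L* / tail length, *c′* = tail length / anal body diameter,
- *V*, *G1*, *G2* = vulva distance and gonad lengths as % of *L*,
- tooth apex position = 100 · (apex distance / buccal capsule length),

with population cells rendered `mean ± sd (min–max)` (sample SD, n−1).

**Key engine.** A dichotomous key is data: couplets with two contrasting
leads, each a conjunction of conditions. Evidence (points, population
ranges, qualitative states) is evaluated in three-valued logic — a
condition an incomplete specimen cannot decide is *unknown*, and every
non-false lead is followed — so identification returns a candidate set
with full paths, instead of failing on missing characters. `validate_key`
reports the gap/overlap zones between the two leads' ranges.

**Sequence divergence.** For aligned sequences *i*, *j*, the uncorrected
p-distance is *p* = (differing sites) / (compared sites), with compared
sites chosen under pairwise or complete deletion of gaps/ambiguities.
Pairs are partitioned into divergence tiers, and a pair of nominal
species whose divergence falls below the reference interspecific band is
flagged as a conspecificity candidate (conversely, divergence above the
band flags generic misplacement). Trees are built by neighbour joining
(Saitou–Nei Q-criterion, deterministic tie-breaking) with
column-resampling bootstrap supports.

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

Key out the *Mononchus pseudoaquaticus* holotype female from its raw
measurements (µm):

```python
from monotax import SpecimenMeasurements, compute_indices, load_bundled_key, identify
from monotax.key import CharacterValue as CV

m = SpecimenMeasurements(
    specimen_id="holotype", body_length=1450, tail_length=195,
    pharynx_length=365, max_body_diameter=72, body_diameter_at_anus=39,
    buccal_capsule_length=29, buccal_capsule_width=16, tooth_apex_distance=6,
    lip_region_width=25,
)
idx = compute_indices(m)
print({k: v for k, v in idx.formatted().items() if v != "–"})

key = load_bundled_key("mononchus")
evidence = [
    CV("body_length", idx.L), CV("c_prime", idx.c_prime),
    CV("bc_ratio", idx.bc_ratio), CV("tooth_position", idx.tooth_position),
    CV("buccal_capsule_length", 29), CV("buccal_vs_labial", 29 / 25),
    CV("gonads", "didelphic"), CV("spinneret", "terminal"),
    CV("pars_refringens", "rhomb"), CV("subventral_ribs", "at_level_or_posterior"),
    CV("amphid_position", "anterior"), CV("vagina", "not_spotted"),
]
result = identify(key, evidence, sex="female")
print(result.status, sorted(result.candidates), result.paths)
```

prints

```
{'L': '1.45', 'a': '20.1', 'b': '4.0', 'c': '7.4', 'c_prime': '5.0', 'bc_ratio': '1.8', 'tooth_position': '21'}
unique ['M. pseudoaquaticus sp. nov.'] (('1', '13', '14', '15', '17', '20', '21', '23', '24', '26', '28', '30', '31'),)
```

i.e. the specimen is a mid-sized female (L = 1.45 mm) with tail ≈ 5 anal
body diameters (c′ = 5.0), a buccal capsule 1.8× as long as wide with the
tooth apex at 21% of capsule length — and it keys out uniquely, via
couplets 1 → 13 → … → 31, to *M. pseudoaquaticus*.

The same operations are available from the shell:

```bash
monotax indices --in specimens.csv --group-by taxon_label --out report.tsv
monotax identify --key mononchus --evidence specimen.csv --explain
monotax validate-key --key mononchus
monotax distances --fasta aln.fasta --labels map.csv --deletion pairwise
monotax nj --fasta aln.fasta --bootstrap 1000 --seed 42 --out tree.nwk
monotax simulate sequences --seed 1 --length 1000
monotax run --specimens specimens.csv --fasta aln.fasta --labels map.csv --seed 42
```

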
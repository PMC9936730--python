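# karyofish

Comparative single-gene FISH karyotype analysis for Triticeae
allopolyploids — built around the *Elymus* St/H/Y system (*E. sibiricus*,
StStHH; *E. nutans*, StStHHYY; the diploid H-genome outgroup
*Hordeum bogdanii*).

Single-gene FISH places one fluorescent signal per gene per chromosome,
giving an ordered physical map of 7–10 markers along each mitotic
chromosome. Against a reference collinearity standard (the rearrangement-
free D-genome gene order), those maps reveal chromosomal rearrangements:
pericentric and paracentric inversions (PeI/PaI), reciprocal and simple
translocations (RT/T), duplications-with-insertion (Du) and deletions
(De). `karyofish` turns the by-hand reading of such maps into a tested
pipeline:

* **collinearity** — reduce an observed chromosome to an unsigned
  permutation of its homoeologous group's reference indices, with a
  centromere token at the observed centromere rank; foreign-group runs,
  missing probes and extra copies are separated out; breakpoints counted.
* **rearrangement inference** — exact breadth-first search for *all*
  minimal reversal scenarios (sorting by reversals, unsigned, with the
  centromere constraint: a step spanning the token is pericentric);
  translocation calls from terminal foreign runs (reciprocal pairs merged
  into one RT); Du/De calls guarded against truncated maps.
* **comparative accounting** — species-specific vs. polymorphic
  classification of rearrangement complexes across materials (an
  inversion series on one chromosome counts once), and breakpoint-reuse
  tallies over reference intervals.
* **pattern variants** — chromosome-variant counts from repeat-FISH
  letter matrices (distinct letter+prime codes per chromosome column).
* **probe design** — the single-copy, collinear, length- and
  spacing-filtered gene selection used to build such probe sets.
* **simulator** — karyotypes with known applied rearrangements and
  pattern grids with known variant structure, so every inference stage
  has a ground-truth recovery test.

The model is deliberately order-based: FISH gives relative placement, not
base pairs or orientation, so marker *ranks* (plus arm membership) drive
all inference. The minimal scenario length d obeys d ≥ ⌈b/2⌉, where b is
the unsigned breakpoint count — one reversal repairs at most two
breakpoints — and the search is exact up to a configurable depth
(default 4).

## Worked example

Infer rearrangements for the packaged reconstruction of the
*E. sibiricus* reference material:

```sh
python -c "
from karyofish import fixtures as fx
from karyofish.core import write_karyotype
write_karyotype(fx.demo_karyotype('DY')[0], 'dy.map.tsv')"
karyofish infer --map dy.map.tsv \
    --reference src/karyofish/data/reference_orders.tsv \
    --manifest  src/karyofish/data/probes_manifest.tsv \
    --out-prefix dy
```

`dy.report.txt` renders each chromosome as its observed marker order
(`|` = centromere, `<...>` = a foreign-group run):

```
  4H  <6H041> 4H138 4H242 | 4H388 4H289 4H435 4H481 4H530 4H604
  6H  <4H052> 6H090 6H125 6H277 | 6H198 6H356 6H442 6H518 6H590

events:
  4H/6H  RT (4H/6H)
  1H  PeI I
  ...
```

The exchanged distal short-arm probes (6H041 sitting on 4H and vice
versa) are read as one reciprocal translocation, and each chromosome
whose own-group order departs from the reference gets its minimal
inversion scenario — here one pericentric inversion on each of 1H, 2H,
3H, 6H, 2St and 5St, a paracentric one on 4St, and a two-step pericentric
series on 4H, matching the events the map was built from.

Classification and variant counting run straight off the packaged
transcribed tables:

```sh
karyofish compare  --events src/karyofish/data/table1_events.tsv --out calls.tsv
karyofish variants --patterns src/karyofish/data/table2_patterns.tsv \
    --species E_nutans --out variants.tsv
```

`calls.tsv` ends with

```
# E_sibiricus: species_specific=8 polymorphic_types=4 material_specific=3
# E_nutans: species_specific=5 polymorphic_types=15 material_specific=9
```

— eight rearrangement complexes fixed in all six *E. sibiricus*
materials, five in all four *E. nutans* materials, and fifteen
polymorphic event types segregating within *E. nutans*. `variants.tsv`
tabulates per-chromosome variant counts with subgenome totals
(*E. nutans*: 20 H + 21 St + 25 Y = 66 variants, 18 of them carrying a
polymorphic rearrangement).

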
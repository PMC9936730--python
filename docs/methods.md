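# Methods

## Coordinate model

A chromosome map is a strictly increasing list of marker positions in
[0, 1] measured from the short-arm telomere, plus a centromere fraction.
Positions carry no metric meaning beyond ordering and arm assignment
(arm = S iff position < centromere): single-gene FISH resolves relative
placement, not distance or orientation. All inference therefore runs on
ranks. Reference indices are 0-based and intervals half-open, so a
reversal of `[lo, hi)` composes with ordinary slice arithmetic.

Each homoeologous group (1–7) has one reference order — the
rearrangement-free D-genome standard — shared by all subgenomes: a
single-gene probe hybridises to its locus on every homoeologue, so the
same order is expected on 4H, 4St and 4Y alike.

## From map to permutation

`build_permutation` separates three signals before any inversion
reasoning, mirroring how such maps are read by eye:

* **Foreign runs** — maximal runs of sites whose probe belongs to a
  different homoeologous group. Terminal runs are translocation signal;
  interstitial ones duplication signal. They are excised from the
  backbone.
* **Missing probes** — shrink the reference index set, which is
  re-ranked densely (the backbone is always a permutation of 0..k−1);
  a boundary map keeps dense boundaries addressable in full-reference
  coordinates so breakpoint loci stay comparable across materials with
  different missing sets.
* **Extra copies** — for a probe observed twice on one chromosome the
  lowest copy index stays in the backbone, the rest become Du
  candidates.

The centromere enters the backbone as a token at the observed centromere
rank. Breakpoints are counted on markers only (framed by telomere
sentinels; a pair is intact iff the indices differ by one); the token is
ignored there because centromere position is an observation about arms,
not an adjacency.

## Minimal inversion scenarios

The search solves unsigned sorting-by-reversals with a centromere
constraint. Valid reversals cover at least two sequence elements (two
markers, or one marker plus the token — the move that flips a marker
across the centromere). A step is classified PeI iff its interval
contains the token at application time, else PaI: moving the centromere
is precisely what distinguishes a pericentric inversion and changes arm
ratios.

The implementation is a level-synchronised breadth-first search from the
reference sequence to the observed one, keeping parent links so that
*all* minimal scenarios are reconstructed from the layered DAG, sorted
lexicographically by interval list; the first (canonical) one names the
emitted events, and downstream logic treats the scenario *set* —
multiple minimal histories are common and forcing one would overstate
certainty. States that cannot reach the target within the remaining
depth are pruned with the admissible bound d ≥ ⌈b/2⌉ (a reversal repairs
at most two breakpoints), which leaves the result set unchanged; the
test suite cross-checks the search against an independently written
iterative-deepening oracle.

`max_depth` defaults to 4: observed chromosomes resolve within three
successive inversions, marker counts are 7–10, and exhaustive search at
that scale is interactive. Beyond the cap the search reports an infinite
distance and an empty scenario set rather than a truncated answer.

Inversion events are reported with the reference span of the inverted
segment (dense marker values mapped through the boundary map). For
multi-step scenarios the spans of later steps are expressed in the
coordinates of the already-rearranged order's content, which is also how
multi-inversion series are described in idiogram form.

## Translocations and copy number

A terminal foreign run on A sourced from group g pairs with a terminal
foreign run on some group-g chromosome B sourced from A's group: one RT,
chromosomes sorted lexicographically, never two one-way calls. Unpaired
terminal runs become T(source → A), the donor identified as the
source-group chromosome most depleted of the run's probes.
Single-probe terminal foreign sites are translocation candidates only
when the probe's home chromosome actually lacks its copy; otherwise they
are duplications — this separates an extra inserted site from a moved
one. Interstitial foreign sites are always Du.

De calls require the two nearest reference neighbours of the missing
probe to be present on the chromosome (a truncated or sparse map is not
a deletion) and that the karyotype-wide complement of the probe is
actually short (a probe sitting in a translocated run elsewhere has
moved, not vanished). Expected complement is one site per home group per
subgenome; the two genuinely double-homed probes carry one manifest
record per home.

## Comparative accounting

Species-specificity is decided on **complexes**: all inversions on one
chromosome in one material form one inversion series (a multiply
inverted chromosome is one rearrangement), RT partner rows merge, Du/De
stand alone. A signature is species-specific for X iff identical in all
materials of X and not identical-and-uniform in the other species; the
diploid outgroup is excluded from the comparison, so a rearrangement
inherited from the H-genome progenitor still counts for the species
fixed for it. Polymorphic-type accounting deliberately uses **raw event
types** (chromosome + label, reciprocal rows deduplicated) instead,
because co-located polymorphic events on one chromosome are distinct
types even though they share a series.

Breakpoint reuse: a locus is the open interval between two
reference-adjacent probes (boundaries 0 and n are telomere gaps); a
locus's count is the number of *distinct* complexes, across all
materials and species, with an interval endpoint there — identical
complexes shared by several materials are one origin, not several.
Counts of two or more flag reuse. The endpoint-incidence total equals
the sum over complexes of their endpoint counts (a conservation check in
the tests).

## Pattern-variant counting

A chromosome variant is a distinct (letter, prime) code within a
chromosome column of the repeat-FISH pattern matrix; a primed letter is
a different variant from its unprimed base, since the prime marks a
co-occurring polymorphic rearrangement on an otherwise similar repeat
pattern. Totals are per subgenome and overall; primed counts use primed
cells only. Counts are set cardinalities, hence invariant to material
order — both properties are tested, the latter against a brute-force
enumeration oracle.

## Probe selection

Candidates are filtered to single-copy in every subgenome, collinear
across reference genomes, and longer than 2 kb (exclusive — enough
hybridisation target for a detectable single-gene signal), then thinned
per homoeologous group by a greedy pick: the first eligible gene, then
repeatedly the eligible gene nearest to the last pick plus 100 Mb (ties
toward the smaller position) until the chromosome runs out. The greedy
nearest-to-target rule is the simplest deterministic reading of "evenly
spaced at ~100 Mb"; spacing is enforced per chromosome, not genome-wide,
since probe panels are assembled chromosome by chromosome.

## Simulator

`simulate_karyotype` starts from identity maps over the reference and
applies inversions (carrying the token for pericentric ones), terminal
reciprocal/one-way translocations, duplications and deletions, then
re-spaces positions uniformly preserving order, the centromere midway
between its flanking markers. Everything derives from one integer seed.

Sampled inversions default to *breakpoint-disjoint*: intervals of ≥ 2
markers, pairwise separated by at least one untouched marker. Each such
reversal then creates exactly two fresh breakpoints, so k inversions
leave 2k breakpoints and the minimal scenario length is exactly k
(lower bound ⌈2k/2⌉ = k; construction gives ≤ k) — this is what makes
100 % recovery a provable expectation rather than an empirical hope.
With the constraint off, overlapping reversals may compose into fewer
steps, and recovery tests assert only d ≤ k plus map reproduction.

`simulate_pattern_matrix` plans variant cells first (a fresh letter per
column per variant cell, primes on a chosen subset) and reports expected
counts from the plan, not by re-scanning the grid, so it can serve as an
independent oracle for the counting code.

The simulator emulates marker *order* data only. It does not model
hybridisation intensity, signal overlap between close probes, repeat-
family evolution, partial homoeologue loss in natural accessions, or
measurement noise in positions; passing recovery tests shows the
inference is exact on clean ordered maps, not that real images would be
scored without error.

## Packaged fixtures and their status

The event presence grid and the repeat-FISH letter grid are transcribed
from the printed comparative tables (material rows only — the printed
summary rows are recomputed, never copied; the transcription was checked
against those summary rows before freezing). The probe manifest and
per-group reference orders are prose-derived reconstructions: probe
names given in the text sit on their stated groups and arms, and the
remainder of the counted 59-probe set (22 previously reported, 37 new,
plus 4 discarded candidates) carries synthetic ids. Probes 4H138 and
4H289 are reference-adjacent so the recurrent group-4 short-arm
breakpoint between them is expressible as a single locus. Demonstration
karyotypes apply the narrated rearrangements of two materials to this
reference via the simulator; they support end-to-end demonstrations and
smoke tests, not quantitative claims.

## Numerical and determinism notes

All computations are exact integer/rank arithmetic; the only floating
point is map positions, written with full round-trip precision. Every
source of randomness is a `numpy` `default_rng` seeded explicitly; CLI
commands are pure functions of their inputs and `--seed`, and identical
invocations produce byte-identical outputs. Test problem sizes — random
permutations of n ≤ 8 at search depth 4, 200 simulator replicates with
1–3 inversions — keep the exhaustive searches at interactive scale while
covering every depth the default cap admits.

## Known limitations

* Unsigned model: marker orientation is unobservable by single-gene
  FISH, so signed (Hannenhalli–Pevzner) machinery is out of scope; the
  reported d is the unsigned minimum.
* Transpositions are not modelled as elementary events.
* Same-group inter-subgenome exchanges (e.g. between 2H and 2St) are
  invisible to the foreign-run detector, since homoeologues share probe
  sets; detecting them needs genomic in situ signal, which enters this
  pipeline only as the subgenome labels of chromosome ids.
* Reference intervals of later steps in multi-step scenarios are spans
  in partially rearranged coordinates; breakpoint-reuse tallies are
  exact for single-inversion complexes and first steps.
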
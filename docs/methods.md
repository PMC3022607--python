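# Methods

## The observable and the model behind it

Metazoan rDNA is a tandem family of hundreds of near-identical repeats.
Turnover machinery (gene conversion, unequal crossover) homogenizes
copies within a genome and fixes variants within an interbreeding
population; when the array sits in a low-recombination region (near a
centromere, as in anopheline mosquitoes), turnover is predominantly
intrachromosomal and homogenization is incomplete: a genome carries a
majority spacer plus a few SNP/indel copy variants, and — because the
array moves through the population as a single linked unit — those
variants are the *same in every individual of the species*. That is the
signal this package measures, three ways: crude sequence variation
(restriction profiles), copy-variant organization (heteroduplex
signatures), and full sequences.

## Analysis components

**Restriction genotyping.** Cut sites are exact motif matches on the
canonical strand (complete for palindromic motifs; N never matches, a
deliberately conservative call). Complete digestion is assumed — the
assay scores clean profiles. The gel model has two parameters: a
detection floor (`min_detectable`, default 50 bp, the smallest band
scored on a 3% agarose gel) and a co-migration tolerance
(`comigration_tolerance`, default 5% of the larger fragment, the
resolution limit of such gels; analyses that need to separate profiles
whose bands differ by ~4% use 3%, which such gels resolve for bands
under ~350 bp). Band patterns cluster by greedy descending-size
one-to-one matching within tolerance — the algorithmic analogue of
eye-matching lanes against a ladder — with class labels A, B, C, … by
first appearance; the partition is order-stable.

**Copy variants and duplex signatures.** Cloned (or simulated) spacer
copies of one individual group into variant classes by exact identity;
an optional error-correction pass (off by default) folds singleton
classes one substitution away from a larger class into it, a Taq-error
model. Class differences are described by a global affine-gap aligner
(Gotoh three-state DP, vectorized; a gap of length L scores
`open + (L-1)·extend`; ties break deterministically: aligned column over
gap, gap in the first sequence over gap in the second). The duplex
signature of k classes is k homoduplexes plus C(k,2) heteroduplexes,
each typed by substitution count and indel bp — indel heteroduplexes
are the overtly slow bands on native gels. Signature equality is
multiset equality ignoring clone counts, since gels are scored by band
presence, not intensity; electrophoretic mobility itself is not modeled
(classes are ordered only qualitatively: homoduplex < SNP het < indel
het). The fixation test asks whether all conspecific individuals share
one signature and returns the first discordant pair as a witness.

When the pipeline runs on simulated data it scores signatures and
restriction profiles on each individual's full amplified pool, which is
what a native gel of a bulk PCR sees; when it runs on files it uses the
clones, and rare variants can then escape detection (four or five clones
can miss a 1-in-20 copy class). This distinction is why clone-based and
gel-based genotyping can disagree in practice.

**Alignment statistics.** Column classification excludes gaps and N
from state counts (constant: ≤1 state left, all-gap columns count as
constant; parsimony-informative: ≥2 states each in ≥2 sequences;
otherwise variable-uninformative); the three counts always partition
the alignment length. Haplotype identity, by contrast, is strict
character identity with gaps significant, so indel variants still
separate spacer haplotypes. Because "sites with gaps or missing data"
is ambiguous, both the column count (≥1 gap, and ≥1 gap-or-N) and the
cell count are reported. COI translation uses NCBI table 5
(invertebrate mitochondrial); the reading frame is supplied, not
inferred, and diagnostic hits report both the 1-based alignment column
and the residue number within the frame, since published positions may
use either indexing. A diagnostic site is one where a group is fixed
for a state while all remaining sequences are fixed for another; with
exactly two groups the mirror-image report is collapsed to the smaller
(derived) group.

**Distances and trees.** Mutational steps are raw differences over
columns where both sequences have real bases. The proportional distance
divides steps by the alignment length (for a 524-column barcode, 9 and
10 steps are 1.7% and 1.9%); per-pair compared-site counts are kept so
percentages over comparable sites are also available (17 steps is 3.2%
of 524 but slightly more over compared sites — step counts, not
percentages, are the primary quantity). The barcode gap holds for a
group when its nearest interspecific distance exceeds the intraspecific
spread of both groups in that nearest comparison; failures are reported
with witnesses. Neighbor joining runs on the proportional distances
with ties in the Q criterion broken by the smallest label pair and
negative branch estimates clamped to zero (logged); bootstrap resamples
columns with replacement and scores each internal bipartition of the
full-data tree by its replicate frequency. NJ+bootstrap is a
deliberate desk-scale stand-in for likelihood/Bayesian inference: the
conclusions consumed downstream (clade recovery, monophyly, support)
are topological, and on additive matrices NJ is exact (property-tested;
cross-checked against an independent implementation). Monophyly is
evaluated on the unrooted tree as existence of a bipartition isolating
the group, with the smallest covering clade size reported.

**Sympatry and isolation.** Genotypes are sympatric when they share a
collection site. Isolation evidence for a genotype requires sympatry,
no spacer sequence class shared with any partner, and no individual
whose band pattern equals the superposition of two genotypes' profiles
(the hybrid test, run within co-migration tolerance). A superposition
indistinguishable from a single parental profile is not called a
hybrid — absence of evidence, not evidence. In the bundled survey
tables, unsubscripted "C" entries in the sympatry listing are read as
C2, the widespread subtype; the abundance table places genotype H at
two sites that the sympatry listing shows as single-genotype, an
internal inconsistency of the source tables that the package reports
as given rather than reconciles.

**CBC screening.** RNA folding is not performed — structures (from any
folding engine, in dot-bracket) are inputs, and the named template row
maps pairs through its gap pattern into alignment columns. Canonical
pairs are AU/UA/GC/CG plus the GU/UG wobble (T read as U). A pair is a
CBC when both partners differ and both sequences still pair
canonically, a hemi-CBC when exactly one partner differs, disrupted
when either sequence fails to pair, and indel-overlap when a gap covers
either column; the five categories partition the pair set and the
symmetric totals are invariant to sequence order. Pseudoknots are out
of scope (nested structures only).

## The simulator

One species tree (supplied newick, or Yule with `birth_rate`); one
array of `array_copies` spacers per species evolving along each branch
under a Gillespie scheme with three competing event types:

- **Substitution**, `sub_rate_rdna` per site per unit branch length,
  HKY-style: replacement drawn with probability ∝ stationary frequency
  (set by `gc_target`, default 0.62) with transitions up-weighted by
  `kappa` (default 2), and per-base leaving rates equalized by rejection
  thinning so the chain is exactly stationary — without this, long
  simulations drift toward 50% GC and violate the compositional
  stability real spacers show.
- **Gene conversion**, `conversion_rate` events per array: a random
  donor copy overwrites a random recipient (whole-spacer by default, or
  a geometric tract). Conversion is strictly intrachromosomal, matching
  the reduced-recombination setting of a centromere-proximal array.
- **Tandem indel**, `indel_rate` per copy: duplication or deletion of a
  1–10 bp adjacent motif.

Individuals inherit the species array (optionally perturbed at
`within_species_noise` per site); clones are copies drawn uniformly
with replacement plus optional `pcr_error`; amplicons are the spacer
(620 bp default) flanked by 30 bp conserved primer pads (~680 bp
total). A single-copy COI locus (524 bp) evolves on the same tree at
`sub_rate_coi` (default 5× the spacer rate; an optional codon-aware
mode rejects in-frame stops so diagnostic-substitution tests are
meaningful). Species are scattered over `n_sites` collection sites with
an expected fraction `sympatry_overlap` of two-species sites. All
randomness flows from one seed; identical configurations give
byte-identical output. Known-answer features can be planted: extra
restriction sites, a compensatory base change on a declared pair, a
species-wide indel copy variant, or a private (single-individual)
variant that breaks fixation.

**Default regime.** No quantitative conversion or mutation rates exist
for these arrays, so the defaults are chosen once to land in the
qualitative regime the system exhibits and are documented free
parameters: `sub_rate_rdna` 0.04/site and `conversion_rate` 10 000/array
give, on trees of depth ~2, a handful of fixed variant classes per
20-copy array (conversion outpacing array-wide mutation influx ~20:1),
~5–25% interspecific spacer divergence (enough for restriction-motif
turnover), and `indel_rate` 0.05/copy leaves indel variants in some but
not all species. Sanity properties — no-mutation limit, homogenization
limit at high conversion:mutation ratios, fixation under zero noise,
GC tracking, faster COI clock — are tested.

**What the simulator does not emulate.** Copy-number change (unequal
crossover), interchromosomal exchange, selection, population-level
coalescence within species (species arrays are points, individuals
noise around them), alignment construction for indel-bearing spacers
(column statistics are computed only for equal-length sets; pairwise
alignment handles the rest), chimeric PCR artifacts, and quantitative
gel mobility. Passing end-to-end tests therefore demonstrates that the
analysis recovers species structure from data exhibiting incomplete
concerted evolution with fixation — not that it is robust to every
artifact of real gels and real PCR.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere internally; 1-based only
  in reports. Residues canonicalize at the boundary (uppercase, U→T,
  anything else → N with a warning).
- Phylip I/O is the relaxed sequential dialect (whitespace-delimited
  names, one line per sequence), matching modern deposited alignments;
  interleaved files are out of scope.
- Alignment scoring defaults to match 1, mismatch −1, open −4,
  extend −1: gaps cost enough that the 1–10 bp tandem indels of spacer
  arrays align as single events rather than scattered gaps.
- The deterministic tie-breaks (alignment traceback preference, NJ
  smallest-label-pair, lexicographic class ordering, first-appearance
  labels) exist so that identical inputs give identical reports.
- Simulated end-to-end runs use a supplied species tree of depth ~2
  with all splits ≥0.5 units apart: the study system's genotypes are
  deeply separated, and a pure-birth tree can by chance place two
  species so close that they are genuinely indistinguishable at the
  rDNA locus (which the typing method correctly reports as one
  genotype). Problem sizes in tests and the acceptance script — five
  species × three individuals × five clones, 100-replicate bootstraps —
  keep full runs in seconds while leaving every stage's behavior
  observable.

## Known limitations

Variant classes are exact-identity groups: sequencing error inflates
class counts unless the optional correction pass is enabled. The hybrid
test detects only band-level superpositions, not sequence-level
recombination. Bootstrap supports on trees with many identical
sequences are arbitrary among equivalent resolutions (though
deterministic for a seed). The barcode-gap verdict uses the
nearest-neighbour comparison only; it does not model sampling error in
either distribution.
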
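# Methods

This note records the models behind each analysis, the tunable parameters
with their defaults and rationale, what the synthetic-data generators do
and do not emulate, and the numerical choices made where the design was
genuinely open.

## Coordinates and formats

All intervals are 0-based half-open inside the package. GFF3 (1-based
closed) and VCF POS (1-based) are converted exactly at the reading
boundary and back on writing; the conversion is a bijection on integers,
so round trips are lossless. Readers validate strictly (duplicate FASTA
ids, non-IUPAC characters, CDS outside the parent gene, non-binary PAV
cells, unknown SV type codes are all hard errors) because silent coercion
of malformed genomics files is a classic source of off-by-one drift.
Insertions are stored as zero-length anchor points whose `length` field
carries the inserted-sequence length, matching VCF symbolic-allele
semantics. The per-accession SV exchange TSV (columns `accession,
chromosome, start, end, type, length, inserted_seq`) is this project's
own dialect, documented here because no community standard exists for
tabular SV interchange.

## Pangenome composition

Family classes are defined on presence counts over N accessions: core =
present in all; softcore = absent in exactly 1 or 2; private = present in
exactly 1; dispensable = the rest. Precedence is core > softcore >
private > dispensable: a family seen once is simultaneously "missing in
more than two" and "exclusive to one", and resolving the clash in favour
of exclusivity is what makes a private class exist at all. At the species
level presence means "present in at least one member of the species" and
the partition is three-way (core/dispensable/private): "absent in one or
two accessions" has no species analogue, so softcore is not emitted.

Saturation curves draw, per replicate, one uniform random permutation of
the accessions (sampling without replacement, not bootstrap) and track
the union (pan) and intersection (core) of family sets over growing
prefixes; 100 replicates is the default. Closure is judged by fitting
Δ(n) = κ·n^(−α) to the increments of the mean pan curve by least squares
on log–log values over n = 2..N, dropping zero increments; α > 1 means
the discovery curve converges (closed pangenome). The power-law-decay
form and the α > 1 threshold are the standard Heaps'-law openness
criterion; when every increment is zero the fit degenerates and the
verdict is trivially closed (α = +∞ sentinel).

Nucleotide diversity is π = [2/(n(n−1))] · Σ_{i<j} d_ij / L_ij on an
equal-length alignment, where positions carrying a gap or N in either
sequence of a pair are excluded from both the mismatch count and that
pair's effective length; a pair with no comparable site makes π undefined
and raises. PAV distance is Jaccard distance on presence sets — chosen
because it ignores joint absences, which dominate any pangenome matrix
and carry no phylogenetic signal.

## Neighbor joining

Classical Saitou–Nei agglomeration on the Q-criterion
Q(i,j) = (m−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), with ties broken by
lexicographic order of node labels (internal nodes inherit the smallest
leaf label beneath them), so identical inputs give identical Newick
output. Negative branch-length estimates — legitimate under NJ on
non-additive inputs — are clamped to zero and counted on the returned
root. Monomer trees use the normalized edit distance
Levenshtein(a,b)/max(|a|,|b|); this pairwise-distance route is a
deliberate simplification of alignment-plus-maximum-likelihood monomer
phylogenetics, adequate at desk scale for the property that matters here
(separation of monomer families into distinct clades).

## Tandem arrays, centromeres, telomeres

Tandem repeats are detected in three stages.

1. **Period voting.** Every k-mer (k = min(8, max(3, min_period))) that
   recurs at distance d ∈ [min_period, max_period] votes for period d in
   its 256-bp bucket; (bucket, d) pairs with ≥ 3 votes nominate d. For a
   true array nearly every position votes for the true period, while a
   random 8-mer coincidence contributes ~0.004 votes per bucket, so the
   threshold separates cleanly.
2. **Verification and extension.** A nominated period p is verified by
   shifted-self identity: the fraction of positions i with s[i] = s[i+p]
   inside a one-monomer window must reach `min_identity` (default 0.8).
   Maximal runs of verified windows, bridging single divergent monomers
   (gaps < p), become array spans; spans shorter than
   `min_copies × period` are dropped.
3. **Period collapse and boundary refinement.** The smallest divisor of p
   that still verifies is reported (so (ACGT)×3 is period 4, not 8), and
   the span is then re-derived from the collapsed period's own identity
   profile — runs found at period multiples have window-width edge slop,
   and the smallest shift localizes boundaries to monomer resolution.
   Overlapping arrays are resolved by keeping the higher covered-bp ×
   identity score.

Because the chromosome generator mutates monomer copies by substitution
only, the true period is preserved exactly, and at zero divergence the
detected period equals the monomer length exactly; at 5% divergence the
expected copy-to-copy identity is ≈ 0.90, comfortably above the 0.8
threshold.

Monomer clustering is greedy incremental: array consensus monomers are
processed by decreasing length and join the first cluster whose
representative identity (best of forward and reverse complement) reaches
the threshold (default 0.8), else found a new cluster. Cluster abundance
is the summed copy number of member arrays — copy count, not member
count, since a centromere's signal is how much sequence its monomer
occupies.

Centromere calling scores sliding windows (default 100 kb, step 50 kb):
score = 1.0·(bp covered by monomers of the top-8 clusters)/window +
0.3·(Gypsy bp fraction) − 0.3·(gene count / max gene count). The
weights encode the biology — monomer arrays are the primary signal,
Gypsy-LTR enrichment corroborates, gene density contradicts — and are
exposed as parameters since the integration rule is a design choice. A
candidate is a maximal run of consecutive windows with monomer coverage
≥ 0.3; the run with the highest mean score wins (ties leftmost;
monocentric assumption, at most one call per chromosome). The reported
span is the window union clipped to the extent of the contributing
arrays: windows quantize to 50-kb boundaries, and clipping restores
monomer-resolution edges, which is what makes span recovery at
Jaccard ≥ 0.8 achievable for sub-window-scale centromeres.

Telomeres are counted as copies of CCCTAAA in the 5′ terminal window and
of its reverse complement TTTAGGG in the 3′ window (default window 10 kb);
an end is telomere-complete at ≥ 10 copies. A complete 11-chromosome
genome therefore reports 22 telomeres.

## SV landscape

Same-type records merge when: DEL/DUP/INV reciprocally overlap ≥ 0.5;
INS anchors lie within 100 bp and min/max length ≥ 0.5; TRA breakpoints
both lie within 100 bp. These are community-standard SURVIVOR/truvari-like
defaults, fully parameterized. Merging takes connected components of the
pairwise criterion (computed with a sorted sweep, verified in tests
against an all-pairs graph oracle); the representative is the member with
median length, and presence vectors union member accessions. Merging is
idempotent and input-order invariant.

Annotation precedence is cds > genic_noncds > flank2kb > intergenic by
any-overlap of the span (insertions: anchor point) with CDS parts, gene
spans and gene spans ± 2 kb. Coding effect is sequence-free: a
CDS-overlapping DEL/INS/DUP is frameshift iff length mod 3 ≠ 0, else
in-frame; CDS-overlapping INV/TRA are structural. Repeat enrichment
builds the 2×2 table [[SV midpoints in repeat, in nonrepeat],
[repeat bp, nonrepeat bp]] — midpoint membership avoids double-counting
an SV across regions — and applies the two-sided Fisher exact test (sum
of tables no more likely than the observed one); per-500-kb-bin densities
(midpoints per Mb of class sequence) are reported alongside. Inversion
hotspots are 1-Mb windows sliding by 100 kb holding ≥ 3 inversion
midpoints, merged when overlapping. "Core SVs" of a group are
nonredundant SVs present in every group member; ancestry partitioning
tests each against two ancestor call sets using the same pairwise merge
criterion, yielding onlyA / onlyB / both / neither counts. The Bonferroni
threshold is α/m.

Type percentages are rounded half-up to two decimals. Note that half-up
rounding of a five-way composition can disagree with an independently
rounded published figure in the last digit for the minor categories;
the summary reports the arithmetic result.

## Synthetic data: what it emulates, and what it does not

`simulate_pav` realises each family's class exactly: all-ones rows
(core), rows missing 1–2 uniformly chosen accessions (softcore),
single-carrier rows (private), and dispensable rows carried by k
accessions with k geometric (p = 0.3) truncated to 2 ≤ k ≤ N−3 — a
descending occupancy spectrum that, together with the core block, gives
the U-shaped spectrum typical of pangenomes while keeping classes
separable. The default panel is 28 accessions in seven species groups
(14/5/4/2/1/1/1) with class mix 43/9/46/2%, the study-system conditions.
Classification recovery on this generator is exact by construction; what
the recovery tests genuinely probe is the saturation/closure pipeline
downstream.

`simulate_chromosome` plants (CCCTAAA)n telomeres at both ends, fills
the centromere span with tandem copies of one random monomer (default
171 bp, a typical plant centromeric monomer length) independently
substituted at the divergence rate, places Gypsy-labelled repeat
annotations at 15% background density, raised by `gypsy_enrichment`
(default 3×) inside the centromere, and genes outside it at one per
15 kb. It does not emulate indel divergence within arrays, higher-order
repeat structure, nested TEs, or sequence (rather than annotation) for
the repeat elements — so passing recovery tests show boundary and period
accuracy under substitution divergence, not robustness to array indels.

`simulate_sv_landscape` draws each ground-truth SV a type (default mix
46.99/51.88/0.67/0.28/0.18%), a per-type log-normal length floored at
21 bp, a midpoint whose odds of falling in a repeat interval are
multiplied by the enrichment factor (placement is otherwise iid — an
earlier minimum-spacing rule was removed because the induced repulsion
underdisperses bin counts and biases the null calibration of the
enrichment test), and an inheritance origin with default proportions
33:68:200:61 (ancestor A : ancestor B : both : neither). Target-group
accessions carry every SV; ancestors carry those matching their origin.
Per-accession records are jittered within the merge tolerance
(±length/10 for interval SVs, ±25 bp for insertion anchors) so that
cross-accession merging is exercised non-trivially. Independent iid
placement means occasional same-type collisions merge two true SVs into
one record (≈ 2% at 2,000 SVs on 2 Mb); recovery tests use binomial
confidence intervals that absorb this.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale: 400-kb
chromosomes (20 of them for centromere recovery), a 20,000-family ×
28-accession PAV matrix, SV landscapes of 2,000–10,000 events on 2–20 Mb
genomes, 200 null simulations for the type-I-error check. All randomness
flows through `numpy.random.default_rng` seeded from one integer;
generators spawn independent substreams via `SeedSequence`, so outputs
are bit-identical across runs and platforms.

## Known limitations

- The tandem-repeat detector assumes substitution-dominated divergence;
  arrays with frequent indels shift register and may fragment.
- Centromere calling is monocentric by construction and will report only
  the best candidate on holocentric or dicentric input.
- Coding-effect classification is length-based; it does not inspect
  codons, splice sites or stop gains.
- The Fisher enrichment test treats base pairs as independent units of
  exposure; long-range autocorrelation of real repeat landscapes would
  make its p-values anti-conservative on real data.
- Heaps'-law closure is a two-parameter summary; saturation curves with
  strong private-family floors are fit only approximately (the verdict is
  robust, the α estimate less so).
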
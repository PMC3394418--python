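# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates. It is the package's own account; every number
mentioned is computed by the tests or by `scripts/acceptance.py`.

## Data model

A `MultipleAlignment` is a rectangle of columns over `{A,C,G,T,-,~}` plus
`N`. Reads are **gapless**: each occupies one contiguous column interval;
`-` inside a read is a deletion *allele* that can conflict with a base,
while `~` (outside the read's span) is absence of information and conflicts
with nothing. This distinction is load-bearing: the polynomial-time
coloring guarantee below holds only for gapless reads, which is why mates
of a pair are parsed as two independent reads and mate phasing is ignored.
`N` is carried as a fifth, non-informative character: it never counts
toward allele tallies, depth, or conflicts.

Coordinates are 0-based half-open everywhere; SAM's 1-based positions are
converted at the parser boundary. SAM insertions create shared padded
columns: the inserting read contributes its bases (left-aligned, `-`-padded
to the widest insertion at that point), reads crossing the point without an
insertion show `-`, reads not spanning it show `~` by virtue of span. The
TIGR `.contig` reader assumes the classic TIGR Assembler layout (`##`
contig header, gapped consensus, `#name(offset)` read headers with 0-based
padded offsets).

## SNP calling

Four callers with different error tolerance; haplotyping sees only the
columns they return.

* `simple` — every polymorphic column. Usable only on error-free data.
* `simple_strict` — minority allele present ≥ 2 times, or locus depth
  < 10 (low-coverage columns are kept so haplotyping, not the caller,
  resolves them). The depth clause is read as attaching to the locus.
* `454` — majority allele must not be `-`; minority support must either be
  repeated (clause read as "a minority non-`-` allele occurs ≥ 2 times";
  the literal "two distinct non-`-` alleles" reading is available as
  `literal_two_alleles=True`) or fall outside a homopolymer run of length
  ≥ 3 in the carrying read.
* `binomial` (default) — at each column of depth *d*, call iff the
  second-most-frequent allele count strictly exceeds
  `binom.ppf(1 - alpha/L, d, e/3)`, with `e = 0.005`, `alpha = 0.05`, *L*
  the alignment length. `e/3` reflects the uniform substitution model
  (|A| = 4, an error lands on one of the three other bases); the inverse
  CDF is the smallest integer q with CDF(q) ≥ 1 − α/L, and the comparison
  is strict. Thresholds are verified against exact-arithmetic CDF
  summation for all depths ≤ 100.

User-provided positions files are 0-based (`alignment<TAB>position`, or
bare positions).

## Haplotyping

Masking scans profiles by (first covered SNP, covered-SNP count
descending, id); each unmasked read subsumes every later unmasked read
whose covered SNPs are an agreeing subset, and masked reads cannot mask.
This is exactly what makes the compatibility graph of survivors
transitively orientable; `build_dag` verifies transitivity (matrix square)
and raises if masking ever failed.

"Starts before" for the DAG orientation is the same total order; ties in
first SNP are broken by longer-first, then id, keeping the relation
acyclic where the underlying papers leave equal starts unspecified.

Minimum coloring solves the assignment problem on an n×n integer matrix:
arc edges weigh `n+1`, self edges `1` (an exact integer rescaling of 1 and
1/(n+1) — lexicographic by construction, no floating-point ties).
`scipy.optimize.linear_sum_assignment` provides exact optimality; the
specific Hungarian implementation is immaterial. Every call asserts that
exactly *k* arc edges were selected, *k* being the Hopcroft–Karp maximum
matching size of the unweighted bipartite graph; chains = n − k, and the
number of single-read chains is maximal among all minimum chain covers
(checked against an exhaustive set-partition oracle on ≥ 500 random
instances with ≤ 9 irredundant reads).

Randomization enters solely through a permutation of the node order before
the matrix is built; the assignment solver is deterministic, so a seed
fixes the entire pipeline. Repetition keeps the meet of all colorings —
reads stay grouped iff co-colored in every repetition — whose class count
is non-decreasing by construction. Stopping: at least `min_reps` (default
20) repetitions, then stop once the class count is constant over the most
recent ⌈r/2⌉ repetitions; a hard cap (`max_reps`, default 1000) guards
against pathological non-termination.

Region consensus: SNP loci take the majority allele among member reads
(irredundant plus their masked reads — redundant reads do vote); ties are
broken by the whole-alignment column majority, then alphabetically
(A<C<G<T<-). Non-SNP covered loci take the whole-alignment majority,
because per-region coverage is usually too thin to filter errors there.
Region "length" statistics are covered-base counts, since a region can in
principle be non-contiguous; coverage is member-read depth averaged over
covered columns.

## Consensus reconstruction and evaluation

A *possible crossover* is an adjacent called-SNP pair that no single
region covers-and-agrees with at both columns of the chosen consensus.
The DP charges a transition exactly when the chosen allele pair has no
joint supporter — not merely when the providing region changes — so two
regions that overlap-agree across a junction can hand off for free. This
follows the definition of a crossover rather than its common
region-identity shorthand, which overcounts precisely in that hand-off
case; it also makes reconstruction and evaluation exactly consistent.
Criteria, in order: fewest possible crossovers; largest summed support of
the chosen alleles (support = member reads carrying the region's allele at
that locus); fewest distinct regions. The third criterion is resolved
exactly by a search over used-region sets on the criteria-1/2-optimal
transition graph when the instance is small (≤ 16 SNPs and ≤ 12 regions —
always the case for the oracle checks); larger instances use a
deterministic greedy backtrack (prefer staying, then lowest region index),
since with free hand-offs the exact search is exponential and the
tie-break is immaterial at that scale. Remaining ties resolve to the
lowest region index. The universal haplotype never enters the DP:
switching through reads consistent with every haplotype is not evidence of
chimerism.

Evaluation of an arbitrary consensus against a reference set (true
haplotypes, or assembled regions) uses the same accounting with the
consensus fixed: evaluation SNPs default to the loci polymorphic among the
references (ignoring `~`); the minimum crossover count is the number of
adjacent evaluation-SNP pairs no single reference covers-and-agrees at
both. A locus where no reference explains the consensus allele is reported
as an error locus and is naturally charged on both sides — two crossovers
at interior loci, one at the first or last evaluation SNP (the boundary
charge is the one transition the accounting naturally applies; a blanket
two-per-error rule would double-charge boundaries). A `~` in the consensus
agrees with nothing. Mismatches at non-SNP loci are ignored: they cannot
be phasing errors.

The DP is validated against exhaustive enumeration of every per-SNP region
assignment (≥ 200 random instances, ≤ 8 SNPs × ≤ 5 regions), including
the coverage and distinct-region tie-breaks.

## Simulator

The generator emulates population-sampled gene data. **Diversity is the
proportion of polymorphic (segregating) columns** — e.g. 7 SNPs in a
600 bp region = 1.16% — not mean pairwise distance; `round(diversity ×
length)` biallelic SNPs are placed at random columns at least 2 apart,
each with a random derived allele on a random nonempty proper subset of
haplotypes. The letter-swap expansion (s + s(T↔C) + s(A↔G) + s(A↔T))
quadruples length while preserving diversity exactly (each swap is an
alphabet bijection), allowing long reads to be tested on full-gene
alignments.

Sequencing drops read windows uniformly over all positions overlapping the
sequence, truncating at the ends, so expected coverage is uniform along
the alignment (accounting by emitted bases, per haplotype copy until
`coverage × length`); each base is substituted with one of the other three
uniformly with probability `error_rate`. Reads are placed at their true
offsets — "perfect assembly"; alignment error is out of scope, as are
indels, homopolymer noise, quality strings, and paired ends. Unequal
representation is a `multiplicities` tuple (e.g. `(3,1,1,1)` at 4X per
copy). Defaults are the low-diversity study conditions: 4 haplotypes,
600 bp, 1.16%, 6X each, 400 bp reads, expansion to 2400 bp.

A region is scored *correct* iff a single haplotype matches every
contiguous covered segment of its consensus at the right offsets (the
exact-substring criterion, extended segment-wise for the rare
non-contiguous region).

## What the simulations do and do not show

Passing tests demonstrate behavior under the simulator's assumptions:
substitution-only errors, uniform coverage, perfectly placed reads, and a
random biallelic SNP geometry. Real data add alignment error, indels,
coverage biases, and phylogenetically structured allele splits, none of
which are modeled. Problem sizes in the default suite (≈ 145–190 reads,
2400 columns, ≤ 5 seeds per condition) were chosen so each pipeline run
completes in about a second; the algorithms scale as O(r·n³) in the
largest block (r repetitions, n irredundant reads) and O(m·k²) for the
consensus DP.

Two observed properties of the error regime deserve note. At 5% per-base
error and 24X, roughly 2–3% of columns acquire three or more coincident
same-base errors; the binomial caller (assuming its default e = 0.005)
correctly flags them as variant, and the reads sharing such an error are
mutually compatible but conflict with every clean chain — the coloring is
therefore *forced* to assemble them into a coherent 2–3-read "error
haplotype" whose mean coverage can just exceed 2X. Consequently the
fraction of correct regions at the 2X coverage cutoff degrades with error
rate (measured ≈ 98% at 1% error but ≈ 53% at 5% error over 15 trials;
≈ 97% pooled at a 2.5X cutoff), while essentially all singleton and
two-read regions remain the intended error-isolation sink. Raising the
caller's assumed error rate does not help: it trades spurious SNPs for
missed true SNPs, whose loci then receive whole-alignment majority fill
and corrupt minority-haplotype regions. This trade-off is inherent to the
method, and the corresponding acceptance check at the strict
95%-at-2X/5%-error bound fails honestly.

## Known limitations

* Gapless reads only; CIGAR `N` (reference skip) is rejected.
* One reference sequence per SAM input (one multiple alignment per
  contig); multi-contig TIGR files are iterated.
* The universal haplotype covering a user-declared SNP that no block
  region covers is an error by design: the consensus DP requires every
  SNP to be region-covered, which the built-in callers guarantee.
* Criterion-3 tie-breaking is heuristic above 16 SNPs / 12 regions (see
  above); criteria 1 and 2 are always exact.
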
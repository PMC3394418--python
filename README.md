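# hapweave

Conservative haplotype-region assembly and minimum-chimerism consensus
reconstruction from multiple alignments of population-sampled sequencing
reads.

## The problem

When reads come from a pool of genetically distinct individuals — an
ecological sample, a population-level transcriptome — the usual
majority-vote consensus silently splices alleles from different
chromosomes into a chimeric sequence, and it says nothing about where those
splices happened. `hapweave` addresses the *population haplotype assembly
problem* for exactly this regime: low diversity (SNP densities around
1–4%), shallow coverage (say 6X per haplotype), an unknown number of
source haplotypes, and gapless reads. It assembles only haplotype fragments
the data actually support, then reconstructs a full consensus that
minimizes — and explicitly reports — its possible chimeric junctions.

## The method

Given a padded multiple alignment *M* and a set of called SNP columns:

1. **SNP calling.** Variant columns are selected by one of: `simple` (any
   polymorphic column), `simple_strict` (minority allele seen ≥ 2 times or
   locus depth < 10), a pyrosequencing-aware `454` rule, a Bonferroni-
   corrected binomial test (call iff the second-allele count exceeds
   *F*⁻¹(1 − α/L; d, e/3) at locus depth *d*, alignment length *L*), or a
   user-supplied list.
2. **Masking.** A read whose covered SNPs are a non-conflicting subset of
   another's is masked; this makes the compatibility relation of the
   surviving reads transitively orientable.
3. **Blocks.** Connected components of the conflict graph *G_M* (reads
   joined when they overlap a SNP with different alleles) are haplotype
   blocks; singleton components form the *universal* haplotype, consistent
   with every other.
4. **Minimum coloring by weighted matching.** Within a block the
   compatibility DAG is transitive, so by Dilworth's theorem its minimum
   chain decomposition equals the minimum proper coloring of the block's
   conflict graph. It is found via a maximum-weight matching of a
   "connects-to" bipartite graph with arc weight 1 and self-edge weight
   1/(n+1): the matching selects exactly *k* arc edges (*k* = unweighted
   maximum matching size, chains = n − k) while maximizing the number of
   single-read chains — isolating likely-erroneous reads.
5. **Randomized repetition.** The coloring is repeated (≥ 20 times, until
   the class count is stable over the latest half of the repetitions) with
   randomized node order; only reads co-colored in *every* repetition stay
   grouped. Each surviving group becomes a haplotype region: member alleles
   at SNP loci, whole-alignment majority elsewhere, `~` where uncovered.
6. **Consensus.** A dynamic program picks, per SNP, the region providing
   the allele, lexicographically minimizing (possible crossovers, −total
   supporting coverage, distinct regions), where a *possible crossover* is
   an adjacent SNP pair that no single region covers-and-agrees with at
   both. The same accounting evaluates any consensus against a reference
   set (true haplotypes or assembled regions); an allele no reference
   explains costs two crossovers at interior loci.

A seeded simulator generates the matching study conditions (diverse
population, letter-swap length expansion, uniform-coverage truncated reads,
uniform substitution errors) so the whole pipeline is testable offline.

## Worked example

```bash
python examples/03_reconstruct_consensus.py
```

prints (seed 16, 2% error, 4 haplotypes at 6X):

```
consensus over 30 SNPs: 3 possible crossovers, total allele coverage 248, 7 regions used
  possible crossover between SNP cols 561 and 995 (sim_seed16.region_2 -> sim_seed16.region_9)
  possible crossover between SNP cols 1161 and 1595 (sim_seed16.region_6 -> sim_seed16.region_15)
  possible crossover between SNP cols 1761 and 2164 (sim_seed16.region_12 -> sim_seed16.region_25)
reconstruction: 0 true crossovers (vs source haplotypes), 3 estimated (vs own regions, a conservative overestimate)
majority vote:  0 true crossovers
```

The three reported junctions are where no assembled region spans adjacent
SNPs — the only places the consensus *could* switch source haplotypes. The
evaluation against the (here known) truth shows none of them is a real
switch: the estimate deliberately bounds chimerism from above. The other
scripts in `examples/` walk through simulation, region assembly, and SNP
caller behavior.

The same pipeline runs from the shell, pipe-friendly:

```bash
hapweave simulate --seed 3 --error-rate 0.01 --outdir sim
hapweave run --input sim/reads.sam --truth sim/truth.fasta --seed 2 --outdir out
hapweave run --input - --format tigr --seed 2 < contigs.contig
```

`run` writes, per alignment: the SNP list, region FASTA + TSV, the
universal haplotype, the consensus FASTA, a crossover TSV and (given
`--truth`/`--evaluate`) a chimerism report.

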
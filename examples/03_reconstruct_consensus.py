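"""Reconstruct a minimum-chimerism consensus and audit its crossovers.

The consensus takes the whole-alignment majority at non-SNP loci; at SNP
loci a dynamic program picks the providing haplotype region so that the
number of adjacent SNP pairs unsupported by any single region (possible
chimeric junctions) is minimal, then coverage is maximized and the number
of distinct regions minimized. The same machinery scores any consensus
against a reference set, so the reconstruction is compared with the naive
majority vote.
"""

from hapweave import (
    SimulationConfig,
    evaluate_consensus,
    expand_population,
    generate_population,
    majority_vote_consensus,
    simulate_reads,
)
from hapweave.pipeline import run_alignment

cfg = SimulationConfig(seed=16, error_rate=0.02)
pop = expand_population(generate_population(cfg))
sim = simulate_reads(pop, cfg)
res = run_alignment(sim, seed=3)

cons = res.consensus
print(f"consensus over {len(cons.snp_cols)} SNPs: "
      f"{cons.score[0]} possible crossovers, "
      f"total allele coverage {cons.score[1]}, "
      f"{cons.score[2]} regions used")
for cj, ck, left, right in cons.crossover_pairs:
    print(f"  possible crossover between SNP cols {cj} and {ck} "
          f"({left} -> {right})")

true_rep = evaluate_consensus(cons.sequence, pop)
est_rep = evaluate_consensus(cons.sequence, res.haplotyping.regions)
mv_rep = evaluate_consensus(majority_vote_consensus(sim), pop)
print(f"reconstruction: {true_rep.min_crossovers} true crossovers "
      f"(vs source haplotypes), {est_rep.min_crossovers} estimated "
      f"(vs own regions, a conservative overestimate)")
print(f"majority vote:  {mv_rep.min_crossovers} true crossovers")
# The estimate is conservative: each reported junction is a *possible*
# crossover (no single assembled region spans it), so the estimate bounds
# the true chimerism from above. The reported column pairs are the places
# to avoid when, e.g., designing primers over the consensus.
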
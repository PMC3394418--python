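"""Conservative haplotype-region assembly from SNP profiles of gapless reads.

Pipeline (per alignment): project reads onto the called SNP columns; mask
redundant reads (so the compatibility relation becomes transitively
orientable); split the conflict graph into connected components ("haplotype
blocks" — phasing across blocks is impossible from the data); within each
block, build the transitive compatibility DAG and decompose it into the
minimum number of chains. By Dilworth's theorem that minimum equals the
minimum proper coloring of the block's conflict graph, and it is computed
via a maximum-weight matching of a "connects-to" bipartite representation:
arc edges carry weight ``n+1`` and self edges weight ``1`` (an integer
rescaling of ``1`` and ``1/(n+1)``), so the matching first maximizes the
number of arc edges (minimizing the chain count ``n - k``) and secondarily
maximizes the number of single-read chains — isolating reads that likely
carry sequencing errors. The coloring is repeated with randomized input
order, and only co-coloring relations common to *every* repetition are kept
(the meet of the partitions); the groups that survive become haplotype
regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.algorithms.bipartite import hopcroft_karp_matching
from scipy.optimize import linear_sum_assignment

from .alignment import ALLELES, GAP, AlignedRead, MultipleAlignment
from .snps import SnpSet

__all__ = [
    "SnpProfile",
    "MaskingMap",
    "ConflictGraph",
    "CompatibilityDag",
    "Coloring",
    "RepetitionResult",
    "HaplotypeRegion",
    "build_profiles",
    "conflicts",
    "mask_redundant",
    "build_conflict_graph",
    "haplotype_blocks",
    "build_dag",
    "min_color_once",
    "repeat_colorings",
    "assemble_region",
    "assemble_haplotypes",
    "majority_string",
]

_NOINFO = -1  # profile code for "no informative allele at this SNP column"


@dataclass(frozen=True)
class SnpProfile:
    """A read projected onto the ordered SNP columns.

    ``codes`` has one entry per SNP (in SnpSet order): the allele code
    (index into ``"ACGT-"``) where the read informatively covers the column,
    ``-1`` elsewhere (outside the span, or an ``N`` base).
    """

    id: str
    codes: np.ndarray
    first: int  # index (into the SnpSet) of the first informative column
    last: int   # index of the last informative column

    @property
    def n_covered(self) -> int:
        return int((self.codes != _NOINFO).sum())

    def allele(self, snp_index: int) -> str:
        c = int(self.codes[snp_index])
        return ALLELES[c] if c != _NOINFO else GAP

    def alleles(self) -> dict[int, str]:
        """Covered SNP index -> allele character."""
        return {
            int(i): ALLELES[int(self.codes[i])]
            for i in np.flatnonzero(self.codes != _NOINFO)
        }


def build_profiles(
    aln: MultipleAlignment, snps: SnpSet
) -> tuple[list[SnpProfile], list[str]]:
    """Project reads onto SNP columns.

    Returns ``(profiles, universal_pool)`` where the pool holds ids of reads
    covering no SNP column informatively — they are consistent with every
    haplotype and later join the universal haplotype.
    """
    cols = np.asarray(list(snps), dtype=np.int64)
    profiles: list[SnpProfile] = []
    pool: list[str] = []
    for r in aln.reads:
        codes = np.full(len(cols), _NOINFO, dtype=np.int8)
        if len(cols):
            inside = (cols >= r.start) & (cols < r.end)
            for i in np.flatnonzero(inside):
                ch = r.bases[int(cols[i]) - r.start]
                if ch != "N":
                    codes[i] = ALLELES.index(ch)
        covered = np.flatnonzero(codes != _NOINFO)
        if len(covered) == 0:
            pool.append(r.id)
        else:
            profiles.append(
                SnpProfile(r.id, codes, int(covered[0]), int(covered[-1]))
            )
    return profiles, pool


def conflicts(a: SnpProfile, b: SnpProfile) -> bool:
    """True iff the two reads share a SNP column with different alleles."""
    both = (a.codes != _NOINFO) & (b.codes != _NOINFO)
    return bool((a.codes[both] != b.codes[both]).any())


def _scan_order(p: SnpProfile) -> tuple[int, int, str]:
    # first covered SNP ascending, covered-SNP count descending, id ascending
    return (p.first, -p.n_covered, p.id)


@dataclass
class MaskingMap:
    """Which redundant reads each irredundant read subsumes."""

    masked_by: dict[str, list[str]] = field(default_factory=dict)

    def masked_of(self, read_id: str) -> list[str]:
        return self.masked_by.get(read_id, [])

    @property
    def n_masked(self) -> int:
        return sum(len(v) for v in self.masked_by.values())


def mask_redundant(
    profiles: list[SnpProfile],
) -> tuple[list[SnpProfile], MaskingMap]:
    """Mask reads whose covered SNPs are a non-conflicting subset of another
    read's.

    Reads are scanned by (first covered SNP, covered count descending, id);
    each unmasked read in turn subsumes every later unmasked read it makes
    redundant; a masked read is removed from consideration as a masker.
    Masking guarantees the compatibility graph of the survivors can be
    transitively oriented.
    """
    order = sorted(profiles, key=_scan_order)
    masked: set[str] = set()
    mmap = MaskingMap({})
    for i, p in enumerate(order):
        if p.id in masked:
            continue
        p_cov = p.codes != _NOINFO
        for q in order[i + 1 :]:
            if q.id in masked:
                continue
            q_cov = q.codes != _NOINFO
            # q redundant under p: everywhere q is informative, p agrees
            if bool(np.all(~q_cov | (p_cov & (p.codes == q.codes)))):
                masked.add(q.id)
                mmap.masked_by.setdefault(p.id, []).append(q.id)
    irredundant = [p for p in order if p.id not in masked]
    return irredundant, mmap


@dataclass
class ConflictGraph:
    """Conflict relation over irredundant reads (undirected)."""

    graph: nx.Graph
    profiles: dict[str, SnpProfile]

    @property
    def nodes(self):
        return self.graph.nodes


def build_conflict_graph(irredundant: list[SnpProfile]) -> ConflictGraph:
    g = nx.Graph()
    g.add_nodes_from(p.id for p in irredundant)
    n = len(irredundant)
    if n > 1:
        mat = np.stack([p.codes for p in irredundant])
        cov = mat != _NOINFO
        for i in range(n):
            clash = ((mat[i + 1 :] != mat[i]) & cov[i + 1 :] & cov[i]).any(axis=1)
            for j in np.flatnonzero(clash):
                g.add_edge(irredundant[i].id, irredundant[i + 1 + int(j)].id)
    return ConflictGraph(g, {p.id: p for p in irredundant})


def haplotype_blocks(
    cg: ConflictGraph, universal_pool: list[str]
) -> tuple[list[list[SnpProfile]], list[str]]:
    """Split into haplotype blocks (conflict components of size >= 2).

    Reads in singleton components are consistent with every haplotype and
    join the universal pool, as do reads covering no SNP column. Each
    block's covered SNP indices form one contiguous stretch (conflicts
    require overlap, so a component's span intervals chain together); this
    is verified.
    """
    blocks: list[list[SnpProfile]] = []
    universal = list(universal_pool)
    for comp in nx.connected_components(cg.graph):
        if len(comp) == 1:
            universal.extend(comp)
            continue
        members = sorted((cg.profiles[i] for i in comp), key=_scan_order)
        _check_contiguous(members)
        blocks.append(members)
    blocks.sort(key=lambda b: b[0].first)
    return blocks, universal


def _check_contiguous(members: list[SnpProfile]) -> None:
    ivs = sorted((p.first, p.last) for p in members)
    reach = ivs[0][1]
    for lo, hi in ivs[1:]:
        if lo > reach + 1:
            raise RuntimeError(
                "haplotype block covers non-contiguous SNP stretches — "
                "masking/conflict invariant violated"
            )
        reach = max(reach, hi)


@dataclass
class CompatibilityDag:
    """Transitive DAG of non-conflicting irredundant reads of one block.

    Nodes are in "starts before" order: (first covered SNP, covered count
    descending, id). ``adj[i, j]`` is True iff an arc runs from the i-th to
    the j-th node in that order.
    """

    nodes: list[SnpProfile]
    adj: np.ndarray
    _k_unweighted: int | None = None

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def max_matching_size(self) -> int:
        """Maximum-cardinality matching of the unweighted connects-to
        bipartite graph; the minimum chain count is ``n - k``."""
        if self._k_unweighted is None:
            g = nx.Graph()
            left = [("L", i) for i in range(self.n)]
            right = [("R", i) for i in range(self.n)]
            g.add_nodes_from(left, bipartite=0)
            g.add_nodes_from(right, bipartite=1)
            for i, j in zip(*np.nonzero(self.adj)):
                g.add_edge(("L", int(i)), ("R", int(j)))
            m = hopcroft_karp_matching(g, top_nodes=left)
            self._k_unweighted = sum(1 for k in m if k[0] == "L")
        return self._k_unweighted


def build_dag(block: list[SnpProfile]) -> CompatibilityDag:
    """Orient the block's compatibility relation by read start order.

    An arc x -> y is drawn iff x starts before y (total order: first SNP,
    then covered count descending, then id) and x does not conflict with y.
    The result must be transitive — guaranteed by redundant-read masking and
    verified here.
    """
    nodes = sorted(block, key=_scan_order)
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    if n > 1:
        mat = np.stack([p.codes for p in nodes])
        cov = mat != _NOINFO
        for i in range(n - 1):
            clash = ((mat[i + 1 :] != mat[i]) & cov[i + 1 :] & cov[i]).any(axis=1)
            adj[i, i + 1 :] = ~clash
    reach2 = (adj.astype(np.int64) @ adj.astype(np.int64)) > 0
    if bool((reach2 & ~adj).any()):
        raise RuntimeError(
            "compatibility DAG is not transitive — redundant-read masking "
            "failed to enforce transitive orientability"
        )
    return CompatibilityDag(nodes, adj)


@dataclass
class Coloring:
    """A chain decomposition: each class is a chain of the DAG, hence a
    conflict-free candidate haplotype."""

    chains: list[list[str]]

    @property
    def classes(self) -> list[frozenset[str]]:
        return [frozenset(c) for c in self.chains]

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.chains if len(c) == 1)

    def __len__(self) -> int:
        return len(self.chains)


def min_color_once(dag: CompatibilityDag, rng: np.random.Generator) -> Coloring:
    """One minimum chain decomposition via maximum-weight bipartite matching.

    Builds the connects-to bipartite graph (left copy x_l, right copy y_r,
    edge iff arc x -> y) with integer weight ``n+1`` on arc edges and ``1``
    on self edges (x_l, x_r), then solves the assignment problem exactly.
    The selected arc edges, contracted, are the chains; the chain count is
    ``n - k`` with ``k`` the unweighted maximum matching size, and among all
    minimum decompositions the number of single-node chains is maximized.
    Node order is permuted by ``rng`` so repeated calls sample different
    optima.
    """
    n = dag.n
    if n == 0:
        return Coloring([])
    perm = rng.permutation(n)
    # benefit[i, j]: left copy of node perm[i] vs right copy of node perm[j];
    # arcs weigh n+1, self edges 1 (integer rescale of 1 and 1/(n+1))
    benefit = dag.adj[np.ix_(perm, perm)].astype(np.int64) * (n + 1)
    np.fill_diagonal(benefit, np.maximum(np.diag(benefit), 1))
    rows, cols = linear_sum_assignment(benefit, maximize=True)

    successor: dict[int, int] = {}
    has_pred: set[int] = set()
    n_arc_edges = 0
    for i, j in zip(rows, cols):
        w = benefit[i, j]
        if w == n + 1:
            successor[int(perm[i])] = int(perm[j])
            has_pred.add(int(perm[j]))
            n_arc_edges += 1

    k = dag.max_matching_size
    if n_arc_edges != k:
        raise RuntimeError(
            f"weighted matching selected {n_arc_edges} arc edges but the "
            f"unweighted maximum matching has size {k} — optimality "
            f"invariant violated"
        )

    chains: list[list[str]] = []
    for v in range(n):
        if v in has_pred:
            continue
        chain = [v]
        while chain[-1] in successor:
            chain.append(successor[chain[-1]])
        chains.append([dag.nodes[u].id for u in chain])
    assert len(chains) == n - k
    return Coloring(chains)


@dataclass
class RepetitionResult:
    """Meet (common refinement) of repeated random minimum colorings."""

    classes: list[frozenset[str]]
    history: list[int]  # meet class count after each repetition

    @property
    def n_repetitions(self) -> int:
        return len(self.history)


def repeat_colorings(
    dag: CompatibilityDag,
    rng: np.random.Generator,
    min_reps: int = 20,
    max_reps: int = 1000,
) -> RepetitionResult:
    """Repeat randomized minimum coloring and keep only common groupings.

    Reads stay grouped iff they were co-colored in *every* repetition (the
    meet of the partitions), so surviving groups are robust across the
    sampled space of minimum colorings. Runs at least ``min_reps``
    repetitions and stops once the meet's class count has been stable over
    the most recent half of the repetitions (hard cap ``max_reps``).
    """
    if min_reps < 1:
        raise ValueError("min_reps must be >= 1")
    labels: dict[str, tuple] = {p.id: () for p in dag.nodes}
    history: list[int] = []
    for r in range(1, max_reps + 1):
        coloring = min_color_once(dag, rng)
        for ci, chain in enumerate(coloring.chains):
            for rid in chain:
                labels[rid] = labels[rid] + (ci,)
        # compact labels so tuples stay short
        canon: dict[tuple, int] = {}
        for rid, lab in labels.items():
            canon.setdefault(lab, len(canon))
        labels = {rid: (canon[lab],) for rid, lab in labels.items()}
        history.append(len(canon))
        if r >= min_reps:
            w = math.ceil(r / 2)
            if len(history) >= w and len(set(history[-w:])) == 1:
                break
    groups: dict[int, list[str]] = {}
    for rid, (lab,) in labels.items():
        groups.setdefault(lab, []).append(rid)
    classes = [frozenset(v) for _, v in sorted(groups.items())]
    return RepetitionResult(classes, history)


# ---------------------------------------------------------------------------
# Region assembly
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeRegion:
    """One assembled haplotype: member reads and their per-locus consensus.

    ``consensus`` is over ``{A,C,G,T,-,~}`` with ``'~'`` exactly at loci no
    member read covers; ``covered_bases`` counts non-``'~'`` loci (the
    "length" statistic for possibly non-contiguous regions) and
    ``mean_coverage`` is the member-read depth averaged over covered loci.
    """

    name: str
    core: list[str]           # irredundant reads of the color class
    members: list[str]        # core plus accompanying masked (redundant) reads
    consensus: str
    covered_bases: int
    mean_coverage: float
    member_reads: list[AlignedRead] = field(repr=False, default_factory=list)

    def covers(self, col: int) -> bool:
        return self.consensus[col] != GAP

    def allele(self, col: int) -> str:
        return self.consensus[col]

    def support(self, col: int, allele: str) -> int:
        """Member reads carrying ``allele`` at ``col`` (redundant included)."""
        return sum(
            1
            for r in self.member_reads
            if r.covers(col) and r.bases[col - r.start] == allele
        )


def majority_string(aln: MultipleAlignment) -> str:
    """Whole-alignment per-column modal allele (ties A < C < G < T < '-';
    zero-depth columns give 'N')."""
    if aln.length == 0:
        return ""
    counts = aln.counts[:, :5]
    # argmax takes the first maximum: ALLELES order is the tie-break order
    best = counts.argmax(axis=1)
    out = np.array(list(ALLELES))[best]
    out[counts.sum(axis=1) == 0] = "N"
    return "".join(out)


def assemble_region(
    class_ids: frozenset[str] | list[str],
    mmap: MaskingMap,
    aln: MultipleAlignment,
    snps: SnpSet,
    name: str = "region",
    _majority: str | None = None,
) -> HaplotypeRegion:
    """Build the consensus of one color class.

    Members are the class's irredundant reads plus the redundant reads they
    mask. At non-SNP covered loci the consensus is the majority vote of the
    whole alignment (haplotype-specific coverage is low, so the full
    alignment is the better error filter); at SNP loci it is the majority
    allele among member reads (ties broken by whole-alignment majority, then
    alphabetically); loci covered by no member read are ``'~'``.
    """
    core = sorted(class_ids)
    member_ids = list(core)
    for rid in core:
        member_ids.extend(mmap.masked_of(rid))
    by_id = {r.id: r for r in aln.reads}
    member_reads = [by_id[i] for i in member_ids]

    majority = _majority if _majority is not None else majority_string(aln)
    snp_cols = set(snps)
    cons = [GAP] * aln.length
    depth = np.zeros(aln.length, dtype=np.int64)
    for r in member_reads:
        depth[r.start : r.end] += 1
    covered_cols = np.flatnonzero(depth > 0)

    # allele counts among member reads at SNP columns
    for col in covered_cols:
        col = int(col)
        if col not in snp_cols:
            cons[col] = majority[col]
            continue
        tallies: dict[str, int] = {}
        for r in member_reads:
            if r.covers(col):
                ch = r.bases[col - r.start]
                if ch != "N":
                    tallies[ch] = tallies.get(ch, 0) + 1
        if not tallies:
            cons[col] = majority[col]
            continue
        top = max(tallies.values())
        tied = [a for a, c in tallies.items() if c == top]
        if len(tied) > 1:
            whole = aln.counts[col]
            tied.sort(key=lambda a: (-int(whole[ALLELES.index(a)]), ALLELES.index(a)))
        cons[col] = tied[0]

    covered_bases = int(len(covered_cols))
    mean_cov = float(depth[covered_cols].mean()) if covered_bases else 0.0
    return HaplotypeRegion(
        name=name,
        core=core,
        members=member_ids,
        consensus="".join(cons),
        covered_bases=covered_bases,
        mean_coverage=mean_cov,
        member_reads=member_reads,
    )


@dataclass
class HaplotypingResult:
    regions: list[HaplotypeRegion]
    universal: HaplotypeRegion
    masking: MaskingMap
    n_blocks: int
    n_irredundant: int
    repetitions: list[RepetitionResult]


def assemble_haplotypes(
    aln: MultipleAlignment,
    snps: SnpSet,
    rng: np.random.Generator,
    min_reps: int = 20,
    max_reps: int = 1000,
) -> HaplotypingResult:
    """Run the full haplotyping stage on one alignment.

    Returns the assembled regions (one per robust read group, across all
    blocks) and the universal haplotype built from reads consistent with
    every haplotype (SNP-free reads and singleton conflict components,
    together with the reads they mask).
    """
    profiles, pool = build_profiles(aln, snps)
    irredundant, mmap = mask_redundant(profiles)
    cg = build_conflict_graph(irredundant)
    blocks, universal_ids = haplotype_blocks(cg, pool)

    majority = majority_string(aln)
    regions: list[HaplotypeRegion] = []
    reps: list[RepetitionResult] = []
    idx = 0
    for block in blocks:
        dag = build_dag(block)
        rep = repeat_colorings(dag, rng, min_reps=min_reps, max_reps=max_reps)
        reps.append(rep)
        for cls in rep.classes:
            regions.append(
                assemble_region(
                    cls, mmap, aln, snps, name=f"{aln.name}.region_{idx}",
                    _majority=majority,
                )
            )
            idx += 1

    universal = assemble_region(
        universal_ids, mmap, aln, snps, name=f"{aln.name}.universal",
        _majority=majority,
    ) if universal_ids else HaplotypeRegion(
        f"{aln.name}.universal", [], [], GAP * aln.length, 0, 0.0, []
    )
    return HaplotypingResult(
        regions=regions,
        universal=universal,
        masking=mmap,
        n_blocks=len(blocks),
        n_irredundant=len(irredundant),
        repetitions=reps,
    )
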
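"""Within-well genotype trees, dynamics classification, and adaptive-evidence
classification.

Each well's sequenced isolates define a binary isolate-by-mutation matrix
relative to the well's ancestor.  When the matrix satisfies the four-gamete
condition for every mutation pair, the unique perfect phylogeny is returned
(every mutation arises exactly once); otherwise a greedy minimal-homoplasy
tree is built by the same column-ordering construction, allowing a mutation
to recur on multiple edges, and the number of extra origins is reported.

Tree shapes map onto four modes of within-well dynamics: a fixed population
(all isolates identical), a star of single tip mutations off one shared
background (classic clonal interference), an unbranched chain (sequential
mutations on the best background), and an extended branching tree
(competing multi-step lineages).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .data import Dataset, WellRecord

DYNAMICS_CLASSES = ("fixed_identical", "interference_star",
                    "sequential_chain", "branched_multistep")


@dataclass
class GenotypeTree:
    """Rooted genotype tree for one well.

    Node 0 is the root (the well's ancestral genotype, an empty de novo
    set).  Every other node gains exactly one mutation relative to its
    parent; ``multiplicity[i]`` counts sampled isolates with exactly that
    genotype (0 for inferred intermediate genotypes).
    """

    well_id: str
    nodes: list[frozenset[str]]
    parents: list[int]
    edge_labels: list[str | None]
    multiplicity: list[int]
    compatible: bool
    homoplasy_count: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def observed_nodes(self) -> list[int]:
        return [i for i, m in enumerate(self.multiplicity) if m > 0]

    def children(self, node: int) -> list[int]:
        return [i for i, p in enumerate(self.parents) if p == node]

    def nearest_observed_ancestor(self, node: int) -> int:
        """Closest ancestor that is either sampled or the root."""
        node = self.parents[node]
        while node != 0 and self.multiplicity[node] == 0:
            node = self.parents[node]
        return node

    def observed_parent_map(self) -> dict[frozenset[str], frozenset[str]]:
        """Observed genotype -> genotype of its nearest observed-or-root
        ancestor (the tree restricted to sampled genotypes)."""
        return {self.nodes[i]: self.nodes[self.nearest_observed_ancestor(i)]
                for i in self.observed_nodes if i != 0}

    def to_newick(self) -> str:
        def label(i: int) -> str:
            name = self.edge_labels[i] if i else "root"
            return f"{name}[&mult={self.multiplicity[i]}]"

        def rec(i: int) -> str:
            kids = self.children(i)
            inner = "(" + ",".join(rec(c) for c in kids) + ")" if kids else ""
            return inner + label(i)

        return rec(0) + ";"


def four_gamete_compatible(genotypes: list[frozenset[str]],
                           mutations: list[str]) -> bool:
    """Perfect-phylogeny test for genotypes rooted at the all-absent
    ancestor: no mutation pair may show all three of the patterns
    (1,0), (0,1), (1,1) across genotypes."""
    for a, b in combinations(mutations, 2):
        seen = set()
        for g in genotypes:
            seen.add((a in g, b in g))
        if {(True, False), (False, True), (True, True)} <= seen:
            return False
    return True


def build_tree(well: WellRecord) -> GenotypeTree:
    """Parsimony genotype tree for one well.

    Mutations are sorted by decreasing isolate count (ties broken by key)
    and each observed genotype is threaded into a prefix tree in that
    order.  For a matrix passing the four-gamete condition this yields the
    unique perfect phylogeny; otherwise mutations may label multiple edges
    and the homoplasy count reports the number of extra origins.
    Reversions are ordinary derived characters here (a back-mutation edge).
    """
    if not well.isolates:
        raise ValueError(f"well {well.well_id} has no isolates")
    genotype_mult: dict[frozenset[str], int] = {}
    carrier: dict[str, int] = {}
    for iso in well.isolates:
        genotype_mult[iso.mutations] = genotype_mult.get(iso.mutations, 0) + 1
        for k in iso.mutations:
            carrier[k] = carrier.get(k, 0) + 1
    order = sorted(carrier, key=lambda k: (-carrier[k], k))
    rank = {k: r for r, k in enumerate(order)}

    nodes: list[frozenset[str]] = [frozenset()]
    parents: list[int] = [-1]
    labels: list[str | None] = [None]
    mult: list[int] = [0]
    child_index: dict[tuple[int, str], int] = {}

    for genotype in sorted(genotype_mult, key=lambda g: sorted(rank[k] for k in g)):
        cur = 0
        for k in sorted(genotype, key=rank.get):
            nxt = child_index.get((cur, k))
            if nxt is None:
                nodes.append(nodes[cur] | {k})
                parents.append(cur)
                labels.append(k)
                mult.append(0)
                nxt = len(nodes) - 1
                child_index[(cur, k)] = nxt
            cur = nxt
        mult[cur] += genotype_mult[genotype]

    compatible = four_gamete_compatible(list(genotype_mult), order)
    homoplasy = (len(nodes) - 1) - len(order)
    return GenotypeTree(well.well_id, nodes, parents, labels, mult,
                        compatible, homoplasy)


def build_trees(dataset: Dataset) -> dict[str, GenotypeTree]:
    return {w.well_id: build_tree(w) for w in dataset.wells}


def classify_dynamics(tree: GenotypeTree) -> str:
    """Assign one of the four within-well dynamics classes.

    Checks run in order — fixed population, interference star, sequential
    chain — and anything else is a branching multi-step tree, so the
    classes partition all wells.
    """
    observed = [tree.nodes[i] for i in tree.observed_nodes]
    distinct = set(observed)
    if len(distinct) == 1:
        return "fixed_identical"
    base = frozenset.intersection(*distinct)
    if all(g == base or len(g - base) == 1 for g in distinct):
        return "interference_star"
    ordered = sorted(distinct, key=len)
    if all(a <= b for a, b in zip(ordered, ordered[1:])):
        return "sequential_chain"
    return "branched_multistep"


def dynamics_counts(trees: dict[str, GenotypeTree]) -> pd.Series:
    counts = pd.Series(0, index=list(DYNAMICS_CLASSES))
    for t in trees.values():
        counts[classify_dynamics(t)] += 1
    return counts


# ---------------------------------------------------------------------------
# Adaptive-evidence classification
# ---------------------------------------------------------------------------

@dataclass
class AdaptiveEvidence:
    """Per-mutation evidence of being adaptive.

    A mutation is called adaptive when it (1) arose independently in more
    than one well, or (2) in at least one well it rose to appreciable
    frequency *unaccompanied*: it is carried by at least
    ``min_isolates_for_rise`` isolates and labels a step where it is the
    sole new mutation relative to the nearest sampled ancestor genotype.
    """

    table: pd.DataFrame             # key, functional_class, well_count, flags
    min_isolates_for_rise: int

    @property
    def n_adaptive(self) -> int:
        return int(self.table["adaptive"].sum())

    @property
    def adaptive_events(self) -> int:
        return int(self.table.loc[self.table["adaptive"], "well_count"].sum())

    @property
    def total_events(self) -> int:
        return int(self.table["well_count"].sum())

    def venn_counts(self, weight_by_events: bool = False) -> pd.Series:
        """Counts of the evidence partitions (multi-well only, rise only,
        both, neither); event-weighted when requested."""
        t = self.table
        w = t["well_count"] if weight_by_events else 1
        both = (t["multi_well"] & t["frequency_rise"])
        mw = (t["multi_well"] & ~t["frequency_rise"])
        fr = (~t["multi_well"] & t["frequency_rise"])
        neither = ~(t["multi_well"] | t["frequency_rise"])
        agg = (lambda m: int((w * m).sum())) if weight_by_events \
            else (lambda m: int(m.sum()))
        return pd.Series({"multi_well_only": agg(mw), "rise_only": agg(fr),
                          "both": agg(both), "neither": agg(neither)})


def classify_adaptive(dataset: Dataset, trees: dict[str, GenotypeTree],
                      min_isolates_for_rise: int = 2) -> AdaptiveEvidence:
    from .data import count_mutations_and_events

    _, _, well_counts = count_mutations_and_events(dataset,
                                                   include_reversions=True)
    rise: dict[str, bool] = {k: False for k in well_counts}
    for tree in trees.values():
        carriers: dict[str, int] = {}
        for i in tree.observed_nodes:
            for k in tree.nodes[i]:
                carriers[k] = carriers.get(k, 0) + tree.multiplicity[i]
        lone_step = set()
        for i in tree.observed_nodes:
            if i == 0:
                continue
            anc = tree.nearest_observed_ancestor(i)
            gained = tree.nodes[i] - tree.nodes[anc]
            if len(gained) == 1:
                lone_step |= gained
        for k, n in carriers.items():
            if n >= min_isolates_for_rise and k in lone_step:
                rise[k] = True

    rows = []
    for k, wc in sorted(well_counts.items()):
        rec = dataset.mutation_catalog[k]
        multi = wc >= 2
        rows.append((k, rec.functional_class, wc, multi, rise[k],
                     multi or rise[k]))
    table = pd.DataFrame(rows, columns=["key", "functional_class",
                                        "well_count", "multi_well",
                                        "frequency_rise", "adaptive"])
    return AdaptiveEvidence(table.set_index("key"), min_isolates_for_rise)
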
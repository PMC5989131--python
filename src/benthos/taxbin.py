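"""MEGAN-style taxonomic binning of protein-search read hits.

Reads carrying lists of (taxon, bit score) candidate hits are assigned to
taxonomy nodes by a score-thresholded lowest-common-ancestor (LCA) rule,
after a sequence-complexity filter, followed by a min-support pass that
moves sparsely supported nodes upward.  Assignments are finally projected
onto a fixed rank (e.g. genus) to give a taxon-by-sample count matrix.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "NOHITS",
    "UNASSIGNED",
    "RANKS",
    "TaxonomyTree",
    "ReadHitSet",
    "BinningParams",
    "sequence_complexity",
    "lca_assign",
    "bin_reads",
    "apply_min_support",
    "profile_at_rank",
]

#: Sentinel bin for reads whose hits all fall below the score threshold.
NOHITS = -1
#: Sentinel bin for reads diverted by the complexity filter.
UNASSIGNED = -2

#: Rank ladder from root to leaves used throughout the package.
RANKS = ("root", "phylum", "class", "order", "family", "genus", "species")


class TaxonomyTree:
    """Rooted, rank-labeled taxonomy.

    Parameters
    ----------
    parents : mapping of node id -> parent id (root maps to itself).
    ranks : mapping of node id -> rank label.
    names : mapping of node id -> display name.
    """

    def __init__(self, parents: Mapping[int, int], ranks: Mapping[int, str],
                 names: Mapping[int, str] | None = None):
        self.parents = dict(parents)
        self.ranks = dict(ranks)
        self.names = dict(names) if names else {n: str(n) for n in self.parents}
        roots = [n for n, p in self.parents.items() if p == n]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._children: dict[int, list[int]] = {n: [] for n in self.parents}
        for n, p in self.parents.items():
            if n != p:
                if p not in self.parents:
                    raise ValueError(f"node {n} has unknown parent {p}")
                self._children[p].append(n)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for n in self.parents:
            seen = set()
            while n != self.parents[n]:
                if n in seen:
                    raise ValueError("taxonomy contains a cycle")
                seen.add(n)
                n = self.parents[n]

    def __contains__(self, node: int) -> bool:
        return node in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    def children(self, node: int) -> list[int]:
        return self._children[node]

    def rank_of(self, node: int) -> str:
        return self.ranks[node]

    def ancestors(self, node: int) -> list[int]:
        """Path from ``node`` (inclusive) up to the root (inclusive)."""
        if node not in self.parents:
            raise KeyError(f"unknown taxon {node}")
        path = [node]
        while node != self.parents[node]:
            node = self.parents[node]
            path.append(node)
        return path

    def lca(self, nodes: Sequence[int]) -> int:
        """Lowest common ancestor of a non-empty set of nodes."""
        if not nodes:
            raise ValueError("lca of empty node set")
        paths = [self.ancestors(n)[::-1] for n in nodes]  # root -> node
        depth = min(len(p) for p in paths)
        anc = self.root
        for i in range(depth):
            cand = paths[0][i]
            if all(p[i] == cand for p in paths):
                anc = cand
            else:
                break
        return anc

    def ancestor_at_rank(self, node: int, rank: str) -> int | None:
        """Ancestor of ``node`` annotated at ``rank``, or None if the node
        sits above that rank."""
        for a in self.ancestors(node):
            if self.ranks[a] == rank:
                return a
        return None

    def leaves(self) -> list[int]:
        return [n for n, c in self._children.items() if not c]

    # --- tabular round trip (node_id, parent_id, rank, name) -----------
    def to_table(self) -> pd.DataFrame:
        rows = [(n, self.parents[n], self.ranks[n], self.names[n])
                for n in sorted(self.parents)]
        return pd.DataFrame(rows, columns=["node_id", "parent_id", "rank", "name"])

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "TaxonomyTree":
        return cls(dict(zip(df["node_id"], df["parent_id"])),
                   dict(zip(df["node_id"], df["rank"])),
                   dict(zip(df["node_id"], df["name"])))


@dataclass
class ReadHitSet:
    """Candidate database hits for one read."""
    read_id: str
    hits: list[tuple[int, float]] = field(default_factory=list)
    complexity: float = 1.0


@dataclass
class BinningParams:
    """LCA binning thresholds (MEGAN-style defaults)."""
    min_score: float = 35.0
    top_percent: float = 10.0
    min_support: int = 25
    min_complexity: float = 0.44

    def __post_init__(self):
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")
        if not 0 <= self.top_percent <= 100:
            raise ValueError("top_percent must be in [0, 100]")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not 0 <= self.min_complexity <= 1:
            raise ValueError("min_complexity must be in [0, 1]")


_IUPAC = set("ACGTURYSWKMBDHVN")


def sequence_complexity(sequence: str) -> float:
    """Normalized mononucleotide Shannon entropy of a read, in [0, 1].

    Entropy of the A/C/G/T composition divided by log 4, so homopolymers
    score 0 and a perfectly balanced composition scores 1.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    if not set(seq) <= _IUPAC:
        raise ValueError("sequence contains non-IUPAC characters")
    counts = Counter(seq)
    n = len(seq)
    h = -sum((c / n) * math.log(c / n) for c in counts.values())
    return min(h / math.log(4), 1.0)


def lca_assign(read: ReadHitSet, params: BinningParams, tree: TaxonomyTree) -> int:
    """Assign one read by the score-thresholded LCA rule.

    Hits below ``min_score`` are discarded; among survivors only hits whose
    bit score is within ``top_percent`` percent of the best are retained;
    the read goes to the LCA of the retained taxa, or to :data:`NOHITS`
    when nothing survives.  Ties at the top-percent boundary are retained.
    """
    for taxon, _ in read.hits:
        if taxon not in tree:
            raise KeyError(f"hit taxon {taxon} absent from taxonomy (read {read.read_id})")
    scored = [(t, s) for t, s in read.hits if s >= params.min_score]
    if not scored:
        return NOHITS
    best = max(s for _, s in scored)
    floor = (1.0 - params.top_percent / 100.0) * best
    retained = sorted({t for t, s in scored if s >= floor})
    return tree.lca(retained)


def bin_reads(reads: Iterable[ReadHitSet], params: BinningParams,
              tree: TaxonomyTree, min_support_to_unassigned: bool = False,
              ) -> Counter:
    """Bin a stream of reads: complexity filter, LCA, then min-support.

    Returns a Counter mapping node id (or NOHITS/UNASSIGNED) to read count.
    """
    counts: Counter = Counter()
    for read in reads:
        if read.complexity < params.min_complexity:
            counts[UNASSIGNED] += 1
        else:
            counts[lca_assign(read, params, tree)] += 1
    return apply_min_support(counts, params.min_support, tree,
                             to_unassigned=min_support_to_unassigned)


def apply_min_support(assignments: Mapping[int, int], min_support: int,
                      tree: TaxonomyTree, to_unassigned: bool = False) -> Counter:
    """Move reads at nodes holding fewer than ``min_support`` reads upward.

    Nodes are processed leaves-first; a failing node's reads go to its
    parent (accumulating until some ancestor reaches the threshold or the
    root is hit).  With ``to_unassigned`` the failing reads go to the
    UNASSIGNED bin instead.  Total read count is conserved either way.
    """
    counts = Counter({n: int(c) for n, c in assignments.items() if c})
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative read counts")
    # deepest-first sweep over the whole tree so reassigned reads cascade
    depth = {n: len(tree.ancestors(n)) for n in tree.parents}
    for node in sorted(tree.parents, key=lambda n: depth[n], reverse=True):
        c = counts.get(node, 0)
        if 0 < c < min_support and node != tree.root:
            del counts[node]
            if to_unassigned:
                counts[UNASSIGNED] += c
            else:
                counts[tree.parents[node]] += c
    return counts


def profile_at_rank(assignments_per_sample: Mapping[str, Mapping[int, int]],
                    rank: str, tree: TaxonomyTree,
                    audit: bool = False) -> pd.DataFrame:
    """Project per-sample node assignments onto a taxonomy rank.

    Each read assigned at or below ``rank`` is counted toward its ancestor
    at that rank; rows are the taxa observed at ``rank`` (labeled by name),
    columns are samples.  With ``audit`` three extra rows report reads
    assigned above the rank, NoHits reads and Unassigned reads.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    cols = {}
    for sample, counts in assignments_per_sample.items():
        at_rank: Counter = Counter()
        above = nohits = unassigned = 0
        for node, c in counts.items():
            if node == NOHITS:
                nohits += c
            elif node == UNASSIGNED:
                unassigned += c
            else:
                anc = tree.ancestor_at_rank(node, rank)
                if anc is None:
                    above += c
                else:
                    at_rank[anc] += c
        cols[sample] = (at_rank, above, nohits, unassigned)
    taxa = sorted({t for c, *_ in cols.values() for t in c})
    data = {s: [c[0].get(t, 0) for t in taxa] for s, c in cols.items()}
    index = [tree.names[t] for t in taxa]
    df = pd.DataFrame(data, index=pd.Index(index, name="taxon"), dtype=float)
    if audit:
        extra = pd.DataFrame(
            {s: [cols[s][1], cols[s][2], cols[s][3]] for s in cols},
            index=["__above_rank__", "__no_hits__", "__unassigned__"], dtype=float)
        df = pd.concat([df, extra])
    return df
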
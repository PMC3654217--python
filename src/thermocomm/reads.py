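"""Per-read G+C profiling with lowest-common-ancestor taxonomic assignment.

Mirrors the classic shotgun-read community profile: each ~800 bp read gets
a G+C fraction and an LCA placement computed from its tabular homology
hits, assignments are projected to a chosen rank (family, genus, ...), and
G+C histograms are accumulated for arbitrary taxon subsets so multi-modal
population structure is visible per lineage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TaxonomyTree",
    "GcHistogram",
    "gc_content",
    "assign_reads_lca",
    "project_to_rank",
    "gc_taxon_histogram",
]

# S (G or C) is the only ambiguity code that is unambiguously G+C; W (A or T)
# is unambiguously A+T. Everything else is excluded from the denominator.
_GC_BASES = set("GCSgcs")
_COUNTABLE = set("ACGTSWacgtsw")

UNASSIGNED = "unassigned"
UNCLASSIFIED = "unclassified"


def gc_content(seq: str) -> float:
    """G+C fraction of a sequence, ignoring ambiguous bases.

    Raises ValueError when no countable base (A, C, G, T, S, W) is present.
    """
    if not seq:
        raise ValueError("empty sequence")
    denom = sum(c in _COUNTABLE for c in seq)
    if denom == 0:
        raise ValueError("sequence has no bases countable for G+C")
    return sum(c in _GC_BASES for c in seq) / denom


class TaxonomyTree:
    """Rooted taxonomy: nodes with parent links, a rank and a name.

    Built from a table with columns (node_id, parent_id, rank, name); the
    root is the single node whose parent is itself (or empty). Node ids are
    handled as strings.
    """

    def __init__(self, nodes: pd.DataFrame):
        self.parent: dict[str, str] = {}
        self.rank: dict[str, str] = {}
        self.name: dict[str, str] = {}
        roots = []
        for row in nodes.itertuples(index=False):
            nid = str(row.node_id)
            pid = "" if pd.isna(row.parent_id) else str(row.parent_id)
            self.parent[nid] = pid
            self.rank[nid] = str(row.rank)
            self.name[nid] = str(row.name)
            if pid in ("", nid):
                roots.append(nid)
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for nid, pid in self.parent.items():
            if nid != self.root and pid not in self.parent:
                raise ValueError(f"node {nid} has unknown parent {pid}")
        self._depth: dict[str, int] = {}
        for nid in self.parent:
            self.depth(nid)

    def depth(self, node: str) -> int:
        if node in self._depth:
            return self._depth[node]
        chain = []
        cur = node
        while cur not in self._depth and cur != self.root:
            chain.append(cur)
            cur = self.parent[cur]
            if len(chain) > len(self.parent):
                raise ValueError("cycle in taxonomy")
        base = 0 if cur == self.root else self._depth[cur]
        self._depth.setdefault(self.root, 0)
        for i, nid in enumerate(reversed(chain)):
            self._depth[nid] = base + i + 1
        return self._depth[node]

    def path_to_root(self, node: str) -> list[str]:
        """Node and all its ancestors, ending at the root."""
        out = [node]
        while out[-1] != self.root:
            out.append(self.parent[out[-1]])
        return out

    def lca(self, nodes: list[str]) -> str:
        paths = [set(self.path_to_root(n)) for n in nodes]
        common = set.intersection(*paths)
        return max(common, key=lambda n: self._depth[n])

    def ancestor_at_rank(self, node: str, rank: str) -> str | None:
        for n in self.path_to_root(node):
            if self.rank[n] == rank:
                return n
        return None

    def is_descendant(self, node: str, ancestor: str) -> bool:
        """True when ``node`` is ``ancestor`` or lies below it."""
        return ancestor in self.path_to_root(node)

    @classmethod
    def from_populations(cls, populations) -> "TaxonomyTree":
        """Build a tree from PopulationSpec taxon paths (plus a root)."""
        rows = [("root", "", "no rank", "root")]
        seen = {"root"}
        for pop in populations:
            parent = "root"
            for rank, name in pop.taxon_path:
                if name not in seen:
                    rows.append((name, parent, rank, name))
                    seen.add(name)
                parent = name
        return cls(pd.DataFrame(rows, columns=["node_id", "parent_id", "rank", "name"]))


def assign_reads_lca(
    hits: pd.DataFrame,
    tree: TaxonomyTree,
    subject_taxon: dict[str, str],
    min_score: float = 35.0,
    top_percent: float = 10.0,
    min_support: int = 5,
) -> pd.DataFrame:
    """MEGAN-style LCA assignment from tabular hits.

    Per read, hits with bit score >= ``min_score`` and within ``top_percent``
    of the read's best score are retained and the read is placed at the LCA
    of their taxa. Nodes gathering fewer than ``min_support`` reads then
    promote their reads to the nearest sufficiently supported ancestor
    (the root always qualifies), so no read is discarded.

    Returns a frame with columns (read_id, node_id, support, status);
    ``node_id`` is NA and status ``unassigned`` for reads with no retained hit.
    """
    required = {"qseqid", "sseqid", "bitscore"}
    if not required.issubset(hits.columns):
        raise ValueError(f"hit table must have columns {sorted(required)}")
    hits = hits.copy()
    all_reads = sorted(set(hits["qseqid"]))
    taxa = hits["sseqid"].map(lambda s: subject_taxon.get(str(s)))
    unmapped = taxa.isna()
    if unmapped.any():
        warnings.warn(f"{int(unmapped.sum())} hits to subjects without taxon mapping dropped")
        hits, taxa = hits[~unmapped], taxa[~unmapped]
    hits = hits.assign(taxon=taxa.astype(str))

    rows = []
    seen = set(hits["qseqid"])
    for read_id in all_reads:
        if read_id not in seen:
            rows.append((read_id, pd.NA, 0, UNASSIGNED))
    for read_id, grp in hits.groupby("qseqid", sort=True):
        best = grp["bitscore"].max()
        kept = grp[(grp["bitscore"] >= min_score)
                   & (grp["bitscore"] >= best * (1 - top_percent / 100.0))]
        if len(kept) == 0:
            rows.append((read_id, pd.NA, 0, UNASSIGNED))
        else:
            node = tree.lca(sorted(set(kept["taxon"])))
            rows.append((read_id, node, len(kept), "assigned"))
    out = pd.DataFrame(rows, columns=["read_id", "node_id", "support", "status"])

    # min_support promotion: deepest nodes first so moves cascade upward
    counts = out[out["status"] == "assigned"]["node_id"].value_counts().to_dict()
    remap: dict[str, str] = {}
    for node in sorted(tree.parent, key=lambda n: -tree.depth(n)):
        total = counts.get(node, 0)
        if total == 0:
            continue
        if node != tree.root and total < min_support:
            parent = tree.parent[node]
            counts[parent] = counts.get(parent, 0) + total
            counts[node] = 0
            remap[node] = parent

    def resolve(node):
        if pd.isna(node):
            return node
        while node in remap:
            node = remap[node]
        return node

    out["node_id"] = out["node_id"].map(resolve)
    return out


def project_to_rank(
    assignments: pd.DataFrame, tree: TaxonomyTree, rank: str
) -> pd.DataFrame:
    """Replace each assignment by its ancestor at ``rank``.

    Assignments whose lineage has no node at that rank (placements above
    the rank) get status ``unclassified``; unassigned reads pass through.
    """
    if rank not in set(tree.rank.values()):
        raise ValueError(f"rank {rank!r} not present in taxonomy")
    out = assignments.copy()
    new_nodes, new_status = [], []
    for node, status in zip(out["node_id"], out["status"]):
        if status == UNASSIGNED or pd.isna(node):
            new_nodes.append(pd.NA)
            new_status.append(UNASSIGNED)
            continue
        anc = tree.ancestor_at_rank(node, rank)
        if anc is None:
            new_nodes.append(pd.NA)
            new_status.append(UNCLASSIFIED)
        else:
            new_nodes.append(anc)
            new_status.append("assigned")
    out["node_id"] = new_nodes
    out["status"] = new_status
    return out


@dataclass
class GcHistogram:
    """G+C histogram series (percent scale, bins covering [0, 100])."""

    edges: np.ndarray
    counts: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for series, cnt in self.counts.items():
            for i, c in enumerate(cnt):
                rows.append((series, self.edges[i], self.edges[i + 1], int(c)))
        return pd.DataFrame(rows, columns=["series", "bin_left", "bin_right", "count"])


def gc_taxon_histogram(
    reads,
    assignments: pd.DataFrame,
    tree: TaxonomyTree,
    subsets: list[str] = (),
    bin_width: float = 1.0,
) -> GcHistogram:
    """G+C histograms for all reads plus one series per taxon subset.

    A read contributes to a subset when its assignment equals the subset
    node or a descendant of it. Bin edges span [0, 100] percent.
    """
    n_bins = int(np.ceil(100.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 100.0)
    gc = {}
    for rec in reads:
        gc[rec.id] = 100.0 * gc_content(str(rec.seq))
    all_vals = np.array(list(gc.values()))
    counts = {"total": np.histogram(all_vals, bins=edges)[0] if len(all_vals) else
              np.zeros(n_bins, dtype=int)}
    assigned = assignments[assignments["status"] == "assigned"]
    for node in subsets:
        member = assigned[assigned["node_id"].map(lambda x: tree.is_descendant(x, node))]
        vals = np.array([gc[r] for r in member["read_id"] if r in gc])
        counts[node] = (np.histogram(vals, bins=edges)[0] if len(vals) else
                        np.zeros(n_bins, dtype=int))
    return GcHistogram(edges=edges, counts=counts)
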
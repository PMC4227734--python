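"""Species-tree handling.

Trees are parsed from Newick via dendropy and converted to a flat array
representation (parent pointers, postorder node list, per-edge branch
lengths) that the likelihood engine consumes.  The CODEML-style ``#1``
suffix on a leaf or internal-node label marks the foreground branch of a
branch-site analysis; exactly one branch may carry the mark.

The default study topology is the five-taxon amniote tree used throughout
the package: ``(((vlangalii, przewalskii), carolinensis), gallus, sinensis)``
with the high-elevation *P. vlangalii* terminal as the foreground branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

#: taxon labels of the default five-species study tree
DEFAULT_TAXA = ("vlangalii", "przewalskii", "carolinensis", "gallus", "sinensis")

#: default branch lengths (expected codon substitutions per codon site);
#: configurable everywhere, these are only a realistic starting point for
#: simulation of a close species pair against three deep outgroups
DEFAULT_NEWICK = (
    "(((vlangalii:0.30,przewalskii:0.15):0.25,carolinensis:0.45):0.15,"
    "gallus:0.55,sinensis:0.50);"
)


@dataclass
class PhyloTree:
    """Rooted array representation of a (possibly trifurcating) tree.

    Node 0 is the root.  ``lengths[i]`` is the length of the edge above node
    ``i`` (0 for the root).  ``foreground`` is the node id whose parent edge
    is the foreground branch, or ``None``.
    """

    parent: np.ndarray
    children: list[list[int]]
    lengths: np.ndarray
    labels: dict[int, str]  # node id -> label (leaves always labelled)
    foreground: int | None = None
    postorder: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.postorder:
            self.postorder = self._compute_postorder()

    def _compute_postorder(self) -> list[int]:
        order: list[int] = []
        stack = [0]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    # -- basic structure ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    @property
    def edges(self) -> list[int]:
        """Non-root nodes in postorder; each identifies the edge above it."""
        return [n for n in self.postorder if n != 0]

    def edge_label(self, node: int) -> str:
        if node in self.labels:
            return self.labels[node]
        tips = sorted(self.labels[t] for t in self._subtree_leaves(node))
        return "(" + ",".join(tips) + ")"

    def _subtree_leaves(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            if self.children[n]:
                stack.extend(self.children[n])
            else:
                out.append(n)
        return out

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, foreground_taxon: str | None = None) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return cls.from_dendropy(dtree, foreground_taxon=foreground_taxon)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree", foreground_taxon: str | None = None) -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        ids = {id(n): k for k, n in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.intp)
        children: list[list[int]] = [[] for _ in nodes]
        lengths = np.zeros(len(nodes))
        labels: dict[int, str] = {}
        foreground = None
        for n in nodes:
            k = ids[id(n)]
            raw = n.taxon.label if n.taxon is not None else n.label
            if raw is not None:
                label = raw.strip()
                if label.endswith("#1"):
                    label = label[:-2].strip()
                    foreground = k
                if label:
                    labels[k] = label
            if n.parent_node is not None:
                p = ids[id(n.parent_node)]
                parent[k] = p
                children[p].append(k)
                lengths[k] = n.edge.length if n.edge.length is not None else 0.0
        tree = cls(parent=parent, children=children, lengths=lengths, labels=labels, foreground=foreground)
        if foreground_taxon is not None:
            tree.set_foreground(foreground_taxon)
        if np.any(tree.lengths < 0):
            raise ValueError("negative branch length in tree")
        return tree

    @classmethod
    def default(cls, foreground_taxon: str | None = "vlangalii") -> "PhyloTree":
        return cls.from_newick(DEFAULT_NEWICK, foreground_taxon=foreground_taxon)

    # -- manipulation ------------------------------------------------------
    def set_foreground(self, taxon: str) -> None:
        for node, label in self.labels.items():
            if label == taxon:
                self.foreground = node
                return
        raise ValueError(f"taxon {taxon!r} not in tree")

    def with_lengths(self, lengths_by_edge: np.ndarray) -> "PhyloTree":
        """Copy of the tree with edge lengths replaced (order of ``self.edges``)."""
        new = np.zeros_like(self.lengths)
        for val, node in zip(lengths_by_edge, self.edges, strict=True):
            new[node] = float(val)
        return PhyloTree(
            parent=self.parent.copy(),
            children=[list(c) for c in self.children],
            lengths=new,
            labels=dict(self.labels),
            foreground=self.foreground,
            postorder=list(self.postorder),
        )

    def rerooted(self, new_root: int) -> tuple["PhyloTree", dict[int, int]]:
        """Re-hang the tree at ``new_root``; edge lengths are preserved.

        For the reversible processes used here the likelihood is invariant
        to the rooting (pulley principle), which the likelihood code
        exploits to profile out a single branch cheaply.  Returns the new
        tree and the old-id -> new-id node map.
        """
        neighbours: dict[int, list[tuple[int, float]]] = {i: [] for i in range(self.n_nodes)}
        for child in range(self.n_nodes):
            p = int(self.parent[child])
            if p >= 0:
                neighbours[child].append((p, float(self.lengths[child])))
                neighbours[p].append((child, float(self.lengths[child])))
        id_map = {new_root: 0}
        parent = [-1]
        children: list[list[int]] = [[]]
        lengths = [0.0]
        queue = [new_root]
        while queue:
            node = queue.pop(0)
            for nbr, length in neighbours[node]:
                if nbr in id_map:
                    continue
                id_map[nbr] = len(parent)
                parent.append(id_map[node])
                children.append([])
                children[id_map[node]].append(id_map[nbr])
                lengths.append(length)
                queue.append(nbr)
        labels = {id_map[k]: v for k, v in self.labels.items()}
        fg = id_map[self.foreground] if self.foreground is not None else None
        tree = PhyloTree(
            parent=np.asarray(parent, dtype=np.intp),
            children=children,
            lengths=np.asarray(lengths),
            labels=labels,
            foreground=fg,
        )
        return tree, id_map

    def to_newick(self, mark_foreground: bool = True) -> str:
        def fmt(node: int) -> str:
            mark = "#1" if (mark_foreground and node == self.foreground) else ""
            if not self.children[node]:
                core = self.labels[node] + mark
            else:
                core = "(" + ",".join(fmt(c) for c in self.children[node]) + ")" + mark
            if node == 0:
                return core
            return f"{core}:{self.lengths[node]:.10g}"

        return fmt(0) + ";"

    def pairwise_path_matrix(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        """Leaf-pair x edge incidence matrix (1 if the edge lies on the path).

        Used for least-squares branch-length initialisation from pairwise
        distances.
        """
        leaves = self.leaves
        edges = self.edges
        edge_pos = {e: k for k, e in enumerate(edges)}
        anc: dict[int, set[int]] = {}
        for leaf in leaves:
            path = set()
            n = leaf
            while n != 0:
                path.add(n)
                n = int(self.parent[n])
            anc[leaf] = path
        pairs, rows = [], []
        for i, a in enumerate(leaves):
            for b in leaves[i + 1 :]:
                onpath = anc[a] ^ anc[b]
                row = np.zeros(len(edges))
                for e in onpath:
                    row[edge_pos[e]] = 1.0
                pairs.append((self.labels[a], self.labels[b]))
                rows.append(row)
        return pairs, np.asarray(rows)
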
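"""Rooted phylogenies, Newick I/O, p-distances, neighbor joining.

The tree machinery here is deliberately modest: the correlated-evolution
test downstream is tree-agnostic, so any rooted bifurcating tree with
branch lengths will do.  Users with a maximum-likelihood tree from an
external program can import it via :func:`read_newick`; this module also
provides a desk-scale tree builder (p-distances on a concatenated
alignment, neighbor joining, midpoint rooting) so the whole pipeline runs
without external tools.

Newick parsing, NJ agglomeration and midpoint rooting are delegated to
:mod:`dendropy`; this module wraps them behind a small, validated
:class:`Phylogeny` container with the array views the pruning likelihood
needs.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "DistanceMatrix",
    "PruningArrays",
    "read_newick",
    "write_newick",
    "p_distance",
    "neighbor_joining",
]


class NewickError(ValueError):
    """Malformed or invalid Newick input."""


@dataclass(frozen=True)
class PruningArrays:
    """Index arrays for a postorder sweep over a bifurcating rooted tree.

    Node ids are 0..n_nodes-1; tips occupy 0..n_tips-1 in the order of
    ``tip_labels``.  ``children[i]`` holds the two child ids of the i-th
    internal node in postorder; ``postorder_internal[i]`` is that node's
    own id.  ``branch_lengths[v]`` is the length of the edge above node v
    (0.0 for the root, never used).
    """

    tip_labels: tuple[str, ...]
    n_nodes: int
    postorder_internal: np.ndarray  # (n_internal,)
    children: np.ndarray  # (n_internal, 2)
    branch_lengths: np.ndarray  # (n_nodes,)
    root: int

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)


class Phylogeny:
    """A rooted phylogeny with unique tip labels and branch lengths.

    Thin, validated wrapper around a :class:`dendropy.Tree`.  Internal
    multifurcations can be resolved into zero-length bifurcations (the
    pruning likelihood requires a strictly bifurcating topology).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
        if any(lab is None for lab in labels):
            raise NewickError("every tip must be labeled")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise NewickError(f"duplicate tip labels: {sorted(dupes)}")
        self._tip_labels = tuple(sorted(labels))

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickError(f"could not parse Newick: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        return (
            self._tree.as_string(
                schema="newick", suppress_rooting=True, real_value_format_specifier=".10g"
            ).strip()
        )

    # -- basic queries -----------------------------------------------------

    @property
    def tip_labels(self) -> tuple[str, ...]:
        """Tip labels in sorted order."""
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def n_internal(self) -> int:
        return sum(1 for n in self._tree.preorder_node_iter() if not n.is_leaf())

    def is_bifurcating(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self._tree.preorder_node_iter()
            if not n.is_leaf()
        )

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    # -- transforms --------------------------------------------------------

    def resolve_polytomies(self) -> "Phylogeny":
        """Arbitrarily resolve multifurcations into zero-length bifurcations."""
        if self.is_bifurcating():
            return self
        tree = self._tree.clone(depth=1)
        tree.resolve_polytomies()
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                edge.length = 0.0
        warnings.warn("multifurcations resolved into zero-length bifurcations")
        return Phylogeny(tree)

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        out: dict[str, float] = {}
        for leaf in self._tree.leaf_node_iter():
            out[leaf.taxon.label] = leaf.distance_from_root()
        return out

    # -- pruning view ------------------------------------------------------

    def as_arrays(self) -> PruningArrays:
        """Postorder index arrays for the pruning likelihood.

        Raises
        ------
        ValueError
            If any internal node is not strictly bifurcating.
        """
        if not self.is_bifurcating():
            raise ValueError(
                "tree has multifurcations; call resolve_polytomies() first"
            )
        tip_ids = {lab: i for i, lab in enumerate(self._tip_labels)}
        n_tips = len(tip_ids)
        node_id: dict[int, int] = {}
        next_internal = n_tips
        post_internal: list[int] = []
        children: list[tuple[int, int]] = []
        blen: dict[int, float] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                nid = tip_ids[node.taxon.label]
            else:
                nid = next_internal
                next_internal += 1
                kids = node.child_nodes()
                post_internal.append(nid)
                children.append((node_id[id(kids[0])], node_id[id(kids[1])]))
            node_id[id(node)] = nid
            length = node.edge.length
            if node is self._tree.seed_node:
                length = 0.0
            elif length is None:
                raise ValueError("all non-root branches must have lengths")
            elif length < 0:
                raise ValueError("negative branch length")
            blen[nid] = float(length)
        n_nodes = next_internal
        bl = np.zeros(n_nodes)
        for nid, length in blen.items():
            bl[nid] = length
        return PruningArrays(
            tip_labels=self._tip_labels,
            n_nodes=n_nodes,
            postorder_internal=np.asarray(post_internal, dtype=np.intp),
            children=np.asarray(children, dtype=np.intp),
            branch_lengths=bl,
            root=post_internal[-1],
        )


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`."""
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny) -> str:
    """Serialize a :class:`Phylogeny` to Newick."""
    return tree.to_newick()


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over an ordered taxon list."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and nonnegative")

    def to_tsv(self) -> str:
        lines = ["\t".join(["taxon"] + self.taxa)]
        for i, t in enumerate(self.taxa):
            lines.append("\t".join([t] + [f"{x:.10g}" for x in self.d[i]]))
        return "\n".join(lines) + "\n"


def p_distance(sequences: dict[str, str], gap_char: str = "-") -> DistanceMatrix:
    """Pairwise p-distances from an equal-length (gapped) alignment.

    d(a, b) = mismatches / compared columns, where a column is compared
    only if neither sequence has a gap there.  A pair with zero comparable
    columns is an error (no distance is defined).
    """
    taxa = list(sequences)
    if len(taxa) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    mats = np.array(
        [np.frombuffer(sequences[t].upper().encode(), dtype=np.uint8) for t in taxa]
    )
    gap = np.uint8(ord(gap_char))
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mats[i] != gap) & (mats[j] != gap)
            ncomp = int(ok.sum())
            if ncomp == 0:
                raise ValueError(
                    f"no comparable columns between {taxa[i]!r} and {taxa[j]!r}"
                )
            mism = int((mats[i][ok] != mats[j][ok]).sum())
            d[i, j] = d[j, i] = mism / ncomp
    return DistanceMatrix(taxa=taxa, d=d)


def neighbor_joining(dm: DistanceMatrix) -> Phylogeny:
    """Neighbor-joining tree, midpoint-rooted.

    Standard NJ agglomeration (via dendropy) on the distance matrix;
    negative branch lengths are clamped to zero with a warning; the
    unrooted result is midpoint-rooted so downstream consumers get a
    rooted bifurcating topology.
    """
    if len(dm.taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    buf = io.StringIO()
    buf.write("." + "".join("," + t for t in dm.taxa) + "\n")
    for i, t in enumerate(dm.taxa):
        buf.write(t + "".join(f",{x:.17g}" for x in dm.d[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    n_clamped = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            n_clamped += 1
    if n_clamped:
        warnings.warn(f"clamped {n_clamped} negative NJ branch length(s) to 0")
    tree.reroot_at_midpoint(update_bipartitions=True)
    # midpoint rooting can leave a trifurcation at the seed node on some
    # inputs; resolve so the pruning code always sees a bifurcating root
    phylo = Phylogeny(tree)
    if not phylo.is_bifurcating():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            phylo = phylo.resolve_polytomies()
    return phylo
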
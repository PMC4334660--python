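"""Pairwise p-distances, neighbour-joining identification trees and
clade-based species assignment.

The tree machinery here is deliberately small: identification trees only
need topology, branch lengths and bootstrap supports.  Neighbour joining is
implemented directly (Saitou-Nei Q-criterion with a fixed lowest-index
tie-break) so results are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_core import Alignment


class DistanceError(ValueError):
    pass


class MonophylyError(ValueError):
    """Reference species do not form monophyletic groups."""

    def __init__(self, message: str, conflicts: list[str]):
        super().__init__(message)
        self.conflicts = conflicts


# ---------------------------------------------------------------------------
# p-distances
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(aln: Alignment) -> np.ndarray:
    """Byte-encode sequences; anything outside A/C/G/T becomes missing."""
    arr = np.frombuffer("".join(aln.sequences).encode("ascii"), dtype=np.uint8)
    return _CODE[arr].reshape(len(aln), aln.length)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of proportions of differing sites."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise DistanceError("matrix shape does not match id count")
        if not np.allclose(self.d, self.d.T):
            raise DistanceError("distance matrix is not symmetric")
        if (np.diag(self.d) != 0).any():
            raise DistanceError("nonzero diagonal")
        if ((self.d < 0) | (self.d > 1)).any():
            raise DistanceError("p-distances must lie in [0, 1]")

    def value(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])


def p_distance_matrix(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Proportion of differing sites for every pair of sequences.

    Sites with a gap, N or IUPAC ambiguity in either sequence of a pair are
    excluded from that pair under ``pairwise`` deletion; under ``complete``
    deletion such sites are removed for all pairs at once.
    """
    if len(aln) < 2:
        raise DistanceError("need at least two sequences")
    if deletion not in ("pairwise", "complete"):
        raise DistanceError(f"unknown deletion mode {deletion!r}")
    codes = _encode(aln)
    valid = codes != 255
    if deletion == "complete":
        keep = valid.all(axis=0)
        codes = codes[:, keep]
        valid = valid[:, keep]
    n = len(aln)
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        compared = both.sum(axis=1)
        zero = np.flatnonzero(compared == 0)
        if zero.size:
            j = int(zero[0]) + i + 1
            raise DistanceError(
                f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
            )
        diffs = ((codes[i] != codes[i + 1:]) & both).sum(axis=1)
        d[i, i + 1:] = d[i + 1:, i] = diffs / compared
    return DistanceMatrix(list(aln.ids), d)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class Clade:
    name: str | None = None
    branch_length: float = 0.0
    support: int | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary (trifurcating) root."""

    root: Clade

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def _clade_sides(self) -> list[tuple[Clade, frozenset[str]]]:
        out = []

        def walk(node: Clade):
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset()
            for c in node.children:
                s = walk(c)
                out.append((c, s))
                below = below | s
            return below

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized as the side not containing
        the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaves())
        anchor = min(all_leaves)
        out = set()
        for _, side in self._clade_sides():
            if len(side) < 2 or len(side) > len(all_leaves) - 2:
                continue
            out.add(side if anchor not in side else all_leaves - side)
        return out

    def edge_sides(self) -> set[frozenset[str]]:
        """Both sides of every edge (including pendant edges)."""
        all_leaves = frozenset(self.leaves())
        out: set[frozenset[str]] = set()
        for _, side in self._clade_sides():
            out.add(side)
            out.add(all_leaves - side)
        return out

    def patristic(self, a: str, b: str) -> float:
        """Path length between two leaves along branch lengths."""
        adj: dict[int, list[tuple[int, float]]] = {}
        label: dict[int, str] = {}
        counter = [0]

        def walk(node: Clade) -> int:
            nid = counter[0]
            counter[0] += 1
            if node.is_leaf:
                label[nid] = node.name
            for c in node.children:
                cid = walk(c)
                adj.setdefault(nid, []).append((cid, c.branch_length))
                adj.setdefault(cid, []).append((nid, c.branch_length))
            return nid

        walk(self.root)
        src = next(k for k, v in label.items() if v == a)
        dst = next(k for k, v in label.items() if v == b)
        stack = [(src, -1, 0.0)]
        while stack:
            node, prev, acc = stack.pop()
            if node == dst:
                return acc
            for nxt, w in adj.get(node, []):
                if nxt != prev:
                    stack.append((nxt, node, acc + w))
        raise KeyError((a, b))

    def newick(self) -> str:
        def fmt(node: Clade) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.branch_length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else str(node.support)
            return f"({inner}){label}:{node.branch_length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbour joining with deterministic lowest-index tie-breaking.

    Negative branch lengths are clamped to zero.  The returned tree is
    unrooted, represented with a trifurcating root.
    """
    n = len(dm.ids)
    if n < 3:
        raise DistanceError("neighbour joining needs at least 3 taxa")
    d = dm.d.copy()
    nodes: list[Clade] = [Clade(name=i) for i in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: first minimum in row-major scan
        flat = np.argmin(q)
        ai, aj = divmod(int(flat), m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = max(0.0, li)
        child_j.branch_length = max(0.0, lj)
        parent = Clade(children=[child_i, child_j])
        # distances from the new node to remaining actives
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_d
        d[:, i] = new_d
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        nodes[idx].branch_length = max(0.0, ln)
    return Tree(root=Clade(children=[nodes[a], nodes[b], nodes[c]]))


def bootstrap_supports(aln: Alignment, n_reps: int = 100, seed: int = 0,
                       deletion: str = "pairwise") -> Tree:
    """Point-estimate NJ tree annotated with site-bootstrap supports.

    Sites are resampled with replacement ``n_reps`` times; each bipartition
    of the point tree is labelled with the percentage of replicates in which
    it reappears (integer, floor rounding).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(p_distance_matrix(aln, deletion))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    L = aln.length
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        resampled = Alignment(
            [(rid, "".join(seq[c] for c in cols)) for rid, seq in aln.records]
        )
        rep = nj_tree(p_distance_matrix(resampled, deletion))
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(tree.leaves())
    anchor = min(all_leaves)
    for clade, side in tree._clade_sides():
        if clade.is_leaf:
            continue
        key = side if anchor not in side else all_leaves - side
        if key in counts:
            clade.support = math.floor(100 * counts[key] / n_reps)
    return tree


# ---------------------------------------------------------------------------
# Species assignment
# ---------------------------------------------------------------------------

def assign_species(tree: Tree, references: dict[str, str]) -> dict[str, str]:
    """Assign query leaves to species using reference clades.

    Every reference species must be monophyletic ignoring query leaves:
    some split must isolate exactly that species' references from all other
    references.  A query then takes the species of the smallest
    single-species clade (tree side) that contains it and at least one
    reference, ranked by patristic distance to the nearest reference inside
    the clade.  Queries with no such clade, or sitting at an exact tie
    between two species, are ``"unassigned"``.
    """
    leaves = set(tree.leaves())
    unknown = [r for r in references if r not in leaves]
    if unknown:
        raise ValueError(f"reference specimens not in tree: {sorted(unknown)}")
    by_species: dict[str, set[str]] = {}
    for rid, sp in references.items():
        by_species.setdefault(sp, set()).add(rid)

    sides = tree.edge_sides()
    minimal_clade: dict[str, frozenset[str]] = {}
    for sp, refs in by_species.items():
        candidates = [s for s in sides
                      if set(r for r in s if r in references) == refs]
        if not candidates:
            raise MonophylyError(
                f"references for {sp!r} are not monophyletic",
                conflicts=sorted(refs),
            )
        minimal_clade[sp] = min(candidates,
                                key=lambda s: (len(s), tuple(sorted(s))))

    # ambiguity margin for basal queries: 10% of the closest gap between
    # references of different species
    inter = [tree.patristic(a, b)
             for a in references for b in references
             if a < b and references[a] != references[b]]
    margin = 0.1 * min(inter) if inter else 0.0

    result: dict[str, str] = dict(references)
    for leaf in sorted(leaves - set(references)):
        hits = [sp for sp, clade in minimal_clade.items() if leaf in clade]
        if len(hits) == 1:
            result[leaf] = hits[0]
            continue
        if len(hits) > 1:  # nested clades cannot share references; pick inner
            result[leaf] = min(hits, key=lambda sp: (len(minimal_clade[sp]), sp))
            continue
        # basal to every clade: nearest reference wins only by a clear margin
        dists = {sp: min(tree.patristic(leaf, r) for r in refs)
                 for sp, refs in by_species.items()}
        ranked = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
        if len(ranked) == 1 or ranked[1][1] - ranked[0][1] > margin:
            result[leaf] = ranked[0][0]
        else:
            result[leaf] = "unassigned"
    return result


def write_distance_csv(path, dm: DistanceMatrix) -> None:
    import pandas as pd

    pd.DataFrame(dm.d, index=dm.ids, columns=dm.ids).to_csv(path)
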
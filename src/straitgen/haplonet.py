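"""Haplotype collapsing and parsimony-limited minimum spanning networks.

Sequences with any ambiguity (N, IUPAC codes, or gaps) are excluded before
collapsing; identical sequences merge into haplotypes carrying frequencies
and the set of land units where they occur.

The network is a minimum spanning network: an edge joins two haplotypes iff
their endpoints are not connected by strictly fewer-step edges (equivalently,
the union of all minimum spanning trees, which retains tied alternative
connections as loops), truncated at an explicit mutational-step limit.
The default limit of 11 steps is the conventional 95% statistical-parsimony
cutoff for ~658 bp barcode fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

import numpy as np

from .io_core import Alignment, LocalityTable, UNAMBIGUOUS

#: Conventional 95% parsimony connection limit for a 658-bp COI barcode.
DEFAULT_CONNECTION_LIMIT = 11


class NetworkError(ValueError):
    pass


@dataclass
class Haplotype:
    hap_id: str
    sequence: str
    members: list[str]
    units: set[str] = field(default_factory=set)

    @property
    def frequency(self) -> int:
        return len(self.members)


@dataclass
class HaploNetwork:
    haplotypes: list[Haplotype]
    edges: list[tuple[int, int, int]]  # (index i, index j, steps)
    connection_limit: int

    def components(self) -> list[list[int]]:
        """Connected components as sorted lists of haplotype indices."""
        n = len(self.haplotypes)
        adj: dict[int, list[int]] = {i: [] for i in range(n)}
        for i, j, _ in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        seen = [False] * n
        comps = []
        for start in range(n):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in adj[u]:
                    if not seen[v]:
                        seen[v] = True
                        stack.append(v)
            comps.append(sorted(comp))
        return comps

    def degree(self, idx: int) -> int:
        return sum(1 for i, j, _ in self.edges if idx in (i, j))


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def collapse_haplotypes(aln: Alignment, loc: LocalityTable | None = None,
                        report=None) -> list[Haplotype]:
    """Merge identical unambiguous sequences into haplotypes.

    Sequences containing anything outside A/C/G/T (N, ambiguity codes or
    gaps) are excluded and, when a report is given, listed in it.  Units are
    populated from the locality table's ``land_unit`` column.
    """
    kept: list[tuple[str, str]] = []
    excluded: list[str] = []
    for rid, seq in aln.records:
        if set(seq) <= UNAMBIGUOUS:
            kept.append((rid, seq))
        else:
            excluded.append(rid)
    if not kept:
        raise NetworkError("all sequences contain ambiguities; nothing to collapse")

    by_seq: dict[str, list[str]] = {}
    order: list[str] = []
    for rid, seq in kept:
        if seq not in by_seq:
            by_seq[seq] = []
            order.append(seq)
        by_seq[seq].append(rid)

    haps = []
    for k, seq in enumerate(order, start=1):
        members = by_seq[seq]
        units = set()
        if loc is not None:
            for m in members:
                u = loc.unit_for(m)
                if u is not None:
                    units.add(u)
        haps.append(Haplotype(hap_id=f"H{k}", sequence=seq,
                              members=members, units=units))
    if report is not None:
        report.log("collapse_haplotypes", n_input=len(aln),
                   n_excluded_ambiguous=len(excluded), excluded_ids=excluded,
                   n_haplotypes=len(haps))
    return haps


def build_network(haps: list[Haplotype],
                  connection_limit: int = DEFAULT_CONNECTION_LIMIT
                  ) -> HaploNetwork:
    """Minimum spanning network over haplotypes, capped at a step limit.

    An edge (i, j) with ``w`` mutational steps is retained iff i and j are
    not connected using only edges of fewer than ``w`` steps (Kruskal by
    weight class, keeping ties).  Edges above ``connection_limit`` are then
    dropped, possibly disconnecting the network.
    """
    if not haps:
        raise NetworkError("no haplotypes")
    n = len(haps)
    cand = []
    for i in range(n):
        for j in range(i + 1, n):
            w = hamming(haps[i].sequence, haps[j].sequence)
            if w == 0:
                raise NetworkError(
                    f"haplotypes {haps[i].hap_id} and {haps[j].hap_id} are identical"
                )
            cand.append((w, i, j))
    cand.sort()

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int, int]] = []
    for w, group in groupby(cand, key=lambda t: t[0]):
        batch = list(group)
        # test all edges of this weight against components formed by
        # strictly lighter edges, then union
        keep = [(i, j) for _, i, j in batch if find(i) != find(j)]
        for i, j in keep:
            if w <= connection_limit:
                edges.append((i, j, w))
        for i, j in keep:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    return HaploNetwork(haplotypes=haps, edges=edges,
                        connection_limit=connection_limit)


def network_to_csv(edge_path, hap_path, net: HaploNetwork) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"hap_i": net.haplotypes[i].hap_id, "hap_j": net.haplotypes[j].hap_id,
          "steps": w} for i, j, w in net.edges]
    ).to_csv(edge_path, index=False)
    pd.DataFrame(
        [{"hap_id": h.hap_id, "frequency": h.frequency,
          "members": ";".join(h.members), "units": ";".join(sorted(h.units))}
         for h in net.haplotypes]
    ).to_csv(hap_path, index=False)
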
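"""Minimum over-sea dispersal events from haplotype networks.

Scoring rules: a sea crossing is evidenced between two effective land units
when (a) a haplotype is shared between them, or (b) two haplotypes occupying
them are directly linked in the network.  Per network component, the minimum
event set is a minimum spanning tree of the unit-level evidence graph
(ties broken by shortest crossing, then lexicographic unit names), so the
minimum count is (occupied units - connected parts) regardless of where the
ancestor sat.  Candidate events can then be conservatively excluded as
ambiguous, either automatically (a strictly shorter stepping-stone route
exists through occupied units AND every witnessing haplotype is an interior
network node, i.e. plausibly ancestral and explainable by extinction or
non-detection elsewhere) or through an explicit per-event override file.

Events are unordered crossings: counts and lengths, not directions.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .haplonet import HaploNetwork
from .io_core import ConfigError, LocalityTable, StraitGraph, haversine_km


class DispersalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Land-unit merging
# ---------------------------------------------------------------------------

@dataclass
class LandUnitSet:
    mapping: dict[str, str]  # original unit -> effective unit
    localities: LocalityTable  # re-labelled copy

    def effective(self, unit: str) -> str:
        return self.mapping[unit]

    @property
    def effective_units(self) -> set[str]:
        return set(self.mapping.values())


def apply_isobath_merges(loc: LocalityTable, sg: StraitGraph) -> LandUnitSet:
    """Re-label locality land units to their post-merge effective units.

    Merges are closed transitively (A->B, B->C gives A->C); crossings inside
    a merged pair are never scored because both ends share an effective unit.
    """
    mapping = {u: u for u in sg.units}
    for a, b in sg.merges:
        mapping[a] = b
    # transitive closure
    for u in mapping:
        seen = {u}
        cur = u
        while mapping[cur] != cur:
            cur = mapping[cur]
            if cur in seen:
                raise ConfigError(f"cyclic merge chain involving {u!r}")
            seen.add(cur)
        mapping[u] = cur

    df = loc.df.copy()
    unknown = sorted(set(df["land_unit"].dropna()) - set(sg.units))
    if unknown:
        raise DispersalError(f"localities reference unknown land units: {unknown}")
    df["land_unit"] = df["land_unit"].map(lambda u: mapping.get(u, u))
    return LandUnitSet(mapping=mapping, localities=LocalityTable(df))


# ---------------------------------------------------------------------------
# Evidence graph
# ---------------------------------------------------------------------------

@dataclass
class EvidenceEdge:
    unit_a: str
    unit_b: str
    length_km: float
    evidence: str  # shared_haplotype | linked_haplotypes
    witnesses: list[tuple[str, ...]] = field(default_factory=list)
    flagged_no_strait: bool = False


@dataclass
class ComponentEvidence:
    component_index: int
    units: set[str]
    edges: list[EvidenceEdge]


def _effective_units_of(hap, lus: LandUnitSet) -> set[str]:
    return {lus.mapping.get(u, u) for u in hap.units}


def _unit_centroids(lus: LandUnitSet) -> dict[str, tuple[float, float]]:
    df = lus.localities.df.dropna(subset=["land_unit"])
    out = {}
    for unit, grp in df.groupby("land_unit"):
        out[str(unit)] = (float(grp["lat"].mean()), float(grp["lon"].mean()))
    return out


def evidence_graph(net: HaploNetwork, lus: LandUnitSet, sg: StraitGraph,
                   report=None) -> list[ComponentEvidence]:
    """Unit-level crossing evidence for each haplotype-network component."""
    comps = net.components()
    centroids = _unit_centroids(lus)
    out = []
    for ci, comp in enumerate(comps):
        units: set[str] = set()
        edge_map: dict[tuple[str, str], EvidenceEdge] = {}

        def add_edge(u: str, v: str, evidence: str, witness: tuple[str, ...]):
            key = tuple(sorted((u, v)))
            if key not in edge_map:
                km = sg.distance(u, v)
                flagged = False
                if not np.isfinite(km):
                    # no strait listed: fall back to centroid great-circle km
                    ca, cb = centroids.get(u), centroids.get(v)
                    if ca is None or cb is None:
                        raise DispersalError(
                            f"no strait distance and no centroid for {u}-{v}"
                        )
                    km = float(haversine_km(ca[0], ca[1], cb[0], cb[1]))
                    flagged = True
                    if report is not None:
                        report.log("evidence_graph_warning",
                                   pair=[u, v], used="centroid_great_circle",
                                   km=km)
                edge_map[key] = EvidenceEdge(key[0], key[1], km, evidence,
                                             flagged_no_strait=flagged)
            edge_map[key].witnesses.append(witness)
            # shared-haplotype evidence dominates linked evidence
            if evidence == "shared_haplotype":
                edge_map[key].evidence = "shared_haplotype"

        for idx in comp:
            hu = _effective_units_of(net.haplotypes[idx], lus)
            units |= hu
            # rule (a): one haplotype spanning several units
            hu_sorted = sorted(hu)
            for a in range(len(hu_sorted)):
                for b in range(a + 1, len(hu_sorted)):
                    add_edge(hu_sorted[a], hu_sorted[b], "shared_haplotype",
                             (net.haplotypes[idx].hap_id,))
        # rule (b): adjacent haplotypes in different units
        for i, j, _ in net.edges:
            if i not in comp or j not in comp:
                continue
            ui = _effective_units_of(net.haplotypes[i], lus)
            uj = _effective_units_of(net.haplotypes[j], lus)
            for u in sorted(ui):
                for v in sorted(uj):
                    if u != v:
                        add_edge(u, v, "linked_haplotypes",
                                 (net.haplotypes[i].hap_id,
                                  net.haplotypes[j].hap_id))
        out.append(ComponentEvidence(ci, units, sorted(
            edge_map.values(), key=lambda e: (e.unit_a, e.unit_b))))
    if report is not None:
        report.log("evidence_graph", n_components=len(out),
                   units_per_component=[sorted(c.units) for c in out],
                   edges_per_component=[len(c.edges) for c in out])
    return out


# ---------------------------------------------------------------------------
# Event minimization
# ---------------------------------------------------------------------------

@dataclass
class DispersalEvent:
    event_id: str
    from_unit: str
    to_unit: str
    evidence: str
    witnesses: list[tuple[str, ...]]
    length_km: float
    component_index: int
    status: str = "retained"  # retained | excluded_ambiguous
    reason: str = ""

    @property
    def units(self) -> tuple[str, str]:
        return (self.from_unit, self.to_unit)


def minimize_events(evidence: list[ComponentEvidence],
                    report=None) -> list[DispersalEvent]:
    """Minimum spanning tree of each component's evidence graph.

    The per-component event count is (occupied units - connected evidence
    parts); disconnected evidence graphs are spanned per part and flagged.
    """
    events: list[DispersalEvent] = []
    k = 0
    for comp in evidence:
        unit_ids = {u: i for i, u in enumerate(sorted(comp.units))}
        parent = list(range(len(unit_ids)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ordered = sorted(comp.edges,
                         key=lambda e: (e.length_km, e.unit_a, e.unit_b))
        n_parts_edges = 0
        for e in ordered:
            ra, rb = find(unit_ids[e.unit_a]), find(unit_ids[e.unit_b])
            if ra == rb:
                continue
            parent[rb] = ra
            k += 1
            events.append(DispersalEvent(
                event_id=f"E{k}", from_unit=e.unit_a, to_unit=e.unit_b,
                evidence=e.evidence, witnesses=list(e.witnesses),
                length_km=e.length_km, component_index=comp.component_index,
            ))
            n_parts_edges += 1
        n_parts = len(unit_ids) - n_parts_edges
        if report is not None and len(unit_ids) > 0:
            report.log("minimize_events_component",
                       component=comp.component_index,
                       occupied_units=sorted(comp.units),
                       events=n_parts_edges, evidence_parts=n_parts,
                       disconnected=n_parts > 1)
    return events


# ---------------------------------------------------------------------------
# Ambiguity flagging
# ---------------------------------------------------------------------------

def _minimax_bottleneck(adj: dict[str, list[tuple[str, float]]],
                        src: str, dst: str) -> float:
    """Smallest possible maximum single crossing on any src->dst path."""
    best = {src: 0.0}
    heap = [(0.0, src)]
    while heap:
        bott, u = heapq.heappop(heap)
        if u == dst:
            return bott
        if bott > best.get(u, np.inf):
            continue
        for v, w in adj.get(u, []):
            nb = max(bott, w)
            if nb < best.get(v, np.inf):
                best[v] = nb
                heapq.heappush(heap, (nb, v))
    return np.inf


def flag_ambiguous(events: list[DispersalEvent], net: HaploNetwork,
                   lus: LandUnitSet, sg: StraitGraph,
                   overrides: dict[str, str] | None = None,
                   report=None) -> list[DispersalEvent]:
    """Mark events whose pattern is better explained without the crossing.

    An event is auto-excluded when BOTH hold: (a) a stepping-stone route
    between its units exists through other occupied units whose longest
    single crossing is strictly shorter than the event's length, and (b)
    every witnessing haplotype is an interior node (degree >= 2) of the
    network, so its presence on both sides can reflect an unsampled or
    extinct intermediate.  Overrides (event_id -> retain|exclude) win and
    are logged.
    """
    overrides = overrides or {}
    unknown = sorted(set(overrides) - {e.event_id for e in events})
    if unknown:
        raise DispersalError(f"override references unknown event ids: {unknown}")

    # occupied units across the whole dataset
    occupied: set[str] = set()
    for h in net.haplotypes:
        occupied |= _effective_units_of(h, lus)
    # stepping-stone graph: finite straits between occupied units
    adj: dict[str, list[tuple[str, float]]] = {u: [] for u in occupied}
    occ = sorted(occupied)
    for i, u in enumerate(occ):
        for v in occ[i + 1:]:
            km = sg.distance(u, v)
            if np.isfinite(km) and km > 0:
                adj[u].append((v, km))
                adj[v].append((u, km))

    hap_index = {h.hap_id: i for i, h in enumerate(net.haplotypes)}
    for e in events:
        if e.event_id in overrides:
            action = overrides[e.event_id]
            if action not in ("retain", "exclude"):
                raise DispersalError(f"override action {action!r} invalid")
            e.status = "retained" if action == "retain" else "excluded_ambiguous"
            e.reason = f"override:{action}"
            continue
        # (a) strictly shorter alternative route, not using the direct edge
        adj_wo = {u: [(v, w) for v, w in nb
                      if {u, v} != {e.from_unit, e.to_unit}]
                  for u, nb in adj.items()}
        bottleneck = _minimax_bottleneck(adj_wo, e.from_unit, e.to_unit)
        has_alternative = bottleneck < e.length_km
        # (b) all witnessing haplotypes interior (degree >= 2)
        wits = {h for pair in e.witnesses for h in pair}
        interior = all(net.degree(hap_index[h]) >= 2 for h in wits)
        if has_alternative and interior:
            e.status = "excluded_ambiguous"
            e.reason = (f"alternative route bottleneck {bottleneck:.1f} km < "
                        f"{e.length_km:.1f} km; witnesses interior")
        else:
            e.status = "retained"
            e.reason = ""
    if report is not None:
        report.log("flag_ambiguous",
                   retained=sum(1 for e in events if e.status == "retained"),
                   excluded=sum(1 for e in events
                                if e.status == "excluded_ambiguous"),
                   overrides=dict(overrides),
                   decisions=[{"event_id": e.event_id, "status": e.status,
                               "reason": e.reason} for e in events])
    return events


# ---------------------------------------------------------------------------
# Length spectra
# ---------------------------------------------------------------------------

@dataclass
class DispersalSummary:
    retained_count: int
    excluded_count: int
    bin_edges: np.ndarray
    histogram: np.ndarray
    retained_lengths: list[float]
    reference_widths: dict[str, float]
    reference_within_capability: dict[str, bool | None]


def summarize_lengths(events: list[DispersalEvent],
                      bins: np.ndarray | list[float] | None = None,
                      reference_straits: dict[str, tuple[str, str]] | None = None,
                      sg: StraitGraph | None = None) -> DispersalSummary:
    """Histogram of retained crossing lengths plus reference-strait checks.

    Each reference strait's width is compared against the maximum retained
    event length; with zero retained events capability is undefined (None).
    """
    retained = [e.length_km for e in events if e.status == "retained"]
    excluded = sum(1 for e in events if e.status == "excluded_ambiguous")
    if bins is None:
        top = max(retained) if retained else 1.0
        bins = np.linspace(0.0, max(top, 1.0), 11)
    bins = np.asarray(bins, dtype=float)
    hist, edges = np.histogram(retained, bins=bins)

    ref_widths: dict[str, float] = {}
    ref_ok: dict[str, bool | None] = {}
    if reference_straits:
        if sg is None:
            raise DispersalError("reference straits given without a StraitGraph")
        cap = max(retained) if retained else None
        for name, (a, b) in reference_straits.items():
            w = sg.distance(a, b)
            ref_widths[name] = w
            ref_ok[name] = None if cap is None else bool(w <= cap)
    return DispersalSummary(
        retained_count=len(retained), excluded_count=excluded,
        bin_edges=edges, histogram=hist, retained_lengths=sorted(retained),
        reference_widths=ref_widths, reference_within_capability=ref_ok,
    )


def events_to_csv(path, events: list[DispersalEvent]) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"event_id": e.event_id, "from_unit": e.from_unit,
          "to_unit": e.to_unit, "evidence": e.evidence,
          "witnesses": ";".join("+".join(w) for w in e.witnesses),
          "length_km": e.length_km, "component": e.component_index,
          "status": e.status, "reason": e.reason} for e in events]
    ).to_csv(path, index=False)


def read_overrides_csv(path) -> dict[str, str]:
    import pandas as pd

    df = pd.read_csv(path)
    missing = [c for c in ("event_id", "action") if c not in df.columns]
    if missing:
        raise DispersalError(f"override file missing columns: {missing}")
    return {str(r["event_id"]): str(r["action"]) for _, r in df.iterrows()}
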
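"""RG-core extraction: finding the common subgraphs that define series.

An RG core is a connected, node-labelled subgraph shared by a set of
reduced graphs — the RG-level analogue of a Markush scaffold.  Cores are
found by an iterative maximum-common-subgraph (MCS) procedure: the
molecule with most near neighbours seeds a candidate MCS (starting from
its most distant neighbour), and the candidate is then matched against,
and possibly refined by, every remaining molecule.

Similarity between two RGs A and B is the graph variant of the Tanimoto
coefficient, ``T = MCS / (A + B - MCS)`` with node counts.

RG graphs are small (typically < 16 nodes), so the MCS is computed
exactly: connected induced subgraphs of the smaller graph are enumerated
by decreasing size and tested for label- and edge-multiplicity-preserving
embedding into the larger one.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
from networkx.algorithms import isomorphism as iso
from rdkit import Chem

from .config import RunConfig
from .rg_builder import ReducedGraph, rg_to_nx

logger = logging.getLogger("rgcore")

__all__ = [
    "RGCore",
    "SimilarityRecord",
    "rg_mcs",
    "tanimoto",
    "neighbour_lists",
    "find_candidate_mcs",
    "extract_cores",
    "graph_contains",
    "canonical_graph_smiles",
]


@dataclass
class RGCore:
    """A connected labelled subgraph common to ``member_ids``' RGs."""

    core_id: int
    graph: nx.Graph  # nodes carry 'label', edges carry 'mult'
    core_smarts: str
    member_ids: list[str]
    sub_minimal: bool = False  # fallback core below min_core_size

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass(frozen=True)
class SimilarityRecord:
    A: int
    B: int
    mcs_size: int

    @property
    def T(self) -> float:
        return self.mcs_size / (self.A + self.B - self.mcs_size)


def _node_match(a: dict, b: dict) -> bool:
    return a["label"] == b["label"]


def _edge_match(a: dict, b: dict) -> bool:
    return a.get("mult", 1) == b.get("mult", 1)


def graph_contains(big: nx.Graph, small: nx.Graph) -> bool:
    """True if ``small`` occurs in ``big`` as a label- and
    multiplicity-matched induced subgraph."""
    gm = iso.GraphMatcher(big, small, node_match=_node_match, edge_match=_edge_match)
    return gm.subgraph_is_isomorphic()


def canonical_graph_smiles(g: nx.Graph) -> str:
    """Canonical SMILES serialisation of a labelled RG-style graph.

    Used both as the printable core form (e.g. ``[Ca][Ge][Li][No][Hg]``)
    and as a canonical certificate for caching and tie-breaking.
    """
    emol = Chem.RWMol()
    order = sorted(g.nodes)
    pos = {n: k for k, n in enumerate(order)}
    for n in order:
        atom = Chem.Atom(g.nodes[n]["label"])
        atom.SetNoImplicit(True)
        emol.AddAtom(atom)
    for u, v, data in g.edges(data=True):
        bt = Chem.BondType.DOUBLE if data.get("mult", 1) == 2 else Chem.BondType.SINGLE
        emol.AddBond(pos[u], pos[v], bt)
    m = emol.GetMol()
    m.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(m)
    return Chem.MolToSmiles(m, canonical=True)


def _canonical_relabel(g: nx.Graph) -> nx.Graph:
    """Relabel nodes 0..n-1 in a canonical order (via RDKit atom ranks)."""
    emol = Chem.RWMol()
    order = sorted(g.nodes)
    pos = {n: k for k, n in enumerate(order)}
    for n in order:
        atom = Chem.Atom(g.nodes[n]["label"])
        atom.SetNoImplicit(True)
        emol.AddAtom(atom)
    for u, v, data in g.edges(data=True):
        bt = Chem.BondType.DOUBLE if data.get("mult", 1) == 2 else Chem.BondType.SINGLE
        emol.AddBond(pos[u], pos[v], bt)
    m = emol.GetMol()
    m.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(m)
    ranks = list(Chem.CanonicalRankAtoms(m, breakTies=True))
    mapping = {n: ranks[pos[n]] for n in order}
    return nx.relabel_nodes(g, mapping, copy=True)


def _connected_subsets(g: nx.Graph, k: int):
    """All connected node subsets of size ``k``, each yielded exactly once
    (ESU enumeration: subsets are rooted at their order-smallest node and
    grown only through exclusive neighbours)."""
    order = {n: i for i, n in enumerate(sorted(g.nodes))}

    def extend(sub: set, ext: set, root):
        if len(sub) == k:
            yield frozenset(sub)
            return
        ext = sorted(ext, key=order.get)
        while ext:
            w = ext.pop(0)
            nbh_sub = {u for s in sub for u in g.neighbors(s)}
            exclusive = {
                u
                for u in g.neighbors(w)
                if order[u] > order[root] and u not in sub and u not in nbh_sub
            }
            yield from extend(sub | {w}, set(ext) | exclusive, root)

    for v in sorted(g.nodes, key=order.get):
        ext0 = {u for u in g.neighbors(v) if order[u] > order[v]}
        yield from extend({v}, ext0, v)


def rg_mcs(a: ReducedGraph | nx.Graph, b: ReducedGraph | nx.Graph) -> nx.Graph:
    """Maximum connected common induced subgraph of two labelled RGs.

    Deterministic: among equally sized MCSs the one with the smallest
    canonical serialisation is returned, relabelled canonically.
    Disjoint label sets give an empty graph.
    """
    ga = a if isinstance(a, nx.Graph) else rg_to_nx(a)
    gb = b if isinstance(b, nx.Graph) else rg_to_nx(b)
    if ga.number_of_nodes() == 0 or gb.number_of_nodes() == 0:
        return nx.Graph()
    small, big = (ga, gb) if len(ga) <= len(gb) else (gb, ga)
    for k in range(len(small), 0, -1):
        best: tuple[str, nx.Graph] | None = None
        for subset in _connected_subsets(small, k):
            cand = small.subgraph(subset)
            if graph_contains(big, cand):
                key = canonical_graph_smiles(cand)
                if best is None or key < best[0]:
                    best = (key, cand)
        if best is not None:
            return _canonical_relabel(nx.Graph(best[1]))
    return nx.Graph()


def tanimoto(a: ReducedGraph, b: ReducedGraph) -> SimilarityRecord:
    """Graph Tanimoto similarity ``T = MCS / (A + B - MCS)``."""
    na, nb = len(a), len(b)
    if na == 0 and nb == 0:
        raise ValueError("Tanimoto undefined for two empty reduced graphs")
    mcs = rg_mcs(a, b)
    return SimilarityRecord(A=na, B=nb, mcs_size=mcs.number_of_nodes())


class _MCSCache:
    """MCS results keyed by unordered pair of canonical RG SMILES."""

    def __init__(self) -> None:
        self._store: dict[frozenset, nx.Graph] = {}

    def mcs(self, a: ReducedGraph, b: ReducedGraph) -> nx.Graph:
        key = frozenset((a.rg_smiles, b.rg_smiles))
        if key not in self._store:
            self._store[key] = rg_mcs(a, b)
        return self._store[key]


def neighbour_lists(
    rgs: list[ReducedGraph],
    threshold: float,
    cache: _MCSCache | None = None,
) -> dict[str, list[tuple[str, float]]]:
    """Near neighbours of every RG: all others with T >= threshold.

    Lists are sorted by descending similarity, ties broken by input order,
    so the most distant neighbour is the list tail.
    """
    cache = cache or _MCSCache()
    position = {rg.compound_id: k for k, rg in enumerate(rgs)}
    sims: dict[str, list[tuple[str, float]]] = {rg.compound_id: [] for rg in rgs}
    for a, b in itertools.combinations(rgs, 2):
        mcs_n = cache.mcs(a, b).number_of_nodes()
        t = mcs_n / (len(a) + len(b) - mcs_n)
        if t >= threshold:
            sims[a.compound_id].append((b.compound_id, t))
            sims[b.compound_id].append((a.compound_id, t))
    for cid in sims:
        sims[cid].sort(key=lambda pair: (-pair[1], position[pair[0]]))
    return sims


def find_candidate_mcs(
    centroid: ReducedGraph,
    neighbours: list[ReducedGraph],
    min_size: int,
    cache: _MCSCache | None = None,
) -> tuple[nx.Graph, ReducedGraph, bool]:
    """Seed a candidate MCS from the centroid's neighbour list.

    Walks the neighbours from most distant to nearest and returns the
    first MCS of at least ``min_size`` nodes together with the consumed
    neighbour.  If none qualifies the largest MCS over all neighbours is
    returned flagged sub-minimal.
    """
    if not neighbours:
        raise ValueError("find_candidate_mcs needs a non-empty neighbour list")
    cache = cache or _MCSCache()
    best: tuple[int, nx.Graph, ReducedGraph] | None = None
    for nb in reversed(neighbours):  # most distant first
        mcs = cache.mcs(centroid, nb)
        if mcs.number_of_nodes() >= min_size:
            return mcs, nb, False
        if best is None or mcs.number_of_nodes() > best[0]:
            best = (mcs.number_of_nodes(), mcs, nb)
    _, mcs, nb = best
    return mcs, nb, True


def extract_cores(
    rgs: list[ReducedGraph], config: RunConfig | None = None
) -> list[RGCore]:
    """Iteratively extract RG cores until every molecule is covered.

    Each round: the listed molecule with most neighbours becomes the
    centroid; a candidate MCS is seeded from its neighbour list; every
    remaining RG either contains the candidate (and joins it) or proposes
    a refinement, accepted only when the refined MCS stays a subgraph of
    the candidate and keeps at least ``min_core_size`` nodes; the final
    candidate becomes a core.  Molecules whose neighbour list is exhausted
    become singleton cores made of their whole RG.
    """
    config = config or RunConfig()
    cache = _MCSCache()
    nn = neighbour_lists(rgs, config.similarity_threshold, cache)
    by_id = {rg.compound_id: rg for rg in rgs}
    working = [rg.compound_id for rg in rgs]
    cores: list[RGCore] = []

    while working:
        in_list = set(working)
        centroid_id = max(working, key=lambda cid: (len(nn[cid]), -working.index(cid)))
        centroid = by_id[centroid_id]
        members = [centroid_id]
        avail_nbrs = [by_id[cid] for cid, _t in nn[centroid_id] if cid in in_list]

        if not avail_nbrs:
            candidate = rg_to_nx(centroid)
            sub_minimal = candidate.number_of_nodes() < config.min_core_size
            working.remove(centroid_id)
        else:
            candidate, consumed, sub_minimal = find_candidate_mcs(
                centroid, avail_nbrs, config.min_core_size, cache
            )
            members.append(consumed.compound_id)
            working.remove(centroid_id)
            working.remove(consumed.compound_id)

            for cid in list(working):
                rg = by_id[cid]
                g = rg_to_nx(rg)
                if graph_contains(g, candidate):
                    members.append(cid)
                    working.remove(cid)
                    continue
                refined = rg_mcs(g, candidate)
                if (
                    refined.number_of_nodes() >= config.min_core_size
                    and graph_contains(candidate, refined)
                ):
                    candidate = refined
                    members.append(cid)
                    working.remove(cid)

        core = RGCore(
            core_id=len(cores) + 1,
            graph=_canonical_relabel(candidate),
            core_smarts=canonical_graph_smiles(candidate),
            member_ids=members,
            sub_minimal=sub_minimal,
        )
        cores.append(core)
        logger.info(
            "core %d: %s (%d nodes, %d members)",
            core.core_id,
            core.core_smarts,
            len(core),
            len(members),
        )
    return cores
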
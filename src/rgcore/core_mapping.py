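"""Assigning and mapping molecules onto RG cores.

After core extraction a second pass associates every molecule with every
core its RG contains.  A molecule can embed into a core in more than one
way (e.g. two like-labelled nodes hanging off the same linker); such
ambiguous mappings are resolved by comparing topological distance maps
against the maps aggregated from the molecules that map uniquely:

* the *node* distance map holds, for every pair of core nodes, the
  shortest through-bond distance between their atoms in the molecule;
* the *substituent* distance map holds, for every core node, the sorted
  distances to each substitution site (a molecule atom outside the core
  image bonded to an atom inside it).

The resolution cascade prefers a candidate whose node map matches exactly
one reference map, then the candidate matching the most frequent
reference, then the same two steps on substituent maps, and finally a
deterministic fallback (smallest mapped atom image).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
from networkx.algorithms import isomorphism as iso
from rdkit import Chem
from rdkit.Chem import rdmolops

from .core_extraction import RGCore, _edge_match, _node_match
from .rg_builder import ReducedGraph, rg_to_nx

logger = logging.getLogger("rgcore")

__all__ = [
    "CoreMapping",
    "NodeDistanceMap",
    "SubstituentDistanceMap",
    "ResolutionStage",
    "enumerate_mappings",
    "node_distance_map",
    "substituent_distance_map",
    "aggregate_reference_maps",
    "resolve_mapping",
    "assign_all",
]


class ResolutionStage(str, Enum):
    UNIQUE = "unique"
    NODE_MAP = "node_map"
    NODE_MAP_FREQUENCY = "node_map_frequency"
    SUBSTITUENT_MAP = "substituent_map"
    SUBSTITUENT_MAP_FREQUENCY = "substituent_map_frequency"
    FALLBACK = "fallback"


@dataclass
class CoreMapping:
    """One resolved correspondence core node -> molecule RG node."""

    compound_id: str
    core_id: int
    correspondence: dict[int, int]
    ambiguous: bool = False
    resolution_stage: ResolutionStage = ResolutionStage.UNIQUE


@dataclass
class NodeDistanceMap:
    """Shortest through-bond distance for every unordered core-node pair."""

    entries: dict[tuple[int, int], int]
    count: int = 1

    def key(self) -> frozenset:
        return frozenset(self.entries.items())


@dataclass
class SubstituentDistanceMap:
    """Per core node, ascending distances to each substitution site."""

    entries: dict[int, tuple[int, ...]]
    count: int = 1

    def key(self) -> frozenset:
        return frozenset(self.entries.items())


# ---------------------------------------------------------------------------

_MOL_CACHE: dict[str, tuple[Chem.Mol, object]] = {}


def _mol_and_dists(rg: ReducedGraph):
    """Molecule and topological distance matrix for an RG's source SMILES."""
    if rg.smiles not in _MOL_CACHE:
        mol = Chem.MolFromSmiles(rg.smiles)
        if mol is None:
            raise ValueError(f"cannot re-parse SMILES for {rg.compound_id!r}")
        _MOL_CACHE[rg.smiles] = (mol, rdmolops.GetDistanceMatrix(mol))
    return _MOL_CACHE[rg.smiles]


def enumerate_mappings(rg: ReducedGraph, core: RGCore) -> list[CoreMapping]:
    """All embeddings of the core into a molecule's RG.

    Embeddings that differ only by a core automorphism over the same
    molecule-atom image collapse to one canonical candidate; embeddings
    hitting different RG nodes stay distinct.  The returned list is
    canonically ordered (smallest mapped atom image first).
    """
    g = rg_to_nx(rg)
    gm = iso.GraphMatcher(g, core.graph, node_match=_node_match, edge_match=_edge_match)
    by_image: dict[frozenset, dict[int, int]] = {}
    for rg_to_core in gm.subgraph_isomorphisms_iter():
        corr = {c: r for r, c in rg_to_core.items()}
        image = frozenset(corr.values())
        tup = tuple(corr[c] for c in sorted(corr))
        prev = by_image.get(image)
        if prev is None or tup < tuple(prev[c] for c in sorted(prev)):
            by_image[image] = corr

    def image_key(corr: dict[int, int]) -> tuple:
        atoms = sorted(
            a for r in corr.values() for a in rg.nodes[r].atom_indices
        )
        return (tuple(atoms), tuple(corr[c] for c in sorted(corr)))

    return [
        CoreMapping(rg.compound_id, core.core_id, corr)
        for corr in sorted(by_image.values(), key=image_key)
    ]


def node_distance_map(rg: ReducedGraph, mapping: CoreMapping) -> NodeDistanceMap:
    """Minimum bond-path length between every pair of mapped core nodes.

    The distance between two nodes is the shortest distance over atom
    pairs drawn one from each node's atom set in the source molecule.
    """
    _, dmat = _mol_and_dists(rg)
    nodes = sorted(mapping.correspondence)
    entries: dict[tuple[int, int], int] = {}
    for i, ci in enumerate(nodes):
        ai = rg.nodes[mapping.correspondence[ci]].atom_indices
        for cj in nodes[i + 1 :]:
            aj = rg.nodes[mapping.correspondence[cj]].atom_indices
            entries[(ci, cj)] = int(min(dmat[x][y] for x in ai for y in aj))
    return NodeDistanceMap(entries)


def substituent_distance_map(
    rg: ReducedGraph, mapping: CoreMapping
) -> SubstituentDistanceMap:
    """Sorted distances from each core node to every substitution site.

    A substitution site is an atom outside the core image bonded to a
    core-image atom; its distance to a node is the minimum over the
    node's atoms of the through-bond distance to the site atom.
    """
    mol, dmat = _mol_and_dists(rg)
    image_atoms = {
        a
        for r in mapping.correspondence.values()
        for a in rg.nodes[r].atom_indices
    }
    sites = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (i in image_atoms) != (j in image_atoms):
            sites.append(j if j not in image_atoms else i)
    entries: dict[int, tuple[int, ...]] = {}
    for c, r in mapping.correspondence.items():
        atoms = rg.nodes[r].atom_indices
        entries[c] = tuple(
            sorted(int(min(dmat[x][s] for x in atoms)) for s in sites)
        )
    return SubstituentDistanceMap(entries)


def aggregate_reference_maps(
    rgs_by_id: dict[str, ReducedGraph],
    unique_mappings: list[CoreMapping],
) -> tuple[list[NodeDistanceMap], list[SubstituentDistanceMap]]:
    """Unique distance maps with frequency counts over uniquely-mapped
    molecules, in first-seen (dataset) order."""
    node_maps: list[NodeDistanceMap] = []
    sub_maps: list[SubstituentDistanceMap] = []
    for m in unique_mappings:
        rg = rgs_by_id[m.compound_id]
        nd = node_distance_map(rg, m)
        for existing in node_maps:
            if existing.key() == nd.key():
                existing.count += 1
                break
        else:
            node_maps.append(nd)
        sd = substituent_distance_map(rg, m)
        for existing in sub_maps:
            if existing.key() == sd.key():
                existing.count += 1
                break
        else:
            sub_maps.append(sd)
    return node_maps, sub_maps


def _match_stage(candidates, cand_keys, references):
    """Shared logic of the node-map and substituent-map stages.

    Returns (winner, 'unique'), (survivors, 'tie') after frequency
    filtering, or (None, 'none') when no candidate matches a reference.
    """
    ref_by_key = {}
    for ref in references:
        ref_by_key.setdefault(ref.key(), ref)
    matched = [
        (cand, ref_by_key[key])
        for cand, key in zip(candidates, cand_keys)
        if key in ref_by_key
    ]
    if not matched:
        return None, "none"
    if len(matched) == 1:
        return matched[0][0], "unique"
    best_count = max(ref.count for _c, ref in matched)
    survivors = [c for c, ref in matched if ref.count == best_count]
    if len(survivors) == 1:
        return survivors[0], "frequency"
    return survivors, "tie"


def resolve_mapping(
    rg: ReducedGraph,
    candidates: list[CoreMapping],
    references: tuple[list[NodeDistanceMap], list[SubstituentDistanceMap]],
) -> CoreMapping:
    """Pick one mapping out of several via the distance-map cascade."""
    node_refs, sub_refs = references
    pool = list(candidates)

    keys = [node_distance_map(rg, c).key() for c in pool]
    res, how = _match_stage(pool, keys, node_refs)
    if how == "unique":
        return _stamp(res, ResolutionStage.NODE_MAP)
    if how == "frequency":
        return _stamp(res, ResolutionStage.NODE_MAP_FREQUENCY)
    if how == "tie":
        pool = res

    keys = [substituent_distance_map(rg, c).key() for c in pool]
    res, how = _match_stage(pool, keys, sub_refs)
    if how == "unique":
        return _stamp(res, ResolutionStage.SUBSTITUENT_MAP)
    if how == "frequency":
        return _stamp(res, ResolutionStage.SUBSTITUENT_MAP_FREQUENCY)
    if how == "tie":
        pool = res

    # deterministic fallback: candidates are canonically ordered already
    return _stamp(pool[0], ResolutionStage.FALLBACK)


def _stamp(mapping: CoreMapping, stage: ResolutionStage) -> CoreMapping:
    mapping.ambiguous = True
    mapping.resolution_stage = stage
    return mapping


def assign_all(
    rgs: list[ReducedGraph], cores: list[RGCore]
) -> dict[int, list[CoreMapping]]:
    """Second pass: map every molecule onto every core it contains.

    Per core, molecules with a single embedding are registered first and
    their distance maps aggregated; molecules with several embeddings are
    then resolved against those frozen reference maps.  A molecule appears
    under every core its RG contains.
    """
    rgs_by_id = {rg.compound_id: rg for rg in rgs}
    out: dict[int, list[CoreMapping]] = {}
    for core in cores:
        unique: list[CoreMapping] = []
        ambiguous: list[tuple[ReducedGraph, list[CoreMapping]]] = []
        for rg in rgs:
            cands = enumerate_mappings(rg, core)
            if len(cands) == 1:
                unique.append(cands[0])
            elif len(cands) > 1:
                ambiguous.append((rg, cands))
        references = aggregate_reference_maps(rgs_by_id, unique)
        resolved = [resolve_mapping(rg, cands, references) for rg, cands in ambiguous]
        ordered = {m.compound_id: m for m in unique + resolved}
        out[core.core_id] = [
            ordered[rg.compound_id] for rg in rgs if rg.compound_id in ordered
        ]
    return out
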
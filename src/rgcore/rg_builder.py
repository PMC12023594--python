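"""Reduced-graph (RG) generation.

A reduced graph is a summary representation of a molecule in which groups
of atoms collapse to typed nodes: each SSSR ring becomes a ring node,
acyclic hydrogen-bonding groups become HBA/HBD/HBA-HBD nodes, acyclic
heteroatoms and branched acyclic carbons become "complex" nodes, and the
remaining acyclic atoms become inert linker nodes.  Node types are written
with two-letter element codes so an RG can be serialised as a standard
SMILES string:

========================  ====
node type                 code
========================  ====
acyclic inert             Li
acyclic HBA               Ga
acyclic HBD               Gd
acyclic HBA-HBD           Ge
aromatic inert            No
aromatic HBA              Na
aromatic HBD              Nd
aromatic HBA-HBD          Ne
aliphatic inert           Co
aliphatic HBA             Ca
aliphatic HBD             Cd
aliphatic HBA-HBD         Ce
complex                   Hg
========================  ====

Because many substructures reduce to the same node type the mapping from
molecules to RGs is many-to-one; that insensitivity to small substructural
change is what lets RGs group closely related analogues into one series.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
from rdkit import Chem

from .config import RunConfig

__all__ = [
    "RGNode",
    "ReducedGraph",
    "LABEL_TABLE",
    "perceive_functional_groups",
    "perceive_rings",
    "build_raw_nodes",
    "apply_special_rules",
    "merge_nodes",
    "assemble_rg",
    "annotate_substructures",
    "rg_to_nx",
    "parse_rg_smiles",
]

# (structural_class, hbond_class) -> two-letter element code
LABEL_TABLE: dict[tuple[str, str | None], str] = {
    ("acyclic", "inert"): "Li",
    ("acyclic", "HBA"): "Ga",
    ("acyclic", "HBD"): "Gd",
    ("acyclic", "HBA_HBD"): "Ge",
    ("aromatic_ring", "inert"): "No",
    ("aromatic_ring", "HBA"): "Na",
    ("aromatic_ring", "HBD"): "Nd",
    ("aromatic_ring", "HBA_HBD"): "Ne",
    ("aliphatic_ring", "inert"): "Co",
    ("aliphatic_ring", "HBA"): "Ca",
    ("aliphatic_ring", "HBD"): "Cd",
    ("aliphatic_ring", "HBA_HBD"): "Ce",
    ("complex", None): "Hg",
}

_HALOGENS = {9, 17, 35, 53, 85}


@dataclass
class RGNode:
    """One node of a reduced graph.

    ``atom_indices`` is the node's share of the heavy-atom partition; for
    ring nodes ``annotation_atoms`` additionally holds the full SSSR ring
    (a fusion atom is owned by one ring node only, but both fused rings
    annotate with the complete ring substructure).
    """

    node_index: int
    structural_class: str  # acyclic | aromatic_ring | aliphatic_ring | complex
    hbond_class: str | None  # inert | HBA | HBD | HBA_HBD; None for complex
    atom_indices: frozenset[int]
    annotation_atoms: frozenset[int] = field(default=frozenset())
    substructure_smarts: str = ""

    def __post_init__(self) -> None:
        if not self.annotation_atoms:
            self.annotation_atoms = self.atom_indices

    @property
    def label(self) -> str:
        return LABEL_TABLE[(self.structural_class, self.hbond_class)]


@dataclass
class ReducedGraph:
    compound_id: str
    nodes: list[RGNode]
    edges: list[tuple[int, int, int]]  # (node_index, node_index, multiplicity)
    rg_smiles: str = ""
    smiles: str = ""  # source SMILES; atom_indices refer to its atom order

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    def __len__(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------------
# perception


def perceive_functional_groups(
    mol: Chem.Mol, config: RunConfig
) -> dict[int, dict[str, bool]]:
    """Match every atom against the HBA and HBD SMARTS independently.

    Returns ``{atom_idx: {"is_HBA": bool, "is_HBD": bool}}``.  An atom
    matching both patterns has donor *and* acceptor character (HBA-HBD).
    """
    qa = config.hba_query
    qd = config.hbd_query
    hba = {m[0] for m in mol.GetSubstructMatches(qa, maxMatches=mol.GetNumAtoms() + 1)}
    hbd = {m[0] for m in mol.GetSubstructMatches(qd, maxMatches=mol.GetNumAtoms() + 1)}
    return {
        a.GetIdx(): {"is_HBA": a.GetIdx() in hba, "is_HBD": a.GetIdx() in hbd}
        for a in mol.GetAtoms()
    }


def _hbond_class(has_a: bool, has_d: bool) -> str:
    if has_a and has_d:
        return "HBA_HBD"
    if has_a:
        return "HBA"
    if has_d:
        return "HBD"
    return "inert"


def perceive_rings(
    mol: Chem.Mol, fg_flags: dict[int, dict[str, bool]]
) -> list[dict]:
    """One descriptor per SSSR ring.

    A ring is aromatic iff every bond of the ring is aromatic.  Its
    hydrogen-bond class comes from the flags of its member atoms: both
    kinds present (or one HBA-HBD atom) -> HBA_HBD, one kind -> that kind,
    none -> inert.
    """
    ri = mol.GetRingInfo()
    out = []
    for atoms, bonds in zip(ri.AtomRings(), ri.BondRings()):
        aromatic = all(mol.GetBondWithIdx(b).GetIsAromatic() for b in bonds)
        has_a = any(fg_flags[i]["is_HBA"] for i in atoms)
        has_d = any(fg_flags[i]["is_HBD"] for i in atoms)
        out.append(
            {
                "atoms": frozenset(atoms),
                "aromatic": aromatic,
                "hbond_class": _hbond_class(has_a, has_d),
            }
        )
    return out


# ---------------------------------------------------------------------------
# node construction

_NEXT = itertools.count  # not used; node indices assigned at assembly


def _acyclic_carbonyl_carbons(mol: Chem.Mol) -> set[int]:
    """Acyclic carbons double-bonded to an acyclic oxygen (carbonyl rule)."""
    out = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.DOUBLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        for c, o in ((a, b), (b, a)):
            if (
                c.GetAtomicNum() == 6
                and o.GetAtomicNum() == 8
                and not c.IsInRing()
                and not o.IsInRing()
            ):
                out.add(c.GetIdx())
    return out


def _connected_components(mol: Chem.Mol, atoms: set[int]) -> list[frozenset[int]]:
    """Connected components of the induced subgraph on ``atoms``."""
    atoms = set(atoms)
    comps = []
    while atoms:
        seed = min(atoms)
        comp = {seed}
        frontier = [seed]
        while frontier:
            cur = frontier.pop()
            for nb in mol.GetAtomWithIdx(cur).GetNeighbors():
                j = nb.GetIdx()
                if j in atoms and j not in comp:
                    comp.add(j)
                    frontier.append(j)
        atoms -= comp
        comps.append(frozenset(comp))
    return comps


@dataclass
class _ProtoNode:
    """Mutable node used during construction, before index assignment."""

    structural_class: str
    hbond_class: str | None
    atoms: set[int]
    ring_atoms: frozenset[int] | None = None  # full SSSR ring, ring nodes only


def build_raw_nodes(
    mol: Chem.Mol,
    fg_flags: dict[int, dict[str, bool]],
    rings: list[dict],
) -> list[_ProtoNode]:
    """Assign every heavy atom to exactly one node (pre-merge).

    Precedence: SSSR ring nodes first (a fusion atom is owned by the first
    ring that claims it), then connected acyclic hydrogen-bonding groups,
    then acyclic heteroatoms / halogens / branched carbons as single-atom
    complex nodes, then the leftover acyclic atoms as inert nodes.
    """
    nodes: list[_ProtoNode] = []
    assigned: set[int] = set()

    for ring in rings:
        owned = set(ring["atoms"]) - assigned
        nodes.append(
            _ProtoNode(
                "aromatic_ring" if ring["aromatic"] else "aliphatic_ring",
                ring["hbond_class"],
                owned,
                ring_atoms=ring["atoms"],
            )
        )
        assigned |= set(ring["atoms"])

    acyclic = {a.GetIdx() for a in mol.GetAtoms()} - assigned

    hb_atoms = {
        i
        for i in acyclic
        if fg_flags[i]["is_HBA"] or fg_flags[i]["is_HBD"]
    }
    for comp in _connected_components(mol, hb_atoms):
        has_a = any(fg_flags[i]["is_HBA"] for i in comp)
        has_d = any(fg_flags[i]["is_HBD"] for i in comp)
        nodes.append(_ProtoNode("acyclic", _hbond_class(has_a, has_d), set(comp)))
    assigned |= hb_atoms

    for i in sorted(acyclic - hb_atoms):
        atom = mol.GetAtomWithIdx(i)
        heavy_deg = atom.GetDegree()
        if atom.GetAtomicNum() != 6 or (heavy_deg >= 3):
            # heteroatom (incl. halogen) or branched acyclic carbon
            nodes.append(_ProtoNode("complex", None, {i}))
            assigned.add(i)

    for comp in _connected_components(mol, acyclic - assigned):
        nodes.append(_ProtoNode("acyclic", "inert", set(comp)))

    return nodes


def _node_of_atom(nodes: list[_ProtoNode], idx: int) -> _ProtoNode:
    for n in nodes:
        if idx in n.atoms:
            return n
    raise KeyError(idx)


def _reclass_hb(node: _ProtoNode, fg_flags, forced_hba: set[int]) -> None:
    has_a = any(fg_flags[i]["is_HBA"] or i in forced_hba for i in node.atoms)
    has_d = any(fg_flags[i]["is_HBD"] for i in node.atoms)
    node.hbond_class = _hbond_class(has_a, has_d)


def apply_special_rules(
    nodes: list[_ProtoNode],
    mol: Chem.Mol,
    fg_flags: dict[int, dict[str, bool]],
) -> list[_ProtoNode]:
    """Carbonyl and halogen rules.

    (a) An acyclic carbonyl carbon joins its oxygen's acyclic HBA group
        (a carbonyl carbon inside a ring stays with the ring; the exocyclic
        oxygen already forms its own acyclic HBA node).
    (b) An acyclic halogen bonded to an acceptor-bearing acyclic group is
        absorbed into that group, so e.g. an acyl chloride is one node.
    """
    forced_hba: set[int] = set()
    for c_idx in sorted(_acyclic_carbonyl_carbons(mol)):
        c_node = _node_of_atom(nodes, c_idx)
        if c_node.structural_class not in ("acyclic", "complex"):
            continue
        o_idx = next(
            nb.GetIdx()
            for nb in mol.GetAtomWithIdx(c_idx).GetNeighbors()
            if nb.GetAtomicNum() == 8
            and mol.GetBondBetweenAtoms(c_idx, nb.GetIdx()).GetBondType()
            == Chem.BondType.DOUBLE
        )
        o_node = _node_of_atom(nodes, o_idx)
        if o_node is c_node:
            continue
        c_node.atoms.discard(c_idx)
        o_node.atoms.add(c_idx)
        forced_hba.add(c_idx)
        _reclass_hb(o_node, fg_flags, forced_hba)
        if not c_node.atoms:
            nodes.remove(c_node)
        elif c_node.structural_class == "acyclic":
            # removing an atom can disconnect the remainder
            comps = _connected_components(mol, c_node.atoms)
            if len(comps) > 1:
                c_node.atoms = set(comps[0])
                for extra in comps[1:]:
                    nodes.append(
                        _ProtoNode("acyclic", c_node.hbond_class, set(extra))
                    )

    for n in list(nodes):
        if n.structural_class != "complex" or len(n.atoms) != 1:
            continue
        (h_idx,) = n.atoms
        if mol.GetAtomWithIdx(h_idx).GetAtomicNum() not in _HALOGENS:
            continue
        for nb in mol.GetAtomWithIdx(h_idx).GetNeighbors():
            target = _node_of_atom(nodes, nb.GetIdx())
            if (
                target.structural_class == "acyclic"
                and target.hbond_class in ("HBA", "HBA_HBD")
            ):
                target.atoms.add(h_idx)
                nodes.remove(n)
                break
    return nodes


def _adjacent(mol: Chem.Mol, a: _ProtoNode, b: _ProtoNode) -> bool:
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (i in a.atoms and j in b.atoms) or (j in a.atoms and i in b.atoms):
            return True
    return False


def merge_nodes(
    nodes: list[_ProtoNode], mol: Chem.Mol
) -> list[_ProtoNode]:
    """Combine adjoining acyclic nodes until a fixed point.

    Rule order per pass: same-type merge; HBA or HBD subsumed into an
    adjacent HBA-HBD node; inert nodes connected to complex nodes combined
    into one complex node.  Ring nodes are never merged (that would lose
    ring-count information).
    """

    def mergeable(n: _ProtoNode) -> bool:
        return n.structural_class in ("acyclic", "complex")

    changed = True
    while changed:
        changed = False
        # 1. same (structural_class, hbond_class) neighbours
        for a, b in itertools.combinations([n for n in nodes if mergeable(n)], 2):
            if (
                a.structural_class == b.structural_class
                and a.hbond_class == b.hbond_class
                and _adjacent(mol, a, b)
            ):
                a.atoms |= b.atoms
                nodes.remove(b)
                changed = True
                break
        if changed:
            continue
        # 2. HBA / HBD next to HBA-HBD is subsumed
        for a, b in itertools.combinations(
            [n for n in nodes if n.structural_class == "acyclic"], 2
        ):
            pair = {a.hbond_class, b.hbond_class}
            if (
                "HBA_HBD" in pair
                and pair & {"HBA", "HBD"}
                and _adjacent(mol, a, b)
            ):
                keeper = a if a.hbond_class == "HBA_HBD" else b
                other = b if keeper is a else a
                keeper.atoms |= other.atoms
                nodes.remove(other)
                changed = True
                break
        if changed:
            continue
        # 3. acyclic inert + adjoining complex nodes -> one complex node
        for inert in [
            n
            for n in nodes
            if n.structural_class == "acyclic" and n.hbond_class == "inert"
        ]:
            partners = [
                c
                for c in nodes
                if c.structural_class == "complex" and _adjacent(mol, inert, c)
            ]
            if partners:
                merged = set(inert.atoms)
                for c in partners:
                    merged |= c.atoms
                    nodes.remove(c)
                inert.structural_class = "complex"
                inert.hbond_class = None
                inert.atoms = merged
                changed = True
                break
    return nodes


# ---------------------------------------------------------------------------
# assembly


def _canonical_node_order(mol: Chem.Mol, nodes: list[_ProtoNode]) -> list[_ProtoNode]:
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    return sorted(nodes, key=lambda n: min(ranks[i] for i in n.atoms))


def _rg_smiles(nodes: list[RGNode], edges: list[tuple[int, int, int]]) -> str:
    emol = Chem.RWMol()
    for node in nodes:
        atom = Chem.Atom(node.label)
        atom.SetNoImplicit(True)
        emol.AddAtom(atom)
    for i, j, mult in edges:
        emol.AddBond(i, j, Chem.BondType.DOUBLE if mult == 2 else Chem.BondType.SINGLE)
    m = emol.GetMol()
    m.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(m)
    return Chem.MolToSmiles(m, canonical=True)


def parse_rg_smiles(rg_smiles: str) -> nx.Graph:
    """Parse an RG SMILES back into a labelled graph.

    A double bond encodes the multiplicity-2 edge between fused-ring nodes.
    """
    m = Chem.MolFromSmiles(rg_smiles, sanitize=False)
    if m is None:
        raise ValueError(f"unparseable RG SMILES: {rg_smiles!r}")
    g = nx.Graph()
    for atom in m.GetAtoms():
        g.add_node(atom.GetIdx(), label=atom.GetSymbol())
    for bond in m.GetBonds():
        mult = 2 if bond.GetBondType() == Chem.BondType.DOUBLE else 1
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), mult=mult)
    return g


def rg_to_nx(rg: ReducedGraph) -> nx.Graph:
    """Labelled NetworkX view of a reduced graph (edge attr ``mult``)."""
    g = nx.Graph()
    for node in rg.nodes:
        g.add_node(node.node_index, label=node.label)
    for i, j, mult in rg.edges:
        g.add_edge(i, j, mult=mult)
    return g


def assemble_rg(record, config: RunConfig | None = None) -> ReducedGraph:
    """Full molecule -> reduced-graph pipeline.

    ``record`` is a MoleculeRecord (or anything with ``compound_id`` and
    ``smiles``).  Node order is canonical with respect to the molecule, so
    two SMILES of the same structure yield identical graphs.
    """
    config = config or RunConfig()
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {record.compound_id!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ValueError(
            f"{record.compound_id!r}: molecule must be a single fragment "
            "(clean the dataset first)"
        )

    fg = perceive_functional_groups(mol, config)
    rings = perceive_rings(mol, fg)
    proto = build_raw_nodes(mol, fg, rings)
    proto = apply_special_rules(proto, mol, fg)
    proto = merge_nodes(proto, mol)
    proto = _canonical_node_order(mol, proto)

    nodes = [
        RGNode(
            node_index=k,
            structural_class=p.structural_class,
            hbond_class=p.hbond_class,
            atom_indices=frozenset(p.atoms),
            annotation_atoms=p.ring_atoms or frozenset(p.atoms),
        )
        for k, p in enumerate(proto)
    ]

    edges: dict[tuple[int, int], int] = {}
    for bond in mol.GetBonds():
        bi, bj = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        ni = next(n.node_index for n in nodes if bi in n.atom_indices)
        nj = next(n.node_index for n in nodes if bj in n.atom_indices)
        if ni != nj:
            edges[(min(ni, nj), max(ni, nj))] = 1
    for a, b in itertools.combinations(nodes, 2):
        if a.structural_class.endswith("_ring") and b.structural_class.endswith(
            "_ring"
        ):
            if len(a.annotation_atoms & b.annotation_atoms) >= 2:
                edges[
                    (min(a.node_index, b.node_index), max(a.node_index, b.node_index))
                ] = 2

    edge_list = sorted((i, j, m) for (i, j), m in edges.items())
    rg = ReducedGraph(
        compound_id=record.compound_id,
        nodes=nodes,
        edges=edge_list,
        smiles=record.smiles,
    )
    rg.rg_smiles = _rg_smiles(nodes, edge_list)
    annotate_substructures(rg, mol)
    return rg


def annotate_substructures(rg: ReducedGraph, mol: Chem.Mol) -> ReducedGraph:
    """Fill each node's substructure SMARTS.

    The node's atoms are extracted as a fragment; every bond leaving the
    node becomes a wildcard ("*") attachment atom, so substructures with
    different substitution patterns canonicalise to distinct strings.
    Ring nodes annotate with the full SSSR ring even when a fusion atom is
    owned by a neighbouring ring node.
    """
    for node in rg.nodes:
        node.substructure_smarts = _fragment_smiles(mol, node.annotation_atoms)
    return rg


def _fragment_smiles(mol: Chem.Mol, atoms: Iterable[int]) -> str:
    atoms = set(atoms)
    emol = Chem.RWMol(mol)
    dummies = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        for inside, outside in ((i, j), (j, i)):
            if inside in atoms and outside not in atoms:
                d = emol.AddAtom(Chem.Atom(0))
                emol.AddBond(inside, d, Chem.BondType.SINGLE)
                dummies.append(d)
    keep = atoms | set(dummies)
    for idx in sorted(
        (a.GetIdx() for a in emol.GetAtoms() if a.GetIdx() not in keep),
        reverse=True,
    ):
        emol.RemoveAtom(idx)
    frag = emol.GetMol()
    try:
        Chem.SanitizeMol(frag)
    except Exception:
        frag.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(frag)
    return Chem.MolToSmiles(frag, canonical=True)
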
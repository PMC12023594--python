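"""SAR summaries of RG cores.

Once molecules are mapped onto a core, each core node is annotated with
the substructures it represents across the series: the per-node tables
give substructure counts and pIC50 statistics (the Markush/R-group-table
analogue), the pie metadata drives node-as-pie-chart depictions (node
size = number of distinct substructures, segment size = frequency), and
the core table lists unique per-node substructure combinations with the
reassembled connected substructure.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import pandas as pd

from .core_extraction import RGCore
from .core_mapping import CoreMapping, _mol_and_dists
from .rg_builder import ReducedGraph, _fragment_smiles

__all__ = [
    "SubstituentRecord",
    "annotate_core",
    "build_core_table",
    "pie_metadata",
    "overlap_matrix",
    "dataset_summary",
]


@dataclass(frozen=True)
class SubstituentRecord:
    """One substructure observed at one core node position."""

    core_id: int
    node_index: int
    substructure_smarts: str
    count: int
    pic50_median: float
    pic50_mean: float
    pic50_std: float | None  # sample (n-1) std; None for a single molecule


def _mapped_smarts(rg: ReducedGraph, mapping: CoreMapping, node: int) -> str:
    return rg.nodes[mapping.correspondence[node]].substructure_smarts


def annotate_core(
    core: RGCore,
    assignments: dict[int, list[CoreMapping]],
    rg_by_id: dict[str, ReducedGraph],
    rec_by_id: dict[str, object],
) -> list[SubstituentRecord]:
    """Group the core's members by the substructure at each node.

    Records are sorted by node index, then descending count, ties by
    SMARTS lexicographic order.
    """
    out: list[SubstituentRecord] = []
    mappings = assignments.get(core.core_id, [])
    for node in sorted(core.graph.nodes):
        groups: dict[str, list[float]] = {}
        for m in mappings:
            smarts = _mapped_smarts(rg_by_id[m.compound_id], m, node)
            groups.setdefault(smarts, []).append(rec_by_id[m.compound_id].pic50)
        for smarts, acts in sorted(
            groups.items(), key=lambda kv: (-len(kv[1]), kv[0])
        ):
            out.append(
                SubstituentRecord(
                    core_id=core.core_id,
                    node_index=node,
                    substructure_smarts=smarts,
                    count=len(acts),
                    pic50_median=statistics.median(acts),
                    pic50_mean=statistics.fmean(acts),
                    pic50_std=(
                        statistics.stdev(acts) if len(acts) > 1 else None
                    ),
                )
            )
    return out


def _combined_substructure(rg: ReducedGraph, mapping: CoreMapping) -> str:
    """Reassemble the mapped node substructures into one connected
    substructure; remaining wildcards mark onward substitution."""
    mol, _ = _mol_and_dists(rg)
    atoms = {
        a
        for r in mapping.correspondence.values()
        for a in rg.nodes[r].annotation_atoms
    }
    return _fragment_smiles(mol, atoms)


def build_core_table(
    core: RGCore,
    assignments: dict[int, list[CoreMapping]],
    rg_by_id: dict[str, ReducedGraph],
    rec_by_id: dict[str, object],
) -> pd.DataFrame:
    """One row per unique tuple of per-node substructures.

    Multiple molecules can share a row because only core-internal
    variation is keyed; variation beyond the core shows up solely as
    wildcard substitution markers in the combined substructure.
    """
    nodes = sorted(core.graph.nodes)
    rows: dict[tuple, dict] = {}
    for m in assignments.get(core.core_id, []):
        rg = rg_by_id[m.compound_id]
        tup = tuple(_mapped_smarts(rg, m, n) for n in nodes)
        if tup not in rows:
            rows[tup] = {
                **{
                    f"node_{n}_{core.graph.nodes[n]['label']}": s
                    for n, s in zip(nodes, tup)
                },
                "combined_substructure": _combined_substructure(rg, m),
                "molecule_count": 0,
            }
        rows[tup]["molecule_count"] += 1
    df = pd.DataFrame(list(rows.values()))
    if not df.empty:
        df.insert(0, "core_id", core.core_id)
        df = df.sort_values(
            "molecule_count", ascending=False, kind="stable"
        ).reset_index(drop=True)
    return df


def pie_metadata(
    core: RGCore, records: list[SubstituentRecord]
) -> dict[int, dict]:
    """Per-node pie-chart metadata.

    ``size`` is the number of distinct substructures at the node and each
    segment's ``fraction`` is that substructure's share of the members;
    fractions per node sum to one.
    """
    out: dict[int, dict] = {}
    for node in sorted(core.graph.nodes):
        recs = [r for r in records if r.node_index == node]
        total = sum(r.count for r in recs)
        out[node] = {
            "size": len(recs),
            "segments": [
                {
                    "smarts": r.substructure_smarts,
                    "fraction": r.count / total if total else 0.0,
                }
                for r in recs
            ],
        }
    return out


def overlap_matrix(
    cores: list[RGCore], assignments: dict[int, list[CoreMapping]]
) -> pd.DataFrame:
    """Shared-member counts between cores; the diagonal is core size."""
    ids = [c.core_id for c in cores]
    members = {
        c.core_id: {m.compound_id for m in assignments.get(c.core_id, [])}
        for c in cores
    }
    data = [
        [len(members[i] & members[j]) for j in ids]
        for i in ids
    ]
    return pd.DataFrame(
        data,
        index=pd.Index(ids, name="core_id"),
        columns=[str(j) for j in ids],
    )


def dataset_summary(records, rgs: list[ReducedGraph]) -> dict:
    """Dataset-level statistics: molecule count, mean heavy atoms, unique
    RG count and mean nodes per RG / per unique RG."""
    from rdkit import Chem

    if not records:
        return {
            "n_molecules": 0,
            "mean_heavy_atoms": None,
            "n_unique_rgs": 0,
            "mean_nodes_per_rg": None,
            "mean_nodes_per_unique_rg": None,
        }
    heavy = [
        Chem.MolFromSmiles(r.smiles).GetNumHeavyAtoms() for r in records
    ]
    unique: dict[str, int] = {}
    for rg in rgs:
        unique.setdefault(rg.rg_smiles, len(rg))
    return {
        "n_molecules": len(records),
        "mean_heavy_atoms": sum(heavy) / len(heavy),
        "n_unique_rgs": len(unique),
        "mean_nodes_per_rg": sum(len(rg) for rg in rgs) / len(rgs),
        "mean_nodes_per_unique_rg": sum(unique.values()) / len(unique),
    }
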
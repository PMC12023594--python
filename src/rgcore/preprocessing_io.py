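"""Dataset input, cleaning and results output.

Input is a delimited text file (CSV/TSV with a header, or a .smi file with
whitespace-separated SMILES and ID columns) carrying a SMILES string, a
compound identifier and a pIC50 value per record.  Cleaning keeps the
largest fragment of each structure, neutralises formal charges where a
neutral valence-consistent form exists, drops records without an activity
value and removes exact structural duplicates.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .config import ConfigurationError

logger = logging.getLogger("rgcore")

__all__ = [
    "MoleculeRecord",
    "EmptyDatasetError",
    "read_dataset",
    "clean_dataset",
    "export_results",
]


class EmptyDatasetError(ValueError):
    """The input file contains no molecule records."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One input compound: identifier, (cleaned) SMILES and pIC50.

    pIC50 is the negative decadic logarithm of the molar IC50; ``None``
    marks a missing activity, and such records are removed by
    :func:`clean_dataset`.
    """

    compound_id: str
    smiles: str
    pic50: float | None


def read_dataset(
    path: str | Path,
    id_col: str = "id",
    smiles_col: str = "smiles",
    activity_col: str = "pic50",
) -> list[MoleculeRecord]:
    """Read molecule records from ``path``, preserving file order.

    Unparseable SMILES are skipped with a logged warning; records with an
    empty activity cell are kept (with ``pic50=None``) for
    :func:`clean_dataset` to drop.
    """
    path = Path(path)
    if path.suffix.lower() in (".smi", ".smiles"):
        df = pd.read_csv(
            path, sep=r"\s+", header=None, names=[smiles_col, id_col], comment="#"
        )
        df[activity_col] = math.nan
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep)
        missing = {id_col, smiles_col, activity_col} - set(df.columns)
        if missing:
            raise ConfigurationError(
                f"column(s) {sorted(missing)} not found in {path.name}; "
                f"available: {list(df.columns)}"
            )
    if df.empty:
        raise EmptyDatasetError(f"{path} contains no records")

    records: list[MoleculeRecord] = []
    for row in df.itertuples(index=False):
        smiles = str(getattr(row, smiles_col))
        cid = str(getattr(row, id_col))
        if Chem.MolFromSmiles(smiles) is None:
            logger.warning("skipping %s: unparseable SMILES %r", cid, smiles)
            continue
        raw = getattr(row, activity_col)
        pic50 = None if pd.isna(raw) else float(raw)
        records.append(MoleculeRecord(cid, smiles, pic50))
    if not records:
        raise EmptyDatasetError(f"{path}: no parseable records")
    return records


# -- neutralisation ---------------------------------------------------------
# Pattern-based neutralisation: protonate negatively charged atoms and
# deprotonate positively charged atoms that carry hydrogens, skipping atoms
# whose charge is balanced by a charged neighbour (e.g. nitro, N-oxide).
_NEUTRALISE_PATTERN = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)


def _neutralise(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.Mol(mol)
    at_matches = mol.GetSubstructMatches(_NEUTRALISE_PATTERN)
    if at_matches:
        for (idx,) in at_matches:
            atom = mol.GetAtomWithIdx(idx)
            chg = atom.GetFormalCharge()
            hcount = atom.GetTotalNumHs()
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(hcount - chg)
            atom.UpdatePropertyCache()
    return mol


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return max(frags, key=lambda f: f.GetNumHeavyAtoms())


def clean_dataset(records: list[MoleculeRecord]) -> list[MoleculeRecord]:
    """Salt-strip, neutralise, drop missing activities, deduplicate.

    For each record the largest fragment by heavy-atom count is kept and
    neutralised; records without a pIC50 are dropped; exact duplicates
    (identical canonical SMILES after cleaning) keep the first occurrence.
    Output order is a subsequence of input order and the operation is
    idempotent.
    """
    out: list[MoleculeRecord] = []
    seen_smiles: set[str] = set()
    seen_ids: set[str] = set()
    for rec in records:
        if rec.pic50 is None or (
            isinstance(rec.pic50, float) and math.isnan(rec.pic50)
        ):
            logger.info("dropping %s: no pIC50", rec.compound_id)
            continue
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            logger.warning("dropping %s: unparseable SMILES", rec.compound_id)
            continue
        mol = _largest_fragment(mol)
        Chem.SanitizeMol(mol)
        mol = _neutralise(mol)
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen_smiles:
            logger.info("dropping %s: duplicate structure", rec.compound_id)
            continue
        if rec.compound_id in seen_ids:
            logger.warning("dropping %s: duplicate compound id", rec.compound_id)
            continue
        seen_smiles.add(canonical)
        seen_ids.add(rec.compound_id)
        out.append(MoleculeRecord(rec.compound_id, canonical, float(rec.pic50)))
    return out


def export_results(cores, assignments, rgs, records, out_dir: str | Path) -> None:
    """Write the results bundle under ``out_dir``.

    Per core: ``core_<k>.json`` (node substituent tables + pie metadata)
    and ``core_<k>_table.csv`` (combined-substructure rows); plus
    ``core_overlap.csv`` and ``dataset_summary.csv``.
    """
    from . import sar_tables  # deferred: sar_tables imports nothing from here

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summary = sar_tables.dataset_summary(records, rgs)
    pd.DataFrame([summary]).to_csv(out_dir / "dataset_summary.csv", index=False)

    if cores:
        overlap = sar_tables.overlap_matrix(cores, assignments)
        overlap.to_csv(out_dir / "core_overlap.csv")

    rg_by_id = {rg.compound_id: rg for rg in rgs}
    rec_by_id = {r.compound_id: r for r in records}
    for core in cores:
        recs = sar_tables.annotate_core(core, assignments, rg_by_id, rec_by_id)
        pies = sar_tables.pie_metadata(core, recs)
        doc = {
            "core_id": core.core_id,
            "core_smarts": core.core_smarts,
            "n_members": len(assignments.get(core.core_id, [])),
            "nodes": [
                {
                    "node_index": idx,
                    "label": core.graph.nodes[idx]["label"],
                    "substructures": [
                        {
                            "smarts": r.substructure_smarts,
                            "count": r.count,
                            "pic50_median": r.pic50_median,
                            "pic50_mean": r.pic50_mean,
                            "pic50_std": r.pic50_std,
                        }
                        for r in recs
                        if r.node_index == idx
                    ],
                    "pie": pies[idx],
                }
                for idx in sorted(core.graph.nodes)
            ],
        }
        with open(out_dir / f"core_{core.core_id}.json", "w") as fh:
            json.dump(doc, fh, indent=2)

        table = sar_tables.build_core_table(core, assignments, rg_by_id, rec_by_id)
        table.to_csv(out_dir / f"core_{core.core_id}_table.csv", index=False)
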
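"""Synthetic lead-optimisation series with known ground truth.

Real LO datasets are hundreds of analogues enumerated around a handful of
scaffolds.  :func:`make_series` emulates that: a scaffold SMILES carries
numbered attachment points (``[*:1]``, ``[*:2]``, ...) and every
combination of the supplied substituents is enumerated onto them, so the
common scaffold — and therefore the expected RG core — is known by
construction rather than inferred.  All generators are pure functions of
their arguments and seed.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass, field

from rdkit import Chem

from .preprocessing_io import MoleculeRecord

logger = logging.getLogger("rgcore")

__all__ = ["FixtureSeries", "make_series", "make_ambiguous_pair_series", "demo_dataset"]


@dataclass
class FixtureSeries:
    name: str
    records: list[MoleculeRecord]
    expected_core_smarts: str | None = None
    expected_member_count: int = 0
    # populated by make_ambiguous_pair_series only
    ambiguous_id: str | None = None
    expected_node_map: dict | None = None

    def __post_init__(self) -> None:
        if not self.expected_member_count:
            self.expected_member_count = len(self.records)


def _attach(scaffold: Chem.Mol, parts: tuple[str, ...]) -> str | None:
    """Zip substituent fragments (each with one ``*``) onto the scaffold's
    numbered attachment points."""
    combo = Chem.RWMol(scaffold)
    for k, frag_smiles in enumerate(parts, start=1):
        frag = Chem.MolFromSmiles(frag_smiles)
        if frag is None:
            return None
        frag = Chem.RWMol(frag)
        dummies = [a for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            raise ValueError(
                f"substituent {frag_smiles!r} must have exactly one '*'"
            )
        dummies[0].SetAtomMapNum(k)
        combo.InsertMol(frag)
    try:
        zipped = Chem.molzip(combo)
        Chem.SanitizeMol(zipped)
    except Exception:
        return None
    return Chem.MolToSmiles(zipped)


def make_series(
    scaffold_smiles: str,
    substituents: list[str],
    activities: list[float],
    seed: int = 0,
    name: str = "series",
    expected_core_smarts: str | None = None,
) -> FixtureSeries:
    """Enumerate scaffold x substituent combinations deterministically.

    ``scaffold_smiles`` carries ``[*:1]``..``[*:n]`` attachment markers and
    each substituent one plain ``*``.  The cartesian product over the
    markers is enumerated in order, activities are drawn cyclically, and
    the seed only shuffles record order (series membership is unaffected).
    Combinations that fail valence on attachment are skipped with a warning.
    """
    scaffold = Chem.MolFromSmiles(scaffold_smiles)
    if scaffold is None:
        raise ValueError(f"unparseable scaffold {scaffold_smiles!r}")
    n_sites = sum(1 for a in scaffold.GetAtoms() if a.GetAtomicNum() == 0)
    if n_sites == 0:
        raise ValueError("scaffold has no attachment markers")
    if not substituents or not activities:
        raise ValueError("substituents and activities must be non-empty")

    records = []
    k = 0
    for parts in itertools.product(substituents, repeat=n_sites):
        smiles = _attach(scaffold, parts)
        if smiles is None:
            logger.warning("%s: skipping invalid combination %s", name, parts)
            continue
        records.append(
            MoleculeRecord(
                f"{name}-{k:03d}", smiles, float(activities[k % len(activities)])
            )
        )
        k += 1
    random.Random(seed).shuffle(records)
    return FixtureSeries(
        name=name,
        records=records,
        expected_core_smarts=expected_core_smarts,
    )


def make_ambiguous_pair_series(seed: int = 0) -> FixtureSeries:
    """A series whose core maps ambiguously into one member.

    Most members are benzylic alcohols with a halide ring substituent
    (RG ``[Ge][Li][No][Hg]``); the odd one out carries a second hydroxyl
    on a longer tether (RG ``[Ge][Li][No][Li][Ge]``), so the shared
    ``[Ge][Li][No]`` core embeds into it twice.  By construction every
    uniquely-mapped member places the hydroxyl two bonds from the ring,
    which is exactly the node distance map of the intended (benzylic)
    mapping: resolution must pick it at the node-map stage.
    """
    unique = make_series(
        "OCc1ccc(cc1)[*:1]",
        ["*Cl", "*Br", "*F", "*I"],
        [5.0, 5.5, 6.0, 6.5],
        seed=seed,
        name="amb-u",
    )
    ambiguous = MoleculeRecord("amb-x", "OCc1ccc(CCO)cc1", 7.0)
    records = unique.records + [ambiguous]
    return FixtureSeries(
        name="ambiguous-pair",
        records=records,
        expected_core_smarts="[Ge][Li][No]",
        ambiguous_id="amb-x",
        # shortest O..ring distance of the intended benzylic mapping
        expected_node_map={"Ge-No": 2},
    )


def demo_dataset(seed: int = 0) -> list[MoleculeRecord]:
    """A small multi-series LO-style dataset for demos and end-to-end runs.

    Three scaffold families — halogenated benzamides, aryl-piperidine
    amides and benzyl pyridyl ethers — each enumerated over a substituent
    panel, mirroring a programme that explored several related series.
    """
    rng = random.Random(seed)
    series = [
        make_series(
            "NC(=O)Cc1ccc([*:1])c([*:2])c1",
            ["*Cl", "*Br", "*F", "*C(F)(F)F"],
            [round(5.0 + 0.2 * i, 2) for i in range(16)],
            seed=seed,
            name="benzamide",
        ),
        make_series(
            "O=C(CC1CCNCC1)Nc1ccc([*:1])cc1[*:2]",
            ["*Cl", "*F", "*C", "*OC"],
            [round(6.0 + 0.15 * i, 2) for i in range(16)],
            seed=seed + 1,
            name="pipamide",
        ),
        make_series(
            "c1ccncc1COc1ccc([*:1])cc1",
            ["*Cl", "*Br", "*C", "*CC", "*OC", "*N(C)C"],
            [round(4.5 + 0.3 * i, 2) for i in range(6)],
            seed=seed + 2,
            name="ether",
        ),
    ]
    records = [r for s in series for r in s.records]
    rng.shuffle(records)
    return records
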
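"""Run configuration: similarity threshold, core size and SMARTS definitions."""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

# Default hydrogen-bond perception patterns.  The acceptor pattern takes any
# neutral non-carbon atom and excludes halogens, aromatic O/S, trisubstituted
# aromatic N and hypervalent N/P/S; the donor pattern is any non-carbon atom
# carrying at least one hydrogen.
DEFAULT_HBA_SMARTS = "[$([!#6;+0]);!$([F,Cl,Br,I]);!$([o,s,nX3]);!$([Nv5,Pv5,Sv4,Sv6])]"
DEFAULT_HBD_SMARTS = "[!#6;!H0]"


class ConfigurationError(ValueError):
    """Invalid run parameters (bad SMARTS, missing column, ...)."""


@dataclass
class RunConfig:
    """Parameters of one run.

    similarity_threshold : float in [0, 1]
        Graph-Tanimoto cut-off used to build near-neighbour lists.
    min_core_size : int >= 2
        Minimum number of nodes an RG core should have.
    hba_smarts, hbd_smarts : str
        Atom-level SMARTS for acceptor / donor perception.

    The defaults (threshold 0.5, minimum size 5) are the operating point
    used for the P2X7 case study.
    """

    similarity_threshold: float = 0.5
    min_core_size: int = 5
    hba_smarts: str = DEFAULT_HBA_SMARTS
    hbd_smarts: str = DEFAULT_HBD_SMARTS

    def __post_init__(self) -> None:
        if not (0.0 <= self.similarity_threshold <= 1.0):
            raise ConfigurationError(
                f"similarity_threshold must be in [0, 1], got "
                f"{self.similarity_threshold}"
            )
        if self.min_core_size < 2:
            raise ConfigurationError(
                f"min_core_size must be >= 2, got {self.min_core_size}"
            )
        self.hba_query = Chem.MolFromSmarts(self.hba_smarts)
        self.hbd_query = Chem.MolFromSmarts(self.hbd_smarts)
        if self.hba_query is None:
            raise ConfigurationError(f"invalid HBA SMARTS: {self.hba_smarts!r}")
        if self.hbd_query is None:
            raise ConfigurationError(f"invalid HBD SMARTS: {self.hbd_smarts!r}")
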
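# rgcore

Reduced-graph series detection and SAR tables for lead-optimisation
datasets.

## What it does

Lead-optimisation (LO) programmes produce hundreds of analogues built
around a handful of scaffolds. The usual way to review them — a Markush
structure with an R-group table — keys the series on an exact common
substructure, so a small scaffold change splits the SAR across several
tables. `rgcore` organises a compound set at the **reduced-graph** level
instead: each molecule collapses to a typed summary graph (RG) whose
nodes are rings, hydrogen-bonding groups, complex groups and inert
linkers; a maximum-common-subgraph procedure then finds **RG cores** —
connected RG subgraphs shared by subsets of the data — which act as
series definitions that tolerate small substructural change (Cl vs Br
vs CF3, pyrrolidine vs imidazole, ...). Every molecule is mapped onto
every core it contains (ambiguous mappings are resolved with topological
distance maps), and per-position substructure frequencies with pIC50
statistics are tabulated.

Node labels use elements uncommon in organic molecules so an RG is a
valid SMILES: `Li` acyclic inert, `Ga`/`Gd`/`Ge` acyclic HBA/HBD/both,
`No`/`Na`/`Nd`/`Ne` aromatic rings, `Co`/`Ca`/`Cd`/`Ce` aliphatic rings,
`Hg` complex. Similarity between RGs A and B is the graph Tanimoto

    T = MCS / (A + B − MCS)

with A, B and MCS counted in nodes, and the MCS computed exactly
(connected, label- and edge-multiplicity-matched). See
[docs/methods.md](docs/methods.md) for the full construction rules,
the core-extraction loop and the mapping-resolution cascade.

## Worked example

```python
from rgcore import MoleculeRecord, RunConfig, assemble_rg, extract_cores, assign_all
from rgcore.sar_tables import annotate_core

records = [
    MoleculeRecord("m1", "NC(=O)Cc1ccc(Cl)cc1", 5.2),
    MoleculeRecord("m2", "NC(=O)Cc1ccc(Br)cc1", 5.9),
    MoleculeRecord("m3", "NC(=O)Cc1ccc(C(F)(F)F)cc1", 6.4),
    MoleculeRecord("m4", "CNC(=O)Cc1ccc(Cl)cc1", 6.0),
]
cfg = RunConfig(similarity_threshold=0.5, min_core_size=4)
rgs = [assemble_rg(r, cfg) for r in records]
print([rg.rg_smiles for rg in rgs])
# ['[Ge][Li][No][Hg]', '[Ge][Li][No][Hg]', '[Ge][Li][No][Hg]', '[Li][Ge][Li][No][Hg]']

cores = extract_cores(rgs, cfg)
print(cores[0].core_smarts, cores[0].member_ids)
# [Ge][Li][No][Hg] ['m1', 'm4', 'm2', 'm3']

assignments = assign_all(rgs, cores)
for r in annotate_core(cores[0], assignments,
                       {g.compound_id: g for g in rgs},
                       {r.compound_id: r for r in records}):
    print(r.node_index, r.substructure_smarts, r.count,
          round(r.pic50_median, 2), round(r.pic50_mean, 2))
# 0 *C(N)=O      3 5.9  5.83
# 0 *NC(*)=O     1 6.0  6.0
# 1 *Cl          2 5.6  5.6
# 1 *Br          1 5.9  5.9
# 1 *C(F)(F)F    1 6.4  6.4
# 2 *C*          4 5.95 5.88
# 3 *c1ccc(*)cc1 4 5.95 5.88
```

The three halide analogues share the RG `[Ge][Li][No][Hg]`
(amide – CH2 – phenyl – halogen-type group); the N-methyl analogue has
one extra node but contains the same core, so all four land in one
series. The table shows, per core node, which substructures occur, how
often, and the activity of the molecules carrying them: the `Hg`
position has been varied (Cl, Br, CF3, with CF3 the most potent), the
amide position splits by substitution pattern (plain vs N-methylated),
and the linker and phenyl are invariant.

## Command line

```bash
rgcore run --input data.csv --id-col id --smiles-col smiles \
           --activity-col pic50 --threshold 0.5 --min-core-size 5 \
           --out results/ [--fg-defs smarts.yaml]
rgcore sweep --input data.csv --thresholds 0.1:0.9:0.1 --min-sizes 2:7 --out grid.csv
rgcore demo  --out demo-results/ --seed 0
```

`run` writes one JSON (substituent tables + pie metadata) and one CSV
(unique substructure combinations) per core, a core-overlap matrix and a
dataset summary. `--fg-defs` takes a YAML file with `HBA:`/`HBD:` SMARTS
to override the bundled hydrogen-bond definitions. Logs go to stderr;
machine outputs only under `--out`.

`scripts/fetch_chembl_p2x7.py` is an optional convenience script that
downloads a published P2X7-antagonist LO dataset from ChEMBL (network
required; nothing in the package or tests depends on it).

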
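# Methods

## The problem

Lead-optimisation (LO) datasets contain hundreds of analogues enumerated
around a few scaffolds. Classical Markush/R-group decomposition keys the
series on an exact common substructure, so a small scaffold change (an
extra methylene, a swapped heteroring) starts a "new" series and
fragments the SAR picture. This package organises such datasets at the
**reduced-graph (RG)** level instead: atoms collapse into typed nodes
(ring / acyclic, donor / acceptor / inert / complex), so different
substructures with the same pharmacophoric shape reduce to the same node
and closely related scaffolds land in one series.

## Reduced-graph construction

Per molecule (sanitised, single fragment):

1. **Functional-group perception.** Every atom is matched independently
   against an HBA and an HBD SMARTS. Defaults:
   `[$([!#6;+0]);!$([F,Cl,Br,I]);!$([o,s,nX3]);!$([Nv5,Pv5,Sv4,Sv6])]`
   (acceptor) and `[!#6;!H0]` (donor). An atom matching both is HBA-HBD.
   Both patterns are user-replaceable via a YAML definitions file.
2. **Ring perception.** One node per SSSR ring (RDKit's ring model;
   recorded in output metadata). A ring is aromatic iff all its bonds
   are aromatic; its H-bond class is derived from member-atom flags.
   A fusion atom is *owned* by the first ring in SSSR order (the
   heavy-atom partition is strict), but both rings annotate their
   substructure with the full ring so aromatic fragments stay intact.
3. **Acyclic nodes.** Connected groups of H-bond-flagged acyclic atoms
   become HBA / HBD / HBA-HBD nodes; remaining acyclic heteroatoms
   (halogens included) and acyclic carbons with ≥ 3 heavy neighbours
   become single-atom *complex* nodes; what is left becomes inert
   linker nodes.
4. **Special rules.** (a) An acyclic carbonyl carbon joins its oxygen's
   acceptor node (one node for an amide C(=O)N after merging); if the
   carbonyl carbon is in a ring, the exocyclic oxygen forms its own
   acyclic HBA node. (b) An acyclic halogen bonded to an
   acceptor-bearing acyclic node is absorbed into it (acyl halides are
   one node).
5. **Merging, to a fixed point, in order:** same-type neighbours
   combine; an HBA or HBD node adjacent to an HBA-HBD node is subsumed
   by it; inert nodes touching complex nodes fuse into one complex
   node. Ring nodes never merge — that would erase ring counts. The
   order is part of the contract and is tested (it reproduces e.g.
   `[Ge][Li][No]([Hg])[Hg]` for di-halogenated benzamides).
6. **Edges.** Nodes joined by ≥ 1 bond get an edge; two ring nodes
   sharing ≥ 2 atoms (fused) get multiplicity 2. The RG is serialised
   as canonical SMILES over the two-letter node codes (Li, Ga, Gd, Ge,
   No, Na, Nd, Ne, Co, Ca, Cd, Ce, Hg); the multiplicity-2 edge is
   written as a double bond (`[No]=[No]` for naphthalene) because
   SMILES cannot carry two parallel single bonds between one atom pair.
   The edge list is authoritative; the SMILES is a serialisation that
   round-trips through `parse_rg_smiles`.

Node order is canonicalised through RDKit atom ranks, so the same
structure gives an identical RG regardless of input atom numbering
(property-tested by permuting atoms). Stereo descriptors are preserved
in the stored SMILES and node substructure annotations (so an R- and an
S-ring count as distinct substituents), but RG node typing itself is
stereo-blind.

## Core extraction

Similarity between two RGs is the graph Tanimoto
`T = MCS / (A + B − MCS)` over node counts. The MCS is the maximum
connected common induced subgraph under exact label and
edge-multiplicity match, computed exactly: connected subsets of the
smaller graph are enumerated (ESU enumeration, largest first) and
tested for embedding into the larger graph with VF2. Ties between
equal-sized MCSs are broken by the lexicographically smallest canonical
serialisation, making the whole pipeline bit-reproducible. RG graphs
are small (≲ 15 nodes) and tree-like, so exact search is cheap; MCS
results are cached per unordered RG-SMILES pair.

Cores are found iteratively: the unprocessed molecule with the most
near neighbours (T ≥ threshold; ties to earliest input position) seeds
a candidate MCS starting from its *most distant* neighbour, accepting
the first MCS of at least `min_core_size` nodes (otherwise the largest
found, flagged sub-minimal). Every remaining molecule in list order
then either contains the candidate (it joins and leaves the list) or
proposes MCS(molecule, candidate) as a refinement, accepted only if it
stays a subgraph of the candidate and keeps the minimum size. The
candidate becomes a core; rounds repeat until the list empties, so
every molecule belongs to at least one core. A molecule whose
neighbours are exhausted becomes a singleton core of its entire RG —
the procedure is silent on this case and this choice guarantees
termination and full coverage.

Defaults: similarity threshold **0.5**, minimum core size **5**
(`RunConfig`). The bundled demo and tests use minimum size 3–4 because
the synthetic molecules are smaller than typical LO compounds.

## Mapping and ambiguity resolution

A second pass associates each molecule with *every* core its RG
contains (extraction order can make the first pass miss some).
Embeddings are enumerated with VF2; embeddings differing only by a core
automorphism over the same atom image collapse to one candidate.

Ambiguous molecules (≥ 2 candidates) are resolved against the
uniquely-mapped members:

* **Node distance map** — for every core-node pair, the shortest
  through-bond distance between their atom sets in the molecule.
* **Substituent distance map** — for every core node, the ascending
  distances to each substitution site. A site is an atom outside the
  core image bonded to an atom inside it; distances are measured to
  that external atom (the reference atom of a site is otherwise
  undefined — any fixed convention works since maps are only ever
  compared with each other).

Maps from uniquely-mapped molecules are aggregated with frequency
counts (reference maps are frozen before any ambiguous molecule is
resolved). The cascade picks: the single candidate whose node map
matches a reference; else the matching candidate with the most frequent
reference; else the same two steps on substituent maps; else a
deterministic fallback — the candidate with the lexicographically
smallest mapped atom image. The stage that decided is recorded per
mapping (`unique`, `node_map`, ..., `fallback`), and resolution is
invariant under candidate-order permutation (tested).

## SAR outputs

Per core: per-node substructure tables (count, pIC50 median / mean /
sample-std; std is NA for a single molecule), pie metadata (node size =
distinct substructure count, segment fraction = count / members,
fractions sum to 1 within 1e-9), a core table with one row per unique
per-node substructure tuple plus a combined substructure, the core
overlap matrix, and a dataset summary (molecules, mean heavy atoms,
unique RGs, mean nodes per RG and per unique RG). The combined
substructure is produced by extracting a representative molecule's
core-image atoms with wildcard attachment points — equivalent to
stitching the per-node fragments along core edges but robust to
wildcard bookkeeping. All outputs are CSV/JSON; depiction and
interactive charting are front-end concerns outside this package.

## Synthetic data

`rgcore.fixtures` generates test series the way LO programmes produce
them: a scaffold with numbered attachment points crossed with a
substituent panel, activities assigned cyclically, record order
shuffled by the seed (membership is seed-independent). The bundled
demo dataset combines three families — halogenated benzamides,
aryl-piperidine amides, benzyl pyridyl ethers — of 38 molecules total,
a deliberately small size that keeps exhaustive-oracle cross-checks
fast. `make_ambiguous_pair_series` engineers the ambiguous-mapping
case: benzylic alcohols with ring halides plus one bis-hydroxyl
molecule whose `[Ge][Li][No]` core embeds twice, with the intended
(benzylic) mapping known by construction.

What the generator does *not* emulate: activity cliffs and realistic
pIC50 noise, series-size imbalance at real scale (hundreds per core),
stereo-rich scaffolds, tautomer/protomer ambiguity, and the messiness
of curated public data. Passing tests demonstrate the algorithmic
contracts — partition, determinism, exact MCS, resolution — not
field performance on a real LO programme.

## Numerical and degenerate-case choices

* Duplicate molecules: canonical-SMILES equality after cleaning; first
  occurrence wins. Cleaning is idempotent and order-preserving.
* Empty datasets, single-molecule datasets, single-node cores and
  molecules equal to their core all have defined, tested behaviour
  (empty maps / full-fraction segments rather than errors).
* All tie-breaks (centroid choice, neighbour order, MCS choice,
  candidate order, fallback mapping) are deterministic and documented
  at the point of use; there is no randomness anywhere in the pipeline
  itself — seeds only shuffle synthetic input order.

## Limitations

* The MCS is exact but exponential in the worst case; RGs of highly
  fused polycycles with many like-labelled nodes would slow it down.
* Only the main resolution cascade is implemented; rare ties that fall
  through both map stages end at the deterministic fallback and are
  flagged as such rather than resolved by deeper structural criteria.
* Ring perception inherits RDKit's SSSR and aromaticity models;
  alternative ring bases would shift node boundaries for bridged
  systems.
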
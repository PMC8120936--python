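# pairpot

Trainable, representation-configurable distance-dependent statistical
scoring of protein structure models, with a built-in evaluation protocol
(TM-score ground truth, pairwise ranking accuracy, correlation averaging,
rank statistics) and a seeded synthetic-structure generator so everything is
testable offline.

Two scoring formalisms are provided over the same trained models:

- **PMF** — negative log-likelihood ratio of pair distances under a
  conditional model M1 (one binned KDE distance distribution per
  residue/site pair class) versus a reference model M2 (pooled over a prior
  representation), summed over all site pairs within 15 Å and at sequence
  separation ≥ 3. Lower is more native-like.
- **TIG** — the same pipeline with the log-likelihood ratio replaced by a
  negated relative difference, preserving the "lower is better" orientation.

Ten structural representations are supported: `CA`, `CB`, `CA_CB`,
`BACKBONE`, `BACKBONE_CB`, `SIDECHAINS`, `ALL_ATOM` plus the coarse-grained
`BB`, `SC`, `BB_SC` (MARTINI-style backbone/side-chain beads at centroids of
fixed atom groups). In CB-containing representations glycine is represented
by its Cα by default (`--glycine substitute_ca`) or excluded. The reference
state is trained on the all-atom (or all-bead) projection by default
(`all_atom_prior`) or on the representation's own pairs
(`representation_prior`).

## Command line

All functionality is reachable through the `pairpot` entry point:

```sh
# generate synthetic fixtures (PDB files + manifest TSV)
pairpot simulate trainset --out train/ --n-chains 50 --n-residues 60 --seed 1
pairpot simulate ladder   --out decoys/ --n-residues 40 --sigmas 0.5,1,2,4,8 --seed 2

# train a potential (defaults: 17 A training / 15 A scoring cutoffs,
# 0.5 A bins, separation >= 3)
pairpot train train/train_*.pdb --rep CB --glycine substitute_ca \
    --reference all_atom -o model.json

# score structures (TSV: file, score, n_pairs)
pairpot score --model model.json --formalism pmf decoys/*.pdb -o scores.tsv

# TM-score against a native (TSV: model, tm, category)
pairpot tmscore decoys/s*.pdb --native decoys/native.pdb

# full evaluation over a scored decoy table (+ optional per-class subsets)
pairpot benchmark --scores table.tsv --labels cath.tsv -o report.json
```

A TOML config file can supply any `train` option (`--config run.toml`);
explicit flags win. Outputs carry a provenance header (version, config
hash, seed) and are byte-reproducible for a fixed seed.

## Library layout

| module                  | contents                                                             |
| ----------------------- | -------------------------------------------------------------------- |
| `pairpot.structure_io`  | heavy-atom `Chain`/`Residue`/`Atom` model, PDB read/write            |
| `pairpot.representation`| the ten projections, bead table, pair-class enumeration              |
| `pairpot.potential`     | pair collection, Scott-bandwidth KDE fitting, training, PMF/TIG      |
| `pairpot.similarity`    | Kabsch superposition, TM-score, quality categories                   |
| `pairpot.benchmark`     | decoy tables, pairwise accuracy, correlations, ranks, Wilcoxon       |
| `pairpot.fixtures`      | seeded synthetic chains, training sets, graded decoy ladders         |
| `pairpot.cli`           | the `pairpot` command                                                |

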
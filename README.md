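# mpbind

Residue-level, multitask protein binding-site prediction. The package
labels residues of a protein chain by whether they contact five categories
of partners (other proteins, DNA/RNA, ligands, ions, lipids), builds
residue graphs with sequence- and structure-derived features, and trains an
E(3)-equivariant graph neural network with per-task sigmoid heads.

Pipeline stages:

1. **structure_io** — mmCIF/PDB parsing (first model), cleaning (H/D atoms,
   water/heavy water, first-altloc rule), classification of entities
   against a 79-molecule registry (20 amino acids / 8 nucleotides /
   16 ions / 31 ligands / 4 lipids), per-residue virtual atoms
   {N, C, CA, O, R} where R is the side-chain centroid.
2. **labeling** — heavy-atom contacts at 5 Å (inclusive), the 20×79
   interface-type matrix, five per-residue binary task labels, and a
   dataset filter (≤ 8192 atoms, ≥ 48 residues).
3. **graph_features** — residue graph with a 15 Å Cα cutoff; node features
   L×2247 (two 1024-dim embedding blocks, 9-dim secondary structure + RSA,
   160-dim geometric, 30-dim atomic); edge features E×450 (400 RBF-encoded
   virtual-atom distances, 30 frame-local directions, 4-dim orientation
   quaternion, 16-dim positional encoding). Embedding providers are
   pluggable: a deterministic stub (used throughout the tests) or
   precomputed HDF5/NPZ matrices from external protein language models.
4. **nn** — four-layer EGNN + five MLP heads, implemented on a small
   reverse-mode autograd engine over NumPy (no deep-learning framework
   required). Predictions are invariant to global rotations/translations.
5. **train_eval** — BCE loss, Adam (lr 0.001), best-model selection on
   validation loss; AUROC/AUPRC/accuracy at threshold 0.5.
6. **proteome_overlap** — overlap proportions between annotated residue
   feature spans and predicted sites, with pLDDT/PAE quality gating.
7. **fixtures** — deterministic synthetic complexes (ideal backbones,
   partners planted at exact distances) and a separable planted training
   task, so every stage is testable offline.

## CLI

```bash
mpbind fixtures  --spec spec.yaml --out fixture_dir/       # synthetic complex
mpbind label     --structure f.cif --chain A --cutoff 5.0  # contact labels
mpbind featurize --structure f.cif --chain A --out g.npz   # residue graph
mpbind train     --config train.yaml                       # planted-task training
mpbind predict   --model ckpt.npz --graph g.npz --out preds.tsv
mpbind evaluate  --model ckpt.npz --config train.yaml --out report.json
mpbind overlap   --features spans.tsv --predictions preds.tsv --out table.tsv
```

Every command writes a JSON manifest (inputs, config hash, package
version, seed) next to its outputs.

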
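# synthrna

Synthetic-data evaluation framework for RNA secondary-structure machine
learning: generate controlled ground-truth datasets from a thermodynamic
folding oracle, train small reference predictors, and quantify what they do
and do not learn (structural statistics, length-distribution bias, quadratic
base-pair scaling, structure-bias overfitting).

Everything is self-contained and text-only:

* **`synthrna.fold`** — a full Turner-2004 nearest-neighbor MFE folder
  (Zuker dynamic program, double-dangle model, special hairpin loops,
  1×1/2×1/2×2 interior-loop tables) with the parameter tables vendored as a
  plain-text file, plus a labeled non-thermodynamic fallback
  (base-pair maximization). The engine reproduces the reference
  thermodynamic folder's MFE energies exactly on frozen test vectors.
* **`synthrna.structures`** — pair tables, dot-bracket/bpseq I/O, pseudoknot
  removal (max-weight nested subset DP), loop decomposition
  (EL/BL/HL/IL/ML), matrix postprocessing, structural-statistics reports.
* **`synthrna.synthdata`** — random sequence samplers (fixed/uniform/beta
  length laws, D1–D4 presets), oracle-folded dataset bundles, exact
  dinucleotide shuffling (Euler-walk), inverse folding (best-of-k adaptive
  walk), and a structure-bias emulator.
* **`synthrna.pairedness`** — per-nucleotide paired/unpaired predictors:
  sliding-window FFN and CNN, window-less bidirectional LSTM.
* **`synthrna.pairmatrix`** — n×n base-pair-matrix predictors (residual
  conv nets; variant 3 adds a row/column bidirectional-LSTM block).
* **`synthrna.evaluation`** — MCC/F1/accuracy/loss at per-base, per-entry
  and per-pair granularity; structural-statistics tables; linear-vs-quadratic
  scaling fits with nested-model F-tests; cross-distribution grids; the
  structure-bias experiment; pseudoknot/multi-pair censuses.
* **`synthrna.nn`** — a minimal numpy reverse-mode autodiff engine
  (gradient-checked) backing all models; no deep-learning framework needed.

## CLI

One subcommand per experiment family; every run writes a `manifest.json`
echoing the resolved configuration (seed, oracle id, sizes):

```sh
synthrna --seed 1 --outdir out fold --length 70 --count 100
synthrna --seed 1 --outdir out generate --preset D1 --train 300 --val 50
synthrna --seed 1 --outdir out table3 --length 70 --length 100 --count 2000
synthrna --seed 1 --outdir out scaling --min-length 30 --max-length 250
synthrna --seed 1 --outdir out pairedness --family BLSTM --layers 3 --hidden 40
synthrna --seed 1 --outdir out matrix --variant 0 --epochs 10
synthrna --seed 1 --outdir out grid
synthrna --seed 1 --outdir out bias
synthrna --seed 1 --outdir out census
```

Global flags: `--seed`, `--outdir`, `--oracle {turner,fallback}`,
`--config FILE` (YAML overrides), `--log-level`.

## Notes on scale

The bundled models are intentionally small (numpy autodiff, single CPU).
The test suite exercises the full experiment battery at reduced scale;
all dataset sizes, epochs and architecture widths are exposed so the same
code runs the full-scale protocol given a real compute budget.
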
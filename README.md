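# interpeprank

Graph-network scoring and ranking of rigid-body-docked peptide–protein
decoys.

## The problem

Peptide–protein interactions — a short, often disordered peptide binding a
folded receptor — are common and biologically central, but hard to model:
FFT-based rigid-body docking can sample the binding space exhaustively,
yet its energy function rarely separates the near-native poses it produced
from the millions of poor ones.  Downstream all-atom refinement is far too
expensive to apply to everything, so docking pipelines need a fast,
accurate *re-scoring* step that decides which decoys are worth refining.

This package implements such a scorer for people building or studying
peptide docking pipelines.  A decoy complex is encoded as a residue graph
— evolutionary and sequence features on the nodes, physical interaction
types on the edges — and scored by an edge-conditioned graph convolution
network trained to predict the decoy's ligand RMSD.  Everything needed to
build, train and test the scorer is generated synthetically; no downloads
or pretrained weights are required.

## The model

A decoy with peptide P docked on receptor R becomes a graph over at most
100 residues (the peptide plus the receptor residues closest to it):

* node features (64): one-hot amino acid (21, X for unknown), PSSM column
  (21, incl. gap), self-entropy column (21), peptide flag (1), with
  `PSSM_i = −log(p_i/p_bi)` and `S_i = −p_i log(p_i/p_bi)` from a receptor
  MSA; peptide nodes carry zero profiles;
* edge channels (4): self, sequence (peptide bond), proximity (any heavy
  atoms within 4.5 Å), and identity (the OR of the rest).

The network embeds the one-hot block, runs stacked edge-conditioned graph
convolutions (neighbor-transform weights generated from the edge features)
with ReLU, concatenates all convolution outputs, pools over real nodes,
and predicts a softmax over bins of

    LRMSD_norm = 1 / (1 + (LRMSD / 4.0)²).

The score is the probability-weighted mean of bin centers,
`S = Σᵢ xᵢ P(xᵢ)` — higher S, lower predicted LRMSD.  A decoy is *correct*
when LRMSD < 4.0 Å.  Trained networks can be ensembled by score averaging,
and decoys are selected for refinement by top-N or by the score cutoff
S ≥ 0.47.  See `docs/methods.md` for assumptions, conventions and
limitations.

## Worked example

```python
import numpy as np
import interpeprank as ipr

# a small synthetic benchmark: 6 targets x 50 decoys with exact LRMSD labels
ds = ipr.make_planted_dataset(n_targets=6, decoys_per_target=50, seed=7)
tids = sorted(set(ds.target_ids()))
train, val, test = ds.split_by_targets([set(tids[:4]), set(tids[4:5]), set(tids[5:])])

net = ipr.InterPepRankNet(conv_channels=(16, 16), embedding_dim=8,
                          dense_sizes=(32, 16), max_epochs=40, batch_size=32, seed=0)
net.fit(train.graphs, train.lrmsd(), validation_data=(val.graphs, val.lrmsd()))
print(f"selected epoch: {net.best_epoch_}")

scores = net.predict(test.graphs)
labels = np.array([d.is_correct for d in test.labels])
print(f"held-out AUC: {ipr.roc_curve(scores, labels).auc:.3f}   "
      f"Spearman(score, LRMSD_norm): "
      f"{ipr.spearman(scores, ipr.normalize_lrmsd(test.lrmsd())):.3f}")

picked = ipr.select_for_refinement(
    list(zip([d.graph_ref for d in test.labels], scores)), mode="cutoff", value=0.47)
print(f"decoys selected for refinement at score >= 0.47: {len(picked)}/{len(scores)}")
```

Output:

```
selected epoch: 30
held-out AUC: 0.998   Spearman(score, LRMSD_norm): 0.859
decoys selected for refinement at score >= 0.47: 34/50
```

The model never saw the held-out target; AUC measures how well its scores
separate correct (LRMSD < 4 Å) from incorrect decoys there, the Spearman
value how well the score tracks decoy quality overall, and the selection
line is the refinement shortlist a pipeline would pass on.

The same workflow is available from the shell:

```sh
interpeprank make-fixtures --out bench --n-targets 4 --decoys-per-target 16 --seed 11
interpeprank featurize --benchmark bench --out graphs.npz
interpeprank train --graphs graphs.npz --labels bench/labels.tsv --out model --members 2
interpeprank score --graphs graphs.npz --model model --out scores.tsv
interpeprank select --scores scores.tsv --cutoff 0.47 --out selection.tsv
interpeprank evaluate --scores scores.tsv --labels bench/labels.tsv --out eval.tsv
```

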
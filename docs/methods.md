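# Methods

## Problem and model

Rigid-body (FFT) peptide-protein docking produces very large decoy pools in
which near-native poses are present but poorly separated by the docking
energy itself.  This package scores each decoy so that the pool can be
ranked and only promising poses passed to expensive all-atom refinement.
A decoy counts as *correct* when its ligand RMSD (LRMSD — peptide backbone
RMSD after superposing the receptor onto the native complex) is below
4.0 Å, the regime from which refinement can reliably reach sub-ångström
accuracy.

Each decoy is encoded as a residue graph:

* **Nodes** (64 features): one-hot amino-acid code over 20 residues + X
  (21), a PSSM column (21, including the gap symbol), a self-entropy column
  (21), and a peptide-indicator flag (1).  The profile features come from a
  receptor multiple sequence alignment via

      PSSM_i = −log(p_i / p_bi),      S_i = −p_i · log(p_i / p_bi),

  where `p_i` is the observed column frequency (with a background-weighted
  pseudocount) and `p_bi` the background probability.  Peptides are too
  short for meaningful alignments and cannot be assumed to be fragments of
  larger proteins, so peptide nodes carry all-zero PSSM/entropy blocks.
* **Edges** (4 one-hot channels): self edges on the diagonal; sequence
  edges between chain-consecutive, peptide-bonded residues; proximity edges
  between residues with any heavy-atom pair within 4.5 Å; and an identity
  channel set wherever any other channel is set, which marks where
  convolutions need to run.
* **Node cap**: at most 100 nodes — the whole peptide plus the receptor
  residues nearest to it (e.g. a 25-residue peptide keeps the 75 closest
  receptor residues); smaller complexes are zero-padded and masked.

The network embeds the one-hot block (a linear map, cutting weights and
overfitting), concatenates the embedding with the remaining 43 features,
and applies a stack of edge-conditioned graph convolutions: the weights
that transform a neighbor's features are generated from the edge feature
vector by a small filter network, neighbor messages are mean-aggregated,
and ReLU follows each layer.  All convolution outputs are concatenated
node-wise, globally pooled over real nodes, and passed through two dense
layers to a softmax over bins of the normalized LRMSD

    LRMSD_norm = 1 / (1 + (LRMSD / 4.0)^2)  ∈ (0, 1],

with 2–4 even bins (two bins put the boundary exactly at the 4 Å
correctness threshold).  The scalar score is the probability-weighted mean
of bin centers, `S = Σ_i x_i P(x_i)`; higher S predicts lower LRMSD.
Several independently trained networks may be ensembled by averaging their
scores.

## Training protocol

Cross-entropy on the bin labels, ADAM at learning rate 0.001, at most
1,000 epochs (defaults; all configurable).  As augmentation, a fraction of
all edges (default 0.15, sensible range 0.1–0.25) is zeroed per decoy per
epoch; symmetric partners are dropped together so the channel-symmetry and
identity-OR invariants survive.  When a validation set is supplied, every
epoch logs validation loss, Spearman correlation between score and
LRMSD_norm, and precision/recall at score 0.5; the final weights come from
the epoch with the best *combination* of the three, implemented as the
minimum rank-sum of (loss ascending, −Spearman, −F1).  Rank-sum was chosen
because the three metrics live on incomparable scales; the criterion is a
single pluggable function.

Dataset balancing mirrors the docking-benchmark conventions: per target,
the majority correctness class is down-sampled to the minority count; then
any homology group contributing more decoys than the median group total is
down-sampled to that median.  Train/validation/test splits are grouped (a
homology group never spans two partitions) and overlap is an error.

## Quality measures

`structure_io` implements the standard docking model-quality measures.
The LRMSD atom set is the DockQ/CAPRI convention: superpose on receptor
backbone (N, CA, C, O), measure RMSD over peptide backbone without
refitting.  Interface residues for iRMSD are native residues with any
heavy atom within 10.0 Å of the other chain; fnat contacts use a 5.0 Å
heavy-atom cutoff.  DockQ is the three-term average with d1 = 8.5 Å and
d2 = 1.5 Å.  CAPRI classes: High (LRMSD < 1.0, iRMSD < 0.5, fnat > 0.8),
Medium (< 2.0, < 1.0, > 0.5), Acceptable (< 5.0, < 2.0, > 0.2), else
Incorrect.

## Numerical and design choices

* **Numerics**: superposition by SVD (Kabsch) with determinant correction;
  all network math in float64; softmax computed shift-invariantly; the
  training loss raises on non-finite values.
* **Backend**: the network is plain numpy with hand-written gradients and
  ADAM.  The four binary edge channels admit at most 16 distinct edge
  vectors, so message passing is computed per distinct edge type as a
  batched matrix product; gradients were verified against central finite
  differences (see the test suite).
* **Boundary conventions** (fixed, documented, tested): proximity cutoff
  inclusive (edge at exactly 4.5 Å); refinement score cutoff inclusive
  (score ≥ 0.47 selected); LRMSD_norm bins right-closed so a perfect decoy
  (norm = 1.0) has a bin and exactly 4.0 Å falls on the incorrect side,
  consistent with the strict `LRMSD < 4 Å` correctness rule; receptor-node
  selection ties break toward the lower residue index; sequence edges
  require an actual peptide bond (C–N ≤ 2.0 Å) so chain breaks never link.
* **Background frequencies**: BLOSUM62 amino-acid marginals renormalized to
  0.95 with 0.05 assigned to the gap symbol; natural log (log2 available);
  total pseudocount weight 1.0 distributed by the background.  Alignment
  rows are weighted uniformly; redundancy filtering is assumed done by the
  MSA producer.  X symbols are treated as unobserved.
* **Pooling**: masked mean by default (divide by the real-node count, not
  the padded size), so the output is invariant to the amount of padding;
  max and sum pooling are available.
* **Defaults**: 3 convolution layers of 32 channels, embedding width 8,
  dense (64, 32), 2 bins — small enough to train on one CPU core while the
  ensemble machinery covers architectural heterogeneity.
* **Missing backbone atoms** are skipped from RMSD atom sets with a logged
  warning; the computation proceeds while at least 3 residues remain.
* **Residue matching** between decoy and native is by (chain, residue
  number, insertion code) with identical one-letter codes; no realignment.

## Synthetic fixtures: what they emulate and what they do not

The generators produce everything needed to exercise the pipeline without
downloads.  A toy native is a helical receptor (CA helix: radius 2.3 Å,
rise 1.5 Å, 100°/turn) threaded with backbone N/C/O atoms placed so
consecutive C–N distances sit under the 2 Å bond cutoff, plus an extended
peptide slid to a 4.0 Å closest approach.  The receptor face toward the
peptide is hydrophobic (L/I/V/F/M) and evolutionarily conserved (low
per-column mutation rate in the toy alignments), the rest polar and
variable — the conserved-hydrophobic-patch signature real binding grooves
tend to show.  Decoys are rigid peptide perturbations: pure translations
hit their LRMSD target exactly (the label is analytic); mixed
rotation+translation decoys solve the translation length from
`target² = rms_rot² + |t|²` and are verified against `compute_lrmsd`.

The planted-signal dataset builds on this: correct decoys (LRMSD < 4 Å)
are jittered poses that keep a native-like contact patch, incorrect decoys
(LRMSD ≥ 8 Å) are mirrored to the opposite receptor face.  A network can
therefore separate the classes from chemistry and conservation of the
contacted face — a target-transferable signal — rather than memorizing
targets.  What the fixtures deliberately lack: side chains, realistic
energetics and sterics, peptide conformer variability, alignment gaps and
phylogenetic correlation, and mid-range (4–8 Å) ambiguous decoys.  Passing
the learning tests shows the representation, network, gradients and
training loop work end to end on a learnable geometric/evolutionary
signal; it says nothing about accuracy on real docking decoys, which
requires real decoy sets and full-scale training.

## Problem sizes used in the tests

The learning check trains a two-member ensemble (2 conv layers × 16
channels, embedding 8) on a 20-target × 100-decoy planted benchmark for up
to 60 epochs with a grouped 14/3/3 target split; the pipeline check runs
the full CLI on 4 targets × 16 decoys.  These sizes keep the whole suite
in the minutes range on one CPU core while leaving every code path
exercised at the representation's real dimensions (64-feature nodes,
100-node cap).

## Known limitations

* No mmCIF input, no nucleic-acid chains, no interface-area (SASA) filter.
* The scorer is only as transferable as its training decoys; the shipped
  code trains from scratch — no pretrained weights are distributed.
* Alignment handling assumes the MSA is already redundancy-filtered and in
  query-column space (A3M lowercase inserts are removed on read).
* The numpy backend targets desk-scale experiments; very large decoy pools
  would want a compiled/GPU implementation of the same architecture.
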
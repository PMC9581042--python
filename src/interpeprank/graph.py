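"""Decoy graph representation: 64-feature nodes, 4-channel edges, 100-node cap.

A decoy complex becomes a graph whose nodes are residues and whose edges are
one-hot interaction types.  Node features (width 64, column order):

* ``[0:21]``   one-hot amino-acid code (20 aa + X),
* ``[21:42]``  PSSM profile column (20 aa + gap),
* ``[42:63]``  self-entropy profile column,
* ``[63]``     peptide indicator (1 for peptide residues).

Peptide residues carry all-zero PSSM/entropy blocks: peptides are too short
for meaningful alignments and cannot be assumed to come from larger
proteins.  Edge channels (order): self, sequence (peptide bond), proximity
(any heavy-atom pair within 4.5 Å, inclusive), and identity — the OR of the
other three, which marks where convolutions need to run.

At most ``max_nodes`` (default 100) residues are kept: the whole peptide
plus the receptor residues closest to it; smaller complexes are zero-padded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evolution_features import ProfileFeatures, one_hot
from .structure_io import ComplexStructure, ResidueRecord

#: Heavy-atom distance (Å) at or below which residues get a proximity edge.
PROXIMITY_CUTOFF = 4.5

#: C-N distance (Å) at or below which consecutive residues count as bonded.
PEPTIDE_BOND_CUTOFF = 2.0

DEFAULT_MAX_NODES = 100
N_NODE_FEATURES = 64
N_EDGE_CHANNELS = 4
EDGE_SELF, EDGE_SEQUENCE, EDGE_PROXIMITY, EDGE_IDENTITY = range(4)


@dataclass
class DecoyGraph:
    """Padded graph input for the network.

    ``edge_features`` is symmetric in its first two axes for the sequence,
    proximity and identity channels; the self channel lives on the diagonal
    of real nodes.  Padded rows/columns are all zero.
    """

    node_features: np.ndarray  # (max_nodes, 64) float32
    edge_features: np.ndarray  # (max_nodes, max_nodes, 4) uint8
    node_mask: np.ndarray      # (max_nodes,) bool
    node_index: list[tuple[str, int]]  # node -> (chain_id, res_seq)
    decoy_id: str = ""
    lrmsd: float | None = None
    lrmsd_norm: float | None = None

    def __post_init__(self):
        n = self.node_features.shape[0]
        if self.node_features.shape != (n, N_NODE_FEATURES):
            raise ValueError(f"node_features shape {self.node_features.shape}")
        if self.edge_features.shape != (n, n, N_EDGE_CHANNELS):
            raise ValueError(f"edge_features shape {self.edge_features.shape}")
        if self.node_mask.shape != (n,):
            raise ValueError(f"node_mask shape {self.node_mask.shape}")

    @property
    def max_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_real_nodes(self) -> int:
        return int(self.node_mask.sum())

    def validate(self) -> None:
        """Check the structural invariants of the representation."""
        e = self.edge_features
        mask = self.node_mask.astype(bool)
        ident = e[:, :, EDGE_IDENTITY]
        other = e[:, :, (EDGE_SELF, EDGE_SEQUENCE, EDGE_PROXIMITY)].max(axis=-1)
        if not np.array_equal(ident, other):
            raise ValueError("identity channel is not the OR of the other channels")
        for ch in (EDGE_SEQUENCE, EDGE_PROXIMITY, EDGE_IDENTITY):
            if not np.array_equal(e[:, :, ch], e[:, :, ch].T):
                raise ValueError(f"edge channel {ch} not symmetric")
        selfc = e[:, :, EDGE_SELF]
        if np.any(selfc[~np.eye(self.max_nodes, dtype=bool)]):
            raise ValueError("self channel has off-diagonal entries")
        pad = ~mask
        if np.any(self.node_features[pad] != 0) or np.any(e[pad] != 0) or np.any(
            e[:, pad] != 0
        ):
            raise ValueError("padding rows/columns are not all zero")
        pep = self.node_features[:, 63] > 0
        if np.any(np.abs(self.node_features[pep, 21:63]) > 0):
            raise ValueError("peptide nodes carry nonzero PSSM/entropy")


def select_nodes(
    complex_: ComplexStructure, max_nodes: int = DEFAULT_MAX_NODES
) -> list[ResidueRecord]:
    """Residues kept in the graph: whole peptide + nearest receptor residues.

    Receptor residues are ranked by minimum heavy-atom distance to any
    peptide heavy atom; ties break toward the lower receptor index.  Output
    order is peptide residues in chain order, then the selected receptor
    residues in chain order.
    """
    pep = list(complex_.peptide)
    rec = list(complex_.receptor)
    if len(pep) > max_nodes:
        raise ValueError(
            f"peptide ({len(pep)} residues) exceeds max_nodes ({max_nodes})"
        )
    n_rec_keep = min(len(rec), max_nodes - len(pep))
    if n_rec_keep == len(rec):
        return pep + rec
    pep_coords = np.concatenate([r.coords() for r in pep], axis=0)
    dists = np.empty(len(rec))
    for i, r in enumerate(rec):
        rc = r.coords()
        d2 = np.sum((rc[:, None, :] - pep_coords[None, :, :]) ** 2, axis=-1)
        dists[i] = np.sqrt(np.min(d2))
    # stable sort keeps chain order among equal distances
    order = np.argsort(dists, kind="stable")[:n_rec_keep]
    keep = sorted(order)
    return pep + [rec[i] for i in keep]


def build_edges(
    residues: list[ResidueRecord],
    proximity_cutoff: float = PROXIMITY_CUTOFF,
    bond_cutoff: float = PEPTIDE_BOND_CUTOFF,
) -> np.ndarray:
    """Edge tensor (n, n, 4) over an ordered residue list.

    Self edges on the diagonal; sequence edges between chain-consecutive,
    peptide-bonded residues (C-N distance <= ``bond_cutoff``); proximity
    edges between residues with any heavy-atom pair within
    ``proximity_cutoff`` (inclusive); identity = OR of the rest.
    """
    n = len(residues)
    e = np.zeros((n, n, N_EDGE_CHANNELS), dtype=np.uint8)
    e[np.arange(n), np.arange(n), EDGE_SELF] = 1

    coords = [r.coords() for r in residues]
    names = [[a[0] for a in r.heavy_atoms] for r in residues]
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = residues[i], residues[j]
            d2 = np.sum((coords[i][:, None, :] - coords[j][None, :, :]) ** 2, axis=-1)
            if np.min(d2) <= proximity_cutoff**2:
                e[i, j, EDGE_PROXIMITY] = e[j, i, EDGE_PROXIMITY] = 1
            if ri.chain_id == rj.chain_id and abs(ri.res_seq - rj.res_seq) == 1:
                first, second = (i, j) if ri.res_seq < rj.res_seq else (j, i)
                try:
                    c_idx = names[first].index("C")
                    n_idx = names[second].index("N")
                except ValueError:
                    continue
                d = np.linalg.norm(coords[first][c_idx] - coords[second][n_idx])
                if d <= bond_cutoff:
                    e[i, j, EDGE_SEQUENCE] = e[j, i, EDGE_SEQUENCE] = 1
    e[:, :, EDGE_IDENTITY] = e[:, :, :EDGE_IDENTITY].max(axis=-1)
    return e


def featurize_decoy(
    complex_: ComplexStructure,
    profile: ProfileFeatures,
    max_nodes: int = DEFAULT_MAX_NODES,
    lrmsd: float | None = None,
) -> DecoyGraph:
    """Assemble the padded DecoyGraph for one decoy.

    ``profile`` must cover the receptor sequence (same length and letters,
    X in the structure matching any profile letter).  Peptide nodes get
    zero PSSM/entropy and peptide indicator 1.
    """
    if len(profile.query) != len(complex_.receptor):
        raise ValueError(
            f"profile length {len(profile.query)} != receptor length "
            f"{len(complex_.receptor)}"
        )
    for pos, (letter, res) in enumerate(zip(profile.query, complex_.receptor)):
        if res.aa1 != "X" and letter != res.aa1:
            raise ValueError(
                f"profile letter '{letter}' does not match receptor residue "
                f"{res.chain_id}{res.res_seq} ({res.aa1}) at position {pos}"
            )
    rec_pos = {res.key: i for i, res in enumerate(complex_.receptor)}
    pep_keys = {res.key for res in complex_.peptide}

    selected = select_nodes(complex_, max_nodes)
    n = len(selected)
    node_features = np.zeros((max_nodes, N_NODE_FEATURES), dtype=np.float32)
    for i, res in enumerate(selected):
        node_features[i, 0:21] = one_hot(res.aa1)
        if res.key in pep_keys:
            node_features[i, 63] = 1.0
        else:
            p = rec_pos[res.key]
            node_features[i, 21:42] = profile.pssm[p]
            node_features[i, 42:63] = profile.self_entropy[p]

    edge = np.zeros((max_nodes, max_nodes, N_EDGE_CHANNELS), dtype=np.uint8)
    edge[:n, :n] = build_edges(selected)
    mask = np.zeros(max_nodes, dtype=bool)
    mask[:n] = True

    from .training import normalize_lrmsd

    return DecoyGraph(
        node_features=node_features,
        edge_features=edge,
        node_mask=mask,
        node_index=[(r.chain_id, r.res_seq) for r in selected],
        decoy_id=complex_.id,
        lrmsd=lrmsd,
        lrmsd_norm=None if lrmsd is None else normalize_lrmsd(lrmsd),
    )


def apply_edge_dropout(graph: DecoyGraph, rate: float, seed: int) -> DecoyGraph:
    """Randomly zero a fraction of real edge positions (all channels).

    Each undirected edge position (i <= j with any channel set) is dropped
    independently with probability ``rate``; symmetric partners are dropped
    together so channel symmetry and the identity-OR invariant survive.
    Training-time augmentation only; deterministic under ``seed``.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return graph
    rng = np.random.default_rng(seed)
    e = graph.edge_features.copy()
    present = e.max(axis=-1) > 0
    iu, ju = np.where(np.triu(present))
    drop = rng.random(len(iu)) < rate
    e[iu[drop], ju[drop], :] = 0
    e[ju[drop], iu[drop], :] = 0
    return DecoyGraph(
        node_features=graph.node_features,
        edge_features=e,
        node_mask=graph.node_mask,
        node_index=graph.node_index,
        decoy_id=graph.decoy_id,
        lrmsd=graph.lrmsd,
        lrmsd_norm=graph.lrmsd_norm,
    )


# ---------------------------------------------------------------------------
# on-disk container: one .npz per decoy set + TSV manifest


def save_graphs(graphs: list[DecoyGraph], path) -> None:
    """Write a decoy set as a single .npz container plus a TSV manifest.

    The manifest (``<path>.manifest.tsv``) maps decoy id -> array offset.
    """
    import pandas as pd

    path = Path(path)
    nodes = np.stack([g.node_features for g in graphs])
    edges = np.stack([g.edge_features for g in graphs])
    masks = np.stack([g.node_mask for g in graphs])
    lrmsd = np.array(
        [np.nan if g.lrmsd is None else g.lrmsd for g in graphs], dtype=float
    )
    index_json = json.dumps([g.node_index for g in graphs])
    np.savez_compressed(
        path,
        node_features=nodes,
        edge_features=edges,
        node_mask=masks,
        lrmsd=lrmsd,
        node_index=np.frombuffer(index_json.encode(), dtype=np.uint8),
        decoy_ids=np.array([g.decoy_id for g in graphs]),
    )
    pd.DataFrame(
        {"decoy_id": [g.decoy_id for g in graphs], "offset": np.arange(len(graphs))}
    ).to_csv(path.with_suffix(path.suffix + ".manifest.tsv"), sep="\t", index=False)


def load_graphs(path) -> list[DecoyGraph]:
    """Read a decoy set written by :func:`save_graphs`."""
    from .training import normalize_lrmsd

    with np.load(path, allow_pickle=False) as data:
        nodes = data["node_features"]
        edges = data["edge_features"]
        masks = data["node_mask"]
        lrmsd = data["lrmsd"]
        ids = data["decoy_ids"]
        node_index = json.loads(bytes(data["node_index"]).decode())
    out = []
    for k in range(nodes.shape[0]):
        lv = None if np.isnan(lrmsd[k]) else float(lrmsd[k])
        out.append(
            DecoyGraph(
                node_features=nodes[k],
                edge_features=edges[k],
                node_mask=masks[k],
                node_index=[tuple(t) for t in node_index[k]],
                decoy_id=str(ids[k]),
                lrmsd=lv,
                lrmsd_norm=None if lv is None else normalize_lrmsd(lv),
            )
        )
    return out
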
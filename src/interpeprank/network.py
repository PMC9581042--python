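"""Edge-conditioned graph convolution network for decoy scoring.

Architecture (feed-forward): the 21-wide one-hot amino-acid block is passed
through a linear embedding to cut dimensionality; the embedding is
concatenated with the remaining 43 node features (PSSM, self-entropy,
peptide flag) and run through a stack of edge-conditioned graph
convolutions with ReLU after each layer.  In an edge-conditioned
convolution the neighbor-transform weights are *generated* from the edge
feature vector by a small filter network, so different edge types (self /
sequence / proximity) apply different learned filters.  The outputs of all
convolution layers are concatenated node-wise, globally pooled over real
(non-padding) nodes, and passed through two dense layers to a softmax over
bins of normalized LRMSD.  The scalar score is the probability-weighted
mean of the bin centers,

    S = sum_i x_i * P(x_i),     x_i = (i + 0.5) / n_bins,

so higher S predicts lower LRMSD.  Several trained networks may be
ensembled by averaging their scores.

Everything is plain numpy with hand-written gradients and an ADAM
optimizer; the four binary edge channels admit at most 16 distinct edge
feature vectors, so message passing is computed per distinct edge type,
which keeps both the forward and backward passes vectorized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .graph import DecoyGraph, N_EDGE_CHANNELS, N_NODE_FEATURES
from .training import (
    assign_bin,
    normalize_lrmsd,
    precision_recall_at,
    spearman,
)

N_ONEHOT = 21
N_EXTRA = N_NODE_FEATURES - N_ONEHOT  # PSSM + entropy + peptide flag = 43


# ---------------------------------------------------------------------------
# configuration and outputs


@dataclass
class NetworkConfig:
    """Hyperparameters of one network; round-trips losslessly through YAML."""

    n_bins: int = 2
    embedding_dim: int = 8
    conv_channels: tuple[int, ...] = (32, 32, 32)
    filter_hidden: int = 16
    dense_sizes: tuple[int, int] = (64, 32)
    pooling: str = "mean"
    edge_dropout: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_bins not in (2, 3, 4):
            raise ValueError(f"n_bins must be 2, 3 or 4, got {self.n_bins}")
        self.conv_channels = tuple(int(c) for c in self.conv_channels)
        self.dense_sizes = tuple(int(c) for c in self.dense_sizes)
        sizes = (self.embedding_dim, self.filter_hidden) + self.conv_channels + self.dense_sizes
        if any(s <= 0 for s in sizes):
            raise ValueError("all layer sizes must be positive")
        if self.pooling not in ("mean", "max", "sum"):
            raise ValueError(f"unknown pooling '{self.pooling}'")
        if not 0.0 <= self.edge_dropout < 1.0:
            raise ValueError("edge_dropout must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_channels"] = list(self.conv_channels)
        d["dense_sizes"] = list(self.dense_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


def bin_centers(n_bins: int) -> np.ndarray:
    """Centers of ``n_bins`` even bins of [0, 1]: ``(i + 0.5) / n_bins``."""
    return (np.arange(n_bins) + 0.5) / n_bins


@dataclass
class BinProbabilities:
    """Softmax output over LRMSD_norm bins, with the bin centers."""

    probs: np.ndarray
    centers: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.centers is None:
            self.centers = bin_centers(len(self.probs))
        if np.any(self.probs < -1e-12) or abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probs must be a probability vector")
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")

    @property
    def score(self) -> float:
        return float(self.probs @ self.centers)


def score_from_probs(bp: BinProbabilities | np.ndarray) -> float:
    """Scalar score from bin probabilities: probability-weighted bin centers."""
    if isinstance(bp, BinProbabilities):
        return bp.score
    probs = np.asarray(bp, dtype=float)
    return float(probs @ bin_centers(probs.shape[-1]))


# ---------------------------------------------------------------------------
# parameter initialization and low-level passes


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


def init_params(config: NetworkConfig, rng: np.random.Generator) -> dict:
    """Seeded Glorot-uniform initialization of all weights."""
    p: dict[str, np.ndarray] = {}
    p["embed"] = _glorot(rng, (N_ONEHOT, config.embedding_dim))
    din = config.embedding_dim + N_EXTRA
    hf = config.filter_hidden
    for l, dout in enumerate(config.conv_channels):
        p[f"conv{l}_f1_W"] = _glorot(rng, (N_EDGE_CHANNELS, hf))
        p[f"conv{l}_f1_b"] = np.zeros(hf)
        p[f"conv{l}_f2_W"] = _glorot(rng, (hf, din * dout)) / np.sqrt(din)
        p[f"conv{l}_f2_b"] = np.zeros(din * dout)
        p[f"conv{l}_bias"] = np.zeros(dout)
        din = dout
    cat = sum(config.conv_channels)
    d1, d2 = config.dense_sizes
    p["dense1_W"] = _glorot(rng, (cat, d1))
    p["dense1_b"] = np.zeros(d1)
    p["dense2_W"] = _glorot(rng, (d1, d2))
    p["dense2_b"] = np.zeros(d2)
    p["out_W"] = _glorot(rng, (d2, config.n_bins))
    p["out_b"] = np.zeros(config.n_bins)
    return p


def edge_code(edge_features: np.ndarray) -> np.ndarray:
    """Pack the 4 binary edge channels into one integer code per (i, j)."""
    e = edge_features.astype(np.uint8)
    return (e[..., 0] + 2 * e[..., 1] + 4 * e[..., 2] + 8 * e[..., 3]).astype(np.uint8)


def _code_bits(c: int) -> np.ndarray:
    return np.array([(c >> k) & 1 for k in range(N_EDGE_CHANNELS)], dtype=float)


def _filter_theta(params: dict, layer: int, c: int, din: int, dout: int):
    """Edge-type filter: tiny MLP mapping edge vector -> (din, dout) matrix."""
    e = _code_bits(c)
    z = np.maximum(e @ params[f"conv{layer}_f1_W"] + params[f"conv{layer}_f1_b"], 0.0)
    theta = (z @ params[f"conv{layer}_f2_W"] + params[f"conv{layer}_f2_b"]).reshape(
        din, dout
    )
    return e, z, theta


def _conv_forward(params, layer, H, code, mask, din, dout):
    """Batched edge-conditioned convolution with mean aggregation.

    For each real node i:  out_i = relu( mean_{j in N(i)} Theta(e_ij) x_j + b )
    where N(i) = nodes with any nonzero edge channel to i (self edge
    included on the diagonal).  Padded nodes output zeros.
    """
    deg = (code > 0).sum(axis=-1).astype(float)  # (B, N)
    M = np.zeros((H.shape[0], H.shape[1], dout))
    per_code = []
    for c in np.unique(code[code > 0]):
        c = int(c)
        e, z, theta = _filter_theta(params, layer, c, din, dout)
        A = (code == c).astype(float)
        U = np.einsum("bij,bjd->bid", A, H, optimize=True)
        M += U @ theta
        per_code.append((c, e, z, theta, U))
    degc = np.maximum(deg, 1.0)
    P = M / degc[..., None] + params[f"conv{layer}_bias"]
    Hout = np.maximum(P, 0.0) * mask[..., None]
    cache = (H, code, mask, degc, P, per_code)
    return Hout, cache


def _conv_backward(params, layer, cache, dHout, grads):
    H, code, mask, degc, P, per_code = cache
    dP = dHout * (P > 0) * mask[..., None]
    dM = dP / degc[..., None]
    grads[f"conv{layer}_bias"] += dP.sum(axis=(0, 1))
    dH = np.zeros_like(H)
    for c, e, z, theta, U in per_code:
        A = (code == c).astype(float)
        dtheta = np.einsum("bnd,bno->do", U, dM, optimize=True)
        dU = dM @ theta.T
        dH += np.einsum("bij,bio->bjo", A, dU, optimize=True)
        dflat = dtheta.ravel()
        grads[f"conv{layer}_f2_W"] += np.outer(z, dflat)
        grads[f"conv{layer}_f2_b"] += dflat
        dz = (params[f"conv{layer}_f2_W"] @ dflat) * (z > 0)
        grads[f"conv{layer}_f1_W"] += np.outer(e, dz)
        grads[f"conv{layer}_f1_b"] += dz
    return dH


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def _forward(params, config: NetworkConfig, feats, code, mask, need_cache=False):
    """Full forward pass on a batch; returns (probs, cache)."""
    onehot = feats[..., :N_ONEHOT]
    H = np.concatenate([onehot @ params["embed"], feats[..., N_ONEHOT:]], axis=-1)
    H = H * mask[..., None]
    din = config.embedding_dim + N_EXTRA
    conv_outs, conv_caches = [], []
    for l, dout in enumerate(config.conv_channels):
        H, cache = _conv_forward(params, l, H, code, mask, din, dout)
        conv_outs.append(H)
        conv_caches.append(cache)
        din = dout
    X = np.concatenate(conv_outs, axis=-1)

    n_real = mask.sum(axis=1).astype(float)
    if config.pooling == "mean":
        g = (X * mask[..., None]).sum(axis=1) / n_real[:, None]
        pool_cache = n_real
    elif config.pooling == "sum":
        g = (X * mask[..., None]).sum(axis=1)
        pool_cache = None
    else:  # max
        Xm = np.where(mask[..., None], X, -np.inf)
        arg = Xm.argmax(axis=1)
        g = np.take_along_axis(Xm, arg[:, None, :], axis=1)[:, 0, :]
        pool_cache = arg

    z1 = g @ params["dense1_W"] + params["dense1_b"]
    a1 = np.maximum(z1, 0.0)
    z2 = a1 @ params["dense2_W"] + params["dense2_b"]
    a2 = np.maximum(z2, 0.0)
    logits = a2 @ params["out_W"] + params["out_b"]
    probs = _softmax(logits)
    if np.any(~np.isfinite(probs)):
        raise FloatingPointError("non-finite activations in forward pass")
    cache = None
    if need_cache:
        cache = (onehot, mask, conv_outs, conv_caches, X, pool_cache, g, z1, a1, z2, a2)
    return probs, cache


def _backward(params, config: NetworkConfig, cache, probs, labels_onehot):
    """Gradients of mean cross-entropy w.r.t. every parameter."""
    onehot, mask, conv_outs, conv_caches, X, pool_cache, g, z1, a1, z2, a2 = cache
    B = probs.shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    dlogits = (probs - labels_onehot) / B
    grads["out_W"] += a2.T @ dlogits
    grads["out_b"] += dlogits.sum(axis=0)
    da2 = (dlogits @ params["out_W"].T) * (z2 > 0)
    grads["dense2_W"] += a1.T @ da2
    grads["dense2_b"] += da2.sum(axis=0)
    da1 = (da2 @ params["dense2_W"].T) * (z1 > 0)
    grads["dense1_W"] += g.T @ da1
    grads["dense1_b"] += da1.sum(axis=0)
    dg = da1 @ params["dense1_W"].T

    if config.pooling == "mean":
        n_real = pool_cache
        dX = (dg[:, None, :] * mask[..., None]) / n_real[:, None, None]
    elif config.pooling == "sum":
        dX = dg[:, None, :] * mask[..., None]
    else:
        arg = pool_cache
        dX = np.zeros_like(X)
        np.put_along_axis(dX, arg[:, None, :], dg[:, None, :], axis=1)

    # split concat gradient per conv layer, then run layers in reverse;
    # layer l's output feeds both the concat and layer l+1
    splits = np.cumsum(config.conv_channels)[:-1]
    chunks = np.split(dX, splits, axis=-1)
    dH_next = None
    dims = [config.embedding_dim + N_EXTRA] + list(config.conv_channels)
    for l in range(len(config.conv_channels) - 1, -1, -1):
        dH_out = chunks[l].copy()
        if dH_next is not None:
            dH_out += dH_next
        dH_next = _conv_backward(params, l, conv_caches[l], dH_out, grads)
    dH0 = dH_next * mask[..., None]
    grads["embed"] += np.einsum("bni,bne->ie", onehot, dH0[..., : config.embedding_dim])
    return grads


class _Adam:
    """Plain ADAM (adaptive moment estimation) on a parameter dict."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# batching helpers


def graphs_to_batch(graphs: list[DecoyGraph], crop: bool = True):
    """Stack graphs into (features, edge codes, mask) arrays.

    With ``crop`` the arrays are trimmed to the largest real-node count in
    the set; masked pooling makes the network output invariant to padding,
    so this only saves compute.
    """
    feats = np.stack([g.node_features.astype(np.float64) for g in graphs])
    code = np.stack([edge_code(g.edge_features) for g in graphs])
    mask = np.stack([g.node_mask for g in graphs])
    if crop:
        n = int(mask.sum(axis=1).max())
        feats, code, mask = feats[:, :n], code[:, :n, :n], mask[:, :n]
    return feats, code, mask


def _dropout_codes(code: np.ndarray, rate: float, rng: np.random.Generator):
    """Zero a fraction of undirected edge positions (symmetric pairs)."""
    if rate <= 0:
        return code
    B, N, _ = code.shape
    upper = np.triu(rng.random((B, N, N)))
    full = upper + np.tril(upper.transpose(0, 2, 1), -1)
    drop = full < rate
    return np.where(drop, 0, code)


# ---------------------------------------------------------------------------
# spec-surface single-graph operations


def embed_aa(one_hot_block: np.ndarray, embed_weights: np.ndarray) -> np.ndarray:
    """Linear embedding of the one-hot amino-acid block (per node)."""
    one_hot_block = np.asarray(one_hot_block, dtype=float)
    if one_hot_block.shape[-1] != embed_weights.shape[0]:
        raise ValueError(
            f"one-hot width {one_hot_block.shape[-1]} != embedding input "
            f"{embed_weights.shape[0]}"
        )
    return one_hot_block @ embed_weights


def edge_conditioned_conv(node_feats, edge_tensor, mask, params, layer=0):
    """Single-graph edge-conditioned convolution (testing surface).

    ``params`` holds the ``conv{layer}_*`` weight arrays; returns the
    post-ReLU node features.
    """
    H = np.asarray(node_feats, dtype=float)[None]
    code = edge_code(np.asarray(edge_tensor))[None]
    m = np.asarray(mask, dtype=bool)[None]
    din = H.shape[-1]
    dout = params[f"conv{layer}_bias"].shape[0]
    out, _ = _conv_forward(params, layer, H, code, m, din, dout)
    return out[0]


# ---------------------------------------------------------------------------
# estimator


class InterPepRankNet(BaseEstimator):
    """Graph-network decoy scorer with a scikit-learn estimator surface.

    ``fit`` takes a list of :class:`DecoyGraph` and their LRMSD labels (Å),
    trains with ADAM on cross-entropy over LRMSD_norm bins, and (when a
    validation set is given) selects the epoch with the best combination of
    validation Spearman, loss, and precision/recall — implemented as the
    minimum rank-sum of (loss ascending, -Spearman, -F1 at score 0.5).
    ``predict`` returns the scalar score S in (0, 1); higher predicts lower
    LRMSD.

    Parameters mirror :class:`NetworkConfig` plus the training knobs;
    everything is deterministic under ``seed``.
    """

    def __init__(
        self,
        n_bins: int = 2,
        embedding_dim: int = 8,
        conv_channels: tuple[int, ...] = (32, 32, 32),
        filter_hidden: int = 16,
        dense_sizes: tuple[int, int] = (64, 32),
        pooling: str = "mean",
        edge_dropout: float = 0.15,
        learning_rate: float = 0.001,
        max_epochs: int = 1000,
        batch_size: int = 64,
        patience: int | None = None,
        seed: int = 0,
        verbose: int = 0,
    ):
        self.n_bins = n_bins
        self.embedding_dim = embedding_dim
        self.conv_channels = conv_channels
        self.filter_hidden = filter_hidden
        self.dense_sizes = dense_sizes
        self.pooling = pooling
        self.edge_dropout = edge_dropout
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.seed = seed
        self.verbose = verbose

    # -- helpers -----------------------------------------------------------

    def _config(self) -> NetworkConfig:
        return NetworkConfig(
            n_bins=self.n_bins,
            embedding_dim=self.embedding_dim,
            conv_channels=tuple(self.conv_channels),
            filter_hidden=self.filter_hidden,
            dense_sizes=tuple(self.dense_sizes),
            pooling=self.pooling,
            edge_dropout=self.edge_dropout,
            seed=self.seed,
        )

    @staticmethod
    def _as_batch(X):
        if isinstance(X, tuple):
            return X
        return graphs_to_batch(list(X))

    def _labels(self, y) -> np.ndarray:
        norm = normalize_lrmsd(np.asarray(y, dtype=float))
        return np.asarray(
            [assign_bin(v, self.n_bins) for v in np.atleast_1d(norm)], dtype=int
        )

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, validation_data=None, groups=None, validation_groups=None):
        """Train on decoy graphs ``X`` with LRMSD labels ``y`` (Å).

        ``validation_data`` is an optional ``(graphs, lrmsd)`` pair used for
        per-epoch metrics and final-epoch selection.  ``groups`` /
        ``validation_groups`` (target or homology ids) are checked for
        disjointness when both are given.
        """
        if groups is not None and validation_groups is not None:
            overlap = set(groups) & set(validation_groups)
            if overlap:
                raise ValueError(
                    f"train/validation group overlap: {sorted(overlap)[:5]}"
                )
        config = self._config()
        rng = np.random.default_rng(self.seed)
        feats, code, mask = self._as_batch(X)
        labels = self._labels(y)
        if len(labels) != feats.shape[0]:
            raise ValueError("X and y length mismatch")
        eye = np.eye(self.n_bins)

        has_val = validation_data is not None
        if has_val:
            v_graphs, v_lrmsd = validation_data
            v_feats, v_code, v_mask = self._as_batch(v_graphs)
            v_lrmsd = np.asarray(v_lrmsd, dtype=float)
            v_norm = normalize_lrmsd(v_lrmsd)
            v_labels = self._labels(v_lrmsd)
            v_correct = v_lrmsd < 4.0

        params = init_params(config, rng)
        opt = _Adam(params, lr=self.learning_rate)
        n = feats.shape[0]
        history: list[dict] = []
        snapshots: list[dict] = []

        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                bcode = _dropout_codes(code[idx], self.edge_dropout, rng)
                probs, cache = _forward(
                    params, config, feats[idx], bcode, mask[idx], need_cache=True
                )
                yb = eye[labels[idx]]
                loss = -np.mean(np.log(np.sum(probs * yb, axis=1) + 1e-12))
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                grads = _backward(params, config, cache, probs, yb)
                opt.step(params, grads)
                epoch_loss += float(loss)
                n_batches += 1
            row = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
            if has_val:
                v_probs, _ = _forward(params, config, v_feats, v_code, v_mask)
                v_loss = -np.mean(
                    np.log(np.sum(v_probs * eye[v_labels], axis=1) + 1e-12)
                )
                scores = v_probs @ bin_centers(self.n_bins)
                rho = spearman(scores, v_norm)
                prec, rec, f1 = precision_recall_at(scores, v_correct, 0.5)
                row.update(
                    val_loss=float(v_loss),
                    val_spearman=rho,
                    val_precision=prec,
                    val_recall=rec,
                    val_f1=f1,
                )
                snapshots.append({k: v.copy() for k, v in params.items()})
            history.append(row)
            if self.verbose:
                print(
                    "  ".join(f"{k}={v:.4g}" if k != "epoch" else f"epoch {v}"
                              for k, v in row.items())
                )
            if has_val and self.patience is not None:
                best = self._select_epoch(history)
                if epoch - best >= self.patience:
                    break

        import pandas as pd

        self.history_ = pd.DataFrame(history)
        if has_val and snapshots:
            self.best_epoch_ = self._select_epoch(history)
            self.weights_ = snapshots[self.best_epoch_]
        else:
            self.best_epoch_ = len(history) - 1
            self.weights_ = params
        self.config_ = config
        return self

    @staticmethod
    def _select_epoch(history: list[dict]) -> int:
        """Epoch with minimum rank-sum of (val loss, -Spearman, -F1)."""
        from scipy.stats import rankdata

        loss = np.array([h["val_loss"] for h in history])
        rho = np.array([h["val_spearman"] for h in history])
        f1 = np.array([h["val_f1"] for h in history])
        total = rankdata(loss) + rankdata(-rho) + rankdata(-f1)
        return int(np.argmin(total))

    def predict_proba(self, X) -> np.ndarray:
        """Bin probabilities, shape (n_decoys, n_bins)."""
        if not hasattr(self, "weights_"):
            raise ValueError("estimator is not fitted")
        feats, code, mask = self._as_batch(X)
        if feats.shape[-1] != N_NODE_FEATURES:
            raise ValueError(
                f"node feature width {feats.shape[-1]} != {N_NODE_FEATURES}"
            )
        out = []
        for start in range(0, feats.shape[0], 256):
            sl = slice(start, start + 256)
            probs, _ = _forward(self.weights_, self.config_, feats[sl], code[sl], mask[sl])
            out.append(probs)
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        """Scores S in (0, 1); higher predicts lower LRMSD."""
        return self.predict_proba(X) @ bin_centers(self.n_bins)

    def score(self, X, y) -> float:
        """Spearman correlation between predicted score and LRMSD_norm."""
        return spearman(self.predict(X), normalize_lrmsd(np.asarray(y, dtype=float)))

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint weights + config to a .npz file."""
        if not hasattr(self, "weights_"):
            raise ValueError("estimator is not fitted")
        meta = {
            "config": self.config_.to_dict(),
            "params": self.get_params(),
            "best_epoch": int(self.best_epoch_),
        }
        np.savez_compressed(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.weights_,
        )

    @classmethod
    def load(cls, path) -> "InterPepRankNet":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            weights = {k: data[k] for k in data.files if k != "__meta__"}
        params = meta["params"]
        params["conv_channels"] = tuple(params["conv_channels"])
        params["dense_sizes"] = tuple(params["dense_sizes"])
        est = cls(**params)
        est.config_ = NetworkConfig.from_dict(meta["config"])
        est.weights_ = weights
        est.best_epoch_ = meta["best_epoch"]
        return est


class EnsembleScorer(BaseEstimator):
    """Average-score ensemble of trained networks.

    Members may have different architectures; they only need to accept the
    same graph shape.  ``fit`` trains each member with a distinct seed
    offset; ``predict`` is the arithmetic mean of member scores.
    """

    def __init__(self, members: list[InterPepRankNet]):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members

    def fit(self, X, y, validation_data=None, **kwargs):
        batch = InterPepRankNet._as_batch(X)
        vbatch = None
        if validation_data is not None:
            vbatch = (InterPepRankNet._as_batch(validation_data[0]), validation_data[1])
        for m in self.members:
            vd = (vbatch[0], vbatch[1]) if vbatch else None
            m.fit(batch, y, validation_data=vd, **kwargs)
        return self

    def member_scores(self, X) -> np.ndarray:
        batch = InterPepRankNet._as_batch(X)
        return np.stack([m.predict(batch) for m in self.members], axis=0)

    def predict(self, X) -> np.ndarray:
        return self.member_scores(X).mean(axis=0)

    def save(self, directory) -> None:
        """Write member checkpoints plus a manifest listing them."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = []
        for i, m in enumerate(self.members):
            name = f"member_{i}.npz"
            m.save(directory / name)
            names.append(name)
        (directory / "ensemble.json").write_text(json.dumps({"members": names}))

    @classmethod
    def load(cls, directory) -> "EnsembleScorer":
        directory = Path(directory)
        manifest = json.loads((directory / "ensemble.json").read_text())
        members = [InterPepRankNet.load(directory / n) for n in manifest["members"]]
        return cls(members)


def ensemble_score(graph: DecoyGraph, ensemble: EnsembleScorer) -> float:
    """Mean member score of a single decoy graph."""
    return float(ensemble.predict([graph])[0])
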
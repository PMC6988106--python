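"""Learned graph potentials: T-NET (t-links) and N-NET (n-links).

Both networks are built from Patch-NET feature extractors — stacked 3x3x3
convolution + max-pool blocks ending in a sigmoid feature vector — with one
parallel pathway per patch scale.  T-NET regresses the per-node scar
probability L-hat from the node's multi-scale patches.  N-NET is siamese:
the shared extractor maps both nodes' patch stacks to features F_i, F_j in
[0, 1]^d, fused into the elementwise similarity

    G_ij = F_i * F_j + (1 - F_i) * (1 - F_j),

concatenated with the (normalized) geodesic distance d_ij and regressed to
the label similarity M-hat.  Both are trained with plain SGD on squared
error against L_i and M_ij = L_i L_j + (1 - L_i)(1 - L_j); class imbalance
is handled by balanced node sampling, never inside the loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import prod

import numpy as np

from .msp import MSPConfig, extract_msp_batch
from .nn import SGD, Conv3d, Dense, Flatten, MaxPool3d, ReLU, Sequential, Sigmoid
from .surface import SurfaceMesh
from .volume import ImageVolume

__all__ = [
    "NetConfig", "TrainConfig", "PatchNet", "TNet", "NNet",
    "label_similarity", "similarity_features",
    "make_training_set", "make_edge_training_set", "TrainingSample",
    "fit_t_net", "fit_n_net", "train_t_net", "train_n_net",
    "t_net_predict", "n_net_predict",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class NetConfig:
    channels: tuple[int, ...] = (16, 32, 64)
    feature_dim: int = 64
    hidden: int = 32


@dataclass
class TrainConfig:
    """SGD hyperparameters; the defaults are the reference configuration."""

    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 50
    weight_decay: float = 1e-4
    epochs_t: int = 15
    epochs_n: int = 10
    lr_decay: float = 0.8
    lr_decay_every: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.momentum, self.batch_size, self.epochs_t,
               self.epochs_n, self.lr_decay, self.lr_decay_every) < 0:
            raise ValueError("training hyperparameters must be non-negative")


# ---------------------------------------------------------------------------
# similarity primitives

def label_similarity(l_i: float, l_j: float) -> float:
    """Ground-truth label similarity M_ij = Li*Lj + (1-Li)*(1-Lj)."""
    l_i, l_j = np.asarray(l_i, dtype=float), np.asarray(l_j, dtype=float)
    if np.any((l_i < 0) | (l_i > 1)) or np.any((l_j < 0) | (l_j > 1)):
        raise ValueError("label probabilities must lie in [0, 1]")
    return l_i * l_j + (1.0 - l_i) * (1.0 - l_j)


def similarity_features(f_i: np.ndarray, f_j: np.ndarray) -> np.ndarray:
    """Elementwise feature similarity G_ij; each component is in [0, 1]."""
    f_i, f_j = np.asarray(f_i, dtype=float), np.asarray(f_j, dtype=float)
    if f_i.shape != f_j.shape:
        raise ValueError(f"feature length mismatch: {f_i.shape} vs {f_j.shape}")
    return f_i * f_j + (1.0 - f_i) * (1.0 - f_j)


# ---------------------------------------------------------------------------
# architectures

class PatchNet:
    """Conv(3, pad 1) + ReLU + MaxPool(2) blocks, then Dense -> sigmoid features."""

    def __init__(self, dims, channels, feature_dim, rng):
        layers = []
        c_prev = 1
        shape = tuple(dims)
        for c in channels:
            layers += [Conv3d(c_prev, c, rng), ReLU(), MaxPool3d()]
            shape = MaxPool3d.out_shape(shape)
            c_prev = c
        self.flat_size = c_prev * prod(shape)
        layers += [Flatten(), Dense(self.flat_size, feature_dim, rng), Sigmoid()]
        self.net = Sequential(layers)

    def forward(self, x):  # x: (B, 1, D, H, W)
        return self.net.forward(x)

    def backward(self, grad):
        return self.net.backward(grad)

    def params(self):
        return self.net.params()


class _MultiScaleBase:
    """Shared plumbing for networks with per-scale Patch-NET pathways."""

    def __init__(self, dims, n_scales, net_cfg: NetConfig, rng):
        self.dims = tuple(dims)
        self.n_scales = n_scales
        self.cfg = net_cfg
        self.pathways = [PatchNet(dims, net_cfg.channels, net_cfg.feature_dim, rng)
                         for _ in range(n_scales)]
        self.trained = False
        # intensity standardization, fitted on the training patches
        self.x_mean = 0.0
        self.x_scale = 1.0

    def fit_input_scaling(self, x: np.ndarray) -> None:
        self.x_mean = float(np.mean(x))
        self.x_scale = float(np.std(x)) or 1.0

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.x_mean) / self.x_scale

    def _check_input(self, x):
        if x.ndim != 5 or x.shape[1] != self.n_scales or x.shape[2:] != self.dims:
            raise ValueError(
                f"expected patches of shape (B, {self.n_scales}, {self.dims}), "
                f"got {x.shape}")

    def _pathway_features(self, x):
        feats = [pw.forward(x[:, s][:, None]) for s, pw in enumerate(self.pathways)]
        return np.concatenate(feats, axis=1)

    def _pathway_backward(self, g_feat):
        fd = self.cfg.feature_dim
        for s, pw in enumerate(self.pathways):
            pw.backward(g_feat[:, s * fd:(s + 1) * fd])

    def params(self):
        out = [p for pw in self.pathways for p in pw.params()]
        return out + self.head.params()


class TNet(_MultiScaleBase):
    """Regresses the t-link weight L-hat(P_i) in [0, 1] from a node's MSPs."""

    def __init__(self, dims, n_scales, net_cfg: NetConfig, rng):
        super().__init__(dims, n_scales, net_cfg, rng)
        self.head = Sequential([
            Dense(n_scales * net_cfg.feature_dim, net_cfg.hidden, rng), ReLU(),
            Dense(net_cfg.hidden, 1, rng), Sigmoid(),
        ])

    def forward(self, x):
        self._check_input(x)
        z = self._pathway_features(self._normalize(x))
        return self.head.forward(z)[:, 0]

    def backward(self, g):
        gz = self.head.backward(g[:, None])
        self._pathway_backward(gz)

    def predict(self, x, chunk: int = 256) -> np.ndarray:
        out = [self.forward(x[i:i + chunk]) for i in range(0, len(x), chunk)]
        return np.concatenate(out) if out else np.zeros(0)


class NNet(_MultiScaleBase):
    """Regresses the n-link weight M-hat(P_i, P_j, d_ij); symmetric in (i, j)."""

    def __init__(self, dims, n_scales, net_cfg: NetConfig, rng):
        super().__init__(dims, n_scales, net_cfg, rng)
        self.head = Sequential([
            Dense(n_scales * net_cfg.feature_dim + 1, net_cfg.hidden, rng), ReLU(),
            Dense(net_cfg.hidden, 1, rng), Sigmoid(),
        ])
        self.d_min = 0.0
        self.d_max = 1.0

    def normalize_distance(self, d):
        span = self.d_max - self.d_min
        if span <= 0:
            return np.zeros_like(np.asarray(d, dtype=float))
        return np.clip((np.asarray(d, dtype=float) - self.d_min) / span, 0.0, 1.0)

    def forward(self, x_i, x_j, d):
        self._check_input(x_i)
        self._check_input(x_j)
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise ValueError("geodesic distances must be non-negative")
        b = len(x_i)
        # one pass through the shared pathways on the stacked pair batch
        f = self._pathway_features(self._normalize(np.concatenate([x_i, x_j], axis=0)))
        self._f_i, self._f_j = f[:b], f[b:]
        g_ij = similarity_features(self._f_i, self._f_j)
        z = np.concatenate([g_ij, self.normalize_distance(d)[:, None]], axis=1)
        return self.head.forward(z)[:, 0]

    def backward(self, g):
        gz = self.head.backward(g[:, None])
        g_sim = gz[:, :-1]
        g_fi = g_sim * (2.0 * self._f_j - 1.0)
        g_fj = g_sim * (2.0 * self._f_i - 1.0)
        self._pathway_backward(np.concatenate([g_fi, g_fj], axis=0))

    def predict(self, x_i, x_j, d, chunk: int = 256) -> np.ndarray:
        out = [self.forward(x_i[i:i + chunk], x_j[i:i + chunk], d[i:i + chunk])
               for i in range(0, len(x_i), chunk)]
        return np.concatenate(out) if out else np.zeros(0)


def t_net_predict(net: TNet, patches: np.ndarray) -> np.ndarray:
    """Per-node scar probabilities L-hat for a (B, N_s, *dims) patch array."""
    return net.predict(np.asarray(patches, dtype=float))


def n_net_predict(net: NNet, patches_i, patches_j, d_ij) -> np.ndarray:
    """Per-edge label similarities M-hat; symmetric under swapping i and j."""
    return net.predict(np.asarray(patches_i, dtype=float),
                       np.asarray(patches_j, dtype=float),
                       np.asarray(d_ij, dtype=float))


# ---------------------------------------------------------------------------
# training-set construction

@dataclass
class TrainingSample:
    scar_nodes: np.ndarray
    boundary_nodes: np.ndarray
    background_nodes: np.ndarray

    @property
    def nodes(self) -> np.ndarray:
        return np.concatenate([self.scar_nodes, self.boundary_nodes,
                               self.background_nodes])


def make_training_set(mesh: SurfaceMesh, labels: np.ndarray,
                      rng: np.random.Generator) -> TrainingSample:
    """Balanced node sample: all scar and scar-boundary nodes plus an
    equal-size uniform sample of the remaining background nodes."""
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0.0, 1.0}:
        raise ValueError("training labels must be binary")
    scar = np.flatnonzero(labels == 1)
    if len(scar) == 0:
        raise ValueError("no scar nodes; degenerate training case")
    is_scar = labels == 1
    e = mesh.edges
    boundary_mask = np.zeros(mesh.n_nodes, dtype=bool)
    cut = is_scar[e[:, 0]] != is_scar[e[:, 1]]
    boundary_mask[e[cut].ravel()] = True
    boundary = np.flatnonzero(boundary_mask & ~is_scar)
    rest = np.flatnonzero(~is_scar & ~boundary_mask)
    n_pick = len(scar) + len(boundary)
    if len(rest) == 0:
        raise ValueError("no background nodes to sample from")
    pick = rng.choice(rest, size=min(n_pick, len(rest)), replace=False)
    return TrainingSample(scar, boundary, np.sort(pick))


def make_edge_training_set(mesh: SurfaceMesh, labels: np.ndarray,
                           nodes: np.ndarray,
                           rng: np.random.Generator | None = None,
                           balance: bool = True):
    """Edge samples (i, j, d_ij, M_ij) over mesh edges internal to ``nodes``.

    n-links exist only on mesh edges, and for adjacent nodes the geodesic
    distance is the Euclidean edge length.  With ``balance`` (and an rng),
    dissimilar edges (M = 0), which sit only on the scar boundary and are
    rare, are all kept while similar edges are subsampled to at most twice
    their count — the same imbalance mitigation used for nodes.
    """
    labels = np.asarray(labels, dtype=float)
    in_set = np.zeros(mesh.n_nodes, dtype=bool)
    in_set[np.asarray(nodes, dtype=int)] = True
    e = mesh.edges
    keep = in_set[e[:, 0]] & in_set[e[:, 1]]
    edges = e[keep]
    d = mesh.edge_lengths[keep]
    m = label_similarity(labels[edges[:, 0]], labels[edges[:, 1]])
    if balance and rng is not None:
        cut = np.flatnonzero(m < 0.5)
        same = np.flatnonzero(m >= 0.5)
        if 0 < len(cut) and 2 * len(cut) < len(same):
            pick = np.sort(rng.choice(same, size=2 * len(cut), replace=False))
            sel = np.sort(np.r_[cut, pick])
            edges, d, m = edges[sel], d[sel], m[sel]
    return edges, d, m


# ---------------------------------------------------------------------------
# optimisation loops

def _make_optimizer(net, cfg: TrainConfig) -> SGD:
    return SGD(net.params(), lr=cfg.lr, momentum=cfg.momentum,
               weight_decay=cfg.weight_decay, decay=cfg.lr_decay,
               decay_every=cfg.lr_decay_every)


def _epoch_pass(batches, forward_backward, optimizer, epoch) -> float:
    total, count = 0.0, 0
    for batch in batches:
        loss = forward_backward(batch)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}, iteration {optimizer.iteration}; "
                "lower the learning rate or check the input scaling")
        optimizer.step()
        total += loss * len(batch)
        count += len(batch)
    return total / max(count, 1)


def _batches(n, batch_size, rng):
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def fit_t_net(net: TNet, x: np.ndarray, y: np.ndarray, cfg: TrainConfig,
              rng: np.random.Generator, epochs: int | None = None,
              optimizer: SGD | None = None) -> list[float]:
    """SGD on the squared t-link loss over fixed arrays; returns epoch losses."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0:
        raise ValueError("empty training set")
    if optimizer is None:
        net.fit_input_scaling(x)
        optimizer = _make_optimizer(net, cfg)
    losses = []

    def step(idx):
        pred = net.forward(x[idx])
        err = pred - y[idx]
        net.backward(2.0 * err / len(idx))
        return float(np.mean(err**2))

    for epoch in range(epochs if epochs is not None else cfg.epochs_t):
        losses.append(_epoch_pass(_batches(len(x), cfg.batch_size, rng),
                                  step, optimizer, epoch))
    net.trained = True
    return losses


def fit_n_net(net: NNet, x_i, x_j, d, m, cfg: TrainConfig,
              rng: np.random.Generator, epochs: int | None = None,
              optimizer: SGD | None = None) -> list[float]:
    """SGD on the squared n-link loss over fixed arrays; returns epoch losses."""
    x_i, x_j = np.asarray(x_i, dtype=float), np.asarray(x_j, dtype=float)
    d, m = np.asarray(d, dtype=float), np.asarray(m, dtype=float)
    if len(x_i) == 0:
        raise ValueError("empty training set")
    if optimizer is None:
        net.fit_input_scaling(np.concatenate([x_i, x_j]))
        net.d_min, net.d_max = float(d.min()), float(d.max())
        optimizer = _make_optimizer(net, cfg)
    losses = []

    def step(idx):
        pred = net.forward(x_i[idx], x_j[idx], d[idx])
        err = pred - m[idx]
        net.backward(2.0 * err / len(idx))
        return float(np.mean(err**2))

    for epoch in range(epochs if epochs is not None else cfg.epochs_n):
        losses.append(_epoch_pass(_batches(len(x_i), cfg.batch_size, rng),
                                  step, optimizer, epoch))
    net.trained = True
    return losses


def train_t_net(cases, msp_cfg: MSPConfig, cfg: TrainConfig,
                rng: np.random.Generator, net_cfg: NetConfig | None = None,
                net: TNet | None = None) -> tuple[TNet, list[float]]:
    """Train T-NET on a list of cases, re-extracting shifted patches per epoch.

    ``cases`` is a list of ``(image, mesh, nodes, labels)`` with ``labels``
    aligned to ``nodes``; the random shift gamma is redrawn once per node per
    epoch, which is how the shift acts as augmentation.
    """
    if not cases:
        raise ValueError("no training cases")
    if net is None:
        net = TNet(msp_cfg.dims, msp_cfg.n_scales, net_cfg or NetConfig(), rng)
    optimizer = None
    losses = []
    for epoch in range(cfg.epochs_t):
        xs, ys = [], []
        for image, mesh, nodes, labels in cases:
            patches, _ = extract_msp_batch(image, mesh, nodes, msp_cfg, rng)
            xs.append(patches)
            ys.append(np.asarray(labels, dtype=float))
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if optimizer is None:
            net.fit_input_scaling(x)
            optimizer = _make_optimizer(net, cfg)
        losses += fit_t_net(net, x, y, cfg, rng, epochs=1, optimizer=optimizer)
    net.trained = True
    return net, losses


def train_n_net(cases, msp_cfg: MSPConfig, cfg: TrainConfig,
                rng: np.random.Generator, net_cfg: NetConfig | None = None,
                net: NNet | None = None) -> tuple[NNet, list[float]]:
    """Train N-NET on a list of ``(image, mesh, edges, d, m)`` cases.

    Patches are extracted per epoch with one shift per participating node, so
    both endpoints of an edge see consistent augmentation.
    """
    if not cases:
        raise ValueError("no training cases")
    if net is None:
        net = NNet(msp_cfg.dims, msp_cfg.n_scales, net_cfg or NetConfig(), rng)
    all_d = np.concatenate([np.asarray(c[3], dtype=float) for c in cases])
    net.d_min, net.d_max = float(all_d.min()), float(all_d.max())
    optimizer = None
    losses = []
    for epoch in range(cfg.epochs_n):
        xi, xj, ds, ms = [], [], [], []
        for image, mesh, edges, d, m in cases:
            uniq, inv = np.unique(edges, return_inverse=True)
            patches, _ = extract_msp_batch(image, mesh, uniq, msp_cfg, rng)
            pair = patches[inv.reshape(edges.shape)]
            xi.append(pair[:, 0])
            xj.append(pair[:, 1])
            ds.append(np.asarray(d, dtype=float))
            ms.append(np.asarray(m, dtype=float))
        bxi, bxj = np.concatenate(xi), np.concatenate(xj)
        if optimizer is None:
            net.fit_input_scaling(np.concatenate([bxi, bxj]))
            optimizer = _make_optimizer(net, cfg)
        losses += fit_n_net(net, bxi, bxj, np.concatenate(ds), np.concatenate(ms),
                            cfg, rng, epochs=1, optimizer=optimizer)
    # keep the normalization fitted on the full set, not the last epoch's batch
    net.d_min, net.d_max = float(all_d.min()), float(all_d.max())
    net.trained = True
    return net, losses


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(net: TNet | NNet, path: str, extra: dict | None = None) -> None:
    meta = {
        "kind": type(net).__name__,
        "dims": list(net.dims),
        "n_scales": net.n_scales,
        "channels": list(net.cfg.channels),
        "feature_dim": net.cfg.feature_dim,
        "hidden": net.cfg.hidden,
        "trained": bool(net.trained),
        "x_mean": net.x_mean,
        "x_scale": net.x_scale,
        "extra": extra or {},
    }
    if isinstance(net, NNet):
        meta["d_min"], meta["d_max"] = net.d_min, net.d_max
    arrays = {f"p{i}": getattr(p["layer"], p["name"])
              for i, p in enumerate(net.params())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str) -> TNet | NNet:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    net_cfg = NetConfig(tuple(meta["channels"]), meta["feature_dim"], meta["hidden"])
    cls = TNet if meta["kind"] == "TNet" else NNet
    net = cls(tuple(meta["dims"]), meta["n_scales"], net_cfg,
              np.random.default_rng(0))
    for i, p in enumerate(net.params()):
        getattr(p["layer"], p["name"])[...] = data[f"p{i}"]
    net.trained = meta["trained"]
    net.x_mean = meta.get("x_mean", 0.0)
    net.x_scale = meta.get("x_scale", 1.0)
    if isinstance(net, NNet):
        net.d_min, net.d_max = meta["d_min"], meta["d_max"]
    return net
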
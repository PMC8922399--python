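"""Attentive graph network with a shared trunk and per-target heads.

The architecture follows the attentive-fingerprint family: each atom
repeatedly aggregates messages from its bonded neighbors through a
softmax attention

    alpha_{k<-j} = softmax_j( LeakyReLU( a^T [W h_k || W h_j] ) )

and updates its state with a gated recurrent unit; a molecule embedding
is then built by an attentive readout in which a virtual super-node
attends over all atoms for a fixed number of timesteps.  A single linear
layer maps the shared embedding to one predicted pIC50 per target, so
sparsely labelled targets borrow representation learned from densely
labelled ones (multitask learning with a masked loss).

Training-relevant defaults mirror common practice for this architecture
family: two attentive layers, LeakyReLU slope 0.01, Glorot-uniform
initialization from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np

from .graphs import (BatchedGraph, FeatureSchema, batch_graphs, mol_to_graph)
from .tensor import (Tensor, concat, gather, leaky_relu, segment_mean,
                     segment_softmax, segment_sum, sigmoid, tanh)

__all__ = ["MTModelConfig", "MTModelState", "ForwardResult", "init_model",
           "forward_multitask", "predict", "masked_mse_loss",
           "attention_scores", "save_checkpoint", "load_checkpoint",
           "single_task_config"]


@dataclass(frozen=True)
class MTModelConfig:
    """Hyperparameters of the shared-trunk multitask graph network."""

    targets: tuple
    n_attentive_layers: int = 2
    graph_feat_size: int = 300
    n_readout_timesteps: int = 2
    dropout: float = 0.2
    leakyrelu_slope: float = 0.01
    use_bond_features: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_attentive_layers < 1:
            raise ValueError("need at least one attentive layer")
        if self.graph_feat_size < 1:
            raise ValueError("graph_feat_size must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if len(self.targets) < 1:
            raise ValueError("need at least one target")


@dataclass
class MTModelState:
    """Learned parameters plus the config and feature-schema hash.

    ``y_mean``/``y_std`` hold the per-target label standardization
    fitted on the training split; heads are trained on z-scored labels
    and predictions are mapped back to pIC50 units at inference.
    """

    config: MTModelConfig
    params: dict          # name -> Tensor(requires_grad=True)
    schema_hash: str
    y_mean: np.ndarray | None = None
    y_std: np.ndarray | None = None

    def rescale(self, raw_predictions: np.ndarray) -> np.ndarray:
        """Map head outputs from z-score space back to pIC50 units."""
        if self.y_mean is None:
            return raw_predictions
        return raw_predictions * self.y_std + self.y_mean

    def trainables(self) -> list[Tensor]:
        return list(self.params.values())

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def copy_params(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_params(self, snapshot: dict) -> None:
        for k, v in snapshot.items():
            self.params[k].data = v.copy()


@dataclass
class ForwardResult:
    predictions: Tensor                 # (n_mols, n_targets)
    atom_embedding: Tensor              # initial atom states (for saliency)
    attention_per_layer: list           # list of (n_edges,) numpy weights
    edge_dst: np.ndarray                # destination atom of each edge used
    readout_attention: list             # per-timestep (n_atoms,) numpy weights
    mol_index: np.ndarray


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def _gru_params(rng, d_in: int, d: int, prefix: str) -> dict:
    p = {}
    for gate in ("r", "z", "n"):
        p[f"{prefix}_Wx{gate}"] = _glorot(rng, d_in, d, (d_in, d))
        p[f"{prefix}_Wh{gate}"] = _glorot(rng, d, d, (d, d))
        p[f"{prefix}_b{gate}"] = Tensor(np.zeros(d), requires_grad=True)
    return p


def init_model(config: MTModelConfig,
               schema: FeatureSchema | None = None) -> MTModelState:
    """Glorot-uniform initialization, fully determined by ``config.seed``."""
    schema = schema or FeatureSchema()
    rng = np.random.default_rng(config.seed)
    d = config.graph_feat_size
    fa, fb = schema.atom_width, schema.bond_width
    msg_in = d + fb if config.use_bond_features else d

    params: dict = {
        "embed_W": _glorot(rng, fa, d, (fa, d)),
        "embed_b": Tensor(np.zeros(d), requires_grad=True),
    }
    for layer in range(config.n_attentive_layers):
        pre = f"l{layer}"
        params[f"{pre}_Watt"] = _glorot(rng, d, d, (d, d))
        params[f"{pre}_a"] = _glorot(rng, 2 * d, 1, (2 * d, 1))
        params[f"{pre}_Wmsg"] = _glorot(rng, msg_in, d, (msg_in, d))
        params[f"{pre}_bmsg"] = Tensor(np.zeros(d), requires_grad=True)
        params.update(_gru_params(rng, d, d, pre))
    params["ro_Watt"] = _glorot(rng, d, d, (d, d))
    params["ro_a"] = _glorot(rng, 2 * d, 1, (2 * d, 1))
    params["ro_Wmsg"] = _glorot(rng, d, d, (d, d))
    params["ro_bmsg"] = Tensor(np.zeros(d), requires_grad=True)
    params.update(_gru_params(rng, d, d, "ro"))
    params["head_W"] = _glorot(rng, d, len(config.targets),
                               (d, len(config.targets)))
    params["head_b"] = Tensor(np.zeros(len(config.targets)),
                              requires_grad=True)
    return MTModelState(config=config, params=params,
                        schema_hash=schema.fingerprint())


def _gru(x: Tensor, h: Tensor, p: dict, prefix: str) -> Tensor:
    r = sigmoid(x @ p[f"{prefix}_Wxr"] + h @ p[f"{prefix}_Whr"] + p[f"{prefix}_br"])
    z = sigmoid(x @ p[f"{prefix}_Wxz"] + h @ p[f"{prefix}_Whz"] + p[f"{prefix}_bz"])
    n = tanh(x @ p[f"{prefix}_Wxn"] + r * (h @ p[f"{prefix}_Whn"]) + p[f"{prefix}_bn"])
    return (Tensor(1.0) - z) * n + z * h


def _with_self_loops(batch: BatchedGraph) -> tuple[np.ndarray, np.ndarray]:
    """Append a self-edge (zero bond features) for atoms with no bonds.

    This is the fallback that keeps single-heavy-atom molecules scorable:
    an isolated atom attends to itself with weight one.
    """
    if len(batch.edges):
        in_deg = np.bincount(batch.edges[:, 1], minlength=batch.n_atoms)
    else:
        in_deg = np.zeros(batch.n_atoms, dtype=int)
    isolated = np.flatnonzero(in_deg == 0)
    if len(isolated) == 0:
        return batch.edges, batch.bond_features
    self_edges = np.stack([isolated, isolated], axis=1)
    edges = np.vstack([batch.edges, self_edges]) if len(batch.edges) else self_edges
    fb = batch.bond_features.shape[1]
    bonds = np.vstack([batch.bond_features, np.zeros((len(isolated), fb))])
    return edges.astype(np.intp), bonds


def forward_multitask(batch: BatchedGraph, state: MTModelState,
                      train: bool = False,
                      dropout_rng: np.random.Generator | None = None
                      ) -> ForwardResult:
    """Run the shared trunk and all target heads on a batched graph.

    Dropout is applied to the molecule embedding only when ``train`` is
    true; at inference the forward pass is deterministic.
    """
    cfg = state.config
    p = state.params
    slope = cfg.leakyrelu_slope
    d = cfg.graph_feat_size
    n_atoms, n_mols = batch.n_atoms, batch.n_mols
    edges, bond_feats = _with_self_loops(batch)
    src, dst = edges[:, 0], edges[:, 1]

    x = Tensor(batch.atom_features)
    h0 = leaky_relu(x @ p["embed_W"] + p["embed_b"], slope)
    h = h0

    attn_layers = []
    for layer in range(cfg.n_attentive_layers):
        pre = f"l{layer}"
        hp = h @ p[f"{pre}_Watt"]
        logits = _attention_logits(hp, p[f"{pre}_a"], src, dst, slope)
        alpha = segment_softmax(logits, dst, n_atoms)
        if cfg.use_bond_features:
            msg_in = concat([gather(h, src), Tensor(bond_feats)], axis=1)
        else:
            msg_in = gather(h, src)
        msg = leaky_relu(msg_in @ p[f"{pre}_Wmsg"] + p[f"{pre}_bmsg"], slope)
        ctx = segment_sum(alpha.reshape(-1, 1) * msg, dst, n_atoms)
        h = _gru(ctx, h, p, pre)
        attn_layers.append(alpha.data.copy())

    # attentive readout over a virtual super-node
    s = segment_mean(h, batch.mol_index, n_mols)
    readout_attn = []
    for _ in range(cfg.n_readout_timesteps):
        hp = h @ p["ro_Watt"]
        sp = s @ p["ro_Watt"]
        logits = _attention_logits_readout(sp, hp, p["ro_a"],
                                           batch.mol_index, slope)
        alpha = segment_softmax(logits, batch.mol_index, n_mols)
        msg = leaky_relu(h @ p["ro_Wmsg"] + p["ro_bmsg"], slope)
        ctx = segment_sum(alpha.reshape(-1, 1) * msg, batch.mol_index, n_mols)
        s = _gru(ctx, s, p, "ro")
        readout_attn.append(alpha.data.copy())

    if train and cfg.dropout > 0.0:
        if dropout_rng is None:
            raise ValueError("training forward with dropout needs an rng")
        keep = (dropout_rng.random(s.data.shape) >= cfg.dropout)
        s = s * Tensor(keep / (1.0 - cfg.dropout))

    pred = s @ p["head_W"] + p["head_b"]
    return ForwardResult(predictions=pred, atom_embedding=h0,
                         attention_per_layer=attn_layers, edge_dst=dst,
                         readout_attention=readout_attn,
                         mol_index=batch.mol_index)


def _attention_logits(hp: Tensor, a: Tensor, src: np.ndarray,
                      dst: np.ndarray, slope: float) -> Tensor:
    """e_kj = LeakyReLU(a^T [W h_k || W h_j]) for every directed edge j->k."""
    zk = gather(hp, dst)
    zj = gather(hp, src)
    return leaky_relu((concat([zk, zj], axis=1) @ a).reshape(-1), slope)


def _attention_logits_readout(sp: Tensor, hp: Tensor, a: Tensor,
                              mol_index: np.ndarray, slope: float) -> Tensor:
    zs = gather(sp, mol_index)
    return leaky_relu((concat([zs, hp], axis=1) @ a).reshape(-1), slope)


def attention_scores(h_k: np.ndarray, neighbor_states: list[np.ndarray],
                     W: np.ndarray, a: np.ndarray,
                     slope: float = 0.01) -> np.ndarray:
    """Reference (non-batched) neighbor attention for one node.

    Returns softmax_j over LeakyReLU(a^T [W h_k || W h_j]); used both as
    the documented definition and as a cross-check of the batched path.
    """
    if len(neighbor_states) == 0:
        raise ValueError("attention over an empty neighbor set is undefined")
    wk = W.T @ np.asarray(h_k, dtype=float)
    logits = []
    for h_j in neighbor_states:
        cat = np.concatenate([wk, W.T @ np.asarray(h_j, dtype=float)])
        e = float(np.asarray(a).reshape(-1) @ cat)
        logits.append(e if e > 0 else slope * e)
    logits = np.array(logits)
    ex = np.exp(logits - logits.max())
    return ex / ex.sum()


def masked_mse_loss(pred: Tensor, labels: np.ndarray,
                    mask: np.ndarray) -> Tensor:
    """Mean squared error over labelled (molecule, target) entries only.

    Entries with absent labels contribute exactly zero loss and zero
    gradient; the mean is taken over all masked-true entries in the
    batch.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask selects no labelled entries")
    filled = np.where(mask, np.asarray(labels, dtype=float), 0.0)
    diff = (pred - Tensor(filled)) * Tensor(mask.astype(float))
    return (diff * diff).sum() * (1.0 / n)


def predict(smiles_list: list[str], state: MTModelState,
            schema: FeatureSchema | None = None) -> np.ndarray:
    """Predicted pIC50 matrix (n_molecules, n_targets) at inference."""
    schema = schema or FeatureSchema()
    if schema.fingerprint() != state.schema_hash:
        raise ValueError("feature schema does not match the trained model")
    batch = batch_graphs([mol_to_graph(s, schema) for s in smiles_list])
    raw = forward_multitask(batch, state, train=False).predictions.data
    return state.rescale(raw)


def single_task_config(config: MTModelConfig, target: str) -> MTModelConfig:
    """Restrict a multitask config to one target (single-task reduction)."""
    if target not in config.targets:
        raise ValueError(f"unknown target {target!r}")
    return MTModelConfig(targets=(target,),
                         n_attentive_layers=config.n_attentive_layers,
                         graph_feat_size=config.graph_feat_size,
                         n_readout_timesteps=config.n_readout_timesteps,
                         dropout=config.dropout,
                         leakyrelu_slope=config.leakyrelu_slope,
                         use_bond_features=config.use_bond_features,
                         seed=config.seed)


# -- checkpoint io ------------------------------------------------------

def save_checkpoint(state: MTModelState, path: str) -> None:
    payload = {
        "config": asdict(state.config),
        "schema_hash": state.schema_hash,
        "params": {k: v.data.tolist() for k, v in state.params.items()},
        "y_mean": None if state.y_mean is None else state.y_mean.tolist(),
        "y_std": None if state.y_std is None else state.y_std.tolist(),
    }
    payload["config"]["targets"] = list(state.config.targets)
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path: str,
                    schema: FeatureSchema | None = None) -> MTModelState:
    """Load a checkpoint; refuses to load under a mismatched schema."""
    with open(path) as fh:
        payload = json.load(fh)
    schema = schema or FeatureSchema()
    if payload["schema_hash"] != schema.fingerprint():
        raise ValueError("checkpoint was trained under a different feature schema")
    cfg_d = payload["config"]
    cfg_d["targets"] = tuple(cfg_d["targets"])
    config = MTModelConfig(**cfg_d)
    state = init_model(config, schema)
    for k, v in payload["params"].items():
        state.params[k].data = np.asarray(v, dtype=np.float64)
    if payload.get("y_mean") is not None:
        state.y_mean = np.asarray(payload["y_mean"])
        state.y_std = np.asarray(payload["y_std"])
    return state
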
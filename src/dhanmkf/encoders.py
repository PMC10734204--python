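"""Dual hierarchical relation-aware attention encoders.

Two encoders run in sequence on the typed heterogeneous graph:

* the **intra-type** encoder aggregates same-type neighbors per intra
  relation with node-level attention, layer-normalizes per relation, and
  fuses relations with a learned mixture of *local* (per-node softmax) and
  *global* (graph-level softmax) relation importances smoothed by a learned
  scalar ``t``;
* the **inter-type** encoder projects both node types into a common space,
  aggregates cross-type neighbors per inter relation, and fuses relations
  with per-node softmax importances.

Node features are initialized as ``H0_c = S_c @ Y_train @ W_c`` (drugs
analogously with ``Y_train^T``), and every layer's output is stacked for the
downstream multi-kernel stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import (
    Tensor,
    concat,
    layer_norm,
    segment_softmax,
    segment_sum,
    stack_mean,
)
from .hetgraph import EdgeList, TypedEdges

logger = logging.getLogger(__name__)


@dataclass
class EncoderConfig:
    dim: int = 16
    heads: int = 5
    layers_intra: int = 1
    layers_inter: int = 1
    dropout: float = 0.026
    leaky_slope: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1 or self.heads < 1:
            raise ValueError("dim and heads must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class EmbeddingStack:
    """Per-layer embedding matrices {H0, Z1..Zt, U1..UM} for one node type."""

    layers: list[Tensor] = field(default_factory=list)
    kinds: list[str] = field(default_factory=list)  # "init" | "intra" | "inter"

    def __len__(self) -> int:
        return len(self.layers)

    def arrays(self) -> list[np.ndarray]:
        return [t.data for t in self.layers]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[1] if len(shape) > 1 else 1
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(
    n_circ: int,
    n_drug: int,
    graph: TypedEdges,
    cfg: EncoderConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, Tensor]:
    """Glorot-uniform parameter initialization for the configured encoder."""
    rng = rng or np.random.default_rng(cfg.seed)
    d = cfg.dim
    p: dict[str, Tensor] = {}

    def param(name: str, shape: tuple[int, ...], init: str = "glorot") -> None:
        if init == "glorot":
            data = _glorot(rng, shape)
        elif init == "ones":
            data = np.ones(shape)
        else:
            data = np.zeros(shape)
        p[name] = Tensor(data, requires_grad=True)

    param("W_intra_c", (n_drug, d))
    param("W_intra_d", (n_circ, d))

    intra_rels = {"c": sorted(graph.intra_c), "d": sorted(graph.intra_d)}
    for layer in range(cfg.layers_intra):
        for side in ("c", "d"):
            for r in intra_rels[side]:
                for h in range(cfg.heads):
                    param(f"a_intra_{side}{layer}_r{r}_h{h}", (2 * d, 1))
                param(f"ln_g_intra_{side}{layer}_r{r}", (d,), "ones")
                param(f"ln_b_intra_{side}{layer}_r{r}", (d,), "zeros")
            param(f"q_intra_{side}{layer}", (2 * d, 1))
            # one global-importance slot per possible intra relation id;
            # the layer softmaxes over the relations present at call time
            param(f"betaG_{side}{layer}", (3, 1), "zeros")
            param(f"t_raw_{side}{layer}", (1, 1), "zeros")

    inter_rels = sorted(graph.inter)
    for layer in range(cfg.layers_inter):
        param(f"W_inter_c_{layer}", (d, d))
        param(f"W_inter_d_{layer}", (d, d))
        for side in ("c", "d"):
            for r in inter_rels:
                for h in range(cfg.heads):
                    param(f"a_inter_{side}{layer}_r{r}_h{h}", (2 * d, 1))
                param(f"ln_g_inter_{side}{layer}_r{r}", (d,), "ones")
                param(f"ln_b_inter_{side}{layer}_r{r}", (d,), "zeros")
            param(f"q_inter_{side}{layer}", (2 * d, 1))
    return p


def init_features(
    s: np.ndarray, y_train: np.ndarray, w: Tensor
) -> Tensor:
    """H0 = S @ Y_train @ W (pass Y_train^T for the drug side)."""
    base = np.asarray(s, dtype=float) @ np.asarray(y_train, dtype=float)
    if base.shape[1] != w.shape[0]:
        raise ValueError(f"projection shape {w.shape} incompatible with {base.shape}")
    return Tensor(base) @ w


def _dropout_mask(
    shape: tuple[int, ...], p: float, rng: np.random.Generator | None
) -> np.ndarray | None:
    if rng is None or p <= 0.0:
        return None
    return (rng.random(shape) >= p).astype(float) / (1.0 - p)


def _attend(
    feats_src: Tensor,
    feats_dst: Tensor,
    edges: EdgeList,
    att_vectors: list[Tensor],
    ln_gain: Tensor,
    ln_bias: Tensor,
    n_out: int,
    slope: float,
    dropout: float,
    rng: np.random.Generator | None,
    probe: dict | None = None,
    probe_key: tuple = (),
) -> Tensor:
    """Single relation, multi-head attention aggregation.

    Edge (src, dst) means *dst* is a neighbor aggregated into *src*.
    Attention scores are LeakyReLU(a^T [f_src || f_dst]) softmaxed over each
    src node's edges; messages are the dst features.  Heads run the full
    single-head pipeline (aggregate, LayerNorm, LeakyReLU) and are averaged.
    Nodes without edges under this relation keep a zero row.
    """
    src, dst = edges
    cat = concat([feats_src.gather_rows(src), feats_dst.gather_rows(dst)], axis=1)
    mask = np.zeros((n_out, 1))
    mask[np.unique(src)] = 1.0

    head_outputs = []
    for head, a in enumerate(att_vectors):
        scores = (cat @ a).reshape(len(src)).leaky_relu(slope)
        alpha = segment_softmax(scores, src, n_out)
        if probe is not None:
            probe[probe_key + (head,)] = (alpha.data.copy(), src.copy())
        dmask = _dropout_mask(alpha.shape, dropout, rng)
        if dmask is not None:
            alpha = alpha * dmask
        messages = alpha.reshape(len(src), 1) * feats_dst.gather_rows(dst)
        agg = segment_sum(messages, src, n_out)
        head_outputs.append(layer_norm(agg, ln_gain, ln_bias).leaky_relu(slope))
    return stack_mean(head_outputs) * mask


def _relation_softmax(gates: list[Tensor]) -> list[Tensor]:
    """Per-node softmax across a list of (N,1) gate columns."""
    stacked = np.stack([g.data[:, 0] for g in gates], axis=1)
    shift = Tensor(stacked.max(axis=1, keepdims=True))  # constant; softmax-invariant
    exps = [(g - shift).exp() for g in gates]
    denom = exps[0]
    for e in exps[1:]:
        denom = denom + e
    return [e / denom for e in exps]


def intra_layer(
    feats: Tensor,
    rel_edges: dict[int, EdgeList],
    params: dict[str, Tensor],
    side: str,
    layer: int,
    cfg: EncoderConfig,
    rng: np.random.Generator | None = None,
    probe: dict | None = None,
) -> Tensor:
    """One intra-type layer: per-relation attention + global/local fusion."""
    n = feats.shape[0]
    rels = sorted(rel_edges)
    if not rels:
        logger.warning("intra layer %s%d has no relations; passing features through", side, layer)
        return feats
    per_rel: list[Tensor] = []
    for r in rels:
        att = [params[f"a_intra_{side}{layer}_r{r}_h{h}"] for h in range(cfg.heads)]
        per_rel.append(
            _attend(
                feats, feats, rel_edges[r], att,
                params[f"ln_g_intra_{side}{layer}_r{r}"],
                params[f"ln_b_intra_{side}{layer}_r{r}"],
                n, cfg.leaky_slope, cfg.dropout, rng,
                probe, ("intra", side, layer, r),
            )
        )
    q = params[f"q_intra_{side}{layer}"]
    gates = [concat([feats, h_rel], axis=1) @ q for h_rel in per_rel]
    beta_local = _relation_softmax(gates)

    beta_g_param = params[f"betaG_{side}{layer}"]
    exps = beta_g_param.gather_rows(np.asarray([r - 1 for r in rels])).exp()
    denom = exps.sum()
    t = params[f"t_raw_{side}{layer}"].sigmoid()

    out = None
    weight_cols = []
    for k, h_rel in enumerate(per_rel):
        beta_g_k = exps.gather_rows(np.asarray([k])) / denom  # (1,1)
        weight = t * beta_g_k + (1.0 - t) * beta_local[k]  # (N,1) by broadcast
        weight_cols.append(np.broadcast_to(weight.data, (n, 1)))
        term = weight * h_rel
        out = term if out is None else out + term
    if probe is not None:
        probe[("intra", side, layer, "weights")] = np.concatenate(weight_cols, axis=1)
    return out


def inter_layer(
    z_c: Tensor,
    z_d: Tensor,
    inter_edges: dict[int, EdgeList],
    params: dict[str, Tensor],
    layer: int,
    cfg: EncoderConfig,
    rng: np.random.Generator | None = None,
    probe: dict | None = None,
) -> tuple[Tensor, Tensor]:
    """One inter-type layer for both sides.

    Both types are projected into a common space; each side aggregates its
    cross-type neighbors per inter relation and fuses relations with
    per-node softmax importances.
    """
    n_c, n_d = z_c.shape[0], z_d.shape[0]
    rels = sorted(inter_edges)
    if not rels:
        logger.warning("inter layer %d has no relations; passing features through", layer)
        return z_c, z_d
    proj_c = z_c @ params[f"W_inter_c_{layer}"]
    proj_d = z_d @ params[f"W_inter_d_{layer}"]

    def one_side(side: str, feats_self: Tensor, proj_self: Tensor, proj_other: Tensor,
                 n_self: int) -> Tensor:
        per_rel = []
        for r in rels:
            ci, dj = inter_edges[r]
            src, dst = (ci, dj) if side == "c" else (dj, ci)
            att = [params[f"a_inter_{side}{layer}_r{r}_h{h}"] for h in range(cfg.heads)]
            per_rel.append(
                _attend(
                    proj_self, proj_other, (src, dst), att,
                    params[f"ln_g_inter_{side}{layer}_r{r}"],
                    params[f"ln_b_inter_{side}{layer}_r{r}"],
                    n_self, cfg.leaky_slope, cfg.dropout, rng,
                    probe, ("inter", side, layer, r),
                )
            )
        q = params[f"q_inter_{side}{layer}"]
        gates = [concat([feats_self, z_rel], axis=1) @ q for z_rel in per_rel]
        eps_weights = _relation_softmax(gates)
        out = None
        for w, z_rel in zip(eps_weights, per_rel):
            term = w * z_rel
            out = term if out is None else out + term
        if probe is not None:
            probe[("inter", side, layer, "weights")] = np.concatenate(
                [w.data for w in eps_weights], axis=1
            )
        return out

    u_c = one_side("c", z_c, proj_c, proj_d, n_c)
    u_d = one_side("d", z_d, proj_d, proj_c, n_d)
    return u_c, u_d


def forward(
    graph: TypedEdges,
    s_c: np.ndarray,
    s_d: np.ndarray,
    y_train: np.ndarray,
    params: dict[str, Tensor],
    cfg: EncoderConfig,
    rng: np.random.Generator | None = None,
    probe: dict | None = None,
) -> tuple[EmbeddingStack, EmbeddingStack]:
    """Run t intra layers then M inter layers; stack every layer's output.

    With t = M = 1 each stack holds three matrices: {H0, Z1, U1}.
    Pass ``rng`` only during training (it drives attention dropout).
    ``probe`` (a dict) collects every attention coefficient vector and
    relation-mixture weight matrix for inspection.
    """
    h_c = init_features(s_c, y_train, params["W_intra_c"])
    h_d = init_features(s_d, np.asarray(y_train).T, params["W_intra_d"])
    stack_c = EmbeddingStack([h_c], ["init"])
    stack_d = EmbeddingStack([h_d], ["init"])

    for layer in range(cfg.layers_intra):
        h_c = intra_layer(h_c, graph.intra_c, params, "c", layer, cfg, rng, probe)
        h_d = intra_layer(h_d, graph.intra_d, params, "d", layer, cfg, rng, probe)
        stack_c.layers.append(h_c)
        stack_c.kinds.append("intra")
        stack_d.layers.append(h_d)
        stack_d.kinds.append("intra")

    z_c, z_d = h_c, h_d
    for layer in range(cfg.layers_inter):
        z_c, z_d = inter_layer(z_c, z_d, graph.inter, params, layer, cfg, rng, probe)
        stack_c.layers.append(z_c)
        stack_c.kinds.append("inter")
        stack_d.layers.append(z_d)
        stack_d.kinds.append("inter")
    return stack_c, stack_d
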
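"""Model and results objects.

``DhanMkf`` bundles the full pipeline behind a statsmodels-style interface:
build the model from an association matrix plus the two primary similarity
matrices, call :meth:`DhanMkf.fit`, and read predictions and diagnostics off
the returned :class:`DhanMkfResults`.

One fit runs, per epoch: (1) the dual hierarchical attention encoders
forward; (2) Gaussian kernels over every embedding layer, averaged into the
fused kernels; (3) exact closed-form alternating updates of the two
coefficient matrices; (4) the regularized least-squares loss restricted to
the balanced training sample, backpropagated through kernels and embeddings
into the encoder parameters (coefficients held constant) and applied with
Adam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dlaprls
from .autodiff import Adam, Tensor
from .encoders import EncoderConfig, forward, init_params
from .fusion import FusionConfig, snf_fuse
from .hetgraph import NodePartition, TypedEdges, build_graph
from .io_data import AssociationMatrix, sample_negatives
from .similarity import gip_bandwidth, gip_kernel

logger = logging.getLogger(__name__)

ABLATIONS = ("none", "intra", "inter", "multi")


@dataclass
class ModelConfig:
    """All tunable knobs of the pipeline with their default settings."""

    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    snf: FusionConfig = field(default_factory=FusionConfig)
    k_circ: int | str = 27  # head/tail degree threshold (circRNA side)
    k_drug: int | str = 39  # head/tail degree threshold (drug side)
    sparsify_k: int = 10  # similarity neighbors kept per node
    gamma: float = 1.0 / 75.0  # embedding-kernel bandwidth
    phi_c: float = 1.0 / 120.0
    phi_d: float = 1.0 / 120.0
    gip_alpha: float = 1.0
    epochs: int = 40
    learning_rate: float = 0.05
    weight_decay: float = 0.01
    jitter: float = 1e-8
    ablation: str = "none"

    def __post_init__(self) -> None:
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs >= 1 and learning_rate > 0 required")


@dataclass
class DhanMkfResults:
    """Fitted pipeline state: score matrix, coefficients and diagnostics."""

    model: "DhanMkf"
    predictions: np.ndarray
    state: dlaprls.DLapRLSState
    fused_ic: np.ndarray
    fused_id: np.ndarray
    loss_history: list[float]
    snf_info_c: dict
    snf_info_d: dict
    n_train_pairs: int
    seed: int

    @property
    def prediction_frame(self) -> pd.DataFrame:
        m = self.model.y
        return pd.DataFrame(
            self.predictions,
            index=list(m.row_index.ids),
            columns=list(m.col_index.ids),
        )

    def score_pairs(self, pairs: list[tuple[int, int]]) -> np.ndarray:
        idx = np.asarray(pairs, dtype=int)
        return self.predictions[idx[:, 0], idx[:, 1]]

    def rank_candidates(
        self, drug_id: str, top_n: int = 20, exclude_known: bool = False
    ) -> list[tuple[str, float]]:
        """circRNAs ranked by predicted score for one drug.

        Ties break lexicographically by circRNA id.  ``exclude_known`` drops
        circRNAs whose association with the drug was in the training matrix.
        """
        j = self.model.y.col_index.position(drug_id)
        ids = self.model.y.row_index.ids
        scores = self.predictions[:, j]
        known = self.model.y_train[:, j] == 1
        rows = [
            (ids[i], float(scores[i]))
            for i in range(len(ids))
            if not (exclude_known and known[i])
        ]
        rows.sort(key=lambda r: (-r[1], r[0]))
        if top_n > len(rows):
            logger.warning("top_n=%d exceeds %d candidates; returning all", top_n, len(rows))
        return rows[:top_n]

    def summary(self) -> str:
        m = self.model
        n_c, n_d = m.y.shape
        lines = [
            "Dual hierarchical attention + multi-kernel fusion + DLapRLS",
            "=" * 62,
            f"circRNAs: {n_c:5d}    drugs: {n_d:5d}    known associations: {int(m.y.values.sum())}",
            f"training pairs (balanced sample): {self.n_train_pairs}",
            f"ablation: {m.config.ablation}    seed: {self.seed}",
            f"encoder: dim={m.config.encoder.dim} heads={m.config.encoder.heads} "
            f"t={m.config.encoder.layers_intra} M={m.config.encoder.layers_inter} "
            f"dropout={m.config.encoder.dropout}",
            f"kernel bandwidth gamma={m.config.gamma:.6g}   "
            f"phi_c={m.config.phi_c:.6g} phi_d={m.config.phi_d:.6g}",
            f"epochs: {m.config.epochs}  lr={m.config.learning_rate} "
            f"weight_decay={m.config.weight_decay}",
            f"loss: {self.loss_history[0]:.4f} (epoch 1) -> "
            f"{self.loss_history[-1]:.4f} (epoch {len(self.loss_history)})",
            f"cross-diffusion iterations: circRNA {self.snf_info_c['iterations']}, "
            f"drug {self.snf_info_d['iterations']}",
            f"prediction scores: min={self.predictions.min():.4f} "
            f"max={self.predictions.max():.4f}",
        ]
        return "\n".join(lines)


class DhanMkf:
    """Bipartite association predictor over one association matrix.

    Parameters
    ----------
    y : AssociationMatrix
        Full binary association matrix (evaluation ground truth).
    css, dss : ndarray
        circRNA sequence similarity and drug structural similarity, square
        over the respective index.
    config : ModelConfig, optional
    part_c, part_d : NodePartition, optional
        User-supplied head/tail partitions overriding degree-based typing.
    """

    def __init__(
        self,
        y: AssociationMatrix,
        css: np.ndarray,
        dss: np.ndarray,
        config: ModelConfig | None = None,
        part_c: NodePartition | None = None,
        part_d: NodePartition | None = None,
    ):
        n_c, n_d = y.shape
        css = np.asarray(css, dtype=float)
        dss = np.asarray(dss, dtype=float)
        if css.shape != (n_c, n_c) or dss.shape != (n_d, n_d):
            raise ValueError(
                f"similarity shapes {css.shape}/{dss.shape} do not match matrix {y.shape}"
            )
        self.y = y
        self.css = css
        self.dss = dss
        self.config = config or ModelConfig()
        self.part_c = part_c
        self.part_d = part_d
        # set by fit()
        self.y_train: np.ndarray | None = None
        self.graph: TypedEdges | None = None
        self.params: dict[str, Tensor] | None = None
        self.s_c: np.ndarray | None = None
        self.s_d: np.ndarray | None = None

    @classmethod
    def from_dataframes(
        cls,
        y_frame: pd.DataFrame,
        css_frame: pd.DataFrame,
        dss_frame: pd.DataFrame,
        config: ModelConfig | None = None,
    ) -> "DhanMkf":
        from .io_data import EntityIndex

        y = AssociationMatrix(
            y_frame.to_numpy(),
            EntityIndex(tuple(map(str, y_frame.index)), "circRNA"),
            EntityIndex(tuple(map(str, y_frame.columns)), "drug"),
        )
        css = css_frame.loc[list(y.row_index.ids), list(y.row_index.ids)].to_numpy()
        dss = dss_frame.loc[list(y.col_index.ids), list(y.col_index.ids)].to_numpy()
        return cls(y, css, dss, config)

    # ------------------------------------------------------------------
    def _select_stack(self, stack) -> list[np.ndarray]:
        return [
            h.data for h, kind in zip(stack.layers, stack.kinds)
            if self._keep_layer(kind)
        ]

    def _select_stack_ad(self, stack) -> list[Tensor]:
        return [
            h for h, kind in zip(stack.layers, stack.kinds)
            if self._keep_layer(kind)
        ]

    def _keep_layer(self, kind: str) -> bool:
        # H0 is always retained; the intra/inter ablations drop the
        # corresponding encoder layers from the kernel fusion only.
        if kind == "init":
            return True
        if self.config.ablation == "intra" and kind == "intra":
            return False
        if self.config.ablation == "inter" and kind == "inter":
            return False
        return True

    def fit(
        self,
        y_train: np.ndarray | None = None,
        train_pairs: list[tuple[int, int]] | None = None,
        train_labels: np.ndarray | None = None,
        seed: int = 0,
    ) -> DhanMkfResults:
        """Train the encoders and solve for the coefficient matrices.

        Without explicit arguments the model trains on the full matrix with
        a freshly sampled balanced negative set.  Cross-validation passes a
        masked ``y_train`` and the training folds' balanced sample.
        """
        cfg = self.config
        if y_train is None:
            y_train = self.y.values.astype(float)
        else:
            y_train = np.asarray(y_train, dtype=float)
        if train_pairs is None:
            pos = list(zip(*np.nonzero(y_train)))
            pos = [(int(i), int(j)) for i, j in pos]
            negs = sample_negatives(self.y, len(pos), seed)
            train_pairs = pos + negs
            train_labels = np.asarray([1] * len(pos) + [0] * len(negs), dtype=np.int8)
        self.y_train = y_train

        rng = np.random.default_rng(seed)
        init_rng = np.random.default_rng(rng.integers(2**31))
        alpha_rng = np.random.default_rng(rng.integers(2**31))
        drop_seed = int(rng.integers(2**31))

        # similarity fusion from the masked training matrix
        cgs = gip_kernel(y_train, "rows", gip_bandwidth(y_train, "rows", cfg.gip_alpha))
        dgs = gip_kernel(y_train, "cols", gip_bandwidth(y_train, "cols", cfg.gip_alpha))
        self.s_c, info_c = snf_fuse(self.css, cgs, cfg.snf)
        self.s_d, info_d = snf_fuse(self.dss, dgs, cfg.snf)

        graph, part_c, part_d = build_graph(
            y_train,
            self.s_c,
            self.s_d,
            k_circ=cfg.k_circ,
            k_drug=cfg.k_drug,
            sparsify_k=cfg.sparsify_k,
            part_c=self.part_c,
            part_d=self.part_d,
            collapse_relations=cfg.ablation == "multi",
        )
        self.graph = graph
        self.fitted_part_c, self.fitted_part_d = part_c, part_d

        n_c, n_d = self.y.shape
        params = init_params(n_c, n_d, graph, cfg.encoder, init_rng)
        self.params = params
        opt = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

        alpha_c = alpha_rng.standard_normal((n_c, n_d)) * 0.01
        alpha_d = alpha_rng.standard_normal((n_d, n_c)) * 0.01

        mask = np.zeros((n_c, n_d))
        idx = np.asarray(train_pairs, dtype=int)
        mask[idx[:, 0], idx[:, 1]] = 1.0

        loss_history: list[float] = []
        state = dlaprls.DLapRLSState(
            alpha_c=alpha_c,
            alpha_d=alpha_d,
            lap_c=np.eye(n_c),
            lap_d=np.eye(n_d),
            phi_c=cfg.phi_c,
            phi_d=cfg.phi_d,
            jitter=cfg.jitter,
        )

        for epoch in range(cfg.epochs):
            drop_rng = (
                np.random.default_rng((drop_seed + epoch) % 2**31)
                if cfg.encoder.dropout > 0
                else None
            )
            stack_c, stack_d = forward(
                graph, self.s_c, self.s_d, y_train, params, cfg.encoder, drop_rng
            )
            kernels_c = [
                dlaprls.gaussian_kernel_ad(h, cfg.gamma)
                for h in self._select_stack_ad(stack_c)
            ]
            kernels_d = [
                dlaprls.gaussian_kernel_ad(h, cfg.gamma)
                for h in self._select_stack_ad(stack_d)
            ]
            ic_ad = dlaprls.fuse_kernels_ad(kernels_c)
            id_ad = dlaprls.fuse_kernels_ad(kernels_d)

            # closed-form coefficient updates on the detached kernels
            ic, id_ = ic_ad.data.copy(), id_ad.data.copy()
            state.lap_c = dlaprls.normalized_laplacian(ic)
            state.lap_d = dlaprls.normalized_laplacian(id_)
            state.alpha_c = dlaprls.update_alpha_c(state, ic, id_, y_train)
            state.alpha_d = dlaprls.update_alpha_d(state, ic, id_, y_train)

            # loss: Frobenius term restricted to the balanced sample for the
            # gradient; coefficients are constants here
            fit_term = ic_ad @ Tensor(state.alpha_c) + (id_ad @ Tensor(state.alpha_d)).T
            residual = (fit_term - Tensor(2.0 * y_train)) * Tensor(mask)
            loss = (residual**2.0).sum()
            loss = loss + cfg.phi_c * dlaprls.laplacian_trace_ad(
                ic_ad, state.alpha_c @ state.alpha_c.T
            )
            loss = loss + cfg.phi_d * dlaprls.laplacian_trace_ad(
                id_ad, state.alpha_d @ state.alpha_d.T
            )
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {value}; "
                    f"|IC|max={np.abs(ic).max():.3e} |alpha_c|max={np.abs(state.alpha_c).max():.3e}"
                )
            loss_history.append(value)
            opt.zero_grad()
            loss.backward()
            opt.step()

        # final deterministic forward (no dropout) and prediction
        stack_c, stack_d = forward(
            graph, self.s_c, self.s_d, y_train, params, cfg.encoder, rng=None
        )
        ic = dlaprls.fuse_kernels(
            dlaprls.embedding_gip_kernels(self._select_stack(stack_c), cfg.gamma)
        )
        id_ = dlaprls.fuse_kernels(
            dlaprls.embedding_gip_kernels(self._select_stack(stack_d), cfg.gamma)
        )
        state.lap_c = dlaprls.normalized_laplacian(ic)
        state.lap_d = dlaprls.normalized_laplacian(id_)
        state.alpha_c = dlaprls.update_alpha_c(state, ic, id_, y_train)
        state.alpha_d = dlaprls.update_alpha_d(state, ic, id_, y_train)
        state.history.append(dlaprls.dlaprls_loss(state, ic, id_, y_train))

        return DhanMkfResults(
            model=self,
            predictions=dlaprls.predict(state, ic, id_),
            state=state,
            fused_ic=ic,
            fused_id=id_,
            loss_history=loss_history,
            snf_info_c=info_c,
            snf_info_d=info_d,
            n_train_pairs=len(train_pairs),
            seed=seed,
        )

    def with_ablation(self, ablation: str) -> "DhanMkf":
        """Copy of the model configured for one ablation variant."""
        return DhanMkf(
            self.y,
            self.css,
            self.dss,
            replace(self.config, ablation=ablation),
            self.part_c,
            self.part_d,
        )
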
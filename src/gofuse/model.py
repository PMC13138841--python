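"""The gated multimodal fusion network for protein–GO term matching.

One input instance is a pooled embedding triple (E_seq, E_dom, E_label) for
a single protein–term pair; the output is the probability that the protein
carries that function. Four stages:

1. **Projection** — each modality is mapped into a shared ``d_model``-wide
   latent space by its own block: linear → LayerNorm → GELU → neuron dropout.
2. **Asymmetric modality dropout** (training only) — the sequence and domain
   hidden vectors are independently zeroed with probability ``p``; if both
   would be dropped, one is forced back on, chosen uniformly. The label
   modality is never dropped: a candidate term's definition is always
   available at inference, whereas protein-side evidence may be missing.
3. **Adaptive gated fusion** — the concatenated context
   ``S = [ĥ_dom ∥ ĥ_seq ∥ h_label]`` passes through a gate network
   (linear → LN → ReLU → linear → softmax) producing weights
   ``α = (α_seq, α_dom, α_label)`` on the 2-simplex; the fused vector is a
   projection of the α-weighted sum of a shared transform of each modality.
4. **Classification** — an MLP (d_model → final_hidden → 1) with GELU and
   neuron dropout, ending in a sigmoid.

Everything is NumPy with in-repo reverse-mode autodiff; no GPU or deep
learning framework is required at these model sizes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._autodiff import Tensor, concat
from .pooling import EmbeddingTriple

__all__ = [
    "ModelConfig",
    "ModalityMask",
    "GateWeights",
    "GatedFusionModel",
    "sample_modality_mask",
    "sample_modality_mask_batch",
]

# selection columns used to read a single gate weight out of the softmax
_SEL = [np.eye(3)[:, [k]] for k in range(3)]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults follow the reference setup)."""

    d_seq: int = 1280
    d_text: int = 2560
    d_model: int = 512
    d_ctx: int = 512
    final_hidden: int = 256
    modality_drop_p: float = 0.15
    neuron_dropout: float = 0.5
    seed: int = 0


@dataclass(frozen=True)
class ModalityMask:
    """Binary keep/drop mask for the two protein-side modalities."""

    m_seq: int
    m_dom: int
    p: float = 0.15

    def __post_init__(self):
        if (self.m_seq, self.m_dom) == (0, 0):
            raise ValueError("forced retention violated: mask (0, 0) is illegal")


@dataclass(frozen=True)
class GateWeights:
    """Softmax gate weights (α_seq, α_dom, α_label); non-negative, sum to 1."""

    alpha: np.ndarray

    @property
    def a_seq(self) -> float:
        return float(self.alpha[0])

    @property
    def a_dom(self) -> float:
        return float(self.alpha[1])

    @property
    def a_label(self) -> float:
        return float(self.alpha[2])


def sample_modality_mask(p: float, rng: np.random.Generator) -> ModalityMask:
    """Draw one modality mask with forced retention.

    Each protein modality is kept iff its uniform draw exceeds ``p``. If both
    are dropped, exactly one (chosen uniformly) is forced back on, so the
    marginal drop probability of each modality is ``p - p²/2``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    r_seq, r_dom = rng.uniform(size=2)
    m_seq, m_dom = int(r_seq > p), int(r_dom > p)
    if m_seq == 0 and m_dom == 0:
        if rng.integers(2) == 0:
            m_seq = 1
        else:
            m_dom = 1
    return ModalityMask(m_seq, m_dom, p)


def sample_modality_mask_batch(
    p: float, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Vectorized mask sampling; returns an (n, 2) 0/1 array [m_seq, m_dom]."""
    masks = (rng.uniform(size=(n, 2)) > p).astype(np.float64)
    both_zero = masks.sum(axis=1) == 0
    k = both_zero.sum()
    if k:
        choice = rng.integers(2, size=k)
        idx = np.flatnonzero(both_zero)
        masks[idx, choice] = 1.0
    return masks


def _init_linear(rng, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out))


class GatedFusionModel:
    """Trainable protein–GO matching model (one instance per namespace)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        p: dict[str, Tensor] = {}

        def param(name, arr):
            p[name] = Tensor(arr, requires_grad=True)

        for m, d_in in (("seq", c.d_seq), ("dom", c.d_text), ("label", c.d_text)):
            param(f"W_{m}", _init_linear(rng, d_in, c.d_model))
            param(f"b_{m}", np.zeros(c.d_model))
            param(f"ln_{m}_g", np.ones(c.d_model))
            param(f"ln_{m}_b", np.zeros(c.d_model))
        # gate network
        param("W_ctx", _init_linear(rng, 3 * c.d_model, c.d_ctx))
        param("ln_ctx_g", np.ones(c.d_ctx))
        param("ln_ctx_b", np.zeros(c.d_ctx))
        param("W_gate", _init_linear(rng, c.d_ctx, 3))
        # shared transform and projection
        for blk in ("trans", "proj"):
            param(f"W_{blk}", _init_linear(rng, c.d_model, c.d_model))
            param(f"b_{blk}", np.zeros(c.d_model))
            param(f"ln_{blk}_g", np.ones(c.d_model))
            param(f"ln_{blk}_b", np.zeros(c.d_model))
        # classifier head
        param("W_hid", _init_linear(rng, c.d_model, c.final_hidden))
        param("b_hid", np.zeros(c.final_hidden))
        param("W_out", _init_linear(rng, c.final_hidden, 1))
        param("b_out", np.zeros(1))
        self.params = p

    # ------------------------------------------------------------ components
    def _dropout(self, x: Tensor, rate: float, train: bool, rng) -> Tensor:
        if not train or rate <= 0.0:
            return x
        keep = (rng.uniform(size=x.shape) >= rate) / (1.0 - rate)
        return x * Tensor(keep)

    def project_modality(
        self, e, modality: str, mode: str = "eval", rng=None
    ) -> Tensor:
        """Dropout(GELU(LN(W·E + b))) for one modality batch (B, d_in)."""
        if modality not in ("seq", "dom", "label"):
            raise ValueError(f"unknown modality {modality!r}")
        x = e if isinstance(e, Tensor) else Tensor(np.atleast_2d(e))
        p = self.params
        if x.shape[-1] != p[f"W_{modality}"].shape[0]:
            raise ValueError(
                f"{modality} input width {x.shape[-1]} != "
                f"{p[f'W_{modality}'].shape[0]}"
            )
        h = (x @ p[f"W_{modality}"] + p[f"b_{modality}"]).layer_norm(
            p[f"ln_{modality}_g"], p[f"ln_{modality}_b"]
        ).gelu()
        return self._dropout(h, self.config.neuron_dropout, mode == "train", rng)

    def _block(self, x: Tensor, name: str) -> Tensor:
        p = self.params
        return (x @ p[f"W_{name}"] + p[f"b_{name}"]).layer_norm(
            p[f"ln_{name}_g"], p[f"ln_{name}_b"]
        ).gelu()

    def gated_fuse(
        self, h_seq: Tensor, h_dom: Tensor, h_label: Tensor
    ) -> tuple[Tensor, Tensor]:
        """Fuse already-masked hidden vectors; returns (H_fused, alpha).

        Masked modalities must arrive as zero vectors — zeros enter both the
        gate context and the weighted sum.
        """
        p = self.params
        s = concat([h_dom, h_seq, h_label], axis=1)
        ctx = (s @ p["W_ctx"]).layer_norm(p["ln_ctx_g"], p["ln_ctx_b"]).relu()
        alpha = (ctx @ p["W_gate"]).softmax(axis=-1)  # (B, 3): seq, dom, label
        weighted = (
            (alpha @ _SEL[0]) * self._block(h_seq, "trans")
            + (alpha @ _SEL[1]) * self._block(h_dom, "trans")
            + (alpha @ _SEL[2]) * self._block(h_label, "trans")
        )
        return self._block(weighted, "proj"), alpha

    def score_pair(self, h_fused: Tensor, mode: str = "eval", rng=None) -> Tensor:
        """Classifier head: MLP to final_hidden, then sigmoid output."""
        p = self.params
        hid = (h_fused @ p["W_hid"] + p["b_hid"]).gelu()
        hid = self._dropout(hid, self.config.neuron_dropout, mode == "train", rng)
        return (hid @ p["W_out"] + p["b_out"]).sigmoid()

    # --------------------------------------------------------------- forward
    def forward_batch(
        self,
        e_seq: np.ndarray,
        e_dom: np.ndarray,
        e_label: np.ndarray,
        mode: str = "eval",
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Score a batch of pairs; returns (probs (B,1), alpha (B,3)) tensors.

        In eval mode no neuron or modality dropout is applied and the result
        is a pure function of the inputs and parameters.
        """
        if mode not in ("train", "eval"):
            raise ValueError("mode must be 'train' or 'eval'")
        if mode == "train" and rng is None:
            raise ValueError("training mode requires an rng")
        e_seq, e_dom, e_label = map(np.atleast_2d, (e_seq, e_dom, e_label))
        h_seq = self.project_modality(e_seq, "seq", mode, rng)
        h_dom = self.project_modality(e_dom, "dom", mode, rng)
        h_label = self.project_modality(e_label, "label", mode, rng)
        if mode == "train":
            masks = sample_modality_mask_batch(
                self.config.modality_drop_p, rng, e_seq.shape[0]
            )
            h_seq = h_seq * Tensor(masks[:, [0]])
            h_dom = h_dom * Tensor(masks[:, [1]])
        h_fused, alpha = self.gated_fuse(h_seq, h_dom, h_label)
        return self.score_pair(h_fused, mode, rng), alpha

    def forward(
        self,
        triple: EmbeddingTriple,
        mode: str = "eval",
        rng: np.random.Generator | None = None,
    ) -> tuple[float, GateWeights]:
        """Score one protein–term pair."""
        probs, alpha = self.forward_batch(
            triple.e_seq, triple.e_dom, triple.e_label, mode, rng
        )
        return float(probs.data[0, 0]), GateWeights(alpha.data[0])

    # ------------------------------------------------------------ persistence
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=np.float64).reshape(v.data.shape)

    def save(self, path) -> None:
        """Single-file checkpoint: config JSON + parameter tensors (npz)."""
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(asdict(self.config)).encode(), dtype=np.uint8
            ),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "GatedFusionModel":
        with np.load(path) as data:
            cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
            model = cls(cfg)
            model.load_state_dict(
                {k: data[k] for k in data.files if k != "__config__"}
            )
        return model
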
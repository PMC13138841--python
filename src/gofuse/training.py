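"""Pair sampling, Adam, and the per-namespace training loop.

Each namespace (BP/MF/CC) gets its own independently trained model, matching
the observation that jointly trained models blur namespace-specific
semantics. Within a namespace, every (protein, annotated term) pair is a
positive once per epoch; negatives are drawn uniformly from the namespace's
term universe minus the protein's propagated annotation set, at a
configurable negatives-per-positive ratio, and resampled every epoch.
"""

from __future__ import annotations

import sys
import time
import warnings
from dataclasses import dataclass

import numpy as np

from .losses import LossConfig, loss_tensor
from .model import GatedFusionModel
from .ontology import AnnotationTable

__all__ = [
    "TrainConfig",
    "EPOCH_DEFAULTS",
    "default_loss_for",
    "sample_training_pairs",
    "AdamOptimizer",
    "train",
]

#: per-namespace training epochs (reference setup)
EPOCH_DEFAULTS = {"BP": 30, "MF": 20, "CC": 20}

#: per-namespace default objectives: plain BCE for BP/MF, focal for the
#: more imbalanced CC namespace (γ=2, α disabled)
def default_loss_for(namespace: str) -> LossConfig:
    if namespace == "CC":
        return LossConfig(kind="focal", gamma=2.0, alpha=None)
    return LossConfig(kind="bce")


@dataclass(frozen=True)
class TrainConfig:
    namespace: str = "BP"
    learning_rate: float = 5e-4
    batch_size: int = 16
    epochs: int | None = None  # None -> EPOCH_DEFAULTS[namespace]
    negative_ratio: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.namespace not in EPOCH_DEFAULTS:
            raise ValueError(f"namespace must be one of {sorted(EPOCH_DEFAULTS)}")
        if self.learning_rate < 0 or self.batch_size < 1 or self.negative_ratio < 0:
            raise ValueError("learning_rate, batch_size, negative_ratio must be >= 0")

    @property
    def n_epochs(self) -> int:
        return EPOCH_DEFAULTS[self.namespace] if self.epochs is None else self.epochs


def sample_training_pairs(
    annotations: AnnotationTable,
    term_universe: set[str],
    ratio: int,
    rng: np.random.Generator,
) -> list[tuple[str, str, int]]:
    """One epoch's shuffled stream of (protein, term, y) pairs.

    Positives: every annotated (protein, term) with the term inside
    ``term_universe``. Negatives: per protein, ``ratio`` × its positive count
    terms sampled uniformly without replacement from the universe minus the
    protein's (propagated) annotations. A protein annotated to the whole
    universe contributes positives only (with a warning).
    """
    universe = sorted(term_universe)
    universe_set = set(universe)
    pairs: list[tuple[str, str, int]] = []
    for protein in sorted(annotations.annotations):
        terms = annotations.annotations[protein]
        positives = sorted(terms & universe_set)
        if not positives:
            continue
        for t in positives:
            pairs.append((protein, t, 1))
        if ratio == 0:
            continue
        candidates = [t for t in universe if t not in terms]
        if not candidates:
            warnings.warn(
                f"protein {protein} annotated to the full term universe; "
                "no negatives drawn"
            )
            continue
        n_neg = min(ratio * len(positives), len(candidates))
        chosen = rng.choice(len(candidates), size=n_neg, replace=False)
        for i in chosen:
            pairs.append((protein, candidates[i], 0))
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


class AdamOptimizer:
    """Plain Adam over the model's parameter dict."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            p.data -= self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps
            )


def train(
    model: GatedFusionModel,
    embeddings,
    annotations: AnnotationTable,
    term_universe: set[str],
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainConfig | None = None,
    log_path=None,
    verbose: bool = False,
) -> list[float]:
    """Train one namespace's model; returns the per-epoch mean-loss history.

    ``embeddings`` must expose ``seq[protein_id]``, ``dom[protein_id]`` and
    ``label[term_id]`` pooled vectors (see :class:`gofuse.io.EmbeddingSet`).
    Fully deterministic for a fixed seed on one thread.
    """
    cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or default_loss_for(cfg.namespace)
    rng = np.random.default_rng(cfg.seed)
    opt = AdamOptimizer(model.params, cfg.learning_rate)
    history: list[float] = []
    log_fh = open(log_path, "w") if log_path else None
    if log_fh:
        log_fh.write("epoch\tmean_loss\twall_time_s\n")
    try:
        for epoch in range(cfg.n_epochs):
            t0 = time.perf_counter()
            pairs = sample_training_pairs(
                annotations, term_universe, cfg.negative_ratio, rng
            )
            epoch_losses: list[float] = []
            for start in range(0, len(pairs), cfg.batch_size):
                batch = pairs[start : start + cfg.batch_size]
                e_seq = np.stack([embeddings.seq[p] for p, _, _ in batch])
                e_dom = np.stack([embeddings.dom[p] for p, _, _ in batch])
                e_lab = np.stack([embeddings.label[t] for _, t, _ in batch])
                y = np.array([lab for _, _, lab in batch], dtype=np.float64)
                probs, _ = model.forward_batch(e_seq, e_dom, e_lab, "train", rng)
                loss = loss_tensor(probs, y, loss_cfg)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch offset {start}: "
                        f"{loss.data}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
            mean_loss = float(np.mean(epoch_losses)) if epoch_losses else float("nan")
            history.append(mean_loss)
            wall = time.perf_counter() - t0
            line = f"epoch={epoch}\tmean_loss={mean_loss:.6f}\twall={wall:.2f}s"
            if verbose:
                print(line, file=sys.stderr)
            if log_fh:
                log_fh.write(f"{epoch}\t{mean_loss:.6f}\t{wall:.2f}\n")
    finally:
        if log_fh:
            log_fh.close()
    return history
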
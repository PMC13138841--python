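# Methods

## Model

`gofuse` scores protein–GO term pairs with a gated multimodal fusion
network. The scoring function is

    ŷ(p, t) = σ( W_out · MLP( φ_proj( Σ_k α_k φ_trans(ĥ_k) ) ) + b_out ),

where k ranges over the three modalities (sequence, domain text, label
text), `h_m = Dropout(GELU(LN(W_m E_m + b_m)))` projects each pooled input
embedding into a shared `d_model`-dimensional space, and the gate weights

    α = Softmax( W_gate · ReLU( LN( W_ctx [ĥ_dom ∥ ĥ_seq ∥ h_label] ) ) )

lie on the 2-simplex. `φ_trans` (shared across modalities) and `φ_proj` are
each linear → LayerNorm → GELU blocks of width `d_model`; the classifier
MLP compresses `d_model → final_hidden → 1` with GELU and neuron dropout
between layers.

**Modality dropout.** During training the two protein-side hidden vectors
are independently zeroed with probability p; if both draws are zero exactly
one (uniformly chosen) is forced back on, giving each modality a marginal
drop probability of p − p²/2 (0.13875 at the default p = 0.15). The label
modality is never dropped: this asymmetry mirrors annotation practice — the
candidate term's definition is always available, protein-side evidence (in
particular domain annotations) may be missing. Masked hidden vectors enter
*both* the gate context and the weighted sum as zeros, with no
renormalization of α. (The algebra is ambiguous about whether the weighted
sum should use masked or unmasked hiddens; we mask consistently on both
paths, which keeps "modality absent" a single well-defined condition.)

**Where dropout lives.** The dropout inside the projection block is
ordinary neuron dropout (inverted scaling); modality dropout acts on the
projected hidden vectors, i.e. projection → modality drop → fusion. In eval
mode neither is applied and the forward pass is a pure function of inputs
and parameters.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `d_seq` | 1280 | width of pooled sequence embeddings (a 650M-parameter protein language model emits 1280) |
| `d_text` | 2560 | width of pooled text embeddings (domain descriptions, GO definitions) |
| `d_model` | 512 | shared latent width; the reference setup's sweet spot between capacity and overfitting |
| `d_ctx` | = d_model | gate-network hidden width; unstated in the reference, so tied to `d_model` and configurable |
| `final_hidden` | 256 | classifier bottleneck |
| `modality_drop_p` | 0.15 | protein-modality drop rate |
| `neuron_dropout` | 0.5 | neuron-level rate tuned for the 512-dim model; the CPU-scale experiments below use 0.2 — at `d_model` = 128 a 0.5 rate starves the gradient signal |
| learning rate | 5e-4 | Adam, batch size 16 |
| epochs | BP 30 / MF 20 / CC 20 | per-namespace defaults |
| loss | BCE (BP, MF), focal γ=2 no α (CC) | CC's heavier imbalance benefits from down-weighting easy negatives; "no α" removes both class-balance factors |
| negative ratio | 5:1 | negatives per positive, resampled uniformly each epoch from the namespace's non-annotated terms; the reference construction is unpublished, uniform sampling is the standard default for pairwise matchers |

All randomness (initialization, mask sampling, pair sampling) flows from
explicit seeds; training is bitwise-reproducible on one thread.

## Ontology handling

The hierarchy is defined by `is_a` and `part_of` edges only — the common
CAFA choice; `regulates`-family relations are ignored. Obsolete terms are
flagged on parse and excluded from the DAG, all partitions and propagation.
True-path propagation closes annotation sets under ancestors and is
idempotent. Hierarchical post-processing of predictions sets each term's
score to the max over itself and its descendants (never lowering a score);
it is off by default in `evaluate` because the fused semantic space already
yields near-consistent scores and the measured gain is negligible.

Zero-shot labels come from a temporal diff of two ontology releases: terms
present in the new release and absent from the old. In the four-way label
partition, zero-shot takes precedence over unseen when a test term
qualifies for both, keeping the sets disjoint.

## Evaluation conventions

* **Fmax**: threshold grid τ ∈ {0.00, 0.01, …, 1.00}; at τ, a pair is a
  prediction iff score ≥ τ *and* score > 0 (so an all-zero matrix scores 0);
  precision averaged over proteins with ≥1 prediction, recall over proteins
  with ≥1 true term among the evaluated columns; F = 0 when p + r = 0.
* **AUPR**: micro over protein–term pairs, ties collapsed into one
  threshold group, step-wise area Σ(R_i − R_{i−1})·P_i. Constant scores give
  exactly the prevalence. A macro-per-term mode exists behind
  `evaluation.macro_aupr`. Whether the reference protocol micro- or
  macro-averages is unstated; micro is the default here.
* Namespace root terms are excluded from evaluation columns by default when
  a graph is supplied.
* Seen/unseen AUPR restricted to a set with no columns or no positives is
  reported as not-applicable (None), never silently 0; H is only computed
  when both sides exist.
* ε-clamp for all log terms: 1e-7.

## The synthetic world

Each term owns a latent vector z_t ~ N(0, I_16); a protein's latent is the
mean z over its annotated terms (Poisson(λ=3)+1 terms each, optionally
propagated on a random-tree toy DAG). Observed embeddings are linear images
of the latents, scaled by an alignment strength s and corrupted by N(0, σ²)
noise. Domain and label embeddings share one text-space map (they come from
the same text encoder in the real pipeline — this is what makes domain and
label vectors directly comparable); sequences get their own map. A
configurable fraction of proteins carries a zero domain vector (default 0.2,
matching that roughly 80% of catalogued proteins have domain annotations).
Default world: 2000 proteins, 50 terms with 10 held out as "new", s = 1,
σ = 0.1, dimensions 64 (sequence) and 96 (text) over a 16-dim latent space —
a deliberately small stand-in for 1280/2560-dim encoder output that keeps
CPU training in minutes.

What a green zero-shot test establishes: the trained model transfers to
held-out terms *through label semantics* — shuffling label embeddings
across terms at inference, or retraining with one-hot label identifiers,
collapses unseen AUPR to chance while the one-hot model still memorizes
seen labels. What it does not establish: performance on real proteome-scale
data, real GO topology, anisotropic encoder geometry, or long-tail
annotation frequencies — none of which the generator emulates.

The toy homology filter removes test proteins with identity strictly above
0.30 ("over 30%") against any training protein; the built-in 3-mer
containment estimate is for synthetic sequences only, real data should
supply a precomputed identity table (missing pairs count as 0, with a
warning).

## Numerical choices

* LayerNorm uses ε = 1e-5 inside the square root, so the zero vector maps
  to zero.
* GELU is the exact erf form (not the tanh approximation).
* Weights are initialized N(0, 1/√fan_in), biases zero, LN affine at
  identity; all seeded.
* The in-repo autodiff computes exact gradients by construction (composed
  primitives); verified against central finite differences to ~1e-6
  relative error across all parameter groups.
* Score matrices are kept at full precision internally; the CAFA prediction
  TSV rounds to 3 decimals on disk only.

## Known limitations

* Training is plain Adam, fixed epochs: no schedules, early stopping or
  validation-based selection (out of scope by design).
* NumPy on one CPU bounds practical problem sizes to roughly 10⁴ proteins ×
  10² terms per namespace; the architecture is the point, not throughput.
* The pairwise scorer evaluates every candidate term per protein — cost
  grows linearly with the ontology size.
* The synthetic generator's linear-Gaussian structure makes the matching
  problem nearly linearly solvable; it exercises every component but cannot
  certify performance on harder, real geometries.
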
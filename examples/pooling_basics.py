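"""Pooling token-level encoder output into the three modality vectors.

Any encoder produces one embedding row per token; the fusion model needs a
single fixed-length vector per modality. Sequences and label definitions are
mean-pooled in one step; domain descriptions use two-level pooling (tokens
within a domain first, then across domains) so each domain counts equally
regardless of its description length.
"""

import numpy as np

from gofuse.pooling import TokenEmbeddingMatrix, build_triple, mean_pool, pool_domains
from gofuse.synthetic import synthetic_encoder

seq_encoder = synthetic_encoder(width=6, seed=1)
text_encoder = synthetic_encoder(width=6, seed=1, source_tag="label_text")
dom_encoder = synthetic_encoder(width=6, seed=1, source_tag="domain_text")

seq_tokens = seq_encoder.encode("M K V L A T")  # six residues -> six rows
label_tokens = text_encoder.encode("catalysis of a redox reaction")
domain_a = dom_encoder.encode("short domain")
domain_b = dom_encoder.encode("a much longer domain description with more tokens")

e_seq = mean_pool(seq_tokens)
e_dom = pool_domains([domain_a, domain_b], d_text=6)
e_label = mean_pool(label_tokens)
print(f"E_seq   ({e_seq.modality}):", np.round(e_seq.values, 3))
print(f"E_dom   ({e_dom.modality}):", np.round(e_dom.values, 3))
print(f"E_label ({e_label.modality}):", np.round(e_label.values, 3))

# two-level pooling weighs the 2-token and 8-token domains equally; flat
# pooling over all 10 tokens would let the long domain dominate
flat = mean_pool(TokenEmbeddingMatrix(np.vstack([domain_a.rows, domain_b.rows])))
print("two-level vs flat domain pooling differ:",
      not np.allclose(e_dom.values, flat.values))

# a protein without domain annotations gets the zero-vector placeholder
triple = build_triple(seq_tokens, [], label_tokens)
print("no domains -> E_dom is the zero placeholder:", not triple.e_dom.any())
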
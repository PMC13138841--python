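"""Homology reduction of a test set against training sequences.

Zero-shot evaluation must not be contaminated by near-duplicate sequences:
test proteins with more than 30% identity to any training protein are
removed. Real pipelines supply a precomputed identity table from an aligner;
for synthetic sequences a 3-mer containment estimate stands in.
"""

import numpy as np

from gofuse.synthetic import random_protein_sequences, toy_identity_filter

rng = np.random.default_rng(8)
train_seqs = random_protein_sequences([f"TR{i}" for i in range(5)], rng)
test_seqs = random_protein_sequences([f"TE{i}" for i in range(4)], rng)
test_seqs["TE_leak"] = train_seqs["TR0"]  # an exact duplicate sneaks in

retained = toy_identity_filter(test_seqs, train_seqs, cutoff=0.30)
print("retained after k-mer screen:", sorted(retained))
print("duplicate removed:", "TE_leak" not in retained)

# with a precomputed identity table the cutoff is strict: exactly 30% stays
table = {("A", "R"): 0.30, ("B", "R"): 0.31}
kept = toy_identity_filter({"A": "", "B": ""}, {"R": ""}, identity_table=table)
print("identity 0.30 kept, 0.31 removed:", kept == ["A"])
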
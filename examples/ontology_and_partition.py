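"""Temporal ontology diffing and the four-way label partition.

Two ontology releases are parsed; terms that exist only in the newer release
are the candidate zero-shot labels. Together with which terms appear in the
training and test annotation sets, this yields the disjoint
shared / unseen / training-only / zero-shot partition that drives
seen-vs-unseen evaluation.
"""

from gofuse.ontology import (
    AnnotationTable,
    parse_obo,
    partition_labels,
    propagate_true_path,
    temporal_label_diff,
)

OLD_OBO = """\
[Term]
id: GO:0000001
name: metabolic process
namespace: biological_process

[Term]
id: GO:0000002
name: catabolic process
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: lipid catabolic process
namespace: biological_process
is_a: GO:0000002
"""

# the 2nd release adds one new leaf term under catabolic process
NEW_OBO = OLD_OBO + """
[Term]
id: GO:0000004
name: sterol catabolic process
namespace: biological_process
is_a: GO:0000002
"""

old = parse_obo(OLD_OBO, "BP", version_tag="release-1")
new = parse_obo(NEW_OBO, "BP", version_tag="release-2")

diff = temporal_label_diff(old, new)
print("terms new in release-2:", sorted(diff))

# annotating the deepest term implies every ancestor (true-path rule)
annotations = AnnotationTable({"P00001": {"GO:0000003"}}, "BP")
propagated = propagate_true_path(annotations, old)
print("propagated annotation set of P00001:",
      sorted(propagated.annotations["P00001"]))

partition = partition_labels(
    train_terms={"GO:0000001", "GO:0000002", "GO:0000003"},
    test_terms={"GO:0000002", "GO:0000003", "GO:0000004"},
    old=old,
    new=new,
)
for category in ("shared", "unseen", "training_only", "zero_shot"):
    print(f"{category:>13}:", sorted(getattr(partition, category)))
# GO:0000004 lands in zero_shot (created by the update), not in unseen
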
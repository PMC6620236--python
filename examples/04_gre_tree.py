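"""Phylogenetic disambiguation of glycyl radical enzymes (GRE).

The GRE superfamily contains functionally distinct members (CutC choline
trimethylamine-lyase, PduC-type propanediol dehydratase, DhaB, HpdB,
HypD, PhdB), so a locus carrying one cannot be typed by similarity
alone; the query is placed on a reference tree and takes the function of
the labeled clade it falls in.
"""

import numpy as np

from bmcscan.phylo import classify_gre
from bmcscan.simulate import generate_reference_set, mutate

bundle = generate_reference_set(seed=5)
rng = np.random.default_rng(5)

refs = {g.family: g.sequence for g in bundle.gre_references}
queries = [
    ("query_cutC_like", mutate(refs["CutC"], 0.10, rng)),
    ("query_pduC_like", mutate(refs["PduC"], 0.10, rng)),
    ("query_dhaB_like", mutate(refs["DhaB"], 0.10, rng)),
]
labels = classify_gre(bundle, queries)
for qid, _ in queries:
    print(f"{qid:18s} -> {labels[qid]}")
print(
    "\nA CutC label types a locus as choline utilization (Cut), a PduC label"
    "\nas 1,2-propanediol utilization (Pdu); DhaB is not a BMC signature, so"
    "\na locus carrying only it stays untyped."
)
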
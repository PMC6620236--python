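"""Presence/absence matrices and phyletic summaries.

Runs detection on a cohort with implants in three phyla and prints the
per-pathway counts with survey-style percentages (round half up at one
decimal, integral values without the decimal).
"""

from bmcscan.pipeline import detect
from bmcscan.report import build_presence_matrix, phylum_breakdown, summarize
from bmcscan.simulate import CohortSpec, ImplantSpec, generate_cohort, generate_reference_set

bundle = generate_reference_set(seed=9)
spec = CohortSpec(
    n_genomes=8,
    seed=9,
    phyla=["Firmicutes"] * 4 + ["Proteobacteria"] * 2 + ["Actinobacteria"] * 2,
    implants=[
        ImplantSpec(pathway="Pdu", genomes=[0, 1]),
        ImplantSpec(pathway="Eut", genomes=[4, 5]),
    ],
)
genomes, _ = generate_cohort(spec, bundle)
result = detect(genomes, bundle)
matrix = build_presence_matrix(genomes, result)

print(summarize(matrix).to_string(index=False))
print()
print(phylum_breakdown(matrix).to_string(index=False))
print(
    "\n'any_BMC' counts each genome once however many BMC types it carries;"
    "\npercentages are exact counts over the cohort or phylum size."
)
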
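"""Standard synthetic benchmark scenarios for the detection pipeline.

These fix the study conditions under which the pipeline is validated:
a 20-genome cohort with all six BMC pathways implanted in two species
each against 25 background genes per genome, a held-out GRE query panel,
a mutation-rate sensitivity curve, and background-only negative-control
cohorts.  Both the test suite and the reproduction script run these.
"""

from __future__ import annotations

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .model import GRE_FAMILIES, PATHWAYS
from .phylo import classify_gre
from .pipeline import detect, evaluate_detection
from .simulate import (
    CohortSpec,
    ImplantSpec,
    generate_cohort,
    generate_reference_set,
    mutate,
)


def standard_cohort_spec(
    seed: int,
    mutation_rate: float = 0.0,
    n_genomes: int = 20,
    n_background_genes: int = 25,
) -> CohortSpec:
    """Six pathways, one implant pair per pathway in two distinct species."""
    implants = [
        ImplantSpec(
            pathway=pw, genomes=[2 * i, 2 * i + 1], mutation_rate=mutation_rate
        )
        for i, pw in enumerate(PATHWAYS)
    ]
    return CohortSpec(
        n_genomes=n_genomes,
        seed=seed,
        n_background_genes=n_background_genes,
        implants=implants,
    )


def small_cohort_spec(seed: int, mutation_rate: float) -> CohortSpec:
    """Reduced three-pathway cohort used for the mutation-rate curve."""
    implants = [
        ImplantSpec(pathway=pw, genomes=[2 * i, 2 * i + 1], mutation_rate=mutation_rate)
        for i, pw in enumerate(("Eut", "Pdu", "Cut"))
    ]
    return CohortSpec(
        n_genomes=6, seed=seed, n_background_genes=12, implants=implants
    )


def locus_recovery(
    seed: int,
    mutation_rate: float = 0.0,
    spec: CohortSpec | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """Detect loci on a standard cohort; sensitivity/precision vs ground truth."""
    bundle = generate_reference_set(seed)
    if spec is None:
        spec = standard_cohort_spec(seed, mutation_rate)
    genomes, truth = generate_cohort(spec, bundle)
    result = detect(genomes, bundle, config)
    metrics = evaluate_detection(result.loci, truth)
    metrics["n_standalone"] = len(result.standalone)
    return metrics


def sensitivity_curve(
    seed: int, rates: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3)
) -> list[float]:
    """Locus-detection sensitivity at increasing per-residue mutation rates."""
    out = []
    for rate in rates:
        m = locus_recovery(seed, spec=small_cohort_spec(seed, rate))
        out.append(m["sensitivity"])
    return out


def gre_assignment_accuracy(
    seed: int, n_queries: int = 100, mutation_rate: float = 0.1
) -> float:
    """Fraction of held-out GRE family members assigned to their own family."""
    bundle = generate_reference_set(seed)
    fam_ref = {
        g.family: g.sequence
        for g in bundle.gre_references
        if g.family in GRE_FAMILIES
    }
    rng = np.random.default_rng([2, seed])
    queries, expected = [], []
    for i in range(n_queries):
        fam = GRE_FAMILIES[i % len(GRE_FAMILIES)]
        queries.append((f"q{i}", mutate(fam_ref[fam], mutation_rate, rng)))
        expected.append(fam)
    labels = classify_gre(bundle, queries)
    return sum(labels[f"q{i}"] == expected[i] for i in range(n_queries)) / n_queries


def negative_control(seeds: list[int], n_genomes: int = 2, n_background_genes: int = 10) -> int:
    """Number of background-only cohorts in which no BMC locus is called."""
    clean = 0
    for seed in seeds:
        bundle = generate_reference_set(seed)
        spec = CohortSpec(
            n_genomes=n_genomes, seed=seed, n_background_genes=n_background_genes
        )
        genomes, _ = generate_cohort(spec, bundle)
        result = detect(genomes, bundle)
        if not result.loci:
            clean += 1
    return clean
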
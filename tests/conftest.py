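"""Shared fixtures: generator bundles and (expensive) projections are
session-scoped so the suite builds each study condition once."""

from __future__ import annotations

import numpy as np
import pytest

from tfxkit import cysclass, embedspace, genefind, synthgen


@pytest.fixture(scope="session")
def demo_genome():
    """Default demo cluster (seed 42): 10 genes incl. 1 pseudogene and
    1 dup-exon-3 gene, plus 1 orphan exon set, at 5% protein divergence."""
    config = synthgen.default_genome_config(seed=42)
    family = synthgen.generate_protein_family(config.groups, seed=config.seed,
                                              divergence=config.divergence)
    genome = synthgen.generate_genome(config, family)
    return config, family, genome


@pytest.fixture(scope="session")
def demo_recovery(demo_genome):
    """Hits, chained models, and the recovery report for the demo cluster."""
    _, family, genome = demo_genome
    scaffold = genome.scaffolds[0]
    params = genefind.SearchParams()
    hits = genefind.find_exon_hits(scaffold, family.panel, params)
    models = genefind.chain_hits_to_genes(hits, scaffold, params)
    report = genefind.evaluate_recovery(genome.genes, models)
    return hits, models, report


@pytest.fixture(scope="session")
def clean_cohort():
    """203 noise-free proteins across all seven groups (29 per group)."""
    return synthgen.generate_protein_family(synthgen.default_groups(29), seed=11)


@pytest.fixture(scope="session")
def diverged_cohort():
    """210 proteins (30 per group) at 5% divergence, for clustering."""
    return synthgen.generate_protein_family(synthgen.default_groups(30),
                                            seed=5, divergence=0.05)


@pytest.fixture(scope="session")
def cohort_projection(diverged_cohort):
    """Stacked composition+framework features and their 3D UMAP projection."""
    seqs = {t.protein_id: t.mature_sequence for t in diverged_cohort.truth}
    ids, comp = embedspace.compose_features(seqs, "composition20")
    _, cys = embedspace.compose_features(seqs, "cys_descriptor")
    features = embedspace.stack_features(comp, embedspace.zscore(cys))
    coords = embedspace.project(features, embedspace.ProjectionParams())
    return ids, features, coords


@pytest.fixture(scope="session")
def classified_cohort(clean_cohort):
    """Full classifier pipeline over the noise-free cohort."""
    out = {}
    for rec in clean_cohort.records:
        out[rec.id] = cysclass.classify_protein(rec)
    return out


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
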
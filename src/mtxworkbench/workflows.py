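"""End-to-end pipeline orchestration shared by the CLI, the tests, and the
reproduction script: fixture construction and the preprocess -> classify ->
reestimate -> decontaminate chain."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .decontamination import ContaminantScore, DecontamConfig, clean_profile
from .preprocess import DepletionIndex, PreprocessReport, run_preprocess
from .profiles import TaxonomicProfile
from .reads import ReadSet
from .synthetic_community import (
    CommunitySpec,
    ReferenceSet,
    build_toy_reference,
)
from .taxonomic_profiling import (
    KmerIndex,
    build_kmer_index,
    classify_readset,
    reestimate_species,
)
from .taxonomy import TaxonomyTree


@dataclass
class Fixture:
    """A complete benchmarking universe: taxonomy, references, community,
    prebuilt classifier and depletion indexes."""

    tree: TaxonomyTree
    ref: ReferenceSet
    community: CommunitySpec
    kmer_index: KmerIndex
    depletion_index: DepletionIndex
    k: int = 31

    @property
    def mock_species(self) -> set:
        return {m.taxon_id for m in self.community.species}


def build_fixture(
    n_species: int = 20,
    n_genera: int = 18,
    seed: int = 1,
    k: int = 31,
    **reference_kwargs,
) -> Fixture:
    """Build the standard mock-community fixture and its indexes."""
    tree, ref, community = build_toy_reference(
        n_species=n_species, n_genera=n_genera, seed=seed, **reference_kwargs
    )
    return Fixture(
        tree=tree,
        ref=ref,
        community=community,
        kmer_index=build_kmer_index(ref, tree, k=k),
        depletion_index=DepletionIndex(
            host=ref.host_sequences, virus=ref.virus_sequences,
            rrna=ref.rrna_sequences, k=k,
        ),
        k=k,
    )


def taxonomic_pipeline(
    reads: ReadSet,
    fixture: Fixture,
    confidence: float = 0.0,
    *,
    scores: Optional[Mapping[str, ContaminantScore]] = None,
    decontam: Optional[DecontamConfig] = None,
    min_hit_fraction: float = 0.5,
) -> tuple[TaxonomicProfile, PreprocessReport]:
    """Preprocess, classify with the k-mer LCA family, reestimate to species,
    and decontaminate.  Returns the cleaned species profile and the
    preprocessing report."""
    kept, report = run_preprocess(
        reads, index=fixture.depletion_index, min_hit_fraction=min_hit_fraction
    )
    counts, unclassified, _ = classify_readset(kept, fixture.kmer_index, confidence)
    profile = reestimate_species(
        counts, fixture.tree, fixture.kmer_index.kmer_totals,
        unclassified_count=unclassified,
    )
    if decontam is None:
        decontam = DecontamConfig(protected=frozenset(fixture.mock_species))
    profile = clean_profile(profile, scores or {}, decontam, tree=fixture.tree)
    return profile, report
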
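"""Taxonomy-guided tiered functional profiling.

The profiler mirrors the tiered-search design used for community functional
analysis: a taxonomic prescreen selects the species whose pangenomes form a
sample-specific nucleotide database; reads are assigned to pangenome genes
by best k-mer containment and quantified per (gene family, species); genes
with insufficient subject coverage are dropped and their reads, together
with all nucleotide-tier failures, fall through to a translated search
against the peptide database (contributor "unclassified"); reads failing
both tiers are counted unmapped.  Abundances are reported as reads per
kilobase (RPK) and sum-normalized to copies per million (CPM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import _kmers
from .errors import ParameterError
from .profiles import TaxonomicProfile
from .reads import ReadSet
from .synthetic_community import PangenomeGene, ReferenceSet

UNCLASSIFIED = "unclassified"
TIER_NUCLEOTIDE = "nucleotide"
TIER_TRANSLATED = "translated"


@dataclass
class PangenomeSubset:
    """Pangenome entries restricted to the prescreened species."""

    species: list[str]
    genes: list[tuple[str, PangenomeGene]]  # (species, gene)

    @classmethod
    def from_reference(cls, ref: ReferenceSet, species: Sequence[str]) -> "PangenomeSubset":
        genes = [
            (sid, g)
            for sid in species
            for g in ref.species_pangenomes.get(sid, [])
        ]
        return cls(species=list(species), genes=genes)


@dataclass
class FunctionalProfile:
    table: pd.DataFrame  # columns: gene_family, contributor, tier, reads, rpk, cpm
    tier_cpm: dict = field(default_factory=dict)
    unmapped_count: int = 0

    def n_gene_families(self) -> int:
        return int(self.table["gene_family"].nunique()) if len(self.table) else 0

    def cpm_total(self) -> float:
        return float(self.table["cpm"].sum()) if len(self.table) else 0.0

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary_to_tsv(self, path) -> None:
        rows = [(tier, cpm) for tier, cpm in sorted(self.tier_cpm.items())]
        rows.append(("unmapped_reads", self.unmapped_count))
        pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# prescreen


def prescreen(profile: TaxonomicProfile, threshold: float = 0.001) -> list[str]:
    """Species at or above the abundance threshold, most abundant first."""
    if profile.rank != "species":
        raise ParameterError("prescreen expects a species-rank profile")
    hits = [(t, a) for t, a in profile.abundances.items() if a >= threshold and a > 0]
    hits.sort(key=lambda ta: (-ta[1], ta[0]))
    return [t for t, _ in hits]


# ---------------------------------------------------------------------------
# nucleotide tier


def nucleotide_search(
    reads: ReadSet,
    pangenome: PangenomeSubset,
    k: int = 31,
    min_hit_fraction: float = 0.5,
    subject_coverage_threshold: float = 25.0,
) -> tuple[dict, ReadSet]:
    """Assign reads to pangenome genes by best k-mer containment.

    Ties break toward the longest gene, then the lexicographically smallest
    gene_id.  After assignment, genes whose covered fraction of positions is
    below ``subject_coverage_threshold`` percent are dropped and their reads
    rerouted to the unmapped output.

    Returns (counts keyed by (gene_id, gene_family_id, species), unmapped reads).
    """
    if not pangenome.genes:
        return {}, reads

    # k-mer -> (gene index, position) lookup; shared k-mers keep all owners
    kmer_map: dict[int, list[tuple[int, int]]] = {}
    for gi, (_, gene) in enumerate(pangenome.genes):
        codes = _kmers.seq_canonical_codes(gene.sequence, k)
        for pos, code in enumerate(codes.tolist()):
            kmer_map.setdefault(code, []).append((gi, pos))

    n_genes = len(pangenome.genes)
    gene_order = sorted(
        range(n_genes),
        key=lambda gi: (-pangenome.genes[gi][1].length, pangenome.genes[gi][1].gene_id),
    )
    gene_rank = {gi: r for r, gi in enumerate(gene_order)}

    assigned_reads: dict[int, list[int]] = {}   # gene index -> read indices
    covered: dict[int, set] = {}                # gene index -> covered positions
    unmapped_idx: list[int] = []
    for idx, mat in _kmers.group_by_length(reads.sequences):
        w = mat.shape[1] - k + 1
        if w <= 0:
            unmapped_idx.extend(int(i) for i in idx)
            continue
        codes = _kmers.canonical_codes(mat, k)
        for j, i in enumerate(idx):
            per_gene: dict[int, list[int]] = {}
            for code in codes[j].tolist():
                for gi, pos in kmer_map.get(code, ()):
                    per_gene.setdefault(gi, []).append(pos)
            if not per_gene:
                unmapped_idx.append(int(i))
                continue
            best = max(per_gene, key=lambda gi: (len(per_gene[gi]), -gene_rank[gi]))
            if len(per_gene[best]) < min_hit_fraction * w:
                unmapped_idx.append(int(i))
                continue
            assigned_reads.setdefault(best, []).append(int(i))
            cov = covered.setdefault(best, set())
            for pos in per_gene[best]:
                cov.update(range(pos, pos + k))

    counts: dict[tuple[str, str, str], float] = {}
    for gi, read_idx in assigned_reads.items():
        species, gene = pangenome.genes[gi]
        frac = 100.0 * len(covered[gi]) / gene.length
        if frac < subject_coverage_threshold:
            unmapped_idx.extend(read_idx)
            continue
        counts[(gene.gene_id, gene.gene_family_id, species)] = float(len(read_idx))
    unmapped_idx.sort()
    return counts, reads.subset(unmapped_idx)


# ---------------------------------------------------------------------------
# translated tier


def _read_peptides(seq: str, min_len: int) -> list[str]:
    """Six-frame translation split at stop codons."""
    peptides = []
    for strand_seq in (seq, _kmers.revcomp(seq)):
        for frame in range(3):
            sub = strand_seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) < 3:
                continue
            aa = str(Seq(sub).translate())
            peptides.extend(p for p in aa.split("*") if len(p) >= min_len)
    return peptides


def translated_search(
    unmapped: ReadSet,
    protein_db: Mapping[str, str],
    peptide_k: int = 8,
) -> tuple[dict, int]:
    """Map nucleotide-tier failures to gene families via peptide k-mers.

    Each read is translated in six frames and split at stop codons; it is
    assigned to the family sharing the most peptide k-mers (at least one;
    ties break to the smallest family id).  Returns (family -> read count,
    number of reads failing this tier too).
    """
    if peptide_k < 1:
        raise ParameterError("peptide_k must be >= 1")
    pep_index: dict[str, set] = {}
    for family in sorted(protein_db):
        for pep in protein_db[family].split("*"):
            for i in range(len(pep) - peptide_k + 1):
                pep_index.setdefault(pep[i : i + peptide_k], set()).add(family)
    counts: dict[str, float] = {}
    unmapped_count = 0
    for read in unmapped:
        votes: dict[str, int] = {}
        for pep in _read_peptides(read.sequence, peptide_k):
            for i in range(len(pep) - peptide_k + 1):
                for family in pep_index.get(pep[i : i + peptide_k], ()):
                    votes[family] = votes.get(family, 0) + 1
        if not votes:
            unmapped_count += 1
            continue
        best = min(votes, key=lambda fam: (-votes[fam], fam))
        counts[best] = counts.get(best, 0.0) + 1.0
    return counts, unmapped_count


# ---------------------------------------------------------------------------
# quantification


def quantify(
    nucleotide_counts: Mapping[tuple, float],
    translated_counts: Mapping[str, float],
    family_lengths: Mapping[str, float],
    unmapped_count: int = 0,
) -> FunctionalProfile:
    """RPK/CPM table stratified by contributor and tier.

    ``family_lengths`` supplies the representative gene length per family
    (median source-gene length); nucleotide rows are keyed as
    ``(gene_id, gene_family_id, species)``.
    """
    rows = []
    for (gene_id, family, species), n in nucleotide_counts.items():
        length = family_lengths.get(family)
        if length is None or length <= 0:
            raise ParameterError(f"missing length for family {family}")
        rows.append((family, species, TIER_NUCLEOTIDE, n, n / (length / 1000.0)))
    for family, n in translated_counts.items():
        length = family_lengths.get(family)
        if length is None or length <= 0:
            raise ParameterError(f"missing length for family {family}")
        rows.append((family, UNCLASSIFIED, TIER_TRANSLATED, n, n / (length / 1000.0)))
    df = pd.DataFrame(rows, columns=["gene_family", "contributor", "tier", "reads", "rpk"])
    if len(df):
        df = (
            df.groupby(["gene_family", "contributor", "tier"], as_index=False)
            .agg(reads=("reads", "sum"), rpk=("rpk", "sum"))
            .sort_values(["tier", "gene_family", "contributor"], ignore_index=True)
        )
    total_rpk = float(df["rpk"].sum()) if len(df) else 0.0
    if total_rpk > 0:
        df["cpm"] = df["rpk"] * 1e6 / total_rpk
    else:
        if len(df):
            warnings.warn("total RPK is zero; CPM set to zero", stacklevel=2)
        df["cpm"] = 0.0
    tier_cpm = {
        tier: float(df.loc[df["tier"] == tier, "cpm"].sum())
        for tier in (TIER_NUCLEOTIDE, TIER_TRANSLATED)
    }
    return FunctionalProfile(table=df, tier_cpm=tier_cpm, unmapped_count=unmapped_count)


def family_representative_lengths(ref: ReferenceSet) -> dict[str, float]:
    """Median source-gene length per gene family across the pangenome."""
    lengths: dict[str, list[int]] = {}
    for genes in ref.species_pangenomes.values():
        for g in genes:
            lengths.setdefault(g.gene_family_id, []).append(g.length)
    return {fam: float(np.median(v)) for fam, v in lengths.items()}


# ---------------------------------------------------------------------------
# orchestration


def functional_profile(
    reads: ReadSet,
    ref: ReferenceSet,
    species_profile: TaxonomicProfile,
    *,
    prescreen_threshold: float = 0.001,
    k: int = 31,
    min_hit_fraction: float = 0.5,
    subject_coverage_threshold: float = 25.0,
    peptide_k: int = 8,
    protein_db: Optional[Mapping[str, str]] = None,
) -> FunctionalProfile:
    """Full tiered pipeline: prescreen -> nucleotide search -> translated
    search -> RPK/CPM quantification."""
    species = prescreen(species_profile, prescreen_threshold)
    subset = PangenomeSubset.from_reference(ref, species)
    nuc_counts, leftover = nucleotide_search(
        reads, subset, k=k, min_hit_fraction=min_hit_fraction,
        subject_coverage_threshold=subject_coverage_threshold,
    )
    trans_counts, unmapped = translated_search(
        leftover, protein_db if protein_db is not None else ref.protein_db,
        peptide_k=peptide_k,
    )
    return quantify(
        nuc_counts, trans_counts, family_representative_lengths(ref),
        unmapped_count=unmapped,
    )
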
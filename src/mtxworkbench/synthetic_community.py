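"""Synthetic host-microbiome data generator with full hidden ground truth.

The generator emulates a mock-community benchmarking design for
low-microbial-biomass metatranscriptomics:

* a toy taxonomy and reference universe (bacterial genomes with gene
  (transcript) pools, congeneric shared-ancestry segments, host / rRNA /
  viral nuisance references, a peptide database, and a handful of
  reagent-contaminant species that exist in the reference but not in the
  community);
* cell-ratio samples ("SS series"): a community of cells mixed with host
  cells, where reads are drawn per *transcript* weight, so a 97% host-cell
  sample produces far more than 97% host reads;
* read-fraction mixtures ("SD series"): seeded subsampling without
  replacement from a microbial and a host read pool at fixed depth;
* cross-sample reagent contaminants whose expected read count scales as
  1/concentration (constant contaminant mass).

Every read carries a hidden truth label (species taxon_id, ``host``,
``rrna``, ``virus``, or ``contaminant:<taxon_id>``) used only by evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from Bio.Seq import Seq

from . import _kmers
from .errors import EmptyLibraryError, ParameterError, PoolExhaustionError
from .reads import CONTAMINANT_PREFIX, LABEL_HOST, LABEL_RRNA, LABEL_VIRUS, ReadSet
from .taxonomy import TaxonNode, TaxonomyTree

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CommunityMember:
    taxon_id: str
    genus_id: str
    cell_fraction: float
    activity: float  # nonnegative transcripts-per-cell weight; 0 = silent


@dataclass
class CommunitySpec:
    species: list[CommunityMember]

    def __post_init__(self):
        total = sum(m.cell_fraction for m in self.species)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"cell fractions sum to {total}, not 1")
        for m in self.species:
            if m.activity < 0:
                raise ParameterError(f"{m.taxon_id}: negative activity")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_genera(self) -> int:
        return len({m.genus_id for m in self.species})

    def with_activity(self, taxon_id: str, activity: float) -> "CommunitySpec":
        """Copy of the spec with one species' transcriptional activity replaced."""
        return CommunitySpec(
            [
                CommunityMember(m.taxon_id, m.genus_id, m.cell_fraction,
                                activity if m.taxon_id == taxon_id else m.activity)
                for m in self.species
            ]
        )

    def taxon_ids(self) -> list[str]:
        return [m.taxon_id for m in self.species]


@dataclass(frozen=True)
class PangenomeGene:
    gene_id: str
    gene_family_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceSet:
    species_genomes: dict = field(default_factory=dict)     # taxon_id -> [seq]
    species_pangenomes: dict = field(default_factory=dict)  # taxon_id -> [PangenomeGene]
    host_sequences: list = field(default_factory=list)
    rrna_sequences: list = field(default_factory=list)
    virus_sequences: list = field(default_factory=list)
    protein_db: dict = field(default_factory=dict)           # family -> peptide

    def transcript_pool(self, taxon_id: str) -> list[str]:
        genes = self.species_pangenomes.get(taxon_id)
        if genes:
            return [g.sequence for g in genes]
        return self.species_genomes[taxon_id]


@dataclass(frozen=True)
class MixSpec:
    host_fraction: float
    depth: int
    seed: int
    mode: str  # "cell_ratio" | "read_fraction"

    def __post_init__(self):
        if self.depth <= 0:
            raise ParameterError("depth must be positive")
        if not 0.0 <= self.host_fraction <= 1.0:
            raise ParameterError("host_fraction must lie in [0, 1]")
        if self.mode not in ("cell_ratio", "read_fraction"):
            raise ParameterError(f"unknown mix mode {self.mode!r}")


# ---------------------------------------------------------------------------
# toy reference construction


def _random_seq_mat(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mat_to_str(mat: np.ndarray) -> str:
    return _kmers.decode_matrix(mat[None, :])[0]


def build_toy_reference(
    n_species: int = 20,
    n_genera: int = 18,
    genome_len: int = 10_000,
    genes_per_species: int = 8,
    seed: int = 0,
    *,
    gene_len: int = 900,
    shared_block_len: int = 62,
    n_contaminant_species: int = 3,
    n_host_seqs: int = 30,
    host_seq_len: int = 3_000,
    n_rrna: int = 5,
    rrna_len: int = 1_500,
    n_virus: int = 5,
    virus_len: int = 5_000,
) -> tuple[TaxonomyTree, ReferenceSet, CommunitySpec]:
    """Build the toy taxonomy, reference universe and community specification.

    Species genomes are i.i.d. random sequences; congeneric species
    additionally share an identical ancestry block (so some k-mers resolve
    only to genus level).  Pangenome genes are non-overlapping genome
    substrings whose translations populate the peptide database.  A few
    contaminant species (own genera, own phylum) are part of the reference
    universe but not of the community.  Deterministic for a fixed seed.
    """
    if not 1 <= n_genera <= n_species:
        raise ParameterError("need 1 <= n_genera <= n_species")
    if genes_per_species * gene_len > genome_len:
        raise ParameterError("genes do not fit in the genome")
    if n_species > 99 or n_contaminant_species > 99:
        raise ParameterError("toy references support at most 99 species per class")

    rng = np.random.default_rng(seed)

    # taxonomy -------------------------------------------------------------
    nodes = [TaxonNode("R", None, "root", "root"),
             TaxonNode("D1", "R", "domain", "Bacteria")]
    n_phyla = min(4, n_genera)
    for p in range(n_phyla):
        nodes.append(TaxonNode(f"P{p + 1}", "D1", "phylum", f"Phylum_{p + 1}"))
    genus_of_species: dict[str, str] = {}
    for g in range(n_genera):
        gid = f"G{g + 1:02d}"
        nodes.append(TaxonNode(gid, f"P{g % n_phyla + 1}", "genus", f"Genus_{g + 1:02d}"))
    species_ids = []
    for s in range(n_species):
        sid = f"S{s + 1:02d}"
        gid = f"G{s % n_genera + 1:02d}"
        genus_of_species[sid] = gid
        nodes.append(TaxonNode(sid, gid, "species", f"Species_{s + 1:02d}"))
        species_ids.append(sid)
    contaminant_ids = []
    if n_contaminant_species:
        nodes.append(TaxonNode("PX", "D1", "phylum", "Phylum_contam"))
        for c in range(n_contaminant_species):
            gid, sid = f"GX{c + 1:02d}", f"X{c + 1:02d}"
            nodes.append(TaxonNode(gid, "PX", "genus", f"Genus_contam_{c + 1:02d}"))
            nodes.append(TaxonNode(sid, gid, "species", f"Contaminant_{c + 1:02d}"))
            contaminant_ids.append(sid)
    tree = TaxonomyTree(nodes)

    # genomes with congeneric shared blocks --------------------------------
    ref = ReferenceSet()
    genus_blocks: dict[str, np.ndarray] = {}
    block_pos = genome_len // 2  # fixed implant site, inside a gene region
    for sid in species_ids + contaminant_ids:
        genome = _random_seq_mat(rng, genome_len)
        gid = genus_of_species.get(sid)
        if gid is not None and shared_block_len > 0:
            if gid not in genus_blocks:
                genus_blocks[gid] = _random_seq_mat(rng, shared_block_len)
            genome[block_pos : block_pos + shared_block_len] = genus_blocks[gid]
        ref.species_genomes[sid] = [_mat_to_str(genome)]

        # genes tile the genome front-to-back with even gaps
        gap = (genome_len - genes_per_species * gene_len) // max(genes_per_species, 1)
        genes = []
        for gi in range(genes_per_species):
            start = gi * (gene_len + gap)
            seq = _mat_to_str(genome[start : start + gene_len])
            gene_id = f"{sid}_g{gi + 1}"
            family = f"F_{sid}_{gi + 1}"
            genes.append(PangenomeGene(gene_id, family, seq))
            ref.protein_db[family] = str(Seq(seq).translate())
        ref.species_pangenomes[sid] = genes

    ref.host_sequences = [
        _mat_to_str(_random_seq_mat(rng, host_seq_len)) for _ in range(n_host_seqs)
    ]
    ref.rrna_sequences = [
        _mat_to_str(_random_seq_mat(rng, rrna_len)) for _ in range(n_rrna)
    ]
    ref.virus_sequences = [
        _mat_to_str(_random_seq_mat(rng, virus_len)) for _ in range(n_virus)
    ]

    community = CommunitySpec(
        [
            CommunityMember(sid, genus_of_species[sid], 1.0 / n_species, 1.0)
            for sid in species_ids
        ]
    )
    return tree, ref, community


# ---------------------------------------------------------------------------
# read drawing machinery


class _PoolSampler:
    """Draw fixed-length substrings uniformly from a pool of sequences.

    Start positions are uniform over all valid windows of the pool, so longer
    sequences contribute proportionally more reads.
    """

    def __init__(self, seqs: Sequence[str], read_len: int):
        if not seqs:
            raise ParameterError("empty sequence pool")
        if min(len(s) for s in seqs) < read_len:
            raise ParameterError("pool contains sequences shorter than the read length")
        self.read_len = read_len
        self._big = np.concatenate([_kmers.encode(s) for s in seqs])
        offsets, windows = [], []
        off = 0
        for s in seqs:
            offsets.append(off)
            windows.append(len(s) - read_len + 1)
            off += len(s)
        self._offsets = np.asarray(offsets, dtype=np.int64)
        self._cum_windows = np.cumsum(np.asarray(windows, dtype=np.int64))

    def sample(self, rng: np.random.Generator, n: int, error_rate: float) -> np.ndarray:
        if n == 0:
            return np.empty((0, self.read_len), dtype=np.uint8)
        u = rng.integers(0, self._cum_windows[-1], size=n)
        seq_idx = np.searchsorted(self._cum_windows, u, side="right")
        local = u - np.where(seq_idx > 0, self._cum_windows[seq_idx - 1], 0)
        start = self._offsets[seq_idx] + local
        mat = self._big[start[:, None] + np.arange(self.read_len)]
        if error_rate > 0:
            err = rng.random(mat.shape) < error_rate
            shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            mat = mat.copy()
            mat[err] = (mat[err] + shift) % 4
        return mat


def _draw_qualities(
    rng: np.random.Generator,
    n: int,
    read_len: int,
    base_quality: int,
    tail_quality: int,
    low_quality_tail_fraction: float,
) -> np.ndarray:
    qual = np.full((n, read_len), base_quality, dtype=np.uint8)
    if low_quality_tail_fraction > 0 and n > 0:
        degraded = rng.random(n) < low_quality_tail_fraction
        starts = rng.integers(
            max(1, math.ceil(0.55 * read_len)), max(2, int(0.95 * read_len)), size=n
        )
        cols = np.arange(read_len)[None, :]
        tail = degraded[:, None] & (cols >= starts[:, None])
        qual[tail] = tail_quality
    return qual


# ---------------------------------------------------------------------------
# cell-ratio samples (SS series)


def expected_host_read_share(
    community: CommunitySpec, host_fraction: float, host_weight: float
) -> float:
    """Expected host share among non-nuisance reads in cell-ratio mode.

    ``host_fraction * h / (host_fraction * h + (1 - host_fraction) * sum_s
    cell_fraction_s * activity_s)`` — cell ratio is not read ratio: the host
    transcript weight ``h`` models how many transcripts a host cell
    contributes relative to one unit of bacterial activity.
    """
    micro = sum(m.cell_fraction * m.activity for m in community.species)
    denom = host_fraction * host_weight + (1.0 - host_fraction) * micro
    if denom == 0:
        raise EmptyLibraryError("no transcriptional activity in the mixture")
    return host_fraction * host_weight / denom


def simulate_sample(
    ref: ReferenceSet,
    community: CommunitySpec,
    mix: MixSpec,
    read_len: int = 100,
    error_rate: float = 0.005,
    *,
    host_weight: float = 15.0,
    rrna_fraction: float = 0.01,
    virus_fraction: float = 0.002,
    low_quality_tail_fraction: float = 0.05,
    base_quality: int = 37,
    tail_quality: int = 2,
    id_prefix: str = "r",
) -> ReadSet:
    """Simulate a cell-ratio (SS-series analog) single-end read set.

    Reads are drawn from species transcript (gene) pools, the host reference,
    and small rRNA/viral nuisance fractions; substitution errors at
    ``error_rate``; a configurable fraction of reads carries a sub-Q20 tail to
    exercise quality trimming.  Species with activity 0 contribute no reads.
    """
    if mix.mode != "cell_ratio":
        raise ParameterError("simulate_sample requires mode='cell_ratio'")
    if rrna_fraction + virus_fraction >= 1.0:
        raise ParameterError("nuisance fractions must sum below 1")
    rng = np.random.default_rng(mix.seed)

    host_share = expected_host_read_share(community, mix.host_fraction, host_weight)
    micro = sum(m.cell_fraction * m.activity for m in community.species)
    p_nuis = rrna_fraction + virus_fraction
    labels = [LABEL_RRNA, LABEL_VIRUS, LABEL_HOST]
    probs = [rrna_fraction, virus_fraction, (1 - p_nuis) * host_share]
    for m in community.species:
        w = m.cell_fraction * m.activity / micro if micro > 0 else 0.0
        labels.append(m.taxon_id)
        probs.append((1 - p_nuis) * (1 - host_share) * w)
    counts = rng.multinomial(mix.depth, np.asarray(probs))

    mats, out_labels = [], []
    pools = {
        LABEL_RRNA: ref.rrna_sequences,
        LABEL_VIRUS: ref.virus_sequences,
        LABEL_HOST: ref.host_sequences,
    }
    for label, n in zip(labels, counts):
        if n == 0:
            continue
        seqs = pools.get(label) or ref.transcript_pool(label)
        sampler = _PoolSampler(seqs, read_len)
        mats.append(sampler.sample(rng, int(n), error_rate))
        out_labels.extend([label] * int(n))
    if not mats:
        raise EmptyLibraryError("simulated library is empty")

    mat = np.vstack(mats)
    qual = _draw_qualities(rng, len(mat), read_len, base_quality, tail_quality,
                           low_quality_tail_fraction)
    perm = rng.permutation(len(mat))
    mat, qual = mat[perm], qual[perm]
    out_labels = [out_labels[i] for i in perm]
    seqs = _kmers.decode_matrix(mat)
    return ReadSet(
        ids=[f"{id_prefix}{i}" for i in range(len(seqs))],
        sequences=seqs,
        qualities=[qual[i] for i in range(len(seqs))],
        labels=out_labels,
    )


# ---------------------------------------------------------------------------
# read-fraction mixtures (SD series)


def mix_reads(microbial_pool: ReadSet, host_pool: ReadSet, mix: MixSpec) -> ReadSet:
    """Combine two read pools at an exact host read fraction and fixed depth.

    Sampling is without replacement (subsampler semantics): the output holds
    exactly ``round(host_fraction * depth)`` host-pool reads and the
    remainder from the microbial pool, shuffled, deterministic per seed.
    """
    if mix.mode != "read_fraction":
        raise ParameterError("mix_reads requires mode='read_fraction'")
    n_host = int(round(mix.host_fraction * mix.depth))
    n_micro = mix.depth - n_host
    if n_host > len(host_pool):
        raise PoolExhaustionError("host", n_host, len(host_pool))
    if n_micro > len(microbial_pool):
        raise PoolExhaustionError("microbial", n_micro, len(microbial_pool))
    rng = np.random.default_rng(mix.seed)
    host_idx = rng.choice(len(host_pool), size=n_host, replace=False)
    micro_idx = rng.choice(len(microbial_pool), size=n_micro, replace=False)
    combined = ReadSet.concat(
        [host_pool.subset(host_idx.tolist()), microbial_pool.subset(micro_idx.tolist())]
    )
    perm = rng.permutation(len(combined))
    return combined.subset(perm.tolist())


# ---------------------------------------------------------------------------
# reagent contaminants


def inject_contaminants(
    reads_by_sample: Mapping[str, ReadSet],
    contaminant_taxa: Sequence[str],
    concentrations_by_sample: Mapping[str, float],
    ref: ReferenceSet,
    seed: int,
    *,
    read_len: int = 100,
    error_rate: float = 0.005,
    mass: float = 30.0,
    base_quality: int = 37,
) -> dict[str, ReadSet]:
    """Append reagent-contaminant reads to each sample of a panel.

    Under the constant-contaminant-mass model the expected contaminant read
    count per sample and taxon is ``mass / concentration``, so contaminant
    *frequency* decays as 1/concentration — the signature frequency-based
    decontamination keys on.  Reads are truth-labeled ``contaminant:<taxon>``.
    """
    if set(reads_by_sample) != set(concentrations_by_sample):
        raise ParameterError("sample ids of reads and concentrations differ")
    for s, c in concentrations_by_sample.items():
        if c <= 0:
            raise ParameterError(f"sample {s}: concentration must be positive")
    out: dict[str, ReadSet] = {}
    for i, sample in enumerate(sorted(reads_by_sample)):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        parts = [reads_by_sample[sample]]
        for taxon in contaminant_taxa:
            n = int(rng.poisson(mass / concentrations_by_sample[sample]))
            if n == 0:
                continue
            sampler = _PoolSampler(ref.transcript_pool(taxon), read_len)
            mat = sampler.sample(rng, n, error_rate)
            qual = np.full((n, read_len), base_quality, dtype=np.uint8)
            parts.append(
                ReadSet(
                    ids=[f"{sample}:cont:{taxon}:{j}" for j in range(n)],
                    sequences=_kmers.decode_matrix(mat),
                    qualities=[qual[j] for j in range(n)],
                    labels=[f"{CONTAMINANT_PREFIX}{taxon}"] * n,
                )
            )
        out[sample] = ReadSet.concat(parts)
    return out


# ---------------------------------------------------------------------------
# on-disk formats


def _write_fasta(path: Path, records: Sequence[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_reference(
    outdir,
    tree: TaxonomyTree,
    ref: ReferenceSet,
    community: Optional[CommunitySpec] = None,
) -> None:
    """Serialize the reference universe: FASTA + taxonomy TSV + community YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    recs = []
    for sid in sorted(ref.species_genomes):
        for i, seq in enumerate(ref.species_genomes[sid]):
            recs.append((f"{sid}|genome{i + 1}", seq))
    _write_fasta(outdir / "species_genomes.fasta", recs)
    recs = []
    for sid in sorted(ref.species_pangenomes):
        for g in ref.species_pangenomes[sid]:
            recs.append((f"{g.gene_id}|{g.gene_family_id}|{sid}", g.sequence))
    _write_fasta(outdir / "pangenome.fasta", recs)
    for name, seqs in (
        ("host", ref.host_sequences),
        ("rrna", ref.rrna_sequences),
        ("virus", ref.virus_sequences),
    ):
        _write_fasta(outdir / f"{name}.fasta",
                     [(f"{name}{i + 1}", s) for i, s in enumerate(seqs)])
    _write_fasta(outdir / "proteins.fasta",
                 sorted(ref.protein_db.items()))
    tree.to_tsv(outdir / "taxonomy.tsv")
    if community is not None:
        spec = {
            "species": [
                {"taxon_id": m.taxon_id, "genus_id": m.genus_id,
                 "cell_fraction": m.cell_fraction, "activity": m.activity}
                for m in community.species
            ]
        }
        with open(outdir / "community.yaml", "w") as fh:
            yaml.safe_dump(spec, fh, sort_keys=False)


def read_reference(indir) -> tuple[TaxonomyTree, ReferenceSet, Optional[CommunitySpec]]:
    from Bio import SeqIO

    indir = Path(indir)
    tree = TaxonomyTree.from_tsv(indir / "taxonomy.tsv")
    ref = ReferenceSet()
    for rec in SeqIO.parse(str(indir / "species_genomes.fasta"), "fasta"):
        sid = rec.id.split("|")[0]
        ref.species_genomes.setdefault(sid, []).append(str(rec.seq))
    for rec in SeqIO.parse(str(indir / "pangenome.fasta"), "fasta"):
        gene_id, family, sid = rec.id.split("|")
        ref.species_pangenomes.setdefault(sid, []).append(
            PangenomeGene(gene_id, family, str(rec.seq))
        )
    for name, attr in (("host", "host_sequences"), ("rrna", "rrna_sequences"),
                       ("virus", "virus_sequences")):
        setattr(ref, attr,
                [str(r.seq) for r in SeqIO.parse(str(indir / f"{name}.fasta"), "fasta")])
    ref.protein_db = {
        r.id: str(r.seq) for r in SeqIO.parse(str(indir / "proteins.fasta"), "fasta")
    }
    community = None
    cpath = indir / "community.yaml"
    if cpath.exists():
        with open(cpath) as fh:
            spec = yaml.safe_load(fh)
        community = CommunitySpec(
            [CommunityMember(d["taxon_id"], d["genus_id"], d["cell_fraction"],
                             d["activity"]) for d in spec["species"]]
        )
    return tree, ref, community
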
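"""Two classifier families producing comparable taxonomic profiles.

k-mer LCA family
    A database maps each canonical genome k-mer to the lowest common
    ancestor (LCA) of all species whose genomes contain it.  A read's hit
    taxa are scored along root-to-leaf paths; the leaf-ward taxon with the
    highest path score is the candidate, and a confidence threshold — the
    fraction of the read's k-mers falling inside the clade rooted at the
    assignment — controls precision: when the candidate's clade confidence
    is below the threshold the assignment ascends toward the root until an
    ancestor meets it, else the read is unclassified.  Reads left at
    internal (above-species) nodes are afterwards redistributed to species
    proportionally to direct species evidence (reestimation).

marker family
    A database of windows unique to each species' transcribed sequence.
    Species are detected when enough distinct markers are hit, and
    quantified by a robust (quantile-trimmed) average of marker coverages —
    the mechanism pair behind marker-based profilers' ``stat_q`` and ``-g``
    knobs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from . import _kmers
from .errors import MarkerUniquenessError, ParameterError
from .profiles import TaxonomicProfile
from .reads import ReadSet
from .synthetic_community import ReferenceSet
from .taxonomy import TaxonomyTree

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassifierConfig:
    confidence: float = 0.0   # k-mer family threshold in [0, 1]
    stat_q: float = 0.2       # marker family trim quantile in [0, 0.5)
    g_min: int = 3            # marker family detection threshold (>= 1)

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ParameterError("confidence must lie in [0, 1]")
        if not 0.0 <= self.stat_q < 0.5:
            raise ParameterError("stat_q must lie in [0, 0.5)")
        if self.g_min < 1:
            raise ParameterError("g_min must be >= 1")


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    assigned_taxon: str  # taxon_id or UNCLASSIFIED
    confidence: float


# ---------------------------------------------------------------------------
# k-mer LCA index


class KmerIndex:
    """Canonical k-mer -> LCA taxon table plus per-species k-mer totals."""

    def __init__(self, k: int, table: _kmers.CodeTable, kmer_totals: dict,
                 tree: TaxonomyTree):
        self.k = k
        self.table = table
        self.kmer_totals = kmer_totals  # species taxon_id -> distinct k-mers
        self.tree = tree


def build_kmer_index(ref: ReferenceSet, tree: TaxonomyTree, k: int = 31) -> KmerIndex:
    """Index every species genome; shared k-mers map to the LCA of their sources."""
    if k % 2 == 0 or not 1 <= k <= 31:
        raise ParameterError("k must be odd and in [1, 31]")
    lin = tree.linearize()
    species = sorted(ref.species_genomes)
    if len(set(species)) != len(species):
        raise ParameterError("duplicate species ids in reference")
    code_parts, src_parts = [], []
    kmer_totals = {}
    for sid in species:
        if sid not in tree:
            raise ParameterError(f"species {sid} missing from taxonomy")
        codes = _kmers.unique_canonical_codes(ref.species_genomes[sid], k)
        kmer_totals[sid] = int(codes.size)
        code_parts.append(codes)
        src_parts.append(np.full(codes.size, lin.index[sid], dtype=np.int32))
    codes = np.concatenate(code_parts)
    src = np.concatenate(src_parts)
    order = np.argsort(codes, kind="stable")
    codes, src = codes[order], src[order]

    # run-length groups: unique codes, LCA of the sources of each group
    boundary = np.empty(codes.size, dtype=bool)
    boundary[0] = True
    boundary[1:] = codes[1:] != codes[:-1]
    starts = np.nonzero(boundary)[0]
    ends = np.append(starts[1:], codes.size)
    taxa = src[starts].copy()
    multi = np.nonzero(ends - starts > 1)[0]
    for gi in multi:
        members = {lin.ids[t] for t in src[starts[gi] : ends[gi]]}
        taxa[gi] = lin.index[tree.lca_many(sorted(members))]
    table = _kmers.CodeTable(codes[starts], taxa)
    return KmerIndex(k=k, table=table, kmer_totals=kmer_totals, tree=tree)


# ---------------------------------------------------------------------------
# classification


def _candidate_order(lin) -> np.ndarray:
    """Column order used by argmax: deepest node first, then lowest taxon_id."""
    n = len(lin.ids)
    return np.array(
        sorted(range(n), key=lambda i: (-int(lin.depth[i]), lin.ids[i])), dtype=np.int64
    )


def _classify_matrix(
    mat: np.ndarray, index: KmerIndex, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each row of an equal-length read matrix.

    Returns (assigned taxon position or -1, confidence at the assignment).
    """
    lin = index.tree.linearize()
    n_taxa = len(lin.ids)
    n, length = mat.shape
    w = length - index.k + 1
    if w <= 0:
        return (np.full(n, -1, dtype=np.int64), np.zeros(n))
    codes = _kmers.canonical_codes(mat, index.k)
    hits = index.table.lookup(codes.ravel()).reshape(n, w).astype(np.int64)
    valid = hits >= 0
    rows = np.repeat(np.arange(n, dtype=np.int64), w)[valid.ravel()]
    flat = rows * n_taxa + hits.ravel()[valid.ravel()]
    counts = np.bincount(flat, minlength=n * n_taxa).reshape(n, n_taxa)
    counts = counts.astype(np.float64)

    anc = lin.ancestor.astype(np.float64)  # anc[a, d] = a ancestor-or-self of d
    path = counts @ anc          # path[:, t] = hits on ancestors-or-self of t
    clade = counts @ anc.T       # clade[:, t] = hits inside the clade rooted at t

    order = _candidate_order(lin)
    cand = order[np.argmax(path[:, order], axis=1)]
    total = counts.sum(axis=1)

    assigned = np.full(n, -1, dtype=np.int64)
    conf_out = np.zeros(n)
    active = total > 0
    cur = cand.copy()
    rows_all = np.arange(n)
    for _ in range(int(lin.depth.max()) + 1):
        conf = clade[rows_all, cur] / w
        ok = active & (conf >= threshold) & (assigned < 0)
        assigned[ok] = cur[ok]
        conf_out[ok] = conf[ok]
        pending = active & (assigned < 0)
        at_root = lin.parent[cur] == cur
        active = pending & ~at_root
        cur = np.where(active, lin.parent[cur], cur)
    # reads still pending at the root with conf < threshold stay unclassified;
    # their reported confidence is the (sub-threshold) root-clade fraction
    pending = (assigned < 0) & (total > 0)
    conf_out[pending] = total[pending] / w
    return assigned, conf_out


def classify_read(
    read_seq: str,
    index: KmerIndex,
    tree: TaxonomyTree,
    confidence_threshold: float = 0.0,
    read_id: str = "read",
) -> ReadClassification:
    """Classify one read; shorter-than-k reads are unclassified at confidence 0."""
    if len(read_seq) < index.k:
        return ReadClassification(read_id, UNCLASSIFIED, 0.0)
    mat = _kmers.encode(read_seq)[None, :]
    assigned, conf = _classify_matrix(mat, index, confidence_threshold)
    if assigned[0] < 0:
        return ReadClassification(read_id, UNCLASSIFIED, float(conf[0]))
    return ReadClassification(read_id, tree.linearize().ids[assigned[0]], float(conf[0]))


def classify_readset(
    reads: ReadSet,
    index: KmerIndex,
    confidence_threshold: float = 0.0,
    chunk: int = 200_000,
) -> tuple[dict, int, list[str]]:
    """Classify a read set in vectorized equal-length batches.

    Returns (direct counts per taxon, unclassified count, per-read assignment
    aligned with the input order).
    """
    lin = index.tree.linearize()
    assignments = [UNCLASSIFIED] * len(reads)
    counts: dict[str, float] = {}
    unclassified = 0
    for idx, mat in _kmers.group_by_length(reads.sequences):
        for lo in range(0, len(idx), chunk):
            sub = idx[lo : lo + chunk]
            assigned, _ = _classify_matrix(mat[lo : lo + chunk], index,
                                           confidence_threshold)
            for j, i in enumerate(sub):
                a = int(assigned[j])
                if a < 0:
                    unclassified += 1
                else:
                    t = lin.ids[a]
                    assignments[i] = t
                    counts[t] = counts.get(t, 0.0) + 1.0
    n_empty = len(reads) - sum(len(i) for i, _ in _kmers.group_by_length(reads.sequences))
    unclassified += n_empty
    return counts, unclassified, assignments


# ---------------------------------------------------------------------------
# species-level reestimation


def reestimate_species(
    direct_counts: Mapping[str, float],
    tree: TaxonomyTree,
    kmer_totals: Optional[Mapping[str, float]] = None,
    unclassified_count: int = 0,
) -> TaxonomicProfile:
    """Redistribute internal-node counts down to species.

    Each above-species node's count is shared among its descendant species in
    proportion to their direct-assignment counts; when no descendant species
    has direct evidence, the species' distinct-k-mer totals are used as
    weights instead.  Total read count is conserved exactly.
    """
    species_counts: dict[str, float] = {}
    for t, c in direct_counts.items():
        if t in tree and tree.node(t).rank == "species":
            species_counts[t] = species_counts.get(t, 0.0) + float(c)
    for t, c in direct_counts.items():
        if t not in tree or tree.node(t).rank == "species" or c <= 0:
            continue
        members = tree.subtree_species(t)
        if not members:
            continue
        weights = np.array([direct_counts.get(s, 0.0) for s in members], dtype=float)
        if weights.sum() == 0:
            if kmer_totals is not None:
                weights = np.array([kmer_totals.get(s, 0.0) for s in members], dtype=float)
            if weights.sum() == 0:
                weights = np.ones(len(members))
        weights = weights / weights.sum()
        for s, wgt in zip(members, weights):
            if wgt > 0:
                species_counts[s] = species_counts.get(s, 0.0) + float(c) * wgt
    return TaxonomicProfile.from_counts(species_counts, rank="species",
                                        unclassified_count=unclassified_count)


# ---------------------------------------------------------------------------
# marker database and profiler


@dataclass
class Marker:
    species: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


class MarkerDB:
    """Per-species unique marker windows plus a marker k-mer lookup table."""

    def __init__(self, markers: Sequence[Marker], k: int):
        self.markers = list(markers)
        self.k = k
        codes, ids = [], []
        for mi, m in enumerate(self.markers):
            c = np.unique(_kmers.seq_canonical_codes(m.sequence, k))
            codes.append(c)
            ids.append(np.full(c.size, mi, dtype=np.int32))
        self.table = _kmers.CodeTable(np.concatenate(codes), np.concatenate(ids))

    def species_markers(self) -> dict:
        out: dict[str, list[int]] = {}
        for mi, m in enumerate(self.markers):
            out.setdefault(m.species, []).append(mi)
        return out


def build_marker_db(
    ref: ReferenceSet,
    tree: TaxonomyTree,
    marker_len: int = 300,
    markers_per_species: int = 10,
    seed: int = 0,
    *,
    k: int = 31,
    species: Optional[Sequence[str]] = None,
    max_attempts: int = 200,
) -> MarkerDB:
    """Select unique, disjoint marker windows from each species' transcripts.

    A candidate window is rejected when any of its k-mers occurs in another
    species' genome (this excludes congeneric shared-ancestry segments) or
    when it overlaps an already-selected marker of the same species.
    Deterministic for a fixed seed.
    """
    if species is None:
        species = sorted(ref.species_pangenomes)
    rng = np.random.default_rng(seed)
    # single ownership table: code -> owning species index, or -2 when shared
    all_species = sorted(ref.species_genomes)
    sp_idx = {sid: i for i, sid in enumerate(all_species)}
    parts, owners = [], []
    for sid in all_species:
        c = _kmers.unique_canonical_codes(ref.species_genomes[sid], k)
        parts.append(c)
        owners.append(np.full(c.size, sp_idx[sid], dtype=np.int32))
    codes_all = np.concatenate(parts)
    owner_all = np.concatenate(owners)
    order = np.argsort(codes_all, kind="stable")
    codes_all, owner_all = codes_all[order], owner_all[order]
    dup = np.zeros(codes_all.size, dtype=bool)
    dup[1:] |= codes_all[1:] == codes_all[:-1]
    dup[:-1] |= codes_all[1:] == codes_all[:-1]
    owner_all = np.where(dup, -2, owner_all).astype(np.int32)
    ownership = _kmers.CodeTable(codes_all, owner_all)
    markers: list[Marker] = []
    for sid in species:
        pool = ref.transcript_pool(sid)
        chosen: list[tuple[int, int]] = []  # (gene index, start)
        seqs: list[str] = []
        attempts = 0
        while len(seqs) < markers_per_species:
            attempts += 1
            if attempts > max_attempts * markers_per_species:
                raise MarkerUniquenessError(
                    f"species {sid}: could not find {markers_per_species} unique "
                    f"disjoint windows of length {marker_len}"
                )
            gi = int(rng.integers(0, len(pool)))
            gene = pool[gi]
            if len(gene) < marker_len:
                continue
            start = int(rng.integers(0, len(gene) - marker_len + 1))
            if any(g == gi and not (start + marker_len <= s or start >= s + marker_len)
                   for g, s in chosen):
                continue
            window = gene[start : start + marker_len]
            codes = _kmers.seq_canonical_codes(window, k)
            if (ownership.lookup(codes) != sp_idx[sid]).any():
                continue  # overlaps sequence shared with another species
            chosen.append((gi, start))
            seqs.append(window)
        markers.extend(Marker(sid, s) for s in seqs)
    return MarkerDB(markers, k=k)


def profile_markers(
    reads: ReadSet,
    markerdb: MarkerDB,
    stat_q: float = 0.2,
    g_min: int = 3,
) -> TaxonomicProfile:
    """Marker-based species profile.

    A read hits a marker when at least half of its k-mers occur in that
    marker; marker coverage sums read_len / marker_len over hitting reads.
    A species is detected when >= ``g_min`` of its markers are hit; detected
    species are quantified by the quantile-trimmed robust average of their
    marker coverages, normalized across detected species.
    """
    ClassifierConfig(stat_q=stat_q, g_min=g_min)  # validate
    n_markers = len(markerdb.markers)
    coverage = np.zeros(n_markers)
    hit_reads = np.zeros(n_markers, dtype=np.int64)
    k = markerdb.k
    for idx, mat in _kmers.group_by_length(reads.sequences):
        w = mat.shape[1] - k + 1
        if w <= 0:
            continue
        codes = _kmers.canonical_codes(mat, k)
        marker_hit = markerdb.table.lookup(codes.ravel()).reshape(codes.shape)
        valid = marker_hit >= 0
        if not valid.any():
            continue
        n = mat.shape[0]
        rows = np.repeat(np.arange(n, dtype=np.int64), w)[valid.ravel()]
        flat = rows * n_markers + marker_hit.ravel()[valid.ravel()].astype(np.int64)
        per_read = np.bincount(flat, minlength=n * n_markers).reshape(n, n_markers)
        hits = per_read >= 0.5 * w  # containment rule: >= half the read's k-mers
        read_len = mat.shape[1]
        for mi in np.nonzero(hits.any(axis=0))[0]:
            nh = int(hits[:, mi].sum())
            hit_reads[mi] += nh
            coverage[mi] += nh * read_len / markerdb.markers[mi].length
    abund: dict[str, float] = {}
    for sid, mids in markerdb.species_markers().items():
        detected_markers = int((hit_reads[mids] > 0).sum())
        if detected_markers < g_min:
            continue
        abund[sid] = robust_average(coverage[mids], stat_q)
    return TaxonomicProfile.from_counts(abund, rank="species")


def robust_average(values: Sequence[float], stat_q: float) -> float:
    """Mean after discarding the top and bottom ``stat_q`` quantiles.

    With m values, floor(stat_q * m) entries are dropped from each end of the
    sorted vector; degenerate trims fall back to the plain mean.
    """
    vals = np.sort(np.asarray(values, dtype=float))
    drop = int(np.floor(stat_q * vals.size))
    if vals.size - 2 * drop <= 0:
        return float(vals.mean())
    return float(vals[drop : vals.size - drop].mean())
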
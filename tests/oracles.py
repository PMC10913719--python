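"""Independent brute-force oracles used to pin down expected values.

Everything here is deliberately naive (string scans, explicit enumeration)
and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGT", "TGCA")
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return min(kmer, rc)


def kmer_code(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = (code << 2) | _ENC[b]
    return code


def canonical_code(kmer: str) -> int:
    return kmer_code(canonical_kmer(kmer))


def read_kmers(seq: str, k: int) -> list[str]:
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def genomes_containing(kmer: str, genomes: dict) -> list[str]:
    """Species whose genome contains the k-mer on either strand."""
    rc = revcomp(kmer)
    return sorted(
        sid
        for sid, seqs in genomes.items()
        if any(kmer in s or rc in s for s in seqs)
    )


def lca_by_ancestors(tree, taxa) -> str:
    """LCA as the deepest taxon common to every node's root path."""
    common = set(tree.ancestors(taxa[0]))
    for t in taxa[1:]:
        common &= set(tree.ancestors(t))
    return max(common, key=lambda t: len(tree.ancestors(t)))


def classify_by_path_scores(seq: str, kmer_to_taxon: dict, tree, threshold: float,
                            k: int):
    """Exhaustive path-score classifier over every node of the tree.

    ``kmer_to_taxon`` maps canonical k-mer string -> taxon_id.  Returns
    (assigned taxon or None, confidence).
    """
    kmers = read_kmers(seq, k)
    if not kmers:
        return None, 0.0
    hits: dict[str, int] = {}
    for km in kmers:
        t = kmer_to_taxon.get(canonical_kmer(km))
        if t is not None:
            hits[t] = hits.get(t, 0) + 1
    w = len(kmers)
    if not hits:
        return None, 0.0

    def path_score(t):
        return sum(hits.get(a, 0) for a in tree.ancestors(t))

    def clade_conf(t):
        return sum(hits.get(d, 0) for d in tree.subtree(t)) / w

    # candidate: max path score, ties to the deepest node then lowest id
    candidate = min(
        tree.index,
        key=lambda t: (-path_score(t), -len(tree.ancestors(t)), t),
    )
    node = candidate
    while True:
        conf = clade_conf(node)
        if conf >= threshold:
            return node, conf
        parent = tree.node(node).parent_id
        if parent is None:
            return None, conf
        node = parent


def sliding_window_trim(quals, window: int, min_mean: float):
    """(kept_length or None-if-untrimmed, discarded?) by explicit window scan."""
    n = len(quals)
    for start in range(n - window + 1):
        if sum(quals[start : start + window]) / window < min_mean:
            return start, start <= n / 2
    return None, False


def trimmed_mean(values, q: float) -> float:
    vals = sorted(values)
    drop = int(q * len(vals))
    core = vals[drop : len(vals) - drop] if len(vals) - 2 * drop > 0 else vals
    return sum(core) / len(core)


def redistribute(internal_count: float, species_weights: dict) -> dict:
    total = sum(species_weights.values())
    return {s: internal_count * w / total for s, w in species_weights.items()}


def presence_metrics(detected: set, truth: set):
    tp = len(detected & truth)
    fp = len(detected - truth)
    fn = len(truth - detected)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return tp, fp, fn, precision, recall, f1
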
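"""Read pre-processing: adapter removal, sliding-window quality trimming,
and alignment-free depletion of host, viral, and rRNA reads.

Trimming follows the classic sliding-window contract: scanning 4-base
windows left to right, a read is cut at the start of the first window whose
mean Phred quality drops below 20, and discarded outright when the kept part
is no longer than half the original length.

Depletion replaces a read aligner with k-mer containment: a read is removed
when at least ``min_hit_fraction`` of its canonical k-mers occur in a
reference k-mer set.  Stages are applied host -> virus -> rRNA with
per-stage accounting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kmers
from .errors import ParameterError
from .reads import ReadSet

_STAGES = ("host", "virus", "rrna")


@dataclass
class PreprocessReport:
    input_reads: int = 0
    quality_pass: int = 0
    removed_host: int = 0
    removed_virus: int = 0
    removed_rrna: int = 0
    surviving: int = 0

    def check(self) -> None:
        expect = (self.quality_pass - self.removed_host - self.removed_virus
                  - self.removed_rrna)
        if self.surviving != expect or min(
            self.input_reads, self.quality_pass, self.removed_host,
            self.removed_virus, self.removed_rrna, self.surviving
        ) < 0:
            raise ParameterError("inconsistent preprocessing report")

    def to_tsv(self, path) -> None:
        pd.DataFrame([self.__dict__]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# quality trimming


def _first_failing_window(
    qual: np.ndarray, window: int, min_mean_q: float
) -> np.ndarray:
    """Start of the first window with mean quality below threshold, per read
    of a (n_reads, L) quality matrix; -1 where no window fails."""
    n, length = qual.shape
    w = length - window + 1
    if w <= 0:
        return np.full(n, -1, dtype=np.int64)
    cs = np.cumsum(qual.astype(np.int64), axis=1)
    sums = np.empty((n, w), dtype=np.int64)
    sums[:, 0] = cs[:, window - 1]
    if w > 1:
        sums[:, 1:] = cs[:, window:] - cs[:, :-window]
    fail = sums < min_mean_q * window
    first = np.argmax(fail, axis=1)
    first[~fail.any(axis=1)] = -1
    return first


def quality_trim(reads: ReadSet, window: int = 4, min_mean_q: float = 20.0) -> ReadSet:
    """Sliding-window trim; drops reads whose kept part is <= half the original."""
    if window < 1:
        raise ParameterError("window must be >= 1")
    cuts = np.full(len(reads), -1, dtype=np.int64)  # -1 = untrimmed
    for idx, _ in _kmers.group_by_length(reads.sequences):
        qual = np.vstack([reads.qualities[i] for i in idx])
        cuts[idx] = _first_failing_window(qual, window, min_mean_q)
    out = ReadSet()
    for i in range(len(reads)):
        c = int(cuts[i])
        length = len(reads.sequences[i])
        if c < 0:
            out.ids.append(reads.ids[i])
            out.sequences.append(reads.sequences[i])
            out.qualities.append(reads.qualities[i])
            out.labels.append(reads.labels[i])
        elif c > length / 2:
            out.ids.append(reads.ids[i])
            out.sequences.append(reads.sequences[i][:c])
            out.qualities.append(reads.qualities[i][:c])
            out.labels.append(reads.labels[i])
        # else: discarded (kept part would be <= half the read)
    return out


def adapter_trim(reads: ReadSet, adapter: str) -> ReadSet:
    """Exact-match removal of an adapter string from read ends (prefix/suffix)."""
    if not adapter:
        return reads
    out = ReadSet()
    for i in range(len(reads)):
        seq, qual = reads.sequences[i], reads.qualities[i]
        if seq.startswith(adapter):
            seq, qual = seq[len(adapter):], qual[len(adapter):]
        if seq.endswith(adapter):
            seq, qual = seq[: -len(adapter)], qual[: -len(adapter)]
        if seq:
            out.ids.append(reads.ids[i])
            out.sequences.append(seq)
            out.qualities.append(qual)
            out.labels.append(reads.labels[i])
    return out


# ---------------------------------------------------------------------------
# reference-based depletion


class DepletionIndex:
    """Combined labeled k-mer table over the host/virus/rRNA references.

    The three reference k-mer sets are essentially disjoint (random collisions
    at k=31 are negligible), so a single lookup with stage priority
    host > virus > rrna reproduces sequential per-stage depletion while
    scanning each read once.
    """

    def __init__(
        self,
        host: Sequence[str] = (),
        virus: Sequence[str] = (),
        rrna: Sequence[str] = (),
        k: int = 31,
    ):
        self.k = k
        codes, stages = [], []
        for stage_idx, seqs in enumerate((host, virus, rrna)):
            c = _kmers.unique_canonical_codes(seqs, k)
            codes.append(c)
            stages.append(np.full(c.size, stage_idx, dtype=np.int8))
        all_codes = np.concatenate(codes)
        all_stages = np.concatenate(stages)
        # priority: keep the lowest stage index on collision
        order = np.lexsort((all_stages, all_codes))
        all_codes, all_stages = all_codes[order], all_stages[order]
        keep = np.ones(all_codes.size, dtype=bool)
        keep[1:] = all_codes[1:] != all_codes[:-1]
        self.table = _kmers.CodeTable(all_codes[keep], all_stages[keep])

    def stage_fractions(self, reads: ReadSet) -> np.ndarray:
        """(n_reads, 3) fraction of each read's k-mers found per stage."""
        out = np.zeros((len(reads), 3), dtype=np.float64)
        for idx, mat in _kmers.group_by_length(reads.sequences):
            w = mat.shape[1] - self.k + 1
            if w <= 0:
                continue
            codes = _kmers.canonical_codes(mat, self.k)
            stage = self.table.lookup(codes.ravel()).reshape(codes.shape)
            for s in range(3):
                out[idx, s] = (stage == s).sum(axis=1) / w
        return out


def deplete_by_reference(
    reads: ReadSet,
    reference_sequences: Sequence[str],
    k: int = 31,
    min_hit_fraction: float = 0.5,
) -> tuple[ReadSet, ReadSet]:
    """Single-stage depletion: remove reads whose k-mer containment fraction
    against one reference reaches ``min_hit_fraction``.  Returns (kept, removed)."""
    if not reference_sequences:
        warnings.warn("empty depletion reference; no reads removed", stacklevel=2)
        return reads, ReadSet()
    codes = _kmers.unique_canonical_codes(reference_sequences, k)
    frac = np.zeros(len(reads))
    for idx, mat in _kmers.group_by_length(reads.sequences):
        w = mat.shape[1] - k + 1
        if w <= 0:
            continue
        q = _kmers.canonical_codes(mat, k)
        frac[idx] = _kmers.member_mask(codes, q.ravel()).reshape(q.shape).sum(axis=1) / w
    removed = np.nonzero(frac >= min_hit_fraction)[0]
    kept = np.nonzero(frac < min_hit_fraction)[0]
    return reads.subset(kept.tolist()), reads.subset(removed.tolist())


def run_preprocess(
    reads: ReadSet,
    host: Sequence[str] = (),
    rrna: Sequence[str] = (),
    virus: Sequence[str] = (),
    *,
    window: int = 4,
    min_mean_q: float = 20.0,
    k: int = 31,
    min_hit_fraction: float = 0.5,
    adapter: Optional[str] = None,
    index: Optional[DepletionIndex] = None,
) -> tuple[ReadSet, PreprocessReport]:
    """Full pre-processing pipeline: adapter/quality trimming, then host ->
    virus -> rRNA depletion, with a per-stage accounting report."""
    report = PreprocessReport(input_reads=len(reads))
    if adapter:
        reads = adapter_trim(reads, adapter)
    reads = quality_trim(reads, window=window, min_mean_q=min_mean_q)
    report.quality_pass = len(reads)
    if index is None:
        index = DepletionIndex(host=host, virus=virus, rrna=rrna, k=k)
    frac = index.stage_fractions(reads)
    hit = frac >= min_hit_fraction
    stage = np.where(hit.any(axis=1), np.argmax(hit, axis=1), -1)
    report.removed_host = int((stage == 0).sum())
    report.removed_virus = int((stage == 1).sum())
    report.removed_rrna = int((stage == 2).sum())
    kept = reads.subset(np.nonzero(stage == -1)[0].tolist())
    report.surviving = len(kept)
    report.check()
    return kept, report
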
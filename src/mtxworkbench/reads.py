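"""Read containers and FASTQ / truth-sidecar serialization.

A :class:`ReadSet` is columnar (parallel lists) so batch operations can
re-encode sequences in equal-length groups without touching per-read objects.
Truth labels are the hidden ground-truth channel of the simulator: one of a
species taxon_id, ``host``, ``rrna``, ``virus``, or ``contaminant:<taxon_id>``.
They ride alongside the reads for evaluation and are serialized to a separate
sidecar TSV that is never handed to a profiler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

LABEL_HOST = "host"
LABEL_RRNA = "rrna"
LABEL_VIRUS = "virus"
CONTAMINANT_PREFIX = "contaminant:"


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    quality: np.ndarray  # Phred scores, uint8, same length as sequence
    label: Optional[str] = None


@dataclass
class ReadSet:
    """Columnar collection of reads with an optional hidden truth channel."""

    ids: list[str] = field(default_factory=list)
    sequences: list[str] = field(default_factory=list)
    qualities: list[np.ndarray] = field(default_factory=list)
    labels: list[Optional[str]] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.ids)
        if not (len(self.sequences) == len(self.qualities) == len(self.labels) == n):
            raise ValueError("ReadSet columns must have equal length")
        for s, q in zip(self.sequences, self.qualities):
            if len(s) != len(q):
                raise ValueError("quality vector length must equal sequence length")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[Read]:
        for i in range(len(self)):
            yield Read(self.ids[i], self.sequences[i], self.qualities[i], self.labels[i])

    def subset(self, indices: Sequence[int]) -> "ReadSet":
        return ReadSet(
            ids=[self.ids[i] for i in indices],
            sequences=[self.sequences[i] for i in indices],
            qualities=[self.qualities[i] for i in indices],
            labels=[self.labels[i] for i in indices],
        )

    @staticmethod
    def concat(parts: Sequence["ReadSet"]) -> "ReadSet":
        out = ReadSet()
        for p in parts:
            out.ids.extend(p.ids)
            out.sequences.extend(p.sequences)
            out.qualities.extend(p.qualities)
            out.labels.extend(p.labels)
        return out

    def label_counts(self) -> dict:
        counts: dict = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    # -- FASTQ (Phred+33) -----------------------------------------------------

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for i in range(len(self)):
                qual = (self.qualities[i].astype(np.uint8) + 33).tobytes().decode("ascii")
                fh.write(f"@{self.ids[i]}\n{self.sequences[i]}\n+\n{qual}\n")

    @classmethod
    def from_fastq(cls, path, labels: Optional[dict] = None) -> "ReadSet":
        out = cls()
        for rec in SeqIO.parse(str(path), "fastq"):
            out.ids.append(rec.id)
            out.sequences.append(str(rec.seq))
            out.qualities.append(
                np.asarray(rec.letter_annotations["phred_quality"], dtype=np.uint8)
            )
            out.labels.append(labels.get(rec.id) if labels else None)
        return out

    # -- truth sidecar (read_id, label) ---------------------------------------

    def truth_to_tsv(self, path) -> None:
        pd.DataFrame({"read_id": self.ids, "label": self.labels}).to_csv(
            path, sep="\t", index=False
        )

    @staticmethod
    def truth_from_tsv(path) -> dict:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return dict(zip(df["read_id"], df["label"]))
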
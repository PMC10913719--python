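"""Taxonomic profiles and their two TSV dialects.

A :class:`TaxonomicProfile` holds per-taxon read counts and relative
abundances at a stated rank; it is the object that flows from classification
through decontamination and prescreening into evaluation.  Two on-disk
dialects are supported: a rank/count report (taxon_id, rank, direct_count,
clade_count, in the style of k-mer classifier reports) and a flat
lineage/relative-abundance table (marker-profiler style).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .errors import ParameterError
from .taxonomy import TaxonomyTree

_ABUND_TOL = 1e-9


@dataclass
class TaxonomicProfile:
    rank: str
    counts: dict = field(default_factory=dict)          # taxon_id -> read count
    abundances: dict = field(default_factory=dict)      # taxon_id -> rel abundance
    unclassified_count: int = 0

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, float], rank: str, unclassified_count: int = 0
    ) -> "TaxonomicProfile":
        counts = {t: float(c) for t, c in counts.items() if c > 0}
        total = sum(counts.values())
        abund = {t: c / total for t, c in counts.items()} if total > 0 else {}
        return cls(rank=rank, counts=dict(counts), abundances=abund,
                   unclassified_count=unclassified_count)

    def detected(self) -> set:
        """Taxa with nonzero relative abundance (presence/absence view)."""
        return {t for t, a in self.abundances.items() if a > 0}

    def total_count(self) -> float:
        return sum(self.counts.values())

    def check(self) -> None:
        if self.abundances:
            s = sum(self.abundances.values())
            if abs(s - 1.0) > _ABUND_TOL:
                raise ParameterError(f"relative abundances sum to {s}, not 1")

    # -- rank/count report dialect -------------------------------------------

    def to_report_tsv(self, path, tree: Optional[TaxonomyTree] = None) -> None:
        rows = []
        for t in sorted(self.counts):
            clade = self.counts[t]
            if tree is not None and t in tree:
                clade = sum(self.counts.get(d, 0.0) for d in tree.subtree(t))
            rows.append((t, self.rank if tree is None else tree.node(t).rank,
                         self.counts[t], clade))
        df = pd.DataFrame(rows, columns=["taxon_id", "rank", "direct_count", "clade_count"])
        df.loc[len(df)] = ("unclassified", "none", self.unclassified_count,
                           self.unclassified_count)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_report_tsv(cls, path, rank: str) -> "TaxonomicProfile":
        df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str})
        unclassified = 0
        counts = {}
        for r in df.itertuples():
            if r.taxon_id == "unclassified":
                unclassified = int(r.direct_count)
            else:
                counts[r.taxon_id] = float(r.direct_count)
        return cls.from_counts(counts, rank=rank, unclassified_count=unclassified)

    # -- flat lineage / relative abundance dialect ----------------------------

    def to_abundance_tsv(self, path, tree: Optional[TaxonomyTree] = None) -> None:
        rows = []
        for t in sorted(self.abundances):
            lineage = t
            if tree is not None and t in tree:
                lineage = "|".join(reversed(tree.ancestors(t)))
            rows.append((lineage, self.abundances[t]))
        pd.DataFrame(rows, columns=["lineage", "rel_abundance"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_abundance_tsv(cls, path, rank: str) -> "TaxonomicProfile":
        df = pd.read_csv(path, sep="\t", dtype={"lineage": str})
        abund = {r.lineage.split("|")[-1]: float(r.rel_abundance) for r in df.itertuples()}
        prof = cls(rank=rank, counts={}, abundances=abund)
        return prof
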
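"""Ground-truth evaluation and figure-level summaries.

Detection is presence/absence: a taxon counts as detected when its relative
abundance is positive, regardless of magnitude.  Precision, recall and F1
are computed against the known community membership; species profiles can
be aggregated to genus rank for cross-method comparison, and profiles are
compared by Spearman rank correlation over the union of their taxa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .profiles import TaxonomicProfile
from .taxonomy import TaxonomyTree


@dataclass(frozen=True)
class GroundTruth:
    rank: str
    taxa: frozenset

    def __post_init__(self):
        if not self.taxa:
            raise ParameterError("ground truth must be nonempty")

    @classmethod
    def from_community(cls, community, rank: str = "species") -> "GroundTruth":
        if rank == "species":
            return cls(rank, frozenset(m.taxon_id for m in community.species))
        if rank == "genus":
            return cls(rank, frozenset(m.genus_id for m in community.species))
        raise ParameterError(f"unsupported truth rank {rank!r}")


@dataclass(frozen=True)
class EvalMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def score_profile(profile: TaxonomicProfile, truth: GroundTruth) -> EvalMetrics:
    """Presence/absence precision, recall and F1 against the expected taxa.

    Precision is defined as 0 when nothing is detected, so F1 is always
    computable.
    """
    if profile.rank != truth.rank:
        raise ParameterError(
            f"rank mismatch: profile at {profile.rank!r}, truth at {truth.rank!r}"
        )
    detected = profile.detected()
    tp = len(detected & truth.taxa)
    fp = len(detected - truth.taxa)
    fn = len(truth.taxa - detected)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return EvalMetrics(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1)


def aggregate_to_genus(profile: TaxonomicProfile, tree: TaxonomyTree) -> TaxonomicProfile:
    """Sum species abundances (and counts) into their parent genera."""
    if profile.rank != "species":
        raise ParameterError("aggregate_to_genus expects a species-rank profile")
    counts: dict[str, float] = {}
    abund: dict[str, float] = {}
    for t in set(profile.counts) | set(profile.abundances):
        g = tree.genus_of(t)
        if t in profile.counts:
            counts[g] = counts.get(g, 0.0) + profile.counts[t]
        if t in profile.abundances:
            abund[g] = abund.get(g, 0.0) + profile.abundances[t]
    out = TaxonomicProfile(rank="genus", counts=counts, abundances=abund,
                           unclassified_count=profile.unclassified_count)
    return out


def profile_correlation(
    profiles: Sequence[TaxonomicProfile],
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Symmetric Spearman correlation matrix across profiles.

    Abundances are aligned on the union of taxa (absent = 0); taxa absent
    from every profile are dropped.  Average ranks handle ties.  A pair
    involving a constant profile has no defined rank correlation and is
    reported as NaN; the diagonal is 1.
    """
    if len(profiles) < 2:
        raise ParameterError("need at least two profiles")
    if labels is None:
        labels = [f"profile_{i + 1}" for i in range(len(profiles))]
    taxa = sorted({t for p in profiles for t in p.abundances if p.abundances[t] > 0})
    mat = np.array([[p.abundances.get(t, 0.0) for t in taxa] for p in profiles])
    n = len(profiles)
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            if np.ptp(mat[i]) == 0 or np.ptp(mat[j]) == 0:
                continue  # undefined for a constant profile
            rho = stats.spearmanr(mat[i], mat[j]).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=list(labels), columns=list(labels))


def trend_vs_host_fraction(
    metric_by_sample: Sequence[float],
    host_fraction_by_sample: Sequence[float],
) -> tuple[float, str]:
    """Spearman correlation of a metric against host fraction, with verdict.

    Returns (rho, verdict) where verdict is "decreasing" when rho < 0,
    "increasing" when rho > 0, and "flat" when the correlation is undefined
    (constant input) or exactly zero.
    """
    if len(metric_by_sample) < 4:
        raise ParameterError("need at least 4 samples for a trend")
    if len(metric_by_sample) != len(host_fraction_by_sample):
        raise ParameterError("metric and host-fraction vectors differ in length")
    m = np.asarray(metric_by_sample, dtype=float)
    h = np.asarray(host_fraction_by_sample, dtype=float)
    if np.ptp(m) == 0 or np.ptp(h) == 0:
        return float("nan"), "flat"
    rho = float(stats.spearmanr(m, h).statistic)
    if np.isnan(rho) or rho == 0:
        return rho, "flat"
    return rho, "decreasing" if rho < 0 else "increasing"


def metrics_table(rows: Sequence[Mapping]) -> pd.DataFrame:
    """Per-sample, per-method metrics report (mirrors the benchmark layout)."""
    cols = ["sample", "method", "settings", "tp", "fp", "fn",
            "precision", "recall", "f1"]
    return pd.DataFrame(list(rows), columns=cols)


def write_metrics_tsv(rows: Sequence[Mapping], path) -> None:
    metrics_table(rows).to_csv(path, sep="\t", index=False)


def write_correlation_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")
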
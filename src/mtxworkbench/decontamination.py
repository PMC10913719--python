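"""Frequency-mode decontamination of taxonomic profiles.

Reagent contaminants contribute a roughly constant sequence mass per
library, so their relative frequency varies inversely with the total sample
concentration, while genuinely present taxa keep a concentration-independent
frequency.  Each taxon is scored by comparing two slope-fixed regressions of
log frequency on log concentration — slope -1 (contaminant model) versus
slope 0 (non-contaminant model) — via the F-distribution CDF of their
residual-sum-of-squares ratio.  A score near 0 means contaminant-like; taxa
scoring below the threshold are removed unless protected, together with
taxa whose names mark them as unclassified, and the remaining relative
abundances are renormalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .profiles import TaxonomicProfile
from .taxonomy import TaxonomyTree

MIN_SAMPLES = 4


@dataclass(frozen=True)
class ContaminantScore:
    taxon_id: str
    score: float  # in [0, 1]; nan when undefined
    is_contaminant: bool
    n_samples_used: int
    note: str = ""


@dataclass(frozen=True)
class DecontamConfig:
    threshold: float = 0.1
    protected: frozenset = field(default_factory=frozenset)
    unclassified_markers: tuple = ("unclassified",)

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ParameterError("threshold must lie in (0, 1)")


def score_frequency(
    taxon_freq_by_sample: Mapping[str, float],
    concentration_by_sample: Mapping[str, float],
    taxon_id: str = "",
    threshold: float = 0.1,
) -> ContaminantScore:
    """Score one taxon's frequency profile against the 1/concentration model.

    Samples with zero frequency or unknown concentration are excluded (log
    undefined); fewer than four usable samples leaves the score undefined and
    the taxon retained.
    """
    pairs = [
        (f, concentration_by_sample[s])
        for s, f in taxon_freq_by_sample.items()
        if f > 0 and s in concentration_by_sample and concentration_by_sample[s] > 0
    ]
    n = len(pairs)
    if n < MIN_SAMPLES:
        return ContaminantScore(taxon_id, float("nan"), False, n, "insufficient data")
    logf = np.log(np.array([p[0] for p in pairs]))
    logc = np.log(np.array([p[1] for p in pairs]))
    # contaminant model: log f = -log c + b ; non-contaminant: log f = b
    resid1 = (logf + logc) - (logf + logc).mean()
    resid0 = logf - logf.mean()
    ss1 = float(resid1 @ resid1)
    ss0 = float(resid0 @ resid0)
    if ss0 == 0.0 and ss1 == 0.0:
        score = 1.0  # constant data fits both; retain
    elif ss0 == 0.0:
        score = 1.0
    elif ss1 == 0.0:
        score = 0.0
    else:
        score = float(stats.f.cdf(ss1 / ss0, n - 1, n - 1))
    return ContaminantScore(taxon_id, score, score < threshold, n)


def score_panel(
    freq_table: pd.DataFrame,
    concentration_by_sample: Mapping[str, float],
    threshold: float = 0.1,
) -> dict[str, ContaminantScore]:
    """Score every taxon of a (taxa x samples) frequency table."""
    out = {}
    for taxon, row in freq_table.iterrows():
        out[str(taxon)] = score_frequency(
            row.to_dict(), concentration_by_sample, taxon_id=str(taxon),
            threshold=threshold,
        )
    return out


def frequencies_from_profiles(
    profiles: Mapping[str, TaxonomicProfile]
) -> pd.DataFrame:
    """(taxa x samples) relative-frequency table from per-sample profiles."""
    samples = sorted(profiles)
    taxa = sorted({t for p in profiles.values() for t in p.abundances})
    data = {
        s: [profiles[s].abundances.get(t, 0.0) for t in taxa] for s in samples
    }
    return pd.DataFrame(data, index=taxa)


def clean_profile(
    profile: TaxonomicProfile,
    scores: Mapping[str, ContaminantScore],
    config: DecontamConfig,
    tree: Optional[TaxonomyTree] = None,
) -> TaxonomicProfile:
    """Drop flagged contaminants (unless protected) and unclassified-named
    taxa, then renormalize the remaining relative abundances to 1."""
    kept: dict[str, float] = {}
    for t, c in profile.counts.items():
        name = tree.node(t).name if (tree is not None and t in tree) else t
        if any(m.lower() in name.lower() for m in config.unclassified_markers):
            continue
        sc = scores.get(t)
        if sc is not None and sc.is_contaminant and t not in config.protected \
                and name not in config.protected:
            continue
        kept[t] = c
    if not kept and profile.counts:
        warnings.warn("decontamination removed every taxon", stacklevel=2)
    out = TaxonomicProfile.from_counts(kept, rank=profile.rank,
                                       unclassified_count=profile.unclassified_count)
    # preserve abundance-only profiles (no counts backing them)
    if not profile.counts and profile.abundances:
        kept_ab = {
            t: a for t, a in profile.abundances.items()
            if t in kept or _keep_abundance_only(t, scores, config, tree)
        }
        total = sum(kept_ab.values())
        out.abundances = {t: a / total for t, a in kept_ab.items()} if total else {}
    return out


def _keep_abundance_only(t, scores, config, tree) -> bool:
    name = tree.node(t).name if (tree is not None and t in tree) else t
    if any(m.lower() in name.lower() for m in config.unclassified_markers):
        return False
    sc = scores.get(t)
    return not (sc is not None and sc.is_contaminant and t not in config.protected
                and name not in config.protected)


def scores_to_tsv(scores: Mapping[str, ContaminantScore], path) -> None:
    rows = [
        (s.taxon_id, s.score, s.is_contaminant, s.n_samples_used, s.note)
        for s in scores.values()
    ]
    pd.DataFrame(
        rows, columns=["taxon_id", "score", "is_contaminant", "n_samples_used", "note"]
    ).to_csv(path, sep="\t", index=False)
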
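"""Label-free spectral-count proteomics: normalization, filtering,
decoy FDR and differential abundance.

Spectral counts (MS/MS spectra per database hit) proxy protein
abundance. Two normalization dialects are supported, mirroring the two
digestion workflows:

* **in-gel**: each (sample, band) received its own spike-in standard
  (beta-lactoglobulin), so counts are first divided by the band's
  spike-in count to absorb digestion variability, then by the lane
  total over all hits and bands to absorb loading differences;
* **in-liquid**: division by the per-sample total only.

Either way the normalized values of one sample sum to 1. The
replicate-presence filter (raw count >= 3 in at least 3 of 5 replicates,
evaluated within either group by default) is applied to raw counts
before testing; normalized values feed the shared Mann-Whitney +
resampling-corrected differential machinery. Decoy-database hits give a
target-decoy FDR estimate for the accepted hit list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NormalizationError
from .multiplicity import ResamplingCorrection, apply_cutoff, corrected_cutoff
from .simulate import SpectralCountTable
from .stats import FeatureTestResult, run_per_feature_tests

__all__ = [
    "NormalizedAbundance",
    "normalize_in_gel",
    "normalize_in_liquid",
    "presence_filter",
    "decoy_fdr",
    "differential_abundance",
]


@dataclass
class NormalizedAbundance:
    """Hit x sample normalized abundances plus the normalization trace."""

    matrix: pd.DataFrame
    trace: dict = field(default_factory=dict)


def normalize_in_gel(table: SpectralCountTable) -> NormalizedAbundance:
    """Spike-in then lane-total normalization for in-gel digests.

    Step 1 divides every hit count by the spike-in count of its
    (sample, band); step 2 divides by the sum of step-1 values over all
    hits and bands of the lane, then bands are summed per hit, so each
    sample's values sum to 1.
    """
    if table.mode != "in_gel":
        raise NormalizationError(f"table mode is {table.mode!r}, expected 'in_gel'")
    if table.spike_in is None:
        raise NormalizationError("in-gel table carries no spike-in counts")
    counts = table.counts
    spike = table.spike_in.reindex(counts.columns)
    hit_present = counts.sum(axis=0) > 0
    bad = counts.columns[(spike.fillna(0) <= 0) & hit_present]
    if len(bad):
        sample, band = bad[0]
        raise NormalizationError(
            f"zero spike-in count in sample {sample!r}, band {band} "
            "where hits are present"
        )
    step1 = counts.div(spike, axis=1)
    step1 = step1.fillna(0.0)  # all-zero bands with zero spike contribute nothing
    lane_sums = step1.T.groupby(level="sample").sum().sum(axis=1)
    empty = lane_sums.index[lane_sums <= 0]
    if len(empty):
        raise NormalizationError(f"lane {empty[0]!r} has no spectral counts")
    per_band = step1.div(lane_sums, axis=1, level="sample")
    matrix = per_band.T.groupby(level="sample").sum().T[table.samples]
    return NormalizedAbundance(
        matrix=matrix,
        trace={
            "steps": ["spike_in_per_band", "lane_total"],
            "lane_sums": lane_sums,
        },
    )


def normalize_in_liquid(table: SpectralCountTable) -> NormalizedAbundance:
    """Per-sample total-count normalization for in-liquid digests."""
    if table.mode != "in_liquid":
        raise NormalizationError(f"table mode is {table.mode!r}, expected 'in_liquid'")
    totals_matrix = table.sample_totals()
    totals = totals_matrix.sum(axis=0)
    empty = totals.index[totals <= 0]
    if len(empty):
        raise NormalizationError(f"sample {empty[0]!r} has no spectral counts")
    matrix = totals_matrix.div(totals, axis=1)
    return NormalizedAbundance(
        matrix=matrix, trace={"steps": ["sample_total"], "totals": totals}
    )


def normalize(table: SpectralCountTable) -> NormalizedAbundance:
    """Dispatch on the table's digestion mode."""
    if table.mode == "in_gel":
        return normalize_in_gel(table)
    return normalize_in_liquid(table)


def presence_filter(
    table: SpectralCountTable,
    min_count: int = 3,
    min_replicates: int = 3,
    group_size: int | None = 5,
    scope: Literal["either_group", "pooled"] = "either_group",
) -> tuple[list[str], pd.DataFrame]:
    """Keep hits with raw count >= ``min_count`` in >= ``min_replicates``
    samples of at least one group (default) or of the pooled sample set.

    Evaluated on raw counts (summed over bands), before normalization.
    The filter is monotone: increasing any count never removes a hit.
    Returns ``(retained hit ids, filter log)``.
    """
    totals = table.sample_totals()
    groups = table.groups
    sizes = groups.value_counts()
    if group_size is not None and (sizes != group_size).any():
        raise ConfigurationError(
            f"expected {group_size} replicates per group, got {dict(sizes)}"
        )
    if (sizes < min_replicates).any():
        raise ConfigurationError(
            f"group sizes {dict(sizes)} below min_replicates={min_replicates}"
        )
    qualifying = totals >= min_count
    if scope == "either_group":
        ok = pd.Series(False, index=totals.index)
        for g in groups.unique():
            cols = groups.index[groups == g]
            ok |= qualifying[cols].sum(axis=1) >= min_replicates
    elif scope == "pooled":
        ok = qualifying.sum(axis=1) >= min_replicates
    else:
        raise ConfigurationError(f"unknown scope {scope!r}")
    retained = [str(h) for h in totals.index[ok]]
    log = pd.DataFrame(
        {
            "hit_id": totals.index.astype(str),
            "n_qualifying_samples": qualifying.sum(axis=1).to_numpy(),
            "retained": ok.to_numpy(),
        }
    )
    return retained, log


def decoy_fdr(decoy_flags: pd.Series, accepted_ids: Sequence[str]) -> float:
    """Target-decoy FDR of an accepted hit list:
    ``#accepted decoys / max(1, #accepted targets)``, capped at 1."""
    accepted = list(accepted_ids)
    if len(accepted) == 0:
        raise ConfigurationError("accepted hit list is empty")
    flags = decoy_flags.reindex(accepted)
    if flags.isna().any():
        missing = list(flags.index[flags.isna()])
        raise ConfigurationError(f"accepted ids without decoy flags: {missing}")
    n_decoy = int(flags.sum())
    n_target = len(accepted) - n_decoy
    return min(1.0, n_decoy / max(1, n_target))


def differential_abundance(
    normalized: NormalizedAbundance,
    groups: pd.Series,
    *,
    alpha: float = 0.05,
    n_iterations: int = 1000,
    seed: int = 0,
    hit_ids: Sequence[str] | None = None,
    protein_group: pd.Series | None = None,
    method: Literal["label_permutation", "group_bootstrap"] = "label_permutation",
) -> tuple[list[FeatureTestResult], ResamplingCorrection | None]:
    """Per-hit Mann-Whitney tests with the family's own corrected cutoff.

    ``hit_ids`` restricts testing to the presence-filtered hits.
    Redundant hits that map to the same protein are tested and reported
    individually; the grouping travels along in the results frame
    rather than being collapsed.
    """
    matrix = normalized.matrix
    if hit_ids is not None:
        matrix = matrix.loc[list(hit_ids)]
    if matrix.shape[0] == 0:
        warnings.warn("no hits to test after filtering", stacklevel=2)
        return [], None
    results, untestable = run_per_feature_tests(matrix, groups)
    correction = corrected_cutoff(
        matrix,
        groups,
        test="mwu",
        alpha=alpha,
        n_iterations=n_iterations,
        method=method,
        seed=seed,
    )
    apply_cutoff(results, correction, which_p="mwu")
    if protein_group is not None:
        for r in results:
            r.protein_group = str(protein_group.get(r.feature_id, r.feature_id))
    return results, correction
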
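"""qPCR quantification: from raw measurements to the analysis matrix.

The expression arm measures absolute transcript quantities by qRT-PCR in
technical triplicate against a genomic-DNA standard curve, with one
endogenous control gene (RSP8 in the wasp study) assumed uniformly
expressed. The analysis-ready matrix is built by:

1. standard-curve quantification (Cq -> absolute copies),
2. triplicate aggregation (mean of quantities, CV flag),
3. averaging duplicate runs of the same gene and merging contigs of the
   same gene (both are per-sample means, with an advisory Pearson-r
   check),
4. division by the control gene followed by a log transform, which
   cancels any per-sample technical scale factor exactly,
5. group-median imputation of missing cells (applied before the rank
   test; the ANOVA instead drops missing cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateCurveError,
    DomainError,
    InsufficientDataError,
    UnimputableError,
)
from .stats import pearson_r

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "absolute_quantity",
    "aggregate_technical_replicates",
    "merge_correlated_features",
    "normalize_to_control",
    "impute_group_median",
    "analysis_matrices",
]


@dataclass
class StandardCurve:
    """Least-squares line of Cq on log10 quantity.

    ``efficiency = 10**(-1/slope) - 1`` is 1.0 for perfect doubling
    (slope -3.3219).
    """

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit the standard curve from ``(log10_quantity, Cq)`` pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise DegenerateCurveError("need at least 2 (log10_quantity, Cq) points")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 2:
        raise DegenerateCurveError("need at least 2 distinct quantities")
    slope, intercept = np.polyfit(x, y, 1)
    if slope == 0:
        raise DegenerateCurveError("fitted slope is zero")
    resid = y - (slope * x + intercept)
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if sst == 0 else 1.0 - (resid**2).sum() / sst
    return StandardCurve(slope=float(slope), intercept=float(intercept), r_squared=float(r2))


def absolute_quantity(curve: StandardCurve, cq):
    """Invert the curve: ``quantity = 10**((cq - intercept) / slope)``."""
    cq = np.asarray(cq, dtype=float)
    q = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return float(q) if q.ndim == 0 else q


def aggregate_technical_replicates(
    values: Sequence[float], cv_warn: float = 0.3
) -> tuple[float, bool]:
    """Mean of the non-missing technical replicates.

    Returns ``(mean, flagged)`` where the flag marks a coefficient of
    variation (sd/mean, sample sd) above ``cv_warn``. All replicates
    missing propagates NaN rather than raising, so a fully failed well
    flows through as a missing cell.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return float("nan"), False
    mean = float(vals.mean())
    if len(vals) < 2 or mean == 0:
        return mean, False
    cv = float(vals.std(ddof=1) / mean)
    return mean, cv > cv_warn


@dataclass
class MergeRecord:
    merged_id: str
    members: tuple[str, str]
    r: float
    low_correlation: bool


def merge_correlated_features(
    matrix: pd.DataFrame,
    pair: tuple[str, str],
    min_r: float = 0.9,
    merged_id: str | None = None,
) -> tuple[pd.DataFrame, MergeRecord]:
    """Average two features of a features x samples matrix into one.

    Used both for duplicate qPCR runs of the same gene and for distinct
    contigs of one gene. The Pearson correlation of the pair is recorded
    and, when below ``min_r``, the merge proceeds with an advisory
    low-correlation flag (the study merged after *observing* r = 0.98,
    it did not require it). The merged row replaces the first member's
    position.
    """
    a, b = pair
    for g in (a, b):
        if g not in matrix.index:
            raise InsufficientDataError(f"feature {g!r} not present")
    va = matrix.loc[a].to_numpy(dtype=float)
    vb = matrix.loc[b].to_numpy(dtype=float)
    complete = ~np.isnan(va) & ~np.isnan(vb)
    if complete.sum() < 3:
        raise InsufficientDataError(
            f"merge of ({a}, {b}) needs >=3 samples observed in both"
        )
    r, _ = pearson_r(va[complete], vb[complete])
    merged = np.nanmean(np.vstack([va, vb]), axis=0)
    name = merged_id if merged_id is not None else f"{a}+{b}"
    out = matrix.copy()
    pos = out.index.get_loc(a)
    out = out.drop(index=[a, b])
    row = pd.DataFrame([merged], index=[name], columns=matrix.columns)
    out = pd.concat([out.iloc[:pos], row, out.iloc[pos:]])
    return out, MergeRecord(name, (str(a), str(b)), r, r < min_r)


_LOG = {2: np.log2, 10: np.log10, "e": np.log, "2": np.log2, "10": np.log10}


def normalize_to_control(
    matrix: pd.DataFrame,
    control_gene_id: str,
    log_base: Literal[2, 10, "e"] = 2,
) -> pd.DataFrame:
    """``log(quantity / control quantity)`` per gene and sample.

    The control row becomes exactly zero, and any multiplicative
    per-sample scale factor cancels. Ratio-then-log is the standard
    relative-quantification convention; the two orders are monotone
    equivalent for rank tests.
    """
    if control_gene_id not in matrix.index:
        raise DomainError(f"control gene {control_gene_id!r} absent from matrix")
    control = matrix.loc[control_gene_id]
    if control.isna().any():
        bad = list(matrix.columns[control.isna()])
        raise DomainError(f"control gene missing in samples {bad}")
    vals = matrix.to_numpy(dtype=float)
    nonpos = np.argwhere(np.nan_to_num(vals, nan=1.0) <= 0)
    if len(nonpos):
        g, s = nonpos[0]
        raise DomainError(
            f"non-positive quantity for gene {matrix.index[g]!r} in "
            f"sample {matrix.columns[s]!r}; cannot take logs"
        )
    log = _LOG[log_base]
    return log(matrix.div(control, axis=1))


def impute_group_median(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Replace missing cells by the same-group median of the gene."""
    groups = groups.reindex(matrix.columns)
    out = matrix.copy()
    for g in groups.unique():
        cols = matrix.columns[groups == g]
        block = out[cols]
        missing_rows = block.index[block.isna().any(axis=1)]
        for gene in missing_rows:
            observed = block.loc[gene].dropna()
            if observed.empty:
                raise UnimputableError(
                    f"gene {gene!r} has no observed value in group {g!r}"
                )
            out.loc[gene, cols] = block.loc[gene].fillna(observed.median())
    return out


def analysis_matrices(
    study,
    *,
    log_base: Literal[2, 10, "e"] = 2,
    cv_warn: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full preprocessing of an :class:`~castebias.simulate.ExpressionStudy`.

    Aggregates technical triplicates, averages duplicate runs and contig
    pairs, normalizes to the control gene on a log scale and imputes
    group medians. Returns ``(normalized_imputed, normalized_unimputed,
    log)`` where the rank test consumes the imputed matrix, the ANOVA
    the unimputed one, and ``log`` records CV flags and merges.
    """
    trace: dict = {"cv_flags": [], "merges": []}
    agg = {}
    for gene in study.quantities.index:
        row = []
        for sample in study.samples:
            val, flagged = aggregate_technical_replicates(
                study.quantities.loc[gene, sample].to_numpy(dtype=float), cv_warn
            )
            if flagged:
                trace["cv_flags"].append((str(gene), str(sample)))
            row.append(val)
        agg[gene] = row
    matrix = pd.DataFrame.from_dict(agg, orient="index", columns=list(study.samples))

    for gene, runs in study.replicate_runs.items():
        ids = list(runs)
        while len(ids) > 1:
            matrix, rec = merge_correlated_features(
                matrix, (ids[0], ids[1]), merged_id=gene if len(ids) == 2 else None
            )
            trace["merges"].append(rec)
            ids = [rec.merged_id] + ids[2:]
    for pair in study.contig_pairs:
        matrix, rec = merge_correlated_features(matrix, tuple(pair))
        trace["merges"].append(rec)

    normalized = normalize_to_control(matrix, study.control_gene_id, log_base)
    normalized = normalized.drop(index=study.control_gene_id)
    imputed = impute_group_median(normalized, study.groups)
    return imputed, normalized, trace
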
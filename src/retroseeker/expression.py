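"""Expression-level downstream analyses on a supplied count matrix.

Counting reads over candidate intervals happens upstream (any counter
producing a features x samples table will do); this module normalizes to
reads per million (RPM), applies the expressed-feature filter (> 20 reads
in >= 2 samples by default), aggregates log2(RPM + 1) per tissue and
computes the Tau tissue-specificity index

    tau = sum_i (1 - x_i / max(x)) / (n - 1)

over n per-tissue expression values x on the log scale.  Tau is 0 for a
uniform positive profile, 1 when expression is confined to one tissue,
and features with tau strictly greater than the threshold (0.8 by
default) are labelled tissue specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def rpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads-per-million normalization: count / library_size * 1e6.

    ``library_sizes`` defaults to the column sums of ``counts`` (flagged to
    the caller by documentation rather than silently differing: pass the
    true library sizes whenever the matrix is a subset of the library).
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ValueError("every sample needs a positive library size")
    return counts.div(library_sizes, axis=1) * 1e6


def log2_rpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """log2(RPM + 1); the pseudocount keeps zero counts at exactly 0."""
    return np.log2(rpm(counts, library_sizes) + 1.0)


def is_expressed(
    feature_counts: Sequence[float] | pd.Series,
    min_reads: int = 20,
    min_samples: int = 2,
) -> bool:
    """True iff strictly more than ``min_reads`` reads in >= ``min_samples`` samples."""
    arr = np.asarray(feature_counts, dtype=float)
    return int((arr > min_reads).sum()) >= min_samples


def expressed_mask(
    counts: pd.DataFrame, min_reads: int = 20, min_samples: int = 2
) -> pd.Series:
    """Vectorized :func:`is_expressed` over the rows of a count matrix."""
    return (counts > min_reads).sum(axis=1) >= min_samples


def tissue_means(
    log_expression: pd.DataFrame, sample_to_tissue: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Mean log-expression per tissue (features x tissues).

    Every sample column must be mapped to exactly one tissue.
    """
    mapping = pd.Series(sample_to_tissue)
    missing = [s for s in log_expression.columns if s not in mapping.index]
    if missing:
        raise ValueError(f"samples without a tissue assignment: {missing[:5]}")
    groups = mapping.reindex(log_expression.columns)
    return log_expression.T.groupby(groups).mean().T


def tau(tissue_values: Sequence[float] | pd.Series) -> float:
    """Tau tissue-specificity index of one feature's per-tissue profile.

    Values must be >= 0 (log2(RPM+1) means); an all-zero profile has no
    defined peak and returns NaN.  Invariant to positive rescaling.
    """
    x = np.asarray(tissue_values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a 1-D profile over at least two tissues")
    if np.any(x < 0) or np.any(~np.isfinite(x)):
        raise ValueError("tau expects finite non-negative expression values")
    peak = x.max()
    if peak == 0:
        return float("nan")
    return float(np.sum(1.0 - x / peak) / (x.size - 1))


@dataclass
class TauResult:
    """Per-feature tissue-specificity summary."""

    feature: str
    tau: float
    peak_tissue: str | None
    is_specific: bool


def classify_tissue_specific(
    means: pd.DataFrame, threshold: float = 0.8
) -> pd.DataFrame:
    """Tau + peak tissue + specific/ubiquitous label for every feature.

    ``is_specific`` uses a strict ``tau > threshold`` cut; the peak tissue
    is the argmax of the per-tissue means, ties resolved to the
    lexicographically first tissue name.
    """
    ordered = means.reindex(sorted(means.columns), axis=1)
    rows = []
    for feature, profile in ordered.iterrows():
        t = tau(profile.to_numpy())
        peak = None if math.isnan(t) else profile.idxmax()
        rows.append(
            {
                "feature": feature,
                "tau": t,
                "peakTissue": peak,
                "isSpecific": (not math.isnan(t)) and t > threshold,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def tau_analysis(
    counts: pd.DataFrame,
    sample_to_tissue: Mapping[str, str] | pd.Series,
    library_sizes: pd.Series | None = None,
    min_reads: int = 20,
    min_samples: int = 2,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """The full expression workflow on a count matrix.

    Returns a per-feature table with maxLog2RPM, nSamplesExpressed,
    expressed, tau, peakTissue and isSpecific columns.
    """
    log_expr = log2_rpm(counts, library_sizes)
    means = tissue_means(log_expr, sample_to_tissue)
    table = classify_tissue_specific(means, threshold=threshold)
    table.insert(0, "maxLog2RPM", log_expr.max(axis=1))
    table.insert(1, "nSamplesExpressed", (counts > min_reads).sum(axis=1))
    table.insert(2, "expressed", expressed_mask(counts, min_reads, min_samples))
    return table
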
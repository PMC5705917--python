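"""Expression normalisation and fold-change filtering.

Each gene's post-arrest expression is expressed relative to its level
during logarithmic growth (the baseline sample), and the strict >10-fold
up/down filters pick out the strongly repressed and induced gene sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError


def normalize_counts(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """RPKM-style normalisation: count / (length_kb * library_millions).

    ``counts`` is genes x samples (gene_id index); ``library_sizes``
    defaults to per-sample column sums. Users with pre-normalised tables
    can skip this step entirely.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ValidationError("library sizes must be positive for every sample")
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValidationError("every gene needs a positive length")
    kb = lengths / 1000.0
    millions = library_sizes / 1e6
    return counts.div(kb, axis=0).div(millions, axis=1)


def ratio_to_baseline(expr: pd.DataFrame, baseline: str) -> pd.DataFrame:
    """Per-gene expression ratios versus the logarithmic-growth baseline.

    All values are floored at half the smallest nonzero entry of the table
    before ratio formation, so ratios stay finite and ordering is
    preserved; a gene at zero in both baseline and timepoint gets ratio 1.
    """
    if baseline not in expr.columns:
        raise ValidationError(f"baseline column {baseline!r} not in table")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValidationError("expression values must be finite and >= 0")
    nonzero = values[values > 0]
    if nonzero.size:
        floored = expr.clip(lower=float(nonzero.min()) * 0.5)
    else:
        floored = expr + 1.0  # all-zero table: every ratio is 1
    return floored.div(floored[baseline], axis=0)


def fold_filter(
    ratios: pd.DataFrame,
    timepoint: str,
    fold: float = 10.0,
    direction: str = "down",
) -> tuple[list[str], int]:
    """Genes changed more than ``fold``-fold at ``timepoint``.

    Strict inequality: down keeps ratio < 1/fold, up keeps ratio > fold;
    a gene at exactly the threshold is excluded. Returns the sorted gene
    list and its size.
    """
    if fold <= 1:
        raise ConfigError(f"fold must be > 1, got {fold}")
    if timepoint not in ratios.columns:
        raise ValidationError(f"unknown timepoint {timepoint!r}")
    col = ratios[timepoint]
    if direction == "down":
        hits = col[col < 1.0 / fold]
    elif direction == "up":
        hits = col[col > fold]
    else:
        raise ConfigError(f"direction must be 'down' or 'up', got {direction!r}")
    genes = sorted(hits.index)
    return genes, len(genes)
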
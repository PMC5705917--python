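"""Insertion-fitness calling from site-level Tn-seq read counts.

The per-sample procedure: discard insertion sites in the first 5% and last
10% of each gene's length, total the remaining ("central") reads, normalise
by gene length to reads per kilobase (RpK), take log2, fit a Gaussian to the
histogram of log2 RpK values by nonlinear least squares, and classify each
gene by where its value falls relative to the fitted mean: outside the
two-tailed ``alpha`` band below the mean is *reduced* insertion fitness,
outside above is *increased*, otherwise *neutral*. A call is promoted to a
consensus only when both biological replicates agree, and the longevity gene
set collects genes whose earliest non-neutral consensus is *reduced* within
the post-arrest window (days 3-14 by default), minus genes on any exclusion
list (growth-essential or growth-impaired genes).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import PipelineConfig
from .errors import (
    ConfigError,
    DegenerateDistributionError,
    FitConvergenceError,
    ValidationError,
)

TIMEPOINT_COLUMN = "timepoint_days"


class Call(str, enum.Enum):
    """Per-gene insertion-fitness classification."""

    REDUCED = "reduced"
    NEUTRAL = "neutral"
    INCREASED = "increased"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class InsertionSiteCounts:
    """Site-level read counts for one gene in one sample.

    ``sites`` holds ``(position_bp, count)`` pairs with 1-based positions
    on the gene's own coordinate system.
    """

    gene_id: str
    gene_length_bp: int
    sites: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.gene_length_bp < 1:
            raise ValidationError(
                f"{self.gene_id}: gene_length_bp must be >= 1"
            )
        positions = [p for p, _ in self.sites]
        if len(set(positions)) != len(positions):
            raise ValidationError(f"{self.gene_id}: duplicate insertion positions")
        for pos, count in self.sites:
            if not 1 <= pos <= self.gene_length_bp:
                raise ValidationError(
                    f"{self.gene_id}: position {pos} outside "
                    f"[1, {self.gene_length_bp}]"
                )
            if count < 0:
                raise ValidationError(f"{self.gene_id}: negative count at {pos}")

    @property
    def total_reads(self) -> int:
        return sum(c for _, c in self.sites)


@dataclass(frozen=True)
class RpkValue:
    """Length-normalised central read total for one gene.

    ``rpk`` is the raw central total divided by gene length in kilobases;
    ``log2_rpk`` is computed after the zero-handling pseudocount, so it is
    always finite. ``zero_adjusted`` flags genes whose central total was 0.
    """

    gene_id: str
    rpk: float
    log2_rpk: float
    zero_adjusted: bool = False


@dataclass(frozen=True)
class NormalFitResult:
    """Gaussian fitted to a log2 RpK histogram by nonlinear least squares."""

    mu: float
    sigma: float
    amplitude: float
    rmse: float
    n_bins: int
    bin_width: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu) or not math.isfinite(self.sigma):
            raise ValidationError("non-finite Gaussian fit parameters")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")


@dataclass(frozen=True)
class FitnessCall:
    gene_id: str
    timepoint: float
    replicate: int
    z_score: float
    call: Call


def trim_gene_sites(
    sites: InsertionSiteCounts,
    head_frac: float = 0.05,
    tail_frac: float = 0.10,
) -> InsertionSiteCounts:
    """Drop insertion sites in the first ``head_frac`` and last ``tail_frac``
    of the gene's length; keep a site iff
    ``head_frac < position/length <= 1 - tail_frac``.

    A site exactly at the 5% boundary is discarded; one exactly at the 90%
    boundary is kept.
    """
    if head_frac < 0 or tail_frac < 0 or head_frac + tail_frac >= 1:
        raise ConfigError(
            f"invalid trim fractions head={head_frac} tail={tail_frac}"
        )
    length = sites.gene_length_bp
    kept = tuple(
        (pos, count)
        for pos, count in sites.sites
        if head_frac < pos / length <= 1 - tail_frac
    )
    return replace(sites, sites=kept)


def gene_rpk(
    trimmed: InsertionSiteCounts, pseudocount_reads: float = 0.5
) -> RpkValue:
    """Reads per kilobase of the central (post-trim) read total.

    A gene with a zero central total receives ``pseudocount_reads`` before
    the log transform only, so every gene gets a finite log2 RpK.
    """
    total = trimmed.total_reads
    kb = trimmed.gene_length_bp / 1000.0
    rpk = total / kb
    if total > 0:
        return RpkValue(trimmed.gene_id, rpk, math.log2(rpk))
    return RpkValue(
        trimmed.gene_id, 0.0, math.log2(pseudocount_reads / kb), zero_adjusted=True
    )


def _gauss(x: np.ndarray, mu: float, log_sigma: float, amplitude: float):
    sigma = np.exp(log_sigma)
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_normal_to_histogram(
    values: Iterable[float], bin_width: float = 0.25
) -> NormalFitResult:
    """Fit ``A * exp(-(x - mu)^2 / (2 sigma^2))`` to the histogram of
    ``values`` at bin centres by nonlinear least squares.

    Initialisation uses the sample moments; sigma is kept positive by
    optimising log(sigma). Raises instead of silently falling back when
    the data are degenerate or the optimiser fails.
    """
    v = np.asarray(list(values), dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 30:
        raise ValidationError(
            f"need >= 30 finite values for a histogram fit, got {v.size}"
        )
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        raise DegenerateDistributionError("all values identical; no spread to fit")
    if bin_width <= 0:
        raise ConfigError("bin_width must be positive")

    lo, hi = float(v.min()), float(v.max())
    # first bin centred on the observed minimum, so values on a regular
    # grid land at bin centres and symmetric data give a symmetric histogram
    n_bins = max(int(math.ceil((hi - lo) / bin_width)), 1) + 1
    edges = (lo - bin_width / 2.0) + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(v, bins=edges)
    centers = edges[:-1] + bin_width / 2.0
    if np.count_nonzero(counts) < 4:
        raise DegenerateDistributionError(
            f"only {np.count_nonzero(counts)} populated bins at width "
            f"{bin_width}; reduce bin_width"
        )

    p0 = (float(v.mean()), math.log(sd), float(counts.max()))
    try:
        popt, _ = optimize.curve_fit(
            _gauss, centers, counts.astype(float), p0=p0,
            xtol=1e-8, ftol=1e-8, maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"Gaussian histogram fit did not converge: {exc}", p0=p0,
            n_values=int(v.size),
        ) from exc
    mu, log_sigma, amplitude = (float(x) for x in popt)
    resid = _gauss(centers, *popt) - counts
    rmse = float(np.sqrt(np.mean(resid**2)))
    return NormalFitResult(
        mu=mu, sigma=math.exp(log_sigma), amplitude=abs(amplitude),
        rmse=rmse, n_bins=n_bins, bin_width=bin_width,
    )


def critical_z(alpha: float) -> float:
    """Two-tailed standard-normal critical value (1.959964 at alpha 0.05)."""
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must be in (0, 1), got {alpha}")
    return float(stats.norm.ppf(1 - alpha / 2))


def classify_value(
    log2_rpk: float, fit: NormalFitResult, alpha: float = 0.05
) -> tuple[float, Call]:
    """z-score a log2 RpK value against the fitted Gaussian and classify.

    reduced if z < -z_crit, increased if z > +z_crit, else neutral.
    """
    if fit.sigma <= 0:
        raise ValidationError("fit sigma must be positive")
    z = (log2_rpk - fit.mu) / fit.sigma
    zc = critical_z(alpha)
    if z < -zc:
        return z, Call.REDUCED
    if z > zc:
        return z, Call.INCREASED
    return z, Call.NEUTRAL


def classify_gene(
    gene_id: str,
    log2_rpk: float,
    fit: NormalFitResult,
    alpha: float = 0.05,
    timepoint: float = float("nan"),
    replicate: int = 0,
) -> FitnessCall:
    z, call = classify_value(log2_rpk, fit, alpha)
    return FitnessCall(gene_id, timepoint, replicate, z, call)


def consensus_call(call_rep1: FitnessCall, call_rep2: FitnessCall) -> Call:
    """Consensus across the two biological replicates: a non-neutral call
    stands only when both replicates make the same call."""
    if call_rep1.gene_id != call_rep2.gene_id:
        raise ValidationError(
            f"gene mismatch: {call_rep1.gene_id} vs {call_rep2.gene_id}"
        )
    t1, t2 = call_rep1.timepoint, call_rep2.timepoint
    if t1 != t2 and not (math.isnan(t1) and math.isnan(t2)):
        raise ValidationError(f"timepoint mismatch: {t1} vs {t2}")
    if call_rep1.call == call_rep2.call:
        return call_rep1.call
    return Call.NEUTRAL


def earliest_nonneutral(
    calls: Sequence[tuple[float, Call]],
) -> tuple[Call, float] | None:
    """First (by timepoint) non-neutral consensus call, or None if all
    neutral. ``calls`` is a sequence of (timepoint, call) pairs."""
    if len(calls) == 0:
        raise ValidationError("empty call sequence")
    tps = [t for t, _ in calls]
    if sorted(tps) != tps or len(set(tps)) != len(tps):
        raise ValidationError("timepoints must be strictly increasing")
    for t, call in calls:
        if call != Call.NEUTRAL:
            return call, t
    return None


def build_longevity_set(
    earliest: pd.DataFrame,
    exclusion_lists: Sequence[Iterable[str]] = (),
    reduced_window: Iterable[float] = (3.0, 7.0, 14.0),
) -> pd.DataFrame:
    """Flag genes belonging to the longevity set.

    ``earliest`` must have columns ``gene_id``, ``earliest_call``,
    ``earliest_timepoint`` (call/timepoint may be NA for all-neutral genes).
    A gene is in the set iff its earliest consensus is *reduced*, at a
    timepoint inside ``reduced_window``, and it is on no exclusion list.
    """
    excluded: set[str] = set()
    for lst in exclusion_lists:
        excluded.update(lst)
    window = {float(t) for t in reduced_window}
    out = earliest.copy()
    out["excluded"] = out["gene_id"].isin(excluded)
    out["in_longevity_set"] = (
        (out["earliest_call"] == Call.REDUCED.value)
        & out["earliest_timepoint"].isin(window)
        & ~out["excluded"]
    )
    return out


# ---------------------------------------------------------------------------
# Vectorised pipeline over long-format sample tables
# ---------------------------------------------------------------------------


@dataclass
class FitnessResults:
    """Everything one screen run produces.

    sample_tables : per-sample gene table (gene_id, central_total, rpk,
        log2_rpk, zero_adjusted, z_score, call)
    fits : per-sample NormalFitResult
    timepoint_calls : per-timepoint consensus table
    earliest : per-gene earliest non-neutral consensus
    longevity : earliest plus exclusion and membership flags
    """

    sample_tables: dict[str, pd.DataFrame]
    fits: dict[str, NormalFitResult]
    timepoint_calls: dict[float, pd.DataFrame]
    earliest: pd.DataFrame
    longevity: pd.DataFrame
    config: PipelineConfig

    @property
    def longevity_genes(self) -> list[str]:
        mask = self.longevity["in_longevity_set"]
        return sorted(self.longevity.loc[mask, "gene_id"])

    def increased_genes(
        self, window: Iterable[float] = (3.0, 7.0, 14.0, 30.0)
    ) -> list[str]:
        """Genes whose earliest non-neutral consensus is *increased* within
        ``window`` (the full post-arrest course by default)."""
        w = {float(t) for t in window}
        df = self.earliest
        mask = (df["earliest_call"] == Call.INCREASED.value) & df[
            "earliest_timepoint"
        ].isin(w)
        return sorted(df.loc[mask, "gene_id"])


def rpk_table(
    sample_counts: pd.DataFrame,
    genes: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Trim, total and length-normalise one sample's site counts.

    ``sample_counts`` has columns gene_id, position_bp, count for a single
    sample; ``genes`` maps gene_id to length_bp. Every gene present in the
    sample's table appears in the output, even when all of its sites are
    trimmed away (central total 0, pseudocounted log2 RpK).
    """
    merged = sample_counts.merge(
        genes[["gene_id", "length_bp"]], on="gene_id", how="left", validate="m:1"
    )
    if merged["length_bp"].isna().any():
        missing = sorted(merged.loc[merged["length_bp"].isna(), "gene_id"].unique())
        raise ValidationError(f"genes missing from annotation: {missing[:10]}")
    bad = (merged["position_bp"] < 1) | (merged["position_bp"] > merged["length_bp"])
    if bad.any():
        rows = merged.loc[bad, ["gene_id", "position_bp"]].head(10)
        raise ValidationError(f"insertion positions outside gene bounds:\n{rows}")

    frac = merged["position_bp"] / merged["length_bp"]
    central = merged[(frac > config.head_frac) & (frac <= 1 - config.tail_frac)]
    totals = central.groupby("gene_id")["count"].sum()

    present = genes.set_index("gene_id").loc[
        sorted(sample_counts["gene_id"].unique()), ["length_bp"]
    ]
    out = present.assign(central_total=totals).fillna({"central_total": 0})
    kb = out["length_bp"] / 1000.0
    out["rpk"] = out["central_total"] / kb
    out["zero_adjusted"] = out["central_total"] == 0
    adjusted = out["central_total"].where(
        ~out["zero_adjusted"], config.pseudocount_reads
    )
    out["log2_rpk"] = np.log2(adjusted / kb)
    return out.reset_index()


def run_fitness_pipeline(
    counts: pd.DataFrame,
    manifest: pd.DataFrame,
    genes: pd.DataFrame,
    exclusion_lists: Sequence[Iterable[str]] = (),
    config: PipelineConfig = PipelineConfig(),
) -> FitnessResults:
    """Full screen analysis from long-format site counts to longevity set.

    Parameters
    ----------
    counts : DataFrame with columns gene_id, position_bp, count, sample_id.
    manifest : DataFrame with columns sample_id, timepoint_days, replicate;
        exactly two replicates per timepoint are required for consensus.
    genes : DataFrame with columns gene_id, length_bp (category, product
        optional).
    exclusion_lists : gene-id collections removed from the final set only;
        the per-sample Gaussian is fitted to all genes present.
    """
    required = {"gene_id", "position_bp", "count", "sample_id"}
    if not required.issubset(counts.columns):
        raise ValidationError(
            f"counts table missing columns: {sorted(required - set(counts.columns))}"
        )
    manifest = manifest.copy()
    manifest[TIMEPOINT_COLUMN] = manifest[TIMEPOINT_COLUMN].astype(float)
    by_tp = manifest.groupby(TIMEPOINT_COLUMN)["replicate"].nunique()
    if (by_tp != 2).any():
        raise ValidationError(
            "consensus calling needs exactly two replicates per timepoint; "
            f"offending timepoints: {sorted(by_tp[by_tp != 2].index)}"
        )
    unknown = set(counts["sample_id"].unique()) - set(manifest["sample_id"])
    if unknown:
        raise ValidationError(f"sample_ids not in manifest: {sorted(unknown)[:10]}")

    sample_tables: dict[str, pd.DataFrame] = {}
    fits: dict[str, NormalFitResult] = {}
    zc = critical_z(config.alpha)
    for sample_id, grp in counts.groupby("sample_id"):
        table = rpk_table(grp, genes, config)
        fit = fit_normal_to_histogram(table["log2_rpk"], config.bin_width)
        table["z_score"] = (table["log2_rpk"] - fit.mu) / fit.sigma
        table["call"] = np.select(
            [table["z_score"] < -zc, table["z_score"] > zc],
            [Call.REDUCED.value, Call.INCREASED.value],
            default=Call.NEUTRAL.value,
        )
        sample_tables[sample_id] = table
        fits[sample_id] = fit

    timepoint_calls: dict[float, pd.DataFrame] = {}
    all_genes = sorted(genes["gene_id"])
    for tp, tp_manifest in manifest.groupby(TIMEPOINT_COLUMN):
        reps = tp_manifest.sort_values("replicate")
        merged = pd.DataFrame({"gene_id": all_genes})
        for i, (_, row) in enumerate(reps.iterrows(), start=1):
            st = sample_tables.get(row["sample_id"])
            cols = (
                st[["gene_id", "z_score", "call"]]
                if st is not None
                else pd.DataFrame(columns=["gene_id", "z_score", "call"])
            )
            merged = merged.merge(
                cols.rename(columns={"z_score": f"z_rep{i}", "call": f"call_rep{i}"}),
                on="gene_id", how="left",
            )
        for i in (1, 2):
            # absent from a replicate's table -> neutral (conservative)
            merged[f"call_rep{i}"] = merged[f"call_rep{i}"].fillna(Call.NEUTRAL.value)
        agree = merged["call_rep1"] == merged["call_rep2"]
        merged["consensus"] = merged["call_rep1"].where(agree, Call.NEUTRAL.value)
        timepoint_calls[float(tp)] = merged

    ordered_tps = sorted(timepoint_calls)
    consensus_wide = pd.DataFrame({"gene_id": all_genes})
    for tp in ordered_tps:
        consensus_wide[tp] = timepoint_calls[tp].set_index("gene_id").loc[
            all_genes, "consensus"
        ].to_numpy()
    calls_arr = consensus_wide[ordered_tps].to_numpy()
    nonneutral = calls_arr != Call.NEUTRAL.value
    first_idx = np.where(
        nonneutral.any(axis=1), nonneutral.argmax(axis=1), -1
    )
    earliest = pd.DataFrame(
        {
            "gene_id": all_genes,
            "earliest_call": [
                calls_arr[i, j] if j >= 0 else pd.NA
                for i, j in enumerate(first_idx)
            ],
            "earliest_timepoint": [
                ordered_tps[j] if j >= 0 else np.nan for j in first_idx
            ],
        }
    )
    longevity = build_longevity_set(
        earliest, exclusion_lists, config.reduced_window
    )
    if "category" in genes.columns:
        longevity = longevity.merge(
            genes[["gene_id", "category"]], on="gene_id", how="left"
        )
    return FitnessResults(
        sample_tables=sample_tables,
        fits=fits,
        timepoint_calls=timepoint_calls,
        earliest=earliest,
        longevity=longevity,
        config=config,
    )
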
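"""Synthetic data with the population structure the screen analysis assumes.

A saturating transposon mutant pool enters growth arrest at t0. Each gene's
mutants follow one of three phenotypes afterwards:

* neutral — viable abundance constant (light keeps arrested cells alive);
* longevity_defective — exponential die-off at ``death_rate`` per day;
* positively_selected — exponential growth at ``growth_rate`` per day
  (the takeover phenotype: a mutant that resumes growth and dominates
  late-timepoint reads).

Sequencing goes through an outgrowth step, so reads are drawn from *viable*
abundance only: per sample, site counts are multinomial at the requested
depth over viable-abundance proportions. A per-replicate log-normal
perturbation of abundances (default sd 1.0 log2 units) emulates independent
biological-replicate culture and outgrowth variation; it is what gives real
libraries their ~1-2 log2-unit spread in log2 RpK.

Defaults mirror the screen's study conditions: 4,836 genes, ~36 insertion
sites per gene (~175,000 mutants), 117/4836 of genes longevity-defective,
death rate 0.2/day (>=16-fold depletion by day 14), one positively selected
gene at 0.3/day, sequencing depth 2x10^6 per sample, two replicates sampled
at 0, 3, 7, 14 and 30 days post-arrest.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

DEFAULT_TIMEPOINTS: tuple[float, ...] = (0.0, 3.0, 7.0, 14.0, 30.0)
DEFAULT_N_GENES = 4836
DEFAULT_SITES_PER_GENE = 36
DEFAULT_FRAC_DEFECTIVE = 117 / 4836
DEFAULT_DEATH_RATE = 0.2  # per day; >=16-fold depletion by day 14
DEFAULT_GROWTH_RATE = 0.3  # per day; takeover phenotype
DEFAULT_DEPTH = 2_000_000
DEFAULT_REPLICATE_SIGMA = 1.0  # log2 units

#: Functional categories used for synthetic annotation, with genome weights
#: loosely shaped like a bacterial genome annotation (transporters ~6%).
DEFAULT_CATEGORIES: tuple[tuple[str, float], ...] = (
    ("hypothetical", 0.35),
    ("biosynthesis and metabolism", 0.25),
    ("transporters", 0.06),
    ("translation", 0.08),
    ("DNA replication, recombination and repair", 0.06),
    ("transcription and regulation", 0.10),
    ("other", 0.10),
)


class Phenotype(str, enum.Enum):
    NEUTRAL = "neutral"
    LONGEVITY_DEFECTIVE = "longevity_defective"
    POSITIVELY_SELECTED = "positively_selected"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class SyntheticPool:
    """A transposon mutant pool at the moment of growth arrest.

    genes : per-gene table (gene_id, length_bp, category, phenotype, rate)
        where rate is the death rate for defective genes, the growth rate
        for selected genes and 0 for neutral ones.
    sites : per-mutant table (gene_id, position_bp, abundance0); a gene's
        initial abundance is proportional to its length (constant insertion
        density in a saturating library), split equally over its sites, so
        expected RpK is uniform across genes under the null.
    """

    genes: pd.DataFrame
    sites: pd.DataFrame
    seed: int

    @property
    def n_mutants(self) -> int:
        return len(self.sites)


@dataclass
class AbundanceTrajectory:
    """Viable abundance of every mutant at each sampled timepoint."""

    pool: SyntheticPool
    timepoints: tuple[float, ...]
    abundance: np.ndarray  # mutants x timepoints

    def gene_share(self) -> pd.DataFrame:
        """Expected read share per gene per timepoint (viable-abundance
        proportions summed over each gene's sites)."""
        totals = self.abundance.sum(axis=0)
        df = pd.DataFrame(
            self.abundance / totals, columns=list(self.timepoints)
        )
        df["gene_id"] = self.pool.sites["gene_id"].to_numpy()
        return df.groupby("gene_id").sum()


def _sample_lengths(spec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Gene lengths in bp from a distribution spec.

    Accepts a callable ``f(rng, n)``, ``("constant", L)``,
    ``("uniform", lo, hi)`` or ``("lognormal", median, sigma_ln)``.
    Default: log-normal around a 900 bp median, floored at 150 bp.
    """
    if spec is None:
        spec = ("lognormal", 900.0, 0.4)
    if callable(spec):
        lengths = np.asarray(spec(rng, n))
    else:
        kind = spec[0]
        if kind == "constant":
            lengths = np.full(n, spec[1])
        elif kind == "uniform":
            lengths = rng.integers(int(spec[1]), int(spec[2]) + 1, size=n)
        elif kind == "lognormal":
            lengths = spec[1] * rng.lognormal(0.0, spec[2], size=n)
        else:
            raise ConfigError(f"unknown length sampler spec: {spec!r}")
    lengths = np.maximum(np.rint(lengths).astype(int), 150)
    return lengths


def build_pool(
    n_genes: int = DEFAULT_N_GENES,
    sites_per_gene: int = DEFAULT_SITES_PER_GENE,
    frac_defective: float = DEFAULT_FRAC_DEFECTIVE,
    frac_selected: float = 0.0,
    death_rate: float = DEFAULT_DEATH_RATE,
    growth_rate: float = DEFAULT_GROWTH_RATE,
    gene_length_sampler=None,
    seed: int = 0,
    categories: Sequence[tuple[str, float]] = DEFAULT_CATEGORIES,
) -> SyntheticPool:
    """Assemble a seeded synthetic mutant pool.

    ``sites_per_gene`` is the pool-wide mean; each gene's actual site count
    scales with its length (constant insertion density), with a minimum of
    one site. Phenotypes are assigned by independent per-gene draws with
    probabilities (frac_defective, frac_selected).
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    if sites_per_gene < 1:
        raise ConfigError("sites_per_gene must be >= 1")
    if frac_defective < 0 or frac_selected < 0 or frac_defective + frac_selected > 1:
        raise ConfigError(
            f"invalid phenotype fractions: {frac_defective}, {frac_selected}"
        )
    if death_rate < 0 or growth_rate < 0:
        raise ConfigError("rates must be non-negative")

    rng = np.random.default_rng(seed)
    width = len(str(max(n_genes, 1)))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(1, n_genes + 1)])
    lengths = _sample_lengths(gene_length_sampler, rng, n_genes)

    names = [c for c, _ in categories]
    weights = np.array([w for _, w in categories], dtype=float)
    cats = rng.choice(names, size=n_genes, p=weights / weights.sum())

    draws = rng.random(n_genes)
    phen = np.where(
        draws < frac_defective,
        Phenotype.LONGEVITY_DEFECTIVE.value,
        np.where(
            draws < frac_defective + frac_selected,
            Phenotype.POSITIVELY_SELECTED.value,
            Phenotype.NEUTRAL.value,
        ),
    )
    rate = np.where(
        phen == Phenotype.LONGEVITY_DEFECTIVE.value,
        death_rate,
        np.where(phen == Phenotype.POSITIVELY_SELECTED.value, growth_rate, 0.0),
    )
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "length_bp": lengths,
            "category": cats,
            "phenotype": phen,
            "rate": rate,
        }
    )

    mean_len = lengths.mean()
    n_sites = np.maximum(
        np.rint(sites_per_gene * lengths / mean_len).astype(int), 1
    )
    site_gene = np.repeat(np.arange(n_genes), n_sites)
    positions = np.concatenate(
        [
            rng.choice(lengths[i], size=n_sites[i], replace=False) + 1
            if n_sites[i] <= lengths[i]
            else rng.integers(1, lengths[i] + 1, size=n_sites[i])
            for i in range(n_genes)
        ]
    )
    abundance0 = (lengths / n_sites)[site_gene]
    sites = pd.DataFrame(
        {
            "gene_id": gene_ids[site_gene],
            "position_bp": positions,
            "abundance0": abundance0,
        }
    )
    return SyntheticPool(genes=genes, sites=sites, seed=seed)


def plant_phenotype(
    pool: SyntheticPool, gene_id: str, kind: Phenotype, rate: float
) -> None:
    """Force one gene's phenotype in place (for planting exact truth)."""
    mask = pool.genes["gene_id"] == gene_id
    if not mask.any():
        raise ValidationError(f"unknown gene_id {gene_id}")
    pool.genes.loc[mask, "phenotype"] = kind.value
    pool.genes.loc[mask, "rate"] = rate


def simulate_abundances(
    pool: SyntheticPool, timepoints: Iterable[float] = DEFAULT_TIMEPOINTS
) -> AbundanceTrajectory:
    """Deterministic viable-abundance trajectories post-arrest.

    neutral: a(t) = a(0); defective: a(0) exp(-death_rate t);
    selected: a(0) exp(+growth_rate t).
    """
    tps = tuple(float(t) for t in timepoints)
    if any(t < 0 for t in tps):
        raise ValidationError("timepoints must be non-negative")
    if 0.0 not in tps:
        raise ValidationError("timepoints must include 0")

    gene_rate = pool.genes.set_index("gene_id")
    site_phen = gene_rate.loc[pool.sites["gene_id"], "phenotype"].to_numpy()
    site_rate = gene_rate.loc[pool.sites["gene_id"], "rate"].to_numpy()
    signed = np.where(
        site_phen == Phenotype.LONGEVITY_DEFECTIVE.value,
        -site_rate,
        np.where(site_phen == Phenotype.POSITIVELY_SELECTED.value, site_rate, 0.0),
    )
    t = np.asarray(tps)
    a0 = pool.sites["abundance0"].to_numpy()
    abundance = a0[:, None] * np.exp(signed[:, None] * t[None, :])
    return AbundanceTrajectory(pool=pool, timepoints=tps, abundance=abundance)


def sample_reads(
    trajectory: AbundanceTrajectory,
    depth: int = DEFAULT_DEPTH,
    n_replicates: int = 2,
    seed: int = 0,
    replicate_sigma: float = DEFAULT_REPLICATE_SIGMA,
    drop_zero_sites: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw sequencing reads from viable abundances.

    Per (timepoint, replicate): each *gene's* abundance is perturbed by an
    independent log-normal factor ``2**Normal(0, replicate_sigma)`` shared
    by all of its insertion sites (biological replicate variation in
    gene-level mutant abundance; set 0 for pure multinomial sampling), then
    ``depth`` reads are drawn multinomially over the perturbed proportions.
    Gene-level (not site-level) perturbation keeps the null log2 RpK spread
    homogeneous across genes regardless of their site count. Returns a long-format counts table (gene_id, position_bp,
    count, sample_id) and a sample manifest (sample_id, timepoint_days,
    replicate).
    """
    if depth < 1:
        raise ConfigError("depth must be >= 1")
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    if replicate_sigma < 0:
        raise ConfigError("replicate_sigma must be >= 0")

    sites = trajectory.pool.sites
    gene_codes, _ = pd.factorize(sites["gene_id"])
    n_genes = int(gene_codes.max()) + 1
    frames = []
    manifest_rows = []
    for j, tp in enumerate(trajectory.timepoints):
        viable = trajectory.abundance[:, j]
        if viable.sum() <= 0:
            raise ValidationError(f"all-zero viable abundance at day {tp}")
        for rep in range(1, n_replicates + 1):
            rng = np.random.default_rng([seed, j, rep])
            if replicate_sigma > 0:
                gene_factor = np.exp2(
                    rng.normal(0.0, replicate_sigma, size=n_genes)
                )
                perturbed = viable * gene_factor[gene_codes]
            else:
                perturbed = viable
            p = perturbed / perturbed.sum()
            counts = rng.multinomial(depth, p)
            sample_id = f"t{tp:g}d_r{rep}"
            df = pd.DataFrame(
                {
                    "gene_id": sites["gene_id"],
                    "position_bp": sites["position_bp"],
                    "count": counts,
                    "sample_id": sample_id,
                }
            )
            if drop_zero_sites:
                df = df[df["count"] > 0]
            frames.append(df)
            manifest_rows.append((sample_id, tp, rep))
    counts_df = pd.concat(frames, ignore_index=True)
    manifest = pd.DataFrame(
        manifest_rows, columns=["sample_id", "timepoint_days", "replicate"]
    )
    return counts_df, manifest


# ---------------------------------------------------------------------------
# RNA-seq counterpart
# ---------------------------------------------------------------------------

RNASEQ_TIMEPOINTS_H: tuple[float, ...] = (12.0, 50.0, 90.0, 180.0)
BASELINE_LABEL = "log_phase"


def build_expression_truth(
    n_genes: int = DEFAULT_N_GENES,
    n_down: int = 257,
    n_up: int = 120,
    fold_range: tuple[float, float] = (12.0, 100.0),
    timepoints_h: Sequence[float] = RNASEQ_TIMEPOINTS_H,
    seed: int = 0,
) -> pd.DataFrame:
    """True fold-versus-baseline table emulating a starvation time course.

    ``n_down`` genes are repressed and ``n_up`` induced, with final folds
    drawn log-uniformly from ``fold_range`` (all beyond the 10-fold filter);
    the response is fully established by the first sampled timepoint,
    matching the rapid transcriptional shutdown carbon-starved cells show.
    Remaining genes hold fold 1. Columns: gene_id then one column per
    timepoint label (e.g. '180h').
    """
    if n_down + n_up > n_genes:
        raise ConfigError("n_down + n_up exceeds n_genes")
    rng = np.random.default_rng(seed)
    width = len(str(max(n_genes, 1)))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]
    folds = np.ones(n_genes)
    idx = rng.permutation(n_genes)
    lo, hi = np.log(fold_range[0]), np.log(fold_range[1])
    folds[idx[:n_down]] = 1.0 / np.exp(rng.uniform(lo, hi, size=n_down))
    folds[idx[n_down : n_down + n_up]] = np.exp(rng.uniform(lo, hi, size=n_up))
    truth = pd.DataFrame({"gene_id": gene_ids})
    for tp in timepoints_h:
        truth[f"{tp:g}h"] = folds
    return truth


def generate_rnaseq_counts(
    truth: pd.DataFrame,
    baseline_mean_spec=("lognormal", 600.0, 1.0),
    dispersion: float = 0.05,
    library_sizes: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Negative-binomial count matrix for a fold-truth table.

    Counts for gene i in sample s are NB with mean
    ``baseline_i * fold_is * libsize_s / median_libsize`` and variance
    ``m + dispersion * m**2``. Returns (counts genes x samples, truth,
    gene_lengths in bp). The baseline sample is labelled 'log_phase'.
    """
    if dispersion <= 0:
        raise ConfigError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    n = len(truth)
    baseline = _sample_baseline(baseline_mean_spec, rng, n)
    tp_labels = [c for c in truth.columns if c != "gene_id"]
    samples = [BASELINE_LABEL] + tp_labels
    if library_sizes is None:
        library_sizes = {s: 1.0 for s in samples}
    missing = set(samples) - set(library_sizes)
    if missing:
        raise ConfigError(f"library_sizes missing samples: {sorted(missing)}")
    ref = float(np.median(list(library_sizes.values())))

    counts = pd.DataFrame(index=truth["gene_id"], columns=samples, dtype=float)
    r = 1.0 / dispersion  # NB size parameter
    for s in samples:
        fold = np.ones(n) if s == BASELINE_LABEL else truth[s].to_numpy()
        mean = baseline * fold * (library_sizes[s] / ref)
        p = r / (r + mean)
        counts[s] = rng.negative_binomial(r, p)
    counts = counts.astype(int)
    counts.index.name = "gene_id"
    lengths = pd.Series(
        np.maximum(np.rint(900 * rng.lognormal(0, 0.4, n)).astype(int), 150),
        index=truth["gene_id"], name="length_bp",
    )
    return counts, truth, lengths


def _sample_baseline(spec, rng: np.random.Generator, n: int) -> np.ndarray:
    if callable(spec):
        return np.asarray(spec(rng, n), dtype=float)
    kind = spec[0]
    if kind == "constant":
        return np.full(n, float(spec[1]))
    if kind == "lognormal":
        return spec[1] * rng.lognormal(0.0, spec[2], size=n)
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size=n)
    raise ConfigError(f"unknown baseline spec: {spec!r}")


def simulate_viability(
    death_rate_light: float = 0.0,
    death_rate_dark: float = float(np.log(1e4) / 10.0),
    duration: float = 35.0,
    n_points: int = 36,
) -> pd.DataFrame:
    """Exponential survival curves for light and dark incubation.

    ``survival(t) = exp(-rate * t)``; the default dark rate ln(1e4)/10 per
    day reproduces a 4-order-of-magnitude viability drop by day 10.
    """
    if death_rate_light < 0 or death_rate_dark < 0:
        raise ConfigError("death rates must be >= 0")
    t = np.linspace(0.0, duration, n_points)
    return pd.DataFrame(
        {
            "day": t,
            "survival_light": np.exp(-death_rate_light * t),
            "survival_dark": np.exp(-death_rate_dark * t),
        }
    )
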
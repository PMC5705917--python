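"""Pipeline configuration.

All analysis-level tunables live here so a run can be reproduced from its
echoed parameters alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import ConfigError

#: Timepoints (days post-arrest) eligible for the reduced-fitness longevity
#: window. The final sampling day is excluded because a positively selected
#: takeover mutant dominates late reads and depresses every other gene.
DEFAULT_REDUCED_WINDOW: tuple[float, ...] = (3.0, 7.0, 14.0)


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the insertion-fitness pipeline.

    Attributes
    ----------
    alpha : float
        Two-tailed significance level for the per-sample classification
        band around the fitted mean (default 0.05, i.e. a 95% band).
    head_frac, tail_frac : float
        Fractions of each gene's length trimmed at the 5' and 3' ends
        before read totalling (defaults 0.05 and 0.10: the central
        5-90% of the gene is kept).
    bin_width : float
        Histogram bin width in log2 RpK units for the Gaussian fit.
    pseudocount_reads : float
        Reads added to a gene's central total only when that total is
        zero, so log2 RpK is finite and extreme depletion still
        classifies as reduced.
    reduced_window : tuple of float
        Timepoints (days) at which a reduced consensus admits a gene to
        the longevity set.
    """

    alpha: float = 0.05
    head_frac: float = 0.05
    tail_frac: float = 0.10
    bin_width: float = 0.25
    pseudocount_reads: float = 0.5
    reduced_window: tuple[float, ...] = field(default=DEFAULT_REDUCED_WINDOW)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.head_frac < 0 or self.tail_frac < 0:
            raise ConfigError("trim fractions must be non-negative")
        if self.head_frac + self.tail_frac >= 1:
            raise ConfigError(
                "head_frac + tail_frac must be < 1 "
                f"(got {self.head_frac} + {self.tail_frac})"
            )
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        if self.pseudocount_reads <= 0:
            raise ConfigError("pseudocount_reads must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reduced_window"] = list(self.reduced_window)
        return d
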
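"""Genome-wide copy-number estimation from a BAC-library PCR screen.

Two estimators are provided.  The naive estimator assumes one element per
positive clone: density = positives / (clones x mean clone size); copies =
genome size x density.  The Poisson estimator corrects for clones carrying
more than one element under random insertion: with positive fraction p, the
per-clone mean is lambda = -ln(1 - p).  Exact Clopper-Pearson intervals on
p propagate through either estimator (both are monotone in p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


class ScreenSaturationError(ValueError):
    """Every clone positive: the Poisson mean is unbounded."""


@dataclass
class BACScreenResult:
    n_clones: int
    n_positive: int
    mean_clone_size: float  # Mbp
    genome_size: float      # Mbp, diploid

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_clones:
            raise ValueError("need 0 <= n_positive <= n_clones")
        if self.mean_clone_size <= 0 or self.genome_size <= 0:
            raise ValueError("clone and genome sizes must be positive")

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_clones


@dataclass
class CopyNumberEstimate:
    method: str              # "naive" | "poisson"
    density: float           # elements / Mbp
    spacing: float           # kb / element (inf when density is 0)
    copies: float
    lam: float | None = None  # Poisson mean elements per clone
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def spacing_kb_rounded(self) -> int:
        """Spacing to the nearest kb, as reported in text summaries."""
        if math.isinf(self.spacing):
            raise ValueError("spacing is infinite (no positives)")
        return round(self.spacing)

    @property
    def copies_3sf(self) -> float:
        """Copy number to 3 significant figures, as reported in summaries."""
        if self.copies == 0:
            return 0.0
        exp = math.floor(math.log10(abs(self.copies)))
        q = 10 ** (exp - 2)
        return round(self.copies / q) * q


def estimate_naive(screen: BACScreenResult) -> CopyNumberEstimate:
    """One element assumed per positive clone."""
    surveyed = screen.n_clones * screen.mean_clone_size
    density = screen.n_positive / surveyed
    spacing = 1000.0 / density if density > 0 else math.inf
    return CopyNumberEstimate("naive", density, spacing,
                              screen.genome_size * density)


def estimate_poisson(screen: BACScreenResult) -> CopyNumberEstimate:
    """Poisson correction: lambda = -ln(1 - positive fraction)."""
    p = screen.positive_fraction
    if p >= 1.0:
        raise ScreenSaturationError(
            "all clones positive: lambda = -ln(1-p) diverges")
    lam = -math.log1p(-p)
    density = lam / screen.mean_clone_size
    spacing = 1000.0 / density if density > 0 else math.inf
    return CopyNumberEstimate("poisson", density, spacing,
                              screen.genome_size * density, lam=lam)


def _clopper_pearson(k: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def copies_confidence_interval(screen: BACScreenResult, method: str = "naive",
                               level: float = 0.95) -> tuple[float, float]:
    """Exact binomial interval on the positive fraction, pushed through the
    (monotone) chosen estimator onto the copy-number scale."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    p_low, p_high = _clopper_pearson(screen.n_positive, screen.n_clones, level)

    def copies_of(p: float) -> float:
        if method == "naive":
            density = p / screen.mean_clone_size
        elif method == "poisson":
            if p >= 1.0:
                return math.inf
            density = -math.log1p(-p) / screen.mean_clone_size
        else:
            raise ValueError(f"unknown method {method!r}")
        return screen.genome_size * density

    return copies_of(p_low), copies_of(p_high)


def estimate(screen: BACScreenResult, method: str = "naive",
             ci_level: float | None = None) -> CopyNumberEstimate:
    """Convenience wrapper: point estimate with an optional attached CI."""
    est = estimate_naive(screen) if method == "naive" else estimate_poisson(screen)
    if ci_level is not None:
        est.ci_low, est.ci_high = copies_confidence_interval(screen, method, ci_level)
    return est
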
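"""Survival-adjusted frequency analysis and rank-based redistribution curves.

Relative-frequency ADDs describe only the *shape* of a group's caliber
distribution; after injury the tract also loses axons.  Adjusted frequencies
scale each bin's mean relative frequency by the group's mean axon survival,
so the area under the adjusted curve equals total survival and groups become
comparable on an absolute (per-baseline-axon) footing.  Dividing an injured
group's adjusted curve by the sham curve bin-by-bin gives the per-bin
surviving fraction — the quantity whose monotone decline above ~0.7 μm
reveals size-dependent vulnerability.

Rank (percentile) curves replot the adjusted frequency against each caliber's
percentile rank within its own fitted lognormal, separating redistribution of
ranks from overall diameter shrinkage: two groups whose shapes differ only by
a scale factor have identical rank curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distribution import (
    ADDHistogram,
    LognormalFit,
    bin_probability,
    lognormal_cdf,
    lognormal_quantile,
)

__all__ = [
    "SurvivalEstimate",
    "AdjustedADD",
    "RankCurve",
    "estimate_survival",
    "pad_histograms",
    "adjust_frequencies",
    "per_bin_loss",
    "population_share",
    "rank_frequency_curve",
]

SHAM_FREQ_FLOOR = 1e-4  # sham bins below this mass give unstable ratios


@dataclass(frozen=True)
class SurvivalEstimate:
    """Group axon survival relative to the sham mean count."""

    mean_survival: float
    per_animal: np.ndarray
    reference_mean_count: float

    def __post_init__(self) -> None:
        per = np.asarray(self.per_animal, dtype=float)
        object.__setattr__(self, "per_animal", per)
        if np.any(per <= 0):
            raise ValueError("per-animal survival fractions must be positive")
        if abs(self.mean_survival - per.mean()) > 1e-9:
            raise ValueError("mean_survival must equal the per-animal average")


@dataclass(frozen=True)
class AdjustedADD:
    """Survival-scaled mean relative frequencies on the shared 0.1 μm grid."""

    bin_edges: np.ndarray
    adj_freq: np.ndarray
    sem: np.ndarray  # SEM of the *unadjusted* per-animal relative frequencies
    mean_survival: float
    group: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "adj_freq", np.asarray(self.adj_freq, dtype=float))
        object.__setattr__(self, "sem", np.asarray(self.sem, dtype=float))
        if abs(self.adj_freq.sum() - self.mean_survival) > 1e-9:
            raise ValueError("adjusted-frequency area must equal mean survival")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "adj_freq": self.adj_freq,
                "sem": self.sem,
            }
        )


@dataclass(frozen=True)
class RankCurve:
    """Adjusted frequency indexed by caliber percentile rank."""

    ranks: np.ndarray  # percentile grid
    diameters_um: np.ndarray
    freq_at_rank: np.ndarray
    peak_rank: float  # analytic: 100 * Phi(-sigma), the mode's percentile
    group: str = ""

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.freq_at_rank) < 0):
            raise ValueError("frequencies must be non-negative")
        if not 0 < self.peak_rank < 100:
            raise ValueError("peak rank must lie in (0, 100)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": self.ranks,
                "diameter_um": self.diameters_um,
                "freq": self.freq_at_rank,
            }
        )


# ---------------------------------------------------------------------------


def estimate_survival(group_counts, sham_counts) -> SurvivalEstimate:
    """Per-animal axon counts relative to the mean sham count."""
    g = np.asarray(group_counts, dtype=float).ravel()
    s = np.asarray(sham_counts, dtype=float).ravel()
    if g.size == 0 or s.size == 0:
        raise ValueError("count vectors must be non-empty")
    ref = float(s.mean())
    if ref <= 0:
        raise ValueError("sham mean count must be positive")
    per = g / ref
    return SurvivalEstimate(
        mean_survival=float(per.mean()), per_animal=per, reference_mean_count=ref
    )


def pad_histograms(histograms: list[ADDHistogram]) -> np.ndarray:
    """Stack per-animal rel_freq rows on the shared [0, max) 0.1 μm grid."""
    if not histograms:
        raise ValueError("no histograms given")
    width = histograms[0].bin_width
    for h in histograms:
        if abs(h.bin_width - width) > 1e-12 or abs(h.bin_edges[0]) > 1e-12:
            raise ValueError("histograms must share bin width and origin")
    n_bins = max(h.rel_freq.size for h in histograms)
    out = np.zeros((len(histograms), n_bins))
    for i, h in enumerate(histograms):
        out[i, : h.rel_freq.size] = h.rel_freq
    return out


def adjust_frequencies(
    group_histograms: list[ADDHistogram],
    survival: SurvivalEstimate | float,
    group: str = "",
) -> AdjustedADD:
    """Mean per-animal relative frequency per bin, scaled by mean survival.

    The SEM per bin is computed from the unadjusted per-animal relative
    frequencies; variability in axon survival itself is deliberately not
    propagated.
    """
    rel = pad_histograms(group_histograms)
    mean_survival = (
        survival if isinstance(survival, (int, float)) else survival.mean_survival
    )
    if not 0 < mean_survival <= 1 + 1e-12:
        raise ValueError("mean survival must lie in (0, 1]")
    n_animals = rel.shape[0]
    mean_rel = rel.mean(axis=0)
    sem = (
        rel.std(axis=0, ddof=1) / np.sqrt(n_animals)
        if n_animals > 1
        else np.zeros(rel.shape[1])
    )
    width = group_histograms[0].bin_width
    edges = np.arange(rel.shape[1] + 1, dtype=float) * width
    return AdjustedADD(
        bin_edges=edges,
        adj_freq=mean_rel * mean_survival,
        sem=sem,
        mean_survival=float(mean_survival),
        group=group,
    )


def per_bin_loss(
    adjusted_injured: AdjustedADD,
    sham: AdjustedADD,
    floor: float = SHAM_FREQ_FLOOR,
) -> pd.DataFrame:
    """Per-bin surviving fraction (injured / sham) and loss.

    Bins whose sham frequency falls below ``floor`` are excluded (flagged in
    the ``stable`` column of the returned frame) rather than producing
    unstable ratios.
    """
    n = min(adjusted_injured.adj_freq.size, sham.adj_freq.size)
    edges_a = adjusted_injured.bin_edges[: n + 1]
    edges_b = sham.bin_edges[: n + 1]
    if not np.allclose(edges_a, edges_b):
        raise ValueError("adjusted curves must share their bin grid")
    inj = adjusted_injured.adj_freq[:n]
    ref = sham.adj_freq[:n]
    stable = ref >= floor
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(stable, inj / np.where(stable, ref, 1.0), np.nan)
    out = pd.DataFrame(
        {
            "bin_lo": edges_a[:-1],
            "bin_hi": edges_a[1:],
            "bin_center": 0.5 * (edges_a[:-1] + edges_a[1:]),
            "surviving_fraction": frac,
            "loss": 1.0 - frac,
            "stable": stable,
        }
    )
    return out[out["stable"]].reset_index(drop=True)


def population_share(fit: LognormalFit, threshold: float = 0.7) -> tuple[float, float]:
    """(share above, share below) the threshold under the fitted ADD."""
    below = float(lognormal_cdf(fit, threshold))
    return 1.0 - below, below


def rank_frequency_curve(
    fit: LognormalFit,
    survival: float,
    ranks=None,
    bin_width: float = 0.1,
    mode: str = "bin",
    group: str = "",
) -> RankCurve:
    """Adjusted frequency at each caliber percentile rank.

    For rank q the diameter is the fitted q/100 quantile and the frequency is
    survival times the probability of the 0.1 μm bin containing it (matching
    the histogram presentation); ``mode='density'`` uses the density times the
    bin width instead of the bin mass.
    """
    if not 0 < survival <= 1 + 1e-12:
        raise ValueError("survival must lie in (0, 1]")
    if ranks is None:
        ranks = np.arange(1, 100)
    ranks = np.asarray(ranks, dtype=float)
    if np.any((ranks <= 0) | (ranks >= 100)):
        raise ValueError("ranks must lie strictly between 0 and 100")
    d_q = np.array([lognormal_quantile(fit, q / 100.0) for q in ranks])
    if mode == "bin":
        lo = np.floor(d_q / bin_width) * bin_width
        freq = np.array(
            [survival * bin_probability(fit, l, l + bin_width) for l in lo]
        )
    elif mode == "density":
        dens = stats.lognorm.pdf(d_q, s=fit.sigma, scale=np.exp(fit.mu))
        freq = survival * dens * bin_width
    else:
        raise ValueError("mode must be 'bin' or 'density'")
    peak = 100.0 * stats.norm.cdf(-fit.sigma)
    return RankCurve(
        ranks=ranks, diameters_um=d_q, freq_at_rank=freq, peak_rank=float(peak), group=group
    )
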
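"""Dye-dilution generation assignment, the proliferation index, and
apoptosis gating fractions.

A covalent proliferation dye halves at each division, so generation-i
cells peak at gen0_mean / 2**i. Events are assigned to the generation
whose log-intensity center is nearest; the boundary between adjacent
generations is the midpoint in log space, i.e. the geometric mean of the
two centers. The proliferation index

    PI = sum_i N_i / sum_i (N_i / 2**i)

is total cells over inferred founders (founder-equivalents), the average
number of divisions per founder lineage; PI = 1 iff no cell divided and
PI = 2**k when every cell sits in generation k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel import FlowEventTable
from .errors import AnalysisError

__all__ = [
    "GenerationDistribution",
    "PIResult",
    "ApoptosisGate",
    "assign_generations",
    "distribution_from_counts",
    "proliferation_index",
    "apoptosis_fractions",
]


@dataclass
class GenerationDistribution:
    """Event counts and percentages per division generation 0..i_max."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) == 0:
            raise AnalysisError("counts must be a non-empty 1-D array")
        if (self.counts < 0).any():
            raise AnalysisError("counts must be >= 0")

    @property
    def i_max(self) -> int:
        return len(self.counts) - 1

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def percentages(self) -> np.ndarray:
        """N_i: percentage of cells in each generation (sums to 100)."""
        if self.total == 0:
            raise AnalysisError("empty generation distribution")
        return 100.0 * self.counts / self.total


@dataclass(frozen=True)
class PIResult:
    pi: float
    founders_equivalent: float


@dataclass(frozen=True)
class ApoptosisGate:
    """Channel thresholds: annexin-positive above annexin_threshold,
    viability-dye-positive above viability_threshold."""

    annexin_threshold: float
    viability_threshold: float

    def __post_init__(self):
        if not (math.isfinite(self.annexin_threshold) and math.isfinite(self.viability_threshold)):
            raise AnalysisError("gate thresholds must be finite")


def generation_labels(events: FlowEventTable, gen0_mean: float, i_max: int) -> np.ndarray:
    """Per-event generation assignment by nearest log-scale peak.

    Generation-i center is log(gen0_mean) - i*log(2); boundaries sit at
    the arithmetic midpoints in log space (geometric means of adjacent
    centers). Events dimmer than the last boundary go to i_max, brighter
    than the first to generation 0.
    """
    if gen0_mean <= 0:
        raise AnalysisError("gen0_mean must be > 0")
    if i_max < 0:
        raise AnalysisError("i_max must be >= 0")
    dye = events.table["dye_intensity"].to_numpy(dtype=float)
    if (dye <= 0).any():
        raise AnalysisError("dye intensities must be strictly positive")
    log_dye = np.log(dye)
    centers = math.log(gen0_mean) - np.arange(i_max + 1) * math.log(2.0)
    boundaries = (centers[:-1] + centers[1:]) / 2.0  # descending
    # searchsorted needs ascending order; generation = count of boundaries above.
    return np.searchsorted(-boundaries, -log_dye, side="left")


def assign_generations(
    events: FlowEventTable, gen0_mean: float, i_max: int
) -> GenerationDistribution:
    """Bin events into generations 0..i_max (see :func:`generation_labels`)."""
    gen = generation_labels(events, gen0_mean, i_max)
    counts = np.bincount(gen, minlength=i_max + 1).astype(float)
    return GenerationDistribution(counts=counts)


def distribution_from_counts(counts) -> GenerationDistribution:
    return GenerationDistribution(counts=np.asarray(counts, dtype=float))


def proliferation_index(
    dist: GenerationDistribution, exclude_gen0: bool = False
) -> PIResult:
    """PI = sum N_i / sum (N_i / 2**i): total cells over founder-equivalents.

    Scale-invariant, so percentages and raw counts give the same PI.
    exclude_gen0 drops the undivided peak from both sums (an alternative
    convention, off by default).
    """
    n = dist.percentages  # validates non-empty / non-zero
    i = np.arange(len(n))
    if exclude_gen0:
        n = n[1:]
        i = i[1:]
        if n.sum() == 0:
            raise AnalysisError("no divided cells; PI undefined with exclude_gen0")
    founders = float((n / 2.0**i).sum())
    return PIResult(pi=float(n.sum() / founders), founders_equivalent=founders)


def apoptosis_fractions(events: FlowEventTable, gate: ApoptosisGate) -> dict[str, float]:
    """Gated class fractions: live (annexin-negative), early apoptotic
    (annexin+, viability-dye-), late apoptotic (annexin+, viability-dye+).

    The three classes partition the events, so fractions sum to 1.
    """
    if len(events) == 0:
        raise AnalysisError("empty event table")
    annexin = events.table["annexin"].to_numpy(dtype=float)
    viability = events.table["viability"].to_numpy(dtype=float)
    pos = annexin > gate.annexin_threshold
    dead = viability > gate.viability_threshold
    n = len(events)
    return {
        "live": float((~pos).sum() / n),
        "early_apoptotic": float((pos & ~dead).sum() / n),
        "late_apoptotic": float((pos & dead).sum() / n),
    }
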
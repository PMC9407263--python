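"""Interaction probabilities from normalized top scores.

A :class:`ProbabilityTable` is a step function from a comparison's top
normalized MI score to the percent chance that the two proteins truly
interact, calibrated on labeled (interacting / not-known-to-interact) score
sets.  Built-in tables for vertebrates and bacteria are shipped as packaged
TSV resources; new tables can be rebuilt from labeled scores by equal-width
binning with merging of at-or-below-random bins.

Scores below the lowest tabulated threshold are no better than random and
report the 50% baseline; scores above the highest threshold report the
highest tabulated percent (tables are open-ended upward).  The threshold
comparison is inclusive: a score exactly at a tabulated threshold receives
that threshold's percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from os import PathLike

import numpy as np

from .exceptions import CalibrationError

BASELINE_PERCENT = 50.0
BASELINE_LABEL = "no better than random"


class NonMonotonicTableWarning(UserWarning):
    """A tabulated percent increases as the score threshold decreases."""


@dataclass(frozen=True)
class ProbabilityTable:
    """Step function from score thresholds (descending) to percent chance."""

    taxon: str
    thresholds: tuple[tuple[float, float], ...]  # (score, percent), descending score
    baseline: float = BASELINE_PERCENT

    def __post_init__(self) -> None:
        scores = [s for s, _ in self.thresholds]
        if any(b >= a for a, b in zip(scores, scores[1:])):
            raise ValueError("thresholds must be strictly descending in score")

    @property
    def non_monotonic_indices(self) -> tuple[int, ...]:
        """Indices whose percent is lower than the next (lower-score) entry."""
        pct = [p for _, p in self.thresholds]
        return tuple(i for i in range(len(pct) - 1) if pct[i] < pct[i + 1])

    def monotonized(self) -> "ProbabilityTable":
        """Replace non-monotonic cells by the mean of their neighbours.

        Off by default everywhere; the shipped tables are used as printed.
        """
        pct = [p for _, p in self.thresholds]
        for i in self.non_monotonic_indices:
            lo = pct[i - 1] if i > 0 else pct[i + 1]
            hi = pct[i + 1] if i + 1 < len(pct) else pct[i - 1]
            pct[i] = (lo + hi) / 2.0
        new = tuple((s, p) for (s, _), p in zip(self.thresholds, pct))
        return replace(self, thresholds=new)


def lookup_probability(score: float, table: ProbabilityTable) -> float:
    """Percent chance of interaction for a normalized top score.

    Returns the percent of the largest tabulated threshold that is ≤ the
    score (boundary inclusive); below the lowest threshold returns the
    baseline (50%, no better than random).  Negative scores are a domain
    error.
    """
    if score < 0:
        raise ValueError(f"score must be non-negative, got {score}")
    for thresh, pct in table.thresholds:
        if score >= thresh:
            return pct
    return table.baseline


def _table_from_rows(taxon: str, scores: list[float], pcts: list[float]) -> ProbabilityTable:
    table = ProbabilityTable(taxon, tuple(zip(scores, pcts)))
    if table.non_monotonic_indices:
        cells = ", ".join(
            f"{table.thresholds[i][0]} -> {table.thresholds[i][1]}"
            for i in table.non_monotonic_indices
        )
        warnings.warn(
            f"{taxon} table is non-monotonic at {cells} (kept as published; "
            "use .monotonized() to interpolate)",
            NonMonotonicTableWarning,
            stacklevel=3,
        )
    return table


def read_table(path: str | PathLike, taxon: str = "custom") -> ProbabilityTable:
    """Read a two-row TSV probability table (score row, percent row)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n").split("\t") for ln in fh if ln.strip()]
    if len(lines) != 2 or lines[0][0] != "score" or lines[1][0] != "percent":
        raise CalibrationError(f"{path}: expected 'score' and 'percent' rows")
    scores = [float(v) for v in lines[0][1:]]
    pcts = [float(v) for v in lines[1][1:]]
    return _table_from_rows(taxon, scores, pcts)


def write_table(table: ProbabilityTable, path: str | PathLike) -> None:
    """Write a table in the same two-row TSV layout."""
    with open(path, "w") as fh:
        fh.write("score\t" + "\t".join(f"{s:g}" for s, _ in table.thresholds) + "\n")
        fh.write("percent\t" + "\t".join(f"{p:g}" for _, p in table.thresholds) + "\n")


@lru_cache(maxsize=None)
def _load_builtin(taxon: str) -> ProbabilityTable:
    ref = resources.files("coevmi.data").joinpath(f"{taxon}_thresholds.tsv")
    with resources.as_file(ref) as path:
        return read_table(path, taxon=taxon)


def builtin_table(taxon: str) -> ProbabilityTable:
    """The shipped calibration table for ``"vertebrate"`` or ``"bacteria"``.

    The bacteria table contains one non-monotonic cell (23.93 -> 75.58,
    likely a publication erratum); it is kept as published and a
    :class:`NonMonotonicTableWarning` is emitted once on first load.
    """
    if taxon not in ("vertebrate", "bacteria"):
        raise ValueError(f"unknown taxon {taxon!r}")
    return _load_builtin(taxon)


def build_probability_table(
    known_scores,
    unknown_scores,
    n_bins: int = 20,
    taxon: str = "custom",
) -> ProbabilityTable:
    """Calibrate a probability table from labeled score sets.

    Scores are split into ``n_bins`` equal-width bins spanning
    ``[0, max(all scores)]``; each bin's probability is the fraction of its
    scores that come from the known-interacting set.  The contiguous run of
    bottom bins whose probability is ≤ 50% (or that are empty) is merged
    into the baseline region, since the labeling is far more likely to miss
    true interactions than to invent them.  Surviving bins are emitted as
    (bin lower edge, percent) thresholds in descending score order; empty
    bins above the baseline region extend the step below them.
    """
    known = np.asarray(list(known_scores), dtype=float)
    unknown = np.asarray(list(unknown_scores), dtype=float)
    if known.size == 0 or unknown.size == 0:
        raise CalibrationError("both known and unknown score sets must be non-empty")
    if (known < 0).any() or (unknown < 0).any():
        raise CalibrationError("scores must be non-negative")
    top = float(max(known.max(), unknown.max()))
    if top <= 0:
        raise CalibrationError("all scores are zero; nothing to calibrate")
    edges = np.linspace(0.0, top, n_bins + 1)
    k_counts, _ = np.histogram(known, bins=edges)
    u_counts, _ = np.histogram(unknown, bins=edges)
    totals = k_counts + u_counts
    with np.errstate(invalid="ignore"):
        pct = np.where(totals > 0, 100.0 * k_counts / np.maximum(totals, 1), np.nan)

    # baseline region: maximal bottom run of empty or ≤50% bins
    start = 0
    while start < n_bins and (totals[start] == 0 or pct[start] <= BASELINE_PERCENT):
        start += 1
    thresholds = [
        (float(edges[i]), float(pct[i]))
        for i in range(start, n_bins)
        if totals[i] > 0
    ]
    thresholds.reverse()  # descending score
    return ProbabilityTable(taxon, tuple(thresholds))
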
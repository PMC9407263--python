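"""Filtered mutual information between alignment columns.

For two columns X (protein 1) and Y (protein 2) observed across the same
species, the mutual information is

    MI(X, Y) = sum_{x,y} p_XY(x, y) * log( p_XY(x, y) / (p_X(x) * p_Y(y)) )

where p_X and p_Y are the per-column residue frequencies and p_XY the joint
frequency of a residue combination.  Two per-term filters suppress noise:

* a marginal threshold τ — a combination counts only if p_X(x) ≥ τ and
  p_Y(y) ≥ τ;
* a "percent above random" threshold r — the joint frequency must exceed its
  independence expectation, p_XY(x, y) ≥ (1 + r/100) · p_X(x) · p_Y(y).

Because every retained term then has p_XY > p_X·p_Y, filtered scores are
non-negative.  Cross-protein column pairs only; per-pair scores are divided
by the mean over the whole comparison and scaled ×10,000, which cancels the
logarithm base and makes scores comparable across analyses.

Species contributing a gap or a non-standard residue at either column of a
pair are excluded from that pair's counts; frequencies are computed over the
remaining species (a gap is absence of a residue, not a coevolving state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alignment_io import PairedAlignment

#: the 20 standard amino acids; anything else (gap, X, B, Z, *, ...) is
#: excluded from counting.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_N_AA = len(AMINO_ACIDS)
_EXCLUDED = _N_AA  # sentinel code for gap / non-standard symbols

_CODE = np.full(128, _EXCLUDED, dtype=np.uint8)
for _i, _aa in enumerate(AMINO_ACIDS):
    _CODE[ord(_aa)] = _i


@dataclass(frozen=True)
class FilterParams:
    """Per-term MI filters.

    ``min_px`` is the marginal frequency threshold τ in [0, 1] applied to
    both p_X(x) and p_Y(y); ``pct_above_random`` is the percentage r in
    [0, 100) by which a joint frequency must exceed p_X·p_Y to count.
    """

    min_px: float
    pct_above_random: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_px <= 1.0:
            raise ValueError(f"min_px must be in [0, 1], got {self.min_px}")
        if not 0.0 <= self.pct_above_random < 100.0:
            raise ValueError(
                f"pct_above_random must be in [0, 100), got {self.pct_above_random}"
            )

    @classmethod
    def vertebrate(cls) -> "FilterParams":
        """Default preset tuned on vertebrate ortholog alignments."""
        return cls(min_px=0.17, pct_above_random=35.0)

    @classmethod
    def bacteria(cls) -> "FilterParams":
        """Default preset tuned on bacterial ortholog alignments."""
        return cls(min_px=0.29, pct_above_random=22.0)


PRESETS = {"vertebrate": FilterParams.vertebrate, "bacteria": FilterParams.bacteria}


@dataclass
class ScoreMatrix:
    """Cross-protein MI scores indexed by reference positions.

    ``raw`` holds unnormalized MI values, ``normalized`` the same values
    divided by ``raw.mean()`` and scaled ×10,000.  ``top`` is
    ``(pos1, pos2, normalized_score)`` for the maximal cell (ties broken
    toward the smallest protein-1 then protein-2 position).  When every raw
    score is zero there is no signal to normalize against: ``no_signal`` is
    set and all normalized scores are 0.
    """

    positions1: np.ndarray
    positions2: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray
    top: tuple[int, int, float] | None
    no_signal: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.raw.shape


def encode_column(column: Iterable[str]) -> np.ndarray:
    """Map residue letters to integer codes (20 = excluded symbol)."""
    arr = np.frombuffer("".join(column).upper().encode("ascii"), dtype=np.uint8)
    return _CODE[arr]


def column_distribution(column: Sequence[str]) -> dict[str, float]:
    """Residue frequencies of one column, gaps/non-standard symbols excluded.

    Frequencies sum to 1 over the counted species; an all-excluded column
    yields an empty distribution (pair MI involving it is 0).
    """
    codes = encode_column(column)
    codes = codes[codes != _EXCLUDED]
    if codes.size == 0:
        return {}
    counts = np.bincount(codes, minlength=_N_AA)
    n = codes.size
    return {AMINO_ACIDS[i]: counts[i] / n for i in np.nonzero(counts)[0]}


def pair_mi(
    col1: Sequence[str] | np.ndarray,
    col2: Sequence[str] | np.ndarray,
    filters: FilterParams | None = None,
    *,
    base: float | None = None,
) -> float:
    """Mutual information between two aligned columns.

    ``filters=None`` computes plain (unfiltered) MI of the empirical joint
    distribution, including negative partial terms' full cancellation — the
    textbook quantity.  With :class:`FilterParams`, each residue combination
    is kept only if it passes the τ and percent-above-random filters, so the
    result is a sum of strictly non-negative terms.

    ``base`` selects the logarithm base (natural log by default); it only
    rescales raw scores and cancels under mean-normalization.
    """
    c1 = col1 if isinstance(col1, np.ndarray) else encode_column(col1)
    c2 = col2 if isinstance(col2, np.ndarray) else encode_column(col2)
    if c1.shape != c2.shape:
        raise ValueError("columns must cover the same species")
    valid = (c1 != _EXCLUDED) & (c2 != _EXCLUDED)
    n = int(valid.sum())
    if n == 0:
        return 0.0
    a = c1[valid].astype(np.intp)
    b = c2[valid].astype(np.intp)
    joint = np.bincount(a * _N_AA + b, minlength=_N_AA * _N_AA).reshape(_N_AA, _N_AA)
    nx = joint.sum(axis=1)
    ny = joint.sum(axis=0)
    xi, yi = np.nonzero(joint)
    cxy = joint[xi, yi].astype(np.float64)
    cx = nx[xi].astype(np.float64)
    cy = ny[yi].astype(np.float64)
    # Integer-product ratio keeps exact independence at exactly ratio == 1,
    # so independent columns score exactly 0.
    ratio = cxy * n / (cx * cy)
    if filters is not None:
        tau = filters.min_px
        factor = 1.0 + filters.pct_above_random / 100.0
        keep = (cx / n >= tau) & (cy / n >= tau) & (cxy * n >= factor * cx * cy)
        cxy, ratio = cxy[keep], ratio[keep]
    mi = float(np.sum((cxy / n) * np.log(ratio)))
    if base is not None:
        mi /= math.log(base)
    return mi


def normalize_matrix(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Comparison-wide normalization: raw ÷ mean(raw) × 10,000.

    The mean is taken over every cross-protein cell, zeros included.  When
    all raw scores are zero the normalization is undefined; all normalized
    scores are then 0 and the no-signal flag is returned.
    """
    raw = np.asarray(raw, dtype=float)
    mean = raw.mean() if raw.size else 0.0
    if mean > 0:
        return raw / mean * 10_000.0, False
    return np.zeros_like(raw), True


def _encode_ref_columns(seqs: list[str], refmap: list[tuple[int, int]]) -> np.ndarray:
    """Matrix of residue codes, shape (n_reference_positions, n_species)."""
    full = np.vstack([encode_column(s) for s in seqs])  # species x columns
    cols = [c for c, _ in refmap]
    return full[:, cols].T.copy()


def score_comparison(
    pa: PairedAlignment,
    filters: FilterParams | None = None,
    *,
    base: float | None = None,
) -> ScoreMatrix:
    """Score every cross-protein reference-position pair of a comparison.

    Only cross-protein pairs are computed (intra-protein scores are not part
    of the comparison).  The normalized matrix is ``raw / mean(raw) * 10_000``
    with the mean taken over all cells, zeros included; its own mean is
    therefore exactly 10,000 whenever any raw score is positive.
    """
    pos1 = np.array([p for _, p in pa.refmap1], dtype=int)
    pos2 = np.array([p for _, p in pa.refmap2], dtype=int)
    m1 = _encode_ref_columns(pa.seqs1, pa.refmap1)
    m2 = _encode_ref_columns(pa.seqs2, pa.refmap2)
    raw = np.zeros((len(pos1), len(pos2)))
    for i in range(len(pos1)):
        ci = m1[i]
        for j in range(len(pos2)):
            raw[i, j] = pair_mi(ci, m2[j], filters, base=base)
    if raw.size == 0:
        return ScoreMatrix(pos1, pos2, raw, raw.copy(), top=None, no_signal=True)
    normalized, no_signal = normalize_matrix(raw)
    # argmax in row-major order = smallest pos1 then pos2 on ties
    i, j = np.unravel_index(int(np.argmax(normalized)), normalized.shape)
    top = (int(pos1[i]), int(pos2[j]), float(normalized[i, j]))
    return ScoreMatrix(pos1, pos2, raw, normalized, top=top, no_signal=no_signal)
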
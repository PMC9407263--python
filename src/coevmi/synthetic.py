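"""Synthetic paired alignments with planted coevolving column pairs.

The simulator emulates the shape of paired ortholog alignments without any
phylogeny: background columns draw each species' residue independently from
a background profile (uniform over the 20 amino acids by default), while
each planted column pair models coevolution as a noisy alphabet bijection —
column-1 residues are drawn from a small-support "constrained site" profile
and pushed through a fixed random bijection of the amino-acid alphabet into
column 2, after which a fraction ε of species have their column-2 residue
resampled independently.  At ε = 0 the pair's MI equals the empirical
entropy of column 1; at ε = 1 the pair is statistically independent.

Coevolving sites use a low-cardinality residue profile (default three
residues at 0.5/0.3/0.2) because real covarying positions are functionally
constrained to a few states; a uniform 20-letter column would never pass a
realistic marginal-frequency filter.  Gaps are inserted independently at
``gap_rate`` in every species except the first (the reference), so planted
columns always keep a reference coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment_io import GAP, Alignment
from .mi_engine import AMINO_ACIDS
from .tuning import LabeledScores

DEFAULT_PLANTED_PROBS = (0.5, 0.3, 0.2)


@dataclass(frozen=True)
class PlantedPair:
    """One coevolving column pair: column indices (0-based) and noise ε."""

    col1: int
    col2: int
    epsilon: float = 0.0


@dataclass
class SimulationSpec:
    """Study conditions for one simulated paired alignment."""

    n_species: int = 150
    len1: int = 30
    len2: int = 30
    planted: tuple[PlantedPair, ...] = ()
    background_profile: np.ndarray | None = None  # len-20, sums to 1; uniform default
    planted_probs: tuple[float, ...] = DEFAULT_PLANTED_PROBS
    gap_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be ≥ 1")
        if self.len1 < 1 or self.len2 < 1:
            raise ValueError("alignment lengths must be ≥ 1")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must be in [0, 1)")
        for p in self.planted:
            if not (0 <= p.col1 < self.len1 and 0 <= p.col2 < self.len2):
                raise ValueError(f"planted pair {p} out of bounds")
            if not 0.0 <= p.epsilon <= 1.0:
                raise ValueError(f"noise ε must be in [0, 1], got {p.epsilon}")
        if self.background_profile is not None:
            prof = np.asarray(self.background_profile, dtype=float)
            if prof.shape != (20,) or prof.min() < 0 or not np.isclose(prof.sum(), 1.0):
                raise ValueError("background_profile must be 20 non-negative freqs summing to 1")


def skewed_profile(alpha: float = 0.5, seed: int = 0) -> np.ndarray:
    """A Dirichlet-sampled skewed background profile (exercises the τ filter)."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(20, alpha))


def _species_names(n: int) -> list[str]:
    return [f"species_{i + 1:04d}" for i in range(n)]


def simulate_pair(spec: SimulationSpec) -> tuple[Alignment, Alignment, pd.DataFrame]:
    """Generate two alignments plus a truth table of planted coordinates.

    The truth table has one row per planted pair with 0-based alignment
    columns, 1-based reference positions (the first species is gap-free and
    acts as reference) and the pair's ε.  Identical specs give identical
    output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    background = (
        np.full(20, 1 / 20)
        if spec.background_profile is None
        else np.asarray(spec.background_profile, dtype=float)
    )
    n = spec.n_species

    m1 = rng.choice(20, size=(n, spec.len1), p=background)
    m2 = rng.choice(20, size=(n, spec.len2), p=background)

    probs = np.asarray(spec.planted_probs, dtype=float)
    rows = []
    for pair in spec.planted:
        # constrained-site residues for column 1, bijection image for column 2
        support = rng.choice(20, size=probs.size, replace=False)
        bijection = rng.permutation(20)
        c1 = support[rng.choice(probs.size, size=n, p=probs)]
        c2 = bijection[c1]
        noisy = rng.random(n) < pair.epsilon
        if noisy.any():
            resampled = support[rng.choice(probs.size, size=int(noisy.sum()), p=probs)]
            c2[noisy] = bijection[resampled]
        m1[:, pair.col1] = c1
        m2[:, pair.col2] = c2
        rows.append(
            {
                "col1": pair.col1,
                "col2": pair.col2,
                "ref_pos1": pair.col1 + 1,
                "ref_pos2": pair.col2 + 1,
                "epsilon": pair.epsilon,
            }
        )

    s1 = aa[m1]
    s2 = aa[m2]
    if spec.gap_rate > 0:
        for m in (s1, s2):
            gaps = rng.random(m.shape) < spec.gap_rate
            gaps[0, :] = False  # the reference row stays gap-free
            m[gaps] = GAP

    names = _species_names(n)
    a1 = Alignment({h: "".join(row) for h, row in zip(names, s1)})
    a2 = Alignment({h: "".join(row) for h, row in zip(names, s2)})
    truth = pd.DataFrame(rows, columns=["col1", "col2", "ref_pos1", "ref_pos2", "epsilon"])
    return a1, a2, truth


def reference_species(spec: SimulationSpec) -> str:
    """Header of the simulated reference species (gap-free first row)."""
    return _species_names(spec.n_species)[0]


def simulate_labeled_scores(
    n_known: int,
    n_unknown: int,
    shift: float = 1.0,
    seed: int = 0,
) -> LabeledScores:
    """Labeled top-score sets for exercising tuning and calibration.

    Unknown-pair scores follow a right-skewed lognormal base distribution
    (median 1, shape 1); known-pair scores follow the same distribution
    scaled by e^shift.  At shift 0 the classes are exchangeable (AUC ≈ 0.5);
    large shifts approach perfect separation.
    """
    if n_known < 1 or n_unknown < 1:
        raise ValueError("counts must be ≥ 1")
    rng = np.random.default_rng(seed)
    unknown = rng.lognormal(mean=0.0, sigma=1.0, size=n_unknown)
    known = rng.lognormal(mean=shift, sigma=1.0, size=n_known)
    return LabeledScores(known=known, unknown=unknown)
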
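"""Hyperparameter search over the MI filter grid.

Candidate filter settings are evaluated on labeled score sets — top
normalized scores of protein pairs known to interact versus pairs with no
known interaction — with four statistics per (τ, r) combination: a
two-sample t-test p-value, Cohen's D, the ROC AUC (rank / Mann–Whitney
formulation), and the best achievable precision subject to at least 20%
recall.  The default grid spans τ = 0–0.35 in steps of 0.01 and
r = 10–49% in steps of 1%, i.e. 36 × 40 = 1440 combinations; defaults are
chosen as the combination with the highest constrained precision
(precision prioritized over recall).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment_io import PairedAlignment
from .exceptions import CalibrationError, SelectionError
from .mi_engine import FilterParams, score_comparison

MIN_RECALL = 0.20


@dataclass
class LabeledScores:
    """Top scores for interacting ("known") and unproven pairs ("unknown")."""

    known: np.ndarray
    unknown: np.ndarray

    def __post_init__(self) -> None:
        self.known = np.asarray(self.known, dtype=float)
        self.unknown = np.asarray(self.unknown, dtype=float)
        if self.known.size == 0 or self.unknown.size == 0:
            raise CalibrationError("both labeled score sets must be non-empty")
        if (self.known < 0).any() or (self.unknown < 0).any():
            raise CalibrationError("scores must be non-negative")


@dataclass(frozen=True)
class CombinationStats:
    """Evaluation statistics for one filter combination."""

    p_value: float
    cohens_d: float
    auc: float
    precision: float
    recall: float


@dataclass(frozen=True)
class TuningRecord:
    params: FilterParams
    stats: CombinationStats


def filter_grid(
    tau_start: float = 0.0,
    tau_stop: float = 0.35,
    tau_step: float = 0.01,
    r_start: float = 10.0,
    r_stop: float = 49.0,
    r_step: float = 1.0,
) -> list[FilterParams]:
    """Cartesian grid of filter settings, row-major (τ outer, r inner).

    Endpoints are inclusive; steps use exact decimal arithmetic so the
    default grid has exactly 36 τ values × 40 r values = 1440 combinations.
    """
    def _axis(start: float, stop: float, step: float) -> list[float]:
        if step <= 0 or stop < start:
            raise ValueError("ranges must be non-empty with positive step")
        n = int(round((stop - start) / step)) + 1
        return [round(start + k * step, 10) for k in range(n)]

    taus = _axis(tau_start, tau_stop, tau_step)
    rs = _axis(r_start, r_stop, r_step)
    return [FilterParams(t, r) for t in taus for r in rs]


def _auc(known: np.ndarray, unknown: np.ndarray) -> float:
    """ROC AUC by the Mann–Whitney rank formulation (ties get half credit)."""
    u = stats.mannwhitneyu(known, unknown, alternative="two-sided").statistic
    return float(u) / (known.size * unknown.size)


def _cohens_d(known: np.ndarray, unknown: np.ndarray) -> float:
    """Cohen's D with the pooled standard deviation."""
    n1, n2 = known.size, unknown.size
    v1 = known.var(ddof=1) if n1 > 1 else 0.0
    v2 = unknown.var(ddof=1) if n2 > 1 else 0.0
    dof = n1 + n2 - 2
    pooled = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / dof) if dof > 0 else 0.0
    if pooled == 0.0:
        return math.nan if known.mean() == unknown.mean() else math.inf
    return float((known.mean() - unknown.mean()) / pooled)


def _best_precision(known: np.ndarray, unknown: np.ndarray) -> tuple[float, float]:
    """Max precision over score cut-offs subject to recall ≥ 20%.

    A pair is predicted interacting when its score is at or above the
    cut-off.  Ties in precision break toward higher recall.
    """
    cutoffs = np.unique(np.concatenate([known, unknown]))
    best = (-1.0, -1.0)
    for t in cutoffs:
        tp = int((known >= t).sum())
        fp = int((unknown >= t).sum())
        recall = tp / known.size
        if recall < MIN_RECALL or tp + fp == 0:
            continue
        precision = tp / (tp + fp)
        if (precision, recall) > best:
            best = (precision, recall)
    return best


def evaluate_combination(
    scores: LabeledScores,
    t_test: str = "welch",
) -> CombinationStats:
    """Evaluate one filter combination's labeled scores.

    ``t_test`` is ``"welch"`` (unequal-variance, the default: group sizes
    and variances generally differ) or ``"student"`` (pooled variance).
    With zero variance in both groups the t-test is undefined and the
    p-value is reported as NaN.
    """
    known, unknown = scores.known, scores.unknown
    if t_test not in ("welch", "student"):
        raise ValueError(f"unknown t_test variant {t_test!r}")
    if known.std() == 0.0 and unknown.std() == 0.0:
        p_value = math.nan
    else:
        p_value = float(
            stats.ttest_ind(known, unknown, equal_var=(t_test == "student")).pvalue
        )
    precision, recall = _best_precision(known, unknown)
    return CombinationStats(
        p_value=p_value,
        cohens_d=_cohens_d(known, unknown),
        auc=_auc(known, unknown),
        precision=precision,
        recall=recall,
    )


def bonferroni_alpha(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Bonferroni-corrected per-test significance level, alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be ≥ 1")
    return alpha / n_tests


def select_filters(results: Iterable[TuningRecord]) -> FilterParams:
    """Pick default filters: highest precision with recall ≥ 20%.

    Ties break toward higher AUC, then the smaller (τ, r) pair.  The choice
    does not depend on the order results are supplied in.
    """
    eligible = [r for r in results if r.stats.recall >= MIN_RECALL]
    if not eligible:
        raise SelectionError(f"no combination reaches {MIN_RECALL:.0%} recall")
    return min(
        eligible,
        key=lambda r: (
            -r.stats.precision,
            -r.stats.auc,
            r.params.min_px,
            r.params.pct_above_random,
        ),
    ).params


def score_pairs(
    pairs: Sequence[PairedAlignment],
    params: FilterParams,
) -> np.ndarray:
    """Top normalized score of each protein-pair comparison under ``params``."""
    out = np.zeros(len(pairs))
    for i, pa in enumerate(pairs):
        top = score_comparison(pa, params).top
        out[i] = top[2] if top is not None else 0.0
    return out


def grid_search(
    known_pairs: Sequence[PairedAlignment],
    unknown_pairs: Sequence[PairedAlignment],
    grid: Sequence[FilterParams] | None = None,
    t_test: str = "welch",
) -> list[TuningRecord]:
    """Re-score every labeled pair under every grid combination and evaluate."""
    if grid is None:
        grid = filter_grid()
    records = []
    for params in grid:
        scores = LabeledScores(
            known=score_pairs(known_pairs, params),
            unknown=score_pairs(unknown_pairs, params),
        )
        records.append(TuningRecord(params, evaluate_combination(scores, t_test)))
    return records


def results_frame(records: Iterable[TuningRecord]) -> pd.DataFrame:
    """Tuning results as a tidy DataFrame (one row per combination)."""
    return pd.DataFrame(
        {
            "min_px": r.params.min_px,
            "pct_above_random": r.params.pct_above_random,
            "p_value": r.stats.p_value,
            "cohens_d": r.stats.cohens_d,
            "auc": r.stats.auc,
            "precision": r.stats.precision,
            "recall": r.stats.recall,
        }
        for r in records
    )


def write_results(records: Iterable[TuningRecord], path: str | PathLike) -> None:
    """Write the per-combination statistics table as TSV."""
    results_frame(records).to_csv(path, sep="\t", index=False)


def read_labeled_scores(known_path: str | PathLike, unknown_path: str | PathLike) -> LabeledScores:
    """Read two two-column TSV files (pair id, top score), one per class."""
    def _read(path):
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 2:
            raise CalibrationError(f"{path}: expected two columns (pair id, score)")
        return df.iloc[:, 1].to_numpy(dtype=float)

    return LabeledScores(known=_read(known_path), unknown=_read(unknown_path))


def plot_tuning_heatmaps(records: Sequence[TuningRecord], path: str | PathLike) -> None:
    """Render precision / AUC / −log10 p heatmap grids over (τ, r) to one image."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = results_frame(records)
    df["neg_log10_p"] = -np.log10(df["p_value"])
    fig, axes = plt.subplots(1, 3, figsize=(15, 4))
    for ax, col, title in zip(
        axes,
        ["precision", "auc", "neg_log10_p"],
        ["Best precision (recall ≥ 20%)", "ROC AUC", "−log10 t-test p"],
    ):
        pivot = df.pivot(index="min_px", columns="pct_above_random", values=col)
        im = ax.imshow(
            pivot.to_numpy(),
            origin="lower",
            aspect="auto",
            extent=(
                pivot.columns.min(),
                pivot.columns.max(),
                pivot.index.min(),
                pivot.index.max(),
            ),
        )
        ax.set_xlabel("% above random (r)")
        ax.set_ylabel("min p_X (τ)")
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
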
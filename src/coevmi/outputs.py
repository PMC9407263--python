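"""Result writers: summary TSV (append), detailed CSV, heatmap image."""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

from .mi_engine import ScoreMatrix

SUMMARY_COLUMNS = [
    "protein1",
    "protein2",
    "position1",
    "position2",
    "score",
    "likelihood_pct",
]


@dataclass(frozen=True)
class SummaryRecord:
    """One comparison's headline result (positions in reference coordinates)."""

    protein1: str
    protein2: str
    position1: int
    position2: int
    score: float
    likelihood_pct: float


def write_summary(record: SummaryRecord, path: str | PathLike) -> None:
    """Append one TSV line; the header is written only when creating the file.

    Repeated runs against the same path accumulate lines (append, never
    overwrite), producing one tidy file summarizing several comparisons.
    """
    path = Path(path)
    new_file = not path.exists() or path.stat().st_size == 0
    with open(path, "a") as fh:
        if new_file:
            fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        fh.write(
            f"{record.protein1}\t{record.protein2}\t{record.position1}\t"
            f"{record.position2}\t{record.score:.6g}\t{record.likelihood_pct:g}\n"
        )


def read_summary(path: str | PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_detail(matrix: ScoreMatrix, path: str | PathLike) -> None:
    """Write the normalized score matrix as CSV (overwrites).

    First row: protein-2 reference positions; first column: protein-1
    reference positions; cells: normalized scores at full precision.
    """
    if matrix.raw.size == 0:
        raise ValueError("cannot write an empty score matrix")
    df = pd.DataFrame(matrix.normalized, index=matrix.positions1, columns=matrix.positions2)
    df.to_csv(path)  # default float repr round-trips exactly


def read_detail(path: str | PathLike) -> pd.DataFrame:
    """Read a detail CSV back (index/columns are reference positions)."""
    df = pd.read_csv(path, index_col=0)
    df.columns = df.columns.astype(int)
    return df


def render_heatmap(matrix: ScoreMatrix, path: str | PathLike) -> np.ndarray:
    """Render the normalized matrix as a raster heatmap with a color bar.

    Protein-1 positions run along the vertical axis, protein-2 along the
    horizontal.  Returns the 2-D array as drawn (useful for verifying the
    brightest cell without decoding the image).  A constant matrix renders
    with a degenerate color range without error.
    """
    if matrix.raw.size == 0:
        raise ValueError("cannot render an empty score matrix")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    data = matrix.normalized
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        data,
        origin="lower",
        aspect="auto",
        cmap="viridis",
        extent=(
            matrix.positions2[0] - 0.5,
            matrix.positions2[-1] + 0.5,
            matrix.positions1[0] - 0.5,
            matrix.positions1[-1] + 0.5,
        ),
    )
    ax.set_xlabel("protein 2 reference position")
    ax.set_ylabel("protein 1 reference position")
    ax.set_title("Normalized mutual information")
    fig.colorbar(im, ax=ax, label="score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return data
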
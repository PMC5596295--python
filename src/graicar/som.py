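"""Self-organizing-map visualization of group separation in map space.

Subject spatial maps are projected onto a small rectangular grid of neurons
(default 5x5) trained in the classic online fashion: for each presented
sample the best-matching unit and its Gaussian neighborhood move toward the
sample, with the neighborhood radius and learning rate decaying linearly.
Each neuron's pie chart then shows how many subjects of each group it
attracted — separable groups occupy disjoint regions of the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SomResult", "train_som", "neuron_composition", "plot_composition"]


@dataclass
class SomResult:
    grid: tuple[int, int]
    codebook: np.ndarray    # (rows*cols, dim)
    assignment: np.ndarray  # (n_subjects,) flat neuron index

    def neuron_coords(self, flat: int) -> tuple[int, int]:
        return divmod(flat, self.grid[1])


def _bmu(codebook: np.ndarray, x: np.ndarray) -> int:
    d = ((codebook - x) ** 2).sum(axis=1)
    return int(np.argmin(d))


def train_som(
    matrix: np.ndarray,
    grid: tuple[int, int] = (5, 5),
    epochs: int = 500,
    seed: int = 0,
    radius: tuple[float, float] = (2.5, 1.0),
    learning_rate: tuple[float, float] = (0.5, 0.01),
) -> SomResult:
    """Train a rectangular-topology SOM with Gaussian neighborhood.

    ``epochs`` counts presentations of single samples drawn in a fixed random
    order; radius and learning rate decay linearly from their start to end
    values over the run. Deterministic given the seed.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0 or matrix.ndim != 2 or matrix.shape[0] == 0:
        raise ValueError("empty input matrix")
    rows, cols = grid
    n_neurons = rows * cols
    if matrix.shape[0] < n_neurons:
        logger.warning("fewer samples (%d) than neurons (%d); map will be sparse",
                       matrix.shape[0], n_neurons)
    rng = np.random.default_rng(seed)
    # init codebook from random samples (with replacement) plus small jitter
    picks = rng.integers(0, matrix.shape[0], size=n_neurons)
    codebook = matrix[picks].astype(float) + 1e-6 * rng.standard_normal((n_neurons, matrix.shape[1]))
    coords = np.array([divmod(i, cols) for i in range(n_neurons)], dtype=float)

    for it in range(epochs):
        frac = it / max(epochs - 1, 1)
        sigma = radius[0] + frac * (radius[1] - radius[0])
        lr = learning_rate[0] + frac * (learning_rate[1] - learning_rate[0])
        x = matrix[rng.integers(0, matrix.shape[0])]
        b = _bmu(codebook, x)
        d2 = ((coords - coords[b]) ** 2).sum(axis=1)
        h = np.exp(-d2 / (2 * sigma**2))
        codebook += lr * h[:, None] * (x - codebook)

    assignment = np.array([_bmu(codebook, x) for x in matrix])
    return SomResult(grid=grid, codebook=codebook, assignment=assignment)


def neuron_composition(som: SomResult, truth: np.ndarray) -> pd.DataFrame:
    """Per-neuron subject counts per group (columns: neuron_id, row, col,
    count_<group> for each group, total)."""
    truth = np.asarray(truth)
    groups = sorted(np.unique(truth))
    rows = []
    for flat in range(som.grid[0] * som.grid[1]):
        members = truth[som.assignment == flat]
        r, c = som.neuron_coords(flat)
        row = {"neuron_id": flat, "row": r, "col": c}
        for g in groups:
            row[f"count_{g}"] = int((members == g).sum())
        row["total"] = len(members)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_composition(som: SomResult, truth: np.ndarray, path: str | None = None,
                     colors: dict | None = None):
    """Grid of pie charts, one per neuron, colored by group membership."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comp = neuron_composition(som, truth)
    groups = sorted(np.unique(np.asarray(truth)))
    palette = colors or dict(zip(groups, ["#d62728", "#1f77b4", "#2ca02c", "#9467bd"]))
    nrows, ncols = som.grid
    fig, axes = plt.subplots(nrows, ncols, figsize=(2 * ncols, 2 * nrows))
    axes = np.atleast_2d(axes)
    for _, row in comp.iterrows():
        ax = axes[int(row["row"]), int(row["col"])]
        counts = [row[f"count_{g}"] for g in groups]
        if sum(counts) > 0:
            ax.pie(counts, colors=[palette[g] for g in groups])
        ax.set_title(str(int(row["neuron_id"])), fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    for ax in axes.ravel():
        ax.set_aspect("equal")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
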
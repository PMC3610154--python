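"""Self-organizing-map clustering of mapped measurement profiles.

A SOM quantizes profile space with a small grid of prototype vectors
trained by competitive learning: for each presented profile the
best-matching unit (BMU) and its grid neighbors move toward the profile,
with learning rate and neighborhood radius decaying exponentially over
epochs.  With the default 1 x k grid the units act as k target clusters;
node cluster membership is the index of the nearest prototype.

Profiles are z-scored per row by default, because metabolite, enzyme and
morphological measurements live on incomparable scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import AttributedGraph


@dataclass
class SOMModel:
    weights: np.ndarray          # (units, dim) prototype vectors
    grid: tuple[int, int]        # rows x cols; unit u sits at divmod(u, cols)
    seed: int
    epochs: int
    initial_rate: float
    initial_radius: float
    normalize: bool
    trained: bool = False
    loss_history: list[float] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]

    def unit_positions(self) -> np.ndarray:
        rows, cols = self.grid
        return np.array([divmod(u, cols) for u in range(rows * cols)], dtype=float)


def _prepare(profiles, normalize: bool) -> np.ndarray:
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2:
        raise ValueError("profiles must be a 2-D matrix (rows x observations)")
    # missing cells: mean-impute per row (flagged by the caller's data model)
    row_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=1, keepdims=True)
    x = np.where(np.isnan(x), row_mean, x)
    if normalize:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    return x


def train_som(
    profiles,
    k: int,
    epochs: int = 100,
    seed: int = 0,
    grid: tuple[int, int] | None = None,
    initial_rate: float = 0.5,
    initial_radius: float | None = None,
    normalize: bool = True,
) -> SOMModel:
    """Train a SOM with ``k`` units (1 x k grid unless ``grid`` is given).

    Deterministic for a fixed seed: prototypes are initialized from seeded
    draws of the data rows, rows are presented in a seeded shuffle per
    epoch, and rate/radius decay exponentially to ~1% of their initial
    values over the schedule.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = _prepare(profiles, normalize)
    n, dim = x.shape
    if grid is None:
        grid = (1, k)
    if grid[0] * grid[1] != k:
        raise ValueError(f"grid {grid} does not hold {k} units")
    if k > n:
        import logging
        logging.getLogger(__name__).warning(
            "k=%d exceeds row count %d; empty clusters are possible", k, n)
    rng = np.random.default_rng(seed)
    init_idx = rng.integers(0, n, size=k)
    w = x[init_idx].copy() + 1e-9 * rng.standard_normal((k, dim))
    if initial_radius is None:
        initial_radius = max(grid) / 2.0
    model = SOMModel(w, grid, seed, epochs, initial_rate, initial_radius, normalize)
    pos = model.unit_positions()
    tau = epochs / np.log(100.0)  # decay to 1% at the last epoch

    for epoch in range(epochs):
        rate = initial_rate * np.exp(-epoch / tau)
        radius = max(initial_radius * np.exp(-epoch / tau), 1e-3)
        order = rng.permutation(n)
        for i in order:
            d2 = ((w - x[i]) ** 2).sum(axis=1)
            bmu = int(np.argmin(d2))
            gd2 = ((pos - pos[bmu]) ** 2).sum(axis=1)
            h = np.exp(-gd2 / (2 * radius * radius))
            w += rate * h[:, None] * (x[i] - w)
        bmu_d = np.sqrt(((x[:, None, :] - w[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
        model.loss_history.append(float(bmu_d.mean()))
    model.trained = True
    return model


def predict_clusters(model: SOMModel, profiles) -> np.ndarray:
    """Nearest-prototype unit index per row; ties go to the lowest index."""
    if not model.trained:
        raise ValueError("model is not trained")
    x = _prepare(profiles, model.normalize)
    d2 = ((x[:, None, :] - model.weights[None, :, :]) ** 2).sum(axis=2)
    # argmin returns the first (lowest) index on ties
    return np.argmin(np.round(d2, 12), axis=1)


def assign_clusters(
    model: SOMModel,
    profiles: pd.DataFrame,
    g: AttributedGraph,
    attribute: str = "cluster",
) -> AttributedGraph:
    """Write cluster membership onto the nodes named by the profile index."""
    out = g.copy()
    labels = predict_clusters(model, profiles.values)
    skipped = 0
    for node, lab in zip(profiles.index, labels):
        if not out.has_node(node):
            skipped += 1
            continue
        out.set_attr("node", node, attribute, int(lab))
    if skipped:
        import logging
        logging.getLogger(__name__).info("assign_clusters: %d rows had no node", skipped)
    return out
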
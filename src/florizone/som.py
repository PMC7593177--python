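"""Self-organizing map on binary community rows.

Online Kohonen training from scratch: a rectangular lattice of nodes, each
carrying a codebook weight vector in taxon space.  Presence-absence rows are
presented one at a time; the best-matching unit (BMU) and its lattice
neighborhood move toward the presented row, with learning rate and
neighborhood radius decaying linearly over all presentations.  Defaults
mirror the classical settings: a 9 x 9 square lattice, learning rate
0.05 -> 0.01, initial radius covering two-thirds of node-to-node lattice
distances decaying to 0, 100 epochs, bubble neighborhood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .grid import PresenceAbsenceMatrix


def lattice_coordinates(rows: int, cols: int) -> np.ndarray:
    """(row, col) coordinates of each node, node index row-major."""
    rr, cc = np.divmod(np.arange(rows * cols), cols)
    return np.column_stack([rr, cc]).astype(float)


def default_radius(rows: int, cols: int) -> float:
    """Radius covering two-thirds of all node-to-node lattice distances."""
    coords = lattice_coordinates(rows, cols)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    return float(np.quantile(d[np.triu_indices_from(d, k=1)], 2 / 3))


@dataclass
class SOMModel:
    """Lattice geometry, codebook and training schedule."""

    lattice_rows: int
    lattice_cols: int
    codebook: np.ndarray  # (n_nodes, n_features)
    neighborhood: str = "bubble"  # or "gaussian"
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    radius_start: float | None = None  # None -> default_radius at train time
    radius_end: float = 0.0
    n_epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.lattice_rows < 1 or self.lattice_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        self.codebook = np.asarray(self.codebook, dtype=np.float64)
        if self.codebook.shape[0] != self.n_nodes:
            raise ValueError("codebook rows != lattice size")
        if not (self.alpha_start >= self.alpha_end > 0) and self.alpha_start != 0:
            # alpha_start == alpha_end == 0 is allowed (identity training)
            if not (self.alpha_start == self.alpha_end == 0):
                raise ValueError("require alpha_start >= alpha_end > 0")
        if self.neighborhood not in ("bubble", "gaussian"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")

    @property
    def n_nodes(self) -> int:
        return self.lattice_rows * self.lattice_cols

    @property
    def n_features(self) -> int:
        return self.codebook.shape[1]

    def node_coordinates(self) -> np.ndarray:
        return lattice_coordinates(self.lattice_rows, self.lattice_cols)


@dataclass
class SOMFit:
    """A trained model plus the BMU map of its training cells.

    ``cell_to_node`` has one entry per grid cell; unsurveyed cells carry -1.
    """

    model: SOMModel
    cell_to_node: np.ndarray
    qe_history: list[float]


def init_codebook(
    data: PresenceAbsenceMatrix, rows: int, cols: int, seed: int
) -> SOMModel:
    """Initialize the codebook by sampling distinct surveyed data rows.

    With fewer surveyed rows than nodes, falls back to uniform random
    weights in [0, 1].  Deterministic under ``seed``.
    """
    if rows < 1 or cols < 1:
        raise ValueError("lattice dimensions must be positive")
    n_nodes = rows * cols
    if n_nodes < 2:
        raise ValueError("lattice must have at least 2 nodes")
    rng = np.random.default_rng(seed)
    X = data.surveyed_values()
    if X.shape[0] >= n_nodes:
        idx = rng.choice(X.shape[0], size=n_nodes, replace=False)
        codebook = X[idx].copy()
    else:
        codebook = rng.uniform(0.0, 1.0, size=(n_nodes, data.n_taxa))
    return SOMModel(lattice_rows=rows, lattice_cols=cols, codebook=codebook, seed=seed)


def best_matching_unit(model: SOMModel, x: np.ndarray) -> int:
    """Index of the node whose codebook vector is nearest ``x`` (Euclidean).

    Ties break to the lowest node index.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (model.n_features,):
        raise ValueError(f"expected feature vector of length {model.n_features}")
    d2 = ((model.codebook - x) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def quantization_error(model: SOMModel, data: PresenceAbsenceMatrix) -> float:
    """Mean Euclidean distance of surveyed rows to their BMU codebooks."""
    X = data.surveyed_values()
    if X.shape[0] == 0:
        raise ValueError("no surveyed rows")
    return _qe(model.codebook, X)


def _qe(codebook: np.ndarray, X: np.ndarray) -> float:
    # chunk to bound the (rows x nodes x features) intermediate
    best = np.empty(X.shape[0])
    step = max(1, int(4e7 // (codebook.size or 1)))
    for s in range(0, X.shape[0], step):
        block = X[s : s + step]
        d2 = (
            (block**2).sum(1)[:, None]
            - 2.0 * block @ codebook.T
            + (codebook**2).sum(1)[None, :]
        )
        best[s : s + step] = np.sqrt(np.maximum(d2.min(axis=1), 0.0))
    return float(best.mean())


def train(model: SOMModel, data: PresenceAbsenceMatrix) -> SOMFit:
    """Online Kohonen training over the surveyed rows.

    Each epoch presents every surveyed row once in a seeded-shuffled order.
    At presentation ``s`` of ``S`` total, the learning rate and radius are
    linear interpolations from their start to end values; the BMU and all
    nodes within the neighborhood move toward the row by
    ``w <- w + alpha * h * (x - w)``.  Quantization error is recorded after
    each epoch.  Bit-reproducible given (seed, schedule, data).
    """
    X = data.surveyed_values()
    n = X.shape[0]
    if n == 0:
        raise ValueError("no surveyed rows to train on")
    codebook = model.codebook.copy()
    coords = model.node_coordinates()
    lat_d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    r0 = (
        model.radius_start
        if model.radius_start is not None
        else default_radius(model.lattice_rows, model.lattice_cols)
    )
    r1 = model.radius_end
    a0, a1 = model.alpha_start, model.alpha_end
    total = model.n_epochs * n
    rng = np.random.default_rng([model.seed, 1])

    qe_history: list[float] = []
    s = 0
    for _ in range(model.n_epochs):
        order = rng.permutation(n)
        for i in order:
            frac = s / (total - 1) if total > 1 else 0.0
            alpha = a0 + (a1 - a0) * frac
            radius = r0 + (r1 - r0) * frac
            x = X[i]
            bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
            if alpha != 0.0:
                d = lat_d[bmu]
                if model.neighborhood == "bubble":
                    mask = d <= radius
                    codebook[mask] += alpha * (x - codebook[mask])
                else:
                    if radius > 0:
                        h = np.exp(-(d**2) / (2.0 * radius**2))
                    else:
                        h = (d == 0).astype(float)
                    codebook += (alpha * h)[:, None] * (x - codebook)
            s += 1
        qe_history.append(_qe(codebook, X))

    trained = replace(model, codebook=codebook, radius_start=r0)
    cell_to_node = np.full(data.grid.n_cells, -1, dtype=int)
    surveyed_idx = np.flatnonzero(data.surveyed)
    for row, cell in enumerate(surveyed_idx):
        cell_to_node[cell] = int(np.argmin(((codebook - X[row]) ** 2).sum(axis=1)))
    return SOMFit(model=trained, cell_to_node=cell_to_node, qe_history=qe_history)


def u_matrix(model: SOMModel) -> np.ndarray:
    """Mean codebook distance of each node to its 4-connected lattice neighbors."""
    rows, cols = model.lattice_rows, model.lattice_cols
    W = model.codebook
    out = np.zeros(model.n_nodes)
    for node in range(model.n_nodes):
        r, c = divmod(node, cols)
        dists = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                dists.append(np.linalg.norm(W[node] - W[rr * cols + cc]))
        out[node] = np.mean(dists)
    return out


# -- serialization ---------------------------------------------------------


def save_model(model: SOMModel, json_path: str | Path) -> None:
    """JSON header (geometry, schedule, seed) + CSV codebook alongside."""
    json_path = Path(json_path)
    csv_path = json_path.with_suffix(".codebook.csv")
    header = {
        "lattice_rows": model.lattice_rows,
        "lattice_cols": model.lattice_cols,
        "neighborhood": model.neighborhood,
        "alpha_start": model.alpha_start,
        "alpha_end": model.alpha_end,
        "radius_start": model.radius_start,
        "radius_end": model.radius_end,
        "n_epochs": model.n_epochs,
        "seed": model.seed,
        "codebook_csv": csv_path.name,
    }
    json_path.write_text(json.dumps(header, indent=2) + "\n")
    np.savetxt(csv_path, model.codebook, delimiter=",", fmt="%.17g")


def load_model(json_path: str | Path) -> SOMModel:
    json_path = Path(json_path)
    header = json.loads(json_path.read_text())
    csv_name = header.pop("codebook_csv")
    codebook = np.loadtxt(json_path.parent / csv_name, delimiter=",", ndmin=2)
    return SOMModel(codebook=codebook, **header)
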
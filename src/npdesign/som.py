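"""Cascaded self-organizing-map target prediction.

A query molecule's likely macromolecular targets are inferred from the
company it keeps: two SOMs are trained on a reference library of compounds
with known target annotations — one over a physicochemical descriptor
space, one over the CATS pharmacophore space — and the query is mapped to
its best-matching unit (BMU) in each.  Reference compounds co-located in
the BMU's lattice neighbourhood form a "local ensemble"; the frequency of
each target among them, averaged over the two complementary grids, is the
consensus score.  Significance is assessed empirically: background queries
resampled from the reference library yield a null score distribution, and
p = (1 + #background >= observed) / (1 + n_background) — the add-one
permutation estimator, which can never return p = 0.  Predictions with
p <= 0.05 are considered meaningful by default.

The SOM itself is the classical online algorithm: per-epoch BMU updates
with exponentially decaying learning rate and Gaussian lattice
neighbourhood; a fixed seed fully determines the trained weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .cats import cats_vector

__all__ = [
    "PHYSCHEM_PROPERTIES",
    "physchem_descriptors",
    "DescriptorScaler",
    "SOMGrid",
    "train_som",
    "TargetPrediction",
    "CascadeTargetPredictor",
    "predict_targets",
]

logger = logging.getLogger(__name__)

#: the declared physicochemical property block, in column order
PHYSCHEM_PROPERTIES: tuple[str, ...] = (
    "mol_weight",
    "logp",
    "h_donors",
    "h_acceptors",
    "ring_count",
    "rotatable_bonds",
    "tpsa",
    "heavy_atoms",
)


def physchem_descriptors(mol: Chem.Mol) -> np.ndarray:
    """Fixed-length physicochemical property vector (unscaled)."""
    return np.array(
        [
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            rdMolDescriptors.CalcNumHBD(mol),
            rdMolDescriptors.CalcNumHBA(mol),
            rdMolDescriptors.CalcNumRings(mol),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
            rdMolDescriptors.CalcTPSA(mol),
            mol.GetNumHeavyAtoms(),
        ],
        dtype=float,
    )


@dataclass
class DescriptorScaler:
    """Column-wise z-scaling fitted on the reference library."""

    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    def fit(self, matrix: np.ndarray) -> "DescriptorScaler":
        self.mean = matrix.mean(axis=0)
        std = matrix.std(axis=0)
        std[std == 0] = 1.0  # constant columns pass through unchanged
        self.std = std
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("scaler not fitted")
        return (np.atleast_2d(matrix) - self.mean) / self.std


class SOMGrid:
    """A width x height lattice of neurons with descriptor-space weights."""

    def __init__(
        self,
        width: int,
        height: int,
        dim: int,
        epochs: int = 50,
        learning_rate: float = 0.5,
        sigma: float | None = None,
        seed: int = 0,
        space: str = "",
    ):
        self.width = width
        self.height = height
        self.dim = dim
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.sigma = sigma if sigma is not None else max(width, height) / 2.0
        self.seed = seed
        self.space = space
        self.trained = False
        rng = np.random.default_rng(seed)
        self.weights = rng.normal(0.0, 0.1, size=(width * height, dim))
        cols, rows = np.meshgrid(np.arange(width), np.arange(height), indexing="ij")
        self._coords = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)

    @property
    def n_neurons(self) -> int:
        return self.width * self.height

    def bmu(self, vector: np.ndarray) -> int:
        """Index of the best-matching unit (ties -> lowest index)."""
        d = np.linalg.norm(self.weights - vector, axis=1)
        return int(np.argmin(d))

    def neighbourhood(self, neuron: int, radius: int = 1) -> list[int]:
        """The neuron plus lattice neighbours within Chebyshev ``radius``
        (radius 1 = BMU + its 8-connected neighbours)."""
        cx, cy = self._coords[neuron]
        cheb = np.max(np.abs(self._coords - (cx, cy)), axis=1)
        return np.flatnonzero(cheb <= radius).tolist()

    def train(self, data: np.ndarray) -> "SOMGrid":
        """Classical online SOM training over the full schedule."""
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[1] != self.dim:
            raise ValueError(f"training data must be (n, {self.dim})")
        if data.shape[0] < self.n_neurons:
            logger.warning(
                "training %s SOM on %d vectors for %d neurons — grid may be sparse",
                self.space or "?",
                data.shape[0],
                self.n_neurons,
            )
        rng = np.random.default_rng(self.seed)
        n = data.shape[0]
        total_steps = self.epochs
        # time constant for exponential decay of both lr and sigma
        tau = total_steps / max(np.log(self.sigma), 1e-9)
        for epoch in range(self.epochs):
            lr = self.learning_rate * np.exp(-epoch / total_steps)
            sig = max(self.sigma * np.exp(-epoch / tau), 0.5)
            for i in rng.permutation(n):
                x = data[i]
                b = self.bmu(x)
                lattice_d2 = np.sum((self._coords - self._coords[b]) ** 2, axis=1)
                h = np.exp(-lattice_d2 / (2 * sig**2))
                self.weights += lr * h[:, None] * (x - self.weights)
        self.trained = True
        return self

    def quantization_error(self, data: np.ndarray) -> float:
        """Mean distance of each vector to its BMU weight."""
        data = np.atleast_2d(np.asarray(data, dtype=float))
        return float(
            np.mean(
                [np.linalg.norm(self.weights[self.bmu(x)] - x) for x in data]
            )
        )


def train_som(
    data: np.ndarray,
    width: int,
    height: int,
    epochs: int = 50,
    learning_rate: float = 0.5,
    sigma: float | None = None,
    seed: int = 0,
    space: str = "",
) -> SOMGrid:
    """Train a fresh :class:`SOMGrid` on a descriptor matrix."""
    data = np.asarray(data, dtype=float)
    grid = SOMGrid(width, height, data.shape[1], epochs, learning_rate, sigma, seed, space)
    return grid.train(data)


@dataclass(frozen=True)
class TargetPrediction:
    """(target label, consensus score, empirical p-value)."""

    target: str
    score: float
    p_value: float

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("empirical p-value must be in (0, 1]")


class CascadeTargetPredictor:
    """Two cascaded SOMs over complementary descriptor spaces.

    Parameters
    ----------
    grid_shape:
        lattice dimensions shared by both SOMs.
    neighbourhood_radius:
        Chebyshev radius of the local ensemble around the BMU (1 = the
        8-connected neighbours).
    """

    def __init__(
        self,
        grid_shape: tuple[int, int] = (6, 6),
        epochs: int = 50,
        neighbourhood_radius: int = 1,
        seed: int = 0,
        consensus: str = "mean",
    ):
        if consensus not in {"mean", "max"}:
            raise ValueError("consensus must be 'mean' or 'max'")
        self.grid_shape = grid_shape
        self.epochs = epochs
        self.neighbourhood_radius = neighbourhood_radius
        self.seed = seed
        self.consensus = consensus
        self._fitted = False

    # -- descriptor plumbing -------------------------------------------------
    def _descriptor_pair(self, mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray]:
        return physchem_descriptors(mol), cats_vector(mol).values

    def fit(self, references: Sequence[tuple[Chem.Mol, Sequence[str]]]) -> "CascadeTargetPredictor":
        """Train both SOMs on an annotated reference library."""
        if not references:
            raise ValueError("reference library is empty")
        self.ref_targets = [frozenset(t) for _m, t in references]
        if any(not t for t in self.ref_targets):
            raise ValueError("every reference compound needs >=1 target label")
        self.targets = sorted(set().union(*self.ref_targets))
        phys = np.array([physchem_descriptors(m) for m, _t in references])
        phys_scaler = DescriptorScaler().fit(phys)
        pharm = np.array([cats_vector(m).values for m, _t in references])
        self._scaler = phys_scaler
        w, h = self.grid_shape
        self.grid_physchem = train_som(
            phys_scaler.transform(phys), w, h, self.epochs, seed=self.seed, space="physchem"
        )
        self.grid_pharmacophore = train_som(
            pharm, w, h, self.epochs, seed=self.seed + 1, space="pharmacophore"
        )
        # neuron -> reference indices, per grid
        self._ref_vectors = (phys_scaler.transform(phys), pharm)
        self._assignments = tuple(
            [grid.bmu(v) for v in vecs]
            for grid, vecs in zip(
                (self.grid_physchem, self.grid_pharmacophore), self._ref_vectors
            )
        )
        self._fitted = True
        return self

    def _grid_frequencies(self, grid_idx: int, vector: np.ndarray) -> dict[str, float]:
        grid = (self.grid_physchem, self.grid_pharmacophore)[grid_idx]
        hood = set(grid.neighbourhood(grid.bmu(vector), self.neighbourhood_radius))
        members = [
            i for i, neuron in enumerate(self._assignments[grid_idx]) if neuron in hood
        ]
        freqs = {t: 0.0 for t in self.targets}
        if members:
            for t in self.targets:
                freqs[t] = sum(1 for i in members if t in self.ref_targets[i]) / len(members)
        return freqs

    def _score_vectors(self, phys_row: np.ndarray, pharm_row: np.ndarray) -> dict[str, float]:
        f1 = self._grid_frequencies(0, phys_row)
        f2 = self._grid_frequencies(1, pharm_row)
        if self.consensus == "mean":
            return {t: 0.5 * (f1[t] + f2[t]) for t in self.targets}
        return {t: max(f1[t], f2[t]) for t in self.targets}

    def score(self, mol: Chem.Mol) -> dict[str, float]:
        """Per-target consensus score of a query molecule."""
        if not self._fitted:
            raise RuntimeError("predictor is not fitted")
        phys, pharm = self._descriptor_pair(mol)
        return self._score_vectors(self._scaler.transform(phys)[0], pharm)

    def predict(
        self,
        mol: Chem.Mol,
        n_background: int = 1000,
        seed: int = 0,
        p_max: float | None = 0.05,
    ) -> list[TargetPrediction]:
        """Targets of ``mol`` with empirical p-values.

        The background is drawn from the reference library by seeded
        resampling with replacement; ``p_max=None`` disables the
        significance filter.  Output is sorted by ascending p, then
        descending score, then label.
        """
        observed = self.score(mol)
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(self.ref_targets), size=n_background)
        exceed = {t: 0 for t in self.targets}
        phys_all, pharm_all = self._ref_vectors
        cache: dict[int, dict[str, float]] = {}
        for i in idx:
            i = int(i)
            if i not in cache:
                cache[i] = self._score_vectors(phys_all[i], pharm_all[i])
            bg = cache[i]
            for t in self.targets:
                if bg[t] >= observed[t]:
                    exceed[t] += 1
        predictions = [
            TargetPrediction(t, observed[t], (1 + exceed[t]) / (1 + n_background))
            for t in self.targets
        ]
        predictions.sort(key=lambda p: (p.p_value, -p.score, p.target))
        if p_max is not None:
            predictions = [p for p in predictions if p.p_value <= p_max]
        return predictions


def predict_targets(
    query: Chem.Mol,
    references: Sequence[tuple[Chem.Mol, Sequence[str]]],
    grid_shape: tuple[int, int] = (6, 6),
    epochs: int = 50,
    n_background: int = 1000,
    seed: int = 0,
    p_max: float | None = 0.05,
) -> list[TargetPrediction]:
    """One-shot convenience: fit the cascade on ``references`` and predict
    targets of ``query``."""
    predictor = CascadeTargetPredictor(grid_shape=grid_shape, epochs=epochs, seed=seed)
    predictor.fit(references)
    return predictor.predict(query, n_background=n_background, seed=seed, p_max=p_max)
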
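"""Coarse-graining of a subunit into equivalent-sphere grains.

The atoms of a monomer are partitioned into k clusters by repeated k-means
(k-means++ initialisation) on their unweighted Cartesian coordinates.  Each
cluster becomes a grain: its volume is the summed effective atomic volume of
its members, its weight the summed electron count (total mass is conserved
exactly), and its radius the equivalent sphere radius

    r_s = (3 * V / (4 * pi)) ** (1/3).

Out of ``restarts`` independent clusterings, the run whose grain volumes have
the smallest dispersion (standard deviation by default, standard error
optionally) is selected, so grains are as equal-sized as the geometry allows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .structure import AtomRecord, ScattererSet, to_scatterers

__all__ = [
    "GrainModel",
    "cluster_atoms",
    "equivalent_sphere_radius",
    "grains_to_scatterers",
    "mean_grain_radius",
    "write_grain_model",
    "read_grain_model",
]

_FOUR_THIRDS_PI = 4.0 / 3.0 * math.pi


@dataclass
class GrainModel:
    """k grains of one subunit: centers (Cartesian Å), equivalent-sphere radii
    (Å), electron-count weights, member assignment labels, and the grain-volume
    dispersion of the selected clustering run."""

    k: int
    centers: np.ndarray  # (k, 3)
    radii: np.ndarray  # (k,)
    weights: np.ndarray  # (k,)
    labels: np.ndarray  # (n_atoms,) grain index per atom
    volume_sd: float
    seed: int
    restarts: int
    estimator: str = "sd"


def equivalent_sphere_radius(volumes: Sequence[float]) -> float:
    """Radius of the sphere whose volume is the sum of ``volumes`` (ų -> Å)."""
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise ValueError("equivalent_sphere_radius needs at least one volume")
    if np.any(v <= 0):
        raise ValueError("volumes must be > 0")
    return float(np.cbrt(v.sum() / _FOUR_THIRDS_PI))


def _dispersion(volumes: np.ndarray, estimator: str) -> float:
    sd = float(np.std(volumes))  # population sd: defined (0) for a single grain
    if estimator == "sd":
        return sd
    if estimator == "se":
        return sd / math.sqrt(len(volumes))
    raise ValueError(f"unknown dispersion estimator {estimator!r}")


def cluster_atoms(
    atoms: Sequence[AtomRecord],
    k: int,
    restarts: int = 100,
    seed: int = 0,
    estimator: str = "sd",
    max_iter: int = 300,
    tol: float = 1e-6,
) -> GrainModel:
    """Partition atoms into k grains, keeping the most volume-uniform run.

    Runs ``restarts`` independent k-means++ clusterings (Lloyd iterations,
    convergence tolerance ``tol``, at most ``max_iter`` iterations each) on the
    atom coordinates and returns the run with minimal grain-volume dispersion.
    Empty clusters are relocated automatically by the clustering backend.
    Deterministic for a fixed seed.
    """
    n = len(atoms)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    xyz = np.array([a.position for a in atoms], dtype=float)
    v_eff = np.array([a.v_eff for a in atoms], dtype=float)
    electrons = np.array([a.n_electrons for a in atoms], dtype=float)

    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=restarts)

    best = None
    for run_seed in run_seeds:
        if k == n:
            labels = np.arange(n)
            centers = xyz.copy()
        else:
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=1,
                max_iter=max_iter,
                tol=tol,
                random_state=int(run_seed),
            ).fit(xyz)
            labels = km.labels_
            centers = km.cluster_centers_
        volumes = np.bincount(labels, weights=v_eff, minlength=k)
        disp = _dispersion(volumes, estimator)
        if best is None or disp < best[0]:
            best = (disp, labels, centers, volumes)
        if k in (1, n):
            break  # every restart is identical

    disp, labels, centers, volumes = best
    weights = np.bincount(labels, weights=electrons, minlength=k)
    radii = np.cbrt(volumes / _FOUR_THIRDS_PI)
    return GrainModel(
        k=k,
        centers=centers,
        radii=radii,
        weights=weights,
        labels=labels,
        volume_sd=disp,
        seed=seed,
        restarts=restarts,
        estimator=estimator,
    )


def mean_grain_radius(model: GrainModel) -> float:
    return float(model.radii.mean())


def grains_to_scatterers(
    model: GrainModel,
    axis: tuple[Sequence[float], Sequence[float]] | None = None,
) -> ScattererSet:
    """Turn grains into scatterer sites (cylindrical coordinates, rs, weight)."""
    records = [
        AtomRecord(
            element="CG",
            position=tuple(c),
            vdw_radius=float(r),
            n_electrons=int(round(w)),
            v_eff=_FOUR_THIRDS_PI * float(r) ** 3,
        )
        for c, r, w in zip(model.centers, model.radii, model.weights)
    ]
    sites = to_scatterers(records, axis=axis)
    # keep exact (possibly non-integer) electron weights
    sites.weight = model.weights.astype(float).copy()
    return sites


def write_grain_model(model: GrainModel, path: str | Path) -> None:
    header = (
        f"grain model: k={model.k} restarts={model.restarts} seed={model.seed} "
        f"estimator={model.estimator} volume_sd={model.volume_sd:.10e}\n"
        "x_A y_A z_A rs_A weight_e"
    )
    data = np.column_stack([model.centers, model.radii, model.weights])
    np.savetxt(path, data, fmt="%.10e", header=header)


def read_grain_model(path: str | Path) -> GrainModel:
    """Read back a grain-model table (atom labels are not stored)."""
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    for token in first.replace("#", "").split():
        if "=" in token:
            key, val = token.split("=", 1)
            meta[key] = val
    data = np.loadtxt(path, ndmin=2)
    k = data.shape[0]
    return GrainModel(
        k=int(meta.get("k", k)),
        centers=data[:, 0:3],
        radii=data[:, 3],
        weights=data[:, 4],
        labels=np.array([], dtype=int),
        volume_sd=float(meta.get("volume_sd", "nan")),
        seed=int(meta.get("seed", 0)),
        restarts=int(meta.get("restarts", 0)),
        estimator=meta.get("estimator", "sd"),
    )
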
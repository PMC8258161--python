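"""Uniform sampling of the feasible flux polytope (hit-and-run MCMC).

The robustified design workflow scores tracer mixtures over a population of
flux constellations rather than a single guess.  That population is drawn
uniformly from the flux polytope with a hit-and-run chain: from the current
point, pick a random direction, intersect the chord with the polytope, and
jump to a uniform point on the chord.  Directions are drawn isotropically on a
coordinate-rescaled copy of the polytope (per-coordinate widths from the
bounding box) to mitigate the strong anisotropy of flux polytopes.

Defaults: burn-in 1000 steps, thinning ``ceil(dim**2)`` steps between retained
samples, ``numpy.random.default_rng`` (PCG64) seeded with a single recorded
integer.  Samples are persisted to HDF5 (dataset of free coordinates plus an
attribute block with seed and chain settings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import h5py
import numpy as np

from .stoichiometry import DegeneratePolytopeError, Polytope

__all__ = [
    "FluxSampleSet",
    "chebyshev_center",
    "hit_and_run",
    "center_of_mass",
    "save_samples",
    "load_samples",
]


@dataclass(frozen=True)
class FluxSampleSet:
    """An ordered set of polytope points in free coordinates with provenance."""

    Z: np.ndarray                   # n_samples x dim
    labels: tuple[str, ...]
    seed: int | None = None
    burn_in: int = 0
    thinning: int = 1
    target: str = "uniform"

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    def __iter__(self):
        return iter(self.Z)


def chebyshev_center(polytope: Polytope) -> np.ndarray:
    """Strictly interior point maximizing the inscribed-ball radius.

    Also serves as the deterministic stand-in for the center of mass when a
    single representative flux map is needed before sampling.
    """
    center, radius = polytope.chebyshev_center()
    if radius <= 1e-9:
        raise DegeneratePolytopeError(
            f"polytope is degenerate (inscribed radius {radius:.3g})"
        )
    return center


def _chord_bounds(A, b, x, u, tol=1e-12):
    """Parameter interval [t_lo, t_hi] with x + t*u inside A z <= b."""
    Au = A @ u
    slack = b - A @ x
    t_lo, t_hi = -np.inf, np.inf
    pos = Au > tol
    neg = Au < -tol
    if pos.any():
        t_hi = np.min(slack[pos] / Au[pos])
    if neg.any():
        t_lo = np.max(slack[neg] / Au[neg])
    return t_lo, t_hi


def hit_and_run(
    polytope: Polytope,
    n_samples: int,
    seed: int,
    thinning: int | None = None,
    burn_in: int = 1000,
    start: np.ndarray | None = None,
    gaussian_target: tuple[np.ndarray, np.ndarray] | None = None,
) -> FluxSampleSet:
    """Draw ``n_samples`` (approximately) uniform points from the polytope.

    Reproducible for a fixed ``seed``; every emitted point satisfies all
    constraints.  ``gaussian_target=(mean, cov)`` switches the chord step to a
    truncated-Gaussian target (prior-informed sampling hook); the default is
    the uniform law.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    dim = polytope.dim
    if thinning is None:
        thinning = max(1, math.ceil(dim**2))
    rng = np.random.default_rng(seed)
    x = np.asarray(start, dtype=float) if start is not None else chebyshev_center(polytope)
    if not polytope.contains(x):
        raise ValueError("start point is not inside the polytope")

    box = polytope.bounding_box()
    widths = np.maximum(box[:, 1] - box[:, 0], 1e-12)

    prec = None
    mean = None
    if gaussian_target is not None:
        mean = np.asarray(gaussian_target[0], dtype=float)
        prec = np.linalg.inv(np.asarray(gaussian_target[1], dtype=float))

    samples = np.empty((n_samples, dim))
    kept = 0
    total_steps = burn_in + n_samples * thinning
    for step in range(total_steps):
        u = rng.standard_normal(dim) * widths
        norm = np.linalg.norm(u)
        if norm < 1e-300:  # pragma: no cover - astronomically unlikely
            continue
        u /= norm
        t_lo, t_hi = _chord_bounds(polytope.A, polytope.b, x, u)
        if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi <= t_lo:
            continue  # numerical sliver; keep current point
        if prec is None:
            t = rng.uniform(t_lo, t_hi)
        else:
            # 1-D truncated Gaussian along the chord
            d = x - mean
            a = u @ prec @ u
            bq = d @ prec @ u
            mu_t = -bq / a
            sd_t = 1.0 / math.sqrt(a)
            t = _truncated_normal(rng, mu_t, sd_t, t_lo, t_hi)
        x = x + t * u
        if step >= burn_in and (step - burn_in + 1) % thinning == 0:
            samples[kept] = x
            kept += 1
            if kept == n_samples:
                break
    if kept < n_samples:  # pragma: no cover - only under repeated slivers
        samples = samples[:kept]
    return FluxSampleSet(
        Z=samples,
        labels=polytope.labels,
        seed=seed,
        burn_in=burn_in,
        thinning=thinning,
        target="uniform" if prec is None else "gaussian",
    )


def _truncated_normal(rng, mu, sd, lo, hi):
    from scipy.stats import truncnorm

    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def center_of_mass(
    sample_set: FluxSampleSet, polytope: Polytope | None = None
) -> np.ndarray:
    """Coordinate-wise mean of the samples (the 'most likely' flux map).

    The mean of points in a convex set is feasible up to rounding; if a
    polytope is supplied and float drift pushed the mean outside, it is pulled
    toward the Chebyshev center until feasible.
    """
    if sample_set.n_samples == 0:
        raise ValueError("empty sample set")
    mean = sample_set.Z.mean(axis=0)
    if polytope is not None and not polytope.contains(mean):
        center = chebyshev_center(polytope)
        for alpha in np.linspace(0.0, 1.0, 101)[1:]:
            candidate = (1 - alpha) * mean + alpha * center
            if polytope.contains(candidate):
                return candidate
        return center  # pragma: no cover
    return mean


def save_samples(path, sample_set: FluxSampleSet) -> None:
    """Persist a sample set to HDF5 (dataset ``z`` + provenance attributes)."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("z", data=sample_set.Z)
        ds.attrs["labels"] = list(sample_set.labels)
        ds.attrs["seed"] = -1 if sample_set.seed is None else sample_set.seed
        ds.attrs["burn_in"] = sample_set.burn_in
        ds.attrs["thinning"] = sample_set.thinning
        ds.attrs["target"] = sample_set.target


def load_samples(path) -> FluxSampleSet:
    with h5py.File(path, "r") as fh:
        ds = fh["z"]
        seed = int(ds.attrs["seed"])
        return FluxSampleSet(
            Z=ds[...],
            labels=tuple(str(x) for x in ds.attrs["labels"]),
            seed=None if seed < 0 else seed,
            burn_in=int(ds.attrs["burn_in"]),
            thinning=int(ds.attrs["thinning"]),
            target=str(ds.attrs["target"]),
        )
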
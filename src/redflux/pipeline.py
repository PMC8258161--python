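"""The robustified tracer-design pipeline.

Three phases, orchestrated over a mixture grid and a flux-sample population:

* **Phase I** — sample the feasible flux polytope (``redflux.sampling``).
* **Phase II** — for every (flux sample, mixture): Jacobian -> FIM -> active
  flux sets for every achievable ``n_act`` -> normalized D-criterion against
  a reference mixture evaluated at the same flux sample.  Failures (singular
  labeling systems, fully singular FIMs) mark the record degenerate; they
  never abort the run.
* **Phase III** — aggregate per mixture: the median D-criterion over the
  samples that achieved each ``n_act``, the *coverage* (share of samples in
  percent that achieved it), the tracer cost, and per-flux identifiability
  frequencies with standard-deviation quantiles.

Mixture grids are exact simplex lattices: per substrate with ``s`` species and
step ``d``, all fraction vectors whose entries are multiples of ``d`` and sum
to 1 — ``binom(1/d + s - 1, s - 1)`` of them — with fractions stored as
integer multiples of ``d`` so mixture identities never drift.  Results are
independent of sample evaluation order and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import hashlib

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .labeling import (
    LabelingError,
    emu_decompose,
    measurement_covariance,
)
from .metrics import (
    IdentifiabilityThresholds,
    d_criterion,
    fisher_information,
    tracer_cost,
)
from .model import Mixture, ModelError, NetworkModel, serialize_model
from .sampling import FluxSampleSet
from .sensitivity import jacobian
from .stoichiometry import build_stoichiometry, free_flux_basis

__all__ = [
    "MixtureGrid",
    "enumerate_mixtures",
    "simplex_lattice_size",
    "RedConfig",
    "DesignRecord",
    "RedPool",
    "AggregatedPool",
    "run_red",
    "aggregate",
    "partial_design",
    "export_pool",
    "load_pool",
    "ternary_slice",
]


# ---------------------------------------------------------------------------
# mixture grid
# ---------------------------------------------------------------------------

def simplex_lattice_size(s: int, d: float) -> int:
    """Closed-form count of s-component fraction vectors on a step-d lattice.

    ``1/(s-1)! * prod_{i=0}^{s-2} (1/d + 1 + i)`` — equivalently
    ``binom(1/d + s - 1, s - 1)``.
    """
    levels = _lattice_levels(d)
    return math.comb(levels + s - 1, s - 1)


def _lattice_levels(d: float) -> int:
    levels = round(1.0 / d)
    if abs(levels * d - 1.0) > 1e-9:
        raise ModelError(f"1/d must be integral (got d={d!r})")
    return levels


@dataclass(frozen=True)
class MixtureGrid:
    """Cartesian product of per-substrate simplex lattices.

    ``compositions[substrate]`` holds integer tuples summing to ``1/d``; the
    grid index is the product over substrates in declaration order.
    """

    step: float
    substrates: tuple[str, ...]
    species_labels: tuple[tuple[str, ...], ...]
    compositions: tuple[tuple[tuple[int, ...], ...], ...]

    @property
    def per_substrate_counts(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.compositions)

    @property
    def n_mixtures(self) -> int:
        return int(np.prod(self.per_substrate_counts))

    def mixture(self, index: int) -> Mixture:
        """The mixture at a flat grid index (row-major over substrates)."""
        if not 0 <= index < self.n_mixtures:
            raise IndexError(index)
        levels = _lattice_levels(self.step)
        coords = []
        rest = index
        for count in reversed(self.per_substrate_counts):
            coords.append(rest % count)
            rest //= count
        coords = coords[::-1]
        fractions = {}
        for sub, comp_list, c in zip(self.substrates, self.compositions, coords):
            fractions[sub] = tuple(k / levels for k in comp_list[c])
        return Mixture.from_dict(fractions)

    def index_of(self, mixture: Mixture) -> int:
        levels = _lattice_levels(self.step)
        fr = mixture.as_dict()
        flat = 0
        for sub, comp_list in zip(self.substrates, self.compositions):
            target = tuple(round(x * levels) for x in fr[sub])
            flat = flat * len(comp_list) + comp_list.index(target)
        return flat

    def __iter__(self):
        for i in range(self.n_mixtures):
            yield i, self.mixture(i)


def enumerate_mixtures(catalogue, step: float) -> MixtureGrid:
    """Exact simplex-lattice enumeration over every substrate's species.

    ``catalogue`` maps substrate -> species list (or an integer species
    count, for combinatorial use).  The per-substrate counts match the
    closed-form :func:`simplex_lattice_size`.
    """
    levels = _lattice_levels(step)
    substrates = []
    labels = []
    compositions = []
    for sub, species in catalogue.items():
        s = species if isinstance(species, int) else len(species)
        if s < 1:
            raise ModelError(f"substrate {sub!r} needs at least one species")
        substrates.append(sub)
        labels.append(
            tuple(f"sp{i}" for i in range(s))
            if isinstance(species, int)
            else tuple(sp.label for sp in species)
        )
        comps = tuple(
            comp for comp in _compositions(levels, s)
        )
        assert len(comps) == simplex_lattice_size(s, step)
        compositions.append(comps)
    return MixtureGrid(
        step=step,
        substrates=tuple(substrates),
        species_labels=tuple(labels),
        compositions=tuple(compositions),
    )


def _compositions(total: int, parts: int):
    """All tuples of `parts` nonnegative ints summing to `total` (lexicographic)."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total, -1, -1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


# ---------------------------------------------------------------------------
# configuration and pool containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RedConfig:
    """Run configuration for the robustified design pipeline."""

    reference_mixture: Mixture
    thresholds: IdentifiabilityThresholds = field(
        default_factory=IdentifiabilityThresholds
    )
    objective: str = "det"              # active-set tie-break: det | trace
    exponent: str = "half"              # D-criterion root: half -> 1/(2 n_act)
    selection_method: str = "greedy"    # greedy | exhaustive
    background: float = 0.0             # 13C probability of unlabeled carbons
    amounts: dict | None = None         # grams required per substrate
    seed: int | None = None


@dataclass(frozen=True)
class DesignRecord:
    sample_id: int
    mixture_id: int
    n_act: int
    achieved: bool
    active: tuple[int, ...]
    phi_d: float                      # NaN when not achieved / ref-degenerate
    ref_degenerate: bool
    degenerate: bool                  # simulation or FIM failure at this record
    stddevs: tuple[float, ...]        # per active flux, sqrt(diag Cov)


@dataclass
class RedPool:
    """Phase-II data pool: one record per (sample, mixture, n_act)."""

    records: pd.DataFrame
    fims: dict[tuple[int, int], np.ndarray]
    flux_labels: tuple[str, ...]
    grid: MixtureGrid
    sample_set: FluxSampleSet
    config: RedConfig
    model_hash: str
    n_free: int

    @property
    def n_samples(self) -> int:
        return self.sample_set.n_samples


@dataclass
class AggregatedPool:
    """Phase-III output: per-mixture design criteria and per-flux statistics."""

    criteria: pd.DataFrame      # mixture_id, n_act, phi_d_median, coverage, cost
    per_flux: pd.DataFrame      # mixture_id, n_act, flux, frequency, sd quartiles
    flux_labels: tuple[str, ...]
    provenance: dict


# ---------------------------------------------------------------------------
# phase II
# ---------------------------------------------------------------------------

def _model_hash(model: NetworkModel) -> str:
    return hashlib.sha256(serialize_model(model).encode()).hexdigest()[:16]


def run_red(
    model: NetworkModel,
    catalogue,
    grid: MixtureGrid,
    sample_set: FluxSampleSet,
    config: RedConfig,
) -> RedPool:
    """Evaluate every (flux sample, mixture) pair into the data pool.

    Per pair: labeling Jacobian -> FIM -> greedy elimination path -> for each
    achievable ``n_act`` the D-criterion against the reference mixture at the
    same flux sample.  Work units are independent per sample; the pool is
    invariant under evaluation order.
    """
    config.reference_mixture.validate()
    S, _ = build_stoichiometry(model)
    basis = free_flux_basis(S, model)
    graph = emu_decompose(model)
    n_free = basis.n_free
    if list(sample_set.labels) != list(basis.free_ids):
        raise ModelError("sample set coordinates do not match the model's free fluxes")

    rows = []
    fims: dict[tuple[int, int], np.ndarray] = {}
    for i, z in enumerate(sample_set.Z):
        state = basis.flux_state(z)
        ref_fim = _try_fim(model, graph, state, config.reference_mixture,
                           catalogue, config, basis)
        for t, mixture in grid:
            fim = _try_fim(model, graph, state, mixture, catalogue, config, basis)
            if fim is None:
                for n_act in range(1, n_free + 1):
                    rows.append(_degenerate_record(i, t, n_act))
                continue
            fims[(i, t)] = fim.matrix
            path = _metrics.greedy_elimination_path(fim, config.thresholds)
            for n_act in range(1, n_free + 1):
                subset, ok = path.get(n_act, ((), False))
                if config.selection_method == "exhaustive" and not ok:
                    best = _metrics.exhaustive_best_subset(
                        fim, n_act, config.thresholds, config.objective
                    )
                    if best is not None:
                        subset, ok = best[0], True
                if not ok:
                    rows.append(
                        DesignRecord(i, t, n_act, False, (), math.nan,
                                     False, False, ())
                    )
                    continue
                sub = fim.matrix[np.ix_(subset, subset)]
                cov = np.linalg.inv(sub)
                phi = math.nan
                ref_degen = True
                if ref_fim is not None:
                    ref_sub = ref_fim.matrix[np.ix_(subset, subset)]
                    if config.thresholds.admissible(ref_sub, ref_fim.norm):
                        cov_ref = np.linalg.inv(ref_sub)
                        phi = d_criterion(cov, cov_ref, n_act, config.exponent)
                        ref_degen = False
                rows.append(
                    DesignRecord(
                        i, t, n_act, True, tuple(subset), phi, ref_degen,
                        False, tuple(np.sqrt(np.diag(cov))),
                    )
                )
    records = pd.DataFrame([r.__dict__ for r in rows])
    return RedPool(
        records=records,
        fims=fims,
        flux_labels=basis.free_ids,
        grid=grid,
        sample_set=sample_set,
        config=config,
        model_hash=_model_hash(model),
        n_free=n_free,
    )


def _degenerate_record(i, t, n_act) -> DesignRecord:
    return DesignRecord(i, t, n_act, False, (), math.nan, False, True, ())


def _try_fim(model, graph, state, mixture, catalogue, config, basis):
    try:
        J = jacobian(model, graph, state, mixture, catalogue, config.background)
    except LabelingError:
        return None
    sigma = measurement_covariance(model, J.labeling)
    return fisher_information(J.J, sigma, labels=basis.free_ids)


# ---------------------------------------------------------------------------
# phase III
# ---------------------------------------------------------------------------

def aggregate(pool: RedPool, catalogue=None) -> AggregatedPool:
    """Collapse the data pool into per-mixture design criteria.

    Coverage counts every sample (simulation failures count as non-covering);
    the D-criterion median runs over the achieving, reference-identifiable
    samples only.  Costs need a catalogue with prices and configured
    substrate amounts; without them the cost column is NaN.
    """
    rec = pool.records
    n_s = pool.n_samples
    amounts = pool.config.amounts

    crit_rows = []
    for (mix_id, n_act), grp in rec.groupby(["mixture_id", "n_act"]):
        achieved = grp["achieved"]
        coverage = 100.0 * achieved.sum() / n_s
        phis = grp.loc[achieved & ~grp["ref_degenerate"], "phi_d"].dropna()
        phi_med = float(phis.median()) if len(phis) else math.nan
        cost = math.nan
        if catalogue is not None and amounts is not None:
            cost = tracer_cost(catalogue, pool.grid.mixture(mix_id), amounts)
        crit_rows.append(
            {
                "mixture_id": mix_id,
                "n_act": n_act,
                "phi_d_median": phi_med,
                "coverage": coverage,
                "cost": cost,
                "n_achieving": int(achieved.sum()),
                "n_ref_degenerate": int((achieved & grp["ref_degenerate"]).sum()),
            }
        )
    criteria = pd.DataFrame(crit_rows)

    flux_rows = []
    labels = pool.flux_labels
    for (mix_id, n_act), grp in rec.groupby(["mixture_id", "n_act"]):
        ach = grp[grp["achieved"]]
        counts = np.zeros(len(labels))
        sds: dict[int, list[float]] = {k: [] for k in range(len(labels))}
        for active, stddevs in zip(ach["active"], ach["stddevs"]):
            for pos, flux_idx in enumerate(active):
                counts[flux_idx] += 1
                sds[flux_idx].append(stddevs[pos])
        for k, label in enumerate(labels):
            q = (
                np.percentile(sds[k], [25, 50, 75])
                if sds[k]
                else np.full(3, np.nan)
            )
            flux_rows.append(
                {
                    "mixture_id": mix_id,
                    "n_act": n_act,
                    "flux": label,
                    "frequency": counts[k] / n_s,
                    "sd_q1": q[0],
                    "sd_median": q[1],
                    "sd_q3": q[2],
                }
            )
    per_flux = pd.DataFrame(flux_rows)

    provenance = {
        "seed": pool.sample_set.seed,
        "n_samples": n_s,
        "model_hash": pool.model_hash,
        "min_sv_rel": pool.config.thresholds.min_sv_rel,
        "max_condition": pool.config.thresholds.max_condition,
        "objective": pool.config.objective,
        "exponent": pool.config.exponent,
        "step": pool.grid.step,
    }
    return AggregatedPool(
        criteria=criteria, per_flux=per_flux, flux_labels=labels,
        provenance=provenance,
    )


def partial_design(pool: RedPool, flux_id: str) -> pd.DataFrame:
    """Dimension-reduced (n_act = 1) design statistics for one flux.

    With all other fluxes fixed to the sample's values the restricted FIM is
    the single diagonal element, so the flux is identifiable alone whenever
    that element clears the singular-value floor; its standard deviation is
    ``1/sqrt(FIM_ff)``.  Returns one row per mixture with the identifiability
    frequency and standard-deviation quartiles.
    """
    if flux_id not in pool.flux_labels:
        raise ModelError(f"unknown free flux {flux_id!r}")
    k = pool.flux_labels.index(flux_id)
    thresholds = pool.config.thresholds
    n_s = pool.n_samples
    rows = []
    for mix_id in range(pool.grid.n_mixtures):
        sds = []
        hits = 0
        for i in range(n_s):
            fim = pool.fims.get((i, mix_id))
            if fim is None:
                continue
            f_kk = fim[k, k]
            if f_kk >= thresholds.min_sv_rel * np.linalg.norm(fim, 2) and f_kk > 0:
                hits += 1
                sds.append(1.0 / math.sqrt(f_kk))
        q = np.percentile(sds, [25, 50, 75]) if sds else np.full(3, np.nan)
        rows.append(
            {
                "mixture_id": mix_id,
                "flux": flux_id,
                "frequency": hits / n_s,
                "sd_q1": q[0],
                "sd_median": q[1],
                "sd_q3": q[2],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_pool(aggregated: AggregatedPool, h5_path=None, csv_dir=None) -> None:
    """Persist the aggregated pool to HDF5 and/or tidy CSV tables."""
    if h5_path is not None:
        import h5py

        try:
            with h5py.File(h5_path, "w") as fh:
                g = fh.create_group("aggregated")
                _write_frame(g, "criteria", aggregated.criteria)
                _write_frame(g, "per_flux", aggregated.per_flux)
                g.attrs["flux_labels"] = list(aggregated.flux_labels)
                for key, value in aggregated.provenance.items():
                    g.attrs[key] = -1 if value is None else value
        except OSError as exc:
            raise OSError(f"cannot write aggregated pool to {h5_path}: {exc}") from exc
    if csv_dir is not None:
        import pathlib

        d = pathlib.Path(csv_dir)
        d.mkdir(parents=True, exist_ok=True)
        aggregated.criteria.to_csv(d / "criteria.csv", index=False)
        aggregated.per_flux.to_csv(d / "per_flux.csv", index=False)


def _write_frame(group, name, frame: pd.DataFrame) -> None:
    g = group.create_group(name)
    g.attrs["columns"] = list(frame.columns)
    for col in frame.columns:
        data = frame[col].to_numpy()
        if data.dtype == object:
            data = np.array([str(x) for x in data], dtype="S")
        g.create_dataset(col, data=data)


def load_pool(h5_path) -> AggregatedPool:
    import h5py

    with h5py.File(h5_path, "r") as fh:
        g = fh["aggregated"]
        frames = {}
        for name in ("criteria", "per_flux"):
            sub = g[name]
            cols = [str(c) for c in sub.attrs["columns"]]
            data = {}
            for col in cols:
                arr = sub[col][...]
                if arr.dtype.kind == "S":
                    arr = arr.astype(str)
                data[col] = arr
            frames[name] = pd.DataFrame(data)
        provenance = {k: g.attrs[k] for k in g.attrs if k != "flux_labels"}
        labels = tuple(str(x) for x in g.attrs["flux_labels"])
    return AggregatedPool(
        criteria=frames["criteria"],
        per_flux=frames["per_flux"],
        flux_labels=labels,
        provenance=provenance,
    )


def ternary_slice(
    aggregated: AggregatedPool,
    grid: MixtureGrid,
    vary_substrate: str,
    fixed: dict[str, tuple[float, ...]],
    n_act: int,
) -> pd.DataFrame:
    """Tabulate one substrate's 3-species mixture triangle.

    Holds the other substrates at ``fixed`` compositions and returns rows
    ``(a, b, c, phi_d_median, coverage, cost)`` over the varying substrate's
    simplex lattice — the data behind a ternary mixture-triangle plot.
    """
    if vary_substrate not in grid.substrates:
        raise ModelError(f"unknown substrate {vary_substrate!r}")
    si = grid.substrates.index(vary_substrate)
    if len(grid.species_labels[si]) != 3:
        raise ModelError("ternary slices need exactly 3 species on the varied substrate")
    levels = _lattice_levels(grid.step)
    crit = aggregated.criteria[aggregated.criteria["n_act"] == n_act]
    crit = crit.set_index("mixture_id")
    rows = []
    for comp in grid.compositions[si]:
        fractions = dict(fixed)
        fractions[vary_substrate] = tuple(k / levels for k in comp)
        mix = Mixture.from_dict(fractions)
        mid = grid.index_of(mix)
        entry = crit.loc[mid]
        rows.append(
            {
                "a": comp[0] / levels,
                "b": comp[1] / levels,
                "c": comp[2] / levels,
                "phi_d_median": entry["phi_d_median"],
                "coverage": entry["coverage"],
                "cost": entry["cost"],
            }
        )
    return pd.DataFrame(rows)
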
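"""Steady-state isotope labeling simulation: EMU cascade + cumomer oracle.

Given a flux constellation and a tracer mixture, this module predicts the
mass isotopomer distributions (MIDs) of the measured fragments.  Two
independent formulations are provided:

* :func:`simulate_labeling` — the production path.  The network is first
  decomposed into elementary metabolite units (EMUs): the minimal set of
  carbon-position subsets whose MIDs close under flux-weighted balances.
  Per EMU size the balances form a linear system; condensation reactions
  couple sizes through convolutions of smaller EMU MIDs.
* :func:`cumomer_simulate` — a brute-force oracle.  All ``2**n`` cumulative
  isotopomer fractions (cumomers) of every pool are balanced level by level;
  products of lower-level cumomers replace the EMU convolutions.  Cumomers
  are then converted back to isotopomer fractions (Möbius inversion) and
  marginalized to fragment MIDs.  Intended for networks with <= ~12 carbons
  per metabolite.

Both use the forward/backward flux convention ``fwd = max(net,0)+xch``,
``bwd = max(-net,0)+xch``; substrate pools are fixed boundary conditions with
isotopomer distributions mixed from the tracer catalogue.

Bit convention: in a state/cumomer index for an ``n``-carbon metabolite, bit
``n-1-k`` represents carbon ``k`` (the binary string reads carbons left to
right).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model import (
    Mixture,
    ModelError,
    NetworkModel,
    substrate_isotopomer_distribution,
)
from .stoichiometry import FluxState

__all__ = [
    "LabelingError",
    "SingularSystemError",
    "UnreachableFragmentError",
    "Direction",
    "directions",
    "EMUGraph",
    "emu_decompose",
    "MeasurementVector",
    "simulate_labeling",
    "cumomer_simulate",
    "error_sigma",
    "measurement_covariance",
    "rate_values",
]


class LabelingError(ModelError):
    """Base class for labeling-simulation failures."""


class SingularSystemError(LabelingError):
    """A level balance matrix is singular (zero-throughput pool)."""


class UnreachableFragmentError(LabelingError):
    """A measured fragment cannot be reached from any substrate pool."""


# ---------------------------------------------------------------------------
# reaction directions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Direction:
    """One flow direction of a reaction with its atom transition."""

    rxn: str
    sense: str  # "fwd" | "bwd"
    educts: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]

    def flux(self, state: FluxState) -> float:
        return state.forward(self.rxn) if self.sense == "fwd" else state.backward(self.rxn)


def directions(model: NetworkModel) -> list[Direction]:
    """Forward direction per reaction, plus backward for bidirectional ones."""
    out = []
    for rxn in model.reactions:
        out.append(Direction(rxn.id, "fwd", rxn.educts, rxn.products))
        if rxn.bidirectional:
            out.append(Direction(rxn.id, "bwd", rxn.products, rxn.educts))
    return out


# ---------------------------------------------------------------------------
# EMU decomposition
# ---------------------------------------------------------------------------

# an EMU node is (metabolite_id, frozenset of 0-based carbon positions)
Node = tuple[str, frozenset]

# a balance term: (direction, sources); weight is the direction flux, one term
# per product occurrence of the node's metabolite
Term = tuple[Direction, tuple[Node, ...]]


@dataclass(frozen=True)
class EMUGraph:
    """Minimal EMU dependency graph reaching all measured fragments."""

    nodes_by_size: dict[int, tuple[Node, ...]]   # unknown (non-input) nodes
    terms: dict[Node, tuple[Term, ...]]
    input_nodes: tuple[Node, ...]
    measured: tuple[tuple[str, Node], ...]       # (group id, fragment node)

    @property
    def sizes(self) -> list[int]:
        return sorted(self.nodes_by_size)

    @property
    def n_nodes(self) -> int:
        return sum(len(v) for v in self.nodes_by_size.values())


def _node_terms(model: NetworkModel, dirs: list[Direction], node: Node) -> list[Term]:
    met, positions = node
    terms: list[Term] = []
    for d in dirs:
        for pmet, patoms in d.products:
            if pmet != met:
                continue
            needed = {patoms[p] for p in positions}
            srcs = []
            for emet, eatoms in d.educts:
                spos = frozenset(i for i, a in enumerate(eatoms) if a in needed)
                if spos:
                    srcs.append((emet, spos))
            srcs.sort(key=lambda s: (s[0], tuple(sorted(s[1]))))
            terms.append((d, tuple(srcs)))
    return terms


def emu_decompose(model: NetworkModel, measurement_spec=None) -> EMUGraph:
    """Build the minimal EMU graph reaching all measured fragments.

    Deterministic node ordering (breadth-first from the measured fragments,
    ties by metabolite id and positions).  Raises
    :class:`UnreachableFragmentError` when a fragment's balances never ground
    out in a substrate pool.
    """
    spec = measurement_spec if measurement_spec is not None else model.measurement
    dirs = directions(model)
    roles = {m.id: m.role for m in model.metabolites}

    measured = []
    queue: list[Node] = []
    for grp in spec.groups:
        node: Node = (grp.metabolite, frozenset(grp.positions))
        measured.append((grp.id, node))
        queue.append(node)

    terms: dict[Node, tuple[Term, ...]] = {}
    input_nodes: list[Node] = []
    seen: set[Node] = set()
    while queue:
        node = queue.pop(0)
        if node in seen:
            continue
        seen.add(node)
        met = node[0]
        if met not in roles:
            raise ModelError(f"measured fragment on unknown metabolite {met!r}")
        if roles[met] == "input":
            input_nodes.append(node)
            continue
        node_terms = _node_terms(model, dirs, node)
        if not node_terms:
            raise UnreachableFragmentError(
                f"metabolite {met!r} has no producing reaction; fragment "
                "unreachable from any substrate"
            )
        terms[node] = tuple(node_terms)
        for _, srcs in node_terms:
            queue.extend(srcs)

    # ground check: every unknown node must (transitively) receive label from
    # a substrate through at least one term chain
    grounded: set[Node] = set(input_nodes)
    changed = True
    while changed:
        changed = False
        for node, node_terms in terms.items():
            if node in grounded:
                continue
            for _, srcs in node_terms:
                if all(s in grounded for s in srcs):
                    grounded.add(node)
                    changed = True
                    break
    ungrounded = [n for n in terms if n not in grounded]
    if ungrounded:
        mets = sorted({n[0] for n in ungrounded})
        raise UnreachableFragmentError(
            f"fragments on {mets} are unreachable from any substrate pool"
        )

    nodes_by_size: dict[int, list[Node]] = {}
    for node in sorted(terms, key=lambda n: (len(n[1]), n[0], tuple(sorted(n[1])))):
        nodes_by_size.setdefault(len(node[1]), []).append(node)
    return EMUGraph(
        nodes_by_size={k: tuple(v) for k, v in nodes_by_size.items()},
        terms=terms,
        input_nodes=tuple(sorted(input_nodes, key=lambda n: (n[0], tuple(sorted(n[1]))))),
        measured=tuple(measured),
    )


# ---------------------------------------------------------------------------
# measurement vector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementVector:
    """Simulated labeling values, ordered per group and mass shift."""

    values: np.ndarray
    index: tuple[tuple[str, int], ...]  # (group id, mass shift)

    def group_values(self, group_id: str) -> np.ndarray:
        mask = [i for i, (g, _) in enumerate(self.index) if g == group_id]
        return self.values[mask]

    def __len__(self) -> int:
        return len(self.values)


def _emu_mid_from_idist(dist: np.ndarray, positions: frozenset, n: int) -> np.ndarray:
    """Marginalize a 2**n isotopomer distribution to an EMU MID."""
    k = len(positions)
    mid = np.zeros(k + 1)
    pos_bits = [n - 1 - p for p in sorted(positions)]
    for state, p in enumerate(dist):
        if p == 0.0:
            continue
        weight = sum(state >> b & 1 for b in pos_bits)
        mid[weight] += p
    return mid


def _input_distributions(
    model: NetworkModel, mixture: Mixture, catalogue, background: float
) -> dict[str, np.ndarray]:
    fractions = mixture.as_dict()
    dists = {}
    for met in model.substrates:
        if met.id not in catalogue:
            raise ModelError(f"no tracer species declared for substrate {met.id!r}")
        if met.id not in fractions:
            raise ModelError(f"mixture missing substrate {met.id!r}")
        dists[met.id] = substrate_isotopomer_distribution(
            catalogue[met.id], fractions[met.id], background
        )
    return dists


def _direction_fluxes(model: NetworkModel, state: FluxState) -> dict[tuple[str, str], float]:
    out = {}
    for rxn in model.reactions:
        out[(rxn.id, "fwd")] = state.forward(rxn.id)
        if rxn.bidirectional:
            out[(rxn.id, "bwd")] = state.backward(rxn.id)
    return out


_COND_LIMIT = 1e12
_DENSE_LIMIT = 200  # EMUs per level before switching to a sparse solve


def _solve_level(A: np.ndarray, R: np.ndarray, nodes) -> np.ndarray:
    """Solve one level system, reporting the offending pool when singular."""
    n = A.shape[0]
    if n == 0:
        return R
    use_sparse = n > _DENSE_LIMIT
    if not use_sparse:
        try:
            cond = np.linalg.cond(A)
        except np.linalg.LinAlgError:  # pragma: no cover
            cond = np.inf
        if not np.isfinite(cond) or cond > _COND_LIMIT:
            diag = np.abs(np.diag(A))
            worst = nodes[int(np.argmin(diag))]
            raise SingularSystemError(
                f"labeling balance singular (condition {cond:.3g}); "
                f"pool {worst[0]!r} has (near) zero throughput"
            )
        return scipy.linalg.solve(A, R)
    from scipy.sparse import csc_matrix
    from scipy.sparse.linalg import splu

    lu = splu(csc_matrix(A))
    return lu.solve(R)


def emu_level_systems(
    model: NetworkModel,
    graph: EMUGraph,
    state: FluxState,
    mixture: Mixture,
    catalogue,
    background: float = 0.0,
):
    """Solve the EMU cascade; return MIDs for every node in the graph.

    Yields the dict node -> MID used by :func:`simulate_labeling` and the
    Jacobian machinery (which re-runs the cascade with derivative terms).
    """
    mixture.validate()
    idists = _input_distributions(model, mixture, catalogue, background)
    sizes_n = {m.id: m.n_carbons for m in model.metabolites}
    phi = _direction_fluxes(model, state)

    mids: dict[Node, np.ndarray] = {}
    for node in graph.input_nodes:
        met, positions = node
        mids[node] = _emu_mid_from_idist(idists[met], positions, sizes_n[met])

    for size in graph.sizes:
        nodes = graph.nodes_by_size[size]
        idx = {node: i for i, node in enumerate(nodes)}
        n = len(nodes)
        A = np.zeros((n, n))
        R = np.zeros((n, size + 1))
        for node in nodes:
            i = idx[node]
            for d, srcs in graph.terms[node]:
                w = phi[(d.rxn, d.sense)]
                A[i, i] += w
                if len(srcs) == 1 and srcs[0] in idx:
                    A[i, idx[srcs[0]]] -= w
                else:
                    known = mids[srcs[0]]
                    for s in srcs[1:]:
                        known = np.convolve(known, mids[s])
                    R[i] += w * known
        X = _solve_level(A, R, nodes)
        for node in nodes:
            mids[node] = X[idx[node]]
    return mids


def simulate_labeling(
    model: NetworkModel,
    graph: EMUGraph,
    state: FluxState,
    mixture: Mixture,
    catalogue,
    background: float = 0.0,
) -> MeasurementVector:
    """Noise-free steady-state MIDs of all measured fragments (EMU cascade)."""
    mids = emu_level_systems(model, graph, state, mixture, catalogue, background)
    return _assemble_measurements(model, graph, mids)


def _assemble_measurements(model, graph, mids) -> MeasurementVector:
    groups = {g.id: g for g in model.measurement.groups}
    values = []
    index = []
    for gid, node in graph.measured:
        mid = mids[node]
        for shift in groups[gid].shifts:
            values.append(mid[shift])
            index.append((gid, shift))
    return MeasurementVector(np.array(values), tuple(index))


# ---------------------------------------------------------------------------
# cumomer brute-force oracle
# ---------------------------------------------------------------------------

def cumomer_simulate(
    model: NetworkModel,
    state: FluxState,
    mixture: Mixture,
    catalogue,
    background: float = 0.0,
) -> MeasurementVector:
    """Measurement vector via the full cumomer cascade (independent oracle).

    Enumerates every cumulative isotopomer fraction of every non-substrate
    pool — exponential in carbons per metabolite, so only suitable for small
    networks — and must agree with :func:`simulate_labeling` to ~1e-8.
    """
    mixture.validate()
    idists = _input_distributions(model, mixture, catalogue, background)
    n_carbons = {m.id: m.n_carbons for m in model.metabolites}
    roles = {m.id: m.role for m in model.metabolites}
    dirs = directions(model)
    phi = _direction_fluxes(model, state)

    # input cumomers from isotopomer distributions
    cum: dict[tuple[str, int], float] = {}
    for met in model.substrates:
        n = n_carbons[met.id]
        dist = idists[met.id]
        for mask in range(2**n):
            cum[(met.id, mask)] = float(
                sum(p for s, p in enumerate(dist) if s & mask == mask)
            )

    unknown_mets = [m.id for m in model.metabolites if m.role != "input"]
    for met in unknown_mets:
        cum[(met, 0)] = 1.0  # 0-cumomer normalization

    max_level = max((n_carbons[m] for m in unknown_mets), default=0)
    for level in range(1, max_level + 1):
        nodes = [
            (met, mask)
            for met in unknown_mets
            for mask in range(2 ** n_carbons[met])
            if bin(mask).count("1") == level
        ]
        idx = {node: i for i, node in enumerate(nodes)}
        n = len(nodes)
        A = np.zeros((n, n))
        R = np.zeros(n)
        for met, mask in nodes:
            i = idx[(met, mask)]
            nc = n_carbons[met]
            positions = [k for k in range(nc) if mask >> (nc - 1 - k) & 1]
            produced = False
            for d in dirs:
                for pmet, patoms in d.products:
                    if pmet != met:
                        continue
                    produced = True
                    w = phi[(d.rxn, d.sense)]
                    A[i, i] += w
                    needed = {patoms[p] for p in positions}
                    factors = []
                    for emet, eatoms in d.educts:
                        sub = 0
                        ne = len(eatoms)
                        for k, a in enumerate(eatoms):
                            if a in needed:
                                sub |= 1 << (ne - 1 - k)
                        if sub:
                            factors.append((emet, sub))
                    if (
                        len(factors) == 1
                        and roles[factors[0][0]] != "input"
                        and bin(factors[0][1]).count("1") == level
                    ):
                        A[i, idx[factors[0]]] -= w
                    else:
                        prod = w
                        for f in factors:
                            prod *= cum[f]
                        R[i] += prod
            if not produced:
                raise UnreachableFragmentError(
                    f"pool {met!r} has no producing reaction"
                )
        if n:
            try:
                cond = np.linalg.cond(A)
            except np.linalg.LinAlgError:  # pragma: no cover
                cond = np.inf
            if not np.isfinite(cond) or cond > _COND_LIMIT:
                worst = nodes[int(np.argmin(np.abs(np.diag(A))))]
                raise SingularSystemError(
                    f"cumomer balance singular at level {level}; pool "
                    f"{worst[0]!r} has (near) zero throughput"
                )
            X = scipy.linalg.solve(A, R)
            for node in nodes:
                cum[node] = float(X[idx[node]])

    # cumomers -> isotopomer fractions (Moebius inversion), then fragment MIDs
    values = []
    index = []
    for grp in model.measurement.groups:
        met = grp.metabolite
        n = n_carbons[met]
        c = np.array([cum[(met, mask)] for mask in range(2**n)])
        p = c.copy()
        for bit in range(n):
            b = 1 << bit
            lower = np.array([(mask & b) == 0 for mask in range(2**n)])
            for mask in range(2**n):
                if lower[mask]:
                    p[mask] -= p[mask | b]
        mid = _emu_mid_from_idist(p, frozenset(grp.positions), n)
        for shift in grp.shifts:
            values.append(mid[shift])
            index.append((grp.id, shift))
    return MeasurementVector(np.array(values), tuple(index))


# ---------------------------------------------------------------------------
# error model / covariance
# ---------------------------------------------------------------------------

def error_sigma(y_value, slope: float = 4.120e-2, intercept: float = 6.655e-3):
    """Affine GC-MS standard-deviation model sigma(y) = slope*y + intercept."""
    return slope * np.asarray(y_value, dtype=float) + intercept


def rate_values(model: NetworkModel, state: FluxState) -> np.ndarray:
    """Simulated values of the measured extracellular rates (net fluxes)."""
    return np.array([state.net_of(r.flux) for r in model.measurement.rates])


def measurement_covariance(
    model: NetworkModel, labeling: MeasurementVector
) -> np.ndarray:
    """Diagonal of the measurement covariance (labeling rows then rates)."""
    err = model.measurement.error_model
    sig_lab = err.sigma(labeling.values)
    sig_rate = np.array([r.stddev for r in model.measurement.rates])
    diag = np.concatenate([sig_lab, sig_rate]) ** 2
    if (diag <= 0).any():
        raise ModelError("measurement covariance must be strictly positive")
    return diag
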
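"""First-order sensitivities of the labeling system: d y / d v.

The Fisher information of a tracer experiment is built from the Jacobian of
the measurement vector with respect to the *free* flux coordinates (free net
fluxes, then exchange coordinates); the constant affine map from free
coordinates to the full flux vector is composed in, so columns are labelled
by free-flux ids.

The analytic path differentiates the EMU cascade implicitly: per size level
with balance ``A(v) X = R(v, lower levels)``,

    A dX/dv_k = dR/dv_k - (dA/dv_k) X,

cascading the level solutions.  Rate-measurement rows are the constant linear
map from free coordinates to the measured net fluxes.  A central
finite-difference oracle (:func:`jacobian_fd`) provides the independent
cross-check.

At ``net = 0`` the forward/backward split of a bidirectional reaction is not
smooth; the right derivative is used and the evaluation is flagged when a
bidirectional net flux sits within 1e-9 of the kink.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .labeling import (
    EMUGraph,
    MeasurementVector,
    SingularSystemError,
    _assemble_measurements,
    _COND_LIMIT,
    _direction_fluxes,
    _emu_mid_from_idist,
    _input_distributions,
    rate_values,
    simulate_labeling,
)
from .model import Mixture, NetworkModel
from .stoichiometry import FluxState, Polytope

__all__ = ["JacobianRecord", "jacobian", "jacobian_fd"]

_KINK_TOL = 1e-9


@dataclass(frozen=True)
class JacobianRecord:
    """d y / d z at one flux state: rows = measurements, cols = free fluxes."""

    J: np.ndarray
    row_index: tuple                # (group id, shift) rows then ("rate", flux)
    column_labels: tuple[str, ...]  # free net ids then exchange ids
    y: np.ndarray                   # measurement values (labeling then rates)
    labeling: MeasurementVector
    at_kink: tuple[str, ...] = ()   # bidirectional reactions with net ~ 0


def _direction_flux_gradients(model: NetworkModel, state: FluxState):
    """d phi / d z for every direction, plus the kink diagnostics."""
    basis = state.basis
    p = basis.n_free
    n_net = len(basis.free_net_ids)
    xch_pos = {r: n_net + k for k, r in enumerate(basis.free_xch_ids)}
    grads: dict[tuple[str, str], np.ndarray] = {}
    kinks = []
    for j, rxn in enumerate(model.reactions):
        dnet = np.zeros(p)
        dnet[:n_net] = basis.K[j]
        net = state.net_of(rxn.id)
        fwd = np.where(net >= 0.0, 1.0, 0.0) * dnet
        if rxn.bidirectional:
            e_x = np.zeros(p)
            e_x[xch_pos[rxn.id]] = 1.0
            grads[(rxn.id, "fwd")] = fwd + e_x
            grads[(rxn.id, "bwd")] = np.where(net < 0.0, -1.0, 0.0) * dnet + e_x
            if abs(net) < _KINK_TOL and np.any(dnet != 0.0):
                kinks.append(rxn.id)
        else:
            grads[(rxn.id, "fwd")] = fwd
    return grads, tuple(kinks)


def jacobian(
    model: NetworkModel,
    graph: EMUGraph,
    state: FluxState,
    mixture: Mixture,
    catalogue,
    background: float = 0.0,
) -> JacobianRecord:
    """Analytic Jacobian of (labeling measurements, measured rates) w.r.t. z."""
    mixture.validate()
    basis = state.basis
    p = basis.n_free
    idists = _input_distributions(model, mixture, catalogue, background)
    n_carbons = {m.id: m.n_carbons for m in model.metabolites}
    phi = _direction_fluxes(model, state)
    dphi, kinks = _direction_flux_gradients(model, state)

    mids: dict = {}
    grads: dict = {}
    for node in graph.input_nodes:
        met, positions = node
        mids[node] = _emu_mid_from_idist(idists[met], positions, n_carbons[met])
        grads[node] = np.zeros((p, len(positions) + 1))

    for size in graph.sizes:
        nodes = graph.nodes_by_size[size]
        idx = {node: i for i, node in enumerate(nodes)}
        n = len(nodes)
        A = np.zeros((n, n))
        R = np.zeros((n, size + 1))
        dA = np.zeros((p, n, n))
        dR = np.zeros((p, n, size + 1))
        for node in nodes:
            i = idx[node]
            for d, srcs in graph.terms[node]:
                key = (d.rxn, d.sense)
                w = phi[key]
                dw = dphi[key]
                A[i, i] += w
                dA[:, i, i] += dw
                if len(srcs) == 1 and srcs[0] in idx:
                    j = idx[srcs[0]]
                    A[i, j] -= w
                    dA[:, i, j] -= dw
                else:
                    known = mids[srcs[0]]
                    for s in srcs[1:]:
                        known = np.convolve(known, mids[s])
                    dknown = np.zeros((p, size + 1))
                    for si, s in enumerate(srcs):
                        rest = None
                        for sj, t in enumerate(srcs):
                            if sj == si:
                                continue
                            rest = mids[t] if rest is None else np.convolve(rest, mids[t])
                        for m in range(p):
                            contrib = grads[s][m]
                            if rest is not None:
                                contrib = np.convolve(contrib, rest)
                            dknown[m] += contrib
                    R[i] += w * known
                    dR[:, i] += dw[:, None] * known + w * dknown
        if n:
            cond = np.linalg.cond(A)
            if not np.isfinite(cond) or cond > _COND_LIMIT:
                worst = nodes[int(np.argmin(np.abs(np.diag(A))))]
                raise SingularSystemError(
                    f"labeling balance singular at size {size}; pool "
                    f"{worst[0]!r} has (near) zero throughput"
                )
            lu = scipy.linalg.lu_factor(A)
            X = scipy.linalg.lu_solve(lu, R)
            for m in range(p):
                dX = scipy.linalg.lu_solve(lu, dR[m] - dA[m] @ X)
                for node in nodes:
                    grads.setdefault(node, np.zeros((p, size + 1)))
                    grads[node][m] = dX[idx[node]]
            for node in nodes:
                mids[node] = X[idx[node]]

    labeling = _assemble_measurements(model, graph, mids)
    groups = {g.id: g for g in model.measurement.groups}
    rows = []
    row_index = []
    for gid, node in graph.measured:
        g = grads[node]
        for shift in groups[gid].shifts:
            rows.append(g[:, shift])
            row_index.append((gid, shift))
    for rate in model.measurement.rates:
        rows.append(basis.net_row(rate.flux))
        row_index.append(("rate", rate.flux))
    y = np.concatenate([labeling.values, rate_values(model, state)])
    return JacobianRecord(
        J=np.array(rows),
        row_index=tuple(row_index),
        column_labels=basis.free_ids,
        y=y,
        labeling=labeling,
        at_kink=kinks,
    )


def jacobian_fd(
    model: NetworkModel,
    graph: EMUGraph,
    state: FluxState,
    mixture: Mixture,
    catalogue,
    h: float = 1e-6,
    background: float = 0.0,
    polytope: Polytope | None = None,
) -> JacobianRecord:
    """Central finite-difference Jacobian (the oracle for :func:`jacobian`).

    Per coordinate the step is ``h * max(1, |z_k|)``; when a polytope is
    supplied the step is halved until both perturbed points are feasible
    (raising after 40 halvings).
    """
    basis = state.basis
    p = basis.n_free
    z = np.asarray(state.z, dtype=float)

    def evaluate(zz):
        st = basis.flux_state(zz)
        lab = simulate_labeling(model, graph, st, mixture, catalogue, background)
        return np.concatenate([lab.values, rate_values(model, st)])

    y0 = evaluate(z)
    cols = []
    for k in range(p):
        step = h * max(1.0, abs(z[k]))
        e = np.zeros(p)
        e[k] = 1.0
        if polytope is not None:
            tries = 0
            while not (
                polytope.contains(z + step * e) and polytope.contains(z - step * e)
            ):
                step *= 0.5
                tries += 1
                if tries > 40:
                    raise ValueError(
                        f"cannot find a feasible central-difference step for "
                        f"coordinate {basis.free_ids[k]!r}"
                    )
        cols.append((evaluate(z + step * e) - evaluate(z - step * e)) / (2 * step))
    J = np.array(cols).T
    labeling = simulate_labeling(model, graph, state, mixture, catalogue, background)
    row_index = tuple(labeling.index) + tuple(
        ("rate", r.flux) for r in model.measurement.rates
    )
    return JacobianRecord(
        J=J,
        row_index=row_index,
        column_labels=basis.free_ids,
        y=y0,
        labeling=labeling,
    )
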
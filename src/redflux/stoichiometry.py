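"""Stoichiometric system, free fluxes, and the feasible flux polytope.

At metabolic steady state the net flux vector obeys ``S v = 0`` together with
linear constraints ``C v <= c`` and box bounds; these define a convex polytope
of feasible flux states.  The net fluxes are parametrized by a set of *free*
fluxes (one coordinate per nullspace dimension of the equality system), and
each bidirectional reaction contributes one additional nonnegative *exchange*
coordinate.  The forward/backward convention is

    fwd = max(net, 0) + xch,      bwd = max(-net, 0) + xch.

Free net fluxes are selected deterministically by column-pivoted QR on the
equality system: pivot columns become dependent fluxes, the remaining reaction
fluxes (in declaration order) are the free coordinates.  Fixed measured rates
(the normalization flux and user equalities) are folded into the particular
solution, so they never appear as free coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.optimize import linprog

from .model import ModelError, NetworkModel

__all__ = [
    "InfeasibleError",
    "DegeneratePolytopeError",
    "build_stoichiometry",
    "FreeFluxBasis",
    "free_flux_basis",
    "Polytope",
    "build_polytope",
    "FluxState",
]

_RANK_TOL = 1e-9


class InfeasibleError(ModelError):
    """Constraints admit no flux solution."""


class DegeneratePolytopeError(ModelError):
    """The polytope has no strictly interior point (lower-dimensional).

    Convert near-equality inequality pairs into explicit equality constraints
    so they are eliminated into the particular solution.
    """


def build_stoichiometry(model: NetworkModel) -> tuple[np.ndarray, list[str]]:
    """Stoichiometric matrix over balanced metabolites x reactions (net fluxes).

    Returns ``(S, balanced_ids)`` with one signed row per balanced pool; models
    without balanced pools yield a ``0 x n`` matrix (all fluxes free).
    """
    balanced = [m.id for m in model.balanced_metabolites]
    index = {mid: i for i, mid in enumerate(balanced)}
    S = np.zeros((len(balanced), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.stoichiometry().items():
            if met in index:
                S[index[met], j] += coeff
    return S, balanced


@dataclass(frozen=True)
class FreeFluxBasis:
    """Affine parametrization ``v_net = v0 + K z_net`` plus exchange coordinates.

    ``free_net_ids``/``free_xch_ids`` name the free coordinates; ``z`` vectors
    passed around the package are the concatenation (net block first).
    """

    reaction_ids: tuple[str, ...]
    free_net_ids: tuple[str, ...]
    free_xch_ids: tuple[str, ...]
    v0: np.ndarray          # particular net solution, len n_reactions
    K: np.ndarray           # nullspace map, n_reactions x n_free_net

    @property
    def n_free(self) -> int:
        return len(self.free_net_ids) + len(self.free_xch_ids)

    @property
    def free_ids(self) -> tuple[str, ...]:
        return self.free_net_ids + tuple(f"{r}.xch" for r in self.free_xch_ids)

    def net_fluxes(self, z_net) -> np.ndarray:
        return self.v0 + self.K @ np.asarray(z_net, dtype=float)

    def split(self, z) -> tuple[np.ndarray, np.ndarray]:
        z = np.asarray(z, dtype=float)
        k = len(self.free_net_ids)
        return z[:k], z[k:]

    def flux_state(self, z) -> "FluxState":
        z_net, z_xch = self.split(z)
        if len(z_xch) != len(self.free_xch_ids):
            raise ModelError("free coordinate vector has wrong length")
        net = self.net_fluxes(z_net)
        xch = dict(zip(self.free_xch_ids, z_xch))
        return FluxState(basis=self, z=np.asarray(z, dtype=float), net=net, xch=xch)

    def net_row(self, flux_id: str) -> np.ndarray:
        """Gradient of a reaction's net flux w.r.t. the full z vector."""
        j = self.reaction_ids.index(flux_id)
        row = np.zeros(self.n_free)
        row[: len(self.free_net_ids)] = self.K[j]
        return row


@dataclass(frozen=True)
class FluxState:
    """A full flux constellation together with its free coordinates."""

    basis: FreeFluxBasis
    z: np.ndarray
    net: np.ndarray                 # per reaction, declaration order
    xch: dict[str, float]           # per bidirectional reaction

    def net_of(self, flux_id: str) -> float:
        return float(self.net[self.basis.reaction_ids.index(flux_id)])

    def xch_of(self, flux_id: str) -> float:
        return float(self.xch.get(flux_id, 0.0))

    def forward(self, flux_id: str) -> float:
        return max(self.net_of(flux_id), 0.0) + self.xch_of(flux_id)

    def backward(self, flux_id: str) -> float:
        return max(-self.net_of(flux_id), 0.0) + self.xch_of(flux_id)


def _equality_system(
    model: NetworkModel, S: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Stack S v = 0 with fixed rates and user net equalities."""
    n = len(model.reactions)
    index = {r: j for j, r in enumerate(model.reaction_ids)}
    rows = [S]
    rhs = [np.zeros(S.shape[0])]
    extra = []
    extra_rhs = []
    if model.normalization.fixed:
        row = np.zeros(n)
        row[index[model.normalization.flux]] = 1.0
        extra.append(row)
        extra_rhs.append(model.normalization.value)
    for con in model.net_constraints:
        if con.relation != "eq":
            continue
        row = np.zeros(n)
        for flux, c in con.coeffs:
            row[index[flux]] += c
        extra.append(row)
        extra_rhs.append(con.rhs)
    if extra:
        rows.append(np.array(extra))
        rhs.append(np.array(extra_rhs))
    return np.vstack(rows), np.concatenate(rhs)


def free_flux_basis(S: np.ndarray, model: NetworkModel) -> FreeFluxBasis:
    """Deterministic free-flux selection and affine net-flux parametrization.

    Column-pivoted QR of the equality system picks the dependent fluxes; the
    remaining columns — in reaction declaration order — are the free net
    fluxes.  Each bidirectional reaction contributes one free exchange
    coordinate.  Raises :class:`InfeasibleError` when fixed rates contradict
    the stoichiometry.
    """
    E, e = _equality_system(model, S)
    n = E.shape[1]
    if E.shape[0] == 0:
        rank = 0
        pivots: list[int] = []
    else:
        _, R, perm = scipy.linalg.qr(E, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = max(E.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
        rank = int((diag > max(tol, _RANK_TOL * (diag[0] if diag.size else 1.0))).sum())
        pivots = sorted(perm[:rank])
    free_cols = [j for j in range(n) if j not in set(pivots)]

    E_B = E[:, pivots] if pivots else np.zeros((E.shape[0], 0))
    E_F = E[:, free_cols] if free_cols else np.zeros((E.shape[0], 0))

    # particular solution: free coordinates at 0
    v0 = np.zeros(n)
    if pivots:
        sol, *_ = np.linalg.lstsq(E_B, e, rcond=None)
        v0[pivots] = sol
    resid = E @ v0 - e
    if np.linalg.norm(resid, ord=np.inf) > 1e-6 * max(1.0, np.abs(e).max(initial=1.0)):
        raise InfeasibleError(
            "fixed-rate/equality constraints are inconsistent with S v = 0 "
            f"(residual {np.linalg.norm(resid, np.inf):.3g})"
        )

    K = np.zeros((n, len(free_cols)))
    for k, j in enumerate(free_cols):
        K[j, k] = 1.0
    if pivots and free_cols:
        dep, *_ = np.linalg.lstsq(E_B, -E_F, rcond=None)
        K[pivots, :] = dep

    rids = tuple(model.reaction_ids)
    return FreeFluxBasis(
        reaction_ids=rids,
        free_net_ids=tuple(rids[j] for j in free_cols),
        free_xch_ids=tuple(r.id for r in model.bidirectional_reactions),
        v0=v0,
        K=K,
    )


@dataclass(frozen=True)
class Polytope:
    """Inequality system ``A z <= b`` over the free coordinates.

    Equalities have already been eliminated into the basis; ``labels`` names
    the columns (free net fluxes, then exchange coordinates).
    """

    A: np.ndarray
    b: np.ndarray
    labels: tuple[str, ...]

    @property
    def dim(self) -> int:
        return self.A.shape[1]

    def contains(self, z, tol: float = 1e-9) -> bool:
        return bool(np.all(self.A @ np.asarray(z, dtype=float) <= self.b + tol))

    def chebyshev_center(self) -> tuple[np.ndarray, float]:
        """Center and radius of the largest inscribed ball (via LP)."""
        norms = np.linalg.norm(self.A, axis=1)
        c = np.zeros(self.dim + 1)
        c[-1] = -1.0
        A_ub = np.hstack([self.A, norms[:, None]])
        res = linprog(
            c, A_ub=A_ub, b_ub=self.b, bounds=[(None, None)] * self.dim + [(0, None)],
            method="highs",
        )
        if not res.success:
            raise InfeasibleError(f"polytope is infeasible: {res.message}")
        return res.x[:-1], float(res.x[-1])

    def bounding_box(self) -> np.ndarray:
        """Per-coordinate [min, max] via linear programming (dim x 2)."""
        box = np.zeros((self.dim, 2))
        for k in range(self.dim):
            for col, sign in ((0, 1.0), (1, -1.0)):
                c = np.zeros(self.dim)
                c[k] = sign
                res = linprog(
                    c, A_ub=self.A, b_ub=self.b,
                    bounds=[(None, None)] * self.dim, method="highs",
                )
                if not res.success:
                    raise InfeasibleError(f"polytope is infeasible: {res.message}")
                box[k, col] = res.x[k]
        return box

    def to_csv(self, path) -> None:
        """Export (A | b) rows for external samplers."""
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(list(self.labels) + ["b"])
            for row, rhs in zip(self.A, self.b):
                writer.writerow(list(row) + [rhs])


def build_polytope(basis: FreeFluxBasis, model: NetworkModel) -> Polytope:
    """Express all bounds and inequalities in free coordinates.

    Net bounds apply per reaction (unidirectional reactions are additionally
    floored at zero), exchange coordinates live on their natural bounded
    scale, and user ``C v <= c`` rows are mapped through the affine basis.
    Raises :class:`InfeasibleError` for contradictory constraints and
    :class:`DegeneratePolytopeError` when no strictly interior point exists.
    """
    n_net = len(basis.free_net_ids)
    n_xch = len(basis.free_xch_ids)
    dim = n_net + n_xch
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    lo, hi = model.net_bounds
    bidir = {r.id for r in model.bidirectional_reactions}
    for j, rid in enumerate(basis.reaction_ids):
        row = np.zeros(dim)
        row[:n_net] = basis.K[j]
        const = basis.v0[j]
        lo_j = lo if rid in bidir else max(lo, 0.0)
        if np.allclose(row, 0.0):
            if not (lo_j - 1e-9 <= const <= hi + 1e-9):
                raise InfeasibleError(
                    f"fixed net flux {rid} = {const:g} violates bounds "
                    f"[{lo_j:g}, {hi:g}]"
                )
            continue
        rows.append(row.copy())
        rhs.append(hi - const)
        rows.append(-row)
        rhs.append(const - lo_j)

    index = {r: j for j, r in enumerate(basis.reaction_ids)}
    for con in model.net_constraints:
        if con.relation == "eq":
            continue  # folded into the basis
        c = con.as_le()
        row = np.zeros(dim)
        const = 0.0
        for flux, coeff in c.coeffs:
            j = index[flux]
            row[:n_net] += coeff * basis.K[j]
            const += coeff * basis.v0[j]
        if np.allclose(row, 0.0):
            if const > c.rhs + 1e-9:
                raise InfeasibleError(f"constant constraint violated: {c}")
            continue
        rows.append(row)
        rhs.append(c.rhs - const)

    xlo, xhi = model.xch_bounds
    xlo = max(xlo, 0.0)
    for k, rid in enumerate(basis.free_xch_ids):
        row = np.zeros(dim)
        row[n_net + k] = 1.0
        rows.append(row.copy())
        rhs.append(xhi)
        rows.append(-row)
        rhs.append(-xlo)
    xch_index = {r: k for k, r in enumerate(basis.free_xch_ids)}
    for con in model.xch_constraints:
        if con.relation == "eq":
            raise ModelError("equality constraints on exchange fluxes unsupported")
        c = con.as_le()
        row = np.zeros(dim)
        for flux, coeff in c.coeffs:
            row[n_net + xch_index[flux]] += coeff
        rows.append(row)
        rhs.append(c.rhs)

    poly = Polytope(
        A=np.array(rows).reshape(len(rows), dim),
        b=np.array(rhs),
        labels=basis.free_ids,
    )
    _, radius = poly.chebyshev_center()
    if radius <= 1e-9:
        raise DegeneratePolytopeError(
            f"polytope has no interior (inscribed radius {radius:.3g}); "
            "convert near-equalities to explicit equality constraints"
        )
    return poly
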
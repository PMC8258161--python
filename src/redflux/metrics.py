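"""Design metrics: Fisher information, active fluxes, D-criterion, cost.

For a candidate tracer mixture evaluated at one flux constellation, the
expected information is ``FIM = J' inv(Sigma) J`` and the approximate flux
covariance its inverse.  The FIM of a labeling experiment is routinely rank
deficient, so statistically non-identifiable free fluxes are removed (fixed
to their reference value) until singular-value and condition thresholds are
met; the surviving *active* fluxes (size ``n_act``) carry the design.

The normalized D-criterion compares a candidate to a reference mixture over
the same active set,

    Phi_D = (det(Cov_ref) / det(Cov_cand)) ** (1 / (2 n_act)),

so 1 means "as good as the reference", read as an average standard-deviation
ratio (exponent configurable to ``1/n_act``).  Tracer cost is the
price-weighted mixture composition times the absolute substrate amounts a
chemostat run requires.

Removal rule (greedy): while thresholds are violated, drop the flux with the
largest absolute component in the singular vector of the smallest singular
value (ties by declaration order).  For small problems an exhaustive subset
search is available and doubles as the oracle for the greedy heuristic; among
admissible sets of equal size the one with minimal det(Cov) (configurable:
trace) is preferred.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .model import ModelError, TracerSpecies

__all__ = [
    "IdentifiabilityThresholds",
    "FisherInformation",
    "ActiveFluxSet",
    "fisher_information",
    "select_active_fluxes",
    "greedy_elimination_path",
    "exhaustive_best_subset",
    "covariance",
    "d_criterion",
    "tracer_cost",
    "substrate_amounts",
]

_EXHAUSTIVE_LIMIT = 12


@dataclass(frozen=True)
class IdentifiabilityThresholds:
    """Invertibility thresholds for the (restricted) FIM.

    ``min_sv_rel`` bounds the smallest singular value relative to the spectral
    norm of the full FIM; ``max_condition`` bounds the condition number of the
    restricted FIM.  Both are recorded in the aggregated pool.
    """

    min_sv_rel: float = 1e-9
    max_condition: float = 1e10

    def admissible(self, sub: np.ndarray, fim_norm: float) -> bool:
        if sub.size == 0:
            return False
        svals = np.linalg.svd(sub, compute_uv=False)
        if svals[-1] < self.min_sv_rel * fim_norm:
            return False
        if svals[-1] <= 0 or svals[0] / svals[-1] > self.max_condition:
            return False
        return True


@dataclass(frozen=True)
class FisherInformation:
    matrix: np.ndarray
    labels: tuple[str, ...]
    sample_id: int | None = None
    mixture_id: int | None = None

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.matrix, 2))


@dataclass(frozen=True)
class ActiveFluxSet:
    """An identifiable subset of free fluxes with its covariance submatrix."""

    active: tuple[int, ...]          # indices into the FIM labels
    labels: tuple[str, ...]          # names of the active fluxes
    removed: tuple[int, ...]         # fixed fluxes (to their reference values)
    cov: np.ndarray | None           # inverse of the restricted FIM
    n_act: int
    degenerate: bool = False         # no identifiable subset exists
    condition: float = math.nan
    matches_exhaustive: bool | None = None  # set when cross-checked

    def stddevs(self) -> np.ndarray:
        if self.cov is None:
            return np.full(0, np.nan)
        return np.sqrt(np.diag(self.cov))


def fisher_information(
    J: np.ndarray, sigma_diag: np.ndarray, labels=None, **meta
) -> FisherInformation:
    """``J' inv(Sigma) J`` for a diagonal covariance, symmetrized."""
    J = np.asarray(J, dtype=float)
    sigma_diag = np.asarray(sigma_diag, dtype=float)
    if J.shape[0] != sigma_diag.shape[0]:
        raise ModelError(
            f"Jacobian has {J.shape[0]} rows but Sigma diagonal has "
            f"{sigma_diag.shape[0]} entries"
        )
    if (sigma_diag <= 0).any():
        raise ModelError("Sigma diagonal must be strictly positive")
    W = J / sigma_diag[:, None]
    fim = J.T @ W
    fim = 0.5 * (fim + fim.T)
    if labels is None:
        labels = tuple(f"v{k}" for k in range(fim.shape[0]))
    return FisherInformation(matrix=fim, labels=tuple(labels), **meta)


def _restricted(fim: np.ndarray, subset) -> np.ndarray:
    subset = list(subset)
    return fim[np.ix_(subset, subset)]


def covariance(fim_sub: np.ndarray, thresholds=None, fim_norm=None) -> np.ndarray:
    """Inverse of a restricted FIM (the approximate flux covariance)."""
    thresholds = thresholds or IdentifiabilityThresholds()
    norm = fim_norm if fim_norm is not None else float(np.linalg.norm(fim_sub, 2))
    if not thresholds.admissible(np.asarray(fim_sub, dtype=float), norm):
        raise ModelError("restricted FIM violates the identifiability thresholds")
    cov = np.linalg.inv(fim_sub)
    return 0.5 * (cov + cov.T)


def greedy_elimination_path(
    fim: FisherInformation, thresholds: IdentifiabilityThresholds | None = None
):
    """Greedy removal path: for every size, the retained subset + admissibility.

    Returns a dict ``size -> (subset tuple, admissible bool)`` covering sizes
    ``n_free .. 1``.  The subset for size ``s`` is obtained by s-times-removed
    greedy elimination from the full flux set.
    """
    thresholds = thresholds or IdentifiabilityThresholds()
    F = fim.matrix
    norm = fim.norm
    active = list(range(F.shape[0]))
    path: dict[int, tuple[tuple[int, ...], bool]] = {}
    while active:
        sub = _restricted(F, active)
        path[len(active)] = (tuple(active), thresholds.admissible(sub, norm))
        if len(active) == 1:
            break
        # remove the flux dominating the weakest singular direction
        _, svals, vt = np.linalg.svd(sub)
        weakest = vt[-1]
        k = int(np.argmax(np.abs(weakest)))
        active.pop(k)
    return path


def exhaustive_best_subset(
    fim: FisherInformation,
    n_act: int,
    thresholds: IdentifiabilityThresholds | None = None,
    objective: str = "det",
):
    """Best admissible subset of a given size by brute-force enumeration.

    Minimizes det(Cov) (equivalently maximizes det of the restricted FIM) or
    trace(Cov).  Returns ``(subset, objective value)`` or ``None`` when no
    subset of that size is admissible.  Guarded to <= 12 free fluxes.
    """
    thresholds = thresholds or IdentifiabilityThresholds()
    F = fim.matrix
    n = F.shape[0]
    if n > _EXHAUSTIVE_LIMIT:
        raise ModelError(
            f"exhaustive subset search limited to {_EXHAUSTIVE_LIMIT} fluxes"
        )
    norm = fim.norm
    best = None
    for subset in itertools.combinations(range(n), n_act):
        sub = _restricted(F, subset)
        if not thresholds.admissible(sub, norm):
            continue
        cov = np.linalg.inv(sub)
        if objective == "det":
            sign, logdet = np.linalg.slogdet(cov)
            value = logdet if sign > 0 else math.inf
        elif objective == "trace":
            value = float(np.trace(cov))
        else:
            raise ModelError(f"unknown objective {objective!r}")
        if best is None or value < best[1]:
            best = (subset, value)
    return best


def select_active_fluxes(
    fim: FisherInformation,
    n_act_target="max",
    thresholds: IdentifiabilityThresholds | None = None,
    objective: str = "det",
    method: str = "greedy",
    verify: bool = False,
) -> ActiveFluxSet:
    """Select an identifiable active flux set of the requested size.

    ``n_act_target`` is an integer or ``"max"`` (largest admissible size).  A
    fully singular FIM yields a degenerate result (``n_act = 0``), not an
    exception.  With ``method="exhaustive"`` (or ``verify=True`` on small
    problems) the subsets are enumerated and the minimal-covariance one is
    returned / cross-checked; ``matches_exhaustive`` records the outcome.
    """
    thresholds = thresholds or IdentifiabilityThresholds()
    F = fim.matrix
    n = F.shape[0]
    path = greedy_elimination_path(fim, thresholds)
    admissible_sizes = [s for s, (_, ok) in path.items() if ok]

    if n_act_target == "max":
        sizes = sorted(path, reverse=True)
    else:
        sizes = [int(n_act_target)]
        if sizes[0] < 1 or sizes[0] > n:
            raise ModelError(f"n_act target {n_act_target!r} outside 1..{n}")

    chosen = None
    matches = None
    for size in sizes:
        if method == "exhaustive" or (n_act_target == "max" and size not in path):
            best = exhaustive_best_subset(fim, size, thresholds, objective)
            if best is not None:
                chosen = best[0]
                matches = True
                break
        else:
            subset, ok = path.get(size, (None, False))
            if ok:
                chosen = subset
                break
            if method == "greedy" and n_act_target != "max":
                # the greedy path may miss an admissible subset of this size
                if n <= _EXHAUSTIVE_LIMIT:
                    best = exhaustive_best_subset(fim, size, thresholds, objective)
                    if best is not None:
                        chosen = best[0]
                        matches = True
                        break
    if chosen is None:
        return ActiveFluxSet(
            active=(), labels=(), removed=tuple(range(n)), cov=None,
            n_act=0, degenerate=True,
        )

    if verify and method != "exhaustive" and n <= _EXHAUSTIVE_LIMIT:
        # cross-check: does enumeration find a larger admissible size, or a
        # strictly better subset of the same size?
        larger = any(
            exhaustive_best_subset(fim, s, thresholds, objective) is not None
            for s in range(n, len(chosen), -1)
        )
        best = exhaustive_best_subset(fim, len(chosen), thresholds, objective)
        sub_own = _restricted(F, chosen)
        cov_own = np.linalg.inv(sub_own)
        if objective == "det":
            own = np.linalg.slogdet(cov_own)[1]
        else:
            own = float(np.trace(cov_own))
        matches = bool(
            not larger and best is not None and own <= best[1] + 1e-9
        )

    sub = _restricted(F, chosen)
    cov = np.linalg.inv(sub)
    cov = 0.5 * (cov + cov.T)
    svals = np.linalg.svd(sub, compute_uv=False)
    return ActiveFluxSet(
        active=tuple(chosen),
        labels=tuple(fim.labels[i] for i in chosen),
        removed=tuple(i for i in range(n) if i not in set(chosen)),
        cov=cov,
        n_act=len(chosen),
        degenerate=False,
        condition=float(svals[0] / svals[-1]),
        matches_exhaustive=matches,
    )


def d_criterion(
    cov_candidate: np.ndarray,
    cov_reference: np.ndarray,
    n_act: int,
    exponent: str = "half",
) -> float:
    """Normalized D-criterion over a shared active set of size ``n_act``.

    ``(det(Cov_ref)/det(Cov_cand)) ** (1/(2 n_act))`` (``exponent="half"``,
    the default, reading as an average standard-deviation ratio) or
    ``** (1/n_act)`` (``exponent="full"``).  Values above 1 mean the candidate
    beats the reference.
    """
    cov_candidate = np.asarray(cov_candidate, dtype=float)
    cov_reference = np.asarray(cov_reference, dtype=float)
    if cov_candidate.shape != (n_act, n_act) or cov_reference.shape != (n_act, n_act):
        raise ModelError("covariances must both be n_act x n_act")
    s_c, ld_c = np.linalg.slogdet(cov_candidate)
    s_r, ld_r = np.linalg.slogdet(cov_reference)
    if s_c <= 0 or s_r <= 0:
        raise ModelError("covariance determinants must be positive")
    power = 1.0 / (2.0 * n_act) if exponent == "half" else 1.0 / n_act
    return float(math.exp((ld_r - ld_c) * power))


def substrate_amounts(
    medium_concentrations: dict[str, float],
    dilution_rate: float,
    volume: float,
    residence_times: float = 5.0,
) -> dict[str, float]:
    """Grams of each substrate a chemostat labeling run consumes.

    ``concentration (g/L) * dilution rate (1/h) * volume (L) * duration (h)``
    with duration = residence_times / dilution_rate, hence the rate cancels:
    grams = concentration * volume * residence_times.
    """
    if dilution_rate <= 0:
        raise ModelError("dilution rate must be positive")
    duration = residence_times / dilution_rate
    return {
        sub: conc * dilution_rate * volume * duration
        for sub, conc in medium_concentrations.items()
    }


def tracer_cost(
    catalogue: dict[str, list[TracerSpecies]],
    mixture,
    amounts: dict[str, float],
) -> float:
    """Cost ($) of one mixture: sum of fraction * grams(substrate) * price."""
    fractions = mixture.as_dict() if hasattr(mixture, "as_dict") else dict(mixture)
    total = 0.0
    for substrate, frs in fractions.items():
        species = catalogue.get(substrate)
        if species is None:
            raise ModelError(f"no tracer species for substrate {substrate!r}")
        if len(frs) != len(species):
            raise ModelError(
                f"mixture for {substrate!r} has {len(frs)} fractions for "
                f"{len(species)} species"
            )
        grams = amounts.get(substrate)
        if grams is None:
            raise ModelError(f"missing required amount for substrate {substrate!r}")
        for fr, sp in zip(frs, species):
            total += fr * grams * sp.price
    return total
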
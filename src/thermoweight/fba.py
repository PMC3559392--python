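"""Flux balance analysis: maximize an objective subject to S·v = 0 and bounds.

The LP is solved with scipy's HiGHS backend under a fixed, deterministic
configuration recorded in the solution metadata.  Because FBA optima are
generally degenerate, an optional secondary stage minimizes total absolute
flux Σ|v| at the fixed optimum (the parsimonious-FBA convention) to select a
reproducible representative flux vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_io import StoichiometricModel

logger = logging.getLogger(__name__)

FEASIBILITY_TOL = 1e-9
SOLVER_METHOD = "highs"


class MediaError(ValueError):
    """Raised when a media specification names a non-exchange reaction."""


@dataclass
class FluxProblem:
    """An FBA instance: a model plus (possibly overridden) bounds/objective."""

    model: StoichiometricModel
    objective: np.ndarray | None = None
    lb: np.ndarray | None = None
    ub: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.objective is None:
            self.objective = self.model.objective.copy()
        if self.lb is None:
            self.lb = self.model.lb.copy()
        if self.ub is None:
            self.ub = self.model.ub.copy()
        if not np.any(self.objective):
            raise ValueError("objective has no nonzero coefficient")
        if np.any(self.lb > self.ub):
            raise ValueError("lb > ub after overrides")


@dataclass
class FluxDistribution:
    """Per-reaction flux vector and solver outcome."""

    v: np.ndarray | None
    objective_value: float | None
    solver_status: str  # optimal | infeasible | unbounded
    metadata: dict = field(default_factory=dict)

    def as_dict(self, model: StoichiometricModel) -> dict[str, float]:
        if self.v is None:
            return {}
        return dict(zip(model.reaction_ids, self.v))


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_fba(
    problem: FluxProblem, minimize_total_flux: bool = False
) -> FluxDistribution:
    """Maximize the objective over {v : S·v = 0, lb ≤ v ≤ ub}.

    With ``minimize_total_flux`` a second LP minimizes Σ|v| subject to the
    objective being held at its optimum, picking a canonical point from the
    optimal face.
    """
    model = problem.model
    n = model.n_reactions
    bounds = list(zip(problem.lb, problem.ub))
    res = linprog(
        -problem.objective,
        A_eq=model.S,
        b_eq=np.zeros(model.n_species),
        bounds=bounds,
        method=SOLVER_METHOD,
    )
    status = _STATUS.get(res.status, "failed")
    meta = {
        "solver": f"scipy.linprog/{SOLVER_METHOD}",
        "secondary_objective": "min_total_flux" if minimize_total_flux else None,
    }
    if status != "optimal":
        logger.warning("FBA did not reach optimality: %s", status)
        return FluxDistribution(None, None, status, meta)

    opt = -res.fun
    v = res.x

    if minimize_total_flux:
        # variables [v; t], minimize Σ t with t ≥ |v|, S·v = 0, c·v = opt
        S = model.S.tocsc()
        A_eq = sparse.hstack(
            [
                sparse.vstack([S, sparse.csr_matrix(problem.objective)]),
                sparse.csr_matrix((model.n_species + 1, n)),
            ]
        )
        b_eq = np.zeros(model.n_species + 1)
        b_eq[-1] = opt
        eye = sparse.eye(n)
        A_ub = sparse.vstack(
            [sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])]
        )
        b_ub = np.zeros(2 * n)
        c2 = np.concatenate([np.zeros(n), np.ones(n)])
        big = float(max(np.max(np.abs(problem.lb)), np.max(np.abs(problem.ub)), 1.0))
        bounds2 = bounds + [(0.0, big)] * n
        res2 = linprog(
            c2, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
            bounds=bounds2, method=SOLVER_METHOD,
        )
        if res2.status == 0:
            v = res2.x[:n]
        else:
            logger.warning("secondary flux-minimization LP failed; keeping primary")

    infeas = float(np.max(np.abs(model.S @ v))) if n else 0.0
    meta["steady_state_residual"] = infeas
    if infeas > 1e-6:
        logger.warning("steady-state residual %.2g above tolerance", infeas)
    logger.info("FBA optimal: objective %.6g", opt)
    return FluxDistribution(v, float(opt), "optimal", meta)


def apply_media(
    problem: FluxProblem,
    media: dict[str, tuple[float, float]],
    strict_minimal: bool = True,
) -> FluxProblem:
    """Override exchange bounds with a media specification.

    Every key must name an exchange reaction.  In strict-minimal mode all
    exchange reactions not listed are closed to uptake (lb = 0); secretion
    stays open.
    """
    model = problem.model
    r_idx = model.reaction_index()
    exchange = set(model.reactions_of_class("exchange"))
    bad = sorted(set(media) - exchange)
    if bad:
        raise MediaError(f"media lists non-exchange reactions: {bad}")

    lb, ub = problem.lb.copy(), problem.ub.copy()
    if strict_minimal:
        for rid in exchange - set(media):
            lb[r_idx[rid]] = max(lb[r_idx[rid]], 0.0)
    for rid, (lo, hi) in media.items():
        if lo > hi:
            raise MediaError(f"media bounds reversed for {rid}")
        j = r_idx[rid]
        lb[j], ub[j] = lo, hi
    return FluxProblem(model, problem.objective.copy(), lb, ub)
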
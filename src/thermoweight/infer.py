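"""Least-squares completion of unknown formation and reaction energies.

A reaction's Gibbs energy is the stoichiometry-weighted sum of its species'
formation energies, ΔG_r = Σ_i s_i·ΔGf(i).  Collecting the known formation
energies into a per-species vector P (zeros at unknown entries), the unknown
per-compound formation energies into X, and a binary transfer matrix T that
places each unknown compound's single value into all of its compartmental
species rows, the whole network satisfies

    Sᵀ·(P + T·X) = F

with F the per-reaction energy vector.  Restricting to the reactions whose F
is known *and* whose row of Sᵀ·T is nonzero (i.e. that touch at least one
unknown compound) gives the reduced, generally overdetermined system

    Q·X = b,   Q = (Sᵀ·T)|rows,   b = (F − Sᵀ·P)|rows,

solved in the least-squares sense (minimum-norm on rank deficiency).  The
solution X₀ is back-substituted through F₀ = Sᵀ·(P + T·X₀) to complete the
unknown reaction energies; known reaction energies are never overwritten and
their discrepancies |F₀ − F| are reported instead, per category:

* category 1 — reactions with unknown ΔG_r (filled from F₀, not comparable);
* category 2 — known ΔG_r touching unknown compounds (the reduced rows);
* category 3 — known ΔG_r touching no unknown compound (reproduced exactly);
* category 4 — all reactions with known ΔG_r (union of 2 and 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import lstsq

from .model_io import StoichiometricModel
from .thermo import EnergyTables, PROVENANCE_INFERRED

logger = logging.getLogger(__name__)

DEFAULT_SV_CUTOFF = 1e-10


class UnderdeterminedSystemError(ValueError):
    """No usable equations while unknown compounds remain."""


@dataclass
class InferenceProblem:
    """The reduced least-squares system and its solution diagnostics."""

    X_ids: list[str]
    P: np.ndarray
    T_mat: sparse.csc_matrix
    Q: np.ndarray
    b: np.ndarray
    usable_rows: list[str]
    X0: np.ndarray | None = None
    residuals: np.ndarray | None = None
    rank: int | None = None
    singular_values: np.ndarray | None = None
    weakly_determined: list[str] = field(default_factory=list)

    @property
    def n_unknown(self) -> int:
        return len(self.X_ids)

    def residual_norm(self) -> float:
        if self.residuals is None:
            return float("nan")
        return float(np.linalg.norm(self.residuals))


# --------------------------------------------------------------------------
# system assembly
# --------------------------------------------------------------------------

def build_formation_vector(
    model: StoichiometricModel, tables: EnergyTables
) -> np.ndarray:
    """Per-species formation-energy vector with zeros at unknown compounds."""
    return np.array(
        [
            tables.formation.get(model.species_to_compound[sid], 0.0)
            for sid in model.species_ids
        ]
    )


def build_transfer_matrix(
    model: StoichiometricModel, tables: EnergyTables
) -> tuple[sparse.csc_matrix, list[str]]:
    """Binary species × unknown-compound matrix.

    Column j holds a 1 in every species row that is a compartmental instance
    of unknown compound j; each species row has at most one 1.  Unknown
    compounds are ordered as in ``model.compound_ids`` (first appearance in
    the species list), which fixes the meaning of X₀'s coordinates.
    """
    x_ids = tables.unknown_compounds(model)
    if not x_ids:
        logger.warning("no unknown compounds: transfer matrix has zero columns")
    col_of = {c: k for k, c in enumerate(x_ids)}
    rows, cols = [], []
    for i, sid in enumerate(model.species_ids):
        k = col_of.get(model.species_to_compound[sid])
        if k is not None:
            rows.append(i)
            cols.append(k)
    T_mat = sparse.csc_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(model.n_species, len(x_ids))
    )
    return T_mat, x_ids


def build_inference_system(
    model: StoichiometricModel,
    tables: EnergyTables,
    T_mat: sparse.csc_matrix,
    X_ids: list[str],
) -> InferenceProblem:
    """Assemble the reduced system Q·X = b from reactions with known ΔG_r."""
    P = build_formation_vector(model, tables)
    St = model.S.T.tocsr()  # reactions × species
    M = (St @ T_mat).toarray()  # reactions × n_unknown
    rhs_full = np.asarray(
        [tables.reaction.get(rid, np.nan) for rid in model.reaction_ids]
    ) - St @ P

    known = np.array([rid in tables.reaction for rid in model.reaction_ids])
    touches_unknown = np.abs(M).sum(axis=1) > 0
    usable = known & touches_unknown

    if X_ids and not usable.any():
        raise UnderdeterminedSystemError(
            "no reaction with known energy touches an unknown compound; "
            f"unconstrained compounds: {X_ids}"
        )

    Q = M[usable]
    b = rhs_full[usable]
    if not (np.all(np.isfinite(Q)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite entries in the reduced system")
    usable_rows = [r for r, u in zip(model.reaction_ids, usable) if u]
    logger.info(
        "reduced system: %d equations × %d unknown compounds", *Q.shape
    )
    return InferenceProblem(
        X_ids=X_ids, P=P, T_mat=T_mat, Q=Q, b=b, usable_rows=usable_rows
    )


# --------------------------------------------------------------------------
# solving
# --------------------------------------------------------------------------

def solve_least_squares(
    problem: InferenceProblem, sv_cutoff: float = DEFAULT_SV_CUTOFF
) -> InferenceProblem:
    """Solve Q·X ≈ b by SVD least squares (minimum-norm on rank deficiency).

    Compounds with a significant component in the null space of Q — whose
    inferred value is therefore not unique — are flagged weakly determined.
    """
    Q, b = problem.Q, problem.b
    if Q.size == 0:
        problem.X0 = np.zeros(0)
        problem.residuals = np.zeros(0)
        problem.rank = 0
        return problem

    X0, _, rank, sv = lstsq(Q, b, cond=sv_cutoff, lapack_driver="gelsd")
    problem.X0 = X0
    problem.residuals = b - Q @ X0
    problem.rank = int(rank)
    problem.singular_values = sv

    if rank < len(problem.X_ids):
        # right singular vectors spanning the null space identify the
        # non-unique directions
        _, s_full, Vt = np.linalg.svd(Q, full_matrices=True)
        cutoff = sv_cutoff * (s_full[0] if s_full.size else 1.0)
        null_mask = np.zeros(len(problem.X_ids), dtype=bool)
        n_above = int((s_full > cutoff).sum())
        for v in Vt[n_above:]:
            null_mask |= np.abs(v) > 1e-8
        problem.weakly_determined = [
            c for c, w in zip(problem.X_ids, null_mask) if w
        ]
        logger.warning(
            "rank deficiency: rank %d < %d unknowns; %d weakly determined "
            "compounds", rank, len(problem.X_ids), len(problem.weakly_determined),
        )
    logger.info(
        "least squares solved: rank %d, residual norm %.3g",
        problem.rank, problem.residual_norm(),
    )
    return problem


# --------------------------------------------------------------------------
# back substitution & consistency
# --------------------------------------------------------------------------

def back_substitute(
    model: StoichiometricModel,
    tables: EnergyTables,
    problem: InferenceProblem,
) -> np.ndarray:
    """Complete all reaction energies: F₀ = Sᵀ·(P + T·X₀).

    Unknown reaction energies are filled from F₀ with provenance
    ``inferred``; unknown formation energies get their X₀ value likewise.
    Known values are never overwritten.
    """
    X0 = problem.X0 if problem.X0 is not None else np.zeros(len(problem.X_ids))
    F0 = model.S.T @ (problem.P + problem.T_mat @ X0)

    for compound, value in zip(problem.X_ids, X0):
        if compound not in tables.formation:
            tables.set_formation(compound, value, PROVENANCE_INFERRED)
    n_filled = 0
    for rid, f0 in zip(model.reaction_ids, F0):
        if rid not in tables.reaction:
            tables.set_reaction(rid, f0, PROVENANCE_INFERRED)
            n_filled += 1
    logger.info("back substitution filled %d reaction energies", n_filled)
    return np.asarray(F0)


def consistency_report(
    model: StoichiometricModel,
    tables: EnergyTables,
    problem: InferenceProblem,
    F0: np.ndarray,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Four-category consistency summary of F₀ against the input energies.

    ``tol`` is an absolute floor, inflated by the least-squares residual norm
    so that a noisy but optimally-fit system is still called consistent.
    """
    inferred_mask = np.array(
        [
            tables.reaction_provenance.get(rid) == PROVENANCE_INFERRED
            or rid not in tables.reaction
            for rid in model.reaction_ids
        ]
    )
    usable = set(problem.usable_rows)
    usable_mask = np.array([rid in usable for rid in model.reaction_ids])
    known_mask = ~inferred_mask

    F_in = np.array(
        [
            tables.reaction[rid] if known else np.nan
            for rid, known in zip(model.reaction_ids, known_mask)
        ]
    )
    disc = np.abs(F0 - F_in)

    categories = {
        "unknown_dGr": inferred_mask,
        "known_dGr_with_unknown_compounds": known_mask & usable_mask,
        "known_dGr_no_unknown_compounds": known_mask & ~usable_mask,
        "all_known_dGr": known_mask,
    }
    effective_tol = tol + problem.residual_norm()
    rows = []
    for name, mask in categories.items():
        n = int(mask.sum())
        if name == "unknown_dGr" or n == 0:
            max_d = rms = np.nan
            verdict = "cannot_compare" if name == "unknown_dGr" else "empty"
        else:
            d = disc[mask]
            max_d = float(np.max(d))
            rms = float(np.sqrt(np.mean(d**2)))
            verdict = "consistent" if max_d <= effective_tol else "inconsistent"
        rows.append((name, n, max_d, rms, verdict))
    report = pd.DataFrame(
        rows, columns=["category", "n_reactions", "max_discrepancy",
                       "rms_discrepancy", "verdict"]
    )
    logger.info("consistency categories: %s",
                dict(zip(report["category"], report["n_reactions"])))
    return report


# --------------------------------------------------------------------------
# one-call driver
# --------------------------------------------------------------------------

def complete_energies(
    model: StoichiometricModel,
    tables: EnergyTables,
    sv_cutoff: float = DEFAULT_SV_CUTOFF,
    consistency_tol: float = 1e-6,
) -> tuple[EnergyTables, InferenceProblem, pd.DataFrame]:
    """Run the full completion: assemble, solve, back-substitute, report."""
    tables.validate_against(model)
    T_mat, X_ids = build_transfer_matrix(model, tables)
    problem = build_inference_system(model, tables, T_mat, X_ids)
    solve_least_squares(problem, sv_cutoff)
    F0 = back_substitute(model, tables, problem)
    report = consistency_report(model, tables, problem, F0, consistency_tol)
    return tables, problem, report
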
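"""Synthetic metabolic models with ground-truth thermodynamics.

The generator builds a sparse, compartmentalized stoichiometric model with a
planted substrate→biomass pathway (so the FBA linear program is feasible
with a strictly positive optimum by construction), draws ground-truth
formation energies per base compound, derives every reaction energy from the
stoichiometric relation ΔG_r = Σ s_i·ΔGf(i), then releases a *masked* copy in
which a chosen fraction of compounds have unknown formation energy.
Reactions touching a masked compound keep their (optionally noisy) energy
with a configurable probability — the kept ones are the constraints the
inference step solves; the dropped ones are the unknowns it completes.
Noise, when requested, is applied to those constraint rows: it models
uncertainty in the estimated reaction energies that drive the inference,
while reactions not touching masked compounds stay exactly self-consistent.

Generation is a pure function of the spec: same seed, same output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from .infer import build_inference_system, build_transfer_matrix
from .model_io import StoichiometricModel, build_compound_map
from .thermo import PROVENANCE_INPUT, EnergyTables

logger = logging.getLogger(__name__)


class GenerationError(ValueError):
    """The spec cannot host a feasible model."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic model."""

    n_compounds: int = 40
    n_compartments: int = 2
    n_internal_reactions: int = 60
    n_exchange_reactions: int = 8
    frac_unknown_compounds: float = 0.2
    noise_sd: float = 0.0
    seed: int = 0
    sparsity: float = 4.0
    #: probability that a reaction touching a masked compound keeps its energy
    keep_known_ratio: float = 0.8
    formation_range: tuple[float, float] = (-200.0, 50.0)
    uptake_rate: float = 10.0
    flux_cap: float = 1000.0

    def validate(self) -> None:
        if min(self.n_compounds, self.n_compartments,
               self.n_internal_reactions, self.n_exchange_reactions) < 1:
            raise GenerationError("all size parameters must be ≥ 1")
        if not (0.0 <= self.frac_unknown_compounds < 1.0):
            raise GenerationError("frac_unknown_compounds must lie in [0, 1)")
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be ≥ 0")
        if self.n_compartments > 3:
            raise GenerationError("at most 3 compartments (c, e, p) supported")
        path_len = min(5, self.n_compounds)
        planted_internal = (path_len - 1) + (1 if self.n_compartments > 1 else 0)
        if self.n_internal_reactions < max(planted_internal, 1):
            raise GenerationError(
                f"need at least {planted_internal} internal reactions for the "
                "planted biomass pathway"
            )


@dataclass
class SyntheticResult:
    model: StoichiometricModel
    truth: EnergyTables
    masked: EnergyTables
    masked_compounds: list[str]
    #: rank of the reduced inference system built from the masked tables
    constraint_rank: int
    n_constraints: int = 0
    extras: dict = field(default_factory=dict)


def generate(spec: SyntheticSpec) -> SyntheticResult:
    """Generate (model, ground-truth tables, masked tables) from ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    comps = ["c", "e", "p"][: spec.n_compartments]
    ext = "e" if "e" in comps else "c"
    cap = spec.flux_cap

    compounds = [f"cpd{i:03d}" for i in range(spec.n_compounds)]
    path_len = min(5, spec.n_compounds)
    path = compounds[:path_len]

    # --- species ---------------------------------------------------------
    species: list[str] = [f"{c}[c]" for c in compounds]
    species_set = set(species)

    def ensure_species(compound: str, comp: str) -> str:
        sid = f"{compound}[{comp}]"
        if sid not in species_set:
            species.append(sid)
            species_set.add(sid)
        return sid

    if spec.n_compartments > 1:
        # a quarter of compounds also live in a second compartment
        extra = rng.choice(compounds, size=max(1, spec.n_compounds // 4),
                           replace=False)
        for c in extra:
            ensure_species(c, str(rng.choice([x for x in comps if x != "c"])))

    # --- reactions -------------------------------------------------------
    reactions: list[str] = []
    classes: list[str] = []
    lb: list[float] = []
    ub: list[float] = []
    obj: list[float] = []
    entries: list[tuple[str, str, float]] = []  # species, reaction, coeff

    def add_reaction(rid, cls, lo, hi, objective, stoich):
        reactions.append(rid)
        classes.append(cls)
        lb.append(lo)
        ub.append(hi)
        obj.append(objective)
        entries.extend((sid, rid, co) for sid, co in stoich.items())

    # planted pathway: uptake → (transport) → chain → biomass
    src_ext = ensure_species(path[0], ext)
    add_reaction(f"EX_{path[0]}", "exchange", -spec.uptake_rate, cap, 0.0,
                 {src_ext: -1.0})
    if ext != "c":
        add_reaction(f"T_{path[0]}", "internal", 0.0, cap, 0.0,
                     {src_ext: -1.0, f"{path[0]}[c]": 1.0})
    for a, b in zip(path, path[1:]):
        add_reaction(f"CH_{a}_{b}", "internal", 0.0, cap, 0.0,
                     {f"{a}[c]": -1.0, f"{b}[c]": 1.0})
    add_reaction("BIOMASS", "biomass", 0.0, cap, 1.0, {f"{path[-1]}[c]": -1.0})

    # additional secretion-only exchanges
    others = [c for c in compounds if c != path[0]]
    n_extra_ex = spec.n_exchange_reactions - 1
    for c in rng.choice(others, size=min(n_extra_ex, len(others)), replace=False):
        add_reaction(f"EX_{c}", "exchange", 0.0, cap, 0.0,
                     {ensure_species(c, ext): -1.0})

    # random internal reactions up to the requested count
    n_planted_internal = classes.count("internal")
    for k in range(spec.n_internal_reactions - n_planted_internal):
        n_part = int(min(max(2, rng.poisson(spec.sparsity)), len(species), 6))
        chosen = rng.choice(len(species), size=n_part, replace=False)
        n_react = int(rng.integers(1, n_part))
        stoich = {}
        for pos, si in enumerate(chosen):
            mag = float(rng.choice([1.0, 2.0]))
            stoich[species[si]] = -mag if pos < n_react else mag
        reversible = bool(rng.random() < 0.5)
        add_reaction(f"R{k:03d}", "internal", -cap if reversible else 0.0,
                     cap, 0.0, stoich)

    # --- assemble the model ---------------------------------------------
    s_idx = {s: i for i, s in enumerate(species)}
    r_idx = {r: j for j, r in enumerate(reactions)}
    rows = [s_idx[s] for s, _, _ in entries]
    cols = [r_idx[r] for _, r, _ in entries]
    vals = [v for _, _, v in entries]
    S = sparse.csc_matrix((vals, (rows, cols)),
                          shape=(len(species), len(reactions)))
    s2c, comp_map = build_compound_map(species)
    model = StoichiometricModel(
        species_ids=species,
        reaction_ids=reactions,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        objective=np.array(obj),
        species_to_compound=s2c,
        compartments=comp_map,
        reaction_class=classes,
        provenance={"source": f"synthetic(seed={spec.seed})", "format": "synthetic"},
    )
    model.validate()

    # --- ground-truth energies ------------------------------------------
    lo, hi = spec.formation_range
    dgf = dict(zip(compounds, rng.uniform(lo, hi, size=spec.n_compounds)))
    P_full = np.array([dgf[s2c[sid]] for sid in species])
    F_true = np.asarray(S.T @ P_full)

    truth = EnergyTables()
    for c in compounds:
        truth.set_formation(c, dgf[c], PROVENANCE_INPUT)
    for rid, f in zip(reactions, F_true):
        truth.set_reaction(rid, float(f), PROVENANCE_INPUT)

    # --- masking ---------------------------------------------------------
    n_mask = int(round(spec.frac_unknown_compounds * spec.n_compounds))
    occurrences = {c: 0 for c in compounds}
    for sid in species:
        occurrences[s2c[sid]] += int(S.getrow(s_idx[sid]).nnz)
    # prefer compounds seen in ≥ 2 reactions so constraints exist
    candidates = sorted([c for c in compounds if occurrences[c] >= 2])
    if len(candidates) < n_mask:
        candidates = sorted(compounds)
    masked_compounds = sorted(
        rng.choice(candidates, size=n_mask, replace=False).tolist()
    )
    masked_set = set(masked_compounds)

    masked = EnergyTables()
    for c in compounds:
        if c not in masked_set:
            masked.set_formation(c, dgf[c], PROVENANCE_INPUT)

    touching: dict[str, list[str]] = {c: [] for c in masked_compounds}
    for j, rid in enumerate(reactions):
        col = S.getcol(j)
        touched = {s2c[species[i]] for i in col.indices} & masked_set
        if not touched:
            masked.set_reaction(rid, float(F_true[j]), PROVENANCE_INPUT)
            continue
        if rng.random() < spec.keep_known_ratio:
            noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            masked.set_reaction(rid, float(F_true[j] + noise), PROVENANCE_INPUT)
            for c in touched:
                touching[c].append(rid)

    # every masked compound must be constrained by at least one known row;
    # deterministically re-open the first touching reaction when the random
    # keep pass dropped them all
    for j, rid in enumerate(reactions):
        col = S.getcol(j)
        touched = {s2c[species[i]] for i in col.indices} & masked_set
        for c in touched:
            if not touching[c] and rid not in masked.reaction:
                noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                masked.set_reaction(rid, float(F_true[j] + noise), PROVENANCE_INPUT)
                for cc in touched:
                    touching[cc].append(rid)

    # --- identifiability diagnostics ------------------------------------
    T_mat, x_ids = build_transfer_matrix(model, masked)
    if x_ids:
        problem = build_inference_system(model, masked, T_mat, x_ids)
        rank = int(np.linalg.matrix_rank(problem.Q))
        n_constraints = len(problem.usable_rows)
    else:
        rank, n_constraints = 0, 0
    logger.info(
        "synthetic model: %d species, %d reactions, %d masked compounds, "
        "constraint system rank %d/%d",
        len(species), len(reactions), n_mask, rank, len(x_ids),
    )
    return SyntheticResult(
        model=model,
        truth=truth,
        masked=masked,
        masked_compounds=masked_compounds,
        constraint_rank=rank,
        n_constraints=n_constraints,
    )


def with_noise(spec: SyntheticSpec, noise_sd: float) -> SyntheticSpec:
    """Same study conditions, different constraint-noise level."""
    return replace(spec, noise_sd=noise_sd)
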
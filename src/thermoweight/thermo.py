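"""Energy tables and the standard-state → millimolar reference adjustment.

Standard Gibbs reaction energies (ΔG°′, 1 M reference) are adjusted to the
1 mM reference state that better reflects intracellular concentrations:

    ΔG′m = ΔG°′ + R·T · Σ_{i ∈ PR} n_i · ln(c_i)

where the sum runs over the reactant and product species of the reaction,
n_i is the (signed) stoichiometric coefficient and c_i the compound's
reference concentration — 1 mM by default, with literature overrides for
dissolved H₂ (34 µM) and O₂ (55 µM), and with H₂O and H⁺ excluded from the
concentration sum altogether.  The sum runs over species *occurrences*, so a
compound appearing in two compartments of one reaction contributes one term
per occurrence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_io import StoichiometricModel

logger = logging.getLogger(__name__)

#: gas constant in kcal·mol⁻¹·K⁻¹ (energies default to kcal·mol⁻¹)
R_KCAL = 1.987e-3

PROVENANCE_INPUT = "input"
PROVENANCE_INFERRED = "inferred"


class EnergyTableError(ValueError):
    """Raised on malformed or inconsistent energy-table input."""


@dataclass
class AdjustmentConfig:
    """Parameters of the millimolar concentration adjustment."""

    R: float = R_KCAL
    T: float = 298.0
    default_conc: float = 1e-3
    special_conc: dict[str, float] = field(
        default_factory=lambda: {"h2": 0.000034, "o2": 0.000055}
    )
    excluded_compounds: frozenset[str] = frozenset({"h2o", "h"})
    energy_unit: str = "kcal/mol"

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.default_conc <= 0 or any(c <= 0 for c in self.special_conc.values()):
            raise ValueError("all concentrations must be strictly positive")

    def concentration(self, compound: str) -> float:
        return self.special_conc.get(compound, self.default_conc)


@dataclass
class EnergyTables:
    """Per-compound formation energies and per-reaction energies.

    Only *known* values are stored; absence of a key means the value is
    unknown.  ``provenance`` distinguishes values read from input tables from
    values filled in by the inference step.
    """

    formation: dict[str, float] = field(default_factory=dict)
    formation_provenance: dict[str, str] = field(default_factory=dict)
    reaction: dict[str, float] = field(default_factory=dict)
    reaction_provenance: dict[str, str] = field(default_factory=dict)
    reaction_offset: dict[str, float] = field(default_factory=dict)
    dGm: dict[str, float] = field(default_factory=dict)
    energy_unit: str = "kcal/mol"

    def known_compounds(self) -> set[str]:
        return set(self.formation)

    def unknown_compounds(self, model: StoichiometricModel) -> list[str]:
        """Model compounds with no known formation energy, in model order."""
        return [c for c in model.compound_ids if c not in self.formation]

    def known_reactions(self) -> set[str]:
        return set(self.reaction)

    def unknown_reactions(self, model: StoichiometricModel) -> list[str]:
        return [r for r in model.reaction_ids if r not in self.reaction]

    def set_formation(self, compound: str, value: float, provenance: str) -> None:
        if not math.isfinite(value):
            raise EnergyTableError(f"non-finite formation energy for {compound!r}")
        self.formation[compound] = float(value)
        self.formation_provenance[compound] = provenance

    def set_reaction(self, reaction: str, value: float, provenance: str) -> None:
        if not math.isfinite(value):
            raise EnergyTableError(f"non-finite reaction energy for {reaction!r}")
        self.reaction[reaction] = float(value)
        self.reaction_provenance[reaction] = provenance

    def validate_against(self, model: StoichiometricModel) -> None:
        compounds = set(model.compound_ids)
        reactions = set(model.reaction_ids)
        bad_c = set(self.formation) - compounds
        bad_r = set(self.reaction) - reactions
        if bad_c or bad_r:
            raise EnergyTableError(
                f"energy-table ids absent from model: compounds {sorted(bad_c)[:5]}, "
                f"reactions {sorted(bad_r)[:5]}"
            )


# --------------------------------------------------------------------------
# table I/O
# --------------------------------------------------------------------------

def load_energy_table(
    path: str | Path,
    kind: str,
    model: StoichiometricModel | None = None,
    strict: bool = False,
    tables: EnergyTables | None = None,
) -> EnergyTables:
    """Load a TSV energy table (columns ``id``, ``value``, optional ``offset``).

    Blank/NA values mark the id as unknown.  ``kind`` selects the target map
    (``formation`` → per-compound, ``reaction`` → per-reaction).  Duplicate
    ids warn and keep the last occurrence (strict mode: error); ids absent
    from ``model`` are reported the same way.
    """
    if kind not in ("formation", "reaction"):
        raise ValueError(f"kind must be 'formation' or 'reaction', got {kind!r}")
    tables = tables if tables is not None else EnergyTables()

    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if df.empty:
        logger.warning("energy table %s is empty", path)
        return tables
    if not {"id", "value"} <= set(df.columns):
        raise EnergyTableError(f"{path}: energy table needs 'id' and 'value' columns")

    dups = df["id"][df["id"].duplicated()].unique()
    if len(dups):
        msg = f"{path}: duplicate ids {list(dups)[:5]} (last occurrence wins)"
        if strict:
            raise EnergyTableError(msg)
        logger.warning(msg)
        df = df.drop_duplicates("id", keep="last")

    if model is not None:
        valid = set(model.compound_ids if kind == "formation" else model.reaction_ids)
        unmatched = [i for i in df["id"] if i not in valid]
        if unmatched:
            msg = f"{path}: {len(unmatched)} ids not in model, e.g. {unmatched[:5]}"
            if strict:
                raise EnergyTableError(msg)
            logger.warning(msg)
            df = df[df["id"].isin(valid)]

    n_known = n_unknown = 0
    for rec in df.itertuples(index=False):
        value = getattr(rec, "value")
        if pd.isna(value) or (isinstance(value, str) and value.strip() == ""):
            n_unknown += 1
            continue
        value = float(value)
        if kind == "formation":
            tables.set_formation(rec.id, value, PROVENANCE_INPUT)
        else:
            tables.set_reaction(rec.id, value, PROVENANCE_INPUT)
            offset = getattr(rec, "offset", None)
            if offset is not None and not pd.isna(offset):
                tables.reaction_offset[rec.id] = float(offset)
        n_known += 1
    logger.info(
        "%s table %s: %d known, %d unknown entries", kind, path, n_known, n_unknown
    )
    return tables


def write_energy_tables(tables: EnergyTables, model: StoichiometricModel,
                        path: str | Path) -> None:
    """Write completed reaction energies (ΔG°′, ΔG′m, provenance) to TSV."""
    recs = []
    for rid in model.reaction_ids:
        recs.append(
            (
                rid,
                tables.reaction.get(rid, ""),
                tables.dGm.get(rid, ""),
                tables.reaction_provenance.get(rid, "unknown"),
            )
        )
    df = pd.DataFrame(recs, columns=["reaction", "dGr0", "dGm", "provenance"])
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# the adjustment itself
# --------------------------------------------------------------------------

def concentration_term(
    model: StoichiometricModel, reaction: str, cfg: AdjustmentConfig
) -> float:
    """R·T · Σ n_i ln(c_i) over the reaction's species occurrences."""
    j = model.reaction_index()[reaction]
    col = model.S.getcol(j).tocoo()
    total = 0.0
    for i, n_i in zip(col.row, col.data):
        compound = model.species_to_compound[model.species_ids[i]]
        if compound in cfg.excluded_compounds:
            continue
        total += n_i * math.log(cfg.concentration(compound))
    return cfg.R * cfg.T * total


def adjust_to_millimolar(
    model: StoichiometricModel,
    reaction: str,
    dGr0_value: float,
    cfg: AdjustmentConfig | None = None,
) -> float:
    """Adjust one standard reaction energy to the 1 mM reference state."""
    cfg = cfg or AdjustmentConfig()
    if not math.isfinite(dGr0_value):
        raise EnergyTableError(f"non-finite input energy for reaction {reaction!r}")
    return dGr0_value + concentration_term(model, reaction, cfg)


def adjust_all(
    model: StoichiometricModel,
    tables: EnergyTables,
    cfg: AdjustmentConfig | None = None,
) -> EnergyTables:
    """Fill ``tables.dGm`` for every reaction with a known ΔG°′.

    An optional per-reaction additive offset (e.g. a transmembrane-potential
    contribution supplied with the input table) is applied on top.
    """
    cfg = cfg or AdjustmentConfig()
    for rid, dg0 in tables.reaction.items():
        dgm = adjust_to_millimolar(model, rid, dg0, cfg)
        tables.dGm[rid] = dgm + tables.reaction_offset.get(rid, 0.0)
    tables.energy_unit = cfg.energy_unit
    return tables
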
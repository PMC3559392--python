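"""Free-energy balance between internal chemistry and environmental exchange.

At nonequilibrium steady state the free-energy rate a cell dissipates equals
the rate the environment supplies.  Splitting dissipation into chemical and
physical channels:

    G_env = Σ_{j ∈ exchange} ΔG′m_j · v_j      (environmental input rate)
    G_sys = Σ_{i ∈ internal} ΔG′m_i · v_i      (chemical dissipation rate)
    G_phy = −(G_env + G_sys)                   (physical remainder, by difference)

Both sums exclude the biomass reaction.  G_phy is an estimate by difference,
never independently computed.  An exchange reaction of form A ↔ ∅ gets its
ΔG from the same stoichiometric relation as any other reaction
(−s_A·ΔGf(A), millimolar-adjusted), a convention recorded in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class EnergyBalance:
    """The G_env / G_sys / G_phy decomposition (energy·gDW⁻¹·h⁻¹)."""

    G_env: float
    G_sys: float
    G_phy: float
    chemical_fraction_pct: float
    physical_fraction_pct: float
    energy_unit: str = "kcal/mol"
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": ["G_env", "G_sys", "G_phy"],
                "value": [self.G_env, self.G_sys, self.G_phy],
                "percent_of_G_env": [
                    100.0, self.chemical_fraction_pct, self.physical_fraction_pct,
                ],
            }
        )


def energy_balance(
    dGm: dict[str, float],
    v: dict[str, float],
    reaction_class: dict[str, str],
    energy_unit: str = "kcal/mol",
    metadata: dict | None = None,
) -> EnergyBalance:
    """Compute the balance from completed energies, fluxes and class tags.

    Every internal or exchange reaction with nonzero flux must have a known
    energy; the biomass reaction is excluded from both sums.  The identity
    G_env + G_sys + G_phy = 0 holds by construction; fractions are
    |G_sys|/|G_env| and |G_phy|/|G_env| × 100 (0 when G_env = 0).
    """
    missing = [
        r for r, cls in reaction_class.items()
        if cls in ("internal", "exchange") and r not in dGm and abs(v.get(r, 0.0)) > 0
    ]
    if missing:
        raise KeyError(
            f"reactions with flux but unknown energy, e.g. {missing[:5]}"
        )

    G_sys = sum(
        dGm[r] * v[r]
        for r, cls in reaction_class.items()
        if cls == "internal" and r in dGm and r in v
    )
    G_env = sum(
        dGm[r] * v[r]
        for r, cls in reaction_class.items()
        if cls == "exchange" and r in dGm and r in v
    )
    G_phy = -(G_env + G_sys)

    denom = abs(G_env)
    chem = abs(G_sys) / denom * 100.0 if denom > 0 else 0.0
    phy = abs(G_phy) / denom * 100.0 if denom > 0 else 0.0

    meta = dict(metadata or {})
    meta.setdefault(
        "exchange_energy_convention",
        "exchange ΔG computed from the exchange stoichiometry itself "
        "(−s·ΔGf of the exchanged species, millimolar-adjusted)",
    )
    meta.setdefault("G_phy_note", "estimate by difference: G_phy = −(G_env + G_sys)")
    logger.info(
        "energy balance: G_env=%.4g, G_sys=%.4g, G_phy=%.4g (%s·gDW⁻¹·h⁻¹)",
        G_env, G_sys, G_phy, energy_unit,
    )
    return EnergyBalance(
        G_env=float(G_env),
        G_sys=float(G_sys),
        G_phy=float(G_phy),
        chemical_fraction_pct=chem,
        physical_fraction_pct=phy,
        energy_unit=energy_unit,
        metadata=meta,
    )


def write_balance(balance: EnergyBalance, path: str | Path) -> None:
    df = balance.to_frame()
    df["unit"] = balance.energy_unit + "*gDW^-1*h^-1"
    for k, val in balance.metadata.items():
        df.attrs[k] = val
    with open(path, "w") as fh:
        for k, val in balance.metadata.items():
            fh.write(f"# {k}: {val}\n")
        df.to_csv(fh, sep="\t", index=False)
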
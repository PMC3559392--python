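"""Shared fixtures: programmatic toy models and synthetic study conditions."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse

from thermoweight.model_io import StoichiometricModel, build_compound_map
from thermoweight.synthetic import SyntheticSpec, generate


def make_model(
    reactions: dict[str, dict[str, float]],
    bounds: dict[str, tuple[float, float]] | None = None,
    objective: dict[str, float] | None = None,
    classes: dict[str, str] | None = None,
) -> StoichiometricModel:
    """Build a StoichiometricModel from {reaction: {species: coefficient}}."""
    bounds = bounds or {}
    objective = objective or {}
    classes = classes or {}
    species: list[str] = []
    for stoich in reactions.values():
        for sid in stoich:
            if sid not in species:
                species.append(sid)
    rids = list(reactions)
    s_idx = {s: i for i, s in enumerate(species)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rids):
        for sid, c in reactions[rid].items():
            rows.append(s_idx[sid])
            cols.append(j)
            vals.append(float(c))
    S = sparse.csc_matrix((vals, (rows, cols)), shape=(len(species), len(rids)))
    s2c, comps = build_compound_map(species)

    def cls_of(rid: str) -> str:
        if rid in classes:
            return classes[rid]
        if rid.startswith(("EX_", "DM_")):
            return "exchange"
        if "biomass" in rid.lower():
            return "biomass"
        return "internal"

    model = StoichiometricModel(
        species_ids=species,
        reaction_ids=rids,
        S=S,
        lb=np.array([bounds.get(r, (-1000.0, 1000.0))[0] for r in rids]),
        ub=np.array([bounds.get(r, (-1000.0, 1000.0))[1] for r in rids]),
        objective=np.array([objective.get(r, 0.0) for r in rids]),
        species_to_compound=s2c,
        compartments=comps,
        reaction_class=[cls_of(r) for r in rids],
    )
    model.validate()
    return model


@pytest.fixture
def model_builder():
    return make_model


@pytest.fixture
def chain_model():
    """EX_a → a[e] → a[c] → b[c] → biomass, uptake capped at 10."""
    return make_model(
        {
            "EX_a": {"a[e]": -1.0},
            "T_a": {"a[e]": -1.0, "a[c]": 1.0},
            "CONV": {"a[c]": -1.0, "b[c]": 1.0},
            "BIOMASS": {"b[c]": -1.0},
        },
        bounds={
            "EX_a": (-10.0, 0.0),
            "T_a": (0.0, 1000.0),
            "CONV": (0.0, 1000.0),
            "BIOMASS": (0.0, 1000.0),
        },
        objective={"BIOMASS": 1.0},
    )


@pytest.fixture(scope="session")
def synth_default():
    """The default synthetic study conditions (seed 1), generated once."""
    return generate(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def synth_noisefree_large():
    """Full-rank noise-free conditions used for parameter recovery."""
    return generate(SyntheticSpec(n_compounds=40, frac_unknown_compounds=0.2,
                                  noise_sd=0.0, seed=7))
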
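"""Loading, classifying and writing constraint-based metabolic models.

The central container is :class:`StoichiometricModel`: a sparse stoichiometric
matrix ``S`` (rows = compartmentalized species, columns = reactions) together
with flux bounds, an objective vector and a per-reaction class tag
(``internal`` / ``exchange`` / ``biomass``).  Species identifiers carry a
compartment suffix in one of two common dialects (``atp[c]`` or ``atp_c`` /
``M_atp_c``); species that differ only in compartment map to one *base
compound*, because a compound's Gibbs formation energy does not depend on the
compartment it sits in.

Two on-disk dialects are supported: SBML (read through cobrapy) and a plain
three-file tabular layout (``reactions.tsv``, ``species.tsv``, ``stoich.tsv``)
that round-trips exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

#: reaction identifier prefixes that denote boundary (exchange/demand) reactions
DEFAULT_EXCHANGE_PREFIXES: tuple[str, ...] = ("EX_", "DM_")

#: case-insensitive pattern used to spot a biomass/growth reaction by name
DEFAULT_BIOMASS_PATTERN = r"(?i)biomass|growth"

REACTION_CLASSES = ("internal", "exchange", "biomass")


class ModelFormatError(ValueError):
    """Raised when an input file violates the declared model format."""


class EmptyModelError(ValueError):
    """Raised when a parsed model has no species or no reactions."""


# --------------------------------------------------------------------------
# species-identifier normalization
# --------------------------------------------------------------------------

_BRACKET_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[A-Za-z0-9]+)\]$")
_UNDERSCORE_RE = re.compile(r"^(?:M_)?(?P<base>.+)_(?P<comp>[a-z][a-z0-9]?)$")


def split_species_id(species_id: str) -> tuple[str, str | None]:
    """Split a species identifier into (base compound, compartment).

    Supports the bracket dialect ``atp[c]`` and the SBML underscore dialect
    ``atp_c`` / ``M_atp_c``.  Returns ``(species_id, None)`` when neither
    matches.
    """
    m = _BRACKET_RE.match(species_id)
    if m:
        return m.group("base"), m.group("comp")
    m = _UNDERSCORE_RE.match(species_id)
    if m:
        return m.group("base"), m.group("comp")
    return species_id, None


# --------------------------------------------------------------------------
# container
# --------------------------------------------------------------------------

@dataclass
class StoichiometricModel:
    """Sparse stoichiometric model with metadata.

    ``S`` has one row per compartmentalized species and one column per
    reaction; entries are stoichiometric coefficients (negative = consumed,
    positive = produced).
    """

    species_ids: list[str]
    reaction_ids: list[str]
    S: sparse.csc_matrix
    lb: np.ndarray
    ub: np.ndarray
    objective: np.ndarray
    species_to_compound: dict[str, str] = field(default_factory=dict)
    compartments: dict[str, str | None] = field(default_factory=dict)
    reaction_class: list[str] = field(default_factory=list)
    #: exact coefficient strings as written in a tabular source, for round-trip
    raw_coefficients: dict[tuple[str, str], str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    # -- derived views ----------------------------------------------------
    @property
    def compound_ids(self) -> list[str]:
        """Distinct base compounds, in first-appearance order."""
        seen: dict[str, None] = {}
        for sid in self.species_ids:
            seen.setdefault(self.species_to_compound[sid], None)
        return list(seen)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def species_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species_ids)}

    def reaction_index(self) -> dict[str, int]:
        return {r: j for j, r in enumerate(self.reaction_ids)}

    def reactions_of_class(self, cls: str) -> list[str]:
        if cls not in REACTION_CLASSES:
            raise ValueError(f"unknown reaction class {cls!r}")
        return [r for r, c in zip(self.reaction_ids, self.reaction_class) if c == cls]

    def class_counts(self) -> dict[str, int]:
        return {c: self.reaction_class.count(c) for c in REACTION_CLASSES}

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        n_s, n_r = self.S.shape
        if n_s != len(self.species_ids) or n_r != len(self.reaction_ids):
            raise ValueError(
                f"S shape {self.S.shape} disagrees with "
                f"{len(self.species_ids)} species / {len(self.reaction_ids)} reactions"
            )
        if n_s == 0 or n_r == 0:
            raise EmptyModelError("model has zero species or zero reactions")
        for arr, name in ((self.lb, "lb"), (self.ub, "ub"), (self.objective, "objective")):
            if len(arr) != n_r:
                raise ValueError(f"{name} has length {len(arr)}, expected {n_r}")
        if np.any(self.lb > self.ub):
            bad = [self.reaction_ids[j] for j in np.nonzero(self.lb > self.ub)[0]]
            raise ValueError(f"lb > ub for reactions {bad}")
        missing = [s for s in self.species_ids if s not in self.species_to_compound]
        if missing:
            raise ValueError(f"species without compound mapping: {missing[:5]}")
        if self.reaction_class:
            if len(self.reaction_class) != n_r:
                raise ValueError("reaction_class length mismatch")
            bad_cls = set(self.reaction_class) - set(REACTION_CLASSES)
            if bad_cls:
                raise ValueError(f"unknown reaction classes {bad_cls}")

    def summary(self) -> dict[str, int]:
        """Headline counts; exposes both with- and without-biomass reaction totals."""
        counts = self.class_counts() if self.reaction_class else {}
        n_biomass = counts.get("biomass", 0)
        return {
            "n_species": self.n_species,
            "n_compounds": len(self.compound_ids),
            "n_reactions": self.n_reactions,
            "n_reactions_excl_biomass": self.n_reactions - n_biomass,
            "n_internal": counts.get("internal", 0),
            "n_exchange": counts.get("exchange", 0),
            "n_biomass": n_biomass,
        }


# --------------------------------------------------------------------------
# compound mapping
# --------------------------------------------------------------------------

def build_compound_map(
    species_ids: Iterable[str], strict: bool = False
) -> tuple[dict[str, str], dict[str, str | None]]:
    """Map each species id to its base compound and compartment.

    In lenient mode (default) a species id that matches neither compartment
    dialect maps to itself with compartment ``None``; strict mode raises
    :class:`ModelFormatError` instead.
    """
    s2c: dict[str, str] = {}
    comps: dict[str, str | None] = {}
    for sid in species_ids:
        base, comp = split_species_id(sid)
        if comp is None and strict:
            raise ModelFormatError(
                f"species id {sid!r} does not match any compartment syntax"
            )
        s2c[sid] = base
        comps[sid] = comp
    n_compounds = len(set(s2c.values()))
    logger.info("mapped %d species onto %d distinct compounds", len(s2c), n_compounds)
    return s2c, comps


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def classify_reactions(
    model: StoichiometricModel,
    biomass_id: str | None = None,
    exchange_prefixes: tuple[str, ...] = DEFAULT_EXCHANGE_PREFIXES,
    biomass_pattern: str = DEFAULT_BIOMASS_PATTERN,
) -> StoichiometricModel:
    """Tag every reaction as internal, exchange or biomass (in place).

    Exchange status is decided by identifier prefix (default ``EX_``/``DM_``).
    The biomass reaction is named explicitly via ``biomass_id``; failing that,
    the first reaction matching ``biomass_pattern`` or, as a last resort, the
    reaction carrying a nonzero objective coefficient is used.  Biomass is a
    class of its own so that network-wide sums can exclude it.
    """
    if biomass_id is not None and biomass_id not in model.reaction_ids:
        raise KeyError(f"biomass reaction {biomass_id!r} not in model")

    if biomass_id is None:
        pat = re.compile(biomass_pattern)
        matches = [r for r in model.reaction_ids if pat.search(r)]
        if matches:
            biomass_id = matches[0]
        else:
            nz = np.nonzero(model.objective)[0]
            if len(nz) == 1:
                biomass_id = model.reaction_ids[nz[0]]

    classes = []
    for rid in model.reaction_ids:
        if rid == biomass_id:
            classes.append("biomass")
        elif rid.startswith(exchange_prefixes):
            classes.append("exchange")
        else:
            classes.append("internal")
    model.reaction_class = classes

    counts = model.class_counts()
    if counts["exchange"] == 0:
        logger.warning("no exchange-prefixed reactions found in model")
    logger.info(
        "classified reactions: %d internal, %d exchange, %d biomass",
        counts["internal"], counts["exchange"], counts["biomass"],
    )
    return model


# --------------------------------------------------------------------------
# tabular dialect
# --------------------------------------------------------------------------

TABULAR_FILES = ("reactions.tsv", "species.tsv", "stoich.tsv")


def load_tabular(path: str | Path) -> StoichiometricModel:
    """Load the three-file tabular dialect from directory ``path``."""
    path = Path(path)
    for fname in TABULAR_FILES:
        if not (path / fname).exists():
            raise ModelFormatError(f"missing tabular model file {path / fname}")

    reactions = pd.read_csv(path / "reactions.tsv", sep="\t", dtype={"id": str})
    species = pd.read_csv(path / "species.tsv", sep="\t", dtype=str)
    stoich = pd.read_csv(path / "stoich.tsv", sep="\t", dtype=str)

    for df, fname, cols in (
        (reactions, "reactions.tsv", {"id", "class", "lb", "ub", "objective"}),
        (species, "species.tsv", {"id", "compound", "compartment"}),
        (stoich, "stoich.tsv", {"species_id", "reaction_id", "coefficient"}),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise ModelFormatError(f"{fname} lacks required columns {sorted(missing)}")

    species_ids = species["id"].tolist()
    reaction_ids = reactions["id"].tolist()
    if len(set(species_ids)) != len(species_ids):
        raise ModelFormatError("duplicate species ids in species.tsv")
    if len(set(reaction_ids)) != len(reaction_ids):
        raise ModelFormatError("duplicate reaction ids in reactions.tsv")

    s_idx = {s: i for i, s in enumerate(species_ids)}
    r_idx = {r: j for j, r in enumerate(reaction_ids)}

    rows, cols_, vals = [], [], []
    raw: dict[tuple[str, str], str] = {}
    for rec in stoich.itertuples(index=False):
        if rec.species_id not in s_idx:
            raise ModelFormatError(
                f"stoich.tsv references undeclared species {rec.species_id!r}"
            )
        if rec.reaction_id not in r_idx:
            raise ModelFormatError(
                f"stoich.tsv references undeclared reaction {rec.reaction_id!r}"
            )
        rows.append(s_idx[rec.species_id])
        cols_.append(r_idx[rec.reaction_id])
        vals.append(float(rec.coefficient))
        raw[(rec.species_id, rec.reaction_id)] = str(rec.coefficient)

    if not species_ids or not reaction_ids:
        raise EmptyModelError("tabular model has zero species or zero reactions")

    S = sparse.csc_matrix(
        (vals, (rows, cols_)), shape=(len(species_ids), len(reaction_ids))
    )
    s2c = dict(zip(species_ids, species["compound"]))
    comps = {
        sid: (None if pd.isna(c) or c == "" else c)
        for sid, c in zip(species_ids, species["compartment"])
    }
    model = StoichiometricModel(
        species_ids=species_ids,
        reaction_ids=reaction_ids,
        S=S,
        lb=reactions["lb"].astype(float).to_numpy(),
        ub=reactions["ub"].astype(float).to_numpy(),
        objective=reactions["objective"].astype(float).to_numpy(),
        species_to_compound=s2c,
        compartments=comps,
        reaction_class=reactions["class"].tolist(),
        raw_coefficients=raw,
        provenance={"source": str(path), "format": "tabular"},
    )
    model.validate()
    return model


def write_tabular(model: StoichiometricModel, path: str | Path) -> None:
    """Write a model to the three-file tabular dialect (exact round-trip)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    classes = model.reaction_class or ["internal"] * model.n_reactions
    pd.DataFrame(
        {
            "id": model.reaction_ids,
            "class": classes,
            "lb": model.lb,
            "ub": model.ub,
            "objective": model.objective,
        }
    ).to_csv(path / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "id": model.species_ids,
            "compound": [model.species_to_compound[s] for s in model.species_ids],
            "compartment": [model.compartments.get(s) or "" for s in model.species_ids],
        }
    ).to_csv(path / "species.tsv", sep="\t", index=False)

    coo = model.S.tocoo()
    recs = []
    for i, j, v in zip(coo.row, coo.col, coo.data):
        sid, rid = model.species_ids[i], model.reaction_ids[j]
        recs.append((sid, rid, model.raw_coefficients.get((sid, rid), repr(float(v)))))
    pd.DataFrame(recs, columns=["species_id", "reaction_id", "coefficient"]).to_csv(
        path / "stoich.tsv", sep="\t", index=False
    )


# --------------------------------------------------------------------------
# SBML dialect (via cobrapy)
# --------------------------------------------------------------------------

def load_sbml(path: str | Path) -> StoichiometricModel:
    """Read an SBML model through cobrapy into a :class:`StoichiometricModel`."""
    from cobra.io import read_sbml_model

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        cm = read_sbml_model(str(path))
    except Exception as exc:  # cobra raises various parse errors
        raise ModelFormatError(f"SBML parse failure for {path}: {exc}") from exc

    if len(cm.metabolites) == 0 or len(cm.reactions) == 0:
        raise EmptyModelError(f"SBML model {path} has no species or no reactions")

    species_ids = [m.id for m in cm.metabolites]
    reaction_ids = [r.id for r in cm.reactions]
    s_idx = {s: i for i, s in enumerate(species_ids)}

    rows, cols_, vals = [], [], []
    for j, rxn in enumerate(cm.reactions):
        for met, coeff in rxn.metabolites.items():
            rows.append(s_idx[met.id])
            cols_.append(j)
            vals.append(float(coeff))
    S = sparse.csc_matrix(
        (vals, (rows, cols_)), shape=(len(species_ids), len(reaction_ids))
    )

    s2c, comps = build_compound_map(species_ids)
    # prefer cobra's own compartment annotation when present
    for m in cm.metabolites:
        if m.compartment:
            comps[m.id] = m.compartment

    model = StoichiometricModel(
        species_ids=species_ids,
        reaction_ids=reaction_ids,
        S=S,
        lb=np.array([r.lower_bound for r in cm.reactions], dtype=float),
        ub=np.array([r.upper_bound for r in cm.reactions], dtype=float),
        objective=np.array(
            [r.objective_coefficient for r in cm.reactions], dtype=float
        ),
        species_to_compound=s2c,
        compartments=comps,
        provenance={
            "source": str(path),
            "format": "sbml",
            "stoichiometry_note": (
                "coefficients taken verbatim from the model file; no charge/pH "
                "rebalancing applied"
            ),
        },
    )
    classify_reactions(model)
    model.validate()
    return model


def load_model(path: str | Path, format: str = "tabular") -> StoichiometricModel:
    """Load a model in the declared format (``sbml`` or ``tabular``)."""
    if format == "sbml":
        return load_sbml(path)
    if format == "tabular":
        return load_tabular(path)
    raise ValueError(f"unknown model format {format!r}")
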
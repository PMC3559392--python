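"""Energetic reaction weights and the weighted-network views.

The weight of a reaction is its free-energy dissipation rate,
w = ΔG′m × v (energy·gDW⁻¹·h⁻¹): the energy change per mole times the molar
flux through the reaction.  This module computes the weight vector, its
scope histogram, the highly-dissipative reaction report, (w, v) scatter data
with a Pearson correlation, and a bipartite species–reaction graph export.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .model_io import StoichiometricModel

logger = logging.getLogger(__name__)

#: fluxes and weights below this magnitude snap to exactly zero, so LP solver
#: noise cannot leak reactions out of the exact-zero histogram bin
ZERO_TOL = 1e-9

#: the default weight-scope edges; together with the explicit zero bin they
#: give the scopes <−200, −200∼−100, −100∼−50, −50∼0, 0, 0∼40, 40∼100, >100
DEFAULT_BIN_EDGES = (-200.0, -100.0, -50.0, 0.0, 40.0, 100.0)


class MissingEnergyError(KeyError):
    """An in-scope reaction lacks a known energy."""


def compute_weights(
    dGm: dict[str, float],
    v: dict[str, float],
    scope: list[str],
    zero_tol: float = ZERO_TOL,
) -> pd.Series:
    """w_i = ΔG′m_i × v_i for every reaction in ``scope``.

    Fluxes with |v| below ``zero_tol`` count as exactly zero, giving w = 0
    regardless of the reaction energy.
    """
    missing = [r for r in scope if r not in dGm]
    if missing:
        raise MissingEnergyError(
            f"{len(missing)} in-scope reactions lack energies, e.g. {missing[:5]}"
        )
    missing_v = [r for r in scope if r not in v]
    if missing_v:
        raise KeyError(f"reactions without flux values, e.g. {missing_v[:5]}")

    w = {}
    for rid in scope:
        flux = v[rid]
        if abs(flux) < zero_tol:
            w[rid] = 0.0
        else:
            wi = dGm[rid] * flux
            w[rid] = 0.0 if abs(wi) < zero_tol else wi
    return pd.Series(w, name="w")


def bin_weights(
    w: pd.Series,
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    zero_tol: float = ZERO_TOL,
) -> pd.DataFrame:
    """Histogram of weights over scopes delimited by ``edges``.

    ``edges`` must be strictly increasing and contain 0: negative scopes are
    half-open [lo, hi), the zero scope holds |w| ≤ ``zero_tol``, positive
    scopes are half-open (lo, hi].  Every weight lands in exactly one scope.
    Percentages use the weighted-reaction count as denominator.
    """
    edges = tuple(float(e) for e in edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing (non-overlapping)")
    if 0.0 not in edges:
        raise ValueError("bin specification must include an explicit 0 edge")

    neg = [e for e in edges if e < 0]
    pos = [e for e in edges if e > 0]

    labels: list[str] = [f"<{_fmt(neg[0])}"] if neg else []
    for a, b in zip(neg, neg[1:] + [0.0]):
        labels.append(f"{_fmt(a)}~{_fmt(b)}")
    labels.append("0")
    for a, b in zip([0.0] + pos, pos):
        labels.append(f"{_fmt(a)}~{_fmt(b)}")
    if pos:
        labels.append(f">{_fmt(pos[-1])}")

    counts = dict.fromkeys(labels, 0)
    for x in w.to_numpy():
        counts[_scope_of(x, neg, pos, labels, zero_tol)] += 1

    n = len(w)
    df = pd.DataFrame(
        {
            "scope": labels,
            "count": [counts[l] for l in labels],
        }
    )
    df["percent"] = (df["count"] / n * 100).round(2) if n else 0.0
    assert df["count"].sum() == n
    return df


def _fmt(x: float) -> str:
    return f"{int(x)}" if x == int(x) else f"{x}"


def _scope_of(x, neg, pos, labels, zero_tol) -> str:
    if abs(x) <= zero_tol:
        return "0"
    if x < 0:
        if neg and x < neg[0]:
            return labels[0]
        for a, b in zip(neg, neg[1:] + [0.0]):
            if a <= x < b:
                return f"{_fmt(a)}~{_fmt(b)}"
        return "0"  # unreachable: x in [-zero_tol, 0) handled above
    for a, b in zip([0.0] + pos, pos):
        if a < x <= b:
            return f"{_fmt(a)}~{_fmt(b)}"
    return f">{_fmt(pos[-1])}" if pos else "0"


def extreme_reactions(
    w: pd.Series,
    scopes: list[str],
    annotations: dict[str, str] | None = None,
    zero_tol: float = ZERO_TOL,
) -> dict[str, list[str]]:
    """Reaction ids per requested scope string, sorted by |w| descending.

    Scope strings: ``"<x"``, ``">x"`` or ``"a~b"`` (same half-open
    convention as :func:`bin_weights`).  These are the highly-dissipative
    reaction reports when the scopes sit in the distribution tails.
    """
    out: dict[str, list[str]] = {}
    for scope in scopes:
        mask = _scope_mask(w, scope, zero_tol)
        rids = w[mask].abs().sort_values(ascending=False).index.tolist()
        if annotations:
            rids = [f"{r} ({annotations[r]})" if r in annotations else r for r in rids]
        out[scope] = rids
    return out


_RANGE_RE = re.compile(r"^\s*(-?[\d.]+)\s*~\s*(-?[\d.]+)\s*$")


def _scope_mask(w: pd.Series, scope: str, zero_tol: float) -> pd.Series:
    x = w.where(w.abs() > zero_tol, 0.0)
    s = scope.strip()
    if s.startswith("<"):
        return x < float(s[1:])
    if s.startswith(">"):
        return x > float(s[1:])
    m = _RANGE_RE.match(s)
    if not m:
        raise ValueError(f"unparsable scope {scope!r}")
    a, b = float(m.group(1)), float(m.group(2))
    if b <= 0:
        return (x >= a) & (x < b)
    return (x > a) & (x <= b)


def scatter_and_correlation(
    w: pd.Series, v: pd.Series
) -> tuple[pd.DataFrame, float | None, float | None]:
    """(w, v) pair table plus the Pearson correlation and its p-value.

    Constant vectors have undefined correlation; ``(table, None, None)`` is
    returned with a warning instead of raising.
    """
    if len(w) != len(v):
        raise ValueError(f"length mismatch: {len(w)} weights vs {len(v)} fluxes")
    table = pd.DataFrame({"w": w.to_numpy(), "v": v.reindex(w.index).to_numpy()},
                         index=w.index)
    if np.std(table["w"]) == 0 or np.std(table["v"]) == 0:
        logger.warning("constant vector: Pearson correlation undefined")
        return table, None, None
    r, p = stats.pearsonr(table["w"], table["v"])
    return table, float(r), float(p)


# --------------------------------------------------------------------------
# graph export
# --------------------------------------------------------------------------

def build_graph(model: StoichiometricModel, w: pd.Series) -> nx.DiGraph:
    """Bipartite species–reaction digraph.

    Species nodes carry ``type='metabolite'``; reaction nodes carry
    ``type='reaction'`` and, when weighted, attribute ``w``.  Edges run
    species→reaction for reactants (negative coefficient) and
    reaction→species for products, with the coefficient on the edge.
    """
    g = nx.DiGraph()
    for sid in model.species_ids:
        g.add_node(sid, type="metabolite")
    for rid in model.reaction_ids:
        attrs = {"type": "reaction"}
        if rid in w.index:
            attrs["w"] = float(w[rid])
        g.add_node(rid, **attrs)
    coo = model.S.tocoo()
    for i, j, coeff in zip(coo.row, coo.col, coo.data):
        sid, rid = model.species_ids[i], model.reaction_ids[j]
        if coeff < 0:
            g.add_edge(sid, rid, coefficient=float(coeff))
        else:
            g.add_edge(rid, sid, coefficient=float(coeff))
    return g


def reaction_projection(model: StoichiometricModel, w: pd.Series) -> nx.Graph:
    """Reaction-adjacency projection: reactions sharing a metabolite are
    linked, edge weight = mean of the two reaction weights."""
    g = nx.Graph()
    for rid in w.index:
        g.add_node(rid, w=float(w[rid]))
    S = model.S.tocsr()
    for i in range(model.n_species):
        touching = [
            r for r in (model.reaction_ids[j] for j in S.getrow(i).indices)
            if r in w.index
        ]
        for a in range(len(touching)):
            for b in range(a + 1, len(touching)):
                ra, rb = touching[a], touching[b]
                g.add_edge(ra, rb, weight=(float(w[ra]) + float(w[rb])) / 2.0)
    return g


def export_graph(
    model: StoichiometricModel,
    w: pd.Series,
    path: str | Path,
    format: str = "graphml",
) -> None:
    """Write the bipartite weighted graph as GraphML or an edge-list TSV."""
    g = build_graph(model, w)
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "tsv":
        rows = [
            (u, v, d.get("coefficient", ""))
            for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "coefficient"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown graph format {format!r}")
    logger.info("wrote %s graph: %d nodes, %d edges", format,
                g.number_of_nodes(), g.number_of_edges())
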
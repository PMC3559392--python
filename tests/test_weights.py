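"""Energetic weights, their histogram, extremes, correlation and graph."""

import numpy as np
import pandas as pd
import pytest

from thermoweight.weights import (
    MissingEnergyError,
    bin_weights,
    build_graph,
    compute_weights,
    export_graph,
    extreme_reactions,
    reaction_projection,
    scatter_and_correlation,
)


def test_weight_is_energy_times_flux():
    w = compute_weights({"R1": -10.0}, {"R1": 5.0}, ["R1"])
    assert w["R1"] == -50.0


def test_zero_flux_gives_zero_weight():
    w = compute_weights({"R1": -10.0, "R2": 3.0},
                        {"R1": 0.0, "R2": 1e-12}, ["R1", "R2"])
    assert w["R1"] == 0.0
    assert w["R2"] == 0.0  # below the zero tolerance


def test_elementwise_product_matches_loop_oracle():
    rng = np.random.default_rng(3)
    rids = [f"R{i}" for i in range(20)]
    dgm = dict(zip(rids, rng.normal(scale=50, size=20)))
    v = dict(zip(rids, rng.normal(scale=5, size=20)))
    w = compute_weights(dgm, v, rids)
    for rid in rids:  # naive loop oracle
        assert w[rid] == pytest.approx(dgm[rid] * v[rid], abs=1e-12)


def test_missing_energy_named(chain_model):
    with pytest.raises(MissingEnergyError, match="CONV"):
        compute_weights({}, {"CONV": 1.0}, ["CONV"])


def test_sign_property():
    rng = np.random.default_rng(5)
    rids = [f"R{i}" for i in range(50)]
    dgm = dict(zip(rids, rng.normal(scale=50, size=50)))
    v = dict(zip(rids, rng.normal(scale=5, size=50)))
    w = compute_weights(dgm, v, rids)
    for rid in rids:
        if abs(v[rid]) > 1e-9 and abs(w[rid]) > 1e-9:
            assert (w[rid] < 0) == (np.sign(dgm[rid]) != np.sign(v[rid]))


# --------------------------------------------------------------------------
# binning
# --------------------------------------------------------------------------

def test_hand_binned_example():
    w = pd.Series({"a": -250.0, "b": -10.0, "c": 0.0, "d": 5.0})
    hist = bin_weights(w)
    assert hist["count"].tolist() == [1, 0, 0, 1, 1, 1, 0, 0]
    assert hist["scope"].tolist() == [
        "<-200", "-200~-100", "-100~-50", "-50~0", "0", "0~40", "40~100",
        ">100",
    ]


def test_bin_counts_partition_weights():
    rng = np.random.default_rng(9)
    vals = np.concatenate([rng.normal(scale=150, size=300), np.zeros(100)])
    w = pd.Series(vals, index=[f"R{i}" for i in range(400)])
    hist = bin_weights(w)
    assert hist["count"].sum() == len(w)


def test_boundary_values_land_in_one_bin():
    # negative scopes are [lo, hi); positive scopes are (lo, hi]
    w = pd.Series({"a": -200.0, "b": -100.0, "c": 40.0, "d": 100.0})
    hist = bin_weights(w).set_index("scope")["count"]
    assert hist["<-200"] == 0
    assert hist["-200~-100"] == 1   # −200 included on the left
    assert hist["-100~-50"] == 1    # −100 moves up into the next scope
    assert hist["0~40"] == 1        # 40 included on the right
    assert hist["40~100"] == 1
    assert hist[">100"] == 0
    assert hist.sum() == 4


def test_percentages_round_to_two_decimals():
    # 1753 zeros among 2077 weights → 84.40%
    vals = np.zeros(2077)
    vals[:324] = -10.0
    w = pd.Series(vals, index=[f"R{i}" for i in range(2077)])
    hist = bin_weights(w).set_index("scope")
    assert hist.loc["0", "count"] == 1753
    assert hist.loc["0", "percent"] == 84.40
    assert hist.loc["-50~0", "percent"] == pytest.approx(15.60)


def test_bad_bin_specs_rejected():
    w = pd.Series({"a": 1.0})
    with pytest.raises(ValueError, match="increasing"):
        bin_weights(w, edges=(-100.0, -200.0, 0.0))
    with pytest.raises(ValueError, match="0"):
        bin_weights(w, edges=(-100.0, 50.0))


# --------------------------------------------------------------------------
# extremes
# --------------------------------------------------------------------------

def test_extreme_scope_selects_single_reaction():
    w = pd.Series({"BIG": -300.0, "SMALL": -5.0})
    out = extreme_reactions(w, ["<-200"])
    assert out["<-200"] == ["BIG"]


def test_extreme_empty_scope():
    w = pd.Series({"a": -5.0})
    assert extreme_reactions(w, [">100"]) == {">100": []}


def test_extremes_sorted_by_magnitude_with_annotations():
    w = pd.Series({"a": -300.0, "b": -500.0, "c": 10.0})
    out = extreme_reactions(w, ["<-200", "0~40"], annotations={"b": "resp"})
    assert out["<-200"] == ["b (resp)", "a"]
    assert out["0~40"] == ["c"]


def test_extreme_range_scope_convention():
    w = pd.Series({"a": -100.0, "b": -50.0, "c": -75.0})
    out = extreme_reactions(w, ["-100~-50"])
    # [lo, hi): −100 included, −50 not
    assert set(out["-100~-50"]) == {"a", "c"}


# --------------------------------------------------------------------------
# correlation
# --------------------------------------------------------------------------

def test_perfect_linearity_gives_r_one():
    w = pd.Series(np.arange(1.0, 11.0), index=[f"R{i}" for i in range(10)])
    _, r, p = scatter_and_correlation(w, 3.0 * w)
    assert r == pytest.approx(1.0)


def test_constant_vector_flags_undefined():
    w = pd.Series(np.ones(5), index=list("abcde"))
    v = pd.Series(np.arange(5.0), index=list("abcde"))
    _, r, p = scatter_and_correlation(w, v)
    assert r is None and p is None


def test_correlation_matches_textbook_formula():
    rng = np.random.default_rng(21)
    idx = [f"R{i}" for i in range(50)]
    w = pd.Series(rng.normal(size=50), index=idx)
    v = pd.Series(0.3 * w.to_numpy() + rng.normal(size=50), index=idx)
    _, r, _ = scatter_and_correlation(w, v)
    x, y = w.to_numpy(), v.to_numpy()
    oracle = (((x - x.mean()) * (y - y.mean())).sum()
              / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
    assert r == pytest.approx(oracle, abs=1e-10)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        scatter_and_correlation(pd.Series([1.0]), pd.Series([1.0, 2.0]))


# --------------------------------------------------------------------------
# graph export
# --------------------------------------------------------------------------

def test_toy_graph_counts(model_builder):
    model = model_builder(
        {
            "R1": {"a[c]": -1.0, "b[c]": 1.0},
            "R2": {"b[c]": -1.0, "c[c]": 1.0},
        },
        objective={"R1": 1.0},
    )
    w = pd.Series({"R1": -5.0, "R2": 2.0})
    g = build_graph(model, w)
    assert g.number_of_nodes() == 5  # 3 species + 2 reactions
    assert g.number_of_edges() == 4
    assert g.nodes["R1"]["w"] == -5.0
    # reactants point into the reaction, products out of it
    assert g.has_edge("a[c]", "R1") and g.has_edge("R1", "b[c]")


def test_graphml_round_trip_preserves_weights(tmp_path, model_builder):
    import networkx as nx

    model = model_builder(
        {"R1": {"a[c]": -1.0, "b[c]": 1.0}}, objective={"R1": 1.0},
    )
    w = pd.Series({"R1": -7.25})
    path = tmp_path / "net.graphml"
    export_graph(model, w, path, format="graphml")
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
    assert float(g.nodes["R1"]["w"]) == -7.25


def test_tsv_export_and_bad_format(tmp_path, model_builder):
    model = model_builder(
        {"R1": {"a[c]": -1.0, "b[c]": 1.0}}, objective={"R1": 1.0},
    )
    w = pd.Series({"R1": 1.0})
    export_graph(model, w, tmp_path / "net.tsv", format="tsv")
    df = pd.read_csv(tmp_path / "net.tsv", sep="\t")
    assert len(df) == 2
    with pytest.raises(ValueError, match="format"):
        export_graph(model, w, tmp_path / "x", format="gexf")


def test_reaction_projection_links_sharing_reactions(model_builder):
    model = model_builder(
        {
            "R1": {"a[c]": -1.0, "b[c]": 1.0},
            "R2": {"b[c]": -1.0, "c[c]": 1.0},
            "R3": {"d[c]": -1.0, "e[c]": 1.0},
        },
        objective={"R1": 1.0},
    )
    w = pd.Series({"R1": -4.0, "R2": 2.0, "R3": 1.0})
    g = reaction_projection(model, w)
    assert g.has_edge("R1", "R2")
    assert g["R1"]["R2"]["weight"] == pytest.approx(-1.0)  # mean of −4 and 2
    assert not g.has_edge("R1", "R3")
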
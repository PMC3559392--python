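"""Least-squares completion of formation and reaction energies."""

import numpy as np
import pytest

from thermoweight.infer import (
    InferenceProblem,
    UnderdeterminedSystemError,
    back_substitute,
    build_inference_system,
    build_transfer_matrix,
    complete_energies,
    solve_least_squares,
)
from thermoweight.synthetic import SyntheticSpec, generate
from thermoweight.thermo import EnergyTables


def _tables(formation=None, reaction=None):
    t = EnergyTables()
    for c, v in (formation or {}).items():
        t.set_formation(c, v, "input")
    for r, v in (reaction or {}).items():
        t.set_reaction(r, v, "input")
    return t


# --------------------------------------------------------------------------
# transfer matrix
# --------------------------------------------------------------------------

def test_transfer_matrix_spans_compartments(model_builder):
    model = model_builder(
        {
            "R1": {"u[c]": -1.0, "a[c]": 1.0},
            "R2": {"u[p]": -1.0, "a[c]": 1.0},
        },
        objective={"R1": 1.0},
    )
    tables = _tables(formation={"a": -5.0})
    T, x_ids = build_transfer_matrix(model, tables)
    assert x_ids == ["u"]
    col = T.toarray()[:, 0]
    assert col.sum() == 2  # one 1 per compartmental instance
    assert set(np.nonzero(col)[0]) == {
        model.species_ids.index("u[c]"), model.species_ids.index("u[p]")
    }
    # every row has at most one nonzero entry, equal to 1
    assert T.toarray().max() == 1.0
    assert (T.toarray().sum(axis=1) <= 1).all()


def test_transfer_matrix_all_known_is_empty(model_builder, caplog):
    model = model_builder({"R1": {"a[c]": -1.0, "b[c]": 1.0}},
                          objective={"R1": 1.0})
    with caplog.at_level("WARNING"):
        T, x_ids = build_transfer_matrix(model, _tables(formation={"a": 0.0, "b": 1.0}))
    assert T.shape[1] == 0 and x_ids == []


# --------------------------------------------------------------------------
# system assembly
# --------------------------------------------------------------------------

def test_single_equation_system(model_builder):
    # A → B, ΔGf(A)=0 known, ΔGf(B) unknown, F = −10 known ⇒ Q=[1], b=[−10]
    model = model_builder({"R1": {"a[c]": -1.0, "b[c]": 1.0}},
                          objective={"R1": 1.0})
    tables = _tables(formation={"a": 0.0}, reaction={"R1": -10.0})
    T, x_ids = build_transfer_matrix(model, tables)
    problem = build_inference_system(model, tables, T, x_ids)
    np.testing.assert_allclose(problem.Q, [[1.0]])
    np.testing.assert_allclose(problem.b, [-10.0])
    assert problem.usable_rows == ["R1"]


def test_known_reaction_without_unknowns_excluded(model_builder):
    model = model_builder(
        {
            "R1": {"a[c]": -1.0, "u[c]": 1.0},
            "R2": {"a[c]": -1.0, "b[c]": 1.0},  # touches no unknown
        },
        objective={"R1": 1.0},
    )
    tables = _tables(formation={"a": -1.0, "b": -2.0},
                     reaction={"R1": 5.0, "R2": -1.0})
    T, x_ids = build_transfer_matrix(model, tables)
    problem = build_inference_system(model, tables, T, x_ids)
    assert problem.usable_rows == ["R1"]


def test_zero_usable_rows_with_unknowns_raises(model_builder):
    model = model_builder({"R1": {"a[c]": -1.0, "u[c]": 1.0}},
                          objective={"R1": 1.0})
    tables = _tables(formation={"a": 0.0})  # R1's energy unknown too
    T, x_ids = build_transfer_matrix(model, tables)
    with pytest.raises(UnderdeterminedSystemError, match="u"):
        build_inference_system(model, tables, T, x_ids)


# --------------------------------------------------------------------------
# least squares
# --------------------------------------------------------------------------

def test_exact_1x1_solve():
    p = InferenceProblem(X_ids=["u"], P=np.zeros(2), T_mat=None,
                         Q=np.array([[1.0]]), b=np.array([-10.0]),
                         usable_rows=["R1"])
    solve_least_squares(p)
    np.testing.assert_allclose(p.X0, [-10.0])
    np.testing.assert_allclose(p.residuals, [0.0], atol=1e-12)
    assert p.rank == 1


def test_consistent_overdetermined_matches_normal_equations():
    # two reactions constraining one compound to the same value
    Q = np.array([[1.0], [2.0]])
    b = np.array([3.0, 6.0])
    p = InferenceProblem(X_ids=["u"], P=np.zeros(1), T_mat=None, Q=Q, b=b,
                         usable_rows=["R1", "R2"])
    solve_least_squares(p)
    # independent normal-equations oracle: (QᵀQ) x = Qᵀ b
    oracle = np.linalg.solve(Q.T @ Q, Q.T @ b)
    np.testing.assert_allclose(p.X0, oracle, atol=1e-10)
    np.testing.assert_allclose(p.residuals, 0.0, atol=1e-10)


def test_random_systems_match_pseudoinverse_oracle():
    rng = np.random.default_rng(42)
    for _ in range(20):
        m, n = rng.integers(1, 9), rng.integers(1, 7)
        Q = rng.normal(size=(m, n))
        b = rng.normal(size=m)
        p = InferenceProblem(X_ids=[f"u{i}" for i in range(n)], P=np.zeros(1),
                             T_mat=None, Q=Q, b=b, usable_rows=[])
        solve_least_squares(p)
        np.testing.assert_allclose(p.X0, np.linalg.pinv(Q) @ b, atol=1e-8)


def test_rank_deficient_returns_minimum_norm():
    # two unknowns appearing only as a sum: solution line x0 + x1 = 4
    Q = np.array([[1.0, 1.0]])
    b = np.array([4.0])
    p = InferenceProblem(X_ids=["u0", "u1"], P=np.zeros(1), T_mat=None,
                         Q=Q, b=b, usable_rows=["R1"])
    solve_least_squares(p)
    assert p.rank == 1
    # 1-D grid-search oracle along the solution line
    ts = np.linspace(-10, 10, 20001)
    sols = np.stack([2.0 + ts, 2.0 - ts], axis=1)
    norms = np.linalg.norm(sols, axis=1)
    best = sols[np.argmin(norms)]
    np.testing.assert_allclose(p.X0, best, atol=1e-6)
    assert set(p.weakly_determined) == {"u0", "u1"}


def test_nonfinite_system_rejected(model_builder):
    model = model_builder({"R1": {"a[c]": -1.0, "u[c]": 1.0}},
                          objective={"R1": 1.0})
    tables = _tables(reaction={"R1": 0.0})
    tables.formation["a"] = float("inf")  # bypass the setter's finiteness check
    T, x_ids = build_transfer_matrix(model, tables)
    with pytest.raises(ValueError, match="non-finite"):
        build_inference_system(model, tables, T, x_ids)


# --------------------------------------------------------------------------
# back substitution and the completion driver
# --------------------------------------------------------------------------

def test_two_step_chain_back_substitution(model_builder):
    # A → B with F=−10 known fixes ΔGf(B)=−10; B → C with ΔGf(C)=−25 known
    # then gets inferred F = (−25) − (−10) = −15
    model = model_builder(
        {
            "R1": {"a[c]": -1.0, "b[c]": 1.0},
            "R2": {"b[c]": -1.0, "c[c]": 1.0},
        },
        objective={"R1": 1.0},
    )
    tables = _tables(formation={"a": 0.0, "c": -25.0}, reaction={"R1": -10.0})
    tables, problem, report = complete_energies(model, tables)
    assert tables.formation["b"] == pytest.approx(-10.0)
    assert tables.reaction["R2"] == pytest.approx(-15.0)
    assert tables.reaction_provenance["R2"] == "inferred"
    assert tables.reaction_provenance["R1"] == "input"


def test_known_energies_never_overwritten(synth_default):
    result = synth_default
    original = dict(result.masked.reaction)
    tables, _, _ = complete_energies(result.model, result.masked)
    for rid, val in original.items():
        assert tables.reaction[rid] == val


def test_completion_idempotent(synth_default):
    tables, problem, _ = complete_energies(synth_default.model,
                                           synth_default.masked)
    after = dict(tables.formation)
    tables2, problem2, _ = complete_energies(synth_default.model, tables)
    assert problem2.n_unknown == 0
    assert tables2.formation == after


def test_all_known_completion_is_noop(model_builder):
    model = model_builder({"R1": {"a[c]": -1.0, "b[c]": 1.0}},
                          objective={"R1": 1.0})
    tables = _tables(formation={"a": -3.0, "b": -7.0}, reaction={"R1": -4.0})
    tables, problem, report = complete_energies(model, tables)
    assert problem.n_unknown == 0
    assert tables.reaction["R1"] == -4.0


def test_conservation_relation_on_completed_tables(synth_default):
    # every completed reaction energy equals Σ sᵢ·ΔGf(i) of its species
    model = synth_default.model
    tables, _, _ = complete_energies(model, synth_default.masked)
    P = np.array([tables.formation[model.species_to_compound[s]]
                  for s in model.species_ids])
    F0 = model.S.T @ P
    for rid, f0 in zip(model.reaction_ids, F0):
        if tables.reaction_provenance[rid] == "inferred":
            assert tables.reaction[rid] == pytest.approx(f0, abs=1e-8)


# --------------------------------------------------------------------------
# recovery and consistency reporting
# --------------------------------------------------------------------------

def test_noise_free_recovery(synth_noisefree_large):
    result = synth_noisefree_large
    assert result.constraint_rank == len(result.masked_compounds)
    tables, problem, report = complete_energies(result.model, result.masked)
    for c in result.masked_compounds:
        truth = result.truth.formation[c]
        assert abs(tables.formation[c] - truth) <= 1e-6 * max(abs(truth), 1.0)
    comparable = report[report.category != "unknown_dGr"]
    assert (comparable.verdict == "consistent").all()
    assert (comparable.max_discrepancy.fillna(0) <= 1e-8).all()


def test_consistency_categories_partition(synth_default):
    model = synth_default.model
    _, problem, report = complete_energies(model, synth_default.masked)
    by = dict(zip(report.category, report.n_reactions))
    assert by["known_dGr_with_unknown_compounds"] == len(problem.usable_rows)
    assert (by["known_dGr_with_unknown_compounds"]
            + by["known_dGr_no_unknown_compounds"]) == by["all_known_dGr"]
    assert by["unknown_dGr"] + by["all_known_dGr"] == model.n_reactions


def test_noise_inflates_constrained_category_only():
    sigmas = {}
    for sd in (1.0, 4.0):
        result = generate(SyntheticSpec(seed=11, noise_sd=sd))
        _, _, report = complete_energies(result.model, result.masked)
        by = report.set_index("category")
        # reactions not touching masked compounds stay exactly consistent
        assert by.loc["known_dGr_no_unknown_compounds", "max_discrepancy"] == 0.0
        sigmas[sd] = by.loc["known_dGr_with_unknown_compounds",
                            "rms_discrepancy"]
    assert sigmas[4.0] > sigmas[1.0] > 0.0
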
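"""Reaction-network engine: stoichiometry, rate laws against hand-coded
oracles, conservation analysis, Jacobian, and the text fixture format."""

import numpy as np
import pytest

from trailkin.network import (
    NetworkModel,
    NetworkValidationError,
    ReactionDef,
    SpeciesDef,
    build_network,
    conserved_moieties,
    jacobian_function,
    rate_function,
    read_network_tsv,
    write_network_tsv,
)


def p1(label="cat", **kw):
    kw.setdefault("enzyme", "E"); kw.setdefault("substrate", "S")
    kw.setdefault("complex", "E:S"); kw.setdefault("product", "P")
    return ReactionDef(label=label, paradigm=1, **kw)


def four_species(**initials):
    return [SpeciesDef(n, initial=initials.get(n, 0.0)) for n in ("E", "S", "E:S", "P")]


class TestBuildNetwork:
    def test_inert_network_has_zero_derivative(self):
        model = build_network([SpeciesDef("X", initial=3.0)], [])
        f = rate_function(model)
        assert f(0.0, np.array([3.0])).tolist() == [0.0]
        # the lone species contributes its own conservation vector
        assert [v.tolist() for v in conserved_moieties(model)] == [[1]]

    def test_binding_pair_stoichiometry(self):
        model = build_network(four_species()[:3],
                              [ReactionDef("b", 3, enzyme="E", substrate="S",
                                           complex="E:S", k_plus=1.0, k_minus=2.0)])
        # forward and backward columns, hand-written
        assert model.stoichiometry.T.tolist() == [[-1, -1, 1], [1, 1, -1]]

    def test_dangling_reference_rejected(self):
        with pytest.raises(NetworkValidationError, match="undeclared"):
            build_network(four_species()[:3], [p1()])

    def test_duplicate_names_rejected(self):
        with pytest.raises(NetworkValidationError, match="duplicate"):
            build_network([SpeciesDef("X"), SpeciesDef("X")], [])

    def test_negative_rate_rejected(self):
        with pytest.raises(NetworkValidationError):
            p1(k_plus=-1.0)

    def test_paradigm3_shape_constraints(self):
        with pytest.raises(NetworkValidationError, match="no product"):
            ReactionDef("b", 3, enzyme="E", substrate="S", complex="E:S",
                        product="P", k_plus=1.0)


class TestRateLaws:
    def test_paradigm1_hand_substitution(self):
        # [E,S,ES,P] = [2,3,1,0], k+=0.5, k-=0.1, K+=0.2:
        # dE = -0.5*6 + 0.1 + 0.2 = -2.7 ; dS = -3 + 0.1 = -2.9
        # dES = 3 - 0.1 - 0.2 = 2.7     ; dP = 0.2
        model = build_network(four_species(E=2, S=3), [p1(k_plus=0.5, k_minus=0.1,
                                                          k_cat=0.2)])
        dy = rate_function(model)(0.0, np.array([2.0, 3.0, 1.0, 0.0]))
        assert dy == pytest.approx([-2.7, -2.9, 2.7, 0.2])

    def test_paradigm3_unit_forward_flux(self):
        model = build_network(four_species()[:3],
                              [ReactionDef("b", 3, enzyme="E", substrate="S",
                                           complex="E:S", k_plus=1.0, k_minus=0.0)])
        dy = rate_function(model)(0.0, np.array([1.0, 1.0, 0.0]))
        assert dy == pytest.approx([-1.0, -1.0, 1.0])

    def test_paradigm3_detailed_balance(self):
        model = build_network(four_species()[:3],
                              [ReactionDef("b", 3, enzyme="E", substrate="S",
                                           complex="E:S", k_plus=2.0, k_minus=4.0)])
        # k+ [E][S] = k- [E:S]:  2*1*2 = 4*1
        dy = rate_function(model)(0.0, np.array([1.0, 2.0, 1.0]))
        assert dy == pytest.approx([0.0, 0.0, 0.0], abs=1e-14)

    def test_state_length_mismatch(self):
        model = build_network(four_species(), [p1(k_plus=1.0)])
        with pytest.raises(ValueError, match="shape"):
            rate_function(model)(0.0, np.zeros(3))

    def test_evaluator_matches_hand_coded_paradigms_on_random_states(self):
        """All four paradigms, 1000 random states, against independently
        hand-coded rate expressions (relative error < 1e-12)."""
        species = [SpeciesDef(n) for n in
                   ("E", "S", "E:S", "P", "E2", "S2", "E2:S2", "P2",
                    "B1", "B2", "B1:B2", "Xs", "Xd")]
        model = build_network(species, [
            p1("r1", k_plus=0.31, k_minus=0.07, k_cat=1.3),
            ReactionDef("r2", 2, enzyme="E2", substrate="S2", complex="E2:S2",
                        product="P2", k_plus=0.11, k_minus=0.05, k_cat=0.9),
            ReactionDef("r3", 3, enzyme="B1", substrate="B2", complex="B1:B2",
                        k_plus=0.21, k_minus=0.4),
            ReactionDef("r4", 4, substrate="Xs", product="Xd",
                        k_plus=0.6, k_minus=0.02),
        ])
        f = rate_function(model)
        rng = np.random.default_rng(12345)
        idx = {s.name: i for i, s in enumerate(species)}

        def hand(y):
            d = np.zeros_like(y)
            E, S, ES, P = (y[idx[n]] for n in ("E", "S", "E:S", "P"))
            v_f, v_b, v_c = 0.31 * E * S, 0.07 * ES, 1.3 * ES
            d[idx["E"]] += -v_f + v_b + v_c
            d[idx["S"]] += -v_f + v_b
            d[idx["E:S"]] += v_f - v_b - v_c
            d[idx["P"]] += v_c
            E, S, ES, P = (y[idx[n]] for n in ("E2", "S2", "E2:S2", "P2"))
            v_f, v_b, v_c = 0.11 * E * S, 0.05 * ES, 0.9 * ES
            d[idx["E2"]] += -v_f + v_b
            d[idx["S2"]] += -v_f + v_b
            d[idx["E2:S2"]] += v_f - v_b - v_c
            d[idx["P2"]] += v_c
            v_f, v_b = 0.21 * y[idx["B1"]] * y[idx["B2"]], 0.4 * y[idx["B1:B2"]]
            d[idx["B1"]] += -v_f + v_b
            d[idx["B2"]] += -v_f + v_b
            d[idx["B1:B2"]] += v_f - v_b
            v = 0.6 * y[idx["Xs"]] - 0.02 * y[idx["Xd"]]
            d[idx["Xs"]] += -v
            d[idx["Xd"]] += v
            return d

        for _ in range(1000):
            y = rng.uniform(0.0, 10.0, size=len(species))
            got, want = f(0.0, y), hand(y)
            assert np.allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_homodimerization_consumes_two_copies(self):
        species = [SpeciesDef("A", initial=4.0), SpeciesDef("A2")]
        model = build_network(species, [ReactionDef(
            "dim", 3, enzyme="A", substrate="A", complex="A2",
            k_plus=0.5, k_minus=0.25)])
        dy = rate_function(model)(0.0, np.array([4.0, 1.0]))
        # forward 0.5*16 = 8 (consumes 2A), backward 0.25 (returns 2A)
        assert dy == pytest.approx([-16.0 + 0.5, 8.0 - 0.25])


class TestJacobian:
    def test_matches_finite_differences(self):
        model = build_network(four_species(E=2, S=3),
                              [p1(k_plus=0.5, k_minus=0.1, k_cat=0.2)])
        f, jac = rate_function(model), jacobian_function(model)
        y = np.array([2.0, 3.0, 1.0, 0.5])
        J = jac(0.0, y)
        eps = 1e-7
        for j in range(4):
            dy = np.zeros(4); dy[j] = eps
            col = (f(0.0, y + dy) - f(0.0, y - dy)) / (2 * eps)
            assert np.allclose(J[:, j], col, rtol=1e-6, atol=1e-8)


class TestConservation:
    def test_binding_pair_has_two_moieties(self):
        model = build_network(four_species()[:3],
                              [ReactionDef("b", 3, enzyme="E", substrate="S",
                                           complex="E:S", k_plus=1.0, k_minus=1.0)])
        vs = conserved_moieties(model)
        assert len(vs) == 2
        for v in vs:
            assert (v @ model.stoichiometry == 0).all()

    def test_paradigm1_moieties_are_enzyme_and_substrate_totals(self):
        model = build_network(four_species(), [p1(k_plus=1.0, k_minus=1.0, k_cat=1.0)])
        vs = conserved_moieties(model)
        assert len(vs) == 2   # the left null space is two-dimensional ...
        # ... and contains the hand-derived totals E + E:S and S + E:S + P
        # (species order E, S, E:S, P)
        for total in ([1, 0, 1, 0], [0, 1, 1, 1]):
            assert (np.array(total) @ model.stoichiometry == 0).all()

    def test_moiety_derivative_is_zero_on_random_states(self):
        model = build_network(four_species(), [p1(k_plus=0.7, k_minus=0.2, k_cat=1.1)])
        f = rate_function(model)
        rng = np.random.default_rng(7)
        vs = conserved_moieties(model)
        for _ in range(100):
            y = rng.uniform(0, 5, size=4)
            for v in vs:
                assert abs(v @ f(0.0, y)) < 1e-12 * max(1.0, np.abs(f(0.0, y)).max())


class TestFixtureFormat:
    def test_round_trip_and_determinism(self, tmp_path):
        model = build_network(four_species(E=2, S=3),
                              [p1(k_plus=0.5, k_minus=0.1, k_cat=0.2)])
        path1, path2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_network_tsv(model, path1, header_comment="toy")
        back = read_network_tsv(path1)
        assert back.names == model.names
        assert back.reactions == model.reactions
        assert np.array_equal(back.stoichiometry, model.stoichiometry)
        write_network_tsv(back, path2, header_comment="toy")
        assert path1.read_bytes() == path2.read_bytes()

    def test_malformed_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("[species]\nname\tcompartment\trole\n")
        with pytest.raises(NetworkValidationError):
            read_network_tsv(bad)


def test_overrides_touch_only_named_entries():
    model = build_network(four_species(E=2, S=3), [p1(k_plus=0.5, k_minus=0.1,
                                                      k_cat=0.2)])
    new = model.with_overrides(initials={"E": 7.0},
                               reaction_rates={"cat": {"k_plus": 1.5}})
    assert new.initial_state.tolist() == [7.0, 3.0, 0.0, 0.0]
    assert new.reactions[0].k_plus == 1.5
    assert new.reactions[0].k_minus == 0.1
    with pytest.raises(KeyError):
        model.with_overrides(initials={"nope": 1.0})
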
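import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from feedprot import (
    InferenceConfig,
    ProteinEntry,
    ValidationError,
    build_index,
    protein_probability,
    run_inference,
)
from feedprot.inference_engine import (
    IterationSnapshot,
    PeptideState,
    ProteinState,
    apply_elimination,
    check_convergence,
    putative_proteins,
    recompute_peptide_probabilities,
    replenish_peptides,
    select_peptides,
)
from feedprot.intensity_weights import WeightAssignment

from _oracle import straight_line_loop
from conftest import make_psm


class TestProteinProbability:
    def test_certain_evidence_limit(self):
        assert protein_probability([1.0], [1.0], 1.0, 1, 1) == 1.0

    def test_zero_evidence_limit(self):
        assert protein_probability([0.0, 0.0], [1.0, 1.0], 1.0, 2, 20) == 0.0
        assert protein_probability([], [], 1.0, 0, 5) == 0.0

    def test_exponent_zero_with_no_positive_evidence(self):
        # bracket 0 with n_k == N_k: 0**0 resolves to 0, not 1
        assert protein_probability([0.0], [1.0], 1.0, 1, 1) == 0.0

    def test_hand_derived_two_peptide_case(self):
        q = protein_probability([0.9, 0.8], [1.0, 1.0], 1.0, 2, 20)
        independent = math.exp(-math.log(2 / 20) * math.log(1 - 0.1 * 0.2))
        assert q == pytest.approx(independent, abs=1e-9)
        assert q == pytest.approx(0.95455, abs=5e-6)

    def test_log_base_override_rescales_exponent(self):
        q_nat = protein_probability([0.9], [1.0], 1.0, 1, 10)
        q_b10 = protein_probability([0.9], [1.0], 1.0, 1, 10, log_base=10.0)
        assert q_b10 == pytest.approx(0.9 ** 1.0)
        assert q_nat < q_b10

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            protein_probability([0.9], [1.0, 1.0], 1.0, 2, 5)

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=1, max_size=6
        ),
        q_prev=st.floats(0, 1),
        extra_n=st.integers(0, 10),
        bump=st.floats(0, 1),
        index=st.integers(0, 5),
    )
    def test_monotonicity(self, data, q_prev, extra_n, bump, index):
        xs = [x for x, _ in data]
        ws = [w for _, w in data]
        n = len(xs)
        N = n + extra_n
        base = protein_probability(xs, ws, q_prev, n, N)
        # raising any x_i never decreases q
        i = index % n
        xs_up = list(xs)
        xs_up[i] = min(1.0, xs_up[i] + bump * (1 - xs_up[i]))
        assert protein_probability(xs_up, ws, q_prev, n, N) >= base - 1e-12
        # raising w_ik never decreases q
        ws_up = list(ws)
        ws_up[i] = min(1.0, ws_up[i] + bump * (1 - ws_up[i]))
        assert protein_probability(xs, ws_up, q_prev, n, N) >= base - 1e-12
        # raising q_prev never decreases q
        q_up = min(1.0, q_prev + bump * (1 - q_prev))
        assert protein_probability(xs, ws, q_up, n, N) >= base - 1e-12
        # appending a positive-evidence peptide (N fixed) never decreases q
        if N > n:
            grown = protein_probability(
                xs + [0.5], ws + [0.5], q_prev, n + 1, N
            )
            assert grown >= base - 1e-12
        assert 0.0 <= base <= 1.0


def pep(seq, x, parents, selected=False, initial=None):
    return PeptideState(
        peptide_sequence=seq,
        x=x,
        initial_x=x if initial is None else initial,
        selected=selected,
        parents=frozenset(parents),
    )


class TestLoopSteps:
    def test_selection_threshold_and_elimination(self):
        peptides = {
            "A": pep("A", 0.99, {"P1"}),
            "B": pep("B", 0.95, {"P2"}),
            "C": pep("C", 0.90, {"P1"}),
        }
        assert select_peptides(peptides, 0.95) == {"A", "B"}
        assert select_peptides(peptides, 1.0) == set()
        assert select_peptides(peptides, 0.95, eliminated={"P2"}) == {"A"}

    def test_putative_union_minus_eliminated(self):
        psms = [make_psm("AK", ["P1"]), make_psm("CK", ["P1", "P2"])]
        index = build_index(psms, [])
        assert putative_proteins({"AK", "CK"}, index) == {"P1", "P2"}
        assert putative_proteins({"AK", "CK"}, index, eliminated={"P2"}) == {"P1"}

    def test_replenishment_rule(self):
        psms = [make_psm("AK", ["P1"]), make_psm("CK", ["P2"])]
        index = build_index(psms, [])
        peptides = {
            "AK": pep("AK", 0.3, {"P1"}),
            "CK": pep("CK", 0.3, {"P2"}),
        }
        out = replenish_peptides({"P1"}, peptides, set(), index)
        assert out == {"AK"}
        assert replenish_peptides(set(), peptides, {"CK"}, index) == {"CK"}

    def test_recompute_is_weighted_parent_sum(self):
        weights = {
            "AK": WeightAssignment("AK", {"P1": 1.0}, False),
            "CK": WeightAssignment("CK", {"P1": 0.3, "P2": 0.7}, True),
        }
        q = {"P1": 1.0, "P2": 0.5}
        new_x, dropped = recompute_peptide_probabilities({"AK", "CK"}, weights, q)
        assert new_x["AK"] == pytest.approx(1.0)
        assert new_x["CK"] == pytest.approx(0.3 + 0.35)
        assert dropped == []

    def test_orphaned_selected_peptide_dropped(self):
        new_x, dropped = recompute_peptide_probabilities({"AK"}, {}, {})
        assert dropped == ["AK"] and new_x == {}

    @pytest.mark.parametrize(
        "history,expected",
        [
            (["in", "out", "in"], "eliminated"),
            (["in", "in", "in"], "active"),
            (["in", "out", "out"], "active"),
        ],
    )
    def test_elimination_pattern(self, history, expected):
        state = ProteinState("P1", membership_history=list(history))
        apply_elimination({"P1": state}, InferenceConfig())
        assert state.status == expected

    def test_convergence_requires_stable_sets_and_q(self):
        a = IterationSnapshot(1, frozenset({"P1"}), {"P1": 0.9}, frozenset({"AK"}))
        same = IterationSnapshot(2, frozenset({"P1"}), {"P1": 0.9}, frozenset({"AK"}))
        drift = IterationSnapshot(2, frozenset({"P1"}), {"P1": 0.901}, frozenset({"AK"}))
        grown = IterationSnapshot(
            2, frozenset({"P1", "P2"}), {"P1": 0.9, "P2": 0.9}, frozenset({"AK"})
        )
        config = InferenceConfig()
        assert check_convergence(a, same, config)
        assert not check_convergence(a, drift, config)
        assert not check_convergence(a, grown, config)
        assert not check_convergence(None, same, config)


class TestRunInference:
    def test_single_protein_saturates(self):
        psms = [
            make_psm("AAAK", ["P1"], prob=0.99, spectrum="s1"),
            make_psm("CCCK", ["P1"], prob=0.98, spectrum="s2"),
        ]
        result = run_inference(
            psms, [ProteinEntry("P1", "AAAKCCCK")], theoretical_counts={"P1": 2}
        )
        assert result.converged
        assert result.proteins["P1"].q == 1.0
        assert result.peptides["AAAK"].x == 1.0
        assert result.peptides["CCCK"].x == 1.0

    def test_no_selectable_peptides_converges_empty(self):
        psms = [make_psm("AAAK", ["P1"], prob=0.5)]
        result = run_inference(psms, [ProteinEntry("P1", "AAAK")])
        assert result.converged
        assert result.iterations == 1
        assert result.snapshots[-1].active_proteins == frozenset()
        assert not result.peptides["AAAK"].selected

    def test_elimination_of_oscillating_absent_protein(self, elimination_instance):
        psms, proteins, counts = elimination_instance
        result = run_inference(psms, proteins, theoretical_counts=counts)
        b = result.proteins["B"]
        assert b.status == "eliminated"
        assert b.membership_history[:3] == ["in", "out", "in"]
        # the shared peptide renormalizes to the surviving parent
        shared = result.peptides["SSSSK"]
        assert shared.weights == {"A": 1.0}
        assert shared.selected
        # B's unique low peptides revert to their report probabilities
        assert not result.peptides["EEEEK"].selected
        assert result.peptides["EEEEK"].x == 0.30
        # terminal: B never reappears after its elimination iteration
        elim_iter = next(
            row["iteration"] for row in result.iteration_log if row["eliminated"]
        )
        for snap in result.snapshots:
            if snap.iteration >= elim_iter:
                assert "B" not in snap.active_proteins
        assert result.converged
        assert result.proteins["A"].status == "active"
        assert result.proteins["A"].q >= 0.95

    def test_matches_straight_line_oracle_on_small_instances(self):
        rng = random.Random(11)
        for trial in range(40):
            n_prot = rng.randrange(1, 6)
            n_pep = rng.randrange(1, 11)
            prots = [f"P{i}" for i in range(n_prot)]
            counts = {p: rng.randrange(1, 15) for p in prots}
            psms = []
            for i in range(n_pep):
                seq = f"{'ACDEFGHILMNQSTVWY'[i % 17]}{'ACDEFGHILMNQSTVWY'[(i * 3 + 1) % 17]}PK{i % 10 * 'A'}K"
                parents = rng.sample(prots, rng.randrange(1, n_prot + 1))
                for s in range(rng.randrange(1, 3)):
                    psms.append(
                        make_psm(
                            seq,
                            parents,
                            prob=round(rng.random(), 3),
                            sp=round(rng.uniform(1, 100), 3),
                            spectrum=f"t{trial}.{i}.{s}",
                        )
                    )
            counts = {
                p: max(
                    counts[p],
                    len({m.peptide_sequence for m in psms if p in m.assigned_proteins}),
                )
                for p in prots
            }
            entries = [ProteinEntry(p, "MMMM") for p in prots]
            result = run_inference(psms, entries, theoretical_counts=counts)
            q, status, selected, x, eliminated = straight_line_loop(psms, counts)
            got_selected = {
                s for s, st_ in result.peptides.items() if st_.selected
            }
            assert got_selected == selected, f"trial {trial}"
            got_status = {
                a: s.status
                for a, s in result.proteins.items()
            }
            assert got_status == status, f"trial {trial}"
            for acc in q:
                assert result.proteins[acc].q == pytest.approx(
                    q[acc], abs=1e-9
                ), f"trial {trial}: {acc}"
            for seq_ in x:
                assert result.peptides[seq_].x == pytest.approx(
                    x[seq_], abs=1e-9
                ), f"trial {trial}: {seq_}"

    def test_probabilities_stay_in_unit_interval(self, default_synthetic):
        _, proteins, psms, _ = default_synthetic
        result = run_inference(psms, proteins)
        for snap in result.snapshots:
            for qv in snap.q_vector.values():
                assert 0.0 <= qv <= 1.0
        for state in result.peptides.values():
            assert 0.0 <= state.x <= 1.0
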
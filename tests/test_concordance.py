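import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ifxpanel.concordance import (
    CorrelationCell,
    SignList,
    assemble_panel,
    classify_strong,
    consensus_genes,
    correlation_matrix,
    inverse_ct,
    load_reference_sign_lists,
    spearman_rho,
)
from ifxpanel.io import CtMatrix, DataError


# --- independent midrank oracle --------------------------------------------


def brute_midranks(v):
    """Rank by pairwise comparison counting; ties get the average rank."""
    return [
        1.0
        + sum(1 for u in v if u < x)
        + (sum(1 for u in v if u == x) - 1) / 2.0
        for x in v
    ]


def brute_spearman(x, y):
    rx, ry = brute_midranks(x), brute_midranks(y)
    n = len(x)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 25, 90])[0] == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [9, 5, 4, 1])[0] == pytest.approx(-1.0)

    def test_tied_example_matches_oracle(self):
        x, y = [1, 2, 2, 4], [10, 8, 8, 3]
        rho, n = spearman_rho(x, y)
        assert n == 4
        assert rho == pytest.approx(brute_spearman(x, y))

    def test_missing_pairs_dropped(self):
        rho, n = spearman_rho([1, 2, np.nan, 4, 5], [2, 4, 9, np.nan, 10])
        assert n == 3
        assert rho == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, n = spearman_rho([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho)

    def test_exhaustive_small_vectors_match_oracle(self):
        # every pair of non-constant length-3 and length-4 vectors over {1,2,3}
        for n in (3, 4):
            vecs = [
                v for v in itertools.product((1, 2, 3), repeat=n)
                if len(set(v)) > 1
            ]
            for x in vecs:
                for y in vecs:
                    rho, _ = spearman_rho(x, y)
                    assert rho == pytest.approx(brute_spearman(x, y)), (x, y)

    def test_sampled_longer_vectors_match_oracle(self):
        rng = np.random.default_rng(2024)
        for n in (5, 6):
            vecs = [
                v for v in itertools.product((1, 2, 3), repeat=n)
                if len(set(v)) > 1
            ]
            for _ in range(1500):
                x = vecs[rng.integers(len(vecs))]
                y = vecs[rng.integers(len(vecs))]
                rho, _ = spearman_rho(x, y)
                assert rho == pytest.approx(brute_spearman(x, y)), (x, y)


@settings(max_examples=300, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(-50, 50), st.integers(-50, 50)),
        min_size=3,
        max_size=12,
    )
)
def test_spearman_bounded_and_matches_oracle(pairs):
    x = [a for a, _ in pairs]
    y = [b for _, b in pairs]
    if len(set(x)) == 1 or len(set(y)) == 1:
        with pytest.warns(UserWarning):
            rho, _ = spearman_rho(x, y)
        assert math.isnan(rho)
    else:
        rho, n = spearman_rho(x, y)
        assert n == len(pairs)
        assert -1.0 - 1e-12 <= rho <= 1.0 + 1e-12
        assert rho == pytest.approx(brute_spearman(x, y))


class TestInverseCt:
    def test_reciprocal_and_housekeeping_excluded(self):
        ct = CtMatrix(
            pd.DataFrame({"S1": [20.0, 35.0, 19.0]}, index=["TNF", "IL18", "ACTB"]),
            ("ACTB",),
        )
        proxy = inverse_ct(ct)
        assert proxy.data.at["TNF", "S1"] == pytest.approx(0.05)
        assert proxy.data.at["IL18", "S1"] == pytest.approx(1 / 35)
        assert "ACTB" not in proxy.gene_ids

    def test_ordering_reversed(self):
        ct = CtMatrix(
            pd.DataFrame(
                {"S1": [18.0, 20.0], "S2": [25.0, 20.0], "S3": [30.0, 20.0]},
                index=["G", "ACTB"],
            ),
            ("ACTB",),
        )
        vals = inverse_ct(ct).data.loc["G"]
        assert vals["S1"] > vals["S2"] > vals["S3"]


class TestClassification:
    def _cell(self, rho, genus="G", gene="e", stratum="responders"):
        return CorrelationCell(genus, gene, stratum, rho, 10, "none")

    def test_threshold_boundaries_inclusive(self):
        cells = [
            self._cell(0.85, gene="pos"),
            self._cell(-0.80, gene="negb"),
            self._cell(0.5, gene="weak"),
            self._cell(float("nan"), gene="undef"),
        ]
        (sl,) = classify_strong(cells, 0.8)
        assert sl.positive_genes == {"pos"}
        assert sl.negative_genes == {"negb"}

    def test_sign_list_disjointness_enforced(self):
        with pytest.raises(DataError, match="both sign sets"):
            SignList("G", "responders", {"a"}, {"a"})


class TestConsensus:
    def _lists(self):
        return [
            SignList("g1", "responders", {"A", "B"}, set()),
            SignList("g1", "non_responders", {"C"}, set()),
            SignList("g2", "responders", {"A"}, {"D"}),
            SignList("g3", "responders", set(), {"A", "C"}),
            SignList("g4", "responders", {"B"}, set()),
        ]

    def test_counting_and_threshold(self):
        counts, at_k, union = consensus_genes(self._lists(), ["g1", "g2", "g3", "g4"], 3)
        assert counts["A"] == 3 and counts["B"] == 2
        assert at_k == {"A"}
        assert union == {"A", "B", "C", "D"}

    def test_either_stratum_counts_once(self):
        counts, _, _ = consensus_genes(self._lists(), ["g1"], 1)
        assert counts == {"A": 1, "B": 1, "C": 1}

    def test_union_monotone_in_genera_and_k(self):
        lists = self._lists()
        unions = []
        for i in range(1, 5):
            _, _, u = consensus_genes(lists, [f"g{j}" for j in range(1, i + 1)], 1)
            unions.append(u)
        for a, b in zip(unions, unions[1:]):
            assert a <= b
        sets = [consensus_genes(lists, ["g1", "g2", "g3", "g4"], k)[1]
                for k in (1, 2, 3, 4)]
        for a, b in zip(sets, sets[1:]):
            assert a >= b


class TestAssemblePanel:
    def _lists(self):
        # r1, r2 responder-enriched; n1..n4 non-responder-enriched
        return [
            SignList("r1", "responders", {"good", "lonely"}, {"noDE"}),
            SignList("r2", "responders", {"good", "noDE"}, set()),
            SignList("n1", "responders", set(), {"good", "noDE"}),
            SignList("n2", "responders", {"good"}, set()),
            SignList("n3", "non_responders", {"good", "noDE"}, set()),
            SignList("n4", "responders", {"noDE"}, set()),
        ]

    def test_rule_application(self):
        panel = assemble_panel(
            self._lists(), ["r1", "r2"], ["n1", "n2", "n3", "n4"],
            {"good": "up", "lonely": "up"}, k=3,
        )
        assert panel.genes_up == {"good"}
        assert not panel.genes_down
        tr = panel.rule_trace["good"]
        assert tr["included"] and tr["nonresponder_genus_count"] == 3

    def test_partial_responder_hit_excluded_with_trace(self):
        panel = assemble_panel(
            self._lists(), ["r1", "r2"], ["n1", "n2", "n3", "n4"],
            {"lonely": "up"}, k=3,
        )
        tr = panel.rule_trace["lonely"]
        assert not tr["included"]
        assert not tr["criterion_all_responder_genera"]
        assert tr["responder_genus_hits"] == ["r1"]

    def test_missing_direction_recorded(self):
        panel = assemble_panel(
            self._lists(), ["r1", "r2"], ["n1", "n2", "n3", "n4"], {}, k=3
        )
        tr = panel.rule_trace["noDE"]
        assert tr["criterion_all_responder_genera"] and tr["criterion_k_of_m"]
        assert tr["excluded_reason"] == "missing_de_direction"
        assert not panel.genes

    def test_down_direction_split(self):
        panel = assemble_panel(
            self._lists(), ["r1", "r2"], ["n1", "n2", "n3", "n4"],
            {"good": "down"}, k=3,
        )
        assert panel.genes_down == {"good"}


class TestReferenceFixture:
    def test_fixture_structure(self):
        ref = load_reference_sign_lists()
        genera = {sl.genus for sl in ref.sign_lists}
        assert len(genera) == 6
        assert ref.responder_genera == {"Parvimonas", "Hungatella"}
        assert len(ref.nonresponder_genera) == 4
        for sl in ref.sign_lists:
            assert not sl.positive_genes & sl.negative_genes

    def test_parvimonas_responder_positive_set(self):
        ref = load_reference_sign_lists()
        (sl,) = [
            s for s in ref.sign_lists
            if s.genus == "Parvimonas" and s.stratum == "responders"
        ]
        assert sl.positive_genes == {"CXCL8", "TLR6", "TLR9", "TNFSF14", "SELE"}

    def test_union_cardinalities(self):
        ref = load_reference_sign_lists()
        _, _, union_r = consensus_genes(ref.sign_lists, ref.responder_genera, 1)
        assert len(union_r) == 19
        _, _, union_nr = consensus_genes(ref.sign_lists, ref.nonresponder_genera, 1)
        assert len(union_nr) == 20


def test_correlation_matrix_cardinality_and_errors(toy_meta):
    from ifxpanel.abundance import RelAbundanceTable

    rel = RelAbundanceTable(
        pd.DataFrame(
            {s: [0.2 + 0.1 * i, 0.8 - 0.1 * i] for i, s in enumerate(toy_meta.sample_ids)},
            index=["gA", "gB"],
        ),
        "tss",
    )
    ct = CtMatrix(
        pd.DataFrame(
            {s: [20.0 + i, 25.0 - i, 20.0] for i, s in enumerate(toy_meta.sample_ids)},
            index=["e1", "e2", "ACTB"],
        ),
        ("ACTB",),
    )
    proxy = inverse_ct(ct)
    cells = correlation_matrix(
        rel, proxy, ["gA", "gB"], ["e1", "e2"], toy_meta, "responders"
    )
    assert len(cells) == 4  # 2 genera x 2 genes
    with pytest.raises(DataError, match="absent"):
        correlation_matrix(rel, proxy, ["nope"], ["e1"], toy_meta, "responders")
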
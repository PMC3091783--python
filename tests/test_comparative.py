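import itertools

import numpy as np
import pytest

from dister import (
    AdjacencySource,
    OrthologyMap,
    ancestral_fragments,
    ancestral_pairs,
    bbh_orthologs,
    chi2_2x2,
    classify_map_types,
    classify_tu_type,
    length_evolution_class,
    loss_attribution,
    tu_type_summary,
)
from dister.operon import OperonMap, TranscriptionUnit
from dister.pairs import SAME_STRAND, AdjacentPair


def _map(groups, prefix="", validate=True):
    tus = tuple(
        TranscriptionUnit(f"{prefix}tu{i}", tuple(g), "+")
        for i, g in enumerate(groups)
    )
    return OperonMap(prefix or "m", tus, validate_partition=validate)


class TestBBH:
    def test_mutual_best_hit_kept(self):
        m = bbh_orthologs([("a1", "b1", 90.0), ("a1", "b2", 50.0), ("a2", "b2", 80.0)])
        assert m.a_to_b == {"a1": "b1", "a2": "b2"}

    def test_asymmetric_best_hits_excluded(self):
        sim = [("a1", "b1", 70.0), ("a2", "b1", 90.0)]
        m = bbh_orthologs(sim)
        # b1's best is a2, so a1 gets no partner
        assert "a1" not in m.a_to_b and m.a_to_b == {"a2": "b1"}

    def test_score_ties_broken_lexicographically_and_reported(self):
        m = bbh_orthologs([("a1", "b2", 50.0), ("a1", "b1", 50.0)])
        assert m.a_to_b == {"a1": "b1"}
        assert "a1" in m.ties

    def test_equivalence_with_brute_force_double_loop(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            na, nb = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            rows = []
            for i, j in itertools.product(range(na), range(nb)):
                if rng.random() < 0.6:
                    rows.append((f"a{i}", f"b{j}", float(rng.integers(1, 50))))
            got = bbh_orthologs(rows).a_to_b
            want = {}
            a_ids = {r[0] for r in rows}
            b_ids = {r[1] for r in rows}
            for a in a_ids:
                hits = sorted(
                    [(s, b) for x, b, s in rows if x == a],
                    key=lambda t: (-t[0], t[1]),
                )
                best_b = hits[0][1]
                back = sorted(
                    [(s, x) for x, b, s in rows if b == best_b],
                    key=lambda t: (-t[0], t[1]),
                )
                if back[0][1] == a:
                    want[a] = best_b
            assert got == want


class TestTUTypes:
    ref = _map([["a'", "b'"], ["c'", "d'", "e'"], ["f'"], ["x'", "y'"]], prefix="r")

    def orth(self, pairs, ambiguous=()):
        return OrthologyMap(a_to_b=dict(pairs), ambiguous=frozenset(ambiguous))

    def test_exact_replicate_is_identical(self):
        tu = TranscriptionUnit("t", ("a", "b"), "+")
        call = classify_tu_type(tu, _map([["a", "b"]]), self.ref,
                                self.orth([("a", "a'"), ("b", "b'")]))
        assert call.tu_type == "identical"

    def test_longer_reference_with_orthologless_extra_is_similar(self):
        tu = TranscriptionUnit("t", ("c", "d"), "+")
        call = classify_tu_type(tu, _map([["c", "d"]]), self.ref,
                                self.orth([("c", "c'"), ("d", "d'")]))
        assert call.tu_type == "similar" and call.lost_ref_genes == ("e'",)

    def test_relocated_extra_makes_split(self):
        a_map = _map([["c", "d"], ["e"]])
        orth = self.orth([("c", "c'"), ("d", "d'"), ("e", "e'")])
        call = classify_tu_type(a_map.tus[0], a_map, self.ref, orth)
        assert call.tu_type == "split" and call.relocated_ref_genes == ("e'",)

    def test_several_reference_tus_no_leftover_orthologs_is_merged(self):
        tu = TranscriptionUnit("t", ("a", "c"), "+")
        # a'->refTU0 (other gene b' absent from A), c'->refTU1 (d', e' absent)
        call = classify_tu_type(tu, _map([["a", "c"]]), self.ref,
                                self.orth([("a", "a'"), ("c", "c'")]))
        assert call.tu_type == "merged"
        assert set(call.reference_tus) == {"rtu0", "rtu1"}

    def test_leftover_ortholog_elsewhere_makes_reorganized(self):
        a_map = _map([["a", "c"], ["b"]])
        orth = self.orth([("a", "a'"), ("c", "c'"), ("b", "b'")])
        call = classify_tu_type(a_map.tus[0], a_map, self.ref, orth)
        assert call.tu_type == "reorganized"

    def test_no_ortholog_bearing_gene_is_unclassifiable(self):
        tu = TranscriptionUnit("t", ("q",), "+")
        call = classify_tu_type(tu, _map([["q"]]), self.ref, self.orth([]))
        assert call.tu_type == "unclassifiable"

    def test_ambiguous_rna_extras_do_not_decide(self):
        tu = TranscriptionUnit("t", ("c", "d"), "+")
        orth = self.orth([("c", "c'"), ("d", "d'")], ambiguous=["e'"])
        call = classify_tu_type(tu, _map([["c", "d"]]), self.ref, orth)
        assert call.tu_type == "identical" and call.ambiguous_ref_genes == ("e'",)

    def test_ortholog_outside_reference_map_is_data_error(self):
        tu = TranscriptionUnit("t", ("a",), "+")
        with pytest.raises(ValueError, match="absent from the reference"):
            classify_tu_type(tu, _map([["a"]]), self.ref, self.orth([("a", "zzz")]))

    def test_types_mutually_exclusive_and_exhaustive_fuzz(self):
        rng = np.random.default_rng(53)
        valid = {"identical", "similar", "split", "merged", "reorganized",
                 "unclassifiable"}
        for _ in range(50):
            ref_genes = [f"r{i}" for i in range(10)]
            cuts = sorted(rng.choice(range(1, 10), size=3, replace=False))
            ref_groups, prev = [], 0
            for c in list(cuts) + [10]:
                ref_groups.append(ref_genes[prev:c])
                prev = c
            a_genes = [f"a{i}" for i in range(8)]
            cuts_a = sorted(rng.choice(range(1, 8), size=2, replace=False))
            a_groups, prev = [], 0
            for c in list(cuts_a) + [8]:
                a_groups.append(a_genes[prev:c])
                prev = c
            targets = list(rng.permutation(ref_genes))
            mapping = {
                a: targets[i]
                for i, a in enumerate(a_genes)
                if rng.random() < 0.7
            }
            a_map, ref_map = _map(a_groups), _map(ref_groups, prefix="r")
            calls = classify_map_types(a_map, ref_map, OrthologyMap(mapping))
            assert len(calls) == len(a_map.tus)
            assert all(c.tu_type in valid for c in calls)

    def test_summary_counts_conserve_tus(self):
        a_map = _map([["a", "b"], ["c"], ["e"]])
        orth = self.orth([("a", "a'"), ("b", "b'"), ("c", "c'"), ("e", "e'")])
        calls = classify_map_types(a_map, self.ref, orth)
        df = tu_type_summary(a_map, calls)
        assert df["n_tus"].sum() == len(a_map.tus)


def _pairs_in_order(gene_ids):
    n = len(gene_ids)
    return [
        AdjacentPair(gene_ids[i], gene_ids[(i + 1) % n], SAME_STRAND, 10)
        for i in range(n)
    ]


class TestAncestral:
    def test_reference_adjacency_flags_pair(self):
        pairs = _pairs_in_order(["a", "b", "c", "d"])
        src = AdjacencySource(
            "ref",
            {"a": "a'", "b": "b'", "c": "c'"},
            frozenset({frozenset(("a'", "b'"))}),
        )
        flagged = ancestral_pairs(pairs, [src])
        assert [(f, s) for _, f, s in flagged] == [
            (True, "ref"), (False, None), (False, None), (False, None)
        ]

    def test_outgroup_rescues_pair_missing_in_reference(self):
        pairs = _pairs_in_order(["a", "b", "c"])
        ref = AdjacencySource("ref", {"a": "a'"}, frozenset())
        out = AdjacencySource(
            "outgroup",
            {"b": "b*", "c": "c*"},
            frozenset({frozenset(("b*", "c*"))}),
        )
        flagged = ancestral_pairs(pairs, [ref, out])
        assert flagged[1][1] and flagged[1][2] == "outgroup"

    def test_chain_of_three_pairs_spans_four_genes(self):
        pairs = _pairs_in_order([f"g{i}" for i in range(8)])
        flags = [(p, i < 3, "ref" if i < 3 else None) for i, p in enumerate(pairs)]
        res = ancestral_fragments(flags, circular=True)
        assert res["n_fragments"] == 1
        assert res["fragments"][0]["n_genes"] == 4

    def test_fragment_gene_accounting(self):
        # 441 genes on 68 fragments averages 6.5 (two fragment sizes suffice)
        pairs = _pairs_in_order([f"g{i}" for i in range(1000)])
        flags = []
        i = 0
        sizes = [6] * 35 + [7] * 33  # genes per fragment -> pairs = size-1
        k = 0
        for size in sizes:
            for j in range(size - 1):
                flags.append((pairs[k], True, "ref"))
                k += 1
            flags.append((pairs[k], False, None))  # separator
            k += 1
        while k < 1000:
            flags.append((pairs[k], False, None))
            k += 1
        res = ancestral_fragments(flags, circular=True)
        assert res["n_fragments"] == 68
        assert sum(f["n_genes"] for f in res["fragments"]) == 441
        assert round(res["mean_genes"], 1) == 6.5

    def test_no_ancestral_pairs_no_fragments(self):
        pairs = _pairs_in_order(["a", "b", "c"])
        res = ancestral_fragments([(p, False, None) for p in pairs])
        assert res == {"fragments": [], "n_fragments": 0, "mean_genes": None}

    def test_full_circle_fragment(self):
        pairs = _pairs_in_order(["a", "b", "c", "d"])
        res = ancestral_fragments([(p, True, "ref") for p in pairs], circular=True)
        assert res["n_fragments"] == 1
        assert res["fragments"][0]["closes_circle"]
        assert res["fragments"][0]["n_genes"] == 4

    def test_pair_and_gene_conservation(self):
        rng = np.random.default_rng(61)
        pairs = _pairs_in_order([f"g{i}" for i in range(40)])
        flags = [(p, bool(rng.random() < 0.5), None) for p in pairs]
        res = ancestral_fragments(flags, circular=True)
        assert sum(f["n_pairs"] for f in res["fragments"]) == sum(
            1 for _, f, _ in flags if f
        )
        for f in res["fragments"]:
            if not f["closes_circle"]:
                assert f["n_genes"] == f["n_pairs"] + 1


class TestLengthEvolution:
    @pytest.mark.parametrize(
        "l_a,l_ref,l_out,expected",
        [
            (300, 300, 300, 1),
            (300, 300, 500, 1),   # equality decides before the outgroup
            (300, 330, 300, 2),   # change on the reference branch, ref longer
            (330, 300, 330, 3),   # change on the reference branch, ref shorter
            (270, 300, 300, 4),   # change on the A branch, printed sign rule
            (330, 300, 300, 5),
            (290, 310, 300, 6),   # equidistant outgroup: lineage unresolvable
        ],
    )
    def test_six_classes(self, l_a, l_ref, l_out, expected):
        assert length_evolution_class(l_a, l_ref, l_out) == expected

    def test_missing_outgroup_is_unclassified_sentinel(self):
        assert length_evolution_class(300, 330, None) is None
        assert length_evolution_class(300, 300, None) == 1

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            length_evolution_class(0, 300, 300)

    def test_partitions_random_triples(self):
        rng = np.random.default_rng(71)
        for _ in range(10_000):
            la, lr, lo = (int(x) for x in rng.integers(1, 60, 3) * 3)
            cls = length_evolution_class(la, lr, lo)
            assert cls in {1, 2, 3, 4, 5, 6}


class TestLossAttribution:
    def test_outgroup_presence_means_lost_in_a(self):
        assert loss_attribution({"ancestor": None, "outgroup1": True}) == "lost_in_A"

    def test_absent_everywhere_means_acquired_in_reference(self):
        assert (
            loss_attribution({"ancestor": False, "outgroup1": False})
            == "acquired_in_reference"
        )

    def test_no_usable_evidence_is_ambiguous(self):
        assert loss_attribution({"ancestor": None}) == "ambiguous"
        assert loss_attribution({}) == "ambiguous"


def test_chi2_2x2_matches_scipy_and_flags_association():
    strong = chi2_2x2([[80, 20], [20, 80]])
    assert strong["p_value"] < 1e-6 and strong["dof"] == 1
    weak = chi2_2x2([[50, 50], [48, 52]])
    assert weak["p_value"] > 0.5
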
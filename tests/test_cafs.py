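"""cafs_assembly: eligibility, synteny links, grouping, ordering, building."""

import pytest

from cafskit.cafs import (
    FISHObservation,
    HybridizationBudget,
    PredictedLink,
    SyntenyAnchor,
    anchored_fraction,
    assign_linkage_groups,
    build_chromosome,
    orient_group,
    order_scaffolds,
    predict_linked_scaffolds,
    probe_eligibility,
    reverse_complement,
    run_cafs,
    to_assembly,
)
from cafskit.core_io import ValidationError
from cafskit.synthetic import SimulatedFISH


class DictOracle:
    """Truth table oracle: scaffold -> chromosome label."""

    def __init__(self, chrom_of, order_of=None):
        self.chrom_of = chrom_of
        self.order_of = order_of or {}

    def same_chromosome(self, a, b):
        return self.chrom_of[a] == self.chrom_of[b]

    def order(self, probes):
        return tuple(sorted(probes, key=lambda p: self.order_of[p]))


# ---------------------------------------------------------------------------
# Probe eligibility


def test_probe_eligibility_rule():
    rows = [
        ("bac1", "L", "s1", 95.0), ("bac1", "R", "s1", 97.0),   # eligible
        ("bac2", "L", "s1", 99.0), ("bac2", "R", "s2", 99.0),   # two scaffolds
        ("bac3", "L", "s3", 90.0), ("bac3", "R", "s3", 95.0),   # 90.0 not > 90
        ("bac4", "L", "s4", 95.0),                               # single end
    ]
    assert probe_eligibility(rows) == ["bac1"]


def test_probe_eligibility_duplicate_end_rejected():
    with pytest.raises(ValidationError):
        probe_eligibility([("b", "L", "s", 95.0), ("b", "L", "s", 96.0)])


def test_probe_eligibility_three_ends_rejected():
    with pytest.raises(ValidationError):
        probe_eligibility(
            [("b", "L", "s", 95.0), ("b", "R", "s", 95.0), ("b", "M", "s", 95.0)]
        )


# ---------------------------------------------------------------------------
# Synteny links


def anchors_from_orders(orders_per_species):
    out = {}
    for species, chrom_orders in orders_per_species.items():
        lst = []
        for ci, order in enumerate(chrom_orders):
            for idx, sid in enumerate(order):
                lst.append(SyntenyAnchor(sid, species, f"{species}_r{ci}", idx))
        out[species] = lst
    return out


def test_link_requires_all_three_species():
    anchors = anchors_from_orders(
        {
            "medaka": [["a", "b", "c"]],
            "stickleback": [["a", "b", "c"]],
            "tetraodon": [["a", "c", "b"]],  # a-b broken here
        }
    )
    links = predict_linked_scaffolds(anchors)
    pairs = {l.pair for l in links}
    assert frozenset(("b", "c")) in pairs  # adjacent in all three
    assert frozenset(("a", "b")) not in pairs  # only 2/3


def test_link_species_count_enforced():
    anchors = anchors_from_orders({"medaka": [["a", "b"]]})
    with pytest.raises(ValueError):
        predict_linked_scaffolds(anchors)


def test_predicted_link_invariant():
    with pytest.raises(ValidationError):
        PredictedLink("a", "b", n_supporting_species=2)


def test_links_match_set_intersection_oracle(positions_only_truth):
    truth = positions_only_truth
    links = {l.pair for l in predict_linked_scaffolds(truth.anchors)}

    def adjacency(anchor_list):
        by_chrom = {}
        for a in anchor_list:
            by_chrom.setdefault(a.ref_chrom, []).append(a)
        pairs = set()
        for lst in by_chrom.values():
            lst.sort(key=lambda a: a.ref_index)
            pairs.update(
                frozenset((x.scaffold_id, y.scaffold_id))
                for x, y in zip(lst, lst[1:])
            )
        return pairs

    per_species = [adjacency(truth.anchors[s]) for s in truth.anchors]
    assert links == set.intersection(*per_species)
    for pairs in per_species:  # subset property
        assert links <= pairs


# ---------------------------------------------------------------------------
# Linkage-group assignment


def test_unhinted_worst_case_budget_is_66():
    chrom_of = {f"s{i}": i for i in range(12)}  # one scaffold per chromosome
    groups, budget = assign_linkage_groups(sorted(chrom_of), DictOracle(chrom_of))
    assert len(groups) == 12
    assert budget.n_cohybridizations == sum(range(12))  # 0+1+...+11 = 66


def test_hinted_budget_never_exceeds_unhinted(positions_only_truth):
    truth = positions_only_truth
    fish = SimulatedFISH(truth)
    scaffolds = sorted(truth.scaffold_lengths)
    hints = predict_linked_scaffolds(truth.anchors)
    _, unhinted = assign_linkage_groups(scaffolds, fish)
    _, hinted = assign_linkage_groups(scaffolds, fish, hints=hints)
    assert hinted.n_cohybridizations <= unhinted.n_cohybridizations


def test_partition_matches_truth(positions_only_truth):
    truth = positions_only_truth
    fish = SimulatedFISH(truth)
    groups, _ = assign_linkage_groups(
        sorted(truth.scaffold_lengths), fish, expected_n_groups=12
    )
    want = {}
    for sid in truth.scaffold_lengths:
        want.setdefault(truth.scaffold_chrom(sid), set()).add(sid)
    got = {frozenset(g.members) for g in groups}
    assert got == {frozenset(m) for m in want.values()}
    # disjoint members
    all_members = [s for g in groups for s in g.members]
    assert len(all_members) == len(set(all_members))


def test_too_many_groups_is_inconsistency_error():
    chrom_of = {"a": 1, "b": 2, "c": 3}
    with pytest.raises(ValidationError):
        assign_linkage_groups(["a", "b", "c"], DictOracle(chrom_of), expected_n_groups=2)


def test_budget_counter_monotone():
    b = HybridizationBudget()
    b.charge()
    b.charge(3)
    assert b.n_cohybridizations == 4
    with pytest.raises(ValueError):
        b.charge(-1)


# ---------------------------------------------------------------------------
# Ordering and orientation


def test_noise_free_ordering_is_exact_with_zero_queries():
    distances = {"a": 0.1, "b": 0.4, "c": 0.7}
    budget = HybridizationBudget()
    out = order_scaffolds(distances, distances, oracle=None, budget=budget)
    assert [s for s, _ in out] == ["a", "b", "c"]
    assert budget.n_cohybridizations == 0


def test_identical_means_resolved_by_oracle():
    distances = {"a": 0.5, "b": 0.5}
    oracle = DictOracle({}, order_of={"a": 2, "b": 1})
    budget = HybridizationBudget()
    out = order_scaffolds(distances, distances, oracle=oracle, resolution=0.01,
                          budget=budget)
    assert [s for s, _ in out] == ["b", "a"]
    assert budget.n_cohybridizations == 1


def test_missing_distance_rejected():
    with pytest.raises(ValidationError):
        order_scaffolds(["a", "b"], {"a": 0.1})


def test_rel_positions_non_decreasing_after_oracle_swaps():
    distances = {"a": 0.52, "b": 0.50, "c": 0.9}
    oracle = DictOracle({}, order_of={"a": 1, "b": 2, "c": 3})
    out = order_scaffolds(distances, distances, oracle=oracle, resolution=0.05)
    rels = [d for _, d in out]
    assert rels == sorted(rels)
    assert [s for s, _ in out] == ["a", "b", "c"]


def test_orientation_identity_and_involution():
    ordered = [("a", 0.1), ("b", 0.6), ("c", 0.9)]
    assert orient_group(ordered, head_is_telomeric=False) == ordered
    flipped = orient_group(ordered, head_is_telomeric=True)
    assert [s for s, _ in flipped] == ["c", "b", "a"]
    assert [d for _, d in flipped] == pytest.approx([0.1, 0.4, 0.9])
    again = orient_group(flipped, head_is_telomeric=True)
    assert [s for s, _ in again] == ["a", "b", "c"]
    assert [d for _, d in again] == pytest.approx([d for _, d in ordered])


def test_contradictory_telomere_observation_rejected():
    with pytest.raises(ValidationError):
        orient_group([("a", 0.5)], head_is_telomeric=True, tail_is_telomeric=True)
    with pytest.raises(ValidationError):
        orient_group([], head_is_telomeric=False)


# ---------------------------------------------------------------------------
# Building


def test_build_single_scaffold_no_gap():
    asm = to_assembly("chrA", [("s1", 0.5)])
    rec = build_chromosome(asm, {"s1": "ACGTACGT"})
    assert rec.sequence == "ACGTACGT"


def test_build_gap_arithmetic_and_reverse_complement():
    asm = to_assembly("chrA", [("s1", 0.2), ("s2", 0.8)], orientations={"s2": "-"})
    rec = build_chromosome(asm, {"s1": "AAAA", "s2": "ACGT"})
    assert rec.length == 4 + 1000 + 4
    assert rec.sequence == "AAAA" + "N" * 1000 + "ACGT"  # ACGT is its own revcomp
    asm2 = to_assembly("chrA", [("s1", 0.5)], orientations={"s1": "-"})
    assert build_chromosome(asm2, {"s1": "AACG"}).sequence == "CGTT"
    assert reverse_complement("AACGN") == "NCGTT"


def test_build_missing_sequence_rejected():
    asm = to_assembly("chrA", [("s1", 0.5)])
    with pytest.raises(KeyError):
        build_chromosome(asm, {})


def test_anchored_fraction():
    lengths = {"a": 60, "b": 30, "c": 10}
    assert anchored_fraction(["a", "b"], lengths) == pytest.approx(0.9)
    with pytest.raises(ValueError):
        anchored_fraction([], {})


# ---------------------------------------------------------------------------
# Observations


def test_fish_observation_invariants():
    with pytest.raises(ValidationError):
        FISHObservation(probe_ids=(), same_chromosome=False, mean_rel_distances=None)
    with pytest.raises(ValidationError):
        FISHObservation(("a", "b"), same_chromosome=True, mean_rel_distances=None)
    with pytest.raises(ValidationError):
        FISHObservation(("a", "b"), same_chromosome=False, mean_rel_distances=(0.1, 0.2))


# ---------------------------------------------------------------------------
# End-to-end driver on a hand-built truth table


def test_run_cafs_small_truth_table():
    chrom_of = {"a": 1, "b": 1, "c": 2, "d": 2, "e": 2}
    true_pos = {"a": 0.2, "b": 0.8, "c": 0.1, "d": 0.5, "e": 0.9}
    oracle = DictOracle(chrom_of, order_of=true_pos)
    assemblies, groups, budget = run_cafs(
        scaffolds=sorted(chrom_of),
        distance=true_pos,
        cohyb_oracle=oracle,
        expected_n_groups=2,
    )
    assert len(groups) == 2
    orders = sorted(
        tuple(p.scaffold_id for p in a.placements) for a in assemblies.values()
    )
    assert orders == [("a", "b"), ("c", "d", "e")]
    assert budget.n_cohybridizations > 0
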
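"""synthetic_data: statistical contracts of the generators."""

import numpy as np
import pytest
from scipy import stats

from cafskit.synthetic import (
    DESK_SCALE_CHROM_LENGTHS,
    ConfigError,
    SimulatedFISH,
    SimulationConfig,
    reads_to_fastq,
    simulate_fish,
    simulate_genome,
    simulate_reads,
)


def test_config_validation():
    with pytest.raises(ConfigError):
        SimulationConfig(n_chromosomes=2, chrom_lengths=(1_000_000,))
    with pytest.raises(ConfigError):
        SimulationConfig(cells_per_measurement=4)
    with pytest.raises(ConfigError):
        SimulationConfig(rearrangement_rate=1.5)
    with pytest.raises(ConfigError):
        SimulationConfig(gc_baseline=0.0)
    with pytest.raises(ConfigError):
        SimulationConfig(ridge_intensity_multiplier=0.5)


def test_expected_gene_count_below_one_rejected():
    cfg = SimulationConfig(
        n_chromosomes=1, chrom_lengths=(10_000,), mean_density=33.6,
        ridge_blocks_per_chrom=0, generate_sequences=False,
    )
    with pytest.raises(ConfigError):
        simulate_genome(cfg)


def test_same_seed_reproduces_genome_exactly():
    cfg = SimulationConfig(
        seed=5, n_chromosomes=2, chrom_lengths=(1_200_000, 900_000),
        ridge_blocks_per_chrom=1, ridge_span=200_000,
    )
    a, b = simulate_genome(cfg), simulate_genome(cfg)
    assert a.genes == b.genes
    assert a.tiling == b.tiling
    assert a.anchors == b.anchors
    assert {c: s.sequence for c, s in a.sequences.items()} == {
        c: s.sequence for c, s in b.sequences.items()
    }


def test_genes_within_bounds_and_tiling_covers_exactly(small_truth):
    truth = small_truth
    for g in truth.genes:
        assert 1 <= g.start <= truth.chrom_lengths[g.seq_id]
    for chrom, placements in truth.tiling.items():
        pos = 1
        for p in placements:
            c, s, e = truth.scaffold_spans[p.scaffold_id]
            assert c == chrom and s == pos
            pos = e + 1
        assert pos - 1 == truth.chrom_lengths[chrom]


def test_homogeneous_counts_are_poisson():
    """multiplier irrelevant at 0 blocks: disjoint 1-Mb window counts ~ Poisson."""
    cfg = SimulationConfig(
        seed=11, n_chromosomes=1, chrom_lengths=(200_000_000,),
        mean_density=30.0, ridge_blocks_per_chrom=0, generate_sequences=False,
    )
    truth = simulate_genome(cfg)
    pos, length = truth.gene_positions()["chr1"]
    counts = np.bincount((pos - 1) // 1_000_000, minlength=200)
    lam = 30.0
    # chi-square GOF against Poisson(30) with pooled tails
    edges = [0, 22, 26, 28, 30, 32, 34, 38, 10_000]
    obs = np.histogram(counts, bins=edges)[0]
    probs = []
    for lo, hi in zip(edges, edges[1:]):
        probs.append(stats.poisson.cdf(hi - 1, lam) - stats.poisson.cdf(lo - 1, lam))
    chi2, p = stats.chisquare(obs, f_exp=np.array(probs) * 200)
    assert p > 0.01


def test_realized_density_near_target(positions_only_truth):
    truth = positions_only_truth
    total = sum(truth.chrom_lengths.values())
    realized = len(truth.genes) / (total / 1e6)
    assert realized == pytest.approx(truth.config.mean_density, rel=0.10)


def test_ridge_blocks_elevate_local_density(small_truth):
    truth = small_truth
    bg = truth.config.effective_background_rate
    inside = 0
    span = 0
    for chrom, s, e in truth.ridge_truth:
        inside += sum(1 for g in truth.genes if g.seq_id == chrom and s <= g.start <= e)
        span += e - s + 1
    rate_inside = inside / (span / 1e6)
    assert rate_inside > 1.8 * bg  # nominal 3x, generous noise allowance


def test_gc_coupling_zero_decouples_gc_from_rate(rng):
    cfg = SimulationConfig(
        seed=9, n_chromosomes=1, chrom_lengths=(1_000_000,),
        ridge_blocks_per_chrom=1, ridge_span=300_000, gc_coupling=0.0,
    )
    truth = simulate_genome(cfg)
    seq = truth.sequences["chr1"].sequence
    tiles = [seq[i : i + 1000] for i in range(0, 500_000, 1000)]
    gc = np.array([(t.count("G") + t.count("C")) / len(t) for t in tiles])
    (chrom, s, e) = truth.ridge_truth[0]
    in_ridge = np.array(
        [s <= (i * 1000 + 500) <= e for i in range(len(tiles))], dtype=float
    )
    if in_ridge.std() > 0:
        rho = stats.spearmanr(gc, in_ridge).statistic
        assert abs(rho) < 0.1


def test_desk_scale_defaults():
    cfg = SimulationConfig()
    assert cfg.n_chromosomes == 12
    assert list(cfg.chrom_lengths) == DESK_SCALE_CHROM_LENGTHS
    assert sum(cfg.chrom_lengths) == 55_507_430


# ---------------------------------------------------------------------------
# FISH


def test_fish_zero_noise_exact(small_truth):
    cfg_zero = SimulationConfig(
        seed=42, n_chromosomes=3,
        chrom_lengths=(2_500_000, 2_000_000, 1_500_000),
        ridge_blocks_per_chrom=1, ridge_span=400_000,
        scaffold_target_n50=300_000, fish_noise_sd=0.0,
    )
    probe = next(iter(small_truth.scaffold_lengths))
    obs = simulate_fish(small_truth, [probe], config=cfg_zero)
    assert obs.mean_rel_distances[0] == pytest.approx(
        small_truth.true_rel_position(probe)
    )


def test_fish_cross_chromosome_never_colocalizes(small_truth):
    truth = small_truth
    by_chrom = {}
    for sid in truth.scaffold_lengths:
        by_chrom.setdefault(truth.scaffold_chrom(sid), []).append(sid)
    chroms = sorted(by_chrom)
    a, b = by_chrom[chroms[0]][0], by_chrom[chroms[1]][0]
    obs = simulate_fish(truth, [a, b])
    assert not obs.same_chromosome and obs.mean_rel_distances is None


def test_fish_unknown_probe_rejected(small_truth):
    with pytest.raises(KeyError):
        simulate_fish(small_truth, ["nope"])


def test_fish_sem_matches_sd_over_sqrt_n(small_truth):
    truth = small_truth
    # pick a mid-chromosome scaffold so truncation is negligible
    probe = min(
        truth.scaffold_lengths,
        key=lambda s: abs(truth.true_rel_position(s) - 0.5),
    )
    rng = np.random.default_rng(0)
    means = [
        simulate_fish(truth, [probe], rng=rng).mean_rel_distances[0]
        for _ in range(1000)
    ]
    sem = np.std(means)
    assert sem == pytest.approx(0.02 / np.sqrt(5), rel=0.12)  # ~0.0089


def test_fish_order_rule_separation(small_truth):
    truth = small_truth
    by_chrom = {}
    for sid in truth.scaffold_lengths:
        by_chrom.setdefault(truth.scaffold_chrom(sid), []).append(sid)
    members = max(by_chrom.values(), key=len)
    members = sorted(members, key=truth.true_rel_position)
    a, b = members[0], members[-1]  # separation far above noise sd
    obs = simulate_fish(truth, [a, b])
    assert obs.relative_order == (a, b)


def test_simulated_fish_caches_measurements(small_truth):
    fish = SimulatedFISH(small_truth)
    probe = next(iter(small_truth.scaffold_lengths))
    assert fish.distance(probe) == fish.distance(probe)


def test_random_end_measurement_flips_whole_chromosomes(small_truth):
    fish = SimulatedFISH(small_truth, measure_from_random_end=True)
    flipped = [c for c, f in fish._flip.items() if f]
    for sid in small_truth.scaffold_lengths:
        chrom = small_truth.scaffold_chrom(sid)
        expected = small_truth.true_rel_position(sid)
        if chrom in flipped:
            expected = 1 - expected
        assert fish._true_measured(sid) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Reference species


def test_rearrangement_rate_zero_preserves_all_adjacencies():
    cfg = SimulationConfig(
        seed=2, n_chromosomes=2, chrom_lengths=(2_000_000, 1_500_000),
        ridge_blocks_per_chrom=0, rearrangement_rate=0.0,
        generate_sequences=False, scaffold_target_n50=200_000,
    )
    truth = simulate_genome(cfg)
    for species, anchor_list in truth.anchors.items():
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
        for chrom in truth.chrom_ids:
            order = truth.true_order(chrom)
            for x, y in zip(order, order[1:]):
                assert frozenset((x, y)) in pairs


def test_triple_preservation_fraction_matches_cube():
    """P(adjacency kept in all 3 species) ~ (1 - rate)^3 = 0.729 at rate 0.1."""
    cfg = SimulationConfig(
        seed=6, rearrangement_rate=0.1, generate_sequences=False,
        scaffold_target_n50=50_000,
    )
    truth = simulate_genome(cfg)
    adjacencies = []
    for chrom in truth.chrom_ids:
        order = truth.true_order(chrom)
        adjacencies.extend(
            frozenset((x, y)) for x, y in zip(order, order[1:])
        )
    assert len(adjacencies) > 1000

    def pairs_of(species):
        by_chrom = {}
        for a in truth.anchors[species]:
            by_chrom.setdefault(a.ref_chrom, []).append(a)
        out = set()
        for lst in by_chrom.values():
            lst.sort(key=lambda a: a.ref_index)
            out.update(
                frozenset((x.scaffold_id, y.scaffold_id))
                for x, y in zip(lst, lst[1:])
            )
        return out

    kept_all = set.intersection(*(pairs_of(s) for s in truth.anchors))
    frac = sum(1 for adj in adjacencies if adj in kept_all) / len(adjacencies)
    # 3-sigma band around 0.729 plus slack for reinsertion side effects
    assert frac == pytest.approx(0.729, abs=0.05)


# ---------------------------------------------------------------------------
# Reads


def test_read_count_matches_coverage(small_truth):
    seq = small_truth.sequences["chr3"]
    reads = simulate_reads(seq, coverage=2, read_len=100, seed=1)
    assert len(reads) == round(2 * seq.length / 100)
    assert all(len(r) == 100 for r in reads)


def test_error_free_reads_are_exact_substrings(small_truth):
    seq = small_truth.sequences["chr3"]
    reads = simulate_reads(seq, coverage=0.01, read_len=80, seed=2)
    for r in reads[:20]:
        assert r in seq.sequence


def test_error_rate_binomial_check():
    from cafskit.core_io import SequenceRecord

    rng = np.random.default_rng(3)
    src = "".join(rng.choice(list("ACGT"), size=10_000))
    seq = SequenceRecord("s", src)
    reads = simulate_reads(seq, coverage=10, read_len=100, error_rate=0.01, seed=4)
    # reconstruct alignment by regenerating the same starts
    rng2 = np.random.default_rng(
        np.random.SeedSequence(entropy=4, spawn_key=(12,))
    )
    n_reads = len(reads)
    starts = rng2.integers(0, len(src) - 100 + 1, size=n_reads)
    mismatches = total = 0
    for r, s in zip(reads, starts):
        ref = src[s : s + 100]
        mismatches += sum(1 for a, b in zip(r, ref) if a != b)
        total += 100
    assert mismatches / total == pytest.approx(0.01, abs=0.002)


def test_reads_validation_and_fastq(tmp_path, small_truth):
    seq = small_truth.sequences["chr3"]
    with pytest.raises(ConfigError):
        simulate_reads(seq, coverage=0)
    with pytest.raises(ConfigError):
        simulate_reads(seq, coverage=1, read_len=seq.length + 1)
    reads = simulate_reads(seq, coverage=0.01, read_len=50, seed=5)
    p = tmp_path / "r.fastq"
    reads_to_fastq(reads, p)
    lines = p.read_text().splitlines()
    assert len(lines) == 4 * len(reads)
    assert lines[0].startswith("@read_1") and lines[2] == "+"
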
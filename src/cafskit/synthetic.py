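"""Synthetic genomes with the statistical structure the pipeline assumes.

The generator emulates a 12-chromosome telocentric genome at desk scale
(published per-chromosome sizes divided by 10, ~55.5 Mb total, preserving
the real length ratios):

* gene start positions from a background-plus-ridge inhomogeneous point
  process whose genome-wide mean density defaults to 33.6 genes/Mb;
* per-1-kb-tile GC locally coupled to gene intensity around a 0.408
  baseline, with sequences sampled base-by-base from the tile GC;
* a scaffold tiling of each chromosome (no overlap, full coverage);
* tri-species synteny anchor maps with independent per-species
  rearrangements;
* noisy per-cell FISH distance measurements (truncated normal on [0, 1],
  averaged over >= 5 cells).

Every generator draws from its own RNG stream spawned from the master seed
at a fixed key, so adding or reordering generator calls never perturbs the
others, and a fixed seed reproduces outputs byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cafs import REFERENCE_SPECIES, FISHObservation, SyntenyAnchor
from .core_io import ChromosomeAssembly, GeneRecord, ScaffoldPlacement, SequenceRecord

__all__ = [
    "SimulationConfig",
    "TrueGenome",
    "simulate_genome",
    "simulate_fish",
    "simulate_reference_species",
    "simulate_reads",
    "SimulatedFISH",
    "reads_to_fastq",
    "DESK_SCALE_CHROM_LENGTHS",
]

#: published per-chromosome sizes (kb) of the swamp eel assembly, divided by
#: 10 and expressed in bp — the desk-scale default genome (~55.5 Mb).
DESK_SCALE_CHROM_LENGTHS = [
    7_590_870, 6_510_390, 5_163_730, 5_116_210, 5_008_000, 4_809_310,
    4_241_010, 4_199_970, 4_192_870, 3_469_080, 2_928_550, 2_277_440,
]

_TILE = 1_000  # GC tile size, bp
_GENE_EXTENT = 1_000  # nominal gene length for annotation output, bp

# fixed spawn keys: one RNG stream per generator
_KEY_GENES, _KEY_GC, _KEY_TILING, _KEY_SEQ = 0, 1, 2, 3
_KEY_FISH, _KEY_SYNTENY, _KEY_READS = 10, 11, 12


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    n_chromosomes: int = 12
    chrom_lengths: tuple[int, ...] = tuple(DESK_SCALE_CHROM_LENGTHS)
    mean_density: float = 33.6  # genome-wide genes per Mb
    background_rate: float | None = None  # genes/Mb outside ridges; None = derived
    ridge_blocks_per_chrom: int = 2
    ridge_intensity_multiplier: float = 3.0
    ridge_span: int = 600_000
    gc_baseline: float = 0.408
    gc_coupling: float = 0.05
    gc_noise: float = 0.01  # bounded uniform noise on tile GC
    scaffold_target_n50: int = 250_000
    fish_noise_sd: float = 0.02
    cells_per_measurement: int = 5
    rearrangement_rate: float = 0.1
    seed: int = 0
    generate_sequences: bool = True

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or len(self.chrom_lengths) != self.n_chromosomes:
            raise ConfigError("chrom_lengths must list one length per chromosome")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ConfigError("chromosome lengths must be positive")
        if self.cells_per_measurement < 5:
            raise ConfigError("FISH distances are averages over >= 5 cells")
        if self.ridge_blocks_per_chrom and self.ridge_intensity_multiplier < 1:
            raise ConfigError("ridge_intensity_multiplier must be >= 1")
        if not 0 <= self.rearrangement_rate <= 1:
            raise ConfigError("rearrangement_rate is a probability")
        if not 0 < self.gc_baseline < 1:
            raise ConfigError("gc_baseline must lie in (0, 1)")

    @property
    def effective_background_rate(self) -> float:
        """Background rate (genes/Mb) such that the genome-wide mean density
        equals ``mean_density`` after ridge elevation."""
        if self.background_rate is not None:
            return self.background_rate
        total = sum(self.chrom_lengths)
        ridge_total = min(
            self.ridge_blocks_per_chrom * self.ridge_span * self.n_chromosomes, total
        )
        inflation = 1 + (self.ridge_intensity_multiplier - 1) * ridge_total / total
        return self.mean_density / inflation

    def rng(self, key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(key,))
        )


@dataclass
class TrueGenome:
    """Ground truth for recovery tests: sequences, genes, planted ridge
    blocks, the true scaffold tiling, and per-species synteny anchors."""

    config: SimulationConfig
    chrom_ids: list[str]
    chrom_lengths: dict[str, int]
    sequences: dict[str, SequenceRecord] | None
    genes: list[GeneRecord]
    ridge_truth: list[tuple[str, int, int]]
    tiling: dict[str, list[ScaffoldPlacement]]
    scaffold_lengths: dict[str, int]
    scaffold_spans: dict[str, tuple[str, int, int]]  # scaffold -> (chrom, start, end)
    anchors: dict[str, list[SyntenyAnchor]] = field(default_factory=dict)

    def gene_positions(self) -> dict[str, tuple[np.ndarray, int]]:
        """Per-chromosome gene start positions and lengths (ridge-test input)."""
        by_chrom: dict[str, list[int]] = {c: [] for c in self.chrom_ids}
        for g in self.genes:
            by_chrom[g.seq_id].append(g.start)
        return {
            c: (np.array(sorted(v), dtype=np.int64), self.chrom_lengths[c])
            for c, v in by_chrom.items()
        }

    def scaffold_chrom(self, scaffold_id: str) -> str:
        return self.scaffold_spans[scaffold_id][0]

    def true_rel_position(self, scaffold_id: str) -> float:
        chrom, start, end = self.scaffold_spans[scaffold_id]
        return ((start + end) / 2) / self.chrom_lengths[chrom]

    def true_order(self, chrom: str) -> list[str]:
        return [p.scaffold_id for p in self.tiling[chrom]]

    def scaffold_sequence(self, scaffold_id: str) -> str:
        if self.sequences is None:
            raise ValueError("genome was simulated without sequences")
        chrom, start, end = self.scaffold_spans[scaffold_id]
        return self.sequences[chrom].sequence[start - 1 : end]


# ---------------------------------------------------------------------------
# Genome simulation


def _place_ridge_blocks(
    rng: np.random.Generator, length: int, n_blocks: int, span: int
) -> list[tuple[int, int]]:
    """Non-overlapping elevated blocks, uniform over all valid placements.

    The k-th block start is the k-th order statistic of n uniform draws on
    the free space plus the span already consumed by earlier blocks — the
    standard construction for uniformly placing non-overlapping intervals.
    """
    if n_blocks * span > length:
        raise ConfigError("ridge blocks do not fit on a chromosome")
    free = length - n_blocks * span
    offsets = np.sort(rng.integers(0, free + 1, size=n_blocks))
    return [
        (int(o + k * span + 1), int(o + (k + 1) * span))
        for k, o in enumerate(offsets)
    ]


def _draw_positions_in_segments(
    rng: np.random.Generator, segments: list[tuple[int, int]], rate_per_mb: float
) -> np.ndarray:
    out = []
    for s, e in segments:
        span = e - s + 1
        n = rng.poisson(rate_per_mb * span / 1e6)
        if n:
            out.append(rng.integers(s, e + 1, size=n))
    if not out:
        return np.array([], dtype=np.int64)
    return np.sort(np.concatenate(out)).astype(np.int64)


def _complement_segments(blocks: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    segs, pos = [], 1
    for s, e in blocks:
        if s > pos:
            segs.append((pos, s - 1))
        pos = e + 1
    if pos <= length:
        segs.append((pos, length))
    return segs


def _tile_gc(
    config: SimulationConfig,
    rng: np.random.Generator,
    length: int,
    blocks: list[tuple[int, int]],
) -> np.ndarray:
    """Per-1-kb-tile GC: baseline + coupling x normalized gene intensity +
    bounded uniform noise, clipped inside (0, 1)."""
    n_tiles = (length + _TILE - 1) // _TILE
    bg = config.effective_background_rate
    peak = bg * config.ridge_intensity_multiplier if blocks else bg
    rate = np.full(n_tiles, bg)
    for s, e in blocks:
        rate[(s - 1) // _TILE : (e - 1) // _TILE + 1] = (
            bg * config.ridge_intensity_multiplier
        )
    norm = rate / peak if peak > 0 else np.zeros(n_tiles)
    noise = rng.uniform(-config.gc_noise, config.gc_noise, size=n_tiles)
    return np.clip(config.gc_baseline + config.gc_coupling * norm + noise, 0.01, 0.99)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _sample_sequence(rng: np.random.Generator, tile_gc: np.ndarray, length: int) -> str:
    per_base_gc = np.repeat(tile_gc, _TILE)[:length]
    is_gc = rng.random(length) < per_base_gc
    pick = rng.integers(0, 2, size=length)
    codes = np.where(is_gc, 1 + pick, np.where(pick == 0, 0, 3))  # C/G vs A/T
    return _BASES[codes].tobytes().decode("ascii")


def _tile_chromosome(
    rng: np.random.Generator, length: int, target: int
) -> list[int]:
    """Scaffold lengths covering the chromosome exactly once."""
    lengths: list[int] = []
    remaining = length
    while remaining > 0:
        l = int(rng.uniform(0.5, 1.5) * target)
        l = max(min(l, remaining), 1)
        if remaining - l < 0.3 * target:  # absorb short remainders
            l = remaining
        lengths.append(l)
        remaining -= l
    return lengths


def simulate_genome(config: SimulationConfig) -> TrueGenome:
    """Draw a full ground-truth genome under the configured point process."""
    bg = config.effective_background_rate
    rng_genes = config.rng(_KEY_GENES)
    rng_gc = config.rng(_KEY_GC)
    rng_tiling = config.rng(_KEY_TILING)
    rng_seq = config.rng(_KEY_SEQ)

    chrom_ids = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = dict(zip(chrom_ids, config.chrom_lengths))

    genes: list[GeneRecord] = []
    ridge_truth: list[tuple[str, int, int]] = []
    sequences: dict[str, SequenceRecord] | None = (
        {} if config.generate_sequences else None
    )
    mult = config.ridge_intensity_multiplier

    for chrom in chrom_ids:
        length = chrom_lengths[chrom]
        if bg * length / 1e6 < 1:
            raise ConfigError(f"expected gene count < 1 on {chrom}")
        blocks = (
            _place_ridge_blocks(
                rng_genes, length, config.ridge_blocks_per_chrom, config.ridge_span
            )
            if config.ridge_blocks_per_chrom
            else []
        )
        ridge_truth.extend((chrom, s, e) for s, e in blocks)
        pos_bg = _draw_positions_in_segments(
            rng_genes, _complement_segments(blocks, length), bg
        )
        pos_ridge = _draw_positions_in_segments(rng_genes, blocks, bg * mult)
        positions = np.sort(np.concatenate([pos_bg, pos_ridge]))
        for k, p in enumerate(positions):
            genes.append(
                GeneRecord(
                    gene_id=f"{chrom}_g{k + 1:05d}",
                    seq_id=chrom,
                    start=int(p),
                    end=min(int(p) + _GENE_EXTENT - 1, length),
                    strand="+",
                )
            )
        tile_gc = _tile_gc(config, rng_gc, length, blocks)
        if sequences is not None:
            sequences[chrom] = SequenceRecord(
                seq_id=chrom, sequence=_sample_sequence(rng_seq, tile_gc, length)
            )

    # scaffold tiling: contiguous cover, globally shuffled ids so that the
    # identifier carries no positional information
    per_chrom_lengths = {
        chrom: _tile_chromosome(rng_tiling, chrom_lengths[chrom], config.scaffold_target_n50)
        for chrom in chrom_ids
    }
    n_total = sum(len(v) for v in per_chrom_lengths.values())
    id_perm = rng_tiling.permutation(n_total)
    width = len(str(n_total))
    tiling: dict[str, list[ScaffoldPlacement]] = {}
    scaffold_lengths: dict[str, int] = {}
    scaffold_spans: dict[str, tuple[str, int, int]] = {}
    slot = 0
    for chrom in chrom_ids:
        placements = []
        pos = 1
        for i, l in enumerate(per_chrom_lengths[chrom]):
            sid = f"scf{id_perm[slot] + 1:0{width}d}"
            slot += 1
            start, end = pos, pos + l - 1
            placements.append(
                ScaffoldPlacement(
                    scaffold_id=sid,
                    chrom_id=chrom,
                    order_index=i + 1,
                    orientation="+",
                    evidence="fish",
                    rel_position=((start + end) / 2) / chrom_lengths[chrom],
                )
            )
            scaffold_lengths[sid] = l
            scaffold_spans[sid] = (chrom, start, end)
            pos = end + 1
        tiling[chrom] = placements

    truth = TrueGenome(
        config=config,
        chrom_ids=chrom_ids,
        chrom_lengths=chrom_lengths,
        sequences=sequences,
        genes=genes,
        ridge_truth=ridge_truth,
        tiling=tiling,
        scaffold_lengths=scaffold_lengths,
        scaffold_spans=scaffold_spans,
    )
    truth.anchors = simulate_reference_species(truth, config)
    return truth


# ---------------------------------------------------------------------------
# FISH simulation


def _truncnorm_mean(
    rng: np.random.Generator, mu: float, sd: float, n: int
) -> tuple[float, np.ndarray]:
    if sd == 0:
        cells = np.full(n, mu)
    else:
        cells = np.empty(n)
        for i in range(n):
            while True:
                d = rng.normal(mu, sd)
                if 0.0 <= d <= 1.0:
                    cells[i] = d
                    break
    return float(cells.mean()), cells


def simulate_fish(
    truth: TrueGenome,
    probes: list[str],
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FISHObservation:
    """One co-hybridization of 1-3 scaffold probes.

    Per-cell distances are Normal(true rel_position, fish_noise_sd)
    truncated to [0, 1]; the observation carries their mean over
    ``cells_per_measurement`` cells.  Co-localization is exact.  The
    relative order of co-localized probes is the true order when the mean
    pairwise separation exceeds fish_noise_sd, otherwise the order of the
    noisy means.
    """
    config = config or truth.config
    rng = rng or config.rng(_KEY_FISH)
    for p in probes:
        if p not in truth.scaffold_spans:
            raise KeyError(f"probe scaffold {p!r} not in the tiling")
    chroms = {truth.scaffold_chrom(p) for p in probes}
    same = len(chroms) == 1
    if not same:
        return FISHObservation(
            probe_ids=tuple(probes), same_chromosome=False, mean_rel_distances=None
        )
    means = tuple(
        _truncnorm_mean(
            rng, truth.true_rel_position(p), config.fish_noise_sd,
            config.cells_per_measurement,
        )[0]
        for p in probes
    )
    if len(probes) >= 2:
        true_rel = [truth.true_rel_position(p) for p in probes]
        seps = [
            abs(a - b) for i, a in enumerate(true_rel) for b in true_rel[i + 1 :]
        ]
        if min(seps) > config.fish_noise_sd:
            order = tuple(p for _, p in sorted(zip(true_rel, probes)))
        else:
            order = tuple(p for _, p in sorted(zip(means, probes)))
    else:
        order = None
    return FISHObservation(
        probe_ids=tuple(probes),
        same_chromosome=True,
        mean_rel_distances=means,
        relative_order=order,
    )


class SimulatedFISH:
    """Oracle backend for the Cafs algorithms, driven by a TrueGenome.

    Distance measurements are cached per probe, so repeated queries are
    consistent (one wet-lab measurement per probe).  With
    ``measure_from_random_end=True`` each chromosome's distances are
    measured from a randomly chosen end — as on a pachytene spread, where
    the centromere end is unknown until the metaphase telomere landmark
    resolves it — so downstream orientation is exercised.
    """

    def __init__(
        self,
        truth: TrueGenome,
        config: SimulationConfig | None = None,
        measure_from_random_end: bool = False,
    ) -> None:
        self.truth = truth
        self.config = config or truth.config
        self._rng = self.config.rng(_KEY_FISH)
        self._means: dict[str, float] = {}
        self._flip: dict[str, bool] = {}
        if measure_from_random_end:
            flip_rng = self.config.rng(_KEY_FISH + 1)
            self._flip = {
                c: bool(flip_rng.integers(0, 2)) for c in truth.chrom_ids
            }

    def _true_measured(self, probe: str) -> float:
        rel = self.truth.true_rel_position(probe)
        if self._flip.get(self.truth.scaffold_chrom(probe), False):
            rel = 1.0 - rel
        return rel

    def distance(self, probe: str) -> float:
        """Mean measured distance (over cells) from the measurement end."""
        if probe not in self._means:
            self._means[probe], _ = _truncnorm_mean(
                self._rng,
                self._true_measured(probe),
                self.config.fish_noise_sd,
                self.config.cells_per_measurement,
            )
        return self._means[probe]

    def same_chromosome(self, a: str, b: str) -> bool:
        return self.truth.scaffold_chrom(a) == self.truth.scaffold_chrom(b)

    def order(self, probes) -> tuple[str, ...]:
        """Relative order along the measurement direction (2-3 probes)."""
        rel = [self._true_measured(p) for p in probes]
        seps = [abs(a - b) for i, a in enumerate(rel) for b in rel[i + 1 :]]
        if seps and min(seps) > self.config.fish_noise_sd:
            return tuple(p for _, p in sorted(zip(rel, probes)))
        return tuple(p for _, p in sorted(zip((self.distance(p) for p in probes), probes)))

    def head_is_telomeric(self, ordered: list[str]) -> bool:
        """Metaphase telomere landmark: is the list's head end telomeric?"""
        head = self.truth.true_rel_position(ordered[0])
        tail = self.truth.true_rel_position(ordered[-1])
        return head > tail


# ---------------------------------------------------------------------------
# Reference-species synteny


def simulate_reference_species(
    truth: TrueGenome, config: SimulationConfig | None = None
) -> dict[str, list[SyntenyAnchor]]:
    """Anchor maps for three reference species.

    Each species starts from the true scaffold order; every true adjacency
    is cut independently with probability ``rearrangement_rate``, and the
    resulting segments are translocated — shuffled and reassembled onto
    random reference chromosomes.  Interior adjacencies of a segment are
    untouched, so each true adjacency survives in a species with
    probability exactly (1 - rearrangement_rate); segment junctions add
    spurious adjacencies, emulating rearrangement noise.
    """
    config = config or truth.config
    rng = config.rng(_KEY_SYNTENY)
    anchors: dict[str, list[SyntenyAnchor]] = {}
    n_ref = len(truth.chrom_ids)
    for species in REFERENCE_SPECIES:
        segments: list[list[str]] = []
        for c in truth.chrom_ids:
            order = truth.true_order(c)
            seg = [order[0]]
            for right in order[1:]:
                if rng.random() < config.rearrangement_rate:
                    segments.append(seg)
                    seg = [right]
                else:
                    seg.append(right)
            segments.append(seg)
        chrom_lists: list[list[str]] = [[] for _ in range(n_ref)]
        targets = rng.integers(0, n_ref, size=len(segments))
        for k in rng.permutation(len(segments)):
            chrom_lists[targets[k]].extend(segments[k])
        species_anchors = []
        for ci, lst in enumerate(chrom_lists):
            for idx, sid in enumerate(lst):
                species_anchors.append(
                    SyntenyAnchor(
                        scaffold_id=sid,
                        species=species,
                        ref_chrom=f"{species}_ref{ci + 1}",
                        ref_index=idx,
                    )
                )
        anchors[species] = species_anchors
    return anchors


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(
    seq: SequenceRecord,
    coverage: float,
    read_len: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Uniform error-prone reads at the requested coverage.

    Read starts are uniform over valid positions; each base substitutes to
    one of the three other bases independently at ``error_rate``.
    """
    if coverage <= 0:
        raise ConfigError("coverage must be positive")
    if read_len > seq.length:
        raise ConfigError("read length exceeds the sequence length")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_KEY_READS,))
    )
    n_reads = int(round(coverage * seq.length / read_len))
    arr = np.frombuffer(seq.sequence.encode("ascii"), dtype=np.uint8)
    code = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    coded = code[arr]
    starts = rng.integers(0, seq.length - read_len + 1, size=n_reads)
    idx = starts[:, None] + np.arange(read_len)
    reads = coded[idx]
    if error_rate > 0:
        err = rng.random(reads.shape) < error_rate
        err &= reads != 255  # never substitute N placeholders
        shift = rng.integers(1, 4, size=int(err.sum()))
        reads[err] = (reads[err] + shift) % 4
    decode = np.frombuffer(b"ACGTN", dtype=np.uint8)
    out = decode[np.minimum(reads, 4)]
    return [row.tobytes().decode("ascii") for row in out]


def reads_to_fastq(reads: list[str], path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@{prefix}_{i + 1}\n{r}\n+\n{'I' * len(r)}\n")
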
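"""Cafs: chromosome assembly by FISH walking assisted by conserved synteny.

The strategy turns two kinds of experimental evidence into an ordered,
oriented chromosome assembly:

* co-hybridization of probe pairs (dual-/three-color FISH) answers whether
  two scaffolds sit on the same chromosome and, for nearby probes, their
  relative order;
* conserved synteny across three reference fish genomes (medaka,
  stickleback, Tetraodon) predicts which scaffolds are neighbors, so most
  scaffolds need only a single confirmatory hybridization against the right
  linkage-group landmark.

Scaffolds are grouped into linkage groups against landmark probes, ordered
within each group by their measured distance to the centromere (FISH
walking), oriented using the telomere as a morphological landmark (all
chromosomes are telocentric), and concatenated with fixed 1-kb N gaps.

Experimental evidence enters only through abstract oracle interfaces; the
simulation backend in :mod:`cafskit.synthetic` is the provided
implementation, and real FISH data could implement the same contract.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import numpy as np

from .core_io import (
    ChromosomeAssembly,
    ScaffoldPlacement,
    SequenceRecord,
    ValidationError,
    DEFAULT_GAP_LENGTH,
)

__all__ = [
    "SyntenyAnchor",
    "PredictedLink",
    "FISHObservation",
    "LinkageGroup",
    "HybridizationBudget",
    "probe_eligibility",
    "predict_linked_scaffolds",
    "assign_linkage_groups",
    "order_scaffolds",
    "orient_group",
    "build_chromosome",
    "anchored_fraction",
    "run_cafs",
]

REFERENCE_SPECIES = ("medaka", "stickleback", "tetraodon")


@dataclass(frozen=True)
class SyntenyAnchor:
    """One scaffold's homologous position in a reference genome."""

    scaffold_id: str
    species: str
    ref_chrom: str
    ref_index: int  # ordinal position along ref_chrom


@dataclass(frozen=True)
class PredictedLink:
    """A scaffold pair predicted adjacent because it is linked in all three
    reference species."""

    scaffold_a: str
    scaffold_b: str
    n_supporting_species: int = 3

    def __post_init__(self) -> None:
        if self.n_supporting_species != 3:
            raise ValidationError("links are emitted only with support in all 3 species")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.scaffold_a, self.scaffold_b))


@dataclass(frozen=True)
class FISHObservation:
    """One co-hybridization: 1-3 probes, co-localization flags, and mean
    distances to the centromere (each a mean over >= 5 cells, on a 0-1
    scale).  Distances are present only when all probes share a chromosome."""

    probe_ids: tuple[str, ...]
    same_chromosome: bool
    mean_rel_distances: tuple[float, ...] | None
    relative_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.probe_ids) <= 3:
            raise ValidationError("an observation carries 1-3 probes")
        if self.same_chromosome and self.mean_rel_distances is None:
            raise ValidationError("co-localized probes must carry distances")
        if not self.same_chromosome and self.mean_rel_distances is not None:
            raise ValidationError("distances are defined only for co-localized probes")


@dataclass
class LinkageGroup:
    group_id: str
    landmark_scaffold: str
    members: set[str] = field(default_factory=set)


@dataclass
class HybridizationBudget:
    """Counter of co-hybridization experiments (each 2- or 3-probe
    combination counts as one)."""

    n_cohybridizations: int = 0

    def charge(self, n: int = 1) -> None:
        if n < 0:
            raise ValueError("budget is monotone non-decreasing")
        self.n_cohybridizations += n


class CohybridizationOracle(Protocol):
    def same_chromosome(self, a: str, b: str) -> bool: ...


class OrderOracle(Protocol):
    def order(self, probes: Sequence[str]) -> tuple[str, ...]: ...


# ---------------------------------------------------------------------------
# Probe eligibility


def probe_eligibility(
    bac_end_alignments: Iterable[tuple[str, str, str, float]],
) -> list[str]:
    """BACs usable as FISH probes: both end sequences align to one scaffold,
    each with identity strictly greater than 90%.

    Input rows are (bac_id, end_label, scaffold_id, identity_percent).
    """
    by_bac: dict[str, dict[str, tuple[str, float]]] = {}
    for bac_id, end, scaffold_id, identity in bac_end_alignments:
        ends = by_bac.setdefault(bac_id, {})
        if end in ends:
            raise ValidationError(f"duplicate end record {end!r} for BAC {bac_id!r}")
        if len(ends) >= 2:
            raise ValidationError(f"BAC {bac_id!r} has more than 2 end records")
        ends[end] = (scaffold_id, identity)
    eligible = []
    for bac_id, ends in by_bac.items():
        if len(ends) != 2:
            continue
        (s1, id1), (s2, id2) = ends.values()
        if s1 == s2 and id1 > 90 and id2 > 90:
            eligible.append(bac_id)
    return eligible


# ---------------------------------------------------------------------------
# Synteny link prediction


def _adjacency_set(anchors: Iterable[SyntenyAnchor]) -> set[frozenset[str]]:
    by_chrom: dict[str, list[SyntenyAnchor]] = {}
    seen = set()
    for a in anchors:
        key = (a.species, a.ref_chrom, a.ref_index)
        if key in seen:
            raise ValidationError(f"duplicate anchor position {key}")
        seen.add(key)
        by_chrom.setdefault(a.ref_chrom, []).append(a)
    pairs: set[frozenset[str]] = set()
    for chrom_anchors in by_chrom.values():
        chrom_anchors.sort(key=lambda a: a.ref_index)
        for left, right in zip(chrom_anchors, chrom_anchors[1:]):
            pairs.add(frozenset((left.scaffold_id, right.scaffold_id)))
    return pairs


def predict_linked_scaffolds(
    anchors: Mapping[str, list[SyntenyAnchor]],
) -> list[PredictedLink]:
    """Scaffold pairs adjacent in the reference genomes of all three species."""
    if len(anchors) != 3:
        raise ValueError(f"need anchors for exactly 3 species, got {len(anchors)}")
    per_species = [_adjacency_set(a) for a in anchors.values()]
    shared = set.intersection(*per_species)
    links = [
        PredictedLink(scaffold_a=a, scaffold_b=b)
        for a, b in (sorted(pair) for pair in shared)
    ]
    links.sort(key=lambda l: (l.scaffold_a, l.scaffold_b))
    return links


# ---------------------------------------------------------------------------
# Linkage-group assignment


def _group_ids() -> Iterable[str]:
    for letter in string.ascii_uppercase:
        yield letter
    i = 1
    while True:
        for letter in string.ascii_uppercase:
            yield f"{letter}{i}"
        i += 1


def assign_linkage_groups(
    scaffolds: Sequence[str],
    oracle: CohybridizationOracle,
    hints: Iterable[PredictedLink] = (),
    expected_n_groups: int | None = None,
) -> tuple[list[LinkageGroup], HybridizationBudget]:
    """Partition scaffolds into linkage groups by landmark co-hybridization.

    The first scaffold founds group A and becomes its landmark.  Each later
    scaffold is first tested against the landmark of its synteny-predicted
    group (the group already holding a scaffold it is predicted-linked to),
    then against the remaining landmarks in group-founding order; if every
    test is negative it founds a new group with itself as landmark.  Every
    oracle query charges the hybridization budget.
    """
    neighbors: dict[str, set[str]] = {}
    for link in hints:
        neighbors.setdefault(link.scaffold_a, set()).add(link.scaffold_b)
        neighbors.setdefault(link.scaffold_b, set()).add(link.scaffold_a)

    groups: list[LinkageGroup] = []
    member_group: dict[str, LinkageGroup] = {}
    budget = HybridizationBudget()
    ids = _group_ids()

    for scaffold in scaffolds:
        hinted: LinkageGroup | None = None
        for nb in sorted(neighbors.get(scaffold, ())):
            if nb in member_group:
                hinted = member_group[nb]
                break
        assigned = None
        tried: set[str] = set()
        candidates = ([hinted] if hinted else []) + [
            g for g in groups if g is not hinted
        ]
        for group in candidates:
            if group.group_id in tried:
                continue
            tried.add(group.group_id)
            budget.charge()
            if oracle.same_chromosome(scaffold, group.landmark_scaffold):
                assigned = group
                break
        if assigned is None:
            assigned = LinkageGroup(group_id=next(ids), landmark_scaffold=scaffold)
            groups.append(assigned)
            if expected_n_groups is not None and len(groups) > expected_n_groups:
                raise ValidationError(
                    f"founded {len(groups)} groups but configuration asserts "
                    f"{expected_n_groups} chromosomes"
                )
        assigned.members.add(scaffold)
        member_group[scaffold] = assigned
    return groups, budget


# ---------------------------------------------------------------------------
# Ordering by FISH walking


def order_scaffolds(
    members: Iterable[str],
    distances: Mapping[str, float],
    oracle: OrderOracle | None = None,
    resolution: float = 0.0,
    budget: HybridizationBudget | None = None,
) -> list[tuple[str, float]]:
    """Order a linkage group by ascending mean distance to the centromere.

    Adjacent pairs whose measured distances differ by less than
    ``resolution`` are disambiguated by order-oracle queries (each charged
    to the budget); ties that remain fall back to scaffold-id order.
    Returns (scaffold_id, rel_position) pairs, centromere first, with
    positions made non-decreasing.
    """
    members = sorted(members)
    missing = [m for m in members if m not in distances]
    if missing:
        raise ValidationError(f"no distance measurement for scaffolds {missing}")
    ordered = sorted(members, key=lambda s: (distances[s], s))
    if oracle is not None and resolution > 0 and len(ordered) > 1:
        changed = True
        max_passes = len(ordered)
        pass_no = 0
        queried: dict[frozenset[str], tuple[str, ...]] = {}
        while changed and pass_no < max_passes:
            changed = False
            pass_no += 1
            for i in range(len(ordered) - 1):
                a, b = ordered[i], ordered[i + 1]
                if abs(distances[a] - distances[b]) >= resolution:
                    continue
                key = frozenset((a, b))
                if key not in queried:
                    if budget is not None:
                        budget.charge()
                    queried[key] = tuple(oracle.order((a, b)))
                if queried[key] == (b, a):
                    ordered[i], ordered[i + 1] = b, a
                    changed = True
    rel = np.maximum.accumulate(
        np.clip([distances[s] for s in ordered], 0.0, 1.0)
    )
    return list(zip(ordered, (float(r) for r in rel)))


# ---------------------------------------------------------------------------
# Orientation and chromosome building


def orient_group(
    ordered: list[tuple[str, float]],
    head_is_telomeric: bool,
    tail_is_telomeric: bool | None = None,
) -> list[tuple[str, float]]:
    """Emit the ordered list centromere-first, reversing it when the telomere
    landmark sits at the list's head.  Flipping reflects the distance scale
    (d -> 1 - d)."""
    if not ordered:
        raise ValidationError("cannot orient an empty group")
    if tail_is_telomeric is not None and head_is_telomeric == tail_is_telomeric:
        raise ValidationError(
            "contradictory telomere observation: both ends flagged alike"
        )
    if not head_is_telomeric:
        return list(ordered)
    return [(s, 1.0 - d) for s, d in reversed(ordered)]


def to_assembly(
    chrom_id: str,
    ordered: list[tuple[str, float]],
    evidence: Mapping[str, str] | None = None,
    orientations: Mapping[str, str] | None = None,
    gap_length: int = DEFAULT_GAP_LENGTH,
) -> ChromosomeAssembly:
    """Wrap an oriented (scaffold, rel_position) list as a ChromosomeAssembly."""
    placements = [
        ScaffoldPlacement(
            scaffold_id=s,
            chrom_id=chrom_id,
            order_index=i + 1,
            orientation=(orientations or {}).get(s, "+"),
            evidence=(evidence or {}).get(s, "fish"),
            rel_position=d,
        )
        for i, (s, d) in enumerate(ordered)
    ]
    return ChromosomeAssembly(chrom_id=chrom_id, placements=placements, gap_length=gap_length)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_chromosome(
    assembly: ChromosomeAssembly,
    scaffold_sequences: Mapping[str, str | SequenceRecord],
) -> SequenceRecord:
    """Concatenate the ordered scaffolds with ``gap_length`` Ns between
    neighbors, reverse-complementing reverse-oriented placements."""
    parts: list[str] = []
    gap = "N" * assembly.gap_length
    for i, p in enumerate(assembly.placements):
        if p.scaffold_id not in scaffold_sequences:
            raise KeyError(f"no sequence for scaffold {p.scaffold_id!r}")
        seq = scaffold_sequences[p.scaffold_id]
        if isinstance(seq, SequenceRecord):
            seq = seq.sequence
        if i > 0:
            parts.append(gap)
        parts.append(reverse_complement(seq) if p.orientation == "-" else seq)
    return SequenceRecord(seq_id=assembly.chrom_id, sequence="".join(parts))


def anchored_fraction(
    placed: Iterable[str], scaffold_lengths: Mapping[str, int]
) -> float:
    """Fraction of total scaffold length that was placed on chromosomes."""
    placed = set(placed)
    total = sum(scaffold_lengths.values())
    if total == 0:
        raise ValueError("no scaffolds")
    return sum(scaffold_lengths[s] for s in placed) / total


# ---------------------------------------------------------------------------
# End-to-end driver


def run_cafs(
    scaffolds: Sequence[str],
    distance: Mapping[str, float] | Callable[[str], float],
    cohyb_oracle: CohybridizationOracle,
    order_oracle: OrderOracle | None = None,
    telomere_head: Callable[[list[str]], bool] | None = None,
    hints: Iterable[PredictedLink] = (),
    resolution: float = 0.0,
    expected_n_groups: int | None = None,
) -> tuple[dict[str, ChromosomeAssembly], list[LinkageGroup], HybridizationBudget]:
    """Assign, order, and orient scaffolds into chromosome assemblies.

    ``distance`` maps a scaffold to its measured relative distance to the
    centromere; ``telomere_head`` reports, for an ordered scaffold list,
    whether its head end carries the telomere landmark (None keeps the
    measured direction).
    """
    groups, budget = assign_linkage_groups(
        scaffolds, cohyb_oracle, hints=hints, expected_n_groups=expected_n_groups
    )
    get_d = distance if callable(distance) else distance.__getitem__
    assemblies: dict[str, ChromosomeAssembly] = {}
    for group in groups:
        dist = {s: get_d(s) for s in group.members}
        ordered = order_scaffolds(
            group.members, dist, oracle=order_oracle, resolution=resolution, budget=budget
        )
        if telomere_head is not None:
            ordered = orient_group(
                ordered, head_is_telomeric=telomere_head([s for s, _ in ordered])
            )
        chrom_id = f"chr{group.group_id}"
        assemblies[chrom_id] = to_assembly(chrom_id, ordered)
    return assemblies, groups, budget
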
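"""End-to-end orchestration: simulate -> tracks -> ridge test -> correlation
scan -> Cafs assembly -> summary metrics, with a manifest recording seeds,
config hash, and every artifact written."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cafs import predict_linked_scaffolds, run_cafs
from .core_io import write_agp, write_fasta, write_genes
from .correlation import (
    ScanThresholds,
    flag_summary,
    high_regions_to_bed,
    regional_scan,
    scan_to_tsv,
)
from .metrics import (
    chromosome_summary,
    nxx_table,
    summary_to_tsv,
)
from .ridges import RidgeCutoffs, detect_ridges, permutation_test, ridges_to_bed
from .synthetic import SimulatedFISH, SimulationConfig, simulate_genome
from .windows import WindowSpec, combine_tracks, count_genes_in_windows, gc_track, track_to_tsv


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative run configuration; either a simulation block or real
    input paths must be present."""

    simulation: SimulationConfig | None = None
    fasta: str | None = None
    gff3: str | None = None
    window: WindowSpec = field(default_factory=WindowSpec)
    cutoffs: RidgeCutoffs = field(default_factory=RidgeCutoffs)
    n_perm: int = 10_000
    seed: int = 0
    thresholds: ScanThresholds = field(default_factory=ScanThresholds)
    cafs_resolution: float = 0.0
    outdir: str = "cafskit_out"

    def __post_init__(self) -> None:
        if self.simulation is None and (self.fasta is None or self.gff3 is None):
            raise ConfigError("need a simulation block or FASTA+GFF3 input paths")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        sim = raw.pop("simulation", None)
        kwargs = {}
        if sim is not None:
            if "chrom_lengths" in sim:
                sim["chrom_lengths"] = tuple(sim["chrom_lengths"])
            kwargs["simulation"] = SimulationConfig(**sim)
        if "window" in raw:
            kwargs["window"] = WindowSpec(**raw.pop("window"))
        if "cutoffs" in raw:
            kwargs["cutoffs"] = RidgeCutoffs(**raw.pop("cutoffs"))
        if "thresholds" in raw:
            kwargs["thresholds"] = ScanThresholds(**raw.pop("thresholds"))
        kwargs.update(raw)
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            raise TypeError
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=enc)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "cafskit",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                outputs = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "FAILED", "error": str(exc)}
                (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise StageError(name, exc) from exc
            manifest["stages"][name] = {
                "status": "ok",
                "outputs": outputs,
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
            return outputs

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        if config.simulation is None:
            from .core_io import read_fasta, read_genes

            state["sequences"] = {s.seq_id: s for s in read_fasta(config.fasta)}
            state["genes"] = read_genes(config.gff3, "gff3")
            state["truth"] = None
            return []
        truth = simulate_genome(config.simulation)
        state["truth"] = truth
        state["sequences"] = truth.sequences or {}
        state["genes"] = truth.genes
        paths = []
        if truth.sequences:
            p = outdir / "genome.fasta"
            write_fasta(truth.sequences.values(), p)
            paths.append(str(p))
        p = outdir / "genes.gff3"
        write_genes(truth.genes, p, "gff3")
        paths.append(str(p))
        return paths

    @stage("tracks")
    def _tracks():
        genes_by_chrom: dict[str, list] = {}
        for g in state["genes"]:
            genes_by_chrom.setdefault(g.seq_id, []).append(g)
        lengths = (
            state["truth"].chrom_lengths
            if state["truth"] is not None
            else {c: s.length for c, s in state["sequences"].items()}
        )
        tracks = {}
        paths = []
        for chrom in sorted(lengths):
            count_tr = count_genes_in_windows(
                genes_by_chrom.get(chrom, []), lengths[chrom], config.window, seq_id=chrom
            )
            if chrom in state["sequences"]:
                tr = combine_tracks(count_tr, gc_track(state["sequences"][chrom], config.window))
            else:
                tr = count_tr
            tracks[chrom] = tr
            p = outdir / f"track_{chrom}.tsv"
            p.write_text(track_to_tsv(tr))
            paths.append(str(p))
        state["tracks"] = tracks
        state["chrom_lengths"] = lengths
        return paths

    @stage("ridges")
    def _ridges():
        ridges = []
        for tr in state["tracks"].values():
            ridges.extend(detect_ridges(tr, config.cutoffs))
        genes_by_chrom: dict[str, list[int]] = {}
        for g in state["genes"]:
            genes_by_chrom.setdefault(g.seq_id, []).append(g.start)
        genome = {
            c: (np.array(sorted(v), dtype=np.int64), state["chrom_lengths"][c])
            for c, v in genes_by_chrom.items()
        }
        res = permutation_test(
            genome,
            config.window,
            config.cutoffs,
            n_perm=config.n_perm,
            seed=config.seed,
            observed_n=len(ridges),
        )
        bed = outdir / "ridges.bed"
        bed.write_text(ridges_to_bed(ridges))
        report = outdir / "ridge_test.json"
        report.write_text(
            json.dumps(
                {
                    "observed_n": res.observed_n,
                    "n_perm": res.n_perm,
                    "f": res.f,
                    "p": res.p_label,
                    "qualification": ">=" if config.cutoffs.ge else ">",
                    "seed": res.seed,
                },
                indent=2,
            )
        )
        return [str(bed), str(report)]

    @stage("correlate")
    def _correlate():
        scans = []
        for tr in state["tracks"].values():
            if tr.gc_fractions is None:
                continue
            scans.extend(regional_scan(tr, thresholds=config.thresholds))
        paths = []
        p = outdir / "regional_correlation.tsv"
        p.write_text(scan_to_tsv(scans))
        paths.append(str(p))
        p = outdir / "high_correlation.bed"
        p.write_text(high_regions_to_bed(scans))
        paths.append(str(p))
        if scans:
            p = outdir / "correlation_summary.json"
            p.write_text(json.dumps(flag_summary(scans), indent=2))
            paths.append(str(p))
        return paths

    @stage("cafs")
    def _cafs():
        truth = state["truth"]
        if truth is None:
            return []  # Cafs needs experimental (here: simulated) evidence
        fish = SimulatedFISH(truth, measure_from_random_end=True)
        hints = predict_linked_scaffolds(truth.anchors)
        assemblies, groups, budget = run_cafs(
            scaffolds=sorted(truth.scaffold_lengths),
            distance=fish.distance,
            cohyb_oracle=fish,
            order_oracle=fish,
            telomere_head=fish.head_is_telomeric,
            hints=hints,
            resolution=config.cafs_resolution,
            expected_n_groups=truth.config.n_chromosomes,
        )
        state["assemblies"] = assemblies
        paths = []
        for chrom_id, asm in sorted(assemblies.items()):
            p = outdir / f"{chrom_id}.agp"
            p.write_text(write_agp(asm, truth.scaffold_lengths))
            paths.append(str(p))
        p = outdir / "linkage_groups.tsv"
        p.write_text(
            "group\tlandmark\tmembers\n"
            + "".join(
                f"{g.group_id}\t{g.landmark_scaffold}\t{','.join(sorted(g.members))}\n"
                for g in groups
            )
        )
        paths.append(str(p))
        p = outdir / "budget.json"
        p.write_text(json.dumps({"n_cohybridizations": budget.n_cohybridizations}))
        paths.append(str(p))
        return paths

    @stage("metrics")
    def _metrics():
        paths = []
        truth = state["truth"]
        if truth is not None:
            table = nxx_table(list(truth.scaffold_lengths.values()))
            p = outdir / "nxx.tsv"
            p.write_text(table.to_tsv())
            paths.append(str(p))
            if "assemblies" in state:
                from .core_io import project_to_chromosome, UnplacedScaffoldError

                asm_by_scaffold = {
                    pl.scaffold_id: a
                    for a in state["assemblies"].values()
                    for pl in a.placements
                }
                projected = []
                for g in truth.genes:
                    chrom, start, end = None, None, None
                    # genes are simulated in chromosome coordinates; re-express
                    # on their scaffold, then project through the built assembly
                    for sid, (c, s, e) in truth.scaffold_spans.items():
                        if c == g.seq_id and s <= g.start <= e:
                            chrom, start, end = sid, s, e
                            break
                    if chrom is None:
                        continue
                    local = dataclasses.replace(
                        g,
                        seq_id=chrom,
                        start=g.start - start + 1,
                        end=min(g.end, end) - start + 1,
                    )
                    try:
                        projected.append(
                            project_to_chromosome(
                                local, asm_by_scaffold[chrom], truth.scaffold_lengths
                            )
                        )
                    except (KeyError, UnplacedScaffoldError):
                        pass
                rows, totals = chromosome_summary(
                    list(state["assemblies"].values()), projected, truth.scaffold_lengths
                )
                p = outdir / "chromosome_summary.tsv"
                p.write_text(summary_to_tsv(rows, totals))
                paths.append(str(p))
        return paths

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
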
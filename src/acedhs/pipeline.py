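"""End-to-end orchestration of the accelerated-DHS analysis.

Stages run in a fixed order, each reading its inputs from, and writing its
outputs to, a run directory:

``simulate`` -> ``regions`` -> ``filter`` -> ``accelerate`` -> ``motifs``
-> ``targets`` -> ``snps`` -> ``report``

Every stage is file-driven, so stages can be run one at a time from the CLI;
a stage whose inputs are missing fails fast naming the stage. Re-running the
whole pipeline with the same configuration and seed reproduces all outputs
byte-identically (timing goes to a separate log, never into results).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import assoc, filters, intervals, motifs, phylo, simulate
from .alignment import OrthologAlignment
from .hky import Tree
from .intervals import GenomicInterval, write_bed

STAGES = (
    "simulate", "regions", "filter", "accelerate", "motifs", "targets",
    "snps", "report",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration (YAML-loadable, unknown keys rejected)."""

    run_dir: str = "acedhs_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # fixture
    n_genes: int = 5
    n_dhs_per_gene: int = 10
    n_accelerated: int = 5
    rho: float = 3.0
    filter_violators: dict[str, int] = field(default_factory=dict)
    dhs_length: int = simulate.DEFAULT_DHS_LENGTH
    are_length: int = simulate.DEFAULT_ARE_LENGTH  # > 2x DHS: windows engage
    topology: str = simulate.DEFAULT_TREE
    kappa: float = simulate.DEFAULT_KAPPA
    samples_per_species: int = 4
    # analysis parameters
    half_width: int = 50_000
    are_dist: int = 5_000
    min_len: int = 100
    min_species: int = 4
    alpha: float = 0.05
    r_threshold: float = 0.7
    fimo_p: float = 1e-4
    rel_score: float = 0.8
    motif_file: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        checks = [
            (self.half_width > 0, "half_width must be > 0"),
            (self.are_dist > 0, "are_dist must be > 0"),
            (self.min_len >= 1, "min_len must be >= 1"),
            (self.min_species >= 2, "min_species must be >= 2"),
            (0 < self.alpha < 1, "alpha must be in (0,1)"),
            (0 <= self.r_threshold < 1, "r_threshold must be in [0,1)"),
            (0 < self.fimo_p <= 1, "fimo_p must be in (0,1]"),
            (0 < self.rel_score <= 1, "rel_score must be in (0,1]"),
            (self.n_genes >= 1 and self.n_dhs_per_gene >= 1, "counts must be >= 1"),
            (self.samples_per_species >= 2, "samples_per_species must be >= 2"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage '{stage}' requires {path.name}, produced by stage "
            f"'{produced_by}' — enable it or provide the file"
        )
    return path


def _log(rundir: Path, message: str) -> None:
    with open(rundir / "pipeline.log", "a") as fh:
        fh.write(message + "\n")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, rundir: Path) -> dict:
    planted = simulate.PlantedCases(
        n_accelerated=cfg.n_accelerated, rho=cfg.rho,
        filter_violators=dict(cfg.filter_violators),
    )
    fixture = simulate.generate_genome_fixture(
        n_genes=cfg.n_genes, n_dhs_per_gene=cfg.n_dhs_per_gene,
        planted=planted, seed=cfg.seed, dhs_length=cfg.dhs_length,
        are_length=cfg.are_length, topology=cfg.topology, kappa=cfg.kappa,
    )
    fixture.write(rundir / "fixture")
    return {
        "genes": len(fixture.genes), "dhss": len(fixture.dhss),
        "ares": len(fixture.ares),
        "planted_accelerated": planted.n_accelerated,
        "planted_violators": sum(planted.filter_violators.values()),
    }


def _load_fixture(rundir: Path, stage: str):
    _require(rundir / "fixture" / "config.yaml", stage, "simulate")
    return simulate.load_fixture(rundir / "fixture")


def stage_regions(cfg: RunConfig, rundir: Path) -> dict:
    fixture = _load_fixture(rundir, "regions")
    regions = [
        intervals.define_regulatory_region(g, fixture.chrom_length, cfg.half_width)
        for g in fixture.genes
    ]
    write_bed(regions, rundir / "regulatory_regions.bed")
    merged = intervals.merge_intervals(fixture.dhss)
    related = intervals.elements_of(fixture.dhss, regions)
    write_bed(related, rundir / "brain_dhss.bed")
    with open(rundir / "dhs_annotation.tsv", "w") as fh:
        fh.write("dhs\tfeature\ttss_distance\tnearest_gene\n")
        for d in related:
            feat = intervals.annotate_feature(d, fixture.genes)
            dist, gid = intervals.distance_to_tss(d, fixture.genes)
            fh.write(f"{d.id}\t{feat}\t{dist}\t{gid}\n")
    return {
        "regions": len(regions), "merged_dhs_blocks": len(merged),
        "brain_dhss": len(related),
    }


def stage_filter(cfg: RunConfig, rundir: Path) -> dict:
    fixture = _load_fixture(rundir, "filter")
    _require(rundir / "brain_dhss.bed", "filter", "regions")
    keep = {iv.id for iv in intervals.read_bed(rundir / "brain_dhss.bed")}
    pairs = [
        p for p in filters.build_pairs_from_fixture(fixture) if p.id in keep
    ]
    report = filters.apply_filters(
        pairs,
        {
            "exons": fixture.exons, "promoters": fixture.promoters,
            "simple_repeats": fixture.simple_repeats,
            "low_complexity": fixture.low_complexity, "segdups": fixture.segdups,
        },
        min_length=cfg.min_len, min_species=cfg.min_species,
        max_are_dist=cfg.are_dist,
    )
    report.to_tsv(rundir / "filter_report.tsv")
    write_bed([p.dhs.interval for p in report.surviving], rundir / "surviving_dhss.bed")
    if not report.reconciles():
        raise PipelineError("filter report does not reconcile")
    return {
        "input": report.input_count, "surviving": len(report.surviving),
        **{f"removed_{k}": v for k, v in sorted(report.removal_counts.items())},
    }


def stage_accelerate(cfg: RunConfig, rundir: Path) -> dict:
    fixture = _load_fixture(rundir, "accelerate")
    surviving = intervals.read_bed(
        _require(rundir / "surviving_dhss.bed", "accelerate", "filter")
    )
    topology = Tree.from_newick(fixture.tree)
    results: list[phylo.AccelerationResult] = []
    for dhs_iv in surviving:
        eid = dhs_iv.id
        results += phylo.test_element(
            fixture.element_alignments[eid],
            fixture.element_alignments[f"{eid}_are"],
            topology,
        )
    calls = phylo.call_accelerated(results, alpha=cfg.alpha)
    with open(rundir / "acceleration.tsv", "w") as fh:
        fh.write(
            "element\twindow\tn_windows\tlnl_neutral\trho_a\tlr_a\tp_a\tq_a"
            "\tnu_b\trho_b\tlr_b\tp_b\tq_b\tuntestable\taccelerated\n"
        )
        for r in calls.results:
            fh.write(
                f"{r.element_id}\t{r.window}\t{r.n_windows}\t{r.lnl_neutral:.6f}"
                f"\t{r.rho_a:.6g}\t{r.lr_a:.6g}\t{r.p_a:.6g}\t{r.q_a:.6g}"
                f"\t{r.nu_b:.6g}\t{r.rho_b:.6g}\t{r.lr_b:.6g}\t{r.p_b:.6g}"
                f"\t{r.q_b:.6g}\t{int(r.untestable)}\t{int(r.accelerated)}\n"
            )
    accel_ivs = [iv for iv in surviving if iv.id in set(calls.accelerated_ids)]
    write_bed(accel_ivs, rundir / "accelerated_dhss.bed")
    return {
        "tested": len(surviving), "windows": len(results),
        "accelerated": len(calls.accelerated_ids),
    }


_DEFAULT_MOTIF_COUNTS = np.array(
    # a fixed 8-bp synthetic regulatory motif (near-consensus TGACGTCA)
    [
        [2, 1, 38, 1, 2, 1, 1, 36],
        [1, 1, 1, 37, 2, 1, 37, 2],
        [1, 37, 1, 1, 35, 1, 1, 1],
        [36, 1, 0, 1, 1, 37, 1, 1],
    ],
    dtype=float,
)


def default_motif() -> motifs.PWM:
    return motifs.PWM.from_counts("SYN0001", _DEFAULT_MOTIF_COUNTS)


def stage_motifs(cfg: RunConfig, rundir: Path) -> dict:
    fixture = _load_fixture(rundir, "motifs")
    accel = intervals.read_bed(
        _require(rundir / "accelerated_dhss.bed", "motifs", "accelerate")
    )
    pwms = (
        motifs.read_pwm(cfg.motif_file) if cfg.motif_file else [default_motif()]
    )
    n_hits = 0
    counts = {"human_gain": 0, "human_loss": 0, "conserved": 0, "unclassified": 0}
    with open(rundir / "motif_hits.tsv", "w") as hits_fh, open(
        rundir / "affinity.tsv", "w"
    ) as aff_fh:
        hits_fh.write("element\tmotif\toffset\tstrand\tscore\tp\trelative\n")
        aff_fh.write("element\tmotif\tclassification\tscores\texcluded\n")
        for iv in accel:
            aln = fixture.element_alignments[iv.id]
            human_seq = aln.ungapped("human")
            for pwm in pwms:
                for hit in motifs.scan_sequence(
                    human_seq, pwm, p_threshold=cfg.fimo_p, sequence_id=iv.id
                ):
                    n_hits += 1
                    hits_fh.write(
                        f"{iv.id}\t{hit.motif_id}\t{hit.offset}\t{hit.strand}"
                        f"\t{hit.score:.4f}\t{hit.pvalue:.4g}\t{hit.relative:.4f}\n"
                    )
                    cmp_ = motifs.compare_species_affinity(
                        aln, hit, pwm, threshold=cfg.rel_score
                    )
                    counts[cmp_.classification] += 1
                    scores = ",".join(
                        f"{sp}:{v:.3f}" for sp, v in sorted(cmp_.scores.items())
                    )
                    aff_fh.write(
                        f"{iv.id}\t{hit.motif_id}\t{cmp_.classification}"
                        f"\t{scores}\t{','.join(cmp_.excluded) or '.'}\n"
                    )
    return {"hits": n_hits, **counts}


def stage_targets(cfg: RunConfig, rundir: Path) -> dict:
    fixture = _load_fixture(rundir, "targets")
    accel = intervals.read_bed(
        _require(rundir / "accelerated_dhss.bed", "targets", "accelerate")
    )
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    gene_ids = [g.id for g in fixture.genes]
    expr = simulate.generate_expression_matrix(
        n_genes=len(gene_ids), samples_per_species=cfg.samples_per_species,
        noise_sd=0.25, seed=cfg.seed + 7,
    )
    expr.gene_ids = gene_ids
    expr.to_tsv(rundir / "expression.tsv")
    # element accessibility tracks its host gene's expression plus noise
    host = {}
    for iv in accel:
        containing = [
            g.id for g in fixture.genes
            if abs(iv.center - g.interval.center) <= cfg.half_width
        ]
        host[iv.id] = containing[0] if containing else gene_ids[0]
    dhs_signal = {
        iv.id: expr.row(host[iv.id]) + 0.1 * rng.standard_normal(expr.values.shape[1])
        for iv in accel
    }
    gene_signal = {g: expr.row(g) for g in gene_ids}
    cis = assoc.cis_candidate_pairs(accel, [g.interval for g in fixture.genes])
    links = assoc.assign_targets(
        dhs_signal, gene_signal, r_threshold=cfg.r_threshold, cis_pairs=cis
    )
    with open(rundir / "links.tsv", "w") as fh:
        fh.write("element\ttargets\n")
        for did in sorted(links):
            fh.write(f"{did}\t{','.join(links[did]) or '.'}\n")
    n_links = sum(len(v) for v in links.values())
    return {
        "elements": len(accel), "linked_elements":
        sum(1 for v in links.values() if v), "links": n_links,
        "target_genes": len({g for v in links.values() for g in v}),
    }


def stage_snps(cfg: RunConfig, rundir: Path) -> dict:
    accel = intervals.read_bed(
        _require(rundir / "accelerated_dhss.bed", "snps", "accelerate")
    )
    links: dict[str, list[str]] = {}
    with open(_require(rundir / "links.tsv", "snps", "targets")) as fh:
        next(fh)
        for line in fh:
            eid, targets = line.rstrip("\n").split("\t")
            links[eid] = [] if targets == "." else targets.split(",")
    usable = [e for e in accel if links.get(e.id)]
    n_conc = (len(usable) + 1) // 2
    n_disc = len(usable) - n_conc
    snps, reported = simulate.generate_snp_table(
        accel, links, n_concordant=n_conc, n_discordant=n_disc,
        seed=cfg.seed + 11,
    )
    common = assoc.filter_snps_by_af(snps, min_af=0.01)
    table = assoc.snp_overlap(common, accel, reported, links)
    table.to_csv(rundir / "snps.tsv", sep="\t", index=False)
    return {
        "snps": len(snps), "common_snps": len(common),
        "in_elements": len(table),
        "concordant": int(table["concordant"].sum()) if len(table) else 0,
    }


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    rundir = Path(cfg.run_dir)
    rundir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(rundir / "run_config.yaml")
    stage_fns = {
        "simulate": stage_simulate, "regions": stage_regions,
        "filter": stage_filter, "accelerate": stage_accelerate,
        "motifs": stage_motifs, "targets": stage_targets, "snps": stage_snps,
    }
    params = dataclasses.asdict(cfg)
    params.pop("run_dir")  # environment detail, not part of the analysis
    summary: dict[str, dict] = {"parameters": params}
    enabled = [s for s in STAGES if s in cfg.stages]
    for stage in enabled:
        if stage == "report":
            continue
        t0 = time.monotonic()
        counts = stage_fns[stage](cfg, rundir)
        _log(rundir, f"{stage}: {counts} ({time.monotonic() - t0:.2f}s)")
        summary[stage] = counts
    if "report" in enabled:
        with open(rundir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return rundir
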
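"""Synthetic primate regulatory-genomics data with known ground truth.

Everything the pipeline consumes can be generated here: ortholog alignments
evolving on a fixed primate tree under HKY85 (with an optional human-branch
rate multiplier rho), gene/DHS/ARE coordinate structure on a single synthetic
chromosome ``chrS``, planted filter violations, planted motif instances with
lineage-specific affinity changes, species-labelled expression matrices, and
SNP tables. Coordinates are 0-based half-open.

The default tree keeps the catarrhine topology but compresses evolutionary
time about three-fold relative to the real primates (human terminal branch
0.021 expected substitutions/site, human-macaque path ~0.36): per-element
maximum-likelihood calibration on a single ancient repeat needs enough
substitutions per branch to be informative, and at strict primate depth a
single 1-2 kb element carries too few. The tree root is a trifurcation (an
unrooted topology), so every branch length is identifiable under the
reversible model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .alignment import OrthologAlignment, write_alignment_fasta
from .hky import BASES, HKYModel, Tree
from .intervals import GenomicInterval, GeneRecord, write_bed

#: Five-taxon primate topology with a trifurcating root (unrooted form).
DEFAULT_TREE = (
    "(((human:0.021,chimp:0.021):0.0075,gorilla:0.027):0.030,"
    "orangutan:0.060,macaque:0.300);"
)

#: Six-taxon variant including marmoset (used for binding-affinity comparisons).
DEFAULT_TREE_MARMOSET = (
    "((((human:0.021,chimp:0.021):0.0075,gorilla:0.027):0.030,"
    "orangutan:0.060):0.036,macaque:0.264,marmoset:0.480);"
)

DEFAULT_KAPPA = 4.0
DEFAULT_BASE_FREQS = (0.29, 0.21, 0.21, 0.29)  # 42% GC
DEFAULT_DHS_LENGTH = 800
#: ARE longer than twice the DHS, so the sliding-window majority vote engages.
DEFAULT_ARE_LENGTH = 2000

FILTER_RULES = (
    "min_length",
    "min_species",
    "are_distance",
    "are_length_or_overlap",
    "are_nonneutral",
)


@dataclass
class SimulationConfig:
    """Parameters of one simulated ortholog alignment."""

    topology: str = DEFAULT_TREE
    kappa: float = DEFAULT_KAPPA
    base_freqs: tuple = DEFAULT_BASE_FREQS
    human_rate_multiplier: float = 1.0
    element_length: int = DEFAULT_DHS_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.base_freqs, dtype=float)
        if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("base_freqs must be 4 non-negative reals summing to 1")
        if not np.isfinite(self.kappa) or self.kappa <= 0:
            raise ValueError("kappa must be positive and finite")
        rho = self.human_rate_multiplier
        if not np.isfinite(rho) or rho < 0:
            raise ValueError("human_rate_multiplier must be a non-negative real")
        if self.element_length < 1:
            raise ValueError("element_length must be >= 1")
        tree = Tree.from_newick(self.topology)
        if np.any(tree.blen < 0) or not np.all(np.isfinite(tree.blen)):
            raise ValueError("branch lengths must be finite and >= 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "topology": self.topology,
                    "kappa": self.kappa,
                    "base_freqs": list(self.base_freqs),
                    "human_rate_multiplier": self.human_rate_multiplier,
                    "element_length": self.element_length,
                    "seed": self.seed,
                },
                fh, sort_keys=False,
            )


def _sample_states(rng: np.random.Generator, cum: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw of one categorical state per row of ``cum``."""
    u = rng.random(cum.shape[0])
    return np.minimum((u[:, None] > cum).sum(axis=1), 3)


def simulate_alignment(
    config: SimulationConfig, element_id: str = "element"
) -> OrthologAlignment:
    """Evolve one gap-free element down the tree under HKY85.

    The root sequence is drawn from the equilibrium frequencies; each branch
    applies site-independent substitution with P(t) from the HKY rate matrix,
    the human terminal branch length multiplied by the rate multiplier rho.
    Draw order is fixed (root first, then branches in preorder), so identical
    seed + config gives bit-identical output.
    """
    tree = Tree.from_newick(config.topology)
    model = HKYModel(config.kappa, np.asarray(config.base_freqs, dtype=float))
    rng = np.random.default_rng(config.seed)
    length = config.element_length
    human = tree.leaf_names.get("human")

    states: dict[int, np.ndarray] = {}
    cum_pi = np.tile(np.cumsum(model.pi), (length, 1))
    states[tree.root] = _sample_states(rng, cum_pi)
    for node in reversed(tree.postorder):
        node = int(node)
        if tree.parent[node] < 0:
            continue
        t = tree.blen[node]
        if node == human:
            t *= config.human_rate_multiplier
        cum = np.cumsum(model.transition_matrix(t), axis=1)
        states[node] = _sample_states(rng, cum[states[tree.parent[node]]])

    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    seqs = {
        name: base_arr[states[idx]].tobytes().decode()
        for name, idx in tree.leaf_names.items()
    }
    return OrthologAlignment(element_id, seqs)


# ---------------------------------------------------------------------------
# Genome fixture
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    status: str  # neutral | accelerated | filtered_by:<rule>
    rho: float = 1.0


@dataclass
class PlantedCases:
    """What to plant in a genome fixture.

    ``n_accelerated`` elements evolve with human-branch multiplier ``rho``;
    ``filter_violators`` maps each pre-processing rule id to the number of
    elements violating exactly that rule.
    """

    n_accelerated: int = 0
    rho: float = 3.0
    filter_violators: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.filter_violators) - set(FILTER_RULES)
        if bad:
            raise ValueError(f"unknown filter rules: {sorted(bad)}")
        if self.n_accelerated and self.rho <= 1:
            raise ValueError("planted accelerated elements require rho > 1")

    @property
    def total(self) -> int:
        return self.n_accelerated + sum(self.filter_violators.values())


@dataclass
class GenomeFixture:
    """A synthetic chromosome with genes, DHSs, AREs, tracks, and truth."""

    chrom: str
    chrom_length: int
    tree: str
    genes: list[GeneRecord]
    dhss: list[GenomicInterval]
    ares: list[GenomicInterval]
    exons: list[GenomicInterval]
    promoters: list[GenomicInterval]
    simple_repeats: list[GenomicInterval]
    low_complexity: list[GenomicInterval]
    segdups: list[GenomicInterval]
    chromhmm_segments: list[tuple[GenomicInterval, str]]
    dhs_orthologs: dict[str, dict[str, GenomicInterval]]
    are_orthologs: dict[str, dict[str, GenomicInterval]]
    element_alignments: dict[str, OrthologAlignment]
    truth: dict[str, TruthRecord]
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        """Serialise the fixture: BED6 tracks, per-element multi-FASTA,
        truth TSV, Newick tree and YAML config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bed([g.interval for g in self.genes], outdir / "genes.bed")
        write_bed(self.dhss, outdir / "dhss.bed")
        write_bed(self.ares, outdir / "ares.bed")
        for name in ("exons", "promoters", "simple_repeats", "low_complexity", "segdups"):
            write_bed(getattr(self, name), outdir / f"{name}.bed")
        with open(outdir / "chromhmm.tsv", "w") as fh:
            for seg, state in self.chromhmm_segments:
                fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{state}\n")
        alndir = outdir / "alignments"
        alndir.mkdir(exist_ok=True)
        for eid, aln in self.element_alignments.items():
            write_alignment_fasta(aln, alndir / f"{eid}.fa")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("element\tstatus\trho\n")
            for eid, rec in sorted(self.truth.items()):
                fh.write(f"{eid}\t{rec.status}\t{rec.rho:g}\n")
        with open(outdir / "orthologs.tsv", "w") as fh:
            fh.write("element\tclass\tspecies\tchrom\tstart\tend\n")
            for cls, table in (("dhs", self.dhs_orthologs), ("are", self.are_orthologs)):
                for eid in sorted(table):
                    for sp in sorted(table[eid]):
                        iv = table[eid][sp]
                        fh.write(f"{eid}\t{cls}\t{sp}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
        with open(outdir / "genes_structure.tsv", "w") as fh:
            fh.write("gene\tchrom\tstart\tend\tstrand\texon_starts\texon_ends\n")
            for g in self.genes:
                es = ",".join(str(e.start) for e in g.exons)
                ee = ",".join(str(e.end) for e in g.exons)
                fh.write(
                    f"{g.id}\t{g.interval.chrom}\t{g.interval.start}\t"
                    f"{g.interval.end}\t{g.strand}\t{es}\t{ee}\n"
                )
        with open(outdir / "chrom.tsv", "w") as fh:
            fh.write(f"{self.chrom}\t{self.chrom_length}\n")
        with open(outdir / "tree.nwk", "w") as fh:
            fh.write(self.tree + "\n")
        self.config.to_yaml(outdir / "config.yaml")


def load_fixture(outdir: str | Path) -> GenomeFixture:
    """Reconstruct a serialised GenomeFixture from its output directory."""
    from .alignment import read_alignment_fasta
    from .intervals import read_bed, read_chromhmm

    outdir = Path(outdir)
    with open(outdir / "chrom.tsv") as fh:
        chrom, chrom_length = fh.readline().split("\t")
    genes: list[GeneRecord] = []
    with open(outdir / "genes_structure.tsv") as fh:
        next(fh)
        for line in fh:
            gid, gchrom, gs, ge, strand, es, ee = line.rstrip("\n").split("\t")
            exons = [
                GenomicInterval(gchrom, int(a), int(b))
                for a, b in zip(es.split(","), ee.split(","))
                if a
            ]
            genes.append(
                GeneRecord(gid, GenomicInterval(gchrom, int(gs), int(ge), id=gid),
                           strand, exons=exons)
            )
    dhs_orth: dict[str, dict[str, GenomicInterval]] = {}
    are_orth: dict[str, dict[str, GenomicInterval]] = {}
    with open(outdir / "orthologs.tsv") as fh:
        next(fh)
        for line in fh:
            eid, cls, sp, c, s, e = line.rstrip("\n").split("\t")
            table = dhs_orth if cls == "dhs" else are_orth
            suffix = "" if cls == "dhs" else "_are"
            table.setdefault(eid, {})[sp] = GenomicInterval(
                c, int(s), int(e), id=eid + suffix
            )
    truth: dict[str, TruthRecord] = {}
    with open(outdir / "truth.tsv") as fh:
        next(fh)
        for line in fh:
            eid, status, rho = line.rstrip("\n").split("\t")
            truth[eid] = TruthRecord(status, float(rho))
    alignments = {
        p.stem: read_alignment_fasta(p) for p in sorted((outdir / "alignments").glob("*.fa"))
    }
    with open(outdir / "tree.nwk") as fh:
        tree = fh.read().strip()
    with open(outdir / "config.yaml") as fh:
        cfg_raw = yaml.safe_load(fh)
    cfg_raw["base_freqs"] = tuple(cfg_raw["base_freqs"])
    config = SimulationConfig(**cfg_raw)
    return GenomeFixture(
        chrom=chrom, chrom_length=int(chrom_length), tree=tree, genes=genes,
        dhss=read_bed(outdir / "dhss.bed"), ares=read_bed(outdir / "ares.bed"),
        exons=read_bed(outdir / "exons.bed"),
        promoters=read_bed(outdir / "promoters.bed"),
        simple_repeats=read_bed(outdir / "simple_repeats.bed"),
        low_complexity=read_bed(outdir / "low_complexity.bed"),
        segdups=read_bed(outdir / "segdups.bed"),
        chromhmm_segments=read_chromhmm(outdir / "chromhmm.tsv"),
        dhs_orthologs=dhs_orth, are_orthologs=are_orth,
        element_alignments=alignments, truth=truth, config=config,
    )


_GENE_PITCH = 120_000
_GENE_LENGTH = 20_000
_DHS_PITCH = 7_000
_CHROMHMM_STATES = ("Promoter", "Enhancer", "Transcribed", "Heterochromatin")


def generate_genome_fixture(
    n_genes: int = 5,
    n_dhs_per_gene: int = 10,
    planted: PlantedCases | None = None,
    seed: int = 0,
    dhs_length: int = DEFAULT_DHS_LENGTH,
    are_length: int = DEFAULT_ARE_LENGTH,
    topology: str = DEFAULT_TREE,
    kappa: float = DEFAULT_KAPPA,
    base_freqs: tuple = DEFAULT_BASE_FREQS,
) -> GenomeFixture:
    """Build a synthetic chromosome whose ground truth is fully known.

    Genes sit every 120 kb on ``chrS`` with +-50 kb regulatory space; each
    gene carries ``n_dhs_per_gene`` DHSs, each paired with a nearby neutral
    ARE 2 kb away. Planted cases are assigned to the first DHS slots in a
    fixed order (filter violators rule by rule, then accelerated elements),
    so a given (config, seed) is bit-reproducible.
    """
    if n_genes < 1 or n_dhs_per_gene < 1:
        raise ValueError("counts must be >= 1")
    planted = planted or PlantedCases()
    n_dhs = n_genes * n_dhs_per_gene
    if planted.total > n_dhs:
        raise ValueError(
            f"{planted.total} planted cases exceed {n_dhs} available DHSs"
        )
    rng = np.random.default_rng(seed)
    tree = Tree.from_newick(topology)
    species = sorted(tree.leaf_names)
    chrom = "chrS"
    chrom_length = _GENE_PITCH * (n_genes + 1)

    # assign a role to every DHS slot
    roles: list[tuple[str, float]] = []
    for rule in FILTER_RULES:
        roles += [(f"filtered_by:{rule}", 1.0)] * planted.filter_violators.get(rule, 0)
    roles += [("accelerated", planted.rho)] * planted.n_accelerated
    roles += [("neutral", 1.0)] * (n_dhs - len(roles))

    genes: list[GeneRecord] = []
    exons: list[GenomicInterval] = []
    promoters: list[GenomicInterval] = []
    dhss: list[GenomicInterval] = []
    ares: list[GenomicInterval] = []
    simple_repeats: list[GenomicInterval] = []
    low_complexity: list[GenomicInterval] = []
    segdups: list[GenomicInterval] = []
    dhs_orth: dict[str, dict[str, GenomicInterval]] = {}
    are_orth: dict[str, dict[str, GenomicInterval]] = {}
    alignments: dict[str, OrthologAlignment] = {}
    truth: dict[str, TruthRecord] = {}

    slot = 0
    for gi in range(n_genes):
        gstart = _GENE_PITCH // 2 + gi * _GENE_PITCH
        gene_iv = GenomicInterval(chrom, gstart, gstart + _GENE_LENGTH, id=f"gene{gi}")
        strand = "+" if gi % 2 == 0 else "-"
        gene_exons = [
            GenomicInterval(chrom, gstart + 500, gstart + 1500),
            GenomicInterval(chrom, gstart + _GENE_LENGTH - 1500, gstart + _GENE_LENGTH - 500),
        ]
        gene = GeneRecord(f"gene{gi}", gene_iv, strand, exons=gene_exons)
        genes.append(gene)
        exons += gene_exons
        tss = gene.tss
        promoters.append(
            GenomicInterval(chrom, max(0, tss - 1000), tss + 200, id=f"prom_gene{gi}")
        )
        region_start = gene_iv.center - 50_000
        region_end = gene_iv.center + 50_000
        # clean elements must not touch the gene's exon/promoter footprint
        footprint = (gstart - 3_000, gstart + _GENE_LENGTH + 2_000)
        pos = region_start + 2_000
        for di in range(n_dhs_per_gene):
            status, rho = roles[slot]
            eid = f"dhs_{slot:04d}"
            slot += 1
            this_dhs_len = dhs_length
            this_are_len = are_length
            are_gap = 2_000  # DHS end to ARE start
            if status == "filtered_by:min_length":
                this_dhs_len = 80
            elif status == "filtered_by:are_length_or_overlap":
                this_are_len = max(100, dhs_length // 2)  # ARE shorter than DHS
            span = this_dhs_len + are_gap + this_are_len
            if pos < footprint[1] and pos + span > footprint[0]:
                pos = footprint[1]
            if pos + span > region_end:
                raise ValueError(
                    "n_dhs_per_gene too large for the regulatory region layout"
                )
            d_start = pos
            pos += _DHS_PITCH
            dhs = GenomicInterval(chrom, d_start, d_start + this_dhs_len, id=eid)
            a_start = dhs.end + are_gap
            are = GenomicInterval(chrom, a_start, a_start + this_are_len, id=f"{eid}_are")
            dhss.append(dhs)
            ares.append(are)
            truth[eid] = TruthRecord(status, rho)

            present = list(species)
            if status == "filtered_by:min_species":
                present = [s for s in species if s in ("human", "chimp", "gorilla")]
            dhs_orth[eid] = {s: dhs for s in present}
            if status == "filtered_by:are_distance":
                shifted = GenomicInterval(chrom, are.start + 10_000, are.end + 10_000, id=are.id)
                are_orth[eid] = {
                    s: (shifted if s == "chimp" else are) for s in present
                }
            else:
                are_orth[eid] = {s: are for s in present}
            if status == "filtered_by:are_nonneutral":
                simple_repeats.append(
                    GenomicInterval(chrom, are.start + 50, are.start + 250, id=f"rep_{eid}")
                )

            dhs_cfg = SimulationConfig(
                topology=topology, kappa=kappa, base_freqs=base_freqs,
                human_rate_multiplier=rho, element_length=this_dhs_len,
                seed=int(rng.integers(2**31)),
            )
            are_cfg = SimulationConfig(
                topology=topology, kappa=kappa, base_freqs=base_freqs,
                human_rate_multiplier=1.0, element_length=this_are_len,
                seed=int(rng.integers(2**31)),
            )
            dhs_aln = simulate_alignment(dhs_cfg, eid)
            are_aln = simulate_alignment(are_cfg, f"{eid}_are")
            if status == "filtered_by:min_species":
                dhs_aln = dhs_aln.subset(present)
                are_aln = are_aln.subset(present)
            alignments[eid] = dhs_aln
            alignments[f"{eid}_are"] = are_aln

    # background non-neutral tracks well away from any ARE
    low_complexity.append(GenomicInterval(chrom, 1_000, 1_400, id="lc0"))
    segdups.append(GenomicInterval(chrom, 5_000, 9_000, id="segdup0"))
    chromhmm: list[tuple[GenomicInterval, str]] = []
    seg_width = 25_000
    for k, s in enumerate(range(0, chrom_length, seg_width)):
        chromhmm.append(
            (
                GenomicInterval(chrom, s, min(chrom_length, s + seg_width)),
                _CHROMHMM_STATES[k % len(_CHROMHMM_STATES)],
            )
        )

    cfg = SimulationConfig(
        topology=topology, kappa=kappa, base_freqs=base_freqs,
        element_length=dhs_length, seed=seed,
    )
    return GenomeFixture(
        chrom=chrom, chrom_length=chrom_length, tree=topology,
        genes=genes, dhss=dhss, ares=ares, exons=exons, promoters=promoters,
        simple_repeats=simple_repeats, low_complexity=low_complexity,
        segdups=segdups, chromhmm_segments=chromhmm,
        dhs_orthologs=dhs_orth, are_orthologs=are_orth,
        element_alignments=alignments, truth=truth, config=cfg,
    )


# ---------------------------------------------------------------------------
# Expression matrices and SNP tables
# ---------------------------------------------------------------------------

def generate_expression_matrix(
    n_genes: int,
    samples_per_species: int,
    shifted_genes: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 0.25,
    seed: int = 0,
    species: tuple = ("human", "chimp", "macaque"),
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
):
    """Log-scale expression: gene baseline + species shift + Gaussian noise.

    ``shifted_genes`` maps gene id -> {species: mean shift}. Returns an
    :class:`acedhs.assoc.ExpressionMatrix`.
    """
    from .assoc import ExpressionMatrix  # local import to avoid a cycle

    if samples_per_species < 2:
        raise ValueError("need >= 2 samples per species")
    if noise_sd < 0 or not np.isfinite(noise_sd):
        raise ValueError("noise_sd must be finite and >= 0")
    shifted_genes = shifted_genes or {}
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    baseline = baseline_mean + baseline_sd * rng.standard_normal(n_genes)
    species_labels: list[str] = []
    sample_ids: list[str] = []
    cols = []
    for sp in species:
        for r in range(samples_per_species):
            shift = np.array(
                [shifted_genes.get(g, {}).get(sp, 0.0) for g in gene_ids]
            )
            cols.append(baseline + shift + noise_sd * rng.standard_normal(n_genes))
            species_labels.append(sp)
            sample_ids.append(f"{sp}_{r}")
    values = np.column_stack(cols)
    return ExpressionMatrix(
        values=values, gene_ids=gene_ids, sample_ids=sample_ids,
        species=species_labels,
    )


def generate_snp_table(
    elements: list[GenomicInterval],
    links: dict[str, list[str]],
    n_concordant: int,
    n_discordant: int,
    seed: int = 0,
    n_individuals: int = 100,
):
    """SNPs inside elements, with reported genes concordant or not with links.

    Returns a list of :class:`acedhs.assoc.SNPRecord` plus the reported-gene
    annotation mapping. Genotypes are Hardy-Weinberg draws at a random allele
    frequency, so the alt frequency is consistent with the genotypes.
    """
    from .assoc import SNPRecord

    rng = np.random.default_rng(seed)
    usable = [e for e in elements if e.id in links and links[e.id]]
    if n_concordant + n_discordant > len(usable):
        raise ValueError("not enough linked elements to host the requested SNPs")
    snps: list[SNPRecord] = []
    reported: dict[str, str] = {}
    for k in range(n_concordant + n_discordant):
        host = usable[k]
        pos = int(rng.integers(host.start, host.end))
        af = float(rng.uniform(0.05, 0.5))
        geno = rng.binomial(2, af, size=n_individuals)
        sid = f"rs{k:05d}"
        snps.append(
            SNPRecord(
                id=sid, chrom=host.chrom, position=pos, ref="A", alt="G",
                alt_frequency=float(geno.mean() / 2), genotypes=geno.tolist(),
            )
        )
        if k < n_concordant:
            reported[sid] = links[host.id][0]
        else:
            reported[sid] = f"unrelated_gene_{k}"
    return snps, reported


# ---------------------------------------------------------------------------
# Planted motif instances
# ---------------------------------------------------------------------------

def generate_motif_fixture(
    pwm,
    n_elements: int,
    kind: str = "human_gain",
    seed: int = 0,
    flank: int = 30,
    n_disruptions: int = 2,
    species: tuple = ("human", "chimp", "gorilla", "orangutan", "macaque"),
):
    """Gap-free element alignments with a planted lineage-specific motif.

    ``human_gain``: the human sequence carries the motif consensus, every
    other species carries the consensus with ``n_disruptions`` substitutions
    at the most informative columns. ``human_loss`` is the mirror image;
    ``conserved`` plants the intact consensus in all species. Returns a list
    of (OrthologAlignment, planted offset).
    """
    if kind not in ("human_gain", "human_loss", "conserved"):
        raise ValueError(f"unknown kind: {kind}")
    rng = np.random.default_rng(seed)
    consensus = pwm.consensus()
    w = pwm.width
    # disrupt where it hurts the score most, substituting the worst base
    info_order = np.argsort(-pwm.information_content())
    out = []
    for k in range(n_elements):
        flank_left = "".join(rng.choice(list(BASES), size=flank))
        flank_right = "".join(rng.choice(list(BASES), size=flank))
        broken = list(consensus)
        for j in info_order[:n_disruptions]:
            broken[j] = BASES[int(np.argmin(pwm.log_odds[:, j]))]
        broken = "".join(broken)
        seqs = {}
        for sp in species:
            if kind == "conserved":
                core = consensus
            elif kind == "human_gain":
                core = consensus if sp == "human" else broken
            else:
                core = broken if sp == "human" else consensus
            seqs[sp] = flank_left + core + flank_right
        out.append((OrthologAlignment(f"motif_{kind}_{k:03d}", seqs), flank))
    return out
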
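"""Target-gene assignment, cross-species expression statistics, SNP utilities.

Elements are linked to target genes by cross-sample Pearson correlation of
element accessibility against gene signal (r > 0.7, strict), expression
matrices are Z-score normalised per gene, species differences are assessed by
Welch two-sample t-tests, and SNPs inside elements are checked for
reported-vs-target gene concordance. LD between two variants is the squared
Pearson correlation of allele dosages (composite LD); qPCR relative
expression uses 2^-dCt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval


@dataclass
class ExpressionMatrix:
    """genes x samples real matrix with per-sample species labels."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    species: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids) or n_samples != len(self.sample_ids):
            raise ValueError("matrix shape does not match labels")
        if len(self.species) != n_samples or any(not s for s in self.species):
            raise ValueError("every sample needs a species label")

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def species_columns(self, species: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.species) if s == species])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=self.gene_ids,
            columns=pd.MultiIndex.from_arrays(
                [self.species, self.sample_ids], names=("species", "sample")
            ),
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\t" + "\t".join(self.sample_ids) + "\n")
            fh.write("#species\t" + "\t".join(self.species) + "\n")
            for g, row in zip(self.gene_ids, self.values):
                fh.write(g + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            species_line = fh.readline().rstrip("\n").split("\t")
            if species_line[0] != "#species":
                raise ValueError("second line must be the '#species' row")
            gene_ids, rows = [], []
            for line in fh:
                f = line.rstrip("\n").split("\t")
                gene_ids.append(f[0])
                rows.append([float(x) for x in f[1:]])
        return cls(
            values=np.array(rows), gene_ids=gene_ids,
            sample_ids=header[1:], species=species_line[1:],
        )


@dataclass
class SNPRecord:
    id: str
    chrom: str
    position: int  # 0-based
    ref: str
    alt: str
    alt_frequency: float
    genotypes: list[int] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alt_frequency <= 1.0):
            raise ValueError(f"{self.id}: allele frequency outside [0,1]")
        if self.genotypes is not None:
            if any(g not in (0, 1, 2) for g in self.genotypes):
                raise ValueError(f"{self.id}: genotypes must be dosages 0/1/2")
            n = len(self.genotypes)
            if n and abs(sum(self.genotypes) / (2 * n) - self.alt_frequency) > 1 / (2 * n) + 1e-9:
                raise ValueError(f"{self.id}: frequency inconsistent with genotypes")

    @property
    def maf(self) -> float:
        return min(self.alt_frequency, 1.0 - self.alt_frequency)


# ---------------------------------------------------------------------------
# Target-gene assignment
# ---------------------------------------------------------------------------

def assign_targets(
    dhs_signal: dict[str, np.ndarray],
    gene_signal: dict[str, np.ndarray],
    r_threshold: float = 0.7,
    cis_pairs: set[tuple[str, str]] | None = None,
) -> dict[str, list[str]]:
    """Link each element to genes whose signal correlates with it (r > 0.7).

    Signals must be aligned on the same >= 4 samples. ``cis_pairs`` optionally
    restricts the candidate (element, gene) pairs (e.g. a 1 Mb cis window);
    when None, all pairs are candidates. A DHS may link several genes.
    Zero-variance vectors are skipped with a warning.
    """
    links: dict[str, list[str]] = {}
    for did, dv in dhs_signal.items():
        dv = np.asarray(dv, dtype=float)
        targets = []
        for gid, gv in gene_signal.items():
            if cis_pairs is not None and (did, gid) not in cis_pairs:
                continue
            gv = np.asarray(gv, dtype=float)
            if dv.size != gv.size or dv.size < 4:
                raise ValueError(f"({did},{gid}): need >= 4 aligned samples")
            if np.std(dv) == 0 or np.std(gv) == 0:
                warnings.warn(f"({did},{gid}): zero-variance signal, pair skipped")
                continue
            r = float(np.corrcoef(dv, gv)[0, 1])
            if r > r_threshold:
                targets.append(gid)
        links[did] = targets
    return links


def cis_candidate_pairs(
    elements: list[GenomicInterval],
    genes: list[GenomicInterval],
    window: int = 1_000_000,
) -> set[tuple[str, str]]:
    """(element, gene) pairs whose centers are within ``window`` bp in cis."""
    return {
        (e.id, g.id)
        for e in elements
        for g in genes
        if e.chrom == g.chrom and abs(e.center - g.center) <= window
    }


# ---------------------------------------------------------------------------
# Expression statistics
# ---------------------------------------------------------------------------

def zscore_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene Z scores (mean 0, sd 1 with n-1 denominator).

    Constant genes map to all-zero rows with a warning.
    """
    if expr.values.shape[1] < 2:
        raise ValueError("need >= 2 samples to normalise")
    out = np.empty_like(expr.values)
    for i, row in enumerate(expr.values):
        sd = row.std(ddof=1)
        if sd == 0:
            warnings.warn(f"{expr.gene_ids[i]}: constant gene mapped to zeros")
            out[i] = 0.0
        else:
            out[i] = (row - row.mean()) / sd
    return ExpressionMatrix(
        values=out, gene_ids=list(expr.gene_ids),
        sample_ids=list(expr.sample_ids), species=list(expr.species),
    )


def species_ttest(
    expr: ExpressionMatrix, gene_id: str, species_a: str, species_b: str
) -> tuple[float, float]:
    """Welch two-sample, two-sided t-test of one gene between two species."""
    row = expr.row(gene_id)
    a = row[expr.species_columns(species_a)]
    b = row[expr.species_columns(species_b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 samples in each species group")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0  # identical constant groups: no evidence of difference
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# SNP utilities
# ---------------------------------------------------------------------------

def snp_overlap(
    snps: list[SNPRecord],
    elements: list[GenomicInterval],
    reported_genes: dict[str, str],
    links: dict[str, list[str]],
) -> pd.DataFrame:
    """SNPs inside elements with reported-vs-target gene concordance.

    Membership is the half-open point test position in [start, end). A SNP is
    concordant when its reported gene is among the linked targets of the
    element containing it.
    """
    rows = []
    for snp in snps:
        for el in elements:
            if el.contains_point(snp.chrom, snp.position):
                reported = reported_genes.get(snp.id)
                targets = links.get(el.id, [])
                rows.append(
                    dict(
                        snp=snp.id, element=el.id, position=snp.position,
                        alt_frequency=snp.alt_frequency,
                        reported_gene=reported,
                        concordant=bool(reported in targets),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["snp", "element", "position", "alt_frequency",
                 "reported_gene", "concordant"],
    )


def filter_snps_by_af(snps: list[SNPRecord], min_af: float = 0.01) -> list[SNPRecord]:
    """Keep SNPs with minor-allele frequency strictly above ``min_af``."""
    return [s for s in snps if s.maf > min_af]


def ld_r2(genotypes_a, genotypes_b) -> float:
    """Composite LD: squared Pearson correlation of allele dosages."""
    a = np.asarray(genotypes_a, dtype=float)
    b = np.asarray(genotypes_b, dtype=float)
    if a.size != b.size:
        raise ValueError("dosage vectors must cover the same individuals")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ValueError("monomorphic site: LD undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """qPCR relative expression, 2^-(Ct_target - Ct_reference)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** -(ct_target - ct_reference))


def relative_expression_batch(
    ct_targets: np.ndarray, ct_references: np.ndarray, control_mask: np.ndarray
) -> np.ndarray:
    """Per-sample 2^-dCt, normalised to the control group's mean."""
    rel = 2.0 ** -(np.asarray(ct_targets, float) - np.asarray(ct_references, float))
    control_mask = np.asarray(control_mask, dtype=bool)
    if not control_mask.any():
        raise ValueError("empty control group")
    return rel / rel[control_mask].mean()
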
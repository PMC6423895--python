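"""DHS/ARE pairing and the pre-processing filter rules.

Each DHS is paired with its nearest local ancient repeat element (ARE) within
+-5 kb of the DHS center, then the pair runs a fixed cascade of quality rules.
A removed element is attributed to the FIRST rule it violates, so the report
reconciles exactly: input = survivors + sum of per-rule removals.

Rules, in order:

* ``min_length`` — human DHS or ARE sequence shorter than 100 bp;
* ``min_species`` — DHS or ARE with ortholog sequences in fewer than 4
  species (human must be among them);
* ``are_distance`` — ARE within 5 kb of the DHS center in human but more
  than 5 kb away in any other primate with an ortholog;
* ``are_length_or_overlap`` — DHS longer than its ARE, or DHS and ARE
  overlapping in any genome;
* ``are_nonneutral`` — ARE overlapping coding exons, promoters, simple
  repeats, low-complexity regions, or segmental duplications (any of which
  would break the neutrality assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import OrthologAlignment
from .intervals import GenomicInterval, merge_intervals
from .simulate import FILTER_RULES

MIN_LENGTH = 100
MIN_SPECIES = 4
MAX_ARE_DISTANCE = 5_000

NONNEUTRAL_TRACKS = (
    "exons", "promoters", "simple_repeats", "low_complexity", "segdups",
)


@dataclass
class OrthologElement:
    """A DHS or ARE with per-species coordinates and its alignment."""

    interval: GenomicInterval  # human coordinates
    ortholog_intervals: dict[str, GenomicInterval]
    alignment: OrthologAlignment

    @property
    def species(self) -> set[str]:
        return set(self.ortholog_intervals)


@dataclass
class ElementPair:
    dhs: OrthologElement
    are: OrthologElement

    @property
    def id(self) -> str:
        return self.dhs.interval.id or "?"


@dataclass
class FilterReport:
    input_count: int
    surviving: list[ElementPair]
    removal_counts: dict[str, int] = field(default_factory=dict)
    removed_by: dict[str, str] = field(default_factory=dict)  # element -> rule

    @property
    def surviving_ids(self) -> list[str]:
        return [p.id for p in self.surviving]

    def reconciles(self) -> bool:
        return self.input_count == len(self.surviving) + sum(
            self.removal_counts.values()
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"input\t{self.input_count}\n")
            fh.write(f"surviving\t{len(self.surviving)}\n")
            for rule in FILTER_RULES:
                fh.write(f"removed:{rule}\t{self.removal_counts.get(rule, 0)}\n")


def edge_distance(point: int, interval: GenomicInterval) -> int:
    """Distance from a point to the nearest edge of an interval (0 if inside)."""
    if point < interval.start:
        return interval.start - point
    if point >= interval.end:
        return point - interval.end + 1
    return 0


def pair_dhs_with_are(
    dhs: GenomicInterval,
    ares: list[GenomicInterval],
    max_dist: int = MAX_ARE_DISTANCE,
) -> GenomicInterval | None:
    """Closest ARE whose nearest edge is within ``max_dist`` of the DHS center.

    Ties in distance go to the ARE with the smaller start.
    """
    center = dhs.center
    best = None
    for are in ares:
        if are.chrom != dhs.chrom:
            continue
        d = edge_distance(center, are)
        if d > max_dist:
            continue
        key = (d, are.start)
        if best is None or key < best[0]:
            best = (key, are)
    return None if best is None else best[1]


def _first_violation(
    pair: ElementPair,
    nonneutral_union: list[GenomicInterval],
    min_length: int = MIN_LENGTH,
    min_species: int = MIN_SPECIES,
    max_are_dist: int = MAX_ARE_DISTANCE,
) -> str | None:
    dhs, are = pair.dhs, pair.are
    dhs_len = len(dhs.alignment.ungapped("human")) if "human" in dhs.alignment.species else 0
    are_len = len(are.alignment.ungapped("human")) if "human" in are.alignment.species else 0
    if dhs_len < min_length or are_len < min_length:
        return "min_length"
    if (
        len(dhs.species) < min_species
        or len(are.species) < min_species
        or "human" not in dhs.species
        or "human" not in are.species
    ):
        return "min_species"
    for sp, are_iv in are.ortholog_intervals.items():
        if sp == "human":
            continue
        dhs_iv = pair.dhs.ortholog_intervals.get(sp)
        if dhs_iv is None:
            continue
        if edge_distance(dhs_iv.center, are_iv) > max_are_dist:
            return "are_distance"
    if dhs.interval.length > are.interval.length:
        return "are_length_or_overlap"
    for sp, dhs_iv in dhs.ortholog_intervals.items():
        are_iv = are.ortholog_intervals.get(sp)
        if are_iv is not None and dhs_iv.overlap(are_iv) >= 1:
            return "are_length_or_overlap"
    for iv in nonneutral_union:
        if are.interval.overlap(iv) >= 1:
            return "are_nonneutral"
    return None


def apply_filters(
    pairs: list[ElementPair],
    nonneutral_tracks: dict[str, list[GenomicInterval]],
    min_length: int = MIN_LENGTH,
    min_species: int = MIN_SPECIES,
    max_are_dist: int = MAX_ARE_DISTANCE,
) -> FilterReport:
    """Run the rule cascade over DHS/ARE pairs.

    ``nonneutral_tracks`` must supply all five tracks named in
    :data:`NONNEUTRAL_TRACKS` (an empty list is a valid track; a missing key
    is a configuration error, never silently skipped).
    """
    missing = [t for t in NONNEUTRAL_TRACKS if t not in nonneutral_tracks]
    if missing:
        raise ValueError(f"missing non-neutral tracks: {missing}")
    union = merge_intervals(
        iv for t in NONNEUTRAL_TRACKS for iv in nonneutral_tracks[t]
    )
    surviving: list[ElementPair] = []
    counts: dict[str, int] = {}
    removed_by: dict[str, str] = {}
    for pair in pairs:
        rule = _first_violation(pair, union, min_length, min_species, max_are_dist)
        if rule is None:
            surviving.append(pair)
        else:
            counts[rule] = counts.get(rule, 0) + 1
            removed_by[pair.id] = rule
    return FilterReport(
        input_count=len(pairs), surviving=surviving,
        removal_counts=counts, removed_by=removed_by,
    )


def build_pairs_from_fixture(fixture) -> list[ElementPair]:
    """Assemble ElementPairs from a GenomeFixture via ARE pairing."""
    ares_by_id = {a.id: a for a in fixture.ares}
    pairs = []
    for dhs_iv in fixture.dhss:
        eid = dhs_iv.id
        chosen = pair_dhs_with_are(dhs_iv, fixture.ares)
        if chosen is None:
            continue
        are_id = chosen.id
        dhs = OrthologElement(
            interval=dhs_iv,
            ortholog_intervals=fixture.dhs_orthologs[eid],
            alignment=fixture.element_alignments[eid],
        )
        # ortholog coordinates recorded under the DHS the ARE was generated for
        src = are_id.removesuffix("_are")
        are = OrthologElement(
            interval=ares_by_id[are_id],
            ortholog_intervals=fixture.are_orthologs[src],
            alignment=fixture.element_alignments[are_id],
        )
        pairs.append(ElementPair(dhs=dhs, are=are))
    return pairs
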
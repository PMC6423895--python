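"""PWM scanning with exact p-values and cross-species affinity comparison.

Scoring follows the FIMO convention: counts become probabilities with a total
pseudocount of 0.1 distributed by the background, scores are log2 odds against
a 0-order background, and p-values come from the exact distribution of the
discretised score (dynamic programming over columns, 1/1000-bit bins) under
the background model. Relative scores follow the JASPAR scan convention:
(score - min) / (max - min) on the log-odds scale, with 0.8 the usual
binding-call threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import motifs as bio_motifs

from .alignment import OrthologAlignment
from .hky import BASE_INDEX, BASES

SCALE = 1000  # DP bins per bit
DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_REL_THRESHOLD = 0.8
PSEUDOCOUNT = 0.1
MIN_SCORED_SPECIES = 3

_COMPLEMENT = np.array([3, 2, 1, 0])


@dataclass
class PWM:
    """Position weight matrix with background and cached score machinery."""

    id: str
    probs: np.ndarray  # (4, w) column-stochastic
    background: np.ndarray  # (4,)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.probs.shape[0] != 4 or self.width < 4:
            raise ValueError(f"{self.id}: PWM must be 4 x w with w >= 4")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"{self.id}: PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_counts(
        cls, motif_id: str, counts: np.ndarray, background: np.ndarray | None = None
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError(f"{motif_id}: counts must be a 4 x w matrix")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError(f"{motif_id}: negative or non-finite counts")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        totals = counts.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError(f"{motif_id}: empty PWM column")
        probs = (counts + PSEUDOCOUNT * bg[:, None]) / (totals + PSEUDOCOUNT)
        return cls(motif_id, probs, bg)

    @property
    def log_odds(self) -> np.ndarray:
        """Per-column log2 odds against the background, shape (4, w)."""
        lo = self._cache.get("log_odds")
        if lo is None:
            lo = np.log2(self.probs / self.background[:, None])
            self._cache["log_odds"] = lo
        return lo

    def reverse_complement(self) -> "PWM":
        rc = self._cache.get("rc")
        if rc is None:
            rc = PWM(
                self.id, self.probs[_COMPLEMENT][:, ::-1].copy(),
                self.background.copy(),
            )
            self._cache["rc"] = rc
        return rc

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=0))

    def information_content(self) -> np.ndarray:
        """Per-column relative entropy vs the background, in bits."""
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(self.probs > 0, self.probs * self.log_odds, 0.0)
        return term.sum(axis=0)

    # -- exact discretised score distribution --------------------------------

    def _int_scores(self) -> np.ndarray:
        s = self._cache.get("int_scores")
        if s is None:
            s = np.rint(self.log_odds * SCALE).astype(np.int64)
            self._cache["int_scores"] = s
        return s

    def score_distribution(self) -> tuple[np.ndarray, int]:
        """(probability mass per integer-score bin, offset of bin 0).

        Exact distribution of the discretised log-odds score of a random
        background word, computed by convolving per-column distributions.
        """
        cached = self._cache.get("dist")
        if cached is not None:
            return cached
        ints = self._int_scores()
        # column-by-column convolution against each 4-point column distribution
        cur = np.array([1.0])
        lo = 0
        for j in range(self.width):
            col = ints[:, j]
            cl, ch = int(col.min()), int(col.max())
            new = np.zeros(cur.size + (ch - cl))
            for b in range(4):
                new[col[b] - cl : col[b] - cl + cur.size] += (
                    self.background[b] * cur
                )
            cur = new
            lo += cl
        self._cache["dist"] = (cur, lo)
        return cur, lo

    def tail_pvalues(self) -> tuple[np.ndarray, int]:
        """P(score >= bin) per integer-score bin, with the bin-0 offset."""
        cached = self._cache.get("tail")
        if cached is None:
            dist, lo = self.score_distribution()
            tail = np.cumsum(dist[::-1])[::-1]
            cached = (np.minimum(tail, 1.0), lo)
            self._cache["tail"] = cached
        return cached

    def pvalue_of_score(self, int_score: int) -> float:
        tail, lo = self.tail_pvalues()
        idx = int_score - lo
        if idx < 0:
            return 1.0
        if idx >= tail.size:
            return float(tail[-1])
        return float(tail[idx])


@dataclass
class MotifHit:
    sequence_id: str
    motif_id: str
    offset: int  # 0-based window start on the forward sequence
    strand: str
    score: float  # log2 odds, bits
    pvalue: float
    relative: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"p-value out of (0,1]: {self.pvalue}")
        if not (0.0 <= self.relative <= 1.0 + 1e-12):
            raise ValueError(f"relative score out of [0,1]: {self.relative}")


@dataclass
class AffinityComparison:
    motif_id: str
    element_id: str
    scores: dict[str, float]  # per-species best relative score
    excluded: list[str]
    classification: str  # human_gain | human_loss | conserved | unclassified


# ---------------------------------------------------------------------------
# Reading motif files
# ---------------------------------------------------------------------------

def read_pwm(path: str | Path, background: np.ndarray | None = None) -> list[PWM]:
    """Read motifs from JASPAR PFM (.pfm/.jaspar) or minimal MEME files."""
    path = Path(path)
    with open(path) as fh:
        head = fh.read(4096)
    fmt = "minimal" if "MEME version" in head else "jaspar"
    with open(path) as fh:
        if fmt == "minimal":
            records = bio_motifs.parse(fh, "minimal")
        else:
            records = bio_motifs.parse(fh, "jaspar")
        out = []
        for m in records:
            counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
            name = m.matrix_id if getattr(m, "matrix_id", None) else m.name
            out.append(PWM.from_counts(name or path.stem, counts, background))
    if not out:
        raise ValueError(f"{path}: no motifs found")
    return out


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_int_scores(codes: np.ndarray, ints: np.ndarray) -> np.ndarray:
    """Integer score of every window; windows containing N/gap get INT_MIN."""
    w = ints.shape[1]
    n_win = codes.size - w + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    safe = np.where(valid, codes, 0)
    idx = np.arange(n_win)[:, None] + np.arange(w)[None, :]
    scores = ints[safe[idx], np.arange(w)[None, :]].sum(axis=1)
    ok = valid[idx].all(axis=1)
    scores[~ok] = np.iinfo(np.int64).min
    return scores


def scan_sequence(
    seq: str,
    pwm: PWM,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    sequence_id: str = "seq",
) -> list[MotifHit]:
    """Scan both strands, returning hits with exact p <= threshold.

    Hits are sorted by position (then strand). Windows containing N are
    skipped; a sequence shorter than the motif yields no hits.
    """
    codes = _encode(seq)
    hits: list[MotifHit] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        ints = mat._int_scores()
        scores = _window_int_scores(codes, ints)
        if scores.size == 0:
            continue
        tail, lo = mat.tail_pvalues()
        for off in np.flatnonzero(scores > np.iinfo(np.int64).min):
            p = mat.pvalue_of_score(int(scores[off]))
            if p <= p_threshold:
                window = seq[off : off + pwm.width].upper()
                hits.append(
                    MotifHit(
                        sequence_id=sequence_id, motif_id=pwm.id, offset=int(off),
                        strand=strand, score=scores[off] / SCALE, pvalue=p,
                        relative=relative_score(window, mat),
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def relative_score(window: str, pwm: PWM) -> float:
    """JASPAR-style relative profile score of one w-mer, in [0, 1]."""
    codes = _encode(window)
    if codes.size != pwm.width or np.any(codes >= 4):
        raise ValueError("window must be exactly motif width over {A,C,G,T}")
    lo = pwm.log_odds
    score = float(lo[codes, np.arange(pwm.width)].sum())
    mn = float(lo.min(axis=0).sum())
    mx = float(lo.max(axis=0).sum())
    if mx - mn <= 0:
        warnings.warn(f"{pwm.id}: fully uniform PWM has zero score range")
        return 0.0
    return min(1.0, max(0.0, (score - mn) / (mx - mn)))


def best_relative_score(seq: str, pwm: PWM) -> float | None:
    """Best relative score over all clean w-windows of ``seq`` (None if none)."""
    codes = _encode(seq)
    ints = pwm._int_scores()
    scores = _window_int_scores(codes, ints)
    valid = scores > np.iinfo(np.int64).min
    if not valid.any():
        return None
    best_off = int(np.flatnonzero(valid)[np.argmax(scores[valid])])
    return relative_score(seq[best_off : best_off + pwm.width].upper(), pwm)


def compare_species_affinity(
    element_aln: OrthologAlignment,
    hit: MotifHit,
    pwm: PWM,
    threshold: float = DEFAULT_REL_THRESHOLD,
) -> AffinityComparison:
    """Classify a human motif hit as human-specific gain/loss or conserved.

    The human hit window is mapped through alignment columns to each species;
    each species is scored by its best relative score over the mapped window
    extended by one motif width of flank on each side (absorbing small indel
    slippage). Species whose mapped window is all-gap are excluded. The call
    requires at least 3 scored non-human species.
    """
    if "human" not in element_aln.species:
        raise KeyError(f"{element_aln.id}: human sequence required")
    w = pwm.width
    mat = pwm.reverse_complement() if hit.strand == "-" else pwm
    cols = element_aln.column_of_position("human")
    if hit.offset + w > cols.size:
        raise ValueError(f"{element_aln.id}: hit window outside the alignment")
    col_start, col_end = int(cols[hit.offset]), int(cols[hit.offset + w - 1]) + 1

    human_seq = element_aln.ungapped("human")[hit.offset : hit.offset + w]
    scores = {"human": relative_score(human_seq, mat)}
    excluded: list[str] = []
    for sp in element_aln.species:
        if sp == "human":
            continue
        seq = element_aln.sequences[sp]
        core = seq[col_start:col_end].replace("-", "")
        if not core:
            excluded.append(sp)
            continue
        left = seq[:col_start].replace("-", "")[-w:]
        right = seq[col_end:].replace("-", "")[:w]
        best = best_relative_score(left + core + right, mat)
        if best is None:
            excluded.append(sp)
        else:
            scores[sp] = best

    others = [v for k, v in scores.items() if k != "human"]
    human = scores["human"]
    if len(others) < MIN_SCORED_SPECIES:
        cls = "unclassified"
    elif human >= threshold and all(v >= threshold for v in others):
        cls = "conserved"
    elif human >= threshold and all(v < threshold for v in others):
        cls = "human_gain"
    elif human < threshold and all(v >= threshold for v in others):
        cls = "human_loss"
    else:
        cls = "unclassified"
    return AffinityComparison(
        motif_id=pwm.id, element_id=element_aln.id,
        scores=scores, excluded=excluded, classification=cls,
    )
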
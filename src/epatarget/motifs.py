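"""Position-weight-matrix scanning with exact p-values.

A PWM is scored as log2 odds against a background base composition.  The
null distribution of the score of a random background word is computed
exactly by dynamic programming: per-column score contributions are
discretized on an ``eps``-bit grid and convolved across columns, which gives
the full probability mass function of the score and hence exact tail
p-values — the same construction FIMO uses to turn its p-value threshold
into a score cutoff.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np

from .genome import GenomicInterval

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DEFAULT_PSEUDOCOUNT = 0.25
DEFAULT_EPS = 1e-3  # score grid, bits
DEFAULT_ALPHA = 1e-5  # FIMO-style match p-value threshold


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Background:
    """Background base probabilities (A, C, G, T)."""

    q: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        arr = np.asarray(self.q, dtype=float)
        if arr.shape != (4,) or not np.all(arr > 0) or abs(arr.sum() - 1) > 1e-9:
            raise ValueError("background must be 4 positive probabilities summing to 1")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.q, dtype=float)


@dataclass(frozen=True)
class PWM:
    """A probability matrix over ACGT with an associated TF name.

    ``probs`` has shape (w, 4); each row sums to 1 and is strictly positive
    (a pseudocount is applied when built from counts).
    """

    motif_id: str
    tf_name: str
    probs: tuple[tuple[float, ...], ...]
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        arr = self.matrix
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("PWM needs a (w, 4) matrix")
        if not np.all(arr > 0):
            raise ValueError("PWM probabilities must be strictly positive")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    @property
    def width(self) -> int:
        return len(self.probs)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @staticmethod
    def from_counts(
        motif_id: str,
        tf_name: str,
        counts: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if np.any(counts.sum(axis=1) <= 0):
            raise ValueError(f"motif {motif_id}: column with zero total count")
        probs = counts + pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        return PWM(motif_id, tf_name, tuple(map(tuple, probs)), pseudocount)

    @staticmethod
    def from_probs(
        motif_id: str, tf_name: str, probs: np.ndarray, floor: float = 1e-4
    ) -> "PWM":
        """Build from probability rows, flooring zeros and renormalizing."""
        probs = np.asarray(probs, dtype=float)
        probs = np.maximum(probs, floor)
        probs /= probs.sum(axis=1, keepdims=True)
        return PWM(motif_id, tf_name, tuple(map(tuple, probs)))


@dataclass(frozen=True)
class MotifMatch:
    """A scored, strand-aware PWM hit in forward genomic coordinates."""

    motif_id: str
    interval: GenomicInterval
    strand: str
    score: float
    pvalue: float

    def __post_init__(self) -> None:
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"p-value {self.pvalue} out of (0, 1]")


# ---------------------------------------------------------------------------
# motif file parsing

_MEME_MOTIF_RE = re.compile(r"^MOTIF\s+(\S+)(?:\s+(\S+))?")


def read_motifs(
    path: str | Path,
    format: str = "meme_minimal",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[PWM]:
    """Read PWMs from minimal MEME or TRANSFAC-style count matrices.

    MEME letter-probability rows are taken as probabilities (floored and
    renormalized); TRANSFAC counts get ``pseudocount`` per cell before
    normalization.  Motifs narrower than 4 columns are kept with a warning.
    """
    if format == "meme_minimal":
        motifs = _read_meme(Path(path))
    elif format == "transfac_counts":
        motifs = _read_transfac(Path(path), pseudocount)
    else:
        raise ValueError(f"unknown motif format {format!r}")
    for m in motifs:
        if m.width < 4:
            log.warning("motif %s has width %d (< 4); kept", m.motif_id, m.width)
    return motifs


def _read_meme(path: Path) -> list[PWM]:
    motifs: list[PWM] = []
    name = alt = None
    rows: list[list[float]] = []
    in_matrix = False

    def flush() -> None:
        nonlocal name, alt, rows, in_matrix
        if name is not None:
            if not rows:
                raise ValueError(f"{path}: motif {name} has no probability matrix")
            motifs.append(PWM.from_probs(name, alt or name, np.array(rows)))
        name = alt = None
        rows = []
        in_matrix = False

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            m = _MEME_MOTIF_RE.match(line)
            if m:
                flush()
                name, alt = m.group(1), m.group(2)
                continue
            if line.startswith("ALPHABET"):
                alphabet = line.split("=", 1)[-1].strip()
                if alphabet.upper() != "ACGT":
                    raise ValueError(f"{path}:{lineno}: unsupported alphabet {alphabet!r}")
                continue
            if line.startswith("letter-probability"):
                in_matrix = True
                continue
            if in_matrix and line:
                try:
                    vals = [float(x) for x in line.split()]
                except ValueError:
                    in_matrix = False
                    continue
                if len(vals) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 probabilities")
                rows.append(vals)
            elif in_matrix and not line:
                in_matrix = False
    flush()
    return motifs


def _read_transfac(path: Path, pseudocount: float) -> list[PWM]:
    motifs: list[PWM] = []
    motif_id = tf_name = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal motif_id, tf_name, rows
        if motif_id is not None and rows:
            motifs.append(
                PWM.from_counts(motif_id, tf_name or motif_id, np.array(rows), pseudocount)
            )
        motif_id = tf_name = None
        rows = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            tag = line[:2]
            body = line[2:].strip()
            if tag == "AC":
                flush()
                motif_id = body
            elif tag == "ID":
                if motif_id is None:
                    motif_id = body
            elif tag == "NA":
                tf_name = body
            elif tag in ("P0", "PO"):
                if [h.upper() for h in body.split()[:4]] != list(BASES):
                    raise ValueError(f"{path}:{lineno}: P0 columns must be A C G T")
            elif tag == "//":
                flush()
            elif tag.strip().isdigit():
                parts = line.split()
                if len(parts) < 5:
                    raise ValueError(f"{path}:{lineno}: malformed count row")
                try:
                    vals = [float(x) for x in parts[1:5]]
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: malformed count row") from None
                rows.append(vals)
    flush()
    return motifs


def write_meme(motifs: Sequence[PWM], path: str | Path, bg: Background | None = None) -> None:
    """Write motifs in minimal MEME format."""
    bg = bg or Background()
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            + " ".join(f"{b} {q:.5f}" for b, q in zip(BASES, bg.q))
            + "\n\n"
        )
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id} {m.tf_name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width}\n")
            for row in m.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# scoring


def log_odds_score(pwm: PWM, bg: Background, word: str) -> float:
    """Sum over positions of log2(p(base, i) / q(base)); None-like bases fail."""
    if len(word) != pwm.width:
        raise ValueError(f"word length {len(word)} != motif width {pwm.width}")
    mat = pwm.matrix
    q = bg.array
    score = 0.0
    for i, base in enumerate(word.upper()):
        j = _BASE_INDEX.get(base)
        if j is None:
            raise KeyError(f"non-ACGT base {base!r} at position {i}")
        score += float(np.log2(mat[i, j] / q[j]))
    return score


@dataclass
class ScoreDistribution:
    """Exact pmf of the log-odds score of a background word, on an eps grid.

    ``pmf[k]`` is the probability that the discretized score equals
    ``(offset + k) * eps``.
    """

    eps: float
    offset: int
    pmf: np.ndarray
    _sf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if abs(self.pmf.sum() - 1.0) > 1e-9:
            raise ValueError("pmf must sum to 1")
        # survival function: P(S >= score of bin k)
        self._sf = self.pmf[::-1].cumsum()[::-1]

    @property
    def min_score(self) -> float:
        return self.offset * self.eps

    @property
    def max_score(self) -> float:
        return (self.offset + len(self.pmf) - 1) * self.eps

    def tail(self, score: float) -> float:
        """P(S >= score) under the background, on the discretized grid."""
        k = int(round(score / self.eps)) - self.offset
        if k <= 0:
            return 1.0
        if k >= len(self.pmf):
            return 0.0
        return float(self._sf[k])

    def pvalue(self, score: float) -> float:
        """Like :meth:`tail` but floored so a p-value is never exactly 0."""
        return max(self.tail(score), float(self.pmf[self.pmf > 0].min()) * 1e-3)


def score_distribution(
    pwm: PWM, bg: Background, eps: float = DEFAULT_EPS
) -> ScoreDistribution:
    """Exact null score distribution by column-wise convolution on an eps grid."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    q = bg.array
    # integer score contributions per (column, base)
    contrib = np.rint(np.log2(pwm.matrix / q) / eps).astype(np.int64)
    pmf = np.array([1.0])
    offset = 0
    for i in range(pwm.width):
        col = contrib[i]
        lo, hi = int(col.min()), int(col.max())
        new = np.zeros(len(pmf) + hi - lo)
        for j in range(4):
            shift = int(col[j]) - lo
            new[shift : shift + len(pmf)] += q[j] * pmf
        pmf = new
        offset += lo
    pmf /= pmf.sum()  # guard drift
    return ScoreDistribution(eps=eps, offset=offset, pmf=pmf)


def pvalue_threshold_score(dist: ScoreDistribution, alpha: float = DEFAULT_ALPHA) -> float:
    """Smallest grid score s* with P(S >= s*) <= alpha.

    If even the single top score carries more mass than ``alpha`` no word can
    pass; the returned score is max_score + eps and a warning is logged.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    sf = dist._sf
    idx = np.searchsorted(-sf, -alpha, side="left")  # sf is non-increasing
    while idx < len(sf) and sf[idx] > alpha:
        idx += 1
    if idx >= len(sf):
        log.warning("alpha=%g unreachable (min tail mass %g)", alpha, sf[-1])
        return dist.max_score + dist.eps
    return (dist.offset + int(idx)) * dist.eps


class SequenceProvider(Protocol):
    """Anything that returns the forward-strand sequence of an interval."""

    def fetch(self, chrom: str, start: int, end: int) -> str: ...


class DictSequenceProvider:
    """Sequences held in memory as chrom -> string (synthetic runs)."""

    def __init__(self, sequences: Mapping[str, str]) -> None:
        self.sequences = dict(sequences)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


class FastaSequenceProvider:
    """FASTA-backed sequences via pyfaidx."""

    def __init__(self, path: str | Path) -> None:
        from pyfaidx import Fasta

        self.fasta = Fasta(str(path), sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self.fasta[chrom][start:end])


def scan_windows(
    windows: Iterable[GenomicInterval],
    sequences: SequenceProvider,
    pwm: PWM,
    bg: Background | None = None,
    alpha: float = DEFAULT_ALPHA,
    strands: str = "both",
    dist: ScoreDistribution | None = None,
) -> list[MotifMatch]:
    """FIMO-style scan: report every position/strand with p-value <= alpha.

    Minus-strand words are scored on the reverse complement; the reported
    footprint is always in forward coordinates.  Positions containing
    non-ACGT characters are skipped.
    """
    bg = bg or Background()
    if dist is None:
        dist = score_distribution(pwm, bg)
    threshold = pvalue_threshold_score(dist, alpha)
    w = pwm.width
    log_mat = {
        "+": np.log2(pwm.matrix / bg.array),
        "-": np.log2(pwm.matrix / bg.array)[::-1, ::-1],  # revcomp scoring matrix
    }
    wanted = ("+", "-") if strands == "both" else (strands,)
    matches: list[MotifMatch] = []
    for window in windows:
        if len(window) < w:
            continue
        seq = sequences.fetch(window.chrom, window.start, window.end).upper()
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        idx = np.full(len(codes), -1, dtype=np.int8)
        for b, j in _BASE_INDEX.items():
            idx[codes == ord(b)] = j
        if np.any(idx < 0):
            log.debug("window %s has non-ACGT positions; skipped there", window)
        sub = np.lib.stride_tricks.sliding_window_view(idx, w)
        valid = np.all(sub >= 0, axis=1)
        cols = np.arange(w)
        for strand in wanted:
            mat = log_mat[strand]
            scores = np.where(valid, mat[cols, np.where(sub >= 0, sub, 0)].sum(axis=1), -np.inf)
            for off in np.nonzero(scores >= threshold)[0]:
                score = float(scores[off])
                matches.append(
                    MotifMatch(
                        motif_id=pwm.motif_id,
                        interval=GenomicInterval(
                            window.chrom, window.start + int(off), window.start + int(off) + w
                        ),
                        strand=strand,
                        score=score,
                        pvalue=dist.pvalue(score),
                    )
                )
    return matches


# ---------------------------------------------------------------------------
# motif name -> TF gene symbol


def _normalize_name(name: str) -> str:
    return re.sub(r"[^0-9a-z]", "", name.lower())


def map_motif_to_tf(tf_name: str, alias_table: Mapping[str, Iterable[str]]) -> str | None:
    """Map a motif's TF name to an approved gene symbol.

    Matching is case-insensitive after stripping non-alphanumerics; an exact
    symbol match wins over an alias match.  Returns None when unmapped.
    """
    key = _normalize_name(tf_name)
    for symbol in alias_table:
        if _normalize_name(symbol) == key:
            return symbol
    for symbol, aliases in alias_table.items():
        if any(_normalize_name(a) == key for a in aliases):
            return symbol
    log.info("motif TF name %r not mapped to a gene symbol", tf_name)
    return None


# ---------------------------------------------------------------------------
# match TSV I/O (FIMO-like tabular fields)

MATCH_COLUMNS = ["motif_id", "chrom", "start", "end", "strand", "score", "pvalue"]


def write_matches(matches: Iterable[MotifMatch], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MATCH_COLUMNS) + "\n")
        for m in matches:
            fh.write(
                f"{m.motif_id}\t{m.interval.chrom}\t{m.interval.start}\t"
                f"{m.interval.end}\t{m.strand}\t{m.score:.4f}\t{m.pvalue:.4g}\n"
            )


def read_matches(path: str | Path) -> list[MotifMatch]:
    matches: list[MotifMatch] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != MATCH_COLUMNS:
            raise ValueError(f"{path}: unexpected match TSV header")
        for line in fh:
            mid, chrom, s, e, strand, score, p = line.rstrip("\n").split("\t")
            matches.append(
                MotifMatch(
                    mid,
                    GenomicInterval(chrom, int(s), int(e)),
                    strand,
                    float(score),
                    float(p),
                )
            )
    return matches
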
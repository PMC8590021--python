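"""PWM genome scanning with exact log-odds p-values.

Implements the FIMO-style scan the training pipeline depends on: a MEME
minimal-format motif is scored as a position weight matrix (log-odds in
bits against the background), an exact null distribution of scores under
the background model is computed by dynamic programming on a discretized
score grid, and the genome is scanned on both strands at a p-value
threshold (default 5e-4).  When the plus- and minus-strand hit occupy the
same interval (palindromes) only the better-scoring orientation is kept,
so palindromic matches are counted once per locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import motifs as bio_motifs

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Default discretization granularity of the score grid, in bits.
DEFAULT_GRANULARITY = 1e-3

#: FIMO-style pseudocount added per matrix cell before renormalization.
DEFAULT_PSEUDOCOUNT = 0.1


@dataclass
class PositionWeightMatrix:
    """Per-position base probabilities plus background, scored in bits.

    ``probs`` is m x 4 in A,C,G,T order; rows sum to 1 after pseudocount
    regularization.
    """

    probs: np.ndarray
    background: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    name: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or len(self.probs) < 1:
            raise ValueError("probs must be an m x 4 matrix with m >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1 after regularization")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """m x 4 log2(p / background) matrix (-inf for zero probabilities)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
            name=self.name,
        )


def _regularize(raw: np.ndarray, pseudocount: float) -> np.ndarray:
    reg = raw + pseudocount
    return reg / reg.sum(axis=1, keepdims=True)


def read_meme_motif(
    path: str | Path,
    index: int = 1,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PositionWeightMatrix:
    """Read the ``index``-th motif (1-based, MEME's --motif numbering) from a
    MEME minimal-format file.

    The file's stated background letter frequencies are used; uniform if
    absent.  Rows that do not sum to 1 within 1e-2 before regularization are
    rejected as malformed.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            record = bio_motifs.parse(fh, "minimal")
        except Exception as exc:  # biopython raises bare ValueError subclasses
            raise ValueError(f"malformed MEME minimal file {path}: {exc}") from exc
    if index < 1 or index > len(record):
        raise IndexError(
            f"motif index {index} out of range; file has {len(record)} motifs"
        )
    motif = record[index - 1]
    raw = _raw_probability_rows(path, index)
    if raw.shape != (motif.length, 4):
        raise ValueError(f"matrix block {index} malformed in {path}")
    sums = raw.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-2):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(
            f"matrix row {bad} sums to {sums[bad]:.4f}, not a probability row"
        )
    raw = raw / sums[:, None]
    bg = motif.background or {}
    background = np.array([bg.get(b, 0.25) for b in BASES], dtype=float)
    background = background / background.sum()
    return PositionWeightMatrix(
        probs=_regularize(raw, pseudocount),
        background=background,
        pseudocount=pseudocount,
        name=motif.name or f"motif_{index}",
    )


def _raw_probability_rows(path: Path, index: int) -> np.ndarray:
    """The index-th letter-probability block as printed (biopython
    round-trips through counts, which hides malformed rows)."""
    blocks: list[list[list[float]]] = []
    current: list[list[float]] | None = None
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("letter-probability matrix"):
                current = []
                blocks.append(current)
                continue
            if current is not None:
                parts = stripped.split()
                if len(parts) == 4:
                    try:
                        current.append([float(x) for x in parts])
                        continue
                    except ValueError:
                        pass
                current = None
    if index > len(blocks):
        raise ValueError(f"no letter-probability block {index} in {path}")
    return np.array(blocks[index - 1])


def write_meme_motif(path: str | Path, pwm: PositionWeightMatrix) -> None:
    """Write a PWM as a MEME minimal-format file (probabilities as given)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {p:.6f}" for b, p in zip(BASES, pwm.background)) + "\n\n"
        )
        fh.write(f"MOTIF {pwm.name or 'motif_1'}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.length} "
            f"nsites= 1000000 E= 0\n"
        )
        for row in pwm.probs:
            fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")


def log_odds_score(pwm: PositionWeightMatrix, kmer: str) -> float:
    """Sum over positions of log2(p_i(base) / background(base)), in bits."""
    kmer = kmer.upper()
    if len(kmer) != pwm.length:
        raise ValueError(f"kmer length {len(kmer)} != motif length {pwm.length}")
    lo = pwm.log_odds
    total = 0.0
    for i, c in enumerate(kmer):
        if c not in _BASE_INDEX:
            raise ValueError(f"ambiguity code {c!r} in kmer")
        total += lo[i, _BASE_INDEX[c]]
    return float(total)


class _ScoreDistribution:
    """Exact null distribution of the quantized log-odds score.

    Per-position scores are rounded to an integer grid of ``granularity``
    bits; the distribution of their sum under i.i.d. background-distributed
    bases is built by dynamic-programming convolution.  P-values computed
    here are exact for the quantized score, i.e. within one grid step of the
    continuous value.
    """

    #: Per-cell log-odds floor (bits); zero-probability cells would give
    #: -inf and an unbounded grid.  -30 bits is far below any threshold.
    SCORE_FLOOR = -30.0

    def __init__(self, pwm: PositionWeightMatrix, granularity: float) -> None:
        self.granularity = granularity
        lo = np.maximum(pwm.log_odds, self.SCORE_FLOOR)
        self.q = np.rint(lo / granularity).astype(np.int64)  # m x 4
        offset = self.q.min(axis=1)  # per-position minimum
        spans = self.q.max(axis=1) - offset
        dist = np.zeros(int(spans.sum()) + 1)
        dist[0] = 1.0
        n = 1
        for i in range(pwm.length):
            new = np.zeros(n + int(spans[i]))
            for b in range(4):
                k = int(self.q[i, b] - offset[i])
                new[k : k + n] += pwm.background[b] * dist[:n]
            dist, n = new, len(new)
        self.min_score = int(offset.sum())
        # survival[j] = P(quantized score >= min_score + j)
        self.survival = np.minimum(dist[::-1].cumsum()[::-1], 1.0)

    def quantize(self, score: float) -> int:
        return int(np.rint(score / self.granularity))

    def pvalue_quantized(self, qscore: int) -> float:
        j = qscore - self.min_score
        if j <= 0:
            return 1.0
        if j >= len(self.survival):
            return 0.0
        return float(self.survival[j])

    def pvalue(self, score: float) -> float:
        return self.pvalue_quantized(self.quantize(score))

    def threshold_qscore(self, pthresh: float) -> int | None:
        """Smallest quantized score with p-value <= pthresh, or None."""
        idx = np.nonzero(self.survival <= pthresh)[0]
        if len(idx) == 0:
            return None
        return self.min_score + int(idx[0])


def score_pvalue(
    pwm: PositionWeightMatrix,
    score: float,
    granularity: float = DEFAULT_GRANULARITY,
) -> float:
    """P(log-odds of a random background m-mer >= score), exact DP.

    The minimum attainable score (and anything below) has p-value 1.
    """
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    return _ScoreDistribution(pwm, granularity).pvalue(score)


@dataclass(frozen=True)
class MotifHit:
    """One genomic motif occurrence; coordinates 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str
    score: float  # log-odds, bits
    pvalue: float
    matched_seq: str  # plus-orientation of the motif


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def scan_genome(
    genome: Mapping[str, str],
    pwm: PositionWeightMatrix,
    pthresh: float = 5e-4,
    max_per_locus: int = 1,
    granularity: float = DEFAULT_GRANULARITY,
) -> list[MotifHit]:
    """Report all motif occurrences on both strands with p-value <= pthresh.

    With ``max_per_locus=1`` (the --max-strand 1 semantics) a plus- and
    minus-strand hit occupying the same interval are collapsed to the
    better-scoring one, ties going to the plus strand.  Hits are sorted by
    (contig, start).  Windows containing non-ACGT characters are skipped.
    """
    m = pwm.length
    dist = _ScoreDistribution(pwm, granularity)
    qthresh = dist.threshold_qscore(pthresh)
    hits: list[MotifHit] = []
    if qthresh is None:
        return hits
    q_plus = dist.q  # m x 4 quantized log-odds
    q_minus = q_plus[::-1, ::-1]  # revcomp orientation scored on plus bases
    for contig in sorted(genome):
        seq = genome[contig].upper()
        enc = _encode(seq)
        n_win = len(seq) - m + 1
        if n_win <= 0:
            continue
        valid = np.ones(n_win, dtype=bool)
        s_plus = np.zeros(n_win, dtype=np.int64)
        s_minus = np.zeros(n_win, dtype=np.int64)
        for j in range(m):
            col = enc[j : j + n_win]
            ok = col >= 0
            valid &= ok
            safe = np.where(ok, col, 0)
            s_plus += q_plus[j, safe]
            s_minus += q_minus[j, safe]
        for start in np.nonzero(valid & ((s_plus >= qthresh) | (s_minus >= qthresh)))[0]:
            start = int(start)
            window = seq[start : start + m]
            cand = []
            if s_plus[start] >= qthresh:
                cand.append(("+", int(s_plus[start]), window))
            if s_minus[start] >= qthresh:
                cand.append(("-", int(s_minus[start]), reverse_complement_seq(window)))
            if max_per_locus == 1 and len(cand) == 2:
                # better score wins; tie -> plus strand (cand[0])
                cand = [max(cand, key=lambda c: (c[1], c[0] == "+"))]
            for strand, qscore, mseq in cand:
                hits.append(
                    MotifHit(
                        contig=contig,
                        start=start,
                        end=start + m,
                        strand=strand,
                        score=qscore * granularity,
                        pvalue=dist.pvalue_quantized(qscore),
                        matched_seq=mseq,
                    )
                )
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def reverse_complement_seq(seq: str) -> str:
    from .shape import reverse_complement

    return reverse_complement(seq)


def hits_to_table(hits: Sequence[MotifHit]):
    """Hits as a DataFrame with FIMO-like column names."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sequence_name": [h.contig for h in hits],
            "start": [h.start for h in hits],
            "stop": [h.end for h in hits],
            "strand": [h.strand for h in hits],
            "score": [h.score for h in hits],
            "p-value": [h.pvalue for h in hits],
            "matched_sequence": [h.matched_seq for h in hits],
        }
    )


def write_hits_bed(path: str | Path, hits: Sequence[MotifHit]) -> None:
    """BED6 + score/p-value columns."""
    with open(path, "w") as fh:
        for i, h in enumerate(hits):
            fh.write(
                f"{h.contig}\t{h.start}\t{h.end}\thit{i}\t0\t{h.strand}"
                f"\t{h.score:.4f}\t{h.pvalue:.3e}\n"
            )
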
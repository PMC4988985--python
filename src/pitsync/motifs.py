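"""Position-weight-matrix scanning of promoter windows.

A PWM over A/C/G/T (counts or frequencies) is converted to log-odds weights
against a background model, with a pseudocount split by background
frequency. Match quality is reported as the min-max–normalized percentage

    100 × (S − S_min) / (S_max − S_min)

where S is the summed log2-odds of the site and S_min/S_max the sums of the
per-position minima/maxima — so the consensus scores 100% and the
per-position-worst sequence 0%. A promoter window of fixed length upstream
of the transcription start site (TSS) is scanned on both strands; hit
positions are reported 1-based in bp upstream of the TSS, measured to the
hit edge nearest the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

__all__ = [
    "PWM",
    "PromoterSequence",
    "MotifHit",
    "relative_score",
    "scan_promoter",
    "read_pwm",
    "read_promoter_fasta",
    "reverse_complement",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position weight matrix over A, C, G, T.

    `matrix` is 4 × L (rows in A, C, G, T order) of non-negative counts or
    frequencies. The log-odds weights use a total pseudocount distributed by
    the background, default uniform 0.25 per base.
    """

    name: str
    matrix: np.ndarray
    pseudocount: float = 0.8
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 × L (rows A, C, G, T)")
        if self.matrix.shape[1] < 1:
            raise ValueError("PWM must have at least one position")
        if np.any(self.matrix < 0):
            raise ValueError("PWM entries must be non-negative")
        if np.any(self.matrix.sum(axis=0) <= 0):
            raise ValueError("every PWM position needs positive total weight")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """4 × L log2 odds: log2(f'/bg), pseudocount split by background."""
        totals = self.matrix.sum(axis=0, keepdims=True)
        freqs = (self.matrix + self.pseudocount * self.background[:, None]) / (
            totals + self.pseudocount
        )
        return np.log2(freqs / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.log_odds, axis=0))

    def score_range(self) -> tuple[float, float]:
        lo = self.log_odds
        return float(lo.min(axis=0).sum()), float(lo.max(axis=0).sum())


@dataclass
class PromoterSequence:
    """A promoter region with a known TSS position.

    `tss_index` is the 0-based index of the TSS within `sequence`; the scan
    covers the `window_length` bases immediately upstream of it
    (``sequence[tss_index − window_length : tss_index]``).
    """

    sequence: str
    tss_index: int
    window_length: int = 5000
    name: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"sequence contains non-IUPAC-DNA characters: {bad}")
        if not (0 <= self.tss_index <= len(self.sequence)):
            raise ValueError("tss_index must lie within the sequence")

    def upstream_window(self) -> str:
        if self.tss_index < self.window_length:
            raise ValueError(
                f"only {self.tss_index} bp available upstream of the TSS; "
                f"window_length={self.window_length}"
            )
        return self.sequence[self.tss_index - self.window_length : self.tss_index]


@dataclass(frozen=True)
class MotifHit:
    """One PWM match in the upstream window.

    `bp_upstream` is 1-based distance from the TSS to the hit's TSS-proximal
    edge (the base immediately upstream of the TSS is 1). For − strand hits
    `sequence` is given in motif orientation (reverse complement of the +
    strand site).
    """

    motif: str
    strand: str  # "+" or "-"
    bp_upstream: int
    relative_score: float  # percent of maximum, 0–100
    sequence: str


def relative_score(pwm: PWM, subsequence: str) -> float:
    """Min-max–normalized log-odds score of a site, as a percentage."""
    sub = subsequence.upper()
    if len(sub) != len(pwm):
        raise ValueError(
            f"subsequence length {len(sub)} != PWM length {len(pwm)}"
        )
    if "N" in sub:
        raise ValueError("subsequence contains N; site cannot be scored")
    lo = pwm.log_odds
    s = float(sum(lo[_BASE_INDEX[b], i] for i, b in enumerate(sub)))
    smin, smax = pwm.score_range()
    if smax == smin:
        return 100.0
    return 100.0 * (s - smin) / (smax - smin)


def scan_promoter(
    pwm: PWM,
    promoter: PromoterSequence,
    min_score: float = 75.0,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All sites in the upstream window with relative score ≥ min_score.

    Sites containing N are skipped. Overlapping hits are all reported,
    sorted by bp_upstream (TSS-proximal first).
    """
    window = promoter.upstream_window()
    w = len(window)
    L = len(pwm)
    if w < L:
        return []
    hits: list[MotifHit] = []
    for start in range(w - L + 1):
        sub = window[start : start + L]
        if "N" in sub:
            continue
        # TSS-proximal edge of the site is its last base (0-based start+L−1)
        bp_upstream = w - (start + L - 1)
        fwd = relative_score(pwm, sub)
        if fwd >= min_score:
            hits.append(MotifHit(pwm.name, "+", bp_upstream, fwd, sub))
        if both_strands:
            rc = reverse_complement(sub)
            rev = relative_score(pwm, rc)
            if rev >= min_score:
                hits.append(MotifHit(pwm.name, "-", bp_upstream, rev, rc))
    hits.sort(key=lambda h: (h.bp_upstream, h.strand))
    return hits


# ---------------------------------------------------------------------------
# file input
# ---------------------------------------------------------------------------


def read_pwm(source: Union[str, Path, TextIO], pseudocount: float = 0.8) -> list[PWM]:
    """Read one or more JASPAR-format matrices into PWM objects."""
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            records = bio_motifs.parse(handle, "jaspar")
            parsed = list(records)
    else:
        parsed = list(bio_motifs.parse(source, "jaspar"))
    out = []
    for m in parsed:
        mat = np.array([list(m.counts[b]) for b in _BASES], dtype=float)
        name = m.name or m.matrix_id or "pwm"
        out.append(PWM(name=str(name), matrix=mat, pseudocount=pseudocount))
    return out


def read_promoter_fasta(
    path: Union[str, Path],
    tss_index: Optional[int] = None,
    window_length: int = 5000,
) -> PromoterSequence:
    """Read the first FASTA record as a promoter sequence.

    Lowercase bases are uppercased and line wrapping removed. By default the
    TSS is taken to sit at the 3' end of the record (the whole record is
    upstream sequence).
    """
    record = next(SeqIO.parse(str(path), "fasta"))
    seq = str(record.seq).upper()
    if tss_index is None:
        tss_index = len(seq)
    return PromoterSequence(
        sequence=seq, tss_index=tss_index, window_length=window_length, name=record.id
    )
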
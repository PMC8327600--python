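"""Over-representation statistics and promoter motif scanning.

Gene-set enrichment uses the hypergeometric model (Fisher's exact test for
the one-sided tails); motif enrichment scans promoter sequences with a
log-odds position weight matrix on both strands and tests hit counts against
a background rate with an upper-tail binomial test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
BASES = "ACGT"


@dataclass
class ContingencyCounts:
    """k hits in a set of size K, against n hits in a universe of size N."""

    k: int
    K: int
    n: int
    N: int

    def validate(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError("impossible counts: k outside [0, min(K, n)]")
        if self.K > self.N or self.n > self.N:
            raise ValueError("set or hit count exceeds universe size")
        if self.k < self.K - (self.N - self.n):
            raise ValueError("impossible counts: too few hits available")


def fisher_enrichment(cc: ContingencyCounts, alternative: str = "greater"
                      ) -> tuple[float, float]:
    """Odds ratio and Fisher exact p for a 2x2 gene-set table.

    The odds ratio is the sample OR k*(N-K-n+k) / ((K-k)*(n-k)), with 0.5
    added to every cell only when a denominator cell is zero.  The p-value is
    the exact hypergeometric tail for the requested alternative.
    """
    cc.validate()
    k, K, n, N = cc.k, cc.K, cc.n, cc.N
    a, b, c, d = k, K - k, n - k, N - K - n + k
    if b == 0 or c == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    hg = stats.hypergeom(N, n, K)
    if alternative == "greater":
        p = float(hg.sf(k - 1))
    elif alternative == "less":
        p = float(hg.cdf(k))
    elif alternative == "two-sided":
        table = [[k, K - k], [n - k, N - K - n + k]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(odds), min(p, 1.0)


def hypergeom_enrichment(cc: ContingencyCounts) -> float:
    """Upper-tail P(X >= k) with X ~ Hypergeom(N, n, K)."""
    cc.validate()
    return float(min(stats.hypergeom(cc.N, cc.n, cc.K).sf(cc.k - 1), 1.0))


def promoter_regions(gene_annot: pd.DataFrame, upstream: int = 2000,
                     downstream: int = 1000) -> pd.DataFrame:
    """Strand-aware promoter intervals around each TSS (BED conventions).

    Plus strand: [tss - upstream, tss + downstream); minus strand:
    [tss - downstream, tss + upstream).  Starts are clipped at 0.  Expects
    columns chrom, strand, tss; returns chrom, start, end, gene, strand
    (0-based half-open).
    """
    rows = []
    for gene, row in gene_annot.iterrows():
        strand = row.get("strand")
        if strand not in ("+", "-"):
            raise ValueError(f"missing or invalid strand for {gene}")
        tss = int(row["tss"])
        if strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream, tss + upstream
        rows.append((row["chrom"], max(start, 0), end, gene, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene",
                                       "strand"])


@dataclass
class Pwm:
    """Position weight matrix over A, C, G, T with a pseudocount policy."""

    probs: np.ndarray  # 4 x width, column-stochastic
    name: str = "motif"
    pseudocount: float = 0.01

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[0] != 4 or p.shape[1] == 0:
            raise ValueError("PWM must be a non-empty 4 x width matrix")
        p = p + self.pseudocount
        self.probs = p / p.sum(axis=0, keepdims=True)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_counts(cls, counts: np.ndarray, name: str = "motif",
                    pseudocount: float = 0.01) -> "Pwm":
        c = np.asarray(counts, dtype=float)
        return cls(probs=c / c.sum(axis=0, keepdims=True), name=name,
                   pseudocount=pseudocount)

    @classmethod
    def from_jaspar(cls, path: str, pseudocount: float = 0.01) -> "Pwm":
        """Read the first motif of a JASPAR PFM file (via Bio.motifs)."""
        from Bio import motifs
        with open(path) as fh:
            m = motifs.read(fh, "jaspar")
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        return cls.from_counts(counts, name=m.name or "motif",
                               pseudocount=pseudocount)

    @classmethod
    def from_meme(cls, path: str, pseudocount: float = 0.01) -> "Pwm":
        """Read the first motif of a MEME minimal-format file."""
        from Bio import motifs
        with open(path) as fh:
            record = motifs.parse(fh, "minimal")
        m = record[0]
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        return cls.from_counts(counts, name=m.name or "motif",
                               pseudocount=pseudocount)

    def log_odds(self, bg_freqs: np.ndarray | None = None) -> np.ndarray:
        bg = np.full(4, 0.25) if bg_freqs is None else \
            np.asarray(bg_freqs, dtype=float)
        return np.log2(self.probs / bg[:, None])


_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i


def _scan_one(seq: str, lods: np.ndarray, threshold: float,
              n_score: float) -> list[tuple[int, float]]:
    width = lods.shape[1]
    if len(seq) < width:
        return []
    code = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    lods_ext = np.vstack([lods, np.full(width, n_score)])  # row 4 = unknown
    per_pos = lods_ext[code]  # (len, width)
    n_win = len(seq) - width + 1
    scores = np.zeros(n_win)
    for off in range(width):
        scores += per_pos[off:off + n_win, off]
    hits = np.flatnonzero(scores >= threshold)
    return [(int(i), float(scores[i])) for i in hits]


def scan_pwm(seqs: Iterable[tuple[str, str]] | dict[str, str], pwm: Pwm,
             bg_freqs: np.ndarray | None = None, score_frac: float = 0.8
             ) -> pd.DataFrame:
    """Scan sequences for PWM hits on both strands.

    A window is a hit when its log-odds score reaches ``score_frac`` times
    the maximum attainable score.  Unknown bases (N) contribute
    log2(pseudocount).  Accepts an iterable of (id, sequence) pairs or a
    mapping; returns one row per hit (seq_id, position, strand, score) plus
    rows with position -1 for hitless sequences so every input appears.
    """
    items = seqs.items() if isinstance(seqs, dict) else list(seqs)
    lods = pwm.log_odds(bg_freqs)
    max_score = float(lods.max(axis=0).sum())
    threshold = score_frac * max_score
    n_score = math.log2(pwm.pseudocount)
    rows = []
    for sid, seq in items:
        s = str(seq).upper()
        found = _scan_one(s, lods, threshold, n_score)
        rc = s.translate(COMPLEMENT)[::-1]
        found_rc = _scan_one(rc, lods, threshold, n_score)
        for pos, score in found:
            rows.append((sid, pos, "+", score))
        for pos, score in found_rc:
            rows.append((sid, len(s) - pos - pwm.width, "-", score))
        if not found and not found_rc:
            rows.append((sid, -1, ".", np.nan))
    out = pd.DataFrame(rows, columns=["seq_id", "position", "strand", "score"])
    out.attrs["threshold"] = threshold
    out.attrs["max_score"] = max_score
    return out


def hit_counts(scan: pd.DataFrame) -> pd.Series:
    """Per-sequence hit counts from a scan_pwm table (zero rows count 0)."""
    real = scan[scan["position"] >= 0]
    counts = real.groupby("seq_id").size()
    return counts.reindex(scan["seq_id"].unique(), fill_value=0)


def motif_enrichment_binomial(n_hit_targets: int, n_targets: int,
                              bg_hit_rate: float) -> float:
    """Upper-tail binomial P(X >= n_hit_targets), X ~ Bin(n_targets, rate)."""
    if not (0 < bg_hit_rate < 1):
        if bg_hit_rate == 0:
            return 0.0 if n_hit_targets > 0 else 1.0
        if bg_hit_rate == 1:
            return 1.0
        raise ValueError("bg_hit_rate must be in [0, 1]")
    if not (0 <= n_hit_targets <= n_targets):
        raise ValueError("hit count outside [0, n_targets]")
    return float(min(stats.binom(n_targets, bg_hit_rate).sf(n_hit_targets - 1),
                     1.0))


def bh_fdr(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
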
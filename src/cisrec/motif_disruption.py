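"""Transcription-factor binding-site gain/loss calling from PWM p-values.

A somatic substitution is scored against a position weight matrix (PWM) on
the reference and alternate alleles.  Each allele receives the best log-odds
hit over all window offsets covering the variant and over both strands; the
hit score is converted to the p-value of observing a score at least as high
in a single random motif-length window drawn from the background model.  A
variant gains a site when the alternate allele crosses below the p-value
cutoff while the reference stays above it, and loses a site in the mirror
case (default cutoff 1e-5).

The score null distribution is computed by dynamic programming over the
positions of the motif.  For short motifs the DP is carried out over the
exact set of attainable scores, so tail probabilities agree with exhaustive
enumeration over all 4^k words to floating-point precision; for long motifs
the score support is quantized and the tail lookup allows slack of one
quantum per position, preserving monotonicity and never undercounting the
tail at a queried attainable score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4,
              "a": 0, "c": 1, "g": 2, "t": 3, "n": 4}
N_CODE = 4

#: maximum number of distinct DP states kept before quantizing the score support
_EXACT_STATE_CAP = 1 << 19
#: number of quanta spanning the score range in the quantized fallback
_LATTICE_BINS = 1 << 21

DEFAULT_PSEUDOCOUNT = 1e-4
DEFAULT_CUTOFF = 1e-5


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string over {A,C,G,T,N} (case-insensitive) as uint8 codes."""
    try:
        return np.frombuffer(
            bytes(_BASE_CODE[c] for c in seq), dtype=np.uint8
        ).copy()
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from None


def decode_sequence(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


class PWM:
    """Position weight matrix with background model and pseudocount.

    Parameters
    ----------
    motif_id : str
        Identifier for the motif.
    matrix : array-like, shape (k, 4)
        Per-position base probabilities in A, C, G, T order.  Rows are
        renormalized after the pseudocount is added.
    background : array-like of length 4, optional
        Background base frequencies (default uniform).
    pseudocount : float
        Probability mass added to every cell before renormalization.
    """

    def __init__(self, motif_id: str, matrix, background=None,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT):
        mat = np.asarray(matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4 or mat.shape[0] < 1:
            raise ValueError("PWM matrix must have shape (k, 4) with k >= 1")
        if np.any(mat < 0):
            raise ValueError("PWM matrix entries must be non-negative")
        mat = mat + pseudocount
        mat = mat / mat.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 positive frequencies summing to 1")
        self.motif_id = motif_id
        self.matrix = mat
        self.background = bg
        self.pseudocount = pseudocount
        self._dist: Optional[tuple] = None

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def __repr__(self) -> str:
        return f"PWM({self.motif_id!r}, length={len(self)})"

    @property
    def log_odds(self) -> np.ndarray:
        """Per-position log-likelihood ratios log(p_i(base)/bg(base)), shape (k, 4)."""
        with np.errstate(divide="ignore"):  # zero cells allowed at pseudocount 0
            return np.log(self.matrix) - np.log(self.background)[None, :]

    @property
    def log_odds_rc(self) -> np.ndarray:
        """Log-odds of the reverse complement motif (scan of the minus strand)."""
        return self.log_odds[::-1, ::-1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=1))

    # -- score null distribution -------------------------------------------

    def _score_distribution(self):
        """(sorted_scores, tail, slack): tail[i] = P(S >= sorted_scores[i]).

        Sparse DP over attainable window scores under the background model.
        Exact while the state count stays below ``_EXACT_STATE_CAP``;
        otherwise the support is quantized and ``slack`` widens so a queried
        attainable score is never dropped from the tail.
        """
        if self._dist is not None:
            return self._dist
        L = self.log_odds
        k = len(self)
        scores = np.zeros(1)
        probs = np.ones(1)
        exact = True
        quantum = (L.max(axis=1) - L.min(axis=1)).sum() / _LATTICE_BINS
        quantum = max(quantum, 1e-12)
        for j in range(k):
            s = (scores[:, None] + L[j][None, :]).ravel()
            p = (probs[:, None] * self.background[None, :]).ravel()
            if exact and s.size > _EXACT_STATE_CAP:
                exact = False
            if not exact:
                s = np.round(s / quantum) * quantum
            scores, inv = np.unique(s, return_inverse=True)
            probs = np.zeros_like(scores)
            np.add.at(probs, inv, p)
        tail = np.cumsum(probs[::-1])[::-1]
        slack = 1e-9 if exact else (k + 1) * quantum
        self._dist = (scores, tail, slack)
        return self._dist

    def score_pvalue(self, score) -> np.ndarray | float:
        """P(S >= score) for the score of one random motif-length window.

        Monotone non-increasing in ``score`` and clamped to (0, 1]: a score
        above the maximum attainable returns the probability of the best word.
        """
        scores, tail, slack = self._score_distribution()
        q = np.asarray(score, dtype=float)
        if not np.all(np.isfinite(q)):
            raise ValueError("score must be finite")
        idx = np.searchsorted(scores, q - slack, side="left")
        idx = np.minimum(idx, len(scores) - 1)
        p = tail[idx]
        return float(p) if np.isscalar(score) or q.ndim == 0 else p


def score_window(pwm: PWM, sequence: str) -> Optional[float]:
    """Best log-odds hit of ``pwm`` in ``sequence`` over both strands.

    Windows containing N are skipped; returns None when every window is
    skipped.  Raises if the sequence is shorter than the motif.
    """
    codes = sequence if isinstance(sequence, np.ndarray) else encode_sequence(sequence)
    k = len(pwm)
    if len(codes) < k:
        raise ValueError(
            f"sequence length {len(codes)} shorter than motif length {k}")
    best = -np.inf
    for L in (pwm.log_odds, pwm.log_odds_rc):
        # pad an N column so code 4 poisons any window containing it
        Lx = np.hstack([L, np.full((k, 1), -np.inf)])
        n_off = len(codes) - k + 1
        s = np.zeros(n_off)
        for j in range(k):
            s += Lx[j, codes[j:j + n_off]]
        m = s.max()
        if m > best:
            best = m
    return None if best == -np.inf else float(best)


@dataclass(frozen=True)
class MotifChangeCall:
    """Gain/loss/none call of one motif for one variant."""
    motif_id: str
    p_ref: float
    p_alt: float
    call: str  # {"gain", "loss", "none"}
    variant: Optional[tuple] = None  # (sample, chrom, pos, ref, alt) if known


def _decide(p_ref: float, p_alt: float, cutoff: float) -> str:
    if p_alt <= cutoff < p_ref:
        return "gain"
    if p_ref <= cutoff < p_alt:
        return "loss"
    return "none"


def call_motif_change(pwm: PWM, ref_window: str, alt_window: str,
                      cutoff: float = DEFAULT_CUTOFF,
                      correct_windows: bool = False) -> MotifChangeCall:
    """Call motif gain/loss between a reference and an alternate window.

    Both windows must be centered on the variant and differ only at the
    variant base(s).  The per-allele p-value is the minimum single-window
    p over offsets and strands; with ``correct_windows`` it is Bonferroni
    multiplied by the number of windows scanned (off by default, mirroring
    per-position FIMO p-values).
    """
    if ref_window == alt_window:
        raise ValueError("ref and alt windows are identical: not a substitution")
    if len(ref_window) != len(alt_window):
        raise ValueError("ref and alt windows must have equal length")
    k = len(pwm)
    n_windows = 2 * (len(ref_window) - k + 1)
    ps = []
    for win in (ref_window, alt_window):
        s = score_window(pwm, win)
        if s is None:
            ps.append(1.0)
            continue
        p = pwm.score_pvalue(s)
        if correct_windows:
            p = min(1.0, p * n_windows)
        ps.append(p)
    p_ref, p_alt = ps
    return MotifChangeCall(pwm.motif_id, p_ref, p_alt, _decide(p_ref, p_alt, cutoff))


# -- genome-wide disruption index ------------------------------------------


class DisruptionIndex:
    """Precomputed motif significance for every (position, base) of a genome.

    For each PWM and each genomic position, the index stores whether the best
    hit over all windows covering the position (both strands) is below the
    p-value cutoff, for each of the four possible bases at that position.
    A substitution is then motif-changing exactly when significance flips for
    at least one PWM — identical to calling :func:`call_motif_change` on the
    variant-centred windows, but O(1) per variant, which makes thousand-
    replicate permutation nulls affordable.

    Windows extending past the chromosome ends or containing an N are skipped
    for both alleles.
    """

    def __init__(self, genome: Dict[str, np.ndarray], pwms: Sequence[PWM],
                 cutoff: float = DEFAULT_CUTOFF):
        self.cutoff = cutoff
        self.pwms = list(pwms)
        self._ref_codes = {
            c: (v if isinstance(v, np.ndarray) else encode_sequence(v)).astype(np.uint8)
            for c, v in genome.items()
        }
        self._sig: Dict[str, np.ndarray] = {}   # chrom -> (len, 4, n_pwm) bool
        for chrom, codes in self._ref_codes.items():
            self._sig[chrom] = self._build_chrom(codes)

    def _build_chrom(self, codes: np.ndarray) -> np.ndarray:
        n = len(codes)
        sig = np.zeros((n, 4, len(self.pwms)), dtype=bool)
        for pi, pwm in enumerate(self.pwms):
            k = len(pwm)
            if n < k:
                continue
            best = np.full((n, 4), -np.inf)
            for L in (pwm.log_odds, pwm.log_odds_rc):
                Lx = np.hstack([L, np.full((k, 1), -np.inf)]).astype(float)
                n_off = n - k + 1
                S = np.zeros(n_off)
                for j in range(k):
                    S += Lx[j, codes[j:j + n_off]]
                # window at offset o covers positions o..o+k-1; for position
                # pos = o + j with center base replaced by b:
                #   S'(o, b) = S(o) - L[j, codes[pos]] + L[j, b]
                for j in range(k):
                    sl = slice(j, j + n_off)  # positions covered at offset j
                    base_here = Lx[j, codes[sl]]
                    # windows containing N anywhere stay invalid for both alleles
                    core = np.where(np.isfinite(S) & np.isfinite(base_here),
                                    S - base_here, -np.inf)
                    for b in range(4):
                        view = best[sl, b]
                        np.maximum(view, core + Lx[j, b], out=view)
            scores, tail, slack = pwm._score_distribution()
            valid = np.isfinite(best)
            p = np.ones((n, 4))
            idx = np.searchsorted(scores, best[valid] - slack, side="left")
            idx = np.minimum(idx, len(scores) - 1)
            p[valid] = tail[idx]
            sig[:, :, pi] = p <= self.cutoff
        return sig

    def is_changing(self, chrom: str, pos: np.ndarray,
                    alt_code: np.ndarray) -> np.ndarray:
        """Boolean array: does substituting ``alt_code`` at ``pos`` flip any motif?"""
        sig = self._sig[chrom]
        pos = np.asarray(pos, dtype=np.intp)
        alt_code = np.asarray(alt_code, dtype=np.intp)
        ref_code = self._ref_codes[chrom][pos]
        flip = sig[pos, alt_code] != sig[pos, ref_code]
        return flip.any(axis=1)

    def call_table(self, chrom: str, pos: np.ndarray, alt_code: np.ndarray):
        """Per-variant per-pwm flip matrix (n_variants, n_pwms)."""
        sig = self._sig[chrom]
        pos = np.asarray(pos, dtype=np.intp)
        ref_code = self._ref_codes[chrom][pos]
        return sig[pos, np.asarray(alt_code, np.intp)] != sig[pos, ref_code]


def build_disruption_index(genome: Dict[str, np.ndarray], pwms: Sequence[PWM],
                           cutoff: float = DEFAULT_CUTOFF) -> DisruptionIndex:
    """Build a :class:`DisruptionIndex` over a genome for a PWM collection."""
    return DisruptionIndex(genome, pwms, cutoff)


def call_variants(variants, genome: Dict[str, str | np.ndarray],
                  pwms: Sequence[PWM], cutoff: float = DEFAULT_CUTOFF):
    """Call motif changes for a variant table against a genome.

    Parameters
    ----------
    variants : pandas.DataFrame
        Columns sample, chrom, pos (0-based), ref, alt.
    genome : mapping chrom -> sequence
    pwms : PWM collection
    Returns a DataFrame with one row per (variant, motif) with non-``none``
    call, plus a ``changing`` boolean column on the variant level accessible
    via :func:`flag_changing`.
    """
    import pandas as pd

    codes = {c: (s if isinstance(s, np.ndarray) else encode_sequence(s))
             for c, s in genome.items()}
    rows = []
    for row in variants.itertuples(index=False):
        seq = codes.get(row.chrom)
        if seq is None:
            logger.warning("variant chrom %s absent from genome; skipped", row.chrom)
            continue
        if seq[row.pos] != _BASE_CODE[row.ref]:
            raise ValueError(
                f"ref mismatch at {row.chrom}:{row.pos}: genome has "
                f"{'ACGTN'[seq[row.pos]]}, variant says {row.ref}")
        for pwm in pwms:
            k = len(pwm)
            lo, hi = max(0, row.pos - (k - 1)), min(len(seq), row.pos + k)
            if hi - lo < k:
                continue
            ref_win = seq[lo:hi].copy()
            alt_win = ref_win.copy()
            alt_win[row.pos - lo] = _BASE_CODE[row.alt]
            s_ref = score_window(pwm, ref_win)
            s_alt = score_window(pwm, alt_win)
            p_ref = 1.0 if s_ref is None else pwm.score_pvalue(s_ref)
            p_alt = 1.0 if s_alt is None else pwm.score_pvalue(s_alt)
            call = _decide(p_ref, p_alt, cutoff)
            rows.append((row.sample, row.chrom, row.pos, row.ref, row.alt,
                         pwm.motif_id, p_ref, p_alt, call))
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt",
                                       "motif_id", "p_ref", "p_alt", "call"])


def flag_changing(variants, calls):
    """Annotate a variant table with a ``changing`` column (>=1 gain/loss motif)."""
    import pandas as pd

    hit = calls[calls["call"] != "none"]
    keys = set(zip(hit["sample"], hit["chrom"], hit["pos"], hit["alt"]))
    out = variants.copy()
    out["changing"] = [
        (s, c, p, a) in keys
        for s, c, p, a in zip(out["sample"], out["chrom"], out["pos"], out["alt"])
    ]
    return out
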
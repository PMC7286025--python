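"""Global pairwise alignment (affine gaps) and E-value scoring.

A numpy row-vectorised Gotoh dynamic program computes optimal global
alignments under a substitution matrix with affine gap cost
``gap_open + k * gap_extend`` for a gap of length ``k``.  Raw scores are
converted to bit scores and expectations with Karlin–Altschul-style
calibration constants; applying that (local-alignment) statistic to global
scores is an acknowledged approximation — downstream only the ordering of
E-values against a threshold matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from cyanogst.seqio import ValidationError

#: default gapped-BLOSUM62 calibration
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

_NEG = -1.0e30  # effectively -inf but safe in arithmetic


def default_matrix() -> dict[tuple[str, str], float]:
    """BLOSUM62 as a plain ``{(a, b): score}`` dict (X rows included)."""
    blosum = substitution_matrices.load("BLOSUM62")
    out = {}
    for a in blosum.alphabet:
        for b in blosum.alphabet:
            out[(a, b)] = float(blosum[a, b])
    return out


def load_matrix(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a square substitution matrix in standard text layout.

    First non-comment line holds the column residues; each following line a
    row residue and its scores.
    """
    lines = [
        ln
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    cols = lines[0].split()
    out: dict[tuple[str, str], float] = {}
    for ln in lines[1:]:
        parts = ln.split()
        row = parts[0]
        if len(parts) != len(cols) + 1:
            raise ValidationError(f"matrix row {row!r}: expected {len(cols)} scores")
        for c, v in zip(cols, parts[1:]):
            out[(row, c)] = float(v)
    return out


@dataclass(frozen=True)
class AlignmentResult:
    """An optimal global alignment with its scores."""

    aligned_a: str
    aligned_b: str
    raw_score: float
    bit_score: float
    evalue: float


def _encode(seq: str, alphabet: str) -> np.ndarray:
    idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int32)
    for k, ch in enumerate(alphabet):
        lut[ord(ch)] = k
    codes = lut[idx]
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise ValidationError(f"invalid residue {bad!r} for substitution matrix")
    return codes


def _matrix_array(matrix: dict[tuple[str, str], float]):
    alphabet = sorted({a for a, _ in matrix})
    arr = np.zeros((len(alphabet), len(alphabet)))
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            arr[i, j] = matrix[(a, b)]
    return "".join(alphabet), arr


def _fill(a_codes, b_codes, sub, gap_open, gap_extend):
    """Gotoh matrices M (diagonal), E (gap in a), F (gap in b), row-vectorised."""
    m, n = len(a_codes), len(b_codes)
    go, ge = gap_open, gap_extend
    M = np.full((m + 1, n + 1), _NEG)
    E = np.full((m + 1, n + 1), _NEG)
    F = np.full((m + 1, n + 1), _NEG)
    M[0, 0] = 0.0
    j = np.arange(1, n + 1)
    E[0, 1:] = -(go + ge * j)
    i = np.arange(1, m + 1)
    F[1:, 0] = -(go + ge * i)
    jj = np.arange(n + 1)
    for r in range(1, m + 1):
        srow = sub[a_codes[r - 1]][b_codes]  # scores vs every b residue
        best_prev = np.maximum(np.maximum(M[r - 1], E[r - 1]), F[r - 1])
        M[r, 1:] = best_prev[:-1] + srow
        F[r, 1:] = np.maximum(M[r - 1, 1:] - go - ge, F[r - 1, 1:] - ge)
        # E[r, j] = max(M[r, j-1] - go - ge, E[r, j-1] - ge): prefix-max scan
        h = np.empty(n + 1)
        h[0] = _NEG
        h[1:] = M[r, :-1] + ge * (jj[1:] - 1) - go
        g = np.maximum.accumulate(h)
        E[r, 1:] = g[1:] - ge * jj[1:]
        E[r, 0] = _NEG
    return M, E, F


def align_score(
    a: str,
    b: str,
    matrix: dict[tuple[str, str], float] | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Optimal global alignment score only (no traceback)."""
    if not a or not b:
        raise ValidationError("sequences must be non-empty")
    if gap_open <= 0 or gap_extend <= 0:
        raise ValidationError("affine gap penalties must be positive")
    matrix = matrix if matrix is not None else default_matrix()
    alphabet, sub = _matrix_array(matrix)
    M, E, F = _fill(_encode(a, alphabet), _encode(b, alphabet), sub, gap_open, gap_extend)
    return float(max(M[-1, -1], E[-1, -1], F[-1, -1]))


def global_align(
    a: str,
    b: str,
    matrix: dict[tuple[str, str], float] | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    lam: float = DEFAULT_LAMBDA,
    kappa: float = DEFAULT_K,
) -> AlignmentResult:
    """Optimal affine-gap global alignment with deterministic traceback.

    Traceback precedence is fixed (substitution > gap in ``a`` > gap in ``b``;
    within a gap state, closing the gap beats extending it), so equal-scoring
    alignments resolve identically across runs.
    """
    if not a or not b:
        raise ValidationError("sequences must be non-empty")
    if gap_open <= 0 or gap_extend <= 0:
        raise ValidationError("affine gap penalties must be positive")
    matrix = matrix if matrix is not None else default_matrix()
    alphabet, sub = _matrix_array(matrix)
    ac, bc = _encode(a, alphabet), _encode(b, alphabet)
    M, E, F = _fill(ac, bc, sub, gap_open, gap_extend)
    go, ge = gap_open, gap_extend
    i, j = len(a), len(b)
    scores = (M[i, j], E[i, j], F[i, j])
    raw = float(max(scores))
    state = int(np.argmax(scores))  # 0=M, 1=E, 2=F
    out_a: list[str] = []
    out_b: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == 0:  # diagonal step ending at (i, j)
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - sub[ac[i - 1], bc[j - 1]]
            i, j = i - 1, j - 1
            if abs(M[i, j] - target) < tol:
                state = 0
            elif abs(E[i, j] - target) < tol:
                state = 1
            else:
                state = 2
        elif state == 1:  # gap in a: consume b[j-1]
            out_a.append("-")
            out_b.append(b[j - 1])
            state = 0 if abs(M[i, j - 1] - go - ge - E[i, j]) < tol else 1
            j -= 1
        else:  # gap in b: consume a[i-1]
            out_a.append(a[i - 1])
            out_b.append("-")
            state = 0 if abs(M[i - 1, j] - go - ge - F[i, j]) < tol else 2
            i -= 1
    out_a.reverse()
    out_b.reverse()
    bits = bit_score(raw, lam, kappa)
    ev = evalue(raw, len(a), len(b), lam, kappa)
    return AlignmentResult("".join(out_a), "".join(out_b), raw, bits, ev)


def bit_score(raw_score: float, lam: float = DEFAULT_LAMBDA, kappa: float = DEFAULT_K) -> float:
    """``(lambda * S - ln K) / ln 2``."""
    if lam <= 0 or kappa <= 0:
        raise ValidationError("calibration constants must be positive")
    return (lam * raw_score - math.log(kappa)) / math.log(2.0)


def evalue(
    raw_score: float,
    m: int,
    n: int,
    lam: float = DEFAULT_LAMBDA,
    kappa: float = DEFAULT_K,
) -> float:
    """Expected chance hits: ``m * n * 2**(-bit)``; monotone in the raw score."""
    bits = bit_score(raw_score, lam, kappa)
    # work in log space: 2^-bits underflows for strong alignments
    log10_e = math.log10(m) + math.log10(n) - bits * math.log10(2.0)
    return 10.0 ** max(log10_e, -307.0) if log10_e > -307 else 0.0


def alignment_score(
    aligned_a: str,
    aligned_b: str,
    matrix: dict[tuple[str, str], float] | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Score an explicit gapped alignment (used to cross-check tracebacks)."""
    matrix = matrix if matrix is not None else default_matrix()
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" and y == "-":
            raise ValidationError("columns may not be all-gap")
        if x == "-":
            score -= gap_extend + (0.0 if in_gap_a else gap_open)
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score -= gap_extend + (0.0 if in_gap_b else gap_open)
            in_gap_a, in_gap_b = False, True
        else:
            score += matrix[(x, y)]
            in_gap_a = in_gap_b = False
    return score
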
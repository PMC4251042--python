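"""Pairwise alignment with affine gaps: sequence, sequence-profile, profile-profile.

All three entry points reduce to the same Gotoh dynamic programme over a
precomputed position-score matrix.  A gap of length ``g`` costs
``gap_open + (g - 1) * gap_extend`` (both penalties are non-positive;
defaults follow the BLAST convention of -11 / -1 with BLOSUM62).

Coordinates are 0-based throughout; ``aligned_pairs`` lists the matched
(position-in-first, position-in-second) index pairs, strictly increasing in
both coordinates.  Traceback ties prefer diagonal over up (gap in the second
input) over left, and a gap closes as early as possible, so output is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from ._kernels import NEG, gotoh_fill
from .residues import AA, Profile, residue_matrix

__all__ = [
    "AlignmentResult",
    "align_sequences",
    "align_sequence_profile",
    "align_profiles",
    "simple_matrix",
]


@dataclass
class AlignmentResult:
    """Optimal alignment score plus the matched coordinates."""

    score: float
    aligned_pairs: list[tuple[int, int]] = field(default_factory=list)
    normalized_score: float = 0.0


def simple_matrix(match: float, mismatch: float, alphabet: str = AA) -> dict:
    """A match/mismatch substitution scheme as a pair-keyed dict."""
    return {
        (a, b): (match if a == b else mismatch)
        for a in alphabet
        for b in alphabet
    }


@lru_cache(maxsize=8)
def _named_matrix(name: str):
    return substitution_matrices.load(name)


def _pair_score_matrix(a: str, b: str, matrix) -> np.ndarray:
    """Dense (len(a), len(b)) substitution-score matrix for two sequences."""
    if isinstance(matrix, str):
        matrix = _named_matrix(matrix)
    if isinstance(matrix, dict):
        lookup = matrix
        alphabet = {x for (x, _) in lookup}
    else:  # Bio.Align.substitution_matrices.Array
        alphabet = set(str(matrix.alphabet))
        lookup = None
    for seq, which in ((a, "first"), (b, "second")):
        for r in seq:
            if r not in alphabet:
                raise KeyError(
                    f"residue {r!r} in the {which} sequence is absent from the "
                    "substitution matrix"
                )
    S = np.empty((len(a), len(b)))
    if lookup is not None:
        for i, ra in enumerate(a):
            for j, rb in enumerate(b):
                S[i, j] = lookup[(ra, rb)]
    else:
        alpha = str(matrix.alphabet)
        ia = np.array([alpha.index(r) for r in a])
        ib = np.array([alpha.index(r) for r in b])
        S = np.asarray(matrix)[np.ix_(ia, ib)].astype(float)
    return S


def _validate_gaps(gap_open: float, gap_extend: float) -> None:
    if gap_open > 0 or gap_extend > 0:
        raise ValueError("gap penalties must be <= 0")


def _traceback(H, Ix, Iy, S, gap_open, gap_extend, local, end) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    i, j = end
    # entry state: prefer match (diagonal), then Ix (up), then Iy (left)
    if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
        state = "M"
    elif H[i, j] == Ix[i, j]:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if local and H[i, j] == 0.0 and state == "M":
            break
        if state == "M":
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
            if i == 0 and j == 0:
                break
            if local and H[i, j] == 0.0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
                state = "M"
            elif i > 0 and H[i, j] == Ix[i, j]:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            # vertical move consuming position i-1 of the first input
            closes = H[i - 1, j] + gap_open
            i -= 1
            if i == 0 and j == 0:
                break
            if Ix[i + 1, j] == closes:
                if local and H[i, j] == 0.0:
                    break
                if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
                    state = "M"
                elif i > 0 and H[i, j] == Ix[i, j]:
                    state = "X"
                else:
                    state = "Y"
            # else: stay in X (gap extension)
        else:  # "Y"
            closes = H[i, j - 1] + gap_open
            j -= 1
            if i == 0 and j == 0:
                break
            if Iy[i, j + 1] == closes:
                if local and H[i, j] == 0.0:
                    break
                if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
                    state = "M"
                elif i > 0 and H[i, j] == Ix[i, j]:
                    state = "X"
                else:
                    state = "Y"
    pairs.reverse()
    return pairs


def _align_from_scores(
    S: np.ndarray,
    gap_open: float,
    gap_extend: float,
    local: bool,
    min_len: int,
    traceback: bool = True,
) -> AlignmentResult:
    _validate_gaps(gap_open, gap_extend)
    H, Ix, Iy = gotoh_fill(
        np.ascontiguousarray(S, dtype=np.float64),
        float(gap_open),
        float(gap_extend),
        local,
    )
    n, m = S.shape
    if local:
        flat = int(np.argmax(H))
        end = (flat // (m + 1), flat % (m + 1))
        score = float(H[end])
    else:
        end = (n, m)
        score = float(H[n, m])
    pairs: list[tuple[int, int]] = []
    if traceback and not (local and score == 0.0):
        pairs = _traceback(H, Ix, Iy, S, gap_open, gap_extend, local, end)
    return AlignmentResult(
        score=score,
        aligned_pairs=pairs,
        normalized_score=score / min_len,
    )


def align_sequences(
    a: str,
    b: str,
    mode: str = "global",
    matrix="BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    traceback: bool = True,
) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch) or local (Smith-Waterman) alignment.

    ``matrix`` may be a named biopython substitution matrix (for example
    ``"BLOSUM62"``), a ``(residue, residue) -> score`` dict, or a
    ``substitution_matrices.Array``.  Local scores are never negative.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if mode not in ("global", "local"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    S = _pair_score_matrix(a, b, matrix)
    return _align_from_scores(
        S, gap_open, gap_extend, mode == "local", min(len(a), len(b)), traceback
    )


def align_sequence_profile(
    profile: Profile,
    seq: str,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    mode: str = "global",
    traceback: bool = True,
) -> AlignmentResult:
    """Align a profile to a plain sequence.

    Matching profile column ``c`` to residue ``r`` scores
    ``log2(c[r] / background)`` with a uniform 1/20 background, i.e. the
    log-odds of the residue under the column model.  Ambiguous residues
    contribute through their uniform ambiguity distribution.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    R = residue_matrix(seq)  # (m, 20)
    with np.errstate(divide="ignore"):
        S = np.log2(np.maximum(20.0 * profile.columns @ R.T, 1e-300))
    S[S < NEG] = NEG
    return _align_from_scores(
        S, gap_open, gap_extend, mode == "local", min(profile.length, len(seq)), traceback
    )


def align_profiles(
    p: Profile,
    q: Profile,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    mode: str = "global",
    traceback: bool = True,
) -> AlignmentResult:
    """Align two profiles column-wise.

    Column pair (c, d) scores ``log2( (c . d) / (b . b) )`` with the uniform
    background ``b = 1/20``, i.e. ``log2(20 * c . d)`` -- the dot-product
    profile-profile score.
    """
    if p.length == 0 or q.length == 0:
        raise ValueError("profiles must be non-empty")
    with np.errstate(divide="ignore"):
        S = np.log2(np.maximum(20.0 * p.columns @ q.columns.T, 1e-300))
    return _align_from_scores(
        S, gap_open, gap_extend, mode == "local", min(p.length, q.length), traceback
    )
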
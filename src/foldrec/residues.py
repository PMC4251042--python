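"""Residue alphabet, ambiguity handling, and MSA-derived profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: The 20 standard amino acids, alphabetical one-letter codes.
AA = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {r: i for i, r in enumerate(AA)}

#: Ambiguity and non-standard codes mapped to their ambiguity sets; each
#: contributes uniformly over its set (X over all 20, U = selenocysteine
#: to C, O = pyrrolysine to K).
AMBIGUITY = {
    "B": "DN",
    "Z": "EQ",
    "J": "IL",
    "X": AA,
    "U": "C",
    "O": "K",
}

GAP_CHARS = "-."


def residue_distribution(residue: str) -> np.ndarray:
    """Length-20 contribution vector for one residue letter."""
    v = np.zeros(len(AA))
    r = residue.upper()
    if r in AA_INDEX:
        v[AA_INDEX[r]] = 1.0
        return v
    if r in AMBIGUITY:
        members = AMBIGUITY[r]
        v[[AA_INDEX[m] for m in members]] = 1.0 / len(members)
        return v
    raise ValueError(f"unknown residue letter {residue!r}")


def residue_matrix(seq: str) -> np.ndarray:
    """Per-position (L, 20) contribution matrix for a sequence.

    Standard residues are one-hot; ambiguity codes spread their unit mass
    uniformly over their ambiguity set.
    """
    if not seq:
        raise ValueError("empty sequence")
    return np.stack([residue_distribution(r) for r in seq])


@dataclass
class Profile:
    """Per-position amino-acid weights built from an MSA (a simple PSSM).

    ``columns`` has shape (L, 20); every row sums to 1.  Columns where the
    reference row (the first MSA row) carries a gap are dropped, so ``L``
    equals the reference sequence length.
    """

    columns: np.ndarray

    @property
    def length(self) -> int:
        return int(self.columns.shape[0])


def build_profile(msa: list[str], pseudocount: float = 0.01) -> Profile:
    """Pseudocount-smoothed per-column frequencies from aligned rows.

    The first row is the reference; gaps in non-reference rows are simply
    excluded from the column counts.  ``pseudocount`` is added to each of
    the 20 residue counts before normalisation.
    """
    if not msa:
        raise ValueError("empty MSA")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged MSA rows")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    keep = [j for j in range(width) if msa[0][j] not in GAP_CHARS]
    cols = np.full((len(keep), len(AA)), float(pseudocount))
    for out_j, j in enumerate(keep):
        for row in msa:
            c = row[j]
            if c in GAP_CHARS:
                continue
            cols[out_j] += residue_distribution(c)
    totals = cols.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("profile column with zero total weight")
    return Profile(columns=cols / totals)
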
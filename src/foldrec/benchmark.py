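"""Data model for a fold-recognition benchmark.

A benchmark is a set of proteins annotated with a three-level structural
hierarchy (family nested in superfamily nested in fold, SCOP-style), from
which every ordered (target, template) pair is enumerated and labelled with
the deepest level at which the two proteins are related.  Pairs related at
any level are the positive class; the overwhelming majority of pairs share
no fold and form the negative class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Relationship labels, deepest first.  ``none`` means different folds.
RELATIONSHIPS = ("family", "superfamily", "fold", "none")

#: The three structural levels at which recognition is evaluated.
LEVELS = ("family", "superfamily", "fold")


@dataclass
class Protein:
    """A benchmark protein: sequence, hierarchy labels, optional extras.

    Parameters
    ----------
    id
        Unique identifier within a dataset.
    sequence
        Amino-acid sequence (20-letter alphabet plus common ambiguity codes).
    family_id, superfamily_id, fold_id
        Hierarchy labels; every protein sharing a family must share the
        superfamily and fold (checked at dataset level).
    msa
        Optional multiple sequence alignment as a list of equal-length
        aligned rows; the first row is the protein's own (gapless) sequence.
    struct_states
        Optional map of track name to per-residue state string (for example
        3-state secondary structure ``H``/``E``/``C``); each string must have
        the same length as ``sequence``.
    """

    id: str
    sequence: str
    family_id: str
    superfamily_id: str
    fold_id: str
    msa: list[str] | None = None
    struct_states: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        if self.struct_states is not None:
            for track, states in self.struct_states.items():
                if len(states) != len(self.sequence):
                    raise ValueError(
                        f"protein {self.id!r}: track {track!r} has length "
                        f"{len(states)} but sequence has length {len(self.sequence)}"
                    )
        if self.msa is not None and self.msa:
            width = len(self.msa[0])
            if any(len(row) != width for row in self.msa):
                raise ValueError(f"protein {self.id!r}: ragged MSA rows")


def label_relationship(target: Protein, template: Protein) -> str:
    """Deepest structural level shared by two proteins.

    Returns ``"family"``, ``"superfamily"``, ``"fold"`` or ``"none"``.
    Symmetric in its arguments.
    """
    for p in (target, template):
        if not (p.family_id and p.superfamily_id and p.fold_id):
            raise ValueError(f"protein {p.id!r} is missing hierarchy labels")
    if target.family_id == template.family_id:
        return "family"
    if target.superfamily_id == template.superfamily_id:
        return "superfamily"
    if target.fold_id == template.fold_id:
        return "fold"
    return "none"


@dataclass
class PairRecord:
    """An ordered (target, template) pair with its relationship label."""

    target_id: str
    template_id: str
    relationship: str
    features: np.ndarray | None = None

    @property
    def positive(self) -> bool:
        return self.relationship != "none"


def enumerate_pairs(proteins: list[Protein]) -> list[PairRecord]:
    """All ordered (target, template) pairs, target != template.

    For ``n`` proteins this yields exactly ``n * (n - 1)`` pairs, each
    carrying its relationship label.  Raises on duplicate protein ids.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins to enumerate pairs")
    seen: set[str] = set()
    for p in proteins:
        if p.id in seen:
            raise ValueError(f"duplicate protein id {p.id!r}")
        seen.add(p.id)
    pairs: list[PairRecord] = []
    for t in proteins:
        for p in proteins:
            if t.id == p.id:
                continue
            pairs.append(PairRecord(t.id, p.id, label_relationship(t, p)))
    return pairs


@dataclass
class BenchmarkDataset:
    """Proteins plus their enumerated, labelled ordered pairs."""

    proteins: list[Protein]
    pairs: list[PairRecord] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check hierarchy consistency: family determines superfamily and fold."""
        fam_to_upper: dict[str, tuple[str, str]] = {}
        sf_to_fold: dict[str, str] = {}
        for p in self.proteins:
            upper = (p.superfamily_id, p.fold_id)
            if fam_to_upper.setdefault(p.family_id, upper) != upper:
                raise ValueError(
                    f"family {p.family_id!r} maps to inconsistent superfamily/fold labels"
                )
            if sf_to_fold.setdefault(p.superfamily_id, p.fold_id) != p.fold_id:
                raise ValueError(
                    f"superfamily {p.superfamily_id!r} maps to inconsistent fold labels"
                )

    def protein_by_id(self, pid: str) -> Protein:
        if not hasattr(self, "_by_id") or len(self._by_id) != len(self.proteins):
            self._by_id = {p.id: p for p in self.proteins}
        return self._by_id[pid]


def target_levels(ds: BenchmarkDataset) -> dict[str, set[str]]:
    """For each protein, the set of levels at which it has >= 1 match.

    A protein is a family-level target if some other protein shares its
    family; a superfamily-level target if some other protein is related at
    exactly the superfamily level (same superfamily, different family); and
    analogously for the fold level.  A protein may appear at several levels.
    """
    levels: dict[str, set[str]] = {p.id: set() for p in ds.proteins}
    for a in ds.proteins:
        for b in ds.proteins:
            if a.id == b.id:
                continue
            rel = label_relationship(a, b)
            if rel != "none":
                levels[a.id].add(rel)
    return levels


@dataclass
class DatasetSummary:
    """Headline counts for a fully enumerated benchmark."""

    n_proteins: int
    n_pairs: int
    n_positive: int
    n_negative: int
    imbalance_ratio: float  # negatives per positive; inf when no positives
    targets_per_level: dict[str, int]

    @property
    def imbalance_ratio_rounded(self) -> float | int:
        """The conventionally reported rounded ratio (for example 127 for 126.94)."""
        if math.isinf(self.imbalance_ratio):
            return math.inf
        return round(self.imbalance_ratio)

    def __str__(self) -> str:
        ratio = (
            "inf"
            if math.isinf(self.imbalance_ratio)
            else f"{self.imbalance_ratio:.2f} (~{self.imbalance_ratio_rounded}:1)"
        )
        per_level = ", ".join(
            f"{lvl}={self.targets_per_level[lvl]}" for lvl in LEVELS
        )
        return (
            f"{self.n_proteins} proteins, {self.n_pairs} ordered pairs: "
            f"{self.n_positive} positive / {self.n_negative} negative "
            f"(ratio {ratio}); eligible targets: {per_level}"
        )


def dataset_summary(ds: BenchmarkDataset) -> DatasetSummary:
    """Counts of positives/negatives and per-level eligible-target tallies."""
    n_pos = sum(1 for pr in ds.pairs if pr.positive)
    n_neg = len(ds.pairs) - n_pos
    ratio = (n_neg / n_pos) if n_pos else math.inf
    levels = target_levels(ds)
    per_level = {
        lvl: sum(1 for s in levels.values() if lvl in s) for lvl in LEVELS
    }
    return DatasetSummary(
        n_proteins=len(ds.proteins),
        n_pairs=len(ds.pairs),
        n_positive=n_pos,
        n_negative=n_neg,
        imbalance_ratio=ratio,
        targets_per_level=per_level,
    )
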
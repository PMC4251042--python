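"""Pairwise similarity features for (target, template) protein pairs.

Five categories, mirroring the classic information sources of pairwise fold
recognition but computed self-contained:

1. sequence/family information: monomer and dimer composition vectors
   compared with cosine, Pearson-correlation and Gaussian kernels;
2. sequence-sequence alignment: global and local affine-gap alignment
   scores (raw and length-normalised);
3. sequence-profile alignment: each protein's MSA profile aligned to the
   other protein's sequence;
4. profile-profile alignment: the two profiles aligned column-wise;
5. structural information: the fraction of aligned positions whose
   predicted structural states (secondary structure, accessibility, ...)
   agree, evaluated on the profile-profile global alignment.

Features whose inputs are missing (no MSA, no structural track) are imputed
to 0 and flagged by a per-category binary indicator, so every pair in a
dataset yields a vector of identical length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmark import BenchmarkDataset, Protein, label_relationship
from .residues import AA, Profile, build_profile, residue_matrix

META_COLUMNS = ["target_id", "template_id", "relationship"]


@dataclass
class CompositionVector:
    """Relative monomer (20) or dimer (400) frequencies; entries sum to 1."""

    values: np.ndarray
    order: str  # "monomer" | "dimer"


def monomer_composition(sequence: str) -> CompositionVector:
    """Relative frequency of each of the 20 amino acids."""
    R = residue_matrix(sequence)  # raises on empty / unknown letters
    return CompositionVector(values=R.mean(axis=0), order="monomer")


def dimer_composition(sequence: str) -> CompositionVector:
    """Relative frequency of each of the 400 ordered residue pairs.

    Computed over the L-1 overlapping windows; ambiguity codes contribute
    the product of their per-position distributions.
    """
    if len(sequence) < 2:
        raise ValueError("dimer composition requires a sequence of length >= 2")
    R = residue_matrix(sequence)
    counts = np.einsum("ij,ik->jk", R[:-1], R[1:]).ravel()
    return CompositionVector(values=counts / (len(sequence) - 1), order="dimer")


def _as_array(u) -> np.ndarray:
    if isinstance(u, CompositionVector):
        return np.asarray(u.values, dtype=float)
    return np.asarray(u, dtype=float)


def cosine_similarity(u, v) -> float:
    """dot(u, v) / (||u|| ||v||); in [0, 1] for non-negative inputs."""
    a, b = _as_array(u), _as_array(v)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def correlation_similarity(u, v) -> float:
    """Pearson correlation in [-1, 1]; 0 by convention if either is constant."""
    a, b = _as_array(u), _as_array(v)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("correlation requires length >= 2")
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 or nb == 0:
        return 0.0
    return float(da @ db / (na * nb))


def gaussian_similarity(u, v, gamma: float) -> float:
    """exp(-gamma * ||u - v||^2); in (0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    a, b = _as_array(u), _as_array(v)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    d = a - b
    return float(np.exp(-gamma * (d @ d)))


def structural_compatibility(
    track_t: str, track_p: str, aligned_pairs: list[tuple[int, int]]
) -> float:
    """Fraction of aligned positions with identical structural states.

    Returns 0.0 for an empty alignment.  Raises if an aligned index falls
    outside either string.
    """
    if not aligned_pairs:
        return 0.0
    same = 0
    for i, j in aligned_pairs:
        if i < 0 or i >= len(track_t) or j < 0 or j >= len(track_p):
            raise IndexError(f"aligned pair ({i}, {j}) out of range")
        if track_t[i] == track_p[j]:
            same += 1
    return same / len(aligned_pairs)


@dataclass
class FeatureConfig:
    """Feature-set configuration with documented defaults.

    Gaussian bandwidths default to 1/d for a length-d composition vector
    (scale-free).  Alignment defaults are BLOSUM62 with affine gaps -11/-1.
    ``tracks`` names the structural-state tracks compared per pair.
    Category switches allow ablations; the canonical feature order is the
    order of :func:`feature_names`.
    """

    composition: bool = True
    seq_align: bool = True
    seq_profile: bool = True
    profile_profile: bool = True
    structural: bool = True
    tracks: tuple[str, ...] = ("ss", "acc")
    gamma_monomer: float | None = None  # None -> 1/20
    gamma_dimer: float | None = None  # None -> 1/400
    matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    pseudocount: float = 0.01


def feature_names(config: FeatureConfig | None = None) -> list[str]:
    """Canonical ordered feature labels for a configuration."""
    config = config or FeatureConfig()
    names: list[str] = []
    if config.composition:
        for order in ("mono", "dimer"):
            for kernel in ("cosine", "correlation", "gaussian"):
                names.append(f"comp_{order}_{kernel}")
    if config.seq_align:
        names += [
            "seq_global_score",
            "seq_global_norm",
            "seq_local_score",
            "seq_local_norm",
        ]
    if config.seq_profile:
        names += [
            "profseq_target_score",
            "profseq_target_norm",
            "profseq_template_score",
            "profseq_template_norm",
            "profseq_imputed",
        ]
    if config.profile_profile:
        names += ["profprof_score", "profprof_norm", "profprof_imputed"]
    if config.structural:
        names += [f"struct_{track}_match" for track in config.tracks]
        names.append("struct_imputed")
    return names


@dataclass
class FeatureVector:
    """A fixed-length real feature vector with its ordered labels."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)


class _ProteinCache:
    """Per-protein derived quantities shared across that protein's pairs."""

    def __init__(self, protein: Protein, config: FeatureConfig):
        self.protein = protein
        self.mono = monomer_composition(protein.sequence)
        self.dimer = dimer_composition(protein.sequence)
        self.profile: Profile | None = (
            build_profile(protein.msa, config.pseudocount)
            if protein.msa
            else None
        )


def _featurize_cached(
    t: _ProteinCache, p: _ProteinCache, config: FeatureConfig
) -> np.ndarray:
    # imported here to keep residues/alignment/features dependency acyclic
    from .alignment import align_profiles, align_sequence_profile, align_sequences

    go, ge = config.gap_open, config.gap_extend
    values: list[float] = []
    if config.composition:
        gm = config.gamma_monomer or 1.0 / len(AA)
        gd = config.gamma_dimer or 1.0 / (len(AA) ** 2)
        for a, b, gamma in ((t.mono, p.mono, gm), (t.dimer, p.dimer, gd)):
            values.append(cosine_similarity(a, b))
            values.append(correlation_similarity(a, b))
            values.append(gaussian_similarity(a, b, gamma))
    seq_t, seq_p = t.protein.sequence, p.protein.sequence
    need_struct = config.structural and bool(config.tracks)
    struct_pairs: list[tuple[int, int]] | None = None
    if config.seq_align or (need_struct and (t.profile is None or p.profile is None)):
        want_tb = need_struct and (t.profile is None or p.profile is None)
        g = align_sequences(
            seq_t, seq_p, "global", config.matrix, go, ge, traceback=want_tb
        )
        if want_tb:
            struct_pairs = g.aligned_pairs
        if config.seq_align:
            loc = align_sequences(
                seq_t, seq_p, "local", config.matrix, go, ge, traceback=False
            )
            values += [g.score, g.normalized_score, loc.score, loc.normalized_score]
    if config.seq_profile:
        imputed = 0.0
        if t.profile is not None:
            r = align_sequence_profile(t.profile, seq_p, go, ge, traceback=False)
            values += [r.score, r.normalized_score]
        else:
            values += [0.0, 0.0]
            imputed = 1.0
        if p.profile is not None:
            r = align_sequence_profile(p.profile, seq_t, go, ge, traceback=False)
            values += [r.score, r.normalized_score]
        else:
            values += [0.0, 0.0]
            imputed = 1.0
        values.append(imputed)
    if config.profile_profile or need_struct:
        if t.profile is not None and p.profile is not None:
            r = align_profiles(t.profile, p.profile, go, ge, traceback=need_struct)
            if need_struct:
                struct_pairs = r.aligned_pairs
            if config.profile_profile:
                values += [r.score, r.normalized_score, 0.0]
        elif config.profile_profile:
            values += [0.0, 0.0, 1.0]
    if config.structural:
        struct_imputed = 0.0
        tracks_t = t.protein.struct_states or {}
        tracks_p = p.protein.struct_states or {}
        for track in config.tracks:
            if track in tracks_t and track in tracks_p and struct_pairs is not None:
                values.append(
                    structural_compatibility(
                        tracks_t[track], tracks_p[track], struct_pairs
                    )
                )
            else:
                values.append(0.0)
                struct_imputed = 1.0
        values.append(struct_imputed)
    return np.asarray(values, dtype=float)


def featurize_pair(
    target: Protein, template: Protein, config: FeatureConfig | None = None
) -> FeatureVector:
    """Full pairwise feature vector for one ordered (target, template) pair.

    Composition-kernel features are symmetric in the two proteins; alignment
    scores under a symmetric substitution matrix are too, while the two
    sequence-profile scores are direction-specific.  Missing MSAs or tracks
    never fail: the affected features are imputed to 0 with the category's
    indicator set to 1.
    """
    config = config or FeatureConfig()
    v = _featurize_cached(
        _ProteinCache(target, config), _ProteinCache(template, config), config
    )
    return FeatureVector(values=v, names=feature_names(config))


def featurize_dataset(
    ds: BenchmarkDataset,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature table with one row per ordered pair in the dataset.

    Columns: ``target_id``, ``template_id``, ``relationship``, then the
    canonical feature columns.  Per-protein work (compositions, profiles)
    is computed once and shared across that protein's pairs.  Also records
    the feature names on ``ds.feature_names``.
    """
    config = config or FeatureConfig()
    names = feature_names(config)
    caches = {p.id: _ProteinCache(p, config) for p in ds.proteins}
    pairs = ds.pairs
    if not pairs:
        raise ValueError("dataset has no enumerated pairs")
    rows = np.empty((len(pairs), len(names)))
    for i, pr in enumerate(pairs):
        rows[i] = _featurize_cached(
            caches[pr.target_id], caches[pr.template_id], config
        )
    table = pd.DataFrame(
        {
            "target_id": [pr.target_id for pr in pairs],
            "template_id": [pr.template_id for pr in pairs],
            "relationship": [pr.relationship for pr in pairs],
        }
    )
    table[names] = rows
    ds.feature_names = names
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature columns of a table (everything after the meta columns)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as TSV (atomic: write then rename)."""
    from .io import atomic_write_text

    atomic_write_text(path, table.to_csv(sep="\t", index=False))


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def relationship_lookup(ds: BenchmarkDataset) -> dict[tuple[str, str], str]:
    """(target_id, template_id) -> relationship for every ordered pair."""
    out: dict[tuple[str, str], str] = {}
    for a in ds.proteins:
        for b in ds.proteins:
            if a.id != b.id:
                out[(a.id, b.id)] = label_relationship(a, b)
    return out
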
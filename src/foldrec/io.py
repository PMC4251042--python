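"""On-disk benchmark format: manifest TSV, FASTA, aligned FASTA, track files.

A benchmark directory contains one FASTA per protein under ``seqs/``, an
aligned-FASTA MSA under ``msas/`` (optional), a FASTA-like structural-track
file under ``tracks/`` (optional; record ids are track names, letters are
per-residue states), and a tab-separated ``manifest.tsv`` with columns::

    protein_id  family_id  superfamily_id  fold_id  fasta_path  msa_path  struct_path

Missing optional paths are written as ``-``.  Paths are relative to the
manifest's directory.  All writes are atomic (write to a temp file in the
same directory, then rename), so an interrupted run never leaves a
truncated file behind.
"""

from __future__ import annotations

import io as _stdio
import json
import os
import tempfile
from pathlib import Path

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .benchmark import BenchmarkDataset, Protein, enumerate_pairs

MANIFEST_COLUMNS = [
    "protein_id",
    "family_id",
    "superfamily_id",
    "fold_id",
    "fasta_path",
    "msa_path",
    "struct_path",
]


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` via a same-directory temp file plus rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _fasta_text(records: list[tuple[str, str]]) -> str:
    buf = _stdio.StringIO()
    SeqIO.write(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records],
        buf,
        "fasta",
    )
    return buf.getvalue()


def write_benchmark(ds: BenchmarkDataset, outdir, provenance: dict | None = None) -> Path:
    """Write a dataset as a manifest-rooted benchmark directory.

    Returns the manifest path.  ``provenance`` (config, seed, versions) is
    stored as ``provenance.json`` beside the manifest when given.
    """
    outdir = Path(outdir)
    rows = ["\t".join(MANIFEST_COLUMNS)]
    for p in ds.proteins:
        fasta_rel = f"seqs/{p.id}.fasta"
        atomic_write_text(outdir / fasta_rel, _fasta_text([(p.id, p.sequence)]))
        if p.msa:
            msa_rel = f"msas/{p.id}.afa"
            records = [(p.id if i == 0 else f"{p.id}_hom{i}", row)
                       for i, row in enumerate(p.msa)]
            atomic_write_text(outdir / msa_rel, _fasta_text(records))
        else:
            msa_rel = "-"
        if p.struct_states:
            struct_rel = f"tracks/{p.id}.tracks"
            records = sorted(p.struct_states.items())
            atomic_write_text(outdir / struct_rel, _fasta_text(records))
        else:
            struct_rel = "-"
        rows.append(
            "\t".join(
                [p.id, p.family_id, p.superfamily_id, p.fold_id,
                 fasta_rel, msa_rel, struct_rel]
            )
        )
    manifest = outdir / "manifest.tsv"
    atomic_write_text(manifest, "\n".join(rows) + "\n")
    if provenance is not None:
        atomic_write_text(outdir / "provenance.json", json.dumps(provenance, indent=2))
    return manifest


def _read_single_fasta(path: Path, pid: str) -> str:
    try:
        records = list(SeqIO.parse(path, "fasta"))
    except Exception as exc:  # malformed file
        raise ValueError(f"{path}: cannot parse FASTA for {pid!r}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no FASTA record for protein {pid!r}")
    return str(records[0].seq)


def load_benchmark(manifest_path, with_pairs: bool = True) -> BenchmarkDataset:
    """Load a benchmark from its manifest, enumerating labelled pairs."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    proteins: list[Protein] = []
    with open(manifest_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != MANIFEST_COLUMNS:
            raise ValueError(
                f"{manifest_path}: unexpected manifest header {header!r}"
            )
        for lineno, line in enumerate_lines(fh):
            fields = line.split("\t")
            if len(fields) != len(MANIFEST_COLUMNS):
                raise ValueError(
                    f"{manifest_path}:{lineno}: expected "
                    f"{len(MANIFEST_COLUMNS)} fields, got {len(fields)}"
                )
            pid, fam, sf, fold, fasta_rel, msa_rel, struct_rel = fields
            sequence = _read_single_fasta(base / fasta_rel, pid)
            msa = None
            if msa_rel != "-":
                aln = AlignIO.read(base / msa_rel, "fasta")
                msa = [str(rec.seq) for rec in aln]
            struct_states = None
            if struct_rel != "-":
                struct_states = {
                    rec.id: str(rec.seq)
                    for rec in SeqIO.parse(base / struct_rel, "fasta")
                }
                if not struct_states:
                    raise ValueError(
                        f"{base / struct_rel}: no track records for {pid!r}"
                    )
            proteins.append(
                Protein(pid, sequence, fam, sf, fold, msa, struct_states)
            )
    pairs = enumerate_pairs(proteins) if with_pairs else []
    return BenchmarkDataset(proteins=proteins, pairs=pairs)


def enumerate_lines(fh):
    """(line number, stripped line) for non-empty lines, 2-based."""
    for lineno, raw in enumerate(fh, start=2):
        line = raw.rstrip("\n")
        if line:
            yield lineno, line
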
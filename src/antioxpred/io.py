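"""Readers and writers for FASTA, PSI-BLAST ASCII PSSM, PSI-PRED .ss2 and
feature tables.

PSSM files are the ``-out_ascii_pssm`` dialect: a few header lines, a column
header naming the 20 amino acids twice, then one row per residue carrying the
row index, the residue letter, 20 integer log-odds scores, 20 weighted
observed percentages and two trailing statistics. Only the log-odds block is
retained — those are the substitution scores the features are defined on.

.ss2 files are PSI-PRED VFORMAT: a comment line, a blank line, then
``index residue state pC pH pE`` rows; the (C, H, E) probability column order
of the file is preserved in :class:`~antioxpred.types.SSProfile`.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AA_ORDER, SS_STATES
from .types import FeatureTable, FormatError, ProteinRecord, PSSMProfile, SSProfile

PathLike = str | os.PathLike

FEATURE_TABLE_DIALECTS = ("csv", "sparse")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Read a FASTA file into validated protein records.

    Sequences are upper-cased; record order is preserved. A record containing
    a residue outside the 20-letter alphabet (e.g. B, X, Z) raises
    :class:`ValidationError` naming the record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ProteinRecord], path: PathLike) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM

def _is_pssm_row(tokens: list[str]) -> bool:
    return (
        len(tokens) >= 2
        and tokens[0].isdigit()
        and len(tokens[1]) == 1
        and tokens[1].isalpha()
    )


def read_pssm(path: PathLike, protein_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM, keeping the 20-column log-odds block.

    Raises :class:`FormatError` with the 1-based line number for a row with
    fewer than 20 parsable scores, and for an empty body.
    """
    pid = protein_id or Path(path).stem
    scores: list[list[float]] = []
    residues: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not _is_pssm_row(tokens):
                continue
            raw = tokens[2:22]
            row: list[float] = []
            for tok in raw:
                try:
                    row.append(float(tok))
                except ValueError:
                    break
            if len(row) < 20:
                raise FormatError(
                    f"{path}:{lineno}: expected 20 log-odds scores, "
                    f"found {len(row)} parsable values"
                )
            scores.append(row)
            residues.append(tokens[1].upper())
    if not scores:
        raise FormatError(f"{path}: no PSSM score rows found")
    return PSSMProfile(protein_id=pid, scores=np.array(scores), sequence="".join(residues))


def write_pssm(profile: PSSMProfile, path: PathLike) -> None:
    """Write a profile in the PSI-BLAST ASCII layout read by :func:`read_pssm`.

    The weighted-percentage block is emitted as zeros; only the log-odds
    block carries information.
    """
    seq = profile.sequence or "A" * profile.length
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        header = " ".join(f"{aa:>3}" for aa in AA_ORDER)
        fh.write(f"          {header}  {header}\n")
        for i in range(profile.length):
            odds = " ".join(f"{int(round(v)):>3d}" for v in profile.scores[i])
            pcts = " ".join(f"{0:>3d}" for _ in range(20))
            fh.write(f"{i + 1:>5d} {seq[i]}  {odds}  {pcts}  0.00 0.00\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# PSI-PRED .ss2

def read_ss2(path: PathLike, protein_id: str | None = None) -> SSProfile:
    """Parse a PSI-PRED VFORMAT .ss2 file.

    Each data row is ``index residue state pC pH pE``; the probability column
    order (C, H, E) is stored as-is. An unknown state letter or a row-index
    discontinuity raises :class:`FormatError`.
    """
    pid = protein_id or Path(path).stem
    states: list[str] = []
    probs: list[list[float]] = []
    expected_idx = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 'index residue state pC pH pE', "
                    f"got {len(tokens)} fields"
                )
            try:
                idx = int(tokens[0])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad row index {tokens[0]!r}") from None
            if idx != expected_idx:
                raise FormatError(
                    f"{path}:{lineno}: row index {idx}, expected {expected_idx}"
                )
            state = tokens[2]
            if state not in SS_STATES:
                raise FormatError(
                    f"{path}:{lineno}: unknown secondary-structure state {state!r} "
                    f"(expected one of {SS_STATES})"
                )
            try:
                row = [float(tokens[3]), float(tokens[4]), float(tokens[5])]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: unparsable probability") from None
            states.append(state)
            probs.append(row)
            expected_idx += 1
    if not states:
        raise FormatError(f"{path}: no .ss2 data rows found")
    return SSProfile(protein_id=pid, states="".join(states), probabilities=np.array(probs))


def write_ss2(
    profile: SSProfile, path: PathLike, sequence: str | None = None
) -> None:
    """Write an .ss2 file in the VFORMAT layout read by :func:`read_ss2`."""
    seq = sequence or "A" * profile.length
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (antioxpred synthetic)\n\n")
        for i, state in enumerate(profile.states):
            c, h, e = profile.probabilities[i]
            fh.write(f"{i + 1:>4d} {seq[i]} {state}  {c:6.3f} {h:6.3f} {e:6.3f}\n")


# ---------------------------------------------------------------------------
# Feature tables

def write_feature_table(table: FeatureTable, path: PathLike, dialect: str = "csv") -> None:
    """Serialize a feature table.

    ``csv``: header ``id,F1..FM,label``, 12 significant digits.
    ``sparse``: libsvm-style ``label j:value ...`` (1-based feature indices,
    zeros omitted) with a leading ``# features=M`` line and the sample id as
    a trailing ``#`` comment.
    """
    if dialect not in FEATURE_TABLE_DIALECTS:
        raise ValueError(f"unknown feature-table dialect {dialect!r}; use one of {FEATURE_TABLE_DIALECTS}")
    if dialect == "csv":
        with open(path, "w") as fh:
            fh.write("id," + ",".join(table.feature_names) + ",label\n")
            for i, sid in enumerate(table.sample_ids):
                vals = ",".join(f"{v:.12g}" for v in table.matrix[i])
                fh.write(f"{sid},{vals},{table.labels[i]}\n")
    else:
        with open(path, "w") as fh:
            fh.write(f"# features={table.n_features}\n")
            for i, sid in enumerate(table.sample_ids):
                row = table.matrix[i]
                nz = np.nonzero(row)[0]
                pairs = " ".join(f"{j + 1}:{row[j]:.12g}" for j in nz)
                fh.write(f"{table.labels[i]} {pairs} # {sid}\n".replace("  #", " #"))


def read_feature_table(path: PathLike, dialect: str | None = None) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`.

    The dialect is sniffed from the first line when not given.
    """
    with open(path) as fh:
        first = fh.readline()
    if dialect is None:
        dialect = "sparse" if first.startswith("# features=") else "csv"
    if dialect not in FEATURE_TABLE_DIALECTS:
        raise ValueError(f"unknown feature-table dialect {dialect!r}; use one of {FEATURE_TABLE_DIALECTS}")
    if dialect == "csv":
        return _read_csv_table(path)
    return _read_sparse_table(path)


def _read_csv_table(path: PathLike) -> FeatureTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        if len(header) < 3 or header[0] != "id" or header[-1] != "label":
            raise FormatError(f"{path}: csv feature table must have 'id,...,label' header")
        names = header[1:-1]
        ids, rows, labels = [], [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(",")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: {len(fields)} fields, expected {len(header)}"
                )
            ids.append(fields[0])
            rows.append([float(v) for v in fields[1:-1]])
            labels.append(int(fields[-1]))
    return FeatureTable(sample_ids=ids, matrix=np.array(rows), labels=np.array(labels),
                        feature_names=names)


def _read_sparse_table(path: PathLike) -> FeatureTable:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# features="):
            raise FormatError(f"{path}: sparse table must start with '# features=M'")
        m = int(first.split("=", 1)[1])
        ids, rows, labels = [], [], []
        for lineno, line in enumerate(fh, start=2):
            stripped = line.strip()
            if not stripped:
                continue
            body, _, comment = stripped.partition("#")
            sid = comment.strip() or f"s{lineno - 1}"
            tokens = body.split()
            if not tokens:
                raise FormatError(f"{path}:{lineno}: missing label")
            try:
                label = int(tokens[0])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad label {tokens[0]!r}") from None
            row = np.zeros(m)
            for tok in tokens[1:]:
                j, _, v = tok.partition(":")
                idx = int(j) - 1
                if not 0 <= idx < m:
                    raise FormatError(
                        f"{path}:{lineno}: feature index {j} outside 1..{m}"
                    )
                row[idx] = float(v)
            ids.append(sid)
            rows.append(row)
            labels.append(label)
    return FeatureTable(sample_ids=ids, matrix=np.array(rows), labels=np.array(labels))


# ---------------------------------------------------------------------------
# Consistency

def check_consistency(
    record: ProteinRecord, pssm: PSSMProfile, ss: SSProfile
) -> None:
    """Require PSSM and .ss2 content to match the FASTA record exactly.

    Length or residue mismatches are errors, not warnings: a profile computed
    for a different sequence silently corrupts every downstream feature.
    """
    if pssm.length != len(record):
        raise FormatError(
            f"{record.id}: sequence length {len(record)} but PSSM has {pssm.length} rows"
        )
    if pssm.sequence and pssm.sequence != record.sequence:
        raise FormatError(f"{record.id}: PSSM residue string differs from FASTA sequence")
    if ss.length != len(record):
        raise FormatError(
            f"{record.id}: sequence length {len(record)} but .ss2 has {ss.length} rows"
        )
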
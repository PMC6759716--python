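"""Domain types shared across the package.

The central objects are per-protein profiles (a PSSM and a secondary-structure
profile) and the N x M feature table fed to selection and classification.
Validation happens at construction; downstream code may assume invariants hold.
Sequence positions and matrix rows are 1-based in documentation and error
messages; storage is ordinary 0-based numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_ORDER, SS_PROB_ORDER, SS_STATES


class ValidationError(ValueError):
    """Input violates a domain invariant."""


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20-letter amino-acid alphabet.

    Records containing ambiguous residues (B/X/Z or anything outside
    ``ARNDCQEGHILKMFPSTWYV``) are rejected, mirroring the benchmark filter
    that drops sequences of uncertain composition.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record has an empty identifier")
        if len(self.sequence) < 1:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = sorted({c for c in self.sequence if c not in AA_ORDER})
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal residue(s) {''.join(bad)} "
                f"(allowed: {AA_ORDER})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PSSMProfile:
    """L x 20 position-specific scoring matrix (log-odds block).

    ``scores[i, n]`` is the substitution score of sequence position i+1
    mutating to the n-th amino acid of ``ARNDCQEGHILKMFPSTWYV``.
    """

    protein_id: str
    scores: np.ndarray
    sequence: str = ""

    alphabet_order = AA_ORDER

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValidationError(
                f"PSSM for {self.protein_id!r}: expected L x 20 scores, got {scores.shape}"
            )
        if scores.shape[0] < 1:
            raise ValidationError(f"PSSM for {self.protein_id!r}: no rows")
        if not np.all(np.isfinite(scores)):
            raise ValidationError(f"PSSM for {self.protein_id!r}: non-finite entries")
        if self.sequence and len(self.sequence) != scores.shape[0]:
            raise ValidationError(
                f"PSSM for {self.protein_id!r}: {len(self.sequence)} residues "
                f"but {scores.shape[0]} score rows"
            )

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class SSProfile:
    """Per-residue secondary-structure states and 3-state probabilities.

    ``states`` is a string over H (helix), E (strand), C (coil).
    ``probabilities`` has one row per residue in column order (C, H, E), as
    printed in PSI-PRED .ss2 files. Rows need not sum exactly to 1 because
    the file format rounds to three decimals; sums must lie in [0.9, 1.1].
    """

    protein_id: str
    states: str
    probabilities: np.ndarray

    prob_order = SS_PROB_ORDER

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", probs)
        bad = sorted({c for c in self.states if c not in SS_STATES})
        if bad:
            raise ValidationError(
                f"SS profile for {self.protein_id!r}: unknown state(s) {''.join(bad)}"
            )
        if probs.ndim != 2 or probs.shape[1] != 3:
            raise ValidationError(
                f"SS profile for {self.protein_id!r}: expected L x 3 probabilities, "
                f"got {probs.shape}"
            )
        if len(self.states) != probs.shape[0]:
            raise ValidationError(
                f"SS profile for {self.protein_id!r}: {len(self.states)} states but "
                f"{probs.shape[0]} probability rows"
            )
        if np.any(probs < 0):
            raise ValidationError(f"SS profile for {self.protein_id!r}: negative probability")
        sums = probs.sum(axis=1)
        off = np.where((sums < 0.9) | (sums > 1.1))[0]
        if off.size:
            raise ValidationError(
                f"SS profile for {self.protein_id!r}: probability row {off[0] + 1} "
                f"sums to {sums[off[0]]:.3f}, outside [0.9, 1.1]"
            )

    @property
    def length(self) -> int:
        return len(self.states)


@dataclass
class FeatureTable:
    """N samples x M features with aligned 0/1 labels."""

    sample_ids: list[str]
    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValidationError(f"feature matrix must be 2-D, got shape {self.matrix.shape}")
        n, m = self.matrix.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids but {n} feature rows"
            )
        if self.labels.shape != (n,):
            raise ValidationError(
                f"label vector length {self.labels.shape} does not match {n} samples"
            )
        if not np.all(np.isin(self.labels, [0, 1])):
            raise ValidationError("labels must contain only 0 and 1")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("feature matrix contains missing/non-finite values")
        if not self.feature_names:
            self.feature_names = [f"F{j + 1}" for j in range(m)]
        elif len(self.feature_names) != m:
            raise ValidationError(
                f"{len(self.feature_names)} feature names but {m} columns"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def select_features(self, indices: np.ndarray | list[int]) -> "FeatureTable":
        """Column-subset view (copy) preserving sample ids and labels."""
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            sample_ids=list(self.sample_ids),
            matrix=self.matrix[:, idx].copy(),
            labels=self.labels.copy(),
            feature_names=[self.feature_names[j] for j in idx],
        )
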
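"""The 473-dimension profile feature vector.

One protein contributes 473 features computed from its PSSM and its
secondary-structure profile, laid out in a fixed block order:

========  =====  ==================================================
positions  size  block
========  =====  ==================================================
1-20         20  weighted 1-gram frequencies of the consensus sequence
21-420      400  weighted 2-gram frequencies of the consensus sequence
421-440      20  per-column PSSM means (A first, V last)
441-446       6  secondary-structure sequence scores
                 (F_H, F_C, F_E, F_Max_H, F_Max_E, F_freq_bab)
447-470      24  local 3-state probability means (8 blocks x (C,H,E))
471-473       3  global 3-state probability means (C, H, E)
========  =====  ==================================================

The consensus sequence replaces each residue by the amino acid maximizing
the background-weighted exponentiated PSSM score ``2**(p * bf)`` in its row;
n-grams are counted on that consensus, not on the original sequence. The
1-gram and 2-gram blocks are rescaled by 20/420 and 400/420 so the combined
420 values sum to 1 whenever each raw block does.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabet import AA_INDEX, AA_ORDER, ROBINSON_ROBINSON, validate_background
from .types import FeatureTable, PSSMProfile, SSProfile, ProteinRecord, ValidationError

N_FEATURES = 473

#: (name, size) of the blocks in vector order.
BLOCK_LAYOUT = (
    ("one_gram", 20),
    ("two_gram", 400),
    ("pssm", 20),
    ("ss_sequence", 6),
    ("prob_local", 24),
    ("prob_global", 3),
)

ONE_GRAM_WEIGHT = 20 / 420
TWO_GRAM_WEIGHT = 400 / 420


def feature_names() -> list[str]:
    """``F1`` ... ``F473`` so that F421 is the A-column PSSM mean."""
    return [f"F{j + 1}" for j in range(N_FEATURES)]


# ---------------------------------------------------------------------------
# PSSM-derived blocks

def compute_fpssm(profile: PSSMProfile) -> np.ndarray:
    """Column means of the PSSM: the average substitution score toward each
    of the 20 residues over the whole sequence."""
    return profile.scores.mean(axis=0)


def compute_frequency_matrix(
    profile: PSSMProfile, bf: np.ndarray | None = None
) -> np.ndarray:
    """Elementwise ``2 ** (p[i, n] * bf[n])``.

    Entries are strictly positive and equal 1 wherever the score is 0.
    """
    bf = validate_background(ROBINSON_ROBINSON if bf is None else bf)
    return np.exp2(profile.scores * bf[np.newaxis, :])


def derive_consensus(freq: np.ndarray) -> str:
    """Row-wise argmax letter of the frequency matrix.

    Ties go to the first letter in alphabet order A..V (numpy argmax keeps
    the first maximal column).
    """
    freq = np.asarray(freq, dtype=float)
    if freq.ndim != 2 or freq.shape[1] != 20:
        raise ValidationError(f"frequency matrix must be L x 20, got {freq.shape}")
    return "".join(AA_ORDER[j] for j in freq.argmax(axis=1))


def compute_one_gram(seq: str) -> np.ndarray:
    """Residue frequencies O(a)/L in alphabet order; sums to 1."""
    if len(seq) < 1:
        raise ValidationError("1-gram requires a non-empty sequence")
    counts = np.zeros(20)
    for c in seq:
        counts[AA_INDEX[c]] += 1
    return counts / len(seq)


def compute_two_gram(seq: str) -> np.ndarray:
    """Overlapping adjacent-pair frequencies O(ab)/(L-1), row-major over the
    alphabet (AA, AR, ..., AV, RA, ..., VV); sums to 1."""
    if len(seq) < 2:
        raise ValidationError("2-gram requires a sequence of length >= 2")
    counts = np.zeros((20, 20))
    for a, b in zip(seq, seq[1:]):
        counts[AA_INDEX[a], AA_INDEX[b]] += 1
    return counts.ravel() / (len(seq) - 1)


def weight_ngrams(one_gram: np.ndarray, two_gram: np.ndarray) -> np.ndarray:
    """Proportionally weight the raw n-gram blocks into one 420-vector:
    1-gram entries by 20/420, 2-gram entries by 400/420."""
    one_gram = np.asarray(one_gram, dtype=float)
    two_gram = np.asarray(two_gram, dtype=float)
    if one_gram.shape != (20,) or two_gram.shape != (400,):
        raise ValidationError(
            f"expected 20 + 400 n-gram values, got {one_gram.shape} + {two_gram.shape}"
        )
    return np.concatenate([one_gram * ONE_GRAM_WEIGHT, two_gram * TWO_GRAM_WEIGHT])


# ---------------------------------------------------------------------------
# Secondary-structure sequence block

@dataclass(frozen=True)
class SSFeatureSet:
    """Six secondary-structure sequence scores plus their intermediates.

    The position scores F_H/F_E/F_C sum the 1-based positions of each state
    and divide by L(L-1); they are not bounded by 1 (an all-coil sequence
    gives F_C = (L+1)/(2(L-1))). F_Max_H and F_Max_E are longest-run
    fractions in [0, 1]. F_freq_bab counts overlapping beta-alpha-beta
    windows of the segment sequence and divides by L-2.
    """

    f_h: float
    f_c: float
    f_e: float
    f_max_h: float
    f_max_e: float
    f_freq_bab: float
    count_h: int
    count_e: int
    count_c: int
    posi_h: int
    posi_e: int
    posi_c: int
    max_length_h: int
    max_length_e: int
    count_bab: int
    segment: str

    def as_vector(self) -> np.ndarray:
        """Vector order (F_H, F_C, F_E, F_Max_H, F_Max_E, F_freq_bab)."""
        return np.array(
            [self.f_h, self.f_c, self.f_e, self.f_max_h, self.f_max_e, self.f_freq_bab]
        )


def segment_sequence(states: str) -> str:
    """Collapse maximal H runs to alpha and E runs to beta, dropping coils.

    ``EECCCHHHEEECHHHEECCEE`` becomes ``βαβαββ``.
    """
    out = []
    for state, _run in groupby(states):
        if state == "H":
            out.append("α")
        elif state == "E":
            out.append("β")
    return "".join(out)


def _longest_run(states: str, state: str) -> int:
    return max((sum(1 for _ in run) for s, run in groupby(states) if s == state), default=0)


def compute_ss_sequence_features(states: str) -> SSFeatureSet:
    if len(states) < 3:
        raise ValidationError(
            f"secondary-structure features need L >= 3, got L={len(states)}"
        )
    bad = sorted({c for c in states if c not in "HEC"})
    if bad:
        raise ValidationError(f"unknown secondary-structure state(s) {''.join(bad)}")
    L = len(states)
    posi = {"H": 0, "E": 0, "C": 0}
    count = {"H": 0, "E": 0, "C": 0}
    for i, s in enumerate(states, start=1):
        posi[s] += i
        count[s] += 1
    denom = L * (L - 1)
    segment = segment_sequence(states)
    count_bab = sum(
        1 for i in range(len(segment) - 2) if segment[i : i + 3] == "βαβ"
    )
    return SSFeatureSet(
        f_h=posi["H"] / denom,
        f_c=posi["C"] / denom,
        f_e=posi["E"] / denom,
        f_max_h=_longest_run(states, "H") / L,
        f_max_e=_longest_run(states, "E") / L,
        f_freq_bab=count_bab / (L - 2),
        count_h=count["H"],
        count_e=count["E"],
        count_c=count["C"],
        posi_h=posi["H"],
        posi_e=posi["E"],
        posi_c=posi["C"],
        max_length_h=_longest_run(states, "H"),
        max_length_e=_longest_run(states, "E"),
        count_bab=count_bab,
        segment=segment,
    )


# ---------------------------------------------------------------------------
# Probability-matrix block

def compute_prob_features(probabilities: np.ndarray, lam: int = 8) -> np.ndarray:
    """27 values from the L x 3 state-probability matrix.

    The matrix is split into ``lam`` contiguous row blocks whose sizes differ
    by at most one (larger blocks first); each block contributes its three
    column means (C, H, E). Output is the 24 local values in block order
    followed by the 3 global column means.
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 3:
        raise ValidationError(f"probability matrix must be L x 3, got {probs.shape}")
    if lam < 1:
        raise ValidationError(f"lambda must be positive, got {lam}")
    L = probs.shape[0]
    if L < lam:
        raise ValidationError(f"probability features need L >= lambda ({lam}), got L={L}")
    # np.array_split gives contiguous near-equal blocks, larger first
    local = np.concatenate([block.mean(axis=0) for block in np.array_split(probs, lam)])
    global_ = probs.mean(axis=0)
    return np.concatenate([local, global_])


# ---------------------------------------------------------------------------
# Assembly

def assemble_feature_vector(
    weighted_ngrams: np.ndarray,
    fpssm: np.ndarray,
    ss_features: SSFeatureSet | np.ndarray,
    prob_features: np.ndarray,
) -> np.ndarray:
    """Concatenate the blocks into the fixed vector order.

    The probability block has 3*lambda + 3 values; at the default lambda = 8
    the full vector has exactly 473 entries.
    """
    ss_vec = ss_features.as_vector() if isinstance(ss_features, SSFeatureSet) else np.asarray(ss_features, dtype=float)
    prob = np.asarray(prob_features, dtype=float)
    parts = {
        "weighted n-grams": (np.asarray(weighted_ngrams, dtype=float), 420),
        "PSSM means": (np.asarray(fpssm, dtype=float), 20),
        "SS sequence scores": (ss_vec, 6),
    }
    for name, (arr, size) in parts.items():
        if arr.shape != (size,):
            raise ValidationError(f"{name}: expected {size} values, got shape {arr.shape}")
    if prob.ndim != 1 or prob.size < 6 or prob.size % 3 != 0:
        raise ValidationError(
            f"probability features: expected 3*lambda + 3 values, got shape {prob.shape}"
        )
    vec = np.concatenate([arr for arr, _ in parts.values()] + [prob])
    assert prob.size != 27 or vec.shape == (N_FEATURES,)
    return vec


def compute_feature_vector(
    pssm: PSSMProfile,
    ss: SSProfile,
    bf: np.ndarray | None = None,
    lam: int = 8,
) -> np.ndarray:
    """Full 473-feature vector for one protein."""
    if pssm.length != ss.length:
        raise ValidationError(
            f"{pssm.protein_id}: PSSM has {pssm.length} rows but SS profile has {ss.length}"
        )
    freq = compute_frequency_matrix(pssm, bf)
    consensus = derive_consensus(freq)
    weighted = weight_ngrams(compute_one_gram(consensus), compute_two_gram(consensus))
    return assemble_feature_vector(
        weighted,
        compute_fpssm(pssm),
        compute_ss_sequence_features(ss.states),
        compute_prob_features(ss.probabilities, lam=lam),
    )


def extract_features(
    triplets: list[tuple[ProteinRecord, PSSMProfile, SSProfile]],
    labels: list[int] | np.ndarray,
    bf: np.ndarray | None = None,
    lam: int = 8,
) -> FeatureTable:
    """Featurize a batch of (record, PSSM, SS) triplets into an N x 473 table.

    Each protein is processed independently; any per-protein failure aborts
    with the protein id attached.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (len(triplets),):
        raise ValidationError(
            f"{len(triplets)} proteins but {labels.shape} labels"
        )
    rows, ids = [], []
    for record, pssm, ss in triplets:
        if len(record) != pssm.length or len(record) != ss.length:
            raise ValidationError(
                f"{record.id}: sequence length {len(record)} does not match "
                f"profiles (PSSM {pssm.length}, SS {ss.length})"
            )
        try:
            rows.append(compute_feature_vector(pssm, ss, bf=bf, lam=lam))
        except ValidationError as exc:
            raise ValidationError(f"{record.id}: {exc}") from exc
        ids.append(record.id)
    return FeatureTable(
        sample_ids=ids,
        matrix=np.array(rows),
        labels=labels,
        feature_names=feature_names(),
    )


class ProfileFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer from profile triplets to the 473-feature matrix.

    Parameters
    ----------
    bf : array-like of shape (20,), optional
        Amino-acid background frequencies in alphabet order; defaults to the
        Robinson-Robinson composition.
    lam : int, default 8
        Number of contiguous blocks for the local probability features.
    """

    def __init__(self, bf: np.ndarray | None = None, lam: int = 8):
        self.bf = bf
        self.lam = lam

    def fit(self, X, y=None):
        validate_background(ROBINSON_ROBINSON if self.bf is None else np.asarray(self.bf))
        self.n_features_out_ = N_FEATURES
        return self

    def transform(self, X) -> np.ndarray:
        """X is a list of (ProteinRecord, PSSMProfile, SSProfile) triplets."""
        rows = [
            compute_feature_vector(pssm, ss, bf=self.bf, lam=self.lam)
            for _record, pssm, ss in X
        ]
        return np.array(rows).reshape(len(rows), N_FEATURES)

    def get_feature_names_out(self, input_features=None):
        return np.array(feature_names())
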
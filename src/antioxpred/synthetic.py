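"""Seeded synthetic PSSM / secondary-structure profile pairs.

Real inputs to this package come from PSI-BLAST (a log-odds PSSM) and a
secondary-structure predictor (per-residue H/E/C states with probabilities).
This module emulates both so every stage is testable without either tool or
any database:

* sequences are drawn from the Robinson-Robinson residue composition;
* PSSM scores are integer-rounded Gaussian draws in the typical log-odds
  range [-8, 12], centered higher on the column matching the sequence
  residue (conservation) — positives additionally get their means shifted
  by ``effect_size`` on the designated ``signal_columns``;
* states follow a 3-state Markov chain with realistic run persistence —
  positives get excess helix propensity controlled by ``ss_bias``;
* state probabilities are consistent with the sampled state (the sampled
  state always receives the largest probability).

Every profile is fully reproducible from ``(seed, label, index)``: each
protein owns an independent random stream, so datasets are order-independent
and the two classes are generated by identical processes whenever
``effect_size == 0`` and ``ss_bias == 0`` (see :func:`class_params`).

The default sample counts follow the 1:6 positive:negative imbalance of the
curated antioxidant benchmark this kind of classifier is trained on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import AA_ORDER, ROBINSON_ROBINSON, SS_PROB_ORDER
from .io import write_fasta, write_pssm, write_ss2
from .types import ProteinRecord, PSSMProfile, SSProfile, ValidationError

SCORE_MIN, SCORE_MAX = -8, 12
SCORE_SD = 2.5
MATCH_BONUS = 3.0  # mean lift on the column matching the sequence residue

# transition rows/cols in SS_PROB_ORDER = (C, H, E); diagonal persistence
# gives helix/strand run lengths of a few residues, like real predictions
_BASE_TRANSITION = np.array(
    [
        [0.70, 0.15, 0.15],  # from C
        [0.12, 0.85, 0.03],  # from H
        [0.16, 0.04, 0.80],  # from E
    ]
)
_BASE_INITIAL = np.array([0.50, 0.30, 0.20])


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``effect_size`` is the mean shift (in score units) applied to
    ``signal_columns`` of positive-class PSSMs; ``ss_bias`` in [0, 1] mixes
    the positives' state chain toward helix. Zero effect and zero bias make
    the two classes exchangeable.
    """

    seed: int = 0
    n_pos: int = 10
    n_neg: int = 60
    length_range: tuple[int, int] = (50, 120)
    effect_size: float = 4.0
    ss_bias: float = 0.3
    signal_columns: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValidationError("sample counts must be >= 1")
        lo, hi = self.length_range
        if lo < 8 or hi < lo:
            raise ValidationError(
                f"length range must satisfy 8 <= L_min <= L_max, got {self.length_range}"
            )
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if not 0 <= self.ss_bias <= 1:
            raise ValidationError("ss_bias must lie in [0, 1]")
        if any(not 0 <= c < 20 for c in self.signal_columns):
            raise ValidationError("signal_columns must index the 20 PSSM columns")


def class_params(
    config: SyntheticConfig, label: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class-conditional generating parameters.

    Returns ``(column_shift, transition, initial)``: the per-column PSSM mean
    shift, the state transition matrix and the initial state distribution.
    For ``effect_size == 0`` and ``ss_bias == 0`` the two labels yield
    identical parameters — the classes are the same process.
    """
    shift = np.zeros(20)
    if label == 1 and config.effect_size > 0:
        shift[list(config.signal_columns)] = config.effect_size
    bias = config.ss_bias if label == 1 else 0.0
    helix = np.array([0.0, 1.0, 0.0])  # one-hot H in (C, H, E) order
    transition = (1 - bias) * _BASE_TRANSITION + bias * helix[np.newaxis, :]
    initial = (1 - bias) * _BASE_INITIAL + bias * helix
    return shift, transition, initial


def _rng_for(config: SyntheticConfig, label: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(int(label), int(index)))
    )


def generate_profile_pair(
    config: SyntheticConfig, label: int, index: int
) -> tuple[ProteinRecord, PSSMProfile, SSProfile]:
    """One (record, PSSM, SS profile) triplet, reproducible from
    ``(seed, label, index)``."""
    if label not in (0, 1):
        raise ValidationError(f"label must be 0 or 1, got {label}")
    rng = _rng_for(config, label, index)
    shift, transition, initial = class_params(config, label)

    lo, hi = config.length_range
    L = int(rng.integers(lo, hi + 1))
    residues = rng.choice(list(AA_ORDER), size=L, p=ROBINSON_ROBINSON / ROBINSON_ROBINSON.sum())
    sequence = "".join(residues)

    means = np.full((L, 20), -1.0) + shift[np.newaxis, :]
    for i, aa in enumerate(sequence):
        means[i, AA_ORDER.index(aa)] += MATCH_BONUS + 1.0
    scores = np.clip(np.rint(rng.normal(means, SCORE_SD)), SCORE_MIN, SCORE_MAX)

    state_idx = np.empty(L, dtype=int)
    state_idx[0] = rng.choice(3, p=initial)
    for i in range(1, L):
        state_idx[i] = rng.choice(3, p=transition[state_idx[i - 1]])
    states = "".join(SS_PROB_ORDER[s] for s in state_idx)

    probs = np.empty((L, 3))
    top = rng.uniform(0.55, 0.95, size=L)
    split = rng.uniform(0.0, 1.0, size=L)
    for i, s in enumerate(state_idx):
        rest = 1.0 - top[i]
        others = [j for j in range(3) if j != s]
        probs[i, s] = top[i]
        probs[i, others[0]] = rest * split[i]
        probs[i, others[1]] = rest * (1 - split[i])
    probs = np.round(probs, 3)

    pid = f"{'pos' if label else 'neg'}_{index:04d}"
    record = ProteinRecord(id=pid, sequence=sequence)
    pssm = PSSMProfile(protein_id=pid, scores=scores, sequence=sequence)
    ss = SSProfile(protein_id=pid, states=states, probabilities=probs)
    return record, pssm, ss


@dataclass
class SyntheticDataset:
    triplets: list[tuple[ProteinRecord, PSSMProfile, SSProfile]]
    labels: np.ndarray
    config: SyntheticConfig = field(default_factory=SyntheticConfig)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """``n_pos`` positives followed by ``n_neg`` negatives, labels aligned."""
    triplets, labels = [], []
    for i in range(config.n_pos):
        triplets.append(generate_profile_pair(config, 1, i))
        labels.append(1)
    for i in range(config.n_neg):
        triplets.append(generate_profile_pair(config, 0, i))
        labels.append(0)
    return SyntheticDataset(triplets=triplets, labels=np.asarray(labels), config=config)


def write_dataset(dataset: SyntheticDataset, outdir) -> Path:
    """Write FASTA + per-protein .pssm/.ss2 files plus a labels table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = [record for record, _, _ in dataset.triplets]
    write_fasta(records, outdir / "sequences.fasta")
    with open(outdir / "labels.csv", "w") as fh:
        fh.write("id,label\n")
        for (record, pssm, ss), label in zip(dataset.triplets, dataset.labels):
            write_pssm(pssm, outdir / f"{record.id}.pssm")
            write_ss2(ss, outdir / f"{record.id}.ss2", sequence=record.sequence)
            fh.write(f"{record.id},{label}\n")
    return outdir
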
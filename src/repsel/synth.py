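"""Synthetic protein-family generator with labelled, planted structure.

Families are simulated on a star topology: an ancestor is drawn from
background residue frequencies and each member is derived from it by
per-site substitution (BLOSUM62-conditional exchange probabilities, so the
identity/score structure resembles real divergence) and per-site single
residue deletions. Insertions relative to the ancestor are deliberately
not modelled: the first member ("center") is kept identical to the
ancestor and is therefore always the unique longest member, which pins
the planted best representative. With more than one subgroup, each
subgroup gets an intermediate ancestor evolved at double the member rate.

Controlled fractions of members are then overwritten with anomalies:

* ``fragment`` - contiguous truncation to 20-50% of the ancestor length;
* ``lowcomp`` - a homopolymer run (poly-Q/E/S/T) of 0.6x the member
  length inserted at a random position;
* ``tm`` - a 25-residue strongly hydrophobic block overwritten in place;
* ``outlier`` - full replacement with a background-random sequence.

Labels record every planted role; downstream tests treat the labels as
ground truth and never re-derive them.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._scoring import AA, BACKGROUND, blosum62_exchange_probs
from .seqio import FamilyDataset, ProteinSequence

ROLE_CENTER = "center"
ROLE_MEMBER = "member"
ROLE_FRAGMENT = "fragment"
ROLE_LOWCOMP = "lowcomp"
ROLE_TM = "tm"
ROLE_OUTLIER = "outlier"

_HOMOPOLYMER_RESIDUES = "QEST"
_HYDROPHOBIC = "ILVFM"
_TM_BLOCK_LEN = 25
_LOWCOMP_RUN_FACTOR = 0.6


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic family."""

    n_members: int = 30
    ancestor_length: int = 150
    mutation_rate: float = 0.35
    indel_rate: float = 0.02
    n_subgroups: int = 1
    fragment_fraction: float = 0.0
    lowcomp_fraction: float = 0.0
    tm_fraction: float = 0.0
    outlier_fraction: float = 0.0
    rng_seed: int = 0
    family_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_members < 4:
            raise ValueError("n_members must be >= 4")
        if self.ancestor_length < 10:
            raise ValueError("ancestor_length must be >= 10")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be in [0, 1]")
        if self.n_subgroups < 1:
            raise ValueError("n_subgroups must be >= 1")
        total = (
            self.fragment_fraction
            + self.lowcomp_fraction
            + self.tm_fraction
            + self.outlier_fraction
        )
        for f in (
            self.fragment_fraction,
            self.lowcomp_fraction,
            self.tm_fraction,
            self.outlier_fraction,
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError("anomaly fractions must be in [0, 1]")
        if total > 0.5:
            raise ValueError("sum of planted-anomaly fractions must be <= 0.5")


def _draw_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(20, size=length, p=BACKGROUND)


def _mutate(
    rng: np.random.Generator,
    template: np.ndarray,
    mutation_rate: float,
    deletion_rate: float,
) -> np.ndarray:
    exch = blosum62_exchange_probs()
    out = template.copy()
    if mutation_rate > 0:
        hit = rng.random(out.shape[0]) < mutation_rate
        for pos in np.nonzero(hit)[0]:
            out[pos] = rng.choice(20, p=exch[out[pos]])
    if deletion_rate > 0:
        keep = rng.random(out.shape[0]) >= deletion_rate
        if keep.sum() >= 10:  # never delete a member down to nothing
            out = out[keep]
    return out


def _to_str(idx: np.ndarray) -> str:
    return "".join(AA[i] for i in idx)


def generate_family(spec: FamilySpec) -> tuple[FamilyDataset, dict[str, str]]:
    """Simulate a family; returns the dataset and a member-id -> role map."""
    rng = np.random.default_rng(spec.rng_seed)
    ancestor = _draw_sequence(rng, spec.ancestor_length)

    subgroup_roots = [ancestor]
    for _ in range(1, spec.n_subgroups):
        subgroup_roots.append(
            _mutate(rng, ancestor, min(1.0, 2.0 * spec.mutation_rate), 0.0)
        )

    n = spec.n_members
    width = max(3, len(str(n - 1)))
    ids = [f"{spec.family_id}_m{i:0{width}d}" for i in range(n)]
    seqs: list[np.ndarray] = []
    labels: dict[str, str] = {}
    for i in range(n):
        if i == 0:
            seqs.append(ancestor.copy())
            labels[ids[0]] = ROLE_CENTER
            continue
        root = subgroup_roots[i % spec.n_subgroups]
        seqs.append(_mutate(rng, root, spec.mutation_rate, spec.indel_rate))
        labels[ids[i]] = ROLE_MEMBER

    counts = {
        ROLE_FRAGMENT: round(spec.fragment_fraction * n),
        ROLE_LOWCOMP: round(spec.lowcomp_fraction * n),
        ROLE_TM: round(spec.tm_fraction * n),
        ROLE_OUTLIER: round(spec.outlier_fraction * n),
    }
    total_anomalies = sum(counts.values())
    if total_anomalies:
        chosen = rng.choice(np.arange(1, n), size=total_anomalies, replace=False)
        it = iter(int(c) for c in chosen)
        for role, k in counts.items():
            for _ in range(k):
                idx = next(it)
                seqs[idx] = _plant(rng, seqs[idx], role, spec)
                labels[ids[idx]] = role

    members = [ProteinSequence(ids[i], _to_str(seqs[i])) for i in range(n)]
    return FamilyDataset(spec.family_id, members), labels


def _plant(
    rng: np.random.Generator, seq: np.ndarray, role: str, spec: FamilySpec
) -> np.ndarray:
    if role == ROLE_FRAGMENT:
        frac = rng.uniform(0.2, 0.5)
        length = max(10, int(round(frac * spec.ancestor_length)))
        length = min(length, seq.shape[0])
        start = int(rng.integers(0, seq.shape[0] - length + 1))
        return seq[start : start + length]
    if role == ROLE_LOWCOMP:
        run_len = math.ceil(_LOWCOMP_RUN_FACTOR * seq.shape[0])
        residue = AA.index(rng.choice(list(_HOMOPOLYMER_RESIDUES)))
        pos = int(rng.integers(0, seq.shape[0] + 1))
        run = np.full(run_len, residue, dtype=seq.dtype)
        return np.concatenate([seq[:pos], run, seq[pos:]])
    if role == ROLE_TM:
        out = seq.copy()
        if out.shape[0] <= _TM_BLOCK_LEN:
            start = 0
            block_len = out.shape[0]
        else:
            start = int(rng.integers(0, out.shape[0] - _TM_BLOCK_LEN + 1))
            block_len = _TM_BLOCK_LEN
        block = rng.choice([AA.index(c) for c in _HYDROPHOBIC], size=block_len)
        out[start : start + block_len] = block
        return out
    if role == ROLE_OUTLIER:
        # uniform over the 20 residues: no family signal, no composition bias
        return rng.integers(0, 20, size=seq.shape[0])
    raise ValueError(f"unknown planted role {role!r}")


def generate_decoys(
    n: int, dataset: FamilyDataset, rng_seed: int, prefix: str = "decoy"
) -> FamilyDataset:
    """Residue-shuffled copies of randomly chosen dataset members."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    members: list[ProteinSequence] = []
    for i in range(n):
        src = dataset.members[int(rng.integers(0, len(dataset)))]
        shuffled = "".join(rng.permutation(list(src.residues)))
        members.append(ProteinSequence(f"{prefix}{i:04d}", shuffled))
    return FamilyDataset(f"{dataset.family_id}_decoys", members)
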
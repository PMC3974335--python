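"""Iterative PSSM profile construction, search and E-value calibration.

A candidate seed is turned into a family profile by iterative search:
round one scores the search set with a single-sequence PSSM built from the
seed; targets passing the inclusion E-value are globally re-aligned to the
seed and merged into the profile alignment (the seed's coordinate system
is the master — seed-gap columns are dropped); the PSSM is rebuilt and the
search repeated, for up to three rounds or until the hit set stops
growing. Included hits accumulate across rounds.

Scores are log-odds in bits with Henikoff position-based sequence weights
and a background pseudocount blend::

    f' = (N_eff * f + b * g) / (N_eff + b),     score = log2(f' / g)

where ``g`` is the background distribution, ``b`` the pseudocount weight
and ``N_eff`` the mean number of distinct residue types per column.

E-values come from a per-profile decoy calibration: residue-shuffled
copies of search-set sequences are scored, their best local-alignment bit
scores are fitted to a Gumbel distribution by maximum likelihood, and

    E(S) = k * L_profile * N_db * 2**(-lambda * S)

with ``lambda = 1 / (beta * ln 2)`` and ``k`` chosen so that E at the
fitted Gumbel location equals the number of database sequences. This is
valid for arbitrary PSSMs and gap settings, and deterministic under a
fixed RNG seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import _align
from ._scoring import AA, BACKGROUND, GAP_EXTEND, GAP_OPEN, encode
from .pairwise import global_align
from .seqio import FamilyDataset, ProteinSequence, write_stockholm
from .synth import generate_decoys

DEFAULT_PSEUDOCOUNT = 5.0
DEFAULT_INCLUSION_EVALUE = 1e-3
DEFAULT_ITERATIONS = 3
DEFAULT_N_DECOYS = 200
SCORE_FLOOR = -10.0
_LN2 = math.log(2.0)


class CalibrationError(RuntimeError):
    pass


@dataclass
class Pssm:
    """Position-specific log-odds scores (bits) over the 20 amino acids."""

    seed_id: str
    scores: np.ndarray  # (L, 20) bits
    probs: np.ndarray  # (L, 20) pseudocount-blended frequencies f'
    background: np.ndarray  # (20,)
    pseudocount_weight: float

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("scores must be (L, 20)")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        if abs(self.background.sum() - 1.0) > 1e-9 or (self.background <= 0).any():
            raise ValueError("background must be positive and sum to 1")

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])

    def scores_with_x(self) -> np.ndarray:
        """(L, 21) score matrix where the X column scores 0 bits."""
        out = np.zeros((self.length, 21))
        out[:, :20] = self.scores
        return out

    def to_tsv(self, path: str | Path, seed_residues: str | None = None) -> Path:
        cols = {"position": np.arange(1, self.length + 1)}
        if seed_residues is not None:
            cols["seed_residue"] = list(seed_residues)
        for j, aa in enumerate(AA):
            cols[aa] = self.scores[:, j]
        pd.DataFrame(cols).to_csv(
            path, sep="\t", index=False, float_format="%.4f"
        )
        return Path(path)


@dataclass
class Calibration:
    """Gumbel E-value parameters fitted from shuffled decoys."""

    lambda_hat: float  # per bit
    k_hat: float
    n_decoys: int
    decoy_seed: int
    db_residues: int
    db_sequences: int
    mu_hat: float = 0.0
    beta_hat: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_hat <= 0 or self.k_hat <= 0:
            raise ValueError("lambda_hat and k_hat must be positive")
        if self.n_decoys < 50:
            raise ValueError("n_decoys must be >= 50")

    def evalue(self, bit_score: float, profile_length: int) -> float:
        log2_e = (
            math.log2(self.k_hat)
            + math.log2(profile_length)
            + math.log2(max(self.db_residues, 1))
            - self.lambda_hat * bit_score
        )
        # clamp to avoid under/overflow on extreme scores
        return float(2.0 ** min(max(log2_e, -900.0), 900.0))


@dataclass
class Hit:
    target_id: str
    bit_score: float
    e_value: float
    seed_start: int
    seed_end: int
    target_start: int
    target_end: int

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if self.seed_start > self.seed_end or self.target_start > self.target_end:
            raise ValueError("aligned region start must be <= end")


@dataclass
class SeedAlignment:
    """Gapped rows in seed coordinates; the seed row comes first."""

    seed_id: str
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.ids or self.ids[0] != self.seed_id:
            raise ValueError("first alignment row must be the seed")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("ragged alignment rows")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def to_stockholm(self, path: str | Path) -> Path:
        return write_stockholm(list(zip(self.ids, self.rows)), path)


@dataclass
class Profile:
    """A calibrated PSSM plus the hit alignment it was built from."""

    pssm: Pssm
    calibration: Calibration
    hit_alignment: SeedAlignment
    iteration: int
    enriched: bool = False
    history: list[int] = field(default_factory=list)

    @property
    def seed_id(self) -> str:
        return self.pssm.seed_id

    @property
    def length(self) -> int:
        return self.pssm.length


def henikoff_weights(rows: list[str]) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights, normalized.

    Gaps and X do not contribute. Columns with no scorable residue are
    skipped; a fully degenerate alignment falls back to uniform weights.
    """
    n = len(rows)
    if n == 1:
        return np.ones(1)
    width = len(rows[0])
    w = np.zeros(n)
    for col in range(width):
        residues = [row[col] for row in rows]
        counts: dict[str, int] = {}
        for ch in residues:
            if ch not in "-X":
                counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        if r == 0:
            continue
        for i, ch in enumerate(residues):
            if ch in counts:
                w[i] += 1.0 / (r * counts[ch])
    total = w.sum()
    if total <= 0:
        return np.full(n, 1.0 / n)
    return w / total


def build_pssm(
    seed: ProteinSequence,
    hit_alignment: SeedAlignment,
    background: np.ndarray | None = None,
    pseudocount_weight: float = DEFAULT_PSEUDOCOUNT,
    score_floor: float = SCORE_FLOOR,
) -> Pssm:
    """Build a log-odds PSSM (bits) from a seed-coordinate alignment."""
    if hit_alignment.seed_id != seed.id:
        raise ValueError("hit alignment seed row does not match seed")
    if len(hit_alignment.rows[0]) != seed.length:
        raise ValueError("alignment width must equal seed length")
    g = BACKGROUND if background is None else np.asarray(background, dtype=float)
    rows = hit_alignment.rows
    weights = henikoff_weights(rows)
    L = seed.length

    freqs = np.zeros((L, 20))
    distinct = np.zeros(L)
    for col in range(L):
        seen: set[str] = set()
        for w, row in zip(weights, rows):
            ch = row[col]
            if ch in "-X":
                continue
            freqs[col, AA.index(ch)] += w
            seen.add(ch)
        distinct[col] = len(seen)
    col_tot = freqs.sum(axis=1, keepdims=True)
    occupied = col_tot[:, 0] > 0
    freqs[occupied] /= col_tot[occupied]
    # empty columns (all gap/X) fall back to background -> zero score
    freqs[~occupied] = g

    n_eff = float(distinct[occupied].mean()) if occupied.any() else 1.0
    b = pseudocount_weight
    probs = (n_eff * freqs + b * g[None, :]) / (n_eff + b)
    with np.errstate(divide="ignore"):
        scores = np.log2(probs / g[None, :])
    scores = np.maximum(scores, score_floor)
    return Pssm(seed.id, scores, probs, g, pseudocount_weight)


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel (location, scale) fit."""
    scores = np.asarray(scores, dtype=float)
    if scores.std() == 0:
        raise CalibrationError("calibration failed: degenerate score distribution")
    mu, beta = stats.gumbel_r.fit(scores)
    return float(mu), float(beta)


def best_local_score(pssm: Pssm, seq: ProteinSequence) -> float:
    score, *_ = _align.sw_pssm(
        pssm.scores_with_x(), encode(seq.residues), GAP_OPEN, GAP_EXTEND
    )
    return float(score)


def calibrate(
    pssm: Pssm,
    db: FamilyDataset,
    n_decoys: int = DEFAULT_N_DECOYS,
    rng_seed: int = 0,
) -> Calibration:
    """Fit the profile's E-value statistics from residue-shuffled decoys."""
    if n_decoys < 50:
        raise ValueError("n_decoys must be >= 50")
    decoys = generate_decoys(n_decoys, db, rng_seed)
    scores = np.array([best_local_score(pssm, d) for d in decoys])
    mu, beta = fit_gumbel(scores)
    if beta <= 0:
        raise CalibrationError("calibration failed: non-positive Gumbel scale")
    lambda_hat = 1.0 / (beta * _LN2)
    db_residues = sum(s.length for s in db)
    k_hat = len(db) * math.exp(mu / beta) / (pssm.length * db_residues)
    return Calibration(
        lambda_hat=lambda_hat,
        k_hat=k_hat,
        n_decoys=n_decoys,
        decoy_seed=rng_seed,
        db_residues=db_residues,
        db_sequences=len(db),
        mu_hat=mu,
        beta_hat=beta,
    )


def pssm_search(
    pssm: Pssm, db: FamilyDataset | list[ProteinSequence], calibration: Calibration
) -> list[Hit]:
    """Score every database sequence; hits sorted by E-value then id."""
    members = db.members if isinstance(db, FamilyDataset) else list(db)
    mat = pssm.scores_with_x()
    hits: list[Hit] = []
    for seq in members:
        score, ps, pe, ts, te = _align.sw_pssm(
            mat, encode(seq.residues), GAP_OPEN, GAP_EXTEND
        )
        hits.append(
            Hit(
                target_id=seq.id,
                bit_score=float(score),
                e_value=calibration.evalue(float(score), pssm.length),
                seed_start=int(ps),
                seed_end=int(pe),
                target_start=int(ts),
                target_end=int(te),
            )
        )
    hits.sort(key=lambda h: (h.e_value, h.target_id))
    return hits


def align_to_seed(seed: ProteinSequence, target: ProteinSequence) -> str:
    """Project a global alignment of ``target`` onto seed coordinates.

    Seed-gap columns (target insertions) are dropped, so the result has
    exactly one character per seed position.
    """
    aln = global_align(seed, target)
    out = []
    for sa, ta in zip(aln.row_a, aln.row_b):
        if sa == "-":
            continue
        out.append(ta)
    return "".join(out)


def _make_alignment(
    seed: ProteinSequence, db: FamilyDataset, included_ids: set[str]
) -> SeedAlignment:
    ids = [seed.id]
    rows = [seed.residues]
    for member in db:
        if member.id == seed.id or member.id not in included_ids:
            continue
        ids.append(member.id)
        rows.append(align_to_seed(seed, member))
    return SeedAlignment(seed.id, ids, rows)


def _derive_seed(rng_seed: int, salt: int) -> int:
    return int((rng_seed * 1_000_003 + salt) % (2**31 - 1))


def iterative_profile(
    seed: ProteinSequence,
    db: FamilyDataset,
    iterations: int = DEFAULT_ITERATIONS,
    inclusion_evalue: float = DEFAULT_INCLUSION_EVALUE,
    pseudocount_weight: float = DEFAULT_PSEUDOCOUNT,
    n_decoys: int = DEFAULT_N_DECOYS,
    rng_seed: int = 0,
) -> Profile:
    """Build a profile by up to ``iterations`` rounds of search-and-rebuild."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    included: set[str] = {seed.id}
    alignment = _make_alignment(seed, db, included)
    history: list[int] = []
    rounds = 0
    for it in range(1, iterations + 1):
        pssm = build_pssm(seed, alignment, pseudocount_weight=pseudocount_weight)
        cal = calibrate(pssm, db, n_decoys, _derive_seed(rng_seed, it))
        hits = pssm_search(pssm, db, cal)
        accepted = {h.target_id for h in hits if h.e_value <= inclusion_evalue}
        new_included = included | accepted
        rounds = it
        history.append(len(new_included & ({seed.id} | set(db.ids))))
        if new_included == included:
            break
        included = new_included
        alignment = _make_alignment(seed, db, included)
    final_pssm = build_pssm(seed, alignment, pseudocount_weight=pseudocount_weight)
    final_cal = calibrate(final_pssm, db, n_decoys, _derive_seed(rng_seed, 0))
    return Profile(
        pssm=final_pssm,
        calibration=final_cal,
        hit_alignment=alignment,
        iteration=rounds,
        enriched=False,
        history=history,
    )


def enrich_profile(
    profile: Profile,
    seed: ProteinSequence,
    full_family: FamilyDataset,
    inclusion_evalue: float = DEFAULT_INCLUSION_EVALUE,
    n_decoys: int = DEFAULT_N_DECOYS,
    rng_seed: int = 0,
) -> Profile:
    """One extra search-and-rebuild round against the full family set."""
    cal = calibrate(
        profile.pssm, full_family, n_decoys, _derive_seed(rng_seed, 101)
    )
    hits = pssm_search(profile.pssm, full_family, cal)
    accepted = {h.target_id for h in hits if h.e_value <= inclusion_evalue}
    included = set(profile.hit_alignment.ids) | accepted
    included &= {seed.id} | set(full_family.ids)
    alignment = _make_alignment(seed, full_family, included)
    pssm = build_pssm(
        seed, alignment, pseudocount_weight=profile.pssm.pseudocount_weight
    )
    final_cal = calibrate(pssm, full_family, n_decoys, _derive_seed(rng_seed, 102))
    return Profile(
        pssm=pssm,
        calibration=final_cal,
        hit_alignment=alignment,
        iteration=profile.iteration,
        enriched=True,
        history=profile.history + [alignment.n_rows],
    )
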
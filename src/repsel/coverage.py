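"""Family coverage, best-representative selection and enrichment.

Coverage of a candidate seed is the percentage of family members its
profile recognizes at the association E-value threshold (profile engine)
or that its motif set assigns (motif engine); the seed counts in both
numerator and denominator. Per engine, the candidate with maximum
coverage is the best representative sequence (BRS); ties break by higher
mean bit score over recognized members, then longer seed, then smallest
id. When the winning coverage falls below the enrichment threshold
(default 90%), the profile is rebuilt with one extra search round against
the full family and the better of the two profiles is kept.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .motifs import MotifSet, extract_motifs, motif_assign
from .profile import (
    DEFAULT_INCLUSION_EVALUE,
    DEFAULT_N_DECOYS,
    Profile,
    enrich_profile,
    iterative_profile,
    pssm_search,
)
from .seqio import FamilyDataset, ProteinSequence

logger = logging.getLogger(__name__)

DEFAULT_ASSOC_EVALUE = 1e-2
DEFAULT_ENRICH_BELOW = 90.0
ENGINES = ("profile", "motif")


@dataclass
class RecognitionTable:
    """Per-member recognition decisions of one engine under one model."""

    engine: str
    entries: dict[str, tuple[bool, float]]  # member_id -> (recognized, score)

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ValueError(f"unknown engine {self.engine!r}")

    @property
    def n_recognized(self) -> int:
        return sum(1 for rec, _ in self.entries.values() if rec)

    def recognized_ids(self) -> set[str]:
        return {m for m, (rec, _) in self.entries.items() if rec}

    def to_tsv(self, path: str | Path) -> Path:
        rows = [
            {
                "member_id": m,
                "engine": self.engine,
                "recognized": int(rec),
                "score": val,
            }
            for m, (rec, val) in self.entries.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4g")
        return Path(path)


@dataclass
class CoverageReport:
    family_id: str
    per_candidate: dict[str, dict[str, float]]  # seed_id -> engine -> coverage
    brs: dict[str, str]  # engine -> seed_id
    enrichment_applied: dict[str, bool]
    agreement: bool
    # per-engine artifacts for the winning candidate (used by the pipeline)
    tables: dict[str, RecognitionTable] = field(default_factory=dict)
    profiles: dict[str, Profile] = field(default_factory=dict)
    motif_sets: dict[str, MotifSet] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> Path:
        rows = []
        for seed_id, per_engine in self.per_candidate.items():
            for engine, cov in per_engine.items():
                rows.append(
                    {
                        "seed_id": seed_id,
                        "engine": engine,
                        "coverage": f"{cov:.1f}",
                        "is_brs": int(self.brs.get(engine) == seed_id),
                        "enrichment_applied": int(
                            self.enrichment_applied.get(seed_id, False)
                        ),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return Path(path)


def family_coverage(
    model: Profile | MotifSet,
    family: FamilyDataset,
    engine: str,
    assoc_evalue: float = DEFAULT_ASSOC_EVALUE,
) -> RecognitionTable:
    """Recognition table of every family member under one engine."""
    if engine == "profile":
        if not isinstance(model, Profile):
            raise TypeError("profile engine needs a Profile")
        hits = pssm_search(model.pssm, family, model.calibration)
        entries = {
            h.target_id: (h.e_value <= assoc_evalue, h.e_value) for h in hits
        }
        entries = {m: entries[m] for m in family.ids}
    elif engine == "motif":
        if not isinstance(model, MotifSet):
            raise TypeError("motif engine needs a MotifSet")
        entries = {}
        for member in family:
            if len(model) == 0:
                entries[member.id] = (False, 0.0)
                continue
            res = motif_assign(model, member)
            entries[member.id] = (res.assigned, res.total_score)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return RecognitionTable(engine, entries)


def coverage_percent(table: RecognitionTable) -> float:
    if not table.entries:
        raise ValueError("empty recognition table")
    return 100.0 * table.n_recognized / len(table.entries)


def format_coverage(value: float) -> str:
    """Coverage formatted to one decimal, as reported."""
    return f"{value:.1f}"


def _mean_bit_score(table: RecognitionTable, profile: Profile | None) -> float:
    """Tie-break statistic: mean engine score over recognized members."""
    vals = [v for rec, v in table.entries.values() if rec]
    if not vals:
        return 0.0
    if table.engine == "profile":
        # e-values: smaller is better -> use the recognized count-weighted
        # mean bit score implied by -log2(e); guard zero e-values.
        import math

        return float(
            sum(-math.log2(max(v, 1e-300)) for v in vals) / len(vals)
        )
    return float(sum(vals) / len(vals))


def _engine_model(profile: Profile, engine: str, family_id: str):
    if engine == "profile":
        return profile
    return extract_motifs(profile, family_id=family_id)


def select_brs(
    family: FamilyDataset,
    candidates: list[ProteinSequence],
    nr50: FamilyDataset,
    engines: Iterable[str] = ENGINES,
    enrich_below: float = DEFAULT_ENRICH_BELOW,
    assoc_evalue: float = DEFAULT_ASSOC_EVALUE,
    inclusion_evalue: float = DEFAULT_INCLUSION_EVALUE,
    n_decoys: int = DEFAULT_N_DECOYS,
    rng_seed: int = 0,
) -> CoverageReport:
    """Coverage table over all candidates and the per-engine BRS choice."""
    if not candidates:
        raise ValueError("no candidate seeds")
    engines = list(engines)
    missing = set(nr50.ids) - set(family.ids)
    if missing:
        raise ValueError(f"nr50 contains ids not in family: {sorted(missing)}")

    profiles: dict[str, Profile] = {}
    tables: dict[str, dict[str, RecognitionTable]] = {}
    models: dict[str, dict[str, Profile | MotifSet]] = {}
    per_candidate: dict[str, dict[str, float]] = {}
    for i, seed in enumerate(candidates):
        prof = iterative_profile(
            seed,
            nr50,
            inclusion_evalue=inclusion_evalue,
            n_decoys=n_decoys,
            rng_seed=rng_seed + 7919 * (i + 1),
        )
        profiles[seed.id] = prof
        tables[seed.id] = {}
        models[seed.id] = {}
        per_candidate[seed.id] = {}
        for engine in engines:
            model = _engine_model(prof, engine, family.family_id)
            table = family_coverage(model, family, engine, assoc_evalue)
            models[seed.id][engine] = model
            tables[seed.id][engine] = table
            per_candidate[seed.id][engine] = coverage_percent(table)

    brs: dict[str, str] = {}
    enrichment_applied: dict[str, bool] = {s.id: False for s in candidates}
    final_tables: dict[str, RecognitionTable] = {}
    final_profiles: dict[str, Profile] = {}
    final_motifs: dict[str, MotifSet] = {}
    by_id = {s.id: s for s in candidates}

    for engine in engines:
        # tie-break chain: coverage, mean bit score over recognized members,
        # seed length; remaining ties resolve to the smallest seed id
        # because candidates are visited in id order and only strict
        # improvements replace the incumbent.
        winner = None
        winner_key = None
        for seed_id in sorted(by_id):
            key = (
                per_candidate[seed_id][engine],
                _mean_bit_score(tables[seed_id][engine], profiles[seed_id]),
                by_id[seed_id].length,
            )
            if winner is None or key > winner_key:
                winner = seed_id
                winner_key = key
        win_cov = per_candidate[winner][engine]
        win_table = tables[winner][engine]
        win_profile = profiles[winner]
        win_model = models[winner][engine]

        if win_cov < enrich_below:
            enriched = enrich_profile(
                win_profile,
                by_id[winner],
                family,
                inclusion_evalue=inclusion_evalue,
                n_decoys=n_decoys,
                rng_seed=rng_seed + 104729,
            )
            enrichment_applied[winner] = True
            e_model = _engine_model(enriched, engine, family.family_id)
            e_table = family_coverage(e_model, family, engine, assoc_evalue)
            e_cov = coverage_percent(e_table)
            if e_cov > win_cov:
                logger.info(
                    "%s engine: enrichment improved coverage %.1f -> %.1f",
                    engine, win_cov, e_cov,
                )
                win_cov = e_cov
                win_table = e_table
                win_profile = enriched
                win_model = e_model
                per_candidate[winner][engine] = e_cov

        brs[engine] = winner
        final_tables[engine] = win_table
        final_profiles[engine] = win_profile
        if engine == "motif":
            final_motifs[engine] = win_model  # type: ignore[assignment]

    agreement = len(set(brs.values())) == 1 if len(brs) > 1 else True
    return CoverageReport(
        family_id=family.family_id,
        per_candidate=per_candidate,
        brs=brs,
        enrichment_applied=enrichment_applied,
        agreement=agreement,
        tables=final_tables,
        profiles=final_profiles,
        motif_sets=final_motifs,
    )
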
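import math

import numpy as np
import pytest
from scipy import stats

from repsel.profile import (
    Calibration,
    CalibrationError,
    Pssm,
    SeedAlignment,
    align_to_seed,
    best_local_score,
    build_pssm,
    calibrate,
    enrich_profile,
    fit_gumbel,
    henikoff_weights,
    iterative_profile,
    pssm_search,
)
from repsel.seqio import FamilyDataset, ProteinSequence
from repsel.synth import FamilySpec, generate_decoys, generate_family

UNIFORM_BG = np.full(20, 0.05)


def single_seq_alignment(seq):
    return SeedAlignment(seq.id, [seq.id], [seq.residues])


def test_pseudocount_blend_single_residue_column():
    """Column of one residue type, N_eff=1, b=1, g=0.05: f'=0.525."""
    seed = ProteinSequence("s", "AAAAA")
    pssm = build_pssm(seed, single_seq_alignment(seed), background=UNIFORM_BG,
                      pseudocount_weight=1.0)
    assert pssm.probs[0, 0] == pytest.approx(0.525)
    assert pssm.scores[0, 0] == pytest.approx(math.log2(0.525 / 0.05), abs=1e-6)


def test_zero_pseudocount_limit():
    """b -> 0: observed residue scores log2(1/g); others hit the floor."""
    seed = ProteinSequence("s", "ACD")
    pssm = build_pssm(seed, single_seq_alignment(seed), background=UNIFORM_BG,
                      pseudocount_weight=0.0)
    assert pssm.scores[0, 0] == pytest.approx(math.log2(1 / 0.05))
    assert pssm.scores[0, 1] == -10.0  # floor for zero-frequency cells


def test_all_residues_column_matches_hand_recomputation():
    """A 20-row column with every residue once, recomputed independently."""
    from repsel._scoring import AA, BACKGROUND

    seed = ProteinSequence("s", "A")
    rows = list(AA)
    aln = SeedAlignment("s", ["s"] + [f"r{i}" for i in range(1, 20)], rows)
    b = 5.0
    pssm = build_pssm(seed, aln, pseudocount_weight=b)
    # independent recomputation: equal weights 1/20, f_a = 0.05, N_eff = 20
    n_eff = 20.0
    for a_idx in range(20):
        g = BACKGROUND[a_idx]
        f_prime = (n_eff * 0.05 + b * g) / (n_eff + b)
        assert pssm.probs[0, a_idx] == pytest.approx(f_prime, abs=1e-12)
        assert pssm.scores[0, a_idx] == pytest.approx(
            math.log2(f_prime / g), abs=1e-9
        )


def test_henikoff_weights_downweight_duplicates():
    # two identical rows share the weight a distinct row gets alone
    rows = ["AAAA", "AAAA", "WYWY"]
    w = henikoff_weights(rows)
    assert w[0] == pytest.approx(w[1])
    assert w[2] > w[0]
    assert w.sum() == pytest.approx(1.0)


def test_seed_row_required():
    seed = ProteinSequence("s", "ACD")
    with pytest.raises(ValueError):
        build_pssm(seed, SeedAlignment("t", ["t"], ["ACD"]))


def test_fit_gumbel_parameter_recovery():
    """ML fit recovers the scale of simulated Gumbel(10, 2) scores."""
    scores = stats.gumbel_r.rvs(loc=10, scale=2, size=2000,
                                random_state=np.random.default_rng(0))
    mu, beta = fit_gumbel(scores)
    assert abs(1 / beta - 0.5) / 0.5 < 0.10
    assert mu == pytest.approx(10, rel=0.05)


def test_calibration_deterministic_and_degenerate(subgroup_family):
    fam, _ = subgroup_family
    seed = fam.members[0]
    pssm = build_pssm(seed, single_seq_alignment(seed))
    c1 = calibrate(pssm, fam, n_decoys=60, rng_seed=5)
    c2 = calibrate(pssm, fam, n_decoys=60, rng_seed=5)
    assert (c1.lambda_hat, c1.k_hat) == (c2.lambda_hat, c2.k_hat)
    with pytest.raises(CalibrationError):
        fit_gumbel(np.full(100, 7.0))
    with pytest.raises(ValueError):
        calibrate(pssm, fam, n_decoys=10, rng_seed=0)


def test_evalue_monotone_in_bit_score():
    cal = Calibration(lambda_hat=0.5, k_hat=1.0, n_decoys=100, decoy_seed=0,
                      db_residues=1000, db_sequences=10)
    evs = [cal.evalue(s, 100) for s in (0, 10, 20, 40, 80)]
    assert evs == sorted(evs, reverse=True)


def test_search_self_hit_dominates_decoys(subgroup_family):
    fam, _ = subgroup_family
    seed = fam.members[0]
    pssm = build_pssm(seed, single_seq_alignment(seed))
    cal = calibrate(pssm, fam, n_decoys=60, rng_seed=1)
    decoys = generate_decoys(30, FamilyDataset("d", [seed]), rng_seed=3)
    db = FamilyDataset("db", [seed] + decoys.members)
    hits = pssm_search(pssm, db, cal)
    assert hits[0].target_id == seed.id
    self_hit = hits[0]
    assert all(self_hit.bit_score > h.bit_score for h in hits[1:])


def test_search_empty_db_returns_no_hits(subgroup_family):
    fam, _ = subgroup_family
    seed = fam.members[0]
    pssm = build_pssm(seed, single_seq_alignment(seed))
    cal = calibrate(pssm, fam, n_decoys=60, rng_seed=1)
    assert pssm_search(pssm, [], cal) == []


def test_planted_homologs_outrank_shuffled_decoys():
    """10 homologs at 30-60% identity all outscore 40 shuffled decoys."""
    fam, labels = generate_family(
        FamilySpec(n_members=11, ancestor_length=100, mutation_rate=0.4,
                   indel_rate=0.02, rng_seed=31, family_id="h")
    )
    seed = fam.members[0]
    homologs = fam.members[1:]
    decoys = generate_decoys(40, fam, rng_seed=7).members
    pssm = build_pssm(seed, single_seq_alignment(seed))
    cal = calibrate(pssm, fam, n_decoys=60, rng_seed=2)
    db = FamilyDataset("db", homologs + decoys)
    hits = {h.target_id: h.bit_score for h in pssm_search(pssm, db, cal)}
    worst_homolog = min(hits[h.id] for h in homologs)
    best_decoy = max(hits[d.id] for d in decoys)
    assert worst_homolog > best_decoy


def test_seed_score_beats_shuffled_seed_scores(subgroup_family):
    fam, _ = subgroup_family
    seed = fam.members[0]
    pssm = build_pssm(seed, single_seq_alignment(seed))
    self_score = best_local_score(pssm, seed)
    shuffles = generate_decoys(100, FamilyDataset("s", [seed]), rng_seed=13)
    assert all(best_local_score(pssm, d) < self_score for d in shuffles)


def test_align_to_seed_projects_onto_seed_coordinates():
    seed = ProteinSequence("s", "ACDEFGHIKL")
    target = ProteinSequence("t", "ACDFGHIKL")  # E deleted
    row = align_to_seed(seed, target)
    assert len(row) == seed.length
    assert row == "ACD-FGHIKL"


def test_iterative_profile_converges_on_seed_only_db():
    seed = ProteinSequence("s", "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKL")
    db = FamilyDataset("db", [seed])
    prof = iterative_profile(seed, db, n_decoys=60, rng_seed=1)
    assert prof.iteration <= 2
    assert prof.hit_alignment.ids == [seed.id]


def test_iterative_profile_rows_nondecreasing(subgroup_family, subgroup_nr50):
    fam, _ = subgroup_family
    seed = fam.get(min(fam.ids))
    prof = iterative_profile(seed, subgroup_nr50, n_decoys=60, rng_seed=4)
    assert prof.history == sorted(prof.history)
    assert 1 <= prof.iteration <= 3
    assert set(prof.hit_alignment.ids) <= {seed.id} | set(subgroup_nr50.ids)


def test_enrich_identical_db_keeps_hit_set(subgroup_family, subgroup_nr50):
    fam, _ = subgroup_family
    seed = fam.get(min(fam.ids))
    prof = iterative_profile(seed, subgroup_nr50, n_decoys=60, rng_seed=4)
    enriched = enrich_profile(prof, seed, subgroup_nr50, n_decoys=60, rng_seed=4)
    assert enriched.enriched
    assert set(enriched.hit_alignment.ids) == set(prof.hit_alignment.ids)
    assert np.allclose(enriched.pssm.scores, prof.pssm.scores)


def test_enrich_superset_db_grows_alignment(subgroup_family, subgroup_nr50):
    fam, _ = subgroup_family
    seed = fam.get(min(fam.ids))
    prof = iterative_profile(seed, subgroup_nr50, n_decoys=60, rng_seed=4)
    enriched = enrich_profile(prof, seed, fam, n_decoys=60, rng_seed=4)
    assert enriched.hit_alignment.n_rows >= prof.hit_alignment.n_rows


def test_pssm_tsv_export(tmp_path):
    seed = ProteinSequence("s", "ACDEF")
    pssm = build_pssm(seed, single_seq_alignment(seed))
    path = pssm.to_tsv(tmp_path / "p.tsv", seed_residues=seed.residues)
    lines = path.read_text().splitlines()
    assert lines[0].split("\t")[:2] == ["position", "seed_residue"]
    assert len(lines) == seed.length + 1
    assert len(lines[1].split("\t")) == 22
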
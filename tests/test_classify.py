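import numpy as np
import pytest

from repsel.classify import (
    CATEGORY_COMPBIAS,
    CATEGORY_LOWCOMP,
    CATEGORY_OUTLIER,
    CATEGORY_PARTIAL,
    CATEGORY_UNEXPLAINED,
    category_from_measurements,
    classify_unrecognized,
    divergence_ratio,
    polar_fraction,
    seg_low_complexity,
    tm_segments,
)
from repsel.pairwise import IdentityMatrix, identity_matrix
from repsel.seqio import FamilyDataset, ProteinSequence
from repsel.synth import FamilySpec, generate_family
from repsel._scoring import AA, KYTE_DOOLITTLE

from oracles import seg_segments_bruteforce, tm_count_bruteforce


def test_seg_homopolymer_full_span():
    assert seg_low_complexity("A" * 30) == [(1, 30)]


def test_seg_high_complexity_no_segments():
    # 12 distinct residues per window: K2 = log2(12) > extend threshold
    s = "ACDEFGHIKLMN" * 2
    assert seg_low_complexity(s) == []


def test_seg_short_sequence_empty():
    assert seg_low_complexity("AAAA") == []


def test_seg_matches_bruteforce_oracle():
    """SEG segments equal per-window recomputation on biased random input."""
    rng = np.random.default_rng(123)
    biased = np.array([0.3, 0.2, 0.1, 0.1] + [0.3 / 16] * 16)
    for k in range(200):
        n = int(rng.integers(12, 120))
        if k % 2:
            seq = "".join(AA[i] for i in rng.choice(20, size=n, p=biased))
        else:
            seq = "".join(AA[i] for i in rng.integers(0, 20, n))
        assert seg_low_complexity(seq) == seg_segments_bruteforce(seq), seq


def test_tm_trivial_blocks():
    assert tm_segments("I" * 40) >= 1
    assert tm_segments("D" * 40) == 0
    assert tm_segments("I" * 10) == 0  # shorter than the window


def test_tm_alternating_blocks_counted_by_oracle():
    seq = ("I" * 25 + "D" * 25) * 3
    want = tm_count_bruteforce(seq, KYTE_DOOLITTLE)
    assert want == 3
    assert tm_segments(seq) == want


def test_tm_matches_oracle_on_random_sequences():
    rng = np.random.default_rng(7)
    hydro = "ILVFMACDEKRST"
    for _ in range(100):
        n = int(rng.integers(19, 150))
        seq = "".join(hydro[i] for i in rng.integers(0, len(hydro), n))
        assert tm_segments(seq) == tm_count_bruteforce(seq, KYTE_DOOLITTLE)


def test_polar_fraction_shuffle_invariant():
    rng = np.random.default_rng(5)
    s = "".join(AA[i] for i in rng.integers(0, 20, 80))
    p = polar_fraction(ProteinSequence("a", s))
    for _ in range(10):
        shuffled = "".join(rng.permutation(list(s)))
        assert polar_fraction(ProteinSequence("b", shuffled)) == pytest.approx(p)


def _matrix_from(vals, ids):
    return IdentityMatrix(ids, np.array(vals, dtype=float))


def test_divergence_ratio_identical_family():
    fam = FamilyDataset("f", [ProteinSequence(f"s{i}", "ACDEFGHIKL") for i in range(4)])
    mat = identity_matrix(fam)
    assert divergence_ratio("s0", fam, mat) == pytest.approx(1.0)


def test_divergence_ratio_boundary_is_not_outlier():
    # member at exactly 0.8: the outlier rule is strictly below
    assert (
        category_from_measurements(1.0, 0.0, 0, 0.5, 0.8)
        == CATEGORY_UNEXPLAINED
    )
    assert (
        category_from_measurements(1.0, 0.0, 0, 0.5, 0.79999)
        == CATEGORY_OUTLIER
    )


def test_divergence_ratio_planted_outlier(subgroup_family, subgroup_matrix, subgroup_nr50):
    fam, _ = subgroup_family
    # replace one member's identity pattern by planting a fresh outlier family
    fam2, labels = generate_family(
        FamilySpec(n_members=20, ancestor_length=120, mutation_rate=0.35,
                   indel_rate=0.02, n_subgroups=2, outlier_fraction=0.1,
                   rng_seed=3, family_id="o")
    )
    mat2 = identity_matrix(fam2)
    from repsel.redundancy import nonredundant_set

    nr = nonredundant_set(fam2, mat2)
    outliers = [i for i, r in labels.items() if r == "outlier"]
    for o in outliers:
        assert divergence_ratio(o, nr, mat2) < 0.8


def test_divergence_ratio_needs_three_sequences():
    fam = FamilyDataset("f", [ProteinSequence("a", "ACDE"), ProteinSequence("b", "ACDE")])
    mat = identity_matrix(fam)
    with pytest.raises(ValueError):
        divergence_ratio("a", fam, mat)


def test_partial_boundary_at_60_percent():
    assert category_from_measurements(0.59, 0, 0, 0, 1.0) == CATEGORY_PARTIAL
    assert category_from_measurements(0.60, 0, 0, 0, 1.0) == CATEGORY_UNEXPLAINED


def test_lowcomp_rule_after_partial():
    assert category_from_measurements(1.0, 0.35, 0, 0, 1.0) == CATEGORY_LOWCOMP
    # partial takes precedence even when low complexity is present
    assert category_from_measurements(0.5, 0.35, 0, 0, 1.0) == CATEGORY_PARTIAL


def test_composition_bias_via_tm_or_polar():
    assert category_from_measurements(1.0, 0.0, 1, 0.0, 1.0) == CATEGORY_COMPBIAS
    assert category_from_measurements(1.0, 0.0, 0, 0.76, 1.0) == CATEGORY_COMPBIAS
    assert category_from_measurements(1.0, 0.0, 0, 0.75, 1.0) == CATEGORY_UNEXPLAINED


def test_planted_anomalies_recovered_and_precedence_reproducible():
    fam, labels = generate_family(
        FamilySpec(n_members=40, ancestor_length=150, mutation_rate=0.35,
                   indel_rate=0.02, n_subgroups=2, fragment_fraction=0.1,
                   lowcomp_fraction=0.1, outlier_fraction=0.1,
                   rng_seed=1000, family_id="tax")
    )
    mat = identity_matrix(fam)
    from repsel.redundancy import nonredundant_set

    nr50 = nonredundant_set(fam, mat)
    want = {
        "fragment": CATEGORY_PARTIAL,
        "lowcomp": CATEGORY_LOWCOMP,
        "outlier": CATEGORY_OUTLIER,
    }
    planted = [i for i, r in labels.items() if r in want]
    records = classify_unrecognized(planted, fam, nr50, mat)
    assert [r.member_id for r in records] == planted
    for rec in records:
        # every record's category re-derives from its own measurements
        assert rec.category == category_from_measurements(
            rec.length_ratio,
            rec.lowcomp_fraction,
            rec.tm_segments,
            rec.polar_fraction,
            rec.divergence_ratio,
        )
        assert 0 <= rec.lowcomp_fraction <= 1
        assert 0 <= rec.polar_fraction <= 1
        assert rec.length_ratio >= 0 and rec.divergence_ratio >= 0
    correct = sum(
        rec.category == want[labels[rec.member_id]] for rec in records
    )
    assert correct >= len(records) - 1


def test_unknown_ids_rejected(base_family, base_matrix):
    fam, _ = base_family
    from repsel.redundancy import nonredundant_set

    with pytest.raises(ValueError):
        classify_unrecognized(["nope"], fam, fam, base_matrix)
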
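"""Alignment and error statistics: DP oracle equivalence, event
classification, rate conservation, estimator recovery."""

import functools
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import maskless as mk
from maskless.profiler import (DEL, MATCH, SUB, TRUNC, AlignScoring,
                               EventMatrix, align_read, classify_events,
                               cycle_indices)

S = AlignScoring()


def oracle_score(ref: str, read: str) -> float:
    """Exhaustive affine-gap DP mirroring the production scoring exactly:
    match +1 / mismatch -2; gaps open at -5 and extend at -1; the leading
    reference gap (before any read base) extends at -0.01."""

    @functools.cache
    def best(i: int, j: int, prev: str) -> float:
        if i == len(ref) and j == len(read):
            return 0.0
        cands = []
        if i < len(ref) and j < len(read):
            s = S.match if ref[i] == read[j] else S.mismatch
            cands.append(s + best(i + 1, j + 1, "a"))
        if i < len(ref):  # deletion of ref[i]
            if prev == "d":
                step = S.trunc_per_base if j == 0 else S.gap_extend
            else:
                step = S.gap_open + S.gap_extend
            cands.append(step + best(i + 1, j, "d"))
        if j < len(read):  # insertion of read[j]
            step = S.gap_extend if prev == "i" else S.gap_open + S.gap_extend
            cands.append(step + best(i, j + 1, "i"))
        return max(cands)

    return best(0, 0, "s")


def test_aligner_score_equals_dp_oracle_on_random_pairs():
    rng = random.Random(17)
    for _ in range(200):
        ref = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
        read = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
        a = align_read(read, ref)
        assert a.score == pytest.approx(oracle_score(ref, read)), (ref, read)


@given(st.text(alphabet="ACGT", min_size=1, max_size=10),
       st.text(alphabet="ACGT", min_size=1, max_size=10))
@settings(deadline=None, max_examples=100)
def test_aligner_score_equals_dp_oracle_property(ref, read):
    assert align_read(read, ref).score == pytest.approx(oracle_score(ref, read))


def test_perfect_read_is_all_match():
    a = align_read("ACGTACGT", "ACGTACGT")
    assert (a.codes == MATCH).all()
    assert a.insertions == []
    assert a.identity == 1.0


def test_single_deletion_left_aligned():
    # the deleted T is reported at the leftmost equivalent position
    a = align_read("ACGACGT", "ACGTACGT")
    assert list(np.nonzero(a.codes == DEL)[0]) == [3]
    assert (a.codes != SUB).all()


def test_deletion_left_aligned_within_homopolymer():
    a = align_read("CAG", "CAAG")
    assert list(np.nonzero(a.codes == DEL)[0]) == [1]
    b = align_read("CAAG", "CAAAAG")
    assert list(np.nonzero(b.codes == DEL)[0]) == [1, 2]


def test_empty_read_yields_all_deletions():
    a = align_read("", "ACGT")
    assert (a.codes == DEL).all()
    assert a.identity == 0.0


def test_truncated_read_classified_not_deleted():
    ref = "AAAACCCCGGGGTTTT"
    a = align_read("GGGGTTTT", ref)
    assert (a.codes[:8] == TRUNC).all()
    assert (a.codes[8:] == MATCH).all()
    assert a.covered == 8
    assert a.identity == 1.0


def test_substitution_recorded_with_expected_and_observed():
    ref = "ACGTA"
    a = align_read("ACTTA", ref)
    df = classify_events(a, ref)
    subs = df[df.event == "substitution"]
    assert len(subs) == 1
    assert subs.iloc[0].position == 2
    assert (subs.iloc[0].expected, subs.iloc[0].observed) == ("G", "T")


def test_deletion_run_recorded_once_not_as_singles():
    a = align_read("ACTA", "ACGGTA")
    em = EventMatrix.from_alignments([a], {"ref": "ACGGTA"})
    runs = mk.deletion_run_lengths(em)
    assert runs.loc["2", "rate_runs"] > 0
    assert runs.loc["1", "rate_runs"] == 0


def test_rate_conservation_and_event_coverage(deletion_recovery):
    """Every reference position is classified exactly once and
    total = deletion + insertion + substitution on a shared denominator."""
    _, _, em = deletion_recovery
    r = mk.per_bp_rates(em)
    assert r.total == pytest.approx(r.deletion + r.insertion + r.substitution)
    n_events = ((em.codes == MATCH) | (em.codes == SUB) |
                (em.codes == DEL) | (em.codes == TRUNC)).sum()
    assert n_events == em.codes.size


def test_per_bp_rates_from_constructed_counts():
    """4 650 deleted + 580 inserted + 970 mismatched in 100 000 bases."""
    rng = np.random.default_rng(0)
    L = 100
    n_reads = 1000
    codes = np.zeros((n_reads, L), dtype=np.uint8)
    flat = codes.reshape(-1)
    pos = rng.choice(flat.size, size=4650 + 970, replace=False)
    flat[pos[:4650]] = DEL
    flat[pos[4650:]] = SUB
    refs = np.full((n_reads, L), ord("A"), dtype=np.uint8)
    obs = np.where(codes == SUB, ord("C"), ord("A")).astype(np.uint8)
    obs[codes == DEL] = 0
    em = EventMatrix(
        codes=codes, obs=obs, refs=refs,
        ref_ids=["r"] * n_reads, read_ids=[str(i) for i in range(n_reads)],
        feature_ids=None,
        ins_read=np.arange(580) % n_reads, ins_slot=np.full(580, 50),
        ins_len=np.ones(580, dtype=int),
        readable=np.ones(n_reads, bool), identity=np.ones(n_reads),
        min_identity=0.5)
    r = mk.per_bp_rates(em)
    assert (r.deletion, r.insertion, r.substitution) == (4.65, 0.58, 0.97)
    assert r.total == pytest.approx(6.20)


def test_deletion_recovery_within_three_mc_sigma(deletion_recovery):
    """The profiler recovers the configured 5% photolysis shortfall."""
    _, _, em = deletion_recovery
    r = mk.per_bp_rates(em)
    sigma = 100 * np.sqrt(0.05 * 0.95 / r.n_ref_bases)
    assert r.deletion == pytest.approx(5.0, abs=max(3 * sigma, 0.3))
    assert r.insertion < 0.05
    assert round(r.deletion) == 5


def test_coupling_efficiency_estimator_recovers_truth(coupling_recovery):
    """Corrected estimator: G ~ 99.7%, A/C/T >= 99.9% (true 99.95%)."""
    _, _, em = coupling_recovery
    eff = mk.estimate_coupling_efficiencies(em)
    assert eff.loc["G", "corrected"] == pytest.approx(99.7, abs=0.05)
    for b in "ACT":
        assert eff.loc[b, "corrected"] >= 99.9
        assert eff.loc[b, "naive"] >= 99.9
    # the naive G estimate is biased upward by deletion-masked substitutions
    assert eff.loc["G", "naive"] > eff.loc["G", "corrected"]


def test_estimator_warns_on_capped_data(capping_pair):
    _, (_, _, em_c) = capping_pair
    with pytest.warns(UserWarning, match="capped"):
        eff = mk.estimate_coupling_efficiencies(em_c, capped=True)
    assert eff["corrected"].isna().all()


def test_substitution_matrix_dominated_by_G_to_T(coupling_recovery):
    _, _, em = coupling_recovery
    sm = mk.substitution_matrix(em)
    assert np.diag(sm.to_numpy()).sum() == 0
    g_t = sm.loc["G", "T"]
    flat = np.sort(sm.to_numpy(), axis=None)
    assert g_t == flat[-1]          # largest entry is (G, T)
    assert g_t > 3 * flat[-2]       # and it dominates the runner-up
    rates = mk.per_bp_rates(em)
    assert sm.to_numpy().sum() == pytest.approx(rates.substitution, rel=1e-9)


def test_match_matrix_rows_sum_to_one_and_G_lowest(capping_pair):
    (_, _, em_u), _ = capping_pair
    mm = mk.match_matrix(em_u)
    assert np.allclose(mm.sum(axis=1), 1.0)
    diag = {b: mm.loc[b, b] for b in "ACGT"}
    assert min(diag, key=diag.get) == "G"
    # apparent deletion excess for G (masked G->T substitutions)
    dels = mm["deletion"]
    assert dels["G"] > dels[["A", "C", "T"]].max()


@pytest.mark.parametrize("pair,expected", [
    (("A", "C"), 1), (("A", "A"), 4), (("T", "A"), 1), (("C", "A"), 3),
    (("G", "T"), 1), (("A", "T"), 3),
])
def test_wait_number(pair, expected):
    assert mk.wait_number(*pair) == expected


@pytest.mark.parametrize("seq,cycles", [
    ("A", [0]), ("AC", [4, 1]), ("GGG", [10, 6, 2]), ("TG", [3, 2]),
])
def test_coupling_cycle_index(seq, cycles):
    assert [mk.coupling_cycle_index(seq, i) for i in range(len(seq))] == cycles
    assert mk.coupling_cycle_index(seq, 0) + 1 == mk.cycles_required(seq)


@given(st.text(alphabet="ACGT", min_size=2, max_size=15))
@settings(deadline=None)
def test_cycle_indices_consistent_with_wait_numbers(seq):
    cyc = cycle_indices(seq)
    for i in range(len(seq) - 1):
        gap = cyc[i] - cyc[i + 1]  # 5' base couples after its 3' neighbor
        assert gap == mk.wait_number(seq[i + 1], seq[i])


def test_insertion_wait_histogram_monotone_under_constant_stray(stray_sim):
    """More OFF cycles between flanking couplings leave more chances for a
    stray deprotection: counts rise strictly from wait 1 to wait 4."""
    _, _, em = stray_sim
    h = mk.insertion_wait_histogram(em)
    assert list(h.index) == [1, 2, 3, 4]
    assert h[1] < h[2] < h[3] < h[4]
    assert h.sum() > 500


def test_wait_histogram_empty_without_insertions(deletion_recovery):
    _, _, em = deletion_recovery
    h = mk.insertion_wait_histogram(em)
    # a deletion-only run leaves (essentially) no insertion records:
    # < 0.001% of the ~6.7M reference bases
    assert h.sum() < 1e-5 * em.codes.size


def test_per_cycle_substitution_periodicity(coupling_recovery):
    """Uncapped failed-G couplings recur wherever G couples; substitution
    peaks land on G cycles (cycle index 2 mod 4)."""
    _, _, em = coupling_recovery
    refs = None
    pc = mk.per_cycle_rates(em, {rid: em.refs[i].tobytes().decode()
                                 for i, rid in enumerate(em.ref_ids)})
    sub = pc["substitution"].to_numpy()
    ok = pc["n_bases"].to_numpy() > 2000
    by_phase = [np.nanmean(sub[ok & (np.arange(len(sub)) % 4 == p)])
                for p in range(4)]
    assert np.argmax(by_phase) == 2  # G phase


def test_per_position_rates_flat_for_uniform_deletion(deletion_recovery):
    _, _, em = deletion_recovery
    pp = mk.per_position_rates(em)
    mid = pp.iloc[5:-5]
    assert mid["deletion"].mean() == pytest.approx(5.0, abs=0.3)
    assert mid["deletion"].std() < 0.6
    assert (mid["match"] + mid["deletion"] + mid["substitution"]).mean() == \
        pytest.approx(100.0, abs=1e-6)


def test_dinucleotide_distribution_properties(capping_pair):
    (_, _, em_u), _ = capping_pair
    dn = mk.dinucleotide_distribution(em_u)
    assert np.allclose(dn.sum(axis=1), 1.0)
    # GG contexts are the most depleted base pair (lowest G coupling yield)
    base_block = dn.loc[list("ACGT"), list("ACGT")]
    assert base_block.loc["G", "G"] == base_block.min().min()


def test_blocking_raises_deletion_to_deletion_share(panel100):
    """With deprotection ideal, chain blocking is the only deletion source;
    the deletions it leaves come in runs, so a deletion is followed by a
    second one far more often than the per-bp deletion rate predicts."""
    from conftest import CLEAN_OPTICS, PERFECT_COUPLING, quick_sim
    photo = mk.PhotochemParams(k_rate=1e9, **CLEAN_OPTICS)
    _, _, em = quick_sim(panel100, molecules=150, photo=photo,
                         chem_kw={"coupling_efficiency": PERFECT_COUPLING,
                                  "block_rate": 0.002}, seed=13)
    dn = mk.dinucleotide_distribution(em)
    rate = mk.per_bp_rates(em).deletion / 100.0
    assert rate < 0.01
    assert dn.loc["deletion", "deletion"] > 10 * rate


def test_independent_run_rate_closed_form():
    assert mk.expected_independent_run_rate(4.0, 2) == pytest.approx(0.16)
    assert mk.expected_independent_run_rate(4.0, 3) == pytest.approx(0.0064)
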
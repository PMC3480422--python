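"""Signature discovery, primer pairing, specificity scoring and selection."""

import numpy as np
import pytest

from conftest import make_alignment, make_group

import nemaquant.design as dsn
from nemaquant.synth import SyntheticSpec, generate_reference_set
from nemaquant.thermo import compute_tm

# ---------------------------------------------------------------------------
# signature windows


def _overlaps(window, site):
    return window.start < site[1] and site[0] < window.end


def test_planted_motif_is_top_ranked_signature():
    spec = SyntheticSpec(seed=7)
    refset = generate_reference_set(spec)
    groups = refset.groups()
    for taxon in ("Fam01", "Fam05", "Fam15"):
        windows = dsn.find_signature_windows(refset.sequences, groups[taxon])
        assert windows, f"no signature found for {taxon}"
        fwd_site, rev_site = refset.motif_sites[taxon]
        assert _overlaps(windows[0], fwd_site) or _overlaps(windows[0], rev_site)


def test_taxon_without_planted_motif_yields_no_signature():
    names = [f"Fam{i + 1:02d}" for i in range(15)]
    spec = SyntheticSpec(seed=7, motif_taxa=tuple(n for n in names if n != "Fam02"))
    refset = generate_reference_set(spec)
    groups = refset.groups()
    assert dsn.find_signature_windows(refset.sequences, groups["Fam02"]) == []


def test_target_identical_to_nontarget_has_no_signature():
    base = "ACGT" * 20
    aln = make_alignment(T1=base, T2=base, N1=base)
    group = make_group("T", {"T1", "T2"})
    assert dsn.find_signature_windows(aln, group, min_len=18, max_len=20) == []


def test_disagreeing_target_members_have_no_signature():
    aln = make_alignment(T1="A" * 80, T2="C" * 80, N1="G" * 80)
    group = make_group("T", {"T1", "T2"})
    assert dsn.find_signature_windows(aln, group, min_len=18, max_len=20) == []


def test_windows_respect_gapped_representative_coordinates():
    # representative has a 4-column gap: window coordinates are ungapped
    target = "ACGTACGTAC----GTACGTACGTACGTACGTACGTACGT"
    other = "TTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTT"
    aln = make_alignment(T1=target, N1=other)
    group = make_group("T", {"T1"})
    windows = dsn.find_signature_windows(aln, group, min_len=18, max_len=18)
    assert windows
    rep_ungapped = target.replace("-", "")
    for w in windows:
        assert w.sequence == rep_ungapped[w.start : w.end]


# ---------------------------------------------------------------------------
# primer pairing


def _window(start, seq, nt_mm=10, nt_mm3=3):
    return dsn.SignatureWindow(
        start=start,
        end=start + len(seq),
        sequence=seq,
        columns=tuple(range(start, start + len(seq))),
        min_nontarget_mismatches=nt_mm,
        min_nontarget_3p_mismatches=nt_mm3,
    )


# two 20-mers with near-63 degC melting temperature, 150 nt apart
FWD_SITE = "AGAGGTGGCCGCACGGCTAC"  # Tm 63.14
REV_SITE = "CGGTGGCCAGTCCGCAGTCT"  # Tm 63.07


@pytest.fixture(scope="module")
def planted_windows():
    w1 = _window(10, FWD_SITE)
    w2 = _window(140, REV_SITE)
    assert abs(compute_tm(FWD_SITE) - 63) < 2.5 and abs(compute_tm(REV_SITE) - 63) < 2.5
    return [w1, w2]


def test_pair_enumeration_amplicon_bookkeeping(planted_windows):
    constraints = dsn.PairConstraints(ta_tolerance=3.0)
    pairs = dsn.enumerate_primer_pairs(planted_windows, constraints=constraints)
    assert len(pairs) == 1
    pair = pairs[0]
    assert pair.forward.sequence == FWD_SITE
    assert pair.reverse.sequence == dsn.reverse_complement(REV_SITE)
    # amplicon spans forward start .. reverse end = 160 - 10 = 150
    assert pair.amplicon_length == 150


def test_amplicon_length_constraint_excludes_pairs(planted_windows):
    constraints = dsn.PairConstraints(ta_tolerance=3.0, amplicon_max=100)
    assert dsn.enumerate_primer_pairs(planted_windows, constraints=constraints) == []


def test_zero_ta_tolerance_excludes_offset_tm(planted_windows):
    constraints = dsn.PairConstraints(ta_tolerance=0.0)
    assert dsn.enumerate_primer_pairs(planted_windows, constraints=constraints) == []


# ---------------------------------------------------------------------------
# specificity


def _pair_on_alignment(target_seq):
    """Build a primer pair whose sites are the first and last 20 nt."""
    n = len(target_seq)
    w1 = _window(0, target_seq[:20])
    w2 = _window(n - 20, target_seq[-20:])
    fwd = dsn.PrimerCandidate(
        sequence=w1.sequence, ref_window=(w1.start, w1.end), strand="forward",
        tm=compute_tm(w1.sequence), gc_fraction=0.5, columns=w1.columns,
    )
    rev = dsn.PrimerCandidate(
        sequence=dsn.reverse_complement(w2.sequence),
        ref_window=(w2.start, w2.end), strand="reverse",
        tm=compute_tm(w2.sequence), gc_fraction=0.5, columns=w2.columns,
    )
    return dsn.PrimerPair(forward=fwd, reverse=rev, amplicon_length=n)


TARGET = "AGGCGCAATACGATGGTCGC" + "ACGT" * 15 + "CGGGACGTGACCCTCAGCGG"


def test_empirical_delta_ct_is_ct_gap():
    pair = _pair_on_alignment(TARGET)
    score = dsn.score_specificity(
        pair, {"T1": TARGET}, {"N1": TARGET}, empirical=(16.0, 42.0)
    )
    assert score.delta_ct == 26.0
    assert score.source == "empirical"


def test_identical_nontarget_gives_zero_proxy_delta():
    pair = _pair_on_alignment(TARGET)
    score = dsn.score_specificity(pair, {"T1": TARGET}, {"N1": TARGET})
    assert score.delta_ct == 0.0
    assert score.per_nontarget["N1"].predicted_amplifiable


def test_three_prime_mismatches_block_amplification():
    # flip two bases in each primer's 3'-terminal pentamer of the non-target
    nt = list(TARGET)
    for i in (16, 18):  # forward primer 3' region (positions 15-19)
        nt[i] = "A" if nt[i] != "A" else "C"
    for i in (len(TARGET) - 20 + 1, len(TARGET) - 20 + 3):  # reverse 3' region
        nt[i] = "A" if nt[i] != "A" else "C"
    pair = _pair_on_alignment(TARGET)
    score = dsn.score_specificity(pair, {"T1": TARGET}, {"N1": "".join(nt)})
    assert not score.per_nontarget["N1"].predicted_amplifiable
    assert score.delta_ct is None  # no non-target signal predicted
    assert score.source == "in_silico"


def test_pair_must_match_every_target_member():
    pair = _pair_on_alignment(TARGET)
    bad = "T" + TARGET[1:]
    with pytest.raises(ValueError, match="T2"):
        dsn.score_specificity(pair, {"T1": TARGET, "T2": bad}, {"N1": TARGET})


def test_empirical_delta_antisymmetric():
    pair = _pair_on_alignment(TARGET)
    s1 = dsn.score_specificity(pair, {"T1": TARGET}, {"N1": TARGET}, empirical=(16, 42))
    s2 = dsn.score_specificity(pair, {"T1": TARGET}, {"N1": TARGET}, empirical=(42, 16))
    assert s1.delta_ct == -s2.delta_ct


# ---------------------------------------------------------------------------
# Ta optimum


def _profile(points):
    return dsn.TaProfile(points=tuple(points))


def test_sharp_optimum_at_design_ta_passes():
    # flat below 63, rising 3 cycles per degC above
    profile = _profile([(59, 20.1), (61, 20.0), (63, 20.0), (65, 26.0), (67, 32.0)])
    result = dsn.assess_ta_optimum(profile)
    assert result.passed
    assert result.sharpness == pytest.approx(3.0, abs=0.01)


def test_flat_profile_fails():
    profile = _profile([(59, 20.0), (61, 20.0), (63, 20.0), (65, 20.0), (67, 20.0)])
    assert not dsn.assess_ta_optimum(profile).passed


def test_optimum_away_from_design_ta_fails():
    profile = _profile([(58, 17.0), (61, 19.0), (63, 21.0), (65, 24.0), (67, 27.0)])
    result = dsn.assess_ta_optimum(profile)
    assert not result.passed
    assert "optimum" in result.reason


def test_short_profile_rejected():
    with pytest.raises(ValueError):
        dsn.assess_ta_optimum(_profile([(63, 20.0), (65, 23.0)]))


# ---------------------------------------------------------------------------
# assay selection


def _candidate(delta, unit_ct, fwd="AGGCGCAATACGATGGTCGC", rev=REV_SITE):
    pair = dsn.PrimerPair(
        forward=dsn.PrimerCandidate(
            sequence=fwd, ref_window=(0, 20), strand="forward",
            tm=63.0, gc_fraction=0.5, columns=tuple(range(20)),
        ),
        reverse=dsn.PrimerCandidate(
            sequence=dsn.reverse_complement(rev), ref_window=(140, 160),
            strand="reverse", tm=63.0, gc_fraction=0.5,
            columns=tuple(range(140, 160)),
        ),
        amplicon_length=160,
    )
    score = dsn.SpecificityScore(per_nontarget={}, delta_ct=delta, source="empirical")
    return (pair, score, unit_ct)


def test_low_delta_ct_discarded():
    chosen = dsn.select_assay([_candidate(11, 20.0), _candidate(13, 25.0)])
    assert chosen.delta_ct == 13


def test_tie_broken_by_lowest_unit_template_ct():
    chosen = dsn.select_assay(
        [_candidate(20, 24.0, fwd="AGGCGCAATACGATGGTCGA"), _candidate(20, 21.0)]
    )
    assert chosen.delta_ct == 20
    # the Ct-21 candidate wins the tie
    assert chosen.pair.forward.sequence == "AGGCGCAATACGATGGTCGC"


def test_missing_delta_ranks_above_numeric():
    chosen = dsn.select_assay(
        [_candidate(42, 20.0), _candidate(None, 30.0, fwd="AGGCGCAATACGATGGTCGA")]
    )
    assert chosen.delta_ct is None


def test_single_large_gap_candidate_selected():
    chosen = dsn.select_assay([_candidate(42, 20.0)], taxon="Aphelenchidae")
    assert chosen.status == "selected"
    assert chosen.delta_ct == 42


def test_all_candidates_below_threshold_is_an_error():
    with pytest.raises(ValueError, match="no assay passes"):
        dsn.select_assay([_candidate(11, 20.0), _candidate(-5, 25.0)])


def test_selection_invariant_under_candidate_permutation():
    rng = np.random.default_rng(9)
    fwd_variants = ["AGGCGCAATACGATGGTCG" + b for b in "ACGT"]
    candidates = [
        _candidate(d, u, fwd=f)
        for d, u, f in zip((13, 20, 20, None), (25, 24, 21, 30), fwd_variants)
    ]
    baseline = dsn.select_assay(candidates)
    for _ in range(10):
        perm = [candidates[i] for i in rng.permutation(len(candidates))]
        assert dsn.select_assay(perm) == baseline


def test_negative_empirical_delta_always_discarded():
    with pytest.raises(ValueError, match="no assay passes"):
        dsn.select_assay([_candidate(-26, 20.0)])
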
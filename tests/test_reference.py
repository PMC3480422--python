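"""Reference-framework loading, monophyly and occurrence-table summaries."""

import itertools

import numpy as np
import pytest

from conftest import make_alignment, make_group, make_tree

import nemaquant.reference as ref
from nemaquant.synth import SyntheticSpec, generate_reference_set

# ---------------------------------------------------------------------------
# loading


def _write_framework(tmp_path, fasta, taxonomy, newick):
    a = tmp_path / "aln.fasta"
    t = tmp_path / "tax.tsv"
    n = tmp_path / "tree.nwk"
    a.write_text(fasta)
    t.write_text(taxonomy)
    n.write_text(newick)
    return a, t, n


SMALL_FASTA = (
    ">A\nACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT\n"
    ">B\nACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGA\n"
    ">C\nTTGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT\n"
    ">D\nTTGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGA\n"
)
SMALL_TAX = (
    "id\tgenus\tfamily\tguild\tcp\n"
    "A\tG1\tF1\tB\t2\nB\tG1\tF1\tB\t2\nC\tG2\tF2\tF\t3\nD\tG2\tF2\tF\t3\n"
)


def test_load_framework_builds_groups_at_both_ranks(tmp_path):
    paths = _write_framework(tmp_path, SMALL_FASTA, SMALL_TAX, "((A,B),(C,D));")
    seqs, groups, tree = ref.load_framework(*paths)
    assert len(seqs) == 4
    assert groups["G1"].member_ids == frozenset({"A", "B"})
    assert groups["G2"].member_ids == frozenset({"C", "D"})
    assert groups["F1"].rank == "family" and groups["G1"].rank == "genus"
    assert seqs["A"].ungapped_length == 60


def test_ragged_alignment_rejected(tmp_path):
    fasta = ">A\nACGTACGT\n>B\nACGTACG\n"
    paths = _write_framework(tmp_path, fasta, SMALL_TAX, "(A,B);")
    with pytest.raises(ref.FrameworkFormatError, match="ragged"):
        ref.load_framework(*paths)


def test_unknown_taxonomy_id_reported_by_name(tmp_path):
    tax = SMALL_TAX + "X9\tG3\tF3\tB\t2\n"
    paths = _write_framework(tmp_path, SMALL_FASTA, tax, "((A,B),(C,D));")
    with pytest.raises(ref.FrameworkFormatError, match="X9"):
        ref.load_framework(*paths)


def test_empty_taxonomy_rejected(tmp_path):
    paths = _write_framework(
        tmp_path, SMALL_FASTA, "id\tgenus\tfamily\n", "((A,B),(C,D));"
    )
    with pytest.raises(ref.FrameworkFormatError, match="empty"):
        ref.load_framework(*paths)


def test_stray_tree_leaf_warned_and_pruned(tmp_path):
    paths = _write_framework(tmp_path, SMALL_FASTA, SMALL_TAX, "((A,B),(C,(D,E)));")
    with pytest.warns(UserWarning, match="E"):
        _seqs, _groups, tree = ref.load_framework(*paths)
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    assert leaves == {"A", "B", "C", "D"}


def test_synthetic_framework_round_trips(tmp_path):
    refset = generate_reference_set(SyntheticSpec(seed=1, n_taxa=8))
    paths = refset.write(tmp_path)
    seqs, groups, _tree = ref.load_framework(
        paths["alignment"], paths["taxonomy"], paths["tree"]
    )
    assert {k: v.aligned_seq for k, v in seqs.items()} == {
        k: v.aligned_seq for k, v in refset.sequences.items()
    }
    original = refset.groups()
    assert set(groups) == set(original)
    for name in groups:
        assert groups[name].member_ids == original[name].member_ids
        assert groups[name].rank == original[name].rank


# ---------------------------------------------------------------------------
# monophyly


def test_clean_bipartition_is_monophyletic(quartet_tree):
    report = ref.check_monophyly(quartet_tree, make_group("F", {"A", "B"}))
    assert report.status == ref.MONOPHYLETIC
    assert report.intruder_ids == frozenset()


def test_split_pair_is_not_monophyletic(quartet_tree):
    report = ref.check_monophyly(quartet_tree, make_group("F", {"A", "C"}))
    assert report.status == ref.NOT_MONOPHYLETIC
    # MRCA of {A, C} is the root: B and D intrude
    assert report.intruder_ids == frozenset({"B", "D"})


def test_single_leaf_taxon_monophyletic_by_convention(quartet_tree):
    report = ref.check_monophyly(quartet_tree, make_group("F", {"A"}))
    assert report.status == ref.SINGLE_LEAF
    assert report.is_monophyletic


def test_absent_taxon_unresolvable(quartet_tree):
    report = ref.check_monophyly(quartet_tree, make_group("F", {"X", "Y"}))
    assert report.status == ref.UNRESOLVABLE


def _random_newick(rng, labels):
    """Random rooted topology over the given leaf labels."""
    if len(labels) == 1:
        return labels[0]
    k = int(rng.integers(1, len(labels)))
    left, right = labels[:k], labels[k:]
    return f"({_random_newick(rng, left)},{_random_newick(rng, right)})"


def _oracle_monophyly(tree, members):
    """Brute force: enumerate every clade (each node's leaf set)."""
    clades = []
    for node in tree.preorder_node_iter():
        leaves = frozenset(
            l.taxon.label for l in node.leaf_iter() if l.taxon is not None
        )
        clades.append(leaves)
    is_mono = frozenset(members) in clades
    supersets = [c for c in clades if frozenset(members) <= c]
    smallest = min(supersets, key=len)
    return is_mono, smallest - frozenset(members)


def test_monophyly_agrees_with_clade_enumeration_oracle():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(3, 9))
        labels = [f"L{i}" for i in rng.permutation(n)]
        tree = make_tree(_random_newick(rng, labels) + ";")
        k = int(rng.integers(2, n + 1))
        members = set(rng.choice([f"L{i}" for i in range(n)], size=k, replace=False))
        report = ref.check_monophyly(tree, make_group("T", members))
        is_mono, intruders = _oracle_monophyly(tree, members)
        assert (report.status == ref.MONOPHYLETIC) == is_mono
        assert report.intruder_ids == frozenset(intruders)


# ---------------------------------------------------------------------------
# assay-target resolution


def _groups_and_reports(newick, fam_members, genus_members):
    tree = make_tree(newick)
    groups = {}
    for fam, members in fam_members.items():
        groups[fam] = make_group(fam, members, rank="family")
    for genus, members in genus_members.items():
        groups[genus] = make_group(genus, members, rank="genus")
    reports = {n: ref.check_monophyly(tree, g) for n, g in groups.items()}
    return groups, reports


def test_monophyletic_family_targeted_at_family_rank():
    groups, reports = _groups_and_reports(
        "((A,B),(C,D));", {"F1": {"A", "B"}}, {"G1": {"A", "B"}}
    )
    res = ref.resolve_assay_targets(groups, reports)
    assert [t.name for t in res.targets] == ["F1"]
    assert res.unassayable == []


def test_polyphyletic_family_split_into_monophyletic_genera():
    # family {A, B, C, D} interleaved with outgroup X; genera {A,B} and {C,D}
    # each form clades: two genus-rank targets
    groups, reports = _groups_and_reports(
        "(((A,B),X),(C,D));",
        {"F1": {"A", "B", "C", "D"}},
        {"G1": {"A", "B"}, "G2": {"C", "D"}},
    )
    res = ref.resolve_assay_targets(groups, reports)
    assert sorted(t.name for t in res.targets) == ["G1", "G2"]
    assert all(t.rank == "genus" for t in res.targets)


def test_family_with_no_monophyletic_genus_flagged_unassayable():
    # genera fully interleaved: neither family nor genus rank works
    groups, reports = _groups_and_reports(
        "((A,C),(B,D),(X,Y));",
        {"F1": {"A", "B", "C", "D"}},
        {"G1": {"A", "B"}, "G2": {"C", "D"}},
    )
    res = ref.resolve_assay_targets(groups, reports)
    assert res.targets == []
    assert res.unassayable == ["F1"]


def test_resolved_targets_never_overlap():
    refset = generate_reference_set(SyntheticSpec(seed=5, polyphyletic_family="Fam02"))
    groups = refset.groups()
    tree = make_tree(refset.newick)
    reports = ref.check_all_monophyly(tree, groups)
    res = ref.resolve_assay_targets(groups, reports)
    seen = set()
    for t in res.targets:
        assert not (seen & t.member_ids)
        seen |= t.member_ids


# ---------------------------------------------------------------------------
# occurrence table


def test_packaged_survey_tallies():
    table = ref.load_occurrence_table()
    assert table.n_genera() == 45
    assert table.n_present("field") == 38
    assert table.n_present("forest") == 25
    assert table.n_qpcr() == 20
    assert table.n_range() == 16


def test_coverage_fractions_from_packaged_survey():
    table = ref.load_occurrence_table()
    # forest: 13 of 18 non-plant-parasitic genera covered
    assert ref.coverage_fraction(table, "forest") == 72
    # field: 20 of 31 by the same counting rule
    assert ref.coverage_fraction(table, "field") == 65


def test_counts_invariant_under_row_permutation():
    table = ref.load_occurrence_table()
    rng = np.random.default_rng(3)
    shuffled = ref.OccurrenceTable(
        table.rows.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(
            drop=True
        )
    )
    assert shuffled.n_present("field") == table.n_present("field")
    assert ref.coverage_fraction(shuffled, "forest") == ref.coverage_fraction(
        table, "forest"
    )


def test_empty_table_counts_zero(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text("genus,family,qpcr,range,plant_parasite,field,forest\n")
    table = ref.load_occurrence_table(p)
    assert table.n_genera() == 0
    assert table.n_present("field") == 0
    with pytest.raises(ValueError):
        ref.coverage_fraction(table, "field")


def test_duplicate_genus_rejected(tmp_path):
    p = tmp_path / "dup.csv"
    p.write_text(
        "genus,family,qpcr,range,plant_parasite,field,forest\n"
        "Plectus,Plectidae,1,1,0,1,1\nPlectus,Plectidae,1,0,0,1,0\n"
    )
    with pytest.raises(ref.FrameworkFormatError, match="Plectus"):
        ref.load_occurrence_table(p)


def test_all_flagged_non_parasitic_gives_full_coverage(tmp_path):
    p = tmp_path / "full.csv"
    p.write_text(
        "genus,family,qpcr,range,plant_parasite,field,forest\n"
        "Ga,F,1,0,0,1,1\nGb,F,1,0,0,1,0\n"
    )
    assert ref.coverage_fraction(ref.load_occurrence_table(p), "field") == 100
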
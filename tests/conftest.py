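import dendropy
import pytest

from nemaquant.reference import ReferenceSequence, TaxonGroup


def make_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def make_alignment(**seqs: str) -> dict[str, ReferenceSequence]:
    return {sid: ReferenceSequence(sid, s) for sid, s in seqs.items()}


def make_group(name: str, members, rank: str = "family") -> TaxonGroup:
    return TaxonGroup(name=name, rank=rank, member_ids=frozenset(members))


@pytest.fixture
def quartet_tree():
    return make_tree("((A,B),(C,D));")
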
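"""Reference framework: aligned SSU rDNA set, taxonomy, phylogeny, monophyly.

Taxon-specific qPCR assays are only meaningful for groups that form clades in
the reference phylogeny — a single sequence signature cannot cover a
polyphyletic family. This module loads and validates the aligned reference
set, decides per family whether the assay target is the family itself or its
monophyletic constituent genera, and summarizes genus-occurrence tables from
microscopy surveys.

Coordinates are 0-based half-open internally and 1-based inclusive in
user-facing reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO

from .iupac import GAP

GUILD_CODES = frozenset({"B", "F", "FP", "O", "P"})

MONOPHYLETIC = "monophyletic"
NOT_MONOPHYLETIC = "paraphyletic/polyphyletic"
SINGLE_LEAF = "single-leaf"
UNRESOLVABLE = "unresolvable"


class FrameworkFormatError(ValueError):
    """Malformed alignment, taxonomy or tree input."""


@dataclass(frozen=True)
class ReferenceSequence:
    """One aligned reference sequence (IUPAC codes plus '-')."""

    id: str
    aligned_seq: str

    @property
    def ungapped_length(self) -> int:
        return len(self.aligned_seq) - self.aligned_seq.count(GAP)

    def ungapped(self) -> str:
        return self.aligned_seq.replace(GAP, "")


@dataclass
class TaxonGroup:
    """A monitored family or genus with its member reference sequences.

    guild uses the five legend codes (B bacterivore, F fungivore,
    FP facultative plant parasite, O omnivore, P predator); cp_value is the
    1-5 colonizer-persister life-history score.
    """

    name: str
    rank: str  # "family" | "genus"
    member_ids: frozenset[str]
    guild: str | None = None
    cp_value: int | None = None
    observed_genera: int = 0

    def __post_init__(self) -> None:
        if self.rank not in ("family", "genus"):
            raise ValueError(f"rank must be family or genus, got {self.rank!r}")
        if not self.member_ids:
            raise ValueError(f"taxon group {self.name!r} has no members")
        if self.guild is not None:
            for code in str(self.guild).replace("/", ",").split(","):
                if code.strip() and code.strip() not in GUILD_CODES:
                    raise ValueError(f"unknown guild code {code!r}")
        if self.cp_value is not None and not 1 <= int(self.cp_value) <= 5:
            raise ValueError(f"cp value must be in [1, 5], got {self.cp_value}")


@dataclass(frozen=True)
class MonophylyReport:
    taxon: str
    status: str
    intruder_ids: frozenset[str] = frozenset()
    member_leaves: frozenset[str] = frozenset()

    @property
    def is_monophyletic(self) -> bool:
        return self.status in (MONOPHYLETIC, SINGLE_LEAF)


@dataclass
class AssayTargetResolution:
    targets: list[TaxonGroup]
    unassayable: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# loading


def read_alignment(path: str | Path) -> dict[str, ReferenceSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FrameworkFormatError(f"no sequences in {path}")
    seqs: dict[str, ReferenceSequence] = {}
    lengths = set()
    for rec in records:
        if rec.id in seqs:
            raise FrameworkFormatError(f"duplicate sequence id {rec.id!r}")
        aligned = str(rec.seq).upper()
        if not aligned:
            raise FrameworkFormatError(f"empty sequence {rec.id!r}")
        seqs[rec.id] = ReferenceSequence(rec.id, aligned)
        lengths.add(len(aligned))
    if len(lengths) != 1:
        raise FrameworkFormatError(
            f"ragged alignment: aligned lengths {sorted(lengths)}"
        )
    return seqs


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"id", "genus", "family"}
    missing = required - set(tax.columns)
    if missing:
        raise FrameworkFormatError(f"taxonomy missing columns: {sorted(missing)}")
    if tax.empty:
        raise FrameworkFormatError("taxonomy table is empty")
    if tax["id"].duplicated().any():
        dups = sorted(tax.loc[tax["id"].duplicated(), "id"])
        raise FrameworkFormatError(f"duplicate taxonomy ids: {dups}")
    return tax


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree; topology is treated as rooted as written."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


def build_groups(tax: pd.DataFrame) -> dict[str, TaxonGroup]:
    """Family- and genus-rank groups keyed by taxon name."""
    groups: dict[str, TaxonGroup] = {}
    for rank in ("family", "genus"):
        for name, sub in tax.groupby(rank, sort=True):
            meta = {}
            if "guild" in sub.columns:
                guilds = sub["guild"].dropna().unique()
                meta["guild"] = guilds[0] if len(guilds) else None
            if "cp" in sub.columns:
                cps = sub["cp"].dropna().unique()
                meta["cp_value"] = int(cps[0]) if len(cps) else None
            if name in groups:
                raise FrameworkFormatError(
                    f"taxon name {name!r} used at more than one rank"
                )
            groups[str(name)] = TaxonGroup(
                name=str(name),
                rank=rank,
                member_ids=frozenset(sub["id"]),
                observed_genera=sub["genus"].nunique(),
                **meta,
            )
    return groups


def load_framework(
    alignment_path: str | Path,
    taxonomy_path: str | Path,
    tree_path: str | Path,
) -> tuple[dict[str, ReferenceSequence], dict[str, TaxonGroup], dendropy.Tree]:
    """Load and cross-validate alignment, taxonomy and phylogeny.

    Taxonomy ids must be a subset of alignment ids; tree leaves not in the
    alignment are pruned with a warning.
    """
    seqs = read_alignment(alignment_path)
    tax = read_taxonomy(taxonomy_path)
    unknown = sorted(set(tax["id"]) - set(seqs))
    if unknown:
        raise FrameworkFormatError(
            f"taxonomy references ids absent from the alignment: {unknown}"
        )
    groups = build_groups(tax)
    tree = read_tree(tree_path)
    stray = [
        leaf.taxon.label
        for leaf in tree.leaf_node_iter()
        if leaf.taxon is not None and leaf.taxon.label not in seqs
    ]
    if stray:
        warnings.warn(
            f"tree leaves absent from the alignment were ignored: {sorted(stray)}",
            stacklevel=2,
        )
        tree.prune_taxa_with_labels(stray)
    return seqs, groups, tree


# ---------------------------------------------------------------------------
# monophyly


def _leaf_labels(node: dendropy.Node) -> set[str]:
    return {
        leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon is not None
    }


def check_monophyly(tree: dendropy.Tree, taxon: TaxonGroup) -> MonophylyReport:
    """Monophyly status of a taxon on the rooted tree as written.

    The smallest clade (MRCA subtree) spanning the member leaves is located;
    non-member leaves inside it are the intruders. Single-leaf taxa are
    monophyletic by convention; taxa with no leaf in the tree are
    unresolvable.
    """
    tree.is_rooted = True  # rooted as written; see module design notes
    labels = {
        leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None
    }
    members = set(taxon.member_ids) & labels
    if not members:
        return MonophylyReport(taxon.name, UNRESOLVABLE)
    if len(members) == 1:
        return MonophylyReport(
            taxon.name, SINGLE_LEAF, member_leaves=frozenset(members)
        )
    mrca = tree.mrca(taxa=[t for t in tree.taxon_namespace if t.label in members])
    clade = _leaf_labels(mrca)
    intruders = frozenset(clade - members)
    status = MONOPHYLETIC if not intruders else NOT_MONOPHYLETIC
    return MonophylyReport(
        taxon.name, status, intruder_ids=intruders, member_leaves=frozenset(members)
    )


def check_all_monophyly(
    tree: dendropy.Tree, groups: Mapping[str, TaxonGroup]
) -> dict[str, MonophylyReport]:
    return {name: check_monophyly(tree, grp) for name, grp in groups.items()}


def resolve_assay_targets(
    groups: Mapping[str, TaxonGroup],
    reports: Mapping[str, MonophylyReport],
) -> AssayTargetResolution:
    """Decide the rank at which each family can be targeted by one assay.

    Monophyletic families are kept at family rank. A non-monophyletic family
    is replaced by those of its constituent genus groups that are themselves
    monophyletic (the Diphtherophoridae pattern: one assay per genus). A
    family with no monophyletic representation at either rank is flagged
    un-assayable (the Rhabditidae case) — flagged, never silently dropped.
    """
    resolution = AssayTargetResolution(targets=[])
    families = sorted(n for n, g in groups.items() if g.rank == "family")
    for fam in families:
        report = reports.get(fam)
        if report is None:
            raise KeyError(f"no monophyly report for family {fam!r}")
        if report.is_monophyletic:
            resolution.targets.append(groups[fam])
            continue
        fam_members = groups[fam].member_ids
        genus_targets = [
            groups[name]
            for name in sorted(groups)
            if groups[name].rank == "genus"
            and groups[name].member_ids <= fam_members
            and name in reports
            and reports[name].is_monophyletic
        ]
        if genus_targets:
            resolution.targets.extend(genus_targets)
        else:
            resolution.unassayable.append(fam)
    seen: set[str] = set()
    for tgt in resolution.targets:
        overlap = seen & tgt.member_ids
        if overlap:
            raise AssertionError(
                f"overlapping member sets across assay targets: {sorted(overlap)}"
            )
        seen |= tgt.member_ids
    return resolution


# ---------------------------------------------------------------------------
# genus-occurrence tables


@dataclass
class OccurrenceTable:
    """Genus-level microscopy occurrence table with assay and habitat flags."""

    rows: pd.DataFrame  # genus, family, qpcr, range, plant_parasite, field, forest

    REQUIRED = ("genus", "family", "qpcr", "range", "plant_parasite", "field", "forest")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.rows.columns)
        if missing:
            raise FrameworkFormatError(
                f"occurrence table missing columns: {sorted(missing)}"
            )
        if self.rows["genus"].duplicated().any():
            dups = sorted(self.rows.loc[self.rows["genus"].duplicated(), "genus"])
            raise FrameworkFormatError(f"duplicate genera: {dups}")
        for col in ("qpcr", "range", "plant_parasite", "field", "forest"):
            self.rows[col] = self.rows[col].astype(bool)

    def n_genera(self) -> int:
        return len(self.rows)

    def n_present(self, habitat: str) -> int:
        return int(self.rows[_habitat_col(habitat)].sum())

    def n_qpcr(self) -> int:
        return int(self.rows["qpcr"].sum())

    def n_range(self) -> int:
        return int(self.rows["range"].sum())


def _habitat_col(habitat: str) -> str:
    if habitat not in ("field", "forest"):
        raise ValueError(f"habitat must be 'field' or 'forest', got {habitat!r}")
    return habitat


def load_occurrence_table(path: str | Path | None = None) -> OccurrenceTable:
    """Load a genus-occurrence CSV; with no path, the packaged survey table."""
    if path is None:
        from .datasets import occurrence_table_path

        path = occurrence_table_path()
    rows = pd.read_csv(path, comment="#")
    if rows.empty:
        rows = pd.DataFrame(columns=list(OccurrenceTable.REQUIRED))
    return OccurrenceTable(rows)


def coverage_fraction(table: OccurrenceTable, habitat: str) -> int:
    """Percent of a habitat's non-plant-parasitic genera covered by qPCR assays.

    100 x (genera present in the habitat with a qPCR assay) /
          (genera present in the habitat that are not obligate plant
           parasites), rounded to the nearest integer percent.
    """
    col = _habitat_col(habitat)
    present = table.rows[table.rows[col]]
    denom = int((~present["plant_parasite"]).sum())
    if denom == 0:
        raise ValueError(f"no non-plant-parasitic genera present in {habitat}")
    numer = int(present["qpcr"].sum())
    return int(round(100.0 * numer / denom))
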
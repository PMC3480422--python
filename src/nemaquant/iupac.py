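"""IUPAC nucleotide codes, ambiguity-set matching and reverse complement.

A reference position matches a primer base when the two IUPAC ambiguity sets
intersect; gaps ('-') never match anything. This "intersection" rule is
deliberately conservative for specificity claims: a degenerate base that
*could* pair is counted as a match, so in-silico mismatch counts are lower
bounds.
"""

from __future__ import annotations

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}

GAP = "-"


def is_nucleotide(ch: str) -> bool:
    return ch.upper() in IUPAC_SETS


def bases_intersect(a: str, b: str) -> bool:
    """True if the ambiguity sets of two IUPAC codes share a base.

    A gap on either side never matches.
    """
    a, b = a.upper(), b.upper()
    if a == GAP or b == GAP:
        return False
    try:
        return bool(IUPAC_SETS[a] & IUPAC_SETS[b])
    except KeyError as exc:
        raise ValueError(f"not an IUPAC nucleotide code: {exc.args[0]!r}") from exc


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[ch] for ch in seq.upper()[::-1])
    except KeyError as exc:
        raise ValueError(f"not an IUPAC nucleotide code: {exc.args[0]!r}") from exc


def expand_ambiguities(seq: str, limit: int = 64) -> list[str]:
    """All unambiguous A/C/G/T expansions of ``seq``, at most ``limit``.

    Raises ValueError if the expansion space exceeds ``limit``.
    """
    seq = seq.upper()
    n = 1
    for ch in seq:
        if ch == GAP or ch not in IUPAC_SETS:
            raise ValueError(f"not an IUPAC nucleotide code: {ch!r}")
        n *= len(IUPAC_SETS[ch])
        if n > limit:
            raise ValueError(
                f"sequence expands to more than {limit} unambiguous variants"
            )
    variants = [""]
    for ch in seq:
        variants = [v + b for v in variants for b in sorted(IUPAC_SETS[ch])]
    return variants


def ungap(seq: str) -> str:
    return seq.replace(GAP, "")
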
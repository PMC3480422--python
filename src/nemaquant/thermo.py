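"""Nearest-neighbor duplex melting temperature for primer design.

The model is the unified two-state nearest-neighbor formalism: duplex
formation enthalpy and entropy are sums of stacked-dinucleotide terms plus
terminal initiation terms, entropy is corrected for monovalent cation
concentration with a logarithmic term, and

    Tm = 1000 * dH / (dS + R * ln(C_T / x)) - 273.15

with R = 1.987 cal/(mol*K), C_T the primer strand concentration and x = 4
for non-self-complementary duplexes (x = 1, plus a symmetry entropy penalty,
for self-complementary ones). The parameter table ships as a versioned data
file (``data/nn_unified.csv``) so golden values stay stable.

Default conditions are 50 mM Na+-equivalent and 200 nM primer.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .iupac import expand_ambiguities, reverse_complement

R_GAS = 1.987  # cal/(mol*K)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class ThermoConditions:
    """Solution conditions for the duplex model.

    monovalent_cation_M
        Na+-equivalent concentration in mol/l.
    primer_conc_M
        Total primer strand concentration in mol/l.
    """

    monovalent_cation_M: float = 0.05
    primer_conc_M: float = 200e-9


DEFAULT_CONDITIONS = ThermoConditions()


@lru_cache(maxsize=1)
def _load_nn_table() -> dict[str, tuple[float, float]]:
    text = resources.files("nemaquant.data").joinpath("nn_unified.csv").read_text()
    table: dict[str, tuple[float, float]] = {}
    for row in csv.DictReader(
        line for line in text.splitlines() if not line.startswith("#")
    ):
        table[row["pair"]] = (float(row["dh"]), float(row["ds"]))
    # complementary stacks share parameters with their reverse complement
    for pair in list(table):
        if len(pair) == 2:
            rc = pair.translate(_COMPLEMENT)[::-1]
            table.setdefault(rc, table[pair])
    return table


def _is_self_complementary(seq: str) -> bool:
    return seq == seq.translate(_COMPLEMENT)[::-1]


def _tm_unambiguous(seq: str, conditions: ThermoConditions) -> float:
    table = _load_nn_table()
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = table[seq[i : i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = table["init_GC"] if terminal in "GC" else table["init_AT"]
        dh += h
        ds += s
    selfcomp = _is_self_complementary(seq)
    if selfcomp:
        h, s = table["symmetry"]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(conditions.monovalent_cation_M)
    x = 1.0 if selfcomp else 4.0
    return 1000.0 * dh / (ds + R_GAS * math.log(conditions.primer_conc_M / x)) - 273.15


def compute_tm(
    primer_sequence: str,
    conditions: ThermoConditions = DEFAULT_CONDITIONS,
) -> float:
    """Melting temperature (°C) of a primer against its perfect complement.

    Ambiguous IUPAC bases are expanded (up to 64 variants) and the worst-case
    — lowest — Tm over the expansions is returned, the conservative choice
    when checking that a degenerate primer still anneals at the assay
    temperature.

    Raises ValueError for sequences shorter than 8 nt or containing
    non-nucleotide characters.
    """
    seq = primer_sequence.upper()
    if len(seq) < 8:
        raise ValueError("primer must be at least 8 nt for the duplex model")
    variants = expand_ambiguities(seq)  # validates the alphabet
    return min(_tm_unambiguous(v, conditions) for v in variants)


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    return sum(ch in "GCS" for ch in seq) / len(seq)


__all__ = [
    "ThermoConditions",
    "DEFAULT_CONDITIONS",
    "compute_tm",
    "gc_fraction",
    "reverse_complement",
]
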
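"""Taxon-specific assay design from the aligned SSU rDNA reference set.

The design logic mirrors signature-based qPCR primer development: find
alignment windows where every member of the target taxon agrees but every
close non-target differs (a *signature motif*), turn window pairs into primer
pairs constrained to a uniform annealing temperature (63 °C by default, so
all assays run on one plate), score specificity — empirically as the ΔCt gap
between the latest target and earliest non-target when measurements exist,
otherwise with an explicit in-silico mismatch heuristic — and select one
assay per taxon, discarding anything with ΔCt below 12 cycles.

IUPAC degeneracy is handled by ambiguity-set intersection: intersecting sets
count as a match, which makes in-silico mismatch counts conservative lower
bounds for specificity claims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from .iupac import GAP, IUPAC_SETS, reverse_complement
from .reference import ReferenceSequence, TaxonGroup
from .thermo import DEFAULT_CONDITIONS, ThermoConditions, compute_tm, gc_fraction

#: 3'-terminal region (nt) used for mismatch weighting and the amplification
#: block rule: polymerase extension is far more sensitive to mismatches here.
THREE_PRIME_REGION = 5

_BITS = {code: sum(1 << "ACGT".index(b) for b in bases)
         for code, bases in IUPAC_SETS.items()}
_BITS[GAP] = 0


@lru_cache(maxsize=8192)
def _seq_bits_cached(seq: str) -> np.ndarray:
    return np.array([_BITS.get(ch, 0) for ch in seq.upper()], dtype=np.uint8)


def _seq_bits(seq: str) -> np.ndarray:
    return _seq_bits_cached(seq)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SignatureWindow:
    """A candidate signature motif on the representative target sequence.

    start/end are 0-based half-open ungapped coordinates on the
    representative; columns are the corresponding alignment columns.
    """

    start: int
    end: int
    sequence: str
    columns: tuple[int, ...]
    min_nontarget_mismatches: int
    min_nontarget_3p_mismatches: int

    def report_coords(self) -> tuple[int, int]:
        """1-based inclusive coordinates for user-facing reports."""
        return self.start + 1, self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PrimerCandidate:
    sequence: str  # 5'->3'
    ref_window: tuple[int, int]  # ungapped coords on the representative
    strand: str  # "forward" | "reverse"
    tm: float
    gc_fraction: float
    columns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 15 <= len(self.sequence) <= 30:
            raise ValueError(
                f"primer length {len(self.sequence)} outside 15-30 nt"
            )
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"strand must be forward/reverse, got {self.strand!r}")
        if not math.isfinite(self.tm):
            raise ValueError("primer Tm must be finite")


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    amplicon_length: int
    ta: float = 63.0

    def __post_init__(self) -> None:
        if self.forward.ref_window[0] >= self.reverse.ref_window[0]:
            raise ValueError("forward primer must precede the reverse primer")
        if self.amplicon_length <= 0:
            raise ValueError("amplicon length must be positive")


@dataclass(frozen=True)
class NonTargetHit:
    mismatches_total_fwd: int
    mismatches_3prime_fwd: int
    mismatches_total_rev: int
    mismatches_3prime_rev: int
    predicted_amplifiable: bool


@dataclass(frozen=True)
class SpecificityScore:
    per_nontarget: Mapping[str, NonTargetHit]
    delta_ct: float | None  # None = not available (no non-target signal)
    source: str  # "in_silico" | "empirical"


@dataclass(frozen=True)
class TaProfile:
    """Ct readings of one primer pair on target template across Ta values."""

    points: tuple[tuple[float, float], ...]  # (ta °C, ct cycles)


@dataclass(frozen=True)
class TaAssessment:
    sharpness: float  # ΔCt per °C above the design Ta
    passed: bool
    reason: str = ""


@dataclass(frozen=True)
class AssayDefinition:
    taxon: str
    pair: PrimerPair
    delta_ct: float | None
    status: str  # "selected" | "discarded"


@dataclass(frozen=True)
class PairConstraints:
    ta_target: float = 63.0
    ta_tolerance: float = 1.0
    amplicon_min: int = 80
    amplicon_max: int = 400
    primer_min_len: int = 18
    primer_max_len: int = 25
    max_tm_difference: float = 2.0


# ---------------------------------------------------------------------------
# signature discovery


def _aligned_str(seq: ReferenceSequence | str) -> str:
    return seq.aligned_seq if isinstance(seq, ReferenceSequence) else str(seq)


def find_signature_windows(
    alignment: Mapping[str, ReferenceSequence | str],
    target: TaxonGroup,
    nontarget_ids: Iterable[str] | None = None,
    min_len: int = 18,
    max_len: int = 25,
    min_mismatches: int = 3,
) -> list[SignatureWindow]:
    """Windows where all target members agree and every non-target differs.

    Windows are enumerated on the ungapped coordinate system of the
    representative target sequence (the lexicographically first member) for
    every length in [min_len, max_len]. A window qualifies when every target
    member matches the representative at every column (ambiguity sets
    intersect; any member gap disqualifies) and every non-target carries at
    least ``min_mismatches`` mismatching columns. Ranking is by the worst
    (smallest) non-target mismatch count, 3'-region mismatches weighted
    first. Returns an empty list when no signature exists.
    """
    member_ids = sorted(target.member_ids)
    missing = [m for m in member_ids if m not in alignment]
    if missing:
        raise KeyError(f"target members absent from alignment: {missing}")
    if nontarget_ids is None:
        nontarget_ids = [k for k in alignment if k not in target.member_ids]
    nontarget_ids = sorted(nontarget_ids)
    if not nontarget_ids:
        raise ValueError("at least one non-target sequence is required")

    rep_id = member_ids[0]
    rep_aligned = _aligned_str(alignment[rep_id])
    cols = np.flatnonzero(_seq_bits(rep_aligned) != 0)  # non-gap columns of rep
    rep_bits = _seq_bits(rep_aligned)[cols]
    L = cols.size

    member_bits = np.stack(
        [_seq_bits(_aligned_str(alignment[m]))[cols] for m in member_ids]
    )
    target_ok = ((member_bits & rep_bits) != 0).all(axis=0)  # (L,)

    nt_bits = np.stack(
        [_seq_bits(_aligned_str(alignment[t]))[cols] for t in nontarget_ids]
    )
    nt_mismatch = ((nt_bits & rep_bits) == 0).astype(np.int32)  # (n_nt, L)

    ok_cum = np.concatenate([[0], np.cumsum(target_ok.astype(np.int32))])
    mm_cum = np.concatenate(
        [np.zeros((nt_mismatch.shape[0], 1), dtype=np.int64),
         np.cumsum(nt_mismatch, axis=1)], axis=1
    )

    rep_ungapped = "".join(rep_aligned[c] for c in cols)
    windows: list[SignatureWindow] = []
    for length in range(min_len, max_len + 1):
        if length > L:
            break
        starts = np.arange(L - length + 1)
        conserved = (ok_cum[starts + length] - ok_cum[starts]) == length
        tot = mm_cum[:, starts + length] - mm_cum[:, starts]  # (n_nt, n_starts)
        p3 = mm_cum[:, starts + length] - mm_cum[:, starts + length - THREE_PRIME_REGION]
        min_tot = tot.min(axis=0)
        for s in starts[conserved & (min_tot >= min_mismatches)]:
            windows.append(
                SignatureWindow(
                    start=int(s),
                    end=int(s + length),
                    sequence=rep_ungapped[s : s + length],
                    columns=tuple(int(c) for c in cols[s : s + length]),
                    min_nontarget_mismatches=int(tot[:, s].min()),
                    min_nontarget_3p_mismatches=int(p3[:, s].min()),
                )
            )
    windows.sort(
        key=lambda w: (
            -w.min_nontarget_3p_mismatches,
            -w.min_nontarget_mismatches,
            w.start,
            -(w.end - w.start),
        )
    )
    return windows


# ---------------------------------------------------------------------------
# primer pairing


def _window_to_primer(
    window: SignatureWindow, strand: str, conditions: ThermoConditions
) -> PrimerCandidate:
    seq = (
        window.sequence
        if strand == "forward"
        else reverse_complement(window.sequence)
    )
    return PrimerCandidate(
        sequence=seq,
        ref_window=(window.start, window.end),
        strand=strand,
        tm=compute_tm(seq, conditions),
        gc_fraction=gc_fraction(seq),
        columns=window.columns,
    )


def enumerate_primer_pairs(
    windows: Sequence[SignatureWindow],
    conditions: ThermoConditions = DEFAULT_CONDITIONS,
    constraints: PairConstraints = PairConstraints(),
) -> list[PrimerPair]:
    """All forward/reverse window combinations meeting the pair constraints.

    Both primers must sit within the annealing-temperature window
    (ta_target ± ta_tolerance), differ by at most max_tm_difference, and
    bracket an amplicon within the configured length bounds. Sorted by worst
    deviation from the target Ta.
    """
    usable = [
        w for w in windows
        if constraints.primer_min_len <= len(w) <= constraints.primer_max_len
    ]
    primers: dict[tuple[int, int], tuple[PrimerCandidate, PrimerCandidate]] = {}
    for w in usable:
        primers[(w.start, w.end)] = (
            _window_to_primer(w, "forward", conditions),
            _window_to_primer(w, "reverse", conditions),
        )
    pairs: list[PrimerPair] = []
    for w1 in usable:
        for w2 in usable:
            if w2.start <= w1.end:  # reverse site must lie downstream
                continue
            amplicon = w2.end - w1.start
            if not constraints.amplicon_min <= amplicon <= constraints.amplicon_max:
                continue
            fwd = primers[(w1.start, w1.end)][0]
            rev = primers[(w2.start, w2.end)][1]
            dev = max(
                abs(fwd.tm - constraints.ta_target),
                abs(rev.tm - constraints.ta_target),
            )
            if dev > constraints.ta_tolerance:
                continue
            if abs(fwd.tm - rev.tm) > constraints.max_tm_difference:
                continue
            pairs.append(
                PrimerPair(
                    forward=fwd,
                    reverse=rev,
                    amplicon_length=amplicon,
                    ta=constraints.ta_target,
                )
            )
    pairs.sort(
        key=lambda p: (
            max(abs(p.forward.tm - constraints.ta_target),
                abs(p.reverse.tm - constraints.ta_target)),
            abs(p.forward.tm - constraints.ta_target)
            + abs(p.reverse.tm - constraints.ta_target),
            p.forward.sequence,
            p.reverse.sequence,
        )
    )
    return pairs


# ---------------------------------------------------------------------------
# specificity


def _site_mismatches(
    primer_bits: np.ndarray, template: str, columns: tuple[int, ...]
) -> np.ndarray:
    tmpl_bits = _seq_bits(template)[np.array(columns)]
    return (primer_bits & tmpl_bits) == 0


#: in-silico heuristic: cycles of delay contributed per primer-template
#: mismatch (roughly one tenfold dilution per three mismatches).
PROXY_CYCLES_PER_MISMATCH = 3.3


def score_specificity(
    pair: PrimerPair,
    target_seqs: Mapping[str, ReferenceSequence | str],
    nontarget_seqs: Mapping[str, ReferenceSequence | str],
    empirical: tuple[float, float] | None = None,
) -> SpecificityScore:
    """ΔCt specificity of a primer pair, empirical or in-silico.

    With empirical Cts (latest target Ct, earliest non-target Ct) the gap is
    ``earliest_nontarget - latest_target``. Otherwise a labelled heuristic:
    a non-target is predicted non-amplifiable when either primer carries ≥2
    mismatches in its 3'-terminal 5 nt or ≥4 total mismatches; amplifiable
    non-targets contribute a proxy ΔCt of 3.3 cycles per total mismatch, and
    if no non-target is predicted amplifiable ΔCt is not available (None).
    The pair must match every target member exactly (ambiguity-aware).
    """
    fwd_bits = _seq_bits(pair.forward.sequence)
    # reverse primer read 5'->3' on the opposite strand; compare its
    # template-strand image at the window columns
    rev_template = reverse_complement(pair.reverse.sequence)
    rev_bits = _seq_bits(rev_template)
    fwd_cols, rev_cols = pair.forward.columns, pair.reverse.columns
    if not fwd_cols or not rev_cols:
        raise ValueError("primers lack alignment columns for specificity scoring")

    for member, seq in target_seqs.items():
        aligned = _aligned_str(seq)
        if _site_mismatches(fwd_bits, aligned, fwd_cols).any() or _site_mismatches(
            rev_bits, aligned, rev_cols
        ).any():
            raise ValueError(f"primer pair fails to match target member {member!r}")

    per_nontarget: dict[str, NonTargetHit] = {}
    proxy_candidates: list[float] = []
    for nt_id in sorted(nontarget_seqs):
        aligned = _aligned_str(nontarget_seqs[nt_id])
        mm_f = _site_mismatches(fwd_bits, aligned, fwd_cols)
        mm_r = _site_mismatches(rev_bits, aligned, rev_cols)
        tot_f, tot_r = int(mm_f.sum()), int(mm_r.sum())
        # forward 3' end = last window columns; reverse primer 3' end maps to
        # the *first* columns of its template-strand window
        p3_f = int(mm_f[-THREE_PRIME_REGION:].sum())
        p3_r = int(mm_r[:THREE_PRIME_REGION].sum())
        amplifiable = not (
            p3_f >= 2 or p3_r >= 2 or tot_f >= 4 or tot_r >= 4
        )
        per_nontarget[nt_id] = NonTargetHit(tot_f, p3_f, tot_r, p3_r, amplifiable)
        if amplifiable:
            proxy_candidates.append(PROXY_CYCLES_PER_MISMATCH * (tot_f + tot_r))

    if empirical is not None:
        latest_target_ct, earliest_nontarget_ct = empirical
        return SpecificityScore(
            per_nontarget=per_nontarget,
            delta_ct=earliest_nontarget_ct - latest_target_ct,
            source="empirical",
        )
    delta = min(proxy_candidates) if proxy_candidates else None
    return SpecificityScore(
        per_nontarget=per_nontarget, delta_ct=delta, source="in_silico"
    )


def empirical_delta_ct(latest_target_ct: float, earliest_nontarget_ct: float) -> float:
    """Specificity gap: cycles between earliest non-target and latest target."""
    return earliest_nontarget_ct - latest_target_ct


# ---------------------------------------------------------------------------
# annealing-temperature optimum


def assess_ta_optimum(
    profile: TaProfile,
    ta_target: float = 63.0,
    sharpness_threshold: float = 1.0,
    minimum_tolerance: float = 0.5,
) -> TaAssessment:
    """Does the pair lose signal sharply above the design Ta?

    Sharpness is the slope of Ct against Ta over the points above the target
    temperature. The assessment passes when sharpness meets the threshold
    (default 1 cycle/°C) *and* the Ct at the design Ta is the profile minimum
    within tolerance — a pair whose optimum sits elsewhere is mis-designed.
    """
    pts = sorted(profile.points)
    if len(pts) < 3:
        raise ValueError("a Ta profile needs at least 3 temperature points")
    tas = np.array([p[0] for p in pts])
    cts = np.array([p[1] for p in pts])
    at = np.isclose(tas, ta_target, atol=0.25)
    if not at.any() or not (tas < ta_target).any() or not (tas > ta_target).any():
        raise ValueError("profile must include points at, below and above the design Ta")
    ct_at = float(cts[at].min())
    above = tas > ta_target
    if above.sum() >= 2:
        slope = float(np.polyfit(tas[above], cts[above], 1)[0])
    else:
        slope = float((cts[above][0] - ct_at) / (tas[above][0] - ta_target))
    if slope < sharpness_threshold:
        return TaAssessment(slope, False, "no sharp Ct increase above the design Ta")
    if ct_at > cts.min() + minimum_tolerance:
        return TaAssessment(slope, False, "Ct optimum is not at the design Ta")
    return TaAssessment(slope, True)


# ---------------------------------------------------------------------------
# assay selection


def _selection_key(candidate: tuple[PrimerPair, SpecificityScore, float]):
    pair, score, unit_ct = candidate
    # ΔCt not-available (no non-target signal) ranks above any numeric gap
    na_rank = 0 if score.delta_ct is None else 1
    delta = -math.inf if score.delta_ct is None else score.delta_ct
    return (
        na_rank,
        -delta,
        unit_ct,
        pair.forward.sequence,
        pair.reverse.sequence,
    )


def select_assay(
    candidates: Sequence[tuple[PrimerPair, SpecificityScore, float]],
    taxon: str = "",
    delta_ct_min: float = 12.0,
) -> AssayDefinition:
    """Pick one assay: drop ΔCt < 12, then maximize specificity.

    Among survivors the largest ΔCt wins (a missing ΔCt — no non-target
    signal at all — ranks above every numeric gap); ties break on the lowest
    Ct per unit of template, then on primer sequence for determinism under
    candidate-order permutation.
    """
    if not candidates:
        raise ValueError("no candidate primer pairs supplied")
    survivors = [
        c for c in candidates
        if c[1].delta_ct is None or c[1].delta_ct >= delta_ct_min
    ]
    if not survivors:
        raise ValueError("no assay passes ΔCt filter")
    pair, score, _ = min(survivors, key=_selection_key)
    return AssayDefinition(
        taxon=taxon, pair=pair, delta_ct=score.delta_ct, status="selected"
    )


def design_assay(
    alignment: Mapping[str, ReferenceSequence | str],
    target: TaxonGroup,
    nontarget_ids: Iterable[str] | None = None,
    conditions: ThermoConditions = DEFAULT_CONDITIONS,
    constraints: PairConstraints = PairConstraints(),
    min_mismatches: int = 3,
    max_windows: int = 300,
    max_pairs: int = 50,
) -> AssayDefinition | None:
    """End-to-end in-silico design for one target taxon.

    Signature discovery -> pair enumeration -> in-silico specificity ->
    selection. Returns None when no signature or no pair survives (the
    un-assayable outcome), never raising for an empty design space.
    """
    windows = find_signature_windows(
        alignment,
        target,
        nontarget_ids,
        min_len=constraints.primer_min_len,
        max_len=constraints.primer_max_len,
        min_mismatches=min_mismatches,
    )
    if not windows:
        return None
    pairs = enumerate_primer_pairs(windows[:max_windows], conditions, constraints)
    if not pairs:
        return None
    if nontarget_ids is None:
        nontarget_ids = [k for k in alignment if k not in target.member_ids]
    targets = {m: alignment[m] for m in target.member_ids}
    nontargets = {n: alignment[n] for n in nontarget_ids}
    candidates = []
    for pair in pairs[:max_pairs]:
        try:
            score = score_specificity(pair, targets, nontargets)
        except ValueError:
            continue
        candidates.append((pair, score, 0.0))
    if not candidates:
        return None
    try:
        return select_assay(candidates, taxon=target.name)
    except ValueError:
        return None
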
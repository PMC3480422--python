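"""Seeded synthetic inputs with the structure the pipeline assumes.

The generator emulates the study's data shapes so every stage is testable
without downloads: an aligned SSU-rDNA-like reference set in which each
monitored taxon carries planted signature motifs (unique 20-mers with
annealing temperatures near the 63 °C design target), a concordant reference
tree with an optional polyphyly switch that interleaves one family's genera,
hand-picked-nematode calibration series (1, 5, 10, 50, 100 individuals) with
Gaussian Ct noise, and a seasonal survey — 18 sampling weeks across a
40-week season, 4 field and 2 forest composite samples per week — whose Ct
panels derive from known true densities through the true calibration curves,
so ground truth is available for closure tests.

All draws run through one seeded generator per operation: a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, CalibrationSeries, predict_ct
from .quantify import DEFAULT_DILUTION_ADJUSTMENT, CommunityProfile
from .reference import ReferenceSequence, TaxonGroup, build_groups
from .thermo import DEFAULT_CONDITIONS, compute_tm

#: default true calibration parameters (a, b): the 15 study assays
_DEFAULT_AB: tuple[tuple[float, float], ...] = (
    (-3.31, 25.47), (-4.31, 17.53), (-3.06, 24.09), (-4.21, 21.95),
    (-3.22, 19.18), (-3.02, 22.36), (-5.90, 17.30), (-5.09, 24.40),
    (-4.25, 21.06), (-2.94, 15.19), (-4.02, 12.03), (-1.93, 26.82),
    (-3.33, 21.03), (-5.13, 21.64), (-4.41, 25.13),
)

#: guild mix of the study's 15 assays: 8 bacterivores, 4 fungivores,
#: 1 omnivore, 2 predators
_DEFAULT_GUILDS = ("B",) * 8 + ("F",) * 4 + ("O",) + ("P",) * 2

CALIBRATION_COUNTS = (1, 5, 10, 50, 100)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic world (defaults mirror the study design)."""

    seed: int = 0
    n_taxa: int = 15
    members_per_taxon: int = 4
    genera_per_taxon: int = 2
    seq_length: int = 1200
    motif_length: int = 20
    motif_taxa: tuple[str, ...] | None = None  # None = plant for all taxa
    ct_noise_sd: float = 0.3  # cycles, on calibration and panel Cts
    true_curves: Mapping[str, tuple[float, float]] | None = None
    polyphyletic_family: str | None = None
    # survey design
    weeks: tuple[int, ...] = (1, 3, 5, 8, 10, 12, 15, 17, 19, 21,
                              24, 26, 28, 31, 33, 35, 38, 40)
    n_field_reps: int = 4
    n_forest_reps: int = 2
    density_noise_sd_log10: float = 0.15  # sample-to-sample density scatter
    observation_sd_log10: float = 0.2  # microscopy counting error
    extraction_sd_cycles: float = 0.5  # internal-standard Ct scatter
    reference_standard_ct: float = 20.0
    dilution_adjustment: float = DEFAULT_DILUTION_ADJUSTMENT
    # sequence divergence (substitutions per site)
    family_divergence: float = 0.02
    genus_divergence: float = 0.01
    member_divergence: float = 0.005

    def taxon_names(self) -> list[str]:
        return [f"Fam{i + 1:02d}" for i in range(self.n_taxa)]

    def curve_map(self) -> dict[str, tuple[float, float]]:
        if self.true_curves is not None:
            return dict(self.true_curves)
        ab = _DEFAULT_AB
        return {
            name: ab[i % len(ab)] for i, name in enumerate(self.taxon_names())
        }

    def guild_map(self) -> dict[str, str]:
        names = self.taxon_names()
        if len(names) == len(_DEFAULT_GUILDS):
            return dict(zip(names, _DEFAULT_GUILDS))
        cycle = ("B", "F", "O", "P")
        return {n: cycle[i % 4] for i, n in enumerate(names)}


@dataclass
class ReferenceSet:
    """In-memory synthetic reference framework plus writers."""

    sequences: dict[str, ReferenceSequence]
    taxonomy: pd.DataFrame
    newick: str
    motif_sites: dict[str, tuple[tuple[int, int], tuple[int, int]]]

    def groups(self) -> dict[str, TaxonGroup]:
        return build_groups(self.taxonomy)

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "alignment": directory / "alignment.fasta",
            "taxonomy": directory / "taxonomy.tsv",
            "tree": directory / "tree.nwk",
        }
        with open(paths["alignment"], "w") as fh:
            for sid in sorted(self.sequences):
                fh.write(f">{sid}\n{self.sequences[sid].aligned_seq}\n")
        self.taxonomy.to_csv(paths["taxonomy"], sep="\t", index=False)
        paths["tree"].write_text(self.newick + "\n")
        return paths


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    for i in hits:
        out[i] = rng.choice([b for b in range(4) if b != out[i]])
    return out


_BASES = np.array(list("ACGT"))


def _draw_motif(
    rng: np.random.Generator,
    length: int,
    ta_target: float = 63.0,
    ta_halfwidth: float = 0.8,
    max_tries: int = 2000,
) -> str:
    """A random motif whose duplex Tm sits near the design Ta."""
    for _ in range(max_tries):
        motif = "".join(rng.choice(_BASES, size=length))
        if abs(compute_tm(motif, DEFAULT_CONDITIONS) - ta_target) <= ta_halfwidth:
            return motif
    raise RuntimeError("could not draw a motif with Tm near the design Ta")


def generate_reference_set(spec: SyntheticSpec) -> ReferenceSet:
    """Aligned reference set + taxonomy + tree with planted signatures.

    Sequences descend from one ancestral sequence with family-, genus- and
    member-level substitution divergence, plus family-shared deletions in a
    variable region so the alignment is genuinely gapped. Each taxon in
    ``motif_taxa`` receives two planted windows (forward and reverse primer
    sites, one amplicon apart) that are identical across its members and
    divergent from every non-target. The tree is concordant with the
    taxonomy unless the polyphyly switch interleaves one family's genera.
    """
    if spec.motif_length < 8:
        raise ValueError("motif length must be at least 8 nt")
    amplicon_gap = 110
    motif_zone_start = 100
    # taxon motif regions may overlap: each taxon's motif is planted only in
    # its own members, so a modest stagger suffices
    stride = spec.motif_length + 10
    needed = motif_zone_start + (spec.n_taxa - 1) * stride + 2 * spec.motif_length + amplicon_gap
    if needed > spec.seq_length:
        raise ValueError(
            f"motif layout needs {needed} columns but seq_length is "
            f"{spec.seq_length}: motif space too small"
        )
    rng = np.random.default_rng([spec.seed, 101])
    names = spec.taxon_names()
    motif_taxa = set(spec.motif_taxa) if spec.motif_taxa is not None else set(names)
    guilds = spec.guild_map()

    L = spec.seq_length
    ancestral = rng.integers(0, 4, size=L)

    members_per_genus, rem = divmod(spec.members_per_taxon, spec.genera_per_taxon)
    if members_per_genus == 0:
        raise ValueError("members_per_taxon must be >= genera_per_taxon")

    sequences: dict[str, np.ndarray] = {}
    gaps: dict[str, tuple[int, int]] = {}  # family -> deleted column span
    tax_rows = []
    family_genus_members: dict[str, dict[str, list[str]]] = {}
    cp_cycle = (2, 3, 4)

    for fi, fam in enumerate(names):
        fam_seq = _mutate(rng, ancestral, spec.family_divergence)
        if rng.random() < 0.5:  # family-shared deletion in the variable region
            gstart = int(rng.integers(30, 76))
            gaps[fam] = (gstart, gstart + 4)
        family_genus_members[fam] = {}
        for gi in range(spec.genera_per_taxon):
            genus = f"{fam}_G{gi + 1}"
            genus_seq = _mutate(rng, fam_seq, spec.genus_divergence)
            n_members = members_per_genus + (1 if gi < rem else 0)
            family_genus_members[fam][genus] = []
            for mi in range(n_members):
                sid = f"{genus}_s{mi + 1}"
                sequences[sid] = _mutate(rng, genus_seq, spec.member_divergence)
                family_genus_members[fam][genus].append(sid)
                tax_rows.append(
                    {
                        "id": sid,
                        "genus": genus,
                        "family": fam,
                        "guild": guilds[fam],
                        "cp": cp_cycle[fi % len(cp_cycle)],
                    }
                )

    # plant signature motifs
    motif_sites: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {}
    for fi, fam in enumerate(names):
        if fam not in motif_taxa:
            continue
        fwd_start = motif_zone_start + fi * stride
        rev_start = fwd_start + spec.motif_length + amplicon_gap
        sites = ((fwd_start, fwd_start + spec.motif_length),
                 (rev_start, rev_start + spec.motif_length))
        members = [m for g in family_genus_members[fam].values() for m in g]
        nontargets = [
            s for s in sequences if s not in members
        ]
        for start, end in sites:
            for _ in range(200):
                motif = _draw_motif(rng, spec.motif_length)
                motif_codes = np.array([("ACGT").index(ch) for ch in motif])
                min_dist = min(
                    int((sequences[nt][start:end] != motif_codes).sum())
                    for nt in nontargets
                )
                if min_dist >= max(6, spec.motif_length // 4):
                    break
            else:
                raise RuntimeError("could not plant a unique signature motif")
            for m in members:
                sequences[m][start:end] = motif_codes
        motif_sites[fam] = sites

    # render aligned strings with family-shared deletions as gap columns
    rendered: dict[str, ReferenceSequence] = {}
    for fam in names:
        span = gaps.get(fam)
        for genus, members in family_genus_members[fam].items():
            for m in members:
                chars = _BASES[sequences[m]].tolist()
                if span:
                    for c in range(*span):
                        chars[c] = "-"
                rendered[m] = ReferenceSequence(m, "".join(chars))

    taxonomy = pd.DataFrame(tax_rows).sort_values("id", ignore_index=True)
    newick = _build_newick(names, family_genus_members, spec.polyphyletic_family)
    return ReferenceSet(
        sequences=rendered,
        taxonomy=taxonomy,
        newick=newick,
        motif_sites=motif_sites,
    )


def _build_newick(
    families: list[str],
    fam_genus_members: dict[str, dict[str, list[str]]],
    polyphyletic_family: str | None,
) -> str:
    def genus_clade(genus: str, members: list[str]) -> str:
        if len(members) == 1:
            return members[0]
        return "(" + ",".join(members) + ")"

    if polyphyletic_family is not None and polyphyletic_family not in families:
        raise ValueError(f"unknown family {polyphyletic_family!r}")
    hosts = [f for f in families if f != polyphyletic_family]
    grafts: list[str] = []
    if polyphyletic_family is not None:
        grafts = [
            genus_clade(g, m)
            for g, m in fam_genus_members[polyphyletic_family].items()
        ]
        if len(grafts) < 2 or len(hosts) < 2:
            raise ValueError(
                "polyphyly switch needs >= 2 genera in the split family and "
                ">= 2 host families"
            )
    clades = []
    for i, fam in enumerate(hosts):
        sub = [genus_clade(g, m) for g, m in fam_genus_members[fam].items()]
        # interleave the split family's genera into the first host clades
        if grafts and i < len(grafts):
            sub.append(grafts[i])
        clades.append("(" + ",".join(sub) + ")" if len(sub) > 1 else sub[0])
    extra = grafts[len(hosts):]
    return "(" + ",".join(clades + extra) + ");"


def true_curve(spec: SyntheticSpec, taxon: str) -> CalibrationCurve:
    curves = spec.curve_map()
    if taxon not in curves:
        raise KeyError(f"no true calibration parameters for taxon {taxon!r}")
    a, b = curves[taxon]
    return CalibrationCurve(assay=taxon, a=a, b=b, r2=1.0, n_points=0)


def generate_calibration_series(
    spec: SyntheticSpec,
    taxon: str,
    genus: str | None = None,
    counts: Iterable[float] = CALIBRATION_COUNTS,
    replicate: int = 0,
) -> CalibrationSeries:
    """Dilution-series Cts on the taxon's true line plus Gaussian noise."""
    curves = spec.curve_map()
    if taxon not in curves:
        raise KeyError(f"no true calibration parameters for taxon {taxon!r}")
    a, b = curves[taxon]
    idx = spec.taxon_names().index(taxon) if taxon in spec.taxon_names() else 0
    rng = np.random.default_rng([spec.seed, 211, idx, replicate])
    pts = []
    for n in counts:
        ct = a * math.log10(n) + b + (
            rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd > 0 else 0.0
        )
        pts.append((float(n), float(ct)))
    return CalibrationSeries(
        assay=taxon, genus=genus or f"{taxon}_G1", points=tuple(pts)
    )


@dataclass
class SurveyData:
    panels: pd.DataFrame  # sample_id, site, week, assay, ct, internal_standard_ct
    true_profiles: dict[str, CommunityProfile]
    microscopy: pd.DataFrame  # sample_id, site, week, total

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "panels": directory / "panels.csv",
            "microscopy": directory / "microscopy.csv",
        }
        self.panels.to_csv(paths["panels"], index=False)
        self.microscopy.to_csv(paths["microscopy"], index=False)
        return paths


def _seasonal_mean(
    base: float, amplitude: float, phase: float, week: int, site_factor: float
) -> float:
    return base * site_factor * math.exp(
        amplitude * math.sin(2.0 * math.pi * (week + phase) / 40.0)
    )


def generate_survey(spec: SyntheticSpec) -> SurveyData:
    """Seasonal sample Ct panels with known true community profiles.

    True per-taxon densities follow smooth log-normal seasonal trajectories
    with site-specific offsets; Cts derive from the true calibration curves
    after extraction-recovery and dilution bookkeeping, plus Gaussian Ct
    noise; microscopy totals are the true totals under log-normal
    observation error. Zero noise everywhere closes the loop exactly.
    """
    rng = np.random.default_rng([spec.seed, 307])
    curves = {t: true_curve(spec, t) for t in spec.taxon_names()}
    names = spec.taxon_names()
    # per-taxon trajectory parameters (densities per 100 ml of soil)
    base = 10.0 ** rng.uniform(0.8, 2.6, size=len(names))
    amplitude = rng.uniform(0.3, 1.0, size=len(names))
    phase = rng.uniform(0.0, 40.0, size=len(names))
    site_factor = {
        "field": rng.uniform(0.5, 1.5, size=len(names)),
        "forest": rng.uniform(0.5, 1.5, size=len(names)),
    }

    panel_rows = []
    micro_rows = []
    true_profiles: dict[str, CommunityProfile] = {}
    for week in spec.weeks:
        for site, reps in (("field", spec.n_field_reps), ("forest", spec.n_forest_reps)):
            for rep in range(reps):
                sample_id = f"{site}_w{week:02d}_r{rep + 1}"
                densities = {}
                for i, taxon in enumerate(names):
                    mean = _seasonal_mean(
                        base[i], amplitude[i], phase[i], week, site_factor[site][i]
                    )
                    noise = (
                        10.0 ** rng.normal(0.0, spec.density_noise_sd_log10)
                        if spec.density_noise_sd_log10 > 0
                        else 1.0
                    )
                    densities[taxon] = mean * noise
                delta = (
                    rng.normal(0.0, spec.extraction_sd_cycles)
                    if spec.extraction_sd_cycles > 0
                    else 0.0
                )
                internal_ct = spec.reference_standard_ct + delta
                recovery = 2.0 ** (-delta)
                for taxon in names:
                    template = densities[taxon] * recovery / spec.dilution_adjustment
                    ct = predict_ct(curves[taxon], template)
                    if spec.ct_noise_sd > 0:
                        ct += rng.normal(0.0, spec.ct_noise_sd)
                    panel_rows.append(
                        {
                            "sample_id": sample_id,
                            "site": site,
                            "week": week,
                            "assay": taxon,
                            "ct": ct if ct < 60.0 else np.nan,
                            "internal_standard_ct": internal_ct,
                        }
                    )
                total = float(sum(densities.values()))
                obs = (
                    total * 10.0 ** rng.normal(0.0, spec.observation_sd_log10)
                    if spec.observation_sd_log10 > 0
                    else total
                )
                micro_rows.append(
                    {"sample_id": sample_id, "site": site, "week": week, "total": obs}
                )
                true_profiles[sample_id] = CommunityProfile(
                    sample_id=sample_id, densities=densities
                )
    return SurveyData(
        panels=pd.DataFrame(panel_rows),
        true_profiles=true_profiles,
        microscopy=pd.DataFrame(micro_rows),
    )


def panels_to_samples(panels: pd.DataFrame):
    """Group a long-format panel table into SampleRecord objects."""
    from .quantify import SampleRecord

    samples = []
    for sid, sub in panels.groupby("sample_id", sort=True):
        samples.append(
            SampleRecord(
                sample_id=str(sid),
                site=str(sub["site"].iloc[0]),
                week=int(sub["week"].iloc[0]),
                cts={
                    str(r.assay): float(r.ct) if not pd.isna(r.ct) else float("nan")
                    for r in sub.itertuples()
                },
                internal_standard_ct=float(sub["internal_standard_ct"].iloc[0]),
            )
        )
    return samples
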
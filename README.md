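# nemaquant

Quantitative-PCR community monitoring for soil nematodes, built on a
phylum-wide SSU (18S) rDNA reference framework.

Nematodes are the standard indicator group for biological soil quality, but
microscopic community analysis is slow and requires rare taxonomic
expertise. `nemaquant` implements the DNA-signature alternative end to end:

- **Reference framework** (`nemaquant.reference`) — load and validate a
  gapped SSU rDNA alignment, taxonomy and reference phylogeny; test each
  family for monophyly (a family can only carry one sequence signature if it
  forms a clade) and resolve every assay target to family or genus rank,
  flagging un-assayable groups.
- **Assay design** (`nemaquant.design`, `nemaquant.thermo`) — discover
  signature motifs (windows conserved across all target members and
  divergent from every non-target), enumerate primer pairs at a uniform
  annealing temperature of 63 °C using a unified nearest-neighbor melting
  model, score specificity as the ΔCt gap between the latest target and
  earliest non-target, and select one assay per taxon (ΔCt < 12 is
  discarded).
- **Calibration** (`nemaquant.calibration`) — fit the per-assay line
  **Ct = a·log₁₀(N) + b** on dilution series of 1, 5, 10, 50, 100
  hand-picked nematodes, pool genus series into family curves, and invert
  the line to estimate densities (N = 10^((Ct − b)/a)).
- **Quantification** (`nemaquant.quantify`) — turn an environmental Ct panel
  into a per-taxon profile in individuals per 100 ml of soil, corrected for
  extraction recovery via a spiked internal standard; aggregate to feeding
  guilds; diagnose coverage against microscopy totals with a log-log
  regression and a ±0.5-log precision band.
- **Survey statistics** (`nemaquant.stats`) — two-period moving-average
  trends, coefficients of variation, exact/approximate Mann-Whitney U site
  comparisons, Welch t on log totals, (partial) Mantel permutation tests,
  and rainfall window sums.
- **Synthetic fixtures** (`nemaquant.synth`) — seeded generators for a
  reference set with planted signatures, calibration series, and a full
  18-week two-site seasonal survey with known ground truth.

The package also ships the study's genus-occurrence survey (45 genera) and
the 15 selected assays with their calibration parameters as packaged CSVs
(`nemaquant.datasets`).

## Worked example

```python
import nemaquant as nq
from nemaquant.datasets import load_assay_curves

curves = load_assay_curves()
alaimidae = curves["Alaimidae"]          # Ct = -3.31 * log10(N) + 25.47

print(nq.predict_ct(alaimidae, 1))       # 25.47  (one nematode = intercept)
print(nq.predict_ct(alaimidae, 10))      # 22.16  (tenfold = one slope unit)
est = nq.estimate_density(alaimidae, 20.5)
print(round(est.value, 1))               # 31.7   (individuals at Ct 20.5)
print(round(alaimidae.efficiency, 3))    # 1.005  (per-cycle amplification)
```

The intercept `b` is the Ct a single target nematode produces; the slope
`a` is the Ct change per tenfold abundance (perfect per-cycle doubling gives
a ≈ −3.32, so the Alaimidae assay runs at essentially 100 % efficiency).

A full synthetic pipeline run from the shell:

```sh
nemaquant simulate --seed 4 --out fixtures/
nemaquant framework targets --alignment fixtures/alignment.fasta \
    --taxonomy fixtures/taxonomy.tsv --tree fixtures/tree.nwk
nemaquant design    --alignment fixtures/alignment.fasta \
    --taxonomy fixtures/taxonomy.tsv --tree fixtures/tree.nwk --out assays.csv
nemaquant calibrate --series fixtures/calibration_series.csv --out curves.csv
nemaquant quantify  --samples fixtures/panels.csv --curves curves.csv \
    --out profiles.csv --reference-ct 20
nemaquant report    --profiles profiles.csv --samples fixtures/panels.csv --out report/
```

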
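"""Packaged survey and assay tables.

Two small CSVs ship with the package: the genus-level microscopy occurrence
survey of the field/forest site pair, and the 15 selected taxon-specific
assays with their empirical specificity gaps and Ct-vs-log10(N) calibration
parameters.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd


def _data_path(name: str) -> Path:
    with resources.as_file(resources.files("nemaquant.data").joinpath(name)) as p:
        return Path(p)


def occurrence_table_path() -> Path:
    return _data_path("table1_occurrence.csv")


def curve_table_path() -> Path:
    return _data_path("table2_curves.csv")


def load_curve_table() -> pd.DataFrame:
    """The packaged assay table: one row per selected assay.

    Columns: assay, family, rank, guild, cp, delta_ct (NaN when no non-target
    produced any signal), a, b, r2, n_genera.
    """
    return pd.read_csv(curve_table_path(), comment="#")


def load_assay_curves():
    """Calibration curves for the packaged assays, keyed by assay name."""
    from .calibration import CalibrationCurve

    table = load_curve_table()
    return {
        row.assay: CalibrationCurve(
            assay=row.assay,
            a=float(row.a),
            b=float(row.b),
            r2=float(row.r2),
            n_points=0,
            genera_pooled=(),
        )
        for row in table.itertuples()
    }


def assay_guilds() -> dict[str, str]:
    """Primary feeding-guild code per packaged assay (first code listed)."""
    table = load_curve_table()
    return {
        row.assay: str(row.guild).split(",")[0].strip()
        for row in table.itertuples()
    }
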
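"""Packaged reference measurement tables for 31 tuberculate Silene species.

Two tables transcribed from the published quantitative tubercle survey of
Silene seed coats ship with the package:

* per-tubercle worked values (width, height, slope, max/mean curvature and
  their ratio) for six representative tubercles of each of 11 species;
* per-species summaries (N, mean, CV%, min, max for the six variables) for
  all 21 rugose and 10 echinate species, with seed-type, subgenus and
  section labels.

Values are packaged exactly as printed.  A few cells of the source tables
are internally inconsistent (e.g. a printed max/mean ratio that does not
follow from the printed max and mean, or a per-tubercle value outside the
species-level min/max); no attempt is made to repair them here — analyses
that depend on such cells should treat the packaged table as authoritative
input and note the discrepancy.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_tubercle_tables", "load_species_summaries"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh)


def load_tubercle_tables() -> pd.DataFrame:
    """Per-tubercle reference values: 11 species x 6 tubercles.

    Columns: species, tubercle, W, H, S, max_curvature, mean_curvature,
    ratio.  W and H are printed as integers (microns); S, the curvatures
    (micron^-1 x 1000) and the ratio to one decimal place.
    """
    return _read("tubercle_tables.csv")


def load_species_summaries() -> pd.DataFrame:
    """Per-species summary statistics for all 31 species.

    One row per species with seed type (rugose/echinate), subgenus
    (Behenantha/Silene), section, tubercle and seed counts, and
    mean/CV/min/max for each of the six measurement variables.  Tubercle
    counts total 268 (rugose) and 128 (echinate).
    """
    return _read("species_summaries.csv")
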
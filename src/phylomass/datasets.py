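"""Packaged reference tables for the subfossil lemur application.

Three small CSVs ship with the package:

* ``subfossil_femora.csv`` — the 127 subfossil lemur femoral specimens
  (two sources: this study's micro-CT measurements, tagged ``Thompson``,
  and an earlier compilation tagged ``Jungers``) with each specimen's FCSA
  and its published phylogenetically informed body-mass estimate and 95%
  prediction limits;
* ``prior_species_estimates.csv`` — earlier non-phylogenetic species-mean
  body-mass estimates from two prior studies (Godfrey, Jungers columns);
* ``species_synonyms.csv`` — alias -> canonical spellings reconciling the
  orthographic variants used across the source tables
  (e.g. Palaeopropithecus / Paleopropithecus).

The extant reference dataset itself (570 individuals, 77 species) is not
redistributable; the published specimen estimates above, which lie exactly
on the fitted allometric line, let the fitted coefficients be recovered to
full precision by an ordinary log-log regression.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_subfossil_specimens",
    "load_prior_estimates",
    "load_synonyms",
    "reference_allometry",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("phylomass.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_subfossil_specimens() -> pd.DataFrame:
    """Specimen table: species, specimen_id, dataset, fcsa_mm2, published
    estimate and 95% limits (kg)."""
    return _read("subfossil_femora.csv")


def load_prior_estimates() -> pd.DataFrame:
    """Prior species-mean body-mass estimates (kg), NaN where unreported."""
    return _read("prior_species_estimates.csv")


def load_synonyms() -> dict[str, str]:
    df = _read("species_synonyms.csv")
    return dict(zip(df["alias"], df["canonical"]))


def reference_allometry() -> tuple[float, float]:
    """Recover the published allometry's (intercept, slope) at full precision.

    The published per-specimen estimates all lie on the fitted line
    ln(BM, grams) = a + b ln(FCSA), but the coefficients are printed rounded
    to two decimals; an ordinary least-squares fit across the 127 published
    (FCSA, estimate) pairs recovers them to far better precision than the
    printed rounding.
    """
    df = load_subfossil_specimens()
    x = np.log(df["fcsa_mm2"].to_numpy(dtype=float))
    y = np.log(df["published_bm_kg"].to_numpy(dtype=float) * 1000.0)
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)
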
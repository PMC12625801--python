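"""Species-level aggregation of specimen predictions and cross-study tests.

Specimen-level estimates are pooled into species means with equal weight per
specimen.  When specimens come from several sources this equals the
specimen-count-weighted combination of per-source means, which is the sense
in which the species means are "weighted".  Cross-study comparisons use a
paired t-test on natural-log masses: body masses are log-normally
distributed across taxa spanning two orders of magnitude, so differences
are multiplicative and the log scale is the appropriate pairing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "species_weighted_mean",
    "combine_datasets",
    "paired_log_t_test",
]

#: dataset tags counted in the nT / nJ columns (this study, prior study)
DEFAULT_SOURCE_ORDER = ("Thompson", "Jungers")


def combine_datasets(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Concatenate two specimen tables, keeping source tags.

    Specimen ids must be unique within each source; an id occurring in both
    sources is disambiguated by prefixing it with its dataset tag.
    """
    for name, df in (("first", a), ("second", b)):
        if len(df) and df["specimen_id"].astype(str).duplicated().any():
            raise ValueError(f"duplicate specimen ids within the {name} table")
    out = pd.concat([a, b], ignore_index=True)
    if len(a) and len(b):
        ids = out["specimen_id"].astype(str)
        clash = set(a["specimen_id"].astype(str)) & set(b["specimen_id"].astype(str))
        if clash:
            mask = ids.isin(clash)
            out.loc[mask, "specimen_id"] = (
                out.loc[mask, "dataset"].astype(str) + ":" + ids[mask]
            )
    return out


def species_weighted_mean(
    predictions: pd.DataFrame,
    source_order: Sequence[str] = DEFAULT_SOURCE_ORDER,
) -> pd.DataFrame:
    """Pool specimen predictions into per-species means.

    ``predictions`` needs columns ``species``, ``dataset``, ``fcsa_mm2``,
    ``estimate_kg``, ``lower95_kg``, ``upper95_kg``.  Output has one row per
    species with counts by source (``nT``, ``nJ``, total ``N``) and the
    arithmetic mean of FCSA, estimate, and both limits over all pooled
    specimens.  Rounding is left to the report writer.
    """
    required = {"species", "dataset", "fcsa_mm2", "estimate_kg",
                "lower95_kg", "upper95_kg"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    df = predictions.dropna(subset=["species"])
    df = df[df["species"].astype(str).str.len() > 0]
    if len(df) < len(predictions):
        warnings.warn("predictions without a species label were excluded",
                      stacklevel=2)
    rows = []
    for species, grp in df.groupby("species", sort=True):
        tags = grp["dataset"].astype(str)
        nT = int((tags == source_order[0]).sum())
        nJ = int((tags == source_order[1]).sum())
        rows.append(
            {
                "species": species,
                "nT": nT,
                "nJ": nJ,
                "N": len(grp),
                "mean_fcsa_mm2": grp["fcsa_mm2"].mean(),
                "mean_bm_kg": grp["estimate_kg"].mean(),
                "mean_lower95_kg": grp["lower95_kg"].mean(),
                "mean_upper95_kg": grp["upper95_kg"].mean(),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    """Paired t-test between two sets of species mass estimates."""

    n_pairs: int
    t: float
    df: int
    p: float
    mean_log_ratio: float  # mean ln(current / prior); negative = lighter

    def summary(self) -> str:
        return (f"paired t-test on ln(kg): t = {self.t:.1f}, "
                f"df = {self.df}, p = {self.p:.2g}, "
                f"mean log-ratio = {self.mean_log_ratio:.3f} "
                f"({np.exp(self.mean_log_ratio):.2f}x)")


def paired_log_t_test(
    current: Mapping[str, float],
    prior: Mapping[str, float],
) -> ComparisonResult:
    """Two-sided paired t-test on natural-log body masses.

    Species absent from either map, or with a missing (NaN) value, are
    dropped pairwise.  At least two complete pairs are required.
    """
    shared = sorted(set(current) & set(prior))
    pairs = [
        (float(current[s]), float(prior[s]))
        for s in shared
        if np.isfinite(current[s]) and np.isfinite(prior[s])
    ]
    if len(pairs) < 2:
        raise ValueError(f"need at least 2 complete pairs, got {len(pairs)}")
    cur = np.log([p[0] for p in pairs])
    pri = np.log([p[1] for p in pairs])
    diff = cur - pri
    if np.std(diff, ddof=1) == 0.0:
        # degenerate: all pairs differ by the same factor
        t = 0.0 if diff.mean() == 0.0 else math.inf * np.sign(diff.mean())
        p = 1.0 if diff.mean() == 0.0 else 0.0
    else:
        t, p = stats.ttest_rel(cur, pri)
    return ComparisonResult(
        n_pairs=len(pairs), t=float(t), df=len(pairs) - 1, p=float(p),
        mean_log_ratio=float(np.mean(cur - pri)),
    )
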
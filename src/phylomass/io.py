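"""Delimited-text readers and writers for the pipeline's tables.

All tabular I/O is CSV with a header row.  Values are kept at full
precision in memory; rounding (default two decimals, matching how body
masses are conventionally reported) happens only when a report is written.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .pgls import PGLSFit, validate_trait_table
from .tree import PhyloTree, normalize_label, parse_newick

__all__ = [
    "read_tree",
    "read_trait_table",
    "read_specimen_table",
    "read_synonym_map",
    "apply_synonyms",
    "write_model_report",
    "write_predictions",
    "write_species_summaries",
]


def read_tree(path: str | Path) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def read_trait_table(path: str | Path, require_fl: bool = False) -> pd.DataFrame:
    """Species-mean traits: columns species, bm_kg, fcsa_mm2 [, fl_mm]."""
    return validate_trait_table(pd.read_csv(path), require_fl=require_fl)


def read_specimen_table(path: str | Path) -> pd.DataFrame:
    """Fossil specimens: columns specimen_id, species, dataset, fcsa_mm2."""
    df = pd.read_csv(path)
    required = {"specimen_id", "species", "dataset", "fcsa_mm2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"specimen table missing columns: {sorted(missing)}")
    df["species"] = df["species"].map(normalize_label)
    return df


def read_synonym_map(path: str | Path) -> dict[str, str]:
    """Two-column alias -> canonical species-name map."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("synonym map needs two columns: alias, canonical")
    alias, canon = df.columns[:2]
    return {
        normalize_label(str(a)): normalize_label(str(c))
        for a, c in zip(df[alias], df[canon])
    }


def apply_synonyms(names: Sequence[str], synonyms: Mapping[str, str]) -> list[str]:
    """Map each name through the synonym table (identity when absent)."""
    norm = {normalize_label(k): v for k, v in synonyms.items()}
    return [norm.get(normalize_label(n), normalize_label(n)) for n in names]


def write_model_report(fits: Sequence[PGLSFit], path: str | Path) -> pd.DataFrame:
    """Model-summary report: equation, λ, SEs, p-values, AIC, adjusted R²."""
    rows = []
    for f in fits:
        slopes = f.params.index[1:]
        rows.append(
            {
                "formula": f.formula,
                "equation": f.equation(),
                "lambda": round(f.lambda_hat, 2),
                "se": "; ".join(f"{f.se[s]:.2f}" for s in slopes),
                "p": "; ".join(f"{f.pvalues[s]:.3g}" for s in slopes),
                "aic": round(f.aic, 0),
                "adj_r2": round(f.adj_r2, 2),
                "f_stat": round(f.fstat, 1),
                "df": f"{f.df_model},{f.df_resid}",
                "n": f.n,
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(path, index=False)
    return out


def write_predictions(
    predictions: pd.DataFrame, path: str | Path, decimals: int = 2
) -> pd.DataFrame:
    out = predictions.copy()
    for col in ("fcsa_mm2", "estimate_kg", "lower95_kg", "upper95_kg"):
        out[col] = out[col].round(decimals)
    out.to_csv(path, index=False)
    return out


def write_species_summaries(
    summaries: pd.DataFrame, path: str | Path, decimals: int = 2
) -> pd.DataFrame:
    out = summaries.copy()
    for col in out.columns:
        if col.startswith("mean_"):
            out[col] = out[col].round(decimals)
    out.to_csv(path, index=False)
    return out
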
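"""Monte-Carlo validation studies for the estimation pipeline.

Two experiments back the package's claims about its own statistics:

* parameter recovery — repeated trait simulation on one tree followed by
  PGLS fitting, summarizing the sampling distribution of the slope and λ̂;
* prediction-interval coverage — repeated full datasets (reference fit plus
  fossils drawn from the same process) counting how often the nominal 95%
  interval contains the true mass.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .pgls import fit_model
from .predict import predict_interval
from .simulate import SimulationConfig, simulate_dataset, simulate_traits, simulate_tree

__all__ = ["parameter_recovery_study", "coverage_study"]


def parameter_recovery_study(
    n_replicates: int = 500,
    config: SimulationConfig | None = None,
    seed: int = 0,
    formula: str = "BM~FCSA",
) -> pd.DataFrame:
    """Fit the allometry to ``n_replicates`` trait sets simulated on one tree.

    Returns one row per replicate with the fitted slope, intercept, λ̂, σ̂²,
    and whether the replicate's 95% CI covered the generating slope.
    """
    config = config if config is not None else SimulationConfig()
    root = np.random.default_rng(seed)
    tree = simulate_tree(config.n_extant, seed=int(root.integers(2**31 - 1)))
    rows = []
    for _ in range(n_replicates):
        traits = simulate_traits(tree, config, rng=root)
        fit = fit_model(traits, tree, formula)
        slope_name = fit.params.index[1]
        rows.append(
            {
                "slope": fit.params.iloc[1],
                "intercept": fit.params.iloc[0],
                "lambda_hat": fit.lambda_hat,
                "sigma2": fit.sigma2,
                "slope_ci_covers": bool(
                    fit.conf_int.loc[slope_name, "lower95"]
                    <= config.slope
                    <= fit.conf_int.loc[slope_name, "upper95"]
                ),
            }
        )
    return pd.DataFrame(rows)


def coverage_study(
    n_replicates: int = 20,
    config: SimulationConfig | None = None,
    seed: int = 0,
    mode: str = "independent",
    level: float = 0.95,
) -> dict[str, float]:
    """Empirical coverage of prediction intervals on synthetic fossils.

    Each replicate simulates a fresh dataset, fits the FCSA allometry to the
    extant table, predicts every fossil specimen, and scores the interval
    against that species' true mass.  The default configuration (25 fossil
    species x 4 specimens, 20 replicates) scores 2,000 intervals.

    Returns ``{"coverage": fraction, "n": intervals scored}``.
    """
    if config is None:
        config = SimulationConfig(n_fossil_species=25, specimens_per_species=(4, 4))
    root = np.random.default_rng(seed)
    hits = 0
    total = 0
    for _ in range(n_replicates):
        ds = simulate_dataset(replace(config, seed=int(root.integers(2**31 - 1))))
        fit = fit_model(ds.traits, ds.tree, "BM~FCSA")
        for row in ds.specimens.itertuples(index=False):
            rec = predict_interval(
                fit,
                float(row.fcsa_mm2),
                level=level,
                mode=mode,
                placement=ds.placements[row.species] if mode == "blup" else None,
            )
            truth = float(ds.true_mass_kg[row.species])
            hits += int(rec.lower95_kg <= truth <= rec.upper95_kg)
            total += 1
    return {"coverage": hits / total, "n": total}
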
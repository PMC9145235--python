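"""Simulated line x environment x replicate phenotype panels.

Observations follow the standard multi-environment trial decomposition

    y_ijr = mu + f_i + e_j + (fe)_ij + eps_ijr

with line effects f ~ N(0, Vg), environment effects e ~ N(0, env_sd^2),
line-by-environment interactions (fe) ~ N(0, Vgl) and residuals
eps ~ N(0, Ve).  The simulator returns both the long-format panel and the
full set of drawn effects, so variance-component estimators can be
validated against the exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..exceptions import ValidationError


@dataclass(frozen=True)
class PanelSimSpec:
    """Design and variance components of a simulated phenotype panel.

    Defaults emulate a two-location trial of an inbred association panel
    with three replicates per location.  ``env_sd`` scales the environment
    main effect; it is separate from the genetic variance triple because
    broad-sense heritability does not involve it.
    """

    n_lines: int = 202
    n_env: int = 2       # L, number of environments (locations)
    n_rep: int = 3       # R, replicates per line x environment
    mu: float = 100.0
    vg: float = 1.0      # genotypic variance
    vgl: float = 0.2     # line x environment interaction variance
    ve: float = 0.5      # residual variance
    env_sd: float = 1.0  # sd of the environment main effect
    seed: int = 0

    def __post_init__(self):
        if self.n_lines < 2:
            raise ValidationError("need at least 2 lines")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValidationError("L and R must be at least 1")
        if min(self.vg, self.vgl, self.ve) < 0 or self.env_sd < 0:
            raise ValidationError("variances must be non-negative")


@dataclass
class PanelTruth:
    """All effects drawn by the simulator, keyed like the panel."""

    mu: float
    line_effects: pd.Series          # index: line id
    env_effects: pd.Series           # index: env id
    interaction: pd.DataFrame        # index: line id, columns: env id
    residuals: np.ndarray            # aligned with the panel rows


def generate_phenotype_panel(spec: PanelSimSpec) -> tuple[pd.DataFrame, PanelTruth]:
    """Draw one balanced panel; returns (long DataFrame, truth).

    The DataFrame has columns ``line``, ``env``, ``rep``, ``value`` with
    one row per line x environment x replicate.  Reconstruction from the
    truth object reproduces every observation exactly.
    """
    rng = np.random.default_rng(spec.seed)
    lines = [f"L{i:04d}" for i in range(spec.n_lines)]
    envs = [f"E{j}" for j in range(spec.n_env)]

    f = rng.normal(0.0, np.sqrt(spec.vg), spec.n_lines)
    e = rng.normal(0.0, spec.env_sd, spec.n_env)
    fe = rng.normal(0.0, np.sqrt(spec.vgl), (spec.n_lines, spec.n_env))
    eps = rng.normal(0.0, np.sqrt(spec.ve),
                     (spec.n_lines, spec.n_env, spec.n_rep))

    li, ej, rr = np.meshgrid(
        np.arange(spec.n_lines), np.arange(spec.n_env), np.arange(spec.n_rep),
        indexing="ij",
    )
    li, ej, rr = li.ravel(), ej.ravel(), rr.ravel()
    values = spec.mu + f[li] + e[ej] + fe[li, ej] + eps[li, ej, rr]

    panel = pd.DataFrame(
        {
            "line": np.array(lines)[li],
            "env": np.array(envs)[ej],
            "rep": rr + 1,
            "value": values,
        }
    )
    truth = PanelTruth(
        mu=spec.mu,
        line_effects=pd.Series(f, index=lines),
        env_effects=pd.Series(e, index=envs),
        interaction=pd.DataFrame(fe, index=lines, columns=envs),
        residuals=eps[li, ej, rr],
    )
    return panel, truth
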
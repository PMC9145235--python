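"""REML variance components, line BLUPs and broad-sense heritability.

The model for one trait observed over lines, environments and replicates
is

    y = mu + env (fixed) + line (random, Vg) + line:env (random, Vgl)
        + residual (Ve)

Environments enter as fixed effects: with only a handful of locations an
environment variance is not estimable, and the heritability formula used
downstream involves only Vg, Vgl and Ve.

Two estimators are provided.  ``method="em"`` is EM-REML on Henderson's
mixed-model equations: monotone, robust, truncating negative updates at
zero.  ``method="anova"`` gives the balanced-design closed-form
(expected-mean-square) estimates, which coincide with REML on balanced
panels when the estimates are interior; they also serve as the EM
starting values.  ``method="auto"`` (default) picks the closed form for
balanced panels and EM otherwise.

Broad-sense heritability on an entry-mean basis is

    H^2 = Vg / (Vg + Vgl / L + Ve / (L R))

with L environments and R replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

REQUIRED_COLS = ("line", "env", "rep", "value")


@dataclass
class VarianceComponents:
    """REML estimates for one trait."""

    mu: float
    vg: float
    vgl: float
    ve: float
    converged: bool = True
    n_iter: int = 0
    method: str = "anova"

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.vg, self.vgl, self.ve)


def _check_panel(panel: pd.DataFrame) -> pd.DataFrame:
    for c in REQUIRED_COLS:
        if c not in panel.columns:
            raise ValidationError(f"panel is missing column {c!r}")
    panel = panel.dropna(subset=["value"])
    if panel["line"].nunique() < 2:
        raise ValidationError("need at least 2 lines")
    if panel.duplicated(["line", "env", "rep"]).any():
        raise ValidationError("(line, env, rep) must be unique")
    return panel


def _is_balanced(panel: pd.DataFrame) -> bool:
    counts = panel.groupby(["line", "env"], observed=True).size()
    n_lines = panel["line"].nunique()
    n_env = panel["env"].nunique()
    return len(counts) == n_lines * n_env and counts.nunique() == 1


def _anova_components(panel: pd.DataFrame) -> VarianceComponents:
    """Closed-form expected-mean-square estimates for a balanced panel."""
    a = panel["line"].nunique()
    b = panel["env"].nunique()
    r = len(panel) // (a * b)
    y = panel["value"].to_numpy()
    grand = y.mean()

    cell = panel.groupby(["line", "env"], observed=True)["value"].mean()
    line_m = panel.groupby("line", observed=True)["value"].mean()
    env_m = panel.groupby("env", observed=True)["value"].mean()

    ss_line = b * r * ((line_m - grand) ** 2).sum()
    ss_env = a * r * ((env_m - grand) ** 2).sum()
    ss_cells = r * ((cell - grand) ** 2).sum()
    ss_int = ss_cells - ss_line - ss_env
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_cells

    ms_line = ss_line / (a - 1)
    if b > 1:
        ms_int = ss_int / ((a - 1) * (b - 1))
    else:
        ms_int = np.nan
    if r > 1:
        ms_err = ss_err / (a * b * (r - 1))
    else:
        ms_err = np.nan

    if b == 1:
        # single environment: interaction structurally zero
        ve = float(ms_err) if r > 1 else 0.0
        vg = max((ms_line - ve) / r, 0.0)
        vgl = 0.0
    elif r == 1:
        # no replicates within environment: interaction confounded with error
        ve = float(ms_int)
        vgl = 0.0
        vg = max((ms_line - ve) / b, 0.0)
    else:
        ve = float(ms_err)
        vgl = max((ms_int - ve) / r, 0.0)
        vg = max((ms_line - ms_int) / (b * r), 0.0)
    return VarianceComponents(mu=float(grand), vg=float(vg), vgl=float(vgl),
                              ve=float(ve), converged=True, n_iter=0,
                              method="anova")


def _design(panel: pd.DataFrame, include_interaction: bool):
    lines = pd.Categorical(panel["line"])
    envs = pd.Categorical(panel["env"])
    n = len(panel)
    X = np.ones((n, 1))
    if len(envs.categories) > 1:
        E = np.zeros((n, len(envs.categories) - 1))
        codes = envs.codes
        for j in range(1, len(envs.categories)):
            E[codes == j, j - 1] = 1.0
        X = np.column_stack([X, E])
    Z1 = np.zeros((n, len(lines.categories)))
    Z1[np.arange(n), lines.codes] = 1.0
    Zs = [Z1]
    if include_interaction:
        cell = lines.codes.astype(np.int64) * len(envs.categories) + envs.codes
        cats = np.unique(cell)
        Z2 = np.zeros((n, len(cats)))
        Z2[np.arange(n), np.searchsorted(cats, cell)] = 1.0
        Zs.append(Z2)
    return X, Zs, list(lines.categories)


def _em_reml(
    y: np.ndarray,
    X: np.ndarray,
    Zs: list[np.ndarray],
    tol: float,
    max_iter: int,
    init: list[float],
    ve_init: float,
):
    """EM-REML on the mixed-model equations.

    Components stuck at (numerical) zero are frozen there; the residual
    update is the REML trace-free form (y'Py over n - p).
    """
    n, p = X.shape
    W = np.column_stack([X] + Zs)
    WtW = W.T @ W
    Wty = W.T @ y
    q = [Z.shape[1] for Z in Zs]
    starts = np.concatenate([[p], p + np.cumsum(q)[:-1]])
    blocks = [slice(int(s), int(s) + qi) for s, qi in zip(starts, q)]

    var_y = float(np.var(y))
    floor = max(var_y, 1e-12) * 1e-10
    sig = [max(v, floor) for v in init]
    ve = max(ve_init, floor)
    active = [v > floor for v in sig]

    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        C = WtW.copy()
        for i, bl in enumerate(blocks):
            lam = ve / sig[i] if active[i] else 1e12
            C[bl, bl] += np.eye(q[i]) * lam
        Cinv = np.linalg.pinv(C)
        s = Cinv @ Wty

        new_sig = []
        for i, bl in enumerate(blocks):
            if not active[i]:
                new_sig.append(0.0)
                continue
            u = s[bl]
            tr = np.trace(Cinv[bl, bl])
            v = (float(u @ u) + ve * tr) / q[i]
            new_sig.append(max(v, 0.0))
        new_ve = float(y @ y - s @ Wty) / (n - p)
        new_ve = max(new_ve, floor)

        denom = max(abs(ve), floor)
        delta = abs(new_ve - ve) / denom
        for old, new in zip(sig, new_sig):
            delta = max(delta, abs(new - old) / max(abs(old), floor, 1e-8))
        sig = [v if a else 0.0 for v, a in zip(new_sig, active)]
        ve = new_ve
        # freeze components collapsing to zero
        for i, v in enumerate(sig):
            if active[i] and v < floor:
                sig[i] = 0.0
                active[i] = False
        if delta < tol:
            converged = True
            break
    return sig, ve, converged, it


def fit_variance_components(
    panel: pd.DataFrame,
    method: str = "auto",
    include_interaction: bool | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> VarianceComponents:
    """Estimate (mu, Vg, Vgl, Ve) by REML from a long-format panel.

    ``panel`` needs columns line, env, rep, value.  With a single
    environment, or ``include_interaction=False``, Vgl is structurally
    zero.  Non-convergence of EM returns the last iterate with
    ``converged=False`` and a warning, never silently.
    """
    panel = _check_panel(panel)
    n_env = panel["env"].nunique()
    reps = panel.groupby(["line", "env"], observed=True).size()
    if include_interaction is None:
        # interaction estimable only with >1 env and replicates within cells
        include_interaction = n_env > 1 and (reps > 1).any()

    if method not in ("auto", "em", "anova"):
        raise ValidationError(f"unknown method {method!r}")
    balanced = _is_balanced(panel)
    if method == "anova" and not balanced:
        raise ValidationError("closed-form estimates require a balanced panel")
    if method in ("auto", "anova") and balanced:
        vc = _anova_components(panel)
        if not include_interaction:
            vc.vgl = 0.0
        if method == "auto" or method == "anova":
            return vc

    # EM-REML (general / unbalanced path)
    y = panel["value"].to_numpy(float)
    X, Zs, _ = _design(panel, include_interaction)
    if balanced:
        init_vc = _anova_components(panel)
        init = [init_vc.vg, init_vc.vgl][: len(Zs)]
        ve0 = init_vc.ve
    else:
        v = float(np.var(y))
        init = [v / 3.0] * len(Zs)
        ve0 = v / 3.0
    if all(v == 0 for v in init) and ve0 == 0:
        return VarianceComponents(float(y.mean()), 0.0, 0.0, 0.0, True, 0, "em")
    sig, ve, converged, it = _em_reml(y, X, Zs, tol, max_iter, init, ve0)
    if not converged:
        warnings.warn("EM-REML did not converge within max_iter", stacklevel=2)
    vg = sig[0]
    vgl = sig[1] if len(sig) > 1 else 0.0
    mu = float(panel["value"].mean())
    return VarianceComponents(mu, float(vg), float(vgl), float(ve),
                              converged, it, "em")


def blup(panel: pd.DataFrame, components: VarianceComponents) -> pd.Series:
    """Per-line BLUPs: mu plus the predicted random line effect.

    Solves the mixed-model equations at the supplied variance components.
    With Vg = 0 (or all variances zero) every line shrinks completely to
    the grand mean.
    """
    panel = _check_panel(panel)
    lines = sorted(panel["line"].unique())
    mu = components.mu
    if components.vg <= 0:
        return pd.Series(mu, index=lines, name="blup")

    include_interaction = components.vgl > 0 and panel["env"].nunique() > 1
    y = panel["value"].to_numpy(float)
    X, Zs, line_levels = _design(panel, include_interaction)
    W = np.column_stack([X] + Zs)
    C = W.T @ W
    p = X.shape[1]
    ve = max(components.ve, 1e-12 * max(abs(float(np.var(y))), 1.0))
    off = p
    for Z, v in zip(Zs, [components.vg, components.vgl]):
        q = Z.shape[1]
        C[off : off + q, off : off + q] += np.eye(q) * (ve / max(v, 1e-300))
        off += q
    s, *_ = np.linalg.lstsq(C, W.T @ y, rcond=None)
    u = s[p : p + len(line_levels)]
    # report deviations around the panel grand mean
    return pd.Series(mu + u, index=line_levels, name="blup").loc[lines]


def heritability(components: VarianceComponents, L: int, R: int) -> float:
    """Broad-sense heritability H^2 = Vg / (Vg + Vgl/L + Ve/(L R))."""
    if L < 1 or R < 1:
        raise ValidationError("L and R must be at least 1")
    vg, vgl, ve = components.as_tuple()
    if min(vg, vgl, ve) < 0:
        raise ValidationError("variance components must be non-negative")
    denom = vg + vgl / L + ve / (L * R)
    if denom == 0:
        raise ValidationError("all variance components are zero: H^2 undefined")
    return float(vg / denom)


def fit_trait(panel: pd.DataFrame, method: str = "auto"):
    """Convenience: components, per-line BLUPs and H^2 for one trait."""
    vc = fit_variance_components(panel, method=method)
    L = panel["env"].nunique()
    R = int(round(len(panel) / (panel["line"].nunique() * L)))
    b = blup(panel, vc)
    h2 = heritability(vc, L, max(R, 1))
    return vc, b, h2
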
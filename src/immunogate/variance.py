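"""Longitudinal variance decomposition, detectable change, and sample size.

For each subset variable measured on A animals at T timepoints
(log10 cells/µL), a two-factor repeated-measures decomposition without
replication splits the total sum of squares into an animal (inter-
individual) component, a timepoint (intra-individual/repetition)
component, and a residual:

    SS_total = SS_animal + SS_time + SS_residual

η² for a factor is its share of SS_total.  Following the convention of
the reported tables, η²_intra maps to the timepoint factor and the
residual stays unassigned by default; because per-occasion noise that
is not synchronized across animals lands mostly in the residual, an
``intra_includes_residual`` reading is provided as well.

The minimum detectable change at effect size d is d x SD across the
repeated measurements; the companion sample-size computation inverts
the exact noncentral-t power function of a two-sided two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LongitudinalMatrix:
    """Animals x timepoints matrix of one variable (log10 cells/µL)."""

    variable_name: str
    values: np.ndarray
    balanced: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (animals x timepoints)")
        if min(self.values.shape) < 2:
            raise ValueError("need >= 2 animals and >= 2 timepoints")
        if np.isnan(self.values).any():
            if self.balanced:
                raise ValueError("missing cells in a balanced design")
            # listwise handling: drop timepoints with any missing value
            keep = ~np.isnan(self.values).any(axis=0)
            if keep.sum() < 2:
                raise ValueError("fewer than 2 complete timepoints after listwise drop")
            self.values = self.values[:, keep]


@dataclass
class AnovaComponents:
    ss_animal: float
    ss_time: float
    ss_residual: float
    ss_total: float
    n_animals: int
    n_timepoints: int


@dataclass
class VarianceDecomposition:
    """Shares of total sum of squares; components sum to 1."""

    variable_name: str
    eta_sq_inter: float
    eta_sq_intra: float
    eta_sq_residual: float

    def __post_init__(self):
        for v in (self.eta_sq_inter, self.eta_sq_intra, self.eta_sq_residual):
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError("η² components must lie in [0, 1]")
        if abs(self.eta_sq_inter + self.eta_sq_intra + self.eta_sq_residual - 1) > 1e-9:
            raise ValueError("η² components must sum to 1")


@dataclass
class DetectableChange:
    variable_name: str
    mdc_cells: float
    mdc_relative_pct: float
    cohens_d: float = 0.5
    power: float = 0.80
    alpha: float = 0.05


class ConstantVariableError(ValueError):
    """A variable with zero total variance has no defined η² shares."""


def anova_components(data: LongitudinalMatrix) -> AnovaComponents:
    """Two-factor decomposition without replication, from row/column means.

    SS_animal from row (animal) means, SS_time from column (timepoint)
    means, SS_residual by exact subtraction; additivity holds to
    floating point.
    """
    x = data.values
    a, t = x.shape
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_animal = float(t * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_time = float(a * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_residual = ss_total - ss_animal - ss_time
    return AnovaComponents(ss_animal, ss_time, ss_residual, ss_total, a, t)


def eta_squared(
    components: AnovaComponents,
    variable_name: str = "",
    intra_includes_residual: bool = False,
) -> VarianceDecomposition:
    """η² shares of the animal (inter) and repetition (intra) factors.

    With ``intra_includes_residual`` the unassigned residual share is
    folded into the intra component (appropriate when per-occasion
    variation is not synchronized across animals, e.g. under the
    simulator's noise model); the residual share is then reported as 0.
    """
    if components.ss_total <= 0:
        raise ConstantVariableError(
            f"variable {variable_name!r} is constant: η² undefined"
        )
    inter = components.ss_animal / components.ss_total
    intra = components.ss_time / components.ss_total
    resid = max(components.ss_residual / components.ss_total, 0.0)
    # guard against tiny negative residuals from subtraction
    resid = min(resid, 1.0)
    if intra_includes_residual:
        intra, resid = intra + resid, 0.0
    total = inter + intra + resid
    return VarianceDecomposition(variable_name, inter / total, intra / total, resid / total)


def variance_components(components: AnovaComponents) -> tuple[float, float]:
    """Method-of-moments (σ²_inter, σ²_intra) from the ANOVA mean squares.

    Under the additive model log10 y = μ + u_animal + v_occasion with
    iid occasion noise, E[MS_animal] = T σ²_inter + σ²_intra and the
    pooled within-animal mean square estimates σ²_intra, so

        σ̂²_intra = (SS_time + SS_residual) / (A (T - 1))
        σ̂²_inter = (MS_animal - σ̂²_intra) / T   (clipped at 0)

    Both are unbiased (before clipping); per-replicate *shares* built
    from them are still small-sample biased — average the components
    over replicates before forming shares.
    """
    a, t = components.n_animals, components.n_timepoints
    ms_animal = components.ss_animal / (a - 1)
    s2_intra = (components.ss_time + components.ss_residual) / (a * (t - 1))
    s2_inter = max((ms_animal - s2_intra) / t, 0.0)
    return s2_inter, s2_intra


def decompose_study(
    counts: pd.DataFrame,
    value_col: str = "log10_value",
    variable_col: str = "node",
    intra_includes_residual: bool = False,
) -> pd.DataFrame:
    """η² decomposition for every variable of a tidy longitudinal table.

    ``counts`` needs columns animal_id, timepoint, ``variable_col`` and
    ``value_col``; each variable is pivoted to animals x timepoints.
    Returns a frame mirroring the published layout (variable, η² intra %,
    η² inter %, plus the residual share).
    """
    rows = []
    for var, sub in counts.groupby(variable_col, sort=False):
        mat = sub.pivot_table(index="animal_id", columns="timepoint", values=value_col)
        try:
            lm = LongitudinalMatrix(var, mat.to_numpy(), balanced=not mat.isna().any().any())
            dec = eta_squared(anova_components(lm), var, intra_includes_residual)
        except (ConstantVariableError, ValueError):
            rows.append((var, np.nan, np.nan, np.nan))
            continue
        rows.append(
            (var, 100 * dec.eta_sq_intra, 100 * dec.eta_sq_inter, 100 * dec.eta_sq_residual)
        )
    return pd.DataFrame(
        rows, columns=["variable", "eta_intra_pct", "eta_inter_pct", "eta_residual_pct"]
    )


def panel_mean_eta(decompositions) -> tuple[float, float]:
    """Arithmetic mean (intra, inter) η² across a panel's variables.

    Accepts a list of ``VarianceDecomposition`` or a frame with
    eta_intra_pct/eta_inter_pct columns (then means are in %).
    """
    if isinstance(decompositions, pd.DataFrame):
        if decompositions.empty:
            raise ValueError("empty decomposition table")
        return (
            float(decompositions["eta_intra_pct"].mean()),
            float(decompositions["eta_inter_pct"].mean()),
        )
    decompositions = list(decompositions)
    if not decompositions:
        raise ValueError("empty decomposition list")
    return (
        float(np.mean([d.eta_sq_intra for d in decompositions])),
        float(np.mean([d.eta_sq_inter for d in decompositions])),
    )


def detectable_change(
    values,
    cohens_d: float = 0.5,
    denominator: str = "own_mean",
    leukocyte_mean: float | None = None,
    variable_name: str = "",
    power: float = 0.80,
    alpha: float = 0.05,
) -> DetectableChange:
    """Minimum detectable change: d x sample SD of the repeated values.

    The relative threshold divides by the variable's own mean
    (default) or by a supplied leukocyte mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 values")
    sd = float(arr.std(ddof=1))
    if sd == 0:
        raise ValueError("zero SD: detectable change undefined")
    if denominator == "own_mean":
        denom = float(arr.mean())
    elif denominator == "leukocyte_mean":
        if leukocyte_mean is None:
            raise ValueError("leukocyte_mean required for that denominator")
        denom = float(leukocyte_mean)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("zero denominator mean")
    mdc = cohens_d * sd
    return DetectableChange(variable_name, mdc, 100 * mdc / denom, cohens_d, power, alpha)


def two_sample_power(n: int, cohens_d: float, alpha: float = 0.05) -> float:
    """Exact power of a two-sided two-sample t-test with n per group."""
    if n < 2:
        return 0.0
    df = 2 * n - 2
    ncp = cohens_d * math.sqrt(n / 2)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def required_n(
    cohens_d: float, power: float = 0.80, alpha: float = 0.05
) -> tuple[int, int]:
    """Per-group n for a two-sided two-sample comparison.

    Returns (exact, normal_approximation): the exact value iterates the
    noncentral-t power function to the smallest n reaching the target;
    the approximation is ceil(2 (z_{1-α/2} + z_{power})² / d²).
    """
    if cohens_d <= 0:
        raise ValueError("cohens_d must be > 0")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must be in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    n_norm = max(2, math.ceil(2 * (za + zb) ** 2 / cohens_d**2))
    n = 2
    while two_sample_power(n, cohens_d, alpha) < power:
        n += 1
        if n > 10**7:  # pragma: no cover - unreachable for d > 0
            raise RuntimeError("power target not reached")
    return n, n_norm


def load_reference_variability() -> pd.DataFrame:
    """The bundled per-subset variance shares and detectable-change
    thresholds for healthy mice (reference dataset shipped with the
    package): panel, variable, η² intra %, η² inter %, MDC in cells/µL
    and as % of the variable's reference denominator."""
    from importlib import resources

    ref = resources.files("immunogate") / "data" / "reference_variability.csv"
    with ref.open() as fh:
        return pd.read_csv(fh)
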
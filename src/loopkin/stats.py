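"""Statistics for the cell-tissue correlation stage.

Continuous per-bin change variables are far from Gaussian, so they are
normalized with Templeton's two-step transformation (fractional rank to a
uniform probability, then the inverse standard normal).  Regional contrasts
use pairwise two-sided Mann-Whitney U tests with Bonferroni correction, and
the relation between tissue volume change and the cellular change features
is modelled with a Gaussian identity-link linear model built by step-up
(forward) selection under AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "templeton_transform",
    "region_tests",
    "GlmSpec",
    "StepwiseGLMResult",
    "stepwise_glm",
]


def templeton_transform(values) -> np.ndarray:
    """Two-step rank-based inverse normal transformation.

    Step 1 converts values to fractional ranks p = rank / (n + 1) (mean rank
    for ties), a uniform probability scale that avoids the boundary
    infinities; step 2 applies the inverse standard normal.  The output is
    standard-normal distributed for continuous inputs and strictly preserves
    the input ordering.  An all-constant input maps to all zeros.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1D array")
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 values")
    ranks = sps.rankdata(v, method="average")
    return sps.norm.ppf(ranks / (n + 1.0))


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for thr, s in _STAR_LEVELS:
        if p < thr:
            return s
    return "ns"


def region_tests(bins: pd.DataFrame, feature: str,
                 group_column: str = "region", groups=None) -> pd.DataFrame:
    """Pairwise Mann-Whitney U tests between groups with Bonferroni correction.

    Two-sided tests on the raw per-bin feature values; the adjusted p-value
    is min(1, p * m) over the m pairwise comparisons.  Each group needs at
    least 3 bins.
    """
    if groups is None:
        groups = sorted(g for g in bins[group_column].dropna().unique())
    samples = {}
    for g in groups:
        x = bins.loc[bins[group_column] == g, feature].dropna().to_numpy()
        if x.size == 0:
            raise ValueError(f"group {g!r} is empty")
        if x.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 bins")
        samples[g] = x
    pairs = list(combinations(groups, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        stat, p = sps.mannwhitneyu(samples[a], samples[b],
                                   alternative="two-sided")
        p_adj = min(1.0, p * m)
        rows.append([a, b, len(samples[a]), len(samples[b]), float(stat),
                     float(p), float(p_adj), _stars(p_adj)])
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b",
                                       "U", "p_raw", "p_adj", "signif"])


@dataclass
class GlmSpec:
    """Step-up GLM specification for tissue volume change.

    ``response`` regressed on fixed factors (Time, Region, and their
    interaction once both main effects are in) plus the continuous cellular
    change terms.  Cell-count and cell-density changes are collinear by
    construction (density = count / tissue volume) and never co-occur.
    """

    response: str = "dV_tissue"
    continuous_terms: tuple = ("dN_cell", "dV_cell", "dA_cell", "dV_ICS",
                               "drho_cell")
    factor_terms: tuple = ("Time", "Region")
    interactions: tuple = (("Time", "Region"),)
    mutually_exclusive: tuple = (("dN_cell", "drho_cell"),)


@dataclass
class StepwiseGLMResult:
    """Final model, selection path and fit quality of the step-up search."""

    results: object  # statsmodels RegressionResults
    formula: str
    terms: list
    aic_trace: list
    skipped: list = field(default_factory=list)

    @property
    def aic(self) -> float:
        return self.aic_trace[-1]

    @property
    def rsquared(self) -> float:
        return float(self.results.rsquared)

    @property
    def params(self):
        return self.results.params

    def summary(self):
        return self.results.summary()


def _term_formula(term) -> str:
    if isinstance(term, tuple):
        return ":".join(f"C({t})" for t in term)
    return term


def stepwise_glm(data: pd.DataFrame, spec: GlmSpec = None,
                 transform: bool = True) -> StepwiseGLMResult:
    """Forward (step-up) AIC selection of the tissue-growth linear model.

    Starts from the intercept-only model; at each step the admissible
    candidate whose addition lowers AIC the most is added, and selection
    stops when no candidate lowers it.  Factors enter dummy-coded; an
    interaction becomes admissible once both its main effects are in;
    mutually exclusive term pairs never co-occur.  With ``transform`` the
    response and continuous terms are Templeton-normalized first.
    Rank-deficient candidate designs are skipped with a note.
    """
    spec = spec or GlmSpec()
    df = data.copy()
    if transform:
        for col in (spec.response, *spec.continuous_terms):
            if col in df.columns:
                df[col] = templeton_transform(df[col].to_numpy())
    df = df.dropna(subset=[c for c in (spec.response, *spec.continuous_terms)
                           if c in df.columns])

    candidates = [t for t in spec.continuous_terms if t in df.columns]
    candidates += [t for t in spec.factor_terms if t in df.columns]
    inter = [tuple(t) for t in spec.interactions
             if all(x in df.columns for x in t)]
    factors = set(spec.factor_terms)

    selected: list = []
    skipped: list = []
    current_formula = f"{spec.response} ~ 1"
    model = smf.ols(current_formula, data=df).fit()
    aic_trace = [float(model.aic)]

    def admissible(term):
        if term in selected:
            return False
        for pair in spec.mutually_exclusive:
            if term in pair and any(o in selected for o in pair if o != term):
                return False
        if isinstance(term, tuple):
            return all(t in selected for t in term)
        return True

    while True:
        best = None
        pool = [t for t in candidates + inter if admissible(t)]
        for term in pool:
            rhs = " + ".join(
                [_term_formula(t) if not (isinstance(t, str) and t in factors)
                 else f"C({t})" for t in selected + [term]])
            formula = f"{spec.response} ~ {rhs}"
            try:
                cand = smf.ols(formula, data=df).fit()
            except Exception:
                skipped.append(term)
                continue
            if np.linalg.matrix_rank(cand.model.exog) < cand.model.exog.shape[1]:
                skipped.append(term)
                continue
            if best is None or cand.aic < best[1]:
                best = (term, float(cand.aic), cand, formula)
        if best is None or best[1] >= aic_trace[-1]:
            break
        selected.append(best[0])
        aic_trace.append(best[1])
        model = best[2]
        current_formula = best[3]
    return StepwiseGLMResult(model, current_formula, list(selected),
                             aic_trace, skipped)
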
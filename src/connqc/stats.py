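"""Confound analysis of connectivity-covariate associations.

The central object is :class:`ConfoundModel`: given per-participant
connectivity outcomes, the seven demographic/clinical covariates and the
three modality-matched image-quality metrics, ``fit()`` estimates, for every
outcome, Model 1 (outcome ~ covariates) and Model 2 (Model 1 + quality
metrics) as standardized OLS regressions, and reports the signed percent
change of each Model-1 coefficient after quality adjustment. Coefficients
that were significant in Model 1 and changed by more than the configured
threshold (default 10%) are flagged as relevantly confounded.

All variables are z-scored before fitting (relative WMH volume is
log10-transformed first), so coefficients are standardized betas comparable
across predictors. Significance uses two-sided OLS t-tests at alpha = 0.05
with no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from . import presets
from .cohort import covariate_zscores

QUALITY_SHORT = ("isnr", "motion", "mismatch")


@dataclass
class RegressionResult:
    """Standardized OLS fit for one outcome."""

    outcome: str
    params: pd.Series          # standardized betas, indexed by predictor
    pvalues: pd.Series
    rsquared: float
    nobs: int
    alpha: float = 0.05

    def significant(self, name: str) -> bool:
        return bool(self.pvalues[name] < self.alpha)


def zscore_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = (df - df.mean()) / df.std(ddof=1)
    return out


def standardized_regression(outcome: pd.Series | np.ndarray,
                            predictors: pd.DataFrame,
                            alpha: float = 0.05,
                            name: str = "outcome") -> RegressionResult:
    """OLS of a z-scored outcome on z-scored predictors (plus intercept).

    Raises on constant predictors and on perfect collinearity, naming the
    offending columns.
    """
    X = pd.DataFrame(predictors).astype(float)
    y = np.asarray(outcome, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more observations than predictors + 1")
    sd = X.std(ddof=1)
    const = sd[sd == 0].index.tolist()
    if const:
        raise ValueError(f"constant predictor(s): {const}")
    Xz = (X - X.mean()) / sd
    if np.linalg.matrix_rank(Xz.to_numpy()) < Xz.shape[1]:
        # identify an offending column: rank-deficient submatrix search
        bad = []
        cols: list = []
        M = Xz.to_numpy()
        for j, c in enumerate(Xz.columns):
            if np.linalg.matrix_rank(M[:, cols + [j]]) == len(cols):
                bad.append(c)
            else:
                cols.append(j)
        raise ValueError(f"perfectly collinear predictor(s): {bad}")
    ysd = y.std(ddof=1)
    if ysd <= 1e-12 * max(1.0, abs(y.mean())):
        raise ValueError("outcome is constant")
    yz = (y - y.mean()) / ysd
    model = sm.OLS(yz, sm.add_constant(Xz))
    res = model.fit()
    return RegressionResult(
        outcome=name,
        params=res.params.drop("const"),
        pvalues=res.pvalues.drop("const"),
        rsquared=float(res.rsquared),
        nobs=int(res.nobs),
        alpha=alpha,
    )


def percent_change(beta1: float, beta2: float) -> float:
    """Signed percent change of a coefficient after quality adjustment:
    (beta2 - beta1) / beta1 * 100. A sign flip yields a change below -100%."""
    if beta1 == 0:
        raise ZeroDivisionError("percent change undefined for beta1 = 0")
    return (beta2 - beta1) / beta1 * 100.0


# ---------------------------------------------------------------------------
# Model 1 / Model 2 confound comparison
# ---------------------------------------------------------------------------

def _merged(tables: list[pd.DataFrame]) -> pd.DataFrame:
    out = tables[0]
    for t in tables[1:]:
        out = out.merge(t, on="participant_id", how="inner", validate="1:1")
    return out


def _design_frames(cohort: pd.DataFrame, quality: pd.DataFrame, modality: str
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(covariate z-scores, quality z-scores) aligned on participant order."""
    Z = covariate_zscores(cohort)
    prefix = "dmri" if modality == "SC" else "fmri"
    qcols = [f"{prefix}_{m}" for m in QUALITY_SHORT]
    missing = [c for c in qcols if c not in quality.columns]
    if missing:
        raise ValueError(
            f"quality table lacks {missing} required for modality {modality!r}")
    Q = zscore_frame(quality[qcols].astype(float))
    Q.columns = list(QUALITY_SHORT)
    return Z, Q


@dataclass
class ConfoundResults:
    """Fitted Model 1 / Model 2 pairs and the percent-change ledger."""

    modality: str
    alpha: float
    change_threshold: float
    model1: dict = field(default_factory=dict)   # outcome -> RegressionResult
    model2: dict = field(default_factory=dict)
    ledger: pd.DataFrame = None

    def summary(self) -> str:
        lines = [
            f"Confound analysis ({self.modality}), alpha={self.alpha}, "
            f"relevant-change threshold={self.change_threshold:.0%}",
            "",
        ]
        for outcome, r1 in self.model1.items():
            r2 = self.model2[outcome]
            lines.append(f"{outcome}  (n={r1.nobs}, R2: {r1.rsquared:.3f} -> "
                         f"{r2.rsquared:.3f})")
            lines.append(f"  {'predictor':<12}{'Model 1':>10}{'Model 2':>10}"
                         f"{'delta %':>10}  relevant")
            sub = self.ledger[self.ledger.outcome == outcome]
            for _, row in sub.iterrows():
                d = f"{row.delta_pct:+.0f}" if np.isfinite(row.delta_pct) else "-"
                lines.append(f"  {row.covariate:<12}{row.beta_model1:>10.3f}"
                             f"{row.beta_model2:>10.3f}{d:>10}"
                             f"  {'*' if row.relevant else ''}")
            lines.append("")
        return "\n".join(lines)


class ConfoundModel:
    """Model-1/Model-2 comparison of connectivity-covariate associations.

    Parameters
    ----------
    connectivity : DataFrame with ``participant_id`` plus one column per
        connectivity outcome (e.g. overall, nu, gamma, e_global).
    cohort : DataFrame of demographic/clinical covariates.
    quality : DataFrame of the six quality metrics.
    modality : 'SC' (adjusts for dMRI quality) or 'FC' (rs-fMRI quality).
    """

    def __init__(self, connectivity: pd.DataFrame, cohort: pd.DataFrame,
                 quality: pd.DataFrame, modality: str = "SC"):
        if modality not in ("SC", "FC"):
            raise ValueError("modality must be 'SC' or 'FC'")
        for t, nm in ((connectivity, "connectivity"), (cohort, "cohort"),
                      (quality, "quality")):
            if "participant_id" not in t.columns:
                raise ValueError(f"{nm} table lacks a participant_id column")
        self.modality = modality
        prefix = "dmri" if modality == "SC" else "fmri"
        needed = [f"{prefix}_{m}" for m in QUALITY_SHORT]
        lacking = [c for c in needed if c not in quality.columns]
        if lacking:
            raise ValueError(
                f"quality table lacks {lacking} required for modality {modality!r}")
        self.outcomes = [c for c in connectivity.columns if c != "participant_id"]
        merged = _merged([cohort, quality, connectivity])
        if merged.empty:
            raise ValueError("no participants shared by the three tables")
        self._cohort = merged[cohort.columns]
        self._quality = merged[quality.columns]
        self._connectivity = merged[connectivity.columns]

    @classmethod
    def from_dataframes(cls, connectivity, cohort, quality, modality="SC"):
        return cls(connectivity, cohort, quality, modality)

    def fit(self, alpha: float = 0.05, change_threshold: float = 0.10) -> ConfoundResults:
        Z, Q = _design_frames(self._cohort, self._quality, self.modality)
        res = ConfoundResults(modality=self.modality, alpha=alpha,
                              change_threshold=change_threshold)
        rows = []
        for outcome in self.outcomes:
            y = self._connectivity[outcome]
            r1 = standardized_regression(y, Z, alpha=alpha, name=outcome)
            X2 = pd.concat([Z, Q], axis=1)
            r2 = standardized_regression(y, X2, alpha=alpha, name=outcome)
            res.model1[outcome] = r1
            res.model2[outcome] = r2
            for cov in presets.COVARIATES:
                b1, b2 = r1.params[cov], r2.params[cov]
                delta = percent_change(b1, b2) if b1 != 0 else np.nan
                rows.append({
                    "outcome": outcome, "covariate": cov,
                    "beta_model1": b1, "beta_model2": b2,
                    "p_model1": r1.pvalues[cov], "p_model2": r2.pvalues[cov],
                    "delta_pct": delta,
                    "relevant": bool(r1.pvalues[cov] < alpha
                                     and np.isfinite(delta)
                                     and abs(delta) > change_threshold * 100),
                })
            rows.append({
                "outcome": outcome, "covariate": "R2",
                "beta_model1": r1.rsquared, "beta_model2": r2.rsquared,
                "p_model1": np.nan, "p_model2": np.nan,
                "delta_pct": percent_change(r1.rsquared, r2.rsquared)
                if r1.rsquared != 0 else np.nan,
                "relevant": False,
            })
        res.ledger = pd.DataFrame(rows)
        return res


def fit_model1_model2(connectivity: pd.DataFrame, cohort: pd.DataFrame,
                      quality: pd.DataFrame, modality: str = "SC",
                      alpha: float = 0.05, change_threshold: float = 0.10
                      ) -> ConfoundResults:
    """Functional wrapper around :class:`ConfoundModel`."""
    return ConfoundModel(connectivity, cohort, quality, modality).fit(
        alpha=alpha, change_threshold=change_threshold)


# ---------------------------------------------------------------------------
# quality determinants & correlations
# ---------------------------------------------------------------------------

def _forward_selection(y, X: pd.DataFrame, alpha_enter: float = 0.05) -> list[str]:
    """p-value-driven forward selection; returns entered column names."""
    selected: list[str] = []
    remaining = list(X.columns)
    while remaining:
        best_p, best_c = None, None
        for c in remaining:
            Xs = sm.add_constant(X[selected + [c]])
            p = sm.OLS(y, Xs).fit().pvalues[c]
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_p is not None and best_p < alpha_enter:
            selected.append(best_c)
            remaining.remove(best_c)
        else:
            break
    return selected


def quality_determinants(cohort: pd.DataFrame, quality: pd.DataFrame,
                         alpha: float = 0.05,
                         forward_selection: bool = False) -> dict[str, RegressionResult]:
    """Regress each of the six quality metrics on the seven covariates.

    By default the full model is fitted (one standardized beta per covariate);
    ``forward_selection=True`` instead enters covariates stepwise at
    alpha = 0.05 and reports betas only for the selected set.
    """
    merged = _merged([cohort, quality])
    Z = covariate_zscores(merged)
    out = {}
    for mod, met in presets.QUALITY_METRICS:
        col = f"{mod}_{met}"
        y = merged[col].astype(float)
        yz = (y - y.mean()) / y.std(ddof=1)
        X = Z
        if forward_selection:
            chosen = _forward_selection(yz, Z, alpha_enter=alpha)
            X = Z[chosen] if chosen else Z[[]]
            if X.shape[1] == 0:
                out[col] = RegressionResult(col, pd.Series(dtype=float),
                                            pd.Series(dtype=float), 0.0, len(yz), alpha)
                continue
            res = sm.OLS(yz, sm.add_constant(X)).fit()
            out[col] = RegressionResult(col, res.params.drop("const"),
                                        res.pvalues.drop("const"),
                                        float(res.rsquared), int(res.nobs), alpha)
        else:
            out[col] = standardized_regression(yz, X, alpha=alpha, name=col)
    return out


def quality_cross_correlations(quality: pd.DataFrame
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r (and p-values) between every pair of the six quality metrics."""
    cols = [f"{m}_{k}" for m, k in presets.QUALITY_METRICS if f"{m}_{k}" in quality]
    if len(quality) < 3:
        raise ValueError("need at least three complete rows")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            x, y = quality[a].astype(float), quality[b].astype(float)
            if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = sps.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p


# ---------------------------------------------------------------------------
# interpretation helpers
# ---------------------------------------------------------------------------

def motion_age_equivalence(beta_motion: float, beta_age: float,
                           sd_motion: float, sd_age: float,
                           delta_motion: float = 0.1) -> float:
    """Years of aging whose effect on the outcome matches a motion increment.

    With standardized coefficients, a ``delta_motion`` mm increase shifts the
    standardized outcome by ``beta_motion * delta_motion / sd_motion``; the
    age change producing the same shift is
    ``|beta_motion / beta_age| * (delta_motion / sd_motion) * sd_age`` years.
    """
    if beta_age == 0:
        raise ZeroDivisionError("equivalence undefined for beta_age = 0")
    if sd_motion <= 0 or sd_age <= 0:
        raise ValueError("SDs must be positive")
    return abs(beta_motion / beta_age) * (delta_motion / sd_motion) * sd_age


@dataclass
class ExclusionRefit:
    threshold: float
    n_excluded: int
    n_retained: int
    cohort: pd.DataFrame
    quality: pd.DataFrame
    connectivity: pd.DataFrame | None
    results: dict = None  # modality -> ConfoundResults, when connectivity given


def exclude_high_motion(cohort: pd.DataFrame, quality: pd.DataFrame,
                        connectivity: pd.DataFrame | None = None,
                        threshold: float = 1.0,
                        metric: str = "dmri_motion",
                        modality: str = "SC",
                        alpha: float = 0.05) -> ExclusionRefit:
    """Drop participants with ``metric`` above ``threshold`` mm and refit.

    Mirrors the post-hoc sensitivity analysis excluding high-motion scans;
    when a connectivity table is supplied the Model-1/Model-2 comparison is
    rerun on the retained subset.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keep_ids = quality.loc[quality[metric] <= threshold, "participant_id"]
    n_excluded = len(quality) - len(keep_ids)
    if len(keep_ids) == 0:
        raise ValueError(f"threshold {threshold} excludes every participant")
    sub_c = cohort[cohort.participant_id.isin(keep_ids)].reset_index(drop=True)
    sub_q = quality[quality.participant_id.isin(keep_ids)].reset_index(drop=True)
    sub_y = None
    results = None
    if connectivity is not None:
        sub_y = connectivity[connectivity.participant_id.isin(keep_ids)].reset_index(drop=True)
        results = {modality: ConfoundModel(sub_y, sub_c, sub_q, modality).fit(alpha=alpha)}
    return ExclusionRefit(threshold=threshold, n_excluded=int(n_excluded),
                          n_retained=int(len(keep_ids)), cohort=sub_c,
                          quality=sub_q, connectivity=sub_y, results=results)
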
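"""Synthetic population-cohort generator.

Emulates a large imaging cohort (ages 40-75, type-2-diabetes oversampled) at
the level the downstream analyses need:

* covariates drawn from configured marginals (truncated-normal age, log-normal
  relative WMH volume calibrated to median/quartiles, categorical proportions),
  mutually independent except a configurable age-WMH Gaussian-copula
  correlation;
* per-scan image-quality metrics (iSNR, head motion, atlas mismatch, for dMRI
  and rs-fMRI) generated from standardized linear models on the covariates
  plus correlated residuals, then rescaled to the configured native means/SDs;
* per-participant structural and functional connectomes built from a seeded
  base template whose subject-level scaling is linear (on the standardized
  scale) in covariates and quality metrics.

Because every outcome is generated from an explicit standardized linear
equation, refitting the corresponding regression on the synthetic data
recovers the configured coefficients — the property the test-suite and the
confound analyses rely on.
"""

from __future__ import annotations

import logging
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import presets
from .config import GeneratorConfig, substream
from .connectome import Connectome

log = logging.getLogger(__name__)

QUALITY_COLUMNS = [f"{mod}_{met}" for mod, met in presets.QUALITY_METRICS]


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def _truncnorm_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Underlying (mu, sigma) of a normal whose [lo, hi]-truncation has the
    requested mean and SD.

    Naively plugging the target moments in as loc/scale undershoots both
    (truncation pulls the mean toward the interval centre and shrinks the
    spread), so the pair is solved numerically.
    """
    if sd == 0:
        return mean, 0.0
    max_sd = (hi - lo) / np.sqrt(12.0)  # uniform limit
    if sd >= max_sd:
        raise ValueError(
            f"target SD {sd} not attainable by a truncated normal on [{lo}, {hi}]"
        )

    def moments(p):
        mu, lsig = p
        sig = np.exp(lsig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ier, msg = optimize.fsolve(
        moments, x0=[mean, np.log(sd)], full_output=True)
    if ier != 1:
        raise RuntimeError(f"truncated-normal calibration failed: {msg}")
    return float(sol[0]), float(np.exp(sol[1]))


def lognormal_params_from_quantiles(median: float, q25: float, q75: float) -> tuple[float, float]:
    """Natural-log (mu, sigma) of a log-normal matching median and quartiles.

    mu = ln(median); sigma from the interquartile log-ratio,
    sigma = ln(q75/q25) / (2 * z_0.75).
    """
    if not (0 < q25 <= median <= q75):
        raise ValueError("require 0 < q25 <= median <= q75")
    mu = np.log(median)
    if q75 == q25:
        return float(mu), 0.0
    z75 = stats.norm.ppf(0.75)
    sigma = np.log(q75 / q25) / (2.0 * z75)
    return float(mu), float(sigma)


def _categorical(rng: np.random.Generator, props, n: int, codes) -> np.ndarray:
    return rng.choice(np.asarray(codes), size=n, p=np.asarray(props, float))


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw ``config.n`` synthetic participants.

    Returns a DataFrame with columns ``participant_id, age, sex, education,
    bmi, diabetes, cvd, wmh_rel``. Sex is coded 0 = male / 1 = female,
    education 1-3 (low/middle/high), diabetes status 0-3 ordinal
    (none, prediabetes, T2DM, other). ``wmh_rel`` is the relative WMH volume
    in % of ICV (log-normal; log10-transform before modelling).
    """
    cp = config.covariate_params
    n = config.n
    rng = substream(config.seed, "cohort")

    lo, hi = cp["age_range"]
    mu_a, sig_a = _truncnorm_params(cp["age_mean"], cp["age_sd"], lo, hi)
    mu_w, sig_w = lognormal_params_from_quantiles(
        cp["wmh_median"], cp["wmh_q25"], cp["wmh_q75"])

    # Gaussian copula for the configured age-WMH dependence.
    rho = float(cp.get("age_wmh_corr", 0.0))
    z = rng.standard_normal((n, 2))
    z[:, 1] = rho * z[:, 0] + np.sqrt(max(0.0, 1 - rho**2)) * z[:, 1]
    if sig_a > 0:
        a, b = (lo - mu_a) / sig_a, (hi - mu_a) / sig_a
        age = stats.truncnorm.ppf(stats.norm.cdf(z[:, 0]), a, b, loc=mu_a, scale=sig_a)
    else:
        age = np.full(n, mu_a)
    wmh = np.exp(mu_w + sig_w * z[:, 1])

    sex = (rng.random(n) < cp["female_prop"]).astype(int)
    edu = _categorical(rng, cp["education_props"], n, [1, 2, 3])
    bmi = cp["bmi_mean"] + cp["bmi_sd"] * rng.standard_normal(n)
    dia = _categorical(rng, cp["diabetes_props"], n, [0, 1, 2, 3])
    cvd = (rng.random(n) < cp["cvd_prop"]).astype(int)

    return pd.DataFrame({
        "participant_id": [f"P{i:06d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "education": edu,
        "bmi": bmi,
        "diabetes": dia,
        "cvd": cvd,
        "wmh_rel": wmh,
    })


def covariate_zscores(cohort: pd.DataFrame) -> pd.DataFrame:
    """Sample z-scores of the seven model covariates (WMH log10 first).

    Constant columns are mapped to zero (they carry no signal and would
    otherwise divide by zero in degenerate configurations).
    """
    raw = pd.DataFrame({
        "age": cohort["age"],
        "sex": cohort["sex"],
        "education": cohort["education"],
        "bmi": cohort["bmi"],
        "diabetes": cohort["diabetes"],
        "cvd": cohort["cvd"],
        "log_wmh": np.log10(cohort["wmh_rel"]),
    }, index=cohort.index).astype(float)
    sd = raw.std(ddof=1)
    out = raw - raw.mean()
    for c in raw.columns:
        out[c] = out[c] / sd[c] if sd[c] > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# quality metrics
# ---------------------------------------------------------------------------

def _standardized_outcome(lp: np.ndarray, resid: np.ndarray, noise_sd: float | None,
                          key) -> np.ndarray:
    """lp + scaled residual; residual SD completes the variance to 1 unless pinned."""
    v = float(np.var(lp))
    if noise_sd is None:
        if v >= 1.0:
            raise ValueError(
                f"{key}: coefficient set implies linear-predictor variance {v:.3f} >= 1 "
                "under the configured covariate structure; residual variance would be "
                "negative. Reduce the coefficients or the covariate correlations.")
        noise_sd = float(np.sqrt(1.0 - v))
    return lp + noise_sd * resid


def generate_quality(cohort: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Generate the six per-scan quality metrics for every participant.

    Each standardized metric is sum(beta_k * z(covariate_k)) plus a Gaussian
    residual completing the variance to one; residuals across metrics are
    correlated such that the configured *total* metric-metric Pearson
    correlations are met. Metrics are then rescaled to the configured native
    means/SDs; head motion is clipped at zero (count logged).

    Columns: ``dmri_isnr, dmri_motion, dmri_mismatch, fmri_isnr, fmri_motion,
    fmri_mismatch`` (iSNR unitless and negative, motion in mm, mismatch in
    [0, 1] for realistic scales).
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    Z = covariate_zscores(cohort)
    rng = substream(config.seed, "quality")
    metrics = list(presets.QUALITY_METRICS)
    n = len(cohort)

    lps = {}
    resid_sd = {}
    for key in metrics:
        beta = config.quality_coeffs[key]
        lp = sum(beta[c] * Z[c].to_numpy() for c in presets.COVARIATES)
        lp = np.asarray(lp, float) if np.ndim(lp) else np.zeros(n)
        v = float(np.var(lp))
        pinned = config.noise_scales.get(key)
        if pinned is None and v >= 1.0:
            raise ValueError(
                f"{key}: linear-predictor variance {v:.3f} >= 1; residual variance "
                "would be negative under the configured coefficients/correlations.")
        lps[key] = lp
        resid_sd[key] = float(pinned) if pinned is not None else float(np.sqrt(1.0 - v))

    # residual correlation matrix achieving the configured total correlations
    R = np.eye(len(metrics))
    for (k1, k2), r_target in config.quality_target_corr.items():
        i, j = metrics.index(tuple(k1)), metrics.index(tuple(k2))
        shared = float(np.cov(lps[k1], lps[k2])[0, 1]) if n > 1 else 0.0
        denom = resid_sd[k1] * resid_sd[k2]
        if denom == 0:
            raise ValueError(f"cannot correlate residuals of {k1} and {k2}: zero residual SD")
        rho = (r_target - shared) / denom
        if not -1.0 < rho < 1.0:
            raise ValueError(
                f"target correlation {r_target} between {k1} and {k2} requires residual "
                f"correlation {rho:.3f} outside (-1, 1)")
        R[i, j] = R[j, i] = rho
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as e:
        raise ValueError("residual correlation matrix is not positive definite") from e

    eps = rng.standard_normal((n, len(metrics))) @ L.T
    eps -= eps.mean(axis=0)  # exact centering: native means hit exactly

    out = {}
    clipped_total = 0
    for j, key in enumerate(metrics):
        y = lps[key] + resid_sd[key] * eps[:, j]
        mean, sd = config.quality_scale[key]
        y = mean + sd * y
        if key[1] == "motion":
            neg = y < 0
            if neg.any():
                clipped_total += int(neg.sum())
                y = np.clip(y, 0.0, None)
        out[f"{key[0]}_{key[1]}"] = y
    if clipped_total:
        log.info("generate_quality: clipped %d negative motion values to 0", clipped_total)

    qual = pd.DataFrame(out, index=cohort.index)
    qual.insert(0, "participant_id", cohort["participant_id"].to_numpy())
    return qual


# ---------------------------------------------------------------------------
# connectomes
# ---------------------------------------------------------------------------

def hemisphere_labels(n_regions: int = presets.N_REGIONS) -> np.ndarray:
    """Default hemisphere assignment: regions 1..n, odd = left, even = right."""
    return np.array(["L" if r % 2 == 1 else "R" for r in range(1, n_regions + 1)])


class ConnectomeTemplate:
    """Seeded base edge-weight/prevalence template shared by a cohort.

    Regions are placed at random positions in a unit box split into two
    hemisphere blocks; edge strength decays with Euclidean distance (times a
    log-normal tract-volume-like jitter), which yields the spatially clustered,
    intra-hemisphere-dominated topology of real connectomes. For SC an edge
    *prevalence* (probability an individual expresses the edge) increases with
    the edge's strength rank, so the strongest edges are near-universal. FC
    weights are mapped into (0, 0.7] with a weaker distance dependence and a
    homotopic (mirror-region) boost.
    """

    def __init__(self, config: GeneratorConfig, modality: str):
        if modality not in ("SC", "FC"):
            raise ValueError("modality must be 'SC' or 'FC'")
        self.modality = modality
        self.n_regions = p = config.n_regions
        rng = substream(config.seed, "template", modality)

        pos = rng.random((p, 3))
        hemi = hemisphere_labels(p)
        # separate the hemispheres along x; SC more than FC
        gap = 0.30 if modality == "SC" else 0.05
        pos[:, 0] = pos[:, 0] * (1 - gap) / 2 + np.where(hemi == "R", (1 + gap) / 2, 0.0)
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        iu = np.triu_indices(p, 1)

        if modality == "SC":
            lam = 0.35
            w = np.exp(-d / lam) * np.exp(0.6 * rng.standard_normal((p, p)))
            w = np.triu(w, 1)
            # prevalence from strength rank: strongest quintile ~0.93-0.996
            vals = w[iu]
            rank_q = stats.rankdata(vals) / vals.size
            prev = np.where(rank_q >= 0.8,
                            0.93 + 0.33 * (rank_q - 0.8),
                            0.05 + 1.1 * rank_q)
            P = np.zeros((p, p))
            P[iu] = np.clip(prev, 0.0, 1.0)
            self.prevalence = P + P.T
        else:
            lam = 3.0
            w = np.exp(-d / lam) * np.exp(0.25 * rng.standard_normal((p, p)))
            w = np.triu(w, 1)
            # homotopic boost for mirror pairs (2k-1, 2k)
            for k in range(0, p - 1, 2):
                w[k, k + 1] *= 2.5
            vals = w[iu]
            w[iu] = 0.7 * vals / vals.max()
            self.prevalence = None

        W = w + w.T
        np.fill_diagonal(W, 0.0)
        self.weights = W
        self.mean_upper = float(W[iu].mean())


def _subject_overall_targets(cohort: pd.DataFrame, quality: pd.DataFrame,
                             config: GeneratorConfig, modality: str) -> np.ndarray:
    """Per-subject target overall connectivity, linear in covariates+quality."""
    Z = covariate_zscores(cohort)
    qmod = "dmri" if modality == "SC" else "fmri"
    qcols = {m: f"{qmod}_{m}" for m in ("isnr", "motion", "mismatch")}
    beta = config.connectivity_coeffs[modality]
    n = len(cohort)
    lp = np.zeros(n)
    for c in presets.COVARIATES:
        lp += beta[c] * Z[c].to_numpy()
    for m, col in qcols.items():
        q = quality[col].to_numpy(float)
        sd = q.std(ddof=1)
        zq = (q - q.mean()) / sd if sd > 0 else np.zeros(n)
        lp += beta[m] * zq
    rng = substream(config.seed, "overall", modality)
    eps = rng.standard_normal(n)
    eps -= eps.mean()
    g = _standardized_outcome(lp, eps, config.noise_scales.get(modality), modality)
    mean, sd = config.overall_scale[modality]
    return mean + sd * g


def generate_connectomes(cohort: pd.DataFrame, quality: pd.DataFrame,
                         config: GeneratorConfig, modality: str,
                         ) -> Iterator[tuple[str, Connectome]]:
    """Yield ``(participant_id, Connectome)`` for every participant.

    Each connectome is the modality template modulated per subject:

    * SC: edges expressed with the template prevalence, log-normal
      multiplicative edge noise, then rescaled so the subject's overall
      connectivity (mean of all region-pair weights) equals the configured
      linear target exactly. Weights are nonnegative by construction.
    * FC: template plus additive Gaussian edge noise clipped at zero, rescaled
      to the subject's overall target, final clip into [0, 1] (clip counts
      logged).

    With zero connectivity coefficients, zero residual noise and zero edge
    noise, every participant receives the identical base template.
    """
    tpl = ConnectomeTemplate(config, modality)
    targets = _subject_overall_targets(cohort, quality, config, modality)
    iu = np.triu_indices(tpl.n_regions, 1)
    sigma = float(config.edge_noise[modality])
    labels = hemisphere_labels(tpl.n_regions)
    n_clip_neg = 0

    for i, pid in enumerate(cohort["participant_id"]):
        rng = substream(config.seed, "edges", modality, i)
        w = tpl.weights[iu].copy()
        if sigma > 0:
            if modality == "SC":
                present = rng.random(w.size) < tpl.prevalence[iu]
                w = w * present * np.exp(sigma * rng.standard_normal(w.size)
                                         - sigma**2 / 2)
            else:
                w = np.clip(w + sigma * rng.standard_normal(w.size), 0.0, None)
        if modality == "SC":
            m = w.mean()
            if m > 0:
                w = w * (targets[i] / m)
            neg = w < 0
            if neg.any():
                n_clip_neg += int(neg.sum())
                w = np.clip(w, 0.0, None)
        else:
            # rescale under the [0, 1] clip (fixed point: a handful of top
            # edges saturate, the rest absorb the deficit)
            for _ in range(6):
                m = w.mean()
                if m <= 0 or abs(m - targets[i]) < 1e-12:
                    break
                w = np.clip(w * (targets[i] / m), 0.0, 1.0)
        W = np.zeros((tpl.n_regions, tpl.n_regions))
        W[iu] = w
        W = W + W.T
        yield str(pid), Connectome(W, modality=modality, hemispheres=labels,
                                   validate=False)
    if n_clip_neg:
        log.info("generate_connectomes(%s): clipped %d negative weights", modality, n_clip_neg)
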
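"""Numeric presets for the synthetic-cohort generator.

The constants below encode the published summary statistics of the Maastricht
Study imaging sub-cohort (n = 5110, ages 40-75, T2DM oversampled): covariate
distributions, per-scan image-quality calibration (mean/SD on the native
scale), and the standardized linear-model coefficient sets that tie quality
metrics and overall connectivity to the seven demographic/clinical covariates.
They parameterize :class:`connqc.config.GeneratorConfig` presets so that a
fully synthetic cohort reproduces the printed marginal distributions and
regression structure.

Covariate order is fixed everywhere in the package: age (years), sex
(0 = male, 1 = female), education (ordinal 1-3), BMI (kg/m^2), diabetes
status (ordinal 0-3: none, prediabetes, T2DM, other), CVD history (0/1),
and log10 relative WMH volume (% of ICV, log10-transformed before modelling).
"""

from __future__ import annotations

from pathlib import Path

COVARIATES = ("age", "sex", "education", "bmi", "diabetes", "cvd", "log_wmh")

QUALITY_METRICS = (
    ("dmri", "isnr"),
    ("dmri", "motion"),
    ("dmri", "mismatch"),
    ("fmri", "isnr"),
    ("fmri", "motion"),
    ("fmri", "mismatch"),
)

#: Covariate marginals of the reference cohort (n = 5110).
TABLE1_COVARIATES: dict = {
    "age_mean": 59.4,
    "age_sd": 8.7,
    "age_range": (40.0, 75.0),
    "female_prop": 0.494,
    # low / middle / high educational level
    "education_props": (0.320, 0.284, 0.397),
    "bmi_mean": 26.6,
    "bmi_sd": 4.2,
    # no diabetes / prediabetes / type 2 diabetes / other
    "diabetes_props": (0.641, 0.147, 0.206, 0.006),
    "cvd_prop": 0.126,
    # relative WMH volume, % of ICV: median (25-75th pct)
    "wmh_median": 0.016,
    "wmh_q25": 0.005,
    "wmh_q75": 0.050,
    # only configured pairwise covariate dependence (Gaussian copula)
    "age_wmh_corr": 0.4,
}

#: Native-scale (mean, SD) for each quality metric. iSNR is the *negative*
#: of the SNR, so the printed SNR 22 (6.5) becomes mean -22.
QUALITY_SCALE: dict = {
    ("dmri", "isnr"): (-22.0, 6.5),
    ("dmri", "motion"): (0.64, 0.16),       # mm
    ("dmri", "mismatch"): (0.087, 0.0092),
    ("fmri", "isnr"): (-39.0, 11.0),
    ("fmri", "motion"): (0.13, 0.088),      # mm
    ("fmri", "mismatch"): (0.089, 0.0086),
}

#: Standardized coefficients of each quality metric on the seven covariates
#: (full linear model, dMRI metrics).
QUALITY_COEFFS: dict = {
    ("dmri", "isnr"): {
        "age": 0.117, "sex": -0.071, "education": -0.017, "bmi": 0.067,
        "diabetes": 0.032, "cvd": 0.004, "log_wmh": -0.038,
    },
    ("dmri", "motion"): {
        "age": 0.368, "sex": -0.279, "education": 0.001, "bmi": 0.028,
        "diabetes": 0.095, "cvd": 0.020, "log_wmh": 0.048,
    },
    ("dmri", "mismatch"): {
        "age": 0.056, "sex": -0.303, "education": -0.009, "bmi": 0.093,
        "diabetes": -0.023, "cvd": 0.009, "log_wmh": 0.017,
    },
    ("fmri", "isnr"): {
        "age": 0.170, "sex": -0.027, "education": -0.044, "bmi": 0.408,
        "diabetes": 0.096, "cvd": -0.012, "log_wmh": 0.030,
    },
    ("fmri", "motion"): {
        "age": 0.079, "sex": -0.071, "education": -0.010, "bmi": 0.321,
        "diabetes": 0.024, "cvd": -0.004, "log_wmh": -0.016,
    },
    ("fmri", "mismatch"): {
        "age": -0.088, "sex": 0.317, "education": -0.003, "bmi": -0.113,
        "diabetes": -0.020, "cvd": 0.004, "log_wmh": 0.013,
    },
}

#: Target *total* Pearson correlations between quality metrics; the generator
#: solves for the residual correlation that achieves them given the
#: covariate-shared part.
QUALITY_TARGET_CORR: dict = {
    (("dmri", "isnr"), ("dmri", "motion")): 0.298,
    (("fmri", "isnr"), ("fmri", "motion")): 0.522,
    (("dmri", "motion"), ("fmri", "motion")): 0.21,
}

#: Fully-adjusted (covariates + modality-matched quality metrics) standardized
#: coefficient sets that drive the subject-level overall-connectivity factor.
CONNECTIVITY_COEFFS: dict = {
    "SC": {
        "age": -0.074, "sex": 0.213, "education": -0.045, "bmi": 0.109,
        "diabetes": 0.003, "cvd": -0.010, "log_wmh": 0.048,
        "isnr": -0.120, "motion": -0.249, "mismatch": 0.021,
    },
    "FC": {
        "age": 0.015, "sex": -0.062, "education": 0.014, "bmi": -0.008,
        "diabetes": -0.030, "cvd": -0.017, "log_wmh": -0.027,
        "isnr": -0.082, "motion": 0.048, "mismatch": 0.027,
    },
}

#: Native-scale (mean, SD) of overall connectivity per modality.
OVERALL_SCALE: dict = {
    "SC": (5.3e-3, 0.6e-3),
    "FC": (0.32, 0.03),
}

#: Standardized Model-2 coefficients for overall structural connectivity and
#: cohort SDs used by the head-motion/aging equivalence conversion.
MOTION_AGE_INPUTS: dict = {
    "beta_motion": -0.249,
    "beta_age": -0.074,
    "sd_motion": 0.16,   # mm
    "sd_age": 8.7,       # years
    "delta_motion": 0.1,  # mm
}

N_REGIONS = 94
N_COHORT = 5110

PRESET_DIR = Path(__file__).parent


def preset_path(name: str) -> Path:
    """Path of a shipped run-config preset (``maastricht_table1`` or ``null``)."""
    p = PRESET_DIR / f"{name}.cfg"
    if not p.exists():
        raise KeyError(f"unknown preset {name!r}; available: "
                       + ", ".join(sorted(q.stem for q in PRESET_DIR.glob('*.cfg'))))
    return p
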
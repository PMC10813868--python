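"""Generator configuration and deterministic seed splitting.

All randomness in the package flows from a single root seed. Named substreams
are derived with :func:`substream`, which hashes a text label (CRC-32) into a
``numpy.random.SeedSequence`` together with the root seed, so every stage and
every participant gets an independent, reproducible stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from . import presets


def substream(seed: int, *labels) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Labels may be strings or integers; strings are hashed with CRC-32.
    ``substream(s, "cohort")`` and ``substream(s, "quality")`` are
    statistically independent for any fixed ``s``.
    """
    keys = [int(seed)]
    for lab in labels:
        if isinstance(lab, str):
            keys.append(zlib.crc32(lab.encode()) & 0x7FFFFFFF)
        else:
            keys.append(int(lab) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(keys))


def _check_props(name: str, props) -> tuple:
    props = tuple(float(p) for p in props)
    if any(p < 0 or p > 1 for p in props):
        raise ValueError(f"{name}: proportions must lie in [0, 1], got {props}")
    s = sum(props)
    # printed percentages may carry rounding error; renormalize within 2%
    if abs(s - 1.0) > 0.02:
        raise ValueError(f"{name}: proportions must sum to 1, got sum {s:.6f}")
    return tuple(p / s for p in props)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-cohort generator.

    ``covariate_params`` holds the marginal distributions of the seven
    demographic/clinical covariates; ``quality_coeffs`` the standardized
    coefficient set of each quality metric on the covariates;
    ``connectivity_coeffs`` the fully-adjusted coefficient set (covariates
    plus three modality-matched quality metrics) driving overall
    connectivity. ``noise_scales`` may pin the residual SD of any generated
    outcome; entries left unset are completed so the standardized outcome
    has unit variance.
    """

    n: int = presets.N_COHORT
    seed: int = 0
    covariate_params: dict = field(
        default_factory=lambda: dict(presets.TABLE1_COVARIATES))
    quality_coeffs: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in presets.QUALITY_COEFFS.items()})
    quality_scale: dict = field(
        default_factory=lambda: dict(presets.QUALITY_SCALE))
    quality_target_corr: dict = field(
        default_factory=lambda: dict(presets.QUALITY_TARGET_CORR))
    connectivity_coeffs: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in presets.CONNECTIVITY_COEFFS.items()})
    overall_scale: dict = field(
        default_factory=lambda: dict(presets.OVERALL_SCALE))
    #: residual SD per outcome key (quality metric tuple or modality string);
    #: None -> complete to unit outcome variance
    noise_scales: dict = field(default_factory=dict)
    #: SD of the multiplicative (SC, log-normal) / additive (FC) edge noise.
    #: The FC value is chosen so that, as in real data, a subject's weakest
    #: consensus edges are sometimes clipped to zero (absent edge).
    edge_noise: Mapping[str, float] = field(
        default_factory=lambda: {"SC": 0.4, "FC": 0.15})
    n_regions: int = presets.N_REGIONS

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        cp = self.covariate_params
        cp["education_props"] = _check_props("education_props", cp["education_props"])
        cp["diabetes_props"] = _check_props("diabetes_props", cp["diabetes_props"])
        for key in ("female_prop", "cvd_prop"):
            p = float(cp[key])
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{key} must lie in [0, 1], got {p}")
        for coeffs in self.quality_coeffs.values():
            missing = set(presets.COVARIATES) - set(coeffs)
            if missing:
                raise ValueError(f"quality coefficient set missing covariates: {missing}")

    # -- presets -----------------------------------------------------------

    @classmethod
    def from_preset(cls, name: str, n: int | None = None, seed: int = 0) -> "GeneratorConfig":
        """Build a config from a named preset.

        ``maastricht_table1``: the reference-cohort calibration (default
        everywhere). ``null``: all coefficient sets and edge noise zero —
        quality metrics are pure noise and every participant shares the base
        connectome template.
        """
        if name == "maastricht_table1":
            cfg = cls(seed=seed)
        elif name == "null":
            cfg = cls(
                seed=seed,
                quality_coeffs={k: {c: 0.0 for c in presets.COVARIATES}
                                for k in presets.QUALITY_METRICS},
                quality_target_corr={},
                connectivity_coeffs={m: {c: 0.0 for c in v}
                                     for m, v in presets.CONNECTIVITY_COEFFS.items()},
                noise_scales={"SC": 0.0, "FC": 0.0},
                edge_noise={"SC": 0.0, "FC": 0.0},
            )
        else:
            raise KeyError(f"unknown generator preset {name!r}")
        if n is not None:
            cfg.n = int(n)
            cfg.__post_init__()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
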
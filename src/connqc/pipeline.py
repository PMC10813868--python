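"""Config-driven pipeline: simulate -> quality -> connectomes -> graph
measures -> confound statistics -> report.

The pipeline is deterministic under a fixed :class:`RunConfig`: a single root
seed is split per stage and per participant, connectome generation is
re-runnable (the second pass regenerates the identical connectomes rather than
holding the cohort in memory), and all CSV outputs are byte-identical across
re-runs. A manifest records the config, its hash and package versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, presets
from .cohort import generate_cohort, generate_connectomes, generate_quality
from .config import GeneratorConfig, substream
from .connectome import (Connectome, apply_group_mask, group_average,
                         interhemispheric_fraction, overall_connectivity,
                         proportional_threshold)
from .graph import (average_node_degree, make_null_ensemble, normalized_measures)
from .stats import (ConfoundModel, exclude_high_motion, quality_cross_correlations,
                    quality_determinants)

log = logging.getLogger(__name__)

SC_SPARSITY_GRID = tuple(np.round(np.arange(0.60, 0.901, 0.05), 2))
FC_SPARSITY_GRID = tuple(np.round(np.arange(0.10, 0.901, 0.10), 2))


@dataclasses.dataclass
class RunConfig:
    """Run-level options for the end-to-end pipeline."""

    mode: str = "simulate"            # or "from-files"
    preset: str = "maastricht_table1"
    n: int = 500
    seed: int = 0
    default_sparsity: float = 0.80
    sc_sparsity_grid: tuple = SC_SPARSITY_GRID
    fc_sparsity_grid: tuple = FC_SPARSITY_GRID
    n_null: int = 100
    swaps_per_edge: float = 10.0
    alpha: float = 0.05
    change_threshold: float = 0.10
    motion_exclusion_mm: float = 1.0
    outdir: str = "connqc_run"
    paths: dict = dataclasses.field(default_factory=dict)  # from-files inputs
    log_level: str = "INFO"

    def __post_init__(self):
        for s in (self.default_sparsity, *self.sc_sparsity_grid, *self.fc_sparsity_grid):
            if not 0.0 < s < 1.0:
                raise ValueError(f"sparsity {s} outside (0, 1)")
        if self.mode not in ("simulate", "from-files"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sc_sparsity_grid", "fc_sparsity_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["sc_sparsity_grid"] = list(self.sc_sparsity_grid)
        d["fc_sparsity_grid"] = list(self.fc_sparsity_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def generator(self) -> GeneratorConfig:
        return GeneratorConfig.from_preset(self.preset, n=self.n, seed=self.seed)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _graph_row(pid: str, conn: Connectome, mask, sparsity: float,
               cfg: RunConfig, subject_index: int) -> dict:
    masked = apply_group_mask(conn, mask)
    null_seed = int(substream(cfg.seed, "nulls", conn.modality, subject_index,
                              int(round(sparsity * 100))).integers(2**31))
    ens = make_null_ensemble(masked, n_null=cfg.n_null, seed=null_seed,
                             swaps_per_edge=cfg.swaps_per_edge)
    gamma, e_glob = normalized_measures(masked, ens)
    return {
        "participant_id": pid,
        "modality": conn.modality,
        "sparsity": sparsity,
        "overall": overall_connectivity(conn),
        "nu": average_node_degree(masked),
        "gamma": gamma,
        "e_global": e_glob,
        "null_seed": null_seed,
    }


def compute_measures(cohort: pd.DataFrame, quality: pd.DataFrame,
                     gen: GeneratorConfig, cfg: RunConfig, modality: str,
                     sparsities: tuple | None = None) -> pd.DataFrame:
    """Two-pass streaming computation of graph measures for one modality.

    Pass 1 accumulates the group-averaged consensus connectome (binarized
    prevalence for SC, mean weight for FC); pass 2 regenerates each
    participant's connectome (same seeds) and evaluates the measures under
    each sparsity mask.
    """
    sparsities = (cfg.default_sparsity,) if sparsities is None else tuple(sparsities)
    total = None
    count = 0
    for _, conn in generate_connectomes(cohort, quality, gen, modality):
        contrib = (conn.weights > 0).astype(float) if modality == "SC" else conn.weights
        total = contrib if total is None else total + contrib
        count += 1
    group = Connectome(total / count, modality=modality, validate=False)
    masks = {s: proportional_threshold(group, s) for s in sparsities}

    rows = []
    for idx, (pid, conn) in enumerate(generate_connectomes(cohort, quality, gen, modality)):
        for s in sparsities:
            rows.append(_graph_row(pid, conn, masks[s], s, cfg, idx))
    df = pd.DataFrame(rows)
    df.attrs["interhemispheric_fraction"] = {
        s: interhemispheric_fraction(m, conn.hemispheres) for s, m in masks.items()}
    return df


def run(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    gen = cfg.generator()

    stage = "simulate"
    try:
        cohort = generate_cohort(gen)
        quality = generate_quality(cohort, gen)
        _write_csv(cohort, out / "cohort.csv")
        _write_csv(quality, out / "quality.csv")

        stage = "graph"
        measures = {}
        for modality in ("SC", "FC"):
            m = compute_measures(cohort, quality, gen, cfg, modality)
            _write_csv(m.drop(columns=["null_seed"]), out / f"measures_{modality}.csv")
            _write_csv(m[["participant_id", "sparsity", "null_seed"]],
                       out / f"null_seeds_{modality}.csv")
            measures[modality] = m

        stage = "stats"
        report_parts = []
        for modality in ("SC", "FC"):
            m = measures[modality]
            conn_tbl = m[m.sparsity == cfg.default_sparsity][
                ["participant_id", "overall", "nu", "gamma", "e_global"]]
            res = ConfoundModel(conn_tbl, cohort, quality, modality).fit(
                alpha=cfg.alpha, change_threshold=cfg.change_threshold)
            _write_csv(res.ledger, out / f"confound_{modality}.csv")
            report_parts.append(res.summary())

        det = quality_determinants(cohort, quality, alpha=cfg.alpha)
        det_rows = []
        for col, r in det.items():
            for cov in r.params.index:
                det_rows.append({"metric": col, "covariate": cov,
                                 "beta": r.params[cov], "p": r.pvalues[cov],
                                 "r2": r.rsquared})
        _write_csv(pd.DataFrame(det_rows), out / "quality_determinants.csv")

        r_tab, p_tab = quality_cross_correlations(quality)
        r_tab.to_csv(out / "quality_correlations.csv", float_format="%.10g")

        excl = exclude_high_motion(cohort, quality,
                                   threshold=cfg.motion_exclusion_mm)
        report_parts.append(
            f"High-motion exclusion (> {cfg.motion_exclusion_mm} mm dMRI): "
            f"{excl.n_excluded} excluded, {excl.n_retained} retained.\n")

        (out / "report.txt").write_text("\n".join(report_parts))
    except Exception:
        log.exception("pipeline failed at stage %r; partial outputs kept in %s",
                      stage, out)
        raise

    manifest = {
        "connqc_version": __version__,
        "numpy_version": np.__version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "n_participants": int(cfg.n),
        "n_regions": presets.N_REGIONS,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def sparsity_sweep(cfg: RunConfig, modality: str = "SC") -> pd.DataFrame:
    """Graph measures per participant across the modality's sparsity grid,
    with a per-sparsity summary (mean and 5-95th percentiles) in ``.attrs``."""
    gen = cfg.generator()
    cohort = generate_cohort(gen)
    quality = generate_quality(cohort, gen)
    grid = cfg.sc_sparsity_grid if modality == "SC" else cfg.fc_sparsity_grid
    if len(grid) < 2:
        raise ValueError("sparsity grid needs at least two values")
    df = compute_measures(cohort, quality, gen, cfg, modality, sparsities=grid)

    summ = (df.groupby("sparsity")[["nu", "gamma", "e_global"]]
            .agg(["mean",
                  lambda x: np.percentile(x, 5),
                  lambda x: np.percentile(x, 95)]))
    summ.columns = [f"{m}_{s}" for m, s in zip(
        summ.columns.get_level_values(0),
        ["mean", "p05", "p95"] * 3)]
    df.attrs["summary"] = summ.reset_index()
    return df


def plot_sweep(summary: pd.DataFrame, ax=None):
    """Mean and 5-95th percentile band of each measure over sparsity."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(1, 3, figsize=(12, 3.5))
    for k, m in enumerate(["nu", "gamma", "e_global"]):
        a = ax[k]
        a.plot(summary["sparsity"], summary[f"{m}_mean"], "o-")
        a.fill_between(summary["sparsity"], summary[f"{m}_p05"],
                       summary[f"{m}_p95"], alpha=0.25)
        a.set_xlabel("sparsity")
        a.set_ylabel(m)
    return ax
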
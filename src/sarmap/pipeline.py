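"""End-to-end orchestration: simulate -> standardize -> smooth -> cluster.

A single config (YAML file or :class:`PipelineConfig`) drives the whole
synthetic study: tract geography and admissions are simulated (or loaded
from CSV/GAL files), indirectly standardised per sex, smoothed with the
requested CAR prior, optionally refitted jointly with the shared-component
model, and cluster-tested on the smoothed relative risks (clustering runs
on SRR, not raw SAR: the smoothing removes the small-population noise the
cluster statistics would otherwise chase).  Every run writes a manifest
with inputs, parameters and seeds, and reruns of the same config are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .car import CARModel
from .graph import AdjacencyGraph, lattice_geojson
from .moran import lisa, make_weights, morans_i_test
from .shared import SharedComponentModel, sar_cross_correlation
from .standardize import standardize
from .synthetic import asturias_like

log = logging.getLogger("sarmap.pipeline")

# deterministic per-stage seed offsets from the global seed
STAGE_OFFSETS = {"simulate": 0, "smooth_male": 1, "smooth_female": 2,
                 "joint": 3, "cluster_male": 4, "cluster_female": 5}


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (display convention for reports)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def retention_summary(records: pd.DataFrame) -> dict:
    """Geocoding retention: rows with a resolvable tract id vs the rest."""
    if len(records) == 0:
        raise ValueError("empty record table")
    assigned = records["tract_id"].notna() & (records["tract_id"].astype(str) != "")
    retained = int(assigned.sum())
    total = len(records)
    pct = 100.0 * retained / total
    return {"retained": retained, "excluded": total - retained, "total": total,
            "retained_pct": pct, "retained_pct_2dp": round2(pct)}


def threshold_summary(values, threshold: float, direction: str = "above") -> float:
    """% of defined (non-NaN) tract values strictly beyond a threshold."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no defined values")
    if direction == "above":
        frac = np.mean(v > threshold)
    elif direction == "below":
        frac = np.mean(v < threshold)
    else:
        raise ValueError("direction must be 'above' or 'below'")
    return round2(100.0 * frac)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; loadable from a YAML file."""

    preset: str = "asturias-like"
    null_risk: bool = False
    # external inputs (override the preset when all three are given)
    population_csv: str | None = None
    counts_csv: str | None = None
    adjacency_gal: str | None = None
    # smoothing
    model: str = "bym"
    chains: int = 2
    n_iter: int = 2000
    burnin: int | None = None
    thin: int = 1
    joint: bool = True
    # clustering
    weights_style: str = "row-standardized"
    n_perm: int = 999
    alpha: float = 0.05
    cluster_on_joint: bool = False
    # global
    seed: int = 0
    out_dir: str = "sarmap_out"
    write_geojson: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        for k, v in raw.items():
            if isinstance(v, dict):
                flat.update(v)
            else:
                flat[k] = v
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGE_OFFSETS[stage]


@dataclass
class SummaryReport:
    """The paper-style headline numbers of one run, per sex."""

    n_tracts: int
    per_sex: dict = field(default_factory=dict)
    cross_sar_pearson: float | None = None
    retention: dict | None = None
    joint: dict | None = None
    model_comparison: list | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def render(self) -> str:
        lines = [f"Tracts: {self.n_tracts}"]
        if self.retention:
            lines.append(
                f"Records: {self.retention['retained']} of {self.retention['total']} "
                f"geocoded ({self.retention['retained_pct_2dp']:.2f}%)")
        for sex, d in self.per_sex.items():
            lines.append(
                f"{sex}: SAR>100 in {d['pct_sar_above_100']:.2f}% of CTs; "
                f"PP>=0.8 in {d['pct_pp_ge_0.8']:.2f}%; PP<0.2 in {d['pct_pp_lt_0.2']:.2f}%; "
                f"Moran I(SRR) = {d['moran_i']:.3f} (z = {d['moran_z']:.1f}, "
                f"p = {d['moran_p']:.4g})")
        if self.cross_sar_pearson is not None:
            lines.append(f"Cross-sex SAR Pearson r = {self.cross_sar_pearson:.4f}")
        if self.joint:
            lines.append(
                f"Joint model: kappa mean {self.joint['kappa_mean']:.3f} "
                f"(95% CrI {self.joint['kappa_ci'][0]:.3f}-{self.joint['kappa_ci'][1]:.3f}), "
                f"cross-sex log-risk corr {self.joint['cross_correlation']:.3f}")
        return "\n".join(lines)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def _load_inputs(cfg: PipelineConfig):
    if cfg.population_csv and cfg.counts_csv and cfg.adjacency_gal:
        pop = pd.read_csv(cfg.population_csv)
        counts = pd.read_csv(cfg.counts_csv)
        graph = AdjacencyGraph.from_gal(cfg.adjacency_gal)
        return graph, pop, counts, None, None
    if cfg.preset != "asturias-like":
        raise PipelineError("simulate", "unknown-preset",
                            f"unknown preset {cfg.preset!r}")
    study = asturias_like(seed=cfg.stage_seed("simulate"), null_risk=cfg.null_risk)
    return study.graph, study.population, study.counts, study.records, study


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Execute every stage and write all artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    t0 = time.time()

    try:
        graph, pop, counts, records, study = _load_inputs(config)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", "input-error", str(exc)) from exc
    out.mkdir(parents=True, exist_ok=True)
    pop.to_csv(out / "population.csv", index=False)
    counts.to_csv(out / "counts.csv", index=False)
    graph.to_gal(str(out / "adjacency.gal"))
    if records is not None:
        records.to_csv(out / "records.csv", index=False)
    log.info("stage simulate/load done (%.1fs): %d tracts", time.time() - t0, graph.n)

    try:
        std = standardize(counts, pop)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("standardize", "invalid-input", str(exc)) from exc
    std.to_csv(out / "sar.csv", index=False)

    report = SummaryReport(n_tracts=graph.n)
    if records is not None:
        report.retention = retention_summary(records)

    results = {}
    for sex in ("male", "female"):
        try:
            model = CARModel.from_dataframe(std, graph, sex=sex, model=config.model)
            res = model.fit(n_iter=config.n_iter, burnin=config.burnin,
                            thin=config.thin, chains=config.chains,
                            seed=config.stage_seed(f"smooth_{sex}"))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"smooth_{sex}", "fit-error", str(exc)) from exc
        results[sex] = res
        res.to_frame().to_csv(out / f"smooth_{sex}.csv", index=False)
        log.info("stage smooth_%s done (%.1fs)", sex, time.time() - t0)

    joint_res = None
    if config.joint:
        try:
            jm = SharedComponentModel.from_dataframe(std, graph)
            joint_res = jm.fit(n_iter=config.n_iter, burnin=config.burnin,
                               thin=config.thin, chains=config.chains,
                               seed=config.stage_seed("joint"))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("joint", "fit-error", str(exc)) from exc
        joint_res.to_frame().to_csv(out / "smooth_joint.csv", index=False)
        report.joint = {
            "kappa_mean": float(joint_res.kappa_draws.mean()),
            "kappa_ci": list(joint_res.kappa_interval()),
            "cross_correlation": joint_res.cross_correlation,
            **{k: float(v) for k, v in joint_res.fit_indices().items()},
        }
        log.info("stage joint done (%.1fs)", time.time() - t0)

    weights = make_weights(graph, config.weights_style)
    sar_by_sex = {}
    for sex in ("male", "female"):
        res = results[sex]
        srr = (joint_res.srr(sex) if (config.cluster_on_joint and joint_res is not None)
               else res.srr)
        srr_def = np.where(np.isnan(srr), np.nanmean(srr), srr)
        try:
            mres = morans_i_test(srr_def, weights, n_perm=config.n_perm,
                                 seed=config.stage_seed(f"cluster_{sex}"))
            lres = lisa(srr_def, weights, n_perm=config.n_perm, alpha=config.alpha,
                        seed=config.stage_seed(f"cluster_{sex}"))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"cluster_{sex}", "cluster-error", str(exc)) from exc
        lres.to_frame().to_csv(out / f"lisa_{sex}.csv", index=False)

        sdf = std[std["sex"] == sex].set_index("tract_id").loc[list(graph.tract_ids)]
        sar_by_sex[sex] = sdf["SAR"].to_numpy()
        report.per_sex[sex] = {
            "n_tracts": graph.n,
            "pct_sar_above_100": threshold_summary(sdf["SAR"], 100.0, "above"),
            "pct_pp_ge_0.8": round2(100.0 * np.nanmean(res.pp >= 0.8)),
            "pct_pp_lt_0.2": round2(100.0 * np.nanmean(res.pp < 0.2)),
            "moran_i": mres.i,
            "moran_z": mres.z_score,
            "moran_p": mres.p_value,
            "lisa_counts": lres.counts(),
            "dic": res.dic,
            "waic": res.waic,
        }
        log.info("stage cluster_%s done (%.1fs)", sex, time.time() - t0)

    report.cross_sar_pearson = sar_cross_correlation(sar_by_sex["male"],
                                                     sar_by_sex["female"])

    if config.write_geojson and study is not None:
        gj = lattice_geojson(study.meta["n_rows"], study.meta["n_cols"])
        attach = {}
        for sex in ("male", "female"):
            fr = results[sex].to_frame().set_index("tract_id")
            attach[f"SRR_{sex}"] = fr["SRR"]
            attach[f"PP_{sex}"] = fr["PP"]
        for feat in gj["features"]:
            tid = feat["properties"]["tract_id"]
            for k, series in attach.items():
                val = series.get(tid)
                feat["properties"][k] = None if pd.isna(val) else float(val)
        with open(out / "tracts.geojson", "w") as fh:
            json.dump(gj, fh)

    manifest = {
        "sarmap_version": __version__,
        "config": asdict(config),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGE_OFFSETS},
        "n_tracts": graph.n,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()
                          and p.name not in ("manifest.json", "summary.json")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    log.info("pipeline complete (%.1fs)", time.time() - t0)
    return report
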
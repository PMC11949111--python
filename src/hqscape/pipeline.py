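"""End-to-end workflow: simulate -> transitions -> habitat quality ->
autocorrelation -> driver detection, from one config, with a provenance
manifest.

Every stage writes fixed-name CSV/ASCII-grid outputs under
``outdir/{landuse,transitions,hq,autocorr,opgd}`` and the run manifest
records the config hash, package version and a SHA-256 per output file, so
a re-run with the same config and seed is byte-identical and checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .change import chord_table, compute_transition_matrix, dynamics_report
from .grid import CLASS_CODES, LandUseRaster, Raster, write_ascii_grid
from .hotspots import build_weights, gi_star, morans_i
from .opgd import DISCRETIZATION_METHODS, FactorStack, factor_report
from .quality import (DEFAULT_THREATS, DEFAULT_Z, SensitivityTable, ThreatSpec,
                      default_sensitivity, degradation, grade_hq,
                      habitat_quality, hq_summary)
from .synth import (LandscapeConfig, generate_covariates,
                    generate_landuse_series, parse_transition_rates)

log = logging.getLogger("hqscape")

#: ordinal human-disturbance recode of the land-cover legend: natural
#: covers (forest, shrub, grassland, water — and wasteland, which carries
#: no active human use) = 1, cropland = 2, impervious = 3
LAND_USE_INTENSITY = {
    CLASS_CODES["forest"]: 1, CLASS_CODES["shrub"]: 1,
    CLASS_CODES["grassland"]: 1, CLASS_CODES["water"]: 1,
    CLASS_CODES["wasteland"]: 1,
    CLASS_CODES["cropland"]: 2, CLASS_CODES["impervious"]: 3,
}


@dataclass
class RunConfig:
    """One pipeline run.  Either a simulation block or explicit input paths
    must be present (a simulation block is the default)."""

    outdir: str = "hqscape_run"
    seed: int = 0
    years_per_step: float = 10.0
    simulation: dict = field(default_factory=dict)   # LandscapeConfig kwargs
    landuse_paths: list[str] = field(default_factory=list)
    covariate_paths: dict[str, str] = field(default_factory=dict)
    threats: list[ThreatSpec] = field(default_factory=lambda: list(DEFAULT_THREATS))
    sensitivity: SensitivityTable = field(default_factory=default_sensitivity)
    z_exponent: float = DEFAULT_Z
    weights_scheme: str = "queen"
    moran_permutations: int = 0
    opgd_methods: tuple[str, ...] = DISCRETIZATION_METHODS
    opgd_classes: tuple[int, int] = (3, 8)
    planted_driver: str | None = None
    planted_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if not self.simulation and not self.landuse_paths:
            raise ValueError("config needs a simulation block or landuse paths")

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "threats" in raw:
            raw["threats"] = [
                ThreatSpec(name=t["name"],
                           source_classes=frozenset(t["source_classes"]),
                           d_rmax_km=t["d_rmax_km"], weight=t["weight"],
                           decay=t["decay"])
                for t in raw["threats"]
            ]
        if "sensitivity" in raw:
            s = raw["sensitivity"]
            raw["sensitivity"] = SensitivityTable(
                suitability={int(k): v for k, v in s["suitability"].items()},
                sensitivity={(int(c), t): v
                             for (c, t), v in
                             ((tuple(k.split(":")), v)
                              for k, v in s["sensitivity"].items())},
            )
        if "opgd_classes" in raw:
            raw["opgd_classes"] = tuple(raw["opgd_classes"])
        if "opgd_methods" in raw:
            raw["opgd_methods"] = tuple(raw["opgd_methods"])
        return RunConfig(**raw)

    def digest(self) -> str:
        payload = json.dumps(
            {k: repr(v) for k, v in sorted(vars(self).items())},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def compare_periods(hq_rasters: list) -> pd.DataFrame:
    """Per-period and overall change of the masked HQ mean and of the
    four grade-area proportions.  With >= 3 years the per-period mean
    changes telescope to the overall row."""
    if len(hq_rasters) < 2:
        raise ValueError("need at least 2 years of habitat quality")
    ref_mask = hq_rasters[0].mask
    for r in hq_rasters[1:]:
        if not np.array_equal(ref_mask, r.mask):
            raise ValueError("habitat-quality rasters have mismatched masks")
    stats = []
    for r in hq_rasters:
        mean, _ = hq_summary(r)
        grades = grade_hq(r).set_index("grade")["proportion"]
        stats.append((r.label, mean, grades))
    rows = []
    pairs = list(zip(stats[:-1], stats[1:]))
    if len(stats) > 2:
        pairs.append((stats[0], stats[-1]))
    for (la, ma, ga), (lb, mb, gb) in pairs:
        row = {"period": f"{la}->{lb}", "mean_start": ma, "mean_end": mb,
               "mean_change": mb - ma}
        for g in ga.index:
            row[f"d_prop_{g}"] = gb[g] - ga[g]
        rows.append(row)
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Execute the full workflow; returns the run manifest (also written to
    ``outdir/manifest.json``).  Identical config + seed reproduce identical
    CSV outputs byte for byte."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config_sha": config.digest(),
                      "seed": config.seed, "stages": {}, "files": {}}
    stage = "init"
    try:
        # ---- stage 1: inputs -------------------------------------------
        stage = "simulate"
        if config.simulation:
            sim_kwargs = dict(config.simulation)
            sim_kwargs.setdefault("seed", config.seed)
            sim_kwargs["transition_rates"] = parse_transition_rates(
                sim_kwargs.get("transition_rates", {}))
            lconf = LandscapeConfig(**sim_kwargs)
            covariates = generate_covariates(lconf)
            landuse, truth = generate_landuse_series(lconf, covariates)
            lu_dir = out / "landuse"
            lu_dir.mkdir(exist_ok=True)
            for r in landuse:
                write_ascii_grid(lu_dir / f"{r.label}.asc", r, fmt="%d")
            for name, r in covariates.layers.items():
                write_ascii_grid(lu_dir / f"cov_{name}.asc", r)
            (lu_dir / "truth.json").write_text(
                json.dumps(truth.to_jsonable(), indent=2))
            manifest["stages"]["simulate"] = {
                "n_years": len(landuse), "grid": list(landuse[0].shape)}
        else:
            from .grid import read_ascii_grid
            landuse = [read_ascii_grid(p, landuse=True)
                       for p in config.landuse_paths]
            covariates = FactorStack(layers={
                name: read_ascii_grid(p)
                for name, p in config.covariate_paths.items()})
            manifest["stages"]["simulate"] = {"loaded": len(landuse)}

        # ---- stage 2: transitions --------------------------------------
        stage = "transitions"
        tdir = out / "transitions"
        tdir.mkdir(exist_ok=True)
        T = config.years_per_step
        matrices = []
        for a, b in zip(landuse[:-1], landuse[1:]):
            m = compute_transition_matrix(a, b)
            matrices.append(m)
            tag = f"{a.label}_{b.label}"
            m.labelled().to_csv(tdir / f"matrix_{tag}.csv",
                                float_format="%.10g")
            _write_csv(chord_table(m), tdir / f"chord_{tag}.csv")
            _write_csv(dynamics_report(m, T).to_frame(),
                       tdir / f"dynamics_{tag}.csv")
        if len(landuse) > 2:
            m_all = compute_transition_matrix(landuse[0], landuse[-1])
            T_all = T * (len(landuse) - 1)
            _write_csv(dynamics_report(m_all, T_all).to_frame(),
                       tdir / "dynamics_overall.csv")
        (tdir / "sidecar.json").write_text(json.dumps({
            "years_per_step": T, "cell_size_m": landuse[0].cell_size,
            "mask_area_ha": float(landuse[0].mask.sum()
                                  * landuse[0].cell_area_ha),
        }, indent=2))
        manifest["stages"]["transitions"] = {
            "periods": len(matrices),
            "integrated_dynamics": [
                dynamics_report(m, T).integrated for m in matrices],
        }

        # ---- stage 3: habitat quality ----------------------------------
        stage = "hq"
        hdir = out / "hq"
        hdir.mkdir(exist_ok=True)
        hq_rasters = []
        summaries = []
        for lu in landuse:
            D = degradation(lu, config.threats, config.sensitivity)
            Q = habitat_quality(lu, D, config.sensitivity, z=config.z_exponent)
            hq_rasters.append(Q)
            write_ascii_grid(hdir / f"degradation_{lu.label}.asc", D)
            write_ascii_grid(hdir / f"quality_{lu.label}.asc", Q)
            _write_csv(grade_hq(Q), hdir / f"grades_{lu.label}.csv")
            mean, sd = hq_summary(Q)
            summaries.append({"year": lu.label, "mean": mean, "sd": sd,
                              "k": Q.k_half_saturation})
        _write_csv(pd.DataFrame(summaries), hdir / "summary.csv")
        _write_csv(compare_periods(hq_rasters), hdir / "change.csv")
        (hdir / "params.json").write_text(json.dumps({
            "z": config.z_exponent,
            "threats": [vars(t) | {"source_classes": sorted(t.source_classes)}
                        for t in config.threats],
            "sensitivity_sha": config.sensitivity.digest(),
        }, indent=2, default=str))
        manifest["stages"]["hq"] = {"means": [s["mean"] for s in summaries]}

        # ---- stage 4: spatial autocorrelation --------------------------
        stage = "autocorr"
        adir = out / "autocorr"
        adir.mkdir(exist_ok=True)
        mask = hq_rasters[0].mask
        w_moran = build_weights(mask, scheme=config.weights_scheme,
                                standardization="row",
                                cell_size=hq_rasters[0].cell_size)
        w_gi = build_weights(mask, scheme=config.weights_scheme,
                             standardization="binary", include_self=True,
                             cell_size=hq_rasters[0].cell_size)
        moran_rows = []
        hot_fracs = []
        for Q in hq_rasters:
            mr = morans_i(Q.values, w_moran,
                          permutations=config.moran_permutations,
                          seed=config.seed)
            moran_rows.append({"year": Q.label, "I": mr.I, "z": mr.z_score,
                               "p": mr.p_value, "n": mr.n,
                               "scheme": config.weights_scheme})
            gi = gi_star(Q.values, w_gi)
            z_r = Raster(values=np.nan_to_num(gi.z_values, nan=-9999.0),
                         cell_size=Q.cell_size, mask=mask,
                         label=f"gi_z_{Q.label}")
            write_ascii_grid(adir / f"gi_z_{Q.label}.asc", z_r)
            cls_r = Raster(values=gi.class_codes.astype(float),
                           cell_size=Q.cell_size, nodata=-99,
                           mask=mask, label=f"gi_class_{Q.label}")
            write_ascii_grid(adir / f"gi_class_{Q.label}.asc", cls_r, fmt="%d")
            hot_fracs.append({
                "year": Q.label,
                "hotspot_prop": float((gi.class_codes[mask] > 0).mean()),
                "coldspot_prop": float((gi.class_codes[mask] < 0).mean()),
            })
        _write_csv(pd.DataFrame(moran_rows), adir / "moran.csv")
        _write_csv(pd.DataFrame(hot_fracs), adir / "hotspot_proportions.csv")
        manifest["stages"]["autocorr"] = {
            "moran_I": [r["I"] for r in moran_rows]}

        # ---- stage 5: OPGD driver analysis -----------------------------
        stage = "opgd"
        odir = out / "opgd"
        odir.mkdir(exist_ok=True)
        lu_final = landuse[-1]
        intensity = np.vectorize(LAND_USE_INTENSITY.get)(lu_final.values)
        stack = FactorStack(
            layers={**covariates.layers,
                    "land_use_intensity": Raster(
                        values=intensity.astype(float),
                        cell_size=lu_final.cell_size,
                        mask=covariates.mask.copy(),
                        label="land_use_intensity")},
            categorical={"land_use_intensity"},
        )
        if config.planted_driver:
            from .synth import plant_hq_driver
            response = plant_hq_driver(covariates, config.planted_driver,
                                       noise_sd=config.planted_noise_sd,
                                       seed=config.seed)
        else:
            response = hq_rasters[-1]
        report = factor_report(
            response, stack, methods=config.opgd_methods,
            n_classes_range=range(config.opgd_classes[0],
                                  config.opgd_classes[1] + 1))
        _write_csv(report.factors, odir / "factor_q.csv")
        _write_csv(report.interactions, odir / "interactions.csv")
        _write_csv(report.top_interactions(4), odir / "top_interactions.csv")
        (odir / "discretizations.json").write_text(json.dumps({
            code: None if d is None else {
                "method": d.method, "n_classes": d.n_classes,
                "breaks": [float(b) for b in d.break_points]}
            for code, d in report.discretizations.items()}, indent=2))
        manifest["stages"]["opgd"] = {
            "ranking": report.factors["factor"].tolist(),
            "top_q": float(report.factors["q"].iloc[0]),
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc!r}\n")
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
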
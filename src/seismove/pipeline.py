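"""End-to-end orchestration: file IO, configuration, manifests, runs.

Composes the stages — ingest fixes, attribute the line network, build
strata and fit the SSF candidate set, assemble the near-line rate dataset
and fit the mixed/piecewise models — with per-stage record counts logged to
a run manifest, so the many inclusion filters are auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import LineString

from . import rates, ssf, telemetry
from .lines import SegmentIndex, ewam_transform
from .telemetry import (CLUSTER_GAPS_H, STATIONARY_THRESHOLDS, Track,
                        tracks_from_fixes)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunables of a run; defaults are the published study settings."""

    species: str = "wolf"
    sexes: tuple[str, ...] = ("F", "M")      # rate arm narrows to F for wolves
    seasons: tuple[str, ...] = ()            # empty = all seasons present
    fix_interval_h: float = 2.0
    rarefy_tolerance_min: float = 5.0
    stationary_radius_m: float = 300.0
    stationary_duration_h: float = 6.0
    min_locations_ssf: int = 40
    min_locations_rate: int = 20
    rate_buffer_m: float = 100.0
    pack_filter_radius_m: float = 200.0
    cluster_gap_h: float = 120.0
    k_available: int = 10
    cv_reps: int = 100
    cv_train_frac: float = 0.8
    n_boot: int = 1000
    alpha: float = 0.05
    edist_rate: float = 0.002                # 1/m
    ewam_rate: float = 1.55                  # 1/m
    extent: tuple | None = None              # study boundary for availability
    seed: int = 0
    fixes_path: str = ""
    lines_path: str = ""
    out_dir: str = "out"

    @classmethod
    def for_species(cls, species: str, **overrides) -> "RunConfig":
        """Study defaults per species (thresholds, intervals, gaps)."""
        radius, duration = STATIONARY_THRESHOLDS[species]
        base = dict(species=species,
                    stationary_radius_m=radius,
                    stationary_duration_h=duration,
                    cluster_gap_h=CLUSTER_GAPS_H[species],
                    fix_interval_h=telemetry.NOMINAL_INTERVALS_H[species])
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sexes"] = list(d["sexes"])
        d["seasons"] = list(d["seasons"])
        d["extent"] = list(d["extent"]) if d["extent"] else None
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["sexes"] = tuple(d.get("sexes", ("F", "M")))
        d["seasons"] = tuple(d.get("seasons", ()))
        if d.get("extent"):
            d["extent"] = tuple(d["extent"])
        return cls(**d)


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------

def read_fix_csv(path) -> pd.DataFrame:
    """Read a fix table (animal_id, species, sex, group, timestamp, x, y,
    pfix); missing pfix defaults to 1. Returns the internal fix schema with
    ``t`` timestamps and ``weight`` = 1/pfix."""
    raw = pd.read_csv(path)
    required = {"animal_id", "species", "sex", "group", "timestamp", "x", "y"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"fix CSV missing columns: {sorted(missing)}")
    bad = raw.index[~np.isfinite(raw[["x", "y"]]).all(axis=1)]
    if len(bad):
        raise ValueError(f"non-finite coordinates at rows {list(bad[:5])}")
    out = raw.rename(columns={"timestamp": "t"}).copy()
    out["t"] = pd.to_datetime(out["t"])
    pfix = out["pfix"] if "pfix" in out else pd.Series(1.0, index=out.index)
    if (pfix <= 0).any() or (pfix > 1).any():
        raise ValueError("pfix must lie in (0, 1]")
    out["weight"] = 1.0 / pfix
    return out[telemetry.FIX_COLUMNS]


def read_lines_geojson(path) -> pd.DataFrame:
    """Read attributed segments (or bare polylines) from GeoJSON.

    Properties veght_m, wam_m, landcover, density become segment
    attributes when present; eWAM is recomputed from wam_m.
    """
    with open(path) as fh:
        gj = json.load(fh)
    rows = []
    for i, feat in enumerate(gj["features"]):
        geom = feat["geometry"]
        if geom["type"] != "LineString":
            raise ValueError(f"feature {i}: expected LineString, got "
                             f"{geom['type']}")
        props = feat.get("properties") or {}
        ln = LineString(geom["coordinates"])
        rows.append({
            "segment_id": props.get("segment_id", i),
            "geometry": ln,
            "length": ln.length,
            "veght": props.get("veght_m", np.nan),
            "wam": props.get("wam_m", np.nan),
            "landcover": props.get("landcover", "NF"),
            "density": props.get("density", np.nan),
        })
    segs = pd.DataFrame(rows)
    with np.errstate(invalid="ignore"):
        segs["ewam"] = ewam_transform(np.nan_to_num(segs["wam"].to_numpy(),
                                                    nan=0.0))
    return segs


# ---------------------------------------------------------------------------
# Shared preprocessing
# ---------------------------------------------------------------------------

def prepare_steps(fixes: pd.DataFrame, config: RunConfig,
                  manifest: dict) -> pd.DataFrame:
    """Fixes -> rarefied, state-labelled, season-labelled movement steps."""
    fixes = fixes[fixes["species"] == config.species]
    fixes = fixes[fixes["sex"].isin(config.sexes)]
    manifest["n_fixes_in"] = int(len(fixes))
    if len(fixes) == 0:
        raise ValueError("no fixes for the configured species/sex filters")
    all_steps = []
    n_stationary = 0
    for track in tracks_from_fixes(fixes):
        track = telemetry.rarefy(track, config.fix_interval_h,
                                 config.rarefy_tolerance_min)
        states = telemetry.classify_stationary(
            track, config.stationary_radius_m, config.stationary_duration_h)
        n_stationary += int((states == "stationary").sum())
        steps = telemetry.build_steps(track, states)
        if len(steps):
            all_steps.append(steps)
    if not all_steps:
        raise ValueError("no movement steps after preprocessing")
    steps = pd.concat(all_steps, ignore_index=True)
    if config.seasons:
        steps = steps[steps["season"].isin(config.seasons)]
    manifest["n_stationary_fixes"] = n_stationary
    manifest["n_steps_raw"] = int(len(steps))
    return steps.reset_index(drop=True)


# ---------------------------------------------------------------------------
# SSF run
# ---------------------------------------------------------------------------

def run_ssf_analysis(config: RunConfig, fixes: pd.DataFrame | None = None,
                     segments: pd.DataFrame | None = None) -> dict:
    """Broad-scale run: strata, QIC_U competition, pooling, validation.

    Returns a dict of artifacts (QIC table, population coefficients, CV
    summary, manifest) and writes them as CSV/JSON under the configured
    output directory. Deterministic under the configured seed.
    """
    manifest: dict = {"config": config.to_dict(), "stage_counts": {}}
    sc = manifest["stage_counts"]
    if fixes is None:
        fixes = read_fix_csv(config.fixes_path)
    if segments is None:
        segments = read_lines_geojson(config.lines_path)
    seg_index = SegmentIndex(segments)

    steps = prepare_steps(fixes, config, sc)
    steps, report = telemetry.apply_inclusion_filters(
        steps, config.min_locations_ssf)
    sc["n_steps_after_min_locations"] = int(len(steps))
    if config.species == "wolf":
        steps = ssf.filter_pack_correlated(
            steps, config.pack_filter_radius_m, seed=config.seed)
        sc["n_steps_after_pack_filter"] = int(len(steps))
    ssf.check_lt_ta_correlation(steps)

    strata = ssf.build_strata(steps, seg_index, K=config.k_available,
                              seed=config.seed, extent=config.extent)
    sc["n_strata"] = int(strata["stratum_id"].nunique())

    fits = {}
    for name, spec in ssf.SSF_MODELS.items():
        try:
            fits[name] = ssf.fit_clogit(strata, spec)
        except ValueError as err:
            log.warning("model %s excluded from competition: %s", name, err)
    if not fits:
        raise ValueError("no candidate model could be fit")
    sc["n_models_fit"] = len(fits)
    qic_table = ssf.qicu_select(fits)
    best_name = qic_table["model"].iloc[0]
    best_spec = ssf.SSF_MODELS[best_name]

    # per-individual refits of the selected model, with robust SEs from
    # independence clusters of steps
    individual_fits = []
    for animal, sub in strata.groupby("animal_id", sort=True):
        sub = sub.reset_index(drop=True)
        try:
            f = ssf.fit_clogit(sub, best_spec)
            per_stratum = sub.groupby("stratum_id", sort=True)["t0"].first()
            clusters = ssf.assign_clusters(
                per_stratum.rename("t0").reset_index(),
                config.cluster_gap_h)
            ssf.robust_cov(f, clusters)
            individual_fits.append(f)
        except ValueError as err:
            log.info("individual %s excluded from pooling: %s", animal, err)
    pooled = ssf.population_average(individual_fits)
    sc["n_individuals_pooled"] = int(pooled["n_individuals"].iloc[0])

    cv = ssf.kfold_cv(strata, best_spec, reps=config.cv_reps,
                      train_frac=config.cv_train_frac, seed=config.seed)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qic_table.to_csv(out / "ssf_qic.csv", index=False)
    pooled.to_csv(out / "ssf_population_coefficients.csv", index=False)
    pd.DataFrame([cv]).to_csv(out / "ssf_cv.csv", index=False)
    report.to_csv(out / "ssf_exclusions.csv", index=False)
    manifest["best_model"] = best_name
    manifest["cv"] = cv
    with open(out / "ssf_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {"qic_table": qic_table, "population": pooled, "cv": cv,
            "best_model": best_name, "manifest": manifest,
            "individual_fits": individual_fits, "strata": strata}


# ---------------------------------------------------------------------------
# Rate run
# ---------------------------------------------------------------------------

def run_rate_analysis(config: RunConfig, fixes: pd.DataFrame | None = None,
                      segments: pd.DataFrame | None = None) -> dict:
    """Fine-scale run: rate dataset, AICc competition, breakpoint bootstrap."""
    manifest: dict = {"config": config.to_dict(), "stage_counts": {}}
    sc = manifest["stage_counts"]
    if fixes is None:
        fixes = read_fix_csv(config.fixes_path)
    if segments is None:
        segments = read_lines_geojson(config.lines_path)
    seg_index = SegmentIndex(segments)

    steps = prepare_steps(fixes, config, sc)
    table = rates.build_rate_dataset(steps, seg_index,
                                     max_distance=config.rate_buffer_m,
                                     min_per_season=config.min_locations_rate)
    sc["n_within_buffer"] = int(len(table))

    aicc_table = rates.compete_rate_models(table)
    best_name = aicc_table["model"].iloc[0]
    best_fit = rates.fit_lmm(table, rates.RATE_MODELS[best_name])

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aicc_table.to_csv(out / "rate_aicc.csv", index=False)
    best_fit.fixed.to_csv(out / "rate_coefficients.csv", index=False)

    breakpoint_result = None
    if best_name in ("M7", "M8"):
        # post-hoc hinge regression on the marginal data, as the height
        # effect only exists in these models
        breakpoint_result = rates.estimate_breakpoint_m(
            table, n_boot=config.n_boot, alpha=config.alpha,
            seed=config.seed)
        with open(out / "rate_breakpoint.json", "w") as fh:
            json.dump(breakpoint_result, fh, indent=2)
    manifest["best_model"] = best_name
    manifest["r2_marginal"] = best_fit.r2_marginal
    manifest["r2_conditional"] = best_fit.r2_conditional
    with open(out / "rate_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {"aicc_table": aicc_table, "best_fit": best_fit,
            "breakpoint": breakpoint_result, "manifest": manifest,
            "table": table}
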
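"""End-to-end orchestration: simulate -> mask -> SECR two-step -> RSF ->
extrapolate -> compare.

Every stage writes its artifacts under the run directory as plain text
(TSV/CSV/JSON/GeoJSON) and the whole run is a pure function of
(config, seeds): rerunning a config reproduces byte-identical outputs.
Densities are stored per km^2 internally and reported per 1,000 km^2.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import io, rsf, secr, survey_tables
from .config import SimConfig, TrueParams
from .containers import DetectorArray, MaskGrid, TENURE_LEVELS
from .landscape import (
    generate_landscape,
    place_detectors,
    simulate_captures,
    simulate_population,
)
from .mask import attach_covariates, build_mask, compute_rpsv, mcp_buffer


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message and
    artifacts written so far are left on disk."""


def _default_truth() -> dict:
    return {
        "F": TrueParams(sex="F"),
        "M": TrueParams(
            sex="M", sigma=4.0, lambda0=0.035, density_intercept=-3.0
        ),
    }


def _default_rsf_candidates() -> dict:
    return {
        "tenure+habitat": ("tenure", "ndvi", "burn"),
        "habitat": ("ndvi", "canopy"),
        "tenure": ("tenure",),
    }


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    truth: dict = field(default_factory=_default_truth)
    sexes: tuple = ("F", "M")
    mask_spacing: float = 2.5
    buffer: object = "3rpsv"  # or a fixed km value
    step1_candidates: list = field(
        default_factory=lambda: list(secr.STEP1_CANDIDATES)
    )
    step2_candidates: list = field(
        default_factory=lambda: list(secr.STEP2_CANDIDATES)
    )
    distribution: str = "poisson"
    rsf_candidates: dict = field(default_factory=_default_rsf_candidates)
    mcp_buffer_km: float = 2.4
    #: per-sex (density, lo, hi) per 1,000 km^2 for the reference area;
    #: None skips the RSF extrapolation.
    reference_density: dict | None = field(
        default_factory=lambda: dict(survey_tables.REFERENCE_DENSITY)
    )
    session: str = "sim"


def sex_ratio(f_abundance: float, m_abundance: float, decimals: int = 1) -> float:
    """Female-to-male abundance ratio, rounded as reported."""
    if m_abundance == 0:
        raise ZeroDivisionError("male abundance is zero")
    return round(f_abundance / m_abundance, decimals)


@dataclass
class ComparisonReport:
    """Side-by-side SECR and RSF densities and abundances by region."""

    table: pd.DataFrame
    sex_ratios: pd.DataFrame
    notes: list = field(default_factory=list)


def _detector_covariates(landscape: MaskGrid, detectors: DetectorArray) -> pd.DataFrame:
    tree = cKDTree(landscape.coords)
    _, idx = tree.query(detectors.coords)
    out = landscape.covariates.iloc[idx].reset_index(drop=True)
    out.insert(0, "x", detectors.x)
    out.insert(1, "y", detectors.y)
    return out


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kw):
            try:
                return fn(*args, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("simulate")
def _run_simulate(config: RunConfig, out: Path) -> dict:
    landscape = generate_landscape(config.sim)
    detectors = place_detectors(landscape, config.sim)
    io.write_grid(landscape, out / "landscape.tsv")
    io.write_detectors(detectors, out / "detectors.tsv")
    data = {"landscape": landscape, "detectors": detectors, "captures": {}}
    base = config.sim.seed
    for i, sex in enumerate(config.sexes):
        truth = config.truth[sex]
        pop = simulate_population(landscape, truth, seed=base + 11 + i)
        hist = simulate_captures(pop, detectors, truth, seed=base + 21 + i)
        hist.session = config.session
        io.write_captures(hist, detectors, out / f"captures_{sex}.tsv")
        data["captures"][sex] = hist
    return data


@_stage("secr")
def _run_secr(config: RunConfig, out: Path, data: dict) -> dict:
    landscape = data["landscape"]
    detectors = data["detectors"]
    w, h = landscape.meta["extent"]
    results = {}
    base = config.sim.seed
    for i, sex in enumerate(config.sexes):
        hist = data["captures"][sex]
        if config.buffer == "3rpsv":
            buffer = 3.0 * compute_rpsv(hist, detectors)
        else:
            buffer = float(config.buffer)
        mask = build_mask(
            detectors, buffer, config.mask_spacing, clip_bounds=(0, 0, w, h)
        )
        mask = attach_covariates(mask, landscape)
        two = secr.run_two_step(
            config.step1_candidates,
            config.step2_candidates,
            hist,
            detectors,
            mask,
            distribution=config.distribution,
            seed=base + 31 + i,
        )
        fit = two.best_fit
        surface = secr.predict_density(fit, mask)
        abund = secr.region_abundance(
            fit, mask, "tenure", regions=list(TENURE_LEVELS),
            seed=base + 41 + i,
        )
        area = (
            pd.Series(mask.covariates["tenure"]).value_counts()
            * mask.cell_area
        )
        abund["area_km2"] = abund["region"].map(area).fillna(0.0)
        io.write_json(fit.to_dict(), out / f"secr_fit_{sex}.json")
        surface.to_csv(out / f"secr_surface_{sex}.tsv", sep="\t",
                       index=False, float_format="%.8g", lineterminator="\n")
        for label, tab in (("step1", two.step1_table),
                           ("step2", two.step2_table)):
            tab.to_csv(out / f"secr_{label}_{sex}.csv", index=False,
                       float_format="%.8g", lineterminator="\n")
        results[sex] = {
            "fit": fit, "mask": mask, "surface": surface,
            "abundance": abund, "buffer": buffer, "two_step": two,
        }
    return results


@_stage("rsf")
def _run_rsf(config: RunConfig, out: Path, data: dict, notes: list) -> dict:
    landscape = data["landscape"]
    detectors = data["detectors"]
    det_cov = _detector_covariates(landscape, detectors)
    domain_poly = mcp_buffer(detectors.coords, config.mcp_buffer_km)
    io.write_polygon(domain_poly, out / "mcp_domain.geojson")

    # availability domain: landscape cells inside the buffered MCP
    from shapely import points as shp_points

    inside = domain_poly.contains(shp_points(landscape.coords))
    cells = landscape.covariates.loc[inside].reset_index(drop=True)
    cells.insert(0, "x", landscape.x[inside])
    cells.insert(1, "y", landscape.y[inside])
    a = landscape.cell_area

    results = {}
    for sex in config.sexes:
        hist = data["captures"][sex]
        det_any = hist.detections.any(axis=(0, 2))
        used = det_cov.loc[det_any].reset_index(drop=True)
        available = det_cov
        model, tab = rsf.select_rsf(config.rsf_candidates, used, available)
        tab.to_csv(out / f"rsf_aic_{sex}.csv", index=False,
                   float_format="%.8g", lineterminator="\n")
        io.write_json(
            {
                "model": model.name,
                "terms": list(model.terms),
                "coef": model.coef.to_dict(),
                "aic": model.aic,
            },
            out / f"rsf_model_{sex}.json",
        )
        entry = {"model": model, "cells": cells, "used": used}
        if config.reference_density is None:
            notes.append(
                f"RSF extrapolation skipped for sex {sex}: no reference "
                "abundance estimate in config"
            )
            results[sex] = entry
            continue
        scores = model.score(cells)
        bins = rsf.expected_use(rsf.bin_scores(scores, a))
        ref_sel = cells["tenure"].to_numpy() == "protected"
        if not ref_sel.any():
            notes.append(
                f"RSF extrapolation skipped for sex {sex}: availability "
                "domain contains no protected (reference) cells"
            )
            results[sex] = entry
            continue
        ref_bins = rsf.expected_use(
            rsf.bins_within(bins, ref_sel, a)
        )
        pt, lo, hi = config.reference_density[sex]
        reference = rsf.ReferenceEstimate(pt, lo, hi, float(ref_sel.sum() * a))
        cell_dens = rsf.extrapolate_density(
            reference, ref_bins, bins.bin_of_cell
        )
        regional = rsf.region_density(
            cell_dens, a, cells["tenure"].to_numpy()
        )
        cell_out = cells[["x", "y"]].copy().join(cell_dens)
        cell_out.to_csv(out / f"rsf_surface_{sex}.tsv", sep="\t", index=False,
                        float_format="%.8g", lineterminator="\n")
        regional.to_csv(out / f"rsf_regions_{sex}.csv", index=False,
                        float_format="%.8g", lineterminator="\n")
        entry.update(
            {"bins": bins, "reference": reference, "regional": regional,
             "cell_density": cell_dens}
        )
        results[sex] = entry
    return results


@_stage("report")
def _run_report(config: RunConfig, out: Path, secr_res: dict,
                rsf_res: dict, notes: list) -> ComparisonReport:
    rows = []
    for sex in config.sexes:
        sr = secr_res[sex]
        for rec in sr["abundance"].itertuples(index=False):
            if rec.area_km2 == 0:
                continue
            rows.append(
                {
                    "method": "SECR", "sex": sex, "session": config.session,
                    "region": rec.region,
                    "density_per_1000km2": rec.nhat / rec.area_km2 * 1000,
                    "lo": rec.lcl / rec.area_km2 * 1000,
                    "hi": rec.ucl / rec.area_km2 * 1000,
                    "abundance": rec.nhat,
                }
            )
        rr = rsf_res.get(sex, {})
        if "regional" in rr:
            for rec in rr["regional"].itertuples(index=False):
                rows.append(
                    {
                        "method": "RSF", "sex": sex,
                        "session": config.session, "region": rec.region,
                        "density_per_1000km2": rec.D * 1000,
                        "lo": rec.D_lo * 1000,
                        "hi": rec.D_hi * 1000,
                        "abundance": rec.nhat,
                    }
                )
    table = pd.DataFrame(rows)

    ratio_rows = []
    if {"F", "M"} <= set(config.sexes):
        for method in table["method"].unique():
            sub = table[table["method"] == method]
            piv = sub.pivot_table(
                index="region", columns="sex", values="abundance"
            )
            for region, rec in piv.iterrows():
                if {"F", "M"} <= set(rec.dropna().index):
                    ratio_rows.append(
                        {
                            "method": method, "region": region,
                            "ratio_F_to_M": sex_ratio(rec["F"], rec["M"]),
                        }
                    )
    ratios = pd.DataFrame(ratio_rows)
    table.to_csv(out / "report.csv", index=False, float_format="%.8g",
                 lineterminator="\n")
    ratios.to_csv(out / "sex_ratios.csv", index=False, float_format="%.8g",
                  lineterminator="\n")
    return ComparisonReport(table, ratios, notes)


def run_pipeline(config: RunConfig, outdir) -> ComparisonReport:
    """Run the full pipeline and write all artifacts under `outdir`."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    notes: list = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = _run_simulate(config, out)
        secr_res = _run_secr(config, out, data)
        rsf_res = _run_rsf(config, out, data, notes)
        report = _run_report(config, out, secr_res, rsf_res, notes)
    io.write_json(
        {
            "seed": config.sim.seed,
            "sexes": list(config.sexes),
            "distribution": config.distribution,
            "mask_spacing": config.mask_spacing,
            "buffer": config.buffer,
            "n_occasions": config.sim.n_occasions,
            "notes": notes,
        },
        out / "runlog.json",
    )
    return report
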
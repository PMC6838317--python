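"""Input validation, CSV readers/writers, and the end-to-end pipeline.

CSV dialect: UTF-8, comma separated, mandatory header, '.' decimal; isotope
columns are spelled d13C / d15N.  All randomness flows from one top-level
seed through named substreams, so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fecal, landscape, mixing, simulate, tef

__all__ = [
    "RunConfig",
    "ValidationReport",
    "validate_inputs",
    "read_taxa",
    "read_scats",
    "read_cats",
    "read_consumers",
    "read_sources",
    "read_shelter",
    "run_all",
    "stage_seed",
]

log = logging.getLogger("subsidydiet")

_SCHEMAS = {
    "taxa": {"name": str, "habitat": str, "body_weight_g": float, "status": str},
    "scats": {"scat_id": str, "cat_id": str, "taxon": str, "count": int},
    "cats": {"cat_id": str, "group": str, "sex": str, "weight_kg": float},
    "consumers": {"cat_id": str, "group": str, "d13C": float, "d15N": float},
    "sources": {"name": str, "isotope": str, "mean": float, "sd": float,
                "tef_mean": float, "tef_sd": float},
    "shelter": {"cat_id": str, "isotope": str, "days": int, "delta_diff": float},
    "buildings": {"x": float, "y": float},
    "landuse_grid": {"x": float, "y": float, "landuse_class": str},
}
_OPTIONAL = {
    "taxa": {"status"},
    "cats": {"sex", "weight_kg", "x", "y", "ear_tipped", "date"},
}
_DELTA_SUSPECT = 60.0  # ‰; beyond this a value is flagged, not rejected


def stage_seed(seed: int, stage: str) -> int:
    """Named substream seed below 2**31, stable across runs and platforms."""
    h = np.uint32(2166136261)
    for ch in f"{stage}:{seed}":
        h = np.uint32((int(h) ^ ord(ch)) * 16777619 & 0xFFFFFFFF)
    return int(h % (2**31 - 1))


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_failed(self):
        if self.errors:
            raise fecal.InvalidInputError("; ".join(self.errors))


def _check_frame(df: pd.DataFrame, kind: str, report: ValidationReport, path=""):
    schema = _SCHEMAS[kind]
    optional = _OPTIONAL.get(kind, set())
    for col in schema:
        if col not in df.columns and col not in optional:
            report.errors.append(f"{path or kind}: missing column {col!r}")
    for col, typ in schema.items():
        if col not in df.columns or typ is str:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            report.errors.append(f"{path or kind}: row {i + 2}: non-numeric {col!r}")
    if kind == "cats" and "cat_id" in df.columns and df["cat_id"].duplicated().any():
        dupes = df.loc[df["cat_id"].duplicated(), "cat_id"].tolist()
        report.errors.append(f"{path or kind}: duplicate cat_id {dupes}")
    if kind == "consumers":
        for iso in ("d13C", "d15N"):
            if iso in df.columns:
                big = df.index[pd.to_numeric(df[iso], errors="coerce").abs() > _DELTA_SUSPECT]
                for i in big:
                    report.warnings.append(
                        f"{path or kind}: row {i + 2}: |{iso}| > {_DELTA_SUSPECT}‰ looks suspicious"
                    )


def validate_inputs(paths: dict[str, str | Path]) -> ValidationReport:
    """Schema-check each table; cross-check scat -> cat references.

    ``paths`` maps schema kind (taxa, scats, cats, consumers, sources,
    shelter, buildings, landuse_grid) to a CSV path.  Schema violations are
    errors; suspicious values (|δ| > 60‰) are warnings.
    """
    report = ValidationReport()
    frames = {}
    for kind, p in paths.items():
        if kind not in _SCHEMAS:
            report.errors.append(f"unknown table kind {kind!r}")
            continue
        p = Path(p)
        if not p.exists():
            report.errors.append(f"{p}: file not found")
            continue
        df = pd.read_csv(p)
        frames[kind] = (df, str(p))
        _check_frame(df, kind, report, str(p))
    if "scats" in frames and "cats" in frames:
        scats, sp = frames["scats"]
        cats, _ = frames["cats"]
        if "cat_id" in scats.columns and "cat_id" in cats.columns:
            known = set(cats["cat_id"].astype(str))
            for i, cid in scats["cat_id"].astype(str).items():
                if cid not in known:
                    report.errors.append(f"{sp}: row {i + 2}: unknown cat_id {cid!r}")
    if "scats" in frames and "taxa" in frames:
        scats, sp = frames["scats"]
        taxa, _ = frames["taxa"]
        if "taxon" in scats.columns and "name" in taxa.columns:
            known = set(taxa["name"].astype(str))
            for i, t in scats["taxon"].astype(str).items():
                if t not in known:
                    report.errors.append(f"{sp}: row {i + 2}: unresolvable taxon {t!r}")
    return report


# ---------------------------------------------------------------------------
# Readers (CSV -> domain objects) and writers
# ---------------------------------------------------------------------------

def read_taxa(path) -> list[fecal.PreyTaxon]:
    df = pd.read_csv(path)
    return [
        fecal.PreyTaxon(
            name=str(r["name"]),
            habitat=str(r["habitat"]),
            mean_body_weight=None if pd.isna(r.get("body_weight_g")) else float(r["body_weight_g"]),
            conservation_status=None if pd.isna(r.get("status")) else str(r["status"]),
        )
        for _, r in df.iterrows()
    ]


def read_scats(path) -> list[fecal.ScatRecord]:
    df = pd.read_csv(path)
    out = []
    for (sid, cid), grp in df.groupby(["scat_id", "cat_id"], sort=False):
        items = tuple((str(t), int(c)) for t, c in zip(grp["taxon"], grp["count"]))
        out.append(fecal.ScatRecord(scat_id=str(sid), cat_id=str(cid), items=items))
    return out


def read_cats(path) -> list[fecal.CatRecord]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        xy = None
        if "x" in r and "y" in r and not (pd.isna(r["x"]) or pd.isna(r["y"])):
            xy = (float(r["x"]), float(r["y"]))
        out.append(
            fecal.CatRecord.from_kg(
                cat_id=str(r["cat_id"]),
                group=str(r["group"]),
                sex=str(r.get("sex", "unknown")) if not pd.isna(r.get("sex")) else "unknown",
                weight_kg=None if pd.isna(r.get("weight_kg")) else float(r["weight_kg"]),
                ear_tipped=None if pd.isna(r.get("ear_tipped")) else bool(r["ear_tipped"]),
                capture_xy=xy,
                capture_date=None if pd.isna(r.get("date")) else str(r["date"]),
            )
        )
    return out


def read_consumers(path) -> list[mixing.ConsumerSample]:
    df = pd.read_csv(path)
    return [
        mixing.ConsumerSample(str(r["cat_id"]), str(r["group"]),
                              float(r["d13C"]), float(r["d15N"]))
        for _, r in df.iterrows()
    ]


def read_sources(path) -> list[mixing.SourceProfile]:
    df = pd.read_csv(path)
    out = []
    for name, grp in df.groupby("name", sort=False):
        g = grp.set_index("isotope")
        out.append(
            mixing.SourceProfile(
                name=str(name),
                mean=g["mean"].to_dict(),
                sd=g["sd"].to_dict(),
                tef_mean=g["tef_mean"].to_dict(),
                tef_sd=g["tef_sd"].to_dict(),
            )
        )
    return out


def read_shelter(path) -> dict[str, tef.ShelterSeries]:
    df = pd.read_csv(path)
    out = {}
    for iso, grp in df.groupby("isotope", sort=False):
        out[str(iso)] = tef.ShelterSeries(
            isotope=str(iso),
            days=tuple(float(d) for d in grp["days"]),
            delta_diff=tuple(float(v) for v in grp["delta_diff"]),
        )
    return out


def write_consumers(consumers, path):
    pd.DataFrame(
        [{"cat_id": c.cat_id, "group": c.group, "d13C": c.d13C, "d15N": c.d15N}
         for c in consumers]
    ).to_csv(path, index=False)


def write_sources(sources, path):
    rows = []
    for s in sources:
        for iso in s.mean:
            rows.append({"name": s.name, "isotope": iso, "mean": s.mean[iso],
                         "sd": s.sd[iso], "tef_mean": s.tef_mean[iso],
                         "tef_sd": s.tef_sd[iso]})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fixture(taxa, scats, cats, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"name": t.name, "habitat": t.habitat, "body_weight_g": t.mean_body_weight,
          "status": t.conservation_status} for t in taxa]
    ).to_csv(outdir / "taxa.csv", index=False)
    pd.DataFrame(
        [{"scat_id": s.scat_id, "cat_id": s.cat_id, "taxon": n, "count": c}
         for s in scats for n, c in s.items]
    ).to_csv(outdir / "scats.csv", index=False)
    pd.DataFrame(
        [{"cat_id": c.cat_id, "group": c.group, "sex": c.sex,
          "weight_kg": None if c.weight_g is None else c.weight_g / 1000.0,
          "x": None if c.capture_xy is None else c.capture_xy[0],
          "y": None if c.capture_xy is None else c.capture_xy[1],
          "ear_tipped": c.ear_tipped, "date": c.capture_date} for c in cats]
    ).to_csv(outdir / "cats.csv", index=False)


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Stage toggles, thresholds and the top-level seed for a full run."""

    seed: int = 1
    outdir: str | Path = "out"
    contribution_threshold: float = 3.0
    hdr_mass: float = 0.95
    delta_aicc_max: float = 2.0
    radii: tuple = landscape.RADII
    mcmc: mixing.MCMCConfig | None = None
    run_glm: bool = True
    run_tef: bool = True
    scenario: simulate.ScenarioConfig | None = None


def run_all(config: RunConfig) -> dict:
    """Run fecal -> source selection -> TEF -> mixing (-> GLM) on a scenario.

    With no explicit scenario the shipped island-calibrated one is used.
    Writes per-stage CSVs plus a machine-readable summary.json in
    ``config.outdir`` and returns the summary dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scen = config.scenario or simulate.ScenarioConfig(seed=stage_seed(config.seed, "scenario"))
    summary: dict = {"seed": config.seed}

    # --- fecal stage -------------------------------------------------------
    taxa, scats, cats = simulate.table1_fixture(seed=stage_seed(config.seed, "fecal"))
    write_fixture(taxa, scats, cats, outdir)
    dcb = fecal.mean_dcb(cats)
    table = fecal.category_contributions(
        taxa,
        {t.name: sum(c for s in scats for n, c in s.items if n == t.name) for t in taxa},
        n_scats=len(scats),
        mean_dcb=dcb["mean"],
        max_dcb=dcb["max"],
        scats=scats,
        cats=cats,
    )
    table.format().to_csv(outdir / "contribution_table.csv")
    selected = fecal.select_sources(table, config.contribution_threshold)
    summary["fecal"] = {
        "n_scats": table.n_scats,
        "mean_dcb": dcb["mean"],
        "max_dcb": dcb["max"],
        "selected_sources": selected.index.tolist(),
    }
    log.info("fecal stage: %d scats, %d sources selected", table.n_scats, len(selected))

    # --- TEF stage ---------------------------------------------------------
    tef_used = dict(tef.DEFAULT_TEF)
    if config.run_tef:
        shelter = simulate.gen_shelter_series(scen)
        shelter.to_csv(outdir / "shelter.csv", index=False)
        series = read_shelter(outdir / "shelter.csv")
        fits = tef.tef_pair(series.get("d13C"), series.get("d15N"))
        tef_used = {iso: (f.C, f.se_C) for iso, f in fits.items()}
        pd.DataFrame(
            [{"isotope": iso, "A": f.A, "B": f.B, "C": f.C, "se_C": f.se_C,
              "converged": f.converged} for iso, f in fits.items()]
        ).to_csv(outdir / "tef.csv", index=False)
        summary["tef"] = {iso: {"C": f.C, "se_C": f.se_C} for iso, f in fits.items()}

    # --- mixing stage ------------------------------------------------------
    consumers = [c for c in simulate.gen_consumer_isotopes(scen) if c.group != "indoor"]
    sources = simulate.tokunoshima_sources(tef_used)
    write_consumers(consumers, outdir / "consumers.csv")
    write_sources(sources, outdir / "sources.csv")
    mcfg = config.mcmc or mixing.MCMCConfig(seed=stage_seed(config.seed, "mixing"))
    post = mixing.run_mixing_mcmc(consumers, sources, mcfg, mass=config.hdr_mass)
    post.summary_table().to_csv(outdir / "posterior_summary.csv", index=False)
    draws = pd.concat(
        {g: pd.DataFrame(d, columns=post.source_names) for g, d in post.draws.items()},
        names=["group", "draw"],
    )
    draws.to_csv(outdir / "posterior_draws.csv")
    summary["mixing"] = {
        g: {name: s["mean"][k] for k, name in enumerate(post.source_names)}
        for g, s in post.summaries.items()
    }

    # --- landscape GLM stage ----------------------------------------------
    if config.run_glm:
        landuse, buildings, sites = simulate.gen_landscape(scen)
        covs = landscape.site_covariates(sites, landuse, buildings, radii=config.radii)
        covs.to_csv(outdir / "sites_covariates.csv", index=False)
        vars500 = [c for c in covs.columns if c.endswith("_500m")]
        fs = landscape.factor_analysis(covs[vars500])
        fs.loadings.to_csv(outdir / "factors.csv")
        basis = landscape.mem_construct(sites[["x", "y"]].to_numpy())
        rng = np.random.default_rng(stage_seed(config.seed, "glm"))
        # per-cat dependence: posterior-mean proportions plus site-level noise
        p_art = np.clip(
            rng.normal(summary["mixing"].get("feral", {}).get("artificial resources", 0.6),
                       0.08, size=len(sites)), 0.01, 0.99)
        y = landscape.arcsine_sqrt(p_art)
        mems = landscape.mem_select(basis, pd.DataFrame({"artificial": y}))
        design = pd.concat(
            [fs.scores.reset_index(drop=True),
             pd.DataFrame({"weight": rng.normal(3.3, 1.0, len(sites)),
                           "sex_male": rng.integers(0, 2, len(sites))}),
             mems.reset_index(drop=True)],
            axis=1,
        )
        basis.vectors.to_csv(outdir / "mem_scores.csv", index=False)
        avg = landscape.fit_and_average(y, design, response_name="artificial",
                                        delta_max=config.delta_aicc_max)
        avg.estimates.to_csv(outdir / "glm_table.csv")
        summary["glm"] = {
            "n_sites": len(sites),
            "n_mems_retained": mems.shape[1],
            "n_models_averaged": avg.n_models_averaged,
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
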
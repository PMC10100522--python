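"""End-to-end orchestration: ingest/generate -> filter -> tree -> metrics ->
zones -> null SES -> models -> report.

A single global seed deterministically derives all stage seeds (via
``numpy.random.SeedSequence(global_seed).spawn``, one child per named
stage in a fixed order), so a rerun with the same config reproduces every
artifact checksum.  Two profiles trade fidelity for wall time: ``full``
uses 999 null iterations and the 4x(1000+3000) MCMC settings; ``desk``
uses 199 null iterations and 4x(400+400) draws, which is plenty for sign
calls and end-to-end checks.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as cio
from . import synthetic
from .diversity import (CommunityMetricsEngine, build_trait_space,
                        community_metrics, gower_matrix)
from .models import default_battery, run_model_battery
from .nulls import NullConfig, ses_table
from .trees import build_tree, write_newick
from .zoning import assign_zones

__all__ = ["RunConfig", "run_pipeline", "report"]

STAGES = ("generate", "nulls", "models")  # stages that consume randomness

PROFILES = {
    "desk": {"n_iter": 199, "chains": 4, "warmup": 400, "draws": 400},
    "full": {"n_iter": 999, "chains": 4, "warmup": 1000, "draws": 3000},
}


@dataclass
class RunConfig:
    mode: str = "synthetic"               # synthetic | user-data
    sim: synthetic.SimConfig | None = None
    paths: dict = field(default_factory=dict)  # user-data: lakes, taxa, occurrences
    profile: str = "desk"
    k_zones: int | None = None
    null: NullConfig | None = None
    battery: dict = field(default_factory=dict)  # kwargs for default_battery
    out_dir: str = "results/pipeline"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "user-data"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "user-data" and not self.paths:
            raise ValueError("user-data mode needs input paths")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")


def _stage_seeds(global_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(global_seed).spawn(len(STAGES))
    return {name: int(ss.generate_state(1)[0] % (2**31))
            for name, ss in zip(STAGES, children)}


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, fit_models: bool = True) -> dict:
    """Run all stages and write artifacts; returns the run manifest dict."""
    import os

    os.makedirs(cfg.out_dir, exist_ok=True)
    profile = PROFILES[cfg.profile]
    seeds = _stage_seeds(cfg.seed)
    manifest = {
        "config": {
            "mode": cfg.mode, "profile": cfg.profile, "seed": cfg.seed,
            "k_zones": cfg.k_zones,
            "sim": asdict(cfg.sim) if cfg.sim else None,
            "paths": cfg.paths,
        },
        "stage_seeds": seeds,
        "counts": {},
        "timings": {},
        "artifacts": {},
    }
    t_all = time.perf_counter()

    def timed(name):
        class _T:
            def __enter__(self):
                self.t = time.perf_counter()
            def __exit__(self, *exc):
                manifest["timings"][name] = round(time.perf_counter() - self.t, 3)
        return _T()

    def persist(name, writer):
        path = f"{cfg.out_dir}/{name}"
        writer(path)
        manifest["artifacts"][name] = _checksum(path)
        return path

    # --- ingest / generate -------------------------------------------------
    with timed("ingest"):
        if cfg.mode == "synthetic":
            sim = cfg.sim or synthetic.SimConfig(seed=seeds["generate"])
            lakes = synthetic.generate_lakes(sim)
            lakes = synthetic.generate_climate(lakes, sim)
            taxa = synthetic.generate_species_pool(sim)
            occ = synthetic.generate_occurrences(lakes, taxa, sim)
        else:
            lakes = cio.read_lake_table(cfg.paths["lakes"])
            taxa = cio.read_taxon_table(cfg.paths["taxa"])
            occ = cio.read_occurrences(
                cfg.paths["occurrences"], layout=cfg.paths.get("layout", "long"))
            cio.validate_occurrences(occ, lakes=lakes, taxa=taxa)
            # lakes absent from the (presence-only) long file are empty
            # communities; taxa never observed still belong to the pool
            occ = occ.reindex(index=lakes["lake_id"],
                              columns=taxa["taxon_id"],
                              fill_value=0).astype(np.int8)
    # canonical ordering so results are independent of input row/column order
    lakes = lakes.sort_values("lake_id").reset_index(drop=True)
    taxa = taxa.sort_values("taxon_id").reset_index(drop=True)
    occ = occ.sort_index().sort_index(axis=1)
    manifest["counts"]["lakes_in"] = len(lakes)
    manifest["counts"]["taxa_in"] = len(taxa)

    # --- compilation rules --------------------------------------------------
    with timed("filter"):
        occ, taxa, removed = cio.filter_nontarget(occ, taxa)
    manifest["counts"]["taxa_excluded"] = len(removed)
    manifest["counts"]["taxa_retained"] = len(taxa)

    # --- tree + trait space -------------------------------------------------
    with timed("tree"):
        species = taxa[taxa["rank"] == "species"].reset_index(drop=True)
        tree = build_tree(species)
        persist("taxonomy_tree.nwk",
                lambda p: open(p, "w").write(write_newick(tree) + "\n"))
        gower = gower_matrix(taxa)
        space = build_trait_space(gower)

    # --- metrics -------------------------------------------------------------
    with timed("metrics"):
        metrics = community_metrics(occ, taxa, space, tree)
    manifest["counts"]["richness_eligible"] = int((metrics["richness"] >= 0).sum())
    manifest["counts"]["pd_eligible"] = int(metrics["pd_eligible"].sum())
    manifest["counts"]["fric_eligible"] = int(metrics["fric_eligible"].sum())

    # --- zones ----------------------------------------------------------------
    with timed("zones"):
        zones = assign_zones(lakes, k=cfg.k_zones)
        persist("zones.csv", lambda p: zones.table.to_csv(p, index=False))
        breaks = pd.DataFrame({
            "zone": np.arange(1, zones.k + 1),
            "elev_break": zones.elev_breaks,
            "lat_break": zones.lat_breaks,
        })
        persist("zone_breaks.csv", lambda p: breaks.to_csv(p, index=False))
    manifest["counts"]["k_zones"] = zones.k

    # --- null SES --------------------------------------------------------------
    with timed("ses"):
        ncfg = cfg.null or NullConfig(seed=seeds["nulls"],
                                      n_iter=profile["n_iter"])
        engine = CommunityMetricsEngine(space, tree)
        ses = ses_table(occ, taxa, engine, zones, ncfg)
        metrics = metrics.merge(ses, on="lake_id")
        persist("metrics.csv", lambda p: metrics.to_csv(p, index=False))
        persist("lakes.csv", lambda p: cio.write_lake_table(lakes, p))
        persist("taxa.csv", lambda p: cio.write_taxon_table(taxa, p))
        persist("occurrences.csv", lambda p: cio.write_occurrences(occ, p))

    # --- models -----------------------------------------------------------------
    summary = None
    if fit_models:
        with timed("models"):
            data = metrics.merge(lakes, on="lake_id").merge(
                zones.table, on="lake_id")
            mcmc = {k: profile[k] for k in ("chains", "warmup", "draws")}
            mcmc["seed"] = seeds["models"]
            battery_kw = dict(cfg.battery)
            battery_kw.setdefault("mcmc", mcmc)
            specs = default_battery(**battery_kw)
            summary, fits = run_model_battery(data, specs)
            persist("model_summary.csv", lambda p: summary.to_csv(p, index=False))
        manifest["counts"]["models_fit"] = int((summary["status"] == "ok").sum())
        manifest["counts"]["models_flagged"] = int(
            (summary["status"] != "ok").sum())

    manifest["timings"]["total"] = round(time.perf_counter() - t_all, 3)
    eligible_ok = (
        manifest["counts"]["richness_eligible"]
        >= manifest["counts"]["pd_eligible"]
        >= manifest["counts"]["fric_eligible"]
    )
    manifest["counts"]["eligibility_ordering_ok"] = bool(eligible_ok)
    with open(f"{cfg.out_dir}/manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def report(manifest: dict, summary: pd.DataFrame | None = None) -> str:
    """Human-readable run summary: counts, timings, per-model sign calls."""
    lines = ["run summary", "==========="]
    c = manifest["counts"]
    lines.append(f"lakes: {c.get('lakes_in')}  taxa retained: {c.get('taxa_retained')}"
                 f" (excluded {c.get('taxa_excluded')})")
    lines.append(
        "eligibility: richness %s >= PD/MPD/FDis %s >= FRic %s (%s)" % (
            c.get("richness_eligible"), c.get("pd_eligible"),
            c.get("fric_eligible"),
            "ok" if c.get("eligibility_ordering_ok") else "VIOLATED",
        ))
    lines.append(f"zones per axis: {c.get('k_zones')}")
    if summary is not None and len(summary):
        lines.append("")
        lines.append("model results (population-level):")
        for _, row in summary.iterrows():
            if row.get("status", "ok") not in ("ok", "flagged"):
                lines.append(f"  {row['model']}: {row['status']}")
                continue
            b2 = (f", beta2={row['beta2_median']:+.2f} ({row['beta2_sign']})"
                  if "beta2_median" in row and pd.notna(row.get("beta2_median"))
                  else "")
            lines.append(
                f"  {row['model']}: beta1={row['beta1_median']:+.2f}"
                f" ({row['beta1_sign']}){b2} [{row['status']}]")
    lines.append("")
    lines.append("timings (s): " + ", ".join(
        f"{k}={v}" for k, v in manifest["timings"].items()))
    return "\n".join(lines)
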
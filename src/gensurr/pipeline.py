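"""End-to-end orchestration: simulate -> metrics -> surrogates -> prioritize
-> evaluate -> report.

Two entry points coexist.  ``analyze_species`` runs the whole analysis for
one synthetic species in memory and returns every intermediate product —
this is what scripts, tests and the replicate experiment use.  The staged
runner (``run_stage`` / ``run_all``) executes the same steps against a run
directory with standard-format artifacts (ESRI ASCII rasters, GENEPOP,
CSV matrices) and a manifest per stage recording seeds and content hashes,
so a rerun with an identical configuration is byte-identical and a missing
upstream stage fails with an actionable message.

All randomness derives from one master seed; per-stage seeds are drawn
from named seed sequences, never from the wall clock.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .containers import (
    DistanceMatrix,
    GensurrError,
    MLPEFit,
    PrioritizationSeries,
    RasterStack,
    ScoreVector,
    SiteTable,
)
from .evaluate import (
    broadscale_curves,
    capture_curves,
    high_diversity_sites,
    mlpe_fit,
    spearman_onesided,
    surrogate_summary,
)
from .popgen import allele_counts, jost_d_pairwise, rarefied_allelic_richness
from .prioritize import ed_series, random_series, rank_series
from .surrogates import (
    geographic_distances,
    longterm_suitability,
    resistance_from_stack,
)
from .synthetic import (
    GenotypeConfig,
    LandscapeConfig,
    TrueStructure,
    make_landscape,
    place_sites,
    simulate_genotypes,
)

STAGES = ["simulate", "metrics", "surrogates", "prioritize", "evaluate", "report"]


def stage_seed(master_seed: int, label: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    state = np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode())])
    return int(state.generate_state(1)[0] >> 1)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RunConfig:
    """One structured configuration for a full pipeline run."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    genotypes: GenotypeConfig = field(default_factory=GenotypeConfig)
    species_id: str = "species01"
    outdir: str = "runs/default"
    master_seed: int = 0
    min_separation: float = 20_000.0
    clamp: float = 1e-5
    connectivity: int = 8
    locus_combine: str = "arithmetic"
    random_reps: int = 1000
    percentiles: tuple[float, ...] = (70.0, 80.0, 90.0)
    k_window: tuple[float, float] = (0.0, 0.25)

    def with_seeds(self) -> "RunConfig":
        """Propagate the master seed into the stage configs."""
        return dataclasses.replace(
            self,
            landscape=dataclasses.replace(
                self.landscape, seed=stage_seed(self.master_seed, "landscape")
            ),
            genotypes=dataclasses.replace(
                self.genotypes, seed=stage_seed(self.master_seed, "genotypes")
            ),
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        land = raw.pop("landscape", {})
        geno = raw.pop("genotypes", {})
        for key in ("samples_per_site", "n_loci", "alleles_per_locus"):
            if key in geno and isinstance(geno[key], list):
                geno[key] = tuple(geno[key])
        for key in ("percentiles", "k_window"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(
            landscape=LandscapeConfig(**land), genotypes=GenotypeConfig(**geno), **raw
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# in-memory analysis


@dataclass
class SpeciesResult:
    """Every product of the per-species analysis, kept in memory."""

    species: str
    stack: RasterStack
    sites: SiteTable
    structure: TrueStructure
    richness: ScoreVector
    suitability: ScoreVector
    genetic: DistanceMatrix
    geographic: DistanceMatrix
    resistance: DistanceMatrix
    sitelevel_curves: pd.DataFrame
    broadscale_curves: pd.DataFrame
    spearman: tuple[float, float]
    mlpe_geographic: MLPEFit
    mlpe_resistance: MLPEFit

    def summary(
        self,
        kind: str = "broadscale",
        threshold: str = "p80",
        k_window: tuple[float, float] = (0.0, 0.25),
        seed: int = 0,
    ) -> pd.DataFrame:
        if kind == "broadscale":
            return surrogate_summary(
                self.broadscale_curves, "jost_d_ed", k_window=k_window, seed=seed
            )
        curves = self.sitelevel_curves
        curves = curves[curves["threshold"] == threshold]
        return surrogate_summary(
            curves, "allelic_richness_rank", k_window=k_window, seed=seed
        )


def analyze_species(config: RunConfig) -> SpeciesResult:
    """Run the full analysis for one synthetic species in memory."""
    cfg = config.with_seeds()
    stack = make_landscape(cfg.landscape)
    sites = place_sites(
        stack,
        cfg.genotypes.n_sites,
        min_separation=cfg.min_separation,
        seed=stage_seed(cfg.master_seed, "sites"),
    )
    genotypes, structure = simulate_genotypes(sites, stack, cfg.genotypes)

    counts = allele_counts(genotypes)
    richness = rarefied_allelic_richness(counts, g="auto")
    genetic = jost_d_pairwise(genotypes, combine=cfg.locus_combine)

    suitability = longterm_suitability(stack, sites)
    geographic = geographic_distances(sites)
    resistance = resistance_from_stack(
        stack, sites, clamp=cfg.clamp, connectivity=cfg.connectivity
    )

    series: list[PrioritizationSeries] = [
        rank_series(richness, species=cfg.species_id),
        rank_series(suitability, species=cfg.species_id),
        ed_series(genetic, species=cfg.species_id),
        ed_series(geographic, species=cfg.species_id),
        ed_series(resistance, species=cfg.species_id),
    ]
    randoms = random_series(
        sites.ids,
        reps=cfg.random_reps,
        seed=stage_seed(cfg.master_seed, "random"),
        species=cfg.species_id,
    )

    rank_like = [s for s in series if s.method.endswith("_rank")] + randoms
    sitelevel = pd.concat(
        [
            capture_curves(
                rank_like,
                high_diversity_sites(richness, percentile=p),
                threshold_label=f"p{int(p)}",
            )
            for p in cfg.percentiles
        ],
        ignore_index=True,
    )
    ed_like = [s for s in series if s.method.endswith("_ed")] + randoms
    broadscale = broadscale_curves(ed_like, genetic)

    # optimality dominance: the exact selector can never lose to a random
    # draw on its own metric
    genetic_ed = next(s for s in series if s.method == "jost_d_ed")
    opt = (
        broadscale[
            (broadscale["method"] == "jost_d_ed")
        ].set_index("k")["performance"]
    )
    rand_best = (
        broadscale[broadscale["method"] == "random"]
        .groupby("k")["performance"]
        .max()
    )
    if not (opt.reindex(rand_best.index) >= rand_best - 1e-9).all():
        raise GensurrError("optimality dominance violated (solver bug)")

    rho, pval = spearman_onesided(richness, suitability)
    return SpeciesResult(
        species=cfg.species_id,
        stack=stack,
        sites=sites,
        structure=structure,
        richness=richness,
        suitability=suitability,
        genetic=genetic,
        geographic=geographic,
        resistance=resistance,
        sitelevel_curves=sitelevel,
        broadscale_curves=broadscale,
        spearman=(rho, pval),
        mlpe_geographic=mlpe_fit(genetic, geographic),
        mlpe_resistance=mlpe_fit(genetic, resistance),
    )


def replicate_experiment(
    config: RunConfig, n_species: int, seeds: list[int] | None = None
) -> dict:
    """Emulate the multi-species design: independent synthetic species with
    configurations drawn within the study envelope, pooled summaries.

    Returns a dict with per-species results, the pooled curve frames, and
    pooled site-level (p80) and broad-scale surrogate summaries.
    """
    if n_species < 1:
        raise GensurrError("n_species must be >= 1")
    if seeds is None:
        seeds = [stage_seed(config.master_seed, f"species{i}") for i in range(n_species)]
    if len(seeds) != n_species:
        raise GensurrError("need one seed per species")
    results: list[SpeciesResult] = []
    failures: dict[str, str] = {}
    for i, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        species_id = f"species{i + 1:02d}"
        geno = dataclasses.replace(
            config.genotypes,
            n_sites=int(rng.integers(10, 25)),
            n_lineages=int(rng.integers(1, 4)),
            stability_effect=float(rng.uniform(0.0, 1.5)),
            admixture_width=float(rng.choice([0.0, 100_000.0])),
        )
        sub = dataclasses.replace(
            config, genotypes=geno, species_id=species_id, master_seed=int(seed)
        )
        try:
            results.append(analyze_species(sub))
        except GensurrError as exc:  # pragma: no cover - defensive
            failures[species_id] = str(exc)
    if failures:
        raise GensurrError(
            f"partial results: {len(results)} species succeeded, failures: {failures}"
        )
    sitelevel = pd.concat([r.sitelevel_curves for r in results], ignore_index=True)
    broadscale = pd.concat([r.broadscale_curves for r in results], ignore_index=True)
    summary_seed = stage_seed(config.master_seed, "summary")
    pooled_site = surrogate_summary(
        sitelevel[sitelevel["threshold"] == "p80"],
        "allelic_richness_rank",
        k_window=config.k_window,
        seed=summary_seed,
    )
    pooled_broad = surrogate_summary(
        broadscale, "jost_d_ed", k_window=config.k_window, seed=summary_seed
    )
    return {
        "species": results,
        "sitelevel_curves": sitelevel,
        "broadscale_curves": broadscale,
        "sitelevel_summary": pooled_site,
        "broadscale_summary": pooled_broad,
    }


# ---------------------------------------------------------------------------
# staged file-based runner


def _species_dir(config: RunConfig) -> Path:
    return Path(config.outdir) / config.species_id


def _hash_file(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    return hashlib.md5(
        yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()


def _write_manifest(stage_dir: Path, config: RunConfig, seeds: dict) -> None:
    outputs = {
        p.name: _hash_file(p)
        for p in sorted(stage_dir.iterdir())
        if p.name != "manifest.json" and p.is_file()
    }
    manifest = {
        "stage": stage_dir.name,
        "config_hash": _config_hash(config),
        "seeds": seeds,
        "outputs": outputs,
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require_stage(config: RunConfig, stage: str) -> Path:
    stage_dir = _species_dir(config) / stage
    if not (stage_dir / "manifest.json").exists():
        raise GensurrError(
            f"missing artifacts for stage {stage!r}: run `gensurr {stage}` first"
        )
    return stage_dir


def _stage_simulate(config: RunConfig) -> None:
    cfg = config.with_seeds()
    out = _species_dir(config) / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    stack = make_landscape(cfg.landscape)
    sites_seed = stage_seed(cfg.master_seed, "sites")
    sites = place_sites(
        stack, cfg.genotypes.n_sites, min_separation=cfg.min_separation, seed=sites_seed
    )
    genotypes, structure = simulate_genotypes(sites, stack, cfg.genotypes)
    gio.write_raster_stack(stack, out)
    gio.write_sites_csv(sites, out / "sites.csv")
    gio.write_genepop(genotypes, out / "genotypes.gen", title=cfg.species_id)
    gio.write_genotypes_csv(genotypes, out / "genotypes.csv")
    (out / "structure.json").write_text(
        json.dumps(
            {
                "lineage_of_site": structure.lineage_of_site,
                "expected_diversity_rank": structure.expected_diversity_rank,
                "generating_params": structure.generating_params,
            },
            indent=2,
            sort_keys=True,
        )
    )
    _write_manifest(
        out,
        config,
        {
            "landscape": cfg.landscape.seed,
            "sites": sites_seed,
            "genotypes": cfg.genotypes.seed,
        },
    )


def _load_stack(config: RunConfig) -> RasterStack:
    sim = _require_stage(config, "simulate")
    periods = ["contemporary"] + [
        f"hist{i}" for i in range(1, config.landscape.n_periods)
    ]
    paths = [sim / f"suitability_{p}.asc" for p in periods]
    return gio.read_raster_stack(paths, periods)


def _stage_metrics(config: RunConfig) -> None:
    sim = _require_stage(config, "simulate")
    out = _species_dir(config) / "metrics"
    out.mkdir(parents=True, exist_ok=True)
    genotypes = gio.read_genepop(sim / "genotypes.gen")
    counts = allele_counts(genotypes)
    rarefied_allelic_richness(counts, g="auto").to_csv(out / "allelic_richness.csv")
    jost_d_pairwise(genotypes, combine=config.locus_combine).to_csv(out / "jost_d.csv")
    _write_manifest(out, config, {})


def _stage_surrogates(config: RunConfig) -> None:
    sim = _require_stage(config, "simulate")
    out = _species_dir(config) / "surrogates"
    out.mkdir(parents=True, exist_ok=True)
    stack = _load_stack(config)
    sites = gio.read_sites_csv(sim / "sites.csv")
    longterm_suitability(stack, sites).to_csv(out / "longterm_suitability.csv")
    geographic_distances(sites).to_csv(out / "geographic.csv")
    resistance_from_stack(
        stack, sites, clamp=config.clamp, connectivity=config.connectivity
    ).to_csv(out / "resistance.csv")
    _write_manifest(out, config, {})


def _stage_prioritize(config: RunConfig) -> None:
    metrics = _require_stage(config, "metrics")
    surr = _require_stage(config, "surrogates")
    out = _species_dir(config) / "prioritize"
    out.mkdir(parents=True, exist_ok=True)
    richness = ScoreVector.from_csv(metrics / "allelic_richness.csv")
    suitability = ScoreVector.from_csv(surr / "longterm_suitability.csv")
    genetic = DistanceMatrix.from_csv(metrics / "jost_d.csv", metric="jost_d")
    geographic = DistanceMatrix.from_csv(surr / "geographic.csv", metric="geographic")
    resistance = DistanceMatrix.from_csv(surr / "resistance.csv", metric="resistance")
    random_seed = stage_seed(config.master_seed, "random")
    all_series = [
        rank_series(richness, species=config.species_id),
        rank_series(suitability, species=config.species_id),
        ed_series(genetic, species=config.species_id),
        ed_series(geographic, species=config.species_id),
        ed_series(resistance, species=config.species_id),
    ] + random_series(
        richness.sites, reps=config.random_reps, seed=random_seed,
        species=config.species_id,
    )
    pd.concat([s.to_rows() for s in all_series], ignore_index=True).to_csv(
        out / "selections.csv", index=False
    )
    obj_rows = [
        {"method": s.method, "k": k, "objective": s.objectives[k]}
        for s in all_series
        if s.objectives
        for k in s.ks
    ]
    pd.DataFrame(obj_rows).to_csv(out / "objectives.csv", index=False)
    _write_manifest(out, config, {"random": random_seed})


def _series_from_rows(rows: pd.DataFrame, species: str) -> list[PrioritizationSeries]:
    out = []
    for (method, rep), grp in rows.groupby(["method", "replicate"], sort=True):
        selections = {
            int(k): frozenset(sub["site_id"].astype(str))
            for k, sub in grp.groupby("k")
        }
        out.append(
            PrioritizationSeries(
                species=species,
                method=str(method),
                selections=selections,
                replicate=None if rep == -1 else int(rep),
            )
        )
    return out


def _stage_evaluate(config: RunConfig) -> None:
    metrics = _require_stage(config, "metrics")
    surr = _require_stage(config, "surrogates")
    prio = _require_stage(config, "prioritize")
    out = _species_dir(config) / "evaluate"
    out.mkdir(parents=True, exist_ok=True)
    richness = ScoreVector.from_csv(metrics / "allelic_richness.csv")
    suitability = ScoreVector.from_csv(surr / "longterm_suitability.csv")
    genetic = DistanceMatrix.from_csv(metrics / "jost_d.csv", metric="jost_d")
    geographic = DistanceMatrix.from_csv(surr / "geographic.csv", metric="geographic")
    resistance = DistanceMatrix.from_csv(surr / "resistance.csv", metric="resistance")
    rows = pd.read_csv(prio / "selections.csv", dtype={"site_id": str})
    all_series = _series_from_rows(rows, config.species_id)
    rank_like = [
        s for s in all_series if s.method.endswith("_rank") or s.method == "random"
    ]
    ed_like = [
        s for s in all_series if s.method.endswith("_ed") or s.method == "random"
    ]
    sitelevel = pd.concat(
        [
            capture_curves(
                rank_like,
                high_diversity_sites(richness, percentile=p),
                threshold_label=f"p{int(p)}",
            )
            for p in config.percentiles
        ],
        ignore_index=True,
    )
    broadscale = broadscale_curves(ed_like, genetic)
    pd.concat([sitelevel, broadscale], ignore_index=True).to_csv(
        out / "curves.csv", index=False
    )
    summary_seed = stage_seed(config.master_seed, "summary")
    site_summary = surrogate_summary(
        sitelevel[sitelevel["threshold"] == "p80"],
        "allelic_richness_rank",
        k_window=config.k_window,
        seed=summary_seed,
    ).assign(kind="sitelevel")
    broad_summary = surrogate_summary(
        broadscale, "jost_d_ed", k_window=config.k_window, seed=summary_seed
    ).assign(kind="broadscale")
    pd.concat([site_summary, broad_summary], ignore_index=True).to_csv(
        out / "summary.csv", index=False
    )
    rho, pval = spearman_onesided(richness, suitability)
    fit_geo = mlpe_fit(genetic, geographic)
    fit_res = mlpe_fit(genetic, resistance)
    stats = {
        "spearman_rho": rho,
        "spearman_p_onesided": pval,
        "mlpe_geographic": dataclasses.asdict(fit_geo),
        "mlpe_resistance": dataclasses.asdict(fit_res),
    }
    (out / "association_stats.json").write_text(
        json.dumps(stats, indent=2, sort_keys=True)
    )
    _write_manifest(out, config, {"summary": summary_seed})


def _stage_report(config: RunConfig) -> None:
    ev = _require_stage(config, "evaluate")
    out = _species_dir(config) / "report"
    out.mkdir(parents=True, exist_ok=True)
    curves = pd.read_csv(ev / "curves.csv")
    summary = pd.read_csv(ev / "summary.csv")
    _plot_curves(curves, out / "performance.png")
    lines = [f"# Run report: {config.species_id}", "", "## Surrogate summary", ""]
    lines.append(summary.to_string(index=False))
    (out / "report.md").write_text("\n".join(lines) + "\n")
    _write_manifest(out, config, {})


def _plot_curves(curves: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), sharey=True)
    panels = [
        ("p80", ["allelic_richness_rank", "longterm_suitability_rank", "random"],
         "(a) site-level genetic diversity"),
        ("broadscale", ["jost_d_ed", "geographic_ed", "resistance_ed", "random"],
         "(b) broad-scale genetic diversity"),
    ]
    for ax, (threshold, methods, title) in zip(axes, panels):
        sub = curves[curves["threshold"] == threshold]
        for method in methods:
            grp = sub[sub["method"] == method]
            if grp.empty:
                continue
            mean = grp.groupby("k")["performance"].mean()
            ax.plot(mean.index, 100 * mean.to_numpy(), label=method)
        ax.set_xlabel("number of selected sites")
        ax.set_title(title)
        ax.legend(fontsize=7)
    axes[0].set_ylabel("performance (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "metrics": _stage_metrics,
    "surrogates": _stage_surrogates,
    "prioritize": _stage_prioritize,
    "evaluate": _stage_evaluate,
    "report": _stage_report,
}


def run_stage(stage: str, config: RunConfig) -> Path:
    """Run one pipeline stage against the run directory."""
    if stage not in _STAGE_FUNCS:
        raise GensurrError(f"unknown stage {stage!r}; choose from {STAGES}")
    _STAGE_FUNCS[stage](config)
    return _species_dir(config) / stage


def run_all(config: RunConfig) -> Path:
    """Run every stage in order; returns the species run directory."""
    for stage in STAGES:
        run_stage(stage, config)
    return _species_dir(config)
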
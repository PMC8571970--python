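"""End-to-end orchestration: meshes + metadata + tree in, statistics out.

The pipeline runs the full analysis sequence on a project directory:

1. read every PLY/OBJ mesh in the mesh directory and standardize it
   (decimate → smooth → decimate);
2. measure OPCR at the configured minimum patch sizes;
3. aggregate tooth-level values into per-taxon OPCRavg;
4. impute missing replacement rates (96-day ornithischian default rule);
5. prune data and tree to their common taxa;
6. run the configured statistics per dataset scope — the complete
   assemblage, the saurischian-analog subset (theropod + sauropod clades),
   and the sauropod-analog subset — at each threshold.

Analyses are isolated: a failure in one records an error status without
aborting the others (the mesh stage is expensive, the statistics are
cheap).  Every output table carries the seed, and no output embeds
wall-clock times, so a re-run with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .mesh import read_mesh, write_mesh
from .opcr import opcr_multi
from .phylo import PhyloTree, TraitVector, prune_to_common, read_newick, \
    write_newick
from .standardize import StandardizationConfig, standardize_tooth
from .stats import (
    TaxonSummary,
    aggregate_taxon,
    blomberg_k,
    default_imputation_rules,
    group_tests,
    impute_replacement_rates,
    kendall_test,
    pagel_lambda_signal,
    pearson_test,
    pgls_fit,
    phylo_anova,
    summaries_to_frame,
)
from .synthetic import AssemblageConfig, assemblage_tree, make_assemblage

logger = logging.getLogger("toothkit.pipeline")

__all__ = ["RunConfig", "StatsReport", "run_pipeline", "make_demo"]

#: dataset scopes, by the clades they retain (None = keep everything)
SCOPES: dict[str, set[str] | None] = {
    "all": None,
    "saurischian": {"theropod", "diplodocoid", "macronarian"},
    "sauropod": {"diplodocoid", "macronarian"},
}

ALL_ANALYSES = ("correlation", "signal", "pgls", "phylo_anova", "groups")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to JSON."""

    mesh_dir: str
    metadata_csv: str
    tree_file: str
    output_dir: str
    thresholds: tuple[int, ...] = (3, 5)
    analyses: tuple[str, ...] = ALL_ANALYSES
    iterations: int = 999
    seed: int = 0
    split_elements: bool = False
    log_rates: bool = False
    standardization: StandardizationConfig = field(
        default_factory=StandardizationConfig)

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ValueError("thresholds must be non-empty")
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")

    def to_file(self, path) -> None:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["analyses"] = list(self.analyses)
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        d["standardization"] = StandardizationConfig(**d["standardization"])
        d["thresholds"] = tuple(d["thresholds"])
        d["analyses"] = tuple(d["analyses"])
        return cls(**d)


@dataclass
class StatsReport:
    """Flat result rows plus provenance for one pipeline run.

    Each row carries ``analysis``, ``scope``, ``threshold``, ``n`` and
    ``status`` alongside the analysis-specific fields.
    """

    rows: list[dict]
    provenance: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_json(self) -> str:
        return json.dumps(
            {"provenance": self.provenance, "results": self.rows},
            indent=2, sort_keys=True, default=str,
        ) + "\n"

    def section(self, analysis: str) -> list[dict]:
        return [r for r in self.rows if r["analysis"] == analysis]


def _per_tooth_frame(results: list) -> pd.DataFrame:
    rows = []
    for res in results:
        row = {"mesh_name": res.mesh_name,
               "min_patch_size": res.min_patch_size}
        for k, c in enumerate(res.trial_counts):
            row[f"trial_{k}"] = c
        row["opcr"] = res.opcr
        rows.append(row)
    return pd.DataFrame(rows).sort_values(
        ["mesh_name", "min_patch_size"]).reset_index(drop=True)


def _scope_summaries(summaries: list[TaxonSummary], scope: str
                     ) -> list[TaxonSummary]:
    keep = SCOPES[scope]
    if keep is None:
        return list(summaries)
    return [s for s in summaries if s.clade in keep]


def _rate_values(summaries: list[TaxonSummary], log_rates: bool
                 ) -> dict[str, float]:
    out = {}
    for s in summaries:
        if s.replacement_rate_days is not None:
            out[s.taxon] = (np.log(s.replacement_rate_days) if log_rates
                            else s.replacement_rate_days)
    return out


def run_pipeline(config: RunConfig) -> StatsReport:
    """Execute the full analysis and persist every intermediate table.

    Writes ``per_tooth_opcr.csv``, ``taxon_summaries.csv``,
    ``stats_report.json`` and ``stats_report.csv`` under
    ``config.output_dir``.  Deterministic for a fixed config and seed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    mesh_dir = Path(config.mesh_dir)
    metadata = pd.read_csv(config.metadata_csv)
    tree = read_newick(config.tree_file)

    mesh_paths = sorted(
        p for p in mesh_dir.iterdir() if p.suffix.lower() in (".ply", ".obj")
    )
    if not mesh_paths:
        raise FileNotFoundError(f"no PLY/OBJ meshes in {mesh_dir}")
    if not set(metadata["taxon"]) & set(tree.tip_labels):
        raise ValueError("metadata and tree share no taxa; nothing to analyse")

    logger.info("stage standardize+opcr: %d meshes", len(mesh_paths))
    per_tooth = []
    for path in mesh_paths:
        mesh = read_mesh(path)
        std = standardize_tooth(mesh, config.standardization)
        results = opcr_multi(std, tuple(config.thresholds))
        per_tooth.extend(results.values())
    tooth_frame = _per_tooth_frame(per_tooth)
    tooth_frame.to_csv(outdir / "per_tooth_opcr.csv", index=False)

    logger.info("stage aggregate: %d tooth rows", len(tooth_frame))
    need_both = {3, 5} | set(config.thresholds)
    if not {3, 5} <= set(config.thresholds):
        # aggregation requires both canonical thresholds; measure the
        # missing one as well but report only configured ones downstream
        extra = sorted(need_both - set(config.thresholds))
        logger.info("measuring extra thresholds %s for aggregation", extra)
        for path in mesh_paths:
            mesh = read_mesh(path)
            std = standardize_tooth(mesh, config.standardization)
            per_tooth.extend(opcr_multi(std, tuple(extra)).values())
    summaries = aggregate_taxon(per_tooth, metadata,
                                split_elements=config.split_elements)
    summaries = impute_replacement_rates(
        summaries, default_imputation_rules(summaries))
    summaries_to_frame(summaries).to_csv(
        outdir / "taxon_summaries.csv", index=False)

    rows: list[dict] = []
    rng = np.random.default_rng(config.seed)
    for scope in SCOPES:
        scoped = _scope_summaries(summaries, scope)
        if len(scoped) < 3:
            continue
        rates = _rate_values(scoped, config.log_rates)
        for threshold in config.thresholds:
            opcr_of = {s.taxon: getattr(s, f"opcr_avg_{threshold}")
                       for s in scoped}
            base = {"scope": scope, "threshold": threshold}
            _run_scope_analyses(rows, base, config, tree, scoped, opcr_of,
                                rates, rng)

    report = StatsReport(
        rows=rows,
        provenance={
            "toothkit_version": __version__,
            "seed": config.seed,
            "iterations": config.iterations,
            "thresholds": list(config.thresholds),
            "n_meshes": len(mesh_paths),
            "standardization": dataclasses.asdict(config.standardization),
        },
    )
    (outdir / "stats_report.json").write_text(report.to_json())
    frame = report.to_frame()
    if len(frame):
        frame.to_csv(outdir / "stats_report.csv", index=False)
    return report


def _run_scope_analyses(rows: list[dict], base: dict, config: RunConfig,
                        tree: PhyloTree, scoped: list[TaxonSummary],
                        opcr_of: dict[str, float], rates: dict[str, float],
                        rng: np.random.Generator) -> None:
    """Run each configured analysis for one scope × threshold, isolated."""

    def record(analysis: str, **payload) -> None:
        rows.append({"analysis": analysis, **base, "status": "ok", **payload})

    def record_error(analysis: str, exc: Exception) -> None:
        logger.warning("analysis %s failed for %s: %s", analysis, base, exc)
        rows.append({"analysis": analysis, **base, "status": "error",
                     "error": str(exc)})

    rate_taxa = [t for t in opcr_of if t in rates]
    x_rate = np.array([rates[t] for t in rate_taxa])
    y_rate = np.array([opcr_of[t] for t in rate_taxa])
    dropped = sorted(set(opcr_of) - set(rate_taxa))
    if dropped:
        logger.info("scope %s: %d taxa lack replacement rates: %s",
                    base["scope"], len(dropped), dropped)

    if "correlation" in config.analyses:
        try:
            pr = pearson_test(x_rate, y_rate)
            kd = kendall_test(x_rate, y_rate)
            record("correlation", method="pearson", n=pr.n,
                   estimate=pr.estimate, statistic=pr.statistic, p=pr.p)
            record("correlation", method="kendall", n=kd.n,
                   estimate=kd.estimate, statistic=kd.statistic, p=kd.p)
        except Exception as exc:
            record_error("correlation", exc)

    # phylogenetic analyses need the tree pruned to scoped taxa
    try:
        trait_all = TraitVector(
            np.array(list(opcr_of.values())), list(opcr_of), units="PPT")
        ptree, trait_aligned, _ = prune_to_common(tree, trait_all)
    except Exception as exc:
        for analysis in ("signal", "pgls", "phylo_anova"):
            if analysis in config.analyses:
                record_error(analysis, exc)
        ptree = None

    if ptree is not None and "signal" in config.analyses:
        try:
            k = blomberg_k(ptree, trait_aligned, n_perm=config.iterations,
                           seed=int(rng.integers(0, 2**31 - 1)))
            record("signal", metric="blomberg_k", n=k.n, estimate=k.estimate,
                   p=k.p, n_perm=k.n_perm)
            lam = pagel_lambda_signal(ptree, trait_aligned)
            record("signal", metric="pagel_lambda", n=lam.n,
                   estimate=lam.estimate, p=lam.p)
        except Exception as exc:
            record_error("signal", exc)

    if ptree is not None and rate_taxa:
        try:
            trait_rate = TraitVector(x_rate, rate_taxa, units="days")
            rtree, rate_aligned, _ = prune_to_common(tree, trait_rate)
            y_aligned = TraitVector(
                np.array([opcr_of[t] for t in rtree.tip_labels]),
                rtree.tip_labels, units="PPT")
        except Exception as exc:
            rtree = None
            for analysis in ("pgls", "phylo_anova"):
                if analysis in config.analyses:
                    record_error(analysis, exc)
        if rtree is not None and "pgls" in config.analyses:
            for model in ("bm", "lambda", "ou"):
                try:
                    fit = pgls_fit(rtree, y_aligned, rate_aligned, model)
                    record("pgls", model=model, n=fit.n, slope=fit.slope,
                           intercept=fit.intercept, slope_se=fit.slope_se,
                           t=fit.t, p=fit.p, fitted_param=fit.fitted_param)
                except Exception as exc:
                    record_error(f"pgls[{model}]", exc)
        if rtree is not None and "phylo_anova" in config.analyses:
            try:
                an = phylo_anova(rtree, y_aligned, rate_aligned,
                                 iterations=config.iterations,
                                 seed=int(rng.integers(0, 2**31 - 1)))
                record("phylo_anova", F=an.F, p=an.p_perm, n=len(y_aligned.values),
                       iterations=an.iterations, df_effect=an.df_effect,
                       df_resid=an.df_resid)
            except Exception as exc:
                record_error("phylo_anova", exc)

    if "groups" in config.analyses:
        try:
            clades = [s.clade for s in scoped]
            values = [opcr_of[s.taxon] for s in scoped]
            rep = group_tests(values, clades, replicates=config.iterations,
                              seed=int(rng.integers(0, 2**31 - 1)))
            if "kruskal" in rep:
                record("groups", test="kruskal", n=len(values),
                       statistic=rep["kruskal"]["H"], p=rep["kruskal"]["p"])
            for (g1, g2), res in rep["pairwise"].items():
                record("groups", test="pairwise", pair=f"{g1}|{g2}",
                       n=len(values),
                       perm_t_p=res["perm_t"]["p"],
                       welch_p=res["perm_t"]["welch_p"],
                       mannwhitney_p=res["mannwhitney"]["p"],
                       ks_p=res["ks"]["p"])
        except Exception as exc:
            record_error("groups", exc)


# ---------------------------------------------------------------------------
# demo project
# ---------------------------------------------------------------------------

def make_demo(outdir, seed: int = 0, n_per_family: int = 2,
              teeth_per_taxon: int = 2, resolution: int = 3000,
              iterations: int = 499) -> RunConfig:
    """Write a ready-to-run example project: synthetic meshes, metadata,
    tree, and config.

    The default sizes keep a full ``run_pipeline`` on one CPU to a couple
    of minutes.  Deterministic per seed (byte-identical files).
    """
    outdir = Path(outdir)
    mesh_dir = outdir / "meshes"
    mesh_dir.mkdir(parents=True, exist_ok=True)
    teeth, metadata = make_assemblage(
        n_per_family, seed=seed,
        config=AssemblageConfig(teeth_per_taxon=teeth_per_taxon,
                                resolution=resolution),
    )
    for _, mesh in teeth:
        write_mesh(mesh, mesh_dir / f"{mesh.name}.ply")
    metadata.to_csv(outdir / "metadata.csv", index=False)
    tree = assemblage_tree(metadata)
    write_newick(tree, outdir / "tree.nwk")
    config = RunConfig(
        mesh_dir=str(mesh_dir),
        metadata_csv=str(outdir / "metadata.csv"),
        tree_file=str(outdir / "tree.nwk"),
        output_dir=str(outdir / "results"),
        iterations=iterations,
        seed=seed,
    )
    config.to_file(outdir / "config.json")
    return config
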
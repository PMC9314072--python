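"""End-to-end orchestration: filters, metrics, traits, models, null comparison.

One :func:`run_pipeline` call takes an MPM collection plus one phylogeny per
kingdom and produces, per kingdom: the filtered collection with its exclusion
log, the resilience and life-history tables, the three model fits
(phylogenetic signal per component, residual correlations, trait
regression), the random-MPM null comparison, and a manifest holding every
setting and seed needed to re-run the analysis bit-compatibly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import life_history, models, nullsim, phylo, resilience
from .mpm import FilterConfig, MPMCollection, filter_collection, read_collection

logger = logging.getLogger("demres")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    collection_path: str = ""
    tree_paths: dict = field(default_factory=dict)  # kingdom -> newick path
    output_dir: str = "demres_output"
    x_scalar: float = 10.0
    recovery_form: str = "textual"  # or "as-printed"
    include_state_in_signal: bool = True
    standardize_vcv: bool = True
    iterations: int = 8000
    warmup: int = 800
    chains: int = 4
    rhat_threshold: float = 1.01
    run_null: bool = True
    null_n_matrices: int = 1000
    seed: int = 0

    def model_config(self, offset: int = 0) -> models.ModelConfig:
        return models.ModelConfig(
            iterations=self.iterations,
            warmup=self.warmup,
            chains=self.chains,
            seed=self.seed + offset,
            rhat_threshold=self.rhat_threshold,
        )


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML key-value config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _stage(name: str):
    logger.info("stage: %s", name)


def metrics_tables(
    collection: MPMCollection, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resilience components joined with life-history traits."""
    res = resilience.compute_all(collection, config.x_scalar, config.recovery_form)
    traits = life_history.compute_traits(collection)
    merged = res.merge(
        traits.drop(columns=["matrix_dimension"]),
        on="population_id",
        suffixes=("", "_traits"),
    )
    merged["flags"] = (
        merged["flags"].fillna("") + ";" + merged["flags_traits"].fillna("")
    ).str.strip(";")
    merged = merged.drop(columns=["flags_traits"])
    return res, merged


def _fit_kingdom(
    table: pd.DataFrame,
    tree,
    config: PipelineConfig,
    outdir: Path,
    kingdom: str,
    manifest: dict,
) -> None:
    components = ["compensation", "resistance", "recovery_time"]
    usable = table.dropna(subset=components)
    usable = usable[(usable[components] > 0).all(axis=1)]
    dropped = len(table) - len(usable)
    if dropped:
        logger.info("%s: %d populations dropped for flagged/non-positive metrics", kingdom, dropped)
    if usable["species_name"].nunique() < 2:
        raise PipelineError(f"{kingdom}: fewer than 2 species with usable metrics")

    tree_b = phylo.resolve_polytomies(tree, seed=config.seed)
    pruned, vcv, aligned, dropped_names = phylo.match_tree_to_data(
        tree_b, usable, standardize=config.standardize_vcv
    )
    manifest[f"{kingdom}_dropped_species"] = dropped_names
    manifest[f"{kingdom}_n_populations"] = int(len(aligned))
    manifest[f"{kingdom}_n_species"] = int(aligned["species_name"].nunique())
    vcv.to_frame().to_csv(outdir / f"{kingdom}_vcv.csv")
    with open(outdir / f"{kingdom}_pruned_tree.nwk", "w") as fh:
        fh.write(pruned.as_string(schema="newick"))

    std = {c: models.preprocess_responses(aligned[c].to_numpy()) for c in components}
    species = aligned["species_name"].tolist()
    states = aligned["state_variable"].tolist()

    # phylogenetic signal, one model per component
    _stage(f"{kingdom}: phylogenetic signal models")
    signal_rows = []
    convergence = {}
    for i, comp in enumerate(components):
        post = models.fit_signal_model(
            std[comp], species, states, vcv, config.model_config(10 + i)
        )
        _, summary = models.phylogenetic_signal(post, config.include_state_in_signal)
        passed, rh = models.check_convergence(post)
        convergence[f"signal_{comp}"] = {"passed": bool(passed), "max_rhat": float(rh.max())}
        row = summary.loc["phylogeny"].to_dict()
        row.update({"component": comp, "max_rhat": float(rh.max()), "converged": bool(passed)})
        signal_rows.append(row)
        post.summary().to_csv(outdir / f"{kingdom}_signal_{comp}_posterior.csv")
    pd.DataFrame(signal_rows).set_index("component").to_csv(
        outdir / f"{kingdom}_phylogenetic_signal.csv"
    )

    # residual correlations among components
    _stage(f"{kingdom}: residual-correlation model")
    Y = np.column_stack([std[c] for c in components])
    post_rc, rc = models.fit_residual_correlation_model(
        Y, species, states, vcv, config.model_config(20)
    )
    passed, rh = models.check_convergence(post_rc)
    convergence["residual_correlations"] = {"passed": bool(passed), "max_rhat": float(rh.max())}
    rc.table.to_csv(outdir / f"{kingdom}_residual_correlations.csv")
    post_rc.summary().to_csv(outdir / f"{kingdom}_correlation_posterior.csv")

    # life-history regression on complete trait cases
    _stage(f"{kingdom}: life-history regression")
    complete = aligned.dropna(subset=["generation_time", "mean_reproductive_output"])
    complete = complete[complete["mean_reproductive_output"] > 0]
    manifest[f"{kingdom}_n_regression_cases"] = int(len(complete))
    if complete["species_name"].nunique() >= 2 and len(complete) >= 10:
        _, vcv_c, aligned_c, _ = phylo.match_tree_to_data(
            tree_b, complete, standardize=config.standardize_vcv
        )
        Yc = np.column_stack(
            [models.preprocess_responses(aligned_c[c].to_numpy()) for c in components]
        )
        G = models.preprocess_responses(aligned_c["generation_time"].to_numpy())
        R = models.preprocess_responses(aligned_c["mean_reproductive_output"].to_numpy())
        D = aligned_c["matrix_dimension"].to_numpy(float)
        D = (D - D.mean()) / (D.std(ddof=1) if D.std(ddof=1) > 0 else 1.0)
        post_reg = models.fit_lifehistory_model(
            Yc,
            G,
            R,
            D,
            aligned_c["species_name"].tolist(),
            aligned_c["state_variable"].tolist(),
            vcv_c,
            config.model_config(30),
        )
        passed, rh = models.check_convergence(post_reg)
        convergence["lifehistory_regression"] = {
            "passed": bool(passed),
            "max_rhat": float(rh.max()),
        }
        post_reg.summary().to_csv(outdir / f"{kingdom}_regression_posterior.csv")
    else:
        logger.warning("%s: too few complete trait cases for the regression", kingdom)
    manifest[f"{kingdom}_convergence"] = convergence
    if not all(c["passed"] for c in convergence.values()):
        manifest[f"{kingdom}_converged"] = False
        logger.warning("%s: at least one fit failed the Rhat gate; outputs marked non-passing", kingdom)
    else:
        manifest[f"{kingdom}_converged"] = True


def run_pipeline(config: PipelineConfig, collection: MPMCollection | None = None) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": []}

    _stage("read_collection")
    if collection is None:
        if not config.collection_path:
            raise PipelineError("read_collection: no collection or collection_path given")
        collection = read_collection(config.collection_path)
    manifest["n_input_records"] = len(collection)

    _stage("filter_collection")
    filtered, exclusions = filter_collection(collection, FilterConfig())
    exclusions.to_csv(outdir / "exclusions.csv", index=False)
    manifest["n_retained"] = len(filtered)
    manifest["n_excluded"] = int(len(exclusions))
    if len(filtered) == 0:
        raise PipelineError("filter_collection: no records retained")

    _stage("metrics")
    res, merged = metrics_tables(filtered, config)
    res.to_csv(outdir / "resilience.csv", index=False)
    merged.to_csv(outdir / "metrics.csv", index=False)

    for kingdom, tree_path in sorted(config.tree_paths.items()):
        tree = phylo.parse_newick(str(tree_path))
        sub = merged[merged["kingdom"] == kingdom]
        if sub.empty:
            logger.warning("no %s populations after filtering; skipping kingdom", kingdom)
            continue
        _fit_kingdom(sub, tree, config, outdir, kingdom, manifest)

    if config.run_null:
        _stage("null simulation")
        null_cfg = nullsim.NullSimConfig(
            n_matrices=config.null_n_matrices, seed=config.seed
        )
        null_table = nullsim.null_correlation_analysis(null_cfg)
        null_table.to_csv(outdir / "null_correlations.csv", index=False)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
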
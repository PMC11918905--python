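"""End-to-end pipeline: load/simulate -> standardize -> distances ->
networks -> densities -> stability regression, with a run manifest.

Every run writes its resolved configuration, the package version, and
SHA-256 hashes of all outputs into ``manifest.json`` so deterministic runs
can be verified byte-for-byte. Each stage consumes the previous stage's
in-memory product; the table outputs let any stage be re-run from cached
artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .distances import cohort_distances
from .network import (
    build_network,
    centrality,
    network_density,
    test_edges,
)
from .panel import PanelCohort, load_panel, standardize, write_panel
from .simulate import GeneratorConfig, generate
from .stability import (
    density_vs_stability,
    severity_trajectories,
    stability_profiles,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run."""

    output_dir: str = "panelwarp_run"
    scores_path: str | None = None  # None -> simulate
    covariates_path: str | None = None
    window: int = 1
    step_pattern: str = "symmetric2"
    metric: str = "absolute"
    alpha: float = 1e-4
    edge_mode: str = "adjusted"
    edge_adjust: str = "pair_mean"
    invert: str = "linear"
    group_by: str = "diagnosis"  # diagnosis | stability | none
    layout_seed: int = 7
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # GeneratorConfig overrides


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _grouping(cfg: PipelineConfig, profiles: pd.DataFrame) -> pd.Series:
    if cfg.group_by == "diagnosis":
        return profiles["subgroup"]
    if cfg.group_by == "stability":
        return profiles["stability_score"]
    if cfg.group_by == "none":
        return pd.Series("all", index=profiles.index)
    raise ValueError(f"unknown group_by {cfg.group_by!r}")


def run_pipeline(cfg: PipelineConfig, cohort: PanelCohort | None = None) -> dict:
    """Execute every stage and write the report bundle.

    Returns the manifest dictionary. A ``cohort`` may be passed directly
    (bypassing file input and simulation); otherwise the configured input
    files are loaded, or a synthetic cohort is generated when no input
    paths are set.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "stages": [],
        "outputs": {},
        "notes": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        if cohort is None:
            if cfg.scores_path is None:
                stage("simulate")
                gen = GeneratorConfig(seed=cfg.seed, **cfg.simulate)
                cohort, _truth = generate(gen)
            else:
                stage("load")
                if cfg.covariates_path is None or not Path(cfg.covariates_path).exists():
                    raise FileNotFoundError(
                        f"covariate file missing: {cfg.covariates_path}"
                    )
                cohort = load_panel(cfg.scores_path, cfg.covariates_path)
                manifest["notes"]["exclusions"] = cohort.exclusions

        stage("standardize")
        panel = standardize(cohort)
        write_panel(
            cohort,
            out / "panel_long.csv",
            out / "covariates.csv",
            z_scores=panel.z_scores,
        )
        manifest["notes"]["zero_variance_items"] = [
            cohort.catalog.item_ids[i]
            for i in np.flatnonzero(panel.zero_variance_items)
        ]

        stage("distances")
        table = cohort_distances(panel, window=cfg.window, metric=cfg.metric)
        table.to_csv(out / "distances_long.csv", index=False)

        stage("edges")
        manifest["notes"]["alpha"] = cfg.alpha
        manifest["notes"]["edge_mode"] = cfg.edge_mode
        manifest["notes"]["edge_adjust"] = cfg.edge_adjust
        edges = test_edges(
            table, alpha=cfg.alpha, mode=cfg.edge_mode, adjust=cfg.edge_adjust
        )
        edges.to_csv(out / "edges.csv", index=False)

        stage("centrality")
        reference = float(table["distance"].max())
        manifest["notes"]["inversion"] = {"mode": cfg.invert, "reference": reference}
        cents = centrality(table, edges, invert=cfg.invert, reference=reference)
        cents.to_csv(out / "centrality.csv", index=False)

        stage("networks")
        scales = {it.item_id: it.scale.value for it in cohort.catalog}
        whole = build_network(
            edges, cents, scales, alpha=cfg.alpha, seed=cfg.layout_seed
        )
        whole.to_graphml(out / "network_all.graphml")
        whole.to_json(out / "network_all.json")
        whole.node_table().to_csv(out / "nodes_all.csv", index=False)

        profiles = stability_profiles(cohort)
        profiles.to_csv(out / "stability.csv")
        grouping = _grouping(cfg, profiles)
        for g in sorted(map(str, grouping.unique())):
            members = grouping.index[grouping.astype(str) == g]
            sub_table = table[table["participant"].isin(members)]
            if sub_table["participant"].nunique() < 2:
                logger.warning("skipping subgroup %s with < 2 participants", g)
                continue
            sub_edges = test_edges(
                sub_table, alpha=cfg.alpha, mode=cfg.edge_mode, adjust=cfg.edge_adjust
            )
            sub_cents = centrality(
                sub_table, sub_edges, invert=cfg.invert, reference=reference
            )
            sub_net = build_network(
                sub_edges, sub_cents, scales, layout_source=whole,
                alpha=cfg.alpha, group=g,
            )
            sub_net.to_json(out / f"network_{g}.json")

        stage("density")
        estimates, comparisons, densities = network_density(
            table,
            cohort.covariates,
            grouping,
            invert=cfg.invert,
            reference=reference,
        )
        pd.DataFrame(
            [
                {
                    "group": e.group,
                    "adjusted_density": e.adjusted_density,
                    "se": e.standard_error,
                    "n": e.n_participants,
                }
                for e in estimates
            ]
        ).to_csv(out / "density.csv", index=False)
        comparisons.to_csv(out / "density_comparisons.csv", index=False)

        stage("trajectories")
        severity_trajectories(cohort, grouping).to_csv(
            out / "trajectories.csv", index=False
        )

        stage("stability_regression")
        severity = (
            table.set_index("participant")["pair_mean_raw"].groupby(level=0).mean()
        )
        try:
            qfit = density_vs_stability(
                densities, profiles, cohort.covariates, severity
            )
            fit_payload = {
                "beta_linear": qfit.beta_linear,
                "beta_quadratic": qfit.beta_quadratic,
                "p_linear": qfit.p_linear,
                "p_quadratic": qfit.p_quadratic,
                "scheme": qfit.scheme,
            }
            qfit.adjusted_means.to_csv(out / "density_by_stability.csv")
        except ValueError as exc:  # e.g. < 3 distinct scores
            logger.warning("stability regression skipped: %s", exc)
            fit_payload = {"skipped": str(exc)}
        (out / "quadratic_fit.json").write_text(json.dumps(fit_payload, indent=1))

    except Exception as exc:
        failed_stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        manifest["failed_stage"] = failed_stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline failed at stage {failed_stage!r}: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
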
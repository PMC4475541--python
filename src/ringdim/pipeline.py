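"""End-to-end orchestration: simulate/read -> normalize -> RV -> CCSWA ->
selection -> network, with a deterministic report bundle on disk.

The report bundle mirrors the tables a ring-trial report is built from:
features retained per instrument, component-selected features and their
overlap with the reference selection, average RV links within and between
technologies, and per-block saliences, plus Cytoscape-loadable network
files.  All outputs are plain text (CSV/YAML/JSON/GraphML/SIF) and byte
-identical across runs with the same configuration and seed.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .blocks import BlockSet
from .ccswa import (
    ComDimModel,
    SeparationResult,
    barycentre_projection,
    explained_variance,
    fit_ccswa,
    score_group_separation,
)
from .errors import ConfigError, PipelineError
from .network import auto_cutoff, build_rv_network, export_network
from .preprocess import (
    align_blocks,
    normalize_blockset,
    read_blocks_from_manifest,
    read_metadata,
    write_feature_table,
)
from .rv import LinkSummary, RVMatrix, average_links, pairwise_permutation_nulls, rv_matrix
from .selection import (
    OverlapResult,
    SelectionResult,
    cc_feature_correlations,
    select_by_threshold,
    selection_overlap,
)
from .simulate import RingStudyConfig, SimTruth, simulate_ring_study

logger = logging.getLogger("ringdim")

_FLOAT_FMT = "%.10g"


def load_config(path: str | Path) -> dict:
    """Load a pipeline configuration from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ConfigError(f"{path}: pipeline config must be a mapping")
    return dict(config)


def bundled_config(name: str) -> dict:
    """Load one of the packaged study configurations (e.g. ``"test1_like"``)."""
    ref = importlib.resources.files("ringdim") / "configs" / f"{name}.yaml"
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ConfigError(f"no bundled config named {name!r}") from None
    return yaml.safe_load(text)


@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline computed."""

    blockset: BlockSet
    preprocessed: BlockSet
    truth: SimTruth | None
    rvm: RVMatrix
    nulls: pd.DataFrame | None
    links: LinkSummary
    model: ComDimModel
    separation: SeparationResult
    selection_component: int
    selections: dict[str, SelectionResult]
    overlaps: dict[str, OverlapResult]
    cutoff: float
    graph: object
    summary: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    """Decorator: re-raise stage failures with the stage named."""

    def wrap(func):
        def inner(*args, **kwargs):
            try:
                return func(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return inner

    return wrap


@_stage("inputs")
def _load_inputs(config: Mapping, seed: int | None, outdir: Path):
    if "simulate" in config:
        sim_conf = RingStudyConfig.from_dict(config["simulate"])
        blockset, truth = simulate_ring_study(sim_conf, seed=seed)
        _write_simulation(outdir / "simulation", blockset, truth)
        return blockset, truth
    if "inputs" in config:
        inputs = config["inputs"]
        blocks = read_blocks_from_manifest(inputs["manifest"])
        metadata = read_metadata(inputs["metadata"]) if "metadata" in inputs else None
        return align_blocks(blocks, metadata), None
    raise ConfigError("config needs a 'simulate' or an 'inputs' section")


def _write_simulation(outdir: Path, blockset: BlockSet, truth: SimTruth) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for block in blockset:
        rel = Path("blocks") / f"{block.instrument_id}.csv"
        write_feature_table(block, outdir / rel)
        manifest.append(
            {
                "instrument_id": block.instrument_id,
                "technology": block.technology,
                "ion_mode": block.ion_mode,
                "n_features": block.n_features,
                "path": rel.as_posix(),
            }
        )
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"blocks": manifest}, fh, sort_keys=True)
    blockset.metadata.to_csv(outdir / "metadata.csv", float_format=_FLOAT_FMT)
    design = truth.design
    payload = {
        "sample_ids": design.sample_ids,
        "individual_ids": design.individual_ids,
        "group_labels": design.group_labels,
        "factor_names": design.factor_names,
        "contrast": design.contrast,
        "paired_spike": design.paired_spike,
        "outlier_individuals": design.outlier_individuals,
        "dilution_factors": [float(d) for d in design.dilution_factors],
        "specific_gravity": [float(s) for s in design.specific_gravity],
        "sg_reference": design.sg_reference,
        "spike_features": truth.spike_features,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def _group_aligned_component(model: ComDimModel, labels: pd.Series) -> int:
    """0-based index of the component most correlated with the group contrast."""
    uniq = sorted(set(labels))
    g = np.asarray([1.0 if l == uniq[-1] else -1.0 for l in labels])
    g = g - g.mean()
    best, best_val = 0, -1.0
    for a in range(model.n_components):
        q = model.scores[:, a]
        val = abs(float(q @ g)) / (np.linalg.norm(q) * np.linalg.norm(g))
        if val > best_val:
            best, best_val = a, val
    return best


def run_pipeline(
    config: Mapping | str | Path,
    outdir: str | Path,
    seed: int | None = None,
) -> PipelineResult:
    """Run the whole analysis and write the report bundle under ``outdir``.

    ``seed`` overrides the configuration's seed; it drives the simulation,
    the RV permutation nulls and the group-separation permutation test
    through independently spawned child seeds.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    master = seed if seed is not None else config.get("seed")
    if master is None:
        raise ConfigError("a seed is required (config key 'seed' or the argument)")
    children = np.random.SeedSequence(master).spawn(3)
    sim_seed, null_seed, perm_seed = (
        int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children
    )

    blockset, truth = _load_inputs(config, sim_seed, outdir)
    logger.info("inputs: %d blocks x %d samples", len(blockset), blockset.n_samples)

    # --- preprocess -------------------------------------------------------
    pconf = dict(config.get("preprocess", {}))
    prep = _stage("preprocess")(normalize_blockset)(
        blockset,
        method=pconf.get("normalize", "none"),
        sg_reference=pconf.get("sg_reference"),
        istd_feature=pconf.get("istd_feature"),
        scale=pconf.get("scale", "unit_block_variance"),
    )

    # --- RV statistics ----------------------------------------------------
    rconf = dict(config.get("rv", {}))
    variant = rconf.get("variant", "classic")
    rvm = _stage("rv")(rv_matrix)(prep, variant=variant)
    n_perm = int(rconf.get("permutations", 0))
    nulls = None
    if n_perm:
        nulls = _stage("rv")(pairwise_permutation_nulls)(
            prep, n_perm=n_perm, seed=null_seed, variant=variant
        )
    technologies = {b.instrument_id: b.technology for b in blockset}
    links = _stage("rv")(average_links)(rvm, technologies)

    rv_dir = outdir / "rv"
    rv_dir.mkdir(exist_ok=True)
    rvm.to_frame().to_csv(rv_dir / "rv_matrix.csv", float_format=_FLOAT_FMT)
    if nulls is not None:
        nulls.to_csv(rv_dir / "rv_nulls.csv", index=False, float_format=_FLOAT_FMT)
    links.per_block.to_csv(rv_dir / "link_summary.csv", float_format=_FLOAT_FMT)

    # --- CCSWA ------------------------------------------------------------
    cconf = dict(config.get("ccswa", {}))
    model = _stage("ccswa")(fit_ccswa)(
        prep,
        n_components=int(cconf.get("n_components", 4)),
        tol=float(cconf.get("tol", 1e-10)),
        max_iter=int(cconf.get("max_iter", 500)),
    )
    labels = blockset.metadata["group"] if "group" in blockset.metadata else None
    if labels is None:
        raise PipelineError("ccswa", ConfigError("metadata lacks a 'group' column"))
    group_cc = _group_aligned_component(model, labels)
    separation = _stage("ccswa")(score_group_separation)(
        model,
        labels,
        component=group_cc,
        n_perm=int(cconf.get("separation_permutations", 199)),
        seed=perm_seed,
    )
    projection = _stage("ccswa")(barycentre_projection)(model, prep)

    cc_dir = outdir / "ccswa"
    cc_dir.mkdir(exist_ok=True)
    scores = model.scores_frame()
    scaled = model.scaled_scores_frame().add_suffix("_scaled")
    pd.concat([scores, scaled], axis=1).to_csv(
        cc_dir / "global_scores.csv", float_format=_FLOAT_FMT, index_label="sample_id"
    )
    explained_variance(model).to_csv(
        cc_dir / "saliences.csv", float_format=_FLOAT_FMT, index_label="block_id"
    )
    pd.DataFrame(model.convergence).to_csv(
        cc_dir / "convergence.csv", index=False, float_format=_FLOAT_FMT
    )
    bary = pd.DataFrame(
        projection.barycentre, index=model.sample_ids,
        columns=[f"{c}_barycentre" for c in model.component_names()],
    )
    disp = pd.DataFrame(
        projection.dispersion, index=model.sample_ids,
        columns=[f"{c}_dispersion" for c in model.component_names()],
    )
    pd.concat([bary, disp], axis=1).to_csv(
        cc_dir / "projections.csv", float_format=_FLOAT_FMT, index_label="sample_id"
    )

    # --- feature selection --------------------------------------------------
    sconf = dict(config.get("selection", {}))
    comp_conf = sconf.get("component", "auto")
    sel_component = group_cc if comp_conf == "auto" else int(comp_conf) - 1
    rule_conf = sconf.get("rule", "auto")
    threshold = sconf.get("threshold")

    selections: dict[str, SelectionResult] = {}
    overlaps: dict[str, OverlapResult] = {}
    sel_rows = []
    for raw, block in zip(blockset, prep):
        corr = _stage("selection")(cc_feature_correlations)(block, model, sel_component)
        rule = rule_conf
        if rule == "auto":  # NMR convention: z-scores; LC-MS: absolute r
            rule = "zscore" if raw.technology == "NMR" else "abs_r"
        sel = _stage("selection")(select_by_threshold)(corr, rule=rule, threshold=threshold)
        selections[block.instrument_id] = sel
        if truth is not None and truth.spike_features.get(block.instrument_id):
            overlaps[block.instrument_id] = selection_overlap(
                sel, truth.spike_features[block.instrument_id]
            )
        frame = pd.DataFrame(
            {
                "block_id": block.instrument_id,
                "feature_id": sel.correlations.index,
                "correlation": sel.correlations.to_numpy(),
                "selected": sel.correlations.index.isin(sel.selected),
            }
        )
        if sel.zscores is not None:
            frame["zscore"] = sel.zscores.to_numpy()
        sel_rows.append(frame)

    sel_dir = outdir / "selection"
    sel_dir.mkdir(exist_ok=True)
    pd.concat(sel_rows, ignore_index=True).to_csv(
        sel_dir / "selections.csv", index=False, float_format=_FLOAT_FMT
    )

    # --- network ------------------------------------------------------------
    nconf = dict(config.get("network", {}))
    cutoff_conf = nconf.get("cutoff", "auto")
    if cutoff_conf == "auto":
        cutoff = _stage("network")(auto_cutoff)(
            rvm, allowed_isolated=int(nconf.get("allowed_isolated", 0))
        )
    else:
        cutoff = float(cutoff_conf)
    graph = _stage("network")(build_rv_network)(rvm, cutoff, blocks=blockset)
    net_paths = _stage("network")(export_network)(graph, outdir / "network")

    # --- summary ------------------------------------------------------------
    summary = {
        "n_samples": blockset.n_samples,
        "blocks": [
            {
                "instrument_id": b.instrument_id,
                "technology": b.technology,
                "ion_mode": b.ion_mode,
                "n_features": b.n_features,
            }
            for b in blockset
        ],
        "rv": {
            "variant": variant,
            "within_technology": {k: round(v, 6) for k, v in links.within.items()},
            "between_technology": {
                f"{a}|{b}": round(v, 6) for (a, b), v in links.between.items()
            },
        },
        "ccswa": {
            "n_components": model.n_components,
            "group_component": f"CC{group_cc + 1}",
            "separation_statistic": round(separation.statistic, 6),
            "separation_p_value": round(separation.p_value, 6),
            "group_separating": separation.p_value <= 0.01,
            "saliences": {
                b: [round(float(v), 6) for v in row]
                for b, row in zip(model.block_ids, model.saliences)
            },
        },
        "selection": {
            "component": f"CC{sel_component + 1}",
            "per_block": {
                bid: {
                    "rule": sel.rule,
                    "threshold": sel.threshold,
                    "n_selected": sel.n_selected,
                    **(
                        {
                            "n_reference": overlaps[bid].n_b,
                            "n_shared": overlaps[bid].n_shared,
                            "percent_shared": (
                                None
                                if overlaps[bid].percent_shared is None
                                else round(overlaps[bid].percent_shared, 2)
                            ),
                        }
                        if bid in overlaps
                        else {}
                    ),
                }
                for bid, sel in selections.items()
            },
        },
        "network": {
            "cutoff": round(cutoff, 6),
            "n_edges": graph.number_of_edges(),
            "isolated_nodes": sorted(n for n in graph.nodes if graph.degree(n) == 0),
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    paths = {
        "summary": outdir / "summary.json",
        "rv_matrix": rv_dir / "rv_matrix.csv",
        "saliences": cc_dir / "saliences.csv",
        "selections": sel_dir / "selections.csv",
        **{f"network_{k}": v for k, v in net_paths.items()},
    }
    return PipelineResult(
        blockset=blockset,
        preprocessed=prep,
        truth=truth,
        rvm=rvm,
        nulls=nulls,
        links=links,
        model=model,
        separation=separation,
        selection_component=sel_component,
        selections=selections,
        overlaps=overlaps,
        cutoff=cutoff,
        graph=graph,
        summary=summary,
        paths=paths,
    )
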
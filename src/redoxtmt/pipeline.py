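"""End-to-end orchestration of the analysis stages.

Realizes the full workflow: (optional) synthetic-data generation ->
reading -> impurity correction -> site rollup -> mix-internal fold changes
-> replicate filter -> median normalization -> PTM-to-protein
normalization -> TMT1 sign inversion -> one-sample t-test with BH ->
enrichment -> cross-timepoint dynamics -> overlap -> annotation, writing
every intermediate table plus a run manifest with parameters, seed and
output checksums.  Re-running with the same config and seed reproduces
byte-identical tables.

Within a layer/time point the chain normalizes PTM sites to their parent
protein *before* inverting the TMT1-derived layer: the free-thiol signal
scales with protein abundance the same way the proteome does, so the
abundance component must be subtracted on the un-inverted scale for a pure
abundance change to cancel exactly; inversion then flips only the genuine
oxidation component.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Any, Mapping

import pandas as pd

from . import io as rio
from .annotation import annotate_sites
from .differential import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_REPLICATES,
    compute_fold_changes,
    filter_min_replicates,
    invert_overall_oxidation,
    median_normalize,
    normalize_site_to_protein,
    summarize_counts,
    test_differential,
)
from .dynamics import (
    correlate_timepoints,
    dynamics_table,
    overlap_multiply_modified,
    venn_counts,
)
from .enrichment import enrich, integrative_enrich, map_compartments, map_to_genes
from .model import (
    ANALYSIS_LAYERS,
    PTM_LAYERS,
    FoldChangeMatrix,
    SampleDesign,
    ValidationError,
)
from .quantification import ImpurityMatrix, correct_impurities, rollup_sites
from .simulate import SimulationConfig, SimulatedExperiment, simulate, truth_report

log = logging.getLogger(__name__)


def parse_config(path: str) -> dict[str, str]:
    """Parse a flat ``key = value`` config file (# starts a comment)."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path} line {i + 1}: expected key = value")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def simulation_config_from_mapping(
    params: Mapping[str, str], seed: int
) -> SimulationConfig:
    """Build a SimulationConfig from flat string params (``sim_`` prefix)."""
    kwargs: dict[str, Any] = {"seed": seed}
    valid = {f.name: f.type for f in dataclasses.fields(SimulationConfig)}
    for key, value in params.items():
        if not key.startswith("sim_"):
            continue
        name = key[4:]
        if name not in valid:
            raise ValidationError(f"unknown simulation parameter {name!r}")
        default = getattr(SimulationConfig, name)
        if isinstance(default, bool):
            kwargs[name] = value.lower() in ("1", "true", "yes")
        elif isinstance(default, int):
            kwargs[name] = int(value)
        elif isinstance(default, float):
            kwargs[name] = float(value)
        elif isinstance(default, tuple):
            parts = [p.strip() for p in value.split(",") if p.strip()]
            elem = type(default[0]) if default else str
            kwargs[name] = tuple(elem(p) for p in parts)
        else:
            kwargs[name] = value
    return SimulationConfig(**kwargs)


def differential_chain(
    fc: FoldChangeMatrix,
    protein_fc: FoldChangeMatrix | None,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[FoldChangeMatrix, pd.DataFrame]:
    """Filter, normalize and test one layer's fold changes.

    ``protein_fc`` must be the (median-normalized) proteome fold changes
    for PTM layers and None for the proteome itself.  Returns the final
    fold-change matrix and the differential result table.
    """
    fc = filter_min_replicates(fc, min_replicates)
    fc = median_normalize(fc)
    if fc.layer in PTM_LAYERS:
        if protein_fc is None:
            raise ValidationError(
                f"{fc.layer}: PTM-to-protein normalization requires proteome "
                "fold changes"
            )
        fc = normalize_site_to_protein(fc, protein_fc)
        fc = filter_min_replicates(fc, min_replicates)
    if fc.layer == "ox_all":
        fc = invert_overall_oxidation(fc)
    return fc, test_differential(fc, alpha=alpha)


def differential_stage(
    tables: Mapping[str, Any],
    design: SampleDesign,
    impurity: ImpurityMatrix | None = None,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[dict, dict, dict]:
    """Impurity correction, rollup and per-layer differential testing.

    Returns (quant matrices by layer, fold-change matrices by (layer, tp),
    differential results by (layer, tp)).
    """
    layers = [
        layer for layer in ANALYSIS_LAYERS
        if len(design.for_layer(layer)) > 0
        and design.for_layer(layer)["layer"].iloc[0] in tables
    ]
    if any(l in PTM_LAYERS for l in layers) and "proteome" not in layers:
        raise ValidationError(
            "PTM layers require the proteome layer for normalization"
        )
    if impurity is not None:
        tables = {
            name: correct_impurities(t, impurity) for name, t in tables.items()
        }
    quant = {}
    for layer in layers:
        table_layer = design.for_layer(layer)["layer"].iloc[0]
        quant[layer] = rollup_sites(tables[table_layer], design, layer)
    fold_changes: dict[tuple[str, str], FoldChangeMatrix] = {}
    differential: dict[tuple[str, str], pd.DataFrame] = {}
    for tp in design.timepoints:
        protein_fc = None
        if "proteome" in layers:
            raw = compute_fold_changes(quant["proteome"], design, tp)
            protein_fc = median_normalize(
                filter_min_replicates(raw, min_replicates)
            )
            fold_changes[("proteome", tp)] = protein_fc
            differential[("proteome", tp)] = test_differential(
                protein_fc, alpha=alpha
            )
        for layer in layers:
            if layer == "proteome":
                continue
            raw = compute_fold_changes(quant[layer], design, tp)
            fc, res = differential_chain(raw, protein_fc, min_replicates, alpha)
            fold_changes[(layer, tp)] = fc
            differential[(layer, tp)] = res
    return quant, fold_changes, differential


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _fc_frame(fc: FoldChangeMatrix) -> pd.DataFrame:
    out = fc.values.copy()
    out.columns = [f"r{run}.{rep}" for run, rep in out.columns]
    out.insert(0, "entity", out.index)
    return out.reset_index(drop=True)


class PipelineResult:
    """Handles to everything a pipeline run computed and wrote."""

    def __init__(self, out_dir: str):
        self.out_dir = out_dir
        self.fold_changes: dict[tuple[str, str], FoldChangeMatrix] = {}
        self.differential: dict[tuple[str, str], pd.DataFrame] = {}
        self.enrichment: dict[tuple[str, str], pd.DataFrame] = {}
        self.dynamics: pd.DataFrame | None = None
        self.overlap: dict[str, pd.DataFrame] = {}
        self.counts: pd.DataFrame | None = None
        self.recovery: pd.DataFrame | None = None
        self.manifest: dict[str, Any] = {}


def run_pipeline(
    config: Mapping[str, str] | str,
    out_dir: str,
    seed: int = 0,
) -> PipelineResult:
    """Execute the full workflow described in the module docstring.

    ``config`` is a flat key-value mapping (or path to one).  With
    ``simulate = true`` all inputs are generated under ``out/inputs``;
    otherwise ``design`` / ``peptides_<layer>`` / ``gene_sets`` /
    ``mapping`` / ``annotations`` / ``impurity`` keys name input files.
    """
    if isinstance(config, str):
        config = parse_config(config)
    params = dict(config)
    min_replicates = int(params.get("min_replicates", DEFAULT_MIN_REPLICATES))
    alpha = float(params.get("alpha", DEFAULT_ALPHA))
    do_simulate = params.get("simulate", "false").lower() in ("1", "true", "yes")
    use_impurity = params.get("impurity_correction", "true").lower() in (
        "1", "true", "yes",
    )

    os.makedirs(out_dir, exist_ok=True)
    result = PipelineResult(out_dir)
    written: list[str] = []

    def save(frame: pd.DataFrame, name: str) -> None:
        path = os.path.join(out_dir, name)
        rio.write_table(frame, path)
        written.append(path)

    experiment: SimulatedExperiment | None = None
    if do_simulate:
        sim_config = simulation_config_from_mapping(params, seed)
        experiment = simulate(sim_config)
        inputs = os.path.join(out_dir, "inputs")
        experiment.write(inputs)
        design = experiment.design
        tables = experiment.tables
        impurity = experiment.impurity
        gene_sets = experiment.gene_sets
        go_cc = experiment.go_cc
        mapping = experiment.mapping
        annotations = experiment.annotations
    else:
        design = rio.read_design(params["design"])
        tables = {}
        for layer in ("proteome", "redoxome", "phospho"):
            key = f"peptides_{layer}"
            if key in params:
                tables[layer] = rio.read_peptide_table(params[key], design)
        gene_sets = rio.read_gmt(params["gene_sets"]) if "gene_sets" in params else None
        go_cc = rio.read_gmt(params["go_cc"]) if "go_cc" in params else None
        mapping = rio.read_mapping(params["mapping"]) if "mapping" in params else {}
        annotations = (
            rio.read_annotations(params["annotations"])
            if "annotations" in params else None
        )
        impurity = (
            ImpurityMatrix.from_tsv(params["impurity"])
            if "impurity" in params else None
        )

    timepoints = design.timepoints
    _, fold_changes, differential = differential_stage(
        tables,
        design,
        impurity=impurity if use_impurity else None,
        min_replicates=min_replicates,
        alpha=alpha,
    )
    result.fold_changes = fold_changes
    result.differential = differential
    layers = list(dict.fromkeys(layer for layer, _ in differential))
    for (layer, tp), fc in fold_changes.items():
        save(_fc_frame(fc), f"fold_changes_{layer}_{tp}.tsv")
        save(differential[(layer, tp)], f"differential_{layer}_{tp}.tsv")

    all_res = pd.concat(result.differential.values(), ignore_index=True)
    result.counts = summarize_counts(all_res)
    save(result.counts, "significant_counts.tsv")

    # --- enrichment ----------------------------------------------------------
    if gene_sets is not None and mapping:
        for tp in timepoints:
            scopes: dict[str, list[str]] = {layer: [layer] for layer in layers}
            if "ox_all" in layers and "ox_rev" in layers:
                scopes["ox_combined"] = ["ox_all", "ox_rev"]
            for scope, members in scopes.items():
                sig: set[str] = set()
                universe: set[str] = set()
                gene_fc: dict[str, list[float]] = {}
                for layer in members:
                    res = result.differential[(layer, tp)]
                    universe |= map_to_genes(res["entity"], mapping)
                    sig_rows = res[res["significant"]]
                    sig |= map_to_genes(sig_rows["entity"], mapping)
                    for entity, value in zip(
                        sig_rows["entity"], sig_rows["log2fc_mean"]
                    ):
                        for g in map_to_genes([entity], mapping):
                            gene_fc.setdefault(g, []).append(float(value))
                if not universe:
                    continue
                enr = enrich(
                    sig, universe, gene_sets, gene_fc or None,
                    alpha=alpha, layer_scope=scope,
                )
                result.enrichment[(scope, tp)] = enr
                save(enr, f"enrichment_{scope}_{tp}.tsv")
            if len(layers) >= 2:
                per_sig = {
                    layer: set(
                        result.differential[(layer, tp)].loc[
                            result.differential[(layer, tp)]["significant"],
                            "entity",
                        ]
                    )
                    for layer in layers
                }
                per_uni = {
                    layer: set(result.differential[(layer, tp)]["entity"])
                    for layer in layers
                }
                per_fc = {
                    layer: dict(
                        zip(
                            result.differential[(layer, tp)]["entity"],
                            result.differential[(layer, tp)]["log2fc_mean"],
                        )
                    )
                    for layer in layers
                }
                enr = integrative_enrich(
                    per_sig, per_uni, gene_sets, mapping, per_fc, alpha=alpha
                )
                result.enrichment[("integrative", tp)] = enr
                save(enr, f"enrichment_integrative_{tp}.tsv")
        if go_cc is not None:
            sig_entities = sorted(set(all_res.loc[all_res["significant"], "entity"]))
            if sig_entities:
                save(
                    map_compartments(sig_entities, go_cc, mapping),
                    "compartments.tsv",
                )

    # --- dynamics and overlap ------------------------------------------------
    if len(timepoints) >= 2:
        early, late = timepoints[0], timepoints[1]
        dyn = []
        for layer in layers:
            for subset in ("significant", "not_affected"):
                dyn.append(
                    correlate_timepoints(
                        result.differential[(layer, early)],
                        result.differential[(layer, late)],
                        subset=subset,
                    )
                )
        result.dynamics = dynamics_table(dyn)
        save(result.dynamics, "dynamics.tsv")

    if {"proteome", "phospho"} <= set(layers) and (
        "ox_all" in layers or "ox_rev" in layers
    ):
        for tp in timepoints:
            ox_parts = [
                result.differential[(l, tp)]
                for l in ("ox_all", "ox_rev") if l in layers
            ]
            overlap = overlap_multiply_modified(
                result.differential[("proteome", tp)],
                pd.concat(ox_parts, ignore_index=True),
                result.differential[("phospho", tp)],
            )
            result.overlap[tp] = overlap
            save(overlap, f"overlap_{tp}.tsv")
            save(venn_counts(overlap), f"venn_counts_{tp}.tsv")

    # --- annotation -----------------------------------------------------------
    if annotations is not None:
        for layer in ("ox_all", "ox_rev"):
            for tp in timepoints:
                if (layer, tp) in result.differential:
                    save(
                        annotate_sites(result.differential[(layer, tp)], annotations),
                        f"annotated_{layer}_{tp}.tsv",
                    )

    # --- recovery report (simulated runs) -------------------------------------
    if experiment is not None:
        per_layer = {}
        for layer in layers:
            per_layer[layer] = pd.concat(
                [result.differential[(layer, tp)] for tp in timepoints],
                ignore_index=True,
            )
        result.recovery = truth_report(experiment.truth, per_layer)
        save(result.recovery, "recovery_report.tsv")

    manifest = {
        "seed": seed,
        "parameters": {**params, "min_replicates": min_replicates, "alpha": alpha},
        "layers": layers,
        "timepoints": list(timepoints),
        "outputs": {
            os.path.relpath(p, out_dir): _sha256(p) for p in sorted(written)
        },
    }
    result.manifest = manifest
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
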
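"""Synthetic multi-layer TMT experiments with known ground truth.

The generator emulates the study design the analysis assumes: 3 LC-MS runs
of 4 biological replicates (12 replicates), two time points (4 h / 24 h of
LPS exposure), treated and control samples multiplexed into the same TMT
mix, and — for the redoxome — sequential iodoTMT labeling where each
sample occupies a TMT1 (free thiol) and a TMT2 (reversibly oxidized thiol)
channel of its mix.

Measurement model, per biological sample (all intensities in arbitrary
reporter-ion units):

* proteome peptide:   abundance x peptide efficiency
* redox TMT1 channel: abundance x efficiency x sum over the peptide's
  cysteines of (1 - oxidized fraction)
* redox TMT2 channel: abundance x efficiency x sum of oxidized fractions
* phospho peptide:    abundance x efficiency x site occupancy

Treatment multiplies abundance by 2^delta_protein and the oxidized
fraction / occupancy by 2^delta_site for affected entities (fractions are
drawn so the scaled value stays below 1; no clipping, which keeps the
noise-free model exactly invertible).  Multiplicative log-normal noise is
added per (peptide, channel), whole peptide rows go missing per mix
completely at random, and forward isotope-impurity mixing is applied so
the correction step has real work to do.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as rio
from .model import (
    DESIGN_COLUMNS,
    GeneSetCollection,
    PeptideTable,
    SampleDesign,
    SiteAnnotationTable,
    ValidationError,
)
from .quantification import ImpurityMatrix

CHANNELS = ["126", "127", "128", "129"]

_AA = np.array(list("ADEFGHIKLNPQRSVWY"))  # no C/M/T/S ambiguity needed


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and effect-model parameters of the generator.

    Defaults mirror the emulated experiment (3 runs x 4 replicates, two
    time points) at desk scale; effect sizes are log2 units.
    """

    seed: int = 0
    n_proteins: int = 500
    n_runs: int = 3
    replicates_per_run: int = 4
    timepoints: tuple[str, ...] = ("4h", "24h")
    layers: tuple[str, ...] = ("proteome", "redoxome", "phospho")
    peptides_per_protein: float = 3.0  # Poisson mean, floor 1
    cys_sites_per_protein: float = 1.2  # Poisson mean
    phospho_sites_per_protein: float = 1.0  # Poisson mean
    peptides_per_site: float = 1.5  # Poisson mean, floor 1
    multi_cys_fraction: float = 0.15  # chance a cys peptide carries a 2nd site
    base_abundance_mean_log2: float = 20.0
    base_abundance_sd_log2: float = 2.0
    peptide_efficiency_sd_log2: float = 1.0
    noise_sd: float = 0.2  # log2 sd per (peptide, channel)
    missing_rate: float = 0.05  # whole peptide row per mix, MCAR
    protein_effect_fraction: float = 0.1
    ox_effect_fraction: float = 0.1
    phospho_effect_fraction: float = 0.1
    effect_size: float = 1.0  # |delta|, log2
    ox_fraction_range: tuple[float, float] = (0.05, 0.6)
    phospho_occupancy_range: tuple[float, float] = (0.05, 0.5)
    impurity_bleed: float = 0.02  # nearest-neighbour channel bleed
    n_gene_sets: int = 30
    gene_set_size: int = 25
    planted_set_effect_prob: float = 0.0  # >0 plants one enriched pathway
    annotation_fraction: float = 0.3
    disulfide_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("missing_rate",):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValidationError(f"{name} must be in [0, 1), got {v}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_proteins < 1:
            raise ValidationError("need at least one protein")
        lo, hi = self.ox_fraction_range
        if not (0 < lo < hi < 1):
            raise ValidationError("ox_fraction_range must be inside (0, 1)")
        unknown = set(self.layers) - {"proteome", "redoxome", "phospho"}
        if unknown:
            raise ValidationError(f"unknown layer(s) {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Per-entity truth of a simulated experiment.

    ``proteins`` / ``ox_sites`` / ``phospho_sites`` carry the planted
    per-entity effects; ``implied`` maps each analysis layer to the
    model-implied noise-free log2 fold change per rolled-up entity on the
    pipeline's reporting scale (after protein normalization and, for
    ox_all, sign inversion).  Rollup of multi-cysteine peptides can make a
    site's implied value differ from its own planted delta — the implied
    value is what a perfect measurement would report.
    """

    proteins: pd.DataFrame
    ox_sites: pd.DataFrame
    phospho_sites: pd.DataFrame
    implied: dict[str, pd.Series]
    planted_set: str | None = None

    def null_entities(self, layer: str) -> pd.Index:
        s = self.implied[layer]
        return s.index[s.abs() < 1e-12]


@dataclass
class SimulatedExperiment:
    design: SampleDesign
    tables: dict[str, PeptideTable]
    impurity: ImpurityMatrix
    gene_sets: GeneSetCollection
    go_cc: GeneSetCollection
    mapping: dict[str, str]
    annotations: SiteAnnotationTable
    truth: GroundTruth
    config: SimulationConfig

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        rio.write_design(self.design, os.path.join(out_dir, "design.tsv"))
        for layer, table in self.tables.items():
            rio.write_peptide_table(
                table, os.path.join(out_dir, f"peptides_{layer}.tsv")
            )
        self.impurity.to_tsv(os.path.join(out_dir, "impurity.tsv"))
        rio.write_gmt(self.gene_sets, os.path.join(out_dir, "gene_sets.gmt"))
        rio.write_gmt(self.go_cc, os.path.join(out_dir, "go_cc.gmt"))
        rio.write_mapping(self.mapping, os.path.join(out_dir, "mapping.tsv"))
        rio.write_annotations(
            self.annotations, os.path.join(out_dir, "annotations.tsv")
        )


def make_design(config: SimulationConfig) -> SampleDesign:
    """The (mix, channel) -> sample map for the configured study design."""
    rows = []
    for run in range(1, config.n_runs + 1):
        for rep in range(1, config.replicates_per_run + 1):
            if "proteome" in config.layers or "phospho" in config.layers:
                assignments = []
                for tp in config.timepoints:
                    assignments += [(tp, "control"), (tp, "treated")]
                for layer in ("proteome", "phospho"):
                    if layer not in config.layers:
                        continue
                    mix = f"{layer[:4]}-r{run}.{rep}"
                    for ch, (tp, treat) in zip(CHANNELS, assignments):
                        rows.append(
                            (mix, ch, run, rep, tp, treat, "NA", layer)
                        )
            if "redoxome" in config.layers:
                for tp in config.timepoints:
                    mix = f"redox-r{run}.{rep}-{tp}"
                    stage_rows = [
                        ("TMT1", "control"), ("TMT1", "treated"),
                        ("TMT2", "control"), ("TMT2", "treated"),
                    ]
                    for ch, (stage, treat) in zip(CHANNELS, stage_rows):
                        rows.append(
                            (mix, ch, run, rep, tp, treat, stage, "redoxome")
                        )
    return SampleDesign(pd.DataFrame(rows, columns=DESIGN_COLUMNS))


def make_impurity(config: SimulationConfig) -> ImpurityMatrix:
    k = len(CHANNELS)
    b = config.impurity_bleed
    m = np.zeros((k, k))
    for j in range(k):
        if j > 0:
            m[j - 1, j] = b
        if j < k - 1:
            m[j + 1, j] = b
        m[j, j] = 1.0 - (m[:, j].sum() - m[j, j])
    return ImpurityMatrix(list(CHANNELS), m)


def _count(rng: np.random.Generator, mean: float, n: int, floor: int = 0) -> np.ndarray:
    if mean <= floor:
        return np.full(n, floor, dtype=int)
    return floor + rng.poisson(mean - floor, size=n)


def _signed_effects(
    rng: np.random.Generator, n: int, fraction: float, size: float,
    override_prob: np.ndarray | None = None,
) -> np.ndarray:
    prob = np.full(n, fraction) if override_prob is None else override_prob
    affected = rng.random(n) < prob
    signs = rng.choice([-1.0, 1.0], size=n)
    return np.where(affected, signs * size, 0.0)


def _random_peptides(rng: np.random.Generator, n: int, length: int = 10) -> list[str]:
    letters = rng.integers(0, len(_AA), size=(n, length))
    return ["".join(_AA[row]) for row in letters]


def simulate(config: SimulationConfig) -> SimulatedExperiment:
    """Generate a complete synthetic experiment; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    accessions = np.array([f"P{i:05d}" for i in range(n)])
    genes = np.array([f"GENE{i:05d}" for i in range(n)])
    mapping = dict(zip(accessions, genes))

    # --- gene sets (set 0 optionally planted with elevated effect prob) ---
    set_size = min(config.gene_set_size, n)
    sets: dict[str, list[str]] = {}
    planted_members = np.zeros(n, dtype=bool)
    planted_name: str | None = None
    if config.planted_set_effect_prob > 0:
        planted_name = "SET_PLANTED"
        member_idx = rng.choice(n, size=set_size, replace=False)
        planted_members[member_idx] = True
        sets[planted_name] = sorted(genes[member_idx])
    # unplanted sets are drawn from the non-planted genes so they are true
    # null pathways (no systematic overlap with the planted one)
    pool = np.flatnonzero(~planted_members)
    null_size = min(set_size, pool.size)
    for s in range(config.n_gene_sets - (planted_name is not None)):
        member_idx = rng.choice(pool, size=null_size, replace=False)
        sets[f"SET_{s:03d}"] = sorted(genes[member_idx])
    gene_sets = GeneSetCollection("reactome_like", sets, mapping)

    compartments = ["GOCC_NUCLEUS", "GOCC_CYTOPLASM", "GOCC_MEMBRANE",
                    "GOCC_MITOCHONDRION", "GOCC_SECRETED"]
    comp_idx = rng.integers(0, len(compartments), size=n)
    cc_sets = {
        c: sorted(genes[comp_idx == i]) for i, c in enumerate(compartments)
        if (comp_idx == i).any()
    }
    go_cc = GeneSetCollection("go_cc_like", cc_sets, mapping)

    # --- protein truth -----------------------------------------------------
    base_log2 = rng.normal(
        config.base_abundance_mean_log2, config.base_abundance_sd_log2, size=n
    )
    override = None
    if planted_name is not None:
        override = np.where(
            planted_members, config.planted_set_effect_prob,
            config.protein_effect_fraction,
        )
    delta_prot = _signed_effects(
        rng, n, config.protein_effect_fraction, config.effect_size, override
    )
    proteins = pd.DataFrame(
        {
            "accession": accessions,
            "gene": genes,
            "base_log2": base_log2,
            "delta": delta_prot,
            "planted_set_member": planted_members,
        }
    )

    # --- cysteine sites and redox peptide catalog --------------------------
    lo, hi = config.ox_fraction_range
    n_cys = _count(rng, config.cys_sites_per_protein, n)
    cys_prot = np.repeat(np.arange(n), n_cys)
    total_cys = cys_prot.size
    cys_pos = rng.integers(1, 600, size=total_cys)
    delta_ox = _signed_effects(
        rng, total_cys, config.ox_effect_fraction, config.effect_size
    )
    # keep f * 2^delta < 0.95 so the treated fraction needs no clipping
    f_hi = np.minimum(hi, 0.95 / np.power(2.0, np.maximum(delta_ox, 0.0)))
    f_control = lo + rng.random(total_cys) * (f_hi - lo)
    f_treated = f_control * np.power(2.0, delta_ox)
    ox_sites = pd.DataFrame(
        {
            "accession": accessions[cys_prot],
            "site": [f"C{p}" for p in cys_pos],
            "f_control": f_control,
            "f_treated": f_treated,
            "delta": delta_ox,
        }
    )
    dup = ox_sites.duplicated(["accession", "site"])
    ox_sites = ox_sites[~dup].reset_index(drop=True)

    # --- phospho sites ------------------------------------------------------
    plo, phi = config.phospho_occupancy_range
    n_pho = _count(rng, config.phospho_sites_per_protein, n)
    pho_prot = np.repeat(np.arange(n), n_pho)
    total_pho = pho_prot.size
    pho_res = rng.choice(list("STY"), size=total_pho, p=[0.84, 0.15, 0.01])
    pho_pos = rng.integers(1, 600, size=total_pho)
    delta_pho = _signed_effects(
        rng, total_pho, config.phospho_effect_fraction, config.effect_size
    )
    occ_hi = np.minimum(phi, 0.95 / np.power(2.0, np.maximum(delta_pho, 0.0)))
    occ_control = plo + rng.random(total_pho) * (occ_hi - plo)
    occ_treated = occ_control * np.power(2.0, delta_pho)
    phospho_sites = pd.DataFrame(
        {
            "accession": accessions[pho_prot],
            "site": [f"{r}{p}" for r, p in zip(pho_res, pho_pos)],
            "occ_control": occ_control,
            "occ_treated": occ_treated,
            "delta": delta_pho,
        }
    )
    phospho_sites = phospho_sites[
        ~phospho_sites.duplicated(["accession", "site"])
    ].reset_index(drop=True)

    design = make_design(config)
    impurity = make_impurity(config)
    eff_sd = config.peptide_efficiency_sd_log2

    tables: dict[str, PeptideTable] = {}
    implied: dict[str, pd.Series] = {}

    # ---- proteome ---------------------------------------------------------
    if "proteome" in config.layers:
        pep_per_prot = _count(rng, config.peptides_per_protein, n, floor=1)
        prot_idx = np.repeat(np.arange(n), pep_per_prot)
        catalog = pd.DataFrame(
            {
                "protein_idx": prot_idx,
                "protein_accession": accessions[prot_idx],
                "peptide_sequence": _random_peptides(rng, prot_idx.size),
                "sites": "",
                "eff_log2": rng.normal(0.0, eff_sd, size=prot_idx.size),
            }
        )
        catalog["num_c"] = 1.0
        catalog["num_t"] = 1.0
        tables["proteome"] = _generate_layer_table(
            rng, config, design, impurity, catalog, "proteome", base_log2, delta_prot
        )
        implied["proteome"] = pd.Series(delta_prot, index=accessions)

    # ---- redoxome ---------------------------------------------------------
    if "redoxome" in config.layers and len(ox_sites):
        acc_index = {a: j for j, a in enumerate(accessions)}
        siblings_of: dict[str, list[int]] = {}
        for i, acc in enumerate(ox_sites["accession"]):
            siblings_of.setdefault(acc, []).append(i)
        n_pep_per_site = _count(
            rng, config.peptides_per_site, len(ox_sites), floor=1
        )
        cat_rows = []
        for s_idx in range(len(ox_sites)):
            acc = ox_sites.at[s_idx, "accession"]
            siblings = siblings_of[acc]
            for _ in range(n_pep_per_site[s_idx]):
                carried = [s_idx]
                if len(siblings) > 1 and rng.random() < config.multi_cys_fraction:
                    other = int(rng.choice([s for s in siblings if s != s_idx]))
                    carried.append(other)
                cat_rows.append(
                    {
                        "protein_idx": acc_index[acc],
                        "protein_accession": acc,
                        "sites": ";".join(ox_sites.loc[carried, "site"]),
                        "num_c": float((1.0 - ox_sites.loc[carried, "f_control"]).sum()),
                        "num_t": float((1.0 - ox_sites.loc[carried, "f_treated"]).sum()),
                        "oxi_c": float(ox_sites.loc[carried, "f_control"].sum()),
                        "oxi_t": float(ox_sites.loc[carried, "f_treated"].sum()),
                    }
                )
        catalog = pd.DataFrame(cat_rows)
        catalog["peptide_sequence"] = _random_peptides(rng, len(catalog))
        catalog["eff_log2"] = rng.normal(0.0, eff_sd, size=len(catalog))
        tables["redoxome"] = _generate_layer_table(
            rng, config, design, impurity, catalog, "redoxome", base_log2, delta_prot
        )
        implied["ox_all"], implied["ox_rev"] = _implied_redox(catalog)

    # ---- phosphoproteome ---------------------------------------------------
    if "phospho" in config.layers and len(phospho_sites):
        n_pep = _count(rng, config.peptides_per_site, len(phospho_sites), floor=1)
        s_idx = np.repeat(np.arange(len(phospho_sites)), n_pep)
        acc_index = {a: j for j, a in enumerate(accessions)}
        catalog = pd.DataFrame(
            {
                "protein_idx": [
                    acc_index[a] for a in phospho_sites["accession"].iloc[s_idx]
                ],
                "protein_accession": phospho_sites["accession"].iloc[s_idx].to_numpy(),
                "sites": phospho_sites["site"].iloc[s_idx].to_numpy(),
                "num_c": phospho_sites["occ_control"].iloc[s_idx].to_numpy(),
                "num_t": phospho_sites["occ_treated"].iloc[s_idx].to_numpy(),
                "peptide_sequence": _random_peptides(rng, s_idx.size),
                "eff_log2": rng.normal(0.0, eff_sd, size=s_idx.size),
            }
        )
        tables["phospho"] = _generate_layer_table(
            rng, config, design, impurity, catalog, "phospho", base_log2, delta_prot
        )
        implied["phospho"] = _implied_single(catalog)

    # ---- annotations -------------------------------------------------------
    annotations = _make_annotations(rng, config, ox_sites)

    truth = GroundTruth(
        proteins=proteins,
        ox_sites=ox_sites,
        phospho_sites=phospho_sites,
        implied=implied,
        planted_set=planted_name,
    )
    return SimulatedExperiment(
        design=design,
        tables=tables,
        impurity=impurity,
        gene_sets=gene_sets,
        go_cc=go_cc,
        mapping=mapping,
        annotations=annotations,
        truth=truth,
        config=config,
    )


def _generate_layer_table(
    rng: np.random.Generator,
    config: SimulationConfig,
    design: SampleDesign,
    impurity: ImpurityMatrix,
    catalog: pd.DataFrame,
    layer: str,
    base_log2: np.ndarray,
    delta_prot: np.ndarray,
) -> PeptideTable:
    """Realize a peptide-isoform table for one physical layer.

    ``catalog`` holds per-peptide control/treated signal factors ``num_c``
    / ``num_t`` (1 for the proteome, summed thiol fractions for the
    redoxome, occupancies for phospho) and, for the redoxome, ``oxi_c`` /
    ``oxi_t`` for the TMT2 stage.
    """
    rows = design.frame[design.frame["layer"] == layer]
    prot = catalog["protein_idx"].to_numpy()
    abundance = base_log2[prot] + catalog["eff_log2"].to_numpy()
    delta = delta_prot[prot]
    frames = []
    for mix, grp in rows.groupby("mix_id", sort=False):
        grp = grp.set_index("channel_id")
        mix_channels = list(grp.index)
        cols = np.empty((len(catalog), len(mix_channels)))
        for ci, ch in enumerate(mix_channels):
            meta = grp.loc[ch]
            treated = meta["treatment"] == "treated"
            log2_abund = abundance + (delta if treated else 0.0)
            if layer == "redoxome" and meta["label_stage"] == "TMT2":
                factor = catalog["oxi_t" if treated else "oxi_c"].to_numpy()
            else:
                factor = catalog["num_t" if treated else "num_c"].to_numpy()
            cols[:, ci] = np.power(2.0, log2_abund) * factor
        if config.noise_sd > 0:
            cols *= np.power(
                2.0, rng.normal(0.0, config.noise_sd, size=cols.shape)
            )
        # forward impurity mixing over the channels this mix actually uses
        sub_idx = [impurity.channels.index(c) for c in mix_channels]
        sub = impurity.matrix[np.ix_(sub_idx, sub_idx)]
        observed = cols @ sub.T
        if config.missing_rate > 0:
            drop = rng.random(len(catalog)) < config.missing_rate
        else:
            drop = np.zeros(len(catalog), dtype=bool)
        frame = pd.DataFrame(
            {
                "mix_id": mix,
                "protein_accession": catalog["protein_accession"].to_numpy(),
                "peptide_sequence": catalog["peptide_sequence"].to_numpy(),
                "sites": catalog["sites"].to_numpy(),
            }
        )
        for ch in CHANNELS:
            frame[ch] = observed[:, mix_channels.index(ch)] if ch in mix_channels else np.nan
        frames.append(frame[~drop])
    table = pd.concat(frames, ignore_index=True)
    return PeptideTable(table, CHANNELS)


def _site_rollup_ratio(
    catalog: pd.DataFrame, num_t: str, num_c: str
) -> pd.Series:
    """Noise-free rolled-up log2 ratio per site entity.

    Weights each peptide by its ionization efficiency and (implicitly) the
    protein's base abundance, exactly as the measured rollup would with
    noise off; the protein-abundance effect cancels after protein
    normalization so it is omitted here.
    """
    w = np.power(2.0, catalog["eff_log2"].to_numpy())
    expanded = catalog.assign(weight=w)
    expanded = expanded.assign(site=expanded["sites"].str.split(";")).explode("site")
    entity = expanded["protein_accession"] + "_" + expanded["site"]
    t = (expanded[num_t] * expanded["weight"]).groupby(entity.to_numpy()).sum()
    c = (expanded[num_c] * expanded["weight"]).groupby(entity.to_numpy()).sum()
    return np.log2(t / c)


def _implied_redox(catalog: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Model-implied (ox_all, ox_rev) log2FCs after normalization.

    ox_all is reported on the inverted scale (positive = more oxidized):
    -log2(sum free_t / sum free_c).
    """
    free = _site_rollup_ratio(catalog, "num_t", "num_c")
    oxi = _site_rollup_ratio(catalog, "oxi_t", "oxi_c")
    return -free, oxi


def _implied_single(catalog: pd.DataFrame) -> pd.Series:
    return _site_rollup_ratio(catalog, "num_t", "num_c")


def _make_annotations(
    rng: np.random.Generator, config: SimulationConfig, ox_sites: pd.DataFrame
) -> SiteAnnotationTable:
    rows = []
    by_prot: dict[str, list[str]] = {}
    for r in ox_sites.itertuples(index=False):
        by_prot.setdefault(r.accession, []).append(r.site)
    for acc, sites in by_prot.items():
        u = rng.random()
        if len(sites) >= 2 and u < config.disulfide_fraction:
            a, b = rng.choice(len(sites), size=2, replace=False)
            rows.append((acc, sites[a], "disulfide_partner", sites[b]))
            rows.append((acc, sites[b], "disulfide_partner", sites[a]))
        elif u < config.disulfide_fraction + config.annotation_fraction:
            s = sites[int(rng.integers(0, len(sites)))]
            rows.append((acc, s, "known_modified", ""))
    frame = pd.DataFrame(
        rows, columns=["protein_accession", "site", "annotation", "partner"]
    )
    if len(frame) == 0:
        frame = pd.DataFrame(
            columns=["protein_accession", "site", "annotation", "partner"]
        )
    return SiteAnnotationTable(frame)


def truth_report(
    truth: GroundTruth, results: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Recovery metrics of differential results against the ground truth.

    Per layer and time point: bias and RMSE of ``log2fc_mean`` against the
    model-implied fold change, sensitivity (TPR at FDR <= 0.05 over
    entities whose implied effect is non-zero) and realized false
    discovery proportion (discoveries among strictly null entities over
    all discoveries).
    """
    rows = []
    for layer, res in results.items():
        if layer not in truth.implied:
            raise ValidationError(f"no ground truth for layer {layer!r}")
        implied = truth.implied[layer]
        for tp, grp in res.groupby("timepoint", sort=False):
            grp = grp.set_index("entity")
            unknown = grp.index.difference(implied.index)
            if len(unknown):
                raise ValidationError(
                    f"{layer}: entities without truth, e.g. {list(unknown[:3])}"
                )
            t = implied.reindex(grp.index)
            err = grp["log2fc_mean"] - t
            affected = t.abs() > 1e-12
            null = ~affected
            sig = grp["significant"].to_numpy(dtype=bool)
            n_disc = int(sig.sum())
            rows.append(
                {
                    "layer": layer,
                    "timepoint": tp,
                    "n_entities": len(grp),
                    "bias": float(err[affected].mean()) if affected.any() else np.nan,
                    "rmse": float(np.sqrt((err**2).mean())),
                    "sensitivity": float(sig[affected.to_numpy()].mean())
                    if affected.any() else np.nan,
                    "fdp": float(sig[null.to_numpy()].sum() / n_disc)
                    if n_disc else 0.0,
                    "n_discoveries": n_disc,
                }
            )
    return pd.DataFrame(rows)
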
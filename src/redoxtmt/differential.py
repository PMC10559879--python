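"""The per-layer differential-analysis chain.

For every layer and time point: mix-internal log2 fold changes (+LPS vs
-LPS within the same TMT mix and biological replicate), a minimum-replicate
filter, per-replicate median centering, sign inversion of the TMT1-derived
overall-oxidation layer (free-thiol signal falls when oxidation rises),
normalization of PTM-site fold changes to the parent protein's fold change,
a one-sample Student t-test of the replicate log2 fold changes against 0
and Benjamini-Hochberg adjustment, with entities called significant at
FDR <= 0.05.

The Benjamini-Hochberg step-up and the t statistic are implemented here;
only the t distribution's survival function comes from scipy.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    DIFFERENTIAL_COLUMNS,
    PTM_LAYERS,
    FoldChangeMatrix,
    SampleDesign,
    SiteQuantMatrix,
    ValidationError,
    split_site_entity,
)

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_REPLICATES = 3


def compute_fold_changes(
    q: SiteQuantMatrix, design: SampleDesign, timepoint: str
) -> FoldChangeMatrix:
    """Mix-internal log2(treated/control) per biological replicate.

    A replicate's value is missing when either side of its pair is missing
    or zero (a zero intensity cannot enter a ratio; zeros are counted in
    the log).  Time points are independent contrasts.
    """
    if timepoint not in design.timepoints:
        raise ValidationError(f"time point {timepoint!r} absent from design")
    vals = q.values
    cols = vals.columns
    at_tp = cols[cols.get_level_values("timepoint") == timepoint]
    if len(at_tp) == 0:
        raise ValidationError(
            f"quant matrix has no samples at time point {timepoint!r}"
        )

    def side(treatment: str) -> pd.DataFrame:
        sub = vals[at_tp[at_tp.get_level_values("treatment") == treatment]]
        sub = sub.copy()
        sub.columns = pd.MultiIndex.from_arrays(
            [sub.columns.get_level_values("run"),
             sub.columns.get_level_values("replicate")],
            names=["run", "replicate"],
        )
        return sub

    treated, control = side("treated"), side("control")
    reps = treated.columns.intersection(control.columns)
    treated, control = treated[reps], control[reps]
    t = treated.to_numpy(dtype=float)
    c = control.to_numpy(dtype=float)
    n_zero = int(np.nansum(t == 0) + np.nansum(c == 0))
    if n_zero:
        log.info(
            "%s %s: %d zero intensities excluded from ratios",
            q.layer, timepoint, n_zero,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where((t > 0) & (c > 0), np.log2(t / c), np.nan)
    values = pd.DataFrame(fc, index=vals.index, columns=reps)
    values = values.dropna(how="all")
    return FoldChangeMatrix(layer=q.layer, timepoint=timepoint, values=values)


def filter_min_replicates(fc: FoldChangeMatrix, k: int = DEFAULT_MIN_REPLICATES) -> FoldChangeMatrix:
    """Keep entities quantified in at least ``k`` replicates."""
    if k < 1:
        raise ValidationError("minimum replicate count must be >= 1")
    keep = fc.values.notna().sum(axis=1) >= k
    return fc.copy_with(fc.values.loc[keep])


def median_normalize(fc: FoldChangeMatrix) -> FoldChangeMatrix:
    """Center each replicate column at zero median over entities.

    Columns with no observed entity are left untouched (logged).
    """
    values = fc.values.copy()
    medians = values.median(axis=0, skipna=True)
    empty = medians.isna()
    if empty.any():
        log.info(
            "%s %s: %d all-missing replicate column(s) left unnormalized",
            fc.layer, fc.timepoint, int(empty.sum()),
        )
        medians = medians.fillna(0.0)
    values = values.sub(medians, axis=1)
    return fc.copy_with(values, median_normalized=True)


def invert_overall_oxidation(
    fc: FoldChangeMatrix, enforce_once: bool = True
) -> FoldChangeMatrix:
    """Negate the TMT1-derived fold changes so positive means more oxidized.

    The TMT1 stage labels free thiols, so its raw fold changes track the
    *reduced* pool.  Inversion is applied exactly once per pipeline run;
    the provenance flag guards against double application unless
    ``enforce_once`` is disabled (the involution property is only testable
    with the guard off).
    """
    if fc.layer != "ox_all":
        raise ValidationError(
            f"inversion applies only to the ox_all layer, not {fc.layer!r}"
        )
    if fc.inverted and enforce_once:
        raise ValidationError("ox_all fold changes were already inverted")
    return fc.copy_with(-fc.values, inverted=not fc.inverted)


def normalize_site_to_protein(
    site_fc: FoldChangeMatrix, protein_fc: FoldChangeMatrix
) -> FoldChangeMatrix:
    """Subtract the parent protein's log2 fold change, replicate-wise.

    Isolates the modification change from the abundance change: a site
    whose fold change equals its protein's is a pure abundance effect and
    maps to 0.  Sites whose parent protein is not quantified in the
    proteome are dropped (counted in the log); a replicate where the
    protein lacks a value becomes missing for the site.
    """
    if site_fc.layer not in PTM_LAYERS:
        raise ValidationError(f"{site_fc.layer!r} is not a PTM layer")
    if protein_fc.layer != "proteome":
        raise ValidationError("second argument must be proteome fold changes")
    if site_fc.timepoint != protein_fc.timepoint:
        raise ValidationError("time points of site and protein fold changes differ")
    parents = pd.Index([split_site_entity(e)[0] for e in site_fc.values.index])
    known = parents.isin(protein_fc.values.index)
    n_dropped = int((~known).sum())
    if n_dropped:
        log.info(
            "%s %s: dropped %d sites whose parent protein is not in the proteome",
            site_fc.layer, site_fc.timepoint, n_dropped,
        )
    values = site_fc.values.loc[known]
    parent_vals = protein_fc.values.reindex(parents[known])
    parent_vals = parent_vals.reindex(columns=values.columns)
    out = pd.DataFrame(
        values.to_numpy() - parent_vals.to_numpy(),
        index=values.index,
        columns=values.columns,
    ).dropna(how="all")
    return site_fc.copy_with(out, protein_normalized=True)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the family and stay NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    result = np.empty(m)
    result[order] = adjusted
    out[mask] = result
    return out


def test_differential(
    fc: FoldChangeMatrix, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """One-sample two-sided Student t-test of replicate log2FCs against 0,
    BH-adjusted across all tested entities of this layer x time point.

    Entities with zero variance across replicates get an undefined p and
    are excluded from the BH family (logged).  Returns a frame with the
    :data:`redoxtmt.model.DIFFERENTIAL_COLUMNS` schema.
    """
    values = fc.values.to_numpy(dtype=float)
    if values.shape[0] == 0:
        raise ValidationError("no entities to test")
    n = (~np.isnan(values)).sum(axis=1)
    if (n < 2).any():
        raise ValidationError(
            "entities with fewer than 2 replicates; apply filter_min_replicates first"
        )
    mean = np.nanmean(values, axis=1)
    sd = np.nanstd(values, axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        log.info(
            "%s %s: %d zero-variance entities excluded from testing",
            fc.layer, fc.timepoint, int(degenerate.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = mean / (sd / np.sqrt(n))
    t_stat[degenerate] = np.nan
    p = np.full(values.shape[0], np.nan)
    ok = ~degenerate
    p[ok] = 2.0 * stats.t.sf(np.abs(t_stat[ok]), df=n[ok] - 1)
    fdr = benjamini_hochberg(p)
    significant = (fdr <= alpha) & ~np.isnan(fdr)
    res = pd.DataFrame(
        {
            "entity": fc.values.index,
            "layer": fc.layer,
            "timepoint": fc.timepoint,
            "n": n,
            "log2fc_mean": mean,
            "t_stat": t_stat,
            "p": p,
            "fdr": fdr,
            "significant": significant,
            "direction": np.sign(mean).astype(int),
        },
        columns=DIFFERENTIAL_COLUMNS,
    )
    return res.reset_index(drop=True)


def summarize_counts(res: pd.DataFrame) -> pd.DataFrame:
    """Counts of significantly increased / decreased entities.

    Strict inequalities: a significant entity with mean log2FC exactly 0 is
    counted in neither direction (logged).
    """
    rows = []
    for (layer, tp), grp in res.groupby(["layer", "timepoint"], sort=False):
        sig = grp[grp["significant"]]
        n_zero = int((sig["log2fc_mean"] == 0).sum())
        if n_zero:
            log.info(
                "%s %s: %d significant entities with mean exactly 0 "
                "counted in neither direction", layer, tp, n_zero,
            )
        rows.append(
            {
                "layer": layer,
                "timepoint": tp,
                "n_up": int((sig["log2fc_mean"] > 0).sum()),
                "n_down": int((sig["log2fc_mean"] < 0).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["layer", "timepoint", "n_up", "n_down"])
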
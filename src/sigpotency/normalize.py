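"""Plate normalization: fold changes, robust rscores, housekeeper correction,
probe collapse and responsive-gene QC.

The processing chain mirrors multiplexed bead-assay practice:

.. code-block:: text

    fold change = 50 * log2(count / median NC count)        (per gene, per plate)
    rscore      = (fold change - median NC fold change) / MAD(NC fold changes)
    HKnorm      = rscore - rscore of the housekeeper gene in the same well

The MAD is the consistency-scaled median absolute deviation (×1.4826), so an
rscore reads as the number of robust standard deviations a treated well lies
from the neutral-control background.  All statistics are computed strictly
per plate from that plate's NC wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import IntegrityError, PlateExpressionSet, Role, Scale

__all__ = [
    "NormalizationStats",
    "fold_change",
    "compute_nc_stats",
    "rscore",
    "hknorm",
    "collapse_probes",
    "qc_responsive_genes",
    "PlateNormalizer",
]

#: minimum NC wells for a defined MAD
MIN_NC_WELLS = 3


@dataclass
class NormalizationStats:
    """Per-gene neutral-control statistics of one plate.

    ``nc_mad`` is the consistency-scaled MAD of NC fold changes (×1.4826).
    """

    per_gene: pd.DataFrame  # columns: nc_median_count, nc_median_foldchange, nc_mad
    n_nc_wells: int

    def __post_init__(self) -> None:
        if (self.per_gene["nc_mad"] < 0).any():
            raise IntegrityError("nc_mad must be >= 0")


def _nc_index(pset: PlateExpressionSet) -> pd.Index:
    idx = pset.wells_with_role(Role.NC)
    if len(idx) == 0:
        raise IntegrityError("plate has no NC wells")
    return idx


def fold_change(pset: PlateExpressionSet) -> PlateExpressionSet:
    """``50 * log2(count / per-gene NC median count)`` for every cell."""
    if pset.scale != Scale.COUNTS:
        raise IntegrityError(f"fold_change needs raw counts, got {pset.scale!r}")
    nc = _nc_index(pset)
    vals = pset.values
    if (vals <= 0).any().any():
        bad = vals.le(0)
        well = bad.any(axis=1).idxmax()
        gene = bad.loc[well].idxmax()
        raise ValueError(
            f"non-positive count in well {well!r}, gene {gene!r}; "
            "fold change is undefined"
        )
    nc_median = vals.loc[nc].median(axis=0)
    fc = 50.0 * np.log2(vals / nc_median)
    out = pset.with_values(fc, scale=Scale.FOLDCHANGE)
    out.attrs["nc_median_count"] = nc_median
    return out


def compute_nc_stats(pset: PlateExpressionSet) -> NormalizationStats:
    """Median and scaled MAD of NC fold changes, per gene."""
    if pset.scale != Scale.FOLDCHANGE:
        raise IntegrityError(f"NC stats need fold changes, got {pset.scale!r}")
    nc = _nc_index(pset)
    if len(nc) < MIN_NC_WELLS:
        raise IntegrityError(
            f"only {len(nc)} NC well(s); at least {MIN_NC_WELLS} are needed "
            "for a defined MAD"
        )
    nc_fc = pset.values.loc[nc]
    med = nc_fc.median(axis=0)
    mad = pd.Series(
        sps.median_abs_deviation(nc_fc.values, axis=0, scale="normal"),
        index=nc_fc.columns,
    )
    per_gene = pd.DataFrame(
        {
            "nc_median_count": pset.attrs.get(
                "nc_median_count", pd.Series(np.nan, index=nc_fc.columns)
            ),
            "nc_median_foldchange": med,
            "nc_mad": mad,
        }
    )
    return NormalizationStats(per_gene=per_gene, n_nc_wells=len(nc))


def rscore(
    pset: PlateExpressionSet, stats: NormalizationStats | None = None
) -> PlateExpressionSet:
    """Robust z-score of fold changes against the plate's NC distribution.

    Genes whose NC MAD is zero carry no information on this plate; they are
    dropped with a warning rather than silently producing NaN/inf.
    """
    if pset.scale != Scale.FOLDCHANGE:
        raise IntegrityError(f"rscore needs fold changes, got {pset.scale!r}")
    if stats is None:
        stats = compute_nc_stats(pset)
    med = stats.per_gene["nc_median_foldchange"]
    mad = stats.per_gene["nc_mad"]
    degenerate = mad.index[mad == 0]
    if len(degenerate):
        warnings.warn(
            "zero NC MAD; excluding non-informative gene(s): "
            + ", ".join(map(str, degenerate)),
            UserWarning,
            stacklevel=2,
        )
    keep = [g for g in pset.values.columns if g not in set(degenerate)]
    rs = (pset.values[keep] - med[keep]) / mad[keep]
    out = pset.with_values(rs, scale=Scale.RSCORE)
    out.attrs["excluded_genes"] = list(degenerate)
    return out


def hknorm(pset: PlateExpressionSet, housekeeper: str) -> PlateExpressionSet:
    """Subtract the same well's housekeeper rscore from every gene, then
    drop the housekeeper column from the readouts."""
    if pset.scale != Scale.RSCORE:
        raise IntegrityError(f"hknorm needs rscores, got {pset.scale!r}")
    if housekeeper not in pset.values.columns:
        raise IntegrityError(f"housekeeper gene {housekeeper!r} not on plate")
    hk = pset.values[housekeeper]
    corrected = pset.values.sub(hk, axis=0).drop(columns=[housekeeper])
    return pset.with_values(corrected, scale=Scale.RSCORE)


def collapse_probes(pset: PlateExpressionSet) -> PlateExpressionSet:
    """One column per gene symbol, keeping the probe of maximal variance.

    Ties are broken toward the lexicographically smallest probe id.  Values
    of retained columns are untouched.
    """
    genes = pset.genes
    symbols = genes["gene_symbol"] if "gene_symbol" in genes.columns else pd.Series(
        genes.index, index=genes.index
    )
    if symbols.is_unique:
        return pset
    variances = pset.values.var(axis=0, ddof=1)
    keep_cols: list = []
    new_symbols: list[str] = []
    for sym in symbols.unique():
        cols = symbols.index[symbols == sym]
        if len(cols) == 1:
            keep_cols.append(cols[0])
        else:
            sub = pd.DataFrame(
                {
                    "var": variances[cols].values,
                    "probe": genes.loc[cols, "probe_id"].astype(str).values,
                },
                index=cols,
            )
            # max variance; tie -> smallest probe_id
            best = sub.sort_values(["var", "probe"], ascending=[False, True]).index[0]
            keep_cols.append(best)
        new_symbols.append(sym)
    values = pset.values[keep_cols].copy()
    values.columns = new_symbols
    new_genes = genes.loc[keep_cols].copy()
    new_genes.index = new_symbols
    new_genes.drop(columns=[c for c in ("gene_symbol",) if c in new_genes.columns],
                   inplace=True)
    out = PlateExpressionSet(
        values=values, wells=pset.wells, genes=new_genes, scale=pset.scale,
        attrs=dict(pset.attrs),
    )
    out.attrs.pop("duplicate_symbols", None)
    return out


def qc_responsive_genes(
    pset: PlateExpressionSet,
    min_rscore: float = 3.0,
    min_fraction: float = 0.5,
    role: str = Role.AC,
) -> pd.Series:
    """Flag genes responding consistently to the active control.

    A gene passes iff in *every* biological replicate at least
    ``min_fraction`` of that replicate's technical-replicate wells have
    rscore > ``min_rscore``.  Default thresholds: more than 3 robust SD in
    at least half the technical replicates, in both biological replicates.
    """
    if pset.scale != Scale.RSCORE:
        raise IntegrityError(f"QC needs rscores, got {pset.scale!r}")
    wells = pset.wells_with_role(role)
    if len(wells) == 0:
        raise IntegrityError(f"no {role} wells to QC against")
    groups = pset.wells.loc[wells].groupby("biological_replicate_id").groups
    passing = pd.Series(True, index=pset.values.columns)
    for _bio, idx in groups.items():
        if len(idx) == 0:
            raise IntegrityError("empty biological replicate group")
        frac = (pset.values.loc[idx] > min_rscore).mean(axis=0)
        passing &= frac >= min_fraction
    return passing


class PlateNormalizer(BaseEstimator, TransformerMixin):
    """Counts → rscore transformer (fold change, robust z-score, optional
    housekeeper correction), scikit-learn style.

    Parameters
    ----------
    housekeeper : str or None
        Gene whose rscore is subtracted per well; the column is dropped
        from the output.
    collapse : bool
        Collapse duplicate probes to one column per symbol (max variance)
        before normalizing.

    Attributes
    ----------
    stats_ : NormalizationStats
        NC statistics of the fitted plate.
    """

    def __init__(self, housekeeper: str | None = None, collapse: bool = False):
        self.housekeeper = housekeeper
        self.collapse = collapse

    def fit(self, pset: PlateExpressionSet, y=None):
        prepared = collapse_probes(pset) if self.collapse else pset
        fc = fold_change(prepared)
        self.stats_ = compute_nc_stats(fc)
        return self

    def transform(self, pset: PlateExpressionSet) -> PlateExpressionSet:
        prepared = collapse_probes(pset) if self.collapse else pset
        fc = fold_change(prepared)
        rs = rscore(fc, self.stats_)
        if self.housekeeper is not None:
            rs = hknorm(rs, self.housekeeper)
        return rs

    def fit_transform(self, pset: PlateExpressionSet, y=None, **kwargs):
        return self.fit(pset).transform(pset)
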
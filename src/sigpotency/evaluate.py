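"""Comparison of signature-derived potencies against a reference potency set
(cAMP EC50s, GR50s, or simulation truth).

Potencies are compared on the log10 scale per method (and per biological
replicate), by Pearson and Spearman correlation and by the fraction of
compounds whose potency lies within one log unit of the reference.
Censored potencies participate at their assigned bounds, so inactive
compounds still inform the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    ConcentrationGrid,
    IntegrityError,
    ReferencePotency,
    harmonize_name,
)

__all__ = [
    "EvaluationResult",
    "censor_flat_reference",
    "correlate_potencies",
]

MIN_COMPOUNDS = 3


def censor_flat_reference(
    ref: ReferencePotency, grid: ConcentrationGrid
) -> ReferencePotency:
    """Assign a bounded potency to a flat reference dose-response curve.

    A flat curve whose infinite-concentration growth value (GRInf) stayed
    above 0.5 showed no real inhibition: its potency is set one log unit
    above the highest tested concentration.  GRInf below 0.5 means the
    compound was already fully inhibiting at the lowest dose: one log
    unit below the lowest tested concentration.  Non-flat references pass
    through unchanged.
    """
    if not ref.flat_curve:
        return ref
    if ref.grinf is None:
        raise IntegrityError(
            f"flat reference curve for {ref.compound_id!r} lacks a GRInf value"
        )
    if ref.grinf >= 0.5:
        return replace(ref, potency_uM=grid.max_uM * 10.0, flat_curve=True)
    return replace(ref, potency_uM=grid.min_uM / 10.0, flat_curve=True)


@dataclass
class EvaluationResult:
    """Correlation of logged potencies with a reference, per method."""

    table: pd.DataFrame  # method [, replicate] × pearson_r, spearman_r, n, frac_within_1log
    diagnostics: dict = field(default_factory=dict)


def _reference_frame(reference) -> pd.DataFrame:
    if isinstance(reference, pd.DataFrame):
        df = reference[["compound_id", "potency_uM"]].copy()
    else:
        df = pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in reference],
                "potency_uM": [r.potency_uM for r in reference],
            }
        )
    df = df.dropna(subset=["potency_uM"])
    df["key"] = df["compound_id"].map(harmonize_name)
    return df.drop_duplicates("key")


def correlate_potencies(
    potencies: pd.DataFrame,
    reference: Sequence[ReferencePotency] | pd.DataFrame,
    min_n: int = MIN_COMPOUNDS,
    pooled: bool = False,
) -> EvaluationResult:
    """Correlate fitted potencies with reference potencies per method.

    Parameters
    ----------
    potencies
        Columns ``compound_id, method, reported_potency_uM`` and optionally
        ``biological_replicate_id``.
    reference
        ``ReferencePotency`` records or a DataFrame with ``compound_id``
        and ``potency_uM``.  Flat curves should be censored beforehand
        (:func:`censor_flat_reference`).
    min_n
        Correlations over fewer joined compounds are withheld (reported in
        ``diagnostics`` instead).
    pooled
        Average log potencies over biological replicates before
        correlating, instead of reporting each replicate separately.

    Compound names are harmonized (lowercase, whitespace and ``-``
    stripped) before joining.
    """
    pot = potencies.copy()
    if "reported_potency_uM" not in pot.columns and "potency_uM" in pot.columns:
        pot = pot.rename(columns={"potency_uM": "reported_potency_uM"})
    pot["key"] = pot["compound_id"].map(harmonize_name)
    ref = _reference_frame(reference)
    merged = pot.merge(
        ref[["key", "potency_uM"]].rename(columns={"potency_uM": "ref_potency_uM"}),
        on="key",
        how="inner",
    )
    merged = merged.dropna(subset=["reported_potency_uM", "ref_potency_uM"])
    merged["log_pot"] = np.log10(merged["reported_potency_uM"].astype(float))
    merged["log_ref"] = np.log10(merged["ref_potency_uM"].astype(float))

    has_rep = "biological_replicate_id" in merged.columns and not pooled
    if pooled and "biological_replicate_id" in merged.columns:
        merged = (
            merged.groupby(["method", "key"], as_index=False)
            .agg(log_pot=("log_pot", "mean"), log_ref=("log_ref", "first"))
        )
    group_cols = ["method", "biological_replicate_id"] if has_rep else ["method"]

    rows, withheld = [], {}
    for keys, sub in merged.groupby(group_cols):
        keys = keys if isinstance(keys, tuple) else (keys,)
        n = len(sub)
        label = keys[0] if len(keys) == 1 else "/".join(map(str, keys))
        if n < min_n:
            withheld[label] = f"only {n} compounds joined (need >= {min_n})"
            continue
        x, y = sub["log_pot"].values, sub["log_ref"].values
        pear = float(sps.pearsonr(x, y)[0]) if np.std(x) > 0 and np.std(y) > 0 else np.nan
        spear = float(sps.spearmanr(x, y)[0]) if np.std(x) > 0 and np.std(y) > 0 else np.nan
        row = dict(zip(group_cols, keys))
        row.update(
            pearson_r=pear,
            spearman_r=spear,
            n=n,
            frac_within_1log=float(np.mean(np.abs(x - y) <= 1.0 + 1e-9)),
        )
        rows.append(row)
    if not rows and withheld:
        return EvaluationResult(
            table=pd.DataFrame(
                columns=group_cols + ["pearson_r", "spearman_r", "n", "frac_within_1log"]
            ),
            diagnostics={"withheld": withheld},
        )
    table = pd.DataFrame(rows).set_index(group_cols) if rows else pd.DataFrame()
    return EvaluationResult(table=table, diagnostics={"withheld": withheld})
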
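"""Multivariate signature-summary scores.

Each treated well's per-gene rscore vector is summarised into a scalar
relative to the plate's active-control (AC) and neutral-control (NC)
signatures.  Twelve methods are provided, in four classes:

direction
    ``cor_p_AC`` (Pearson r to AC), ``cor_s_AC`` (Spearman r),
    ``cos_AC`` (cosine), ``cos_weight_AC`` (cosine × significance weight).
direction & magnitude
    ``dot_p_AC`` (dot product), ``scalar_projection_AC`` (|A|·cosθ,
    projection onto the AC direction).
magnitude
    ``vec_norm`` (‖profile‖), ``euc_NC`` / ``maha_NC`` (Euclidean /
    Mahalanobis distance from the NC centre), ``num_readouts_changed``
    (genes with |rscore| > 3).
AC similarity
    ``euc_AC`` / ``maha_AC`` (distance to the AC signature itself; these
    peak where compound and AC magnitudes coincide, giving bell-shaped
    dose-response when the compound overshoots the AC).

Raw scores are rescaled to percent activity so the NC centre maps to 0%
and the AC signature to 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.covariance import LedoitWolf

from .datatypes import (
    GeneSignature,
    IntegrityError,
    PlateExpressionSet,
    Role,
    Scale,
)
from .io import subset_to_signature

__all__ = [
    "DIRECTION_METHODS",
    "HYBRID_METHODS",
    "MAGNITUDE_METHODS",
    "AC_SIMILARITY_METHODS",
    "ALL_METHODS",
    "ReferenceContext",
    "ScoreSeries",
    "build_reference_context",
    "significance_weight",
    "compute_score",
    "percent_activity",
    "score_treatments",
    "SignatureScorer",
]

DIRECTION_METHODS = ("cor_p_AC", "cor_s_AC", "cos_AC", "cos_weight_AC")
HYBRID_METHODS = ("dot_p_AC", "scalar_projection_AC")
MAGNITUDE_METHODS = ("vec_norm", "euc_NC", "maha_NC", "num_readouts_changed")
AC_SIMILARITY_METHODS = ("euc_AC", "maha_AC")
ALL_METHODS = DIRECTION_METHODS + HYBRID_METHODS + MAGNITUDE_METHODS + AC_SIMILARITY_METHODS

#: methods that need an AC signature
AC_REFERENCED = set(DIRECTION_METHODS + HYBRID_METHODS + AC_SIMILARITY_METHODS)

#: |rscore| above which a readout counts as changed from background
READOUT_CHANGED_THRESHOLD = 3.0

#: profiles with a norm below this are directionally degenerate
DEGENERACY_EPS = 1e-9


@dataclass
class ReferenceContext:
    """Per-plate reference quantities all scores are computed against."""

    genes: tuple[str, ...]
    ac_vector: np.ndarray | None  # per-gene median rscore over AC wells
    nc_vectors: np.ndarray  # NC wells × genes
    nc_center: np.ndarray  # per-gene median over NC wells
    nc_cov: np.ndarray  # gene × gene, shrunk if needed
    nc_cov_inv: np.ndarray
    cov_shrunk: bool = False
    nc_score_center: dict[str, float] = field(default_factory=dict)
    ac_score_center: dict[str, float] = field(default_factory=dict)


def build_reference_context(
    pset: PlateExpressionSet, methods: tuple[str, ...] = ALL_METHODS
) -> ReferenceContext:
    """Compute AC/NC reference vectors, NC covariance and score centres.

    The NC covariance is shrunk (Ledoit-Wolf) whenever there are no more
    NC wells than genes or the sample covariance is numerically singular —
    the L1000 situation of far more genes than control wells.
    """
    if pset.scale not in (Scale.RSCORE, Scale.ZSCORE):
        raise IntegrityError(f"scoring needs rscores/z-scores, got {pset.scale!r}")
    nc_idx = pset.wells_with_role(Role.NC)
    if len(nc_idx) == 0:
        raise IntegrityError("plate has no NC wells")
    nc = pset.values.loc[nc_idx].values.astype(float)
    nc_center = np.median(nc, axis=0)

    n_wells, n_genes = nc.shape
    shrunk = False
    cov = np.cov(nc, rowvar=False, ddof=1) if n_wells > 1 else np.eye(n_genes)
    cov = np.atleast_2d(cov)
    cond = np.linalg.cond(cov)
    if n_wells <= n_genes or not np.isfinite(cond) or cond > 1e8:
        lw = LedoitWolf().fit(nc)
        cov = lw.covariance_
        shrunk = True
        cond = np.linalg.cond(cov)
        if not np.isfinite(cond) or cond > 1e10:  # still degenerate: add ridge
            scale = np.trace(cov) / n_genes
            cov = cov + max(1e-6 * scale, 1e-9) * np.eye(n_genes)
        warnings.warn(
            "NC covariance shrunk toward identity (wells <= genes or singular)",
            UserWarning,
            stacklevel=2,
        )
    cov_inv = np.linalg.inv(cov)

    ac_idx = pset.wells_with_role(Role.AC)
    ac_vector = (
        np.median(pset.values.loc[ac_idx].values.astype(float), axis=0)
        if len(ac_idx)
        else None
    )

    ctx = ReferenceContext(
        genes=tuple(pset.values.columns),
        ac_vector=ac_vector,
        nc_vectors=nc,
        nc_center=nc_center,
        nc_cov=cov,
        nc_cov_inv=cov_inv,
        cov_shrunk=shrunk,
    )
    available = [
        m for m in methods if ac_vector is not None or m not in AC_REFERENCED
    ]
    for m in available:
        ctx.nc_score_center[m] = float(
            np.median([_score(row, ctx, m)[0] for row in nc])
        )
        if len(ac_idx):
            ac_rows = pset.values.loc[ac_idx].values.astype(float)
            ctx.ac_score_center[m] = float(
                np.median([_score(row, ctx, m)[0] for row in ac_rows])
            )
    return ctx


def significance_weight(profile: np.ndarray) -> float:
    """``min(1, mean(|rscore|) / 3)`` — downweights weak-amplitude signatures.

    Equals 1 when the signature genes average 3 robust SD from background,
    the level from which a signal is considered clearly significant.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty profile")
    return float(min(1.0, np.mean(np.abs(profile)) / 3.0))


def _require_ac(ctx: ReferenceContext, method: str) -> np.ndarray:
    if ctx.ac_vector is None:
        raise IntegrityError(f"method {method!r} needs AC wells on the plate")
    return ctx.ac_vector


def _score(profile: np.ndarray, ctx: ReferenceContext, method: str):
    """Raw score and a degeneracy flag for one profile."""
    p = np.asarray(profile, dtype=float)
    if p.shape != (len(ctx.genes),):
        raise ValueError(
            f"profile length {p.shape} != signature size {len(ctx.genes)}"
        )
    norm_p = float(np.linalg.norm(p))
    degenerate = norm_p < DEGENERACY_EPS

    if method == "cor_p_AC":
        ac = _require_ac(ctx, method)
        if degenerate or np.std(p) == 0 or np.std(ac) == 0:
            return 0.0, True
        return float(sps.pearsonr(p, ac)[0]), False
    if method == "cor_s_AC":
        ac = _require_ac(ctx, method)
        if degenerate or np.std(p) == 0 or np.std(ac) == 0:
            return 0.0, True
        return float(sps.spearmanr(p, ac)[0]), False
    if method in ("cos_AC", "cos_weight_AC"):
        ac = _require_ac(ctx, method)
        norm_ac = float(np.linalg.norm(ac))
        if degenerate or norm_ac < DEGENERACY_EPS:
            return 0.0, True
        cos = float(np.dot(p, ac) / (norm_p * norm_ac))
        if method == "cos_AC":
            return cos, False
        return cos * significance_weight(p), False
    if method == "dot_p_AC":
        ac = _require_ac(ctx, method)
        return float(np.dot(p, ac)), False
    if method == "scalar_projection_AC":
        ac = _require_ac(ctx, method)
        norm_ac = float(np.linalg.norm(ac))
        if norm_ac < DEGENERACY_EPS:
            return 0.0, True
        return float(np.dot(p, ac) / norm_ac), False
    if method == "vec_norm":
        return norm_p, False
    if method == "euc_NC":
        return float(np.linalg.norm(p - ctx.nc_center)), False
    if method == "maha_NC":
        d = p - ctx.nc_center
        return float(np.sqrt(d @ ctx.nc_cov_inv @ d)), False
    if method == "num_readouts_changed":
        return float(np.sum(np.abs(p) > READOUT_CHANGED_THRESHOLD)), False
    if method == "euc_AC":
        ac = _require_ac(ctx, method)
        return float(np.linalg.norm(p - ac)), False
    if method == "maha_AC":
        ac = _require_ac(ctx, method)
        d = p - ac
        return float(np.sqrt(d @ ctx.nc_cov_inv @ d)), False
    raise ValueError(f"unknown method {method!r}")


def compute_score(profile, ctx: ReferenceContext, method: str) -> float:
    """Raw signature-summary score of one per-gene rscore profile.

    Directionally degenerate profiles (norm < 1e-9) score 0 for
    angle/correlation methods so dose-response series remain fittable.
    """
    return _score(profile, ctx, method)[0]


def percent_activity(raw_score: float, ctx: ReferenceContext, method: str) -> float:
    """Rescale a raw score so the NC centre maps to 0% and the AC to 100%.

    For most methods this is ``100·(score − nc_centre)/(ac_centre −
    nc_centre)`` with centres the median method scores over NC and AC
    wells.  ``euc_AC``/``maha_AC`` measure distance *to* the AC, so they
    use ``100·(d(NC→AC) − score)/d(NC→AC)``: an exact AC match scores 100%
    and the NC centre 0%.
    """
    if method in AC_SIMILARITY_METHODS:
        d_ref = _score(ctx.nc_center, ctx, method)[0]
        if d_ref < DEGENERACY_EPS:
            raise IntegrityError(
                f"AC and NC centres coincide; {method!r} is uninformative"
            )
        return 100.0 * (d_ref - raw_score) / d_ref
    nc_c = ctx.nc_score_center.get(method)
    ac_c = ctx.ac_score_center.get(method)
    if nc_c is None or ac_c is None:
        raise IntegrityError(f"score centres for {method!r} not available")
    if ac_c == nc_c:
        raise IntegrityError(
            f"AC and NC score centres coincide; {method!r} is uninformative "
            "on this plate"
        )
    return 100.0 * (raw_score - nc_c) / (ac_c - nc_c)


@dataclass
class ScoreSeries:
    """Per-concentration scores of one compound under one method."""

    compound_id: str
    method: str
    biological_replicate_id: str
    concentrations_uM: np.ndarray  # strictly increasing
    raw_score: np.ndarray  # median over technical replicates
    percent_activity: np.ndarray
    well_scores: pd.DataFrame | None = None  # per-replicate detail

    def __post_init__(self) -> None:
        if np.any(np.diff(self.concentrations_uM) <= 0):
            raise IntegrityError("concentrations must be strictly increasing")


def score_treatments(
    pset: PlateExpressionSet,
    sig: GeneSignature | None = None,
    methods: tuple[str, ...] = ALL_METHODS,
    ctx: ReferenceContext | None = None,
) -> list[ScoreSeries]:
    """Score every compound × method on a plate.

    Wells are scored individually; technical replicates at the same
    concentration are summarised by their median score (the per-replicate
    scores are kept in ``well_scores``).  Biological replicates yield
    separate series.  Without AC wells only non-AC-referenced methods are
    produced.
    """
    if sig is not None:
        pset = subset_to_signature(pset, sig)
    if ctx is None:
        ctx = build_reference_context(pset, methods)
    usable = [m for m in methods if ctx.ac_vector is not None or m not in AC_REFERENCED]
    if not usable:
        raise IntegrityError("no AC wells and only AC-referenced methods requested")

    comp_idx = pset.wells_with_role(Role.COMPOUND)
    meta = pset.wells.loc[comp_idx]
    series: list[ScoreSeries] = []
    for (compound, bio), widx in meta.groupby(
        ["compound_id", "biological_replicate_id"], sort=True
    ).groups.items():
        rows = pset.values.loc[widx].values.astype(float)
        concs = meta.loc[widx, "concentration_uM"].values.astype(float)
        for m in usable:
            raw = np.array([_score(r, ctx, m)[0] for r in rows])
            detail = pd.DataFrame(
                {
                    "well_id": list(widx),
                    "concentration_uM": concs,
                    "raw_score": raw,
                    "technical_replicate_id": meta.loc[
                        widx, "technical_replicate_id"
                    ].values,
                }
            )
            agg = (
                detail.groupby("concentration_uM")["raw_score"]
                .median()
                .sort_index()
            )
            if ctx.ac_vector is None:
                # no AC on the plate: raw scores only, no 100% anchor
                pct = np.full(len(agg), np.nan)
            else:
                pct = np.array([percent_activity(s, ctx, m) for s in agg.values])
            series.append(
                ScoreSeries(
                    compound_id=str(compound),
                    method=m,
                    biological_replicate_id=str(bio),
                    concentrations_uM=agg.index.values,
                    raw_score=agg.values,
                    percent_activity=pct,
                    well_scores=detail,
                )
            )
    return series


class SignatureScorer(BaseEstimator, TransformerMixin):
    """Scikit-learn style scorer: ``fit`` learns the plate's AC/NC reference
    context, ``transform`` returns per-well scores.

    Parameters
    ----------
    signature : GeneSignature or None
        Readout subspace; ``None`` uses all plate genes.
    methods : tuple of str
        Subset of :data:`ALL_METHODS`.

    Attributes
    ----------
    context_ : ReferenceContext
    """

    def __init__(
        self,
        signature: GeneSignature | None = None,
        methods: tuple[str, ...] = ALL_METHODS,
    ):
        self.signature = signature
        self.methods = methods

    def _prepare(self, pset: PlateExpressionSet) -> PlateExpressionSet:
        if self.signature is not None:
            return subset_to_signature(pset, self.signature)
        return pset

    def fit(self, pset: PlateExpressionSet, y=None):
        for m in self.methods:
            if m not in ALL_METHODS:
                raise ValueError(f"unknown method {m!r}")
        self.context_ = build_reference_context(self._prepare(pset), tuple(self.methods))
        return self

    def transform(self, pset: PlateExpressionSet) -> pd.DataFrame:
        """Tidy per-well score table (well_id × method, raw and percent)."""
        prepared = self._prepare(pset)
        ctx = self.context_
        usable = [
            m for m in self.methods if ctx.ac_vector is not None or m not in AC_REFERENCED
        ]
        records = []
        for well_id, row in prepared.values.iterrows():
            for m in usable:
                raw, degen = _score(row.values.astype(float), ctx, m)
                records.append(
                    {
                        "well_id": well_id,
                        "method": m,
                        "raw_score": raw,
                        "percent_activity": (
                            percent_activity(raw, ctx, m)
                            if ctx.ac_vector is not None
                            else np.nan
                        ),
                        "degenerate": degen,
                    }
                )
        return pd.DataFrame.from_records(records)

    def score_series(self, pset: PlateExpressionSet) -> list[ScoreSeries]:
        """Per compound × method dose-response series (see
        :func:`score_treatments`)."""
        return score_treatments(
            self._prepare(pset), methods=tuple(self.methods), ctx=self.context_
        )
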
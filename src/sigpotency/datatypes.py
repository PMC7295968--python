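"""Core domain types shared across the package.

The central container is :class:`PlateExpressionSet`: a well × gene numeric
matrix with well metadata (control role, compound, concentration, replicate
structure) and gene metadata (probe id, housekeeper flag).  A ``scale`` tag
records what the numbers mean (raw mRNA counts, fold changes, robust
z-scores/rscores, or externally supplied z-scores) so that each normalization
step can check its precondition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "IntegrityError",
    "Role",
    "Scale",
    "PlateExpressionSet",
    "GeneSignature",
    "ConcentrationGrid",
    "ReferencePotency",
    "harmonize_name",
]


class FormatError(ValueError):
    """A file or table does not conform to the expected format."""


class IntegrityError(ValueError):
    """Data parses but violates an internal consistency requirement."""


class Role:
    """Well roles: neutral control, active control, test compound."""

    NC = "NC"
    AC = "AC"
    COMPOUND = "COMPOUND"

    ALL = frozenset({NC, AC, COMPOUND})


class Scale:
    """Value scales a plate matrix can carry."""

    COUNTS = "counts"
    FOLDCHANGE = "foldchange"
    RSCORE = "rscore"
    ZSCORE = "z-score"

    ALL = frozenset({COUNTS, FOLDCHANGE, RSCORE, ZSCORE})


#: metadata columns every well table carries
WELL_COLUMNS = (
    "plate_id",
    "role",
    "compound_id",
    "concentration_uM",
    "technical_replicate_id",
    "biological_replicate_id",
)

GENE_COLUMNS = ("probe_id", "is_housekeeper")


def harmonize_name(name: str) -> str:
    """Canonical compound/cell-line name for evaluation joins.

    Lowercase, with whitespace and ``-`` removed, so e.g. ``"CGP-20712 A"``
    and ``"cgp20712a"`` join.
    """
    return "".join(str(name).lower().split()).replace("-", "")


@dataclass
class PlateExpressionSet:
    """Well × gene expression matrix plus well and gene metadata.

    Parameters
    ----------
    values
        Numeric DataFrame; index = well ids, columns = gene symbols (or
        probe-level symbols before collapse).
    wells
        Per-well metadata indexed like ``values``; columns
        ``plate_id, role, compound_id, concentration_uM,
        technical_replicate_id, biological_replicate_id``.
    genes
        Per-gene metadata indexed like ``values.columns``; columns
        ``probe_id, is_housekeeper``.
    scale
        One of :class:`Scale`.
    attrs
        Free-form provenance (e.g. counts of signature genes mapped).
    """

    values: pd.DataFrame
    wells: pd.DataFrame
    genes: pd.DataFrame
    scale: str = Scale.COUNTS
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.scale not in Scale.ALL:
            raise IntegrityError(f"unknown scale {self.scale!r}")
        if not self.values.index.equals(self.wells.index):
            raise IntegrityError("values and wells indices differ")
        if not self.values.columns.equals(self.genes.index):
            raise IntegrityError("values columns and genes index differ")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise IntegrityError(f"duplicate well id {dup!r}")
        missing = [c for c in WELL_COLUMNS if c not in self.wells.columns]
        if missing:
            raise FormatError(f"well metadata lacks columns {missing}")
        bad_roles = set(self.wells["role"]) - Role.ALL
        if bad_roles:
            raise IntegrityError(f"unknown well roles {sorted(bad_roles)}")
        if self.values.isna().any().any():
            well = self.values.index[self.values.isna().any(axis=1)][0]
            raise IntegrityError(f"missing value in well {well!r}")
        conc = pd.to_numeric(
            self.wells.loc[self.wells["role"] == Role.COMPOUND, "concentration_uM"],
            errors="coerce",
        )
        if conc.isna().any() or (conc <= 0).any():
            raise IntegrityError(
                "all COMPOUND wells need a finite positive concentration_uM"
            )

    # -- convenience --------------------------------------------------------
    @property
    def n_wells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def wells_with_role(self, role: str) -> pd.Index:
        return self.wells.index[self.wells["role"] == role]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "PlateExpressionSet":
        """New set sharing metadata for the (possibly re-columned) matrix."""
        genes = self.genes.loc[values.columns]
        wells = self.wells.loc[values.index]
        return PlateExpressionSet(
            values=values,
            wells=wells,
            genes=genes,
            scale=self.scale if scale is None else scale,
            attrs=dict(self.attrs),
        )

    def subset_wells(self, well_ids: Iterable) -> "PlateExpressionSet":
        idx = pd.Index(well_ids)
        return PlateExpressionSet(
            values=self.values.loc[idx],
            wells=self.wells.loc[idx],
            genes=self.genes,
            scale=self.scale,
            attrs=dict(self.attrs),
        )

    def copy(self) -> "PlateExpressionSet":
        return PlateExpressionSet(
            values=self.values.copy(),
            wells=self.wells.copy(),
            genes=self.genes.copy(),
            scale=self.scale,
            attrs=dict(self.attrs),
        )


@dataclass(frozen=True)
class GeneSignature:
    """Named, ordered gene list defining the readout subspace."""

    name: str
    genes: tuple[str, ...]
    expected_direction: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        if not genes:
            raise IntegrityError(f"signature {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            dup = [g for g in genes if genes.count(g) > 1][0]
            raise IntegrityError(
                f"signature {self.name!r} lists gene {dup!r} more than once"
            )
        if self.expected_direction is not None:
            ed = tuple(int(s) for s in self.expected_direction)
            object.__setattr__(self, "expected_direction", ed)
            if len(ed) != len(genes):
                raise IntegrityError("expected_direction length != gene count")
            if not set(ed) <= {-1, 1}:
                raise IntegrityError("expected_direction entries must be ±1")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ConcentrationGrid:
    """Strictly increasing positive concentrations, in µM."""

    concentrations_uM: tuple[float, ...]

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations_uM)
        object.__setattr__(self, "concentrations_uM", conc)
        arr = np.asarray(conc, dtype=float)
        if arr.size == 0:
            raise IntegrityError("empty concentration grid")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise IntegrityError("concentrations must be finite and > 0")
        if np.any(np.diff(arr) <= 0):
            raise IntegrityError("concentrations must be strictly increasing")

    @classmethod
    def log_spaced(cls, low_uM: float, high_uM: float, n: int) -> "ConcentrationGrid":
        return cls(tuple(np.logspace(np.log10(low_uM), np.log10(high_uM), n)))

    @property
    def min_uM(self) -> float:
        return self.concentrations_uM[0]

    @property
    def max_uM(self) -> float:
        return self.concentrations_uM[-1]

    def __len__(self) -> int:
        return len(self.concentrations_uM)

    def __iter__(self):
        return iter(self.concentrations_uM)


@dataclass(frozen=True)
class ReferencePotency:
    """Reference potency (e.g. cAMP EC50 or GR50) for one compound.

    ``flat_curve`` marks a reference dose-response that never responded;
    ``grinf`` is that curve's fitted infinite-concentration growth value,
    used to censor flat curves to one log unit outside the tested range.
    """

    compound_id: str
    potency_uM: float | None
    grinf: float | None = None
    flat_curve: bool = False

    def __post_init__(self) -> None:
        if self.potency_uM is not None and not self.potency_uM > 0:
            raise IntegrityError(
                f"reference potency for {self.compound_id!r} must be > 0"
            )
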
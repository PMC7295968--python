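"""Synthetic plate generator.

The generative model mirrors the geometric decomposition the scoring
methods exploit: every well is a point in gene-expression (rscore) space,
the AC signature defines a direction and a magnitude, and a compound's
response moves along its own direction with a 4PL dose dependence:

* NC wells: isotropic Gaussian noise (sd ``noise_sd`` rscore units).
* AC wells: ``ac_amplitude · ac_direction`` + noise.
* Compound wells at concentration c:
  ``E(c) · emax_scale · ac_amplitude · d_compound`` + noise, with
  ``E(c) = 1/(1 + (EC50/c)^hill)`` rising from 0 to 1 and ``d_compound``
  the AC direction rotated by ``offdir_angle_deg`` within a seeded random
  plane.

``emax_scale > 1`` reproduces the amplitude-overshoot regime in which a
compound's expression magnitude exceeds the active control at high
concentrations — the situation that separates direction-based from
magnitude-based potency estimates and bends AC-similarity curves into
bells.  ``simulate_raw_counts`` inverts the fold-change/rscore chain so
the normalization module can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ConcentrationGrid, PlateExpressionSet, Role, Scale

__all__ = [
    "CompoundSpec",
    "SimulationConfig",
    "simulate_plate",
    "simulate_raw_counts",
    "overshoot_benchmark_config",
]

DEFAULT_GRID = ConcentrationGrid.log_spaced(1e-5, 100.0, 8)  # µM, 8-pt 10-fold


@dataclass(frozen=True)
class CompoundSpec:
    """Ground truth for one simulated compound."""

    compound_id: str
    true_ec50_uM: float
    true_hill: float = 1.0
    emax_scale: float = 1.0  # response amplitude as multiple of the AC amplitude
    offdir_angle_deg: float = 0.0  # angular deviation from the AC direction
    noise_sd: float | None = None  # None -> config-level noise_sd

    def __post_init__(self) -> None:
        if not self.true_ec50_uM > 0:
            raise ValueError("true_ec50_uM must be > 0")
        if self.emax_scale < 0:
            raise ValueError("emax_scale must be >= 0")
        if not 0 <= self.offdir_angle_deg <= 180:
            raise ValueError("offdir_angle_deg must be in [0, 180]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated plate.

    Defaults emulate the multiplexed bead-assay setting: a 7-gene
    signature whose AC amplitude corresponds to ≈5 robust SD per gene
    (vector norm 13.2), 24 NC wells, 6 AC wells, 6 technical replicates
    per compound concentration, unit rscore noise, and an 8-point 10-fold
    dilution grid from 1e-5 to 100 µM.
    """

    compounds: tuple[CompoundSpec, ...]
    n_genes: int = 7
    ac_direction: tuple[float, ...] | None = None  # unit vector; None -> seeded
    ac_amplitude: float = 13.2
    n_nc_wells: int = 24
    n_ac_wells: int = 6
    n_tech_replicates: int = 6
    noise_sd: float = 1.0
    grid: ConcentrationGrid = DEFAULT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_genes < 2 and any(c.offdir_angle_deg > 0 for c in self.compounds):
            raise ValueError("off-direction rotation needs n_genes >= 2")
        if self.ac_direction is not None:
            v = np.asarray(self.ac_direction, dtype=float)
            if v.shape != (self.n_genes,):
                raise ValueError("ac_direction length must equal n_genes")
            if np.linalg.norm(v) == 0:
                raise ValueError("ac_direction must be non-zero")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotated_direction(
    u: np.ndarray, angle_deg: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate unit vector ``u`` by ``angle_deg`` within a random plane."""
    # always draw, so the rng stream does not depend on the angle
    raw = rng.standard_normal(u.shape[0])
    if u.shape[0] == 1:
        return u.copy(), np.zeros_like(u)
    v = raw - np.dot(raw, u) * u
    nv = np.linalg.norm(v)
    if nv < 1e-12:  # pathological draw: retry deterministically
        raw = rng.standard_normal(u.shape[0])
        v = raw - np.dot(raw, u) * u
        nv = np.linalg.norm(v)
    v = v / nv
    a = np.deg2rad(angle_deg)
    return np.cos(a) * u + np.sin(a) * v, v


def _hill_activation(c: np.ndarray, ec50: float, hill: float) -> np.ndarray:
    return 1.0 / (1.0 + (ec50 / np.asarray(c, dtype=float)) ** hill)


def _layout(config: SimulationConfig):
    """Deterministic well order: NC, AC, then compounds × conc × replicate."""
    rows = []
    for i in range(config.n_nc_wells):
        rows.append(("NC_%02d" % (i + 1), Role.NC, "", np.nan, str(i + 1)))
    for i in range(config.n_ac_wells):
        rows.append(("AC_%02d" % (i + 1), Role.AC, "AC", np.nan, str(i + 1)))
    for comp in config.compounds:
        for ci, conc in enumerate(config.grid):
            for r in range(config.n_tech_replicates):
                rows.append(
                    (
                        f"{comp.compound_id}_c{ci + 1:02d}_r{r + 1}",
                        Role.COMPOUND,
                        comp.compound_id,
                        conc,
                        str(r + 1),
                    )
                )
    wells = pd.DataFrame(
        rows,
        columns=["well_id", "role", "compound_id", "concentration_uM",
                 "technical_replicate_id"],
    ).set_index("well_id")
    wells["plate_id"] = "plate_1"
    wells["biological_replicate_id"] = "bio_1"
    return wells


def _signal_matrix(config: SimulationConfig, rng: np.random.Generator):
    """Noise-free expected rscores per well plus per-well noise sd."""
    if config.ac_direction is None:
        u = _unit(rng.standard_normal(config.n_genes))
    else:
        u = _unit(np.asarray(config.ac_direction, dtype=float))
        rng.standard_normal(config.n_genes)  # keep stream layout fixed

    wells = _layout(config)
    signal = np.zeros((len(wells), config.n_genes))
    noise_sd = np.full(len(wells), config.noise_sd)
    planes: dict[str, list[float]] = {}

    ac_rows = wells["role"] == Role.AC
    signal[ac_rows.values] = config.ac_amplitude * u

    offset = int(config.n_nc_wells + config.n_ac_wells)
    per_compound = len(config.grid) * config.n_tech_replicates
    for k, comp in enumerate(config.compounds):
        d, plane = _rotated_direction(u, comp.offdir_angle_deg, rng)
        planes[comp.compound_id] = plane.tolist()
        e = _hill_activation(
            np.asarray(config.grid.concentrations_uM), comp.true_ec50_uM, comp.true_hill
        )
        block = np.repeat(e, config.n_tech_replicates)[:, None] * (
            comp.emax_scale * config.ac_amplitude * d
        )
        sl = slice(offset + k * per_compound, offset + (k + 1) * per_compound)
        signal[sl] = block
        if comp.noise_sd is not None:
            noise_sd[sl] = comp.noise_sd
    return wells, signal, noise_sd, u, planes


def simulate_plate(config: SimulationConfig) -> PlateExpressionSet:
    """Simulate a plate directly on the rscore scale.

    Deterministic for a given config (including seed); the AC direction
    and each compound's rotation plane are recorded in ``attrs``.
    """
    rng = np.random.default_rng(config.seed)
    wells, signal, noise_sd, u, planes = _signal_matrix(config, rng)
    noise = rng.standard_normal(signal.shape) * noise_sd[:, None]
    genes = ["G%02d" % (i + 1) for i in range(config.n_genes)]
    values = pd.DataFrame(signal + noise, index=wells.index, columns=genes)
    gene_meta = pd.DataFrame(
        {"probe_id": genes, "is_housekeeper": False}, index=genes
    )
    pset = PlateExpressionSet(
        values=values, wells=wells, genes=gene_meta, scale=Scale.RSCORE
    )
    pset.attrs["ac_direction"] = u.tolist()
    pset.attrs["rotation_planes"] = planes
    pset.attrs["truth"] = {
        c.compound_id: {
            "true_ec50_uM": c.true_ec50_uM,
            "true_hill": c.true_hill,
            "emax_scale": c.emax_scale,
            "offdir_angle_deg": c.offdir_angle_deg,
        }
        for c in config.compounds
    }
    return pset


def simulate_raw_counts(
    config: SimulationConfig,
    nc_baseline_counts: float | np.ndarray = 1000.0,
    fc_per_rscore: float = 10.0,
) -> PlateExpressionSet:
    """Raw-count plate that round-trips through fold_change → rscore.

    The rscore plate of :func:`simulate_plate` (same seed and draws) is
    mapped to fold changes and counts.  Treated and AC wells are anchored
    to the *sample* NC median and MAD of this plate's own NC draws, so
    re-normalizing recovers their target rscores exactly; NC wells
    themselves come back re-standardised (median 0 / robust SD 1), i.e.
    within the NC-statistics estimation noise of their targets.
    """
    baseline = np.broadcast_to(
        np.asarray(nc_baseline_counts, dtype=float), (config.n_genes,)
    )
    if np.any(baseline <= 0):
        raise ValueError("nc_baseline_counts must be positive")
    if config.noise_sd == 0:
        raise ValueError(
            "noise_sd = 0 leaves the NC MAD undefined; counts cannot be inverted"
        )
    target = simulate_plate(config)
    r = target.values.values
    nc_mask = (target.wells["role"] == Role.NC).values
    nc_fc = fc_per_rscore * r[nc_mask]
    m = np.median(nc_fc, axis=0)
    s = sps.median_abs_deviation(nc_fc, axis=0, scale="normal")
    if np.any(s == 0):
        raise ValueError("degenerate NC draws (zero MAD); increase n_nc_wells")

    fc = m + s * r  # treated wells invert exactly against sample NC stats
    fc[nc_mask] = nc_fc
    counts = baseline[None, :] * 2.0 ** (fc / 50.0)
    out = target.with_values(
        pd.DataFrame(counts, index=target.values.index, columns=target.values.columns),
        scale=Scale.COUNTS,
    )
    out.attrs["fc_per_rscore"] = fc_per_rscore
    return out


def overshoot_benchmark_config(
    n_compounds: int = 20,
    emax_scale: float = 3.0,
    ec50_range_uM: tuple[float, float] = (1e-3, 100.0),
    seed: int = 0,
    **kwargs,
) -> SimulationConfig:
    """Benchmark plate for the amplitude-overshoot regime.

    ``n_compounds`` true EC50s are log-spaced over ``ec50_range_uM``
    (5 logs by default) with every compound overshooting the AC amplitude
    by ``emax_scale``; used to contrast direction- and magnitude-based
    potency estimates against the simulation truth.
    """
    lo, hi = np.log10(ec50_range_uM[0]), np.log10(ec50_range_uM[1])
    compounds = tuple(
        CompoundSpec(
            compound_id="cmp%02d" % (i + 1),
            true_ec50_uM=float(10.0 ** e),
            emax_scale=emax_scale,
        )
        for i, e in enumerate(np.linspace(lo, hi, n_compounds))
    )
    return SimulationConfig(compounds=compounds, seed=seed, **kwargs)
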
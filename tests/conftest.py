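"""Shared fixtures: small hand-built plates and an independent straight-line
reimplementation of every scoring formula (the oracle the vectorised code is
checked against)."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from sigpotency.datatypes import PlateExpressionSet, Role, Scale


def make_plate(
    values: np.ndarray,
    roles: list[str],
    gene_names: list[str] | None = None,
    concentrations: list[float] | None = None,
    compounds: list[str] | None = None,
    scale: str = Scale.COUNTS,
    probe_ids: list[str] | None = None,
    tech_reps: list[str] | None = None,
    bio_reps: list[str] | None = None,
) -> PlateExpressionSet:
    """Hand-build a PlateExpressionSet from a well × gene array."""
    values = np.asarray(values, dtype=float)
    n_wells, n_genes = values.shape
    genes = gene_names or [f"G{i+1}" for i in range(n_genes)]
    well_ids = [f"w{i+1}" for i in range(n_wells)]
    wells = pd.DataFrame(
        {
            "plate_id": "p1",
            "role": roles,
            "compound_id": compounds or ["" if r != Role.COMPOUND else "cmpd" for r in roles],
            "concentration_uM": concentrations
            or [np.nan if r != Role.COMPOUND else 1.0 for r in roles],
            "technical_replicate_id": tech_reps or ["1"] * n_wells,
            "biological_replicate_id": bio_reps or ["b1"] * n_wells,
        },
        index=well_ids,
    )
    gene_meta = pd.DataFrame(
        {"probe_id": probe_ids or genes, "is_housekeeper": False}, index=genes
    )
    return PlateExpressionSet(
        values=pd.DataFrame(values, index=well_ids, columns=genes),
        wells=wells,
        genes=gene_meta,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# brute-force scoring oracle (pure python loops, no shared code path)
# ---------------------------------------------------------------------------
def _mean(xs):
    return sum(xs) / len(xs)


def _median(xs):
    s = sorted(xs)
    n = len(s)
    return s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])


def _pearson(x, y):
    mx, my = _mean(x), _mean(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)) * math.sqrt(
        sum((b - my) ** 2 for b in y)
    )
    return num / den


def _ranks(x):
    """Average ranks (1-based) with ties."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_force_score(profile, ac, nc_rows, cov_inv, method) -> float:
    """Straight-line reimplementation of each summary formula."""
    p = list(map(float, profile))
    a = list(map(float, ac))
    n = len(p)
    nc_center = [_median([row[g] for row in nc_rows]) for g in range(n)]

    if method == "cor_p_AC":
        return _pearson(p, a)
    if method == "cor_s_AC":
        return _pearson(_ranks(p), _ranks(a))
    if method == "cos_AC":
        dot = sum(x * y for x, y in zip(p, a))
        return dot / (
            math.sqrt(sum(x * x for x in p)) * math.sqrt(sum(y * y for y in a))
        )
    if method == "cos_weight_AC":
        w = min(1.0, _mean([abs(x) for x in p]) / 3.0)
        return brute_force_score(p, a, nc_rows, cov_inv, "cos_AC") * w
    if method == "dot_p_AC":
        return sum(x * y for x, y in zip(p, a))
    if method == "scalar_projection_AC":
        return sum(x * y for x, y in zip(p, a)) / math.sqrt(sum(y * y for y in a))
    if method == "vec_norm":
        return math.sqrt(sum(x * x for x in p))
    if method == "euc_NC":
        return math.sqrt(sum((x - c) ** 2 for x, c in zip(p, nc_center)))
    if method == "maha_NC":
        d = [x - c for x, c in zip(p, nc_center)]
        q = sum(d[i] * cov_inv[i][j] * d[j] for i in range(n) for j in range(n))
        return math.sqrt(q)
    if method == "num_readouts_changed":
        return float(sum(1 for x in p if abs(x) > 3.0))
    if method == "euc_AC":
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(p, a)))
    if method == "maha_AC":
        d = [x - y for x, y in zip(p, a)]
        q = sum(d[i] * cov_inv[i][j] * d[j] for i in range(n) for j in range(n))
        return math.sqrt(q)
    raise ValueError(method)


@pytest.fixture
def plate_factory():
    return make_plate


@pytest.fixture
def bruteforce():
    return brute_force_score
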
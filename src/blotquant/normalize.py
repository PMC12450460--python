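"""BCA normalization, internal-control subtraction, replicate statistics.

The pipeline behind the per-strain abundance figures: per-well median
intensities are divided by the BCA total-protein concentration of the
well, the pooled mean of the two internal controls (buffer-only wells
and untagged-strain wells) is subtracted, and the mean of the resulting
background-subtracted normalized medians across replicates is the
sample's integrated intensity. Samples are ranked ascending by
integrated intensity, and pairwise differences are assessed with the
Wilcoxon rank-sum (Mann-Whitney U) test.

Control wells carry no BCA value of their own (no cells, or no tagged
protein); they are normalized by the plate-median BCA of the sample
wells so that control and sample signals stay on the same scale.
Background-subtracted negatives are retained, not clipped, to keep
replicate means unbiased.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .plate_io import CONTROL_ROLES, ROLE_SAMPLE, PlateMap

SAMPLE_COLUMNS = ["sample", "n", "integrated_intensity", "sd", "sem", "rank"]


@dataclass
class SampleRecord:
    """One sample's replicate wells and derived intensities."""

    sample_id: str
    replicate_wells: list[str]
    role: str
    bca_concentration: float | None
    raw_medians: list[float] = field(default_factory=list)
    normalized: list[float] = field(default_factory=list)
    background_subtracted: list[float] = field(default_factory=list)

    @property
    def integrated_intensity(self) -> float:
        return float(np.mean(self.background_subtracted))

    @property
    def n_replicates(self) -> int:
        return len(self.background_subtracted)


def normalize_bca(median: float, bca: float) -> float:
    """Median intensity divided by the BCA protein concentration."""
    if bca <= 0:
        raise ValueError("BCA concentration must be positive")
    return median / bca


def subtract_background(normalized: list[float], background: float) -> list[float]:
    """Elementwise subtraction; negatives are retained, not clipped."""
    return [v - background for v in normalized]


def aggregate(values: list[float]) -> tuple[float, float, float]:
    """Replicate mean, sample sd (n-1) and sem.

    For a single replicate the sd and sem are undefined and reported as
    NaN.
    """
    if len(values) == 0:
        raise ValueError("cannot aggregate an empty replicate list")
    mean = float(np.mean(values))
    if len(values) == 1:
        return mean, math.nan, math.nan
    sd = float(np.std(values, ddof=1))
    return mean, sd, sd / math.sqrt(len(values))


def _well_medians(measurements: pd.DataFrame) -> dict[str, float]:
    return dict(zip(measurements["well"], measurements["median"].astype(float)))


def build_sample_records(
    plate_map: PlateMap, measurements: pd.DataFrame
) -> list[SampleRecord]:
    """Join plate map and well measurements into normalized sample records.

    Each sample_id collects its replicate wells; both control roles keep
    one record per control sample_id as well, so the background can be
    recomputed downstream.
    """
    medians = _well_medians(measurements)
    sample_bcas = [
        e.bca_concentration
        for e in plate_map.entries
        if e.role == ROLE_SAMPLE and e.bca_concentration is not None
    ]
    if not sample_bcas:
        raise ValueError("plate map contains no sample wells with BCA values")
    plate_median_bca = float(np.median(sample_bcas))

    records: dict[str, SampleRecord] = {}
    for e in plate_map.entries:
        if e.well not in medians:
            raise KeyError(f"plate map well {e.well} has no measurement")
        rec = records.get(e.sample_id)
        if rec is None:
            rec = SampleRecord(
                sample_id=e.sample_id,
                replicate_wells=[],
                role=e.role,
                bca_concentration=e.bca_concentration,
            )
            records[e.sample_id] = rec
        bca = e.bca_concentration if e.bca_concentration is not None else plate_median_bca
        rec.replicate_wells.append(e.well)
        rec.raw_medians.append(medians[e.well])
        rec.normalized.append(normalize_bca(medians[e.well], bca))
    return list(records.values())


def control_background(records: list[SampleRecord]) -> float:
    """Pooled per-well mean of normalized intensity over both control roles."""
    pooled: list[float] = []
    present_roles: set[str] = set()
    for rec in records:
        if rec.role in CONTROL_ROLES:
            pooled.extend(rec.normalized)
            present_roles.add(rec.role)
    missing = CONTROL_ROLES - present_roles
    if missing:
        raise ValueError(f"required control role(s) absent: {sorted(missing)}")
    return float(np.mean(pooled))


def apply_background(records: list[SampleRecord], background: float) -> None:
    for rec in records:
        rec.background_subtracted = subtract_background(rec.normalized, background)


def rank_samples(records: list[SampleRecord]) -> pd.DataFrame:
    """Aggregate and rank sample records ascending by integrated intensity.

    Ties are broken lexicographically by sample id; control records are
    excluded. Columns: sample, n, integrated_intensity, sd, sem, rank.
    """
    rows = []
    for rec in records:
        if rec.role != ROLE_SAMPLE:
            continue
        mean, sd, sem = aggregate(rec.background_subtracted)
        rows.append(
            {
                "sample": rec.sample_id,
                "n": rec.n_replicates,
                "integrated_intensity": mean,
                "sd": sd,
                "sem": sem,
            }
        )
    df = pd.DataFrame(rows, columns=SAMPLE_COLUMNS[:-1])
    df = df.sort_values(
        ["integrated_intensity", "sample"], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def process_plate(plate_map: PlateMap, measurements: pd.DataFrame) -> pd.DataFrame:
    """Full normalization pipeline: records -> background -> ranked table."""
    records = build_sample_records(plate_map, measurements)
    background = control_background(records)
    apply_background(records, background)
    return rank_samples(records)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney U)

EXACT_MAX_N = 12  # full enumeration of rank splits up to n + m = 12


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x, computed from midranks of the pooled sample."""
    n, m = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[:n].sum() - n * (n + 1) / 2)


def _exact_p(u_obs: float, n: int, m: int, alternative: str) -> float:
    """Exact p by full enumeration of the C(n+m, n) rank assignments."""
    total = n + m
    base = n * (n + 1) / 2
    us = [
        sum(combo) - base
        for combo in itertools.combinations(range(1, total + 1), n)
    ]
    n_comb = len(us)
    if alternative == "less":
        count = sum(1 for u in us if u <= u_obs)
    elif alternative == "greater":
        count = sum(1 for u in us if u >= u_obs)
    else:  # two-sided: distance from the null mean nm/2
        center = n * m / 2
        d_obs = abs(u_obs - center)
        count = sum(1 for u in us if abs(u - center) >= d_obs - 1e-12)
    return count / n_comb


def _approx_p(
    u_obs: float, n: int, m: int, tie_counts: np.ndarray, alternative: str
) -> float:
    """Normal approximation with tie correction and continuity correction."""
    total = n + m
    mu = n * m / 2
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (total * (total - 1))
    var = n * m / 12 * ((total + 1) - tie_term)
    if var <= 0:  # all pooled values identical
        return 1.0
    sigma = math.sqrt(var)
    if alternative == "two-sided":
        z = max(abs(u_obs - mu) - 0.5, 0.0) / sigma
        return min(2 * stats.norm.sf(z), 1.0)
    if alternative == "greater":
        z = (u_obs - mu - 0.5) / sigma
        return float(stats.norm.sf(z))
    z = (u_obs - mu + 0.5) / sigma
    return float(stats.norm.cdf(z))


def wilcoxon_rank_sum(
    x: list[float], y: list[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum test of x against y.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x``.
    The p-value is exact (full enumeration of rank assignments) when
    n + m <= 12 and the pooled data are tie-free; otherwise the normal
    approximation with tie and continuity corrections is used.
    ``alternative`` is one of ``two-sided``, ``less`` (x shifted below
    y) or ``greater``.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = xa.size, ya.size
    u = _u_statistic(xa, ya)
    pooled = np.concatenate([xa, ya])
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    if n + m <= EXACT_MAX_N and not has_ties:
        p = _exact_p(u, n, m, alternative)
    else:
        p = _approx_p(u, n, m, tie_counts, alternative)
    return u, p


def pairwise_tests(
    records: list[SampleRecord], alternative: str = "two-sided"
) -> pd.DataFrame:
    """Wilcoxon rank-sum test between every pair of samples' replicates."""
    sample_recs = sorted(
        (r for r in records if r.role == ROLE_SAMPLE), key=lambda r: r.sample_id
    )
    rows = []
    for ra, rb in itertools.combinations(sample_recs, 2):
        u, p = wilcoxon_rank_sum(
            ra.background_subtracted, rb.background_subtracted, alternative
        )
        rows.append({"sample_a": ra.sample_id, "sample_b": rb.sample_id, "U": u, "p": p})
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "U", "p"])
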
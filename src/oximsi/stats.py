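"""Study measurement tables and nonparametric pre/post comparisons.

The per-animal, per-site oxygen-saturation and perfusion-index measurements
(pulse oximetry and multispectral imaging, rabbit and sheep cohorts) are
packaged as long-format CSV fixtures, together with every printed
"Mean ± SD" summary cell and a documented exclusion list for the handful of
multispectral rabbit-table summary cells that are internally inconsistent
with their own row values (recorded as discrepancies, never corrected).

Pre/post comparisons pool the four cornua sites per phase and use the
two-sided Mann–Whitney U test — exact by full enumeration for small,
untied samples, otherwise the tie- and continuity-corrected normal
approximation — with significance declared at p < 0.05.

A printed-table quirk made explicit here: O₂Sat means are printed in percent
while their SDs are printed as a fraction of 1 (e.g. "98 ± 0.02"); the SD
convention is therefore an explicit argument, never a silent unit mix.  The
day-89 pre-embryo-transfer column of the multispectral rabbit table is
included in that table's post-transplant summary cells (the printed "All UTx"
means demonstrably include it) but excluded from hypothesis tests by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsError",
    "ComparisonResult",
    "SiteSummary",
    "TABLE_IDS",
    "round_half_up",
    "load_study_tables",
    "load_printed_summaries",
    "load_exclusions",
    "site_summary",
    "mann_whitney_u",
    "compare_pre_post",
    "reproduce_tables",
]

TABLE_IDS = ("T1", "T2", "T3", "T4", "T5")

#: Largest pooled sample size for which the exact Mann–Whitney null
#: distribution is enumerated (untied data only).
EXACT_ENUMERATION_MAX_N = 12

_PRE_ET_SUBJECT = "UTx5_preET"


class StatsError(ValueError):
    """Invalid statistical input."""


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero at ``decimals`` places, as the printed tables do.

    Values are snapped to 9 decimals first so that quantities that are exact
    halves in real arithmetic (e.g. a sample SD of exactly 1.5) are not pushed
    below the tie point by floating-point representation error.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(round(x, 9))).quantize(q, rounding=ROUND_HALF_UP))


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("oximsi.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def load_study_tables(table_id: str) -> pd.DataFrame:
    """Load one packaged measurement table (``"T1"``–``"T5"``) in long format.

    Columns: table, modality, measure, species, phase, side, aspect, subject,
    value (NaN where the study recorded no measurement — animals lost
    intraoperatively — plus the pre-embryo-transfer column outside the
    post-transplant phase).  Missing values are preserved, never imputed.
    """
    if table_id not in TABLE_IDS:
        raise KeyError(
            f"unknown table {table_id!r}; available: {', '.join(TABLE_IDS)}"
        )
    df = _read_fixture("site_measurements.csv")
    out = df[df["table"] == table_id].reset_index(drop=True)
    key = ["modality", "measure", "species", "phase", "side", "aspect", "subject"]
    if out.duplicated(subset=key).any():
        raise StatsError(f"duplicate site rows in fixture for {table_id}")
    vals = out["value"].dropna()
    if (out["measure"] == "o2sat").any():
        o2 = out.loc[out["measure"] == "o2sat", "value"].dropna()
        if ((o2 < 0) | (o2 > 100)).any():
            raise StatsError("O2Sat values must lie in [0, 100]")
    if (vals < 0).any():
        raise StatsError("measurement values must be non-negative")
    return out


def load_printed_summaries() -> pd.DataFrame:
    """Every printed "Mean ± SD" cell of the packaged tables."""
    return _read_fixture("printed_summaries.csv")


def load_exclusions() -> pd.DataFrame:
    """Summary cells that are internally inconsistent with their row values.

    All are donor/recipient pre-transplant cells of the multispectral rabbit
    table; each row records the printed and the recomputed value.
    """
    return _read_fixture("table3_exclusions.csv")


@dataclass(frozen=True)
class SiteSummary:
    """One "Mean ± SD" cell: raw statistics plus table-convention rounding."""

    mean: float
    sd: float
    n: int
    mean_rounded: float
    sd_rounded: float
    sd_convention: str


def site_summary(
    table: pd.DataFrame,
    phase: str,
    side: str,
    aspect: str,
    *,
    measure: str | None = None,
    sd_convention: str = "fraction",
) -> SiteSummary:
    """Mean ± SD of the non-missing values at one probe/imaging site.

    The sample SD uses the n−1 denominator.  Rounding follows the printed
    tables: O₂Sat means half-up to integer percent, perfusion-index means to
    2 decimals; ``sd_convention`` is ``"fraction"`` (O₂Sat SD divided by 100,
    2 decimals, the 0.0x notation), ``"percent"`` (1 decimal) or ``"index"``
    (2 decimals, perfusion index).
    """
    sel = table[
        (table["phase"] == phase)
        & (table["side"] == side)
        & (table["aspect"] == aspect)
    ]
    if measure is not None:
        sel = sel[sel["measure"] == measure]
    elif sel["measure"].nunique() > 1:
        raise StatsError(
            "slice mixes measures "
            f"{sorted(sel['measure'].unique())}; pass measure="
        )
    vals = sel["value"].dropna().to_numpy(dtype=float)
    if vals.size == 0:
        raise StatsError(f"no non-missing values for {phase}/{side}/{aspect}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    meas = measure or sel["measure"].iloc[0]
    mean_rounded = round_half_up(mean, 0 if meas == "o2sat" else 2)
    if sd_convention == "fraction":
        sd_rounded = round_half_up(sd / 100.0, 2)
    elif sd_convention == "percent":
        sd_rounded = round_half_up(sd, 1)
    elif sd_convention == "index":
        sd_rounded = round_half_up(sd, 2)
    else:
        raise StatsError(f"unknown sd_convention {sd_convention!r}")
    return SiteSummary(mean, sd, int(vals.size), mean_rounded, sd_rounded, sd_convention)


@dataclass(frozen=True)
class ComparisonResult:
    """Mann–Whitney U comparison of two independent samples."""

    u_statistic: float
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "normal_approx"
    significant_at_0_05: bool

    def __post_init__(self) -> None:
        if not 0 <= self.u_statistic <= self.n1 * self.n2:
            raise StatsError("U outside [0, n1*n2]")
        if not 0 < self.p_value <= 1:
            raise StatsError("p-value outside (0, 1]")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for the first sample from mid-rank ranking of the pooled data."""
    n1 = x.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def _exact_p(u: float, n1: int, n2: int, alternative: str) -> float:
    """Exact p by full enumeration of the C(n1+n2, n1) equally likely labelings."""
    n = n1 + n2
    total = math.comb(n, n1)
    lo = hi = 0
    const = n1 * (n1 + 1) // 2
    for combo in itertools.combinations(range(1, n + 1), n1):
        u_i = sum(combo) - const
        lo += u_i <= u + 1e-9
        hi += u_i >= u - 1e-9
    p_less, p_greater = lo / total, hi / total
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))


def _normal_p(
    u: float, n1: int, n2: int, pooled: np.ndarray, alternative: str
) -> float:
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:  # all values tied: the test carries no information
        return 1.0

    def tail(z: float) -> float:
        return float(sps.norm.sf(z))

    sd = math.sqrt(var)
    if alternative == "greater":
        return tail((u - mu - 0.5) / sd)
    if alternative == "less":
        return tail((mu - u - 0.5) / sd)
    z = (abs(u - mu) - 0.5) / sd
    return min(1.0, 2.0 * tail(z))


def mann_whitney_u(
    x, y, alternative: str = "two-sided"
) -> ComparisonResult:
    """Mann–Whitney U test for two independent samples.

    U is computed from mid-ranks.  The p-value is exact (full enumeration of
    all labelings) when ``n1 + n2 <= 12`` and the pooled data contain no ties,
    otherwise a normal approximation with tie and continuity corrections is
    used.  Two-sided by default; the significance flag applies the study's
    p < 0.05 threshold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise StatsError(f"unknown alternative {alternative!r}")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if pooled.size <= EXACT_ENUMERATION_MAX_N and no_ties:
        p = _exact_p(u, x.size, y.size, alternative)
        method = "exact"
    else:
        p = _normal_p(u, x.size, y.size, pooled, alternative)
        method = "normal_approx"
    p = max(p, np.finfo(float).tiny)
    return ComparisonResult(
        u_statistic=u,
        p_value=float(p),
        n1=int(x.size),
        n2=int(y.size),
        method=method,
        significant_at_0_05=bool(p < 0.05),
    )


def _pool(table: pd.DataFrame, phases, measure: str | None, include_pre_et: bool):
    if isinstance(phases, str):
        phases = [phases]
    sel = table[table["phase"].isin(list(phases))]
    if measure is not None:
        sel = sel[sel["measure"] == measure]
    if not include_pre_et:
        sel = sel[sel["subject"] != _PRE_ET_SUBJECT]
    vals = sel["value"].dropna().to_numpy(dtype=float)
    if vals.size == 0:
        raise StatsError(f"no values for phases {list(phases)}")
    return vals


def compare_pre_post(
    table: pd.DataFrame,
    pre_phases,
    post_phase: str,
    *,
    measure: str | None = None,
    include_pre_et: bool = False,
    alternative: str = "two-sided",
) -> ComparisonResult:
    """Pooled pre- versus post-transplant Mann–Whitney comparison.

    All four cornua sites are pooled per phase group (the study reports one
    comparison per phase pair, not per-site p-values) after dropping missing
    values; the day-89 pre-embryo-transfer re-measurement is excluded unless
    ``include_pre_et`` is set.
    """
    pre = _pool(table, pre_phases, measure, include_pre_et)
    post = _pool(table, post_phase, measure, include_pre_et)
    return mann_whitney_u(pre, post, alternative=alternative)


def _cell_summary(table: pd.DataFrame, row) -> SiteSummary:
    return site_summary(
        table,
        row.phase,
        row.side,
        row.aspect,
        measure=row.measure,
        sd_convention=row.sd_unit,
    )


def reproduce_tables() -> pd.DataFrame:
    """Recompute every printed "Mean ± SD" cell and flag the outcome.

    Returns one row per cell with the printed and recomputed mean/SD, a
    ``match`` flag, and ``known_discrepancy`` for the documented inconsistent
    cells of the multispectral rabbit table.  Deterministic — no randomness
    anywhere in this path.
    """
    printed = load_printed_summaries()
    excl = load_exclusions()
    excl_keys = {
        (r.table, r.measure, r.phase, r.side, r.aspect, r.stat)
        for r in excl.itertuples()
    }
    tables = {tid: load_study_tables(tid) for tid in TABLE_IDS}
    rows = []
    for row in printed.itertuples():
        s = _cell_summary(tables[row.table], row)
        mean_excl = (row.table, row.measure, row.phase, row.side, row.aspect, "mean") in excl_keys
        sd_excl = (row.table, row.measure, row.phase, row.side, row.aspect, "sd") in excl_keys
        mean_match = abs(s.mean_rounded - row.mean_printed) < 1e-9
        sd_match = abs(s.sd_rounded - row.sd_printed) < 1e-9
        rows.append(
            {
                "table": row.table,
                "measure": row.measure,
                "phase": row.phase,
                "side": row.side,
                "aspect": row.aspect,
                "n": s.n,
                "mean_printed": row.mean_printed,
                "mean_recomputed": s.mean_rounded,
                "sd_printed": row.sd_printed,
                "sd_recomputed": s.sd_rounded,
                "mean_match": mean_match,
                "sd_match": sd_match,
                "known_discrepancy": mean_excl or sd_excl,
                "match": (mean_match or mean_excl) and (sd_match or sd_excl),
            }
        )
    return pd.DataFrame(rows)
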
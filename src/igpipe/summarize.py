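"""Per-subset, per-timepoint repertoire summaries and culture-stability tests.

Aggregates annotation records (one row per consensus molecule) into the
readouts used to check that optimised expansion conditions leave the Ig
genotype alone over a 10-day culture: isotype composition per sample, the
SHM trajectory across baseline/day-5/day-10, CDRH3 length densities, and a
formal stability test (total-variation distance between isotype-fraction
vectors plus a chi-square homogeneity test on counts) that turns the
"relative proportions remain stable" claim into an assertable quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ALLOWED_SUBSETS",
    "ALLOWED_DAYS",
    "TrajectoryResult",
    "StabilityResult",
    "isotype_composition",
    "shm_trajectory",
    "cdrh3_density",
    "composition_stability",
    "repertoire_summary",
    "load_manifest",
]

ALLOWED_SUBSETS = ("IgM+IgD+", "IgM+IgD-", "IgM-IgD-", "IgM-IgD+")
ALLOWED_DAYS = (0, 5, 10)


def isotype_composition(records: pd.DataFrame) -> pd.Series:
    """Fraction of records per isotype call (sums to 1).

    This is the "percentage of reads assigned to each isotype" readout; by
    default every consensus record counts once.
    """
    if records.empty:
        raise ValueError("empty sample")
    counts = records["c_call"].value_counts()
    return (counts / counts.sum()).sort_index()


@dataclass
class TrajectoryResult:
    per_day: pd.DataFrame          # index day: mean, sd, n
    difference: float              # mean(last day) - mean(first day)
    ci_low: float
    ci_high: float
    alpha: float
    significant: bool              # CI excludes zero


def shm_trajectory(
    records: pd.DataFrame,
    day_col: str = "day",
    value_col: str = "shm_pct",
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.01,
) -> TrajectoryResult:
    """Per-day SHM summary plus a bootstrap CI on the last-minus-first change.

    Days are resampled independently (``n_boot`` resamples, percentile CI);
    the trajectory is called significant when the CI excludes zero.  Under
    culture conditions that do not induce SHM the CI should cover zero.
    """
    days = sorted(records[day_col].unique())
    if len(days) < 2:
        raise ValueError("need >=2 timepoints")
    per_day = records.groupby(day_col)[value_col].agg(["mean", "std", "count"])
    per_day.columns = ["mean", "sd", "n"]
    if (per_day["n"] == 0).any():
        raise ValueError("a day with no records")
    rng = np.random.default_rng(seed)
    first = records.loc[records[day_col] == days[0], value_col].to_numpy(float)
    last = records.loc[records[day_col] == days[-1], value_col].to_numpy(float)
    b_first = first[rng.integers(first.size, size=(n_boot, first.size))].mean(axis=1)
    b_last = last[rng.integers(last.size, size=(n_boot, last.size))].mean(axis=1)
    diffs = b_last - b_first
    lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    diff = float(last.mean() - first.mean())
    return TrajectoryResult(
        per_day=per_day, difference=diff, ci_low=float(lo), ci_high=float(hi),
        alpha=alpha, significant=not (lo <= 0.0 <= hi),
    )


def cdrh3_density(
    records: pd.DataFrame,
    value_col: str = "junction_length_nt",
    bin_width: int = 3,
) -> tuple[pd.Series, float]:
    """Normalized CDRH3 nt-length histogram plus the undefined fraction.

    Bins are codon-aligned (``bin_width`` = 3 nt by default); the histogram
    sums to 1 over defined lengths and the fraction of records with an
    unlocatable CDRH3 is reported separately.
    """
    vals = records[value_col]
    defined = vals.dropna()
    if defined.empty:
        raise ValueError("no defined CDRH3 lengths")
    bins = (defined.astype(int) // bin_width) * bin_width
    hist = bins.value_counts().sort_index()
    return hist / hist.sum(), float(vals.isna().mean())


@dataclass
class StabilityResult:
    tvd: float          # total-variation distance between fraction vectors
    chi2: float
    p_value: float
    dof: int


def composition_stability(
    counts_a: pd.Series, counts_b: pd.Series
) -> StabilityResult:
    """Compare two isotype count vectors from the same subset/donor.

    Total-variation distance between the fraction vectors, plus a chi-square
    homogeneity test on the raw counts.  Identical compositions give TVD 0
    and p = 1.
    """
    isotypes = sorted(set(counts_a.index) | set(counts_b.index))
    if not set(counts_a.index) & set(counts_b.index):
        raise ValueError("incompatible isotype sets: no shared isotypes")
    a = counts_a.reindex(isotypes, fill_value=0).to_numpy(float)
    b = counts_b.reindex(isotypes, fill_value=0).to_numpy(float)
    pa, pb = a / a.sum(), b / b.sum()
    tvd = 0.5 * float(np.abs(pa - pb).sum())
    table = np.vstack([a, b])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return StabilityResult(tvd=tvd, chi2=0.0, p_value=1.0, dof=0)
    chi2, p, dof, _ = stats.chi2_contingency(table)
    return StabilityResult(tvd=tvd, chi2=float(chi2), p_value=float(p), dof=int(dof))


def repertoire_summary(
    records: pd.DataFrame,
    group_cols: tuple[str, ...] = ("subset", "day", "donor"),
) -> dict[str, pd.DataFrame]:
    """Per-sample summaries: isotype fractions, SHM stats, CDRH3 histograms.

    ``records`` must carry the grouping columns plus ``c_call``, ``shm_pct``
    and ``junction_length_nt``.  Returns long-format frames keyed
    ``composition`` / ``shm`` / ``cdrh3``.
    """
    group_cols = [c for c in group_cols if c in records.columns]
    if not group_cols:
        raise ValueError("no grouping columns present")
    comp_rows, shm_rows, cdr_rows = [], [], []
    for key, grp in records.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        kd = dict(zip(group_cols, key))
        fracs = isotype_composition(grp)
        for iso, frac in fracs.items():
            comp_rows.append({**kd, "isotype": iso, "fraction": float(frac),
                              "count": int((grp["c_call"] == iso).sum())})
        shm_rows.append({**kd, "mean_shm_pct": float(grp["shm_pct"].mean()),
                         "sd_shm_pct": float(grp["shm_pct"].std()),
                         "n": int(len(grp))})
        hist, undef = cdrh3_density(grp)
        for length, dens in hist.items():
            cdr_rows.append({**kd, "cdrh3_nt_bin": int(length),
                             "density": float(dens), "undefined_fraction": undef})
    return {
        "composition": pd.DataFrame(comp_rows),
        "shm": pd.DataFrame(shm_rows),
        "cdrh3": pd.DataFrame(cdr_rows),
    }


def load_manifest(path) -> pd.DataFrame:
    """Sample manifest CSV: columns file, subset, day, donor."""
    df = pd.read_csv(path)
    required = {"file", "subset", "day", "donor"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest missing columns: {required - set(df.columns)}")
    bad_subset = set(df["subset"]) - set(ALLOWED_SUBSETS)
    if bad_subset:
        raise ValueError(f"unknown subsets in manifest: {sorted(bad_subset)}")
    bad_day = set(df["day"].astype(int)) - set(ALLOWED_DAYS)
    if bad_day:
        raise ValueError(f"unknown days in manifest: {sorted(bad_day)}")
    return df
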
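"""Full-factorial design-of-experiments engine for B-cell stimulation screens.

A stimulation screen varies a small number of expansion stimuli (IL-21, the
TLR agonists R848 and CpG, and CD40 signal strength delivered via a
CD154+ feeder-cell ratio) over a full Cartesian grid of dose levels and
reads out secreted immunoglobulin per condition.  This module enumerates
such designs, decomposes the response variance of a balanced factorial
table into first- and second-order terms with a balanced N-way ANOVA,
converts term sums of squares into sensitivity indices
(``SS_term / SS_total``, an eta-squared-style fraction of total variance),
and selects the optimal stimulation condition from the significant factors.

All tabular data are plain :class:`pandas.DataFrame` objects; a response
table has one column per factor (holding level labels), plus ``donor``,
``replicate``, ``isotype`` and ``response`` columns.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Level",
    "Factor",
    "DesignPoint",
    "FactorialDesign",
    "AnovaTerm",
    "AnovaDecomposition",
    "SensitivityReport",
    "OptimalCondition",
    "default_factors",
    "enumerate_design",
    "count_fixed_pair_slice",
    "validate_response_table",
    "marginal_means",
    "anova_decompose",
    "sensitivity_indices",
    "select_optimal",
    "two_way_anova_tukey",
    "read_response_table",
    "write_response_table",
    "decomposition_to_frame",
    "factors_from_yaml",
]

RESERVED_COLUMNS = ("donor", "replicate", "isotype", "response")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Level:
    """One dose level of a stimulation factor."""

    label: str
    dose: float
    units: str = ""


@dataclass(frozen=True)
class Factor:
    """A stimulation factor with >=2 ordered dose levels."""

    name: str
    levels: tuple[Level, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"factor {self.name!r} needs >=2 levels")
        labels = [lv.label for lv in self.levels]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate level labels in factor {self.name!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lv.label for lv in self.levels)

    def dose_of(self, label: str) -> float:
        for lv in self.levels:
            if lv.label == label:
                return lv.dose
        raise KeyError(f"unknown level {label!r} for factor {self.name!r}")


@dataclass(frozen=True)
class DesignPoint:
    """One stimulation condition: exactly one level per factor."""

    assignment: tuple[tuple[str, str], ...]  # (factor name, level label) pairs

    def as_dict(self) -> dict[str, str]:
        return dict(self.assignment)

    def __getitem__(self, factor: str) -> str:
        return self.as_dict()[factor]


@dataclass
class FactorialDesign:
    """The full Cartesian grid of conditions over a factor set."""

    factors: tuple[Factor, ...]
    points: tuple[DesignPoint, ...]

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        rows = [pt.as_dict() for pt in self.points]
        df = pd.DataFrame(rows, columns=[f.name for f in self.factors])
        df.insert(0, "condition_id", np.arange(len(df)))
        return df

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"unknown factor {name!r}")


@dataclass
class AnovaTerm:
    """One row of the variance decomposition."""

    factors: tuple[str, ...]  # member factors, or ("donor",)/("residual",)/("total",)
    ss: float
    df: int
    f_stat: float | None = None
    p_value: float | None = None

    @property
    def name(self) -> str:
        return ":".join(self.factors)

    @property
    def order(self) -> int:
        return len(self.factors) if self.factors[0] not in ("donor", "residual", "total") else 0


@dataclass
class AnovaDecomposition:
    """Balanced orthogonal ANOVA decomposition of a factorial response table."""

    terms: list[AnovaTerm]
    residual: AnovaTerm
    ss_total: float
    n_obs: int

    def term(self, *factors: str) -> AnovaTerm:
        key = tuple(sorted(factors))
        for t in self.terms:
            if tuple(sorted(t.factors)) == key:
                return t
        raise KeyError(f"no term {factors}")

    @property
    def degenerate(self) -> bool:
        return self.ss_total <= 0.0


@dataclass
class SensitivityReport:
    """Per-term variance fractions (sensitivity indices) and p-values."""

    indices: dict[str, float]           # term name -> SS_term / SS_total
    p_values: dict[str, float]          # full precision
    residual_fraction: float
    degenerate: bool = False
    term_factors: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def p_display(self, term: str) -> float:
        """p-value rounded to 4 decimals, for reporting only."""
        return round(self.p_values[term], 4)


@dataclass
class OptimalCondition:
    """Chosen level per factor plus the rule that selected it."""

    levels: dict[str, str]
    rationale: dict[str, str]  # "significant-max" or "default-lowest"

    def to_json(self) -> str:
        return json.dumps({"levels": self.levels, "rationale": self.rationale}, indent=2)


# ---------------------------------------------------------------------------
# Design enumeration
# ---------------------------------------------------------------------------

def default_factors() -> tuple[Factor, ...]:
    """The four-stimulus, three-level grid used for memory-B-cell optimisation.

    IL-21 in ng/ml, CpG ODN2006 and R848 in ug/ml, and CD40 stimulation as the
    CD154+ feeder (HV13280) to memory-B-cell ratio.
    """
    return (
        Factor("IL21", (Level("10", 10, "ng/ml"), Level("50", 50, "ng/ml"),
                        Level("100", 100, "ng/ml"))),
        Factor("CpG", (Level("0", 0.0, "ug/ml"), Level("0.25", 0.25, "ug/ml"),
                       Level("1", 1.0, "ug/ml"))),
        Factor("R848", (Level("0", 0.0, "ug/ml"), Level("0.25", 0.25, "ug/ml"),
                        Level("0.5", 0.5, "ug/ml"))),
        Factor("CD40", (Level("1:5", 0.2, "feeder:MBC"), Level("1:2", 0.5, "feeder:MBC"),
                        Level("1:1", 1.0, "feeder:MBC"))),
    )


def enumerate_design(factors: list[Factor] | tuple[Factor, ...]) -> FactorialDesign:
    """Enumerate the full factorial grid, lexicographic by factor then level order.

    Four factors at three levels each give the 81 conditions of the
    memory-B-cell screen.
    """
    factors = tuple(factors)
    if not factors:
        raise ValueError("empty factor list")
    for f in factors:
        if len(f.levels) < 2:  # Factor already validates; guard plain inputs
            raise ValueError(f"factor {f.name!r} needs >=2 levels")
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise ValueError("duplicate factor names")
    points = tuple(
        DesignPoint(tuple(zip(names, combo)))
        for combo in itertools.product(*[f.labels for f in factors])
    )
    return FactorialDesign(factors=factors, points=points)


def count_fixed_pair_slice(
    design: FactorialDesign,
    factor_a: str,
    level_a: str,
    factor_b: str | None = None,
    level_b: str | None = None,
) -> int:
    """Count design points with one or two factors pinned at given levels.

    With two of four three-level factors pinned this is the 9-condition slice
    over which a second-order interaction cell is averaged.  Passing only
    ``factor_a`` counts the single-factor slice (27 points in a 3^4 design).
    """
    fa = design.factor(factor_a)
    if level_a not in fa.labels:
        raise KeyError(f"unknown level {level_a!r} for factor {factor_a!r}")
    pins = {factor_a: level_a}
    if factor_b is not None:
        fb = design.factor(factor_b)
        if level_b is None or level_b not in fb.labels:
            raise KeyError(f"unknown level {level_b!r} for factor {factor_b!r}")
        pins[factor_b] = level_b
    return sum(
        1 for pt in design.points
        if all(pt[f] == lv for f, lv in pins.items())
    )


# ---------------------------------------------------------------------------
# Response tables
# ---------------------------------------------------------------------------

def validate_response_table(table: pd.DataFrame, factor_names: list[str]) -> None:
    """Check a response table is complete and balanced over the factor grid.

    Balanced means every (factor-cell, donor) combination carries the same
    number of replicates and responses are finite and non-negative.
    """
    if table.empty:
        raise ValueError("empty response table")
    missing = [c for c in factor_names + ["response"] if c not in table.columns]
    if missing:
        raise ValueError(f"response table missing columns: {missing}")
    y = table["response"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite responses")
    if np.any(y < 0):
        raise ValueError("negative Ig responses")
    keys = factor_names + (["donor"] if "donor" in table.columns else [])
    counts = table.groupby(keys, observed=True).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced response table: unequal replicate counts per cell")
    # every grid cell present
    expected = math.prod(table[c].nunique() for c in keys)
    if len(counts) != expected:
        raise ValueError("incomplete factorial grid in response table")


def marginal_means(
    table: pd.DataFrame,
    factor: str,
    response: str = "response",
    by_isotype: bool = False,
) -> pd.Series | pd.DataFrame:
    """Mean response per level of one factor, all other factors varying.

    This is the "mean Ig while factor x is held constant" readout of the
    factorial screen.  On a balanced table the mean of the marginals equals
    the grand mean.
    """
    if table.empty:
        raise ValueError("empty response table")
    if factor not in table.columns:
        raise KeyError(f"factor {factor!r} not in table")
    if by_isotype:
        return table.pivot_table(index=factor, columns="isotype", values=response,
                                 aggfunc="mean", observed=True)
    return table.groupby(factor, observed=True, sort=False)[response].mean()


# ---------------------------------------------------------------------------
# Balanced N-way ANOVA decomposition
# ---------------------------------------------------------------------------

def anova_decompose(
    table: pd.DataFrame,
    factor_names: list[str],
    response: str = "response",
    max_order: int = 2,
    include_donor_block: bool = True,
) -> AnovaDecomposition:
    """Decompose response variance into first/second-order terms on a balanced grid.

    On a balanced full factorial the effect subspaces are orthogonal, so each
    term's sum of squares comes directly from (cell) means:

    * first order:   ``SS_A  = sum_a n_a (mean_a - grand)^2``
    * second order:  ``SS_AB = sum_ab n_ab (mean_ab - mean_a - mean_b + grand)^2``
    * donor block:   additive offset term, same form as a first-order factor

    Interactions of order > ``max_order`` are pooled into the residual.
    F statistics use the residual mean square; p-values come from the F
    distribution.  Degenerate tables (zero total variance) are returned with
    F/p undefined (``None``) rather than raising.
    """
    validate_response_table(table, list(factor_names))
    y = table[response].to_numpy(dtype=float)
    n = y.size
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))

    # cache per-row level means
    def group_means(cols: list[str]) -> pd.Series:
        return table.groupby(cols, observed=True)[response].mean()

    terms: list[AnovaTerm] = []
    block_cols = list(factor_names)
    if include_donor_block and "donor" in table.columns and table["donor"].nunique() > 1:
        block_cols = block_cols + ["donor"]
        dm = group_means(["donor"])
        counts = table.groupby("donor", observed=True).size()
        ss_d = float((counts * (dm - grand) ** 2).sum())
        terms.append(AnovaTerm(("donor",), ss_d, int(len(dm) - 1)))

    main_means: dict[str, pd.Series] = {}
    for f in factor_names:
        m = group_means([f])
        main_means[f] = m
        counts = table.groupby(f, observed=True).size()
        ss = float((counts * (m - grand) ** 2).sum())
        terms.append(AnovaTerm((f,), ss, int(len(m) - 1)))

    if max_order >= 2:
        for fa, fb in itertools.combinations(factor_names, 2):
            cell = group_means([fa, fb])
            counts = table.groupby([fa, fb], observed=True).size()
            ma = main_means[fa]
            mb = main_means[fb]
            dev = (
                cell
                - ma.reindex(cell.index.get_level_values(0)).to_numpy()
                - mb.reindex(cell.index.get_level_values(1)).to_numpy()
                + grand
            )
            ss = float((counts * dev**2).sum())
            df = int((len(ma) - 1) * (len(mb) - 1))
            terms.append(AnovaTerm((fa, fb), ss, df))

    ss_model = sum(t.ss for t in terms)
    df_model = sum(t.df for t in terms)
    ss_res = max(ss_total - ss_model, 0.0)
    df_res = (n - 1) - df_model
    if df_res < 0:
        raise ValueError("model degrees of freedom exceed data")
    residual = AnovaTerm(("residual",), ss_res, df_res)

    if ss_total > 0.0:
        if df_res == 0 or ss_res <= 0.0:
            # perfectly explained or saturated: F undefined
            for t in terms:
                t.f_stat = math.inf if t.ss > 0 else None
                t.p_value = 0.0 if t.ss > 0 else None
        else:
            ms_res = ss_res / df_res
            for t in terms:
                if t.df > 0:
                    t.f_stat = (t.ss / t.df) / ms_res
                    t.p_value = float(stats.f.sf(t.f_stat, t.df, df_res))
    return AnovaDecomposition(terms=terms, residual=residual, ss_total=ss_total, n_obs=n)


def sensitivity_indices(decomp: AnovaDecomposition) -> SensitivityReport:
    """Convert a decomposition into variance-fraction sensitivity indices.

    ``index_term = SS_term / SS_total``; indices plus the residual fraction
    sum to one.  A zero-variance table yields an all-zero report flagged
    degenerate (by convention, not an error).
    """
    if decomp.degenerate:
        return SensitivityReport(
            indices={t.name: 0.0 for t in decomp.terms},
            p_values={t.name: float("nan") for t in decomp.terms},
            residual_fraction=0.0,
            degenerate=True,
            term_factors={t.name: t.factors for t in decomp.terms},
        )
    idx = {t.name: t.ss / decomp.ss_total for t in decomp.terms}
    pvals = {
        t.name: (t.p_value if t.p_value is not None else float("nan"))
        for t in decomp.terms
    }
    return SensitivityReport(
        indices=idx,
        p_values=pvals,
        residual_fraction=decomp.residual.ss / decomp.ss_total,
        degenerate=False,
        term_factors={t.name: t.factors for t in decomp.terms},
    )


def select_optimal(
    report: SensitivityReport,
    marginals: dict[str, "pd.Series | dict[str, float]"],
    factors: list[Factor] | tuple[Factor, ...],
    alpha: float = 0.05,
) -> OptimalCondition:
    """Pick the optimal stimulation condition from first-order results.

    For each factor whose first-order p-value is below ``alpha``, take the
    level with the highest marginal mean (ties toward the lower dose).  A
    non-significant factor defaults to its lowest-dose level — the rule under
    which CpG, with no detectable effect on Ig secretion, drops to zero.
    """
    levels: dict[str, str] = {}
    rationale: dict[str, str] = {}
    for f in factors:
        p = report.p_values.get(f.name, float("nan"))
        lowest = min(f.levels, key=lambda lv: lv.dose).label
        if not report.degenerate and not math.isnan(p) and p < alpha:
            if f.name not in marginals:
                raise KeyError(f"missing marginal means for significant factor {f.name!r}")
            m = marginals[f.name]
            get = m.get if isinstance(m, dict) else (lambda lab: float(m.loc[lab]))
            best_val = max(float(get(lab)) for lab in f.labels)
            candidates = [lab for lab in f.labels if float(get(lab)) == best_val]
            levels[f.name] = min(candidates, key=f.dose_of)
            rationale[f.name] = "significant-max"
        else:
            levels[f.name] = lowest
            rationale[f.name] = "default-lowest"
    return OptimalCondition(levels=levels, rationale=rationale)


# ---------------------------------------------------------------------------
# Classical two-way ANOVA + Tukey post-hoc (final comparison sets)
# ---------------------------------------------------------------------------

def two_way_anova_tukey(
    table: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    response: str = "response",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA with Tukey's HSD pairwise comparisons on ``factor_a``.

    Returns the ANOVA table and a frame of pairwise comparisons with
    studentized-range-adjusted p-values.  Used for head-to-head comparisons of
    a handful of culture conditions rather than the factorial decomposition.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    sizes = table.groupby([factor_a, factor_b], observed=True).size()
    if (sizes < 2).any() or table[factor_a].nunique() < 2:
        raise ValueError("need >=2 groups and >=2 observations per group")
    df = table.rename(columns={factor_a: "_ga", factor_b: "_gb", response: "_y"})
    model = smf.ols("_y ~ C(_ga) + C(_gb) + C(_ga):C(_gb)", data=df).fit()
    anova_tab = sm.stats.anova_lm(model, typ=2)
    tk = pairwise_tukeyhsd(df["_y"], df["_ga"], alpha=alpha)
    tukey = pd.DataFrame(
        tk.summary().data[1:],
        columns=[str(c) for c in tk.summary().data[0]],
    )
    tukey["p-adj"] = tk.pvalues  # full precision, not the rounded summary text
    return anova_tab, tukey


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_response_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def _level_label(value) -> str:
    """Render a CSV-parsed level value back into its canonical string label."""
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def read_response_table(path, factor_names: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if factor_names is not None:
        for col in factor_names:
            if col in df.columns:
                df[col] = df[col].map(_level_label)
        validate_response_table(df, list(factor_names))
    return df


def decomposition_to_frame(decomp: AnovaDecomposition) -> pd.DataFrame:
    """Report frame: term, order, SS, df, F, p (4-decimal display) and index."""
    report = sensitivity_indices(decomp)
    rows = []
    for t in decomp.terms:
        rows.append({
            "term": t.name,
            "order": t.order,
            "SS": t.ss,
            "df": t.df,
            "F": t.f_stat,
            "p": t.p_value,
            "p_display": (round(t.p_value, 4) if t.p_value is not None else None),
            "index": report.indices[t.name],
        })
    rows.append({
        "term": "residual", "order": 0, "SS": decomp.residual.ss,
        "df": decomp.residual.df, "F": None, "p": None, "p_display": None,
        "index": report.residual_fraction,
    })
    rows.append({
        "term": "total", "order": 0, "SS": decomp.ss_total,
        "df": decomp.n_obs - 1, "F": None, "p": None, "p_display": None,
        "index": 1.0 if not decomp.degenerate else 0.0,
    })
    return pd.DataFrame(rows)


def factors_from_yaml(path) -> tuple[Factor, ...]:
    """Load a factor grid from YAML: {factors: [{name, units, levels: [{label, dose}]}]}."""
    import yaml

    with open(path) as fh:
        spec = yaml.safe_load(fh)
    factors = []
    for f in spec["factors"]:
        units = f.get("units", "")
        levels = tuple(
            Level(str(lv["label"]), float(lv["dose"]), lv.get("units", units))
            for lv in f["levels"]
        )
        factors.append(Factor(f["name"], levels))
    return tuple(factors)
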
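"""Cohort-level statistics on spurt parameters and random effects.

Reproduces the standard reporting battery for pubertal growth studies:
descriptive tables (mean, SD, nine centiles from 3% to 97%), Pearson
correlations among the SITAR random effects with two-sided significance,
and top-versus-bottom-quintile contrasts with Welch two-sample t-tests.

Conventions (stated because the reporting literature rarely is):
sample SD uses the n-1 denominator; centiles interpolate linearly
between order statistics (quantile "type 7"); quintile groups take the
floor(0.2 n) largest and smallest subjects with ties broken by a stable
sort on subject id; t-tests are Welch (unequal variances), two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastResult",
    "DescriptiveRow",
    "SummaryTables",
    "build_report",
    "contrast_table",
    "descriptive_summary",
    "descriptive_table",
    "quintile_contrast",
    "random_effect_correlations",
]

CENTILE_LEVELS = (3, 5, 10, 25, 50, 75, 90, 95, 97)

#: Spurt parameters summarised in cohort tables, in reporting order.
SPURT_PARAMETERS = ("aogs", "aphv", "ogsv", "phv", "gsi")

ALPHA = 0.05  # flagging threshold only; nothing is filtered on it


@dataclass(frozen=True)
class DescriptiveRow:
    parameter: str
    n: int
    mean: float
    sd: float
    centiles: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        vals = [self.centiles[c] for c in CENTILE_LEVELS if c in self.centiles]
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValueError("centiles must be non-decreasing")


def descriptive_table(values, parameter: str = "") -> DescriptiveRow:
    """Mean, sample SD and centiles of one parameter across subjects.

    NaN entries (flagged subjects) are ignored; needs >= 2 usable values.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError(f"need at least 2 non-flagged values for {parameter!r}")
    cents = {c: float(np.percentile(v, c)) for c in CENTILE_LEVELS}
    return DescriptiveRow(
        parameter=parameter,
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        centiles=cents,
    )


def descriptive_summary(params: pd.DataFrame,
                        parameters=SPURT_PARAMETERS) -> pd.DataFrame:
    """Descriptive rows for each spurt parameter, one table row per parameter."""
    rows = []
    for p in parameters:
        r = descriptive_table(params[p], p)
        rows.append({"parameter": p, "n": r.n, "mean": r.mean, "sd": r.sd,
                     **{f"p{c}": r.centiles[c] for c in CENTILE_LEVELS}})
    return pd.DataFrame(rows).set_index("parameter")


def random_effect_correlations(random_effects: pd.DataFrame):
    """Pearson correlations among (alpha, beta, gamma) with p-values.

    Returns ``(corr, pvals)`` as symmetric 3x3 DataFrames; p-values are
    two-sided from the t transform with n-2 degrees of freedom.  A
    zero-variance component yields NaN entries and a warning note in
    ``corr.attrs['warnings']``.
    """
    cols = ["alpha", "beta", "gamma"]
    re = random_effects[cols]
    n = len(re)
    if n < 3:
        raise ValueError("need at least 3 subjects for correlations")
    corr = pd.DataFrame(np.eye(3), index=cols, columns=cols)
    pvals = pd.DataFrame(np.zeros((3, 3)), index=cols, columns=cols)
    notes = []
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            x, y = re[a].to_numpy(), re[b].to_numpy()
            if x.std() == 0 or y.std() == 0:
                r, p = np.nan, np.nan
                notes.append(f"zero variance in {a if x.std() == 0 else b}; "
                             f"correlation {a}-{b} undefined")
            else:
                r, p = stats.pearsonr(x, y)
            corr.loc[a, b] = corr.loc[b, a] = r
            pvals.loc[a, b] = pvals.loc[b, a] = p
    corr.attrs["warnings"] = notes
    return corr, pvals


@dataclass(frozen=True)
class ContrastResult:
    rank_by: str
    outcome: str
    mean_difference: float   # mean(top 20%) - mean(bottom 20%), outcome units
    t_statistic: float
    p_value: float
    group_size: int
    had_ties: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value <= ALPHA


def quintile_contrast(params: pd.DataFrame, rank_by: str, outcome: str) -> ContrastResult:
    """Top-20% minus bottom-20% contrast on ``outcome``, ranked by ``rank_by``.

    Rows with NaN in either column are excluded; group size is
    floor(0.2 n); Welch two-sample t-test, two-sided.
    """
    sub = params[list(dict.fromkeys((rank_by, outcome)))].dropna()
    n = len(sub)
    if n < 10:
        raise ValueError("need at least 10 non-flagged subjects for a contrast")
    k = n // 5
    ranked = sub.sort_values(rank_by, kind="mergesort")  # stable on subject index
    bottom = ranked.iloc[:k][outcome].to_numpy()
    top = ranked.iloc[-k:][outcome].to_numpy()
    boundary_vals = (ranked.iloc[k - 1][rank_by], ranked.iloc[k][rank_by],
                     ranked.iloc[-k][rank_by], ranked.iloc[-k - 1][rank_by])
    had_ties = boundary_vals[0] == boundary_vals[1] or boundary_vals[2] == boundary_vals[3]
    t, p = stats.ttest_ind(top, bottom, equal_var=False)
    return ContrastResult(
        rank_by=rank_by,
        outcome=outcome,
        mean_difference=float(top.mean() - bottom.mean()),
        t_statistic=float(t),
        p_value=float(p),
        group_size=int(k),
        had_ties=bool(had_ties),
    )


def contrast_table(params: pd.DataFrame,
                   parameters=("aphv", "phv", "gsi")) -> pd.DataFrame:
    """All rank-by/outcome quintile contrasts (rows rank, columns outcome)."""
    rows = []
    for rank_by in parameters:
        for outcome in parameters:
            c = quintile_contrast(params, rank_by, outcome)
            rows.append({"rank_by": rank_by, "outcome": outcome,
                         "mean_difference": c.mean_difference,
                         "t": c.t_statistic, "p": c.p_value,
                         "group_size": c.group_size, "ties": c.had_ties})
    return pd.DataFrame(rows)


@dataclass
class SummaryTables:
    sex: str
    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    correlation_pvalues: pd.DataFrame
    contrasts: pd.DataFrame | None
    n_flagged: int


def build_report(fit, params: pd.DataFrame, contrasts: pd.DataFrame | None = None,
                 outdir=None, sex: str | None = None) -> SummaryTables:
    """Assemble cohort summary tables (and optionally write tables + figures).

    ``params`` is the spurt-parameter table from ``extract_cohort`` with a
    ``sex`` column or a single-sex cohort; mixed-sex input is an error —
    strata are always analysed separately.  With ``outdir`` set, writes
    ``descriptives.csv``, ``correlations.csv`` (with p-values) and, when
    contrasts are given, ``contrasts.csv``, plus velocity-curve and
    boxplot figures.  Output is deterministic for identical inputs.
    """
    if "sex" in params.columns:
        sexes = set(params["sex"].unique())
        if len(sexes) > 1:
            raise ValueError(f"mixed-sex input: {sorted(sexes)}; analyse strata separately")
        sex = sex or sexes.pop()
    sex = sex or "unknown"

    clean = params[params["flags"] == ""] if "flags" in params.columns else params
    n_flagged = len(params) - len(clean)
    desc = descriptive_summary(clean)
    corr, pv = random_effect_correlations(fit.random_effects)
    tables = SummaryTables(
        sex=sex,
        descriptives=desc,
        correlations=corr,
        correlation_pvalues=pv,
        contrasts=contrasts,
        n_flagged=n_flagged,
    )
    if outdir is not None:
        _write_report(fit, clean, tables, outdir)
    return tables


def _write_report(fit, clean: pd.DataFrame, tables: SummaryTables, outdir) -> None:
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables.descriptives.to_csv(outdir / "descriptives.csv", float_format="%.6g")
    both = pd.concat({"r": tables.correlations, "p": tables.correlation_pvalues},
                     names=["quantity"])
    both.to_csv(outdir / "correlations.csv", float_format="%.6g")
    if tables.contrasts is not None and len(tables.contrasts):
        tables.contrasts.to_csv(outdir / "contrasts.csv", index=False, float_format="%.6g")

    lo, hi = fit.curve.basis.boundary_knots
    grid = np.linspace(lo, hi, 250)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for sid in fit.subject_ids[:60]:
        ax.plot(grid, fit.predict_velocity(fit.random_effects_of(sid), grid,
                                           allow_extrapolation=True),
                color="0.75", lw=0.5)
    ax.plot(grid, fit.mean_velocity(grid, allow_extrapolation=True),
            color="crimson", lw=2, label="mean curve")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("height velocity (cm/year)")
    ax.set_title(f"height velocity, {tables.sex}")
    ax.legend()
    fig.savefig(outdir / "velocity_curves.png", dpi=120)
    plt.close(fig)

    cols = [p for p in SPURT_PARAMETERS if p in clean.columns]
    fig, axes = plt.subplots(1, len(cols), figsize=(2.2 * len(cols), 4))
    for ax, p in zip(np.atleast_1d(axes), cols):
        ax.boxplot(clean[p].dropna(), tick_labels=[p])
    fig.suptitle(f"spurt parameters, {tables.sex}")
    fig.tight_layout()
    fig.savefig(outdir / "boxplots.png", dpi=120)
    plt.close(fig)
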
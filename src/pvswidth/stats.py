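"""Group/level and quintile statistics on per-vessel width summaries.

The statistics layer consumes only the per-vessel record table (one row per
vessel: animal, group, level, mean width, five quintile means) — no images.
It reproduces three analyses:

1. *Pooling check* — within each group × spinal level, are the two animals'
   per-vessel mean widths distinguishable?  (Welch two-sample t-test; if
   not, vessels are pooled across animals.)
2. *Group × level comparison* — two-way ANOVA (type-II sums of squares) of
   per-vessel mean widths on group and level, with Tukey-adjusted pairwise
   contrasts; the contrast of interest is control vs syrinx within each
   level.
3. *Quintile comparison* — per level, a linear mixed model of the five
   quintile means (repeated measures within vessel, random intercept per
   animal) with fixed effects group, quintile and their interaction, and
   Sidak-adjusted group contrasts within each quintile.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import GROUPS, LEVELS

#: canonical column schema of the per-vessel record table
VESSEL_RECORD_COLUMNS = [
    "vessel_id",
    "animal_id",
    "group",
    "level",
    "mean_width_um",
    "q1_um",
    "q2_um",
    "q3_um",
    "q4_um",
    "q5_um",
]
QUINTILE_COLUMNS = ["q1_um", "q2_um", "q3_um", "q4_um", "q5_um"]


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VESSEL_RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"record table missing columns: {missing}")
    bad_group = set(records["group"]) - set(GROUPS)
    bad_level = set(records["level"]) - set(LEVELS)
    if bad_group or bad_level:
        raise ValueError(f"unknown group(s) {bad_group} or level(s) {bad_level}")
    return records


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Sidak multiplicity adjustment: ``1 − (1 − p)^m``, clipped to [0, 1]."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return np.clip(1.0 - (1.0 - np.asarray(p, dtype=float)) ** m, 0.0, 1.0)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Welch t-test p-value with a defined answer for zero-variance samples."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def pooling_check(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Between-animal comparison of per-vessel mean widths per group × level.

    Returns one row per group × level cell with the two animal ids, the
    Welch p-value and a ``pooled`` flag (p ≥ alpha).  Cells with a single
    animal are flagged (``single_animal``), not an error.
    """
    _validate_records(records)
    rows = []
    for (group, level), cell in records.groupby(["group", "level"], sort=False):
        animals = sorted(cell["animal_id"].unique())
        if len(animals) < 2:
            rows.append(
                dict(group=group, level=level, animal_a=animals[0], animal_b=None,
                     p_value=np.nan, pooled=True, single_animal=True)
            )
            continue
        if len(animals) > 2:
            raise ValueError(
                f"cell {group}/{level} has {len(animals)} animals; pairwise pooling "
                "check is defined for two animals per group"
            )
        a = cell.loc[cell["animal_id"] == animals[0], "mean_width_um"].to_numpy()
        b = cell.loc[cell["animal_id"] == animals[1], "mean_width_um"].to_numpy()
        p = _welch_p(a, b)
        rows.append(
            dict(group=group, level=level, animal_a=animals[0], animal_b=animals[1],
                 p_value=p, pooled=bool(p >= alpha), single_animal=False)
        )
    return pd.DataFrame(rows)


@dataclass
class GroupLevelResult:
    """Two-way ANOVA table plus Tukey pairwise results."""

    anova: pd.DataFrame
    tukey: pd.DataFrame
    level_contrasts: pd.DataFrame  # control vs syrinx within each level

    @property
    def group_p(self) -> float:
        return float(self.anova.loc["C(group)", "PR(>F)"])


def compare_group_level(records: pd.DataFrame, post_hoc: bool = True) -> GroupLevelResult:
    """Two-way ANOVA (group × level) on per-vessel mean widths + Tukey HSD.

    The ANOVA uses type-II sums of squares (robust to the unbalanced vessel
    counts); with ``post_hoc``, Tukey's HSD runs over all six group:level
    cells and the within-level control-vs-syrinx contrasts are extracted.

    Raises
    ------
    ValueError
        If any group × level cell has fewer than 2 vessels.
    """
    _validate_records(records)
    counts = records.groupby(["group", "level"]).size()
    empty = [
        (g, l)
        for g in sorted(records["group"].unique())
        for l in sorted(records["level"].unique())
        if counts.get((g, l), 0) < 2
    ]
    if empty:
        raise ValueError(f"cells with <2 vessels: {empty}")

    model = smf.ols("mean_width_um ~ C(group) * C(level)", data=records).fit()
    anova = anova_lm(model, typ=2)

    if not post_hoc:
        return GroupLevelResult(anova=anova, tukey=pd.DataFrame(), level_contrasts=pd.DataFrame())

    cell = records["group"].astype(str) + ":" + records["level"].astype(str)
    tk = pairwise_tukeyhsd(records["mean_width_um"].to_numpy(), cell.to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])

    contrasts = []
    for level in [l for l in LEVELS if l in set(records["level"])]:
        pair = {f"control:{level}", f"syrinx:{level}"}
        row = tukey[
            tukey.apply(lambda r: {str(r["group1"]), str(r["group2"])} == pair, axis=1)
        ]
        if len(row) == 1:
            r = row.iloc[0]
            contrasts.append(
                dict(level=level, meandiff=float(r["meandiff"]),
                     p_adj=float(r["p-adj"]), reject=bool(r["reject"]))
            )
    return GroupLevelResult(anova=anova, tukey=tukey, level_contrasts=pd.DataFrame(contrasts))


@dataclass
class QuintileResult:
    """Mixed-model (or fixed-effects fallback) quintile comparison at one level."""

    level: str
    model_type: str  # mixed | fixed
    group_p: float
    interaction_p: float
    contrasts: pd.DataFrame  # per quintile: estimate, p_raw, p_sidak, reject


def _wald_joint(params: pd.Series, cov: pd.DataFrame, names: list[str]) -> float:
    """Joint Wald chi-square p-value for a subset of coefficients."""
    b = params[names].to_numpy()
    V = cov.loc[names, names].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    return float(sps.chi2.sf(stat, df=len(names)))


def _contrast_p(params: pd.Series, cov: pd.DataFrame, names: list[str]) -> tuple[float, float]:
    """Estimate and two-sided z p-value of a sum of coefficients."""
    est = float(params[names].sum())
    se = float(np.sqrt(cov.loc[names, names].to_numpy().sum()))
    if se == 0:
        return est, 1.0 if est == 0 else 0.0
    z = est / se
    return est, float(2 * sps.norm.sf(abs(z)))


def compare_quintiles(
    records: pd.DataFrame,
    levels: list[str] | None = None,
    alpha: float = 0.05,
) -> dict[str, QuintileResult]:
    """Per-level mixed-model comparison of quintile means between groups.

    Each vessel contributes its five quintile means as repeated measures; a
    linear mixed model with fixed effects group, quintile and group×quintile
    and a random intercept per animal is fitted by REML.  With fewer than
    two animals per group the random effect is degenerate and the model
    falls back to fixed effects (OLS) with a logged warning.  The group
    contrast within each quintile is Sidak-adjusted over the family of five.
    """
    _validate_records(records)
    levels = levels or [l for l in LEVELS if l in set(records["level"])]
    results: dict[str, QuintileResult] = {}
    for level in levels:
        sub = records[records["level"] == level]
        rows = sub.dropna(subset=QUINTILE_COLUMNS)
        long = rows.melt(
            id_vars=["vessel_id", "animal_id", "group"],
            value_vars=QUINTILE_COLUMNS,
            var_name="quintile",
            value_name="width_um",
        )
        long["quintile"] = long["quintile"].str.replace("_um", "", regex=False)

        n_animals = rows.groupby("group")["animal_id"].nunique()
        use_mixed = bool((n_animals >= 2).all())
        formula = "width_um ~ C(group) * C(quintile)"
        res = None
        if use_mixed:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = smf.mixedlm(formula, long, groups=long["animal_id"]).fit(reml=True)
                params = res.fe_params
                cov = res.cov_params().loc[params.index, params.index]
                model_type = "mixed"
            except np.linalg.LinAlgError:
                res = None  # random-effect variance on the boundary
        if res is None:
            reason = (
                "<2 animals per group; random intercept degenerate"
                if not use_mixed
                else "random-effect fit singular (between-animal variance ~ 0)"
            )
            warnings.warn(
                f"level {level}: {reason}; falling back to a fixed-effects model",
                stacklevel=2,
            )
            res = smf.ols(formula, long).fit()
            params = res.params
            cov = res.cov_params()
            model_type = "fixed"

        group_term = "C(group)[T.syrinx]"
        inter_terms = [n for n in params.index if n.startswith(f"{group_term}:")]
        interaction_p = _wald_joint(params, cov, inter_terms)
        group_p = _wald_joint(params, cov, [group_term])

        quints = ["q1", "q2", "q3", "q4", "q5"]
        crows = []
        for q in quints:
            names = [group_term]
            inter = f"{group_term}:C(quintile)[T.{q}]"
            if inter in params.index:
                names.append(inter)
            est, p_raw = _contrast_p(params, cov, names)
            p_adj = float(sidak_adjust(p_raw, m=len(quints)))
            crows.append(dict(quintile=q, estimate=est, p_raw=p_raw,
                              p_sidak=p_adj, reject=bool(p_adj < alpha)))
        results[level] = QuintileResult(
            level=level,
            model_type=model_type,
            group_p=group_p,
            interaction_p=interaction_p,
            contrasts=pd.DataFrame(crows),
        )
    return results


@dataclass
class StatsReport:
    """Aggregate report of the three analyses, serializable to JSON."""

    pooling: pd.DataFrame
    group_level: GroupLevelResult
    quintiles: dict[str, QuintileResult]

    def to_dict(self) -> dict:
        return {
            "pooling": self.pooling.to_dict(orient="records"),
            "anova": {
                str(k): {str(c): _jsonable(v) for c, v in row.items()}
                for k, row in self.group_level.anova.to_dict(orient="index").items()
            },
            "tukey_level_contrasts": self.group_level.level_contrasts.to_dict(orient="records"),
            "quintiles": {
                lvl: {
                    "model_type": r.model_type,
                    "group_p": r.group_p,
                    "interaction_p": r.interaction_p,
                    "contrasts": r.contrasts.to_dict(orient="records"),
                }
                for lvl, r in self.quintiles.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=_jsonable)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, float) and np.isnan(v):
        return None
    return v


def analyze_cohort(records: pd.DataFrame, alpha: float = 0.05) -> StatsReport:
    """Run pooling check, group/level ANOVA and quintile mixed models."""
    return StatsReport(
        pooling=pooling_check(records, alpha=alpha),
        group_level=compare_group_level(records),
        quintiles=compare_quintiles(records, alpha=alpha),
    )
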
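"""Fatty-acid (FAME) composition tables, indices, and group statistics.

Species are named in C:Dn-x nomenclature — carbons : double bonds, with the
omega class suffix (e.g. ``18:1n-9`` = oleic acid) omitted for saturated
species. Percentages are of total measured fatty acids per sample.

Key derived quantities, matching standard desaturase/elongase activity
indices:

* elongation ratio = (18:0 + 18:1n-7 + 18:1n-9) / (16:0 + 16:1n-7)
* desaturation ratio = (18:1n-7 + 18:1n-9 + 16:1n-7) / (16:0 + 18:0)
* SFA / MUFA / PUFA = percentage with 0 / 1 / >= 2 double bonds;
  UFA:SFA = (MUFA + PUFA) / SFA.

Both ratios are quotients of species shares, so they are invariant to the
row normalisation (any common positive rescaling of a sample cancels).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

_SPECIES_RE = re.compile(r"^(\d+):(\d+)(?:n-(\d+))?$")

ELONGATION_NUM = ["18:0", "18:1n-7", "18:1n-9"]
ELONGATION_DEN = ["16:0", "16:1n-7"]
DESATURATION_NUM = ["18:1n-7", "18:1n-9", "16:1n-7"]
DESATURATION_DEN = ["16:0", "18:0"]
REQUIRED_SPECIES = sorted({*ELONGATION_NUM, *ELONGATION_DEN, *DESATURATION_NUM, *DESATURATION_DEN})


class SpeciesFormatError(ValueError):
    """Species name not parseable as C:Dn-x."""


def parse_species(name: str) -> tuple[int, int, int | None]:
    """Parse ``"C:Dn-x"`` into (carbons, double_bonds, omega-or-None)."""
    m = _SPECIES_RE.match(name.strip())
    if m is None:
        raise SpeciesFormatError(f"species name {name!r} is not C:Dn-x")
    carbons, dbonds = int(m.group(1)), int(m.group(2))
    omega = int(m.group(3)) if m.group(3) else None
    return carbons, dbonds, omega


def saturation_class(double_bonds: int) -> str:
    if double_bonds == 0:
        return "SFA"
    return "MUFA" if double_bonds == 1 else "PUFA"


@dataclass
class LipidTable:
    """Samples x species percentage composition with parsed nomenclature.

    ``values`` rows sum to 100 (renormalised at construction); ``species``
    holds per-column (carbons, double_bonds, omega, sat_class); ``metadata``
    optionally carries sample/condition/day/replicate.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None
    species: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        info = []
        for name in self.values.columns:
            c, d, n = parse_species(str(name))
            info.append((str(name), c, d, n, saturation_class(d)))
        self.species = pd.DataFrame(
            info, columns=["species", "carbons", "double_bonds", "omega", "sat_class"]
        ).set_index("species")
        sums = self.values.sum(axis=1)
        off = (sums - 100.0).abs()
        if (off > 1.0).any():
            logger.warning(
                "%d sample rows off 100%% by > 1%%; renormalising", int((off > 1.0).sum())
            )
        self.values = self.values.div(sums, axis=0) * 100.0

    @property
    def samples(self) -> pd.Index:
        return self.values.index


def read_lipid_table(path, metadata: pd.DataFrame | None = None) -> LipidTable:
    """Read a CSV with sample ids in the first column and species headers."""
    df = pd.read_csv(path, index_col=0)
    for col in df.columns:
        try:
            parse_species(str(col))
        except SpeciesFormatError as exc:
            raise SpeciesFormatError(f"column {col!r}: {exc}") from exc
    return LipidTable(df.astype(float), metadata=metadata)


def fa_indices(table: LipidTable) -> pd.DataFrame:
    """Per-sample elongation/desaturation ratios and saturation-class sums."""
    missing = [s for s in REQUIRED_SPECIES if s not in table.values.columns]
    if missing:
        raise ValueError(f"missing required species: {missing}")
    v = table.values
    out = pd.DataFrame(index=v.index)
    out["elongation"] = v[ELONGATION_NUM].sum(axis=1) / v[ELONGATION_DEN].sum(axis=1)
    out["desaturation"] = v[DESATURATION_NUM].sum(axis=1) / v[DESATURATION_DEN].sum(axis=1)
    for cls in ("SFA", "MUFA", "PUFA"):
        cols = table.species.index[table.species["sat_class"] == cls]
        out[cls] = v[cols].sum(axis=1) if len(cols) else 0.0
    out["UFA_SFA"] = (out["MUFA"] + out["PUFA"]) / out["SFA"]
    return out


def _group_key(meta: pd.DataFrame) -> pd.Series:
    return meta["condition"].astype(str) + "_day" + meta["day"].astype(str)


def anova_bonferroni(values: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA per column across groups, Bonferroni over columns,
    plus Bonferroni-adjusted pairwise t-tests of each group against day 0."""
    meta = meta.set_index("sample").loc[values.index]
    groups = _group_key(meta)
    names = sorted(groups.unique())
    baseline = [g for g in names if g.endswith("_day0")]
    base = baseline[0] if baseline else names[0]
    m = values.shape[1]
    rows, posthoc = [], []
    for col in values.columns:
        arrs = [values.loc[groups == g, col].to_numpy() for g in names]
        if all(np.ptp(np.concatenate(arrs)) == 0 for _ in [0]):
            f, p = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*arrs)
            if not np.isfinite(f):
                f, p = 0.0, 1.0
        rows.append((col, f, p, min(1.0, m * p)))
        others = [g for g in names if g != base]
        for g in others:
            a = values.loc[groups == base, col].to_numpy()
            b = values.loc[groups == g, col].to_numpy()
            if np.ptp(np.concatenate([a, b])) == 0:
                tp = 1.0
            else:
                tp = stats.ttest_ind(a, b, equal_var=True).pvalue
            posthoc.append((col, g, tp, min(1.0, len(others) * tp)))
    anova = pd.DataFrame(rows, columns=["feature", "F", "p", "p_adj"]).set_index("feature")
    post = pd.DataFrame(posthoc, columns=["feature", "group", "p", "p_adj"])
    return anova, post


def welch_by_day(metric: pd.Series, meta: pd.DataFrame) -> pd.DataFrame:
    """Welch's two-sample t-test cold vs CL at each matched day."""
    meta = meta.set_index("sample").loc[metric.index]
    rows = []
    for day in sorted(meta.loc[meta["condition"] != "RT", "day"].unique()):
        a = metric[(meta["condition"] == "cold") & (meta["day"] == day)]
        b = metric[(meta["condition"] == "CL") & (meta["day"] == day)]
        if len(a) < 2 or len(b) < 2:
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((day, t, p))
    return pd.DataFrame(rows, columns=["day", "t", "p"])


def slope_compare(metric: pd.Series, meta: pd.DataFrame, days=(1, 3, 7)) -> dict:
    """Compare linear day trends of a metric between cold and CL.

    Fits OLS ``metric ~ day * condition`` on treated samples at the given
    days; the p-value of the day x condition interaction tests whether the
    two slopes differ.
    """
    meta = meta.set_index("sample").loc[metric.index]
    mask = meta["day"].isin(days) & meta["condition"].isin(["cold", "CL"])
    df = pd.DataFrame({
        "y": metric[mask],
        "day": meta.loc[mask, "day"].astype(float),
        "condition": meta.loc[mask, "condition"],
    })
    if df["condition"].nunique() < 2 or df["day"].nunique() < 2:
        raise ValueError("slope comparison needs both treatments over >= 2 days")
    fit = smf.ols("y ~ day * C(condition, Treatment('CL'))", data=df).fit()
    inter = [c for c in fit.params.index if c.startswith("day:")][0]
    slope_cl = fit.params["day"]
    slope_cold = fit.params["day"] + fit.params[inter]
    return {
        "slope_cold": float(slope_cold),
        "slope_CL": float(slope_cl),
        "interaction_estimate": float(fit.params[inter]),
        "interaction_p": float(fit.pvalues[inter]),
    }


def group_tests(table: LipidTable, meta: pd.DataFrame | None = None) -> dict:
    """The composition statistics battery for a lipid table.

    Returns a dict with per-species ANOVA (+ Bonferroni and day-0 post-hoc),
    per-metric ANOVA, per-metric Welch cold-vs-CL tests at matched days, and
    cold-vs-CL slope comparisons for each derived metric.
    """
    if meta is None:
        meta = table.metadata
    if meta is None:
        raise ValueError("group_tests needs sample metadata")
    indices = fa_indices(table)
    species_anova, species_posthoc = anova_bonferroni(table.values, meta)
    metric_anova, metric_posthoc = anova_bonferroni(indices, meta)
    welch = {c: welch_by_day(indices[c], meta) for c in indices.columns}
    slopes = {}
    for c in indices.columns:
        try:
            slopes[c] = slope_compare(indices[c], meta)
        except ValueError:
            continue
    return {
        "species_anova": species_anova,
        "species_posthoc": species_posthoc,
        "metric_anova": metric_anova,
        "metric_posthoc": metric_posthoc,
        "welch": welch,
        "slopes": slopes,
    }
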
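"""Cohort-level analysis: the full macrowear statistical plan as a model object.

:class:`WearPatternModel` is built from a cohort table (one row per
specimen: taxon, sex, wear stage, relative phase areas, phase inclinations,
OR/PDE/PEW); ``fit()`` runs the whole battery and returns a
:class:`WearPatternResults` with tidy test tables, summary statistics and
``summary()`` text.

The plan, stratified by wear stage:

* **areas** — relative phase areas (arcsine-square-root transformed),
  wear stages 2 and 3 pooled to keep group sizes workable: Levene-type
  homoscedasticity gate, Kruskal–Wallis across taxa, Dunn–BH post hoc when
  the omnibus is significant.
* **inclinations** — per wear stage (wear strongly shifts angles, so no
  pooling): Euclidean distances over all inclination variables,
  multivariate dispersion (betadisper + permutation test + Tukey HSD) and
  PERMANOVA; pairwise PERMANOVA across wear stages within the reference
  taxon.
* **topography** — OR, PDE, PEW unstratified: Kruskal–Wallis + Dunn–BH.
* **sex** — Mann–Whitney on every variable within the reference taxon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as st

log = logging.getLogger(__name__)

SCHEMA_VERSION = "macrowear-cohort-v1"

AREA_VARS = ["area_buccal_pi", "area_lingual_pi", "area_phase_ii"]
INCLINATION_VARS = ["incl_buccal_pi", "incl_lingual_pi", "incl_phase_ii", "incl_tip_crush"]
TOPO_VARS = ["OR", "PDE", "PEW"]
REQUIRED_COLUMNS = ["specimen", "taxon", "wear_stage"] + AREA_VARS + INCLINATION_VARS + TOPO_VARS

KNOWN_TAXA = ("G. b. beringei", "G. b. graueri", "G. g. gorilla")


class CohortSchemaError(ValueError):
    """Cohort table violates the expected schema."""


def validate_cohort(df: pd.DataFrame, taxa=None) -> pd.DataFrame:
    """Validate and normalise a cohort table; returns a copy."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort table missing columns: {missing}")
    out = df.copy()
    out["wear_stage"] = out["wear_stage"].astype(int)
    if not out["wear_stage"].isin([1, 2, 3, 4]).all():
        raise CohortSchemaError("wear_stage must be in 1-4")
    if taxa is not None:
        bad = sorted(set(out["taxon"]) - set(taxa))
        if bad:
            raise CohortSchemaError(f"unknown taxon labels {bad}; allowed: {list(taxa)}")
    sums = out[AREA_VARS].sum(axis=1)
    ok = sums.isna() | ((sums - 1.0).abs() < 1e-6)
    if not ok.all():
        raise CohortSchemaError(
            f"relative areas must sum to 1: offending specimens "
            f"{out.loc[~ok, 'specimen'].tolist()}")
    return out


def ternary_coordinates(df: pd.DataFrame) -> pd.DataFrame:
    """Barycentric (buccal PI, lingual PI, phase II) triples with Cartesian
    plotting coordinates in the unit equilateral triangle.

    x = (2b + c) / (2(a+b+c)), y = (sqrt(3)/2) c / (a+b+c) for the triple
    (a, b, c); rows whose triple does not sum to 1 (beyond 1e-6) are
    excluded and reported.
    """
    a = df["area_buccal_pi"].to_numpy(float)
    b = df["area_lingual_pi"].to_numpy(float)
    c = df["area_phase_ii"].to_numpy(float)
    total = a + b + c
    ok = np.isfinite(total) & (np.abs(total - 1.0) < 1e-6)
    if not ok.all():
        bad = df.loc[~ok, "specimen"].tolist() if "specimen" in df else list(np.where(~ok)[0])
        log.warning("excluding %d rows with non-normalised triples: %s", (~ok).sum(), bad)
    out = df.loc[ok, [col for col in ("specimen", "taxon", "wear_stage") if col in df]].copy()
    out["buccal_pi"], out["lingual_pi"], out["phase_ii"] = a[ok], b[ok], c[ok]
    out["x"] = 0.5 * (2 * b[ok] + c[ok]) / total[ok]
    out["y"] = (math.sqrt(3) / 2.0) * c[ok] / total[ok]
    return out.reset_index(drop=True)


def _groups_of(sub: pd.DataFrame, var: str, group_col: str):
    labels, arrays = [], []
    for name, chunk in sub.groupby(group_col, sort=True):
        v = chunk[var].to_numpy(float)
        v = v[np.isfinite(v)]
        if len(v):
            labels.append(name)
            arrays.append(v)
    return labels, arrays


@dataclass
class WearPatternModel:
    """The cohort macrowear analysis, statsmodels-style.

    Parameters
    ----------
    data : validated cohort table (see :func:`validate_cohort`)
    group_col : grouping column for all between-group tests (default taxon)
    reference_group : taxon used for the sex comparison and for the
        across-wear-stage pairwise PERMANOVA (by default the largest group)
    pool_stages_23 : pool wear stages 2 and 3 for the *area* analyses only
    arcsine_areas : arcsine-square-root transform area proportions before
        the Levene and rank tests (rank tests are invariant to it, the
        variance gate is not)
    """

    data: pd.DataFrame
    group_col: str = "taxon"
    reference_group: str | None = None
    pool_stages_23: bool = True
    arcsine_areas: bool = True
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.data = validate_cohort(self.data)
        if self.reference_group is None:
            self.reference_group = self.data[self.group_col].value_counts().idxmax()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "WearPatternModel":
        return cls(data=df, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "WearPatternModel":
        return cls(data=pd.read_csv(path), **kwargs)

    # -- strata ------------------------------------------------------------
    def area_strata(self):
        stages = sorted(self.data["wear_stage"].unique())
        if self.pool_stages_23 and {2, 3} & set(stages):
            out = [(s, [s]) for s in stages if s not in (2, 3)]
            out.append(("2+3", [2, 3]))
            return sorted(out, key=lambda t: str(t[0]))
        return [(s, [s]) for s in stages]

    def inclination_strata(self):
        return [(s, [s]) for s in sorted(self.data["wear_stage"].unique())]

    # -- fit ---------------------------------------------------------------
    def fit(self, n_perm: int = st.DEFAULT_N_PERM, seed: int = 0) -> "WearPatternResults":
        records: list[dict] = []
        extras: dict = {}

        def rec(track, variable, stratum, test, contrast, statistic, pvalue,
                p_adjusted=math.nan, note=""):
            records.append(dict(track=track, variable=variable, stratum=str(stratum),
                                test=test, contrast=contrast, statistic=statistic,
                                pvalue=pvalue, p_adjusted=p_adjusted, note=note))

        self._fit_area_track(rec, n_perm, seed)
        self._fit_inclination_track(rec, extras, n_perm, seed)
        self._fit_topo_track(rec)
        self._fit_sex_track(rec)
        results = pd.DataFrame(records)
        return WearPatternResults(model=self, tests=results,
                                  summary_stats=self.summary_statistics(),
                                  dispersion=extras.get("dispersion", {}),
                                  n_perm=n_perm, seed=seed)

    def _fit_area_track(self, rec, n_perm, seed):
        for stratum, stages in self.area_strata():
            sub = self.data[self.data["wear_stage"].isin(stages)]
            for var in AREA_VARS:
                labels, arrays = _groups_of(sub, var, self.group_col)
                if self.arcsine_areas:
                    arrays = [st.arcsine_transform(a) for a in arrays]
                if len(labels) < 2 or sum(len(a) for a in arrays) < 3:
                    rec("areas", var, stratum, "kruskal-wallis", "all", math.nan, math.nan,
                        note="too few specimens/groups in stratum; skipped")
                    continue
                if all(len(a) >= 2 for a in arrays):
                    lev = st.levene_brown_forsythe(arrays)
                    rec("areas", var, stratum, "levene", "all", lev.statistic, lev.pvalue)
                else:
                    rec("areas", var, stratum, "levene", "all", math.nan, math.nan,
                        note="a group has < 2 observations; variance gate skipped")
                kw = st.kruskal_wallis(arrays)
                rec("areas", var, stratum, "kruskal-wallis", "all", kw.statistic, kw.pvalue)
                if kw.pvalue < self.alpha and len(labels) >= 3:
                    dunn = st.dunn_posthoc(arrays, labels=labels)
                    for _, row in dunn.iterrows():
                        rec("areas", var, stratum, "dunn",
                            f"{row.group1} vs {row.group2}", row.z, row.pvalue, row.p_adjusted)

    def _fit_inclination_track(self, rec, extras, n_perm, seed):
        extras["dispersion"] = {}
        for stratum, stages in self.inclination_strata():
            sub = self.data[self.data["wear_stage"].isin(stages)]
            x = sub[INCLINATION_VARS].to_numpy(float)
            complete = np.isfinite(x).all(axis=1)
            sub = sub[complete]
            groups = sub[self.group_col].to_numpy()
            sizes = pd.Series(groups).value_counts()
            usable = sizes[sizes >= 2].index
            sub = sub[sub[self.group_col].isin(usable)]
            if sub[self.group_col].nunique() < 2 or len(sub) < 4:
                rec("inclinations", "all-phases", stratum, "permanova", "all",
                    math.nan, math.nan, note="insufficient complete specimens; skipped")
                continue
            dm = st.euclidean_distance_matrix(sub[INCLINATION_VARS].to_numpy(float),
                                              ids=sub["specimen"].tolist())
            groups = sub[self.group_col].to_numpy()
            disp = st.betadisper(dm, groups)
            extras["dispersion"][stratum] = disp
            perm_disp = st.permutest_dispersion(disp, n_perm=n_perm, seed=seed)
            rec("inclinations", "all-phases", stratum, "permutest-dispersion", "all",
                perm_disp.statistic, perm_disp.pvalue)
            try:
                tukey = st.tukey_hsd_dispersion(disp)
                for _, row in tukey.iterrows():
                    rec("inclinations", "all-phases", stratum, "tukey-hsd-dispersion",
                        f"{row.group1} vs {row.group2}", row["diff"], row.pvalue)
            except ValueError as exc:
                rec("inclinations", "all-phases", stratum, "tukey-hsd-dispersion", "all",
                    math.nan, math.nan, note=str(exc))
            pmv = st.permanova(dm, groups, n_perm=n_perm, seed=seed)
            rec("inclinations", "all-phases", stratum, "permanova", "all",
                pmv.statistic, pmv.pvalue)
        self._fit_reference_stage_permanova(rec, n_perm, seed)

    def _fit_reference_stage_permanova(self, rec, n_perm, seed):
        """Pairwise PERMANOVA across wear-stage classes within the reference
        taxon (does the wear trajectory itself separate stages?)."""
        sub = self.data[self.data[self.group_col] == self.reference_group]
        x = sub[AREA_VARS].to_numpy(float)
        complete = np.isfinite(x).all(axis=1)
        sub = sub[complete]
        stages = sub["wear_stage"].to_numpy()
        counts = pd.Series(stages).value_counts()
        keep = counts[counts >= 2].index
        sub = sub[sub["wear_stage"].isin(keep)]
        if sub["wear_stage"].nunique() < 3:
            rec("areas", "composition", "stages", "pairwise-permanova", "all",
                math.nan, math.nan, note="fewer than 3 wear-stage classes; skipped")
            return
        dm = st.euclidean_distance_matrix(sub[AREA_VARS].to_numpy(float),
                                          ids=sub["specimen"].tolist())
        table = st.pairwise_permanova(dm, sub["wear_stage"].to_numpy(),
                                      n_perm=n_perm, seed=seed)
        for _, row in table.iterrows():
            rec("areas", "composition", "stages", "pairwise-permanova",
                f"stage {row.group1} vs stage {row.group2}",
                row.pseudo_F, row.pvalue, row.p_adjusted)

    def _fit_topo_track(self, rec):
        for var in TOPO_VARS:
            labels, arrays = _groups_of(self.data, var, self.group_col)
            if len(labels) < 2 or sum(len(a) for a in arrays) < 3:
                rec("topography", var, "all", "kruskal-wallis", "all", math.nan, math.nan,
                    note="too few specimens/groups; skipped")
                continue
            kw = st.kruskal_wallis(arrays)
            rec("topography", var, "all", "kruskal-wallis", "all", kw.statistic, kw.pvalue)
            if kw.pvalue < self.alpha and len(labels) >= 3:
                dunn = st.dunn_posthoc(arrays, labels=labels)
                for _, row in dunn.iterrows():
                    rec("topography", var, "all", "dunn",
                        f"{row.group1} vs {row.group2}", row.z, row.pvalue, row.p_adjusted)

    def _fit_sex_track(self, rec):
        sub = self.data[self.data[self.group_col] == self.reference_group]
        if "sex" not in sub.columns:
            return
        males = sub[sub["sex"] == "M"]
        females = sub[sub["sex"] == "F"]
        if len(males) < 2 or len(females) < 2:
            rec("sex", "all", self.reference_group, "mann-whitney", "M vs F",
                math.nan, math.nan, note="insufficient sexed specimens; skipped")
            return
        for var in AREA_VARS + INCLINATION_VARS + TOPO_VARS:
            x = males[var].to_numpy(float)
            y = females[var].to_numpy(float)
            x, y = x[np.isfinite(x)], y[np.isfinite(y)]
            if len(x) == 0 or len(y) == 0:
                continue
            if var in AREA_VARS and self.arcsine_areas:
                x, y = st.arcsine_transform(x), st.arcsine_transform(y)
            mw = st.mann_whitney(x, y)
            rec("sex", var, self.reference_group, "mann-whitney", "M vs F",
                mw.statistic, mw.pvalue)

    # -- descriptive -------------------------------------------------------
    def summary_statistics(self) -> pd.DataFrame:
        """Median and SD per (group, stratum, variable) — the published
        summary-table layout."""
        rows = []
        for stratum, stages in self.area_strata():
            sub = self.data[self.data["wear_stage"].isin(stages)]
            for name, chunk in sub.groupby(self.group_col, sort=True):
                for var in AREA_VARS:
                    v = chunk[var].dropna()
                    rows.append(dict(stratum=str(stratum), group=name, variable=var,
                                     n=len(v), median=v.median(), sd=v.std(ddof=1)))
        for stratum, stages in self.inclination_strata():
            sub = self.data[self.data["wear_stage"].isin(stages)]
            for name, chunk in sub.groupby(self.group_col, sort=True):
                for var in INCLINATION_VARS:
                    v = chunk[var].dropna()
                    rows.append(dict(stratum=str(stratum), group=name, variable=var,
                                     n=len(v), median=v.median(), sd=v.std(ddof=1)))
        for name, chunk in self.data.groupby(self.group_col, sort=True):
            for var in TOPO_VARS:
                v = chunk[var].dropna()
                rows.append(dict(stratum="all", group=name, variable=var,
                                 n=len(v), median=v.median(), sd=v.std(ddof=1)))
        return pd.DataFrame(rows)


@dataclass
class WearPatternResults:
    """Fitted cohort battery: tidy test table, summary statistics, dispersions."""

    model: WearPatternModel
    tests: pd.DataFrame
    summary_stats: pd.DataFrame
    dispersion: dict = field(default_factory=dict)
    n_perm: int = st.DEFAULT_N_PERM
    seed: int = 0

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        alpha = self.model.alpha if alpha is None else alpha
        p = self.tests["p_adjusted"].fillna(self.tests["pvalue"])
        return self.tests[p < alpha]

    def ternary_coordinates(self) -> pd.DataFrame:
        return ternary_coordinates(self.model.data)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Macrowear cohort analysis",
            "=" * 60,
            f"specimens: {len(m.data)}   groups ({m.group_col}): "
            + ", ".join(f"{g} (n={n})" for g, n in
                        m.data[m.group_col].value_counts().sort_index().items()),
            f"permutations: {self.n_perm}   seed: {self.seed}   "
            f"stage pooling (areas): {'2+3' if m.pool_stages_23 else 'none'}   "
            f"arcsine areas: {m.arcsine_areas}",
            "",
            "Omnibus tests (statistic, p):",
        ]
        omnibus = self.tests[self.tests["contrast"] == "all"]
        for _, r in omnibus.iterrows():
            if math.isnan(r.statistic) and r.note:
                lines.append(f"  [{r.track}] {r.variable} | stratum {r.stratum} | "
                             f"{r.test}: skipped ({r.note})")
            else:
                lines.append(f"  [{r.track}] {r.variable} | stratum {r.stratum} | "
                             f"{r.test}: {r.statistic:.4g}, p = {r.pvalue:.4g}")
        sig = self.significant()
        pairwise = sig[sig["contrast"] != "all"]
        lines.append("")
        if len(pairwise):
            lines.append(f"Significant pairwise contrasts (adjusted p < {m.alpha}):")
            for _, r in pairwise.iterrows():
                padj = r.p_adjusted if not math.isnan(r.p_adjusted) else r.pvalue
                lines.append(f"  [{r.track}] {r.variable} | stratum {r.stratum} | "
                             f"{r.test}: {r.contrast}  p_adj = {padj:.4g}")
        else:
            lines.append(f"No pairwise contrast significant at adjusted p < {m.alpha}.")
        return "\n".join(lines)
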
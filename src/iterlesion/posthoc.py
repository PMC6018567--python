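"""Post-hoc analyses: damage grouping, incidence, chi-square, severity.

After the mapping identifies a frontal and a temporal region, each patient
is assigned to one of five groups by how much of each region their lesion
covers.  Group-wise incidence of the deficit of interest is compared with
Pearson chi-square tests (2x2, no continuity correction), and naming
severity is compared across groups with an ANCOVA adjusting for lesion
volume, with Bonferroni-corrected pairwise contrasts.  A smallest-lesion
report documents that the minimal lesion producing the deficit extends
beyond the statistically identified region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, cohort_composites, cohort_deficits
from .lesion_io import ROISet, roi_damage_fraction

__all__ = [
    "GroupAssignment",
    "IncidenceTable",
    "SeverityResult",
    "assign_damage_groups",
    "assign_cohort_groups",
    "incidence_table",
    "pearson_chi2_2x2",
    "severity_ancova",
    "smallest_lesion_report",
]

GROUP_NAMES = {1: "Frontal", 2: "Temporal", 3: "Both", 4: "Partial",
               5: "Neither"}


@dataclass
class GroupAssignment:
    """Five-group damage classification of a cohort."""

    groups: np.ndarray           # int in 1..5, cohort order
    f_frontal: np.ndarray
    f_temporal: np.ndarray
    patient_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups, dtype=int)
        if not np.all((self.groups >= 1) & (self.groups <= 5)):
            raise ValueError("groups must be in 1..5")

    def counts(self) -> dict[int, int]:
        return {g: int((self.groups == g).sum()) for g in range(1, 6)}


@dataclass
class SeverityResult:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    pairwise: pd.DataFrame       # group_a, group_b, diff, t, p_bonf


def assign_damage_groups(f_frontal: float, f_temporal: float,
                         high: float = 0.75, low: float = 0.25) -> int:
    """One patient's damage group from frontal/temporal damage fractions.

    Group 1: >= 75% frontal damage, <= 25% temporal.
    Group 2: >= 75% temporal damage, <= 25% frontal.
    Group 3: >= 75% damage to both.
    Group 5: <= 25% damage to both.
    Group 4: every remaining combination (partial damage to one or both).
    """
    if not (0.0 <= f_frontal <= 1.0 and 0.0 <= f_temporal <= 1.0):
        raise ValueError("damage fractions must lie in [0, 1]")
    if f_frontal >= high and f_temporal <= low:
        return 1
    if f_temporal >= high and f_frontal <= low:
        return 2
    if f_frontal >= high and f_temporal >= high:
        return 3
    if f_frontal <= low and f_temporal <= low:
        return 5
    return 4


def assign_cohort_groups(cohort: Cohort, rois: ROISet,
                         frontal_label: int, temporal_label: int
                         ) -> GroupAssignment:
    """Group every patient by damage to the given frontal/temporal ROIs."""
    fm = rois.mask_of(frontal_label)
    tm = rois.mask_of(temporal_label)
    ff = np.array([roi_damage_fraction(p.lesion, fm) for p in cohort.patients])
    ft = np.array([roi_damage_fraction(p.lesion, tm) for p in cohort.patients])
    groups = np.array([assign_damage_groups(a, b) for a, b in zip(ff, ft)])
    return GroupAssignment(groups=groups, f_frontal=ff, f_temporal=ft,
                           patient_ids=cohort.patient_ids)


@dataclass
class IncidenceTable:
    """Per-group deficit incidence, Table-3 style."""

    table: pd.DataFrame          # index: group, columns: n/impaired/...

    @classmethod
    def from_counts(cls, counts: dict[int, tuple[int, int]]) -> "IncidenceTable":
        """Build from {group: (impaired, not_impaired)} counts."""
        rows = []
        for g in sorted(counts):
            imp, notimp = counts[g]
            n = imp + notimp
            rows.append({
                "group": g, "name": GROUP_NAMES.get(g, str(g)), "n": n,
                "impaired": imp, "not_impaired": notimp,
                "pct_impaired": int(round(100.0 * imp / n)) if n else np.nan,
            })
        df = pd.DataFrame(rows).set_index("group")
        total = {"name": "Total", "n": int(df["n"].sum()),
                 "impaired": int(df["impaired"].sum()),
                 "not_impaired": int(df["not_impaired"].sum())}
        total["pct_impaired"] = (
            int(round(100.0 * total["impaired"] / total["n"]))
            if total["n"] else np.nan)
        df.loc["total"] = total
        return cls(table=df)

    def row(self, group: int) -> pd.Series:
        return self.table.loc[group]


def incidence_table(groups: GroupAssignment,
                    deficits: np.ndarray) -> IncidenceTable:
    """Count impaired / not-impaired patients per damage group."""
    deficits = np.asarray(deficits, dtype=bool)
    if deficits.shape[0] != groups.groups.shape[0]:
        raise ValueError("groups and deficits cover different patient sets")
    counts = {}
    for g in range(1, 6):
        in_g = groups.groups == g
        counts[g] = (int((in_g & deficits).sum()),
                     int((in_g & ~deficits).sum()))
    return IncidenceTable.from_counts(counts)


def pearson_chi2_2x2(table) -> tuple[float, float, int]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Returns (X^2, p, df=1).  X^2 = sum (O - E)^2 / E with expected counts
    from the margins.  Raises on any zero margin.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("degenerate table: zero margin")
    expected = np.outer(rows, cols) / obs.sum()
    x2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(x2, df=1))
    return x2, p, 1


def severity_ancova(groups: GroupAssignment, composite: np.ndarray,
                    lesion_volumes: np.ndarray) -> SeverityResult:
    """Composite naming severity across groups adjusting for lesion volume.

    Linear model: composite ~ group indicators + lesion volume.  The group
    factor is tested with a partial F-test against the volume-only model;
    pairwise group differences are tested on the adjusted means with
    Bonferroni correction over the number of pairs.  Groups with fewer than
    two members are dropped with a warning.
    """
    import warnings

    import statsmodels.api as sm

    g = np.asarray(groups.groups)
    y = np.asarray(composite, dtype=float)
    vol = np.asarray(lesion_volumes, dtype=float)
    levels = [lev for lev in np.unique(g) if (g == lev).sum() >= 2]
    dropped = set(np.unique(g)) - set(levels)
    if dropped:
        warnings.warn(f"groups with <2 members excluded: {sorted(dropped)}",
                      stacklevel=2)
    keep = np.isin(g, levels)
    g, y, vol = g[keep], y[keep], vol[keep]
    if len(levels) < 2:
        raise ValueError("severity ANCOVA needs at least two non-empty groups")

    # treatment coding against the first level
    dummies = np.column_stack([(g == lev).astype(float)
                               for lev in levels[1:]])
    X_full = sm.add_constant(np.column_stack([dummies, vol]))
    X_red = sm.add_constant(vol)
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    df_num = len(levels) - 1
    df_den = int(full.df_resid)
    f_stat = ((red.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p_value = float(stats.f.sf(f_stat, df_num, df_den))

    # pairwise adjusted-mean contrasts, Bonferroni over the pairs
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    n_pairs = len(pairs)
    rows = []
    ncols = X_full.shape[1]
    for a, b in pairs:
        c = np.zeros(ncols)
        # columns: const, dummies for levels[1:], volume
        if a != levels[0]:
            c[1 + levels[1:].index(a)] = 1.0
        if b != levels[0]:
            c[1 + levels[1:].index(b)] = -1.0
        tt = full.t_test(c)
        rows.append({"group_a": int(a), "group_b": int(b),
                     "diff": float(np.atleast_1d(tt.effect)[0]),
                     "t": float(np.atleast_1d(tt.tvalue).ravel()[0]),
                     "p_bonf": float(min(1.0,
                                         np.atleast_1d(tt.pvalue).ravel()[0]
                                         * n_pairs))})
    return SeverityResult(f_stat=float(f_stat), df_num=df_num, df_den=df_den,
                          p_value=p_value, pairwise=pd.DataFrame(rows))


def smallest_lesion_report(cohort: Cohort, rois: ROISet,
                           deficits: np.ndarray,
                           damage_cutoff: float = 0.25,
                           binarize_u: float = 0.3) -> pd.DataFrame:
    """Per ROI: the smallest lesion among impaired patients damaging it.

    A patient qualifies for an ROI when they carry the deficit of interest
    and their damage fraction to that ROI exceeds ``damage_cutoff``.  The
    report gives the minimum lesion volume among qualifiers and whether
    that minimal lesion extends beyond the ROI (any lesioned voxel outside
    it) — ROIs without qualifiers yield an empty entry.
    """
    if rois.is_empty():
        raise ValueError("smallest_lesion_report needs a non-empty ROI set")
    deficits = np.asarray(deficits, dtype=bool)
    rows = []
    for k in rois.label_ids:
        m = rois.mask_of(k)
        best = None
        for p, has_deficit in zip(cohort.patients, deficits):
            if not has_deficit:
                continue
            if roi_damage_fraction(p.lesion, m) <= damage_cutoff:
                continue
            if best is None or p.lesion_volume_cm3 < best.lesion_volume_cm3:
                best = p
        if best is None:
            rows.append({"roi": k, "name": rois.names.get(k, str(k)),
                         "patient_id": None, "min_volume_cm3": np.nan,
                         "extends_beyond_roi": None})
        else:
            vals = best.lesion.values
            lesioned = (vals > binarize_u if best.lesion.kind == "fuzzy"
                        else vals > 0)
            beyond = bool(np.any(lesioned & ~m))
            rows.append({"roi": k, "name": rois.names.get(k, str(k)),
                         "patient_id": best.patient_id,
                         "min_volume_cm3": float(best.lesion_volume_cm3),
                         "extends_beyond_roi": beyond})
    return pd.DataFrame(rows)


def posthoc_report(cohort: Cohort, rois: ROISet, frontal_label: int,
                   temporal_label: int) -> dict:
    """Convenience bundle: groups, incidence, chi-squares, severity,
    smallest lesions for a mapped cohort."""
    groups = assign_cohort_groups(cohort, rois, frontal_label, temporal_label)
    deficits = cohort_deficits(cohort)
    inc = incidence_table(groups, deficits)
    chi = {}
    for g in (1, 2, 3):
        a = inc.row(g)
        b = inc.row(5)
        tab = [[a["impaired"], a["not_impaired"]],
               [b["impaired"], b["not_impaired"]]]
        try:
            x2, p, _ = pearson_chi2_2x2(tab)
            chi[f"group{g}_vs_group5"] = {"x2": x2, "p": p}
        except ValueError:
            chi[f"group{g}_vs_group5"] = None
    sev = severity_ancova(groups, cohort_composites(cohort),
                          cohort.lesion_volumes())
    smallest = smallest_lesion_report(cohort, rois, deficits)
    return {"groups": groups, "incidence": inc, "chi2": chi,
            "severity": sev, "smallest_lesions": smallest}
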
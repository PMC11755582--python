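"""Preferential activation ratio (PAR) and the study-level statistics.

The PAR quantifies how selectively the transversus abdominis (TrA)
thickens relative to the obliques (OI, OE) when a participant contracts:

    PAR = TrA_C / (TrA_C + OI_C + OE_C) - TrA_R / (TrA_R + OI_R + OE_R)

where ``_R`` and ``_C`` are rest and contracted thicknesses in mm. PAR is
dimensionless, lies in (-1, 1), is invariant to rescaling all six inputs,
and is positive exactly when the TrA's share of the total three-muscle
thickness grows during contraction — the signature of an isolated TrA
contraction (the goal of the abdominal draw-in maneuver).

The rest of the module reproduces the study-level workflow on a
per-repetition PAR table: mixed-design repeated-measures ANOVA with
Mauchly's sphericity test and a Greenhouse-Geisser branch, paired t-tests
with Cohen's d between repetitions, Mann-Whitney U for non-normal group
comparisons, and the three report tables (thickness summary, PAR summary,
repetition contrasts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

MUSCLES = ("OE", "OI", "TrA")
THICKNESS_COLUMNS = ("OE_R", "OI_R", "TrA_R", "OE_C", "OI_C", "TrA_C")
ALPHA = 0.05


@dataclass
class StatReport:
    """One hypothesis-test result in the shape the study reports them.

    ``df`` is a tuple (possibly length 1) of degrees of freedom;
    ``effect_size`` is partial eta-squared for ANOVA rows and Cohen's d for
    paired t-tests (None where no effect size is conventional). ``extra``
    carries test-specific detail such as the full ANOVA table.
    """

    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect_size: float | None = None
    effect_name: str | None = None
    alpha: float = ALPHA
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def compute_par(
    tra_rest: float,
    oi_rest: float,
    oe_rest: float,
    tra_contracted: float,
    oi_contracted: float,
    oe_contracted: float,
) -> float:
    """Preferential activation ratio from six thickness measurements (mm).

    All inputs must be strictly positive. Accepts scalars or equally shaped
    arrays (vectorized elementwise).
    """
    args = [tra_rest, oi_rest, oe_rest, tra_contracted, oi_contracted, oe_contracted]
    arrs = [np.asarray(a, dtype=float) for a in args]
    for name, a in zip(
        ("tra_rest", "oi_rest", "oe_rest", "tra_contracted", "oi_contracted", "oe_contracted"),
        arrs,
    ):
        if np.any(~(a > 0)):
            raise ValueError(f"{name} must be > 0, got {a}")
    tr, oi_r, oe_r, tc, oi_c, oe_c = arrs
    par = tc / (tc + oi_c + oe_c) - tr / (tr + oi_r + oe_r)
    return float(par) if par.ndim == 0 else par


def par_from_table(df: pd.DataFrame) -> pd.Series:
    """PAR for every row of a thickness table with the six ``*_R``/``*_C`` columns."""
    missing = [c for c in THICKNESS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"thickness table missing columns {missing}")
    return pd.Series(
        compute_par(
            df["TrA_R"].to_numpy(), df["OI_R"].to_numpy(), df["OE_R"].to_numpy(),
            df["TrA_C"].to_numpy(), df["OI_C"].to_numpy(), df["OE_C"].to_numpy(),
        ),
        index=df.index,
        name="PAR",
    )


def _complete_cases(
    df: pd.DataFrame, dv: str, within: str, subject: str
) -> tuple[pd.DataFrame, int]:
    """Drop subjects missing any within-level (listwise deletion); return count."""
    levels = df[within].nunique()
    counts = df.dropna(subset=[dv]).groupby(subject)[within].nunique()
    keep = counts[counts == levels].index
    dropped = df[subject].nunique() - len(keep)
    return df[df[subject].isin(keep)].copy(), dropped


def rm_anova(
    df: pd.DataFrame,
    dv: str = "PAR",
    within: str = "repetition",
    between: str = "group",
    subject: str = "participant",
) -> StatReport:
    """Mixed-design ANOVA: within-subject repetitions crossed with group.

    Subjects with any missing repetition are dropped listwise (the count is
    logged in ``extra["n_dropped"]``). The group-related effect reported as
    the headline statistic is the group x repetition interaction, whose
    degrees of freedom match the study's reporting convention
    (df1 = k - 1, df2 = (k - 1)(n - g)). When Mauchly's test rejects
    sphericity at alpha, the Greenhouse-Geisser corrected p-value replaces
    the uncorrected one (the branch is flagged in ``extra``).
    """
    data, dropped = _complete_cases(df, dv, within, subject)
    if data[between].nunique() < 2:
        raise ValueError("need at least 2 groups for a mixed ANOVA")
    per_group = data.groupby(between)[subject].nunique()
    if (per_group < 2).any():
        raise ValueError(f"need >= 2 subjects per group, got {per_group.to_dict()}")

    if np.isclose(data[dv].var(ddof=0), 0.0):
        # no variance anywhere: every effect is exactly zero
        k = data[within].nunique()
        n, g = data[subject].nunique(), data[between].nunique()
        df1 = float((g - 1) * (k - 1))
        df2 = float((k - 1) * (n - g))
        return StatReport(
            test="mixed_anova_group_x_repetition", statistic=0.0,
            df=(df1, df2), p_value=1.0, effect_size=0.0,
            effect_name="partial_eta_squared",
            extra={"anova_table": None, "mauchly": None,
                   "greenhouse_geisser_applied": False,
                   "n_dropped": dropped, "n_subjects": n,
                   "degenerate": "zero variance"},
        )

    table = pg.mixed_anova(
        data=data, dv=dv, within=within, between=between, subject=subject,
        correction=True, effsize="np2",
    )
    sph = mauchly_test(data, dv=dv, within=within, subject=subject)
    inter = table[table["Source"] == "Interaction"].iloc[0]
    use_gg = sph.p_value <= ALPHA
    p = float(inter["p_unc"])
    if use_gg and "p_GG_corr" in table.columns:
        # pingouin attaches the GG column to the within row; correct the
        # interaction p with the same epsilon when sphericity is violated
        eps_row = table.loc[table["Source"] == within, "eps"]
        if not eps_row.isna().all():
            from scipy.stats import f as f_dist

            eps = float(eps_row.iloc[0])
            p = float(f_dist.sf(
                inter["F"], eps * inter["DF1"], eps * inter["DF2"]
            ))
    return StatReport(
        test="mixed_anova_group_x_repetition",
        statistic=float(inter["F"]),
        df=(float(inter["DF1"]), float(inter["DF2"])),
        p_value=p,
        effect_size=float(inter["np2"]),
        effect_name="partial_eta_squared",
        extra={
            "anova_table": table,
            "mauchly": sph,
            "greenhouse_geisser_applied": bool(use_gg),
            "n_dropped": dropped,
            "n_subjects": int(data[subject].nunique()),
        },
    )


def mauchly_test(
    df: pd.DataFrame,
    dv: str = "PAR",
    within: str = "repetition",
    subject: str = "participant",
) -> StatReport:
    """Mauchly's test of sphericity for the within-subject factor.

    With only two within-levels sphericity holds trivially: W = 1, p = 1,
    flagged in ``extra["trivial"]``.
    """
    k = df[within].nunique()
    if k < 2:
        raise ValueError("need >= 2 within-subject levels")
    if k == 2:
        return StatReport(
            test="mauchly", statistic=1.0, df=(0.0,), p_value=1.0,
            extra={"W": 1.0, "trivial": True},
        )
    spher = pg.sphericity(data=df, dv=dv, within=within, subject=subject)
    return StatReport(
        test="mauchly",
        statistic=float(spher.chi2),
        df=(float(spher.dof),),
        p_value=float(spher.pval),
        extra={"W": float(spher.W), "trivial": False},
    )


def paired_t(rep_a: np.ndarray, rep_b: np.ndarray) -> StatReport:
    """Paired t-test with Cohen's d for dependent samples.

    d = mean(diff) / sd(diff). Differences with zero variance (including
    identical vectors) are rejected: the t statistic is undefined there.
    """
    a = np.asarray(rep_a, dtype=float)
    b = np.asarray(rep_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    if len(a) < 2:
        raise ValueError("need n >= 2 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    t, p = stats.ttest_rel(a, b)
    d = diff.mean() / sd
    return StatReport(
        test="paired_t", statistic=float(t), df=(float(len(a) - 1),),
        p_value=float(p), effect_size=float(d), effect_name="cohens_d",
    )


def mann_whitney_u(group_a: np.ndarray, group_b: np.ndarray) -> StatReport:
    """Mann-Whitney U test, two-sided.

    Reports U = min(U1, U2) (the smaller-U convention). The p-value is
    exact for small untied samples (n <= 8 each) and uses the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u2 = len(a) * len(b) - u1
    return StatReport(
        test="mann_whitney_u", statistic=min(u1, u2), df=(float(len(a)), float(len(b))),
        p_value=float(res.pvalue), extra={"U1": u1, "U2": u2, "method": method},
    )


# -- report tables -------------------------------------------------------


def _mean_sd_ci(values: np.ndarray) -> dict:
    """Mean, SD and t-based 95% CI; CI omitted (NaN + flag) when n < 2."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = len(v)
    if n == 0:
        raise ValueError("no observations")
    mean = v.mean()
    if n == 1:
        return {"mean": mean, "sd": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "n": n, "ci_flag": "n=1: SD/CI undefined"}
    sd = v.std(ddof=1)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return {"mean": mean, "sd": sd, "ci_low": mean - half, "ci_high": mean + half,
            "n": n, "ci_flag": ""}


def build_reports(par_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summary tables in the study's three report shapes.

    ``par_table`` is the long per-repetition table: participant, group,
    exercise, repetition, the six thickness columns and (optionally) PAR —
    computed here when absent. Missing repetitions are allowed and logged.

    Returns ``{"thickness": ..., "par": ..., "repetition_contrasts": ...}``:
    per-repetition and pooled thickness summaries; PAR mean/SD/CI per group
    (pooled rows aggregate each participant's repetition mean — mean of
    PARs, not PAR of mean thicknesses); and paired-t contrasts between
    repetition pairs per group.
    """
    if par_table.empty:
        raise ValueError("empty PAR table")
    df = par_table.copy()
    if "PAR" not in df.columns:
        df["PAR"] = par_from_table(df)

    thickness_rows = []
    for (exercise, rep), sub in df.groupby(["exercise", "repetition"]):
        for col in THICKNESS_COLUMNS:
            if col in sub.columns:
                thickness_rows.append(
                    {"exercise": exercise, "repetition": str(rep), "measure": col,
                     **_mean_sd_ci(sub[col].to_numpy())}
                )
    # pooled across repetitions: participant means first
    for exercise, sub in df.groupby("exercise"):
        pooled = sub.groupby("participant")[list(THICKNESS_COLUMNS)].mean()
        for col in THICKNESS_COLUMNS:
            thickness_rows.append(
                {"exercise": exercise, "repetition": "1-3", "measure": col,
                 **_mean_sd_ci(pooled[col].to_numpy())}
            )
    thickness = pd.DataFrame(thickness_rows)

    par_rows = []
    for exercise, sub in df.groupby("exercise"):
        groups = [("All participants", sub)] + [
            (g, gsub) for g, gsub in sub.groupby("group")
        ]
        for gname, gsub in groups:
            for rep, rsub in gsub.groupby("repetition"):
                par_rows.append(
                    {"exercise": exercise, "group": gname, "repetition": str(rep),
                     **_mean_sd_ci(rsub["PAR"].to_numpy())}
                )
            pooled = gsub.groupby("participant")["PAR"].mean()
            par_rows.append(
                {"exercise": exercise, "group": gname, "repetition": "1-3",
                 **_mean_sd_ci(pooled.to_numpy())}
            )
    par_report = pd.DataFrame(par_rows)

    contrast_rows = []
    reps = sorted(df["repetition"].unique())
    pairs = [(reps[i], reps[j]) for i in range(len(reps)) for j in range(i + 1, len(reps))]
    for (exercise, gname), gsub in df.groupby(["exercise", "group"]):
        wide = gsub.pivot_table(index="participant", columns="repetition", values="PAR")
        for ra, rb in pairs:
            if ra not in wide.columns or rb not in wide.columns:
                continue
            pair = wide[[ra, rb]].dropna()
            if len(pair) < 2 or (pair[ra] - pair[rb]).std(ddof=1) == 0:
                warnings.warn(
                    f"repetition contrast {ra} vs {rb} skipped for "
                    f"{exercise}/{gname}: insufficient or degenerate pairs"
                )
                continue
            rep = paired_t(pair[ra].to_numpy(), pair[rb].to_numpy())
            contrast_rows.append(
                {"exercise": exercise, "group": gname,
                 "contrast": f"{ra} vs {rb}", "t": rep.statistic,
                 "p": rep.p_value, "d": rep.effect_size, "n": len(pair)}
            )
    contrasts = pd.DataFrame(contrast_rows)
    return {"thickness": thickness, "par": par_report, "repetition_contrasts": contrasts}


def simulate_par_cohort(
    rng: np.random.Generator,
    n_per_group: int = 12,
    n_repetitions: int = 3,
    mean_par: float = 0.025,
    between_sd: float = 0.025,
    within_sd: float = 0.03,
    group_effect: float = 0.0,
    exercise: str = "ADIM",
) -> pd.DataFrame:
    """Simulate a two-group per-repetition PAR table.

    Participant-level means are drawn around ``mean_par`` (second group
    shifted by ``group_effect``) with between-subject SD; repetition values
    add within-subject noise. With ``group_effect=0`` this is the null model
    used for type-I-error calibration of the mixed ANOVA.
    """
    rows = []
    for gi, group in enumerate(("RUSI", "Palpation")):
        for s in range(n_per_group):
            pid = f"{group[0]}{s:02d}"
            subject_mean = mean_par + gi * group_effect + rng.normal(0, between_sd)
            for rep in range(1, n_repetitions + 1):
                rows.append(
                    {"participant": pid, "group": group, "exercise": exercise,
                     "repetition": rep,
                     "PAR": subject_mean + rng.normal(0, within_sd)}
                )
    return pd.DataFrame(rows)
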
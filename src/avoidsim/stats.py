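"""Split-plot statistical pipeline applied to simulated behavior.

The analyses mirror standard practice for repeated-measures designs in
behavioral work: a mixed-design (split-plot) ANOVA with one within-subject
factor (training session, or ITI segment) and one to three fully crossed
between-subject factors, balanced cells only.  Between-subject effects are
tested against the subjects-within-groups mean square; within-subject
effects and their interactions with between factors are tested against the
within x subjects-within-groups mean square.  Whenever the Greenhouse-
Geisser epsilon estimated from the pooled within-subject covariance falls
below 1, the degrees of freedom of every within effect are multiplied by
it (no sphericity pre-test).  Effect sizes are partial eta squared,
``SS_effect / (SS_effect + SS_error)``; follow-up comparisons are pooled-
variance independent-sample t tests with Bonferroni-adjusted p values and
the effect size ``r = sqrt(t^2 / (t^2 + df))``.

The sums-of-squares decomposition is computed directly from marginal means
(valid for balanced designs) rather than through a regression fit, which
keeps the arithmetic transparent and lets the test suite cross-check it
against an independent general-linear-model oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import ConfigurationError

__all__ = [
    "AnovaResult",
    "AnovaTable",
    "TTestResult",
    "mixed_anova",
    "gg_epsilon",
    "bonferroni_ttests",
    "session_summary",
    "weight_trajectory_summary",
]


class DataIntegrityError(ValueError):
    """Raised when trial records are incomplete or a design is unbalanced."""


@dataclass(frozen=True)
class AnovaResult:
    """One effect of a split-plot ANOVA."""

    effect: str
    ss: float
    df1: float              # uncorrected numerator df
    df2: float              # uncorrected denominator df
    F: float
    p: float                # at (possibly) corrected dfs
    eta_p2: float
    epsilon: float          # GG epsilon applied (1.0 for between effects)
    df1_corr: float
    df2_corr: float
    is_within: bool


@dataclass
class AnovaTable:
    """Full ANOVA decomposition plus its error terms."""

    effects: list[AnovaResult]
    ss_total: float
    ss_subject_error: float
    df_subject_error: float
    ss_within_error: float
    df_within_error: float
    epsilon: float
    covariance_estimator: str = "pooled"

    def __getitem__(self, effect: str) -> AnovaResult:
        for res in self.effects:
            if res.effect == effect:
                return res
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": [r.effect for r in self.effects],
                "SS": [r.ss for r in self.effects],
                "df1": [r.df1_corr for r in self.effects],
                "df2": [r.df2_corr for r in self.effects],
                "F": [r.F for r in self.effects],
                "p": [r.p for r in self.effects],
                "eta_p2": [r.eta_p2 for r in self.effects],
                "epsilon": [r.epsilon for r in self.effects],
            }
        )


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance independent-samples t test with Bonferroni adjustment."""

    name: str
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    r: float


def _effect_name(factors: tuple[str, ...]) -> str:
    return ":".join(factors)


def _check_balanced(data: pd.DataFrame, dv, within, subject, between) -> None:
    counts = data.groupby([subject, within], observed=True)[dv].count()
    if not (counts == 1).all():
        raise DataIntegrityError(
            "each subject must contribute exactly one observation per within level"
        )
    per_subject = data.groupby(subject, observed=True)[within].nunique()
    k = data[within].nunique()
    if not (per_subject == k).all():
        raise DataIntegrityError("missing within-subject levels for some subjects")
    cell_of = data.groupby(subject, observed=True)[between].nunique()
    if not (cell_of == 1).all().all():
        raise DataIntegrityError("subjects must be nested within between-subject cells")
    cell_sizes = (
        data.drop_duplicates(subject).groupby(between, observed=True)[subject].count()
    )
    if cell_sizes.nunique() != 1:
        raise DataIntegrityError("unbalanced design: unequal subjects per cell")
    n_cells_expected = int(np.prod([data[b].nunique() for b in between]))
    if len(cell_sizes) != n_cells_expected:
        raise DataIntegrityError("unbalanced design: empty between-subject cells")


def _factorial_ss(data: pd.DataFrame, dv: str, factors: list[str]) -> dict:
    """Balanced-design sums of squares for every crossed effect.

    For an effect E, the effect estimate in each E-cell is the alternating
    (inclusion-exclusion) sum of marginal means over the subsets of E, and
    ``SS_E`` is the squared estimates summed over E-cells times the number
    of observations per E-cell.
    """
    grand = data[dv].mean()
    n_total = len(data)
    ss = {}
    for r in range(1, len(factors) + 1):
        for eff in itertools.combinations(factors, r):
            cells = data.groupby(list(eff), observed=True)[dv].mean().rename("_m").reset_index()
            est = cells["_m"] - grand if r == 1 else None
            if r > 1:
                est = pd.Series(np.zeros(len(cells)))
                for k in range(r + 1):
                    for sub in itertools.combinations(eff, k):
                        sign = (-1) ** (r - k)
                        if k == 0:
                            est = est + sign * grand
                        else:
                            marg = data.groupby(list(sub), observed=True)[dv].mean().rename("_mm")
                            merged = cells.merge(marg.reset_index(), on=list(sub), how="left")
                            est = est + sign * merged["_mm"].to_numpy()
            levels = int(np.prod([data[f].nunique() for f in eff]))
            n_per_cell = n_total / levels
            ss[_effect_name(eff)] = float(n_per_cell * np.sum(np.asarray(est) ** 2))
    return ss


def _pooled_within_covariance(wide: pd.DataFrame, cells: pd.Series) -> np.ndarray:
    """Covariance of the within-level vectors pooled across between cells."""
    X = wide.to_numpy(dtype=float)
    resid = np.empty_like(X)
    n_cells = 0
    for _, idx in wide.groupby(cells, observed=True).groups.items():
        loc = wide.index.get_indexer(idx)
        resid[loc] = X[loc] - X[loc].mean(axis=0)
        n_cells += 1
    dof = X.shape[0] - n_cells
    if dof < 1:
        raise DataIntegrityError("not enough subjects to estimate the within covariance")
    return resid.T @ resid / dof


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a within-subject covariance matrix.

    Computed as ``(sum lambda)^2 / ((k - 1) sum lambda^2)`` over the
    eigenvalues of the double-centered covariance, clipped to
    ``[1/(k-1), 1]``.  Equals 1 under compound symmetry and the lower bound
    for a rank-one centered covariance.
    """
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    if S.shape != (k, k) or k < 2:
        raise ConfigurationError("covariance must be a square matrix with k >= 2")
    centered = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    lam = np.linalg.eigvalsh(centered)
    lam = np.clip(lam, 0.0, None)
    denom = (k - 1) * np.sum(lam**2)
    if denom <= 0:
        eps = 1.0 / (k - 1)
    else:
        eps = float(np.sum(lam) ** 2 / denom)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: list[str] | tuple[str, ...] | str,
) -> AnovaTable:
    """Split-plot mixed ANOVA for a balanced design.

    ``data`` is long-format with one row per subject x within level.
    Between-subject factors (one to three) must be fully crossed with equal
    numbers of subjects per cell.
    """
    if isinstance(between, str):
        between = [between]
    between = list(between)
    if not 1 <= len(between) <= 3:
        raise ConfigurationError("mixed_anova supports 1-3 between-subject factors")
    _check_balanced(data, dv, within, subject, between)

    factors = between + [within]
    ss = _factorial_ss(data, dv, factors)
    grand = data[dv].mean()
    ss_total = float(((data[dv] - grand) ** 2).sum())

    k = data[within].nunique()
    subj_mean = data.groupby(subject, observed=True)[dv].mean()
    cell_key = data.drop_duplicates(subject).set_index(subject)[between]
    cell_mean = data.groupby(between, observed=True)[dv].mean()
    cell_mean_of_subj = cell_mean.loc[
        pd.MultiIndex.from_frame(cell_key.loc[subj_mean.index])
        if len(between) > 1
        else cell_key.loc[subj_mean.index, between[0]]
    ].to_numpy()
    ss_subj = float(k * np.sum((subj_mean.to_numpy() - cell_mean_of_subj) ** 2))

    n_subjects = data[subject].nunique()
    n_cells = int(np.prod([data[b].nunique() for b in between]))
    df_subj_err = n_subjects - n_cells
    df_within_err = df_subj_err * (k - 1)
    ss_within_err = ss_total - sum(ss.values()) - ss_subj
    ss_within_err = max(ss_within_err, 0.0)

    # GG epsilon from the pooled within-cell covariance of the wide data
    wide = data.pivot_table(index=subject, columns=within, values=dv, observed=True)
    cells = (
        cell_key.loc[wide.index].astype(str).agg("|".join, axis=1)
        if len(between) > 1
        else cell_key.loc[wide.index, between[0]]
    )
    eps = gg_epsilon(_pooled_within_covariance(wide, cells))

    results = []
    for r in range(1, len(factors) + 1):
        for eff in itertools.combinations(factors, r):
            name = _effect_name(eff)
            df1 = float(np.prod([data[f].nunique() - 1 for f in eff]))
            is_within = within in eff
            if is_within:
                ss_err, df_err = ss_within_err, df_within_err
            else:
                ss_err, df_err = ss_subj, df_subj_err
            if df_err <= 0:
                raise DataIntegrityError("degenerate error term; need more subjects")
            e = eps if (is_within and eps < 1.0) else 1.0
            df1_c, df2_c = df1 * e, df_err * e
            if ss_err <= 1e-300:
                # constant data within the error stratum: define 0/0 as F = 0
                F = 0.0 if ss[name] <= 1e-12 else float("inf")
                p = 1.0 if F == 0.0 else 0.0
            else:
                F = (ss[name] / df1) / (ss_err / df_err)
                p = float(sps.f.sf(F, df1_c, df2_c))
            results.append(
                AnovaResult(
                    effect=name, ss=ss[name], df1=df1, df2=float(df_err), F=float(F),
                    p=p,
                    eta_p2=float(ss[name] / (ss[name] + ss_err)) if ss[name] + ss_err > 0 else 0.0,
                    epsilon=e, df1_corr=df1_c, df2_corr=df2_c, is_within=is_within,
                )
            )
    return AnovaTable(
        effects=results,
        ss_total=ss_total,
        ss_subject_error=ss_subj,
        df_subject_error=float(df_subj_err),
        ss_within_error=float(ss_within_err),
        df_within_error=float(df_within_err),
        epsilon=eps,
    )


def bonferroni_ttests(
    comparisons: list[tuple[str, np.ndarray, np.ndarray]],
    family_size: int | None = None,
) -> list[TTestResult]:
    """Pooled-variance two-sample t tests with Bonferroni adjustment.

    ``comparisons`` is a list of ``(name, sample_x, sample_y)``; the family
    size defaults to the number of comparisons actually run.
    """
    if family_size is None:
        family_size = len(comparisons)
    out = []
    for name, x, y in comparisons:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ConfigurationError("each sample needs at least two observations")
        t, p = sps.ttest_ind(x, y, equal_var=True)
        df = len(x) + len(y) - 2
        r = float(np.sqrt(t**2 / (t**2 + df)))
        out.append(
            TTestResult(
                name=name, t=float(t), df=df, p_raw=float(p),
                p_adjusted=float(min(1.0, p * family_size)), r=r,
            )
        )
    return out


def session_summary(
    trials: pd.DataFrame, group_cols: list[str] | None = None, subject: str = "sim"
) -> pd.DataFrame:
    """Per-(subject, phase, session) behavioral measures.

    Computes the proportion of avoidance responses out of the trials of the
    session, the mean press latency, the mean ITRs per ITI segment, and
    their average across segments (``mean_itr``).
    """
    group_cols = list(group_cols or [])
    keys = group_cols + [subject, "phase", "session"]
    counts = trials.groupby(keys, observed=True)["trial"].count()
    if counts.nunique() > 1:
        raise DataIntegrityError("sessions differ in trial count; records incomplete")
    per_subj = trials.groupby(group_cols + [subject, "phase"], observed=True)["session"].nunique()
    if per_subj.nunique() > 1:
        raise DataIntegrityError("missing sessions for some subjects")
    grouped = trials.groupby(keys, observed=True)
    out = grouped.agg(
        prop_avoidance=("response", lambda s: float((s == "avoidance").mean())),
        mean_latency=("latency", "mean"),
        itr_seg1=("itr_seg1", "mean"),
        itr_seg2=("itr_seg2", "mean"),
        itr_seg3=("itr_seg3", "mean"),
    ).reset_index()
    out["mean_itr"] = out[["itr_seg1", "itr_seg2", "itr_seg3"]].mean(axis=1)
    return out


def weight_trajectory_summary(
    weights: pd.DataFrame, group_cols: list[str] | None = None
) -> pd.DataFrame:
    """Group mean and SEM of end-of-trial weights per trial and channel."""
    group_cols = list(group_cols or [])
    keys = group_cols + ["phase", "trial_global" if "trial_global" in weights else "trial",
                         "channel"]
    keys = [k for k in keys if k in weights.columns]
    grouped = weights.groupby(keys, observed=True)
    out = grouped.agg(
        v_mean=("v", "mean"),
        v_sem=("v", "sem"),
        m_press_mean=("m_press", "mean"),
        m_press_sem=("m_press", "sem"),
    ).reset_index()
    return out
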
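"""Method-agreement statistics for paired tonometry tables.

Implements the comparison battery for prototype-versus-reference IOP
tables: the Wilcoxon signed-rank test (exact null distribution by
dynamic programming, or a tie-corrected normal approximation), the
Friedman test as the repeated-measures comparison across body positions,
a right-vs-left laterality check, and the overall agreement report with
the deviation histogram and within-±1/±3 mmHg fractions.

Two-sided p-values throughout; no multiple-testing correction is applied
(flagged in the report metadata).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .study import COMPARED_SESSIONS, MEASUREMENT_COLUMNS

__all__ = [
    "WilcoxonResult",
    "FriedmanResult",
    "GroupAgreement",
    "AgreementReport",
    "wilcoxon_signed_rank",
    "friedman_repeated_measures",
    "laterality_check",
    "agreement_report",
]

EXACT_MAX_N = 25  # auto mode switches to the normal approximation above this
HIST_MAX_BIN = 6


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    pvalue: float
    n_used: int  # pairs entering the ranking (zeros dropped)
    mode: str  # 'exact' or 'approx'
    all_zero: bool = False


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    pvalue: float
    n_complete: int
    n_excluded: int


def _signed_rank_pmf(ranks2: np.ndarray) -> np.ndarray:
    """Null pmf of 2*W+ over the 2^n equiprobable sign vectors.

    ``ranks2`` are the (mid)ranks doubled to integers; returns counts
    (not normalized) indexed by the doubled statistic 0..sum(ranks2).
    Dynamic programming over the subset-sum generating function.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return counts


def wilcoxon_signed_rank(
    x,
    y=None,
    mode: str = "auto",
    zero_method: str = "wilcox",
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Parameters
    ----------
    x, y : array-like
        Paired samples (``y=None`` treats ``x`` as precomputed
        differences). Zero differences are dropped (``wilcox``, classic
        convention) or ranked then discarded from W (``pratt``). Tied
        absolute differences receive midranks.
    mode : {'auto', 'exact', 'approx'}
        ``exact`` enumerates the signed-rank null distribution by dynamic
        programming (conditional on the observed ranks, so correct under
        ties); ``approx`` uses the normal approximation with the exact
        conditional variance sum(r²)/4 and a continuity correction;
        ``auto`` is exact up to n = 25.

    Returns
    -------
    WilcoxonResult
        Statistic W+ (sum of positive-difference ranks), two-sided p.
        All-zero differences give W = 0, p = 1 with ``all_zero`` set.
    """
    if mode not in ("auto", "exact", "approx"):
        raise ValueError("mode must be 'auto', 'exact' or 'approx'")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        d = x - y
    else:
        d = x
    if d.size == 0:
        raise ValueError("need at least one pair")

    if zero_method == "wilcox":
        d = d[d != 0]
        if d.size == 0:
            return WilcoxonResult(0.0, 1.0, 0, "exact", all_zero=True)
        ranks = rankdata(np.abs(d))
    else:  # pratt: rank zeros too, then drop them from both tails
        ranks = rankdata(np.abs(d))
        keep = d != 0
        if not keep.any():
            return WilcoxonResult(0.0, 1.0, 0, "exact", all_zero=True)
        ranks, d = ranks[keep], d[keep]

    n = d.size
    w = float(ranks[d > 0].sum())
    use = mode if mode != "auto" else ("exact" if n <= EXACT_MAX_N else "approx")

    if use == "exact":
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_pmf(ranks2)
        total2 = counts.size - 1
        w2 = int(round(2 * w))
        denom = counts.sum()
        lower = counts[: w2 + 1].sum() / denom
        upper = counts[w2:].sum() / denom
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        mu = ranks.sum() / 2.0
        sigma = math.sqrt((ranks**2).sum() / 4.0)
        if sigma == 0:
            return WilcoxonResult(w, 1.0, n, "approx", all_zero=False)
        delta = w - mu
        cc = 0.5 * np.sign(delta)  # continuity correction toward the mean
        z = (delta - cc) / sigma
        p = min(1.0, 2.0 * norm.sf(abs(z)))
    return WilcoxonResult(w, float(p), n, use)


def friedman_repeated_measures(diff_by_position: pd.DataFrame) -> FriedmanResult:
    """Friedman test across repeated conditions (rows = eyes, cols = positions).

    Rows containing NaN (eyes without all conditions) are excluded and
    counted. Ranks within each row use midranks; the statistic is the
    tie-corrected Friedman chi-square with k−1 degrees of freedom.

    Raises
    ------
    ValueError
        With fewer than 2 complete cases or 2 conditions.
    """
    data = np.asarray(diff_by_position, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need a 2-D table with at least 2 conditions")
    complete = ~np.isnan(data).any(axis=1)
    n_excluded = int((~complete).sum())
    data = data[complete]
    n, k = data.shape
    if n < 2:
        raise ValueError("need at least 2 complete cases")

    r = np.apply_along_axis(rankdata, 1, data)
    col_sums = r.sum(axis=0)
    # tie-corrected form: (k-1) * sum (R_j - n(k+1)/2)^2 / (sum r_ij^2 - n k (k+1)^2 / 4)
    num = (k - 1) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    den = float((r**2).sum()) - n * k * (k + 1) ** 2 / 4.0
    if den == 0:  # all rows fully tied: no variation at all
        return FriedmanResult(0.0, 1.0, n, n_excluded)
    stat = num / den
    p = float(chi2.sf(stat, k - 1))
    return FriedmanResult(float(stat), p, n, n_excluded)


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    return table


def _paired_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Compared rows pivoted to one row per (subject, eye, session) with
    prototype and reference values and their difference."""
    t = table[~table["is_calibration"].astype(bool)].copy()
    t["role"] = np.where(t["instrument"] == "prototype", "prototype", "reference")
    wide = t.pivot_table(
        index=["subject_id", "eye", "session"],
        columns="role",
        values="iop_mmHg",
        aggfunc="first",
    ).reset_index()
    if not {"prototype", "reference"}.issubset(wide.columns):
        return pd.DataFrame(
            columns=["subject_id", "eye", "session", "prototype", "reference", "deviation"]
        )
    wide = wide.dropna(subset=["prototype", "reference"])
    wide["deviation"] = wide["prototype"] - wide["reference"]
    return wide


def laterality_check(table: pd.DataFrame) -> pd.DataFrame:
    """Right-vs-left (OD vs OS) comparison per instrument role and position.

    For each of the six cells (prototype / reference × supine,
    raised-legs, second sitting), subjects contributing both eyes are
    paired OD against OS with the Wilcoxon signed-rank test. Guards the
    study against treating fellow eyes as independent when they are
    strongly correlated.

    Returns a DataFrame with columns ``instrument, session, n_subjects,
    mean_od, mean_os, pvalue``.

    Raises
    ------
    ValueError
        If no subject contributes both eyes.
    """
    _validate_table(table)
    t = table[~table["is_calibration"].astype(bool)].copy()
    t["role"] = np.where(t["instrument"] == "prototype", "prototype", "reference")
    rows = []
    any_two_eyed = False
    for role in ("prototype", "reference"):
        for session in COMPARED_SESSIONS:
            cell = t[(t["role"] == role) & (t["session"] == session)]
            wide = cell.pivot_table(
                index="subject_id", columns="eye", values="iop_mmHg", aggfunc="first"
            )
            if not {"OD", "OS"}.issubset(wide.columns):
                continue
            wide = wide.dropna(subset=["OD", "OS"])
            if len(wide) == 0:
                continue
            any_two_eyed = True
            res = wilcoxon_signed_rank(wide["OD"].to_numpy(), wide["OS"].to_numpy())
            rows.append(
                {
                    "instrument": role,
                    "session": session,
                    "n_subjects": len(wide),
                    "mean_od": float(wide["OD"].mean()),
                    "mean_os": float(wide["OS"].mean()),
                    "pvalue": res.pvalue,
                }
            )
    if not any_two_eyed:
        raise ValueError("no subject contributes both eyes: laterality check undefined")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupAgreement:
    """Prototype-vs-reference summary for one comparison group."""

    n: int
    prototype_mean: float
    prototype_sd: float
    reference_mean: float
    reference_sd: float
    wilcoxon_w: float
    wilcoxon_p: float


@dataclass
class AgreementReport:
    """Full agreement analysis of a paired measurement table."""

    overall: GroupAgreement
    by_group: dict[str, GroupAgreement]
    deviation_hist: dict[int, float]  # |d| rounded to nearest mmHg -> fraction
    frac_within_1: float
    frac_within_3: float
    intergroup_median_diff: dict[str, float]
    intergroup_pvalue: dict[str, float]
    laterality: pd.DataFrame | None
    n_compared: int
    multiple_testing: str = "none"

    @property
    def prototype_group_mean_spread(self) -> float:
        """Max minus min of the per-group prototype mean IOPs, mmHg."""
        means = [g.prototype_mean for g in self.by_group.values()]
        return max(means) - min(means)

    def to_dict(self) -> dict:
        def g2d(g: GroupAgreement) -> dict:
            return {
                "n": g.n,
                "prototype_mean": g.prototype_mean,
                "prototype_sd": g.prototype_sd,
                "reference_mean": g.reference_mean,
                "reference_sd": g.reference_sd,
                "wilcoxon_w": g.wilcoxon_w,
                "wilcoxon_p": g.wilcoxon_p,
            }

        return {
            "overall": g2d(self.overall),
            "by_group": {k: g2d(v) for k, v in self.by_group.items()},
            "deviation_hist": {str(k): v for k, v in self.deviation_hist.items()},
            "frac_within_1": self.frac_within_1,
            "frac_within_3": self.frac_within_3,
            "prototype_group_mean_spread": self.prototype_group_mean_spread,
            "intergroup_median_diff": self.intergroup_median_diff,
            "intergroup_pvalue": self.intergroup_pvalue,
            "laterality": (
                self.laterality.to_dict(orient="records")
                if self.laterality is not None
                else None
            ),
            "n_compared": self.n_compared,
            "multiple_testing": self.multiple_testing,
        }


def _group_agreement(wide: pd.DataFrame) -> GroupAgreement:
    proto = wide["prototype"].to_numpy()
    ref = wide["reference"].to_numpy()
    res = wilcoxon_signed_rank(proto, ref)
    return GroupAgreement(
        n=len(wide),
        prototype_mean=float(proto.mean()),
        prototype_sd=float(proto.std(ddof=1)) if len(wide) > 1 else 0.0,
        reference_mean=float(ref.mean()),
        reference_sd=float(ref.std(ddof=1)) if len(wide) > 1 else 0.0,
        wilcoxon_w=res.statistic,
        wilcoxon_p=res.pvalue,
    )


def agreement_report(table: pd.DataFrame) -> AgreementReport:
    """Compute the full prototype-vs-reference agreement report.

    Calibration rows are excluded; each compared (subject, eye, session)
    contributes one deviation d = prototype − reference. The deviation
    histogram bins |d| at the nearest integer mmHg from 0 to 6 (mass
    beyond 6.5 mmHg is left as residual, so fractions sum to ≤ 1).

    Raises
    ------
    ValueError
        If the table contains no compared pairs.
    """
    _validate_table(table)
    wide = _paired_wide(table)
    if len(wide) == 0:
        raise ValueError("no compared prototype/reference pairs in table")

    by_group = {
        s: _group_agreement(wide[wide["session"] == s])
        for s in COMPARED_SESSIONS
        if (wide["session"] == s).any()
    }
    overall = _group_agreement(wide)

    absdev = wide["deviation"].abs().to_numpy()
    rounded = np.rint(absdev).astype(int)
    hist = {
        b: float((rounded == b).mean()) for b in range(HIST_MAX_BIN + 1)
    }
    frac1 = float((absdev <= 1.0).mean())
    frac3 = float((absdev <= 3.0).mean())

    inter_median: dict[str, float] = {}
    inter_p: dict[str, float] = {}
    sessions = [s for s in COMPARED_SESSIONS if s in by_group]
    for i, s1 in enumerate(sessions):
        for s2 in sessions[i + 1 :]:
            a = wide[wide["session"] == s1].set_index(["subject_id", "eye"])["prototype"]
            b = wide[wide["session"] == s2].set_index(["subject_id", "eye"])["prototype"]
            both = a.index.intersection(b.index)
            if len(both) == 0:
                continue
            diffs = (a.loc[both] - b.loc[both]).to_numpy()
            key = f"{s1}-{s2}"
            inter_median[key] = float(np.median(diffs))
            inter_p[key] = wilcoxon_signed_rank(diffs).pvalue

    try:
        lat = laterality_check(table)
    except ValueError:
        lat = None

    return AgreementReport(
        overall=overall,
        by_group=by_group,
        deviation_hist=hist,
        frac_within_1=frac1,
        frac_within_3=frac3,
        intergroup_median_diff=inter_median,
        intergroup_pvalue=inter_p,
        laterality=lat,
        n_compared=len(wide),
    )


def plot_deviation_hist(report: AgreementReport, path) -> None:
    """Save a bar plot of the |deviation| histogram (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = sorted(report.deviation_hist)
    fracs = [100 * report.deviation_hist[b] for b in bins]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(bins, fracs, color="#4878a8")
    ax.set_xlabel("|prototype − reference| (mmHg)")
    ax.set_ylabel("% of measurement pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
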
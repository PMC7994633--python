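"""Statistical layer: paired t-tests with a Bonferroni family, Pearson
correlation, and the two-way random-effects absolute-agreement average-measures
intraclass correlation ICC(A,k), assembled into per-outcome comparison reports.

Missing-data policy follows the absent-component convention: an absent evoked component
contributes amplitude 0 uV to amplitude comparisons but has no latency, so
latency comparisons lose that pair (pairwise deletion) and degrees of freedom
vary by outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

FAMILY_ALPHA = 0.05
N_FAMILY_COMPARISONS = 7  # N1/N2/P2 latency + amplitude, N2P2 amplitude

#: The seven evoked-potential outcomes forming the Bonferroni family.
EP_OUTCOMES = (
    "n1_latency_ms",
    "n1_amplitude_uv",
    "n2_latency_ms",
    "n2_amplitude_uv",
    "p2_latency_ms",
    "p2_amplitude_uv",
    "n2p2_uv",
)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def paired_t(x, y) -> TTestResult:
    """Two-sided paired t-test on complete pairs.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y, df = n - 1. Raises on fewer
    than two complete pairs or a degenerate (constant nonzero) difference;
    identical pairs — no difference at all — return t = 0, p = 1.
    """
    x, y = _complete_pairs(x, y)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return TTestResult(t=0.0, df=n - 1, p=1.0)
        raise ValueError("zero variance of paired differences: degenerate sample")
    res = sps.ttest_rel(x, y)
    return TTestResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue))


def pearson_r(x, y) -> float:
    """Product-moment correlation on complete pairs (>= 3 required)."""
    x, y = _complete_pairs(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise ValueError("zero variance input")
    return float(sps.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class ICCResult:
    value: float
    msr: float
    msc: float
    mse: float
    n: int
    k: int
    degenerate: bool = False


def icc_a_k(matrix, model: str = "agreement") -> ICCResult:
    """Two-way random-effects, average-measures intraclass correlation.

    ``matrix`` is subjects x k raters/methods (k = 2 in this study), no
    missing cells. The default absolute-agreement form (McGraw & Wong A,k):

        ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

    computed from the two-way ANOVA mean squares (rows = subjects, columns =
    methods). ``model='consistency'`` gives ICC(C,k) = (MSR - MSE)/MSR for
    sensitivity analyses. A non-positive denominator is returned flagged
    rather than raised.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("matrix must be subjects x k with k >= 2")
    if np.isnan(m).any():
        raise ValueError("no missing cells allowed")
    n, k = m.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((m - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if model == "consistency":
        denom = msr
    elif model == "agreement":
        denom = msr + (msc - mse) / n
    else:
        raise ValueError("model must be 'agreement' or 'consistency'")
    degenerate = denom <= 0
    value = float("nan") if degenerate else float((msr - mse) / denom)
    return ICCResult(value, float(msr), float(msc), float(mse), n, k, degenerate)


def bonferroni_adjust(alpha: float, m: int) -> float:
    """Per-comparison significance level alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def format_p(p: float, decimals: int = 3) -> str:
    floor = 10.0**-decimals
    return f"< {floor:g}" if p < floor else f"{p:.{decimals}f}"


@dataclass
class ComparisonReport:
    """Per-outcome paired comparison of two arms, Bonferroni-adjusted."""

    label: str
    table: pd.DataFrame
    family_alpha: float = FAMILY_ALPHA
    m_comparisons: int = N_FAMILY_COMPARISONS

    @property
    def adjusted_alpha(self) -> float:
        return round(bonferroni_adjust(self.family_alpha, self.m_comparisons), 3)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_arms(
    df_a: pd.DataFrame,
    df_b: pd.DataFrame,
    outcomes=EP_OUTCOMES,
    labels: tuple[str, str] = ("a", "b"),
    label: str = "",
    family_alpha: float = FAMILY_ALPHA,
    m_comparisons: int = N_FAMILY_COMPARISONS,
) -> ComparisonReport:
    """Paired per-outcome comparison of two arms indexed by subject.

    Each input frame must carry a ``subject`` column plus the outcome columns;
    pairing is on subject, and each outcome drops its own incomplete pairs
    (so degrees of freedom vary across outcomes). Outcomes with fewer than two
    complete pairs are reported as not computable.
    """
    a = df_a.set_index("subject")
    b = df_b.set_index("subject")
    subjects = a.index.intersection(b.index)
    adj_alpha = round(bonferroni_adjust(family_alpha, m_comparisons), 3)
    rows = []
    for outcome in outcomes:
        x = a.loc[subjects, outcome].to_numpy(dtype=float)
        y = b.loc[subjects, outcome].to_numpy(dtype=float)
        xc, yc = _complete_pairs(x, y)
        row = {
            "outcome": outcome,
            f"mean_{labels[0]}": float(np.mean(xc)) if xc.size else float("nan"),
            f"sd_{labels[0]}": float(np.std(xc, ddof=1)) if xc.size > 1 else float("nan"),
            f"mean_{labels[1]}": float(np.mean(yc)) if yc.size else float("nan"),
            f"sd_{labels[1]}": float(np.std(yc, ddof=1)) if yc.size > 1 else float("nan"),
            "n_pairs": int(xc.size),
        }
        try:
            res = paired_t(x, y)
            row.update(
                t=res.t,
                df=res.df,
                p=res.p,
                p_formatted=format_p(res.p),
                significant=res.p < adj_alpha,
                computable=True,
            )
        except ValueError:
            row.update(
                t=float("nan"), df=max(int(xc.size) - 1, 0), p=float("nan"),
                p_formatted="", significant=False, computable=False,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    return ComparisonReport(
        label=label, table=table, family_alpha=family_alpha, m_comparisons=m_comparisons
    )


def build_reports(
    sessions: pd.DataFrame, hyperalgesia: pd.DataFrame | None = None
) -> dict[str, ComparisonReport]:
    """Assemble the study's comparison reports from a per-session table.

    ``sessions`` needs columns: subject, modality ('chep'/'lep'), condition
    ('sham'/'capsaicin'), excluded, the EP outcome columns, and mean_nrs.
    Excluded (sub-3 dB) sessions are dropped before any comparison.
    ``hyperalgesia``, if given, needs subject, modality, condition, delta_nrs.

    Returns reports keyed 'baseline' (sham CHEP vs sham LEP over the 7-outcome
    Bonferroni family), 'chep_condition' and 'lep_condition' (sham vs
    capsaicin per modality), and — with pinprick data — 'hyperalgesia'
    (mechanical deltas and thermal session means, sham vs capsaicin, one row
    per modality, unadjusted family).
    """
    usable = sessions[~sessions["excluded"].astype(bool)]

    def arm(modality, condition):
        return usable[(usable["modality"] == modality) & (usable["condition"] == condition)]

    reports = {
        "baseline": compare_arms(
            arm("chep", "sham"), arm("lep", "sham"),
            labels=("chep", "lep"), label="baseline sham: CHEP vs LEP",
        ),
        "chep_condition": compare_arms(
            arm("chep", "sham"), arm("chep", "capsaicin"),
            labels=("sham", "capsaicin"), label="CHEP: sham vs capsaicin",
        ),
        "lep_condition": compare_arms(
            arm("lep", "sham"), arm("lep", "capsaicin"),
            labels=("sham", "capsaicin"), label="LEP: sham vs capsaicin",
        ),
    }

    rows = []
    for modality in ("chep", "lep"):
        if hyperalgesia is not None:
            mech = hyperalgesia[hyperalgesia["modality"] == modality]
            sham = mech[mech["condition"] == "sham"].rename(columns={"delta_nrs": "value"})
            caps = mech[mech["condition"] == "capsaicin"].rename(columns={"delta_nrs": "value"})
            rows.append(_paired_row(f"pinprick_delta_{modality}", sham, caps))
        sham = arm(modality, "sham").rename(columns={"mean_nrs": "value"})
        caps = arm(modality, "capsaicin").rename(columns={"mean_nrs": "value"})
        rows.append(_paired_row(f"thermal_pain_{modality}", sham, caps))
    reports["hyperalgesia"] = ComparisonReport(
        label="mechanical and thermal hyperalgesia: sham vs capsaicin",
        table=pd.DataFrame(rows),
        m_comparisons=1,
    )
    return reports


def _paired_row(name: str, sham: pd.DataFrame, caps: pd.DataFrame) -> dict:
    merged = sham.set_index("subject")[["value"]].join(
        caps.set_index("subject")[["value"]], lsuffix="_sham", rsuffix="_capsaicin",
        how="inner",
    ).dropna()
    x = merged["value_sham"].to_numpy()
    y = merged["value_capsaicin"].to_numpy()
    row = {
        "outcome": name,
        "mean_sham": float(x.mean()) if x.size else float("nan"),
        "sd_sham": float(x.std(ddof=1)) if x.size > 1 else float("nan"),
        "mean_capsaicin": float(y.mean()) if y.size else float("nan"),
        "sd_capsaicin": float(y.std(ddof=1)) if y.size > 1 else float("nan"),
        "n_pairs": int(x.size),
    }
    try:
        res = paired_t(x, y)
        row.update(t=res.t, df=res.df, p=res.p, p_formatted=format_p(res.p),
                   significant=res.p < FAMILY_ALPHA, computable=True)
    except ValueError:
        row.update(t=float("nan"), df=max(x.size - 1, 0), p=float("nan"),
                   p_formatted="", significant=False, computable=False)
    return row
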
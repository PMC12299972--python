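"""Normality-gated treatment comparisons, Dunn's post hoc test and CLD.

The routing mirrors the common soil/microbiome workflow: Shapiro-Wilk on the
one-way-model residuals plus Levene across groups decide between parametric
(one-way ANOVA + Tukey HSD) and nonparametric (Kruskal-Wallis + Dunn with
Benjamini-Hochberg adjustment) branches, with a natural-log re-test in
between for right-skewed positive variables.  Tukey p-values carry their own
studentized-range adjustment and are not BH-corrected again.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, ValidationError

ROUTE_ANOVA = "anova_tukey"
ROUTE_KW = "kw_dunn"


@dataclass
class GateDecision:
    route: str
    transform: str  # "none" or "log"
    shapiro_p: float
    levene_p: float
    trace: list[str] = field(default_factory=list)


@dataclass
class ComparisonResult:
    variable: str
    route: str
    transform: str
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p_adjusted
    letters: dict[str, str]
    alpha: float
    gate: GateDecision | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long tidy export: one row per pairwise comparison."""
        df = self.pairwise.copy()
        df.insert(0, "variable", self.variable)
        df["route"] = self.route
        df["transform"] = self.transform
        df["omnibus_stat"] = self.omnibus_stat
        df["omnibus_p"] = self.omnibus_p
        df["letters_a"] = df["group_a"].map(self.letters)
        df["letters_b"] = df["group_b"].map(self.letters)
        return df


def _as_groups(values) -> dict[str, np.ndarray]:
    out = {}
    for k in sorted(values):
        arr = np.asarray(values[k], dtype=float)
        out[str(k)] = arr
    return out


def _residual_normality(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Shapiro p on pooled one-way residuals, Levene p across groups."""
    resid = np.concatenate([g - g.mean() for g in groups.values()])
    if np.allclose(resid, resid[0]):
        return np.nan, np.nan
    shapiro_p = float(sps.shapiro(resid).pvalue)
    levene_p = float(sps.levene(*groups.values()).pvalue)
    return shapiro_p, levene_p


def normality_gate(values, alpha: float = 0.05) -> GateDecision:
    """Decide the comparison route for one variable.

    Shapiro-Wilk on residuals and Levene both above ``alpha`` route to
    ANOVA+Tukey; otherwise the natural-log transform is tried (positive data
    only) and re-tested; a second failure routes to Kruskal-Wallis + Dunn.
    Degenerate (constant) data also route nonparametrically, with a warning.
    """
    groups = _as_groups(values)
    if len(groups) < 2:
        raise ValidationError("normality gate needs at least 2 groups")
    for name, g in groups.items():
        if len(g) < 3:
            raise ValidationError(
                f"group {name!r} has {len(g)} observations; need >= 3 for the gate"
            )
    trace = []
    sh, lv = _residual_normality(groups)
    if np.isnan(sh):
        warnings.warn("constant data: Shapiro-Wilk undefined, routing to kw_dunn")
        return GateDecision(ROUTE_KW, "none", sh, lv, ["constant data -> kw_dunn"])
    trace.append(f"raw: shapiro_p={sh:.4g}, levene_p={lv:.4g}")
    if sh > alpha and lv > alpha:
        trace.append("raw scale passes -> anova_tukey")
        return GateDecision(ROUTE_ANOVA, "none", sh, lv, trace)

    if all((g > 0).all() for g in groups.values()):
        logged = {k: np.log(g) for k, g in groups.items()}
        sh_l, lv_l = _residual_normality(logged)
        if not np.isnan(sh_l):
            trace.append(f"log: shapiro_p={sh_l:.4g}, levene_p={lv_l:.4g}")
            if sh_l > alpha and lv_l > alpha:
                trace.append("log scale passes -> anova_tukey on ln(x)")
                return GateDecision(ROUTE_ANOVA, "log", sh_l, lv_l, trace)
    else:
        trace.append("non-positive values: log transform unavailable")

    trace.append("both scales fail -> kw_dunn")
    return GateDecision(ROUTE_KW, "none", sh, lv, trace)


def dunn_test(values) -> pd.DataFrame:
    """Dunn's rank-based multiple comparisons with tie correction and BH.

    z_{ab} = (Rbar_a - Rbar_b) / sqrt([N(N+1)/12 - T/(12(N-1))](1/n_a + 1/n_b))
    with T = sum(t^3 - t) over tie groups; two-sided normal p-values are
    Benjamini-Hochberg adjusted within the k(k-1)/2 family.
    """
    groups = _as_groups(values)
    names = list(groups)
    all_vals = np.concatenate([groups[n] for n in names])
    n_total = len(all_vals)
    ranks = sps.rankdata(all_vals)
    mean_ranks, sizes, start = {}, {}, 0
    for n in names:
        k = len(groups[n])
        mean_ranks[n] = ranks[start : start + k].mean()
        sizes[n] = k
        start += k
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_base -= tie_term / (12.0 * (n_total - 1))

    rows = []
    for a, b in itertools.combinations(names, 2):
        se_sq = var_base * (1.0 / sizes[a] + 1.0 / sizes[b])
        if se_sq <= 0:  # all observations tied everywhere
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(se_sq)
            p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "statistic": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    return df


def _tukey_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    data = np.concatenate([groups[n] for n in names])
    labels = np.concatenate([[n] * len(groups[n]) for n in names])
    res = pairwise_tukeyhsd(data, labels)
    tbl = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    out = pd.DataFrame(
        {
            "group_a": tbl["group1"].astype(str),
            "group_b": tbl["group2"].astype(str),
            "statistic": res.meandiffs,
            "p_raw": res.pvalues,
            "p_adjusted": res.pvalues,  # Tukey-adjusted already; no extra BH
        }
    )
    return out


def compare_groups(
    values,
    route: str | None = None,
    alpha: float = 0.05,
    variable: str = "value",
    posthoc: bool = True,
) -> ComparisonResult:
    """Omnibus + pairwise comparison of k groups along the chosen route.

    ``route=None`` runs :func:`normality_gate` first.  ANOVA on the log
    scale is used when the gate's passing branch was the log transform.
    ``posthoc=False`` skips the pairwise table and letters (omnibus
    screening, e.g. in calibration studies).
    """
    groups = _as_groups(values)
    for name, g in groups.items():
        if len(g) < 2:
            raise ValidationError(f"group {name!r} has < 2 observations")
    gate = None
    transform = "none"
    if route is None:
        gate = normality_gate(values, alpha=alpha)
        route, transform = gate.route, gate.transform
    if route not in (ROUTE_ANOVA, ROUTE_KW):
        raise ValidationError(f"unknown route {route!r}")

    if route == ROUTE_ANOVA:
        work = (
            {k: np.log(g) for k, g in groups.items()} if transform == "log" else groups
        )
        stat, p = sps.f_oneway(*work.values())
        pairwise = _tukey_pairwise(work) if posthoc else None
    else:
        pooled = np.concatenate(list(groups.values()))
        if np.ptp(pooled) == 0:
            # identical observations everywhere: H = 0, no rank variance
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.kruskal(*groups.values())
        pairwise = dunn_test(groups) if posthoc else None

    if pairwise is None:
        pairwise = pd.DataFrame(
            columns=["group_a", "group_b", "statistic", "p_raw", "p_adjusted"]
        )
        letters = {}
    else:
        letters = assign_letters(pairwise, alpha=alpha)
    return ComparisonResult(
        variable=variable,
        route=route,
        transform=transform,
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
        gate=gate,
    )


_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def assign_letters(pairwise: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Groups sharing a letter are not significantly different at ``alpha``;
    groups sharing no letter differ.  Deterministic: groups are processed in
    alphabetical order and letters follow column creation order.
    """
    required = {"group_a", "group_b", "p_adjusted"}
    if not required <= set(pairwise.columns):
        raise ValidationError(f"pairwise table needs columns {sorted(required)}")
    names = sorted(set(pairwise["group_a"]) | set(pairwise["group_b"]))
    seen = {frozenset((a, b)) for a, b in zip(pairwise["group_a"], pairwise["group_b"])}
    expected = {frozenset(p) for p in itertools.combinations(names, 2)}
    if seen != expected:
        miss = sorted(tuple(sorted(p)) for p in expected - seen)
        raise ValidationError(f"pairwise table missing comparisons: {miss}")

    sig_pairs = [
        tuple(sorted((r.group_a, r.group_b)))
        for r in pairwise.itertuples()
        if r.p_adjusted < alpha
    ]
    columns: list[set[str]] = [set(names)]
    for a, b in sorted(sig_pairs):
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop empty columns, duplicates, and columns contained in another
        columns = []
        for col in new_cols:
            if not col or col in columns:
                continue
            if any(col < other for other in new_cols):
                continue
            columns.append(col)
    if len(columns) > len(_LETTERS):
        raise DegenerateDataError("compact letter display exceeds 26 letters")
    columns.sort(key=lambda col: tuple(sorted(col)))
    letters = {n: "" for n in names}
    for letter, col in zip(_LETTERS, columns):
        for n in sorted(col):
            letters[n] += letter
    return letters


def letters_imply_nonsignificance(letters: dict[str, str]) -> set[frozenset]:
    """Pairs that share at least one letter (the implied 'not different' graph)."""
    out = set()
    for a, b in itertools.combinations(sorted(letters), 2):
        if set(letters[a]) & set(letters[b]):
            out.add(frozenset((a, b)))
    return out


def correlation_matrix(
    table: pd.DataFrame, method: str = "spearman"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman (average ranks on ties) or Pearson correlations.

    Returns (coefficients, p-values), both symmetric with unit diagonal.
    Zero-variance variables yield NaN entries (flagged with a warning).
    """
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown correlation method {method!r}")
    num = table.select_dtypes(include=[np.number])
    if num.shape[0] < 3:
        raise ValidationError("correlation needs at least 3 samples")
    cols = list(num.columns)
    const = [c for c in cols if np.ptp(num[c].to_numpy()) == 0]
    if const:
        warnings.warn(f"zero-variance variables, correlations set to NaN: {const}")
    k = len(cols)
    coef = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    np.fill_diagonal(coef, 1.0)
    np.fill_diagonal(pval, 0.0)
    for i, j in itertools.combinations(range(k), 2):
        if cols[i] in const or cols[j] in const:
            continue
        x, y = num[cols[i]].to_numpy(), num[cols[j]].to_numpy()
        if method == "spearman":
            r, p = sps.spearmanr(x, y)
        else:
            r, p = sps.pearsonr(x, y)
        coef[i, j] = coef[j, i] = r
        pval[i, j] = pval[j, i] = p
    return (
        pd.DataFrame(coef, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
    )


def correlation_long(
    table: pd.DataFrame, method: str = "spearman"
) -> pd.DataFrame:
    """Long export of :func:`correlation_matrix`: var_a, var_b, method, coefficient, p."""
    coef, pval = correlation_matrix(table, method=method)
    rows = []
    cols = list(coef.columns)
    for a, b in itertools.combinations(cols, 2):
        rows.append(
            {
                "var_a": a,
                "var_b": b,
                "method": method,
                "coefficient": coef.at[a, b],
                "p": pval.at[a, b],
            }
        )
    return pd.DataFrame(rows)
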
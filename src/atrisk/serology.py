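"""Antibody-antigen array arm.

Positivity calls, summed antigen-group statistics, covariate-adjusted
group models with FDR control, HLA *04:01 stratification, and the
T-cell/antibody correlation.

An antibody is called positive when its MFI is at least 3 control
standard deviations above the control mean (threshold computed from
the seronegative control group only, per antigen, boundary inclusive).
Group contrasts model the outcome on group status adjusted for age,
sex and ever/never smoking: linear regression for levels (on
log(MFI+1) by default), logistic regression for single-antigen
positivity, Poisson regression for positivity counts. Benjamini-
Hochberg FDR is applied within one outcome type x one pairwise
comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._stats import bh_adjust
from .types import DEFAULT_PAIRS, GroupComparison

log = logging.getLogger("atrisk")

DEFAULT_COVARIATES = ("age", "sex", "smoking_ever")
POSITIVITY_SD = 3.0


@dataclass
class SerumArray:
    """Subjects x antigens MFI with antigen metadata and covariates.

    ``mfi``: DataFrame indexed by subject id, one column per antigen.
    ``antigen_meta``: indexed by antigen, columns ``citrullinated``
    (bool) and ``antigen_group`` (summing group, empty for ungrouped).
    ``covariates``: indexed by subject, columns ``group``, ``age``,
    ``sex`` (1=female), ``smoking_ever`` (0/1), ``hla_0401`` (0/1).
    """

    mfi: pd.DataFrame
    antigen_meta: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.mfi.to_numpy(dtype=float) < 0).any():
            raise ValueError("MFI must be non-negative")
        unknown = set(self.mfi.columns) - set(self.antigen_meta.index)
        if unknown:
            raise ValueError(f"antigens without metadata: {sorted(unknown)[:5]}")
        if not self.mfi.index.equals(self.covariates.index):
            self.covariates = self.covariates.loc[self.mfi.index]

    @property
    def groups(self) -> pd.Series:
        return self.covariates["group"]


@dataclass
class PositivityCalls:
    """Per subject x antigen positivity with the per-antigen thresholds."""

    calls: pd.DataFrame
    thresholds: pd.Series
    n_sd: float = POSITIVITY_SD


# ---------------------------------------------------------------------------
# positivity
# ---------------------------------------------------------------------------

def call_positivity(arr: SerumArray, n_sd: float = POSITIVITY_SD,
                    control_group: str = "ctrl") -> PositivityCalls:
    """Positive ⇔ MFI >= control mean + n_sd * control SD (per antigen)."""
    ctrl = arr.mfi[arr.groups == control_group]
    if len(ctrl) < 2:
        raise ValueError("need at least 2 control subjects to set thresholds")
    mean = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    if (sd == 0).any():
        warnings.warn("zero control variance for some antigens; threshold = control mean")
    thresholds = mean + n_sd * sd
    calls = arr.mfi.ge(thresholds, axis=1)
    return PositivityCalls(calls=calls, thresholds=thresholds, n_sd=n_sd)


def summarize_groups(arr: SerumArray, calls: PositivityCalls) -> dict:
    """Summed levels and positivity counts per antigen summing group.

    Returns ``{"sums": subjects x groups summed MFI,
    "counts": subjects x (total + groups) positive-antibody counts}``.
    """
    groups = arr.antigen_meta["antigen_group"]
    grouped = groups[groups != ""].groupby(groups[groups != ""]).groups
    sums = pd.DataFrame(index=arr.mfi.index)
    counts = pd.DataFrame(index=arr.mfi.index)
    counts["total"] = calls.calls.sum(axis=1).astype(int)
    for name, antigens in grouped.items():
        cols = [a for a in antigens if a in arr.mfi.columns]
        sums[name] = arr.mfi[cols].sum(axis=1)
        counts[name] = calls.calls[cols].sum(axis=1).astype(int)
    return {"sums": sums, "counts": counts}


# ---------------------------------------------------------------------------
# covariate-adjusted group models
# ---------------------------------------------------------------------------

def _design(arr: SerumArray, pair, adjust) -> tuple[pd.DataFrame, pd.Series, str]:
    ga, gb = pair
    cov = arr.covariates
    mask = cov["group"].isin([ga, gb])
    sub = cov[mask]
    before = len(sub)
    sub = sub.dropna(subset=list(adjust))
    if len(sub) < before:
        log.info("dropped %d subjects with missing covariates", before - len(sub))
    X = sub[list(adjust)].astype(float).copy()
    X.insert(0, "group_ind", (sub["group"] == gb).astype(float))
    X = sm.add_constant(X, has_constant="add")
    return X, sub.index, f"{ga}_vs_{gb}"


def fit_group_models(
    outcome: pd.Series,
    arr: SerumArray,
    pair,
    kind: str = "level",
    adjust=DEFAULT_COVARIATES,
    log_mfi: bool = True,
    outcome_name: str = "",
    quasi: bool = False,
) -> GroupComparison:
    """Covariate-adjusted group-effect test for one outcome.

    ``kind``: "level" (linear model, on log(y+1) unless ``log_mfi`` is
    off), "positivity" (logistic on a 0/1 outcome), or "count"
    (Poisson on non-negative integers; ``quasi`` inflates the
    covariance by the Pearson dispersion). The reported p is the
    two-sided Wald p of the group indicator (second group of the pair
    coded 1). Perfect separation in the logistic model falls back to
    an L2-penalised fit (estimate kept, p reported missing, flagged).
    """
    X, idx, label = _design(arr, pair, adjust)
    y = outcome.loc[idx].astype(float)
    flags: list[str] = []
    est = p = float("nan")
    if kind in ("positivity", "count") and y.nunique() <= 1:
        # e.g. no positive subject at all: no information about the group
        return GroupComparison(comparison=label, outcome=outcome_name,
                               estimate=est, p=p, method=f"{kind}_degenerate",
                               flags=["degenerate_constant_outcome"])
    if kind == "level":
        yv = np.log1p(y) if log_mfi else y
        fit = sm.OLS(yv, X).fit()
        est, p = fit.params["group_ind"], fit.pvalues["group_ind"]
        method = "ols" + ("_log" if log_mfi else "")
    elif kind == "positivity":
        method = "logit"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", True) or np.any(
                np.abs(fit.params) > 25
            ):
                raise np.linalg.LinAlgError("separation suspected")
            est, p = fit.params["group_ind"], fit.pvalues["group_ind"]
        except Exception:
            flags.append("separation_penalized")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
            est = fit.params["group_ind"]
            method = "logit_l2"
    elif kind == "count":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        dispersion = fit.pearson_chi2 / fit.df_resid if fit.df_resid > 0 else np.nan
        if quasi and np.isfinite(dispersion) and dispersion > 0:
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale=dispersion)
            flags.append("quasi_poisson")
        flags.append(f"dispersion={dispersion:.3f}")
        est, p = fit.params["group_ind"], fit.pvalues["group_ind"]
        method = "poisson"
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return GroupComparison(
        comparison=label, outcome=outcome_name, estimate=float(est), p=float(p),
        method=method, flags=flags,
    )


def fdr_adjust(results: list[GroupComparison]) -> list[GroupComparison]:
    """BH adjustment in place across one family of comparisons."""
    finite = [r for r in results if np.isfinite(r.p)]
    if finite:
        adj = bh_adjust([r.p for r in finite])
        for r, a in zip(finite, adj):
            r.p_adj = float(a)
    return results


def compare_all(
    arr: SerumArray,
    calls: PositivityCalls | None = None,
    pairs=DEFAULT_PAIRS,
    adjust=DEFAULT_COVARIATES,
    log_mfi: bool = True,
) -> pd.DataFrame:
    """All pairwise group models with FDR per outcome-type x pair family.

    Outcomes: individual-antigen levels, summed group levels,
    individual-antigen positivity (logistic), total and per-group
    positivity counts (Poisson). Returns a tidy results table.
    """
    calls = calls if calls is not None else call_positivity(arr)
    summaries = summarize_groups(arr, calls)
    rows = []
    for pair in pairs:
        families: dict[str, list[GroupComparison]] = {"level": [], "positivity": [], "count": []}
        for antigen in arr.mfi.columns:
            families["level"].append(fit_group_models(
                arr.mfi[antigen], arr, pair, kind="level", adjust=adjust,
                log_mfi=log_mfi, outcome_name=str(antigen)))
            families["positivity"].append(fit_group_models(
                calls.calls[antigen].astype(float), arr, pair, kind="positivity",
                adjust=adjust, outcome_name=str(antigen)))
        for grp in summaries["sums"].columns:
            families["level"].append(fit_group_models(
                summaries["sums"][grp], arr, pair, kind="level", adjust=adjust,
                log_mfi=log_mfi, outcome_name=f"sum:{grp}"))
        for grp in summaries["counts"].columns:
            families["count"].append(fit_group_models(
                summaries["counts"][grp], arr, pair, kind="count", adjust=adjust,
                outcome_name=f"count:{grp}"))
        for fam, res in families.items():
            fdr_adjust(res)
            for r in res:
                rows.append((r.comparison, fam, r.outcome, r.estimate, r.p, r.p_adj,
                             r.method, ";".join(r.flags)))
    return pd.DataFrame(rows, columns=[
        "comparison", "family", "outcome", "estimate", "p", "p_adj", "method", "flags",
    ])


def stratify(
    arr: SerumArray,
    calls: PositivityCalls | None = None,
    pairs=DEFAULT_PAIRS,
    adjust=DEFAULT_COVARIATES,
    min_per_group: int = 5,
    log_mfi: bool = True,
) -> pd.DataFrame:
    """Re-fit all group models within each *04:01 stratum.

    Strata with fewer than ``min_per_group`` subjects in either group
    of a pair are skipped with a skip record in the output. Positivity
    thresholds stay anchored to the full (unstratified) control set.
    """
    calls = calls if calls is not None else call_positivity(arr)
    out = []
    for status in (0, 1):
        mask = arr.covariates["hla_0401"] == status
        sub = SerumArray(arr.mfi[mask.to_numpy()], arr.antigen_meta,
                         arr.covariates[mask.to_numpy()])
        sub_calls = PositivityCalls(calls.calls[mask.to_numpy()], calls.thresholds, calls.n_sd)
        for pair in pairs:
            sizes = [int((sub.groups == g).sum()) for g in pair]
            if min(sizes) < min_per_group:
                log.info("stratum *0401=%d pair %s skipped: group sizes %s", status, pair, sizes)
                out.append(pd.DataFrame([{
                    "comparison": f"{pair[0]}_vs_{pair[1]}", "family": "skip",
                    "outcome": "", "estimate": np.nan, "p": np.nan, "p_adj": np.nan,
                    "method": "skipped_small_stratum", "flags": f"hla_0401={status}",
                }]))
                continue
            res = compare_all(sub, calls=sub_calls, pairs=[pair], adjust=adjust, log_mfi=log_mfi)
            res.insert(0, "stratum", f"hla_0401={status}")
            out.append(res)
    res = pd.concat(out, ignore_index=True)
    if "stratum" not in res.columns:
        res.insert(0, "stratum", "")
    return res


def tcell_ab_correlation(tcell_freqs, ab_levels) -> GroupComparison:
    """Spearman correlation of CILP-reactive T-cell frequency and anti-CILP level.

    The two-sided p is computed by exact permutation of the pairings for
    n <= 7 subjects (where full enumeration is cheap and the asymptotic
    approximation is poor); the usual asymptotic p otherwise.
    """
    x = np.asarray(tcell_freqs, dtype=float)
    y = np.asarray(ab_levels, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired subjects")
    flags = []
    if np.all(x == x[0]) or np.all(y == y[0]):
        flags.append("constant_input")
        rho, p = float("nan"), float("nan")
    elif x.size <= 7:
        import itertools

        rho = float(stats.spearmanr(x, y).statistic)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()

        def _corr(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return (a @ b) / np.sqrt((a @ a) * (b @ b))

        obs = abs(_corr(rx, ry))
        hits = total = 0
        for perm in itertools.permutations(range(x.size)):
            total += 1
            if abs(_corr(rx, ry[list(perm)])) >= obs - 1e-12:
                hits += 1
        p = hits / total
    else:
        rho, p = stats.spearmanr(x, y)
    return GroupComparison(comparison="tcell_vs_antibody", outcome="CILP",
                           estimate=float(rho), p=float(p), method="spearman", flags=flags)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_serum_array(mfi_path, meta_path, covariates_path) -> SerumArray:
    mfi = pd.read_csv(mfi_path, index_col=0)
    meta = pd.read_csv(meta_path, index_col=0)
    meta["citrullinated"] = meta["citrullinated"].astype(bool)
    meta["antigen_group"] = meta["antigen_group"].fillna("")
    cov = pd.read_csv(covariates_path, index_col=0)
    return SerumArray(mfi, meta, cov)


def write_serum_array(arr: SerumArray, mfi_path, meta_path, covariates_path) -> None:
    arr.mfi.to_csv(mfi_path)
    arr.antigen_meta.to_csv(meta_path)
    arr.covariates.to_csv(covariates_path)
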
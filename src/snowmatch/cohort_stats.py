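"""Pooled mismatch/locus statistics for antibody-outcome cohorts.

One pregnancy or transplant contributes up to three observations to the
pooled analysis set — one per mismatched Class I locus — each carrying the
locus's epitope scores and the corresponding immunizer-specific-antibody
flag.  Score families are standardized within locus before pooling
(z-scores), presentation counts are log(1+x)-transformed, and the battery
comprises rank tests, Spearman correlation, univariable logistic regression,
stepwise model selection by AIC, and Cox proportional-hazards regression for
the time-to-antibody cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

SCORE_FAMILIES = ("snowflake", "all_eps", "abv_eps")
Z_COLUMNS = tuple(f"z_{c}" for c in SCORE_FAMILIES)


class DegenerateLocus(ValueError):
    """A locus group has zero variance and cannot be standardized."""


@dataclass
class RegressionResult:
    terms: list[str]
    estimates: dict[str, float]  # odds or hazard ratio per 1 SD
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_values: dict[str, float]
    aic: float
    converged: bool = True
    kind: str = "logistic"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": [self.estimates[t] for t in self.terms],
                "ci_low": [self.ci_low[t] for t in self.terms],
                "ci_high": [self.ci_high[t] for t in self.terms],
                "p": [self.p_values[t] for t in self.terms],
                "aic": self.aic,
            }
        )


# ---------------------------------------------------------------------------
# pooling


def _locus_mismatched(immunizer: tuple[str, str], responder: tuple[str, str]) -> bool:
    """A locus counts as mismatched when the immunizer carries an allele the
    responder does not."""
    return not set(immunizer) <= set(responder)


def pool_pregnancy(cases: Sequence[Mapping], loci: Sequence[str] = ("A", "B", "C")) -> pd.DataFrame:
    """Pool mother/child cases into one record per informative locus.

    Each case mapping carries ``case_id``, per-locus child and mother allele
    pairs (``child``/``mother``: locus -> pair), per-locus scores
    (``scores``: locus -> dict) and per-locus antibody flags (``csa``).
    Matched loci (child alleles all present in the mother) and loci where the
    child is homozygous for a shared allele contribute no record — a
    pregnancy yields at most three data points.
    """
    rows = []
    for case in cases:
        for locus in loci:
            child = tuple(case["child"][locus])
            mother = tuple(case["mother"][locus])
            if not _locus_mismatched(child, mother):
                continue  # matched (includes child homozygous for a shared allele)
            if child[0] == child[1] and child[0] in mother:
                continue
            row = {"case_id": case["case_id"], "locus": locus,
                   "outcome": bool(case["csa"][locus])}
            row.update(case["scores"][locus])
            rows.append(row)
    return pd.DataFrame(rows)


def pool_ktc(cases: Sequence[Mapping], loci: Sequence[str] = ("A", "B", "C")) -> pd.DataFrame:
    """Pool donor/recipient cases into per-locus records with follow-up.

    Records whose four score families are all zero are dropped (low-resolution
    typing makes a zero-mismatch call unreliable, so fully-zero-scored loci
    are treated as matched).  The antibody flag is positive when a DSA was
    observed against either donor allele of the locus.
    """
    rows = []
    for case in cases:
        for locus in loci:
            scores = case["scores"][locus]
            follow_up = float(case["follow_up"][locus])
            if follow_up < 0:
                raise ValueError(f"negative follow-up for case {case['case_id']}")
            pirche_total = sum(
                v for k, v in scores.items() if k.startswith("pirche")
            )
            if (
                scores["snowflake"] == 0
                and scores["all_eps"] == 0
                and scores["abv_eps"] == 0
                and pirche_total == 0
            ):
                continue
            row = {
                "case_id": case["case_id"], "locus": locus,
                "outcome": bool(case["dsa"][locus]), "follow_up": follow_up,
            }
            row.update(scores)
            rows.append(row)
    return pd.DataFrame(rows)


def normalize(records: pd.DataFrame, by: str = "locus") -> pd.DataFrame:
    """Standardize score families within locus and log-transform presentation
    counts.

    z = (x - mean) / sd with the sample (n-1) standard deviation, computed per
    locus on the post-exclusion analysis set before pooling; PIRCHE-family
    columns become log(1 + x).  A zero-variance locus raises
    :class:`DegenerateLocus`.
    """
    out = records.copy()
    pirche_cols = [c for c in records.columns if c.startswith("pirche")]
    for col in SCORE_FAMILIES:
        zcol = f"z_{col}"
        out[zcol] = np.nan
        for locus, group in records.groupby(by):
            sd = group[col].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise DegenerateLocus(f"column {col!r} is degenerate within {by}={locus!r}")
            out.loc[group.index, zcol] = (group[col] - group[col].mean()) / sd
    for col in pirche_cols:
        out[f"log_{col}"] = np.log1p(out[col])
    return out


# ---------------------------------------------------------------------------
# elementary tests


def rank_test(group0: Sequence[float], group1: Sequence[float]) -> float:
    """Two-sided two-sample rank test p-value (Mann-Whitney form).

    Exact enumeration when the combined sample is small and tie-free,
    otherwise the tie-corrected normal approximation.
    """
    x, y = np.asarray(group0, float), np.asarray(group1, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) and its p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# regression


def _logit_fit(y: np.ndarray, X: pd.DataFrame):
    model = sm.GLM(y, sm.add_constant(X, has_constant="add"), family=sm.families.Binomial())
    return model.fit()


def logistic_univariable(records: pd.DataFrame, predictor: str,
                         outcome: str = "outcome") -> RegressionResult:
    """Maximum-likelihood logistic fit of the outcome on one predictor;
    effect reported as the odds ratio per unit (per 1 SD for z-columns) with
    a Wald 95% CI."""
    y = records[outcome].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    X = records[[predictor]].astype(float)
    res = _logit_fit(y, X)
    beta = res.params[predictor]
    converged = bool(res.converged) and abs(beta) < 15  # huge |beta| flags separation
    se = res.bse[predictor]
    # clip the log-scale bounds so a separated fit yields finite-ish output
    ci = np.clip([beta - 1.959963984540054 * se, beta + 1.959963984540054 * se],
                 -500, 500)
    return RegressionResult(
        terms=[predictor],
        estimates={predictor: float(np.exp(np.clip(beta, -500, 500)))},
        ci_low={predictor: float(np.exp(ci[0]))},
        ci_high={predictor: float(np.exp(ci[1]))},
        p_values={predictor: float(res.pvalues[predictor])},
        aic=float(res.aic),
        converged=converged,
    )


def _model_aic(y: np.ndarray, records: pd.DataFrame, terms: Sequence[str]) -> float:
    X = records[list(terms)].astype(float) if terms else pd.DataFrame(index=records.index)
    return float(_logit_fit(y, X).aic)


def stepwise_aic(records: pd.DataFrame, candidates: Sequence[str],
                 outcome: str = "outcome") -> RegressionResult:
    """Bidirectional stepwise logistic model selection by AIC.

    Starts from the full model; at each step the single add or drop giving
    the lowest AIC is taken; stops when no move lowers the AIC.  The final
    AIC never exceeds the full model's.
    """
    if not candidates:
        raise ValueError("need at least one candidate predictor")
    y = records[outcome].astype(float).to_numpy()
    selected = list(candidates)
    current_aic = _model_aic(y, records, selected)
    while True:
        moves: list[tuple[float, list[str]]] = []
        for term in selected:
            trial = [t for t in selected if t != term]
            moves.append((_model_aic(y, records, trial), trial))
        for term in candidates:
            if term not in selected:
                moves.append((_model_aic(y, records, selected + [term]), selected + [term]))
        if not moves:
            break
        best_aic, best_terms = min(moves, key=lambda m: m[0])
        if best_aic < current_aic - 1e-10:
            current_aic, selected = best_aic, best_terms
        else:
            break

    if selected:
        res = _logit_fit(y, records[selected].astype(float))
        z = 1.959963984540054
        return RegressionResult(
            terms=list(selected),
            estimates={t: float(np.exp(res.params[t])) for t in selected},
            ci_low={t: float(np.exp(res.params[t] - z * res.bse[t])) for t in selected},
            ci_high={t: float(np.exp(res.params[t] + z * res.bse[t])) for t in selected},
            p_values={t: float(res.pvalues[t]) for t in selected},
            aic=current_aic,
        )
    return RegressionResult(terms=[], estimates={}, ci_low={}, ci_high={},
                            p_values={}, aic=current_aic)


def cox_regression(records: pd.DataFrame, terms: Sequence[str],
                   duration: str = "follow_up", event: str = "outcome") -> RegressionResult:
    """Cox proportional-hazards fit (partial likelihood); hazard ratio per
    unit (per 1 SD for z-columns) with Wald 95% CI.  Supports univariable and
    multi-term calls."""
    if records[event].sum() == 0:
        raise ValueError("no events in the data")
    if (records[duration] <= 0).any():
        raise ValueError("follow-up must be positive")
    for t in terms:
        if records[t].nunique() < 2:
            raise ValueError(f"covariate {t!r} is constant")
    df = records[[duration, event, *terms]].astype(float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration, event_col=event)
    summary = cph.summary
    return RegressionResult(
        terms=list(terms),
        estimates={t: float(summary.loc[t, "exp(coef)"]) for t in terms},
        ci_low={t: float(summary.loc[t, "exp(coef) lower 95%"]) for t in terms},
        ci_high={t: float(summary.loc[t, "exp(coef) upper 95%"]) for t in terms},
        p_values={t: float(summary.loc[t, "p"]) for t in terms},
        aic=float(cph.AIC_partial_),
        kind="cox",
    )


def cox_score_test(time: Sequence[float], event: Sequence[float],
                   x: Sequence[float]) -> tuple[float, float]:
    """Partial-likelihood score test at beta=0, Breslow tie handling.

    Returns (chi-square statistic, p).  For a binary covariate without tied
    event times this is the log-rank test.
    """
    t = np.asarray(time, float)
    d = np.asarray(event, float)
    xv = np.asarray(x, float)
    U = 0.0
    I = 0.0
    for tt in np.unique(t[d == 1]):
        at_risk = t >= tt
        xr = xv[at_risk]
        mean = xr.mean()
        var = ((xr - mean) ** 2).mean()
        deaths = (t == tt) & (d == 1)
        dj = deaths.sum()
        U += xv[deaths].sum() - dj * mean
        I += dj * var
    if I <= 0:
        raise ValueError("no information in the covariate")
    chi2 = U * U / I
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# cross-locus analysis


def cross_locus_frame(
    cases: Sequence[Mapping],
    loci: Sequence[str] = ("A", "B", "C"),
    pirche_key: str = "pirche_DRB1",
) -> pd.DataFrame:
    """Wide per-case frame for cross-locus analyses, restricted to cases
    mismatched (informative) at every Class I locus.

    Columns: ``z_snowflake_<L>`` (standardized over the retained subset),
    ``log_pirche_<L>`` and ``csa_<L>`` for each source/target locus L.
    """
    rows = []
    for case in cases:
        if not all(
            _locus_mismatched(tuple(case["child"][L]), tuple(case["mother"][L]))
            for L in loci
        ):
            continue
        row = {"case_id": case["case_id"]}
        for L in loci:
            row[f"snowflake_{L}"] = case["scores"][L]["snowflake"]
            row[f"log_pirche_{L}"] = float(np.log1p(case["scores"][L][pirche_key]))
            row[f"csa_{L}"] = bool(case["csa"][L])
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError("no case is mismatched at every locus")
    for L in loci:
        col = frame[f"snowflake_{L}"]
        sd = col.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateLocus(f"snowflake_{L} is constant in the subset")
        frame[f"z_snowflake_{L}"] = (col - col.mean()) / sd
    return frame


def cross_locus_table(
    records: pd.DataFrame,
    target_loci: Sequence[str] = ("A", "B", "C"),
    score_prefixes: Sequence[str] = ("z_snowflake", "log_pirche"),
) -> dict[str, dict]:
    """Cross-reactivity analysis on fully mismatched cases.

    ``records`` must hold one row per case with per-source-locus predictor
    columns (e.g. ``z_snowflake_A``) and per-target-locus outcome columns
    (``csa_A``).  Only cases mismatched at all three loci belong in this
    table; for each antibody target locus, univariable logistic fits over
    every source-locus predictor plus a stepwise minimal model are returned.
    """
    out: dict[str, dict] = {}
    for target in target_loci:
        outcome_col = f"csa_{target}"
        if records[outcome_col].nunique() < 2:
            raise ValueError(f"outcome {outcome_col} has a single class")
        predictors = [
            f"{p}_{src}" for p in score_prefixes for src in target_loci
            if f"{p}_{src}" in records.columns
        ]
        uni = {
            pred: logistic_univariable(records, pred, outcome=outcome_col)
            for pred in predictors
        }
        step = stepwise_aic(records, predictors, outcome=outcome_col)
        out[target] = {"univariable": uni, "stepwise": step}
    return out


def report_to_csv(path, results: Mapping[str, RegressionResult]) -> None:
    """One row per term: estimate, CI bounds, p, model AIC."""
    frames = []
    for label, res in results.items():
        frame = res.to_frame()
        frame.insert(0, "model", label)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
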
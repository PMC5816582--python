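"""Differential expression: pooled ANOVA, per-gene linear models, FWER control.

Per-gene models use +/-0.5 effect coding per two-level factor (interactions
rescaled to the same +/-0.5 range), so each main-effect coefficient is the
level-1-minus-level-2 difference on the log2 residual scale — i.e. a log2
fold change with the same orientation as the factor ratio sets. Genes are
fitted in vectorized groups sharing a missingness pattern; a term enters a
gene's model only when it is estimable from that gene's observed cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .errors import ModelError, ValidationError
from .io_formats import FACTOR_LEVELS

MAIN_TERMS = ("species", "water", "temperature", "date")
INTERACTION_TERMS = ("species:water", "species:temperature", "water:temperature")
ALL_TERMS = MAIN_TERMS + INTERACTION_TERMS

_SIGMA_FLOOR = 1e-12


def observation_factors(design: pd.DataFrame, columns: pd.MultiIndex) -> pd.DataFrame:
    """Factor levels of the sample behind each (array_id, channel) column."""
    key = pd.MultiIndex.from_frame(
        design[["array_id", "dye"]].rename(columns={"dye": "channel"})
    )
    tab = design.set_index(key)[list(MAIN_TERMS) + ["sample_id"]]
    out = tab.reindex(columns)
    if out[list(MAIN_TERMS)].isna().any().any():
        missing = out.index[out["species"].isna()][:5].tolist()
        raise ValidationError(f"design has no row for observation column(s) {missing}")
    return out


def _coded_columns(obs: pd.DataFrame) -> pd.DataFrame:
    """+/-0.5 effect codes for mains; products rescaled by 2 for interactions."""
    coded = {}
    for f in MAIN_TERMS:
        lv1, lv2 = FACTOR_LEVELS[f]
        coded[f] = np.where(obs[f] == lv1, 0.5, -0.5)
    for term in INTERACTION_TERMS:
        a, b = term.split(":")
        coded[term] = 2.0 * coded[a] * coded[b]
    return pd.DataFrame(coded, index=obs.index)


def _estimable_terms(obs: pd.DataFrame, coded: np.ndarray, term_names: list[str]) -> list[str]:
    """Terms identifiable from one missingness pattern's observed cells."""
    chosen: list[str] = []
    cols = [np.ones(len(obs))]
    for f in MAIN_TERMS:
        if obs[f].nunique() < 2:
            continue
        cand = coded[:, term_names.index(f)]
        trial = np.column_stack(cols + [cand])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            chosen.append(f)
            cols.append(cand)
    for term in INTERACTION_TERMS:
        a, b = term.split(":")
        if a not in chosen or b not in chosen:
            continue
        cand = coded[:, term_names.index(term)]
        trial = np.column_stack(cols + [cand])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            chosen.append(term)
            cols.append(cand)
    # keep >=1 residual df: sacrifice interactions first
    n = len(obs)
    while chosen and n - (len(chosen) + 1) < 1:
        inter = [t for t in chosen if ":" in t]
        if not inter:
            break
        chosen.remove(inter[-1])
    return chosen


def fit_per_gene_models(adjusted: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """OLS per gene on positive-adjusted residuals (log2 scale).

    Returns a tidy frame: gene, term, n_obs, estimate_log2, p_raw. Only terms
    estimable from the gene's non-missing pattern appear; degenerate fits
    (no residual df, or zero residual variance) report p_raw = 1.
    """
    obs = observation_factors(design, adjusted.columns)
    coded_full = _coded_columns(obs)
    term_names = list(ALL_TERMS)
    Y = adjusted.to_numpy(dtype=float)
    present = ~np.isnan(Y)

    rows: list[dict] = []
    patterns: dict[bytes, list[int]] = {}
    for gi, mask in enumerate(present):
        patterns.setdefault(mask.tobytes(), []).append(gi)

    genes = adjusted.index.to_numpy()
    for key, gidx in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        n_obs = int(mask.sum())
        if n_obs < 1:
            continue
        sub_obs = obs.loc[mask]
        coded = coded_full.loc[mask].to_numpy()
        chosen = _estimable_terms(sub_obs, coded, term_names)
        if not chosen:
            continue
        X = np.column_stack(
            [np.ones(n_obs)] + [coded[:, term_names.index(t)] for t in chosen]
        )
        p = X.shape[1]
        df_resid = n_obs - p
        XtX_inv = np.linalg.pinv(X.T @ X)
        H = XtX_inv @ X.T
        Yg = Y[np.ix_(gidx, np.flatnonzero(mask))]  # genes-in-group x n_obs
        B = Yg @ H.T  # genes x p
        fitted = B @ X.T
        rss = np.sum((Yg - fitted) ** 2, axis=1)
        diag = np.diag(XtX_inv)
        if df_resid >= 1:
            sigma2 = rss / df_resid
            with np.errstate(divide="ignore", invalid="ignore"):
                se = np.sqrt(np.outer(sigma2, diag))
                tvals = B / se
            pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
            pvals[sigma2 <= _SIGMA_FLOOR, :] = 1.0
        else:
            pvals = np.ones_like(B)
        for j, term in enumerate(chosen, start=1):
            for row_i, gi in enumerate(gidx):
                rows.append(
                    {
                        "gene": genes[gi],
                        "term": term,
                        "n_obs": n_obs,
                        "estimate_log2": B[row_i, j],
                        "p_raw": min(1.0, float(pvals[row_i, j])),
                    }
                )
    out = pd.DataFrame(rows, columns=["gene", "term", "n_obs", "estimate_log2", "p_raw"])
    return out.sort_values(["term", "gene"], kind="stable").reset_index(drop=True)


def bonferroni_adjust(results: pd.DataFrame, method: str = "bonferroni") -> pd.DataFrame:
    """Family-wise adjustment within each term across genes.

    Bonferroni multiplies by m = number of genes with the term fitted; the
    documented alternative is Benjamini-Hochberg ('bh').
    """
    if ((results["p_raw"] < 0) | (results["p_raw"] > 1)).any():
        raise ValidationError("raw p-values outside [0, 1]")
    out = results.reset_index(drop=True).copy()
    adj = np.empty(len(out))
    for term, sub in out.groupby("term"):
        p = sub["p_raw"].to_numpy()
        m = len(p)
        if method == "bonferroni":
            a = np.minimum(1.0, m * p)
        elif method == "bh":
            order = np.argsort(p, kind="stable")
            ranked = p[order] * m / (np.arange(m) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            a = np.empty(m)
            a[order] = np.minimum(1.0, ranked)
        else:
            raise ValueError(f"unknown adjustment {method!r}")
        adj[sub.index.to_numpy()] = a
    out["p_adj"] = adj
    return out


def call_de(
    results: pd.DataFrame, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Attach the DE call: |log2 FC| must exceed the threshold at adjusted p < alpha."""
    out = results.copy()
    sig = out["p_adj"] < alpha
    up = sig & (out["estimate_log2"] > lfc_threshold)
    down = sig & (out["estimate_log2"] < -lfc_threshold)
    out["call"] = np.select([up, down], ["up", "down"], default="ns")
    return out


def de_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per-term totals: genes tested, up, down (the Results-style counts)."""
    rows = []
    for term, sub in results.groupby("term"):
        rows.append(
            {
                "term": term,
                "n_tested": len(sub),
                "n_up": int((sub["call"] == "up").sum()),
                "n_down": int((sub["call"] == "down").sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GeneTestResult:
    """Per-gene view over the tidy results frame."""

    gene: str
    n_obs: int
    terms_fitted: tuple[str, ...]
    estimates: dict[str, float]
    p_raw: dict[str, float]
    p_adj: dict[str, float]
    de_call: dict[str, str]


def gene_result(results: pd.DataFrame, gene: str) -> GeneTestResult:
    sub = results[results["gene"] == gene]
    if len(sub) == 0:
        raise KeyError(gene)
    return GeneTestResult(
        gene=gene,
        n_obs=int(sub["n_obs"].iloc[0]),
        terms_fitted=tuple(sub["term"]),
        estimates=dict(zip(sub["term"], sub["estimate_log2"])),
        p_raw=dict(zip(sub["term"], sub["p_raw"])),
        p_adj=dict(zip(sub["term"], sub["p_adj"])) if "p_adj" in sub else {},
        de_call=dict(zip(sub["term"], sub["call"])) if "call" in sub else {},
    )


@dataclass
class OverallModelResult:
    """Type-II ANOVA of the pooled residual model."""

    table: pd.DataFrame  # index: term; columns: sum_sq, df, F, p
    residual_df: float
    residual_variance: float


_OVERALL_FORMULA = (
    "value ~ C(species, Sum) + C(water, Sum) + C(temperature, Sum) + C(date, Sum)"
    " + C(species, Sum):C(water, Sum) + C(species, Sum):C(temperature, Sum)"
    " + C(water, Sum):C(temperature, Sum)"
)

_TERM_RENAME = {
    "C(species, Sum)": "species",
    "C(water, Sum)": "water",
    "C(temperature, Sum)": "temperature",
    "C(date, Sum)": "date",
    "C(species, Sum):C(water, Sum)": "species:water",
    "C(species, Sum):C(temperature, Sum)": "species:temperature",
    "C(water, Sum):C(temperature, Sum)": "water:temperature",
}


def fit_overall_model(adjusted: pd.DataFrame, design: pd.DataFrame) -> OverallModelResult:
    """Pooled fixed-effects ANOVA over all genes' adjusted residuals."""
    obs = observation_factors(design, adjusted.columns)
    aliased = [f for f in MAIN_TERMS if obs[f].nunique() < 2]
    if aliased:
        raise ModelError(f"rank-deficient design; single-level factor(s): {aliased}")
    long = adjusted.T.reset_index(drop=True)
    long = pd.concat(
        [obs[list(MAIN_TERMS)].reset_index(drop=True), long.reset_index(drop=True)], axis=1
    )
    tall = long.melt(id_vars=list(MAIN_TERMS), value_name="value").dropna(subset=["value"])
    fit = ols(_OVERALL_FORMULA, data=tall).fit()
    tab = anova_lm(fit, typ=2)
    resid_df = float(tab.loc["Residual", "df"])
    resid_var = float(tab.loc["Residual", "sum_sq"] / resid_df)
    tab = tab.drop(index="Residual").rename(index=_TERM_RENAME)
    tab = tab.rename(columns={"PR(>F)": "p"})
    # degenerate zero-variance fits: a term explaining nothing gets F = 0, p = 1
    null_term = tab["sum_sq"] <= 1e-12
    tab.loc[null_term, "F"] = 0.0
    tab.loc[null_term, "p"] = 1.0
    return OverallModelResult(table=tab, residual_df=resid_df, residual_variance=resid_var)
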
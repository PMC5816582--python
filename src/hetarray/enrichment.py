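"""Length-bias-aware category enrichment.

A monotone probability weighting function (PWF) estimates P(DE | probe
length) by isotonic regression; category tests then use the Wallenius
noncentral hypergeometric distribution with odds derived from the PWF, so a
category of long probes is not called enriched merely because long probes
are easier to detect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .errors import ValidationError
from .io_formats import AnnotationMap

logger = logging.getLogger(__name__)

_CLIP = 1e-6


@dataclass
class PWF:
    """Per-probe DE-probability weights, monotone non-decreasing in length."""

    weights: pd.Series  # index: probe_id, values in (0, 1)
    lengths: pd.Series
    method: str = "isotonic"


def fit_pwf(de_status: pd.Series, lengths: pd.Series, min_bin_size: int = 50) -> PWF:
    """Monotone P(DE | length) via isotonic regression on length-quantile bins.

    Raw point-wise isotonic regression of a 0/1 indicator is badly behaved at
    the length extremes (its edge blocks chase single probes), so the DE
    fraction is first pooled in quantile bins of >= ``min_bin_size`` probes and
    the monotone fit is taken through the weighted bin means — the same
    smooth-monotone contract as a spline PWF, without the edge artefacts.
    """
    common = de_status.index.intersection(lengths.index)
    if len(common) == 0:
        raise ValidationError("no probes shared between de_status and lengths")
    de = de_status.loc[common].astype(float)
    ln = lengths.loc[common].astype(float)
    n_de = int(de.sum())
    if n_de == 0 or n_de == len(de):
        raise ValidationError("PWF undefined: need at least one DE and one non-DE probe")
    order = np.argsort(ln.to_numpy(), kind="stable")
    n_bins = max(1, len(order) // max(1, min_bin_size))
    bins = np.array_split(order, n_bins)
    bx = np.array([ln.to_numpy()[b].mean() for b in bins])
    by = np.array([de.to_numpy()[b].mean() for b in bins])
    bw = np.array([len(b) for b in bins], dtype=float)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(bx, by, sample_weight=bw)
    fitted = iso.predict(ln.to_numpy())
    w = pd.Series(np.clip(fitted, _CLIP, 1 - _CLIP), index=common, name="pwf")
    return PWF(weights=w, lengths=ln, method="binned-isotonic")


def wallenius_pmf(n_white: int, n_black: int, n_draws: int, odds: float) -> np.ndarray:
    """Exact pmf of the two-color Wallenius noncentral hypergeometric.

    Computed by the sequential-draw recurrence over states (whites drawn,
    total drawn): each draw takes a white ball with probability
    odds*(remaining white) / (odds*(remaining white) + remaining black).
    Exact up to float rounding; reduces to the central hypergeometric at
    odds = 1. O(n_draws * min(n_white, n_draws)) time.
    """
    if n_draws > n_white + n_black:
        raise ValidationError("cannot draw more balls than the urn holds")
    if odds <= 0 or not np.isfinite(odds):
        raise ValidationError(f"odds must be finite and > 0, got {odds}")
    kmax = min(n_white, n_draws)
    prob = np.zeros(kmax + 1)
    prob[0] = 1.0
    for t in range(n_draws):
        new = np.zeros(kmax + 1)
        lo = max(0, t - n_black)
        for i in range(lo, min(t, kmax) + 1):
            if prob[i] == 0.0:
                continue
            rw = n_white - i
            rb = n_black - (t - i)
            denom = odds * rw + rb
            if rw > 0 and i + 1 <= kmax:
                new[i + 1] += prob[i] * (odds * rw / denom)
            if rb > 0:
                new[i] += prob[i] * (rb / denom)
        prob = new
    return prob


def wallenius_tails(
    n_white: int, n_black: int, n_draws: int, odds: float, k: int
) -> tuple[float, float]:
    """(P(X >= k), P(X <= k)) under Wallenius; both include the observed point."""
    big = n_draws * max(1, min(n_white, n_draws)) > 5_000_000
    if big:
        dist = stats.nchypergeom_wallenius(n_white + n_black, n_white, n_draws, odds)
        p_over = float(dist.sf(k - 1))
        p_under = float(dist.cdf(k))
    else:
        pmf = wallenius_pmf(n_white, n_black, n_draws, odds)
        p_over = float(pmf[k:].sum())
        p_under = float(pmf[: k + 1].sum())
    return min(1.0, p_over), min(1.0, p_under)


def _bh(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(1.0, ranked)
    return out


def wallenius_enrichment(
    de_status: pd.Series,
    annotation: AnnotationMap,
    pwf: PWF,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Per-category Wallenius over/under-representation tests.

    The universe is the index of ``de_status``. For each category, the draw
    odds are mean(PWF inside) / mean(PWF outside); p_over/p_under are the
    upper/lower tails at the observed DE count, and a two-sided p is
    min(tails)*2 capped at 1. ``p_adj`` is Benjamini-Hochberg (default) or
    Bonferroni over p_over across categories.
    """
    universe = list(de_status.index)
    uni_set = set(universe)
    de = de_status.astype(bool)
    n_total = len(universe)
    n_de_total = int(de.sum())
    w = pwf.weights.reindex(universe)
    if w.isna().any():
        raise ValidationError("PWF missing weights for part of the universe")

    cat_members: dict[str, set[str]] = {}
    for probe, cats in annotation.categories.items():
        if probe not in uni_set:
            continue
        for c in cats:
            cat_members.setdefault(c, set()).add(probe)

    rows = []
    for cat in sorted(cat_members):
        members = cat_members[cat]
        n_cat = len(members)
        in_mask = de.index.isin(members)
        k = int(de[in_mask].sum())
        if n_cat == n_total:
            logger.warning("category %s covers the whole universe; degenerate", cat)
            rows.append(
                {"category": cat, "n_cat": n_cat, "n_de_in_cat": k, "odds": np.nan,
                 "p_over": 1.0, "p_under": 1.0, "p_two": 1.0}
            )
            continue
        mean_in = float(w[in_mask].mean())
        mean_out = float(w[~in_mask].mean())
        if not np.isfinite(mean_in) or not np.isfinite(mean_out) or mean_out <= 0:
            logger.warning("category %s skipped: non-finite odds", cat)
            continue
        odds = mean_in / mean_out
        p_over, p_under = wallenius_tails(n_cat, n_total - n_cat, n_de_total, odds, k)
        rows.append(
            {
                "category": cat,
                "n_cat": n_cat,
                "n_de_in_cat": k,
                "odds": odds,
                "p_over": p_over,
                "p_under": p_under,
                "p_two": min(1.0, 2.0 * min(p_over, p_under)),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["category", "n_cat", "n_de_in_cat", "odds", "p_over", "p_under", "p_two"],
    )
    if len(out):
        if adjust == "bh":
            out["p_adj"] = _bh(out["p_over"].to_numpy())
        elif adjust == "bonferroni":
            out["p_adj"] = np.minimum(1.0, out["p_over"] * len(out))
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out.sort_values("p_over", kind="stable").reset_index(drop=True)
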
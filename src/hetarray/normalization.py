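"""Model-based normalization for dye-swap two-color arrays.

Stage one removes array and dye effects with a saturated two-way ANOVA on
log2 background-corrected signal; because the array x dye interaction
saturates the cell structure, each residual is exactly the observation minus
its (array, dye) cell mean. Residuals are then shifted positive, turned into
factor-wise log2 expression ratios, and de-trended against log10 intensity
with a loess fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ModelError, ValidationError
from .io_formats import CHANNELS, FACTOR_LEVELS

logger = logging.getLogger(__name__)


def background_correct(spots: pd.DataFrame) -> pd.DataFrame:
    """Per-(array, channel, probe) signal = fg median - bg median.

    Returns a probes x (array_id, channel) matrix; non-positive differences
    become missing (NaN), with the count logged.
    """
    long = []
    for ch in CHANNELS:
        sub = spots[["array_id", "probe_id"]].copy()
        sub["channel"] = ch
        sub["signal"] = spots[f"fg_{ch}"] - spots[f"bg_{ch}"]
        long.append(sub)
    tall = pd.concat(long, ignore_index=True)
    n_nonpos = int((tall["signal"] <= 0).sum())
    if n_nonpos:
        logger.info("background correction: %d non-positive signal(s) set missing", n_nonpos)
    tall.loc[tall["signal"] <= 0, "signal"] = np.nan
    mat = tall.pivot_table(
        index="probe_id", columns=["array_id", "channel"], values="signal", dropna=False
    )
    mat.columns.names = ["array_id", "channel"]
    return mat.sort_index(axis=1)


@dataclass
class ArrayDyeModelFit:
    """Saturated array + dye + array:dye fit with per-gene residuals."""

    array_effects: pd.Series
    dye_effects: pd.Series
    interaction_effects: pd.DataFrame
    residuals: pd.DataFrame  # probes x (array_id, channel), NaN preserved
    grand_mean: float
    scale: str = "log2"
    offset: float | None = None  # set by adjust_residuals_positive


def fit_array_dye_model(signals: pd.DataFrame, scale: str = "log2") -> ArrayDyeModelFit:
    """Fit the array/dye model on the signal matrix (columns = array x channel).

    With the interaction included the model is saturated in (array, dye), so
    residuals equal within-cell-centered values; effects are reported under
    sum-to-zero coding of the cell means.
    """
    arrays = signals.columns.get_level_values("array_id").unique()
    chans = signals.columns.get_level_values("channel").unique()
    if len(arrays) < 2:
        raise ModelError("need >= 2 arrays to separate array effects")
    if set(chans) != set(CHANNELS):
        raise ModelError(f"need both channels {CHANNELS}, got {tuple(chans)}")
    if scale == "log2":
        if (signals <= 0).any().any():
            raise ValidationError("log2 model scale requires strictly positive signals")
        y = np.log2(signals)
    elif scale == "raw":
        y = signals.astype(float)
    else:
        raise ValueError(f"unknown model scale {scale!r}")

    n_per_cell = y.notna().sum(axis=0)
    thin = n_per_cell[n_per_cell < 2]
    if len(thin):
        raise ModelError(f"cell(s) with < 2 genes: {list(thin.index[:5])}")

    cell_means = y.mean(axis=0)  # per (array, channel) column
    residuals = y - cell_means

    cm = cell_means.unstack("channel")  # arrays x channels
    grand = float(cm.to_numpy().mean())
    array_eff = cm.mean(axis=1) - grand
    dye_eff = cm.mean(axis=0) - grand
    interaction = cm.sub(grand).sub(array_eff, axis=0).sub(dye_eff, axis=1)
    return ArrayDyeModelFit(
        array_effects=array_eff,
        dye_effects=dye_eff,
        interaction_effects=interaction,
        residuals=residuals,
        grand_mean=grand,
        scale=scale,
    )


def adjust_residuals_positive(fit: ArrayDyeModelFit, delta: float = 1.0) -> pd.DataFrame:
    """Shift residuals by their global minimum (plus ``delta``) so all are positive.

    The shift is a single global constant, preserving every between-array and
    between-sample contrast tested downstream; min(adjusted) == delta.
    """
    if delta <= 0:
        raise ValidationError("delta must be > 0")
    r = fit.residuals
    rmin = float(np.nanmin(r.to_numpy()))
    if not np.isfinite(rmin):
        raise ValidationError("residuals contain no finite values")
    fit.offset = delta - rmin
    return r - rmin + delta


def expression_matrix(adjusted: pd.DataFrame) -> pd.DataFrame:
    """Map positive-adjusted log2-scale residuals to the expression scale (2**r).

    Factor ratios of these values are log2 fold changes; the global positivity
    shift cancels in every ratio.
    """
    return np.power(2.0, adjusted)


@dataclass
class FactorRatioSet:
    """Per-gene log2 ratio and log10 intensity for one design factor."""

    factor: str
    data: pd.DataFrame  # index probe_id; columns log2_ratio, log10_intensity
    loess_corrected: bool = False
    levels: tuple[str, str] = ("", "")
    loess_trend: pd.Series | None = field(default=None, repr=False)


def channel_factor_levels(design: pd.DataFrame, factor: str) -> pd.Series:
    """Factor level of the sample hybridized in each (array_id, channel)."""
    if factor not in FACTOR_LEVELS:
        raise ValidationError(f"unknown factor {factor!r}; expected one of {list(FACTOR_LEVELS)}")
    idx = pd.MultiIndex.from_frame(
        design[["array_id", "dye"]].rename(columns={"dye": "channel"})
    )
    return pd.Series(design[factor].to_numpy(), index=idx, name=factor)


def compute_factor_log_ratios(
    values: pd.DataFrame,
    design: pd.DataFrame,
    factor: str,
    require_complete: bool = True,
) -> FactorRatioSet:
    """log2( mean(level 1) / mean(level 2) ) per gene, on a positive value matrix.

    Level orientation is fixed by :data:`FACTOR_LEVELS` (e.g. a positive
    species ratio means higher expression in the first-listed species).
    ``values`` must be strictly positive wherever present; the pipeline feeds
    :func:`expression_matrix` of the adjusted residuals. Genes with missing
    contributing signal are dropped (all-complete by default, per-level
    otherwise).
    """
    levels = FACTOR_LEVELS[factor]
    lv = channel_factor_levels(design, factor)
    lv = lv.reindex(values.columns)
    observed = set(lv.dropna())
    if len(observed & set(levels)) < 2:
        raise ValidationError(f"factor {factor!r} has a single observed level: {observed}")
    cols1 = lv.index[lv == levels[0]]
    cols2 = lv.index[lv == levels[1]]
    if require_complete:
        keep = values.notna().all(axis=1)
    else:
        keep = values[cols1].notna().any(axis=1) & values[cols2].notna().any(axis=1)
    v = values.loc[keep]
    m1 = v[cols1].mean(axis=1)
    m2 = v[cols2].mean(axis=1)
    grand = v.mean(axis=1)
    data = pd.DataFrame(
        {"log2_ratio": np.log2(m1 / m2), "log10_intensity": np.log10(grand)}
    ).dropna()
    return FactorRatioSet(factor=factor, data=data, levels=levels)


def loess_correct_ratios(
    rs: FactorRatioSet, span: float = 0.4, iterations: int = 3
) -> FactorRatioSet:
    """Subtract a loess (locally linear, robust) trend of ratio vs intensity."""
    if not (0 < span <= 1):
        raise ValidationError("span must be in (0, 1]")
    d = rs.data.dropna()
    if len(d) < 20:
        raise ValidationError(f"loess correction needs >= 20 genes, got {len(d)}")
    trend = lowess(
        d["log2_ratio"].to_numpy(),
        d["log10_intensity"].to_numpy(),
        frac=span,
        it=iterations,
        return_sorted=False,
    )
    trend = pd.Series(trend, index=d.index, name="loess_trend")
    out = d.copy()
    out["log2_ratio"] = d["log2_ratio"] - trend
    return FactorRatioSet(
        factor=rs.factor,
        data=out,
        loess_corrected=True,
        levels=rs.levels,
        loess_trend=trend,
    )


def loess_flatness(rs: FactorRatioSet, span: float = 0.4) -> float:
    """Max |refitted loess trend| of a ratio set; small means intensity-flat."""
    d = rs.data.dropna()
    refit = lowess(
        d["log2_ratio"].to_numpy(),
        d["log10_intensity"].to_numpy(),
        frac=span,
        it=3,
        return_sorted=False,
    )
    return float(np.max(np.abs(refit)))
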
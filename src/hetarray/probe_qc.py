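"""Heterologous-hybridization quality control.

Two independent filters gate each probe: a per-spot signal-to-noise window
(guards against weak signal and cross-hybridization/saturation artefacts)
and a cross-species sequence-similarity filter on alignment hits. A probe
enters a species' analysis set only if it passes both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for both probe filters.

    ``snr_low``/``snr_high`` bound fg/bg per channel (inclusive on both
    ends); alignment hits qualify when ``evalue <= evalue_max`` and
    ``align_length > min_align_len`` (strict).
    """

    snr_low: float = 3.0
    snr_high: float = 10.0
    evalue_max: float = 1e-10
    min_align_len: int = 150

    def __post_init__(self) -> None:
        if not (0 < self.snr_low < self.snr_high):
            raise ValidationError("require 0 < snr_low < snr_high")
        if self.evalue_max <= 0:
            raise ValidationError("evalue_max must be > 0")
        if self.min_align_len < 1:
            raise ValidationError("min_align_len must be >= 1")


@dataclass
class IncludedSets:
    """Per-species retained probe sets and their intersection."""

    per_species: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    @property
    def common(self) -> set[str]:
        sets = list(self.per_species.values())
        if not sets:
            return set()
        out = set(sets[0])
        for s in sets[1:]:
            out &= s
        return out

    def summary(self) -> dict:
        n_univ = len(self.universe)
        per = {
            sp: {"n": len(s), "fraction": (len(s) / n_univ if n_univ else 0.0)}
            for sp, s in sorted(self.per_species.items())
        }
        return {"universe": n_univ, "per_species": per, "common": len(self.common)}


def spot_snr(spots: pd.DataFrame) -> pd.DataFrame:
    """Per-spot SNR (fg/bg) for both channels; NaN where background is 0."""
    out = spots[["array_id", "probe_id"]].copy()
    for ch in ("ch1", "ch2"):
        fg, bg = spots[f"fg_{ch}"], spots[f"bg_{ch}"]
        out[f"snr_{ch}"] = (fg / bg).where(bg > 0)
    return out


def filter_by_snr(spots: pd.DataFrame, cfg: QCConfig = QCConfig()) -> pd.DataFrame:
    """Keep spots whose SNR lies in [snr_low, snr_high] in BOTH channels.

    Flagged spots are always removed; spots with a zero background in either
    channel cannot be evaluated and are excluded (count logged).
    """
    snr = spot_snr(spots)
    evaluable = snr["snr_ch1"].notna() & snr["snr_ch2"].notna()
    n_zero_bg = int((~evaluable & ~spots["flagged"]).sum())
    if n_zero_bg:
        logger.info("excluded %d spot(s) with zero background", n_zero_bg)
    ok = evaluable.copy()
    for ch in ("ch1", "ch2"):
        ok &= snr[f"snr_{ch}"].between(cfg.snr_low, cfg.snr_high, inclusive="both")
    ok &= ~spots["flagged"]
    return spots.loc[ok].reset_index(drop=True)


def filter_by_alignment(hits: pd.DataFrame, cfg: QCConfig = QCConfig()) -> dict[str, set[str]]:
    """Per species database, the probes with >=1 qualifying alignment hit."""
    out: dict[str, set[str]] = {}
    if len(hits) == 0:
        return out
    qual = (hits["evalue"] <= cfg.evalue_max) & (hits["align_length"] > cfg.min_align_len)
    for sp, sub in hits.loc[qual].groupby("species_db"):
        out[str(sp)] = set(sub["probe_id"])
    for sp in hits["species_db"].unique():
        out.setdefault(str(sp), set())
    return out


def snr_pass_by_species(snr_pass: pd.DataFrame, design: pd.DataFrame) -> dict[str, set[str]]:
    """Probes passing SNR on at least one array hybridized with each species."""
    array_species = (
        design.groupby("array_id")["species"].agg(lambda s: sorted(set(s))).explode()
    )
    out: dict[str, set[str]] = {sp: set() for sp in design["species"].unique()}
    for array_id, sub in snr_pass.groupby("array_id"):
        for sp in design.loc[design["array_id"] == array_id, "species"].unique():
            out[str(sp)].update(sub["probe_id"])
    return out


def build_included_sets(
    snr_pass: pd.DataFrame,
    design: pd.DataFrame,
    aln_sets: dict[str, set[str]],
    universe: set[str] | None = None,
) -> IncludedSets:
    """Intersect the two filters per species.

    A probe is included for a species iff it passed the SNR window on at
    least one of that species' arrays AND has a qualifying alignment to that
    species' transcript set. Per-array SNR failures elsewhere become missing
    values downstream rather than global exclusions.
    """
    if universe is None:
        universe = set(snr_pass["probe_id"])
        for s in aln_sets.values():
            universe |= s
    if not universe:
        raise ValidationError("empty probe universe: nothing to include")
    by_species = snr_pass_by_species(snr_pass, design)
    per: dict[str, set[str]] = {}
    for sp in sorted(set(by_species) | set(aln_sets)):
        per[sp] = by_species.get(sp, set()) & aln_sets.get(sp, set())
    return IncludedSets(per_species=per, universe=set(universe))
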
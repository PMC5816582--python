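"""End-to-end orchestration: qc -> normalize -> de -> enrich -> modules."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import compute_tom, detect_modules, module_trait_association
from .diffexpr import (
    bonferroni_adjust,
    call_de,
    de_summary,
    fit_overall_model,
    fit_per_gene_models,
)
from .enrichment import fit_pwf, wallenius_enrichment
from .errors import ValidationError
from .io_formats import (
    FACTOR_LEVELS,
    read_alignment_table,
    read_annotation_map,
    read_design_table,
    read_spot_table,
)
from .normalization import (
    adjust_residuals_positive,
    background_correct,
    compute_factor_log_ratios,
    expression_matrix,
    fit_array_dye_model,
    loess_correct_ratios,
)
from .probe_qc import QCConfig, build_included_sets, filter_by_snr

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    spots: str = ""
    design: str = ""
    aln_ag: str = ""
    aln_sn: str = ""
    go: str = ""
    fasta: str = ""
    out_dir: str = "hetarray_out"
    spots_dialect: str = "tsv"
    # thresholds default to the published values
    snr_low: float = 3.0
    snr_high: float = 10.0
    evalue_max: float = 1e-10
    min_align_len: int = 150
    span: float = 0.4
    delta: float = 1.0
    model_scale: str = "log2"
    lfc: float = 1.0
    alpha: float = 0.05
    adjust: str = "bonferroni"
    enrich_term: str = "water"
    enrich_direction: str = "any"
    enrich_adjust: str = "bh"
    power: float = 6.0
    cut_height: float = 0.95
    min_module_size: int = 5
    module_date: str = "day18"
    module_trait: str = "species"
    seed: int = 0
    simulate: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def qc_config(self) -> QCConfig:
        return QCConfig(
            snr_low=self.snr_low,
            snr_high=self.snr_high,
            evalue_max=self.evalue_max,
            min_align_len=self.min_align_len,
        )

    def validate_inputs(self) -> None:
        for key in ("spots", "design", "aln_ag", "aln_sn"):
            p = getattr(self, key)
            if not p or not Path(p).exists():
                raise ValidationError(f"config input {key!r} missing or not found: {p!r}")


def masked_signal_matrix(
    spots: pd.DataFrame, design: pd.DataFrame, included: dict[str, set[str]]
) -> pd.DataFrame:
    """Background-corrected matrix restricted to each species' included probes."""
    mat = background_correct(spots)
    union: set[str] = set()
    for s in included.values():
        union |= s
    mat = mat.loc[mat.index.intersection(sorted(union))]
    array_species = design.drop_duplicates("array_id").set_index("array_id")["species"]
    for col in mat.columns:
        sp = array_species.get(col[0])
        if sp is None:
            continue
        keep = mat.index.isin(list(included.get(sp, set())))
        mat.loc[~keep, col] = np.nan
    return mat


def collapse_to_samples(adjusted: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Average the dye-swap channel duplicates of each sample."""
    key = pd.MultiIndex.from_frame(
        design[["array_id", "dye"]].rename(columns={"dye": "channel"})
    )
    sample_of = pd.Series(design["sample_id"].to_numpy(), index=key)
    groups = sample_of.reindex(adjusted.columns)
    return adjusted.T.groupby(groups.to_numpy()).mean().T


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write outputs + a summary report under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "config": asdict(config)}

    if config.simulate is not None:
        from .synthetic_data import SimulationParams, write_simulation

        params = SimulationParams(seed=config.seed, **(config.simulate or {}))
        paths = write_simulation(params, out / "sim")
        config.spots = str(paths["spots"])
        config.design = str(paths["design"])
        config.aln_ag = str(paths["aln_ag"])
        config.aln_sn = str(paths["aln_sn"])
        config.go = str(paths["go"])
        config.fasta = str(paths["fasta"])
        report["simulated"] = True
    config.validate_inputs()

    # --- QC ---------------------------------------------------------------
    cfg = config.qc_config()
    spots = read_spot_table(config.spots, dialect=config.spots_dialect)
    design = read_design_table(config.design)
    hits = pd.concat(
        [
            read_alignment_table(config.aln_ag, "Ag"),
            read_alignment_table(config.aln_sn, "Sn"),
        ],
        ignore_index=True,
    )
    from .probe_qc import filter_by_alignment

    snr_pass = filter_by_snr(spots, cfg)
    aln_sets = filter_by_alignment(hits, cfg)
    included = build_included_sets(
        snr_pass, design, aln_sets, universe=set(spots["probe_id"])
    )
    report["qc"] = included.summary()
    report["qc"]["spots_total"] = int(len(spots))
    report["qc"]["spots_snr_pass"] = int(len(snr_pass))
    for sp, probes in sorted(included.per_species.items()):
        pd.Series(sorted(probes), name="probe_id").to_csv(
            out / f"included_{sp}.tsv", sep="\t", index=False
        )

    # --- normalization ----------------------------------------------------
    mat = masked_signal_matrix(snr_pass, design, included.per_species)
    fit = fit_array_dye_model(mat, scale=config.model_scale)
    adjusted = adjust_residuals_positive(fit, delta=config.delta)
    adjusted.to_csv(out / "adjusted_residuals.tsv", sep="\t")
    expr = expression_matrix(adjusted)
    ratio_summaries = {}
    for factor in FACTOR_LEVELS:
        rs = compute_factor_log_ratios(expr, design, factor)
        if len(rs.data) >= 20:
            rs = loess_correct_ratios(rs, span=config.span)
        rs.data.to_csv(out / f"ratios_{factor}.tsv", sep="\t")
        ratio_summaries[factor] = {
            "n_genes": int(len(rs.data)),
            "loess_corrected": bool(rs.loess_corrected),
        }
    report["ratios"] = ratio_summaries

    # --- differential expression -----------------------------------------
    overall = fit_overall_model(adjusted, design)
    overall.table.to_csv(out / "overall_anova.tsv", sep="\t")
    report["overall_anova"] = {
        term: {"F": float(row["F"]), "p": float(row["p"])}
        for term, row in overall.table.iterrows()
    }
    results = fit_per_gene_models(adjusted, design)
    results = bonferroni_adjust(results, method=config.adjust)
    results = call_de(results, lfc_threshold=config.lfc, alpha=config.alpha)
    results.to_csv(out / "de.tsv", sep="\t", index=False)
    report["de"] = de_summary(results).set_index("term").to_dict("index")

    # per-species water response (the Results-style per-species counts)
    report["de_per_species"] = {}
    for sp in sorted(design["species"].unique()):
        sub_design = design[design["species"] == sp]
        cols = [c for c in adjusted.columns if c[0] in set(sub_design["array_id"])]
        sub = adjusted[cols].dropna(how="all")
        try:
            r = fit_per_gene_models(sub, sub_design)
        except ValidationError:
            continue
        r = r[r["term"] == "water"]
        if len(r) == 0:
            continue
        r = call_de(
            bonferroni_adjust(r, method=config.adjust),
            lfc_threshold=config.lfc,
            alpha=config.alpha,
        )
        r.to_csv(out / f"de_water_{sp}.tsv", sep="\t", index=False)
        report["de_per_species"][sp] = {
            "n_tested": int(len(r)),
            "n_up_watered": int((r["call"] == "up").sum()),
            "n_up_drought": int((r["call"] == "down").sum()),
        }

    # --- enrichment -------------------------------------------------------
    report["enrichment"] = None
    if config.go and config.fasta and Path(config.go).exists():
        amap = read_annotation_map(config.go, config.fasta)
        term_calls = results[results["term"] == config.enrich_term].set_index("gene")
        universe = term_calls.index.intersection(list(amap.universe()))
        if config.enrich_direction == "any":
            de_status = (term_calls.loc[universe, "call"] != "ns").astype(int)
        else:
            de_status = (term_calls.loc[universe, "call"] == config.enrich_direction).astype(int)
        lengths = pd.Series(amap.lengths).reindex(universe)
        if 0 < int(de_status.sum()) < len(de_status):
            pwf = fit_pwf(de_status, lengths)
            enr = wallenius_enrichment(de_status, amap, pwf, adjust=config.enrich_adjust)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            report["enrichment"] = {
                "term": config.enrich_term,
                "direction": config.enrich_direction,
                "n_categories": int(len(enr)),
                "n_significant": int((enr["p_adj"] < config.alpha).sum()),
            }
        else:
            report["enrichment"] = {"term": config.enrich_term, "note": "no DE contrast"}

    # --- coexpression modules --------------------------------------------
    report["modules"] = {}
    sub_design = design[design["date"] == config.module_date]
    for water in FACTOR_LEVELS["water"]:
        wd = sub_design[sub_design["water"] == water]
        if len(wd) == 0:
            continue
        cols = [c for c in adjusted.columns if c[0] in set(wd["array_id"])]
        expr_w = collapse_to_samples(adjusted[cols], wd).dropna()
        if len(expr_w) < 5 or expr_w.shape[1] < 4:
            report["modules"][water] = {"note": "insufficient data"}
            continue
        try:
            tom = compute_tom(expr_w, power=config.power)
            mods = detect_modules(
                tom,
                min_module_size=config.min_module_size,
                cut_height=config.cut_height,
                power=config.power,
            )
            trait = (
                wd.drop_duplicates("sample_id")
                .set_index("sample_id")[config.module_trait]
                .reindex(expr_w.columns)
            )
            mods = module_trait_association(mods, expr_w.loc[tom.index], trait)
            mods.labels.rename("module").to_csv(
                out / f"modules_{water}.tsv", sep="\t"
            )
            mods.trait_correlation.to_csv(
                out / f"module_trait_{water}.tsv", sep="\t", index=False
            )
            report["modules"][water] = {
                "n_modules": len(mods.module_ids),
                "trait": config.module_trait,
                "associations": mods.trait_correlation.to_dict("records"),
            }
        except ValidationError as exc:
            report["modules"][water] = {"note": str(exc)}

    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
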
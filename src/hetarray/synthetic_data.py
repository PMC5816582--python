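"""Synthetic experiment generator with exact ground truth.

Emulates the published field-study design — 2 species x 2 water x 2 temperature x
2 dates x n replicates (32 samples at the default n = 2, 16 per species),
with heated-vs-ambient sample pairs hybridized on dye-swapped array pairs
(8 arrays per species per sampling date). Planted structure (per-term
effects, inclusion sets, length-biased DE, correlated modules) uses exact
counts rather than Bernoulli draws so recovery tests can assert equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .io_formats import (
    AnnotationMap,
    DESIGN_COLUMNS,
    FACTOR_LEVELS,
    write_alignment_table,
    write_design_table,
    write_spot_table,
)

_TERMS = (
    "species", "water", "temperature", "date",
    "species:water", "species:temperature", "water:temperature",
)


@dataclass
class SimulationParams:
    n_genes: int = 2000
    n_replicates: int = 2
    seed: int = 0
    baseline_mean: float = 8.5
    baseline_sd: float = 0.4
    array_effect_sd: float = 0.2
    dye_effect_sd: float = 0.15
    interaction_sd: float = 0.05
    curved_dye_bias: float = 0.0
    noise_sd: float = 0.3
    # term -> (fraction of genes affected, |log2 effect|); exact counts planted
    effects: dict[str, tuple[float, float]] = dc_field(default_factory=dict)
    effect_sign: str = "random"  # "random" | "positive" | "negative"
    # list of (module size, within-module correlation)
    module_spec: list[tuple[int, float]] = dc_field(default_factory=list)
    # species -> fraction of probes with a qualifying alignment
    qc_spec: dict[str, float] = dc_field(
        default_factory=lambda: {"Ag": 0.6, "Sn": 0.55}
    )
    flag_fraction: float = 0.0
    bg_shape: float = 4.0
    bg_scale: float = 25.0
    length_log_mean: float = 6.0
    length_log_sd: float = 0.5
    n_categories: int = 15
    category_size: int = 25
    enriched_odds: float = 4.0
    de_bias_midpoint: float = 500.0
    de_bias_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.n_genes < 50:
            raise ValidationError("n_genes must be >= 50")
        for name in ("array_effect_sd", "dye_effect_sd", "noise_sd", "interaction_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for term, (frac, _) in self.effects.items():
            if term not in _TERMS:
                raise ValidationError(f"unknown effect term {term!r}")
            if not 0 <= frac <= 1:
                raise ValidationError("effect fractions must be in [0, 1]")
        for sp, frac in self.qc_spec.items():
            if not 0 <= frac <= 1:
                raise ValidationError("qc_spec fractions must be in [0, 1]")


@dataclass
class GroundTruth:
    effects: pd.DataFrame  # genes x terms, planted signed log2 effects
    de_genes: dict[str, set[str]]
    module_labels: pd.Series
    included: dict[str, set[str]] = dc_field(default_factory=dict)
    lengths: pd.Series | None = None
    categories: dict[str, set[str]] = dc_field(default_factory=dict)
    enriched_category: str | None = None
    length_confounded_category: str | None = None


def probe_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(n)]


def make_design(params: SimulationParams) -> pd.DataFrame:
    """Dye-swap design: per (species, water, date, replicate) the ambient and
    heated samples share two arrays with dyes exchanged."""
    rows = []
    for sp in FACTOR_LEVELS["species"]:
        for wa in FACTOR_LEVELS["water"]:
            for da in FACTOR_LEVELS["date"]:
                for rep in range(1, params.n_replicates + 1):
                    samples = {
                        te: f"{sp}_{wa}_{te}_{da}_r{rep}"
                        for te in FACTOR_LEVELS["temperature"]
                    }
                    amb, hot = (samples[t] for t in FACTOR_LEVELS["temperature"])
                    for tag, (s1, s2) in (("a", (amb, hot)), ("b", (hot, amb))):
                        arr = f"arr_{sp}_{wa}_{da}_r{rep}_{tag}"
                        for dye, sid in (("ch1", s1), ("ch2", s2)):
                            te = sid.split("_")[2]
                            rows.append(
                                {
                                    "array_id": arr, "dye": dye, "sample_id": sid,
                                    "species": sp, "water": wa, "temperature": te,
                                    "date": da, "replicate": rep,
                                }
                            )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def _coded(design_row: pd.Series, term: str) -> float:
    if ":" in term:
        a, b = term.split(":")
        return 2.0 * _coded(design_row, a) * _coded(design_row, b)
    return 0.5 if design_row[term] == FACTOR_LEVELS[term][0] else -0.5


def _plant_effects(
    params: SimulationParams, genes: list[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    n = len(genes)
    eff = pd.DataFrame(0.0, index=genes, columns=list(_TERMS))
    de: dict[str, set[str]] = {t: set() for t in _TERMS}
    perm = rng.permutation(n)
    cursor = 0
    for term in sorted(params.effects):
        frac, size = params.effects[term]
        count = int(round(frac * n))
        idx = perm[cursor:cursor + count]
        cursor += count
        if cursor > n:
            raise ValidationError("planted effect fractions exceed the gene universe")
        if params.effect_sign == "positive":
            signs = np.ones(count)
        elif params.effect_sign == "negative":
            signs = -np.ones(count)
        else:
            signs = rng.choice([-1.0, 1.0], size=count)
        chosen = [genes[i] for i in idx]
        eff.loc[chosen, term] = signs * size
        de[term] = set(chosen)
    return eff, de


def _plant_modules(
    params: SimulationParams, genes: list[str], rng: np.random.Generator
) -> pd.Series:
    labels = pd.Series(0, index=genes, dtype=int)
    cursor = len(genes)
    for m, (size, _rho) in enumerate(params.module_spec, start=1):
        cursor -= size
        if cursor < 0:
            raise ValidationError("module sizes exceed the gene universe")
        labels.iloc[cursor:cursor + size] = m
    return labels


def simulate_signal_matrix(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """log2 true signal per gene x (array, channel), plus design and truth.

    This is the fast desk-scale path used by recovery simulations; the spot
    table wrapper adds fluorescence backgrounds on top.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    design = make_design(params)
    genes = probe_ids(params.n_genes)

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, params.n_genes)
    arrays = design["array_id"].unique()
    array_eff = dict(zip(arrays, rng.normal(0, params.array_effect_sd, len(arrays))))
    dye_shift = rng.normal(0, params.dye_effect_sd)
    dye_eff = {"ch1": +dye_shift / 2, "ch2": -dye_shift / 2}
    inter_eff = {
        (a, c): rng.normal(0, params.interaction_sd) for a in arrays for c in ("ch1", "ch2")
    }
    effects, de_genes = _plant_effects(params, genes, rng)
    module_labels = _plant_modules(params, genes, rng)

    samples = design["sample_id"].unique()
    module_latent = {
        (m, s): rng.normal() for m in sorted(set(module_labels) - {0}) for s in samples
    }

    eff_arr = effects.to_numpy()  # genes x terms
    cols, data = [], []
    spread = max(params.baseline_sd, 1e-9)
    for _, row in design.iterrows():
        key = (row.array_id, row.dye)
        x = np.array([_coded(row, t) for t in _TERMS])
        mean = (
            baseline
            + array_eff[row.array_id]
            + dye_eff[row.dye]
            + inter_eff[key]
            + eff_arr @ x
        )
        if params.curved_dye_bias:
            sign = 1.0 if row.dye == "ch2" else -1.0
            mean = mean + sign * 0.5 * params.curved_dye_bias * np.sin(
                (baseline - params.baseline_mean) / spread
            )
        mod = np.zeros(params.n_genes)
        for m in sorted(set(module_labels) - {0}):
            rho = params.module_spec[m - 1][1]
            gamma = params.noise_sd * np.sqrt(rho / (1 - rho)) if rho < 1 else 10.0
            mod[module_labels.to_numpy() == m] = gamma * module_latent[(m, row.sample_id)]
        noise = rng.normal(0, params.noise_sd, params.n_genes)
        cols.append((row.array_id, row.dye))
        data.append(mean + mod + noise)
    mat = pd.DataFrame(
        np.column_stack(data),
        index=genes,
        columns=pd.MultiIndex.from_tuples(cols, names=["array_id", "channel"]),
    ).sort_index(axis=1)
    truth = GroundTruth(effects=effects, de_genes=de_genes, module_labels=module_labels)
    return mat, design, truth


def simulate_experiment(
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Full spot-table simulation: fg = 2**signal + background, bg ~ Gamma."""
    rng = np.random.default_rng(params.seed)
    log2sig, design, truth = simulate_signal_matrix(params, rng)
    arrays = sorted(log2sig.columns.get_level_values("array_id").unique())
    genes = list(log2sig.index)
    frames = []
    for arr in arrays:
        bg1 = rng.gamma(params.bg_shape, params.bg_scale, len(genes))
        bg2 = rng.gamma(params.bg_shape, params.bg_scale, len(genes))
        frames.append(
            pd.DataFrame(
                {
                    "array_id": arr,
                    "probe_id": genes,
                    "fg_ch1": np.power(2.0, log2sig[(arr, "ch1")].to_numpy()) + bg1,
                    "bg_ch1": bg1,
                    "fg_ch2": np.power(2.0, log2sig[(arr, "ch2")].to_numpy()) + bg2,
                    "bg_ch2": bg2,
                    "flagged": False,
                }
            )
        )
    spots = pd.concat(frames, ignore_index=True)
    n_flag = int(round(params.flag_fraction * len(spots)))
    if n_flag:
        flagged_rows = rng.choice(len(spots), size=n_flag, replace=False)
        spots.loc[flagged_rows, "flagged"] = True
    return spots, design, truth


def simulate_alignments(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """BLAST-style hits with exact planted per-species inclusion counts."""
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    genes = probe_ids(params.n_genes)
    rows = []
    included: dict[str, set[str]] = {}
    for sp in sorted(params.qc_spec):
        frac = params.qc_spec[sp]
        n_inc = int(round(frac * params.n_genes))
        perm = rng.permutation(params.n_genes)
        chosen = {genes[i] for i in perm[:n_inc]}
        included[sp] = chosen
        for g in genes:
            if g in chosen:
                evalue = 10.0 ** -rng.uniform(12, 40)
                length = int(rng.integers(151, 401))
            else:
                kind = rng.integers(3)
                if kind == 0:
                    continue  # no hit at all
                if kind == 1:
                    evalue, length = 1e-8, int(rng.integers(151, 401))
                else:
                    evalue, length = 10.0 ** -rng.uniform(12, 40), int(rng.integers(50, 151))
            rows.append(
                {
                    "probe_id": g,
                    "transcript_id": f"{sp.lower()}_tr{rng.integers(1, 10 ** 6)}",
                    "percent_identity": float(np.round(rng.uniform(85, 100), 2)),
                    "align_length": length,
                    "evalue": evalue,
                    "bitscore": float(np.round(rng.uniform(50, 500), 1)),
                    "species_db": sp,
                }
            )
    return pd.DataFrame(rows), included


def simulate_annotations(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[AnnotationMap, GroundTruth]:
    """Lengths, category map, one planted-enriched and one length-confounded
    control category (the longest probes)."""
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    genes = probe_ids(params.n_genes)
    lengths = np.exp(rng.normal(params.length_log_mean, params.length_log_sd, params.n_genes))
    lengths = np.clip(np.round(lengths), 100, 3000).astype(int)
    lengths = pd.Series(lengths, index=genes, name="length")

    categories: dict[str, set[str]] = {}
    size = min(params.category_size, params.n_genes)
    for c in range(params.n_categories):
        members = rng.choice(params.n_genes, size=size, replace=False)
        categories[f"CAT{c:03d}"] = {genes[i] for i in members}
    enr = {genes[i] for i in rng.choice(params.n_genes, size=size, replace=False)}
    categories["CAT_ENRICHED"] = enr
    longest = set(lengths.sort_values(ascending=False).index[:size])
    categories["CAT_LONGEST"] = longest

    cat_by_probe: dict[str, set[str]] = {}
    for cat, members in categories.items():
        for g in members:
            cat_by_probe.setdefault(g, set()).add(cat)
    amap = AnnotationMap(categories=cat_by_probe, lengths=dict(lengths))
    truth = GroundTruth(
        effects=pd.DataFrame(index=genes),
        de_genes={},
        module_labels=pd.Series(0, index=genes),
        lengths=lengths,
        categories=categories,
        enriched_category="CAT_ENRICHED",
        length_confounded_category="CAT_LONGEST",
    )
    return amap, truth


def simulate_de_status(
    lengths: pd.Series,
    rng: np.random.Generator,
    midpoint: float | None = 500.0,
    scale: float = 100.0,
    base_rate: float = 0.1,
    enriched: set[str] | None = None,
    enriched_odds: float = 1.0,
) -> pd.Series:
    """Bernoulli DE labels with optional logistic length bias and category boost.

    With ``midpoint=None`` the DE probability is flat at ``base_rate``;
    otherwise p = sigmoid((length - midpoint)/scale) rescaled to average near
    the base rate. The enriched set's odds are multiplied by
    ``enriched_odds``.
    """
    if midpoint is None:
        p = np.full(len(lengths), base_rate)
    else:
        raw = 1.0 / (1.0 + np.exp(-(lengths.to_numpy() - midpoint) / scale))
        p = raw * base_rate / max(raw.mean(), 1e-12)
        p = np.clip(p, 1e-6, 1 - 1e-6)
    if enriched:
        mask = lengths.index.isin(list(enriched))
        odds = p / (1 - p) * enriched_odds
        p = np.where(mask, odds / (1 + odds), p)
    return pd.Series(rng.random(len(p)) < p, index=lengths.index, name="de").astype(int)


def simulate_module_matrix(
    module_spec: list[tuple[int, float]],
    n_noise_genes: int,
    n_samples: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted-partition expression matrix: blocks share a per-sample latent
    factor giving pairwise within-block correlation ~= rho."""
    rows, labels = [], []
    gi = 0
    for m, (size, rho) in enumerate(module_spec, start=1):
        z = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=n_samples))
            labels.append(m)
            gi += 1
    for _ in range(n_noise_genes):
        rows.append(rng.normal(size=n_samples))
        labels.append(0)
        gi += 1
    genes = probe_ids(gi)
    expr = pd.DataFrame(rows, index=genes, columns=[f"s{j}" for j in range(n_samples)])
    return expr, pd.Series(labels, index=genes, name="module")


def _random_fasta(lengths: pd.Series, rng: np.random.Generator) -> list[SeqRecord]:
    alphabet = np.array(list("ACGT"))
    recs = []
    for probe, n in lengths.items():
        seq = "".join(rng.choice(alphabet, size=int(n)))
        recs.append(SeqRecord(Seq(seq), id=str(probe), description=""))
    return recs


def write_simulation(params: SimulationParams, out_dir: str | Path) -> dict[str, Path]:
    """Simulate a complete experiment and write every pipeline input plus
    plain-text ground-truth tables under ``out_dir``."""
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    spots, design, truth = simulate_experiment(params)
    hits, included = simulate_alignments(params)
    amap, anno_truth = simulate_annotations(params)
    rng = np.random.default_rng(params.seed + 3)

    paths = {
        "spots": out / "spots.tsv",
        "design": out / "design.tsv",
        "aln_ag": out / "aln_ag.tsv",
        "aln_sn": out / "aln_sn.tsv",
        "go": out / "go.tsv",
        "fasta": out / "probes.fa",
    }
    write_spot_table(spots, paths["spots"])
    write_design_table(design, paths["design"])
    write_alignment_table(hits[hits["species_db"] == "Ag"], paths["aln_ag"])
    write_alignment_table(hits[hits["species_db"] == "Sn"], paths["aln_sn"])
    with open(paths["go"], "w") as fh:
        for probe in sorted(amap.categories):
            for cat in sorted(amap.categories[probe]):
                fh.write(f"{probe}\t{cat}\n")
    SeqIO.write(_random_fasta(anno_truth.lengths, rng), str(paths["fasta"]), "fasta")

    truth.effects.to_csv(out / "truth" / "effects.tsv", sep="\t")
    with open(out / "truth" / "de_genes.tsv", "w") as fh:
        fh.write("term\tgene\n")
        for term in sorted(truth.de_genes):
            for g in sorted(truth.de_genes[term]):
                fh.write(f"{term}\t{g}\n")
    truth.module_labels.rename("module").to_csv(out / "truth" / "modules.tsv", sep="\t")
    for sp, probes in sorted(included.items()):
        pd.Series(sorted(probes), name="probe_id").to_csv(
            out / "truth" / f"included_{sp}.tsv", sep="\t", index=False
        )
    return paths
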
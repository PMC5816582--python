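"""Readers and writers for every on-disk format the pipeline touches.

Tables are carried as :class:`pandas.DataFrame` objects with fixed column
schemas (see the ``*_COLUMNS`` constants); small dataclasses define the row
contracts. All writers emit tab-separated text with a header so outputs can
round-trip through the matching reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import DesignError, FormatError, ValidationError

logger = logging.getLogger(__name__)

SPOT_COLUMNS = ["array_id", "probe_id", "fg_ch1", "bg_ch1", "fg_ch2", "bg_ch2", "flagged"]
DESIGN_COLUMNS = [
    "array_id", "dye", "sample_id", "species", "water", "temperature", "date", "replicate",
]
ALIGNMENT_COLUMNS = [
    "probe_id", "transcript_id", "percent_identity", "align_length",
    "evalue", "bitscore", "species_db",
]

CHANNELS = ("ch1", "ch2")
SPECIES_LEVELS = ("Ag", "Sn")
FACTOR_LEVELS: Mapping[str, tuple[str, str]] = {
    "species": ("Ag", "Sn"),
    "water": ("watered", "drought"),
    "temperature": ("ambient", "heated"),
    "date": ("day4", "day18"),
}

# GPR wavelength blocks mapped positionally: 532 nm scan -> ch1, 635 nm -> ch2.
_GPR_CHANNEL_COLS = {
    "fg_ch1": "F532 Median",
    "bg_ch1": "B532 Median",
    "fg_ch2": "F635 Median",
    "bg_ch2": "B635 Median",
}


@dataclass(frozen=True)
class SpotRecord:
    """One array feature: per-channel foreground/background medians plus flag."""

    array_id: str
    probe_id: str
    fg_ch1: float
    bg_ch1: float
    fg_ch2: float
    bg_ch2: float
    flagged: bool = False


@dataclass(frozen=True)
class AlignmentHit:
    probe_id: str
    transcript_id: str
    percent_identity: float
    align_length: int
    evalue: float
    bitscore: float
    species_db: str


@dataclass
class AnnotationMap:
    """probe -> category ids and probe -> length (bp, ungapped FASTA length)."""

    categories: dict[str, set[str]]
    lengths: dict[str, int]

    def universe(self) -> set[str]:
        return set(self.lengths)


def _validate_spots(df: pd.DataFrame, source: str) -> pd.DataFrame:
    for col in ("fg_ch1", "bg_ch1", "fg_ch2", "bg_ch2"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"{source}: non-numeric intensity in column {col!r} at data row {row + 1}"
            )
        neg = vals < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0])
            raise ValidationError(
                f"{source}: negative intensity in column {col!r} at data row {row + 1}"
            )
        df[col] = vals.astype(float)
    dup = df.duplicated(subset=["array_id", "probe_id"])
    if dup.any():
        pair = df.loc[dup, ["array_id", "probe_id"]].iloc[0]
        raise ValidationError(
            f"{source}: duplicate (array_id, probe_id) = ({pair.array_id}, {pair.probe_id})"
        )
    df["flagged"] = df["flagged"].astype(bool)
    return df[SPOT_COLUMNS].reset_index(drop=True)


def read_spot_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a spot-level intensity table (``tsv`` dialect or GenePix ``gpr``).

    Returns a frame with :data:`SPOT_COLUMNS`; GPR rows with negative Flags
    are marked ``flagged`` (GenePix convention for bad features).
    """
    path = Path(path)
    if dialect == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"array_id": str, "probe_id": str})
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"{path}: empty spot table") from exc
        missing = [c for c in SPOT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")
        if len(df) == 0:
            raise FormatError(f"{path}: spot table has a header but no rows")
        df["flagged"] = df["flagged"].astype(int).astype(bool)
        return _validate_spots(df, str(path))
    if dialect == "gpr":
        return _read_gpr(path)
    raise ValueError(f"unknown spot-table dialect {dialect!r}")


def _read_gpr(path: Path) -> pd.DataFrame:
    """Minimal Axon Text File (ATF) reader: consumes only probe name/ID, the
    per-wavelength median foreground/background columns and Flags."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise FormatError(f"{path}: not an ATF/GPR file (missing 'ATF' magic)")
    try:
        n_header = int(lines[1].split("\t")[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed ATF header-count line") from exc
    header_line = 2 + n_header
    if header_line >= len(lines):
        raise FormatError(f"{path}: truncated before the column-header row")
    columns = [c.strip().strip('"') for c in lines[header_line].split("\t")]
    id_col = "ID" if "ID" in columns else ("Name" if "Name" in columns else None)
    if id_col is None:
        raise FormatError(f"{path}: missing mandatory column 'ID' (or 'Name')")
    needed = dict(_GPR_CHANNEL_COLS)
    for ours, theirs in needed.items():
        if theirs not in columns:
            raise FormatError(f"{path}: missing mandatory column {theirs!r}")
    if "Flags" not in columns:
        raise FormatError(f"{path}: missing mandatory column 'Flags'")
    rows = []
    for raw in lines[header_line + 1:]:
        if not raw.strip():
            continue
        fields = [f.strip().strip('"') for f in raw.split("\t")]
        rec = dict(zip(columns, fields))
        rows.append(
            {
                "array_id": path.stem,
                "probe_id": rec[id_col],
                "fg_ch1": rec[needed["fg_ch1"]],
                "bg_ch1": rec[needed["bg_ch1"]],
                "fg_ch2": rec[needed["fg_ch2"]],
                "bg_ch2": rec[needed["bg_ch2"]],
                "flagged": float(rec["Flags"]) < 0,
            }
        )
    if not rows:
        raise FormatError(f"{path}: GPR file contains no feature rows")
    return _validate_spots(pd.DataFrame(rows), str(path))


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    out = spots[SPOT_COLUMNS].copy()
    out["flagged"] = out["flagged"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_design_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the experiment design (one row per array channel)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty design table") from exc
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    df["replicate"] = df["replicate"].astype(int)
    return validate_design(df[DESIGN_COLUMNS].reset_index(drop=True))


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    if design.duplicated(subset=["array_id", "dye"]).any():
        raise DesignError("duplicate (array_id, dye) row in design")
    bad_dye = set(design["dye"]) - set(CHANNELS)
    if bad_dye:
        raise DesignError(f"unknown dye label(s) {sorted(bad_dye)}; expected {CHANNELS}")
    counts = design.groupby("array_id").size()
    odd = counts[counts != 2]
    if len(odd):
        raise DesignError(
            f"every array needs exactly 2 design rows; offending arrays: "
            f"{dict(odd.head(5))}"
        )
    for factor, levels in FACTOR_LEVELS.items():
        extra = set(design[factor]) - set(levels)
        if extra:
            raise DesignError(f"unknown {factor} level(s) {sorted(extra)}; expected {levels}")
    return design


def write_design_table(design: pd.DataFrame, path: str | Path) -> None:
    design[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


def dye_swap_pairs(design: pd.DataFrame) -> list[tuple[str, str]]:
    """Identify dye-swap partner arrays: same two sample_ids with dyes exchanged."""
    by_array: dict[str, dict[str, str]] = {}
    for _, row in design.iterrows():
        by_array.setdefault(row.array_id, {})[row.dye] = row.sample_id
    key_to_arrays: dict[tuple[str, str], list[str]] = {}
    for arr, chans in by_array.items():
        key = tuple(sorted(chans.values()))
        key_to_arrays.setdefault(key, []).append(arr)
    pairs = []
    for key, arrays in key_to_arrays.items():
        if len(arrays) != 2:
            continue
        a, b = sorted(arrays)
        if by_array[a]["ch1"] == by_array[b]["ch2"] and by_array[a]["ch2"] == by_array[b]["ch1"]:
            pairs.append((a, b))
    return sorted(pairs)


def read_alignment_table(path: str | Path, species_db: str) -> pd.DataFrame:
    """Read BLAST tabular output (``-outfmt 6``, NCBI default 12 columns)."""
    if species_db not in SPECIES_LEVELS:
        raise ValidationError(f"species_db must be one of {SPECIES_LEVELS}, got {species_db!r}")
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns (outfmt 6), "
                    f"got {len(fields)}"
                )
            try:
                evalue = float(fields[10])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: unparsable e-value {fields[10]!r}") from exc
            if evalue < 0:
                raise ValidationError(f"{path}:{lineno}: negative e-value {evalue}")
            align_length = int(fields[3])
            if align_length < 1:
                raise ValidationError(f"{path}:{lineno}: alignment length {align_length} < 1")
            rows.append(
                {
                    "probe_id": fields[0],
                    "transcript_id": fields[1],
                    "percent_identity": float(fields[2]),
                    "align_length": align_length,
                    "evalue": evalue,
                    "bitscore": float(fields[11]),
                    "species_db": species_db,
                }
            )
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def write_alignment_table(hits: pd.DataFrame, path: str | Path) -> None:
    """Write hits back out as 12-column outfmt 6 (placeholder coordinates)."""
    with open(path, "w") as fh:
        for _, h in hits.iterrows():
            fh.write(
                "\t".join(
                    [
                        h.probe_id, h.transcript_id, f"{h.percent_identity:.2f}",
                        str(int(h.align_length)), "0", "0", "1",
                        str(int(h.align_length)), "1", str(int(h.align_length)),
                        repr(float(h.evalue)), f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


def read_annotation_map(go_path: str | Path, fasta_path: str | Path) -> AnnotationMap:
    """Build the probe -> categories / probe -> length map.

    Probes present in the category table but absent from the FASTA are dropped
    with a warning; duplicate (probe, category) lines collapse to one entry.
    """
    lengths: dict[str, int] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).replace("-", "")
        if len(seq) >= 1:
            lengths[rec.id] = len(seq)
    if not lengths:
        raise FormatError(f"{fasta_path}: empty FASTA (no usable sequences)")

    categories: dict[str, set[str]] = {}
    n_dropped = 0
    with open(go_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{go_path}:{lineno}: expected 2 columns (probe, category)")
            probe, cat = fields[0], fields[1]
            if not cat:
                raise ValidationError(f"{go_path}:{lineno}: empty category id")
            if probe not in lengths:
                n_dropped += 1
                continue
            categories.setdefault(probe, set()).add(cat)
    if n_dropped:
        logger.warning(
            "%d annotation line(s) referenced probes absent from %s; dropped",
            n_dropped, fasta_path,
        )
    return AnnotationMap(categories=categories, lengths=lengths)


def spots_to_records(spots: pd.DataFrame) -> list[SpotRecord]:
    return [SpotRecord(**row) for row in spots[SPOT_COLUMNS].to_dict("records")]


def records_to_frame(records: Iterable[SpotRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=SPOT_COLUMNS)
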
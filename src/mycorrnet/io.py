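"""Readers and writers for sample tables, annotations, species matrices and results.

All files are plain UTF-8 text; the delimiter is inferred from the extension
(``.tsv`` -> tab, ``.csv`` -> comma).  Round-trips are bit-exact for integer
tables and better than 1e-12 relative for reals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .tables import (
    GUILDS,
    MYCORRHIZAL_TYPES,
    OTUAnnotationTable,
    PlantAnnotationTable,
    SampleTable,
    SpeciesMatrix,
)

_SAMPLE_META_COLS = ["sample_id", "forest_id", "plant_label"]

#: Missing/uninformative guild strings mapped to UNKNOWN.
_UNKNOWN_STRINGS = {"", "na", "nan", "none", "unknown", "unidentified", "-"}


def _sep_for(path: str | Path, fmt: str | None = None) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "csv"):
            raise FormatError(f"unsupported format {fmt!r}")
        return "\t" if fmt == "tsv" else ","
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    return "\t"


def guild_from_string(raw: str | float | None) -> str:
    """Map a free-text functional-group annotation onto the five-guild vocabulary.

    FUNGuild-style strings may name several guilds at once ("Ectomycorrhizal-
    Saprotroph"); the precedence ECM > AM > PATHO > SAPENDO resolves them to a
    single exclusive category, and saprotroph/endophyte combinations pool into
    SAPENDO.  Blank or uninformative strings become UNKNOWN; anything else
    unrecognized is a validation error.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "UNKNOWN"
    text = str(raw).strip()
    if text in GUILDS:
        return text
    low = text.lower()
    if low in _UNKNOWN_STRINGS:
        return "UNKNOWN"
    if "ectomycorrhizal" in low:
        return "ECM"
    if "arbuscular" in low:
        return "AM"
    if "pathogen" in low:
        return "PATHO"
    if "saprotroph" in low or "endophyte" in low or "endophytic" in low:
        return "SAPENDO"
    raise ValidationError(f"unrecognized guild annotation: {text!r}")


def read_sample_table(path: str | Path, format: str | None = None) -> SampleTable:
    """Read a sample x OTU count table.

    Expected header: ``sample_id, forest_id, plant_label`` followed by one
    column per OTU id.  Row and column order are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path, format), dtype={0: str})
    missing = [c for c in _SAMPLE_META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    otu_ids = [c for c in df.columns if c not in _SAMPLE_META_COLS]
    if not otu_ids:
        raise FormatError(f"{path}: no OTU columns found")
    forests = df["forest_id"].astype(str).unique()
    if len(forests) != 1:
        raise FormatError(
            f"{path}: expected a single forest per sample table, found {list(forests)}"
        )
    counts_df = df[otu_ids]
    sample_ids = df["sample_id"].astype(str).tolist()
    for j, col in enumerate(otu_ids):
        vals = pd.to_numeric(counts_df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.floor(vals))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: invalid count {counts_df[col].iloc[i]!r} at "
                f"row {sample_ids[i]!r}, column {col!r}"
            )
    counts = counts_df.to_numpy(dtype=np.int64)
    return SampleTable(
        forest_id=str(forests[0]),
        sample_ids=sample_ids,
        plant_labels=df["plant_label"].astype(str).tolist(),
        otu_ids=otu_ids,
        counts=counts,
    )


def write_sample_table(t: SampleTable, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(t.counts, columns=t.otu_ids)
    df.insert(0, "plant_label", t.plant_labels)
    df.insert(0, "forest_id", t.forest_id)
    df.insert(0, "sample_id", t.sample_ids)
    df.to_csv(path, sep=_sep_for(path, format), index=False)


def read_annotations(
    path: str | Path, kind: str
) -> OTUAnnotationTable | PlantAnnotationTable:
    """Read an OTU (``kind='otu'``) or plant (``kind='plant'``) annotation table."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if kind == "otu":
        if "otu_id" not in df.columns or "guild" not in df.columns:
            raise FormatError(f"{path}: OTU annotations need columns otu_id, guild")
        guilds = [guild_from_string(g) for g in df["guild"]]
        taxonomy = df["taxonomy"].tolist() if "taxonomy" in df.columns else None
        return OTUAnnotationTable(
            otu_ids=df["otu_id"].tolist(), guilds=guilds, taxonomy=taxonomy
        )
    if kind == "plant":
        if "plant_label" not in df.columns or "mycorrhizal_type" not in df.columns:
            raise FormatError(
                f"{path}: plant annotations need columns plant_label, mycorrhizal_type"
            )
        types = []
        for t in df["mycorrhizal_type"]:
            t = t.strip()
            if t not in MYCORRHIZAL_TYPES:
                raise ValidationError(f"{path}: unknown mycorrhizal type {t!r}")
            types.append(t)
        return PlantAnnotationTable(
            plant_labels=df["plant_label"].tolist(), mycorrhizal_types=types
        )
    raise FormatError(f"unknown annotation kind {kind!r}")


def write_otu_annotations(a: OTUAnnotationTable, path: str | Path) -> None:
    df = pd.DataFrame({"otu_id": a.otu_ids, "guild": a.guilds})
    if a.taxonomy is not None:
        df["taxonomy"] = a.taxonomy
    df.to_csv(Path(path), sep=_sep_for(path), index=False)


def write_plant_annotations(a: PlantAnnotationTable, path: str | Path) -> None:
    pd.DataFrame(
        {"plant_label": a.plant_labels, "mycorrhizal_type": a.mycorrhizal_types}
    ).to_csv(Path(path), sep=_sep_for(path), index=False)


def write_species_matrix(m: SpeciesMatrix, path: str | Path) -> None:
    """Species matrix as TSV; forest and category ride in a comment header line."""
    path = Path(path)
    df = pd.DataFrame(m.assoc, index=m.plant_labels, columns=m.otu_ids)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# forest_id={m.forest_id} category={m.category}\n")
        df.to_csv(fh, sep=_sep_for(path), index_label="plant_label")


def read_species_matrix(path: str | Path) -> SpeciesMatrix:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing species-matrix comment header")
        meta = dict(
            item.split("=", 1) for item in header[1:].strip().split() if "=" in item
        )
        df = pd.read_csv(fh, sep=_sep_for(path), index_col="plant_label")
    return SpeciesMatrix(
        plant_labels=[str(x) for x in df.index],
        otu_ids=list(df.columns),
        assoc=df.to_numpy(dtype=np.int64),
        category=meta.get("category", "ALL"),
        forest_id=meta.get("forest_id", ""),
    )


_REQUIRED_PROVENANCE = ("seed", "n_perm")


def write_results(
    property_table: pd.DataFrame, provenance: dict, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the per-(forest, category) property table plus a provenance JSON.

    The provenance record must carry at least the master seed and the
    permutation counts so that any number in the TSV can be regenerated.
    """
    missing = [k for k in _REQUIRED_PROVENANCE if k not in provenance]
    if missing:
        raise ValidationError(f"results provenance missing required fields {missing}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "results.tsv"
    json_path = out_dir / "results.json"
    cols = list(property_table.columns)
    property_table.to_csv(tsv_path, sep="\t", index=False, columns=cols)
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return tsv_path, json_path


def read_results(out_dir: str | Path) -> tuple[pd.DataFrame, dict]:
    out_dir = Path(out_dir)
    table = pd.read_csv(out_dir / "results.tsv", sep="\t", float_precision="round_trip")
    with open(out_dir / "results.json", encoding="utf-8") as fh:
        provenance = json.load(fh)
    return table, provenance
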
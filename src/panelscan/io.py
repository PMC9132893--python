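"""Reading and writing the pipeline's plain-text table formats (all TSV, UTF-8, LF)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .containers import InputError, OmicsMatrix

MUTATION_COLUMNS = ["sample", "cancer_type", "gene", "protein_pos", "variant_class",
                    "sift", "polyphen", "cadd"]


def read_mutations(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a MAF-like TSV; ``column_map`` renames file columns to the canonical names."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # noqa: BLE001 - surfaced as a stage-level input error
        raise InputError(f"cannot parse mutation table {path}: {exc}") from exc
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"mutation table {path} missing columns: {missing}")
    return df[MUTATION_COLUMNS]


def read_matrix(path: str | Path, role: str, meta_path: str | Path | None = None) -> OmicsMatrix:
    """Read a feature x sample TSV (first column = feature id) into an OmicsMatrix."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise InputError(f"cannot parse matrix {path}: {exc}") from exc
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", comment="#", index_col=0)
        if "is_tumor" in meta.columns:
            meta["is_tumor"] = meta["is_tumor"].astype(bool)
    return OmicsMatrix(values=df, role=role, col_meta=meta)


def read_clinical(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise InputError(f"cannot parse clinical table {path}: {exc}") from exc
    for col in ("os_time", "os_event"):
        if col not in df.columns:
            raise InputError(f"clinical table {path} missing column {col!r}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, conventions: str, index: bool = False,
                index_label: str | None = None) -> Path:
    """Write a result TSV with a header comment naming units and conventions."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# {conventions}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g", lineterminator="\n",
                  index=index, index_label=index_label)
    return path
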
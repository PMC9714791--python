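"""Readers and writers for the plain-text interchange formats used by
the pipeline: TSV effect tables, gene lists, GMT gene-set files, CSV
feature matrices, and TIFF image channels."""
from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd
import tifffile

from .signatures import Signature

DE_COLUMNS = ("gene_id", "log2fc", "lfc_se", "pvalue")


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_de_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> frozenset:
    lines = Path(path).read_text().splitlines()
    return frozenset(line.strip() for line in lines if line.strip())


def write_gene_list(sig: Signature, path) -> None:
    Path(path).write_text("\n".join(sorted(sig.genes)) + "\n")


def read_gmt(path) -> Dict[str, Tuple[str, frozenset]]:
    """GMT records: name, description, then one gene per column."""
    out: Dict[str, Tuple[str, frozenset]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, desc, genes = parts[0], parts[1], parts[2:]
        out[name] = (desc, frozenset(g for g in genes if g))
    return out


def write_gmt(sets: Mapping[str, Tuple[str, Iterable[str]]], path) -> None:
    lines = []
    for name, (desc, genes) in sets.items():
        lines.append("\t".join([name, desc, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_csv(path, group_col: str = "group") -> pd.DataFrame:
    df = pd.read_csv(path)
    if group_col not in df.columns:
        raise ValueError(f"{path}: missing group column {group_col!r}")
    return df


def write_image_u16(image: np.ndarray, path) -> None:
    """Write a float image scaled onto the full 16-bit range."""
    img = np.asarray(image, dtype=float)
    peak = img.max()
    if peak > 0:
        img = img / peak
    tifffile.imwrite(path, np.round(img * 65535).astype(np.uint16))


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)
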
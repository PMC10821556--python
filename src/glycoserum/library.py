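"""Glycan library I/O.

A library is a TSV table with columns ``key, class, antennae, bisected,
galactoses, note`` mapping composition keys to curated structural
annotations.  The shipped default covers the oligomannose series (Man5-Man9),
the common hybrid, agalactosylated/galactosylated neutral complex and
mono- to tetra-sialylated complex glycans of human serum, all observable in
the 1000-4500 m/z window as methylamidated [M+Na]+ ions.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, Union

import pandas as pd

from .glycan_core import GlycanAnnotation, parse_composition

__all__ = ["load_library", "default_library", "write_library"]


def _row_to_annotation(row: pd.Series) -> GlycanAnnotation:
    comp = parse_composition(str(row["key"]))
    if comp.neu5ac > comp.hexnac:
        raise ValueError(f"library entry {row['key']}: more sialic acids than HexNAc")
    return GlycanAnnotation(
        composition=comp,
        glycan_class=str(row["class"]),
        antennae=int(row["antennae"]),
        bisected=bool(int(row["bisected"])),
        galactoses=int(row["galactoses"]),
        source="curated",
    )


def load_library(path: Union[str, Path]) -> Dict[str, GlycanAnnotation]:
    """Read a glycan library TSV into a key -> annotation mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"key", "class", "antennae", "bisected", "galactoses"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library {path} missing columns: {sorted(missing)}")
    lib: Dict[str, GlycanAnnotation] = {}
    for _, row in df.iterrows():
        ann = _row_to_annotation(row)
        if ann.key in lib:
            raise ValueError(f"duplicate library entry {ann.key}")
        lib[ann.key] = ann
    return lib


def default_library() -> Dict[str, GlycanAnnotation]:
    """The curated serum N-glycan library shipped with the package."""
    with resources.as_file(resources.files("glycoserum.data") / "default_library.tsv") as p:
        return load_library(p)


def write_library(lib: Dict[str, GlycanAnnotation], path: Union[str, Path]) -> None:
    rows = [
        {
            "key": ann.key,
            "class": ann.glycan_class,
            "antennae": ann.antennae,
            "bisected": int(ann.bisected),
            "galactoses": ann.galactoses,
            "note": "",
        }
        for ann in lib.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
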
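"""Serialization of haplotype tables and derived quantities.

CSV output carries metadata as ``# key: value`` comment lines and numbers
at 10 significant digits; JSON output round-trips values at full double
precision.  Formatting is locale independent (the decimal point is fixed).
"""

from __future__ import annotations

import json
from typing import Any, TextIO

import numpy as np

from . import __version__
from .core import HaplotypeFreqTable, Sex

__all__ = [
    "write_table_csv",
    "write_table_json",
    "write_tables_json",
    "read_table_json",
    "founder_names",
]


def founder_names(n: int) -> list[str]:
    return list("ABCDEFGH"[:n])


def _meta(table: HaplotypeFreqTable, extra: dict[str, Any]) -> dict[str, Any]:
    meta = {"package": "mpphap", "version": __version__}
    meta.update(extra)
    if table.sex is not None:
        meta["sex"] = table.sex.value
    meta["recombinant_mass"] = table.recombinant_mass
    return meta


def write_table_csv(table: HaplotypeFreqTable, fh: TextIO, **metadata: Any) -> None:
    meta = _meta(table, metadata)
    for k, v in meta.items():
        if isinstance(v, float):
            v = format(v, ".10g")
        fh.write(f"# {k}: {v}\n")
    names = founder_names(table.n_founders)
    fh.write("hap_locus1," + ",".join(names) + "\n")
    for i, row in enumerate(table.entries):
        fh.write(names[i] + "," + ",".join(format(x, ".10g") for x in row) + "\n")


def _payload(table: HaplotypeFreqTable, metadata: dict[str, Any]) -> dict[str, Any]:
    return {
        "metadata": _meta(table, metadata),
        "founders": founder_names(table.n_founders),
        "entries": [[float(x) for x in row] for row in table.entries],
    }


def write_table_json(table: HaplotypeFreqTable, fh: TextIO, **metadata: Any) -> None:
    json.dump(_payload(table, metadata), fh, indent=1)
    fh.write("\n")


def write_tables_json(
    tables: list[HaplotypeFreqTable], metadatas: list[dict[str, Any]], fh: TextIO
) -> None:
    json.dump([_payload(t, md) for t, md in zip(tables, metadatas)], fh, indent=1)
    fh.write("\n")


def read_table_json(fh: TextIO) -> tuple[HaplotypeFreqTable, dict[str, Any]]:
    payload = json.load(fh)
    meta = payload.get("metadata", {})
    sex = Sex(meta["sex"]) if "sex" in meta else None
    return HaplotypeFreqTable(np.array(payload["entries"], dtype=float), sex=sex), meta
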
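"""Readers and writers for the plain-text interchange formats.

Everything is TSV/CSV/GMT so every artifact stays human-diffable. Plate
coordinates are 1-based (rows 1-16, letters A-P accepted; columns
1-24); gene identifiers are opaque strings.
"""

from __future__ import annotations

import pandas as pd

from .errors import InputError
from .itr import NETWORK_COLUMNS, RegulatorNetwork
from .screen import WELL_COLUMNS, PlateSet
from .signature import Signature
from .survival import validate_clinical

_ROW_LETTERS = {letter: i + 1 for i, letter in enumerate("ABCDEFGHIJKLMNOP")}


def _parse_row(value):
    s = str(value).strip()
    if s.upper() in _ROW_LETTERS:
        return _ROW_LETTERS[s.upper()]
    try:
        return int(s)
    except ValueError:
        raise InputError(f"unparseable plate row {value!r} (expected A-P or 1-16)")


def read_plates(path) -> PlateSet:
    """Read a long-format screen CSV: plate,row,col,gene,well_type,condition,signal."""
    df = pd.read_csv(path, dtype={"plate": str, "gene": str})
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    df["row"] = df["row"].map(_parse_row)
    df["col"] = df["col"].astype(int)
    df["gene"] = df["gene"].fillna("")
    return PlateSet(wells=df[WELL_COLUMNS].copy())


def write_plates(plates: PlateSet, path):
    plates.wells.to_csv(path, index=False)


def read_network(path) -> RegulatorNetwork:
    """Read a regulator network TSV: regulator,target,sign,weight (sign NA = unknown)."""
    df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    missing = [c for c in NETWORK_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    df["sign"] = pd.to_numeric(df["sign"], errors="coerce")
    df["weight"] = df["weight"].astype(float)
    return RegulatorNetwork(edges=df[NETWORK_COLUMNS].copy())


def write_network(network: RegulatorNetwork, path):
    network.edges.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_de_table(path) -> pd.DataFrame:
    """Read a DE TSV: contrast,gene,log2fc,padj."""
    df = pd.read_csv(path, sep="\t", dtype={"contrast": str, "gene": str})
    for col in ("contrast", "gene", "log2fc", "padj"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise InputError(f"{path}: adjusted p-values outside [0, 1]")
    dup = df[["contrast", "gene"]].duplicated()
    if dup.any():
        g = df.loc[dup, "gene"].iloc[0]
        raise InputError(f"{path}: duplicate gene {g!r} within a contrast")
    return df


def write_de_table(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Read an expression TSV (first column row ids, remaining columns samples)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen = set()
    for name in header[1:]:
        if name in seen:
            raise InputError(f"{path}: duplicate sample column {name!r}")
        seen.add(name)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"{path}: duplicate row id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise InputError(f"{path}: duplicate sample column {dup!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise InputError(f"{path}: non-numeric expression value ({exc})")
    return df


def write_expression(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index_label="id")


def read_probe_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe", "gene"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    if df["probe"].duplicated().any():
        raise InputError(f"{path}: duplicate probe id")
    return pd.Series(df["gene"].to_numpy(), index=df["probe"], name="gene")


def write_probe_map(probe_map: pd.Series, path):
    pd.DataFrame({"probe": probe_map.index, "gene": probe_map.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    return validate_clinical(df)


def write_clinical(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)


def read_signature(path, regulator: str = "signature") -> Signature:
    """Read a signature TSV: gene,direction,support."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "direction", "support"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return Signature(regulator=regulator, genes=df)


def write_signature(signature: Signature, path):
    signature.genes.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict:
    """Read a GMT file into {set name: (description, [members])}."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path}:{lineno}: GMT lines need name, description and "
                    f">= 1 member (got {len(fields)} fields)"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            if not any(members):
                raise InputError(f"{path}:{lineno}: empty member list for {name!r}")
            sets[name] = (desc, members)
    return sets


def write_gmt(sets: dict, path):
    with open(path, "w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def signature_to_gmt(signature: Signature) -> dict:
    """Export a signature as one gene set per direction (REG_UP / REG_DOWN)."""
    reg = signature.regulator
    sets = {}
    for direction, suffix in ((1, "UP"), (-1, "DOWN"), (0, "UNKNOWN")):
        genes = list(signature.genes.loc[
            signature.genes["direction"] == direction, "gene"
        ])
        if genes:
            sets[f"{reg}_{suffix}"] = (
                f"{reg} signature genes, expected direction {direction:+d}"
                if direction
                else f"{reg} signature genes, direction unknown",
                genes,
            )
    return sets


def write_hit_table(hits: pd.DataFrame, path):
    hits.to_csv(path, sep="\t", index=False)


def write_itr_results(res: pd.DataFrame, path):
    out = res.copy()
    for col in ("contributing_genes", "contributing_directions"):
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: ";".join(str(x) for x in v) if isinstance(v, list) else v
            )
    out.to_csv(path, sep="\t", index=False)
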
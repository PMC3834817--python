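"""Table, FASTA and config I/O shared by the CLI and the library.

Tables are TSV with a commented provenance header (package version, config
hash, seed) so every output is traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .ensemble import FretCurve, curves_from_frame, curves_to_frame
from .params import MechParams, ParameterError, params_from_config
from .quantify import ChannelTriple


def provenance_header(config: Mapping[str, Any] | None = None,
                      seed: int | None = None) -> str:
    digest = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    lines = [f"# visemech {__version__}", f"# config_hash {digest}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path: str | Path,
                config: Mapping[str, Any] | None = None,
                seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc


def write_curves(curves: Sequence[FretCurve], path: str | Path,
                 config: Mapping[str, Any] | None = None,
                 seed: int | None = None) -> None:
    write_table(curves_to_frame(curves), path, config, seed)


def read_curves(path: str | Path) -> list[FretCurve]:
    df = read_table(path)
    required = {"loop_id", "condition", "target_len", "E"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curve table {path} lacks columns {sorted(missing)}")
    if "sem" not in df.columns:
        df["sem"] = float("nan")
    return curves_from_frame(df)


def read_channel_table(path: str | Path) -> list[ChannelTriple]:
    df = read_table(path)
    required = {"construct", "a_gg", "a_gr", "a_rr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"channel table {path} lacks columns {sorted(missing)}")
    return [ChannelTriple(str(row.construct), float(row.a_gg),
                          float(row.a_gr), float(row.a_rr))
            for row in df.itertuples(index=False)]


def read_ddg_table(path: str | Path) -> dict[str, float]:
    """Mismatch destabilization table: columns mismatch_code, ddg_kcal_per_mol."""
    df = read_table(path)
    required = {"mismatch_code", "ddg_kcal_per_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ddg table {path} lacks columns {sorted(missing)}")
    return {str(r.mismatch_code): float(r.ddg_kcal_per_mol)
            for r in df.itertuples(index=False)}


def read_params_config(path: str | Path, base: MechParams | None = None) -> MechParams:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ParameterError(f"config {path} must be a mapping")
    return params_from_config(config, base)


def strand_lengths_from_fasta(path: str | Path) -> dict[str, int]:
    """Lengths (nt) of the component strands in a FASTA file.

    Only lengths are consumed: vise geometry is defined by loop/target/stem
    lengths, not by the specific sequences.
    """
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
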
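"""Delimited-text readers/writers with provenance headers.

All pipeline outputs are plain delimited text (comma default, tab
accepted on input) whose first line is a comment header recording tool
version, command, config hash and seed, so any artifact can be traced
back to the exact run that produced it.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["read_table", "write_table", "provenance_header"]


def provenance_header(command: str, cfg_hash: str, seed: int) -> str:
    return f"# socwage {__version__} | command={command} | config={cfg_hash} | seed={seed}"


def _sniff_sep(path: str | Path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a delimited text table, skipping ``#`` comment lines."""
    kwargs.setdefault("sep", _sniff_sep(path))
    kwargs.setdefault("comment", "#")
    return pd.read_csv(path, **kwargs)


def write_table(df: pd.DataFrame, path: str | Path,
                header_lines: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ln in header_lines or []:
            fh.write(ln if ln.endswith("\n") else ln + "\n")
        df.to_csv(fh, index=False)
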
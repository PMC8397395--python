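"""Delimited-text I/O dialect used by every module.

All tabular artifacts are tab-separated files with unit-bearing column
names (``temperature_K``, ``tau_s``, ``wtpct_drug`` ...).  Metadata that
applies to the whole table (temperature, pressure, composition label)
travels in ``# key = value`` header lines so a file is self-describing.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_table", "write_table"]


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write ``df`` as tab-separated text with ``# key = value`` headers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a table written by :func:`write_table`.

    Returns the DataFrame and the metadata dict; numeric metadata values
    are converted to float when possible.
    """
    metadata: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                value = value.strip()
                try:
                    metadata[key.strip()] = float(value)
                except ValueError:
                    metadata[key.strip()] = value
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    return df, metadata
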
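"""Provenance headers and run manifests.

Tabular outputs begin with '#key=value' comment lines (tool version, run
parameters) that downstream readers skip transparently.  Each CLI run also
writes a JSON manifest recording the subcommand, resolved parameters, input
checksums, seed and timestamps, so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd


def tool_version() -> str:
    try:
        return version("neomerkit")
    except PackageNotFoundError:
        return "0+unknown"


def header_lines(meta: dict) -> list[str]:
    lines = [f"#neomerkit={tool_version()}"]
    for key, val in meta.items():
        lines.append(f"#{key}={val}")
    return lines


def write_tsv_with_header(df: pd.DataFrame, path: str | Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for line in header_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv_with_header(path: str | Path, **kwargs) -> tuple[pd.DataFrame, dict]:
    """Read a '#'-headed TSV, returning (table, header metadata)."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                break
            key, _, val = line[1:].rstrip("\n").partition("=")
            meta[key] = val
        fh.seek(pos)
        kwargs.setdefault("keep_default_na", False)
        df = pd.read_csv(fh, sep="\t", **kwargs)
    return df, meta


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(
    out_path: str | Path,
    subcommand: str,
    params: dict,
    inputs: list[str | Path],
    seed: int | None = None,
    started: float | None = None,
) -> Path:
    """Write ``<out>.manifest.json`` next to a CLI output file."""
    manifest = {
        "tool": "neomerkit",
        "version": tool_version(),
        "subcommand": subcommand,
        "parameters": {k: str(v) for k, v in params.items()},
        "inputs": {
            str(p): sha256_file(p) for p in inputs if p and Path(p).is_file()
        },
        "seed": seed,
        "python": sys.version.split()[0],
        "started": started,
        "finished": time.time(),
    }
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
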
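"""Configuration files, tabular output and run manifests.

Scenario configs are plain JSON (or YAML) documents with sections
``architecture``, ``demography``, ``lifecycle`` and ``run``.  All tabular
output is TSV (UTF-8, '.' decimal, header row) preceded by ``#``-prefixed
metadata lines that embed the config hash and master seed, so outputs can
be matched to the exact configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .simulator import Scenario

__all__ = [
    "config_hash",
    "load_scenario",
    "save_scenario",
    "write_tsv",
    "read_tsv",
    "RunManifest",
]

VERSION = "0.1.0"


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-compatible configuration."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_scenario(path: str | Path) -> Scenario:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if "architecture" not in data:
        raise ValueError(f"{path}: scenario config lacks an 'architecture' section")
    if "demography" not in data:
        raise ValueError(f"{path}: scenario config lacks a 'demography' section")
    return Scenario.from_dict(data)


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    path = Path(path)
    data = scenario.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a TSV with ``# key=value`` metadata lines before the header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path, expect_hash: str | None = None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`, checking the embedded config
    hash if one is expected."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    if expect_hash is not None and meta.get("config_hash") != expect_hash:
        raise ValueError(
            f"{path}: config hash {meta.get('config_hash')!r} does not match "
            f"expected {expect_hash!r}"
        )
    df.attrs["meta"] = meta
    return df


@dataclass
class RunManifest:
    """Provenance of a run: config hash, seeds and census bounds.  The same
    config and master seed always give the same manifest and outputs."""

    config_hash: str
    master_seed: int
    n_replicates: int
    generations: int
    version: str = VERSION
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "master_seed": self.master_seed,
            "n_replicates": self.n_replicates,
            "generations": self.generations,
            "version": self.version,
            **self.extra,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
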
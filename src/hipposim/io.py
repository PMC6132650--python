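"""Readers and writers for patterns, maps, result tables and manifests.

Everything human-facing is delimited text: rate patterns and spatial
maps as TSV (one row per unit, or one lattice row per line), experiment
results as CSV via pandas.  Large pattern sweeps can be stored in a
compressed NumPy container.  A JSON manifest records the seed, the
parameters and the package version of every experiment so that any
result table can be regenerated bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hipposim.patterns import PatternSet, SpatialMap

__all__ = [
    "save_pattern",
    "load_pattern",
    "save_pattern_set",
    "load_pattern_set",
    "save_map",
    "load_map",
    "save_pattern_archive",
    "load_pattern_archive",
    "write_table",
    "write_manifest",
    "read_manifest",
]


def save_pattern(path: str | Path, pattern: np.ndarray) -> None:
    """One rate per line (spikes/s)."""
    np.savetxt(path, np.asarray(pattern, dtype=float), fmt="%.10g")


def load_pattern(path: str | Path) -> np.ndarray:
    return np.atleast_1d(np.loadtxt(path, dtype=float))


def save_pattern_set(path: str | Path, patterns: PatternSet) -> None:
    """TSV: one row per unit, one column per pattern; labels as header."""
    df = pd.DataFrame(patterns.patterns.T, columns=patterns.labels)
    df.to_csv(path, sep="\t", index=False)


def load_pattern_set(path: str | Path) -> PatternSet:
    df = pd.read_csv(path, sep="\t")
    return PatternSet(patterns=df.to_numpy().T, labels=list(df.columns))


def save_map(path: str | Path, spatial: SpatialMap) -> None:
    """TSV lattice (one lattice row per line); the extent is recorded on
    a comment line."""
    with open(path, "w") as fh:
        fh.write(f"# extent={spatial.extent:.10g}\n")
        np.savetxt(fh, spatial.values, fmt="%.8g", delimiter="\t")


def load_map(path: str | Path) -> SpatialMap:
    extent = 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# extent="):
            extent = float(first.split("=", 1)[1])
            values = np.loadtxt(fh, delimiter="\t")
        else:
            fh.seek(0)
            values = np.loadtxt(fh, delimiter="\t")
    return SpatialMap(values=values, extent=extent)


def save_pattern_archive(path: str | Path, patterns: PatternSet,
                         **metadata) -> None:
    """Compressed binary container for large sweeps."""
    np.savez_compressed(path, patterns=patterns.patterns,
                        labels=np.array(patterns.labels),
                        metadata=json.dumps(metadata))


def load_pattern_archive(path: str | Path) -> tuple[PatternSet, dict]:
    with np.load(path, allow_pickle=False) as z:
        ps = PatternSet(patterns=z["patterns"],
                        labels=[str(x) for x in z["labels"]])
        meta = json.loads(str(z["metadata"]))
    return ps, meta


def write_table(path: str | Path, rows: list[dict] | pd.DataFrame) -> pd.DataFrame:
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def write_manifest(path: str | Path, **entries) -> None:
    """JSON manifest: seed, parameters, package version."""
    from hipposim import __version__

    payload = {"hipposim_version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=str) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
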
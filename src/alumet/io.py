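"""Readers and writers for the pipeline's plain-text formats.

All tabular outputs are TSV with a provenance header comment naming the
tool version and the hash of the configuration that produced them, so
re-runs are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional

import pandas as pd

from . import __version__
from .cobra import FRAGMENT_LENGTHS, BandProfile

__all__ = ["config_hash", "write_table", "read_table", "read_band_csv", "write_band_csv"]

BAND_COLUMNS = ["sample_id"] + [f"b{frag}" for frag in FRAGMENT_LENGTHS]


def config_hash(config) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, config=None, index: bool = False) -> None:
    """Write a TSV with a provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# alumet {__version__}\n")
        fh.write(f"# config_hash={config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def read_table(path, index_col: Optional[int] = None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_band_csv(path) -> List[BandProfile]:
    """Read a COBRA band-intensity CSV (sample_id, b133..b32; raw
    intensities are normalized to lane shares)."""
    df = pd.read_csv(path)
    missing = set(BAND_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing band columns {sorted(missing)}")
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            BandProfile.from_intensities(
                row[BAND_COLUMNS[1:]].to_numpy(dtype=float),
                sample_id=str(row["sample_id"]),
            )
        )
    return profiles


def write_band_csv(profiles: List[BandProfile], path) -> None:
    rows = [[p.sample_id] + list(p.shares) for p in profiles]
    pd.DataFrame(rows, columns=BAND_COLUMNS).to_csv(path, index=False, float_format="%.8g")
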
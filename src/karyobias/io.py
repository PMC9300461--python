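"""File formats and run configuration.

All genomic intervals are 0-based half-open (BED convention); every
table is plain TSV/CSV with an explicit header.  The run configuration
is YAML with a mandatory seed; unknown keys are rejected so typos fail
loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cnv import HMMParams
from .genome import GenomeSpec, human_genome
from .geometry import GeometryParams
from .simulate import ErrorModel, SequencingModel

__all__ = [
    "BedFormatError",
    "read_bed",
    "write_bed",
    "read_counts",
    "write_counts",
    "RunConfig",
    "load_config",
    "file_checksum",
]

log = logging.getLogger(__name__)


class BedFormatError(ValueError):
    """Malformed BED input; the message carries the offending line."""


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ bin grid, enforcing sorted non-overlapping bins.

    Returns a DataFrame with columns chrom, start, end (ints, 0-based
    half-open).  Overlapping or unsorted bins within a chromosome raise
    BedFormatError with the 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedFormatError(f"line {lineno}: fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedFormatError(f"line {lineno}: non-integer coordinate") from exc
            if not 0 <= start < end:
                raise BedFormatError(f"line {lineno}: need 0 <= start < end")
            rows.append((parts[0], start, end, lineno))
    if not rows:
        raise BedFormatError("empty BED file")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "_line"])
    last_end: dict[str, int] = {}
    for chrom, start, end, lineno in df.itertuples(index=False):
        if chrom in last_end and start < last_end[chrom]:
            raise BedFormatError(
                f"line {lineno}: bins on {chrom} unsorted or overlapping"
            )
        last_end[chrom] = end
    return df.drop(columns="_line")


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_counts(counts: pd.DataFrame, path) -> None:
    """Cells x bins count matrix as TSV with a coordinate-convention header."""
    with open(path, "w") as fh:
        fh.write("# cells x bins; bin ids are chrom:index on the 0-based grid\n")
        counts.to_csv(fh, sep="\t", index_label="cell_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="cell_id")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    ``seed`` is mandatory: every stochastic stage derives a child seed
    from it deterministically, so re-running a config reproduces every
    output byte for byte.
    """

    seed: int
    out_dir: str = "karyobias_run"
    n_cells: int = 200
    genome_scale: float = 0.2
    rpe1_10q_trisomy: bool = False
    error_model: ErrorModel = field(default_factory=ErrorModel)
    sequencing: SequencingModel = field(default_factory=SequencingModel)
    hmm: HMMParams = field(default_factory=HMMParams)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    n_geometry_points: int = 1000
    n_outcome_cells: int = 200

    def genome(self) -> GenomeSpec:
        return human_genome(
            scale=self.genome_scale, rpe1_10q_trisomy=self.rpe1_10q_trisomy
        )

    def child_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the run seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return np.random.default_rng(int.from_bytes(h[:4], "big"))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_BLOCK_TYPES = {
    "error_model": ErrorModel,
    "sequencing": SequencingModel,
    "hmm": HMMParams,
    "geometry": GeometryParams,
}


def load_config(path) -> RunConfig:
    """Parse a YAML run config, rejecting unknown keys at every level."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("config must set an explicit seed")
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _BLOCK_TYPES:
            cls = _BLOCK_TYPES[key]
            block_fields = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - block_fields
            if bad:
                raise ValueError(f"unknown keys in {key}: {sorted(bad)}")
            defaults = {
                f.name: getattr(cls(), f.name)
                for f in dataclasses.fields(cls)
                if f.name not in value
            }
            if defaults:
                log.info("config %s: defaults filled for %s", key, sorted(defaults))
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir: Path, config: RunConfig, outputs: list[str]) -> None:
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "outputs": {
            name: file_checksum(out_dir / name) for name in sorted(outputs)
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
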
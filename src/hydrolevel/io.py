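"""FASTA input, TSV output, profile export and run configuration."""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .levelsets import SpeciesComparison
from .profiling import HydropathyProfile, SequenceRecord

__all__ = [
    "read_fasta",
    "write_results",
    "write_profile",
    "read_profile",
    "RunConfig",
    "read_config",
]

logger = logging.getLogger("hydrolevel")

# standard residues plus codes the unknown-residue policy may handle later
_ALLOWED = set("ACDEFGHIKLMNPQRSTVWY")
_AMBIGUOUS = set("BZXUO")


def _open_text(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_header(description: str) -> tuple[str, str, str]:
    """(id, protein, species) from a FASTA header.

    Headers of the form ``id|protein|species`` populate all three fields.
    UniProt-style ``db|ACCESSION|NAME_SPECIES`` headers are recognized by
    the underscore in the third field: the accession becomes the id and
    NAME/SPECIES the protein/species labels.  Anything else leaves the
    labels blank.
    """
    token = description.split()[0]
    parts = token.split("|")
    if len(parts) == 3:
        if "_" in parts[2] and parts[0].lower() in ("sp", "tr"):
            protein, _, species = parts[2].partition("_")
            return parts[1], protein, species
        return parts[0], parts[1], parts[2]
    return token, "", ""


def read_fasta(path: Union[str, Path], unknown: str = "error",
               region: Optional[tuple[int, int]] = None,
               ) -> List[SequenceRecord]:
    """Read protein records from a plain or gzipped FASTA file.

    Sequences are upper-cased and a terminal ``*`` (stop) is stripped.
    ``unknown`` controls non-amino-acid characters: ``"error"`` (default)
    rejects them, ``"mean"`` lets ambiguity codes (B, Z, X, U, O) through
    for downstream mean-imputation.  ``region`` (1-based inclusive) is
    applied to every record.
    """
    path = Path(path)
    records: List[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            rid, protein, species = _parse_header(entry.description)
            seq = str(entry.seq).upper()
            if seq.endswith("*"):
                seq = seq[:-1]
            if rid in seen:
                raise ValueError(f"{path}: duplicate record id {rid!r}")
            seen.add(rid)
            bad = set(seq) - _ALLOWED
            if bad and not (unknown == "mean" and bad <= _AMBIGUOUS):
                pos = next(i for i, c in enumerate(seq, start=1) if c in bad)
                raise ValueError(
                    f"{path}: record {rid!r} has non-amino-acid character "
                    f"{seq[pos - 1]!r} at position {pos}"
                )
            records.append(SequenceRecord(
                id=rid, residues=seq, species=species, protein=protein,
                region=region,
            ))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    logger.info("read %d record(s) from %s", len(records), path)
    return records


def write_profile(profile: HydropathyProfile, path: Union[str, Path]) -> Path:
    """Export a profile as a position/value TSV suitable for replotting.

    Metadata lines (``# key=value``) carry the sequence id, scale and
    window; values are written in full precision so the file round-trips
    exactly through `read_profile`.
    """
    path = Path(path)
    with open(path, "wt") as out:
        out.write(f"# sequence_id={profile.sequence_id}\n")
        out.write(f"# scale={profile.scale_name}\n")
        out.write(f"# window={profile.window}\n")
        out.write("position\tvalue\n")
        for pos, val in zip(profile.positions, profile.values):
            out.write(f"{int(pos)}\t{float(val)!r}\n")
    return path


def read_profile(path: Union[str, Path]) -> HydropathyProfile:
    """Read a profile TSV written by `write_profile`."""
    path = Path(path)
    meta: dict[str, str] = {}
    positions: list[int] = []
    values: list[float] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            elif line and not line.startswith("position"):
                pos, val = line.split("\t")
                positions.append(int(pos))
                values.append(float(val))
    return HydropathyProfile(
        sequence_id=meta.get("sequence_id", path.stem),
        scale_name=meta.get("scale", ""),
        window=int(meta.get("window", 1)),
        positions=np.array(positions),
        values=np.array(values),
    )


def write_results(result: Union[SpeciesComparison, HydropathyProfile],
                  path: Union[str, Path]) -> Path:
    """Write a species comparison (or a single profile) as TSV.

    Comparison rows are ranked most-level first; deviations are printed
    rounded to 2 decimals (the precision used in comparative tables)
    alongside a full-precision column.
    """
    path = Path(path)
    if isinstance(result, HydropathyProfile):
        return write_profile(result, path)
    rows = []
    for rank, row in enumerate(result.ranking, start=1):
        rows.append({
            "rank": rank,
            "species": row.label,
            "sequence_id": row.sequence_id,
            "deviation": "" if row.deviation is None else f"{row.deviation:.2f}",
            "deviation_full": "" if row.deviation is None else repr(row.deviation),
            "mean_level": "" if row.mean_level is None else f"{row.mean_level:.2f}",
            "n_peaks": row.n_peaks,
            "window": row.window,
            "scale": row.scale_name,
            "definition": row.definition,
            "status": row.status,
        })
    df = pd.DataFrame(rows, columns=[
        "rank", "species", "sequence_id", "deviation", "deviation_full",
        "mean_level", "n_peaks", "window", "scale", "definition", "status",
    ])
    df.to_csv(path, sep="\t", index=False)
    logger.info("wrote %d comparison row(s) to %s", len(rows), path)
    return path


@dataclass
class RunConfig:
    """Flat run configuration mirroring the CLI options."""

    scale_name: str = "MZ"
    windows: tuple[int, ...] = (9,)
    k: int = 5
    definition: str = "mad"
    min_separation: int = 10
    epsilon: Optional[float] = None
    polarity: str = "peaks"
    region: Optional[tuple[int, int]] = None
    seed: int = 0
    unknown: str = "error"
    output: Optional[str] = None


def _parse_region(text: str) -> tuple[int, int]:
    start, _, end = text.partition(":")
    return int(start), int(end)


def _parse_windows(text: str) -> tuple[int, ...]:
    """Windows as 'a:b:step' (inclusive range) or comma list '7,9,11'."""
    if ":" in text:
        parts = [int(p) for p in text.split(":")]
        start, stop = parts[0], parts[1]
        step = parts[2] if len(parts) > 2 else 2
        return tuple(range(start, stop + 1, step))
    return tuple(int(p) for p in text.split(","))


def read_config(path: Union[str, Path]) -> RunConfig:
    """Read a flat ``key = value`` config file into a `RunConfig`.

    Unknown keys are rejected so typos do not silently fall back to
    defaults.  Example::

        scale_name = MZ
        windows = 7:21:2
        k = 5
        definition = mad
        region = 1:360
    """
    cfg = RunConfig()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, sep, value = line.partition("=")
        if not sep:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = key.strip(), value.strip()
        if key == "scale_name":
            cfg.scale_name = value
        elif key in ("window", "windows"):
            cfg.windows = _parse_windows(value)
        elif key == "k":
            cfg.k = int(value)
        elif key == "definition":
            cfg.definition = value
        elif key == "min_separation":
            cfg.min_separation = int(value)
        elif key == "epsilon":
            cfg.epsilon = float(value)
        elif key == "polarity":
            cfg.polarity = value
        elif key == "region":
            cfg.region = _parse_region(value)
        elif key == "seed":
            cfg.seed = int(value)
        elif key == "unknown":
            cfg.unknown = value
        elif key == "output":
            cfg.output = value
        else:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
    if any(w % 2 == 0 or w < 1 for w in cfg.windows):
        raise ValueError(f"{path}: windows must be positive odd integers")
    return cfg
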
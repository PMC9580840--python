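"""Hydropathy scales and the power-law exponent fitter behind fractal scales.

Two scales ship with the package:

``KD``
    The first-order hydropathicity scale of Kyte & Doolittle (1982,
    J. Mol. Biol. 157:105-132), transcribed from Table 2 of that paper.
    Positive values are hydrophobic (isoleucine, +4.5, is the most
    hydrophobic residue; arginine, -4.5, the least).

``MZ``
    The fractal solvent-accessibility scale of Moret & Zebende (2007,
    Phys. Rev. E 75:011920).  For each amino acid the mean
    solvent-accessible surface area SASA(L) of segments of odd length L
    centered on that residue follows a power law

        log SASA(L) ~ const - Psi(aa) * log L        (9 <= L <= 35)

    and Psi(aa) is the scale value.  Hydrophobic residues fold away from
    water faster as segments grow, so a larger exponent means more
    hydrophobic.  Values are stored multiplied by 1000 (cysteine 246 down
    to lysine 69), the dimensionless milli-unit form used in comparative
    profiling work; divide by 1000 (``rescale(scale, 1e-3, 0)``) to
    recover the raw exponents.

`fit_psi_exponent` implements the defining log-log regression so that
MZ-type exponents can be rederived from any per-residue segment-SASA
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AMINO_ACIDS",
    "HydropathyScale",
    "SasaSegmentTable",
    "PowerLawFit",
    "load_scale",
    "available_scales",
    "rescale",
    "fit_psi_exponent",
    "read_scale_file",
    "read_sasa_tables",
]

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

# Kyte & Doolittle (1982), Table 2.
_KD_VALUES = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# Moret & Zebende (2007) SASA power-law exponents Psi(aa), x1000.
_MZ_VALUES = {
    "A": 157.0, "C": 246.0, "D": 87.0, "E": 94.0, "F": 218.0,
    "G": 156.0, "H": 152.0, "I": 222.0, "K": 69.0, "L": 197.0,
    "M": 221.0, "N": 113.0, "P": 121.0, "Q": 105.0, "R": 78.0,
    "S": 100.0, "T": 135.0, "V": 238.0, "W": 174.0, "Y": 222.0,
}


@dataclass(frozen=True)
class HydropathyScale:
    """A named map from the 20 amino acids to hydropathicity values.

    Parameters
    ----------
    name : str
        Scale identifier, e.g. ``"MZ"`` or ``"KD"``.
    values : mapping of str to float
        One value per standard one-letter amino-acid code.
    hydrophobic_is_max : bool
        True when hydrophobic residues sit at the top of the scale, so
        that hydrophobic stretches appear as profile *maxima* (peaks).
        Both shipped scales are oriented this way.
    """

    name: str
    values: Mapping[str, float]
    hydrophobic_is_max: bool = True

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(AMINO_ACIDS):
            missing = sorted(set(AMINO_ACIDS) - keys)
            extra = sorted(keys - set(AMINO_ACIDS))
            raise ValueError(
                f"scale {self.name!r} must map exactly the 20 standard "
                f"amino acids; missing={missing} extra={extra}"
            )
        if not all(math.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} contains non-finite values")

    @property
    def vmin(self) -> float:
        return min(self.values.values())

    @property
    def vmax(self) -> float:
        return max(self.values.values())

    @property
    def mean(self) -> float:
        return sum(self.values.values()) / len(self.values)

    def value(self, residue: str, unknown: str = "error") -> float:
        """Scale value of ``residue``.

        ``unknown`` controls nonstandard codes (B, Z, X, U, O, ...):
        ``"error"`` (default) raises ``KeyError``; ``"mean"`` imputes the
        scale mean.  Erroring is the safe default because the level
        statistic is sensitive to peak heights.
        """
        try:
            return self.values[residue]
        except KeyError:
            if unknown == "mean":
                return self.mean
            raise KeyError(
                f"residue {residue!r} has no value on scale {self.name!r}"
            ) from None

    def encode(self, residues: str, unknown: str = "error") -> np.ndarray:
        """Vector of scale values for a residue string."""
        out = np.empty(len(residues))
        for i, aa in enumerate(residues):
            try:
                out[i] = self.values[aa]
            except KeyError:
                if unknown == "mean":
                    out[i] = self.mean
                else:
                    raise KeyError(
                        f"residue {aa!r} at position {i + 1} has no value "
                        f"on scale {self.name!r} (set unknown='mean' to impute)"
                    ) from None
        return out


_BUILTIN = {
    "KD": HydropathyScale("KD", _KD_VALUES, hydrophobic_is_max=True),
    "MZ": HydropathyScale("MZ", _MZ_VALUES, hydrophobic_is_max=True),
}


def available_scales() -> tuple[str, ...]:
    return tuple(sorted(_BUILTIN))


def load_scale(name: str) -> HydropathyScale:
    """Return a shipped hydropathy scale by name (``"MZ"`` or ``"KD"``)."""
    try:
        return _BUILTIN[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown scale {name!r}; available scales: "
            + ", ".join(available_scales())
        ) from None


def rescale(scale: HydropathyScale, a: float, b: float = 0.0) -> HydropathyScale:
    """Affinely remap every scale value to ``a*v + b``.

    A negative slope flips the hydrophobic orientation flag.  Useful for
    plotting different scales on a common range; the level-deviation
    statistic is equivariant under this map (deviation scales by ``|a|``).
    """
    if a == 0:
        raise ValueError("slope a must be nonzero (a=0 collapses the scale)")
    values = {aa: a * v + b for aa, v in scale.values.items()}
    flag = scale.hydrophobic_is_max if a > 0 else not scale.hydrophobic_is_max
    return HydropathyScale(scale.name, values, hydrophobic_is_max=flag)


def read_scale_file(path: str | Path, name: str | None = None,
                    hydrophobic_is_max: bool = True) -> HydropathyScale:
    """Load a user scale from a two-column text file (code, value).

    Blank lines and ``#`` comments are ignored; columns are whitespace or
    tab separated.  The file must cover exactly the 20 standard residues.
    """
    path = Path(path)
    values: dict[str, float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'code value', got {raw!r}")
        code = parts[0].upper()
        if code in values:
            raise ValueError(f"{path}:{lineno}: duplicate residue {code!r}")
        values[code] = float(parts[1])
    return HydropathyScale(name or path.stem, values,
                           hydrophobic_is_max=hydrophobic_is_max)


@dataclass(frozen=True)
class SasaSegmentTable:
    """Mean segment SASA versus odd segment length for one residue type.

    Rows are ``(L, sasa)`` pairs where ``L = 2N + 1`` is the segment
    length in residues (3..45 in the defining study) and ``sasa`` the mean
    solvent-accessible surface area of segments of that length centered on
    the residue.
    """

    residue: str
    rows: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for L, sasa in self.rows:
            if L % 2 == 0 or not (3 <= L <= 45):
                raise ValueError(f"segment length must be odd in [3, 45], got {L}")
            if sasa <= 0:
                raise ValueError(f"sasa must be positive, got {sasa} at L={L}")


class PowerLawFit(NamedTuple):
    """Result of the log-log SASA regression."""

    psi: float        # negated slope: SASA(L) ~ exp(intercept) * L**(-psi)
    intercept: float  # natural-log intercept
    r_value: float
    stderr: float


def fit_psi_exponent(table: SasaSegmentTable, l_min: int = 9,
                     l_max: int = 35) -> PowerLawFit:
    """Least-squares fit of ``log sasa`` on ``log L`` over ``[l_min, l_max]``.

    Returns the hydropathicity exponent ``psi`` (the negated slope) and
    the natural-log intercept.  This is the regression that defines
    MZ-type fractal scales; the default range [9, 35] is the window in
    which segment SASA is self-similar.
    """
    rows = [(L, s) for L, s in table.rows if l_min <= L <= l_max]
    if len(rows) < 3:
        raise ValueError(
            f"need at least 3 rows with {l_min} <= L <= {l_max}, "
            f"got {len(rows)} for residue {table.residue!r}"
        )
    L = np.array([r[0] for r in rows], dtype=float)
    sasa = np.array([r[1] for r in rows], dtype=float)
    fit = stats.linregress(np.log(L), np.log(sasa))
    return PowerLawFit(psi=-fit.slope, intercept=fit.intercept,
                       r_value=fit.rvalue, stderr=fit.stderr)


def read_sasa_tables(path: str | Path) -> dict[str, SasaSegmentTable]:
    """Read per-residue segment-SASA tables from a TSV.

    Expected columns: ``residue``, ``L``, ``sasa`` (header row required).
    Returns one `SasaSegmentTable` per residue code found.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"residue", "L", "sasa"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    tables = {}
    for residue, grp in df.groupby("residue", sort=True):
        rows = tuple(
            (int(L), float(s)) for L, s in zip(grp["L"], grp["sasa"])
        )
        tables[str(residue)] = SasaSegmentTable(str(residue), rows)
    return tables
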
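"""Turn individual-level census tables into state variables (S, N, E, B).

Processing follows the standard conventions for this kind of analysis:

1. filter to live individuals with a size measurement;
2. combine multi-stem records per individual by root-sum-of-squares of the
   stem diameters (so basal areas add);
3. rescale so the smallest measurement in the plot equals 1;
4. sum the rescaled values and their powers.

Two measurement kinds are supported.  For ``mass`` data (animals) the
measurement is biomass directly: ``B = sum m_i`` and ``E = sum m_i^theta``.
For ``metabolic_proxy`` data (plants, where a size such as DBH-derived basal
area proxies metabolic rate): ``E = sum eps_i`` and ``B = sum eps_i^(1/theta)``.
``theta`` is the metabolic-scaling exponent (3/4 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .equation_of_state import KLEIBER, ScalingConvention
from .mete_core import StateVariables


__all__ = [
    "MIN_SPECIES_DEFAULT",
    "CensusValidationError",
    "SpeciesSelectionError",
    "CommunityCensus",
    "ObservedStateVariables",
    "combine_stems",
    "rescale_min_to_one",
    "compute_observed",
    "observed_ratio",
    "read_censuses",
    "load_column_mapping",
]

#: data-curation selection rule: plots must contain at least this many species
MIN_SPECIES_DEFAULT = 10

_MEASUREMENT_KINDS = ("mass", "metabolic_proxy")

_TRUTHY = {True, 1, "1", "true", "True", "TRUE", "alive", "live", "A", "L",
           "yes", "Y", "y"}


class CensusValidationError(ValueError):
    """A census record violates a structural requirement."""


class SpeciesSelectionError(ValueError):
    """A plot fails the minimum-species selection rule."""


def combine_stems(stems) -> float:
    """Combine per-stem diameters into one effective diameter,
    ``D = sqrt(D_1^2 + ... + D_k^2)`` (basal areas are additive)."""
    arr = np.asarray(list(stems), dtype=float)
    if arr.size == 0:
        raise CensusValidationError("cannot combine an empty list of stems")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise CensusValidationError(f"stem measurements must be positive; got {arr}")
    return float(np.sqrt(np.sum(arr ** 2)))


def rescale_min_to_one(values) -> tuple[np.ndarray, float]:
    """Divide by the minimum so the smallest value is exactly 1.

    Returns the rescaled array and the rescale factor (the minimum raw
    measurement, kept for provenance).  Ties at the minimum all map to 1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise CensusValidationError("cannot rescale an empty list")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise CensusValidationError("all measurements must be positive and finite")
    factor = float(arr.min())
    return arr / factor, factor


@dataclass(frozen=True)
class CommunityCensus:
    """Individual-level records of one censused plot.

    ``table`` has one row per individual with columns ``species`` and
    ``measurement`` (post stem combination, pre rescaling).
    """

    table: pd.DataFrame
    measurement_kind: str
    plot_label: str = ""

    def __post_init__(self):
        if self.measurement_kind not in _MEASUREMENT_KINDS:
            raise CensusValidationError(
                f"measurement_kind must be one of {_MEASUREMENT_KINDS}, "
                f"got {self.measurement_kind!r}")
        missing = {"species", "measurement"} - set(self.table.columns)
        if missing:
            raise CensusValidationError(f"census table missing columns {missing}")
        m = self.table["measurement"].to_numpy(dtype=float)
        if len(m) == 0:
            raise CensusValidationError("census has no individuals")
        if np.any(m <= 0) or not np.all(np.isfinite(m)):
            bad = int(np.flatnonzero(~((m > 0) & np.isfinite(m)))[0])
            raise CensusValidationError(
                f"non-positive measurement at record {bad} "
                f"of plot {self.plot_label!r}")

    @property
    def n_species(self) -> int:
        return int(self.table["species"].nunique())

    @property
    def n_individuals(self) -> int:
        return int(len(self.table))

    @classmethod
    def from_table(cls, raw: pd.DataFrame, *, measurement_kind: str,
                   species_col: str = "species",
                   measurement_col: str = "measurement",
                   alive_col: str | None = None,
                   individual_col: str | None = None,
                   plot_label: str = "") -> "CommunityCensus":
        """Build a census from a raw table: filter dead, combine stems.

        ``alive_col``: optional status column; rows whose value is not
        truthy ("1", "true", "alive", "live", "yes", "A", "L", ...) are
        dropped before anything else.  ``individual_col``: optional grouping
        key; rows sharing (species, individual) are stems of one individual
        and are combined root-sum-of-squares.
        """
        df = raw.copy()
        if alive_col is not None:
            df = df[df[alive_col].isin(_TRUTHY)]
        df = df[pd.notna(df[measurement_col])]
        if individual_col is not None:
            grouped = (df.groupby([species_col, individual_col], sort=False)
                       [measurement_col]
                       .apply(lambda s: combine_stems(s.to_numpy()))
                       .reset_index())
            df = grouped
        out = pd.DataFrame({
            "species": df[species_col].astype(str).to_numpy(),
            "measurement": df[measurement_col].to_numpy(dtype=float),
        })
        return cls(table=out, measurement_kind=measurement_kind,
                   plot_label=plot_label)


@dataclass(frozen=True)
class ObservedStateVariables:
    """State variables plus observed biomass computed from one plot."""

    S: float
    N: float
    E: float
    B: float
    convention: ScalingConvention
    rescale_factor: float
    plot_label: str = ""

    @property
    def state_variables(self) -> StateVariables:
        """The (S, N, E) triple for feeding the predictors."""
        return StateVariables(S=self.S, N=self.N, E=self.E)

    def to_record(self) -> dict:
        return {"plot_label": self.plot_label, "S": self.S, "N": self.N,
                "E": self.E, "B_observed": self.B,
                "rescale_factor": self.rescale_factor,
                "metabolic_exponent": self.convention.metabolic_exponent}


def compute_observed(census: CommunityCensus,
                     convention: ScalingConvention = KLEIBER,
                     min_species: int = MIN_SPECIES_DEFAULT,
                     allow_fewer: bool = False,
                     rescale_factor: float | None = None
                     ) -> ObservedStateVariables:
    """S, N, E and observed B from a census under the units convention.

    ``rescale_factor`` overrides the within-plot minimum (for cases where the
    smallest individual was estimated externally rather than measured).
    """
    s = census.n_species
    if s < min_species:
        msg = (f"plot {census.plot_label!r} has {s} species, fewer than the "
               f"selection threshold {min_species}")
        if not allow_fewer:
            raise SpeciesSelectionError(msg)
        warnings.warn(msg, stacklevel=2)

    raw = census.table["measurement"].to_numpy(dtype=float)
    if rescale_factor is None:
        values, factor = rescale_min_to_one(raw)
    else:
        if rescale_factor <= 0:
            raise CensusValidationError("rescale_factor must be positive")
        values, factor = raw / rescale_factor, float(rescale_factor)

    theta = convention.metabolic_exponent
    if census.measurement_kind == "mass":
        b = float(values.sum())
        e = float(np.sum(values ** theta))
    else:  # metabolic_proxy
        e = float(values.sum())
        b = float(np.sum(values ** convention.biomass_power))
    return ObservedStateVariables(S=float(s), N=float(len(values)), E=e, B=b,
                                  convention=convention, rescale_factor=factor,
                                  plot_label=census.plot_label)


def observed_ratio(obs: ObservedStateVariables) -> float:
    """``E / B^theta`` — always >= 1 by the power-mean inequality."""
    return obs.E / obs.B ** obs.convention.metabolic_exponent


# ---------------------------------------------------------------------------
# delimited-text input
# ---------------------------------------------------------------------------

_MAPPING_KEYS = ("species", "measurement", "alive", "individual", "plot")


def load_column_mapping(path) -> dict:
    """Read a YAML (or simple ``key: value``) column-mapping file.

    Recognized keys: species, measurement, alive, individual, plot.
    """
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise CensusValidationError(f"mapping file {path} must define key: value pairs")
    unknown = set(mapping) - set(_MAPPING_KEYS)
    if unknown:
        raise CensusValidationError(f"unknown mapping keys {sorted(unknown)}; "
                                    f"recognized: {_MAPPING_KEYS}")
    return {k: str(v) for k, v in mapping.items()}


def read_censuses(path, *, measurement_kind: str, mapping: dict | None = None,
                  sep: str | None = None) -> list[CommunityCensus]:
    """Read one or many plots from a delimited text file (CSV/TSV, header row).

    ``mapping`` renames input columns; if it contains a ``plot`` key the file
    is split into one census per distinct plot value, otherwise the whole file
    is one plot labelled by the file stem.
    """
    mapping = dict(mapping or {})
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep)
    kw = dict(
        measurement_kind=measurement_kind,
        species_col=mapping.get("species", "species"),
        measurement_col=mapping.get("measurement", "measurement"),
        alive_col=mapping.get("alive"),
        individual_col=mapping.get("individual"),
    )
    plot_col = mapping.get("plot")
    if plot_col is None:
        return [CommunityCensus.from_table(raw, plot_label=path.stem, **kw)]
    return [CommunityCensus.from_table(sub, plot_label=str(label), **kw)
            for label, sub in raw.groupby(plot_col, sort=True)]
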
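"""Per-individual isotope records: reading, validation, filtering, summaries.

The central container is :class:`IsotopeSample`, one stranded individual's
carbon and nitrogen isotope measurements (δ¹³C, δ¹⁵N, both ‰) together with
the metadata the downstream statistics need: species, habitat group,
stranding year (for the Suess correction), C:N mass ratio (for lipid
normalisation) and optional sex / total body length.

Habitat-group membership is configuration, never inference: a
:class:`GroupConfig` maps each species to one of four depth-habitat groups
(neritic, mesopelagic, bathypelagic, polar) and optionally carries
species-specific minimum total body lengths used to exclude maternally
dependent animals.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

log = logging.getLogger("isoniche")

__all__ = [
    "HabitatGroup",
    "Sex",
    "IsotopeSample",
    "SpeciesSummary",
    "GroupConfig",
    "SchemaError",
    "ConfigError",
    "read_samples",
    "write_samples",
    "filter_independent",
    "summarise_species",
    "DEFAULT_HABITAT_GROUPS",
]


class HabitatGroup(str, Enum):
    NERITIC = "neritic"
    MESOPELAGIC = "mesopelagic"
    BATHYPELAGIC = "bathypelagic"
    POLAR = "polar"


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"
    UNKNOWN = "unknown"


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


class ConfigError(ValueError):
    """Species/group or threshold configuration is incomplete or inconsistent."""


# Plausibility windows for marine mammal tissue; values outside are data errors.
_D13C_RANGE = (-60.0, 0.0)
_D15N_RANGE = (-10.0, 30.0)


@dataclass
class IsotopeSample:
    """One individual's isotope measurements and stranding metadata.

    ``d13C_bulk`` is the measured bulk-tissue value; ``d13C_corrected`` is
    populated only after the lipid + Suess correction stage has run.
    """

    sample_id: str
    species: str
    year: int
    d13C_bulk: float
    d15N: float
    cn_ratio: float
    latin_name: str | None = None
    habitat_group: HabitatGroup | None = None
    d13C_lipid_extracted: float | None = None
    d13C_corrected: float | None = None
    sex: Sex | None = None
    total_length_cm: float | None = None

    def __post_init__(self) -> None:
        if not self.cn_ratio > 0:
            raise ValueError(f"{self.sample_id}: cn_ratio must be > 0, got {self.cn_ratio}")
        if not _D13C_RANGE[0] < self.d13C_bulk < _D13C_RANGE[1]:
            raise ValueError(f"{self.sample_id}: d13C_bulk {self.d13C_bulk} outside {_D13C_RANGE}")
        if not _D15N_RANGE[0] < self.d15N < _D15N_RANGE[1]:
            raise ValueError(f"{self.sample_id}: d15N {self.d15N} outside {_D15N_RANGE}")

    @property
    def d13C(self) -> float:
        """Corrected δ¹³C when available, else the bulk measurement."""
        return self.d13C_corrected if self.d13C_corrected is not None else self.d13C_bulk


@dataclass(frozen=True)
class SpeciesSummary:
    """Mean ± 1 SD of δ¹³C and δ¹⁵N for one species; SDs are undefined at n = 1."""

    species: str
    n: int
    mean_d13C: float
    mean_d15N: float
    sd_d13C: float | None = None
    sd_d15N: float | None = None


# Default species → habitat-group assignment for the 21 New Zealand
# odontocete species of the shipped synthetic scenario.
DEFAULT_HABITAT_GROUPS: dict[str, HabitatGroup] = {
    "Bottlenose dolphin": HabitatGroup.NERITIC,
    "Hector's dolphin": HabitatGroup.NERITIC,
    "Common dolphin": HabitatGroup.MESOPELAGIC,
    "Dusky dolphin": HabitatGroup.MESOPELAGIC,
    "False killer whale": HabitatGroup.MESOPELAGIC,
    "Killer whale": HabitatGroup.MESOPELAGIC,
    "Long-finned pilot whale": HabitatGroup.MESOPELAGIC,
    "Pygmy killer whale": HabitatGroup.MESOPELAGIC,
    "Pygmy sperm whale": HabitatGroup.MESOPELAGIC,
    "Risso's dolphin": HabitatGroup.MESOPELAGIC,
    "Short-finned pilot whale": HabitatGroup.MESOPELAGIC,
    "Striped dolphin": HabitatGroup.MESOPELAGIC,
    "Arnoux's beaked whale": HabitatGroup.BATHYPELAGIC,
    "Cuvier's beaked whale": HabitatGroup.BATHYPELAGIC,
    "Gray's beaked whale": HabitatGroup.BATHYPELAGIC,
    "Southern bottlenose whale": HabitatGroup.BATHYPELAGIC,
    "Sperm whale": HabitatGroup.BATHYPELAGIC,
    "Strap-toothed whale": HabitatGroup.BATHYPELAGIC,
    "Hourglass dolphin": HabitatGroup.POLAR,
    "Southern right whale dolphin": HabitatGroup.POLAR,
    "Spectacled porpoise": HabitatGroup.POLAR,
}


@dataclass
class GroupConfig:
    """Species-level configuration: habitat groups, independence thresholds, n-gate.

    ``length_thresholds`` gives the minimum total body length (cm) for an
    animal to be considered maternally independent; species listed in
    ``length_exempt`` skip the filter entirely.  The shipped default
    thresholds are placeholders — published species-specific weaning lengths
    should replace them for real analyses.  ``analysis_gate_n`` is the
    minimum per-species sample size admitted to tests, metrics and ellipses.
    """

    habitat_groups: Mapping[str, HabitatGroup] = field(
        default_factory=lambda: dict(DEFAULT_HABITAT_GROUPS)
    )
    length_thresholds: Mapping[str, float] = field(default_factory=dict)
    length_exempt: frozenset[str] = frozenset()
    analysis_gate_n: int = 10

    def __post_init__(self) -> None:
        if self.analysis_gate_n < 2:
            raise ConfigError("analysis_gate_n must be >= 2")
        self.length_exempt = frozenset(self.length_exempt)

    def group_of(self, species: str) -> HabitatGroup:
        try:
            return HabitatGroup(self.habitat_groups[species])
        except KeyError:
            raise ConfigError(f"species {species!r} has no habitat-group assignment") from None


DEFAULT_SCHEMA: dict[str, str] = {
    "sample_id": "sample_id",
    "species": "species",
    "latin_name": "latin_name",
    "year": "year",
    "d13C_bulk": "d13C_bulk",
    "d15N": "d15N",
    "cn_ratio": "cn_ratio",
    "d13C_lipid_extracted": "d13C_lipid_extracted",
    "sex": "sex",
    "total_length_cm": "total_length_cm",
}

_REQUIRED = ("species", "year", "d13C_bulk", "d15N", "cn_ratio")
_OPTIONAL_FLOAT = ("d13C_lipid_extracted", "total_length_cm")


def read_samples(
    path,
    schema: Mapping[str, str] | None = None,
    group_config: GroupConfig | None = None,
    year_window: tuple[int, int] | None = None,
) -> list[IsotopeSample]:
    """Read per-individual records from a CSV file.

    ``schema`` maps canonical field names to the file's column names
    (defaults to identity).  Rows whose required fields fail to parse are
    dropped with a row-numbered diagnostic on the logger rather than
    aborting the whole read.  Blank optional columns become absent fields.

    Raises :class:`SchemaError` when a required column is missing and
    ``ValueError`` on an empty file.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty input file")
        header = set(reader.fieldnames)
        for fld in _REQUIRED:
            if colmap[fld] not in header:
                raise SchemaError(f"{path}: required column {colmap[fld]!r} (field {fld}) missing")
        rows = list(reader)
    if not rows:
        raise ValueError(f"{path}: no data rows")

    samples: list[IsotopeSample] = []
    n_bad = 0
    for i, row in enumerate(rows, start=2):  # row 1 is the header
        try:
            samples.append(_parse_row(row, i, colmap, group_config, year_window))
        except (ValueError, KeyError) as exc:
            n_bad += 1
            log.warning("row %d rejected: %s", i, exc)
    log.info("read %d records from %s (%d rejected)", len(samples), path, n_bad)
    return samples


def _parse_row(row, lineno, colmap, group_config, year_window) -> IsotopeSample:
    def get(fld):
        v = row.get(colmap[fld])
        return v.strip() if isinstance(v, str) else v

    species = get("species")
    if not species:
        raise ValueError("species is blank")
    year = int(get("year"))
    if year_window and not (year_window[0] <= year <= year_window[1]):
        raise ValueError(f"year {year} outside study window {year_window}")
    kwargs = dict(
        sample_id=get("sample_id") or f"row{lineno}",
        species=species,
        latin_name=get("latin_name") or None,
        year=year,
        d13C_bulk=float(get("d13C_bulk")),
        d15N=float(get("d15N")),
        cn_ratio=float(get("cn_ratio")),
    )
    for fld in _OPTIONAL_FLOAT:
        v = get(fld)
        kwargs[fld] = float(v) if v not in (None, "") else None
    sex = get("sex")
    kwargs["sex"] = Sex(sex) if sex else None
    if group_config is not None:
        kwargs["habitat_group"] = group_config.group_of(species)
    return IsotopeSample(**kwargs)


def write_samples(path, samples: Iterable[IsotopeSample]) -> None:
    """Write records back to CSV with the canonical column names (round-trips
    with :func:`read_samples` up to floating-point text representation)."""
    cols = list(DEFAULT_SCHEMA) + ["habitat_group", "d13C_corrected"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for s in samples:
            w.writerow(
                [
                    s.sample_id,
                    s.species,
                    s.latin_name or "",
                    s.year,
                    repr(s.d13C_bulk),
                    repr(s.d15N),
                    repr(s.cn_ratio),
                    "" if s.d13C_lipid_extracted is None else repr(s.d13C_lipid_extracted),
                    s.sex.value if s.sex else "",
                    "" if s.total_length_cm is None else repr(s.total_length_cm),
                    s.habitat_group.value if s.habitat_group else "",
                    "" if s.d13C_corrected is None else repr(s.d13C_corrected),
                ]
            )


def filter_independent(
    samples: Sequence[IsotopeSample], config: GroupConfig
) -> list[IsotopeSample]:
    """Drop animals not clearly past the maternal-dependence length threshold.

    A record is retained when its ``total_length_cm`` is at or above the
    species threshold, or when the species is configured as exempt.  Records
    with no length are excluded unless the species is exempt (conservative
    rule).  A species with neither threshold nor exemption is a
    :class:`ConfigError`.  Per-species exclusion counts go to the logger.
    """
    kept: list[IsotopeSample] = []
    excluded: dict[str, int] = {}
    for s in samples:
        if s.species in config.length_exempt:
            kept.append(s)
            continue
        if s.species not in config.length_thresholds:
            raise ConfigError(
                f"species {s.species!r} has no length threshold and is not exempt"
            )
        thr = config.length_thresholds[s.species]
        if s.total_length_cm is not None and s.total_length_cm >= thr:
            kept.append(s)
        else:
            excluded[s.species] = excluded.get(s.species, 0) + 1
            log.info(
                "excluded %s (%s): length %s below independence threshold %s cm",
                s.sample_id, s.species, s.total_length_cm, thr,
            )
    for sp, n in sorted(excluded.items()):
        log.info("independence filter: %d %s record(s) excluded", n, sp)
    return kept


def summarise_species(samples: Sequence[IsotopeSample]) -> list[SpeciesSummary]:
    """Per-species n, mean and sample SD (denominator n − 1) of both isotopes.

    Uses corrected δ¹³C when the correction stage has run.  SDs are omitted
    (``None``) for single-specimen species, never reported as 0.  Species are
    returned in order of first appearance.
    """
    by_species: dict[str, list[IsotopeSample]] = {}
    for s in samples:
        by_species.setdefault(s.species, []).append(s)

    out: list[SpeciesSummary] = []
    for sp, recs in by_species.items():
        c = [r.d13C for r in recs]
        nvals = [r.d15N for r in recs]
        n = len(recs)
        out.append(
            SpeciesSummary(
                species=sp,
                n=n,
                mean_d13C=_mean(c),
                mean_d15N=_mean(nvals),
                sd_d13C=_sample_sd(c),
                sd_d15N=_sample_sd(nvals),
            )
        )
    return out


def _mean(xs: Sequence[float]) -> float:
    return sum(xs) / len(xs)


def _sample_sd(xs: Sequence[float]) -> float | None:
    n = len(xs)
    if n < 2:
        return None
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (n - 1))
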
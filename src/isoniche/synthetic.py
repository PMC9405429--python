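"""Synthetic stranding communities with the statistical structure the
analysis pipeline assumes.

Each species is a bivariate-normal cloud in (δ¹³C, δ¹⁵N) space.  The
generator draws "true" isotope values — lipid-free and already referenced
to the Suess reference year — then works *backwards* through the
measurement process so that the correction pipeline recovers them:

* C:N mass ratios come from a lognormal clipped to the calibration span
  [3.0, 8.6]; lipid content depresses bulk δ¹³C by a piecewise-linear
  effect ``lipid_slope · max(0, C:N − 3.5)``;
* the Suess drift is reversed for the drawn stranding year (an older
  sample's bulk value sits above its reference-year-standardised value by
  0.022‰ per year);
* a configurable fraction of samples also carries a paired
  "lipid-extracted" δ¹³C (bulk with the lipid effect removed), providing
  the calibration pairs the correction model is fitted on.

A misspecification mode replaces the piecewise-linear lipid effect with a
saturating exponential, for robustness checks of the linear correction.

The shipped ``nz_odontocetes`` scenario encodes a 21-species New Zealand
toothed-whale community (means ± SD and n per species, years 2010–2021).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from .corrections import DEFAULT_CN_THRESHOLD, DEFAULT_SUESS_RATE, DEFAULT_REFERENCE_YEAR
from .samples import HabitatGroup, IsotopeSample

__all__ = [
    "SpeciesSimConfig",
    "generate_species",
    "generate_community",
    "load_scenario",
    "nz_odontocetes_scenario",
]

CN_SPAN = (3.0, 8.6)  # calibration span of C:N mass ratios
DEFAULT_LIPID_SLOPE = 0.99  # ‰ per C:N unit above threshold (Post-style)
DEFAULT_CALIBRATION_FRACTION = 0.45


@dataclass(frozen=True)
class SpeciesSimConfig:
    """Simulation parameters for one species' isotope cloud."""

    species: str
    habitat_group: HabitatGroup
    n: int
    mean_d13C: float
    mean_d15N: float
    sd_d13C: float
    sd_d15N: float
    correlation: float = 0.0  # ρ between the isotopes; 0 = axis-aligned cloud
    year_range: tuple[int, int] = (2010, 2021)
    cn_lognormal_params: tuple[float, float] = (np.log(3.9), 0.18)  # (μ, σ) of log C:N
    lipid_slope: float = DEFAULT_LIPID_SLOPE
    calibration_fraction: float = DEFAULT_CALIBRATION_FRACTION
    latin_name: str | None = None
    lipid_effect: str = "linear"  # or "saturating" (misspecification mode)

    def __post_init__(self):
        if not -1.0 < self.correlation < 1.0:
            raise ValueError(f"correlation must be in (-1, 1), got {self.correlation}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_d13C <= 0 or self.sd_d15N <= 0:
            raise ValueError("sds must be > 0")


def _species_rng(seed: int | None, species: str) -> np.random.Generator:
    """Deterministic, order-independent per-species stream: the substream
    key is a stable hash of the species name, so permuting a community's
    config order never changes any species' draws."""
    key = int.from_bytes(hashlib.sha256(species.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, key]))


def _lipid_offset(cn: np.ndarray, cfg: SpeciesSimConfig) -> np.ndarray:
    excess = np.maximum(0.0, cn - DEFAULT_CN_THRESHOLD)
    if cfg.lipid_effect == "linear":
        return cfg.lipid_slope * excess
    if cfg.lipid_effect == "saturating":
        return cfg.lipid_slope * 2.0 * (1.0 - np.exp(-excess / 2.0))
    raise ValueError(f"unknown lipid_effect {cfg.lipid_effect!r}")


def generate_species(
    config: SpeciesSimConfig,
    seed: int | None = None,
    suess_rate: float = DEFAULT_SUESS_RATE,
    reference_year: int = DEFAULT_REFERENCE_YEAR,
) -> list[IsotopeSample]:
    """Draw one species' records, measurement effects included.

    The emitted ``d13C_bulk`` is the true value minus the lipid offset and
    minus the Suess shift for the drawn year, so running the corrections
    (lipid, then Suess at the same rate/reference) recovers the configured
    bivariate normal.  δ¹⁵N carries no measurement effect.
    """
    rng = _species_rng(seed, config.species)
    cov = np.array(
        [
            [config.sd_d13C**2, config.correlation * config.sd_d13C * config.sd_d15N],
            [config.correlation * config.sd_d13C * config.sd_d15N, config.sd_d15N**2],
        ]
    )
    true = rng.multivariate_normal([config.mean_d13C, config.mean_d15N], cov, size=config.n)
    years = rng.integers(config.year_range[0], config.year_range[1] + 1, size=config.n)
    mu, sigma = config.cn_lognormal_params
    cn = np.clip(rng.lognormal(mu, sigma, size=config.n), *CN_SPAN)
    lipid = _lipid_offset(cn, config)
    suess_shift = suess_rate * (reference_year - years)  # what the correction will add
    bulk = true[:, 0] - lipid - suess_shift
    paired = rng.random(config.n) < config.calibration_fraction

    abbrev = "".join(w[0] for w in config.species.split()).upper()
    return [
        IsotopeSample(
            sample_id=f"{abbrev}-{i:03d}",
            species=config.species,
            latin_name=config.latin_name,
            habitat_group=config.habitat_group,
            year=int(years[i]),
            d13C_bulk=float(bulk[i]),
            d15N=float(true[i, 1]),
            cn_ratio=float(cn[i]),
            d13C_lipid_extracted=float(bulk[i] + lipid[i]) if paired[i] else None,
        )
        for i in range(config.n)
    ]


def generate_community(
    configs: Sequence[SpeciesSimConfig],
    seed: int | None = None,
    suess_rate: float = DEFAULT_SUESS_RATE,
    reference_year: int = DEFAULT_REFERENCE_YEAR,
) -> list[IsotopeSample]:
    """Concatenate per-species generations under independent substreams."""
    if not configs:
        raise ValueError("need at least one species config")
    names = [c.species for c in configs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species in community configs")
    out: list[IsotopeSample] = []
    for cfg in configs:
        out.extend(generate_species(cfg, seed, suess_rate, reference_year))
    return out


def load_scenario(source) -> list[SpeciesSimConfig]:
    """Load a scenario (list of species configs) from a YAML file or path."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    defaults = doc.get("defaults", {})
    configs = []
    for entry in doc["species"]:
        kw = {**defaults, **entry}
        kw["habitat_group"] = HabitatGroup(kw["habitat_group"])
        for key in ("year_range", "cn_lognormal_params"):
            if key in kw:
                kw[key] = tuple(kw[key])
        configs.append(SpeciesSimConfig(**kw))
    return configs


def nz_odontocetes_scenario() -> list[SpeciesSimConfig]:
    """The shipped 21-species New Zealand odontocete scenario."""
    with resources.files("isoniche").joinpath("data/nz_odontocetes.yaml").open() as fh:
        return load_scenario(fh)
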
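"""Synthetic OTU tables, coordinates, and environmental gradients with known
generating processes, so every pipeline stage can be exercised and calibrated
without external data.

Four regimes are available:

* ``neutral`` — samples drawn from the neutral community model.
* ``dispersal_limited`` — each OTU gets a latent origin point and its
  sampling weight decays exponentially with distance from it.
* ``env_filtered`` — each OTU gets latent optima on gradient variables and a
  Gaussian response around them.
* ``mixed`` — both factors multiply.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .community_metrics import EARTH_RADIUS_KM
from .data_model import OtuTable, SampleMetadata, derive_aridity_index
from .neutral_model import lognormal_metacommunity, simulate_ncm

REGIMES = ("neutral", "dispersal_limited", "env_filtered", "mixed")

# Sampling box: ~600 km x 600 km of mid-latitude mountain terrain.
_LAT_RANGE = (43.0, 48.4)
_LON_RANGE = (80.0, 87.6)

# Plausible ranges for the remaining environmental variables.
_VARIABLE_RANGES = {
    "altitude": (1000.0, 3000.0),
    "MAT": (-4.0, 9.0),
    "MAP": (150.0, 600.0),
    "PET": (800.0, 1400.0),
    "SM": (5.0, 40.0),
    "pH": (4.3, 7.5),
    "TSN": (0.5, 5.0),
    "TSP": (0.36, 1.04),
    "TOC": (5.0, 80.0),
    "AN": (20.0, 300.0),
    "CN": (5.0, 20.0),
    "NP": (1.0, 15.0),
}


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario."""

    n_samples: int = 24
    n_otus: int = 300
    depth: int = 2000
    regime: str = "mixed"
    m: float = 0.1
    kernel_scale: float = 100.0  # km
    env_strength: float = 0.5  # Gaussian response sd, in gradient-variable units
    metacommunity_sigma: float = 2.0
    gradient_vars: list[str] = field(default_factory=lambda: ["pH", "TSP"])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_samples < 2 or self.n_otus < 1 or self.depth < 1:
            raise ValueError("n_samples, n_otus, depth must be positive")
        if self.m <= 0 or self.kernel_scale <= 0 or self.env_strength <= 0:
            raise ValueError("rates must be positive")

    @classmethod
    def paper_scale(cls, **overrides) -> "ScenarioConfig":
        """Full-study-size preset (slow; for overnight runs)."""
        defaults = dict(n_samples=24, n_otus=1688, depth=21042)
        defaults.update(overrides)
        return cls(**defaults)


def make_metadata(config: ScenarioConfig) -> SampleMetadata:
    """Random site coordinates and environmental gradients, AI derived."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_samples
    data = {
        "latitude": rng.uniform(*_LAT_RANGE, size=n),
        "longitude": rng.uniform(*_LON_RANGE, size=n),
    }
    for var, (lo, hi) in _VARIABLE_RANGES.items():
        data[var] = rng.uniform(lo, hi, size=n)
    df = pd.DataFrame(data, index=pd.Index([f"S{k + 1}" for k in range(n)], name="sample_id"))
    return derive_aridity_index(SampleMetadata(df))


def _site_xy(meta: SampleMetadata) -> np.ndarray:
    """Planar km coordinates via a local equirectangular projection."""
    lat = np.radians(meta.data["latitude"].to_numpy(float))
    lon = np.radians(meta.data["longitude"].to_numpy(float))
    lat0 = lat.mean()
    x = EARTH_RADIUS_KM * (lon - lon.mean()) * np.cos(lat0)
    y = EARTH_RADIUS_KM * (lat - lat0)
    return np.column_stack([x, y])


@dataclass
class CommunityTruth:
    """Latent generating parameters exported beside a synthetic table."""

    regime: str
    metacommunity: np.ndarray
    origins_xy: np.ndarray | None  # (n_otus, 2) km, dispersal regimes
    optima: dict[str, np.ndarray] | None  # per gradient variable
    m: float | None

    def to_json(self, path) -> None:
        payload = {
            "regime": self.regime,
            "metacommunity": self.metacommunity.tolist(),
            "origins_xy": None if self.origins_xy is None else self.origins_xy.tolist(),
            "optima": None if self.optima is None else {k: v.tolist() for k, v in self.optima.items()},
            "m": self.m,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def make_community(
    config: ScenarioConfig, meta: SampleMetadata
) -> tuple[OtuTable, CommunityTruth]:
    """Generate a count table under the configured regime.

    Per-sample sampling weights are the metacommunity abundances times a
    dispersal factor exp(-distance to the OTU's origin / kernel_scale) and/or
    a Gaussian environmental response around per-OTU optima; each sample is
    a multinomial draw of ``depth`` individuals from its weights.
    """
    if len(meta) != config.n_samples:
        raise ValueError("metadata does not match n_samples")
    ss = np.random.SeedSequence([config.seed, 202])
    rng = np.random.default_rng(ss)
    metacomm = lognormal_metacommunity(
        config.n_otus, sigma=config.metacommunity_sigma,
        seed=np.random.SeedSequence([config.seed, 303]),
    )
    sample_ids = meta.sample_ids
    otu_ids = [f"OTU{j + 1}" for j in range(config.n_otus)]

    if config.regime == "neutral":
        table = simulate_ncm(
            config.n_samples, config.depth, config.m, metacomm,
            seed=np.random.SeedSequence([config.seed, 404]),
            sample_ids=sample_ids, otu_ids=otu_ids,
        )
        return table, CommunityTruth("neutral", metacomm, None, None, config.m)

    weights = np.tile(metacomm, (config.n_samples, 1))
    origins = None
    optima = None

    if config.regime in ("dispersal_limited", "mixed"):
        xy = _site_xy(meta)
        span_x = (xy[:, 0].min(), xy[:, 0].max())
        span_y = (xy[:, 1].min(), xy[:, 1].max())
        origins = np.column_stack([
            rng.uniform(*span_x, size=config.n_otus),
            rng.uniform(*span_y, size=config.n_otus),
        ])
        dist = np.sqrt(((xy[:, None, :] - origins[None, :, :]) ** 2).sum(axis=2))
        weights = weights * np.exp(-dist / config.kernel_scale)

    if config.regime in ("env_filtered", "mixed"):
        optima = {}
        for var in config.gradient_vars:
            vals = meta.data[var].to_numpy(float)
            opt = rng.uniform(vals.min(), vals.max(), size=config.n_otus)
            optima[var] = opt
            delta = vals[:, None] - opt[None, :]
            weights = weights * np.exp(-(delta**2) / (2 * config.env_strength**2))

    counts = np.zeros((config.n_samples, config.n_otus), dtype=np.int64)
    for k in range(config.n_samples):
        w = weights[k]
        total = w.sum()
        if total == 0:
            w = metacomm
            total = w.sum()
        counts[k] = rng.multinomial(config.depth, w / total)
    table = OtuTable(counts, sample_ids, otu_ids)
    truth = CommunityTruth(config.regime, metacomm, origins, optima, None)
    return table, truth


def scenario_config_to_yaml_dict(config: ScenarioConfig) -> dict:
    return asdict(config)


def _round_robin(total: int, n_slots: int) -> np.ndarray:
    """Spread ``total`` reads as evenly as possible over ``n_slots``."""
    base, extra = divmod(total, n_slots)
    out = np.full(n_slots, base, dtype=np.int64)
    out[:extra] += 1
    return out


def make_table_with_classes(
    n_samples: int,
    class_otus: dict[str, int],
    class_reads: dict[str, int],
    high_occupancy_rare: int = 0,
    abundant_min_frac: float = 0.001,
    rare_max_frac: float = 0.0001,
) -> OtuTable:
    """Deterministically build a table with an exact class profile.

    Each class's reads are split as evenly as possible over its OTUs, and
    each OTU's reads as evenly as possible over samples.  Rare OTUs are
    confined to the first half of the samples (occupancy <= 0.5) except for
    ``high_occupancy_rare`` of them, which are spread over every sample.
    Raises if the requested profile cannot satisfy the strict thresholds.
    """
    total = sum(class_reads.values())
    lo = rare_max_frac * total
    hi = abundant_min_frac * total
    bounds = {
        "abundant": lambda t: t > hi,
        "intermediate": lambda t: lo <= t <= hi,
        "rare": lambda t: 0 < t < lo,
    }
    counts_cols = []
    otu_ids = []
    half = max(2, n_samples // 2)
    for cls in ("abundant", "intermediate", "rare"):
        n = class_otus.get(cls, 0)
        if n == 0:
            continue
        totals = _round_robin(class_reads[cls], n)
        for i, t in enumerate(totals):
            if not bounds[cls](t):
                raise ValueError(
                    f"cannot build {cls!r} OTU with total {t} under strict "
                    f"thresholds ({lo:.4f}, {hi:.4f})"
                )
            col = np.zeros(n_samples, dtype=np.int64)
            if cls == "rare" and i >= high_occupancy_rare:
                col[:half] = _round_robin(int(t), half)
            else:
                col[:] = _round_robin(int(t), n_samples)
            counts_cols.append(col)
            otu_ids.append(f"{cls[:1].upper()}{i + 1}")
    counts = np.column_stack(counts_cols)
    sample_ids = [f"S{k + 1}" for k in range(n_samples)]
    return OtuTable(counts, sample_ids, otu_ids)
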
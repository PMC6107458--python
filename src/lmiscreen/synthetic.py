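"""Synthetic serum-cohort generator.

Emulates the statistical structure of an untargeted LC-MS serum peak table so
the whole screening pipeline is testable without any raw data:

* log10 peak areas are normal around a baseline (log-normal raw areas — the
  screening operates on log areas and real peak-area distributions are
  right-skewed over decades);
* *null* ions are identically distributed in every group;
* a *planted single* shifts its log-area mean by ``delta`` in the positive
  groups — a marker an individual-ion screen can find;
* a *planted pair* shares a per-sample latent scale ``u ~ Normal(0, tau)``
  between its two ions.  When ``tau`` dominates the residual spread each ion
  alone overlaps across groups, but the difference of the two log areas
  cancels ``u`` and separates — a marker that exists only as a pair;
* independent dropout zeroes raw areas with fixed probability, exercising the
  0 -> 1 logarithm rule downstream.

Generation is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .peak_table import CohortManifest, IonID, PeakTable

__all__ = [
    "PlantedSingle",
    "PlantedPair",
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "recovery_benchmark_config",
]

#: Cohort sizes of the study design: the two target cancer groups, healthy
#: controls, the two positive-control cancers, and the high-risk groups.
DEFAULT_GROUP_SIZES = {
    "PC": 51,
    "BTC": 39,
    "control": 100,
    "CRC": 100,
    "OVC": 30,
    "PC_HRG": 21,
    "BTC_HRG": 25,
}


@dataclass(frozen=True)
class PlantedSingle:
    """One ion whose log10-area mean is shifted by ``delta`` in ``groups``."""

    groups: frozenset[str]
    delta: float
    sigma: float

    def __init__(self, groups, delta: float, sigma: float) -> None:
        object.__setattr__(self, "groups", frozenset(groups))
        object.__setattr__(self, "delta", float(delta))
        object.__setattr__(self, "sigma", float(sigma))
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class PlantedPair:
    """Two ions sharing a latent per-sample scale of sd ``tau``; only the
    first carries the ``delta`` group shift, so their log-area difference
    separates while each ion alone need not."""

    groups: frozenset[str]
    delta: float
    tau: float
    sigma: float

    def __init__(self, groups, delta: float, tau: float, sigma: float) -> None:
        object.__setattr__(self, "groups", frozenset(groups))
        object.__setattr__(self, "delta", float(delta))
        object.__setattr__(self, "tau", float(tau))
        object.__setattr__(self, "sigma", float(sigma))
        if not (self.sigma > 0 and self.tau > 0):
            raise ValueError("sigma and tau must be positive")


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated study: 366 serum samples over seven groups
    and a 6724-ion peak table.  ``baseline_mean`` 4.0 and ``null_sd`` 0.5 put
    log10 areas in the ~2.5-5.5 range typical of integrated LC-MS peak areas;
    ``dropout_rate`` 0.05 plants the exact zeros the logarithm rule handles.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_null_ions: int = 6724
    planted_singles: Sequence[PlantedSingle] = field(default_factory=tuple)
    planted_pairs: Sequence[PlantedPair] = field(default_factory=tuple)
    dropout_rate: float = 0.05
    baseline_mean: float = 4.0
    null_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_singles = tuple(
            p if isinstance(p, PlantedSingle) else PlantedSingle(*p)
            for p in self.planted_singles
        )
        self.planted_pairs = tuple(
            p if isinstance(p, PlantedPair) else PlantedPair(*p)
            for p in self.planted_pairs
        )
        if any(c < 0 for c in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_null_ions < 0:
            raise ValueError("n_null_ions must be non-negative")
        if not self.null_sd > 0:
            raise ValueError("null_sd must be positive")
        known = set(self.group_sizes)
        for marker in (*self.planted_singles, *self.planted_pairs):
            missing = marker.groups - known
            if missing:
                raise ValueError(
                    f"planted marker references unknown group(s) {sorted(missing)}"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["planted_singles"] = [
            PlantedSingle(p["groups"], p["delta"], p["sigma"])
            for p in d.get("planted_singles", [])
        ]
        d["planted_pairs"] = [
            PlantedPair(p["groups"], p["delta"], p["tau"], p["sigma"])
            for p in d.get("planted_pairs", [])
        ]
        return cls(**d)


@dataclass
class GroundTruth:
    """Registry of planted markers, so recovery can be scored directly."""

    singles: list[IonID]
    pairs: list[tuple[IonID, IonID]]  # (minuend/numerator, subtrahend/denominator)

    def to_dict(self) -> dict:
        return {
            "singles": [[i.mz, i.rt] for i in self.singles],
            "pairs": [[[a.mz, a.rt], [b.mz, b.rt]] for a, b in self.pairs],
        }


def _make_ion(index: int) -> IonID:
    # Arbitrary unique coordinates in a plausible m/z x RT window; identity,
    # not chemistry, is all downstream code needs.
    mz = round(100.0 + 0.1337 * index, 4)
    rt = round(1.0 + (index % 400) * 0.0707, 2)
    return IonID(mz, rt)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[PeakTable, CohortManifest, GroundTruth]:
    """Draw one cohort: raw-scale peak table, manifest, planted-marker registry."""
    rng = np.random.default_rng(config.seed)
    samples: list[str] = []
    groups: list[str] = []
    for group, count in config.group_sizes.items():
        for k in range(count):
            samples.append(f"{group}_{k + 1:03d}")
            groups.append(group)
    n_samples = len(samples)
    if n_samples == 0:
        raise ValueError("cohort has no samples")
    group_arr = np.array(groups)

    rows: list[np.ndarray] = []
    ions: list[IonID] = []
    truth = GroundTruth(singles=[], pairs=[])

    def next_ion() -> IonID:
        ion = _make_ion(len(ions))
        ions.append(ion)
        return ion

    for _ in range(config.n_null_ions):
        next_ion()
        rows.append(
            config.baseline_mean + config.null_sd * rng.standard_normal(n_samples)
        )
    for single in config.planted_singles:
        ind = np.isin(group_arr, list(single.groups)).astype(float)
        truth.singles.append(next_ion())
        rows.append(
            config.baseline_mean
            + single.delta * ind
            + single.sigma * rng.standard_normal(n_samples)
        )
    for pair in config.planted_pairs:
        ind = np.isin(group_arr, list(pair.groups)).astype(float)
        u = pair.tau * rng.standard_normal(n_samples)
        ion_a = next_ion()
        rows.append(
            config.baseline_mean
            + u
            + pair.delta * ind
            + pair.sigma * rng.standard_normal(n_samples)
        )
        ion_b = next_ion()
        rows.append(
            config.baseline_mean + u + pair.sigma * rng.standard_normal(n_samples)
        )
        truth.pairs.append((ion_a, ion_b))

    if not ions:
        raise ValueError("config generates no ions")
    log_areas = np.vstack(rows)
    areas = np.power(10.0, log_areas)
    if config.dropout_rate > 0:
        areas[rng.random(areas.shape) < config.dropout_rate] = 0.0
    table = PeakTable(
        ions,
        samples,
        areas,
        scale="raw",
        provenance={"generator": "lmiscreen.synthetic", "seed": config.seed},
    )
    manifest = CohortManifest(dict(zip(samples, groups)))
    return table, manifest, truth


def recovery_benchmark_config(seed: int = 0) -> SyntheticConfig:
    """Planted-marker recovery benchmark: 50 vs 50 samples, 500 null ions,
    three planted singles at delta/sigma = 10 and one planted pair whose
    latent scale (tau = 10 sigma) hides each member ion individually while
    the pair difference separates at ~14 residual standard deviations."""
    return SyntheticConfig(
        group_sizes={"PC": 50, "control": 50},
        n_null_ions=500,
        planted_singles=[PlantedSingle({"PC"}, delta=1.0, sigma=0.1)] * 3,
        planted_pairs=[PlantedPair({"PC"}, delta=2.0, tau=1.0, sigma=0.1)],
        dropout_rate=0.0,
        baseline_mean=4.0,
        null_sd=0.5,
        seed=seed,
    )
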
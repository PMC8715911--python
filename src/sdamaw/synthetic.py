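"""Seeded generator of synthetic reaches, visits, metrics, and flow records.

The generator emulates the statistical structure the assessment method
assumes: three true flow-duration classes sampled across five subregions,
a dry/flowing condition at each visit whose probability depends on class,
class-conditional indicator metrics (overdispersed counts for biological
tallies, a handful of direct water measures driven by the sampling-day
condition, plus class-independent noise), and revisits of a tenth of the
reaches for repeatability. It is a pure function of its config and seed, so
the entire development pipeline can run end to end with no field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    FlowRecord,
    MetricMeta,
    MetricTable,
    Reach,
    StreamflowClass,
    SUBREGIONS,
    Visit,
)

__all__ = [
    "InformativeMetricSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_flow_record",
]

_CLASSES = (
    StreamflowClass.EPHEMERAL,
    StreamflowClass.INTERMITTENT,
    StreamflowClass.PERENNIAL,
)


@dataclass(frozen=True)
class InformativeMetricSpec:
    """One class-responsive count metric: negative-binomial with class-ordered means.

    ``class_means`` are the (E, I, P) means at the reference effect size
    (1.5 standardized adjacent separations); the generator scales the I and P
    offsets from the ephemeral baseline linearly with
    ``effect_size / 1.5``, so effect size 0 removes all signal.
    """

    name: str
    class_means: tuple  # (mu_E, mu_I, mu_P) at reference effect size


#: Reference effect size at which InformativeMetricSpec class means are stated.
REFERENCE_EFFECT_SIZE = 1.5

#: Default informative metrics, mirroring the structure of real indicator
#: suites: two ordered across all classes (total abundance / richness style),
#: two that mainly separate ephemeral from wetter reaches (hydrophyte style),
#: two that mainly separate perennial from the rest (EPT style).
DEFAULT_INFORMATIVE = (
    InformativeMetricSpec("bio_ordered_1", (2.0, 8.0, 20.0)),
    InformativeMetricSpec("bio_ordered_2", (1.0, 6.0, 16.0)),
    InformativeMetricSpec("bio_ephemeral_1", (0.3, 5.0, 7.0)),
    InformativeMetricSpec("bio_ephemeral_2", (0.5, 6.0, 8.0)),
    InformativeMetricSpec("bio_perennial_1", (0.5, 1.5, 12.0)),
    InformativeMetricSpec("bio_perennial_2", (0.8, 2.0, 14.0)),
)


@dataclass
class SimulationConfig:
    """Study design and signal structure of one synthetic dataset."""

    n_reaches: int = 150
    class_proportions: tuple = (1 / 3, 1 / 3, 1 / 3)  # (E, I, P)
    subregion_proportions: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    revisit_fraction: float = 0.10
    #: probability a visit finds the channel dry, by true class
    dry_probability: dict = field(
        default_factory=lambda: {"Ephemeral": 0.93, "Intermittent": 0.40, "Perennial": 0.0}
    )
    informative: tuple = DEFAULT_INFORMATIVE
    effect_size: float = 1.5  # standardized adjacent-class separation scale
    nb_dispersion: float = 5.0  # negative-binomial size parameter
    n_noise_metrics: int = 50
    n_geospatial_noise: int = 6  # of the noise metrics, how many are geospatial
    n_direct_water: int = 2
    #: probability of a live-fish observation, by true class
    fish_probability: dict = field(
        default_factory=lambda: {"Ephemeral": 0.0, "Intermittent": 0.15, "Perennial": 0.35}
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("class_proportions", "subregion_proportions"):
            p = np.asarray(getattr(self, name), dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if len(self.subregion_proportions) != len(SUBREGIONS):
            raise ValueError(f"need {len(SUBREGIONS)} subregion proportions")
        if not 0.0 <= self.revisit_fraction <= 1.0:
            raise ValueError("revisit_fraction must be in [0, 1]")
        if self.effect_size < 0 or self.nb_dispersion <= 0:
            raise ValueError("effect_size must be >= 0 and nb_dispersion > 0")
        if self.n_geospatial_noise > self.n_noise_metrics:
            raise ValueError("n_geospatial_noise cannot exceed n_noise_metrics")


@dataclass
class SimulatedDataset:
    reaches: list  # of Reach
    visits: list  # of Visit (indicators left empty; metrics are direct)
    metric_table: MetricTable
    truth: pd.Series  # reach_id -> StreamflowClass
    fish_present: pd.Series  # (reach_id, visit_index) -> bool
    algal_cover_ge10: pd.Series  # (reach_id, visit_index) -> bool
    informative_metrics: tuple

    @property
    def flow_state(self) -> dict:
        return {(v.reach_id, v.visit_index): v.flow_state for v in self.visits}


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int):
    if mean <= 0:
        return np.zeros(size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(float)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate reaches, visits and a metric table from the config and seed.

    Informative biological metrics have class-ordered means (E <= I <= P),
    matching the empirical pattern that higher indicator values mark longer
    flow durations; noise metrics are class-independent; direct-water
    hydrological metrics are zero at dry visits. Revisited reaches share
    their true class across visits, with metrics re-drawn per visit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_reaches
    if n < 1:
        raise ValueError("n_reaches must be positive")
    classes = rng.choice(len(_CLASSES), size=n, p=np.asarray(config.class_proportions))
    subregions = rng.choice(
        len(SUBREGIONS), size=n, p=np.asarray(config.subregion_proportions)
    )
    reaches = [
        Reach(
            reach_id=f"R{k:04d}",
            subregion=SUBREGIONS[subregions[k]],
            true_class=_CLASSES[classes[k]],
        )
        for k in range(n)
    ]
    truth = pd.Series(
        {r.reach_id: r.true_class for r in reaches}, name="true_class"
    )

    n_revisit = int(round(config.revisit_fraction * n))
    revisit_ids = set(
        rng.choice([r.reach_id for r in reaches], size=n_revisit, replace=False)
    ) if n_revisit else set()

    visits = []
    for r in reaches:
        n_visits = 2 if r.reach_id in revisit_ids else 1
        for vi in range(1, n_visits + 1):
            dry_p = config.dry_probability[r.true_class.value]
            state = "dry" if rng.random() < dry_p else "flowing"
            visits.append(Visit(reach_id=r.reach_id, visit_index=vi, flow_state=state))

    index = pd.MultiIndex.from_tuples(
        [(v.reach_id, v.visit_index) for v in visits], names=["reach_id", "visit_index"]
    )
    class_of_row = np.array(
        [truth[v.reach_id].duration_rank for v in visits]
    )  # 0=E, 1=I, 2=P
    dry_row = np.array([v.flow_state == "dry" for v in visits])
    n_rows = len(visits)

    data = {}
    metadata = {}
    scale = config.effect_size / REFERENCE_EFFECT_SIZE
    for spec in config.informative:
        mu_e = spec.class_means[0]
        means = np.array(
            [mu_e + scale * (m - mu_e) for m in spec.class_means]
        )
        col = np.empty(n_rows)
        for c in range(3):
            mask = class_of_row == c
            col[mask] = _nb_draw(rng, means[c], config.nb_dispersion, mask.sum())
        data[spec.name] = col
        metadata[spec.name] = MetricMeta(
            "biological", description=f"synthetic class-responsive count ({spec.name})"
        )

    # direct measures of water presence: zero when the channel is dry,
    # class-ordered percentages when flowing
    flow_ranges = {0: (1.0, 30.0), 1: (20.0, 80.0), 2: (60.0, 100.0)}
    for j in range(config.n_direct_water):
        col = np.zeros(n_rows)
        for c in range(3):
            mask = (class_of_row == c) & ~dry_row
            lo, hi = flow_ranges[c]
            col[mask] = rng.uniform(lo, hi, mask.sum())
        name = f"h2o_direct_{j + 1}"
        data[name] = col
        metadata[name] = MetricMeta(
            "hydrological",
            direct_water=True,
            description="synthetic direct water-presence measure",
        )

    n_counts = max(0, (config.n_noise_metrics - config.n_geospatial_noise) // 2)
    for j in range(config.n_noise_metrics - config.n_geospatial_noise):
        if j < n_counts:
            name = f"noise_count_{j + 1:02d}"
            col = _nb_draw(rng, 3.0, config.nb_dispersion, n_rows)
            meta = MetricMeta("biological", description="synthetic class-independent count")
        else:
            name = f"noise_cont_{j - n_counts + 1:02d}"
            col = rng.normal(0.0, 1.0, n_rows)
            meta = MetricMeta(
                "geomorphological", description="synthetic class-independent score"
            )
        data[name] = col
        metadata[name] = meta
    for j in range(config.n_geospatial_noise):
        name = f"gis_noise_{j + 1:02d}"
        data[name] = rng.normal(0.0, 1.0, n_rows)
        metadata[name] = MetricMeta(
            "geospatial", description="synthetic class-independent geospatial metric"
        )

    frame = pd.DataFrame(data, index=index)
    table = MetricTable(frame, metadata)

    fish_p = np.array([config.fish_probability[_CLASSES[c].value] for c in class_of_row])
    fish = pd.Series(rng.random(n_rows) < fish_p, index=index, name="fish_present")
    # algal cover >= 10% occurs mostly at wetter reaches
    algal_p = np.where(class_of_row == 0, 0.02, np.where(class_of_row == 1, 0.25, 0.45))
    algal = pd.Series(rng.random(n_rows) < algal_p, index=index, name="algal_cover_ge10")

    return SimulatedDataset(
        reaches=reaches,
        visits=visits,
        metric_table=table,
        truth=truth,
        fish_present=fish,
        algal_cover_ge10=algal,
        informative_metrics=tuple(s.name for s in config.informative),
    )


def simulate_flow_record(
    true_class: StreamflowClass,
    n_days: int = 365,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> FlowRecord:
    """Simulate a daily flow record whose 5% rule recovers the generating class.

    Perennial records have strictly fewer than 5% zero-flow days, ephemeral
    records strictly fewer than 5% flowing days, and intermittent records a
    flowing fraction in between (at least 5% on both sides). Flowing days
    are laid out as a contiguous wet season starting at a random day.
    """
    true_class = StreamflowClass(true_class)
    if n_days < 30:
        raise ValueError("n_days must be at least 30")
    if rng is None:
        rng = np.random.default_rng(seed)
    max_minor = int(np.ceil(0.05 * n_days)) - 1  # largest count with count/n < 0.05
    max_minor = max(max_minor, 0)
    if true_class is StreamflowClass.PERENNIAL:
        n_flow = n_days - rng.integers(0, max_minor + 1)
    elif true_class is StreamflowClass.EPHEMERAL:
        n_flow = rng.integers(0, max_minor + 1)
    else:
        lo = int(np.ceil(0.05 * n_days))
        hi = n_days - lo
        if lo > hi:
            raise ValueError("record too short for an intermittent band")
        n_flow = rng.integers(lo, hi + 1)

    flowing = np.zeros(n_days, dtype=bool)
    start = int(rng.integers(0, n_days))
    wet = (start + np.arange(int(n_flow))) % n_days
    flowing[wet] = True
    dates = pd.date_range("2020-01-01", periods=n_days, freq="D").date
    return FlowRecord(tuple(dates), tuple(bool(b) for b in flowing))
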
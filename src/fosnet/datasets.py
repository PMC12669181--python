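"""Synthetic per-animal datasets with the statistical structure the pipeline assumes.

The immunofluorescence counts behind a c-Fos co-activation study are per-animal
cell counts per brain region.  Across animals of one condition, regions that
participate in the same functional circuit co-fluctuate, which is what the
downstream Spearman-network stage detects.  The generators here plant exactly
that structure: a latent "circuit activation" factor per module, log-normal
counts around a regional baseline, and a four-variable dentate-gyrus
microcircuit driven by known path coefficients so that the Bayesian mediation
stage can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "MicrocircuitSpec",
    "default_study_spec",
    "DEFAULT_GROUP_SIZES",
    "generate_activation_table",
    "generate_dg_microcircuit",
    "generate_behavior_trials",
]

#: Animals per condition in the analyzed cohort (novel-object, distributed
#: similarity, and the fixed 25/50/75 % similarity groups).
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "NOR": 8, "DIST": 8, "25": 7, "50": 7, "75": 6,
}

# Hippocampal / parahippocampal regions grouped by axis position.  Axis labels
# double as the planted correlation modules in the default study spec.
DEFAULT_REGIONS: dict[str, tuple[str, ...]] = {
    "rostral": ("CA1r", "CA3aR", "CA3bR", "CA3cR", "HilusR", "GCLr"),
    "medial": ("CA1m", "CA2", "CA3am", "CA3bm", "CA3cm", "Hilusm", "GCLm", "Subm"),
    "caudal-dorsal": ("CA1d", "CA3d", "Hilusd", "GCLd", "Subdl"),
    "caudal-ventral": ("CA1v", "CA3v", "Hilusv", "GCLv"),
    "parahippocampal": ("Prh36sl", "Prh36dl", "Prh35sl", "Prh35dl", "LECsl", "LECdl"),
}


@dataclass(frozen=True)
class FactorSpec:
    """Latent-factor model for one cohort of regional activation counts.

    Each animal draws one standard-normal factor per module; the count for
    region ``r`` is ``baseline_count * exp(loading_r * g * factor + noise)``
    where ``g`` is the animal's group multiplier.  Regions sharing a module are
    therefore positively rank-correlated, more strongly the larger the loading.
    """

    module_assignment: Mapping[str, object]
    loading: float | Mapping[str, float] = 0.8
    noise_sd: float = 0.4
    group_effect: Mapping[str, float] = field(default_factory=dict)
    baseline_count: float = 100.0
    n_regions: int | None = None

    def __post_init__(self) -> None:
        if not self.module_assignment:
            raise ValueError("module_assignment must name at least one region")
        if self.n_regions is not None and self.n_regions != len(self.module_assignment):
            raise ValueError(
                f"n_regions={self.n_regions} does not match the "
                f"{len(self.module_assignment)} regions in module_assignment"
            )
        for region in self.regions:
            lo = self.loading_for(region)
            if not 0.0 <= lo <= 1.0:
                raise ValueError(f"loading for {region!r} must lie in [0, 1], got {lo}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline_count <= 0:
            raise ValueError("baseline_count must be positive")

    @property
    def regions(self) -> list[str]:
        return list(self.module_assignment)

    def loading_for(self, region: str) -> float:
        if isinstance(self.loading, Mapping):
            return float(self.loading[region])
        return float(self.loading)

    def group_multiplier(self, group: str) -> float:
        return float(self.group_effect.get(group, 1.0))


@dataclass(frozen=True)
class MicrocircuitSpec:
    """Structural path coefficients of the DG excitatory/inhibitory microcircuit.

    Variables (one value per animal, standardized scale):

    * ``PV_H``  — activated PV+ interneurons in the hilus (exogenous),
    * ``MC``    — activated hilar cells (putative mossy cells),
    * ``PV_GL`` — activated PV+ interneurons in the granule cell layer,
    * ``GC``    — activated granule cells.

    Structural equations::

        PV_H  ~ N(0, 1)
        MC    = a1 * PV_H + e1
        PV_GL = a2 * MC + e2
        GC    = b1 * MC + b2 * PV_GL + b3 * PV_H + e3

    with independent ``e_k ~ N(0, residual_sd_k)``.
    """

    a1: float
    a2: float
    b1: float
    b2: float
    b3: float
    residual_sd: float | Sequence[float] = 1.0
    n_animals: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        sds = self.residual_sds
        if any(s <= 0 for s in sds):
            raise ValueError("residual_sd must be positive")
        if self.n_animals < 4:
            raise ValueError("n_animals must be at least 4")

    @property
    def residual_sds(self) -> tuple[float, float, float]:
        """Residual scales for the MC, PV_GL and GC equations."""
        if np.isscalar(self.residual_sd):
            s = float(self.residual_sd)  # type: ignore[arg-type]
            return (s, s, s)
        sds = tuple(float(s) for s in self.residual_sd)  # type: ignore[union-attr]
        if len(sds) != 3:
            raise ValueError("residual_sd must be a scalar or three values")
        return sds  # type: ignore[return-value]


def default_study_spec() -> tuple[FactorSpec, dict[str, int]]:
    """The default synthetic study: 29 regions on five axis modules, five groups.

    Group multipliers scale the factor loadings (connectivity, not mean level):
    co-activation is densest under intermediate similarity demand and in the
    mixed-similarity condition, sparsest for plain novel-object recognition and
    the highest-similarity condition.
    """
    assignment = {
        region: axis for axis, regions in DEFAULT_REGIONS.items() for region in regions
    }
    spec = FactorSpec(
        module_assignment=assignment,
        loading=0.7,
        noise_sd=0.4,
        group_effect={"NOR": 0.75, "DIST": 1.05, "25": 0.95, "50": 1.15, "75": 0.85},
        baseline_count=100.0,
    )
    return spec, dict(DEFAULT_GROUP_SIZES)


def generate_activation_table(
    spec: FactorSpec,
    group_sizes: Mapping[str, int],
    seed: int,
) -> pd.DataFrame:
    """Generate an animals x regions activation table with planted modules.

    Returns a DataFrame with columns ``animal_id``, ``group`` and one column
    per region; deterministic under a fixed seed.
    """
    for group, size in group_sizes.items():
        if size < 4:
            raise ValueError(f"group {group!r} has size {size}; at least 4 required")
    rng = np.random.default_rng(seed)
    regions = spec.regions
    modules = sorted({str(m) for m in spec.module_assignment.values()})
    module_index = {m: i for i, m in enumerate(modules)}
    loadings = np.array([spec.loading_for(r) for r in regions])
    region_module = np.array(
        [module_index[str(spec.module_assignment[r])] for r in regions]
    )

    rows = []
    for group, size in group_sizes.items():
        mult = spec.group_multiplier(group)
        for a in range(size):
            factors = rng.standard_normal(len(modules))
            noise = rng.normal(0.0, spec.noise_sd, size=len(regions))
            values = spec.baseline_count * np.exp(
                loadings * mult * factors[region_module] + noise
            )
            rows.append([f"{group}_{a + 1:02d}", group, *values])
    return pd.DataFrame(rows, columns=["animal_id", "group", *regions])


def generate_dg_microcircuit(spec: MicrocircuitSpec) -> pd.DataFrame:
    """Simulate the four-variable DG microcircuit from its structural equations."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_animals
    s1, s2, s3 = spec.residual_sds
    pv_h = rng.standard_normal(n)
    mc = spec.a1 * pv_h + rng.normal(0.0, s1, n)
    pv_gl = spec.a2 * mc + rng.normal(0.0, s2, n)
    gc = spec.b1 * mc + spec.b2 * pv_gl + spec.b3 * pv_h + rng.normal(0.0, s3, n)
    return pd.DataFrame(
        {
            "animal_id": [f"a{i + 1:03d}" for i in range(n)],
            "MC": mc,
            "PV_H": pv_h,
            "PV_GL": pv_gl,
            "GC": gc,
        }
    )


def generate_behavior_trials(
    n_animals: int,
    n_trials: int,
    novel_bias: float,
    total_time_mean: float,
    seed: int,
    share_noise_sd: float = 0.08,
) -> pd.DataFrame:
    """Simulate exploration times for a multi-trial object-recognition session.

    Per trial the total exploration time is gamma-distributed around
    ``total_time_mean`` seconds and the novel object receives an expected share
    ``0.5 + novel_bias / 2`` of it, jittered by normal noise and clipped to
    [0, 1].  ``novel_bias = 0`` is the chance condition (expected D1 of zero).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if total_time_mean <= 0:
        raise ValueError("total_time_mean must be positive")
    if not 0.0 <= novel_bias < 1.0:
        raise ValueError("novel_bias must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    shape = 25.0  # coefficient of variation 0.2 for total exploration
    records = []
    for a in range(n_animals):
        for t in range(1, n_trials + 1):
            total = rng.gamma(shape, total_time_mean / shape)
            share = np.clip(
                0.5 + novel_bias / 2.0 + rng.normal(0.0, share_noise_sd), 0.0, 1.0
            )
            records.append((f"a{a + 1:03d}", t, total * share, total * (1.0 - share)))
    return pd.DataFrame(
        records, columns=["animal_id", "trial", "t_novel_s", "t_familiar_s"]
    )
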
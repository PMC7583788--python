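"""Seeded generators for calibration, spike-recovery and product-profile data.

The generators emulate the validation design of the real study: a
seven-point solvent curve (1–10 mg L⁻¹) and five-point matrix-matched
curves (3–10 mg kg⁻¹), seven replicate injections per level, five
consecutive days, and spike recoveries at 3, 6 and 10 mg kg⁻¹.

Detector noise is multiplicative (a lognormal factor with a configured
coefficient of variation): HPLC peak-area scatter scales with the
signal, which also makes the data heteroscedastic, matching the design
choice of an unweighted fit on level means. Between-day effects are a
second multiplicative lognormal factor shared by all injections of a
day. Every generator is a pure function of its config's ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import QuantTable, ReplicateTable
from .errors import ValidationError

#: Spike levels of the recovery design, mg kg⁻¹.
SPIKE_LEVELS = (3.0, 6.0, 10.0)


@dataclass(frozen=True)
class ProductGroup:
    """One cluster of product profiles: mean profile, spread and size."""

    name: str
    mean_profile: tuple[float, ...]
    within_sd: float
    n_samples: int


#: Default grouped profiles loosely following the real products: leafy
#: samples rich in compounds 3/6/7/10, seeds rich in 1/6/7/9, and a more
#: heterogeneous commercial group.
DEFAULT_PRODUCT_GROUPS = (
    ProductGroup("leaves", (0.0, 0.5, 6.0, 0.0, 0.5, 7.0, 7.5, 3.0, 0.0, 6.5), 1.0, 9),
    ProductGroup("seeds", (6.0, 3.0, 0.0, 0.0, 0.5, 6.0, 8.5, 0.0, 2.5, 0.0), 1.0, 6),
    ProductGroup("commercial", (1.0, 2.0, 5.0, 1.0, 2.5, 5.5, 6.5, 2.5, 0.0, 3.5), 1.5, 17),
)


@dataclass
class GeneratorConfig:
    """Ground-truth parameters for all three generators.

    ``curves`` maps (compound, medium) → (slope, intercept). Percent
    noise levels: ``noise_cv`` is the per-injection CV, ``day_effect_sd``
    the between-day multiplicative SD. ``recovery_bias`` gives the true
    percent recovery at each spike level.
    """

    seed: int = 0
    curves: dict[tuple[int, str], tuple[float, float]] = field(
        default_factory=lambda: {(1, "solvent"): (5.6426, 0.1675), (1, "leaves"): (6.4329, 0.3185)}
    )
    noise_cv: float = 1.0
    day_effect_sd: float = 2.0
    recovery_bias: dict[float, float] = field(
        default_factory=lambda: {3.0: 76.0, 6.0: 95.0, 10.0: 100.0}
    )
    n_replicates: int = 7
    n_days: int = 5
    c_original: float = 0.0
    lod: float = 1.5
    loq: float = 4.0
    product_groups: tuple[ProductGroup, ...] = DEFAULT_PRODUCT_GROUPS

    def __post_init__(self) -> None:
        for key, (slope, _) in self.curves.items():
            if slope <= 0:
                raise ValidationError(f"slope for {key} must be positive, got {slope}")
        if self.noise_cv < 0 or self.day_effect_sd < 0:
            raise ValidationError("noise levels must be ≥ 0")
        if self.n_replicates < 2:
            raise ValidationError("need ≥ 2 replicates")
        if not (0 < self.lod < self.loq):
            raise ValidationError("need 0 < lod < loq")


def levels_for_medium(medium: str) -> np.ndarray:
    """Calibration levels of the study design for one medium."""
    if medium == "solvent":
        return np.linspace(1.0, 10.0, 7)
    return np.linspace(3.0, 10.0, 5)


def _lognormal_factor(rng: np.random.Generator, cv_percent: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the given percent CV."""
    if cv_percent == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p((cv_percent / 100.0) ** 2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_calibration(config: GeneratorConfig) -> ReplicateTable:
    """Replicate calibration responses for every configured curve."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for (compound, medium), (slope, intercept) in sorted(config.curves.items()):
        levels = levels_for_medium(medium)
        for day in range(1, config.n_days + 1):
            day_factor = _lognormal_factor(rng, config.day_effect_sd, ())
            for level in levels:
                truth = slope * level + intercept
                noise = _lognormal_factor(rng, config.noise_cv, config.n_replicates)
                responses = np.maximum(truth * day_factor * noise, 0.0)
                for rep, resp in enumerate(responses, start=1):
                    rows.append((compound, medium, level, rep, day, resp))
    frame = pd.DataFrame(rows, columns=["compound", "medium", "level", "replicate", "day", "response"])
    return ReplicateTable(frame)


def simulate_recovery(config: GeneratorConfig, *, compound: int = 1, matrix: str = "leaves") -> pd.DataFrame:
    """Tidy spike-recovery table with the generating truth attached.

    Found concentrations follow ``(C_original + C_spiked) · bias/100``
    times day and replicate noise. The returned frame carries the truth
    in ``frame.attrs["recovery_bias"]``.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for level in SPIKE_LEVELS:
        bias = config.recovery_bias.get(level, 100.0)
        truth = (config.c_original + level) * bias / 100.0
        for day in range(1, config.n_days + 1):
            day_factor = _lognormal_factor(rng, config.day_effect_sd, ())
            noise = _lognormal_factor(rng, config.noise_cv, config.n_replicates)
            found = truth * day_factor * noise
            for rep, val in enumerate(found, start=1):
                rows.append((compound, matrix, level, config.c_original, level, rep, day, val))
    frame = pd.DataFrame(
        rows,
        columns=["compound", "matrix", "spike_level", "c_original", "c_spiked", "replicate", "day", "found"],
    )
    frame.attrs["recovery_bias"] = dict(config.recovery_bias)
    return frame


def simulate_products(config: GeneratorConfig) -> QuantTable:
    """Grouped product profiles with detection-status coding applied."""
    if len(config.product_groups) < 1:
        raise ValidationError("need at least one product group")
    rng = np.random.default_rng(config.seed + 2)
    n_compounds = len(config.product_groups[0].mean_profile)
    rows, ids, types = [], [], []
    for group in config.product_groups:
        if len(group.mean_profile) != n_compounds:
            raise ValidationError("all group profiles must have the same length")
        draws = rng.normal(group.mean_profile, group.within_sd, size=(group.n_samples, n_compounds))
        draws = np.maximum(draws, 0.0)
        for k in range(group.n_samples):
            ids.append(f"{group.name}{k + 1}")
            types.append(group.name)
            rows.append(draws[k])
    raw = np.array(rows)
    coded = raw.copy()
    coded[raw < config.lod] = 0.0
    coded[(raw >= config.lod) & (raw < config.loq)] = 0.1
    values = pd.DataFrame(coded, index=pd.Index(ids, name="sample"), columns=list(range(1, n_compounds + 1)))
    labels = pd.DataFrame({"product_type": types}, index=values.index)
    table = QuantTable(values, labels)
    return table
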
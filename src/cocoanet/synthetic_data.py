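"""Synthetic LC-MS-like peak tables with nested group structure.

The generator emulates the study design the analysis assumes: ~140
samples spanning 3 processing stages and 8 origins with uneven origin
counts, and on the order of 1000 nonnegative compound features per sample
normalized to a per-sample sum of 100. Group structure is nested — a
strong stage-level effect and a weaker origin-level effect within each
stage — plus independent per-sample noise.

Profiles are exponentiated Gaussians: the latent log-profile of sample
``a`` with stage s and origin o is

    z_a = mu + stage_effect * u_s + origin_effect * v_{s,o} + noise_sd * eps_a

with mu a shared per-compound baseline, u_s one fixed vector per stage,
v_{s,o} one fixed vector per (stage, origin) cell (the origin effect is
nested within stage) and eps_a per-sample noise, all standard spherical
Gaussians over compounds. Peak areas exp(z_a) are nonnegative and
heavy-tailed like LC-MS intensities, and because exp is monotone the
Spearman correlation between two samples is that of the latent Gaussian
layer, which makes the effect-size algebra transparent: the latent
correlation of two samples is (shared variance) / (total variance), so
same-stage pairs correlate above cross-stage pairs and same-origin pairs
above cross-origin pairs within a stage, in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from cocoanet.errors import ConfigurationError
from cocoanet.lcms_io import PeakTable, make_peak_table, normalize_sample_sums, select_top_compounds

DEFAULT_STAGES = ("unfermented", "fermented", "liquor")
DEFAULT_ORIGINS = (
    "Brazil",
    "Cameroon",
    "Ecuador",
    "Ghana",
    "Indonesia",
    "Ivory Coast",
    "Malaysia",
    "Tanzania",
)
# uneven inventory: largest origin ~4x the smallest
DEFAULT_ORIGIN_PROPORTIONS = (2.0, 2.0, 3.0, 1.0, 2.0, 4.0, 2.0, 2.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic peak-table generator.

    ``stage_effect`` and ``origin_effect`` scale the stage- and
    origin-level separation of latent log-profiles; ``noise_sd`` scales
    per-sample noise and ``baseline_sd`` the shared per-compound baseline
    (all in latent log units). The defaults put the stage effect well
    above the nested origin effect, the ordering under which stage
    structure emerges at lower correlation thresholds than origin
    structure.
    """

    n_samples: int = 140
    stage_labels: Sequence[str] = DEFAULT_STAGES
    origin_labels: Sequence[str] = DEFAULT_ORIGINS
    origin_proportions: Sequence[float] = DEFAULT_ORIGIN_PROPORTIONS
    n_compounds: int = 1000
    stage_effect: float = 1.3
    origin_effect: float = 0.7
    noise_sd: float = 0.5
    baseline_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if self.n_compounds < 2:
            raise ConfigurationError("n_compounds must be >= 2")
        if not self.stage_labels:
            raise ConfigurationError("need at least one stage label")
        if not self.origin_labels:
            raise ConfigurationError("need at least one origin label")
        if len(set(self.stage_labels)) != len(self.stage_labels):
            raise ConfigurationError("duplicate stage labels")
        if len(set(self.origin_labels)) != len(self.origin_labels):
            raise ConfigurationError("duplicate origin labels")
        if len(self.origin_proportions) != len(self.origin_labels):
            raise ConfigurationError(
                "origin_proportions length must match origin_labels"
            )
        props = np.asarray(self.origin_proportions, dtype=float)
        if (props < 0).any() or props.sum() <= 0:
            raise ConfigurationError(
                "origin_proportions must be nonnegative with positive sum"
            )
        for name in ("stage_effect", "origin_effect", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def _origin_counts(proportions: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n samples over origins."""
    quota = proportions / proportions.sum() * n
    counts = np.floor(quota).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def assign_labels(config: GeneratorConfig) -> tuple[list[str], list[str]]:
    """Deterministic (stage, origin) assignment for every sample.

    Origins receive samples by largest-remainder apportionment of their
    proportions; within an origin, samples cycle through the stages (with
    a per-origin offset so stage totals stay balanced overall).
    """
    counts = _origin_counts(
        np.asarray(config.origin_proportions, dtype=float), config.n_samples
    )
    stages, origins = [], []
    pos = 0
    for o_idx, origin in enumerate(config.origin_labels):
        for k in range(counts[o_idx]):
            stages.append(config.stage_labels[(pos + k) % len(config.stage_labels)])
            origins.append(origin)
        pos += counts[o_idx]
    return stages, origins


def generate_dataset(config: GeneratorConfig) -> PeakTable:
    """Generate a peak table under ``config``.

    The result is normalized so every sample row sums to 100 and its
    compound columns are sorted by descending mean peak area across
    samples, matching the conventional on-disk layout. Fixed seeds give
    bit-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    stages, origins = assign_labels(config)
    p = config.n_compounds

    mu = rng.normal(0.0, config.baseline_sd, p)
    stage_vec = {s: rng.standard_normal(p) for s in config.stage_labels}
    origin_vec = {
        (s, o): rng.standard_normal(p)
        for s in config.stage_labels
        for o in config.origin_labels
    }
    noise = rng.standard_normal((config.n_samples, p))

    latent = np.empty((config.n_samples, p))
    for a, (s, o) in enumerate(zip(stages, origins)):
        latent[a] = (
            mu
            + config.stage_effect * stage_vec[s]
            + config.origin_effect * origin_vec[(s, o)]
            + config.noise_sd * noise[a]
        )

    table = make_peak_table(
        np.exp(latent),
        stage=stages,
        origin=origins,
        sample_ids=[f"sample_{a:03d}" for a in range(config.n_samples)],
        compound_ids=[f"compound_{i:04d}" for i in range(p)],
    )
    table = normalize_sample_sums(table, 100.0)
    # re-sort columns by descending mean (the on-disk convention)
    return select_top_compounds(table, table.n_compounds)


def config_from_dict(data: dict) -> GeneratorConfig:
    """Build a GeneratorConfig from a parsed YAML/JSON mapping."""
    known = set(GeneratorConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown generator options: {sorted(unknown)}")
    return GeneratorConfig(**data)
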
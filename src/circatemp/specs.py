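"""Parameter specifications for the synthetic temperature cohort.

An :class:`ArchetypeSpec` describes one cluster of subjects by its generative
cosinor parameters (mesor, amplitude, period, acrophase clock time), its
delayed-sleep-phase (DSP) prevalence, sleep-onset timing distribution, and
morningness (MEQ) score distribution.  A :class:`NoiseSpec` describes the
measurement process layered on top of the cosinor signal: autocorrelated
sensor noise, the warm-up transient after the logger is attached to the
wrist, sensor quantization, and re-attachment gaps (missing runs).

The default three-archetype table is shipped as a versioned YAML fixture
(``data/archetypes.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "ArchetypeSpec",
    "NoiseSpec",
    "default_archetypes",
    "default_noise",
    "load_archetypes",
    "save_archetypes",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative parameters for one cluster of subjects.

    Parameters
    ----------
    label : str
        Cluster name.
    mesor : float
        Rhythm-adjusted mean temperature, °C.
    amplitude : float
        Half the peak-to-trough extent of the cosinor curve, °C.
    period : float
        Cycle length, hours; physiological range [20, 30].
    acrophase_clock : float
        Clock time (hours after midnight) at which the temperature peak is
        expected on the first night.
    dsp_prob : float
        Probability that a subject of this cluster carries the
        delayed-sleep-phase label.
    sleep_onset_mean : float
        Mean sleep-onset clock time, hours in [0, 24).
    sleep_onset_sd : float
        Night-to-night SD of sleep onset, minutes.
    meq_mean, meq_sd : float
        Mean and SD of the 6-item morningness questionnaire sum score.
    n_subjects : int
        Default cluster size.
    """

    label: str
    mesor: float
    amplitude: float
    period: float
    acrophase_clock: float
    dsp_prob: float
    sleep_onset_mean: float
    sleep_onset_sd: float
    meq_mean: float
    meq_sd: float
    n_subjects: int

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if not 20.0 <= self.period <= 30.0:
            raise ValueError(f"period must lie in [20, 30] h, got {self.period}")
        if not 0.0 <= self.dsp_prob <= 1.0:
            raise ValueError(f"dsp_prob must lie in [0, 1], got {self.dsp_prob}")
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-process parameters for a simulated wrist logger.

    ``sigma`` is the AR(1) *innovation* SD in °C; with autocorrelation
    ``ar_coefficient`` = phi the stationary (marginal) noise SD is
    ``sigma / sqrt(1 - phi**2)``.  ``quantization_step`` emulates the
    sensor resolution (0.0625 °C for the DS1922L-class loggers).
    """

    sigma: float = 0.4
    ar_coefficient: float = 0.9
    transient_magnitude: float = 2.0
    transient_duration: int = 120
    missing_fraction: float = 0.05
    quantization_step: float = 0.0625

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if not 0.0 <= self.missing_fraction < 0.5:
            raise ValueError("missing_fraction must lie in [0, 0.5)")
        if self.quantization_step < 0:
            raise ValueError("quantization_step must be >= 0")

    @property
    def marginal_sd(self) -> float:
        """Stationary SD of the AR(1) noise."""
        return self.sigma / (1.0 - self.ar_coefficient**2) ** 0.5

    @classmethod
    def from_marginal_sd(cls, marginal_sd: float, **kwargs) -> "NoiseSpec":
        """Build a spec whose stationary noise SD equals ``marginal_sd``."""
        phi = kwargs.pop("ar_coefficient", 0.9)
        sigma = marginal_sd * (1.0 - phi**2) ** 0.5
        return cls(sigma=sigma, ar_coefficient=phi, **kwargs)


def _fixture_path() -> Path:
    return Path(str(resources.files("circatemp").joinpath("data/archetypes.yaml")))


def load_archetypes(path: str | Path | None = None) -> list[ArchetypeSpec]:
    """Load an archetype table from YAML (the packaged fixture by default)."""
    p = Path(path) if path is not None else _fixture_path()
    with open(p) as fh:
        doc = yaml.safe_load(fh)
    return [ArchetypeSpec(**row) for row in doc["archetypes"]]


def save_archetypes(archetypes: list[ArchetypeSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"archetypes": [asdict(a) for a in archetypes]}, fh, sort_keys=False)


def default_archetypes() -> list[ArchetypeSpec]:
    """The packaged three-cluster table (highest-mesor cluster first)."""
    return load_archetypes(None)


def default_noise() -> NoiseSpec:
    return NoiseSpec()
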
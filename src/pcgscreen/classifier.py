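"""Threshold-rule screening of heart sounds.

Each feature is compared against a pair of decision boundaries derived from
the extreme observed values of the two subject groups: the maximum value seen
in abnormal recordings (``unhealthy_max``) and the minimum value seen in
normal recordings (``healthy_min``).  Because the bounds are themselves
observed sample values they belong to their classes, so the rule is inclusive:
healthy at >= healthy_min, unhealthy at <= unhealthy_max, and the open gap in
between is reported as indeterminate rather than forced to a call.

Default boundaries (dimensionless amplitude units):

======== ============== ===========
feature  unhealthy_max  healthy_min
======== ============== ===========
mean     0.07           0.09
variance 0.01           0.015
energy   2e-08          0.5e-05
======== ============== ===========

The three per-feature verdicts are combined by majority vote among the
non-indeterminate votes; a tie (or all indeterminate) yields indeterminate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .features import FeatureVector, extract_features
from .signal_io import PcgSignal
from .wavelet import DEFAULT_LEVEL, WaveletSpec

__all__ = [
    "HEALTHY",
    "UNHEALTHY",
    "INDETERMINATE",
    "FeatureThresholds",
    "ThresholdConfig",
    "ClassificationResult",
    "classify_feature",
    "classify",
    "screen",
]

HEALTHY = "healthy"
UNHEALTHY = "unhealthy"
INDETERMINATE = "indeterminate"

FEATURE_NAMES = ("mean", "variance", "energy")


@dataclass(frozen=True)
class FeatureThresholds:
    """Decision boundaries for one feature.

    ``unhealthy_max``: label unhealthy at or below; ``healthy_min``: label
    healthy at or above.  Must satisfy unhealthy_max < healthy_min.
    """

    unhealthy_max: float
    healthy_min: float

    def __post_init__(self) -> None:
        if not self.unhealthy_max < self.healthy_min:
            raise ValueError(
                f"require unhealthy_max < healthy_min, got "
                f"{self.unhealthy_max} >= {self.healthy_min}")


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-feature decision boundaries for the screening rule."""

    mean: FeatureThresholds = field(
        default_factory=lambda: FeatureThresholds(0.07, 0.09))
    variance: FeatureThresholds = field(
        default_factory=lambda: FeatureThresholds(0.01, 0.015))
    energy: FeatureThresholds = field(
        default_factory=lambda: FeatureThresholds(2e-08, 0.5e-05))

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        """Build from ``{feature: {unhealthy_max, healthy_min}}`` (JSON shape).

        Missing features keep their defaults.
        """
        kwargs = {}
        for name in FEATURE_NAMES:
            if name in d:
                kwargs[name] = FeatureThresholds(**d[name])
        return cls(**kwargs)

    def as_dict(self) -> dict:
        return {name: {"unhealthy_max": getattr(self, name).unhealthy_max,
                       "healthy_min": getattr(self, name).healthy_min}
                for name in FEATURE_NAMES}


@dataclass(frozen=True)
class ClassificationResult:
    """Per-feature verdicts, vote counts and the overall majority label."""

    per_feature: dict[str, str]
    overall: str
    votes: dict[str, int]
    features: FeatureVector | None = None

    def as_dict(self) -> dict:
        d = {"per_feature": dict(self.per_feature), "overall": self.overall,
             "votes": dict(self.votes)}
        if self.features is not None:
            d["features"] = self.features.as_dict()
        return d


def classify_feature(value: float, thresholds: FeatureThresholds) -> str:
    """Label one feature value against its decision boundaries."""
    if value >= thresholds.healthy_min:
        return HEALTHY
    if value <= thresholds.unhealthy_max:
        return UNHEALTHY
    return INDETERMINATE


def classify(features: FeatureVector,
             config: ThresholdConfig | None = None) -> ClassificationResult:
    """Vote the three per-feature labels into an overall verdict."""
    if config is None:
        config = ThresholdConfig()
    per_feature = {
        "mean": classify_feature(features.abs_mean, config.mean),
        "variance": classify_feature(features.variance, config.variance),
        "energy": classify_feature(features.dwt_energy, config.energy),
    }
    counts = Counter(per_feature.values())
    votes = {label: counts.get(label, 0)
             for label in (HEALTHY, UNHEALTHY, INDETERMINATE)}
    if votes[HEALTHY] > votes[UNHEALTHY]:
        overall = HEALTHY
    elif votes[UNHEALTHY] > votes[HEALTHY]:
        overall = UNHEALTHY
    else:
        overall = INDETERMINATE
    return ClassificationResult(per_feature=per_feature, overall=overall,
                                votes=votes, features=features)


def screen(signal: PcgSignal, config: ThresholdConfig | None = None,
           wavelet: WaveletSpec | str | None = None,
           level: int = DEFAULT_LEVEL) -> ClassificationResult:
    """End-to-end screening: denoise, extract features, classify.

    The result carries the extracted :class:`FeatureVector` for auditability.
    """
    features = extract_features(signal, wavelet, level=level,
                                denoise_first=True)
    return classify(features, config)
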
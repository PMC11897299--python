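"""Synthetic three-class cohort generator with planted ground truth.

Emulates a cross-sectional MCI/AD study cohort: continuous volumetric
region-of-interest (ROI) features confounded by age, sex and total brain
volume, plus ordinal SNP genotypes coded 0 / 0.5 / 1 for zero, one or two
copies of the risk allele.  A configurable subset of features carries
class-dependent signal ("planted" features), recorded alongside the data so
recovery tests can score explainers against a known answer.

The default cohort mirrors the study conditions the package targets:
449 controls (CN), 740 mild-cognitive-impairment (MCI) and 274 Alzheimer's
(AD) subjects aged 60-86, 154 ROI features and 54 SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from ._common import ParameterError

__all__ = [
    "CohortSpec",
    "Cohort",
    "PlantedFeature",
    "generate_cohort",
    "planted_truth",
    "default_cohort_spec",
]

CLASSES = ("CN", "MCI", "AD")

# effect spec: either one signed shift (applied to the last class, i.e. a
# CN-vs-AD contrast) or an explicit per-class mapping
EffectSpec = Union[float, Mapping[str, float]]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort realisation.

    Parameters
    ----------
    n_per_class
        Subject counts for (CN, MCI, AD).
    n_roi, n_snp
        Number of continuous ROI-volume features and ordinal SNP features.
    planted_roi
        ``{roi_index: effect}`` where *effect* is a standardised mean shift
        (in units of ``noise_sd``).  A bare float applies the shift to the
        AD class only; a mapping gives per-class shifts.
    planted_snp
        ``{snp_index: freq}`` where *freq* is the risk-allele frequency.
        A bare float sets the AD-class frequency (other classes keep the
        baseline); a mapping gives per-class frequencies.
    covariate_effects
        Linear coefficients of (age, sex, brain_volume) on every ROI
        feature, or ``{roi_index: (a, s, b)}`` for per-feature control.
    snp_baseline_freq
        Risk-allele frequency of unplanted SNPs (all classes).
    noise_sd
        Residual standard deviation of the ROI features.
    """

    n_per_class: Sequence[int] = (449, 740, 274)
    n_roi: int = 154
    n_snp: int = 54
    planted_roi: Mapping[int, EffectSpec] = field(default_factory=dict)
    planted_snp: Mapping[int, EffectSpec] = field(default_factory=dict)
    covariate_effects: Union[Sequence[float], Mapping[int, Sequence[float]]] = (
        0.0,
        0.0,
        0.0,
    )
    snp_baseline_freq: float = 0.2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) != len(CLASSES):
            raise ParameterError(
                f"n_per_class must have {len(CLASSES)} entries, got "
                f"{len(self.n_per_class)}"
            )
        if any(int(n) < 2 for n in self.n_per_class):
            raise ParameterError("n_per_class: every class needs >= 2 subjects")
        if self.n_roi < 0 or self.n_snp < 0:
            raise ParameterError("n_roi/n_snp must be nonnegative")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        for idx in self.planted_roi:
            if not 0 <= int(idx) < self.n_roi:
                raise ParameterError(f"planted_roi: index {idx} out of range")
        for idx, eff in self.planted_snp.items():
            if not 0 <= int(idx) < self.n_snp:
                raise ParameterError(f"planted_snp: index {idx} out of range")
            freqs = eff.values() if isinstance(eff, Mapping) else [eff]
            if any(not 0.0 <= float(f) <= 1.0 for f in freqs):
                raise ParameterError(
                    f"planted_snp: allele frequency for index {idx} not in [0,1]"
                )
        if not 0.0 <= self.snp_baseline_freq <= 1.0:
            raise ParameterError("snp_baseline_freq must be in [0,1]")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_class))

    @property
    def feature_names(self) -> list[str]:
        return [f"roi_{i:03d}" for i in range(self.n_roi)] + [
            f"snp_{i:03d}" for i in range(self.n_snp)
        ]

    @property
    def feature_kinds(self) -> list[str]:
        return ["roi"] * self.n_roi + ["snp"] * self.n_snp

    def roi_shift(self, idx: int, cls: str) -> float:
        """Standardised mean shift of ROI ``idx`` in class ``cls``."""
        eff = self.planted_roi.get(idx, 0.0)
        if isinstance(eff, Mapping):
            return float(eff.get(cls, 0.0))
        return float(eff) if cls == CLASSES[-1] else 0.0

    def snp_freq(self, idx: int, cls: str) -> float:
        """Risk-allele frequency of SNP ``idx`` in class ``cls``."""
        eff = self.planted_snp.get(idx)
        if eff is None:
            return self.snp_baseline_freq
        if isinstance(eff, Mapping):
            return float(eff.get(cls, self.snp_baseline_freq))
        return float(eff) if cls == CLASSES[-1] else self.snp_baseline_freq

    def covariate_coefs(self, idx: int) -> np.ndarray:
        ce = self.covariate_effects
        if isinstance(ce, Mapping):
            return np.asarray(ce.get(idx, (0.0, 0.0, 0.0)), dtype=float)
        return np.asarray(ce, dtype=float)


@dataclass(frozen=True)
class PlantedFeature:
    """One informative feature with its effect direction (+1 / -1)."""

    index: int  # column index in the full feature matrix
    name: str
    kind: str  # "roi" | "snp"
    direction: int


@dataclass
class Cohort:
    """A realised synthetic cohort.

    ``features`` holds ROI columns first, then SNP columns; SNP entries are
    restricted to {0, 0.5, 1}.  ``truth`` records the planted features.
    """

    features: np.ndarray
    labels: np.ndarray
    covariates: pd.DataFrame  # columns: age, sex, brain_volume
    feature_names: list[str]
    feature_kinds: list[str]
    truth: list[PlantedFeature]
    spec: CohortSpec | None = None

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    def roi_columns(self) -> np.ndarray:
        return np.asarray(
            [i for i, k in enumerate(self.feature_kinds) if k == "roi"], dtype=int
        )

    def snp_columns(self) -> np.ndarray:
        return np.asarray(
            [i for i, k in enumerate(self.feature_kinds) if k == "snp"], dtype=int
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df.insert(0, "subject_id", [f"S{i:05d}" for i in range(self.n_subjects)])
        for j, c in enumerate(("age", "sex", "brain_volume"), start=1):
            df.insert(j, c, self.covariates[c].to_numpy())
        df["label"] = self.labels
        return df


def planted_truth(spec: CohortSpec) -> list[PlantedFeature]:
    """Informative features of ``spec`` with their effect directions.

    The direction of a planted ROI is the sign of its largest-magnitude
    per-class shift (atrophy < 0, enlargement > 0); the direction of a
    planted SNP is the sign of the AD-minus-CN allele-frequency difference.
    """
    out: list[PlantedFeature] = []
    for idx in sorted(spec.planted_roi):
        shifts = [spec.roi_shift(idx, c) for c in CLASSES]
        peak = max(shifts, key=abs)
        if peak == 0.0:
            continue
        out.append(
            PlantedFeature(int(idx), f"roi_{idx:03d}", "roi", 1 if peak > 0 else -1)
        )
    for idx in sorted(spec.planted_snp):
        delta = spec.snp_freq(idx, CLASSES[-1]) - spec.snp_freq(idx, CLASSES[0])
        if delta == 0.0:
            continue
        out.append(
            PlantedFeature(
                spec.n_roi + int(idx),
                f"snp_{idx:03d}",
                "snp",
                1 if delta > 0 else -1,
            )
        )
    return out


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw one cohort realisation; bit-reproducible given ``spec.seed``.

    ROI feature = covariate effect + class shift (in units of ``noise_sd``)
    + Gaussian noise.  SNP genotype = (sum of two Bernoulli alleles at the
    class frequency) / 2.  Covariates: age ~ U(60, 86), sex ~ Bernoulli(0.5),
    brain volume ~ N(0, 1) in arbitrary standardised units.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    labels = np.repeat(CLASSES, spec.n_per_class)

    age = rng.uniform(60.0, 86.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    brain_volume = rng.normal(0.0, 1.0, size=n)
    cov = np.column_stack([age, sex, brain_volume])

    X = np.empty((n, spec.n_roi + spec.n_snp), dtype=float)
    class_of = {c: labels == c for c in CLASSES}

    for j in range(spec.n_roi):
        col = cov @ spec.covariate_coefs(j)
        col = col + rng.normal(0.0, spec.noise_sd, size=n)
        for c in CLASSES:
            shift = spec.roi_shift(j, c)
            if shift:
                col[class_of[c]] += shift * spec.noise_sd
        X[:, j] = col

    for j in range(spec.n_snp):
        p = np.empty(n)
        for c in CLASSES:
            p[class_of[c]] = spec.snp_freq(j, c)
        X[:, spec.n_roi + j] = rng.binomial(2, p, size=n) / 2.0

    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "brain_volume": brain_volume}
    )
    return Cohort(
        features=X,
        labels=labels,
        covariates=covariates,
        feature_names=spec.feature_names,
        feature_kinds=spec.feature_kinds,
        truth=planted_truth(spec),
        spec=spec,
    )


def default_cohort_spec(seed: int = 0, scale: float = 1.0) -> CohortSpec:
    """The package's reference study conditions.

    Twelve planted ROIs model graded neurodegeneration: negative shifts for
    atrophying regions (hippocampus/temporal-like), positive shifts for
    ventricular enlargement, with MCI effects roughly half the AD effects.
    Six planted SNPs model risk alleles whose frequency rises from CN
    through MCI to AD (ApoE-like gradient).  ``scale`` shrinks the class
    sizes proportionally for desk-scale runs.
    """
    n_per_class = tuple(max(8, round(n * scale)) for n in (449, 740, 274))
    atrophy = {i: {"MCI": -0.5 * s, "AD": -s} for i, s in
               zip(range(0, 8), (1.5, 1.4, 1.2, 1.1, 1.0, 0.9, 0.8, 0.7))}
    enlarge = {i: {"MCI": 0.5 * s, "AD": s} for i, s in
               zip(range(8, 12), (1.3, 1.1, 0.9, 0.8))}
    snps = {i: {"CN": 0.10, "MCI": 0.25, "AD": 0.40} for i in range(6)}
    return CohortSpec(
        n_per_class=n_per_class,
        planted_roi={**atrophy, **enlarge},
        planted_snp=snps,
        covariate_effects=(-0.02, 0.3, 0.5),
        noise_sd=1.0,
        seed=seed,
    )
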
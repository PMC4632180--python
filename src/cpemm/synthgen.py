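"""Synthetic multiclass clinical-style tabular data with planted structure.

The generator emulates the shape of the neuropsychological /
neuroimaging extracts the pipeline targets: a few hundred instances,
2-3 imbalanced diagnostic classes (NL / MCI / AD), and a feature roster
mixing a small informative core with redundant near-copies and a large
noise majority, plus missing-completely-at-random cells.

* informative feature j: per class c, values ~ Normal(mu_cj, 1) where
  the class means are spaced ``effect`` standard deviations apart along
  a class ordering permuted independently per feature (so no single
  feature separates all classes the same way);
* redundant feature: one informative source feature plus
  Normal(0, redundancy_noise) — carrying no extra information, so a
  minimal optimal subset excludes it;
* noise feature: Normal(0, 1) independent of the class.

Ground truth (which features are which) is returned alongside the data
for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .dataio import Dataset, FeatureMeta

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "generate_two_class",
           "write_ground_truth"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Defaults mirror a 750 x 48 three-class clinical extract
    (NL:200, MCI:400, AD:150) with a 6/6/36 informative/redundant/noise
    split and class-mean separation of 1.5 sd."""

    class_counts: tuple[tuple[str, int], ...] = (("NL", 200), ("MCI", 400), ("AD", 150))
    n_informative: int = 6
    n_redundant: int = 6
    n_noise: int = 36
    effect: float = 1.5               # class-mean separation, in sd units
    redundancy_noise: float = 0.1
    missing_rate: float = 0.05
    nominal_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(self.class_counts)
        if len(counts) < 2:
            raise ValueError("need at least 2 classes")
        if any(c <= 0 for c in counts.values()):
            raise ValueError("class counts must be positive")
        if self.n_informative < 1 or self.n_redundant < 0 or self.n_noise < 0:
            raise ValueError("invalid feature counts")
        if self.effect < 0:
            raise ValueError("effect must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.nominal_fraction <= 1:
            raise ValueError("nominal_fraction must be in [0, 1]")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.class_counts)

    @property
    def n_instances(self) -> int:
        return sum(n for _, n in self.class_counts)

    @property
    def d(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


@dataclass
class GroundTruth:
    informative_mask: np.ndarray
    redundant_mask: np.ndarray
    noise_mask: np.ndarray
    redundant_source: dict[int, int]           # redundant column -> informative column
    class_means: np.ndarray                    # (k, n_informative)

    def __post_init__(self) -> None:
        overlap = (self.informative_mask & self.redundant_mask) | \
                  (self.informative_mask & self.noise_mask) | \
                  (self.redundant_mask & self.noise_mask)
        if overlap.any():
            raise ValueError("feature role masks must be disjoint")
        if not (self.informative_mask | self.redundant_mask | self.noise_mask).all():
            raise ValueError("feature role masks must cover every feature")


def generate(spec: SyntheticSpec | None = None) -> tuple[Dataset, GroundTruth]:
    """Draw one dataset plus its ground truth; bit-identical per seed."""
    if spec is None:
        spec = SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    classes = spec.classes
    k = len(classes)
    n = spec.n_instances
    d = spec.d

    y_codes = np.concatenate([np.full(cnt, ci, dtype=int)
                              for ci, (_, cnt) in enumerate(spec.class_counts)])
    rng.shuffle(y_codes)
    y = np.array([classes[c] for c in y_codes], dtype=object)

    X = np.empty((n, d))
    class_means = np.zeros((k, spec.n_informative))
    centred = (np.arange(k) - (k - 1) / 2) * spec.effect
    for j in range(spec.n_informative):
        perm = rng.permutation(k)              # per-feature class ordering
        mu = centred[perm]
        class_means[:, j] = mu
        X[:, j] = rng.normal(mu[y_codes], 1.0)

    redundant_source: dict[int, int] = {}
    for r in range(spec.n_redundant):
        col = spec.n_informative + r
        src = r % spec.n_informative
        redundant_source[col] = src
        X[:, col] = X[:, src] + rng.normal(0.0, spec.redundancy_noise, size=n)

    noise_start = spec.n_informative + spec.n_redundant
    X[:, noise_start:] = rng.normal(0.0, 1.0, size=(n, spec.n_noise))

    features: list[FeatureMeta] = (
        [FeatureMeta(f"inf_{j:02d}", "numeric") for j in range(spec.n_informative)]
        + [FeatureMeta(f"red_{j:02d}", "numeric") for j in range(spec.n_redundant)]
        + [FeatureMeta(f"noise_{j:02d}", "numeric") for j in range(spec.n_noise)]
    )

    # optional nominal features by quantile-binning randomly chosen columns
    n_nominal = int(round(spec.nominal_fraction * d))
    if n_nominal:
        cats = ("low", "mid", "high")
        for j in sorted(rng.choice(d, size=n_nominal, replace=False)):
            q = np.quantile(X[:, j], [1 / 3, 2 / 3])
            X[:, j] = np.digitize(X[:, j], q).astype(float)
            features[j] = FeatureMeta(features[j].name, "nominal", categories=cats)

    if spec.missing_rate > 0:
        holes = rng.random((n, d)) < spec.missing_rate
        X[holes] = np.nan

    ds = Dataset(X=X, y=y, classes=classes, features=features).refresh_missing_fractions()
    inf_mask = np.zeros(d, dtype=bool)
    inf_mask[: spec.n_informative] = True
    red_mask = np.zeros(d, dtype=bool)
    red_mask[spec.n_informative:noise_start] = True
    noise_mask = np.zeros(d, dtype=bool)
    noise_mask[noise_start:] = True
    gt = GroundTruth(informative_mask=inf_mask, redundant_mask=red_mask,
                     noise_mask=noise_mask, redundant_source=redundant_source,
                     class_means=class_means)
    return ds, gt


TWO_CLASS_DEFAULTS = dict(
    class_counts=(("NL", 400), ("AD", 250)),
    n_informative=12, n_redundant=12, n_noise=84,
)


def generate_two_class(spec: SyntheticSpec | None = None) -> tuple[Dataset, GroundTruth]:
    """Two-class variant, defaulting to a 650 x 108 NL-vs-AD extract."""
    if spec is None:
        spec = SyntheticSpec(**TWO_CLASS_DEFAULTS)
    if len(spec.classes) != 2:
        raise ValueError("generate_two_class needs exactly 2 classes")
    return generate(spec)


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Persist ground truth as a small key: value text file."""
    lines = [
        "informative\t" + "".join("1" if b else "0" for b in gt.informative_mask),
        "redundant\t" + "".join("1" if b else "0" for b in gt.redundant_mask),
        "noise\t" + "".join("1" if b else "0" for b in gt.noise_mask),
    ]
    for col, src in sorted(gt.redundant_source.items()):
        lines.append(f"redundant_source\t{col}\t{src}")
    Path(path).write_text("\n".join(lines) + "\n")
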
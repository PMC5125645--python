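"""SHAPE reactivity simulation and pseudo-free-energy conversion.

SHAPE probing reports a nonnegative reactivity per nucleotide that tracks
backbone flexibility: unpaired nucleotides tend to react strongly, paired
ones weakly, with helix-terminal pairs in between.  Given a candidate
structure, reactivities are drawn independently per position from a
class-conditional distribution (unpaired / stacked / helix-end), emulating
what a probing experiment would measure if the candidate were the true fold.

Reactivities — simulated or experimental — convert to per-site pseudo-free
energies by the standard log-linear soft constraint

    dG_i = m * ln(SR(i) + 1) + b        (kcal/mol)

with default slope m = 2.6 and intercept b = -0.8, and the structure-level
pseudo-energy weights stacked nucleotides twice:

    PE = 2 * sum_{i stacked} dG_i + sum_{i helix-end} dG_i.

Unpaired and missing-data positions contribute nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy import stats

from .rna_model import SecondaryStructure, StructuralClass, classify_positions

#: file sentinel for a missing reactivity
MISSING_SENTINEL = -999.0


@dataclass(frozen=True)
class PseudoEnergyParams:
    """Slope/intercept of the reactivity-to-energy transform (kcal/mol).

    ``b`` is the pseudo-energy of a paired nucleotide with zero reactivity
    (a stabilising bonus); ``m`` scales the penalty for pairing a highly
    reactive nucleotide.
    """

    m: float = 2.6
    b: float = -0.8

    def __post_init__(self) -> None:
        if not (math.isfinite(self.m) and math.isfinite(self.b)):
            raise ValueError("pseudo-energy parameters must be finite")


@dataclass(frozen=True)
class ShapeProfile:
    """Per-position reactivities; NaN marks missing data."""

    values: np.ndarray
    source: str = "simulated"  # or "experimental"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("reactivity profile must be one-dimensional")
        present = arr[~np.isnan(arr)]
        if np.any(present < 0):
            raise ValueError("reactivities must be nonnegative (clamp first)")
        object.__setattr__(self, "values", arr)
        arr.setflags(write=False)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ClassDistribution:
    """A univariate reactivity distribution: family name + parameters.

    Supported families (parameters):
      - ``point``: [value] — degenerate, mostly for tests
      - ``exponential``: [scale]
      - ``gamma``: [shape, scale]
      - ``lognormal``: [sigma, scale]  (scipy ``lognorm(s=sigma, scale)``)
      - ``gev``: [shape, loc, scale]   (scipy ``genextreme``)

    Sampled values are truncated at zero, since reactivities are nonnegative.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        self._frozen()  # validate family/arity eagerly

    def _frozen(self):
        fam, p = self.family, self.params
        if fam == "point":
            if len(p) != 1 or p[0] < 0:
                raise ValueError(f"point family takes one nonnegative value, got {p}")
            return None
        if fam == "exponential":
            (scale,) = p
            return stats.expon(scale=scale)
        if fam == "gamma":
            a, scale = p
            return stats.gamma(a, scale=scale)
        if fam == "lognormal":
            s, scale = p
            return stats.lognorm(s, scale=scale)
        if fam == "gev":
            c, loc, scale = p
            return stats.genextreme(c, loc=loc, scale=scale)
        raise ValueError(f"unknown distribution family {self.family!r}")

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "point":
            return np.full(size, self.params[0])
        draws = self._frozen().rvs(size=size, random_state=rng)
        return np.maximum(np.asarray(draws, dtype=float), 0.0)

    def mean(self) -> float:
        if self.family == "point":
            return self.params[0]
        return float(self._frozen().mean())

    @classmethod
    def fit(cls, family: str, samples: np.ndarray) -> "ClassDistribution":
        """Maximum-likelihood re-fit of a family to observed reactivities."""
        x = np.asarray(samples, dtype=float)
        x = x[~np.isnan(x)]
        if len(x) == 0:
            raise ValueError("cannot fit a distribution to zero samples")
        if family == "point":
            return cls("point", (float(np.mean(x)),))
        if family == "exponential":
            loc, scale = stats.expon.fit(x, floc=0.0)
            return cls("exponential", (scale,))
        if family == "gamma":
            a, loc, scale = stats.gamma.fit(x, floc=0.0)
            return cls("gamma", (a, scale))
        if family == "lognormal":
            s, loc, scale = stats.lognorm.fit(x[x > 0], floc=0.0)
            return cls("lognormal", (s, scale))
        if family == "gev":
            c, loc, scale = stats.genextreme.fit(x)
            return cls("gev", (c, loc, scale))
        raise ValueError(f"unknown distribution family {family!r}")


@dataclass(frozen=True)
class ShapeDistributionSet:
    """One reactivity distribution per structural class."""

    by_class: Mapping[StructuralClass, ClassDistribution]

    def __post_init__(self) -> None:
        missing = set(StructuralClass) - set(self.by_class)
        if missing:
            raise ValueError(f"distributions missing for classes: {missing}")
        object.__setattr__(self, "by_class", dict(self.by_class))

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping]) -> "ShapeDistributionSet":
        by_class = {
            StructuralClass(name): ClassDistribution(
                family=spec["family"], params=tuple(spec["params"])
            )
            for name, spec in d.items()
        }
        return cls(by_class=by_class)

    def to_dict(self) -> dict:
        return {
            c.value: {"family": d.family, "params": list(d.params)}
            for c, d in self.by_class.items()
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ShapeDistributionSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def default(cls) -> "ShapeDistributionSet":
        """Packaged default distributions (see docs/methods.md for provenance)."""
        ref = resources.files("esdfold").joinpath("data/shape_distributions.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text()))

    @classmethod
    def point_masses(
        cls, unpaired: float = 1.0, stacked: float = 0.0, helix_end: float = 0.2
    ) -> "ShapeDistributionSet":
        """Degenerate set for deterministic runs and tests."""
        return cls(
            by_class={
                StructuralClass.UNPAIRED: ClassDistribution("point", (unpaired,)),
                StructuralClass.STACKED: ClassDistribution("point", (stacked,)),
                StructuralClass.HELIX_END: ClassDistribution("point", (helix_end,)),
            }
        )


def simulate_shape(
    structure: SecondaryStructure,
    dists: ShapeDistributionSet,
    rng: np.random.Generator,
) -> ShapeProfile:
    """Draw one reactivity per position from its class-conditional distribution."""
    labels = classify_positions(structure)
    values = np.empty(structure.n)
    for cls in StructuralClass:
        idx = [i for i, lab in enumerate(labels) if lab is cls]
        if idx:
            values[idx] = dists.by_class[cls].sample(len(idx), rng)
    return ShapeProfile(values=values, source="simulated")


def fit_distribution_set(
    structure: SecondaryStructure,
    profile: ShapeProfile,
    families: Mapping[StructuralClass, str] | None = None,
) -> ShapeDistributionSet:
    """Re-derive class distributions from a (structure, reactivity) training set."""
    if len(profile) != structure.n:
        raise ValueError("profile length does not match structure length")
    if families is None:
        families = {
            StructuralClass.UNPAIRED: "gev",
            StructuralClass.STACKED: "exponential",
            StructuralClass.HELIX_END: "exponential",
        }
    labels = classify_positions(structure)
    by_class = {}
    for cls in StructuralClass:
        samples = profile.values[[i for i, lab in enumerate(labels) if lab is cls]]
        by_class[cls] = ClassDistribution.fit(families[cls], samples)
    return ShapeDistributionSet(by_class=by_class)


def pseudo_energy_per_site(sr: float, params: PseudoEnergyParams) -> float:
    """dG_i = m * ln(SR + 1) + b; a missing reactivity contributes zero."""
    if sr is None or (isinstance(sr, float) and math.isnan(sr)):
        return 0.0
    if sr < 0:
        raise ValueError(f"reactivity {sr} is negative")
    return params.m * math.log(sr + 1.0) + params.b


def pseudo_energy_total(
    structure: SecondaryStructure,
    profile: ShapeProfile,
    params: PseudoEnergyParams,
) -> float:
    """PE = 2 * sum(stacked dG_i) + sum(helix-end dG_i), kcal/mol."""
    if len(profile) != structure.n:
        raise ValueError(
            f"profile length {len(profile)} != structure length {structure.n}"
        )
    labels = classify_positions(structure)
    pe = 0.0
    for i, lab in enumerate(labels):
        if lab is StructuralClass.UNPAIRED:
            continue
        dg = pseudo_energy_per_site(float(profile.values[i]), params)
        pe += 2.0 * dg if lab is StructuralClass.STACKED else dg
    return pe


def read_shape(path: str | Path, clamp_negative: bool = True) -> ShapeProfile:
    """Read a two-column ``index reactivity`` file; -999 marks missing data."""
    entries: dict[int, float] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        cols = ln.split()
        if len(cols) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'index reactivity'")
        try:
            idx, val = int(cols[0]), float(cols[1])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric row {ln!r}")
        if idx < 1:
            raise ValueError(f"{path}:{lineno}: index {idx} < 1")
        if idx in entries:
            raise ValueError(f"{path}:{lineno}: duplicate index {idx}")
        entries[idx] = val
    n = max(entries) if entries else 0
    values = np.full(n, np.nan)
    for idx, val in entries.items():
        if val == MISSING_SENTINEL:
            continue
        if val < 0:
            if not clamp_negative:
                raise ValueError(f"{path}: negative reactivity {val} at index {idx}")
            import warnings

            warnings.warn(
                f"{path}: negative reactivity {val} at index {idx} clamped to 0"
            )
            val = 0.0
        values[idx - 1] = val
    return ShapeProfile(values=values, source="experimental")


def write_shape(path: str | Path, profile: ShapeProfile) -> None:
    lines = []
    for i, val in enumerate(profile.values, start=1):
        out = MISSING_SENTINEL if np.isnan(val) else float(val)
        lines.append(f"{i} {out!r}")
    Path(path).write_text("\n".join(lines) + "\n")
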
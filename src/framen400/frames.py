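"""Sorted stochastic frames: attribute chains, features, and the information ordering.

A frame of some sort assigns each attribute chain in its signature a finite
value space carrying a probability distribution.  Chains whose value is known
(bottom-up or by definition) are *fixed*: their distribution is degenerate.
The set of fixed features of a frame is its feature set; one frame subsumes
another when everything the first commits to, the second commits to as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

__all__ = [
    "PROB_TOL",
    "Sort",
    "SortRegistry",
    "Attribute",
    "Chain",
    "Feature",
    "StochasticFrame",
    "FrameError",
    "SignatureError",
    "UndefinedProbabilityError",
    "feature_set",
    "subsumes",
    "extension_probability",
]

#: tolerance for distributions summing to one
PROB_TOL = 1e-9


class FrameError(ValueError):
    """Base error for malformed frames."""


class SignatureError(FrameError):
    """Two frames do not share a compatible signature."""


class UndefinedProbabilityError(FrameError):
    """An extension fixes a chain for which the base frame has no distribution."""


@dataclass(frozen=True)
class Sort:
    """A sort label, optionally below a parent sort (e.g. tree below plant)."""

    name: str
    parent: Optional[str] = None


class SortRegistry:
    """Acyclic parent-link hierarchy over sorts."""

    def __init__(self, sorts: Iterable[Sort] = ()):
        self._parent: dict[str, Optional[str]] = {}
        for s in sorts:
            self.add(s)

    def add(self, sort: Sort) -> None:
        if sort.name in self._parent:
            raise FrameError(f"duplicate sort {sort.name!r}")
        self._parent[sort.name] = sort.parent
        # reject cycles eagerly
        seen = {sort.name}
        cur = sort.parent
        while cur is not None:
            if cur in seen:
                raise FrameError(f"cyclic sort hierarchy at {cur!r}")
            seen.add(cur)
            cur = self._parent.get(cur)

    def __contains__(self, name: str) -> bool:
        return name in self._parent

    def is_subsort(self, name: str, ancestor: str) -> bool:
        """True if `name` equals `ancestor` or lies below it."""
        cur: Optional[str] = name
        while cur is not None:
            if cur == ancestor:
                return True
            cur = self._parent.get(cur)
        return False


@dataclass(frozen=True)
class Attribute:
    """An attribute with its finite, ordered value space."""

    name: str
    value_space: tuple[str, ...]

    def __post_init__(self):
        if len(self.value_space) < 2:
            raise FrameError(f"attribute {self.name!r} needs >=2 values")
        if len(set(self.value_space)) != len(self.value_space):
            raise FrameError(f"attribute {self.name!r} has duplicate values")


@dataclass(frozen=True, order=True)
class Chain:
    """An attribute chain, e.g. DANGER.LOCATION, over a flat scenario signature."""

    segments: tuple[str, ...]

    def __post_init__(self):
        if not self.segments:
            raise FrameError("empty attribute chain")

    @classmethod
    def parse(cls, dotted: str) -> "Chain":
        return cls(tuple(dotted.split(".")))

    def prefixed(self, *prefix: str) -> "Chain":
        """Concatenate role/context segments in front of this chain."""
        return Chain(tuple(prefix) + self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def __str__(self) -> str:
        return ".".join(self.segments)


@dataclass(frozen=True, order=True)
class Feature:
    """An attribute chain paired with one value from its terminal value space."""

    chain: Chain
    value: str

    def __str__(self) -> str:
        return f"{self.chain}={self.value}"


def _validate_dist(chain: Chain, space: tuple[str, ...], dist: Mapping[str, float]) -> dict[str, float]:
    unknown = set(dist) - set(space)
    if unknown:
        raise FrameError(f"chain {chain}: values {sorted(unknown)} not in value space")
    full = {v: float(dist.get(v, 0.0)) for v in space}
    if any(p < -PROB_TOL or p > 1 + PROB_TOL for p in full.values()):
        raise FrameError(f"chain {chain}: probabilities outside [0, 1]")
    total = sum(full.values())
    if abs(total - 1.0) > PROB_TOL:
        raise FrameError(f"chain {chain}: distribution sums to {total}, not 1")
    return full


@dataclass(frozen=True)
class StochasticFrame:
    """A frame of a given sort over a signature of chains.

    Parameters
    ----------
    sort :
        Name of the frame's sort.
    signature :
        Map chain -> value space (the attributes defined for this frame).
    distributions :
        Map chain -> value -> probability for unfixed chains; degenerate
        distributions are allowed and treated as fixed.
    fixed :
        Features whose value is observed; their chains need no distribution
        entry (a degenerate one is implied).
    """

    sort: str
    signature: Mapping[Chain, tuple[str, ...]]
    distributions: Mapping[Chain, Mapping[str, float]] = field(default_factory=dict)
    fixed: frozenset[Feature] = frozenset()

    def __post_init__(self):
        sig = dict(self.signature)
        dists = {}
        for chain, dist in self.distributions.items():
            if chain not in sig:
                raise FrameError(f"distribution for undeclared chain {chain}")
            dists[chain] = _validate_dist(chain, sig[chain], dist)
        fixed_chains = set()
        for feat in self.fixed:
            if feat.chain not in sig:
                raise FrameError(f"fixed feature on undeclared chain {feat.chain}")
            if feat.value not in sig[feat.chain]:
                raise FrameError(f"fixed value {feat.value!r} not in space of {feat.chain}")
            if feat.chain in fixed_chains:
                raise FrameError(f"chain {feat.chain} fixed to two values")
            fixed_chains.add(feat.chain)
            d = dists.get(feat.chain)
            if d is not None and abs(d.get(feat.value, 0.0) - 1.0) > PROB_TOL:
                raise FrameError(
                    f"chain {feat.chain} both fixed and carrying a non-degenerate distribution"
                )
        object.__setattr__(self, "signature", sig)
        object.__setattr__(self, "distributions", dists)

    # -- accessors ---------------------------------------------------------

    def chains(self) -> frozenset[Chain]:
        """All chains defined for this frame."""
        return frozenset(self.signature)

    def distribution(self, chain: Chain) -> dict[str, float]:
        """Probability vector over `chain`'s value space (degenerate if fixed)."""
        if chain not in self.signature:
            raise SignatureError(f"chain {chain} undefined for sort {self.sort!r}")
        for feat in self.fixed:
            if feat.chain == chain:
                return {v: 1.0 if v == feat.value else 0.0 for v in self.signature[chain]}
        if chain in self.distributions:
            return dict(self.distributions[chain])
        raise UndefinedProbabilityError(f"chain {chain} has no distribution")

    def probability(self, feature: Feature) -> float:
        return self.distribution(feature.chain)[feature.value]

    def is_fixed(self, chain: Chain) -> bool:
        if any(f.chain == chain for f in self.fixed):
            return True
        d = self.distributions.get(chain)
        return d is not None and any(abs(p - 1.0) <= PROB_TOL for p in d.values())

    def unfixed_chains(self) -> frozenset[Chain]:
        return frozenset(c for c in self.signature if not self.is_fixed(c))

    def fix(self, *features: Feature) -> "StochasticFrame":
        """Return a new frame with the given features observed (probability 1)."""
        new_fixed = dict((f.chain, f) for f in self.fixed)
        dists = dict(self.distributions)
        for feat in features:
            if feat.chain not in self.signature:
                raise SignatureError(f"cannot fix undeclared chain {feat.chain}")
            prev = new_fixed.get(feat.chain)
            if prev is not None and prev.value != feat.value:
                raise FrameError(f"chain {feat.chain} already fixed to {prev.value!r}")
            new_fixed[feat.chain] = feat
            dists.pop(feat.chain, None)
        return replace(self, distributions=dists, fixed=frozenset(new_fixed.values()))


# -- operations ------------------------------------------------------------


def feature_set(frame: StochasticFrame) -> frozenset[Feature]:
    """The function theta: all features whose chain is fixed in the frame."""
    feats = {f.chain: f for f in frame.fixed}
    for chain, dist in frame.distributions.items():
        if chain in feats:
            continue
        for value, p in dist.items():
            if abs(p - 1.0) <= PROB_TOL:
                feats[chain] = Feature(chain, value)
                break
    return frozenset(feats.values())


def subsumes(f1: StochasticFrame, f2: StochasticFrame,
             sorts: Optional[SortRegistry] = None) -> bool:
    """Information ordering: f1 below f2 iff f2 carries all of f1's commitments.

    Every chain defined in ``f1`` must be defined in ``f2`` and every fixed
    value of ``f1`` must be fixed identically in ``f2`` (sort-typed values may
    instead be fixed to a subsort when a registry is supplied).
    """
    if sorts is not None:
        if not (sorts.is_subsort(f2.sort, f1.sort) or sorts.is_subsort(f1.sort, f2.sort)):
            raise SignatureError(f"incompatible sorts {f1.sort!r} / {f2.sort!r}")
    for chain, space in f1.signature.items():
        if chain not in f2.signature:
            return False
        if tuple(f2.signature[chain]) != tuple(space):
            raise SignatureError(f"chain {chain} has differing value spaces")
    fs2 = {f.chain: f.value for f in feature_set(f2)}
    for feat in feature_set(f1):
        v2 = fs2.get(feat.chain)
        if v2 is None:
            return False
        if v2 != feat.value:
            if sorts is not None and v2 in sorts and feat.value in sorts:
                if sorts.is_subsort(v2, feat.value):
                    continue
            return False
    return True


def extension_probability(base: StochasticFrame, ext: StochasticFrame) -> float:
    """Probability of reaching `ext` from `base` under the product rule.

    Multiplies, over every chain fixed in ``ext`` but not in ``base``, the
    probability ``base`` assigns to the value chosen in ``ext``.  A scenario
    with correlated chains should supply an explicit joint table instead.
    """
    if not subsumes(base, ext):
        raise SignatureError("extension is not subsumed by base")
    base_feats = {f.chain: f.value for f in feature_set(base)}
    prob = 1.0
    for feat in feature_set(ext):
        if feat.chain in base_feats:
            continue
        if feat.chain not in base.distributions:
            raise UndefinedProbabilityError(
                f"chain {feat.chain} fixed in extension but has no distribution in base"
            )
        prob *= base.distributions[feat.chain][feat.value]
    return prob
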
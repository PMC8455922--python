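"""Category concepts: default inferences above a probability threshold,
context-(in)dependent features, prenominal-evidence revision, contrast classes.

A category concept situates a category in a context.  Its default feature set
contains, per declared chain, the value whose conditional probability is the
unique maximum over the chain's value space and exceeds the threshold r
("Cs normally have V").
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .frames import (
    PROB_TOL,
    Chain,
    Feature,
    FrameError,
    StochasticFrame,
    _validate_dist,
)

__all__ = [
    "CategoryConcept",
    "PrenominalUpdate",
    "ContrastDeclaration",
    "Membership",
    "default_inferences",
    "is_member",
    "apply_prenominal",
    "contrast_classes",
]

log = logging.getLogger(__name__)


class Membership(enum.Enum):
    IN = "in"
    NEGATED_IN = "negated_in"
    UNDEFINED_ATTRIBUTE = "undefined_attribute"
    NEITHER = "neither"


@dataclass(frozen=True)
class ContrastDeclaration:
    """Which antecedent chain licenses the context-dependent defaults, and the
    per-alternative replacement distributions that define each contrast class.

    ``alternatives`` maps each non-actual antecedent value to the chain
    distributions holding in the contrast class it induces.
    """

    antecedent: Chain
    actual_value: str
    alternatives: Mapping[str, Mapping[Chain, Mapping[str, float]]]


@dataclass(frozen=True)
class CategoryConcept:
    """A category as used in context: a stochastic frame plus the chains whose
    defaults are context-independent vs. licensed by the context."""

    name: str
    frame: StochasticFrame
    context_independent: frozenset[Chain] = frozenset()
    context_dependent: frozenset[Chain] = frozenset()
    threshold_r: float = 0.5
    contrast: Optional[ContrastDeclaration] = None

    def __post_init__(self):
        overlap = self.context_independent & self.context_dependent
        if overlap:
            raise FrameError(f"chains both context-independent and -dependent: {sorted(map(str, overlap))}")
        if not (0.0 <= self.threshold_r < 1.0):
            raise FrameError(f"threshold r={self.threshold_r} outside [0, 1)")
        for chain in self.context_independent | self.context_dependent:
            if chain not in self.frame.signature:
                raise FrameError(f"declared chain {chain} undefined in frame of {self.name!r}")

    @property
    def chains(self) -> frozenset[Chain]:
        return self.context_independent | self.context_dependent

    def defines(self, chain: Chain) -> bool:
        return chain in self.frame.signature

    def probability(self, feature: Feature) -> float:
        return self.frame.probability(feature)


@dataclass(frozen=True)
class PrenominalUpdate:
    """Bottom-up evidence from a prenominal element plus the stipulated
    revisions it induces on correlated chains."""

    evidence: Feature
    correlated_revisions: Mapping[Chain, Mapping[str, float]] = field(default_factory=dict)


def default_inferences(c: CategoryConcept) -> frozenset[Feature]:
    """The default feature set: per declared chain, the value with the unique
    maximal conditional probability, provided it exceeds the threshold r.

    A tied maximum above r licenses no single normal value; the chain is
    skipped with a warning.
    """
    out = []
    for chain in sorted(c.chains):
        dist = c.frame.distribution(chain)
        best = max(dist.values())
        if best <= c.threshold_r:
            continue
        winners = [v for v, p in dist.items() if abs(p - best) <= PROB_TOL]
        if len(winners) > 1:
            log.warning("concept %s: tied maximum on chain %s, no default emitted", c.name, chain)
            continue
        out.append(Feature(chain, winners[0]))
    return frozenset(out)


def is_member(c: CategoryConcept, f: Feature) -> Membership:
    """Locate a feature relative to a concept's default feature set."""
    if not c.defines(f.chain):
        return Membership.UNDEFINED_ATTRIBUTE
    defaults = default_inferences(c)
    if f in defaults:
        return Membership.IN
    if any(d.chain == f.chain and d.value != f.value for d in defaults):
        return Membership.NEGATED_IN
    return Membership.NEITHER


def apply_prenominal(c: CategoryConcept, u: PrenominalUpdate) -> CategoryConcept:
    """Revise a concept with prenominal evidence.

    The evidence chain is forced to probability 1; each chain listed in the
    update's correlated revisions gets its replacement distribution; every
    other chain is untouched.
    """
    if not c.defines(u.evidence.chain):
        raise FrameError(f"evidence chain {u.evidence.chain} undefined in {c.name!r}")
    for chain, dist in u.correlated_revisions.items():
        if not c.defines(chain):
            raise FrameError(f"revision chain {chain} undefined in {c.name!r}")
        _validate_dist(chain, c.frame.signature[chain], dist)

    dists = {ch: dict(d) for ch, d in c.frame.distributions.items()}
    for chain, dist in u.correlated_revisions.items():
        dists[chain] = {v: float(dist.get(v, 0.0)) for v in c.frame.signature[chain]}
    dists.pop(u.evidence.chain, None)
    fixed = frozenset(f for f in c.frame.fixed if f.chain != u.evidence.chain) | {u.evidence}
    frame = replace(c.frame, distributions=dists, fixed=fixed)
    return replace(c, frame=frame)


def contrast_classes(c: CategoryConcept) -> list[CategoryConcept]:
    """Sibling concepts obtained by re-assigning the antecedent chain that
    licenses the context-dependent defaults, with the declared replacement
    distributions.  Without a declaration the list is empty and diagnosticity
    must be stipulated."""
    if c.contrast is None:
        return []
    out = []
    for alt_value, revisions in sorted(c.contrast.alternatives.items()):
        dists = {ch: dict(d) for ch, d in c.frame.distributions.items()}
        for chain, dist in revisions.items():
            if chain not in c.frame.signature:
                raise FrameError(f"contrast revision on undeclared chain {chain}")
            dists[chain] = _validate_dist(chain, c.frame.signature[chain], dist)
        frame = replace(c.frame, distributions=dists)
        out.append(replace(c, name=f"{c.name}|{c.contrast.antecedent}={alt_value}", frame=frame))
    return out
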
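"""Plausibility side: min-rule similarity of values, cue-validity and
diagnosticity of attributes, and the typicality of the critical word's
category relative to the argument concept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .concepts import CategoryConcept, contrast_classes, default_inferences
from .frames import PROB_TOL, Chain, Feature, FrameError, SignatureError

__all__ = [
    "DiagnosticityProfile",
    "TypicalityReport",
    "similarity",
    "cue_validity",
    "attribute_d",
    "diagnosticity",
    "typicality",
]

log = logging.getLogger(__name__)


class DegenerateProfileError(FrameError):
    """All attribute d-values are zero; no profile can be normalized."""


@dataclass(frozen=True)
class DiagnosticityProfile:
    """Normalized per-chain attribute weights, either stipulated by the
    scenario or computed from cue-validities against contrast classes."""

    weights: Mapping[Chain, float]
    source: str = "computed"  # "stipulated" | "computed"

    def __post_init__(self):
        if self.source not in ("stipulated", "computed"):
            raise FrameError(f"unknown profile source {self.source!r}")
        total = sum(self.weights.values())
        if abs(total - 1.0) > PROB_TOL:
            raise FrameError(f"diagnosticity weights sum to {total}, not 1")
        object.__setattr__(self, "weights", dict(self.weights))


@dataclass(frozen=True)
class TypicalityReport:
    """Per-value similarity breakdown plus the raw and normalized scores."""

    per_feature: Mapping[Feature, tuple[float, float, float]]  # sim, diag, product
    raw: float
    normalized: float


def similarity(c1: CategoryConcept, c2: CategoryConcept, f: Feature) -> float:
    """min(P(VA|c1), P(VA|c2)): a value counts only as strongly as the less
    committed of the two categories."""
    if not c1.defines(f.chain) or not c2.defines(f.chain):
        raise SignatureError(f"chain {f.chain} undefined in one of the concepts")
    return min(c1.probability(f), c2.probability(f))


def _uniform_priors(k: int) -> tuple[float, ...]:
    return tuple(1.0 / k for _ in range(k))


def cue_validity(c: CategoryConcept, contrasts: Sequence[CategoryConcept],
                 f: Feature, priors: Optional[Sequence[float]] = None) -> float:
    """Reversed conditional P(c | VA) by Bayes' rule against contrast classes.

    Priors default to uniform over {c} ∪ contrasts.  If the feature is
    impossible in every class the value is undefined; 0 is returned with a
    warning.
    """
    classes = [c, *contrasts]
    if priors is None:
        priors = _uniform_priors(len(classes))
    if len(priors) != len(classes):
        raise ValueError("one prior per class required")
    if abs(sum(priors) - 1.0) > PROB_TOL:
        raise ValueError(f"priors sum to {sum(priors)}, not 1")
    likelihoods = [cls.probability(f) for cls in classes]
    denom = sum(l * p for l, p in zip(likelihoods, priors))
    if denom == 0.0:
        log.warning("cue-validity undefined: %s impossible in every class", f)
        return 0.0
    return likelihoods[0] * priors[0] / denom


def attribute_d(c: CategoryConcept, contrasts: Sequence[CategoryConcept],
                chain: Chain, priors: Optional[Sequence[float]] = None) -> float:
    """d(C, A): maximum cue-validity over the chain's value space."""
    space = c.frame.signature.get(chain)
    if space is None:
        raise SignatureError(f"chain {chain} undefined in {c.name!r}")
    return max(cue_validity(c, contrasts, Feature(chain, v), priors) for v in space)


def diagnosticity(c: CategoryConcept, contrasts: Sequence[CategoryConcept],
                  chains: Sequence[Chain],
                  priors: Optional[Sequence[float]] = None,
                  stipulated: Optional[Mapping[Chain, float]] = None) -> DiagnosticityProfile:
    """Normalized attribute weights.

    Stipulated weights, when the scenario provides them, are returned
    verbatim; otherwise each chain's d-value is normalized over the given
    chains.
    """
    if stipulated is not None:
        return DiagnosticityProfile(weights=dict(stipulated), source="stipulated")
    if not chains:
        raise FrameError("diagnosticity needs at least one attribute chain")
    d = {chain: attribute_d(c, contrasts, chain, priors) for chain in chains}
    total = sum(d.values())
    if total == 0.0:
        raise DegenerateProfileError("all attribute d-values are zero")
    return DiagnosticityProfile(weights={ch: v / total for ch, v in d.items()},
                                source="computed")


def typicality(c_arg: CategoryConcept, c_cw: CategoryConcept,
               profile: DiagnosticityProfile) -> TypicalityReport:
    """Diagnosticity-weighted sum of min-rule similarities.

    raw:
        For every profiled chain, sum the min-similarity over its full value
        space, weight by the chain's diagnosticity, and add up.
    normalized:
        Same sum restricted to the argument concept's default features,
        divided by the self-comparison (c_cw := c_arg) of that restricted
        sum — the context-sensitive variant; the restriction to licensed
        defaults is an interpretive choice.
    """
    per_feature: dict[Feature, tuple[float, float, float]] = {}
    raw = 0.0
    for chain, weight in sorted(profile.weights.items()):
        if not c_arg.defines(chain) or not c_cw.defines(chain):
            raise SignatureError(f"profiled chain {chain} undefined in a concept")
        for value in c_arg.frame.signature[chain]:
            feat = Feature(chain, value)
            sim = similarity(c_arg, c_cw, feat)
            per_feature[feat] = (sim, weight, weight * sim)
            raw += weight * sim

    defaults = default_inferences(c_arg)
    num = den = 0.0
    for feat in defaults:
        weight = profile.weights.get(feat.chain)
        if weight is None or not c_cw.defines(feat.chain):
            continue
        num += weight * similarity(c_arg, c_cw, feat)
        den += weight * c_arg.probability(feat)
    normalized = num / den if den > 0 else 0.0
    return TypicalityReport(per_feature=per_feature, raw=raw, normalized=normalized)
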
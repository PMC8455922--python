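"""Predictability side: surprisal, entropy over n-step frame extensions, and
entropy reduction between the pre-critical-word frame (t1) and the post-update
frame (t2).

Entropy is Shannon entropy over the distribution of complete extensions of the
current frame on its open context-dependent chains.  The log base defaults to
10 (configurable); all worked reference values assume base 10.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import entropy as _scipy_entropy

from .concepts import CategoryConcept, default_inferences
from .frames import Chain, Feature, FrameError, StochasticFrame, extension_probability
from .update import PartitionContractError, UpdatePartition

__all__ = [
    "ExtensionSet",
    "enumerate_extensions",
    "entropy",
    "entropy_reduction",
    "surprisal",
    "predictability_component",
    "ExtensionSizeError",
    "DEFAULT_EXTENSION_CAP",
]

DEFAULT_EXTENSION_CAP = 10**5


class ExtensionSizeError(FrameError):
    """Exhaustive extension product would exceed the configured cap."""


@dataclass(frozen=True)
class ExtensionSet:
    """All complete n-step extensions of a base frame with their probabilities."""

    base: StochasticFrame
    extensions: tuple[tuple[StochasticFrame, float], ...]
    depth_n: int

    @property
    def probabilities(self) -> tuple[float, ...]:
        return tuple(p for _, p in self.extensions)


def enumerate_extensions(base: StochasticFrame, chains: Iterable[Chain], n: int = 3,
                         cap: int = DEFAULT_EXTENSION_CAP) -> ExtensionSet:
    """Cross every given (unfixed) chain with its value space.

    Each extension fixes all given chains to one joint assignment; its
    probability is the product of the base frame's per-chain probabilities.
    """
    chains = sorted(set(chains))
    for chain in chains:
        if len(chain) > n:
            raise FrameError(f"chain {chain} longer than extension depth n={n}")
        if base.is_fixed(chain):
            raise FrameError(f"chain {chain} is already fixed in the base frame")

    size = math.prod(len(base.signature[c]) for c in chains) if chains else 1
    if size > cap:
        raise ExtensionSizeError(f"{size} extensions exceed cap {cap}")

    if not chains:
        return ExtensionSet(base, ((base, 1.0),), n)

    spaces = [base.signature[c] for c in chains]
    exts = []
    for assignment in itertools.product(*spaces):
        feats = tuple(Feature(c, v) for c, v in zip(chains, assignment))
        ext = base.fix(*feats)
        exts.append((ext, extension_probability(base, ext)))
    return ExtensionSet(base, tuple(exts), n)


def entropy(es: ExtensionSet, base: float = 10.0) -> float:
    """Shannon entropy of the extension distribution (0 log 0 := 0)."""
    return float(_scipy_entropy(es.probabilities, base=base))


def entropy_reduction(h1: float, h2: float) -> float:
    """Difference in entropy between t1 and t2."""
    return h1 - h2


def surprisal(p: float, base: float = 10.0) -> float:
    """Negative log probability; +inf at p = 0."""
    if p < 0.0 or p > 1.0 + 1e-12:
        raise ValueError(f"probability {p} outside [0, 1]")
    if p == 0.0:
        return math.inf
    return -math.log(p) / math.log(base)


def frame_at_t1(c_arg: CategoryConcept) -> StochasticFrame:
    """The minimal frame closed under context-independent default inferences."""
    defaults = default_inferences(c_arg)
    ci_defaults = [f for f in defaults if f.chain in c_arg.context_independent]
    return c_arg.frame.fix(*ci_defaults)


def predictability_component(c_arg: CategoryConcept, p: UpdatePartition,
                             chains: Iterable[Chain] | None = None, n: int = 3,
                             log_base: float = 10.0,
                             cap: int = DEFAULT_EXTENSION_CAP) -> tuple[float, float, float]:
    """Entropies at t1 and t2 plus their difference.

    t1 is the argument concept's frame closed under its context-independent
    defaults; t2 additionally fixes the confirmed and compatible features
    (compatible ones count as information gain: they can still be verified).
    Both entropies are taken over the remaining open context-dependent chains.
    """
    if p.failed:
        raise PartitionContractError("predictability undefined on a failed partition")
    t1 = frame_at_t1(c_arg)
    if chains is None:
        chains = [c for c in c_arg.context_dependent if not t1.is_fixed(c)]
    chains = sorted(set(chains))

    non_disconfirmed = [f for f in (p.confirmed | p.compatible) if f.chain in set(chains)]
    t2 = t1.fix(*non_disconfirmed)

    h1 = entropy(enumerate_extensions(t1, chains, n, cap), base=log_base)
    open_at_t2 = [c for c in chains if not t2.is_fixed(c)]
    h2 = entropy(enumerate_extensions(t2, open_at_t2, n, cap), base=log_base)
    return h1, h2, entropy_reduction(h1, h2)
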
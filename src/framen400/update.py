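"""Combining the argument concept with the critical word's concept.

``update_set`` partitions the argument concept's pre-activated features into
confirmed / compatible / disconfirmed, or fails when the critical word's
category does not define a pre-activated chain (e.g. animacy for "drawer").
``update_t`` then builds the resulting frame from the confirmed features and
the critical word's disconfirming defaults; merely compatible features are
not carried over.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .concepts import CategoryConcept, default_inferences
from .frames import Chain, Feature, StochasticFrame

__all__ = ["UpdatePartition", "update_set", "update_t", "PartitionContractError"]


class PartitionContractError(RuntimeError):
    """update_t called on a failed partition."""


@dataclass(frozen=True)
class UpdatePartition:
    """The triple (confirmed, compatible, disconfirmed) — or a failure."""

    confirmed: frozenset[Feature] = frozenset()
    compatible: frozenset[Feature] = frozenset()
    disconfirmed: frozenset[Feature] = frozenset()
    failed: bool = False
    failing_chains: frozenset[Chain] = frozenset()

    def __post_init__(self):
        if self.failed:
            if self.confirmed or self.compatible or self.disconfirmed:
                raise ValueError("failed partition must carry no feature sets")
            if not self.failing_chains:
                raise ValueError("failed partition must name failing chains")
        else:
            sets = (self.confirmed, self.compatible, self.disconfirmed)
            total = len(self.confirmed | self.compatible | self.disconfirmed)
            if total != sum(len(s) for s in sets):
                raise ValueError("partition sets are not pairwise disjoint")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.confirmed), len(self.compatible), len(self.disconfirmed))


def update_set(c_arg: CategoryConcept, c_cw: CategoryConcept) -> UpdatePartition:
    """Partition the argument concept's defaults against the critical word.

    For each default feature VA of ``c_arg``: confirmed if VA is also a
    default of ``c_cw``; disconfirmed if some rival value of A is a default
    of ``c_cw``; compatible otherwise.  The operation is partial: if any
    chain carrying a default of ``c_arg`` is undefined for ``c_cw`` the
    whole computation fails (a modeled outcome, not an exception).
    """
    arg_defaults = default_inferences(c_arg)
    failing = frozenset(f.chain for f in arg_defaults if not c_cw.defines(f.chain))
    if failing:
        return UpdatePartition(failed=True, failing_chains=failing)

    cw_defaults = default_inferences(c_cw)
    cw_by_chain = {f.chain: f for f in cw_defaults}
    conf, comp, disc = set(), set(), set()
    for feat in arg_defaults:
        rival = cw_by_chain.get(feat.chain)
        if rival is not None and rival.value == feat.value:
            conf.add(feat)
        elif rival is not None:
            disc.add(feat)
        else:
            comp.add(feat)
    return UpdatePartition(frozenset(conf), frozenset(comp), frozenset(disc))


def update_t(p: UpdatePartition, c_arg: CategoryConcept,
             c_cw: CategoryConcept) -> StochasticFrame:
    """The frame resulting from the second processing step.

    Its feature set is the confirmed features together with, for each
    disconfirmed chain, the critical word's own default value on that chain.
    Compatible features are not taken over.  Unfixed chains keep the critical
    word's distributions where it has any.
    """
    if p.failed:
        raise PartitionContractError("update_t is undefined on a failed partition")
    cw_defaults = {f.chain: f for f in default_inferences(c_cw)}
    carried = set(p.confirmed)
    for feat in p.disconfirmed:
        carried.add(cw_defaults[feat.chain])

    signature = dict(c_arg.frame.signature)
    for chain, space in c_cw.frame.signature.items():
        signature.setdefault(chain, space)
    fixed_chains = {f.chain for f in carried}
    dists = {
        chain: dict(c_cw.frame.distributions[chain])
        for chain in c_cw.frame.distributions
        if chain not in fixed_chains
    }
    return StochasticFrame(
        sort=c_cw.frame.sort,
        signature=signature,
        distributions=dists,
        fixed=frozenset(carried),
    )
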
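"""Combine the predictability and plausibility components into a predicted
N400 index, and the thematic-role extension for schema-based knowledge.

The combining function g is deliberately simple plumbing: a convex combination
of the complementary (rescaled) entropy reduction and the complementary
typicality,

    g = alpha * (1 - dH / dH_max) + beta * (1 - typ),   dH_max = H(t1),

strictly decreasing in both arguments for positive weights.  When there is
nothing to reduce (H(t1) = 0) the predictability term is defined as 0.  Any
monotone g is admissible; every report exposes the raw components so callers
can substitute their own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .concepts import CategoryConcept, apply_prenominal, default_inferences
from .config import ConfigError, RunConfig
from .frames import Chain, Feature
from .information import predictability_component
from .scenarios import ScenarioSpec
from .typicality import DiagnosticityProfile, typicality
from .update import UpdatePartition, update_set

__all__ = [
    "ComponentReport",
    "RoleFeature",
    "RoleProfile",
    "n400_index",
    "evaluate",
    "role_typicality",
    "TSV_COLUMNS",
]

TSV_COLUMNS = ("cw", "failed", "h_t1", "h_t2", "delta_h", "typicality_raw",
               "typicality_normalized", "n400_index", "n_conf", "n_comp", "n_disconf")


@dataclass(frozen=True)
class ComponentReport:
    """Per-critical-word record of every intermediate quantity."""

    cw: str
    failed: bool
    n400_index: float
    h_t1: Optional[float] = None
    h_t2: Optional[float] = None
    delta_h: Optional[float] = None
    typicality_raw: Optional[float] = None
    typicality_normalized: Optional[float] = None
    partition_sizes: Optional[tuple[int, int, int]] = None
    failing_chains: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "cw": self.cw,
            "failed": self.failed,
            "h_t1": self.h_t1,
            "h_t2": self.h_t2,
            "delta_h": self.delta_h,
            "n400_index": self.n400_index,
            "partition_sizes": list(self.partition_sizes) if self.partition_sizes else None,
        }
        if not self.failed:
            d["typicality_raw"] = self.typicality_raw
            d["typicality_normalized"] = self.typicality_normalized
        else:
            d["failing_chains"] = list(self.failing_chains)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def to_tsv_row(self) -> str:
        def fmt(x):
            return "" if x is None else (str(int(x)) if isinstance(x, bool) else repr(x))

        sizes = self.partition_sizes or (None, None, None)
        vals = (self.cw, int(self.failed), self.h_t1, self.h_t2, self.delta_h,
                self.typicality_raw, self.typicality_normalized, self.n400_index,
                *sizes)
        return "\t".join("" if v is None else str(v) for v in vals)


def n400_index(delta_h: float, delta_h_max: float, typ: float,
               weights: tuple[float, float] = (0.5, 0.5)) -> float:
    """Predicted N400 index in [0, 1]; see module docstring for the form."""
    alpha, beta = weights
    if abs(alpha + beta - 1.0) > 1e-9 or alpha < 0 or beta < 0:
        raise ConfigError(f"weights {weights} must be nonnegative and sum to 1")
    if not (0.0 <= typ <= 1.0 + 1e-9):
        raise ValueError(f"typicality {typ} outside [0, 1]")
    if delta_h < -1e-9 or delta_h > delta_h_max + 1e-9:
        raise ValueError(f"delta_h {delta_h} outside [0, {delta_h_max}]")
    if delta_h_max <= 0.0:
        pred_term = 0.0  # nothing to reduce
    else:
        pred_term = 1.0 - delta_h / delta_h_max
    index = alpha * pred_term + beta * (1.0 - typ)
    return min(1.0, max(0.0, index))


def evaluate(scenario: ScenarioSpec, cw: str, config: RunConfig = RunConfig(),
             prenominal: Optional[str] = None) -> ComponentReport:
    """Run the full pipeline for one critical word.

    Prenominal revision (if requested) -> default inferences -> feature
    partition -> on failure a maximal-index report, otherwise the entropy
    component, the typicality component, and the combined index.
    """
    c_arg = scenario.argument_concept()
    if config.threshold_r is not None:
        from dataclasses import replace
        c_arg = replace(c_arg, threshold_r=config.threshold_r)
    if prenominal is not None:
        if prenominal not in scenario.prenominal_updates:
            raise KeyError(f"unknown prenominal {prenominal!r}; "
                           f"declared: {sorted(scenario.prenominal_updates)}")
        c_arg = apply_prenominal(c_arg, scenario.prenominal_updates[prenominal])
    c_cw = scenario.cw_concept(cw)

    partition = update_set(c_arg, c_cw)
    if partition.failed:
        return ComponentReport(
            cw=cw, failed=True, n400_index=1.0,
            failing_chains=tuple(sorted(str(c) for c in partition.failing_chains)),
        )

    h1, h2, dh = predictability_component(
        c_arg, partition, n=config.extension_depth,
        log_base=config.log_base, cap=config.extension_cap,
    )
    profile = scenario.diagnosticity_profile(c_arg)
    report = typicality(c_arg, c_cw, profile)
    typ = report.raw if config.typicality_variant == "raw" else report.normalized
    index = n400_index(dh, h1, typ, weights=(config.alpha, config.beta))
    return ComponentReport(
        cw=cw, failed=False, n400_index=index,
        h_t1=h1, h_t2=h2, delta_h=dh,
        typicality_raw=report.raw, typicality_normalized=report.normalized,
        partition_sizes=partition.sizes,
    )


# ---------------------------------------------------------------------------
# thematic-role extension
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoleFeature:
    """A pre-activated feature situated under a thematic role; the chain of
    the inner feature is the role-prefixed chain."""

    role: str
    inner: Feature
    role_diagnosticity: float


@dataclass(frozen=True)
class RoleProfile:
    """Everything needed to score one role: its argument concept, its
    typicality profile, and the chains whose definedness it requires
    (selection restrictions, e.g. animacy)."""

    arg_concept: CategoryConcept
    profile: DiagnosticityProfile
    restrictions: frozenset[Chain] = frozenset()


def role_typicality(features: Sequence[RoleFeature], c_cw: CategoryConcept,
                    role_profiles: Mapping[str, RoleProfile]) -> float:
    """Role-weighted typicality over several candidate argument positions.

    Each active role contributes its diagnosticity times the typicality of
    its argument concept against the critical word; a role whose selection
    restrictions (or profiled chains) are undefined for the critical word
    contributes 0.
    """
    weights: dict[str, float] = {}
    for rf in features:
        prev = weights.get(rf.role)
        if prev is not None and abs(prev - rf.role_diagnosticity) > 1e-9:
            raise ConfigError(f"role {rf.role!r} carries conflicting weights")
        weights[rf.role] = rf.role_diagnosticity
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"role weights sum to {total}, not 1")

    score = 0.0
    for role, weight in weights.items():
        rp = role_profiles[role]
        needed = set(rp.restrictions) | set(rp.profile.weights)
        if any(not c_cw.defines(chain) for chain in needed):
            continue  # contributes 0
        score += weight * typicality(rp.arg_concept, c_cw, rp.profile).raw
    return score


def scenario_role_typicality(scenario: ScenarioSpec, cw: str) -> float:
    """Convenience wrapper building role features/profiles from a scenario's
    role annotations."""
    if not scenario.roles:
        raise ConfigError(f"scenario {scenario.name!r} declares no roles")
    c_cw = scenario.cw_concept(cw)
    features: list[RoleFeature] = []
    profiles: dict[str, RoleProfile] = {}
    for role in scenario.roles:
        concept = scenario.concept(role.category)
        profile = DiagnosticityProfile(weights=dict(role.profile), source="stipulated")
        profiles[role.name] = RoleProfile(arg_concept=concept, profile=profile,
                                          restrictions=role.restrictions)
        for feat in default_inferences(concept):
            if feat.chain in role.profile:
                features.append(RoleFeature(role.name, feat, role.weight))
        if not any(rf.role == role.name for rf in features):
            # role still participates even without an emitted default
            features.append(RoleFeature(role.name,
                                        Feature(next(iter(role.profile)), "_"),
                                        role.weight))
    return role_typicality(features, c_cw, profiles)
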
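"""Scenario JSON format: serialization, loading, validation.

The format is purpose-defined and versioned (``format_version: 1``).  Chains
are dotted strings, probabilities are value -> number maps serialized at full
precision.  Distributions whose sum is off by at most 1e-6 are renormalized
on load; anything worse is rejected with an itemized report.  Unknown fields
warn but do not fail.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Any, Mapping

from .concepts import ContrastDeclaration, PrenominalUpdate
from .frames import PROB_TOL, Chain, Feature, Sort
from .scenarios import (
    FORMAT_VERSION,
    ArgConceptSpec,
    CategoryTable,
    RoleSpec,
    ScenarioSpec,
    ScenarioValidationError,
)

__all__ = ["scenario_to_dict", "scenario_from_dict", "load_scenario",
           "save_scenario", "load_builtin", "builtin_names"]

log = logging.getLogger(__name__)

RENORM_TOL = 1e-6

_KNOWN_TOP = {"format_version", "name", "constraint_level", "sorts", "attributes",
              "categories", "arg_concept", "prenominal_updates", "critical_words",
              "roles"}


def _dist_to_json(dist: Mapping[str, float]) -> dict[str, float]:
    return {v: float(p) for v, p in dist.items()}


def scenario_to_dict(spec: ScenarioSpec) -> dict:
    """Serializable dict; inverse of :func:`scenario_from_dict`."""
    out: dict[str, Any] = {
        "format_version": FORMAT_VERSION,
        "name": spec.name,
        "constraint_level": spec.constraint_level,
        "sorts": [{"name": s.name, "parent": s.parent} for s in spec.sorts],
        "attributes": [{"name": str(ch), "values": list(vals)}
                       for ch, vals in sorted(spec.attributes.items())],
        "categories": {},
        "critical_words": dict(sorted(spec.critical_words.items())),
    }
    for name, table in sorted(spec.categories.items()):
        out["categories"][name] = {
            "sort": table.sort,
            "provenance": table.provenance,
            "distributions": {str(ch): _dist_to_json(d)
                              for ch, d in sorted(table.distributions.items())},
            "fixed": [{"chain": str(f.chain), "value": f.value}
                      for f in sorted(table.fixed)],
        }
    arg = spec.arg_concept
    arg_json: dict[str, Any] = {
        "category": arg.category,
        "context_independent": sorted(str(c) for c in arg.context_independent),
        "context_dependent": sorted(str(c) for c in arg.context_dependent),
        "threshold_r": arg.threshold_r,
    }
    if arg.stipulated_diagnosticity is not None:
        arg_json["diagnosticity"] = {str(ch): float(w)
                                     for ch, w in sorted(arg.stipulated_diagnosticity.items())}
    if arg.contrast is not None:
        arg_json["contrast"] = {
            "antecedent": str(arg.contrast.antecedent),
            "actual_value": arg.contrast.actual_value,
            "alternatives": {
                val: {str(ch): _dist_to_json(d) for ch, d in sorted(revs.items())}
                for val, revs in sorted(arg.contrast.alternatives.items())
            },
        }
    out["arg_concept"] = arg_json
    if spec.prenominal_updates:
        out["prenominal_updates"] = {
            label: {
                "evidence": {"chain": str(u.evidence.chain), "value": u.evidence.value},
                "revisions": {str(ch): _dist_to_json(d)
                              for ch, d in sorted(u.correlated_revisions.items())},
            }
            for label, u in sorted(spec.prenominal_updates.items())
        }
    if spec.roles:
        out["roles"] = [
            {"name": r.name, "weight": r.weight, "category": r.category,
             "profile": {str(ch): float(w) for ch, w in sorted(r.profile.items())},
             "restrictions": sorted(str(c) for c in r.restrictions)}
            for r in spec.roles
        ]
    return out


def _load_dist(where: str, chain: Chain, raw: Mapping[str, Any],
               errors: list[str]) -> dict[str, float]:
    try:
        dist = {str(v): float(p) for v, p in raw.items()}
    except (TypeError, ValueError):
        errors.append(f"{where}: chain {chain}: non-numeric probability")
        return {}
    total = sum(dist.values())
    if abs(total - 1.0) <= PROB_TOL:
        return dist
    if abs(total - 1.0) <= RENORM_TOL and total > 0:
        log.info("%s: chain %s renormalized (sum %.9f)", where, chain, total)
        return {v: p / total for v, p in dist.items()}
    errors.append(f"{where}: chain {chain}: distribution sums to {total}, not 1")
    return {}


def scenario_from_dict(data: Mapping[str, Any]) -> ScenarioSpec:
    """Build and fully validate a scenario from its JSON form."""
    errors: list[str] = []
    unknown = set(data) - _KNOWN_TOP
    if unknown:
        warnings.warn(f"unknown scenario fields ignored: {sorted(unknown)}")
    version = data.get("format_version")
    if version != FORMAT_VERSION:
        errors.append(f"unsupported format_version {version!r}")

    sorts = tuple(Sort(s["name"], s.get("parent")) for s in data.get("sorts", []))
    attributes = {Chain.parse(a["name"]): tuple(a["values"])
                  for a in data.get("attributes", [])}

    categories: dict[str, CategoryTable] = {}
    for name, cat in data.get("categories", {}).items():
        dists = {}
        for ch_str, raw in cat.get("distributions", {}).items():
            chain = Chain.parse(ch_str)
            dist = _load_dist(f"category {name!r}", chain, raw, errors)
            if dist:
                dists[chain] = dist
        fixed = frozenset(Feature(Chain.parse(f["chain"]), f["value"])
                          for f in cat.get("fixed", []))
        categories[name] = CategoryTable(
            sort=cat.get("sort", ""), distributions=dists, fixed=fixed,
            provenance=cat.get("provenance", "paper"))

    arg_raw = data.get("arg_concept", {})
    contrast = None
    if "contrast" in arg_raw:
        c = arg_raw["contrast"]
        alternatives = {}
        for val, revs in c.get("alternatives", {}).items():
            alternatives[val] = {
                Chain.parse(ch): _load_dist(f"contrast {val!r}", Chain.parse(ch), d, errors)
                for ch, d in revs.items()
            }
        contrast = ContrastDeclaration(antecedent=Chain.parse(c["antecedent"]),
                                       actual_value=c["actual_value"],
                                       alternatives=alternatives)
    stipulated = None
    if "diagnosticity" in arg_raw:
        stipulated = {Chain.parse(ch): float(w)
                      for ch, w in arg_raw["diagnosticity"].items()}
    arg = ArgConceptSpec(
        category=arg_raw.get("category", ""),
        context_independent=frozenset(Chain.parse(c)
                                      for c in arg_raw.get("context_independent", [])),
        context_dependent=frozenset(Chain.parse(c)
                                    for c in arg_raw.get("context_dependent", [])),
        threshold_r=float(arg_raw.get("threshold_r", 0.5)),
        stipulated_diagnosticity=stipulated,
        contrast=contrast,
    )

    prenominal = {}
    for label, u in data.get("prenominal_updates", {}).items():
        revisions = {}
        for ch_str, raw in u.get("revisions", {}).items():
            chain = Chain.parse(ch_str)
            dist = _load_dist(f"prenominal {label!r}", chain, raw, errors)
            if dist:
                revisions[chain] = dist
        prenominal[label] = PrenominalUpdate(
            evidence=Feature(Chain.parse(u["evidence"]["chain"]), u["evidence"]["value"]),
            correlated_revisions=revisions)

    roles = tuple(
        RoleSpec(name=r["name"], weight=float(r["weight"]), category=r["category"],
                 profile={Chain.parse(ch): float(w) for ch, w in r["profile"].items()},
                 restrictions=frozenset(Chain.parse(c) for c in r.get("restrictions", [])))
        for r in data.get("roles", [])
    )

    if errors:
        raise ScenarioValidationError(errors)

    spec = ScenarioSpec(
        name=data.get("name", "unnamed"),
        sorts=sorts,
        attributes=attributes,
        categories=categories,
        arg_concept=arg,
        critical_words=dict(data.get("critical_words", {})),
        prenominal_updates=prenominal,
        roles=roles,
        constraint_level=data.get("constraint_level", "HC"),
    )
    return spec.validated()


def load_scenario(path: str | Path) -> ScenarioSpec:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return scenario_from_dict(data)


def save_scenario(spec: ScenarioSpec, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(scenario_to_dict(spec), fh, indent=2, sort_keys=False)
        fh.write("\n")


# -- built-in fixture files -------------------------------------------------

def _data_dir() -> Path:
    return Path(__file__).parent / "data"


def builtin_names() -> list[str]:
    return sorted(p.stem for p in _data_dir().glob("*.json"))


def load_builtin(name: str) -> ScenarioSpec:
    path = _data_dir() / f"{name}.json"
    if not path.exists():
        raise FileNotFoundError(f"no built-in scenario {name!r}; available: {builtin_names()}")
    return load_scenario(path)
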
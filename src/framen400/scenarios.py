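"""Scenario bundles: canonical worked fixtures and a seeded random generator.

A scenario collects the sorts, the chain signature, per-category probability
tables, the argument-position concept (with its context-independent and
context-dependent chains), optional prenominal updates, optional thematic-role
annotations, and the declared critical words.

Probabilities not printed in the reference tables are fixture choices chosen
to reproduce the qualitative orderings; they are marked with
``provenance="fixture-choice"`` on the category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .concepts import (
    CategoryConcept,
    ContrastDeclaration,
    PrenominalUpdate,
    contrast_classes,
)
from .frames import Chain, Feature, FrameError, Sort, SortRegistry, StochasticFrame
from .typicality import DiagnosticityProfile, diagnosticity

__all__ = [
    "CategoryTable",
    "ArgConceptSpec",
    "RoleSpec",
    "ScenarioSpec",
    "ScenarioValidationError",
    "fixture_holiday_resort",
    "fixture_birthday_party",
    "fixture_seaside_caution",
    "fixture_prescription",
    "generate_random_scenario",
]

FORMAT_VERSION = 1


class ScenarioValidationError(ValueError):
    """Raised with the full list of validation problems."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class CategoryTable:
    """Per-category conditional probability tables P(VA | C)."""

    sort: str
    distributions: Mapping[Chain, Mapping[str, float]] = field(default_factory=dict)
    fixed: frozenset[Feature] = frozenset()
    provenance: str = "paper"  # "paper" | "fixture-choice"


@dataclass(frozen=True)
class ArgConceptSpec:
    category: str
    context_independent: frozenset[Chain] = frozenset()
    context_dependent: frozenset[Chain] = frozenset()
    threshold_r: float = 0.5
    stipulated_diagnosticity: Optional[Mapping[Chain, float]] = None
    contrast: Optional[ContrastDeclaration] = None


@dataclass(frozen=True)
class RoleSpec:
    """A thematic role: its weight (expectation that the critical word fills
    it), the category acting as the role's argument concept, the chains whose
    definedness it requires of the critical word, and its typicality profile."""

    name: str
    weight: float
    category: str
    profile: Mapping[Chain, float]
    restrictions: frozenset[Chain] = frozenset()


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    sorts: tuple[Sort, ...]
    attributes: Mapping[Chain, tuple[str, ...]]
    categories: Mapping[str, CategoryTable]
    arg_concept: ArgConceptSpec
    critical_words: Mapping[str, str]  # cw label -> category name
    prenominal_updates: Mapping[str, PrenominalUpdate] = field(default_factory=dict)
    roles: tuple[RoleSpec, ...] = ()
    constraint_level: str = "HC"

    # -- constructors ------------------------------------------------------

    def sort_registry(self) -> SortRegistry:
        return SortRegistry(self.sorts)

    def _frame(self, table: CategoryTable) -> StochasticFrame:
        sig = {ch: self.attributes[ch]
               for ch in set(table.distributions) | {f.chain for f in table.fixed}}
        return StochasticFrame(sort=table.sort, signature=sig,
                               distributions=table.distributions, fixed=table.fixed)

    def concept(self, category: str) -> CategoryConcept:
        """A critical-word concept: every defined chain counts as
        context-independent for the purpose of its own default inferences."""
        table = self.categories[category]
        frame = self._frame(table)
        return CategoryConcept(name=category, frame=frame,
                               context_independent=frame.chains(),
                               threshold_r=self.arg_concept.threshold_r)

    def argument_concept(self) -> CategoryConcept:
        spec = self.arg_concept
        frame = self._frame(self.categories[spec.category])
        return CategoryConcept(
            name=spec.category,
            frame=frame,
            context_independent=spec.context_independent,
            context_dependent=spec.context_dependent,
            threshold_r=spec.threshold_r,
            contrast=spec.contrast,
        )

    def cw_concept(self, cw: str) -> CategoryConcept:
        if cw not in self.critical_words:
            raise KeyError(f"unknown critical word {cw!r}; declared: {sorted(self.critical_words)}")
        return self.concept(self.critical_words[cw])

    def diagnosticity_profile(self, c_arg: CategoryConcept) -> DiagnosticityProfile:
        spec = self.arg_concept
        if spec.stipulated_diagnosticity is not None:
            return diagnosticity(c_arg, [], [], stipulated=spec.stipulated_diagnosticity)
        chains = sorted(c_arg.chains)
        return diagnosticity(c_arg, contrast_classes(c_arg), chains)

    # -- validation --------------------------------------------------------

    def validate(self) -> list[str]:
        """Collect every cross-reference problem (empty list when valid)."""
        errors: list[str] = []
        try:
            self.sort_registry()
        except FrameError as e:
            errors.append(str(e))
        for name, table in self.categories.items():
            if not any(s.name == table.sort for s in self.sorts):
                errors.append(f"category {name!r}: unknown sort {table.sort!r}")
            for chain in set(table.distributions) | {f.chain for f in table.fixed}:
                if chain not in self.attributes:
                    errors.append(f"category {name!r}: undeclared chain {chain}")
            try:
                self._frame(table)
            except KeyError as e:
                errors.append(f"category {name!r}: undeclared chain {e.args[0]}")
            except FrameError as e:
                errors.append(f"category {name!r}: {e}")
        spec = self.arg_concept
        if spec.category not in self.categories:
            errors.append(f"argument concept references unknown category {spec.category!r}")
        else:
            try:
                self.argument_concept()
            except FrameError as e:
                errors.append(f"argument concept: {e}")
        if spec.stipulated_diagnosticity is not None:
            total = sum(spec.stipulated_diagnosticity.values())
            if abs(total - 1.0) > 1e-9:
                errors.append(f"stipulated diagnosticity sums to {total}, not 1")
        for cw, cat in self.critical_words.items():
            if cat not in self.categories:
                errors.append(f"critical word {cw!r} references unknown category {cat!r}")
        for label, upd in self.prenominal_updates.items():
            if upd.evidence.chain not in self.attributes:
                errors.append(f"prenominal {label!r}: undeclared evidence chain {upd.evidence.chain}")
        if self.roles:
            total = sum(r.weight for r in self.roles)
            if abs(total - 1.0) > 1e-9:
                errors.append(f"role weights sum to {total}, not 1")
            for role in self.roles:
                if role.category not in self.categories:
                    errors.append(f"role {role.name!r} references unknown category {role.category!r}")
        if self.constraint_level not in ("HC", "LC"):
            errors.append(f"unknown constraint level {self.constraint_level!r}")
        return errors

    def validated(self) -> "ScenarioSpec":
        errors = self.validate()
        if errors:
            raise ScenarioValidationError(errors)
        return self


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------

def _c(name: str) -> Chain:
    return Chain.parse(name)


def fixture_holiday_resort() -> ScenarioSpec:
    """Tropical resort with plants along the driveway; critical words
    palms / pines / tulips.

    Argument-concept conditionals are the printed ones (habitat 0.9/0.1,
    height 0.6/0.4); the per-plant tables are fixture choices that realize the
    narrated defaults (palms: tropics+tall, pines: moderate+tall, tulips:
    moderate+small).
    """
    habitat, height, look = _c("habitat"), _c("height"), _c("look")
    attributes = {
        habitat: ("tropics", "moderate"),
        height: ("tall", "small"),
        look: ("tropical", "moderate"),
    }
    categories = {
        "theme_of_planting": CategoryTable(
            sort="plant",
            distributions={habitat: {"tropics": 0.9, "moderate": 0.1},
                           height: {"tall": 0.6, "small": 0.4}},
            fixed=frozenset({Feature(look, "tropical")}),
        ),
        "palms": CategoryTable(
            sort="tree", provenance="fixture-choice",
            distributions={habitat: {"tropics": 0.9, "moderate": 0.1},
                           height: {"tall": 0.9, "small": 0.1}},
        ),
        "pines": CategoryTable(
            sort="tree", provenance="fixture-choice",
            distributions={habitat: {"tropics": 0.1, "moderate": 0.9},
                           height: {"tall": 0.9, "small": 0.1}},
        ),
        "tulips": CategoryTable(
            sort="flower", provenance="fixture-choice",
            distributions={habitat: {"tropics": 0.1, "moderate": 0.9},
                           height: {"tall": 0.1, "small": 0.9}},
        ),
    }
    contrast = ContrastDeclaration(
        antecedent=look, actual_value="tropical",
        alternatives={"moderate": {habitat: {"tropics": 0.1, "moderate": 0.9}}},
    )
    return ScenarioSpec(
        name="holiday_resort",
        sorts=(Sort("plant"), Sort("tree", "plant"), Sort("flower", "plant")),
        attributes=attributes,
        categories=categories,
        arg_concept=ArgConceptSpec(
            category="theme_of_planting",
            context_dependent=frozenset({habitat, height}),
            contrast=contrast,
        ),
        critical_words={"palms": "palms", "pines": "pines", "tulips": "tulips"},
        constraint_level="HC",
    ).validated()


def fixture_birthday_party() -> ScenarioSpec:
    """Birthday-party dessert with prenominal 'sweet' / 'healthy'; critical
    words cake / veggies.  All probabilities and the 0.45/0.1/0.45 weights
    are the printed ones."""
    taste = _c("taste")
    nutrition = _c("nutrition_value")
    served = _c("served_at")
    attributes = {
        taste: ("sweet", "not_sweet"),
        nutrition: ("healthy", "not_healthy"),
        served: ("birthday_party", "not_birthday_party"),
    }
    categories = {
        "dessert": CategoryTable(
            sort="food",
            distributions={taste: {"sweet": 0.95, "not_sweet": 0.05},
                           nutrition: {"healthy": 0.05, "not_healthy": 0.95},
                           served: {"birthday_party": 0.98, "not_birthday_party": 0.02}},
        ),
        "cake": CategoryTable(
            sort="food",
            distributions={taste: {"sweet": 0.9, "not_sweet": 0.1},
                           nutrition: {"healthy": 0.2, "not_healthy": 0.8},
                           served: {"birthday_party": 0.98, "not_birthday_party": 0.02}},
        ),
        "veggies": CategoryTable(
            sort="food",
            distributions={taste: {"sweet": 0.2, "not_sweet": 0.8},
                           nutrition: {"healthy": 0.9, "not_healthy": 0.1},
                           served: {"birthday_party": 0.02, "not_birthday_party": 0.98}},
        ),
    }
    prenominal = {
        "sweet": PrenominalUpdate(
            evidence=Feature(taste, "sweet"),
            correlated_revisions={nutrition: {"healthy": 0.02, "not_healthy": 0.98}},
        ),
        "healthy": PrenominalUpdate(
            evidence=Feature(nutrition, "healthy"),
            correlated_revisions={taste: {"sweet": 0.4, "not_sweet": 0.6},
                                  served: {"birthday_party": 0.95,
                                           "not_birthday_party": 0.05}},
        ),
    }
    return ScenarioSpec(
        name="birthday_party",
        sorts=(Sort("food"),),
        attributes=attributes,
        categories=categories,
        arg_concept=ArgConceptSpec(
            category="dessert",
            context_dependent=frozenset({taste, nutrition, served}),
            stipulated_diagnosticity={taste: 0.45, nutrition: 0.1, served: 0.45},
        ),
        critical_words={"cake": "cake", "veggies": "veggies"},
        prenominal_updates=prenominal,
        constraint_level="HC",
    ).validated()


def fixture_seaside_caution(level: str = "HC") -> ScenarioSpec:
    """Lifeguards cautioning swimmers / trainees / drawer.

    Context-independent chains (animacy, being in danger) are always
    pre-activated; the HC variant additionally licenses the context-dependent
    location and afloat chains.  No probabilities for this scenario are
    printed; all tables are fixture choices reproducing the narrated
    partition behavior (drawer lacks the animacy chains and fails)."""
    if level not in ("HC", "LC"):
        raise ValueError("level must be 'HC' or 'LC'")
    sentient, can_move = _c("sentient"), _c("can_move")
    in_danger, location, afloat = _c("in_danger"), _c("location"), _c("afloat")
    danger_loc = _c("danger.location")
    attributes = {
        sentient: ("yes", "no"),
        can_move: ("yes", "no"),
        in_danger: ("yes", "no"),
        location: ("water", "beach"),
        afloat: ("yes", "no"),
        danger_loc: ("water", "beach"),
    }
    arg_dists = {
        sentient: {"yes": 0.95, "no": 0.05},
        can_move: {"yes": 0.95, "no": 0.05},
        in_danger: {"yes": 0.9, "no": 0.1},
    }
    arg_fixed: frozenset[Feature] = frozenset()
    if level == "HC":
        arg_dists.update({
            location: {"water": 0.9, "beach": 0.1},
            afloat: {"yes": 0.85, "no": 0.15},
        })
        arg_fixed = frozenset({Feature(danger_loc, "water")})
    categories = {
        "theme_of_caution": CategoryTable(
            sort="entity", provenance="fixture-choice",
            distributions=arg_dists, fixed=arg_fixed,
        ),
        "swimmers": CategoryTable(
            sort="animate", provenance="fixture-choice",
            distributions={sentient: {"yes": 0.99, "no": 0.01},
                           can_move: {"yes": 0.99, "no": 0.01},
                           in_danger: {"yes": 0.8, "no": 0.2},
                           location: {"water": 0.95, "beach": 0.05},
                           afloat: {"yes": 0.9, "no": 0.1}},
        ),
        "trainees": CategoryTable(
            sort="animate", provenance="fixture-choice",
            distributions={sentient: {"yes": 0.99, "no": 0.01},
                           can_move: {"yes": 0.99, "no": 0.01},
                           in_danger: {"yes": 0.5, "no": 0.5},
                           location: {"water": 0.5, "beach": 0.5},
                           afloat: {"yes": 0.5, "no": 0.5}},
        ),
        "drawer": CategoryTable(
            sort="inanimate", provenance="fixture-choice",
            distributions={in_danger: {"yes": 0.05, "no": 0.95},
                           location: {"water": 0.05, "beach": 0.95},
                           afloat: {"yes": 0.1, "no": 0.9}},
        ),
    }
    contrast = None
    stipulated = None
    cd: frozenset[Chain] = frozenset()
    if level == "HC":
        cd = frozenset({location, afloat})
        contrast = ContrastDeclaration(
            antecedent=danger_loc, actual_value="water",
            alternatives={"beach": {location: {"water": 0.1, "beach": 0.9},
                                    afloat: {"yes": 0.15, "no": 0.85}}},
        )
    else:
        stipulated = {sentient: 1 / 3, can_move: 1 / 3, in_danger: 1 / 3}
    return ScenarioSpec(
        name=f"seaside_caution_{level}",
        sorts=(Sort("entity"), Sort("animate", "entity"), Sort("inanimate", "entity")),
        attributes=attributes,
        categories=categories,
        arg_concept=ArgConceptSpec(
            category="theme_of_caution",
            context_independent=frozenset({sentient, can_move, in_danger}),
            context_dependent=cd,
            contrast=contrast,
            stipulated_diagnosticity=stipulated,
        ),
        critical_words={"swimmers": "swimmers", "trainees": "trainees",
                        "drawer": "drawer"},
        constraint_level=level,
    ).validated()


def fixture_prescription() -> ScenarioSpec:
    """Schema-knowledge scenario: a prescription for a mental disorder written
    by psychiatrist / schizophrenic / guard / pill / fence.

    Features are prefixed by thematic role (actor, recipient, theme); all
    tables are fixture choices constructed so that role-weighted typicality
    decreases along the narrated N400 ordering."""
    a_prof, a_anim = _c("actor.profession"), _c("actor.animacy")
    r_cond, r_anim = _c("recipient.condition"), _c("recipient.animacy")
    t_form = _c("theme.form")
    attributes = {
        a_prof: ("medical", "nonmedical"),
        a_anim: ("animate", "inanimate"),
        r_cond: ("mental", "other"),
        r_anim: ("animate", "inanimate"),
        t_form: ("medicine", "other"),
    }

    def person(prof_medical: float, cond_mental: float) -> CategoryTable:
        return CategoryTable(
            sort="animate", provenance="fixture-choice",
            distributions={a_prof: {"medical": prof_medical, "nonmedical": 1 - prof_medical},
                           r_cond: {"mental": cond_mental, "other": 1 - cond_mental}},
            fixed=frozenset({Feature(a_anim, "animate"), Feature(r_anim, "animate")}),
        )

    def thing(form_medicine: float) -> CategoryTable:
        return CategoryTable(
            sort="inanimate", provenance="fixture-choice",
            distributions={t_form: {"medicine": form_medicine, "other": 1 - form_medicine}},
        )

    categories = {
        "writer_of_prescription": CategoryTable(
            sort="animate", provenance="fixture-choice",
            distributions={a_prof: {"medical": 0.9, "nonmedical": 0.1}},
            fixed=frozenset({Feature(a_anim, "animate")}),
        ),
        "recipient_of_prescription": CategoryTable(
            sort="animate", provenance="fixture-choice",
            distributions={r_cond: {"mental": 0.9, "other": 0.1}},
            fixed=frozenset({Feature(r_anim, "animate")}),
        ),
        "prescribed_medicine": CategoryTable(
            sort="inanimate", provenance="fixture-choice",
            distributions={t_form: {"medicine": 0.9, "other": 0.1}},
        ),
        "psychiatrist": person(0.95, 0.3),
        "schizophrenic": person(0.05, 0.95),
        "guard": person(0.2, 0.2),
        "pill": thing(0.95),
        "fence": thing(0.02),
    }
    roles = (
        RoleSpec(name="actor", weight=0.5, category="writer_of_prescription",
                 profile={a_prof: 1.0}, restrictions=frozenset({a_anim})),
        RoleSpec(name="recipient", weight=0.35, category="recipient_of_prescription",
                 profile={r_cond: 1.0}, restrictions=frozenset({r_anim})),
        RoleSpec(name="theme", weight=0.15, category="prescribed_medicine",
                 profile={t_form: 1.0}),
    )
    return ScenarioSpec(
        name="prescription",
        sorts=(Sort("entity"), Sort("animate", "entity"), Sort("inanimate", "entity")),
        attributes=attributes,
        categories=categories,
        arg_concept=ArgConceptSpec(
            category="writer_of_prescription",
            context_independent=frozenset({a_anim}),
            context_dependent=frozenset({a_prof}),
            stipulated_diagnosticity={a_prof: 1.0},
        ),
        critical_words={"psychiatrist": "psychiatrist", "schizophrenic": "schizophrenic",
                        "guard": "guard", "pill": "pill", "fence": "fence"},
        roles=roles,
        constraint_level="HC",
    ).validated()


# ---------------------------------------------------------------------------
# random generator
# ---------------------------------------------------------------------------

def generate_random_scenario(seed: int, n_attributes: Optional[int] = None,
                             n_values: Optional[int] = None,
                             n_cws: Optional[int] = None) -> ScenarioSpec:
    """Deterministic random scenario for property testing.

    Draws 2-4 attributes with 2-3 values each and per-attribute distributions
    from a symmetric simplex.  The first critical word is a forced best
    completion (shares the argument concept's tables, hence its defaults);
    with >=2 critical words the second is forced to conflict on the first
    chain, which is peaked above threshold by construction.
    """
    rng = np.random.default_rng(seed)
    if n_attributes is None:
        n_attributes = int(rng.integers(2, 5))
    if n_cws is None:
        n_cws = int(rng.integers(1, 6))
    if not (2 <= n_attributes <= 4 and 1 <= n_cws <= 5):
        raise ValueError("n_attributes must lie in 2..4 and n_cws in 1..5")
    if n_values is not None and not (2 <= n_values <= 3):
        raise ValueError("n_values must lie in 2..3")

    chains, attributes = [], {}
    for i in range(n_attributes):
        k = n_values if n_values is not None else int(rng.integers(2, 4))
        chain = _c(f"attr{i}")
        chains.append(chain)
        attributes[chain] = tuple(f"v{j}" for j in range(k))

    def simplex(k: int) -> list[float]:
        p = rng.dirichlet(np.ones(k))
        return [float(x) for x in p]

    def peaked(k: int, peak_idx: int, peak: float = 0.8) -> dict[str, float]:
        rest = simplex(k - 1)
        vals = iter(rest)
        out = {}
        for j in range(k):
            out[f"v{j}"] = peak if j == peak_idx else (1 - peak) * next(vals)
        return out

    arg_dists: dict[Chain, Mapping[str, float]] = {}
    for i, chain in enumerate(chains):
        space = attributes[chain]
        if i == 0:
            arg_dists[chain] = peaked(len(space), 0)  # guarantee >=1 default
        else:
            arg_dists[chain] = dict(zip(space, simplex(len(space))))

    categories = {"arg": CategoryTable(sort="thing", provenance="fixture-choice",
                                       distributions=arg_dists)}
    critical_words = {}
    for j in range(n_cws):
        name = f"cw{j}"
        if j == 0:  # forced best completion
            dists: Mapping[Chain, Mapping[str, float]] = {
                ch: dict(d) for ch, d in arg_dists.items()}
        elif j == 1:  # forced conflict on the peaked chain
            dists = {ch: dict(d) for ch, d in arg_dists.items()}
            dists[chains[0]] = peaked(len(attributes[chains[0]]), 1)
        else:
            dists = {ch: dict(zip(attributes[ch], simplex(len(attributes[ch]))))
                     for ch in chains}
        categories[f"cat_{name}"] = CategoryTable(sort="thing",
                                                  provenance="fixture-choice",
                                                  distributions=dists)
        critical_words[name] = f"cat_{name}"

    return ScenarioSpec(
        name=f"random_{seed}",
        sorts=(Sort("thing"),),
        attributes=attributes,
        categories=categories,
        arg_concept=ArgConceptSpec(
            category="arg",
            context_dependent=frozenset(chains),
            stipulated_diagnosticity={ch: 1.0 / len(chains) for ch in chains},
        ),
        critical_words=critical_words,
        constraint_level="HC",
    ).validated()
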
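"""NEO-PI-R scale catalog.

The NEO-PI-R operationalizes the Five-Factor Model with 5 domains, each made
of 6 facets (30 facets total). Every facet is scored from 8 items on a 0-4
Likert scale, so facet scores live on [0, 32] and domain scores (48 items) on
[0, 192]. The catalog is the single source of truth for scale names, ordering
and score ranges; every other module resolves scale names through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

ITEMS_PER_FACET = 8
ITEMS_PER_DOMAIN = 48
MAX_ITEM_SCORE = 4
FACET_RANGE = (0, ITEMS_PER_FACET * MAX_ITEM_SCORE)       # (0, 32)
DOMAIN_RANGE = (0, ITEMS_PER_DOMAIN * MAX_ITEM_SCORE)     # (0, 192)

# Domains in catalog order; facets in inventory order within each domain.
DOMAIN_FACETS: dict[str, tuple[str, ...]] = {
    "neuroticism": (
        "anxiety", "hostility", "depression", "self_consciousness",
        "impulsiveness", "vulnerability",
    ),
    "extraversion": (
        "warmth", "gregariousness", "assertiveness", "activity",
        "excitement_seeking", "positive_emotions",
    ),
    "openness": (
        "fantasy", "aesthetics", "feelings", "actions", "ideas", "values",
    ),
    "agreeableness": (
        "trust", "straightforwardness", "altruism", "compliance",
        "modesty", "tender_mindedness",
    ),
    "conscientiousness": (
        "competence", "order", "dutifulness", "achievement_striving",
        "self_discipline", "deliberation",
    ),
}


def _canon_key(name: str) -> str:
    return name.strip().lower().replace("-", "_").replace(" ", "_")


@dataclass(frozen=True)
class ScaleCatalog:
    """Catalog of the 35 NEO-PI-R scales (5 domains + 30 facets)."""

    facets: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DOMAIN_FACETS)
    )

    def __post_init__(self) -> None:
        if len(self.facets) != 5:
            raise ValidationError("catalog must have exactly 5 domains")
        for d, fs in self.facets.items():
            if len(fs) != 6:
                raise ValidationError(f"domain {d!r} must have exactly 6 facets")

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(self.facets)

    @property
    def facet_names(self) -> tuple[str, ...]:
        return tuple(f for fs in self.facets.values() for f in fs)

    @property
    def all_scales(self) -> tuple[str, ...]:
        """All 35 scales in battery order: each domain followed by its facets."""
        out: list[str] = []
        for d, fs in self.facets.items():
            out.append(d)
            out.extend(fs)
        return tuple(out)

    def is_domain(self, name: str) -> bool:
        return self.canonicalize(name) in self.facets

    def canonicalize(self, name: str) -> str:
        """Resolve a scale name case-insensitively; unknown names are an error."""
        key = _canon_key(name)
        if key in self.facets or key in self._facet_set():
            return key
        raise ValidationError(f"unknown NEO-PI-R scale: {name!r}")

    def _facet_set(self) -> frozenset[str]:
        return frozenset(self.facet_names)

    def domain_of(self, facet: str) -> str:
        key = self.canonicalize(facet)
        if key in self.facets:
            return key
        for d, fs in self.facets.items():
            if key in fs:
                return d
        raise ValidationError(f"unknown facet: {facet!r}")  # pragma: no cover

    def score_range(self, name: str) -> tuple[int, int]:
        return DOMAIN_RANGE if self.is_domain(name) else FACET_RANGE

    def display_name(self, name: str) -> str:
        key = self.canonicalize(name)
        return key.replace("_", " ").capitalize()


DEFAULT_CATALOG = ScaleCatalog()
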
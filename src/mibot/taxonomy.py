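"""Smoking-reasons category taxonomy: load, validate, census, and grow.

A :class:`Taxonomy` is an ordered collection of :class:`Category` records, each
a reason people give for or against smoking ("stress", "cost", ...). Every
category carries a valence — ``pro`` (only ever a reason *for* smoking),
``con`` (only ever against), or ``both`` — plus reflection templates the
dialogue engine speaks when it detects the category, example utterances, and
observed-count metadata used by the simulator as sampling weights.

Two fixtures ship with the package:

* ``taxonomy_full.yaml`` — the final 21-category taxonomy with per-polarity
  example utterances and observed counts.
* ``taxonomy_seed.yaml`` — the 10-category starting point (a subset by id of
  the full fixture) from which the iterative training campaign grows.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

VALENCES = ("pro", "con", "both")
POLARITIES = ("pro", "con")

TAXONOMY_SCHEMA = "mibot-taxonomy/1"


class TaxonomyError(ValueError):
    """Raised when a taxonomy file or mutation violates an invariant."""


def normalize_id(name: str) -> str:
    """Normalize a category name to a stable id.

    Unicode NFC, casefolded, runs of non-alphanumeric characters collapsed to
    a single underscore: ``"In my hand"`` → ``"in_my_hand"``.
    """
    text = unicodedata.normalize("NFC", name).casefold()
    text = re.sub(r"[^0-9a-zÀ-￿]+", "_", text)
    return text.strip("_")


@dataclass(frozen=True)
class CategoryExample:
    text: str
    polarity: str  # "pro" | "con"


@dataclass(frozen=True)
class Category:
    """A smoking reason with valence, templates, examples, and count metadata."""

    id: str
    display_name: str
    valence: str  # "pro" | "con" | "both"
    reflection_templates: dict[str, tuple[str, ...]] = field(default_factory=dict)
    examples: tuple[CategoryExample, ...] = ()
    observed_count: dict[str, int] = field(default_factory=dict)
    provenance: str = "seed"  # "seed" | "grown"
    aliases: tuple[str, ...] = ()

    @property
    def allowed_polarities(self) -> tuple[str, ...]:
        return POLARITIES if self.valence == "both" else (self.valence,)

    @property
    def phrase(self) -> str:
        """The short phrase interpolated into templates and prompts."""
        return self.display_name.lower()

    def validate(self) -> None:
        if not self.id or normalize_id(self.id) != self.id:
            raise TaxonomyError(f"category id {self.id!r} is not normalized")
        if self.valence not in VALENCES:
            raise TaxonomyError(
                f"category {self.id!r}: valence {self.valence!r} not in {VALENCES}"
            )
        for pol in self.allowed_polarities:
            if not self.reflection_templates.get(pol):
                raise TaxonomyError(
                    f"category {self.id!r}: no reflection template for allowed "
                    f"polarity {pol!r}"
                )
        for pol in self.reflection_templates:
            if pol not in POLARITIES:
                raise TaxonomyError(
                    f"category {self.id!r}: unknown template polarity {pol!r}"
                )
        for ex in self.examples:
            if ex.polarity not in self.allowed_polarities:
                raise TaxonomyError(
                    f"category {self.id!r}: example polarity {ex.polarity!r} "
                    f"not permitted by valence {self.valence!r}"
                )
        for pol, n in self.observed_count.items():
            if pol not in POLARITIES or n < 0:
                raise TaxonomyError(
                    f"category {self.id!r}: bad observed_count entry {pol!r}={n!r}"
                )


@dataclass(frozen=True)
class Taxonomy:
    """Ordered, versioned collection of categories."""

    categories: tuple[Category, ...]
    version: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cat in self.categories:
            cat.validate()
            if cat.id in seen:
                raise TaxonomyError(f"duplicate category id {cat.id!r}")
            seen.add(cat.id)

    def __len__(self) -> int:
        return len(self.categories)

    def __contains__(self, category_id: str) -> bool:
        return any(c.id == category_id for c in self.categories)

    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.categories)

    def get(self, category_id: str) -> Category:
        for cat in self.categories:
            if cat.id == category_id:
                return cat
        raise KeyError(category_id)

    def find_by_name(self, name: str) -> Category | None:
        """Look a category up by id, display name, or alias (normalized)."""
        key = normalize_id(name)
        for cat in self.categories:
            if key == cat.id or key == normalize_id(cat.display_name):
                return cat
            if any(key == normalize_id(a) for a in cat.aliases):
                return cat
        return None


@dataclass(frozen=True)
class AddResult:
    """Outcome of :func:`add_category`: the (possibly unchanged) taxonomy."""

    taxonomy: Taxonomy
    created: bool
    category_id: str

    @property
    def merged(self) -> bool:
        return not self.created


def valence_census(taxonomy: Taxonomy) -> tuple[int, int, int]:
    """Count (pro-only, con-only, both) categories; components sum to len."""
    n_pro = sum(1 for c in taxonomy.categories if c.valence == "pro")
    n_con = sum(1 for c in taxonomy.categories if c.valence == "con")
    n_both = sum(1 for c in taxonomy.categories if c.valence == "both")
    return n_pro, n_con, n_both


def add_category(
    taxonomy: Taxonomy,
    name: str,
    valence: str,
    templates: dict[str, Iterable[str]],
) -> AddResult:
    """Add a category named by a user or reviewer.

    The id is derived from ``name`` via :func:`normalize_id`. If the id (or an
    alias/display name) collides with an existing category the taxonomy is
    returned unchanged and the collision is signalled (``merged``) — applying
    the same addition twice equals applying it once.
    """
    if not name or not normalize_id(name):
        raise TaxonomyError("category name is empty after normalization")
    existing = taxonomy.find_by_name(name)
    if existing is not None:
        return AddResult(taxonomy, created=False, category_id=existing.id)
    if valence not in VALENCES:
        raise TaxonomyError(f"valence {valence!r} not in {VALENCES}")
    tmpl = {pol: tuple(ts) for pol, ts in templates.items() if ts}
    cat = Category(
        id=normalize_id(name),
        display_name=name.strip(),
        valence=valence,
        reflection_templates=tmpl,
        provenance="grown",
    )
    cat.validate()  # catches missing templates for an allowed polarity
    new = Taxonomy(taxonomy.categories + (cat,), version=taxonomy.version + 1)
    return AddResult(new, created=True, category_id=cat.id)


def widen_valence(taxonomy: Taxonomy, category_id: str, polarity: str) -> Taxonomy:
    """Widen a category's valence to ``both`` when the opposite polarity is
    observed in reviewed data; no-op if the polarity is already allowed."""
    cat = taxonomy.get(category_id)
    if polarity in cat.allowed_polarities:
        return taxonomy
    templates = dict(cat.reflection_templates)
    templates.setdefault(polarity, _placeholder_templates(cat.display_name)[polarity])
    new_cat = replace(cat, valence="both", reflection_templates=templates)
    cats = tuple(new_cat if c.id == category_id else c for c in taxonomy.categories)
    return Taxonomy(cats, version=taxonomy.version + 1)


def _placeholder_templates(name: str) -> dict[str, tuple[str, ...]]:
    """Generic reflection frames for a freshly grown category."""
    phrase = name.strip().lower()
    return {
        "pro": (
            f"I understand, {phrase} is part of what smoking gives you",
            f"I get it, {phrase} is something you value about smoking",
        ),
        "con": (
            f"I hear you, {phrase} is one of the bad sides of smoking for you",
            f"I understand, {phrase} is a real downside of smoking for you",
        ),
    }


# ---------------------------------------------------------------------------
# Serialization

def _category_to_record(cat: Category) -> dict:
    rec: dict = {
        "id": cat.id,
        "display_name": cat.display_name,
        "valence": cat.valence,
        "reflection_templates": {
            pol: list(ts) for pol, ts in cat.reflection_templates.items()
        },
        "examples": [{"text": e.text, "polarity": e.polarity} for e in cat.examples],
        "observed_count": dict(cat.observed_count),
        "provenance": cat.provenance,
    }
    if cat.aliases:
        rec["aliases"] = list(cat.aliases)
    return rec


def _category_from_record(rec: dict) -> Category:
    try:
        cat = Category(
            id=rec["id"],
            display_name=rec["display_name"],
            valence=rec["valence"],
            reflection_templates={
                pol: tuple(ts)
                for pol, ts in (rec.get("reflection_templates") or {}).items()
            },
            examples=tuple(
                CategoryExample(e["text"], e["polarity"])
                for e in (rec.get("examples") or [])
            ),
            observed_count=dict(rec.get("observed_count") or {}),
            provenance=rec.get("provenance", "seed"),
            aliases=tuple(rec.get("aliases") or ()),
        )
    except KeyError as exc:  # missing required field
        raise TaxonomyError(f"category record missing field {exc}") from exc
    cat.validate()
    return cat


def taxonomy_to_dict(taxonomy: Taxonomy) -> dict:
    return {
        "schema": TAXONOMY_SCHEMA,
        "version": taxonomy.version,
        "categories": [_category_to_record(c) for c in taxonomy.categories],
    }


def taxonomy_from_dict(doc: dict) -> Taxonomy:
    schema = doc.get("schema", TAXONOMY_SCHEMA)
    if schema != TAXONOMY_SCHEMA:
        raise TaxonomyError(
            f"unsupported taxonomy schema {schema!r} (this build reads "
            f"{TAXONOMY_SCHEMA!r})"
        )
    cats = tuple(_category_from_record(r) for r in doc.get("categories", []))
    return Taxonomy(cats, version=int(doc.get("version", 0)))


def load_taxonomy(path: str | Path) -> Taxonomy:
    """Load and validate a taxonomy from a YAML (or JSON) file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise TaxonomyError(f"{path}: not a taxonomy document")
    return taxonomy_from_dict(doc)


def save_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(
            taxonomy_to_dict(taxonomy), fh, allow_unicode=True, sort_keys=False
        )


def _load_packaged(name: str) -> Taxonomy:
    ref = resources.files("mibot.data").joinpath(name)
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return taxonomy_from_dict(doc)


def load_full_taxonomy() -> Taxonomy:
    """The packaged 21-category taxonomy."""
    return _load_packaged("taxonomy_full.yaml")


def load_seed_taxonomy() -> Taxonomy:
    """The packaged 10-category starting taxonomy (subset of the full one)."""
    return _load_packaged("taxonomy_seed.yaml")
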
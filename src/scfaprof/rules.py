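"""Declarative pathway-rule grammar for SCFA production phenotypes.

A fermentation product (butyrate, propionate, acetate, formate, L-lactate,
D-lactate) can be reached through one or more pathway *variants*.  Each
variant is an AND over *role groups*; each group is an OR over alternatives,
where an alternative is either a single functional role or a conjunction of
roles (non-orthologous displacements that require several subunits, e.g.
``PduC2+PduD2``).  Variants of one product may reference named *shared
segments* defined once per product (e.g. the universal crotonyl-CoA ->
butyryl-CoA step of butyrate synthesis).

The default rule content covering 4 butyrate variants, 3 propionate
variants and the four single-variant products is shipped as package data
(``data/pathways.yaml``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

PRODUCTS = ("butyrate", "propionate", "acetate", "formate", "L-lactate", "D-lactate")


class ConfigError(ValueError):
    """Raised when a pathway configuration is malformed."""


@dataclass(frozen=True)
class FunctionalRole:
    """A named enzyme/protein function with binary per-genome presence."""

    role_id: str
    ec_number: str = ""
    description: str = ""
    #: accessory roles are recorded in the catalogue but never required
    annotation_only: bool = False

    def __post_init__(self) -> None:
        if not self.role_id:
            raise ConfigError("role_id must be non-empty")


@dataclass(frozen=True)
class RoleGroup:
    """OR-group of alternatives; an alternative is a conjunction of roles."""

    alternatives: tuple[frozenset[str], ...]
    required: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ConfigError("a role group needs at least one alternative")

    def satisfied_by(self, roles: frozenset[str]) -> bool:
        return any(alt <= roles for alt in self.alternatives)

    def satisfying_alternatives(self, roles: frozenset[str]) -> list[frozenset[str]]:
        return [alt for alt in self.alternatives if alt <= roles]

    def all_roles(self) -> frozenset[str]:
        out: set[str] = set()
        for alt in self.alternatives:
            out |= alt
        return frozenset(out)


@dataclass(frozen=True)
class Sublabel:
    """Alternative variant label used when one group is satisfied solely by
    a designated alternative (e.g. propionate P3* for the B12-independent
    propanediol dehydratase)."""

    label: str
    group: int
    sole_alternative: frozenset[str]


@dataclass(frozen=True)
class PathwayDefinition:
    """One pathway variant of one fermentation product."""

    product: str
    variant_label: str
    requirements: tuple[RoleGroup, ...]  # own groups followed by shared segments
    n_own: int = field(default=-1)  # how many leading requirements are variant-specific
    sublabel: Optional[Sublabel] = None

    @property
    def own_groups(self) -> tuple[RoleGroup, ...]:
        n = self.n_own if self.n_own >= 0 else len(self.requirements)
        return self.requirements[:n]

    def is_complete(self, roles: frozenset[str]) -> bool:
        return all(
            group.satisfied_by(roles) for group in self.requirements if group.required
        )

    def call_label(self, roles: frozenset[str]) -> Optional[str]:
        """Variant label if complete in ``roles``, else None.

        The sublabel replaces the base label when its trigger group is
        satisfied by the designated alternative and by no other alternative.
        """
        if not self.is_complete(roles):
            return None
        if self.sublabel is not None:
            sat = self.requirements[self.sublabel.group].satisfying_alternatives(roles)
            if sat == [self.sublabel.sole_alternative]:
                return self.sublabel.label
        return self.variant_label


@dataclass
class RuleSet:
    """A role catalogue plus the full list of pathway definitions."""

    roles: dict[str, FunctionalRole]
    definitions: list[PathwayDefinition]
    shared_segments: dict[str, dict[str, tuple[RoleGroup, ...]]]

    def __iter__(self):
        return iter(self.definitions)

    def __len__(self) -> int:
        return len(self.definitions)

    def for_product(self, product: str) -> list[PathwayDefinition]:
        return [d for d in self.definitions if d.product == product]

    @property
    def products(self) -> tuple[str, ...]:
        seen: list[str] = []
        for d in self.definitions:
            if d.product not in seen:
                seen.append(d.product)
        return tuple(seen)


def base_label(label: str) -> str:
    """Collapse sub-labels for phenotype and summary purposes (P3* -> P3)."""
    return label.rstrip("*")


def _parse_alternative(text: str, catalogue: Mapping[str, FunctionalRole]) -> frozenset[str]:
    roles = [r.strip() for r in str(text).split("+")]
    for r in roles:
        if not r:
            raise ConfigError(f"empty role in alternative {text!r}")
        if r not in catalogue:
            raise ConfigError(f"role {r!r} is not declared in the role catalogue")
    return frozenset(roles)


def _parse_group(entry, catalogue: Mapping[str, FunctionalRole]) -> RoleGroup:
    if isinstance(entry, dict):
        alts = entry.get("alternatives")
        if not alts:
            raise ConfigError("group mapping must provide 'alternatives'")
        required = bool(entry.get("required", True))
        name = str(entry.get("name", ""))
    else:
        alts = entry
        required, name = True, ""
    if not isinstance(alts, list) or not alts:
        raise ConfigError("a role group must be a non-empty list of alternatives")
    parsed = tuple(_parse_alternative(a, catalogue) for a in alts)
    return RoleGroup(alternatives=parsed, required=required, name=name)


def load_pathway_definitions(
    source=None,
    *,
    relaxed_groups: Iterable[str] = (),
) -> RuleSet:
    """Load pathway definitions from YAML (path, text, or parsed mapping).

    With ``source=None`` the default rule content is loaded.  Group names
    listed in ``relaxed_groups`` are marked ``required=False`` (used for the
    propionate P1 CoA-transferase group, where known producers lacking both
    PST and AarC suggest an unidentified transferase).
    """
    if source is None:
        source = (
            importlib.resources.files("scfaprof").joinpath("data/pathways.yaml").read_text()
        )
    if isinstance(source, Path):
        source = source.read_text()
    if isinstance(source, str):
        data = yaml.safe_load(source)
    else:
        data = source
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("pathway config must be a mapping")

    relaxed = set(relaxed_groups)
    catalogue: dict[str, FunctionalRole] = {}
    for role_id, meta in (data.get("roles") or {}).items():
        meta = meta or {}
        if role_id in catalogue:
            raise ConfigError(f"duplicate role {role_id!r} in catalogue")
        catalogue[role_id] = FunctionalRole(
            role_id=str(role_id),
            ec_number=str(meta.get("ec", "") or ""),
            description=str(meta.get("description", "") or ""),
            annotation_only=bool(meta.get("annotation_only", False)),
        )

    definitions: list[PathwayDefinition] = []
    shared_all: dict[str, dict[str, tuple[RoleGroup, ...]]] = {}
    for product, pdata in (data.get("products") or {}).items():
        pdata = pdata or {}
        shared: dict[str, tuple[RoleGroup, ...]] = {}
        for seg_name, groups in (pdata.get("shared") or {}).items():
            shared[seg_name] = tuple(_parse_group(g, catalogue) for g in groups)
        shared_all[product] = shared

        variants_cfg = pdata.get("variants") or {}
        if isinstance(variants_cfg, dict):
            variant_items = [(str(k), v) for k, v in variants_cfg.items()]
        else:  # list form: [{label: ..., groups: ...}, ...]
            variant_items = [(str(v.get("label", "")), v) for v in variants_cfg]
        seen_labels: set[str] = set()
        for label, vdata in variant_items:
            if not label:
                raise ConfigError(f"variant of {product} is missing a label")
            if label in seen_labels:
                raise ConfigError(f"duplicate variant label {label!r} for {product}")
            seen_labels.add(label)
            vdata = vdata or {}
            own = [_parse_group(g, catalogue) for g in vdata.get("groups") or []]
            reqs = list(own)
            for seg_name in vdata.get("shared") or []:
                if seg_name not in shared:
                    raise ConfigError(
                        f"variant {label!r} of {product} references unknown shared "
                        f"segment {seg_name!r}"
                    )
                reqs.extend(shared[seg_name])
            if not reqs:
                raise ConfigError(f"variant {label!r} of {product} has no requirements")
            reqs = [
                RoleGroup(g.alternatives, required=False, name=g.name)
                if g.name and g.name in relaxed
                else g
                for g in reqs
            ]
            sub = None
            if "sublabel" in vdata:
                sdata = vdata["sublabel"]
                sub = Sublabel(
                    label=str(sdata["label"]),
                    group=int(sdata["group"]),
                    sole_alternative=_parse_alternative(sdata["sole_alternative"], catalogue),
                )
                if not 0 <= sub.group < len(reqs):
                    raise ConfigError(f"sublabel group index out of range for {label!r}")
            definitions.append(
                PathwayDefinition(
                    product=str(product),
                    variant_label=label,
                    requirements=tuple(reqs),
                    n_own=len(own),
                    sublabel=sub,
                )
            )
    return RuleSet(roles=catalogue, definitions=definitions, shared_segments=shared_all)


def default_ruleset(relaxed_propionate: bool = False) -> RuleSet:
    """The shipped rule content; ``relaxed_propionate=True`` makes the
    propionate P1 CoA-transferase group optional."""
    relaxed = ("coa_transferase",) if relaxed_propionate else ()
    return load_pathway_definitions(None, relaxed_groups=relaxed)
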
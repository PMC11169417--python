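"""Reaction-template library enumeration.

Builds a virtual combinatorial library by applying reaction transforms
(SMARTS/SMIRKS) to building-block sets, the way make-on-demand ("readily
accessible") libraries are enumerated from validated synthetic methodology.
Each template carries per-role substrate-scope rules so that only building
blocks the published chemistry tolerates enter the cartesian product, and
every emitted product keeps full provenance (template id + block ids) so any
record can be regenerated.

Template files are YAML: a top-level list (or a ``templates:`` key) of
mappings with ``id``, ``transform``, ``roles``, optional ``steps`` (for
multi-component reactions split by mechanism) and optional ``scope``
(role -> list of rules).  See ``parse_templates`` for the rule schema.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import yaml
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors

logger = logging.getLogger("scaffscreen.enumeration")

__all__ = [
    "SubstrateScopeRule",
    "BuildingBlock",
    "ReactionTemplate",
    "ReactionStep",
    "LibraryRecord",
    "ScopeDecision",
    "TemplateError",
    "parse_templates",
    "check_scope",
    "enumerate_products",
    "decompose_multicomponent",
    "canonical_smiles",
]


class TemplateError(ValueError):
    """Raised for malformed or internally inconsistent reaction templates."""


def _parse_rxn(transform: str, context: str):
    try:
        rxn = AllChem.ReactionFromSmarts(transform)
    except Exception as exc:
        raise TemplateError(f"template {context}: unparseable transform "
                            f"{transform!r}: {exc}") from exc
    if rxn is None:
        raise TemplateError(f"template {context}: unparseable transform {transform!r}")
    return rxn


#: named molecular properties usable in property_bound scope rules
PROPERTY_FUNCS = {
    "MW": Descriptors.MolWt,
    "logP": Crippen.MolLogP,
    "TPSA": rdMolDescriptors.CalcTPSA,
    "HBD": rdMolDescriptors.CalcNumHBD,
    "HBA": rdMolDescriptors.CalcNumHBA,
    "RB": rdMolDescriptors.CalcNumRotatableBonds,
    "rings": rdMolDescriptors.CalcNumRings,
    "heavy_atoms": lambda m: m.GetNumHeavyAtoms(),
}


def canonical_smiles(mol: Chem.Mol) -> str:
    """Canonical isomeric SMILES; the dedup key for the whole toolkit."""
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class SubstrateScopeRule:
    """One substrate-scope constraint on a building block.

    kind is one of ``required_substructure``, ``forbidden_substructure`` or
    ``property_bound``.  Substructure kinds use ``pattern`` (SMARTS);
    property_bound uses ``prop`` (a PROPERTY_FUNCS key) with a closed
    interval [lo, hi] (either side may be None for open).
    """

    rule_id: str
    kind: str
    pattern: str | None = None
    prop: str | None = None
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self):
        if self.kind in ("required_substructure", "forbidden_substructure"):
            if not self.pattern or self.prop is not None:
                raise TemplateError(
                    f"rule {self.rule_id}: {self.kind} needs a pattern only"
                )
            if Chem.MolFromSmarts(self.pattern) is None:
                raise TemplateError(
                    f"rule {self.rule_id}: bad SMARTS {self.pattern!r}"
                )
        elif self.kind == "property_bound":
            if self.pattern is not None or not self.prop:
                raise TemplateError(
                    f"rule {self.rule_id}: property_bound needs a property only"
                )
            if self.prop not in PROPERTY_FUNCS:
                raise TemplateError(
                    f"rule {self.rule_id}: unknown property {self.prop!r} "
                    f"(known: {sorted(PROPERTY_FUNCS)})"
                )
        else:
            raise TemplateError(f"rule {self.rule_id}: unknown kind {self.kind!r}")

    @property
    def query(self) -> Chem.Mol | None:
        if self.pattern is None:
            return None
        return Chem.MolFromSmarts(self.pattern)


@dataclass
class BuildingBlock:
    """A reactant with an id and one or more role tags."""

    block_id: str
    mol: Chem.Mol
    role_tags: frozenset[str] = frozenset()

    @classmethod
    def from_smiles(cls, smiles: str, block_id: str, roles=()) -> "BuildingBlock":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"building block {block_id}: unparseable SMILES {smiles!r}")
        return cls(block_id=block_id, mol=mol, role_tags=frozenset(roles))

    @property
    def smiles(self) -> str:
        return canonical_smiles(self.mol)


@dataclass
class ReactionStep:
    """One single-step transform inside a multi-step template.

    ``roles`` name the reactant slots in order; a role may be an original
    template role or the ``produces`` name of an earlier step (an
    intermediate).  ``produces`` names this step's product pool.
    """

    transform: str
    roles: list[str]
    produces: str


@dataclass
class ReactionTemplate:
    """A reaction transform with ordered roles and per-role scope rules."""

    template_id: str
    transform: str
    roles: list[str]
    steps: list[ReactionStep] = field(default_factory=list)
    scope_rules: dict[str, list[SubstrateScopeRule]] = field(default_factory=dict)

    def __post_init__(self):
        rxn = _parse_rxn(self.transform, self.template_id)
        if rxn.GetNumReactantTemplates() != len(self.roles):
            raise TemplateError(
                f"template {self.template_id}: {len(self.roles)} roles declared but "
                f"transform has {rxn.GetNumReactantTemplates()} reactant slots"
            )
        self._validate_steps()

    def _validate_steps(self):
        known = set(self.roles)
        consumed: list[str] = []
        for step in self.steps:
            rxn = _parse_rxn(step.transform, f"{self.template_id}/{step.produces}")
            if rxn.GetNumReactantTemplates() != len(step.roles):
                raise TemplateError(
                    f"template {self.template_id}: step {step.produces} role/arity mismatch"
                )
            for role in step.roles:
                if role not in known:
                    raise TemplateError(
                        f"template {self.template_id}: step {step.produces} references "
                        f"undefined role or intermediate {role!r}"
                    )
                if role in self.roles:
                    consumed.append(role)
            known.add(step.produces)
        if self.steps and sorted(consumed) != sorted(self.roles):
            raise TemplateError(
                f"template {self.template_id}: steps consume roles {sorted(consumed)} "
                f"but template declares {sorted(self.roles)}"
            )

    @property
    def rxn(self) -> AllChem.ChemicalReaction:
        return AllChem.ReactionFromSmarts(self.transform)


@dataclass(frozen=True)
class LibraryRecord:
    """One enumerated product with full provenance."""

    record_id: str
    smiles: str  # canonical isomeric SMILES (the dedup key)
    template_id: str
    block_ids: tuple[str, ...]
    scaffold_key: str | None = None

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass(frozen=True)
class ScopeDecision:
    passed: bool
    matched_rule_ids: tuple[str, ...]


def parse_templates(spec_text: str) -> list[ReactionTemplate]:
    """Parse a YAML template file into validated ReactionTemplates.

    Raises TemplateError on malformed patterns, role/arity mismatches,
    duplicate ids or undefined intermediate roles.
    """
    doc = yaml.safe_load(spec_text)
    if isinstance(doc, dict):
        doc = doc.get("templates", [])
    if not isinstance(doc, list):
        raise TemplateError("template file must be a list (or have a 'templates' key)")
    templates, seen = [], set()
    for entry in doc:
        tid = entry.get("id")
        if not tid:
            raise TemplateError("template entry missing 'id'")
        if tid in seen:
            raise TemplateError(f"duplicate template id {tid!r}")
        seen.add(tid)
        steps = [
            ReactionStep(
                transform=s["transform"],
                roles=list(s["roles"]),
                produces=s.get("produces", f"{tid}.step{i + 1}"),
            )
            for i, s in enumerate(entry.get("steps") or [])
        ]
        scope: dict[str, list[SubstrateScopeRule]] = {}
        for role, rules in (entry.get("scope") or {}).items():
            scope[role] = [
                SubstrateScopeRule(
                    rule_id=r["id"],
                    kind=r["kind"],
                    pattern=r.get("pattern"),
                    prop=r.get("property"),
                    lo=r.get("min"),
                    hi=r.get("max"),
                )
                for r in rules
            ]
        templates.append(
            ReactionTemplate(
                template_id=tid,
                transform=entry["transform"],
                roles=list(entry["roles"]),
                steps=steps,
                scope_rules=scope,
            )
        )
    return templates


def check_scope(
    block: BuildingBlock, rules: list[SubstrateScopeRule]
) -> ScopeDecision:
    """Evaluate substrate-scope rules on a block.

    Fails iff a forbidden substructure matches, a required one is absent, or
    a property bound is violated; matched (= decisive) rule ids are returned
    for audit.  An empty rule list passes vacuously.
    """
    matched: list[str] = []
    passed = True
    for rule in rules:
        if rule.kind == "forbidden_substructure":
            if block.mol.HasSubstructMatch(rule.query):
                matched.append(rule.rule_id)
                passed = False
        elif rule.kind == "required_substructure":
            if not block.mol.HasSubstructMatch(rule.query):
                matched.append(rule.rule_id)
                passed = False
        else:  # property_bound
            value = PROPERTY_FUNCS[rule.prop](block.mol)
            if (rule.lo is not None and value < rule.lo) or (
                rule.hi is not None and value > rule.hi
            ):
                matched.append(rule.rule_id)
                passed = False
    return ScopeDecision(passed=passed, matched_rule_ids=tuple(matched))


def _run_transform(rxn, mols: tuple[Chem.Mol, ...]) -> list[Chem.Mol]:
    """Apply a transform to one reactant tuple, returning sanitized products."""
    out = []
    for prod_set in rxn.RunReactants(mols):
        for mol in prod_set:
            try:
                Chem.SanitizeMol(mol)
            except Exception:  # noqa: BLE001 - unsanitizable product: skip
                continue
            out.append(mol)
    return out


def _passing_blocks(
    template: ReactionTemplate, blocks: dict[str, list[BuildingBlock]]
) -> tuple[dict[str, list[BuildingBlock]], dict[str, int]]:
    passing: dict[str, list[BuildingBlock]] = {}
    rejected: dict[str, int] = {}
    for role in set(role for step in _effective_steps(template) for role in step.roles) | set(
        template.roles
    ):
        if role not in template.roles:
            continue
        pool = sorted(blocks.get(role, []), key=lambda b: b.block_id)
        rules = template.scope_rules.get(role, [])
        kept = [b for b in pool if check_scope(b, rules).passed]
        rejected[role] = len(pool) - len(kept)
        passing[role] = kept
    return passing, rejected


def _effective_steps(template: ReactionTemplate) -> list[ReactionStep]:
    if template.steps:
        return template.steps
    return [
        ReactionStep(
            transform=template.transform,
            roles=list(template.roles),
            produces=f"{template.template_id}.product",
        )
    ]


def enumerate_products(
    template: ReactionTemplate,
    blocks: dict[str, list[BuildingBlock]],
    dedupe: bool = True,
    max_products: int | None = None,
) -> list[LibraryRecord]:
    """Enumerate the library of one template over its building-block pools.

    Applies the transform (or the declared mechanism steps, in order) to the
    cartesian product of scope-passing blocks.  Products are emitted in
    lexicographic order of the block-id tuple so runs are reproducible.
    A tuple on which the transform fails is skipped and logged, never fatal.
    With ``dedupe`` (default), canonical-SMILES uniqueness is enforced.
    """
    passing, rejected = _passing_blocks(template, blocks)
    for role in template.roles:
        if not passing.get(role):
            logger.warning(
                "template %s: role %r has no scope-passing blocks "
                "(%d rejected); empty enumeration",
                template.template_id,
                role,
                rejected.get(role, 0),
            )
            return []

    steps = _effective_steps(template)
    records: list[LibraryRecord] = []
    seen: set[str] = set()
    role_order = list(template.roles)
    pools = [passing[r] for r in role_order]
    for combo in itertools.product(*pools):
        by_role = dict(zip(role_order, combo))
        block_ids = tuple(b.block_id for b in combo)
        # run the step chain; intermediates keyed by their `produces` name
        pools_now: dict[str, list[Chem.Mol]] = {r: [b.mol] for r, b in by_role.items()}
        failed = False
        for step in steps:
            rxn = AllChem.ReactionFromSmarts(step.transform)
            inputs = [pools_now.get(r, []) for r in step.roles]
            produced: list[Chem.Mol] = []
            for mols in itertools.product(*inputs):
                produced.extend(_run_transform(rxn, mols))
            if not produced:
                failed = True
                break
            pools_now[step.produces] = produced
        if failed:
            logger.info(
                "template %s: transform failed on tuple %s; skipped",
                template.template_id,
                block_ids,
            )
            continue
        finals = pools_now[steps[-1].produces]
        for i, mol in enumerate(
            sorted(finals, key=canonical_smiles)
        ):
            smi = canonical_smiles(mol)
            if dedupe:
                if smi in seen:
                    continue
                seen.add(smi)
            suffix = f".{i}" if len(finals) > 1 else ""
            records.append(
                LibraryRecord(
                    record_id=f"{template.template_id}:{'+'.join(block_ids)}{suffix}",
                    smiles=smi,
                    template_id=template.template_id,
                    block_ids=block_ids,
                )
            )
            if max_products is not None and len(records) >= max_products:
                return records
    return records


def decompose_multicomponent(template: ReactionTemplate) -> list[ReactionTemplate]:
    """Return the template's ordered single-step transforms.

    A single-component (or undeclared-steps) template is returned unchanged as
    a length-1 list.  Each declared step becomes a standalone template whose
    scope rules are inherited for the original roles it consumes.  Step chains
    referencing an intermediate that no earlier step produces are rejected at
    template construction time.
    """
    if not template.steps:
        return [template]
    out = []
    for step in template.steps:
        scope = {
            r: template.scope_rules[r]
            for r in step.roles
            if r in template.scope_rules
        }
        out.append(
            ReactionTemplate(
                template_id=f"{template.template_id}:{step.produces}",
                transform=step.transform,
                roles=list(step.roles),
                scope_rules=scope,
            )
        )
    return out
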
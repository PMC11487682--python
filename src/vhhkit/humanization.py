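"""Framework-based VHH humanization with risk-tiered variant design.

Workflow: pick the closest human germline (by framework identity under the
chosen CDR definition), graft the parental CDRs onto the human framework
while retaining Hallmark, Vernier and non-canonical-cysteine residues
(giving the *low-risk variant*), apply the anti-preADA substitution L12V,
then enumerate further variants that humanize the retained key positions
step-by-step or combinatorially, ordered by a risk ladder:

========================  =======================================================
tier                      positions
========================  =======================================================
highest                   Hallmark 42 and 52 (antigen binding / CDR3 stabilization)
high_binding_cys          non-canonical cysteines bridged to CDR3
high_solubility           Hallmark 49 and 50 (hydrophobicity / solubility)
significant_vernier       Vernier zone residues (CDR loop support)
moderate_de_loop          DE loop, IMGT 80-87
low                       everything else in the framework
========================  =======================================================

Humanness is percent framework identity to the closest human germline.
A sequence-level liability scan flags deamidation, isomerization,
N-glycosylation, unpaired-cysteine and CDR-methionine motifs.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from enum import IntEnum

from .annotation import (
    NumberedSequence,
    Residue,
    imgt_key,
    is_fully_annotated,
    noncanonical_cysteines,
    parse_position,
)
from .errors import (
    CapExceededWarning,
    IncompatibleScaffold,
    NoHumanGermline,
)
from .germlines import GermlineDB, GermlineEntry
from .schemes import COMBINED, DEFAULT_VERNIER, RegionScheme, get_scheme


class RiskTier(IntEnum):
    """Humanization risk ladder; lower value = higher risk."""

    HIGHEST = 0
    HIGH_BINDING_CYS = 1
    HIGH_SOLUBILITY = 2
    SIGNIFICANT_VERNIER = 3
    MODERATE_DE_LOOP = 4
    LOW = 5

    @property
    def label(self) -> str:
        return self.name.lower()


_TIER_RATIONALE = {
    RiskTier.HIGHEST: "Hallmark 42/52: crucial for antigen binding or bioactive CDR3 conformation",
    RiskTier.HIGH_BINDING_CYS: "non-canonical cysteine bridged to CDR3; maintains the bioactive conformation",
    RiskTier.HIGH_SOLUBILITY: "Hallmark 49/50: humanization raises hydrophobicity, may reduce solubility",
    RiskTier.SIGNIFICANT_VERNIER: "Vernier zone residue supporting CDR conformation",
    RiskTier.MODERATE_DE_LOOP: "DE loop (IMGT 80-87)",
    RiskTier.LOW: "framework position outside key structural sets",
}


def risk_score(
    position: int,
    context: NumberedSequence,
    vernier: frozenset = DEFAULT_VERNIER,
) -> tuple[RiskTier, str]:
    """Risk tier for humanizing ``position`` in the context of a sequence.

    Precedence: highest > high_binding_cys > high_solubility >
    significant_vernier > moderate_de_loop > low.
    """
    if position in (42, 52):
        tier = RiskTier.HIGHEST
    elif context.get(position) == "C" and position not in (23, 104) and any(
        str(position) in pair
        for pair in noncanonical_cysteines(context).putative_pairs
    ):
        tier = RiskTier.HIGH_BINDING_CYS
    elif position in (49, 50):
        tier = RiskTier.HIGH_SOLUBILITY
    elif position in vernier:
        tier = RiskTier.SIGNIFICANT_VERNIER
    elif 80 <= position <= 87:
        tier = RiskTier.MODERATE_DE_LOOP
    else:
        tier = RiskTier.LOW
    return tier, _TIER_RATIONALE[tier]


# ---------------------------------------------------------------------------
# germline selection and grafting


def closest_human_germline(
    parental: NumberedSequence,
    db: GermlineDB,
    scheme: RegionScheme | str = COMBINED,
) -> tuple[GermlineEntry, float]:
    """Human entry maximizing framework identity; ties by allele name."""
    scheme = get_scheme(scheme)
    humans = db.humans()
    if not humans:
        raise NoHumanGermline("germline database has no human entries")
    scored = sorted(
        ((_fr_identity(parental, e.numbered, scheme), e) for e in humans),
        key=lambda t: (-t[0], t[1].name),
    )
    ident, entry = scored[0]
    return entry, ident


def _fr_identity(seq: NumberedSequence, germ: NumberedSequence, scheme: RegionScheme) -> float:
    fr = scheme.fr_positions
    total = matches = 0
    for r in germ.residues:
        if r.insertion or r.position not in fr:
            continue
        total += 1
        if seq.get(r.position) == r.amino_acid:
            matches += 1
    return 100.0 * matches / total if total else 0.0


def humanness(
    seq: NumberedSequence, db: GermlineDB, scheme: RegionScheme | str = COMBINED
) -> float:
    """Percent framework identity to the closest human germline."""
    entry, ident = closest_human_germline(seq, db, scheme)
    return ident


def graft_cdrs(
    parental: NumberedSequence,
    germline: NumberedSequence,
    scheme: RegionScheme | str = COMBINED,
    retained: frozenset | set = frozenset(),
) -> NumberedSequence:
    """Germline framework + parental CDRs + parental residues at ``retained``.

    CDR columns (including CDR3 insertion codes) are copied byte-identically
    from the parental sequence.
    """
    scheme = get_scheme(scheme)
    if not is_fully_annotated(germline):
        raise IncompatibleScaffold(f"germline {germline.id} is not a full scaffold")
    cdr = scheme.cdr_positions
    out: dict[tuple[int, str], str] = {}
    for r in germline.residues:
        if r.position not in cdr:
            out[(r.position, r.insertion)] = r.amino_acid
    for r in parental.residues:
        if r.position in cdr or (r.position in retained and not r.insertion):
            out[(r.position, r.insertion)] = r.amino_acid
    # a retained position absent from the parental falls back to germline
    residues = [Residue(p, ins, aa) for (p, ins), aa in out.items()]
    residues.sort(key=lambda r: imgt_key(r.position, r.insertion))
    return NumberedSequence(f"{parental.id}-graft", residues)


def build_low_risk_variant(
    parental: NumberedSequence,
    db: GermlineDB,
    scheme: RegionScheme | str = COMBINED,
    vernier: frozenset = DEFAULT_VERNIER,
    apply_preada_fix: bool = True,
) -> NumberedSequence:
    """Graft retaining Hallmark + Vernier + non-canonical Cys, plus L12V.

    The anti-preADA substitution replaces Leu12 by Val when the grafted
    sequence carries leucine there (it is skipped otherwise).
    """
    scheme = get_scheme(scheme)
    entry, _ = closest_human_germline(parental, db, scheme)
    retained = set(_retained_positions(parental, vernier))
    variant = graft_cdrs(parental, entry.numbered, scheme, frozenset(retained))
    if apply_preada_fix and parental.get(12) == "L" and variant.get(12) == "L":
        residues = [
            Residue(r.position, r.insertion, "V") if r.position == 12 and not r.insertion else r
            for r in variant.residues
        ]
        variant = NumberedSequence(variant.id, residues)
    variant.id = f"{parental.id}-v1.1"
    return variant


def _retained_positions(parental: NumberedSequence, vernier: frozenset) -> frozenset:
    cys = {
        parse_position(k)[0]
        for k in noncanonical_cysteines(parental).noncanonical_positions
    }
    return frozenset({42, 49, 50, 52} | set(vernier) | cys)


# ---------------------------------------------------------------------------
# plans and variant enumeration


@dataclass(frozen=True)
class KeyMutation:
    """A candidate humanizing substitution at a retained key position."""

    position: int
    parental_aa: str
    germline_aa: str
    tier: RiskTier
    rationale: str

    @property
    def notation(self) -> str:
        return f"{self.parental_aa}{self.position}{self.germline_aa}"


@dataclass
class HumanizationPlan:
    parental: NumberedSequence
    germline: GermlineEntry
    cdr_definition: RegionScheme
    vernier: frozenset
    low_risk_variant: NumberedSequence
    retained_positions: dict            # position -> reason tag
    key_mutations: list                 # KeyMutation, sorted by (tier, position)
    variants: list = field(default_factory=list)  # (variant id, frozenset of notations)


def plan_humanization(
    parental: NumberedSequence,
    db: GermlineDB,
    scheme: RegionScheme | str = COMBINED,
    vernier: frozenset = DEFAULT_VERNIER,
    mode: str = "stepwise",
    cap: int = 64,
    apply_preada_fix: bool = True,
) -> HumanizationPlan:
    """Full humanization plan: germline, low-risk variant, variant series."""
    scheme = get_scheme(scheme)
    entry, _ = closest_human_germline(parental, db, scheme)
    low_risk = build_low_risk_variant(parental, db, scheme, vernier, apply_preada_fix)

    retained = {}
    for pos in sorted(_retained_positions(parental, vernier)):
        tags = []
        if pos in (42, 49, 50, 52):
            tags.append("hallmark")
        if pos in vernier:
            tags.append("vernier")
        if parental.get(pos) == "C" and pos not in (23, 104):
            tags.append("noncanonical_cys")
        retained[pos] = "+".join(tags)

    keys = []
    fr = scheme.fr_positions
    for pos in sorted(retained):
        if pos not in fr:
            continue  # e.g. Vernier fringe positions inside combined CDRs
        paa, gaa = parental.get(pos), entry.numbered.get(pos)
        if paa is None or gaa is None or paa == gaa:
            continue
        tier, rationale = risk_score(pos, parental, vernier)
        keys.append(KeyMutation(pos, paa, gaa, tier, rationale))
    keys.sort(key=lambda k: (k.tier, k.position))

    plan = HumanizationPlan(parental, entry, scheme, vernier, low_risk, retained, keys)
    plan.variants = enumerate_variants(plan, mode=mode, cap=cap)
    return plan


def enumerate_variants(plan: HumanizationPlan, mode: str = "stepwise", cap: int = 64) -> list:
    """Variant series on top of the low-risk variant.

    ``stepwise``: one variant per additionally humanized key position
    (ids v1.2, v1.3, ...).  ``combinatorial``: all subsets of the key
    humanizations up to ``cap`` (v1.1 is the empty set, i.e. the low-risk
    variant itself), ordered by (risk-tier sum ascending, size ascending,
    notation).  Truncation at the cap emits :class:`CapExceededWarning`.
    """
    keys = plan.key_mutations
    base = plan.parental.id
    if mode == "stepwise":
        return [
            (f"{base}-v1.{i + 2}", frozenset({k.notation}))
            for i, k in enumerate(keys)
        ]
    if mode != "combinatorial":
        raise ValueError(f"unknown enumeration mode {mode!r}")
    subsets = []
    for r in range(len(keys) + 1):
        for combo in itertools.combinations(keys, r):
            subsets.append(combo)
    subsets.sort(
        key=lambda c: (sum(k.tier for k in c), len(c), tuple(sorted(k.notation for k in c)))
    )
    if len(subsets) > cap:
        warnings.warn(
            f"combinatorial enumeration truncated at cap={cap} (of {len(subsets)})",
            CapExceededWarning,
            stacklevel=2,
        )
        subsets = subsets[:cap]
    return [
        (f"{base}-v1.{i + 1}", frozenset(k.notation for k in combo))
        for i, combo in enumerate(subsets)
    ]


def apply_mutations(seq: NumberedSequence, mutations, new_id: str | None = None) -> NumberedSequence:
    """Apply ``XnY`` substitutions (IMGT positions) to a numbered sequence."""
    table = {(r.position, r.insertion): r.amino_acid for r in seq.residues}
    for notation in sorted(mutations):
        m = re.fullmatch(r"([A-Z])(\d+)([A-Z])", notation)
        if not m:
            raise ValueError(f"bad mutation notation {notation!r}")
        old, pos, new = m.group(1), int(m.group(2)), m.group(3)
        if table.get((pos, "")) != old:
            raise ValueError(
                f"{seq.id}: expected {old} at position {pos}, found {table.get((pos, ''))}"
            )
        table[(pos, "")] = new
    residues = [Residue(p, ins, aa) for (p, ins), aa in table.items()]
    residues.sort(key=lambda r: imgt_key(r.position, r.insertion))
    return NumberedSequence(new_id or seq.id, residues)


# ---------------------------------------------------------------------------
# sequence liabilities


DEFAULT_LIABILITY_RULES = {
    "deamidation": r"N[GSTA]",
    "isomerization": r"D[GSTD]",
    "n_glycosylation": r"N[^P][ST]",
}


@dataclass(frozen=True)
class LiabilityFinding:
    motif_class: str
    span: tuple          # IMGT keys of the matched residues
    residues: str


@dataclass
class LiabilityReport:
    findings: list

    def by_class(self, motif_class: str) -> list:
        return [f for f in self.findings if f.motif_class == motif_class]


def liability_scan(
    ns: NumberedSequence,
    scheme: RegionScheme | str = COMBINED,
    rules: dict | None = None,
) -> LiabilityReport:
    """Sequence-level chemical liability scan.

    Regex classes (configurable): deamidation ``N[GSTA]``, isomerization
    ``D[GSTD]``, N-glycosylation ``N[^P][ST]``.  Additionally flags
    unpaired cysteines (odd Cys count or a non-canonical Cys without a
    putative partner) and any methionine inside the CDRs of the active
    scheme.
    """
    scheme = get_scheme(scheme)
    rules = dict(DEFAULT_LIABILITY_RULES if rules is None else rules)
    seq = ns.sequence
    keys = [r.key for r in ns.residues]
    findings = []
    for cls, pattern in rules.items():
        for m in re.finditer(f"(?=({pattern}))", seq):
            s, e = m.start(1), m.end(1)
            findings.append(LiabilityFinding(cls, tuple(keys[s:e]), seq[s:e]))

    cys = [r for r in ns.residues if r.amino_acid == "C"]
    annot = noncanonical_cysteines(ns, scheme)
    paired = {k for pair in annot.putative_pairs for k in pair}
    unpaired = [
        r.key
        for r in cys
        if r.position not in (23, 104) and r.key not in paired
    ]
    if len(cys) % 2 == 1 or unpaired:
        span = tuple(unpaired) if unpaired else tuple(r.key for r in cys)
        findings.append(LiabilityFinding("unpaired_cysteine", span, "C" * len(span)))

    cdr = scheme.cdr_positions
    for r in ns.residues:
        if r.amino_acid == "M" and r.position in cdr:
            findings.append(LiabilityFinding("methionine_cdr", (r.key,), "M"))
    return LiabilityReport(findings)
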
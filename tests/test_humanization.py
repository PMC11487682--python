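"""Germline selection, grafting, risk tiers, humanness and liabilities."""

import warnings

import pytest

import vhhkit as vk
from vhhkit.errors import CapExceededWarning, NoHumanGermline
from vhhkit.germlines import GermlineDB, GermlineEntry
from vhhkit.humanization import RiskTier, apply_mutations, plan_humanization


def _variant(ns, overrides, new_id="var"):
    table = ns.as_dict()
    for pos, aa in overrides.items():
        table[str(pos)] = aa
    return vk.NumberedSequence.from_position_map(new_id, table)


class TestClosestGermline:
    def test_germline_itself_scores_100(self, db, human):
        entry, ident = vk.closest_human_germline(human, db)
        assert entry.name == "synhum-VH3-VGLW*01" and ident == 100.0

    def test_higher_fr_identity_wins(self, db, ferg, human):
        better = _variant(human, {3: "K"}, "hum-B")  # 1 FR mismatch vs ferg? no: vs itself
        db2 = GermlineDB(
            [e for e in db.entries]
            + [GermlineEntry("synhum-extra*01", "human", better)]
        )
        entry, _ = vk.closest_human_germline(human, db2)
        assert entry.name == "synhum-VH3-VGLW*01"

    def test_tie_breaks_lexicographically(self, human):
        a = GermlineEntry("hum-B*01", "human", human)
        b = GermlineEntry("hum-A*01", "human", _variant(human, {}, "hum-A"))
        entry, _ = vk.closest_human_germline(human, GermlineDB([a, b]))
        assert entry.name == "hum-A*01"

    def test_no_human_entries_raises(self, db, ferg):
        camelid_only = GermlineDB([e for e in db.entries if e.species != "human"])
        with pytest.raises(NoHumanGermline):
            vk.closest_human_germline(ferg, camelid_only)


class TestGraft:
    def test_graft_onto_itself_is_identity(self, ferg):
        out = vk.graft_cdrs(ferg, ferg, "combined")
        assert out.as_dict() == ferg.as_dict()

    @pytest.mark.parametrize("scheme", ["imgt", "kabat", "chothia", "combined"])
    def test_cdrs_are_byte_identical_to_parental(self, ferg, human, scheme):
        parental = _variant(ferg, {107: "W", 110: "F"}, "par")
        out = vk.graft_cdrs(parental, human, scheme)
        for region in ("cdr1", "cdr2", "cdr3"):
            assert vk.get_region(out, scheme, region) == vk.get_region(parental, scheme, region)

    def test_positionwise_set_algebra(self, ferg, human):
        # oracle: for every column, output = parental on CDRs+retained, else germline
        retained = frozenset({42, 49, 50, 52, 55})
        scheme = vk.get_scheme("combined")
        out = vk.graft_cdrs(ferg, human, scheme, retained)
        for pos in sorted(human.positions | ferg.positions):
            if pos in scheme.cdr_positions or pos in retained:
                assert out.get(pos) == ferg.get(pos), pos
            else:
                assert out.get(pos) == human.get(pos), pos

    def test_positions_40_and_55_survive_even_with_empty_retained(self, ferg, human):
        # under the combined definition they sit inside the CDRs
        out = vk.graft_cdrs(ferg, human, "combined", frozenset())
        assert out.get(40) == ferg.get(40) != human.get(40)
        assert out.get(55) == ferg.get(55) != human.get(55)


class TestLowRiskVariant:
    def test_l12v_applied(self, db, ferg):
        variant = vk.build_low_risk_variant(ferg, db)
        assert ferg.get(12) == "L" and variant.get(12) == "V"

    def test_l12v_skipped_without_parental_leucine(self, db, ferg, human):
        # position 12 is left to the grafted germline when the parental
        # residue is not the leucine the anti-preADA substitution targets
        parental = _variant(ferg, {12: "T"}, "par")
        variant = vk.build_low_risk_variant(parental, db)
        assert variant.get(12) == human.get(12) == "L"

    def test_hallmark_vernier_cys_retained(self, db, ferg):
        variant = vk.build_low_risk_variant(ferg, db)
        for pos in (42, 49, 50, 52, 55, 78, 87):
            assert variant.get(pos) == ferg.get(pos), pos

    def test_non_key_framework_becomes_human(self, db, ferg, human):
        variant = vk.build_low_risk_variant(ferg, db)
        for pos in (1, 5, 15, 25):
            assert variant.get(pos) == human.get(pos) != ferg.get(pos)

    def test_humanness_never_decreases(self, db, ferg, repertoire):
        seqs, _ = repertoire
        for parental in [ferg] + seqs[:5]:
            variant = vk.build_low_risk_variant(parental, db)
            assert vk.humanness(variant, db) >= vk.humanness(parental, db)


class TestRiskLadder:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (42, RiskTier.HIGHEST),
            (52, RiskTier.HIGHEST),
            (49, RiskTier.HIGH_SOLUBILITY),
            (50, RiskTier.HIGH_SOLUBILITY),
            (78, RiskTier.SIGNIFICANT_VERNIER),
            (87, RiskTier.SIGNIFICANT_VERNIER),
            (83, RiskTier.MODERATE_DE_LOOP),
            (17, RiskTier.LOW),
        ],
    )
    def test_tiers(self, ferg, pos, expected):
        tier, rationale = vk.risk_score(pos, ferg)
        assert tier == expected and rationale

    def test_bridged_cysteine_is_high_risk(self, ferg):
        context = _variant(ferg, {114: "C"}, "cys")  # Cys55 now bridged to CDR3
        tier, _ = vk.risk_score(55, context)
        assert tier == RiskTier.HIGH_BINDING_CYS

    def test_total_function_over_framework(self, ferg):
        for pos in sorted(vk.COMBINED.fr_positions & ferg.positions):
            tier, rationale = vk.risk_score(pos, ferg)
            assert isinstance(tier, RiskTier) and rationale


class TestEnumeration:
    def test_stepwise_yields_one_variant_per_key_position(self, db, ferg):
        plan = plan_humanization(ferg, db, mode="stepwise")
        assert len(plan.variants) == len(plan.key_mutations)
        assert all(len(muts) == 1 for _, muts in plan.variants)

    def test_combinatorial_includes_empty_set(self, db, ferg):
        plan = plan_humanization(ferg, db, mode="combinatorial", cap=1024)
        k = len(plan.key_mutations)
        assert len(plan.variants) == 2 ** k
        assert plan.variants[0][1] == frozenset()

    def test_ordering_single_before_double_at_same_tier(self, db, ferg):
        plan = plan_humanization(ferg, db, mode="combinatorial", cap=1024)
        sizes = {vid: len(m) for vid, m in plan.variants}
        tiers = {k.notation: int(k.tier) for k in plan.key_mutations}
        ranks = [
            (sum(tiers[n] for n in muts), len(muts)) for _, muts in plan.variants
        ]
        assert ranks == sorted(ranks)

    def test_cap_warns_and_truncates(self, db, ferg):
        with pytest.warns(CapExceededWarning):
            plan = plan_humanization(ferg, db, mode="combinatorial", cap=5)
        assert len(plan.variants) == 5

    def test_variants_differ_from_low_risk_only_at_key_positions(self, db, ferg):
        plan = plan_humanization(ferg, db, mode="combinatorial", cap=1024)
        key_pos = {k.position for k in plan.key_mutations}
        for vid, muts in plan.variants[:16]:
            vseq = apply_mutations(plan.low_risk_variant, muts, new_id=vid)
            diff = {
                p for p in plan.low_risk_variant.positions
                if vseq.get(p) != plan.low_risk_variant.get(p)
            }
            assert diff <= key_pos


class TestHumanness:
    def test_germline_scores_100(self, db, human):
        assert vk.humanness(human, db) == 100.0

    def test_single_mismatch_arithmetic(self, db, human):
        scheme = vk.get_scheme("combined")
        n_fr = sum(1 for r in human.residues if r.position in scheme.fr_positions)
        seq = _variant(human, {3: "K"}, "m")  # position 3 is FR1 in every scheme
        expected = 100.0 * (n_fr - 1) / n_fr
        assert vk.humanness(seq, db) == pytest.approx(expected, abs=1e-9)


class TestLiabilities:
    def test_ng_in_cdr2_flags_deamidation(self, ferg):
        seq = _variant(ferg, {62: "N", 63: "G"}, "ng")
        report = vk.liability_scan(seq)
        assert any("62" in f.span for f in report.by_class("deamidation"))

    def test_canonical_cys_pair_is_not_unpaired(self, db):
        clean = db.by_name("syncam-VHH-FERF*01").numbered
        assert not vk.liability_scan(clean).by_class("unpaired_cysteine")

    def test_lone_noncanonical_cys_is_unpaired(self, ferg):
        # germline Cys55 with no CDR3 partner
        assert vk.liability_scan(ferg).by_class("unpaired_cysteine")

    def test_npt_is_not_glycosylation(self, ferg):
        seq = _variant(ferg, {106: "N", 107: "P", 108: "T"}, "npt")
        assert not any(
            "106" in f.span for f in vk.liability_scan(seq).by_class("n_glycosylation")
        )
        seq2 = _variant(ferg, {106: "N", 107: "A", 108: "T"}, "nat")
        assert any(
            "106" in f.span for f in vk.liability_scan(seq2).by_class("n_glycosylation")
        )

    def test_methionine_flagged_only_in_cdrs(self, ferg):
        seq = _variant(ferg, {109: "M"}, "met")
        report = vk.liability_scan(seq)
        flagged = {f.span[0] for f in report.by_class("methionine_cdr")}
        assert "109" in flagged
        assert "91" not in flagged  # scaffold Met91 sits in FR3
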
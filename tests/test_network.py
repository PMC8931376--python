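import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbcflux.network import (
    FluxState,
    NetworkError,
    VARIANT_IDS,
    canonical_network,
    canonical_network_text,
    carbon_accounting,
    check_steady_state,
    full_canonical_network,
    make_variant,
    parse_network,
    photorespiration_return_fraction,
    reference_fluxes,
    reference_pools,
)


class TestParsing:
    def test_canonical_counts(self):
        full = full_canonical_network()
        base = canonical_network()
        # fixture tally: 34 base + 7 recycling + 5 entry + 3 starch-variant
        assert len(full.reactions) == 49
        assert len(base.reactions) == 34
        assert full.compartments == {".p", ".c", ".m", ".v"}
        assert base.compartments == {".p", ".c", ".m"}

    def test_atom_balance_enforced_per_reaction(self):
        full = full_canonical_network()
        for r in full.reactions:
            subs = "".join(r.atom_map.substrates)
            prods = "".join(r.atom_map.products)
            assert sorted(subs) == sorted(prods), r.id

    def test_atom_count_mismatch_names_reaction(self):
        with pytest.raises(NetworkError, match="vX"):
            parse_network("vX: A -> B , ab -> a ; irreversible")

    def test_empty_document(self):
        with pytest.raises(NetworkError, match="empty"):
            parse_network("# nothing here\n")

    def test_syntax_error_reports_line(self):
        text = "a1: A -> B , a -> a ; irreversible\nthis is garbage\n"
        with pytest.raises(NetworkError, match="line 2"):
            parse_network(text)

    def test_conflicting_carbon_counts(self):
        text = (
            "a1: A -> B , ab -> ab ; irreversible\n"
            "a2: B -> C , abc -> abc ; irreversible\n"
        )
        with pytest.raises(NetworkError, match="carbon count"):
            parse_network(text)


class TestSteadyState:
    def test_all_zero_fluxes_balance(self, base_net):
        rep = check_steady_state(base_net, FluxState({}))
        assert all(v["imbalance"] == 0.0 for v in rep.values())

    @pytest.mark.parametrize("variant", VARIANT_IDS)
    def test_reference_fluxes_balance_every_variant(self, base_net, variant):
        kw = {
            "V1": {"glc_entry": 1.9},
            "V2": {"glc_entry_p": 0.5},
            "V3": {"co2_entry": 2.0},
            "V4": {"tp_entry": 0.3},
            "starch_whole": {"starch_turn": 0.5},
            "starch_intermediate": {"starch_turn": 0.5},
        }.get(variant, {})
        net = make_variant(base_net, variant)
        fx = reference_fluxes(variant, **kw)
        rep = check_steady_state(net, fx, tol=1e-9)
        assert all(v["ok"] for v in rep.values()), {
            k: v for k, v in rep.items() if not v["ok"]
        }

    def test_perturbed_flux_flags_adjacent_metabolites(self, base_net):
        fx = reference_fluxes("V0")
        fx.net["prk_p"] += 1.0
        rep = check_steady_state(base_net, fx, tol=1e-9)
        flagged = {k for k, v in rep.items() if not v["ok"]}
        assert flagged == {"RU5P.p", "RUBP.p"}

    def test_infeasible_carbon_balance_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            reference_fluxes("V0", starch=100.0, sucrose_export=30.0)

    def test_flux_state_validation(self, base_net):
        with pytest.raises(ValueError, match="exchange"):
            FluxState({"prk_p": 1.0}, {"prk_p": -0.1}).validate(base_net)
        with pytest.raises(ValueError, match="irreversible"):
            FluxState({"prk_p": -1.0}).validate(base_net)


class TestCarbonAccounting:
    def test_headline_flux_map(self):
        acc = carbon_accounting(
            carboxylation=172,
            glycerate_return=25,
            pentose_return=7,
            photoresp_co2=25,
            shunt_co2=7,
            shunt_glucose=7,
        )
        assert acc["extra_carbons"] == 110  # 75 + 35
        assert acc["photoresp_co2_pct_rounded"] == 18
        assert acc["shunt_co2_pct_rounded"] == 5
        assert acc["atp_per_net_co2"] == pytest.approx(3.15)

    def test_no_oxygenation_no_shunt(self):
        acc = carbon_accounting(
            carboxylation=100,
            glycerate_return=0,
            pentose_return=0,
            photoresp_co2=0,
            shunt_co2=0,
            shunt_glucose=0,
        )
        assert acc["extra_carbons"] == 0
        assert acc["atp_per_net_co2"] == 3.0

    def test_hand_arithmetic_case(self):
        acc = carbon_accounting(
            carboxylation=100,
            glycerate_return=10,
            pentose_return=2,
            photoresp_co2=10,
            shunt_co2=2,
            shunt_glucose=2,
        )
        assert acc["extra_carbons"] == 40
        assert acc["net_assimilation"] == 88
        assert acc["atp_per_net_co2"] == pytest.approx(3 + 6 / 88)

    def test_nonpositive_net_assimilation(self):
        with pytest.raises(ValueError, match="net assimilation"):
            carbon_accounting(
                carboxylation=10,
                glycerate_return=5,
                pentose_return=0,
                photoresp_co2=9,
                shunt_co2=2,
                shunt_glucose=2,
            )

    def test_accounting_from_flux_state_matches_scalars(self):
        fx = reference_fluxes("V5")
        acc = carbon_accounting(fx)
        assert acc["carboxylation"] == 172
        assert acc["net_assimilation"] == 140
        assert acc["extra_carbons"] == 110

    @given(
        st.floats(50, 300),
        st.floats(0, 40),
        st.floats(0, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_accounting_identities(self, vc, gr, pr):
        # releases mirror returns in the lumped salvage stoichiometry
        prco2, shco2 = gr, pr
        if vc - prco2 - shco2 <= 1.0:
            return
        acc = carbon_accounting(
            carboxylation=vc,
            glycerate_return=gr,
            pentose_return=pr,
            photoresp_co2=prco2,
            shunt_co2=shco2,
            shunt_glucose=pr,
        )
        assert acc["extra_carbons"] == pytest.approx(3 * gr + 5 * pr)
        assert acc["net_assimilation"] + prco2 + shco2 == pytest.approx(vc)


class TestPhotorespirationTrace:
    def test_canonical_three_quarters(self, base_net):
        assert photorespiration_return_fraction(base_net) == pytest.approx(0.75)

    def test_lumping_invariance(self):
        lumped = parse_network(
            """
            source S feed
            sink OUT
            sink CO2X
            feed: S -> RUBP , abcde -> abcde ; irreversible
            ox: RUBP -> 2PG + PGA , abcde -> ba + cde ; irreversible
            salvage: 2PG + 2PG -> GA + CO2X , ab + cd -> cdb + a ; irreversible
            ret: GA -> PGA , abc -> abc ; irreversible
            out: PGA -> OUT , abc -> abc ; irreversible
            """
        )
        assert photorespiration_return_fraction(
            lumped, "2PG", "PGA"
        ) == pytest.approx(0.75)

    def test_lossless_salvage_returns_everything(self):
        net = parse_network(
            """
            source S feed
            sink OUT
            feed: S -> RUBP , abcd -> abcd ; irreversible
            ox: RUBP -> 2PG + 2PG , abcd -> ba + cd ; irreversible
            join: 2PG + 2PG -> PGA , ab + cd -> abcd ; irreversible
            out: PGA -> OUT , abcd -> abcd ; irreversible
            """
        )
        assert photorespiration_return_fraction(net, "2PG", "PGA") == pytest.approx(
            1.0
        )

    def test_glycine_export_variant(self):
        # one glycine exported per two 2PG: 4x 2PG = 8 C in, 2 GLY (4 C)
        # exported, remaining 2 GLY -> SER + CO2 -> 3 C reach PGA: 3/8
        net = parse_network(
            """
            source S feed
            sink OUT
            sink GLYX
            sink CO2X
            feed: S -> 2PG , ab -> ab ; irreversible
            pg_gly: 2PG -> GLY , ab -> ab ; irreversible
            gdcx: GLY + GLY + GLY + GLY -> SER + CO2X + GLYX + GLYX , ab + cd + ef + gh -> cdb + a + ef + gh ; irreversible
            ret: SER -> PGA , abc -> abc ; irreversible
            out: PGA -> OUT , abc -> abc ; irreversible
            """
        )
        frac = photorespiration_return_fraction(net, "2PG", "PGA")
        assert frac == pytest.approx(0.375)

    def test_underdetermined_branch_rejected(self):
        net = parse_network(
            """
            source S feed
            sink OUT
            sink GLYX
            sink CO2X
            feed: S -> 2PG , ab -> ab ; irreversible
            pg_gly: 2PG -> GLY , ab -> ab ; irreversible
            export: GLY -> GLYX , ab -> ab ; irreversible
            gdc: GLY + GLY -> SER + CO2X , ab + cd -> cdb + a ; irreversible
            ret: SER -> PGA , abc -> abc ; irreversible
            out: PGA -> OUT , abc -> abc ; irreversible
            """
        )
        with pytest.raises(NetworkError, match="underdetermined"):
            photorespiration_return_fraction(net, "2PG", "PGA")

    def test_missing_path_errors(self):
        net = parse_network(
            """
            source S feed
            sink OUT
            feed: S -> A , ab -> ab ; irreversible
            out: A -> OUT , ab -> ab ; irreversible
            """
        )
        with pytest.raises(NetworkError):
            photorespiration_return_fraction(net, "A", "PGA.p")


class TestVariants:
    def test_v0_identity(self, base_net):
        v0 = make_variant(base_net, "V0")
        assert [r.id for r in v0.reactions] == [r.id for r in base_net.reactions]

    def test_v3_adds_one_co2_entry(self, base_net):
        v3 = make_variant(base_net, "V3")
        added = set(v3.reaction_ids) - set(base_net.reaction_ids)
        assert added == {"co2_entry"}

    def test_v5_adds_recycling_block(self, base_net, v5_net):
        added = set(v5_net.reaction_ids) - set(base_net.reaction_ids)
        assert len(added) == 7
        assert {"inv_c", "hxk_c", "frk_c", "suc_vt", "inv_v"} <= added
        assert v5_net.compartments == {".p", ".c", ".m", ".v"}

    def test_unknown_variant(self, base_net):
        with pytest.raises(NetworkError, match="unknown variant"):
            make_variant(base_net, "V9")

    def test_v5_glucose_entry_is_hexokinase(self):
        fx = reference_fluxes("V5")
        assert fx.net["hxk_c"] == pytest.approx(1.9)

    def test_reference_pools_cover_network(self, v5_net):
        pools = reference_pools(v5_net)
        assert set(pools) == set(v5_net.balanced_metabolites())
        assert all(v > 0 for v in pools.values())
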
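import numpy as np
import pytest
from scipy.linalg import expm

from cbcflux.emu import EMU, emu_decompose
from cbcflux.isotopomer import simulate_isotopomers
from cbcflux.network import FluxState, NetworkError, parse_network
from cbcflux.simulate import (
    CompiledLabelingModel,
    PoolSizes,
    chain_network,
    linear_chain_closed_form,
    simulate_labeling,
)

TIGHT = dict(rtol=1e-11, atol=1e-13)


def brute_force_closure(net, observed):
    """Independent fixpoint computation of the EMU closure (recursive,
    letter-chasing on raw atom maps)."""
    needed = set()

    def trace(met, atoms):
        key = (met, frozenset(atoms))
        if key in needed or not net.metabolites[met].balanced:
            return
        needed.add(key)
        dirs = []
        for r in net.reactions:
            dirs.append((r.substrates, r.products, r.atom_map.substrates, r.atom_map.products))
            if r.reversible:
                dirs.append((r.products, r.substrates, r.atom_map.products, r.atom_map.substrates))
        for subs, prods, smaps, pmaps in dirs:
            for pi, p in enumerate(prods):
                if p != met:
                    continue
                letters = {pmaps[pi][a] for a in atoms}
                for si, s in enumerate(subs):
                    hit = {i for i, ch in enumerate(smaps[si]) if ch in letters}
                    if hit:
                        trace(s, hit)

    for met in observed:
        trace(met, set(range(net.metabolites[met].n_carbons)))
    return needed


class TestDecomposition:
    def test_linear_chain_three_size1_emus(self):
        net = chain_network(3)
        sys = emu_decompose(net, ["P3"])
        assert len(sys.emus) == 3
        assert all(e.size == 1 for e in sys.emus)

    def test_closure_matches_brute_force_on_canonical(self, v5_net):
        sys = emu_decompose(v5_net, ["G6P.c"])
        oracle = brute_force_closure(v5_net, ["G6P.c"])
        mine = {(e.metabolite, e.atoms) for e in sys.emus}
        assert mine == oracle

    def test_closure_invariant(self, v5_net):
        sys = emu_decompose(v5_net, ["S7P.p", "SUC.c"])
        sys.check_closure()  # raises on violation
        # every EMU is reachable from an observed one
        reach = set()
        stack = [e for _, e in sys.observed if e in sys.terms]
        while stack:
            e = stack.pop()
            if e in reach:
                continue
            reach.add(e)
            for t in sys.terms[e]:
                for p in t.pieces:
                    if p in sys.terms and p not in reach:
                        stack.append(p)
        assert reach == set(sys.emus)

    def test_unknown_observed_metabolite(self, base_net):
        with pytest.raises(NetworkError, match="not in network"):
            emu_decompose(base_net, ["NOPE"])


class TestClosedForm:
    def test_single_rate_value(self):
        u = linear_chain_closed_form([1.0], [1.0])
        assert u[0, 0] == pytest.approx(100 * np.exp(-1), abs=1e-12)

    def test_two_rate_form_and_matrix_exponential(self):
        # u2(t) = 2 e^-t - e^-2t for k = (2, 1)
        t = 1.0
        u = linear_chain_closed_form([2.0, 1.0], [t])
        assert u[0, 1] == pytest.approx(100 * (2 * np.exp(-t) - np.exp(-2 * t)))
        # independent oracle: matrix exponential of the chain generator
        k = np.array([2.0, 1.0])
        A = np.array([[-k[0], 0.0], [k[1], -k[1]]])
        u0 = np.ones(2)
        exact = expm(A * t) @ u0
        assert np.allclose(u[0] / 100, exact, atol=1e-12)

    def test_coefficients_sum_to_one(self):
        _, C = linear_chain_closed_form(
            [10.0, 1.0, 0.1], [0.0], return_coefficients=True
        )
        assert np.allclose(C.sum(axis=0), 1.0)

    def test_repeated_rates_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            linear_chain_closed_form([1.0, 1.0], [0.5])


class TestSimulation:
    def test_t0_returns_initial_condition(self, v5_net):
        from cbcflux.network import reference_fluxes, reference_pools

        sys = emu_decompose(v5_net, ["RUBP.p"])
        tc = simulate_labeling(
            CompiledLabelingModel(sys).system,
            reference_fluxes("V5"),
            PoolSizes(reference_pools(v5_net)),
            [0.0],
        )
        assert tc["RUBP.p"].mids[0].fractions[0] == pytest.approx(1.0)

    def test_single_pool_exponential(self, paper_times):
        net = chain_network(1)
        sys = emu_decompose(net, ["P1"])
        k = 3.0  # 1/h
        tc = simulate_labeling(
            sys,
            FluxState({"feed0": 1.0, "r1": 1.0}),
            PoolSizes({"P1": 1.0 / k}),
            paper_times,
            input_enrichment=1.0,
            **TIGHT,
        )
        m0 = tc["P1"].as_array()[:, 0]
        assert np.max(np.abs(m0 - np.exp(-k * paper_times / 60))) < 1e-8

    def test_three_pool_chain_matches_closed_form(self, paper_times):
        k = np.array([10.0, 1.0, 0.1])
        net = chain_network(3)
        sys = emu_decompose(net, ["P1", "P2", "P3"])
        fx = FluxState({f"r{i}": 1.0 for i in range(1, 4)} | {"feed0": 1.0})
        tc = simulate_labeling(
            sys, fx, PoolSizes({f"P{i+1}": 1 / k[i] for i in range(3)}),
            paper_times, input_enrichment=1.0, **TIGHT,
        )
        sim = np.vstack([tc[f"P{j+1}"].twelve_c_series() for j in range(3)]).T
        exact = linear_chain_closed_form(k, paper_times / 60.0)
        assert np.max(np.abs(sim - exact)) / 100 < 1e-8

    def test_emu_equals_isotopomer_brute_force(self, paper_times):
        toy = parse_network(
            """
            source S feed
            source U unlabeled
            sink OUT2
            sink OUT1
            f1: S -> A , a -> a ; irreversible
            f2: U -> B , ab -> ab ; irreversible
            cond: A + B -> C , a + bc -> bca ; reversible
            split: C -> D + E , abc -> ab + c ; irreversible
            d_out: D -> OUT2 , ab -> ab ; irreversible
            e_out: E -> OUT1 , a -> a ; irreversible
            """
        )
        fx = FluxState(
            {"f1": 1.0, "f2": 1.0, "cond": 1.0, "split": 1.0, "d_out": 1.0, "e_out": 1.0},
            {"cond": 0.5},
        )
        pools = PoolSizes({"A": 0.5, "B": 2.0, "C": 1.0, "D": 0.3, "E": 0.7})
        sys = emu_decompose(toy, ["A", "B", "C", "D", "E"])
        emu_tc = simulate_labeling(sys, fx, pools, paper_times, **TIGHT)
        iso_tc = simulate_isotopomers(toy, fx, pools, paper_times)
        for m in ["A", "B", "C", "D", "E"]:
            assert (
                np.max(np.abs(emu_tc[m].as_array() - iso_tc[m].as_array())) < 1e-8
            ), m

    def test_simplex_preserved(self, v5_net, paper_times):
        from cbcflux.network import reference_fluxes, reference_pools

        sys = emu_decompose(v5_net, ["G6P.c", "S7P.p", "SUC.c"])
        tc = simulate_labeling(
            sys,
            reference_fluxes("V5"),
            PoolSizes(reference_pools(v5_net)),
            paper_times,
        )
        for name, course in tc.items():
            arr = course.as_array()
            assert np.all(arr >= 0)
            assert np.allclose(arr.sum(axis=1), 1.0, atol=1e-9)

    def test_monotone_washout_without_unlabeled_entry(self, base_net, paper_times):
        from cbcflux.network import reference_fluxes, reference_pools

        sys = emu_decompose(base_net, ["RUBP.p", "PGA.p", "S7P.p"])
        tc = simulate_labeling(
            sys,
            reference_fluxes("V0"),
            PoolSizes(reference_pools(base_net)),
            paper_times,
            input_enrichment=1.0,
        )
        for name, course in tc.items():
            u = course.twelve_c_series()
            assert np.all(np.diff(u) <= 1e-6), name
            assert u[-1] < 0.2 * u[0]

    def test_steady_state_unlabeled_share(self):
        # pool fed 70% labeled, 30% unlabeled: steady 12C = unlabeled share
        net = parse_network(
            """
            source S feed
            source U unlabeled
            sink OUT
            fin: S -> A , a -> a ; irreversible
            uin: U -> A , a -> a ; irreversible
            out: A -> OUT , a -> a ; irreversible
            """
        )
        fx = FluxState({"fin": 0.7, "uin": 0.3, "out": 1.0})
        tc = simulate_labeling(
            emu_decompose(net, ["A"]), fx, PoolSizes({"A": 0.05}),
            [0.0, 600.0], input_enrichment=1.0,
        )
        assert tc["A"].as_array()[-1, 0] == pytest.approx(0.3, abs=1e-6)

    def test_time_rescaling_equivalence(self, paper_times):
        net = chain_network(2)
        sys = emu_decompose(net, ["P2"])
        fx1 = FluxState({"feed0": 1.0, "r1": 1.0, "r2": 1.0})
        fx2 = FluxState({"feed0": 2.0, "r1": 2.0, "r2": 2.0})
        pools = PoolSizes({"P1": 0.5, "P2": 1.5})
        a = simulate_labeling(sys, fx1, pools, paper_times, **TIGHT)
        b = simulate_labeling(sys, fx2, pools, paper_times / 2.0, **TIGHT)
        assert np.allclose(
            a["P2"].as_array(), b["P2"].as_array(), atol=1e-8
        )

    def test_inactive_fraction_dilutes_observation(self, base_net, paper_times):
        from cbcflux.network import reference_fluxes, reference_pools

        sys = emu_decompose(base_net, ["GLY.m"])
        pools = reference_pools(base_net)
        fx = reference_fluxes("V0")
        plain = simulate_labeling(sys, fx, PoolSizes(pools), paper_times)
        frozen = simulate_labeling(
            sys, fx, PoolSizes(pools, {"GLY.m": 0.4}), paper_times
        )
        a = plain["GLY.m"].as_array()
        b = frozen["GLY.m"].as_array()
        init = np.zeros(a.shape[1])
        init[0] = 1.0
        assert np.allclose(b, 0.6 * a + 0.4 * init, atol=1e-9)
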
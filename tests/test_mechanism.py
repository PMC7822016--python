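import itertools
import math

import numpy as np
import pytest

import mvphi as m
from mvphi import aid, compute_distinction, enumerate_tripartitions, mice, phi_mip
from mvphi.mechanism import PHI_PRECISION

from .oracles import aid_oracle, phi_oracle, tripartitions_oracle


class TestAID:
    def test_identical_distributions_give_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert aid(p, p) == (0.0, 0)

    def test_point_mass_vs_uniform(self):
        for k in (2, 3, 5):
            p = np.zeros(k)
            p[1] = 1.0
            q = np.full(k, 1.0 / k)
            phi, state = aid(p, q)
            assert phi == pytest.approx(math.log2(k))
            assert state == 1

    def test_matches_enumeration_on_random_pairs(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(4))
            q = rng.dirichlet(np.ones(4))
            assert aid(p, q) == aid_oracle(p, q)

    def test_zero_partitioned_probability_is_infinite_unless_capped(self):
        p = np.array([1.0, 0.0])
        q = np.array([0.0, 1.0])
        phi, _ = aid(p, q)
        assert phi == math.inf
        phi_capped, _ = aid(p, q, cap=10.0)
        assert phi_capped == 10.0

    def test_mismatched_purviews_rejected(self, p53_net):
        a = m.effect_repertoire(p53_net, (0,), (0,), (1,))
        b = m.effect_repertoire(p53_net, (0,), (0,), (2,))
        with pytest.raises(m.ValidationError):
            aid(a, b)


class TestTripartitions:
    def test_minimal_pair_yields_only_the_full_cut(self):
        parts = enumerate_tripartitions((0,), (1,))
        assert len(parts) == 1
        assert set(parts[0].parts) == {((0,), ()), ((), (1,))}

    @pytest.mark.parametrize(
        "mech,purview",
        [((0,), (1, 2)), ((0, 1), (1, 2)), ((0, 1), (0, 1, 2)), ((0, 1, 2), (0, 1))],
    )
    def test_counts_match_brute_force_oracle(self, mech, purview):
        got = enumerate_tripartitions(mech, purview)
        want = tripartitions_oracle(mech, purview)
        assert len(got) == len(want)
        as_sets = {
            frozenset((frozenset(pm), frozenset(pz)) for pm, pz in p.parts)
            for p in got
        }
        assert as_sets == want

    def test_identity_never_returned(self):
        for mech, purview in [((0,), (1,)), ((0, 1), (2,)), ((0,), (1, 2))]:
            for p in enumerate_tripartitions(mech, purview):
                assert set(p.parts) != {(tuple(mech), tuple(purview))}

    def test_deterministic_order(self):
        a = enumerate_tripartitions((0, 1), (2, 3))
        b = enumerate_tripartitions((0, 1), (2, 3))
        assert a == b

    def test_empty_purview_rejected(self):
        with pytest.raises(m.ValidationError):
            enumerate_tripartitions((0,), ())


class TestPartitionedRepertoire:
    def test_full_cut_gives_unconstrained(self, p53_net):
        [full_cut] = enumerate_tripartitions((2,), (0,))
        rep = m.partitioned_repertoire(p53_net, full_cut, "effect", (2,), (1,))
        unc = m.unconstrained_repertoire(p53_net, "effect", (0,))
        assert np.allclose(rep.dist, unc.dist)

    def test_parts_compose_by_multiplication(self, p53_net):
        for partition in enumerate_tripartitions((0, 2), (0, 1)):
            rep = m.partitioned_repertoire(
                p53_net, partition, "effect", (0, 2), (0, 1)
            )
            md = np.ones((3, 2))
            for pm, pz in partition.parts:
                if not pz:
                    continue
                part = m.effect_repertoire(
                    p53_net, pm, tuple({0: 0, 2: 1}[i] for i in pm), pz
                )
                shape = [1, 1]
                for z in pz:
                    shape[{0: 0, 1: 1}[z]] = p53_net.radices[z]
                md = md * part.dist.reshape(shape, order="F")
            assert np.allclose(rep.dist, md.ravel(order="F"))


class TestPhiMip:
    def test_no_dependence_means_zero_phi(self, p53_net):
        # Mc has no influence on P': phi of {Mc} over purview {P} (effect) is 0
        res = phi_mip(p53_net, (1,), (0,), (0,), "effect")
        assert res.phi == 0.0

    def test_mn_irreducibly_drives_p(self, p53_net):
        res = phi_mip(p53_net, (2,), (1,), (0,), "effect")
        assert res.phi > 0
        oracle = phi_oracle(p53_net.tpm, p53_net.radices, (2,), (1,), [0], "effect")
        assert res.phi == pytest.approx(oracle, abs=1e-9)

    def test_phi_bounded_by_full_cut(self, p53_net):
        for mech, purv in [((0,), (2,)), ((0, 2), (0, 2)), ((1,), (2,))]:
            for direction in ("cause", "effect"):
                res = phi_mip(p53_net, mech, tuple(0 for _ in mech), purv, direction)
                p = m.repertoires.repertoire(
                    p53_net, direction, mech, tuple(0 for _ in mech), purv
                )
                unc = m.unconstrained_repertoire(p53_net, direction, purv)
                if p.null:
                    continue
                full_cut_phi, _ = aid(p.dist, unc.dist)
                assert res.phi <= full_cut_phi + 1e-12

    def test_matches_brute_force_on_small_networks(self, small_nets):
        rng = np.random.default_rng(3)
        for net in small_nets:
            if net.n != 2:
                continue
            for mech in [(0,), (1,), (0, 1)]:
                mstate = tuple(int(rng.integers(net.radices[i])) for i in mech)
                for purv in [(0,), (1,), (0, 1)]:
                    for direction in ("cause", "effect"):
                        got = phi_mip(net, mech, mstate, purv, direction)
                        want = phi_oracle(
                            net.tpm, net.radices, mech, mstate, list(purv), direction
                        )
                        assert got.phi == pytest.approx(want, abs=1e-9)

    def test_severed_network_has_no_phi(self, p53_net):
        # cut everything: all nodes isolated from each other
        net = p53_net
        for cut in (m.SystemCut((0,), (1, 2)), ):
            cut_net = m.apply_cut(net, cut)
            cut_net = m.apply_cut(cut_net, m.SystemCut((1, 2), (0,)))
            # now no information crosses between {P} and {Mc,Mn}
            res = phi_mip(cut_net, (0,), (0,), (1,), "effect")
            assert res.phi == 0.0


class TestMICE:
    def test_copy_chain_effect_purview_is_the_target(self):
        # A -> B copy chain; A's effect MICE should be over {B}
        tpm = np.zeros((4, 4))
        for h in range(4):
            a = h % 2
            tpm[h, a + 2 * a] = 1.0
        net = m.Network(tpm, (2, 2))
        result = mice(net, (0,), (1,), "effect")
        assert result.purview == (0, 1)  # A also copies itself
        assert result.phi > 0

    def test_constant_node_has_zero_phi_everywhere(self):
        tpm = np.zeros((4, 4))
        tpm[:, 1] = 1.0
        net = m.Network(tpm, (2, 2))
        result = mice(net, (0,), (1,), "effect")
        assert result.phi == 0.0

    def test_p53_cause_of_silent_p_specifies_active_mn(self, p53_net):
        result = mice(p53_net, (0,), (0,), "cause")
        assert result.purview == (2,)
        assert result.specified_state == (1,)
        assert result.phi > 0


class TestDistinction:
    def test_isolated_node_yields_none(self):
        # two nodes, each uniformly random: nothing constrains anything
        tpm = np.full((4, 4), 0.25)
        net = m.Network(tpm, (2, 2))
        assert compute_distinction(net, (0,), (0,)) is None

    def test_returned_distinction_has_positive_phi(self, p53_net):
        for mech in [(0,), (1,), (2,)]:
            d = compute_distinction(p53_net, mech, tuple([(0, 0, 1)[i] for i in mech]))
            if d is not None:
                assert d.phi > PHI_PRECISION
                assert d.phi == pytest.approx(min(d.cause.phi, d.effect.phi))
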
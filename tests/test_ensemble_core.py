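"""Block partitioning, state enumeration, free energies and calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bwsme import (ModelParameters, Microstate, compute_contacts,
                   compute_partition_function, count_states, enumerate_states,
                   heat_capacity_curve, partition_into_blocks,
                   state_free_energy)
from bwsme.ensemble_core import (calibrate_isostable_pair, calibrate_xi,
                                 folded_unfolded_dG)
from bwsme.errors import CalibrationError
from bwsme.fixtures import brute_force_partition, make_random_toy
from bwsme.structure_io import ContactMap
from tests.conftest import make_stub_chain


class TestBlockPartition:
    def test_uniform_300_block3_gives_100_blocks(self):
        part = partition_into_blocks(make_stub_chain(300), 3)
        assert part.Nb == 100

    def test_ss_boundary_never_spanned(self):
        chain = make_stub_chain(16)
        for r in chain.residues[10:]:
            r.ss_label = "coil"
        part = partition_into_blocks(chain, 4)
        sizes = [e - s + 1 for s, e in part.blocks]
        assert sizes == [4, 4, 2, 4, 2]
        assert part.Nb == 5

    def test_block_size_one_gives_one_block_per_residue(self):
        part = partition_into_blocks(make_stub_chain(7), 1)
        assert part.Nb == 7
        assert all(s == e for s, e in part.blocks)


class TestCountAndEnumerate:
    @pytest.mark.parametrize("Nb,expected", [(1, 2), (4, 21), (100, 8_170_901)])
    def test_count_formula_values(self, Nb, expected):
        assert count_states(Nb) == expected

    def test_enumeration_matches_count(self):
        for Nb in range(1, 13):
            assert len(enumerate_states(Nb)) == count_states(Nb)

    def test_nb2_states(self):
        states = enumerate_states(2)
        assert len(states) == 4
        kinds = [s.kind for s in states]
        assert kinds == ["U", "SSA", "SSA", "SSA"]
        assert [s.islands for s in states[1:]] == [((1, 1),), ((1, 2),),
                                                   ((2, 2),)]

    def test_nb3_two_island_config(self):
        states = enumerate_states(3)
        assert len(states) == 9
        two = [s for s in states if s.kind in ("DSA", "DSAwL")]
        assert len(two) == 2
        assert all(s.islands == ((1, 1), (3, 3)) for s in two)

    def test_microstate_invariants_enforced(self):
        with pytest.raises(ValueError):
            Microstate("DSA", (((1, 2), (3, 4))))  # adjacent islands
        with pytest.raises(ValueError):
            Microstate("SSA", ((2, 1),))
        with pytest.raises(ValueError):
            Microstate("U", ((1, 1),))


class TestStateFreeEnergy:
    def test_unfolded_reference_is_zero(self, toy_inputs, toy_params):
        _, part, contacts, charges = toy_inputs
        u = Microstate("U", ())
        for T in (280.0, 310.0, 385.0):
            assert state_free_energy(u, part, contacts, charges,
                                     toy_params, T) == 0.0

    def test_hand_evaluated_single_block(self):
        # 4-residue single-block helix, 3 contacts, no charges, T = T_ref:
        # dG = 3 * xi - T * (4 * dS_res) = -150 + 15400 = 15250 J/mol
        chain = make_stub_chain(4)
        part = partition_into_blocks(chain, 4)
        cm = ContactMap({(1, 2): 1, (2, 3): 1, (3, 4): 1}, 5.0)
        params = ModelParameters(xi=-50.0)
        dg = state_free_energy(Microstate("SSA", ((1, 1),)), part, cm, None,
                               params, 385.0)
        assert dg == pytest.approx(15250.0)

    def test_dsa_vs_dsawl_bookkeeping(self):
        # Two islands with one inter-island contact pair: DSAwL differs from
        # DSA by the cross interaction minus T times the loop entropy.
        chain = make_stub_chain(3)
        part = partition_into_blocks(chain, 1)
        cm = ContactMap({(1, 3): 2}, 5.0)
        params = ModelParameters(xi=-50.0, block_size=1)
        T = 310.0
        islands = ((1, 1), (3, 3))
        dsa = state_free_energy(Microstate("DSA", islands), part, cm, None,
                                params, T)
        wl = state_free_energy(Microstate("DSAwL", islands), part, cm, None,
                               params, T)
        g = (T - params.T_ref) - T * math.log(T / params.T_ref)
        cross = 2 * (params.xi + params.dCp_cont * g)
        loop_entropy = params.dS_res  # residue 2 fixed in the loop
        assert wl - dsa == pytest.approx(cross - T * loop_entropy, rel=1e-12)

    def test_stab_term_scales_with_xi_at_tref(self, toy_inputs):
        _, part, contacts, _ = toy_inputs
        T = 385.0  # solvation term vanishes at T_ref
        base = ModelParameters(xi=-40.0, block_size=1)
        scaled = ModelParameters(xi=-120.0, block_size=1)
        for state in enumerate_states(part)[1:30]:
            e0 = state_free_energy(state, part, contacts, None, base, T)
            e1 = state_free_energy(state, part, contacts, None, scaled, T)
            s = -T * sum(
                -10.0 - (6.1 if part.ss_labels[i - 1] == "coil" else 0.0)
                if part.residue_names[i - 1] != "PRO" else 0.0
                for i in _fixed_residues(state, part))
            assert e1 - s == pytest.approx(3.0 * (e0 - s), rel=1e-9)


def _fixed_residues(state, part):
    fixed = []
    islands = list(state.islands)
    if state.kind == "DSAwL":
        (p1, q1), (p2, q2) = islands
        islands = [(p1, q1), (q1 + 1, p2 - 1), (p2, q2)]
    for p, q in islands:
        for b in range(p - 1, q):
            s, e = part.blocks[b]
            fixed.extend(range(s, e + 1))
    return fixed


class TestPartitionFunction:
    def test_two_state_toy_z_equals_two(self):
        # single two-residue block whose contact energy exactly cancels the
        # entropy at 300 K: dG_folded = 100*(-60) - 300*(2*(-10)) = 0 -> Z = 2
        chain = make_stub_chain(2)
        part = partition_into_blocks(chain, 2)
        cm = ContactMap({(1, 2): 100}, 5.0)
        params = ModelParameters(xi=-60.0, dCp_cont=0.0, dS_res=-10.0,
                                 block_size=1)
        ens = compute_partition_function(part, cm, None, params, 300.0)
        assert ens.Z == pytest.approx(2.0, rel=1e-12)
        assert ens.free_energies[0] == 0.0

    def test_matches_brute_force_oracle(self, toy_inputs, toy_params):
        _, part, contacts, charges = toy_inputs
        structure = toy_inputs[0]
        T = 350.0
        ens = compute_partition_function(part, contacts, charges, toy_params, T)
        bf = brute_force_partition(structure, contacts, charges, toy_params, T)
        assert ens.Z == pytest.approx(bf.Z, rel=1e-10)
        engine = {(s.kind, s.islands): dg
                  for s, dg in zip(ens.states, ens.free_energies)}
        for kind, islands, _, dg, _ in bf.records:
            assert engine[(kind, islands)] == pytest.approx(dg, abs=1e-8)

    def test_z_grows_toward_state_count_in_high_t_limit(self, toy_inputs):
        # with negligible entropy and dCp = 0, dG_i = n_i * xi < 0 is constant
        # and every weight falls monotonically toward 1 as T grows, so Z
        # approaches the microstate count from above
        _, part, contacts, _ = toy_inputs
        params = ModelParameters(xi=-60.0, dCp_cont=0.0, dS_res=-1e-9,
                                 ddS_coil=0.0, block_size=1)
        temps = (300.0, 400.0, 600.0, 1000.0, 5000.0, 1e7)
        zs = [compute_partition_function(part, contacts, None, params, T).Z
              for T in temps]
        assert all(a > b for a, b in zip(zs, zs[1:]))
        n_states = count_states(part.Nb)
        assert all(z > n_states for z in zs)
        assert zs[-1] == pytest.approx(n_states, rel=1e-3)

    def test_reversal_invariance(self, toy_inputs, toy_params):
        structure, part, contacts, charges = toy_inputs
        n = len(structure)
        rev_struct = make_stub_chain(n)
        for i, r in enumerate(rev_struct.residues):
            src = structure.residues[n - 1 - i]
            r.name = src.name
            r.ss_label = src.ss_label
        rev_part = partition_into_blocks(rev_struct, 1)
        rev_contacts = ContactMap(
            {(n + 1 - j, n + 1 - i): c for (i, j), c in contacts.items()}, 5.0)
        from bwsme.structure_io import ChargeEntry, ChargeSet
        rev_charges = ChargeSet(tuple(
            ChargeEntry(n + 1 - e.residue_index, e.charge, e.site_xyz, e.kind)
            for e in charges.entries))
        z1 = compute_partition_function(part, contacts, charges,
                                        toy_params, 340.0).Z
        z2 = compute_partition_function(rev_part, rev_contacts, rev_charges,
                                        toy_params, 340.0).Z
        assert z1 == pytest.approx(z2, rel=1e-10)


class TestHeatCapacity:
    def test_degenerate_ensemble_gives_zero_cp(self, toy_inputs):
        # with no contacts, no charges and negligible entropy every state has
        # dG ~ 0, ln Z is constant in T and the heat capacity vanishes
        _, part, _, _ = toy_inputs
        params = ModelParameters(xi=-60.0, dCp_cont=0.0, dS_res=-1e-9,
                                 ddS_coil=0.0, block_size=1)
        T, Cp = heat_capacity_curve(part, ContactMap({}, 5.0), None, params,
                                    np.arange(300.0, 320.0, 1.0))
        assert np.max(np.abs(Cp)) < 1e-3

    def test_fluctuation_theorem_oracle(self):
        # Cp = <dH/dT> + Var(H)/(R T^2) with H_i = dG_i - T dG_i', evaluated
        # on the explicitly enumerated ensemble with numerical dG derivatives.
        structure = make_random_toy(8, seed=5)
        contacts = compute_contacts(structure)
        part = partition_into_blocks(structure, 1)
        params = ModelParameters(xi=-60.0, block_size=1)
        T0 = 340.0
        T, Cp = heat_capacity_curve(part, contacts, None, params,
                                    np.arange(T0 - 5.0, T0 + 5.5, 1.0))
        i0 = int(np.argmin(np.abs(T - T0)))
        R = params.R
        h = 1e-3
        Hs, Hps, ws = [], [], []
        for state in enumerate_states(part):
            dg = state_free_energy(state, part, contacts, None, params, T0)
            up = state_free_energy(state, part, contacts, None, params, T0 + h)
            dn = state_free_energy(state, part, contacts, None, params, T0 - h)
            d1 = (up - dn) / (2 * h)
            d2 = (up - 2 * dg + dn) / h ** 2
            Hs.append(dg - T0 * d1)
            Hps.append(-T0 * d2)
            ws.append(math.exp(-dg / (R * T0)))
        Hs, Hps, ws = map(np.array, (Hs, Hps, ws))
        ws /= ws.sum()
        Hmean = float(ws @ Hs)
        cp_fluct = float(ws @ Hps) + float(ws @ (Hs - Hmean) ** 2) / (R * T0 ** 2)
        assert Cp[i0] == pytest.approx(cp_fluct, rel=0.01)

    def test_nonnegative_cp_without_solvation_term(self, two_helix_inputs):
        # with dCp_cont = 0 the model Cp reduces to the variance form, which
        # is nonnegative; the solvation term shifts the folded baseline below
        # the unfolded one by construction and is tested separately.
        _, part, contacts, charges = two_helix_inputs
        params = ModelParameters(xi=-120.0, dCp_cont=0.0)
        T, Cp = heat_capacity_curve(part, contacts, None, params,
                                    np.arange(260.0, 420.0, 2.0))
        assert np.all(Cp > -1e-6)


class TestCalibration:
    def test_self_consistency_two_helix(self, two_helix_inputs):
        _, part, contacts, charges = two_helix_inputs
        result = calibrate_xi(part, contacts, charges, ModelParameters())
        assert 332.5 <= result.peak_T <= 333.5
        T, Cp = heat_capacity_curve(part, contacts, charges, result.params,
                                    np.arange(250.0, 421.0, 1.0))
        assert 332.5 <= T[int(np.argmax(Cp))] <= 333.5

    def test_higher_target_needs_stronger_xi(self, two_helix_inputs):
        _, part, contacts, charges = two_helix_inputs
        r333 = calibrate_xi(part, contacts, charges, ModelParameters(),
                            target_Tm=333.0)
        r343 = calibrate_xi(part, contacts, charges, ModelParameters(),
                            target_Tm=343.0)
        assert abs(r343.params.xi) > abs(r333.params.xi)

    def test_two_state_closed_form_recovery(self):
        # single block of 12 residues, 300 contacts, dCp = 0: the closed-form
        # two-state Cp is E^2 p (1-p) / (R T^2); invert its argmax for xi.
        from scipy.optimize import brentq, minimize_scalar
        chain = make_stub_chain(12)
        part = partition_into_blocks(chain, 12)
        cm = ContactMap({(1, 12): 300}, 5.0)
        params = ModelParameters(xi=-100.0, dCp_cont=0.0, block_size=12)
        R, S = params.R, 12 * params.dS_res

        def closed_argmax(xi):
            E = 300.0 * xi

            def neg_cp(T):
                p = 1.0 / (1.0 + math.exp((E - T * S) / (R * T)))
                return -E ** 2 * p * (1.0 - p) / (R * T ** 2)

            return minimize_scalar(neg_cp, bounds=(260.0, 420.0),
                                   method="bounded").x

        xi_closed = brentq(lambda xi: closed_argmax(xi) - 333.0, -200.0, -20.0)
        result = calibrate_xi(part, cm, None, params, target_Tm=333.0)
        assert result.params.xi == pytest.approx(xi_closed, abs=0.5)

    def test_unreachable_target_raises(self, toy_inputs):
        _, part, _, _ = toy_inputs
        cm = ContactMap({}, 5.0)  # nothing to stabilize
        with pytest.raises(CalibrationError):
            calibrate_xi(part, cm, None, ModelParameters(block_size=1))


class TestIsostablePair:
    def test_identical_structures_identical_xi(self, two_helix_inputs):
        _, part, contacts, charges = two_helix_inputs
        triple = (part, contacts, charges)
        pi, pa = calibrate_isostable_pair(triple, triple, ModelParameters())
        assert pi.xi == pytest.approx(pa.xi, abs=1e-3)
        d_i = folded_unfolded_dG(part, contacts, charges, pi, 310.0)
        d_a = folded_unfolded_dG(part, contacts, charges, pa, 310.0)
        assert abs(d_i - d_a) <= 100.0

    def test_more_contacts_need_weaker_xi(self, two_helix_inputs):
        _, part, contacts, charges = two_helix_inputs
        boosted = ContactMap({k: n + max(1, n // 10)
                              for k, n in contacts.pair_counts.items()}, 5.0)
        pi, pa = calibrate_isostable_pair((part, contacts, charges),
                                          (part, boosted, charges),
                                          ModelParameters())
        assert abs(pa.xi) < abs(pi.xi)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(Nb=st.integers(min_value=1, max_value=20))
def test_enumeration_count_property(Nb):
    states = enumerate_states(Nb)
    assert len(states) == count_states(Nb)
    seen = set()
    for s in states:
        key = (s.kind, s.islands)
        assert key not in seen
        seen.add(key)
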
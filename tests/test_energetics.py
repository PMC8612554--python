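import numpy as np
import pandas as pd
import pytest
from scipy import constants

from aptamd.energetics import (
    EnergeticsConfig,
    R_KCAL,
    contribution_correlation,
    coulomb_inter,
    dg_from_kd,
    entropy_terms,
    lj_inter,
    mmpbsa_summary,
    nonpolar_term,
    pb_delta,
    per_residue_decomposition,
    sasa,
    solve_pb,
)
from aptamd.model_io import AtomRecord, Segment, Topology
from aptamd.pb import solve_pb_charges

BORN_EXACT = -332.0636 / 2 * (1 - 1 / 80.0) / 2.0  # q=1e, R=2 Å, eps 1->80


class TestCoulomb:
    def test_single_pair_closed_form(self, config):
        e = coulomb_inter(
            np.array([[0.0, 0, 0]]), np.array([1.0]),
            np.array([[3.320636, 0, 0]]), np.array([-1.0]), config,
        )
        assert e == pytest.approx(-100.0, abs=1e-9)

    def test_zero_charges(self, config, rng):
        e = coulomb_inter(
            rng.normal(size=(5, 3)), rng.normal(size=5),
            rng.normal(size=(4, 3)) + 20.0, np.zeros(4), config,
        )
        assert e == 0.0

    def test_matches_double_loop(self, config, rng):
        """Vectorised sum equals a naive double loop on random instances."""
        for _ in range(20):
            ca = rng.normal(size=(50, 3))
            cb = rng.normal(size=(50, 3)) + 15.0
            qa, qb = rng.normal(size=50), rng.normal(size=50)
            expected = sum(
                config.coulomb_constant * qa[i] * qb[j] / np.linalg.norm(ca[i] - cb[j])
                for i in range(50)
                for j in range(50)
            )
            assert coulomb_inter(ca, qa, cb, qb, config) == pytest.approx(expected, abs=1e-9)

    def test_singularity_error(self, config):
        with pytest.raises(ValueError, match="singular"):
            coulomb_inter(
                np.array([[0.0, 0, 0]]), np.array([1.0]),
                np.array([[0.0, 0, 0]]), np.array([1.0]), config,
            )


class TestLJ:
    def test_minimum_at_rij(self, config):
        e = lj_inter(
            np.array([[0.0, 0, 0]]), (np.array([1.9]), np.array([0.1])),
            np.array([[3.8, 0, 0]]), (np.array([1.9]), np.array([0.4])), config,
        )
        assert e == pytest.approx(-np.sqrt(0.1 * 0.4), abs=1e-12)

    def test_long_range_decay(self, config):
        e = lj_inter(
            np.array([[0.0, 0, 0]]), (np.array([1.9]), np.array([0.1])),
            np.array([[380.0, 0, 0]]), (np.array([1.9]), np.array([0.1])), config,
        )
        assert abs(e) < 1e-9

    def test_matches_double_loop(self, config, rng):
        for _ in range(10):
            ca = rng.normal(size=(30, 3))
            cb = rng.normal(size=(30, 3)) + 12.0
            rma, rmb = rng.uniform(1.5, 2.1, 30), rng.uniform(1.5, 2.1, 30)
            ea, eb = rng.uniform(0.05, 0.3, 30), rng.uniform(0.05, 0.3, 30)
            expected = 0.0
            for i in range(30):
                for j in range(30):
                    r = np.linalg.norm(ca[i] - cb[j])
                    rij = rma[i] + rmb[j]
                    eij = np.sqrt(ea[i] * eb[j])
                    expected += eij * ((rij / r) ** 12 - 2 * (rij / r) ** 6)
            got = lj_inter(ca, (rma, ea), cb, (rmb, eb), config)
            assert got == pytest.approx(expected, abs=1e-9)


class TestSASA:
    def test_isolated_sphere_closed_form(self, config):
        per_atom, total = sasa(np.zeros((1, 3)), np.array([1.6]), config)
        assert total == pytest.approx(4 * np.pi * 3.0**2, rel=0.005)

    def test_buried_atom_zero(self, config):
        # small atom at the centre of a much larger sphere
        per_atom, _ = sasa(
            np.array([[0.0, 0, 0], [0.0, 0, 0.1]]), np.array([1.0, 8.0]), config
        )
        assert per_atom[0] == 0.0

    def test_two_sphere_overlap_matches_cap_formula(self, config):
        """Accessible area of two overlapping spheres vs spherical-cap closed form."""
        r1, r2, d = 1.6, 2.0, 2.5
        probe = config.probe_radius
        R1, R2 = r1 + probe, r2 + probe
        per_atom, total = sasa(
            np.array([[0.0, 0, 0], [d, 0, 0]]), np.array([r1, r2]), config
        )
        h1 = R1 - (d**2 + R1**2 - R2**2) / (2 * d)
        h2 = R2 - (d**2 + R2**2 - R1**2) / (2 * d)
        exact1 = 4 * np.pi * R1**2 - 2 * np.pi * R1 * h1
        exact2 = 4 * np.pi * R2**2 - 2 * np.pi * R2 * h2
        assert per_atom[0] == pytest.approx(exact1, rel=0.01)
        assert per_atom[1] == pytest.approx(exact2, rel=0.01)
        assert total == pytest.approx(exact1 + exact2, rel=0.01)

    def test_per_atom_sums_to_total(self, config, rng):
        coords = rng.normal(scale=3.0, size=(10, 3))
        per_atom, total = sasa(coords, np.full(10, 1.7), config)
        assert per_atom.sum() == pytest.approx(total, abs=1e-9)


class TestNonpolar:
    def test_beta_at_zero_sasa(self, config):
        assert nonpolar_term(0.0, config) == pytest.approx(0.92)

    def test_printed_constants(self, config):
        assert nonpolar_term(1000.0, config) == pytest.approx(6.34)

    def test_beta_cancels_once_in_delta(self, config):
        # complex area equal to the sum of the parts: the gamma terms cancel
        sr, sl = 500.0, 200.0
        delta = nonpolar_term(sr + sl, config) - nonpolar_term(sr, config) - nonpolar_term(sl, config)
        assert delta == pytest.approx(-0.92)


class TestPB:
    def test_zero_charges(self, config):
        top = _two_ion_topology(0.0, 0.0)
        res = solve_pb(top, np.array([[0.0, 0, 0], [8.0, 0, 0]]), config)
        assert res.energy == 0.0

    def test_born_ion_within_5pct_at_paper_spacing(self):
        res = solve_pb_charges(
            np.array([[0.0, 0, 0]]), np.array([1.0]), np.array([2.0]),
            spacing=0.4, iterations=5000, tolerance=1e-8,
        )
        assert res.energy == pytest.approx(BORN_EXACT, rel=0.05)

    def test_distant_ions_superpose(self):
        """Two far-apart ions solvate like the sum of the isolated Born ions
        plus the exact continuum pair screening -k q1 q2 (1 - 1/eps) / d."""
        kw = dict(spacing=0.8, iterations=5000, tolerance=1e-8, min_padding=4.0)
        d = 24.0
        single = solve_pb_charges(
            np.array([[0.0, 0, 0]]), np.array([1.0]), np.array([2.0]), **kw
        ).energy
        double = solve_pb_charges(
            np.array([[0.0, 0, 0], [d, 0, 0]]), np.array([1.0, 1.0]),
            np.array([2.0, 2.0]), **kw,
        ).energy
        cross = -332.0636 * (1 - 1 / 80.0) / d
        assert double == pytest.approx(2 * single + cross, rel=0.03)

    def test_desolvation_opposes_coulomb(self):
        """Binding a +/- pair costs polar solvation while Coulomb favours it."""
        cfg = EnergeticsConfig(pb_grid_spacing=0.8)
        top = _two_ion_topology(1.0, -1.0)
        coords = np.array([[0.0, 0, 0], [4.5, 0, 0]])
        dg_pol = pb_delta(top, coords, np.array([0]), np.array([1]), cfg)
        e_ele = coulomb_inter(coords[:1], [1.0], coords[1:], [-1.0], cfg)
        assert e_ele < 0
        assert dg_pol > 0

    def test_zero_charge_ligand_noninteracting(self):
        cfg = EnergeticsConfig(pb_grid_spacing=0.8)
        top = _two_ion_topology(1.0, 0.0)
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        dg_pol = pb_delta(top, coords, np.array([0]), np.array([1]), cfg)
        assert abs(dg_pol) < 2.0  # grid tolerance around zero


def _two_ion_topology(q1, q2):
    atoms = [
        AtomRecord(1, "M1", "ION", 1, Segment.RNA, "MG", charge=q1,
                   lj_rmin_half=1.5, lj_epsilon=0.1, pb_radius=2.0),
        AtomRecord(2, "M2", "LIG", 2, Segment.LIGAND, "MG", charge=q2,
                   lj_rmin_half=1.5, lj_epsilon=0.1, pb_radius=2.0),
    ]
    return Topology(atoms)


class TestEntropy:
    def test_frozen_mode_limit(self, config):
        terms = entropy_terms([50000.0], 300.0, [100.0, 100.0, 100.0], config)
        assert terms["TS_vib"] == pytest.approx(0.0, abs=1e-10)

    def test_classical_limit(self, config):
        """As hw/kT -> 0, S_vib -> R(1 - ln(hw/kT))."""
        T = config.temperature
        x = 0.01
        nu = x * constants.k * T / (constants.h * constants.c * 100.0)
        terms = entropy_terms([nu], 300.0, [100.0, 100.0, 100.0], config)
        s_vib = terms["TS_vib"] / T
        assert s_vib == pytest.approx(R_KCAL * (1 - np.log(x)), rel=0.01)

    def test_thermodynamic_identity(self):
        """S_vib equals -dF/dT of the QHO free energy, numerically."""
        nu = 100.0  # cm^-1
        def f_vib(T):
            x = constants.h * constants.c * 100.0 * nu / (constants.k * T)
            return R_KCAL * T * np.log(-np.expm1(-x))

        T = 300.0
        dT = 1e-3
        s_numeric = -(f_vib(T + dT) - f_vib(T - dT)) / (2 * dT)
        terms = entropy_terms([nu], 300.0, [100.0, 100.0, 100.0],
                              EnergeticsConfig(temperature=T))
        assert terms["TS_vib"] / T == pytest.approx(s_numeric, rel=1e-6)

    def test_nonpositive_frequency_rejected(self, config):
        with pytest.raises(ValueError):
            entropy_terms([100.0, -5.0], 300.0, [1.0, 1.0, 1.0], config)


class TestMMPBSASummary:
    def test_printed_component_assembly(self, config):
        comp = mmpbsa_summary(
            [pd.DataFrame({"dE_ele": [-32.93], "dE_vdW": [-32.42],
                           "dG_pol": [33.77], "dG_nonpol": [-3.32]})],
            [-16.17], config,
        )
        assert comp.dH == pytest.approx(-34.90, abs=1e-9)
        assert comp.dG_bind == pytest.approx(-18.73, abs=1e-9)

    def test_all_zero(self, config):
        comp = mmpbsa_summary(
            [pd.DataFrame({k: [0.0] for k in ("dE_ele", "dE_vdW", "dG_pol", "dG_nonpol")})],
            [0.0], config,
        )
        assert comp.dG_bind == 0.0 and comp.dH == 0.0

    def test_sem_is_sd_over_sqrt_n(self, config, rng):
        reps = []
        vals = rng.normal(size=(8, 4))
        for row in vals:
            reps.append(pd.DataFrame({
                "dE_ele": [row[0]], "dE_vdW": [row[1]],
                "dG_pol": [row[2]], "dG_nonpol": [row[3]],
            }))
        comp = mmpbsa_summary(reps, np.zeros(8), config)
        assert comp.sem["dE_ele"] == pytest.approx(vals[:, 0].std(ddof=1) / np.sqrt(8))
        assert comp.sem["dH"] == pytest.approx(vals.sum(axis=1).std(ddof=1) / np.sqrt(8))

    def test_zero_frames_error(self, config):
        with pytest.raises(ValueError):
            mmpbsa_summary([pd.DataFrame({k: [] for k in ("dE_ele", "dE_vdW", "dG_pol", "dG_nonpol")})], [0.0], config)


class TestPerResidueDecomposition:
    def _toy_three_atoms(self, q_res1=0.5, q_res2=-0.3, q_lig=1.0):
        atoms = [
            AtomRecord(1, "P1", "G", 1, Segment.RNA, "C", charge=q_res1,
                       lj_rmin_half=1.9, lj_epsilon=0.1, pb_radius=1.7),
            AtomRecord(2, "P2", "U", 2, Segment.RNA, "C", charge=q_res2,
                       lj_rmin_half=1.9, lj_epsilon=0.1, pb_radius=1.7),
            AtomRecord(3, "L1", "LIG", 3, Segment.LIGAND, "C", charge=q_lig,
                       lj_rmin_half=1.9, lj_epsilon=0.1, pb_radius=1.7),
        ]
        coords = np.array([[0.0, 0, 0], [6.0, 0, 0], [3.0, 4.0, 0]])
        return Topology(atoms), coords

    def test_pairwise_shares_equal_single_residue_calcs(self, config):
        top, coords = self._toy_three_atoms()
        df = per_residue_decomposition(top, coords, config, include_pol=False)
        for resi, qi, ci in ((1, 0.5, coords[:1]), (2, -0.3, coords[1:2])):
            row = df[df.residue_index == resi].iloc[0]
            expected = coulomb_inter(ci, [qi], coords[2:], [1.0], config)
            assert row.dE_ele == pytest.approx(expected, abs=1e-9)

    def test_pairwise_sums_to_totals(self, config):
        top, coords = self._toy_three_atoms()
        df = per_residue_decomposition(top, coords, config, include_pol=False)
        total_ele = coulomb_inter(coords[:2], [0.5, -0.3], coords[2:], [1.0], config)
        assert df.dE_ele.sum() == pytest.approx(total_ele, abs=1e-9)
        total_lj = lj_inter(
            coords[:2], (np.full(2, 1.9), np.full(2, 0.1)),
            coords[2:], (np.array([1.9]), np.array([0.1])), config,
        )
        assert df.dE_vdW.sum() == pytest.approx(total_lj, abs=1e-9)

    def test_zero_charge_residue_no_ele_share(self, config):
        top, coords = self._toy_three_atoms(q_res1=0.0)
        df = per_residue_decomposition(top, coords, config, include_pol=False)
        assert df[df.residue_index == 1].iloc[0].dE_ele == 0.0

    def test_charge_annihilation_pol_shares(self):
        cfg = EnergeticsConfig(pb_grid_spacing=0.8)
        top, coords = self._toy_three_atoms()
        df = per_residue_decomposition(top, coords, cfg, include_pol=True)
        # annihilation shares are finite and the zero-charge ligand row gets none
        assert np.isfinite(df.dG_pol).all()

    def test_identical_vectors_correlate_perfectly(self):
        v = pd.DataFrame({"Q1": [1.0, -2.0, 0.5], "Q0": [1.0, -2.0, 0.5]})
        corr = contribution_correlation(v)
        assert corr.loc["Q1", "Q0"] == pytest.approx(1.0)


class TestDGExp:
    @pytest.mark.parametrize(
        "kd,expected",
        [(2.05e-9, -11.93), (35.10e-9, -10.23), (1.0, 0.0)],
    )
    def test_printed_values(self, kd, expected):
        assert dg_from_kd(kd, 300.0) == pytest.approx(expected, abs=0.005)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            dg_from_kd(0.0)
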
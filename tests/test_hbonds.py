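import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import write_multimodel_pdb
from hdxpipe.hbonds import (AmideHBondSeries, LogisticParams,
                            aggregate_to_peptides, calibrate_logistic,
                            classify_hbonds, compute_protection,
                            predict_uptake, read_flag_csv, write_flag_csv)
from hdxpipe.rates import intrinsic_rates
from hdxpipe.synth import (generate_hbond_series, generate_peptide_map,
                           simulate_uptake)
from oracles import oracle_hbond_flags

FAR = 40.0


def _donor_system(acceptor_frames, acceptor_resname="GLY",
                  acceptor_atom="O"):
    """A GLY (acceptor carbonyl) + ALA (donor amide) system; returns
    (resnames, atom_names, elements, res_ids, frames)."""
    # static atoms: GLY N,CA,C then ALA full backbone; acceptor O moves
    atoms = [
        ("GLY", "N", "N", 1, (FAR, 0, 0)),
        ("GLY", "CA", "C", 1, (FAR + 1, 0, 0)),
        ("GLY", "C", "C", 1, (FAR + 2, 0, 0)),
        ("ALA", "N", "N", 2, (0.0, 0.0, 0.0)),
        ("ALA", "H", "H", 2, (0.0, 0.0, 1.0)),
        ("ALA", "CA", "C", 2, (1.4, 0.0, -0.5)),
        ("ALA", "C", "C", 2, (FAR, 5, 0)),
        ("ALA", "O", "O", 2, (FAR, 6, 0)),
    ]
    frames = []
    for acc in acceptor_frames:
        coords = [a[4] for a in atoms] + [acc]
        frames.append(np.round(np.array(coords, dtype=float), 3))
    resnames = [a[0] for a in atoms] + [acceptor_resname]
    atom_names = [a[1] for a in atoms] + [acceptor_atom]
    elements = [a[2] for a in atoms] + ["O"]
    res_ids = [a[3] for a in atoms] + [1 if acceptor_resname == "GLY" else 9]
    return resnames, atom_names, elements, res_ids, frames


class TestClassifyHbonds:
    def test_ideal_geometry_then_separated(self, tmp_path):
        """2.9 A / 5 deg N-H...O geometry in frame 1 is bonded; 6 A
        separation in frame 2 is not."""
        ang = np.deg2rad(5.0)
        near = (0.0, 2.9 * np.sin(ang), 2.9 * np.cos(ang))
        far = (0.0, 0.0, 6.0)
        rn, an, el, ri, frames = _donor_system([near, far])
        path = tmp_path / "sys.pdb"
        write_multimodel_pdb(path, frames, rn, an, el, ri)
        series = classify_hbonds(path)
        assert 2 in series
        assert series[2].bonded_to_protein.tolist() == [True, False]
        assert not series[2].bonded_to_water.any()

    def test_water_only_neighbor(self, tmp_path):
        """An amide whose only in-range acceptor is a water oxygen is
        water-bonded, not protein-bonded."""
        near = (0.0, 0.0, 2.8)
        rn, an, el, ri, frames = _donor_system([near],
                                               acceptor_resname="HOH",
                                               acceptor_atom="O")
        path = tmp_path / "sys.pdb"
        write_multimodel_pdb(path, frames, rn, an, el, ri)
        series = classify_hbonds(path)
        assert series[2].bonded_to_water.tolist() == [True]
        assert not series[2].bonded_to_protein.any()

    def test_angle_criterion_excludes_bent_geometry(self, tmp_path):
        """An acceptor at 2.9 A but 60 deg off the N-H axis is rejected."""
        ang = np.deg2rad(60.0)
        bent = (0.0, 2.9 * np.sin(ang), 2.9 * np.cos(ang))
        rn, an, el, ri, frames = _donor_system([bent])
        path = tmp_path / "sys.pdb"
        write_multimodel_pdb(path, frames, rn, an, el, ri)
        series = classify_hbonds(path)
        assert not series[2].bonded_to_protein.any()

    def test_matches_brute_force_all_pairs_oracle(self, tmp_path):
        """Random small system over 8 frames: flags equal an independent
        O(N^2) distance/angle scan."""
        rng = np.random.default_rng(5)
        n_res, n_wat, n_frames = 4, 6, 8
        resnames, atom_names, elements, res_ids = [], [], [], []
        for r in range(1, n_res + 1):
            for name, el in (("N", "N"), ("H", "H"), ("CA", "C"),
                             ("C", "C"), ("O", "O")):
                resnames.append("ALA")
                atom_names.append(name)
                elements.append(el)
                res_ids.append(r)
        for w in range(n_wat):
            resnames.append("HOH")
            atom_names.append("O")
            elements.append("O")
            res_ids.append(n_res + 1 + w)
        n_atoms = len(resnames)
        frames = []
        for _ in range(n_frames):
            coords = rng.uniform(0, 9, size=(n_atoms, 3))
            # keep each N-H at a sane bond length
            for r in range(n_res):
                base = 5 * r
                coords[base + 1] = coords[base] + rng.normal(size=3) * 0.1 \
                    + np.array([0, 0, 1.0])
            frames.append(np.round(coords, 3))
        path = tmp_path / "rand.pdb"
        write_multimodel_pdb(path, frames, resnames, atom_names, elements,
                             res_ids)
        series = classify_hbonds(path)
        # independent scan on the same rounded coordinates
        prot_acceptors = [i for i, (nm, rn) in
                          enumerate(zip(atom_names, resnames))
                          if rn != "HOH" and nm.startswith("O")]
        water_acceptors = [i for i, rn in enumerate(resnames) if rn == "HOH"]
        for r in range(2, n_res + 1):   # residue 1 has no reportable amide
            base = 5 * (r - 1)
            for fi in range(n_frames):
                c = frames[fi]
                expect_p = oracle_hbond_flags(
                    c[base], c[base + 1], [c[i] for i in prot_acceptors])
                expect_w = oracle_hbond_flags(
                    c[base], c[base + 1], [c[i] for i in water_acceptors])
                assert series[r].bonded_to_protein[fi] == expect_p, (r, fi)
                assert series[r].bonded_to_water[fi] == expect_w, (r, fi)

    def test_missing_trajectory_errors(self):
        with pytest.raises(ValueError, match="cannot open"):
            classify_hbonds("/nonexistent/file.pdb")

    def test_flag_csv_round_trip(self, tmp_path):
        series = generate_hbond_series({2: 0.4, 3: 0.9}, 50, seed=1)
        path = tmp_path / "flags.csv"
        write_flag_csv(series, path)
        back = read_flag_csv(path)
        for r in (2, 3):
            assert (back[r].bonded_to_protein
                    == series[r].bonded_to_protein).all()
            assert (back[r].bonded_to_water
                    == series[r].bonded_to_water).all()


class TestProtection:
    def test_unprotected_limit(self):
        """x = 0 with midpoint 0.5 and steep slope gives PF ~ 1."""
        params = LogisticParams(L=np.log(1e6), x0=0.5, s=30.0)
        s = {1: AmideHBondSeries(1, np.zeros(200, bool), np.ones(200, bool))}
        prof = compute_protection(s, params)
        assert prof.closed_fraction[1] == 0.0
        assert prof.pf[1] == pytest.approx(1.0, abs=1e-3)

    def test_saturation_limit(self):
        params = LogisticParams(L=np.log(1e6), x0=0.5, s=10.0)
        s = {1: AmideHBondSeries(1, np.ones(200, bool), np.zeros(200, bool))}
        prof = compute_protection(s, params)
        expected = np.exp(params.ln_pf(1.0))
        assert prof.pf[1] == pytest.approx(expected)
        assert prof.pf[1] > 1e5

    def test_bernoulli_series_closed_form(self):
        """Empirical fraction ~0.7 maps onto the logistic closed form."""
        params = LogisticParams(L=np.log(1e4), x0=0.5, s=8.0)
        series = generate_hbond_series({3: 0.7}, 100_000, seed=2)
        prof = compute_protection(series, params)
        x = prof.closed_fraction[3]
        assert x == pytest.approx(0.7, abs=0.005)
        assert prof.pf[3] == pytest.approx(float(np.exp(params.ln_pf(x))))

    def test_mode_protein_only(self):
        flags_p = np.array([True, True, False, False])
        flags_w = np.array([True, False, False, False])
        s = {1: AmideHBondSeries(1, flags_p, flags_w)}
        params = LogisticParams(L=1.0, x0=0.5, s=5.0)
        assert compute_protection(s, params,
                                  "protein_only").closed_fraction[1] == 0.5
        assert compute_protection(
            s, params, "protein_not_water").closed_fraction[1] == 0.25


class TestPredictUptake:
    @pytest.fixture()
    def setup(self):
        rates = intrinsic_rates("AGNDLKVSTA", 7.4, 298.15)
        prof_pf = {i: 100.0 for i in range(2, 11)}
        params = LogisticParams(L=np.log(1e6), x0=0.5, s=10.0)
        from hdxpipe.hbonds import ProtectionProfile
        profile = ProtectionProfile(
            {i: 0.5 for i in prof_pf}, prof_pf, params, 100)
        return rates, profile

    def test_time_zero_and_limits(self, setup):
        rates, profile = setup
        d = predict_uptake(profile, rates, [0.0, 60.0])
        assert (d[0.0] == 0).all()
        assert d.loc[1, 60.0] == 0.0          # residue 1 never exchanges
        assert (d[60.0].iloc[1:] > 0).all()

    def test_pf_one_gives_pure_intrinsic_kinetics(self, setup):
        rates, profile = setup
        profile.pf = {i: 1.0 for i in profile.pf}
        d = predict_uptake(profile, rates, [30.0])
        k = rates.k_int_per_min / 60.0
        expected = 1.0 - np.exp(-k[4] * 30.0)
        assert d.loc[5, 30.0] == pytest.approx(expected)

    def test_infinite_protection_gives_zero(self, setup):
        rates, profile = setup
        profile.pf = {i: np.inf for i in profile.pf}
        d = predict_uptake(profile, rates, [1e6])
        assert (d[1e6] == 0).all()

    def test_aggregate_trivial_arithmetic(self, setup):
        rates, _ = setup
        import pandas as pd
        from hdxpipe.io import Peptide
        d = pd.DataFrame(0.5, index=pd.RangeIndex(1, 11, name="residue"),
                         columns=[60.0])
        d.loc[1] = 0.0
        pep = Peptide("P", "map", 2, 8, "GNDLKVS")
        table = aggregate_to_peptides(d, [pep])
        # 6 exchanging residues (positions 3..8) at 0.5 each
        assert table.df["uptake_Da"].iloc[0] == pytest.approx(3.0)

    def test_peptide_of_nonexchanging_residues_zero(self):
        rates = intrinsic_rates("APPPA", 7.4, 298.15)
        import pandas as pd
        from hdxpipe.io import Peptide
        d = pd.DataFrame(1.0, index=pd.RangeIndex(1, 6, name="residue"),
                         columns=[60.0])
        pep = Peptide("P", "map", 1, 4, "APPP")
        table = aggregate_to_peptides(d, [pep])
        assert table.df["uptake_Da"].iloc[0] == 0.0


class TestCrossModuleConsistency:
    def test_prediction_equals_simulation_at_matched_truth(self, truth,
                                                           peptide_map):
        """Feeding the H-bond route the exact PFs of the ground truth
        reproduces the noise-free simulator output to machine precision
        (r^2 = 1)."""
        from hdxpipe.hbonds import ProtectionProfile
        params = LogisticParams(L=np.log(1e6), x0=0.5, s=10.0)
        pf = {i + 1: float(10.0 ** truth.log10_pf["free"][i])
              for i in range(truth.n_residues)}
        profile = ProtectionProfile({i: 0.5 for i in pf}, pf, params, 1000)
        rates = intrinsic_rates(truth.sequence, truth.pD,
                                truth.temperature_K,
                                apply_pD_correction=False)
        d = predict_uptake(profile, rates, [0.0, 30.0, 60.0, 120.0])
        predicted = aggregate_to_peptides(d, peptide_map)
        simulated = simulate_uptake(truth, peptide_map, noise_sd=0.0,
                                    backexchange_frac=0.0, n_reps=1)["free"]
        a = predicted.df.sort_values(["start", "end", "exposure_s"])
        b = simulated.df.sort_values(["start", "end", "exposure_s"])
        assert np.allclose(a["uptake_Da"].to_numpy(),
                           b["uptake_Da"].to_numpy(), atol=1e-12)
        nz = b["exposure_s"] > 0
        r = np.corrcoef(a.loc[nz.values, "uptake_Da"],
                        b.loc[nz.values, "uptake_Da"])[0, 1]
        assert r ** 2 == pytest.approx(1.0, abs=1e-12)


class TestCalibrateLogistic:
    def _make_dataset(self, seed=4):
        rng = np.random.default_rng(seed)
        n = 30
        sequence = "".join(rng.choice(list("ACDEFGHIKLMNQRSTVWY"), size=n))
        rates = intrinsic_rates(sequence, 7.4, 298.15)
        true = LogisticParams(L=np.log(1e5), x0=0.45, s=9.0)
        fractions = {i: float(rng.uniform(0.05, 0.95))
                     for i in range(2, n + 1) if sequence[i - 1] != "P"}
        series = generate_hbond_series(fractions, 40_000, seed=seed)
        peps = generate_peptide_map(sequence, mean_length=8, seed=seed)
        prof = compute_protection(series, true)
        d = predict_uptake(prof, rates, [0.0, 30.0, 60.0, 120.0])
        table = aggregate_to_peptides(d, peps, state="exp")
        return table, series, rates, true

    def test_recovers_planted_parameters(self):
        """L and x0 of the generating logistic are recovered within 10%."""
        table, series, rates, true = self._make_dataset()
        params, sse = calibrate_logistic(table, series, rates)
        assert params.L == pytest.approx(true.L, rel=0.10)
        assert params.x0 == pytest.approx(true.x0, rel=0.10)

    def test_single_peptide_rejected(self):
        table, series, rates, _ = self._make_dataset()
        one = table.df[table.df["start"] == table.df["start"].iloc[0]]
        from hdxpipe.io import UptakeTable
        with pytest.raises(ValueError, match=">= 5 peptides"):
            calibrate_logistic(UptakeTable(one), series, rates)


@settings(max_examples=60, deadline=None)
@given(st.floats(min_value=0.1, max_value=20.0),
       st.floats(min_value=0.0, max_value=1.0),
       st.floats(min_value=0.1, max_value=50.0),
       st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                max_size=8))
def test_pf_monotone_nondecreasing_in_closed_fraction(L, x0, s, xs):
    params = LogisticParams(L=L, x0=x0, s=s)
    xs = sorted(xs)
    lnpf = params.ln_pf(xs)
    assert (np.diff(lnpf) >= -1e-12).all()
    assert (lnpf >= 0).all()
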
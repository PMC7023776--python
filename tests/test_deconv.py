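from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from emtmeth.deconv import (
    CfDNAMethylome,
    TumorReference,
    correlate_tissue_liquid,
    emt_trajectory,
    estimate_f_ctdna,
    exclude_unreliable_markers,
    methylome_from_coverage,
    reconstruct_tumor_methylation,
)
from emtmeth.synthetic import (
    SimConfig,
    simulate_controls,
    simulate_patient_series,
)


def _methylome(m, sample="s", depth=1000):
    m = np.asarray(m, dtype=float)
    ids = np.array([f"cg{i}" for i in range(m.size)], dtype=object)
    return CfDNAMethylome(sample, ids, m, np.full(m.size, depth))


def _reference(m):
    m = np.asarray(m, dtype=float)
    ids = np.array([f"cg{i}" for i in range(m.size)], dtype=object)
    return TumorReference(ids, m, cohort_size=50)


@pytest.fixture(scope="module")
def patient_setup(small_config, small_genome, small_refs):
    # module-scoped view over the session fixtures
    genome, refs = small_genome, small_refs
    ref = TumorReference.from_matrix(refs.tumor, genome.target_ids)
    tsites = [s for s in genome.sites if s.id in set(genome.target_ids)]
    blood = pd.Series(refs.blood_means, index=genome.site_ids).reindex(
        genome.target_ids
    )
    return genome, refs, ref, tsites, blood


class TestEstimateF:
    def test_noiseless_slope(self, rng):
        m_tumor = rng.random(200)
        meas = _methylome(0.1 * m_tumor)
        res = estimate_f_ctdna(meas, _reference(m_tumor), n_boot=50)
        assert res.f_ctdna == pytest.approx(0.1, abs=1e-12)
        assert res.reliable
        assert res.ci_low <= 0.1 <= res.ci_high

    def test_all_zero_measurement(self, rng):
        m_tumor = rng.random(200)
        res = estimate_f_ctdna(_methylome(np.zeros(200)), _reference(m_tumor))
        assert res.f_ctdna == 0.0
        assert not res.reliable

    def test_all_zero_reference_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            estimate_f_ctdna(_methylome(np.full(100, 0.1)), _reference(np.zeros(100)))

    def test_insufficient_cpgs(self, rng):
        m = rng.random(10)
        with pytest.raises(ValueError, match="usable CpGs"):
            estimate_f_ctdna(_methylome(m), _reference(m))

    def test_low_depth_cpgs_masked(self, rng):
        m = rng.random(100)
        meth = CfDNAMethylome("s", np.array([f"cg{i}" for i in range(100)], dtype=object),
                              m, np.concatenate([np.full(60, 100), np.full(40, 2)]))
        res = estimate_f_ctdna(meth, _reference(m), min_cpgs=50)
        assert res.n_cpgs == 60

    def test_slope_clamped(self, rng):
        m_tumor = rng.random(100) * 0.2
        res = estimate_f_ctdna(_methylome(np.minimum(1, m_tumor * 6)),
                               _reference(m_tumor))
        assert res.f_ctdna == 1.0

    def test_recovery_on_synthetic_patient(self, small_config, patient_setup):
        genome, refs, ref, tsites, blood = patient_setup
        cfg = replace(small_config, coverage_mean=100.0)
        ps = simulate_patient_series(cfg, genome, refs, [(0, "start", 0.2, 0.0)])
        meas = methylome_from_coverage(ps.records[ps.sample_ids[0]], tsites, "p")
        res = estimate_f_ctdna(meas, ref, blood=blood, n_boot=0)
        assert res.f_ctdna == pytest.approx(0.2, abs=0.02)

    def test_controls_below_patients(self, small_config, patient_setup):
        """Separation property: f-hat for healthy controls sits below
        patients generated at f >= 0.05."""
        genome, refs, ref, tsites, blood = patient_setup
        ctrl_fs, patient_fs = [], []
        for ctrl in simulate_controls(small_config, genome, refs, n_controls=3):
            meas = methylome_from_coverage(ctrl.records[ctrl.sample_ids[0]],
                                           tsites, ctrl.sample_ids[0])
            ctrl_fs.append(estimate_f_ctdna(meas, ref, n_boot=0).f_ctdna)
        for f in (0.05, 0.1):
            ps = simulate_patient_series(small_config, genome, refs,
                                         [(0, "start", f, 0.0)])
            meas = methylome_from_coverage(ps.records[ps.sample_ids[0]], tsites, "p")
            patient_fs.append(estimate_f_ctdna(meas, ref, n_boot=0).f_ctdna)
        assert max(ctrl_fs) < min(patient_fs)

    def test_free_intercept_diagnostic(self, rng):
        m_tumor = rng.random(300)
        meas = _methylome(0.2 * m_tumor + 0.05)
        res = estimate_f_ctdna(meas, _reference(m_tumor), free_intercept=True)
        assert res.f_ctdna == pytest.approx(0.2, abs=1e-9)
        assert res.intercept == pytest.approx(0.05, abs=1e-9)


class TestReconstruct:
    def test_simple_division(self, rng):
        m_tumor = rng.random(100)
        meas = _methylome(np.full(100, 0.05))
        f = estimate_f_ctdna(meas, _reference(np.full(100, 0.5)))
        assert f.f_ctdna == pytest.approx(0.1)
        recon = reconstruct_tumor_methylation(meas, f)
        assert recon.iloc[0] == pytest.approx(0.5)

    def test_clipping_flagged(self):
        from emtmeth.deconv import DeconvResult

        meas = _methylome(np.full(100, 0.5))
        f = DeconvResult("s", 0.1, 100, True, 0.0, 1.0)
        recon = reconstruct_tumor_methylation(meas, f)
        assert (recon == 1.0).all()
        assert recon.attrs["n_clipped"] == 100

    def test_unreliable_refused(self):
        from emtmeth.deconv import DeconvResult

        meas = _methylome(np.full(100, 0.5))
        f = DeconvResult("s", 0.005, 100, False, 0.0, 1.0)
        with pytest.raises(ValueError, match="unreliable"):
            reconstruct_tumor_methylation(meas, f)
        reconstruct_tumor_methylation(meas, f, force=True)  # no raise

    def test_exact_inversion_of_noise_free_mixture(self, small_config,
                                                   patient_setup):
        """reconstruct . mix = identity when blood is zero and reads are
        noise-free."""
        genome, refs, ref, tsites, blood = patient_setup
        f_true = 0.25
        sid_ids = np.array(genome.target_ids, dtype=object)
        tumor_profile = ref.m_tumor.copy()
        m_meas = f_true * tumor_profile  # blood term exactly zero
        meas = CfDNAMethylome("exact", sid_ids, m_meas,
                              np.full(sid_ids.size, 10_000))
        from emtmeth.deconv import DeconvResult

        fres = DeconvResult("exact", f_true, sid_ids.size, True, 0.0, 1.0)
        recon = reconstruct_tumor_methylation(meas, fres)
        np.testing.assert_allclose(recon.to_numpy(), tumor_profile, rtol=1e-12)


class TestExcludeMarkers:
    def test_planted_exclusions_recovered(self, small_config, patient_setup):
        """The 13 genes given elevated blood methylation by the generator
        are exactly the ones excluded at default caps."""
        genome, refs, ref, tsites, blood = patient_setup
        controls = simulate_controls(small_config, genome, refs, n_controls=4)
        methylomes = [
            methylome_from_coverage(c.records[c.sample_ids[0]], genome.sites,
                                    c.sample_ids[0])
            for c in controls
        ]
        result = exclude_unreliable_markers(methylomes, genome.signature,
                                            genome.promoter_map)
        excluded = set(result.report.loc[result.report["status"] == "excluded", "gene"])
        assert excluded == set(genome.excluded_genes)
        counts = result.retained["klass"].value_counts()
        assert counts["epithelial"] == 9
        assert counts["mesenchymal"] == 28

    def test_reason_codes(self):
        sig = pd.DataFrame({"gene": ["clean", "high", "orphan"],
                            "klass": ["epithelial", "mesenchymal", "mesenchymal"]})
        pmap = {"clean": {"cg0"}, "high": {"cg1"}, "orphan": set()}
        ids = np.array(["cg0", "cg1"], dtype=object)
        controls = [
            CfDNAMethylome(f"c{i}", ids, np.array([0.0, 0.4]), np.full(2, 100))
            for i in range(2)
        ]
        result = exclude_unreliable_markers(controls, sig, pmap)
        report = result.report.set_index("gene")
        assert report.loc["clean", "status"] == "retained"
        assert report.loc["high", "reason"] == "high"
        assert report.loc["orphan", "reason"] == "no_promoter_cpgs"

    def test_requires_two_controls(self):
        with pytest.raises(ValueError, match="2 control"):
            exclude_unreliable_markers([], pd.DataFrame({"gene": [], "klass": []}), {})


def _run_patient(cfg, genome, refs, ref, tsites, blood, traj, patient="p"):
    ps = simulate_patient_series(cfg, genome, refs, traj, patient=patient)
    triples = []
    for sid, (day, *_rest) in zip(ps.sample_ids, traj):
        meas = methylome_from_coverage(ps.records[sid], tsites, sid)
        fres = estimate_f_ctdna(meas, ref, blood=blood, n_boot=0)
        triples.append((meas, fres, day))
    return ps, triples


@pytest.fixture(scope="module")
def retained(small_genome):
    sig = small_genome.signature
    return sig[~sig["gene"].isin(small_genome.excluded_genes)].reset_index(drop=True)


class TestTrajectory:
    def test_constant_methylation_no_shift(self, small_config, patient_setup, retained):
        genome, refs, ref, tsites, blood = patient_setup
        cfg = replace(small_config, coverage_mean=3000.0)
        _, triples = _run_patient(cfg, genome, refs, ref, tsites, blood,
                                  [(0, "start", 0.2, 0.3), (90, "end_of_study", 0.2, 0.3)])
        traj = emt_trajectory(triples, retained, genome.promoter_map)
        assert traj.points[0].relative_score == 0.0
        assert abs(traj.points[-1].relative_score) < 0.05
        assert traj.trend == "no_shift"

    def test_emt_shift_called(self, small_config, patient_setup, retained):
        genome, refs, ref, tsites, blood = patient_setup
        cfg = replace(small_config, coverage_mean=3000.0)
        _, triples = _run_patient(cfg, genome, refs, ref, tsites, blood,
                                  [(0, "start", 0.15, 0.0), (120, "progression", 0.3, 0.9)])
        traj = emt_trajectory(triples, retained, genome.promoter_map)
        assert traj.trend == "emt_shift"
        assert traj.points[-1].relative_score > 0.5

    def test_anchor_moves_when_t0_unreliable(self, small_config, patient_setup,
                                             retained):
        genome, refs, ref, tsites, blood = patient_setup
        cfg = replace(small_config, coverage_mean=3000.0)
        _, triples = _run_patient(
            cfg, genome, refs, ref, tsites, blood,
            [(0, "start", 0.0, 0.0), (60, "on_treatment", 0.2, 0.3),
             (120, "progression", 0.2, 0.3)])
        assert not triples[0][1].reliable
        traj = emt_trajectory(triples, retained, genome.promoter_map)
        assert traj.anchor_index == 1
        assert traj.notes

    def test_too_few_reliable_timepoints(self, small_config, patient_setup, retained):
        genome, refs, ref, tsites, blood = patient_setup
        _, triples = _run_patient(small_config, genome, refs, ref, tsites, blood,
                                  [(0, "start", 0.0, 0.0), (60, "progression", 0.0, 0.3)])
        with pytest.raises(ValueError, match="reliable"):
            emt_trajectory(triples, retained, genome.promoter_map)


class TestTissueLiquidCorrelation:
    def test_identical_profiles_coefficient_one(self, rng):
        from emtmeth.deconv import DeconvResult

        m = rng.random(200)
        meas = _methylome(0.5 * m)
        f = DeconvResult("s", 0.5, 200, True, 0.0, 1.0)
        tissue = pd.Series(m, index=[f"cg{i}" for i in range(200)])
        table = correlate_tissue_liquid(tissue, [(meas, f)])
        assert table["rho"].iloc[0] == pytest.approx(1.0)

    def test_independent_profiles_near_zero(self):
        from emtmeth.deconv import DeconvResult

        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            tissue = pd.Series(r.random(1000), index=[f"cg{i}" for i in range(1000)])
            meas = _methylome(r.random(1000) * 0.2)
            f = DeconvResult("s", 0.2, 1000, True, 0.0, 1.0)
            table = correlate_tissue_liquid(tissue, [(meas, f)])
            if abs(table["rho"].iloc[0]) < 0.1:
                hits += 1
        assert hits >= 0.95 * 20

    def test_same_patient_pair_is_best(self, small_config, patient_setup):
        """Liquid generated from the same synthetic tumor as the tissue
        correlates best among 3 patients."""
        genome, refs, ref, tsites, blood = patient_setup
        cfg = replace(small_config, coverage_mean=500.0)
        liquids = []
        tissue = None
        for i in range(3):
            ps = simulate_patient_series(cfg, genome, refs,
                                         [(0, "start", 0.3, 0.2)],
                                         patient=f"pt{i}")
            sid = ps.sample_ids[0]
            meas = methylome_from_coverage(ps.records[sid], tsites, sid)
            fres = estimate_f_ctdna(meas, ref, blood=blood, n_boot=0)
            liquids.append((meas, fres))
            if i == 0:
                profile = ps.truth.tumor_profiles[sid]
                tissue = pd.Series(profile, index=genome.site_ids).reindex(
                    genome.target_ids
                )
        table = correlate_tissue_liquid(tissue, liquids)
        assert table.loc[table["best"], "sample"].iloc[0] == "pt0_t0"

    def test_min_common_enforced(self, rng):
        from emtmeth.deconv import DeconvResult

        meas = _methylome(rng.random(10))
        f = DeconvResult("s", 0.5, 10, True, 0.0, 1.0)
        tissue = pd.Series(rng.random(10), index=[f"cg{i}" for i in range(10)])
        with pytest.raises(ValueError, match="common CpGs"):
            correlate_tissue_liquid(tissue, [(meas, f)])
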
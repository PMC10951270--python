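"""Peak matching, stepped-CE merging, consensus spectra, filters, I/O."""

import numpy as np
import pytest

from glycospec.fragments import FragmentIndex, GlycopeptidePrecursor
from glycospec.glycans import parse_glycan_struct
from glycospec.peptides import PeptideSequence
from glycospec.simulate import SimConfig, generate_dataset, simulate_spectrum, simulate_precursors, to_peak_list
from glycospec.spectra import (
    AnnotatedSpectrum,
    Spectrum,
    build_consensus,
    load_dataset,
    match_peaks,
    merge_stepped_ce,
    passes_filters,
    read_mgf,
    save_dataset,
    write_mgf,
)


def _annotated(index, pep=None, y=None, b=None):
    return AnnotatedSpectrum(
        index,
        np.zeros(index.n_pep) if pep is None else pep,
        np.zeros(index.n_y) if y is None else y,
        np.zeros(index.n_b) if b is None else b,
    )


class TestMatchPeaks:
    def test_ppm_window(self, simple_precursor):
        idx = FragmentIndex(simple_precursor)
        ions = idx.theoretical_ions()
        part, slot, ion = ions[0]
        near = Spectrum([ion.mz * (1 + 0.7e-6)], [100.0])
        far = Spectrum([ion.mz * (1 + 260e-6)], [100.0])
        ann_near = match_peaks(near, simple_precursor, tol_ppm=20)
        ann_far = match_peaks(far, simple_precursor, tol_ppm=20)
        vec = {"pep": ann_near.s_pep, "Y": ann_near.s_y}[part]
        assert vec[slot] == 100.0
        assert ann_far.full_vector().sum() == 0.0

    def test_closest_fragment_wins_single_peak(self, simple_precursor):
        # one peak between two nearby theoretical fragments goes to the nearer
        idx = FragmentIndex(simple_precursor)
        ions = sorted(idx.theoretical_ions(), key=lambda r: r[2].mz)
        part, slot, ion = ions[0]
        spec = Spectrum([ion.mz + 1e-4], [50.0])
        ann = match_peaks(spec, simple_precursor, tol_ppm=20)
        assert ann.full_vector().sum() == 50.0  # assigned exactly once

    def test_empty_spectrum_all_zero(self, simple_precursor):
        ann = match_peaks(Spectrum([], []), simple_precursor)
        assert ann.full_vector().sum() == 0.0

    def test_roundtrip_recovers_simulated_vector(self):
        cfg = SimConfig(seed=5, n_precursors=1, noise_cv=0.0, missing_rate=0.0)
        prec = simulate_precursors(cfg)[0]
        obs, truth = simulate_spectrum(prec, cfg)
        peaks = to_peak_list(obs)
        ann = match_peaks(peaks, prec, tol_ppm=5)
        assert np.allclose(ann.s_y, obs.s_y, rtol=1e-9)
        assert np.allclose(ann.s_pep, obs.s_pep, rtol=1e-9)

    def test_invalid_tolerance(self, simple_precursor):
        with pytest.raises(ValueError):
            match_peaks(Spectrum([], []), simple_precursor, tol_ppm=0)


class TestMergeSteppedCE:
    def test_elementwise_mean(self, simple_index):
        low = _annotated(simple_index)
        high = _annotated(simple_index)
        low.s_y[0] = 100.0
        high.s_y[0] = 50.0
        low.s_pep[2] = 100.0  # present only in the low-CE spectrum
        merged = merge_stepped_ce(low, high)
        assert merged.s_y[0] == 75.0
        assert merged.s_pep[2] == 50.0

    def test_identical_inputs(self, simple_index):
        a = _annotated(simple_index)
        a.s_y[:] = 3.0
        merged = merge_stepped_ce(a, a)
        assert np.allclose(merged.s_y, a.s_y)

    def test_commutes_with_scaling(self, simple_index):
        rng = np.random.default_rng(0)
        a = _annotated(simple_index, y=rng.random(simple_index.n_y))
        b = _annotated(simple_index, y=rng.random(simple_index.n_y))
        m1 = merge_stepped_ce(a, b)
        a2 = _annotated(simple_index, y=a.s_y * 3.0)
        b2 = _annotated(simple_index, y=b.s_y * 3.0)
        m2 = merge_stepped_ce(a2, b2)
        assert np.allclose(m2.s_y, 3.0 * m1.s_y)

    def test_precursor_mismatch_rejected(self, simple_index):
        other = GlycopeptidePrecursor(
            PeptideSequence("LNSTAVK", 1), parse_glycan_struct("(N(N(H)))"), 2
        )
        idx2 = FragmentIndex(other)
        with pytest.raises(ValueError):
            merge_stepped_ce(_annotated(simple_index), _annotated(idx2))


class TestConsensus:
    def test_single_replicate_is_itself_normalized(self, simple_index):
        a = _annotated(simple_index)
        a.s_y[:3] = [2.0, 6.0, 2.0]
        c = build_consensus([a])
        assert np.allclose(c.s_y[:3], [0.2, 0.6, 0.2])

    def test_identical_replicates(self, simple_index):
        a = _annotated(simple_index)
        a.s_y[0] = 5.0
        c = build_consensus([a, a, a])
        assert c.s_y[0] == pytest.approx(1.0)

    def test_disjoint_replicates_half_weight(self, simple_index):
        a = _annotated(simple_index)
        b = _annotated(simple_index)
        a.s_y[0] = 10.0
        b.s_y[1] = 99.0
        c = build_consensus([a, b])
        assert c.s_y[0] == pytest.approx(0.5)
        assert c.s_y[1] == pytest.approx(0.5)

    def test_order_and_scale_invariance(self, simple_index):
        rng = np.random.default_rng(1)
        reps = []
        for _ in range(3):
            r = _annotated(
                simple_index,
                pep=rng.random(simple_index.n_pep),
                y=rng.random(simple_index.n_y),
            )
            reps.append(r)
        c1 = build_consensus(reps)
        scaled = [
            _annotated(simple_index, pep=r.s_pep * s, y=r.s_y * s)
            for r, s in zip(reps[::-1], (7.0, 0.1, 42.0))
        ]
        c2 = build_consensus(scaled)
        assert np.allclose(c1.full_vector(), c2.full_vector(), atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([])


class TestFilters:
    def _with_counts(self, index, n_by, n_y, n_b=0):
        a = _annotated(index)
        a.s_pep[:n_by] = 1.0
        a.s_y[:n_y] = 1.0
        if n_b:
            a.s_b[:n_b] = 1.0
        return a

    def test_too_few_peptide_ions(self, simple_index):
        assert not passes_filters(self._with_counts(simple_index, 4, 10))

    def test_boundary_accepted(self, simple_index):
        assert passes_filters(self._with_counts(simple_index, 5, 5))

    def test_b_ion_requirement(self):
        t = parse_glycan_struct("(N(N(H(H(N(H)))(H(N)))))")
        idx = FragmentIndex(
            GlycopeptidePrecursor(PeptideSequence("LNSTAVKR", 1), t, 2),
            with_B=True,
        )
        spec = self._with_counts(idx, 8, 8, n_b=1)
        assert not passes_filters(spec, require_B=True)
        assert passes_filters(spec, require_B=False)
        spec.s_b[1] = 1.0
        assert passes_filters(spec, require_B=True)


class TestIO:
    def test_mgf_roundtrip(self, tmp_path):
        spectra = [
            Spectrum([100.0, 200.5], [1.0, 2.0], precursor_mz=523.7,
                     precursor_charge=2, metadata={"title": "s1"}),
            Spectrum([150.0], [5.0], precursor_mz=900.1, precursor_charge=3),
        ]
        path = str(tmp_path / "test.mgf")
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert len(back) == 2
        assert np.allclose(back[0].mz, spectra[0].mz)
        assert back[0].precursor_charge == 2
        assert back[1].precursor_mz == pytest.approx(900.1)

    def test_dataset_roundtrip(self, tmp_path):
        cfg = SimConfig(seed=9, n_precursors=6, with_B=True)
        obs, _truths, manifest = generate_dataset(cfg)
        path = str(tmp_path / "ds")
        save_dataset(obs, path, manifest)
        back, mani = load_dataset(path)
        assert len(back) == len(obs)
        assert mani["sim_config"]["seed"] == 9
        for a, b in zip(obs, back):
            assert a.precursor.key() == b.precursor.key()
            assert np.allclose(a.full_vector(), b.full_vector(), atol=1e-8)
            assert a.ratio == pytest.approx(b.ratio, abs=1e-8)
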
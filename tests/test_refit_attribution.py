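"""Exposure refitting, attribution rules, catalog matching and NMF."""

import numpy as np
import pytest

from sigattrib.channels import Scheme
from sigattrib.errors import ParameterError, ValidationError
from sigattrib.refit_attribution import (
    RefitConfig,
    call_presence,
    extract_denovo,
    match_to_catalog,
    refit_exposures,
    zero_rare_signatures,
)
from sigattrib.spectrum import SampleSpectrum
from sigattrib.synthetic_data import simulate_exposure_spectra


def spectrum_from(counts, sample="s1"):
    return SampleSpectrum(sample, Scheme.SBS96, np.asarray(counts, dtype=int))


class TestRefitExposures:
    def test_single_signature_recovered(self, sep_catalog):
        rng = np.random.default_rng(51)
        counts = rng.multinomial(10_000, sep_catalog.signature("SynthSig4"))
        profile = refit_exposures(spectrum_from(counts), sep_catalog)
        assert profile.weights["SynthSig4"] >= 0.95
        for sig in sep_catalog.signature_ids:
            if sig != "SynthSig4":
                assert profile.weights[sig] == 0.0

    def test_two_component_mixture_recovered(self, sep_catalog):
        rng = np.random.default_rng(52)
        mix = 0.70 * sep_catalog.signature("SynthSig1") \
            + 0.30 * sep_catalog.signature("SynthSig2")
        counts = rng.multinomial(10_000, mix)
        profile = refit_exposures(spectrum_from(counts), sep_catalog)
        assert profile.weights["SynthSig1"] == pytest.approx(0.70, abs=0.05)
        assert profile.weights["SynthSig2"] == pytest.approx(0.30, abs=0.05)

    def test_subcutoff_weight_pruned(self, sep_catalog):
        # a solved weight of ~0.01 sits below the 0.02 cutoff
        mix = 0.99 * sep_catalog.signature("SynthSig1") \
            + 0.01 * sep_catalog.signature("SynthSig2")
        counts = np.rint(mix * 1_000_000)
        profile = refit_exposures(spectrum_from(counts), sep_catalog)
        assert profile.weights["SynthSig2"] == 0.0
        assert profile.weights["SynthSig1"] == pytest.approx(1.0, abs=1e-6)

    def test_weights_zero_or_above_cutoff(self, sep_catalog):
        rng = np.random.default_rng(53)
        config = RefitConfig()
        for _ in range(5):
            counts = rng.integers(0, 60, size=96)
            profile = refit_exposures(spectrum_from(counts), sep_catalog, config)
            retained = [w for w in profile.weights.values() if w > 0]
            assert abs(sum(retained) - 1.0) < 1e-9
            assert all(w >= config.signature_cutoff for w in retained) \
                or len(retained) == 1

    def test_refit_idempotence(self, sep_catalog):
        rng = np.random.default_rng(54)
        spectra, _ = simulate_exposure_spectra(
            3, 5000, sep_catalog, seed=55, min_exposure=0.15
        )
        for sp in spectra:
            profile = refit_exposures(sp, sep_catalog)
            recon = np.zeros(96)
            for sig, w in profile.weights.items():
                recon += w * sep_catalog.signature(sig)
            recon_sp = spectrum_from(np.rint(recon * 100_000), sp.sample_id)
            again = refit_exposures(recon_sp, sep_catalog)
            assert {s for s, w in profile.weights.items() if w > 0} == \
                   {s for s, w in again.weights.items() if w > 0}

    def test_pruning_cost_bounded(self, sep_catalog):
        """The pruned reconstruction stays within the gain threshold per
        removed signature of the unpruned similarity."""
        from scipy.optimize import nnls

        rng = np.random.default_rng(56)
        config = RefitConfig()
        for _ in range(5):
            counts = rng.integers(0, 60, size=96)
            sp = spectrum_from(counts)
            b = sp.proportions()
            A = sep_catalog.channels_by_signatures()
            w_full, _ = nnls(A, b)
            recon = A @ w_full
            sim_full = recon @ b / (np.linalg.norm(recon) * np.linalg.norm(b))
            profile = refit_exposures(sp, sep_catalog, config)
            n_removed = sum(1 for w in profile.weights.values() if w == 0.0)
            assert profile.reconstruction_similarity >= \
                sim_full - config.similarity_gain_threshold * max(n_removed, 1)

    def test_parameter_recovery_simulated(self, sep_catalog):
        spectra, truth = simulate_exposure_spectra(
            10, 5000, sep_catalog, seed=57, active_signatures=(2, 4),
            min_exposure=0.1,
        )
        errors = []
        for sp in spectra:
            profile = refit_exposures(sp, sep_catalog)
            for sig in sep_catalog.signature_ids:
                errors.append(
                    abs(profile.weights[sig] - truth[sp.sample_id].get(sig, 0.0))
                )
        assert np.mean(errors) < 0.05

    def test_zero_spectrum_rejected(self, sep_catalog):
        with pytest.raises(ValidationError):
            refit_exposures(spectrum_from(np.zeros(96)), sep_catalog)


def profile_with(weights, total=1000):
    attributed = {s: w * total for s, w in weights.items()}
    from sigattrib.refit_attribution import ExposureProfile

    return ExposureProfile(
        sample_id="s", weights=dict(weights), attributed_counts=attributed,
        reconstruction_similarity=1.0,
        present={s: False for s in weights}, total_mutations=total,
    )


class TestAttributionRules:
    def test_floor_zeroes_below_point_six_percent(self):
        prof = profile_with({"A": 0.005, "B": 0.995})
        (out,) = zero_rare_signatures([prof])
        assert out.weights["A"] == 0.0
        assert out.weights["B"] == 1.0

    def test_floor_boundary_is_strict_less_than(self):
        prof = profile_with({"A": 0.006, "B": 0.994})
        (out,) = zero_rare_signatures([prof])
        assert out.weights["A"] > 0.0

    def test_all_zero_profile_flagged_not_renormalized(self):
        prof = profile_with({"A": 0.004, "B": 0.003})
        (out,) = zero_rare_signatures([prof])
        assert out.empty_after_floor
        assert all(w == 0.0 for w in out.weights.values())

    @pytest.mark.parametrize(
        "count,expected", [(99, False), (100, True), (0, False), (250, True)]
    )
    def test_presence_boundary_at_100(self, count, expected):
        prof = profile_with({"A": count / 1000, "B": 1 - count / 1000})
        out = call_presence(prof)
        assert out.present["A"] is expected

    def test_presence_monotone_in_counts(self):
        counts = [0, 50, 99, 100, 101, 500]
        flags = [
            call_presence(profile_with({"A": c / 1000, "B": 1 - c / 1000}))
            .present["A"]
            for c in counts
        ]
        assert flags == sorted(flags)


class TestMatchToCatalog:
    def test_identity_match(self, sep_catalog):
        match = match_to_catalog(sep_catalog.signature("SynthSig3"), sep_catalog)
        assert match.signature_id == "SynthSig3"
        assert match.similarity == pytest.approx(1.0)
        assert match.matched

    def test_disjoint_candidate_unmatched(self, sep_catalog):
        # mass concentrated on the catalog's emptiest channels
        support = np.argsort(sep_catalog.matrix.sum(axis=0))[:5]
        candidate = np.zeros(96)
        candidate[support] = 0.2
        match = match_to_catalog(candidate, sep_catalog)
        assert not match.matched
        assert match.signature_id is None
        assert match.similarity < 0.85

    def test_similarity_matches_dot_product_oracle(self, sep_catalog):
        sig = sep_catalog.signature("SynthSig1").copy()
        moved = sig * 0.95
        moved += 0.05 / 96
        match = match_to_catalog(moved, sep_catalog)
        expected = float(
            np.dot(moved, sig) / (np.linalg.norm(moved) * np.linalg.norm(sig))
        )
        assert match.signature_id == "SynthSig1"
        assert match.similarity == pytest.approx(expected, rel=1e-10)

    def test_zero_candidate_rejected(self, sep_catalog):
        with pytest.raises(ValidationError):
            match_to_catalog(np.zeros(96), sep_catalog)


class TestExtractDenovo:
    def _single_sig_cohort(self, sep_catalog, n=20, seed=61):
        rng = np.random.default_rng(seed)
        truth = sep_catalog.signature("SynthSig5")
        X = np.stack([rng.multinomial(3000, truth) for _ in range(n)])
        return X, truth

    def test_objective_non_increasing(self, sep_catalog):
        X, _ = self._single_sig_cohort(sep_catalog)
        result = extract_denovo(X, k=2, seed=1, iterations=100)
        obj = np.array(result.objective)
        assert np.all(np.diff(obj) <= np.abs(obj[:-1]) * 1e-8 + 1e-8)

    def test_k1_recovers_generating_signature(self, sep_catalog):
        X, truth = self._single_sig_cohort(sep_catalog)
        result = extract_denovo(X, k=1, seed=2, iterations=200)
        sig = result.signatures[0]
        cos = np.dot(sig, truth) / (np.linalg.norm(sig) * np.linalg.norm(truth))
        assert cos >= 0.99

    def test_seed_determinism(self, sep_catalog):
        X, _ = self._single_sig_cohort(sep_catalog)
        r1 = extract_denovo(X, k=3, seed=7, iterations=50)
        r2 = extract_denovo(X, k=3, seed=7, iterations=50)
        np.testing.assert_array_equal(r1.signatures, r2.signatures)
        np.testing.assert_array_equal(r1.exposures, r2.exposures)

    def test_k_exceeding_samples_rejected(self, sep_catalog):
        X, _ = self._single_sig_cohort(sep_catalog, n=3)
        with pytest.raises(ParameterError):
            extract_denovo(X, k=4, seed=1)

    def test_final_fit_comparable_to_sklearn(self, sep_catalog):
        """Independent cross-check: our KL-NMF reaches a reconstruction
        divergence comparable to scikit-learn's multiplicative-update
        KL solver on the same matrix."""
        from sklearn.decomposition import NMF

        X, _ = self._single_sig_cohort(sep_catalog, n=10)
        ours = extract_denovo(X, k=2, seed=3, iterations=300)
        skl = NMF(
            n_components=2, solver="mu", beta_loss="kullback-leibler",
            init="random", random_state=3, max_iter=500, tol=1e-8,
        )
        W = skl.fit_transform(X.astype(float))
        H = skl.components_
        V = X.T.astype(float)
        WH = (W @ H).T + 1e-12
        mask = V > 0
        skl_obj = float(
            np.sum(V[mask] * np.log(V[mask] / WH[mask]) - V[mask]) + WH.sum()
        )
        assert ours.objective[-1] <= skl_obj * 1.05 + 1.0
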
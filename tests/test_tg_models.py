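"""Couchman–Karasz and BCKV mixing models: worked values and properties."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import meltflow as mf
from meltflow.errors import FitError
from meltflow.synthetic import TgDatasetSpec, make_tg_dataset
from meltflow.tg_models import KELVIN_OFFSET


def _blend(reference, api, w):
    return mf.BlendSpec(
        api=reference.materials[api],
        polymer=reference.materials["Copovidone"],
        w_api=w,
    )


class TestCouchmanKarasz:
    def test_worked_values_in_kelvin(self, reference):
        # direct evaluation of the mixing rule with the packaged constants
        assert mf.ck_tg(_blend(reference, "Celecoxib", 0.30)) == pytest.approx(92.2, abs=0.1)
        assert mf.ck_tg(_blend(reference, "Naproxen", 0.30)) == pytest.approx(87.2, abs=0.1)

    def test_endpoints_are_pure_components(self, reference):
        b0 = _blend(reference, "Celecoxib", 0.0)
        b1 = _blend(reference, "Celecoxib", 1.0)
        assert mf.ck_tg(b0) == pytest.approx(107.0, abs=1e-12)
        assert mf.ck_tg(b1) == pytest.approx(56.8, abs=1e-12)

    def test_unity_k_reduces_to_linear_kelvin_mean(self):
        p = mf.CKParams(tg_api_K=300.0, tg_polymer_K=400.0, k_ck=1.0)
        w = 0.37
        expected = w * 300.0 + (1 - w) * 400.0 - KELVIN_OFFSET
        assert mf.ck_tg(p, w) == pytest.approx(expected, rel=1e-14)

    @given(
        w=st.floats(0.0, 1.0),
        tg1=st.floats(250.0, 350.0),
        tg2=st.floats(350.0, 450.0),
        k=st.floats(0.1, 10.0),
    )
    def test_monotone_between_endpoints(self, w, tg1, tg2, k):
        p = mf.CKParams(tg_api_K=tg1, tg_polymer_K=tg2, k_ck=k)
        lo = min(tg1, tg2) - KELVIN_OFFSET
        hi = max(tg1, tg2) - KELVIN_OFFSET
        assert lo - 1e-9 <= mf.ck_tg(p, w) <= hi + 1e-9
        # strictly decreasing in drug fraction for tg1 < tg2
        assert mf.ck_tg(p, min(w + 0.01, 1.0)) <= mf.ck_tg(p, w) + 1e-9

    def test_deviation_signs_match_solubility_study(self, reference):
        # CXB is the one positive deviator; NAP/LOR/PZQ deviate negatively
        dev = {lbl: mf.ck_deviation(reference.blends[lbl])
               for lbl in ("CXB 30%", "NAP 30%", "LOR 30%", "PZQ 30%")}
        assert dev["CXB 30%"] == pytest.approx(8.0, abs=1.5)
        assert dev["NAP 30%"] == pytest.approx(-16.0, abs=1.5)
        assert dev["PZQ 30%"] < 0 and dev["LOR 30%"] < 0

    def test_zero_deviation_when_measured_equals_prediction(self, reference):
        spec = _blend(reference, "Praziquantel", 0.2)
        rec = mf.BlendRecord(label="synthetic", blend=spec, tg_measured=mf.ck_tg(spec))
        assert mf.ck_deviation(rec) == pytest.approx(0.0, abs=1e-12)


class TestBCKV:
    def test_zero_coefficients_reduce_to_linear_rule(self):
        p = mf.BCKVParams(tg_api=300.0, tg_polymer=400.0)
        assert mf.bckv_tg(p, 0.5) == pytest.approx(350.0, rel=1e-14)

    @given(
        w=st.sampled_from([0.0, 1.0]),
        a0=st.floats(-50, 50),
        a1=st.floats(-50, 50),
        a2=st.floats(-50, 50),
    )
    def test_correction_vanishes_at_endpoints(self, w, a0, a1, a2):
        p = mf.BCKVParams(tg_api=56.8, tg_polymer=107.0, a0=a0, a1=a1, a2=a2)
        expected = 56.8 if w == 1.0 else 107.0
        assert mf.bckv_tg(p, w) == pytest.approx(expected, rel=1e-14)

    def test_w_out_of_range_rejected(self):
        p = mf.BCKVParams(tg_api=56.8, tg_polymer=107.0)
        with pytest.raises(ValueError):
            mf.bckv_tg(p, 1.01)


class TestBCKVFit:
    TRUTH = mf.BCKVParams(tg_api=6.7, tg_polymer=107.0, a0=-40.0, a1=10.0, a2=5.0)

    def test_noise_free_refit_is_exact(self):
        pts = make_tg_dataset(TgDatasetSpec(bckv=self.TRUTH, noise_sigma_K=0.0))
        res = mf.fit_bckv(pts, tg_api=6.7, tg_polymer=107.0)
        assert res.params.a0 == pytest.approx(-40.0, rel=1e-6)
        assert res.params.a1 == pytest.approx(10.0, rel=1e-6)
        assert res.params.a2 == pytest.approx(5.0, rel=1e-6)
        assert res.adjusted_r2 > 0.99
        # self-consistency: evaluating the fit reproduces the inputs
        for w, tg in pts:
            assert mf.bckv_tg(res.params, w) == pytest.approx(tg, abs=1e-8)

    def test_noisy_recovery_within_scatter(self):
        pts = make_tg_dataset(
            TgDatasetSpec(bckv=self.TRUTH, noise_sigma_K=0.5, seed=7)
        )
        res = mf.fit_bckv(pts, tg_api=6.7, tg_polymer=107.0)
        # linear fit with 9 points at sigma=0.5 K: coefficient errors a few K
        assert res.params.a0 == pytest.approx(-40.0, abs=5.0)
        assert res.params.a1 == pytest.approx(10.0, abs=10.0)
        assert res.params.a2 == pytest.approx(5.0, abs=15.0)

    def test_points_on_linear_rule_give_zero_coefficients(self):
        lin = mf.BCKVParams(tg_api=6.7, tg_polymer=107.0)
        pts = [(w, mf.bckv_tg(lin, w)) for w in (0.2, 0.4, 0.6, 0.8)]
        res = mf.fit_bckv(pts, tg_api=6.7, tg_polymer=107.0)
        for c in (res.params.a0, res.params.a1, res.params.a2):
            assert c == pytest.approx(0.0, abs=1e-9)

    def test_reduced_order_with_few_points(self):
        pts = [(0.3, 80.0), (0.6, 60.0)]
        res = mf.fit_bckv(pts, tg_api=6.7, tg_polymer=107.0)
        assert res.n_coefficients == 2 and res.params.a2 == 0.0

    def test_no_interior_points_is_an_error(self):
        with pytest.raises(FitError):
            mf.fit_bckv([(0.0, 107.0), (1.0, 6.7)], tg_api=6.7, tg_polymer=107.0)


def test_extremum_diagnostic_brackets_printed_deviation(reference):
    """The BCKV−CK gap extremum for NAP-like data lands near w=0.3 territory."""
    cop = reference.materials["Copovidone"]
    nap = reference.materials["Naproxen"]
    pts = [(b.blend.w_api, b.tg_measured)
           for b in reference.blends.values()
           if b.blend.api is nap]
    fit = mf.fit_bckv(pts, tg_api=nap.tg, tg_polymer=cop.tg)
    ck = mf.CKParams.from_materials(nap, cop)
    w_ext, dev = mf.ck_bckv_extremum(fit.params, ck)
    assert 0.0 < w_ext < 1.0
    assert dev < 0  # naproxen blends vitrify below the ideal-mixing prediction
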
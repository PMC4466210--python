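import numpy as np
import pandas as pd
import pytest

from mitonuclear import array_processing as ap
from mitonuclear import synthetic_data as sd


def _slide(n=200, seed=0, orientation=ap.SAMPLE_IN_CY5, slide_id="s1",
           sample_id="x", m=None, a=None, bg=50.0, pct=0.9):
    """Hand-built slide with chosen M/A structure (dye space)."""
    rng = np.random.default_rng(seed)
    if a is None:
        a = rng.uniform(7, 15, n)
    if m is None:
        m = np.zeros(n)
    log_cy5 = a + m / 2
    log_cy3 = a - m / 2
    return ap.ArraySlide(
        slide_id=slide_id, sample_id=sample_id, dye_orientation=orientation,
        probe_ids=np.array([f"P{i:04d}" for i in range(n)]),
        fg_cy3=np.exp2(log_cy3) + bg, bg_cy3=np.full(n, bg),
        fg_cy5=np.exp2(log_cy5) + bg, bg_cy5=np.full(n, bg),
        pct_cy3=np.full(n, pct), pct_cy5=np.full(n, pct),
    )


# ---------------------------------------------------------------------------
# subtract_background
# ---------------------------------------------------------------------------

class TestSubtractBackground:
    def test_simple_subtraction(self):
        s = _slide(n=60)
        s.fg_cy3[0], s.bg_cy3[0] = 1000.0, 100.0
        out = ap.subtract_background(s)
        assert out.cy3[0] == 900.0
        assert not out.floored_cy3[0]

    def test_negative_goes_to_floor_and_is_flagged(self):
        s = _slide(n=60)
        s.fg_cy5[1], s.bg_cy5[1] = 50.0, 100.0
        out = ap.subtract_background(s, floor=0.5)
        assert out.cy5[1] == 0.5
        assert out.floored_cy5[1]

    def test_random_fixture_matches_elementwise_oracle(self, rng):
        s = _slide(n=100, seed=3)
        s.fg_cy3 = rng.uniform(0, 2000, 100)
        s.bg_cy3 = rng.uniform(0, 500, 100)
        out = ap.subtract_background(s, floor=0.5)
        expected = np.array([
            max(f - b, 0.5) for f, b in zip(s.fg_cy3, s.bg_cy3)
        ])
        np.testing.assert_array_equal(out.cy3, expected)


# ---------------------------------------------------------------------------
# call_present
# ---------------------------------------------------------------------------

class TestCallPresent:
    @pytest.mark.parametrize("cy3,cy5,expected", [
        (0.71, 0.10, True),
        (0.70, 0.00, True),   # inclusive boundary
        (0.00, 0.70, True),   # either channel
        (0.69, 0.69, False),
        (0.0, 0.0, False),
    ])
    def test_boundaries(self, cy3, cy5, expected):
        assert bool(ap.call_present(cy3, cy5)) is expected

    def test_vectorized(self):
        out = ap.call_present(np.array([0.8, 0.1]), np.array([0.0, 0.2]))
        np.testing.assert_array_equal(out, [True, False])


# ---------------------------------------------------------------------------
# lowess_normalize
# ---------------------------------------------------------------------------

class TestLowessNormalize:
    def test_constant_offset_removed(self):
        s = _slide(n=300, m=np.full(300, 0.8), seed=1)
        fit = ap.lowess_normalize(s)
        assert np.nanmax(np.abs(fit.m_norm)) < 1e-9
        assert np.allclose(fit.m_raw[np.isfinite(fit.m_raw)], 0.8)

    def test_planted_quadratic_bias_removed(self, rng):
        n = 2000
        a = rng.uniform(7, 15, n)
        m = 0.1 * (a - 10) ** 2 + rng.normal(0, 0.05, n)
        fit = ap.lowess_normalize(_slide(n=n, m=m, a=a))
        deciles = np.quantile(a, np.linspace(0, 1, 11))
        for lo, hi in zip(deciles[:-1], deciles[1:]):
            sel = (fit.a >= lo) & (fit.a <= hi)
            assert abs(np.median(fit.m_norm[sel])) < 0.05

    def test_monotone_bias_fitted_monotone(self, rng):
        n = 1500
        a = rng.uniform(7, 15, n)
        m = 0.3 * (a - 11) + rng.normal(0, 0.03, n)
        fit = ap.lowess_normalize(_slide(n=n, m=m, a=a))
        order = np.argsort(fit.a)
        fitted = fit.bias[order]
        assert np.all(np.diff(fitted) > -0.02)
        # and close to the planted line
        assert np.median(np.abs(fitted - 0.3 * (fit.a[order] - 11))) < 0.05

    def test_orientation_sign(self):
        m = np.full(300, 0.6)
        fit5 = ap.lowess_normalize(_slide(n=300, m=m))
        fit3 = ap.lowess_normalize(_slide(n=300, m=m,
                                          orientation=ap.SAMPLE_IN_CY3))
        finite = np.isfinite(fit5.m_raw)
        assert np.allclose(fit5.m_raw[finite], 0.6)
        assert np.allclose(fit3.m_raw[finite], -0.6)

    def test_idempotence(self, rng):
        n = 1000
        a = rng.uniform(7, 15, n)
        m = 0.2 * np.sin(a) + rng.normal(0, 0.05, n)
        s = _slide(n=n, m=m, a=a)
        fit = ap.lowess_normalize(s)
        # Rebuild a slide carrying the normalized M and renormalize.
        s2 = _slide(n=n, m=np.nan_to_num(fit.m_norm), a=a)
        fit2 = ap.lowess_normalize(s2)
        delta = np.abs(fit2.m_norm - fit.m_norm)
        assert np.nanmax(delta) < 0.05

    def test_too_few_probes_error(self):
        with pytest.raises(ap.ArrayProcessingError, match="usable"):
            ap.lowess_normalize(_slide(n=30))

    def test_floored_probes_get_missing_m(self):
        s = _slide(n=200)
        s.fg_cy3[5] = 0.0  # below background
        fit = ap.lowess_normalize(s)
        assert np.isnan(fit.m_norm[5])


# ---------------------------------------------------------------------------
# combine_dye_swap
# ---------------------------------------------------------------------------

class TestCombineDyeSwap:
    def _pair(self, m_true, n=200):
        a = _slide(n=n, m=m_true, sample_id="x", slide_id="a")
        b = _slide(n=n, m=-m_true, sample_id="x", slide_id="b",
                   orientation=ap.SAMPLE_IN_CY3)
        return ap.lowess_normalize(a), ap.lowess_normalize(b)

    def test_swap_pair_combines_to_common_orientation(self, rng):
        m = rng.normal(0, 0.5, 1000)
        m -= m.mean()  # keep lowess from absorbing a net shift
        fa, fb = self._pair(m, n=1000)
        combined = ap.combine_dye_swap(fa, fb)
        finite = np.isfinite(combined.m)
        # both slides encode the same sample/reference ratio
        assert np.corrcoef(combined.m[finite], m[finite])[0, 1] > 0.99

    def test_missing_on_one_slide_takes_other(self):
        fa, fb = self._pair(np.zeros(200))
        fa.m_norm[7] = np.nan
        fb.m_norm[7] = 0.8
        combined = ap.combine_dye_swap(fa, fb)
        assert combined.m[7] == 0.8
        fa.m_norm[9] = np.nan
        fb.m_norm[9] = np.nan
        assert np.isnan(ap.combine_dye_swap(fa, fb).m[9])

    def test_same_orientation_rejected(self):
        fa, _ = self._pair(np.zeros(200))
        fa2, _ = self._pair(np.zeros(200))
        with pytest.raises(ap.ArrayProcessingError, match="orientation"):
            ap.combine_dye_swap(fa, fa2)

    def test_label_swap_symmetry(self, rng):
        m = rng.normal(0, 0.4, 200)
        fa, fb = self._pair(m)
        c1 = ap.combine_dye_swap(fa, fb)
        c2 = ap.combine_dye_swap(fb, fa)
        np.testing.assert_array_equal(c1.m, c2.m)

    def test_different_samples_rejected(self):
        fa, _ = self._pair(np.zeros(200))
        other = ap.lowess_normalize(
            _slide(n=200, sample_id="y", orientation=ap.SAMPLE_IN_CY3))
        with pytest.raises(ap.ArrayProcessingError, match="different samples"):
            ap.combine_dye_swap(fa, other)


# ---------------------------------------------------------------------------
# filter_informative
# ---------------------------------------------------------------------------

def _toy_fits_and_combined():
    """6 probes x 10 slides (5 samples) with one probe failing each clause."""
    n, n_samples = 6, 5
    rng = np.random.default_rng(0)
    probe_ids = np.array([f"P{i}" for i in range(n)])
    fits, combined = [], []
    for j in range(n_samples):
        for k, orientation in enumerate((ap.SAMPLE_IN_CY5, ap.SAMPLE_IN_CY3)):
            present = np.ones(n, bool)
            # probe 1 present on only half the slides (fails presence clause)
            present[1] = (j + k) % 2 == 0
            corrected = np.full(n, 5000.0)
            corrected[2] = 60.0  # fails raw-intensity clause
            fits.append(ap.NormalizationFit(
                slide_id=f"s{j}{k}", sample_id=f"x{j}",
                dye_orientation=orientation,
                probe_ids=probe_ids,
                a=np.full(n, 10.0), m_raw=np.zeros(n),
                bias=np.zeros(n), m_norm=np.zeros(n),
                span=0.3, iterations=3,
                present_cy3=present, present_cy5=present,
                corrected_cy3=corrected, corrected_cy5=corrected,
            ))
        m = rng.normal(0, 0.2, n)
        m[3] = rng.normal(0, 3.0)  # probe 3: huge SD across samples
        combined.append(ap.CombinedSample(
            sample_id=f"x{j}", probe_ids=probe_ids, m=m,
            slide_ids=(f"s{j}0", f"s{j}1"),
        ))
    return fits, combined


class TestFilterInformative:
    def test_toy_fixture_matches_hand_enumeration(self):
        fits, combined = _toy_fits_and_combined()
        matrix = ap.filter_informative(fits, combined)
        assert list(matrix.informative[matrix.informative].index) == \
            ["P0", "P4", "P5"]
        assert matrix.reasons["P1"] == ["presence_rate"]
        assert matrix.reasons["P2"] == ["raw_intensity"]
        assert matrix.reasons["P3"] == ["ratio_sd"]

    def test_exactly_90_percent_presence_excluded(self):
        fits, combined = _toy_fits_and_combined()
        # probe 0: present on exactly 9 of 10 slides
        for f in fits[:1]:
            f.present_cy3 = f.present_cy3.copy()
            f.present_cy5 = f.present_cy5.copy()
            f.present_cy3[0] = False
            f.present_cy5[0] = False
        matrix = ap.filter_informative(fits, combined)
        assert not matrix.informative["P0"]
        assert "presence_rate" in matrix.reasons["P0"]

    def test_conservation_and_attribution(self):
        fits, combined = _toy_fits_and_combined()
        matrix = ap.filter_informative(fits, combined)
        n_informative = matrix.n_informative
        assert n_informative + len(matrix.reasons) == 6
        assert all(len(v) >= 1 for v in matrix.reasons.values())

    def test_filter_monotonicity_in_sd_cutoff(self):
        fits, combined = _toy_fits_and_combined()
        loose = ap.filter_informative(fits, combined, ratio_sd=5.0)
        tight = ap.filter_informative(fits, combined, ratio_sd=1.4)
        assert set(tight.informative[tight.informative].index) <= \
            set(loose.informative[loose.informative].index)

    def test_filter_monotonicity_in_presence_cutoff(self):
        fits, combined = _toy_fits_and_combined()
        loose = ap.filter_informative(fits, combined, presence_rate=0.4)
        tight = ap.filter_informative(fits, combined, presence_rate=0.95)
        assert set(tight.informative[tight.informative].index) <= \
            set(loose.informative[loose.informative].index)


# ---------------------------------------------------------------------------
# subset_by_origin / percentages
# ---------------------------------------------------------------------------

class TestSubsets:
    def _matrix_and_annotation(self, informative_mask=None):
        cfg = sd.SimulationConfig(n_probes=50, n_nuclear_mito=10, n_mtdna=5)
        ann = sd.build_annotation(cfg)
        values = pd.DataFrame(
            np.zeros((50, 4)),
            index=pd.Index(ann["probe_id"], name="probe_id"),
            columns=list("abcd"),
        )
        if informative_mask is None:
            informative_mask = np.ones(50, bool)
        matrix = ap.ExpressionMatrix(
            values=values,
            informative=pd.Series(informative_mask, index=values.index),
        )
        return matrix, ann

    def test_subset_sizes_all_informative(self):
        matrix, ann = self._matrix_and_annotation()
        assert len(ap.subset_by_origin(matrix, ann, "global").values) == 50
        assert len(ap.subset_by_origin(matrix, ann, "nuclear_mito").values) == 10
        assert len(ap.subset_by_origin(matrix, ann, "mtdna").values) == 5

    def test_empty_when_nothing_informative(self):
        matrix, ann = self._matrix_and_annotation(np.zeros(50, bool))
        for name in ("global", "nuclear_mito", "mtdna"):
            assert len(ap.subset_by_origin(matrix, ann, name).values) == 0

    def test_random_mask_matches_set_intersection(self, rng):
        mask = rng.random(50) < 0.5
        matrix, ann = self._matrix_and_annotation(mask)
        ann_idx = ann.set_index("probe_id")
        informative = set(matrix.values.index[mask])
        expected_nm = informative & set(
            ann_idx.index[ann_idx["mito_function"]
                          & (ann_idx["genome_of_origin"] == "nuclear")]
        )
        got = set(ap.subset_by_origin(matrix, ann, "nuclear_mito").values.index)
        assert got == expected_nm

    def test_unknown_subset(self):
        matrix, ann = self._matrix_and_annotation()
        with pytest.raises(ap.ArrayProcessingError, match="unknown subset"):
            ap.subset_by_origin(matrix, ann, "nope")

    def test_inconsistent_annotation_rejected(self):
        matrix, ann = self._matrix_and_annotation()
        bad = ann.copy()
        bad.loc[bad["genome_of_origin"] == "mitochondrial", "mito_function"] = False
        with pytest.raises(ap.ArrayProcessingError):
            ap.subset_by_origin(matrix, bad, "global")


class TestInformativePercentage:
    @pytest.mark.parametrize("count,total,expected", [
        (9955, 13310, 74.8),
        (9297, 13310, 69.8),
        (0, 10, 0.0),
        (10, 10, 100.0),
    ])
    def test_values(self, count, total, expected):
        assert ap.informative_percentage(count, total) == expected

    def test_invalid(self):
        with pytest.raises(ap.ArrayProcessingError):
            ap.informative_percentage(5, 0)


# ---------------------------------------------------------------------------
# Slide file I/O
# ---------------------------------------------------------------------------

class TestSlideIO:
    def test_round_trip(self, tmp_path):
        s = _slide(n=40, m=np.linspace(-1, 1, 40), seed=2)
        path = tmp_path / "s.tsv"
        ap.write_slide_tsv(s, path)
        back = ap.read_slide_tsv(path)
        assert back.slide_id == s.slide_id
        assert back.dye_orientation == s.dye_orientation
        np.testing.assert_allclose(back.fg_cy5, s.fg_cy5, rtol=1e-5)

    def test_column_reordering_tolerated(self, tmp_path):
        s = _slide(n=40)
        path = tmp_path / "s.tsv"
        ap.write_slide_tsv(s, path)
        lines = path.read_text().splitlines()
        header_idx = next(i for i, l in enumerate(lines)
                          if l.startswith("probe_id"))
        cols = lines[header_idx].split("\t")
        perm = [cols[i] for i in (3, 0, 5, 1, 6, 2, 4)]
        df_lines = [
            "\t".join(
                row.split("\t")[cols.index(c)] for c in perm
            )
            for row in lines[header_idx + 1:]
        ]
        path.write_text("\n".join(
            lines[:header_idx] + ["\t".join(perm)] + df_lines) + "\n")
        back = ap.read_slide_tsv(path)
        np.testing.assert_allclose(back.fg_cy3, s.fg_cy3, rtol=1e-5)

    def test_missing_column_rejected(self, tmp_path):
        s = _slide(n=40)
        path = tmp_path / "s.tsv"
        ap.write_slide_tsv(s, path)
        text = path.read_text().replace("F635_Median", "F000_Median")
        path.write_text(text)
        with pytest.raises(ap.ArrayProcessingError, match="missing columns"):
            ap.read_slide_tsv(path)


# ---------------------------------------------------------------------------
# End-to-end: synthetic slides through the full path
# ---------------------------------------------------------------------------

class TestProcessSlides:
    def test_zero_noise_recovers_latent_exactly(self):
        cfg = sd.SimulationConfig(
            n_probes=1500, n_nuclear_mito=60, n_mtdna=20,
            noise_sd=0.0, dye_bias_coeffs=(0.0,), present_fraction_null=0.0,
            treatment_effect_sd=0.4, seed=6,
        )
        latent = sd.generate_latent(cfg)
        slides = sd.generate_array_dataset(cfg, latent)
        matrix, fits = ap.process_slides(slides)
        for j, sample in enumerate(latent.sample_ids):
            got = matrix.values[sample].to_numpy()
            want = latent.signal[:, j]
            finite = np.isfinite(got)
            # lowess removes any intensity-trend component; tolerate small
            # deviations rather than exact equality
            assert np.nanmedian(np.abs(got[finite] - want[finite])) < 0.05
            assert np.corrcoef(got[finite], want[finite])[0, 1] > 0.98

    def test_unpaired_sample_rejected(self):
        s = _slide(n=60)
        with pytest.raises(ap.ArrayProcessingError, match="dye-swap pair"):
            ap.process_slides([s])
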
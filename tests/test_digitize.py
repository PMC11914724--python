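"""Digitizer: masks, calibration, extraction, full round trip."""

import numpy as np
import pytest

import ecgrisk as er
from ecgrisk.digitize import (
    DigitizationError,
    GridCalibration,
    UnreadableROIError,
    calibrate_grid,
    extract_lead_signal,
    extract_trace_and_grid_masks,
)


class TestMasks:
    def test_trace_mask_matches_gridless_ink(self, base_signal):
        # oracle: the same signal drawn without grid is pure trace ink;
        # the grid-on trace mask must recover >=95% of it with <=5% extras
        on = er.render_paper_ecg(base_signal, style=er.RenderStyle(grid=True))
        off = er.render_paper_ecg(base_signal, style=er.RenderStyle(grid=False))
        m_on, _ = extract_trace_and_grid_masks(on)
        truth = np.all(off.pixels < 128, axis=-1)
        assert (m_on & truth).sum() >= 0.95 * truth.sum()
        assert (m_on & ~truth).sum() <= 0.05 * truth.sum()

    def test_gridless_page_has_empty_grid_mask(self, base_signal):
        off = er.render_paper_ecg(base_signal, style=er.RenderStyle(grid=False))
        _, grid_mask = extract_trace_and_grid_masks(off)
        assert grid_mask.sum() == 0

    def test_blank_page_warns_and_is_empty(self):
        blank = er.RenderedECG(np.full((100, 100, 3), 255, dtype=np.uint8))
        with pytest.warns(UserWarning, match="blank"):
            trace, grid = extract_trace_and_grid_masks(blank)
        assert trace.sum() == 0 and grid.sum() == 0


class TestCalibration:
    @pytest.mark.parametrize("px_per_mm", [10.0, 6.5])
    def test_pitch_recovered_within_2_percent(self, base_signal, px_per_mm):
        style = er.RenderStyle(px_per_mm=px_per_mm, width=2700, height=2100)
        pg = er.render_paper_ecg(base_signal, style=style)
        _, grid_mask = extract_trace_and_grid_masks(pg)
        cal = calibrate_grid(grid_mask)
        assert cal.grid_detected
        assert abs(cal.px_per_mm_x - px_per_mm) <= 0.02 * px_per_mm
        assert abs(cal.px_per_mm_y - px_per_mm) <= 0.02 * px_per_mm

    def test_gridless_fallback_from_layout(self, base_signal):
        off = er.render_paper_ecg(base_signal, style=er.RenderStyle(grid=False))
        trace, grid_mask = extract_trace_and_grid_masks(off)
        cal = calibrate_grid(grid_mask, trace_mask=trace)
        assert not cal.grid_detected
        assert abs(cal.px_per_mm_x - 8.0) <= 0.02 * 8.0

    def test_scale_factor_consistency(self):
        cal = GridCalibration(8.0, 8.0)
        assert cal.seconds_per_px == pytest.approx(1.0 / (25.0 * 8.0))
        assert cal.mv_per_px == pytest.approx(1.0 / (10.0 * 8.0))

    def test_no_grid_no_trace_raises(self):
        with pytest.raises(DigitizationError):
            calibrate_grid(np.zeros((50, 50), dtype=bool))


class TestExtractLeadSignal:
    CAL = GridCalibration(8.0, 8.0)

    def test_flat_line_extracts_to_zero(self):
        mask = np.zeros((80, 200), dtype=bool)
        mask[40:42, :] = True
        vals, miss = extract_lead_signal(mask, self.CAL)
        assert not miss.any()
        assert np.all(np.abs(vals) <= 0.5 * self.CAL.mv_per_px)

    def test_square_pulse_amplitude_recovered(self):
        # 1 mV = 80 rows at 8 px/mm and 10 mm/mV
        mask = np.zeros((200, 300), dtype=bool)
        mask[150:152, :] = True
        mask[70:72, 100:200] = True
        mask[150:152, 100:200] = False
        vals, miss = extract_lead_signal(mask, self.CAL)
        assert abs(np.median(vals[110:190]) - 1.0) <= 0.05
        assert abs(np.median(vals[:90])) <= 0.05

    def test_gap_columns_flagged_missing(self):
        mask = np.zeros((80, 200), dtype=bool)
        mask[40, :] = True
        mask[40, 60:65] = False
        vals, miss = extract_lead_signal(mask, self.CAL)
        assert list(np.flatnonzero(miss)) == [60, 61, 62, 63, 64]

    def test_unreadable_roi_raises(self):
        mask = np.zeros((80, 200), dtype=bool)
        mask[40, :60] = True  # 70% of columns empty
        with pytest.raises(UnreadableROIError):
            extract_lead_signal(mask, self.CAL)

    def test_glyph_component_ignored(self):
        mask = np.zeros((120, 400), dtype=bool)
        mask[80:82, :] = True
        mask[20:30, 10:25] = True  # label-sized blob well above the trace
        vals, _ = extract_lead_signal(mask, self.CAL)
        assert np.all(np.abs(vals) <= 0.5 * self.CAL.mv_per_px)


class TestDigitizeECG:
    def test_masks_mark_window_placement(self, digitized):
        # a column-1 lead occupies exactly [2.5 s, 5.0 s) of the 10-s frame
        m = digitized.lead_mask("aVR")
        assert np.all(m[:1000] == 0)
        assert np.all(m[1000:2000] > 0)
        assert np.all(m[2000:] == 0)

    def test_out_of_window_samples_are_zero(self, digitized):
        for name in er.LEAD_NAMES:
            x = digitized.lead(name)
            m = digitized.lead_mask(name)
            assert np.all(x[m == 0] == 0.0)

    def test_frame_shape_and_rate(self, digitized):
        assert digitized.samples.shape == (12, 4000)
        assert digitized.fs == 400.0

    def test_round_trip_fidelity_clean_page(self, digitized, reference):
        rep = er.fidelity_metrics(reference, digitized)
        assert rep.median_r >= 0.98
        assert rep.mean_mae <= 0.014

    def test_grid_independence(self, base_signal):
        on = er.digitize_ecg(er.render_paper_ecg(base_signal, style=er.RenderStyle(grid=True)))
        off = er.digitize_ecg(er.render_paper_ecg(base_signal, style=er.RenderStyle(grid=False)))
        for name in er.LEAD_NAMES:
            m = (on.lead_mask(name) > 0) & (off.lead_mask(name) > 0)
            r = np.corrcoef(on.lead(name)[m], off.lead(name)[m])[0, 1]
            assert r >= 0.95, name

    def test_degradation_never_helps(self, base_signal, reference):
        clean = er.fidelity_metrics(reference, er.digitize_ecg(er.render_paper_ecg(base_signal)))
        medians = []
        for seed in (0, 1):
            pg = er.apply_scan_degradation(er.render_paper_ecg(base_signal),
                                           rotation=0.5, blur_sd=1.0, noise_sd=5.0,
                                           seed=seed)
            medians.append(er.fidelity_metrics(reference, er.digitize_ecg(pg)).median_r)
        assert np.median(medians) <= clean.median_r + 1e-6

    def test_degraded_page_still_digitizes_well(self, base_signal, reference):
        pg = er.apply_scan_degradation(er.render_paper_ecg(base_signal),
                                       rotation=0.5, blur_sd=1.0, noise_sd=5.0, seed=2)
        rep = er.fidelity_metrics(reference, er.digitize_ecg(pg))
        assert rep.median_r >= 0.93

    def test_blank_page_fatal(self):
        blank = er.RenderedECG(np.full((1700, 2200, 3), 255, dtype=np.uint8))
        with pytest.warns(UserWarning):
            with pytest.raises(DigitizationError):
                er.digitize_ecg(blank)

    def test_gridless_with_fallback_disabled_fatal(self, base_signal):
        off = er.render_paper_ecg(base_signal, style=er.RenderStyle(grid=False))
        with pytest.raises(DigitizationError, match="fallback"):
            er.digitize_ecg(off, allow_layout_fallback=False)

    def test_quality_report_fields(self, digitized):
        q = digitized.quality
        assert q["grid_detected"] is True
        assert set(q["missing_fraction"]) == set(er.LEAD_NAMES)
        assert q["invalid_leads"] == []
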